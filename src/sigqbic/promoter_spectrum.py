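"""Proximal-promoter mutation spectra from mutation calls.

Builds 96-class spectra restricted to regions from 2000 bp 5' to 2000 bp 3'
of annotated transcription start sites (TSS +/- 2000 on the reference —
context classes are strand-collapsed, so the window is applied
strand-agnostically), selects tumors dominated by a signature, optionally
filters to the signature's major substitution types, and compares GR/LR
computed from observed spectra with GR/LR computed from the signature alone.

Coordinates: mutation input is 1-based (VCF-like simple files: sample,
chrom, pos, ref, alt); promoter intervals are kept 0-based half-open
internally and each spans 4001 reference bases centred on the TSS.
Chromosome names are normalized ("chr1" and "1" are equivalent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta
from scipy.stats import pearsonr

from .mutation_model import CLASS_LABELS, N_CLASSES, PYRIMIDINES, canonical_class
from .signature_io import Signature, exposure_fractions

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2000


def _norm_chrom(name: str) -> str:
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class PromoterRegions:
    """TSS-centred promoter intervals, 0-based half-open, one per gene TSS."""

    intervals: pd.DataFrame  # chrom (normalized), start, end, strand, gene_id
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.intervals)

    def _tree(self, chrom: str) -> IntervalTree:
        chrom = _norm_chrom(chrom)
        if chrom not in self._trees:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (r.start, r.end, r.gene_id) for r in sub.itertuples()
            )
        return self._trees[chrom]

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position in any promoter region."""
        return bool(self._tree(chrom)[pos0])

    def overlap_count(self, chrom: str, pos0: int) -> int:
        return len(self._tree(chrom)[pos0])

    def to_bed(self, path) -> None:
        bed = self.intervals[["chrom", "start", "end", "gene_id", "strand"]].copy()
        bed.insert(4, "score", 0)
        bed.to_csv(path, sep="\t", header=False, index=False)


def tss_regions(gtf_path, flank: int = DEFAULT_FLANK, feature: str = "gene") -> PromoterRegions:
    """Promoter regions (TSS +/- ``flank``) from a GTF annotation.

    The TSS is the feature start for + strand genes and the feature end for
    - strand genes.  In 1-based terms a region covers [TSS - flank,
    TSS + flank] inclusive (4001 bases at the default); overlapping regions
    are retained.  Missing strands are an error.
    """
    db = gffutils.create_db(
        str(gtf_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for g in db.features_of_type(feature):
        if g.strand == "+":
            tss = g.start  # 1-based
        elif g.strand == "-":
            tss = g.end
        else:
            raise ValueError(f"feature {g.id} in {gtf_path} has no strand")
        start0 = max(tss - 1 - flank, 0)
        end0 = tss + flank  # half-open; covers 1-based TSS+flank
        rows.append((_norm_chrom(g.seqid), start0, end0, g.strand, g.id))
    if not rows:
        raise ValueError(f"no {feature!r} features found in {gtf_path}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    return PromoterRegions(df)


def read_mutations(path) -> pd.DataFrame:
    """Read a VCF-like simple mutation table (sample, chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    required = ["sample", "chrom", "pos", "ref", "alt"]
    if not set(required).issubset(df.columns):
        raise ValueError(f"mutation file {path} needs columns {required}, got {list(df.columns)}")
    return df[required]


def select_dominant_tumors(
    exposures: pd.DataFrame, signature_name: str, min_fraction: float = 0.4
) -> set[str]:
    """Samples whose exposure fraction for a signature is >= ``min_fraction``."""
    if signature_name not in set(exposures["signature"]):
        raise ValueError(f"unknown signature {signature_name!r} in exposure table")
    frac = exposure_fractions(exposures)
    sel = frac[(frac["signature"] == signature_name) & (frac["value"] >= min_fraction)]
    return set(sel["sample"])


@dataclass
class SpectrumCatalog:
    """Per-sample and aggregate 96-class mutation counts."""

    counts: pd.DataFrame  # index: 96 class labels; columns: samples
    n_outside: int = 0
    n_ref_mismatch: int = 0
    n_type_filtered: int = 0
    n_non_snv: int = 0

    @property
    def aggregate(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def normalized(self, name: str = "aggregate") -> Signature:
        """The aggregate spectrum as a signature (normalized to sum 1)."""
        return Signature.normalized(name, self.aggregate.to_numpy())

    def write(self, path) -> None:
        out = self.counts.copy()
        out["aggregate"] = self.aggregate
        out.index.name = "mutation_class"
        out.to_csv(path, sep="\t")


def build_spectrum(
    mutations: pd.DataFrame,
    regions: PromoterRegions,
    genome_fasta,
    type_filter: set[str] | None = None,
    samples: set[str] | None = None,
    count_once: bool = True,
) -> SpectrumCatalog:
    """Accumulate the 96-class spectrum of mutations inside promoter regions.

    Each SNV falling in any region is assigned its canonical class from the
    +/- 1 bp reference context.  Mutations whose substitution type is not in
    ``type_filter`` (when given) are excluded; mutations whose ref allele
    mismatches the genome are dropped with a logged count.  With
    ``count_once`` (default) a mutation inside overlapping regions is
    counted once (membership), not once per region.
    """
    try:
        fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    except Exception as exc:
        raise ValueError(f"unreadable FASTA {genome_fasta}: {exc}") from exc
    chrom_map = {_norm_chrom(c): c for c in fasta.keys()}
    seqs: dict[str, str] = {}

    counts = np.zeros((N_CLASSES, 0))
    sample_ids: list[str] = []
    col_of: dict[str, int] = {}
    counts_cols: list[np.ndarray] = []
    n_outside = n_mismatch = n_filtered = n_non_snv = 0

    for m in mutations.itertuples():
        if samples is not None and m.sample not in samples:
            continue
        ref, alt = str(m.ref).upper(), str(m.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt or ref not in "ACGT" or alt not in "ACGT":
            n_non_snv += 1
            continue
        chrom = _norm_chrom(m.chrom)
        if chrom not in chrom_map:
            raise ValueError(
                f"chromosome {m.chrom!r} not in FASTA (tried {m.chrom!r} and {chrom!r}; "
                f"FASTA has {list(fasta.keys())[:5]})"
            )
        pos0 = int(m.pos) - 1
        n_hits = regions.overlap_count(chrom, pos0)
        if n_hits == 0:
            n_outside += 1
            continue
        if chrom not in seqs:
            seqs[chrom] = str(fasta[chrom_map[chrom]][:])
        seq = seqs[chrom]
        if pos0 < 1 or pos0 >= len(seq) - 1:
            n_outside += 1
            continue
        if seq[pos0] != ref:
            n_mismatch += 1
            continue
        mc = canonical_class(seq[pos0 - 1 : pos0 + 2], alt)
        if type_filter is not None and mc.substitution_type not in type_filter:
            n_filtered += 1
            continue
        if m.sample not in col_of:
            col_of[m.sample] = len(sample_ids)
            sample_ids.append(m.sample)
            counts_cols.append(np.zeros(N_CLASSES))
        weight = 1 if count_once else n_hits
        counts_cols[col_of[m.sample]][mc.index] += weight

    if n_mismatch:
        logger.warning("dropped %d mutations with ref mismatching the genome", n_mismatch)
    counts = (
        np.stack(counts_cols, axis=1) if counts_cols else np.zeros((N_CLASSES, 0))
    )
    df = pd.DataFrame(counts, index=list(CLASS_LABELS), columns=sample_ids)
    return SpectrumCatalog(df, n_outside, n_mismatch, n_filtered, n_non_snv)


def compare_gr_lr(
    spectrum_based: pd.DataFrame,
    signature_based: pd.DataFrame,
    by: str = "signature",
) -> dict[str, float]:
    """Per-signature R^2 between spectrum-based and signature-based GR/LR.

    Inputs are long-format frames with columns (experiment, signature, GR,
    LR); GR and LR are pooled per signature as paired values and the squared
    Pearson correlation is reported, plus its mean over signatures under the
    key "mean".  Fewer than 3 pairs for a signature is an error.
    """
    merged = spectrum_based.merge(
        signature_based, on=["experiment", by], suffixes=("_spec", "_sig")
    )
    out: dict[str, float] = {}
    for sig_name, grp in merged.groupby(by):
        x = np.concatenate([grp["GR_spec"].to_numpy(), grp["LR_spec"].to_numpy()])
        y = np.concatenate([grp["GR_sig"].to_numpy(), grp["LR_sig"].to_numpy()])
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 paired values for signature {sig_name!r}")
        out[str(sig_name)] = float(pearsonr(x[keep], y[keep])[0] ** 2)
    out["mean"] = float(np.mean([v for k, v in out.items() if k != "mean"]))
    return out
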