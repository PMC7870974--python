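"""Synthetic fixtures: toy binding tables, signatures, genomes and cohorts.

Everything the pipeline consumes can be generated here at toy scale, with
the same statistical structure the method assumes:

* ``synth_qbic_table`` builds a complete score table for a motif-based toy
  TF.  Binding of a k-mer is the best log-odds match of the motif over all
  offsets and both strands; a change's raw score is the binding difference
  plus seeded Gaussian noise, and its p-value is the two-sided normal tail
  of score/scale — by construction strictly decreasing in |score|, as real
  tables promise.  The default reduced flank (2, i.e. 4**4 = 256 changes per
  class) keeps test tables small; flank 4 reproduces the full 11-mer scale.
* ``synth_signature`` builds signatures from per-substitution-type masses
  (e.g. a C>T-dominated signature emulating APOBEC-like processes).
* ``synth_cohort`` writes a random genome with annotated gene starts plus
  mutations drawn class-first from a signature and placed uniformly at
  matching genomic contexts, with the exposure table recording the
  generating fractions.

Noise and p-value scale defaults are chosen so that a few percent of a toy
table's changes pass BH FDR < 0.1, keeping both tails non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import mutation_model as mm
from .mutation_model import BASES, N_CLASSES, SUBSTITUTION_TYPES
from .qbic_table import QbicTable
from .signature_io import Signature

_BG = 0.25  # uniform background base frequency


def motif_from_consensus(consensus: str, match_p: float = 0.85) -> np.ndarray:
    """Log-odds matrix for a consensus site.

    The consensus base gets probability about ``match_p`` (deterministically
    jittered per position) and the remainder is split unevenly over the other
    bases, so per-position log-odds are heterogeneous and binding-change
    scores form a spread distribution rather than a few atoms.
    """
    mm._check_dna(consensus, "consensus")
    w = len(consensus)
    off_splits = np.array([[0.5, 0.3, 0.2], [0.45, 0.35, 0.2], [0.55, 0.25, 0.2]])
    mat = np.empty((w, 4))
    for j, b in enumerate(consensus):
        p_match = match_p - 0.04 * (j % 3)
        probs = np.empty(4)
        others = [i for i in range(4) if i != mm._BASE_INDEX[b]]
        probs[mm._BASE_INDEX[b]] = p_match
        probs[others] = (1 - p_match) * off_splits[j % 3]
        mat[j] = np.log2(probs / _BG)
    return mat


@dataclass
class ToyTF:
    """A motif-based stand-in for one PBM experiment."""

    name: str
    motif: np.ndarray = field(repr=False)  # (width, 4) log-odds
    noise_sd: float = 0.25
    p_scale: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = np.asarray(self.motif, dtype=float)
        if self.motif.ndim != 2 or self.motif.shape[1] != 4:
            raise ValueError("motif must be a (width, 4) log-odds matrix")
        if self.noise_sd < 0 or self.p_scale <= 0:
            raise ValueError("noise_sd must be >= 0 and p_scale > 0")


def _all_kmer_digits(length: int) -> np.ndarray:
    """(4**length, length) digit matrix of every k-mer, lexicographic order."""
    n = 4**length
    cols = []
    for pos in range(length):
        reps = 4 ** (length - 1 - pos)
        cols.append(np.tile(np.repeat(np.arange(4), reps), n // (reps * 4)))
    return np.stack(cols, axis=1)


def _binding(digits: np.ndarray, motif: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Soft-max motif log-odds over all offsets and both strands, per k-mer.

    binding = sum_w tau * softplus(s_w / tau) over window log-odds sums s_w.
    Off-motif windows (s_w << 0) contribute essentially nothing, as in
    occupancy-style energy models, so a central change produces a noticeable
    binding difference only when it creates or destroys a motif-like window;
    the large majority of changes score near zero, with a tail of strong
    gains and losses in motif contexts.
    """
    length = digits.shape[1]
    w = motif.shape[0]
    if w > length:
        raise ValueError(f"motif width {w} exceeds k-mer length {length}")
    rc_motif = motif[::-1, ::-1]  # reverse complement: flip positions and bases
    binding = np.zeros(digits.shape[0])
    for mat in (motif, rc_motif):
        for off in range(length - w + 1):
            window = digits[:, off : off + w]
            s = mat[np.arange(w), window].sum(axis=1) / tau
            binding += tau * np.logaddexp(0.0, s)
    return binding


def synth_qbic_table(tf: ToyTF, flank: int = 2) -> QbicTable:
    """Complete, seeded score/p-value table for a toy TF at a given flank.

    Deterministic given ``tf.seed``; the p-value is an exact strictly
    decreasing function of |score|.
    """
    length = 2 * flank + 3
    digits = _all_kmer_digits(length)
    binding = _binding(digits, tf.motif)
    n = mm.count_changes(flank)
    powers = 4 ** np.arange(length - 1, -1, -1, dtype=np.int64)
    mid = length // 2
    flank_digits = mm.flank_digit_matrix(flank).astype(np.int64)
    # k-mer index contributed by the flanks alone (centre trinucleotide zeroed)
    flank_part = flank_digits[:, :flank] @ powers[:flank] + flank_digits[:, flank:] @ powers[mid + 2 :]
    rng = np.random.default_rng(tf.seed)
    scores = np.empty((N_CLASSES, n))
    for k, mc in enumerate(mm.CLASSES):
        tri = [mm._BASE_INDEX[b] for b in mc.ref_tri]
        alt = mm._BASE_INDEX[mc.alt]
        tri_part = tri[0] * powers[mid - 1] + tri[1] * powers[mid] + tri[2] * powers[mid + 1]
        ref_idx = flank_part + tri_part
        mut_idx = ref_idx + (alt - tri[1]) * powers[mid]
        scores[k] = binding[mut_idx] - binding[ref_idx]
    if tf.noise_sd > 0:
        scores += rng.normal(0.0, tf.noise_sd, size=scores.shape)
    pvalues = 2 * norm.sf(np.abs(scores) / tf.p_scale)
    np.clip(pvalues, np.nextafter(0, 1), 1.0, out=pvalues)
    return QbicTable(tf.name, tf.name.split("_")[0], scores, pvalues, flank)


def synth_signature(
    type_masses: dict[str, float],
    within_type: str = "uniform",
    seed: int | None = None,
    name: str | None = None,
    concentration: float = 15.0,
) -> Signature:
    """Signature from per-substitution-type masses.

    ``within_type`` spreads each type's mass over its 16 context classes
    either uniformly or as a seeded symmetric-Dirichlet draw ("random");
    the default concentration gives the mild context-to-context variation
    (CV about 0.25) seen in smooth, broad-spectrum catalog signatures —
    lower values give spikier, more context-specific signatures.
    """
    masses = np.zeros(6)
    for t, v in type_masses.items():
        if t not in SUBSTITUTION_TYPES:
            raise ValueError(f"unknown substitution type {t!r}")
        if v < 0:
            raise ValueError(f"negative mass for {t!r}")
        masses[SUBSTITUTION_TYPES.index(t)] = v
    if masses.sum() <= 0:
        raise ValueError("all-zero type masses")
    masses /= masses.sum()
    probs = np.empty(N_CLASSES)
    rng = np.random.default_rng(seed)
    for i in range(6):
        if within_type == "uniform":
            within = np.full(16, 1 / 16)
        elif within_type == "random":
            within = rng.dirichlet(np.full(16, concentration))
        else:
            raise ValueError(f"within_type must be 'uniform' or 'random', got {within_type!r}")
        probs[i * 16 : (i + 1) * 16] = masses[i] * within
    if name is None:
        name = "+".join(f"{t}{v:g}" for t, v in sorted(type_masses.items()) if v > 0)
    return Signature(name, probs)


@dataclass
class SyntheticCohort:
    """In-memory synthetic study: genome, gene annotation, mutations, exposures."""

    genome: dict[str, str]
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id (1-based closed, GTF-style)
    mutations: pd.DataFrame  # sample, chrom, pos, ref, alt (1-based)
    exposures: pd.DataFrame  # sample, signature, value
    signature_name: str

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA, GTF, mutation TSV and exposure TSV; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "genes.gtf",
            "mutations": outdir / "mutations.tsv",
            "exposures": outdir / "exposures.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(paths["gtf"], "w") as fh:
            for g in self.genes.itertuples():
                attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        self.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        self.exposures.to_csv(paths["exposures"], sep="\t", index=False)
        return paths


def synth_cohort(
    genome_size: int,
    n_genes: int,
    n_samples: int,
    signature: Signature,
    mutations_per_sample: int,
    seed: int,
    chrom: str = "chr1",
) -> SyntheticCohort:
    """Random genome + TSS annotation + mutations drawn from a signature.

    Genes are evenly spaced along the chromosome with seeded random strands.
    Each mutation samples a class from the signature, then a uniformly
    random genomic position whose +/- strand context realizes the class's
    trinucleotide; the written ref/alt alleles are the genome-strand ones.
    Raises if some required context never occurs in the genome.
    """
    rng = np.random.default_rng(seed)
    genome_digits = rng.integers(0, 4, size=genome_size)
    genome = "".join(BASES[d] for d in genome_digits)

    spacing = genome_size // n_genes
    starts = [spacing // 2 + i * spacing for i in range(n_genes)]
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,  # for '+' the TSS; for '-' we set end=start so TSS coincides
            "end": [min(s + spacing // 3, genome_size) for s in starts],
            "strand": strands,
            "gene_id": [f"G{i + 1}" for i in range(n_genes)],
        }
    )
    # put the TSS at 'start' for + genes and at 'end' for - genes: shift - genes
    minus = genes["strand"] == "-"
    genes.loc[minus, "end"] = genes.loc[minus, "start"]
    genes.loc[minus, "start"] = (genes.loc[minus, "end"] - spacing // 3).clip(lower=1)

    # positions (0-based, interior) whose context matches each pyrimidine-centred
    # trinucleotide on either strand
    tri_positions: dict[str, np.ndarray] = {}
    tri_strand_fwd: dict[str, np.ndarray] = {}
    contexts = np.array([genome[i - 1 : i + 2] for i in range(1, genome_size - 1)])
    for mc_tri in sorted({mc.ref_tri for mc in mm.CLASSES}):
        fwd = contexts == mc_tri
        rev = contexts == mm.reverse_complement(mc_tri)
        pos = np.flatnonzero(fwd | rev) + 1
        if pos.size == 0:
            raise ValueError(f"context {mc_tri} unrealizable in genome of size {genome_size}")
        tri_positions[mc_tri] = pos
        tri_strand_fwd[mc_tri] = fwd[pos - 1]

    n_total = n_samples * mutations_per_sample
    class_draws = rng.choice(N_CLASSES, size=n_total, p=signature.probs)
    rows = {"sample": [], "chrom": [], "pos": [], "ref": [], "alt": []}
    samples = [f"S{i + 1}" for i in range(n_samples)]
    for j, ci in enumerate(class_draws):
        mc = mm.CLASSES[ci]
        pos_arr = tri_positions[mc.ref_tri]
        k = rng.integers(0, pos_arr.size)
        p0 = int(pos_arr[k])
        ref = genome[p0]
        alt = mc.alt if tri_strand_fwd[mc.ref_tri][k] else mm.complement(mc.alt)
        rows["sample"].append(samples[j % n_samples])
        rows["chrom"].append(chrom)
        rows["pos"].append(p0 + 1)  # 1-based, VCF-like
        rows["ref"].append(ref)
        rows["alt"].append(alt)
    mutations = pd.DataFrame(rows)
    exposures = pd.DataFrame(
        {"sample": samples, "signature": signature.name, "value": 1.0}
    )
    return SyntheticCohort(
        genome={chrom: genome},
        genes=genes,
        mutations=mutations,
        exposures=exposures,
        signature_name=signature.name,
    )
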