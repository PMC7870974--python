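"""AT/GC classification of TF motifs and composition-entropy effects of mutations.

Two independent quantities are related here: (1) the average A+T content of
a TF's position weight matrix, used to label TFs as AT-PWM (> 60%) or GC-PWM
(< 40%); and (2) the change in Shannon entropy of a k-mer's base-composition
vector caused by a central single-base change.  AT-increasing mutations in
already AT-rich sequences push the composition toward its dominant letters
and therefore lower entropy; signature-expected entropy changes quantify
this per mutational process.

Entropy is computed on the base-composition frequency vector of the k-mer
(not positional information content), in bits by default; the log base is a
parameter.  Entropy changes are evaluated on the given strand; reverse
complementing swaps A<->T and C<->G counts and leaves the entropy unchanged,
so canonical (pyrimidine-centred) enumeration loses nothing.

The signature-expected change over all (or AT-rich / GC-rich filtered)
contexts is computed exactly by enumerating flank *compositions* with
multinomial multiplicities rather than individual k-mers, which makes even
the full 11-mer scale instantaneous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from scipy.stats import median_abs_deviation

from . import mutation_model as mm
from .mutation_model import BASES, CLASSES, SUBSTITUTION_TYPES
from .qbic_table import QbicTable
from .signature_io import Signature

logger = logging.getLogger(__name__)

AT_PWM_MIN = 0.6
GC_PWM_MAX = 0.4

#: substitution types increasing / decreasing A+T content
PLUS_AT_TYPES = frozenset({"C>A", "C>T"})
MINUS_AT_TYPES = frozenset({"T>C", "T>G"})

_MUTATION_FILTERS = {
    "all": frozenset(SUBSTITUTION_TYPES),
    "+AT": PLUS_AT_TYPES,
    "-AT": MINUS_AT_TYPES,
}


@dataclass
class PWM:
    """Position weight matrix: per-position probabilities over A, C, G, T."""

    tf_name: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"PWM width must be >= 4, got {self.matrix.shape[0]}")
        if (self.matrix < 0).any() or np.abs(self.matrix.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError(f"PWM rows for {self.tf_name!r} must be probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def read_pwm_cisbp(path, tf_name: str | None = None) -> PWM:
    """Read a CIS-BP-style PWM: TSV with a position column and A/C/G/T columns."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    try:
        mat = df[[cols["A"], cols["C"], cols["G"], cols["T"]]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{path}: expected A/C/G/T columns, got {list(df.columns)}") from exc
    from pathlib import Path

    return PWM(tf_name or Path(path).stem, mat)


def read_pwms_meme(path) -> list[PWM]:
    """Read motifs from a MEME minimal-format file."""
    pwms = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name, np.array(rows)))
                name = line.split()[1]
                rows, in_matrix = [], False
            elif line.startswith("letter-probability"):
                in_matrix = True
            elif in_matrix and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
            elif in_matrix and not line:
                in_matrix = False
    if name is not None and rows:
        pwms.append(PWM(name, np.array(rows)))
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def at_percent(pwm: PWM) -> float:
    """Mean over positions of P(A) + P(T)."""
    return float((pwm.matrix[:, 0] + pwm.matrix[:, 3]).mean())


@dataclass(frozen=True)
class ATClassification:
    tf_name: str
    at_percent: float
    label: str  # "AT-PWM" | "GC-PWM" | "neither"


def classify_at(tf_name: str, pwms: list[PWM]) -> ATClassification:
    """AT/GC label for a TF; the median at_percent is used over multiple PWMs."""
    if not pwms:
        raise ValueError(f"no PWMs for TF {tf_name!r}")
    ap = float(np.median([at_percent(p) for p in pwms]))
    if ap > AT_PWM_MIN:
        label = "AT-PWM"
    elif ap < GC_PWM_MAX:
        label = "GC-PWM"
    else:
        label = "neither"
    return ATClassification(tf_name, ap, label)


# ---------------------------------------------------------------------------
# Entropy changes


def _composition_entropy(counts, base: float) -> float:
    return float(shannon_entropy(np.asarray(counts, dtype=float), base=base))


def entropy_change(ref_kmer: str, alt_central: str, base: float = 2.0) -> float:
    """Shannon entropy of the mutated k-mer's base composition minus the reference's.

    Computed on the given strand (entropy is invariant under reverse
    complement, so canonicalization does not change the value).
    """
    ch = mm.KmerChange(ref_kmer, alt_central)  # validates
    ref_counts = [ref_kmer.count(b) for b in BASES]
    mut = ch.mutated
    mut_counts = [mut.count(b) for b in BASES]
    return _composition_entropy(mut_counts, base) - _composition_entropy(ref_counts, base)


def _flank_compositions(n: int):
    """Yield (composition over ACGT summing to n, multinomial multiplicity)."""
    for a in range(n + 1):
        for c in range(n - a + 1):
            for g in range(n - a - c + 1):
                t = n - a - c - g
                mult = factorial(n) // (
                    factorial(a) * factorial(c) * factorial(g) * factorial(t)
                )
                yield np.array([a, c, g, t]), mult


def _sequence_mask(at_fraction: float, sequence_filter: str) -> bool:
    if sequence_filter == "all":
        return True
    if sequence_filter == "AT-rich":
        return at_fraction > AT_PWM_MIN
    if sequence_filter == "GC-rich":
        return at_fraction < GC_PWM_MAX
    raise ValueError(f"unknown sequence filter {sequence_filter!r}")


def expected_entropy_change(
    sig: Signature,
    sequence_filter: str = "all",
    flank: int = mm.FULL_FLANK,
    base: float = 2.0,
) -> float:
    """Signature-expected composition-entropy change over filtered contexts.

    Sum over canonical changes of mass(change) * dH(change), where a change
    of class mu carries mass sigma_mu / |eligible changes of mu| and
    eligibility restricts the *reference* k-mer's AT fraction (> 60% for
    AT-rich, < 40% for GC-rich; strict, evaluated pre-mutation).  Classes
    with an empty eligible set are skipped with a logged note.  Exact: flank
    compositions are enumerated with multinomial multiplicities.
    """
    k = 2 * flank + 3
    total = 0.0
    skipped = []
    for mc in CLASSES:
        tri_counts = np.array([mc.ref_tri.count(b) for b in BASES])
        e_ref = np.eye(4, dtype=int)[mm._BASE_INDEX[mc.ref_tri[1]]]
        e_alt = np.eye(4, dtype=int)[mm._BASE_INDEX[mc.alt]]
        class_sum = 0.0
        n_eligible = 0
        for comp, mult in _flank_compositions(2 * flank):
            ref_counts = comp + tri_counts
            at_frac = (ref_counts[0] + ref_counts[3]) / k
            if not _sequence_mask(at_frac, sequence_filter):
                continue
            dh = _composition_entropy(ref_counts - e_ref + e_alt, base) - _composition_entropy(
                ref_counts, base
            )
            class_sum += mult * dh
            n_eligible += mult
        if n_eligible == 0:
            skipped.append(mc.label)
            continue
        total += sig[mc.label] * class_sum / n_eligible
    if skipped:
        logger.warning(
            "expected_entropy_change: %d classes with empty %s set skipped (e.g. %s)",
            len(skipped), sequence_filter, skipped[:3],
        )
    return total


# ---------------------------------------------------------------------------
# Per-table summaries (entropy change vs score over filtered change sets)


def _table_entropy_and_at(table: QbicTable, base: float) -> tuple[np.ndarray, np.ndarray]:
    """(dH, ref AT fraction) arrays of shape (96, n_per_class) for one table."""
    flank = table.flank
    k = 2 * flank + 3
    fl = mm.flank_digit_matrix(flank).astype(int)  # (n, 2f)
    flank_counts = np.stack([(fl == d).sum(axis=1) for d in range(4)], axis=1)  # (n, 4)
    dh = np.empty((mm.N_CLASSES, fl.shape[0]))
    at = np.empty_like(dh)
    log = np.log2 if base == 2.0 else (lambda x: np.log(x) / np.log(base))

    def H(counts):  # counts: (n, 4)
        p = counts / k
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * log(p), 0.0)
        return -terms.sum(axis=1)

    for i, mc in enumerate(CLASSES):
        tri_counts = np.array([mc.ref_tri.count(b) for b in BASES])
        ref_counts = flank_counts + tri_counts
        mut_counts = ref_counts.copy()
        mut_counts[:, mm._BASE_INDEX[mc.ref_tri[1]]] -= 1
        mut_counts[:, mm._BASE_INDEX[mc.alt]] += 1
        dh[i] = H(mut_counts) - H(ref_counts)
        at[i] = (ref_counts[:, 0] + ref_counts[:, 3]) / k
    return dh, at


@dataclass(frozen=True)
class TailStats:
    median_dh: float
    mad_dh: float
    median_score: float
    mad_score: float
    n: int


def tail_stats_by_filter(
    table: QbicTable,
    mutation_filter: str = "all",
    sequence_filter: str = "all",
    base: float = 2.0,
) -> TailStats:
    """Median/MAD of entropy change and of score over a filtered change set.

    ``mutation_filter``: "all", "+AT" (central C>A or C>T) or "-AT" (central
    T>C or T>G).  ``sequence_filter``: "all", "AT-rich" (> 60% AT in the
    reference k-mer) or "GC-rich" (< 40%).  MAD is normal-consistent
    (scale factor 1.4826).  Deterministic; an empty selection is an error.
    """
    try:
        types = _MUTATION_FILTERS[mutation_filter]
    except KeyError:
        raise ValueError(f"unknown mutation filter {mutation_filter!r}") from None
    dh, at = _table_entropy_and_at(table, base)
    class_mask = np.array([mc.substitution_type in types for mc in CLASSES])
    seq_mask = np.empty_like(dh, dtype=bool)
    if sequence_filter == "all":
        seq_mask[:] = True
    elif sequence_filter == "AT-rich":
        seq_mask = at > AT_PWM_MIN
    elif sequence_filter == "GC-rich":
        seq_mask = at < GC_PWM_MAX
    else:
        raise ValueError(f"unknown sequence filter {sequence_filter!r}")
    mask = class_mask[:, None] & seq_mask
    if not mask.any():
        raise ValueError(
            f"empty selection for filters ({mutation_filter!r}, {sequence_filter!r})"
        )
    sel_dh = dh[mask]
    sel_s = table.scores[mask]
    return TailStats(
        float(np.median(sel_dh)),
        float(median_abs_deviation(sel_dh, scale="normal")),
        float(np.median(sel_s)),
        float(median_abs_deviation(sel_s, scale="normal")),
        int(mask.sum()),
    )
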