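"""Per-experiment binding-change score tables and their per-class slices.

For one TF assay, a table holds a score and a p-value for every canonical
single-nucleotide change at the centre of every k-mer (11-mers at the full
scale).  Positive scores indicate increased binding affinity, negative scores
reduced affinity, and the p-value is a strictly decreasing function of the
score magnitude (checked on load; violations are warned about and
monotonized per score sign).

Internally a table is a pair of dense (96, 4**(2*flank)) arrays — one row per
mutation class, columns in flank-index order — which supports vectorized
per-class slicing and keeps even the full 6.3M-change scale comfortably in
memory (~100 MB for the two float64 arrays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mutation_model as mm
from .mutation_model import CLASSES, N_CLASSES, KmerChange, MutationClass

_MONO_TOL = 1e-9


@dataclass
class QbicTable:
    """Scores and p-values for all canonical k-mer changes of one experiment."""

    experiment_id: str
    tf_name: str
    scores: np.ndarray = field(repr=False)
    pvalues: np.ndarray = field(repr=False)
    flank: int = mm.FULL_FLANK

    def __post_init__(self) -> None:
        n = mm.count_changes(self.flank)
        self.scores = np.asarray(self.scores, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        for name, arr in (("scores", self.scores), ("pvalues", self.pvalues)):
            if arr.shape != (N_CLASSES, n):
                raise ValueError(
                    f"{name} must have shape ({N_CLASSES}, {n}) at flank {self.flank}, got {arr.shape}"
                )
        if ((self.pvalues <= 0) | (self.pvalues > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        self._check_monotone()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_per_class(self) -> int:
        return self.scores.shape[1]

    @property
    def n_changes(self) -> int:
        return self.scores.size

    def _check_monotone(self) -> None:
        """Verify p is decreasing in |score|; monotonize per score sign if not."""
        s = self.scores.ravel()
        p = self.pvalues.ravel()
        order = np.argsort(np.abs(s), kind="stable")
        if (np.diff(p[order]) <= _MONO_TOL).all():
            return
        warnings.warn(
            f"table {self.experiment_id}: p-values are not monotone in |score|; "
            "applying per-side empirical monotonization",
            stacklevel=3,
        )
        p = p.copy()
        for side in (s >= 0, s < 0):
            idx = np.flatnonzero(side)
            o = idx[np.argsort(np.abs(s[idx]), kind="stable")]
            p[o] = np.minimum.accumulate(p[o])
        self.pvalues = p.reshape(self.pvalues.shape)

    # -- queries -----------------------------------------------------------
    def lookup(self, ref_kmer: str, alt: str) -> tuple[float, float]:
        """(score, p-value) of a change; strand-collapses purine-centred queries."""
        ci, fi = mm.change_location(ref_kmer, alt)
        return float(self.scores[ci, fi]), float(self.pvalues[ci, fi])

    def class_distribution(self, mc: MutationClass) -> "ClassDistribution":
        """The per-class slice D_mu: all (change, score, p) triples of one class."""
        i = mc.index
        return ClassDistribution(mc, self.flank, self.scores[i].copy(), self.pvalues[i].copy())

    # -- I/O ---------------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format (ref_kmer, alt, score) and (ref_kmer, alt, pvalue) frames."""
        refs, alts = [], []
        for mc in CLASSES:
            for ch in mm.iter_changes(mc, self.flank):
                refs.append(ch.ref)
                alts.append(ch.alt)
        pred = pd.DataFrame({"ref_kmer": refs, "alt": alts, "score": self.scores.ravel()})
        pval = pd.DataFrame({"ref_kmer": refs, "alt": alts, "pvalue": self.pvalues.ravel()})
        return pred, pval

    def write(self, prediction_path, pvalue_path) -> None:
        pred, pval = self.to_frames()
        pred.to_csv(prediction_path, sep="\t", index=False, float_format="%.17g")
        pval.to_csv(pvalue_path, sep="\t", index=False, float_format="%.17g")

    def save_cache(self, path) -> None:
        """Compact binary cache for fast reuse (npz, keyed by experiment_id)."""
        np.savez_compressed(
            path,
            experiment_id=self.experiment_id,
            tf_name=self.tf_name,
            flank=self.flank,
            scores=self.scores,
            pvalues=self.pvalues,
        )

    @classmethod
    def load_cache(cls, path) -> "QbicTable":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                experiment_id=str(z["experiment_id"]),
                tf_name=str(z["tf_name"]),
                scores=z["scores"],
                pvalues=z["pvalues"],
                flank=int(z["flank"]),
            )


@dataclass
class ClassDistribution:
    """D_mu: the scores and p-values of every change in one mutation class."""

    mutation_class: MutationClass
    flank: int
    scores: np.ndarray = field(repr=False)
    pvalues: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.scores.size

    def changes(self) -> list[KmerChange]:
        return mm.enumerate_changes(self.mutation_class, self.flank)

    def entries(self) -> list[tuple[KmerChange, float, float]]:
        return [
            (ch, float(s), float(p))
            for ch, s, p in zip(self.changes(), self.scores, self.pvalues)
        ]


def _read_value_file(path, seq_col: str, alt_col: str, value_col: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    try:
        df = df[[cols[seq_col.lower()], cols[alt_col.lower()], cols[value_col.lower()]]]
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns ({seq_col}, {alt_col}, {value_col}); got {list(df.columns)}"
        ) from exc
    df.columns = ["seq", "alt", "value"]
    return df


def _canonical_cells(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    seqs = df["seq"].astype(str).str.upper().to_numpy()
    lengths = np.char.str_len(seqs.astype(str))
    if len(set(lengths.tolist())) != 1:
        raise ValueError("mixed k-mer lengths in table")
    digits = mm.seqs_to_digits(seqs)
    alt_digits = mm.seqs_to_digits(df["alt"].astype(str).str.upper().to_numpy())[:, 0]
    return mm.digit_locations(digits, alt_digits)


def read_qbic_table(
    prediction_path,
    pvalue_path,
    experiment_id: str | None = None,
    tf_name: str = "",
    seq_col: str = "ref_kmer",
    alt_col: str = "alt",
    score_col: str = "score",
    pvalue_col: str = "pvalue",
) -> QbicTable:
    """Load a score table from aligned prediction and p-value files.

    Both files are tabular (TSV/CSV auto-detected) keyed by the reference
    k-mer and the alternate central base; column names are configurable for
    other dialects.  Keys are strand-collapsed on load, completeness over the
    full 96-class x flank grid is enforced, and duplicate canonical keys are
    tolerated only when their values agree exactly (both strand
    representations of the same change), otherwise an error is raised.
    """
    pred = _read_value_file(prediction_path, seq_col, alt_col, score_col)
    pval = _read_value_file(pvalue_path, seq_col, alt_col, pvalue_col)
    if len(pred) != len(pval):
        raise ValueError(
            f"row count mismatch: {prediction_path} has {len(pred)} rows, "
            f"{pvalue_path} has {len(pval)}"
        )
    ci, fi = _canonical_cells(pred)
    ci2, fi2 = _canonical_cells(pval)
    if not (np.array_equal(ci, ci2) and np.array_equal(fi, fi2)):
        raise ValueError("prediction and p-value files are not keyed by the same changes")
    flank = (len(pred["seq"].iloc[0]) - 3) // 2
    n = mm.count_changes(flank)
    scores = np.full((N_CLASSES, n), np.nan)
    pvalues = np.full((N_CLASSES, n), np.nan)
    sv = pred["value"].to_numpy(dtype=float)
    pv = pval["value"].to_numpy(dtype=float)
    lin = ci.astype(np.int64) * n + fi
    order = np.argsort(lin, kind="stable")
    same = np.diff(lin[order]) == 0
    if same.any():
        conflict = same & ((np.diff(sv[order]) != 0) | (np.diff(pv[order]) != 0))
        if conflict.any():
            k = order[int(np.flatnonzero(conflict)[0])]
            raise ValueError(
                f"conflicting duplicate entry for change "
                f"{pred['seq'].iloc[k]}>{pred['alt'].iloc[k]} in {prediction_path}"
            )
    seen = np.zeros((N_CLASSES, n), dtype=bool)
    scores[ci, fi] = sv
    pvalues[ci, fi] = pv
    seen[ci, fi] = True
    if not seen.all():
        missing_classes = [CLASSES[i].label for i in np.flatnonzero(~seen.all(axis=1))]
        raise ValueError(
            f"incomplete table {prediction_path}: missing changes in classes {missing_classes[:5]}"
            + ("..." if len(missing_classes) > 5 else "")
        )
    if experiment_id is None:
        experiment_id = str(prediction_path)
    return QbicTable(experiment_id, tf_name, scores, pvalues, flank)
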