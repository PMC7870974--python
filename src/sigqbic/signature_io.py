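"""Reading, writing and summarizing 96-channel mutational-signature catalogs.

A mutational signature is a multinomial distribution over the 96
strand-collapsed mutation classes: the probability that a new mutation caused
by the corresponding process falls in each class.  Catalogs are tabular, one
row per class (either "TCA>TTA" or COSMIC "T[C>T]A" labels, auto-detected)
and one column per signature.  Exposure tables record, per tumor sample, how
many (or what fraction) of its mutations each signature explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mutation_model import (
    CLASS_LABELS,
    CLASSES,
    N_CLASSES,
    SUBSTITUTION_TYPES,
    MutationClass,
)

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Signature:
    """A named probability vector over the 96 mutation classes (COSMIC order)."""

    name: str
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_CLASSES,):
            raise ValueError(f"signature needs {N_CLASSES} probabilities, got {probs.shape}")
        if (probs < 0).any():
            raise ValueError(f"signature {self.name!r} has negative probabilities")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"signature {self.name!r} probabilities sum to {probs.sum():.6g}, not 1; "
                "use Signature.normalized()"
            )
        object.__setattr__(self, "probs", probs)

    @classmethod
    def normalized(cls, name: str, values) -> "Signature":
        """Build a signature from non-negative weights, renormalizing to sum 1."""
        values = np.asarray(values, dtype=float)
        total = values.sum()
        if total <= 0:
            raise ValueError(f"signature {name!r} has non-positive total mass")
        if abs(total - 1.0) > _SUM_TOL:
            logger.warning("signature %r summed to %.6g; renormalized to 1", name, total)
        return cls(name, values / total)

    def __getitem__(self, key: "MutationClass | str") -> float:
        if isinstance(key, str):
            key = MutationClass.from_label(key)
        return float(self.probs[key.index])

    def to_series(self) -> pd.Series:
        return pd.Series(self.probs, index=list(CLASS_LABELS), name=self.name)

    def type_masses(self) -> dict[str, float]:
        """Total probability per substitution type (C>A .. T>G)."""
        blocks = self.probs.reshape(6, 16).sum(axis=1)
        return dict(zip(SUBSTITUTION_TYPES, blocks.tolist()))


def uniform_signature(name: str = "uniform") -> Signature:
    """The equal-frequency signature: every class has probability 1/96."""
    return Signature(name, np.full(N_CLASSES, 1.0 / N_CLASSES))


def _label_indices(labels: pd.Index) -> np.ndarray:
    """Map catalog row labels (either dialect) onto canonical class indices."""
    idx = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        try:
            idx[i] = MutationClass.from_label(str(lab)).index
        except ValueError as exc:
            raise ValueError(f"unrecognized mutation-class row label {lab!r}") from exc
    return idx


def read_signature_catalog(path) -> list[Signature]:
    """Read a signature catalog (TSV or CSV; label dialect auto-detected).

    Each column becomes a :class:`Signature`; probabilities are renormalized
    to sum 1 (with a logged warning when the raw sum is off by > 1e-6).
    Missing classes, duplicate rows or negative values raise ``ValueError``
    naming the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    idx = _label_indices(df.index)
    dup = pd.Series(idx).duplicated()
    if dup.any():
        raise ValueError(f"duplicate mutation-class rows in {path}: {list(df.index[dup.values])}")
    if len(idx) != N_CLASSES:
        have = set(idx)
        missing = [CLASSES[i].label for i in range(N_CLASSES) if i not in have]
        raise ValueError(f"catalog {path} is missing {len(missing)} classes, e.g. {missing[:3]}")
    sigs = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="raise").to_numpy()
        if (values < 0).any():
            bad = df.index[values < 0][0]
            raise ValueError(f"negative probability for class {bad!r} in signature {col!r}")
        ordered = np.empty(N_CLASSES)
        ordered[idx] = values
        sigs.append(Signature.normalized(str(col), ordered))
    return sigs


def write_signature_catalog(signatures: list[Signature], path) -> None:
    """Write signatures as a TSV with 'TCA>TTA'-style row labels."""
    df = pd.DataFrame({s.name: s.probs for s in signatures}, index=list(CLASS_LABELS))
    df.index.name = "mutation_class"
    df.to_csv(path, sep="\t", float_format="%.12g")


def major_mutation_types(sig: Signature, threshold: float = 0.9) -> set[str]:
    """The smallest set of substitution types collectively exceeding ``threshold``.

    Types are taken in descending order of total signature mass (ties broken
    by canonical type order) until the cumulative mass is strictly greater
    than ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    masses = sig.type_masses()
    order = sorted(masses, key=lambda t: (-masses[t], SUBSTITUTION_TYPES.index(t)))
    chosen: set[str] = set()
    cum = 0.0
    for t in order:
        chosen.add(t)
        cum += masses[t]
        if cum > threshold:
            break
    return chosen


def at_gain_fraction(sig: Signature) -> tuple[float, float]:
    """Mass of AT-increasing vs AT-decreasing mutations in a signature.

    "+AT" mutations convert C or G to A or T (central C>A or C>T on the
    pyrimidine strand); "-AT" mutations do the reverse (central T>C or T>G).
    C>G and T>A change neither, so the two fractions sum to at most 1.
    """
    masses = sig.type_masses()
    plus_at = masses["C>A"] + masses["C>T"]
    minus_at = masses["T>C"] + masses["T>G"]
    return plus_at, minus_at


# ---------------------------------------------------------------------------
# Exposure tables


def read_exposure_table(path) -> pd.DataFrame:
    """Read a long-format exposure table: sample, signature, value.

    ``value`` may be mutation counts or per-sample fractions; see
    :func:`exposure_fractions`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    required = {"sample", "signature", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"exposure table {path} needs columns {sorted(required)}, got {list(df.columns)}")
    if (df["value"] < 0).any():
        raise ValueError(f"negative exposures in {path}")
    return df[["sample", "signature", "value"]]


def exposure_fractions(exposures: pd.DataFrame) -> pd.DataFrame:
    """Convert an exposure table to per-sample fractions.

    Counts are divided by each sample's total; tables already in fractions
    (per-sample sums <= 1 + tolerance) are passed through unchanged.
    """
    totals = exposures.groupby("sample")["value"].transform("sum")
    if (totals <= 1.0 + _SUM_TOL).all():
        frac = exposures["value"]
    else:
        frac = exposures["value"] / totals
    out = exposures.copy()
    out["value"] = frac
    return out
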