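"""The signature x binding-change statistic: weighted tails, GR/LR, significance.

Given one experiment's score table and a mutational signature sigma, the
per-class score distributions D_mu are reweighted by the signature,

    D'_sigma = sum_mu sigma_mu * D_mu,

so each change of class mu carries mass sigma_mu / n_per_class (the baseline,
equal-frequency distribution D corresponds to the uniform signature:
1 / n_changes per change).  Benjamini-Hochberg FDR < 0.1 applied jointly to
the table's p-values induces a score-magnitude threshold T (the p-value is a
decreasing function of |score|), defining the significant tails.  The gain
ratio and loss ratio are the tail-mass ratios

    GR = area(D'_Pos) / area(D_Pos),    LR = area(D'_Neg) / area(D_Neg),

with area computed as exact weighted sums over changes (histograms are
presentation only).  Significance comes from a resampling test under the
null that mutations arise with equal class frequencies.

Because BH is applied jointly and then split by score sign, a single
symmetric threshold T serves both tails; tails are score >= T and
score <= -T with T the minimum passing |score|, so the tail set equals the
BH-passing set exactly.  Undefined ratios (no significant tail) propagate as
missing values, never as 0 or 1; they are imputed as 1 (no effect, logged)
only inside clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .mutation_model import N_CLASSES
from .qbic_table import QbicTable
from .signature_io import Signature, uniform_signature

logger = logging.getLogger(__name__)

UNIFORM_NAME = "uniform"


class NoSignificantTailError(ValueError):
    """No change passes the FDR threshold; GR/LR are undefined for this table."""


@dataclass(frozen=True)
class WeightedDistribution:
    """D'_sigma: per-change mass sigma_mu / n_per_class over a table's changes."""

    class_probs: np.ndarray
    flank: int
    experiment_id: str
    signature_name: str

    @property
    def n_per_class(self) -> int:
        return 4 ** (2 * self.flank)

    def mass_per_change(self) -> np.ndarray:
        """(96,) vector: the mass each individual change of class mu carries."""
        return self.class_probs / self.n_per_class

    @property
    def total_mass(self) -> float:
        return float(self.class_probs.sum())


@dataclass(frozen=True)
class TailAreas:
    """Probability mass beyond the significance threshold, per tail."""

    threshold: float
    area_pos: float
    area_neg: float


@dataclass
class GainLossResult:
    experiment_id: str
    tf_name: str
    signature_name: str
    gr: float
    lr: float
    threshold: float
    p_gain: float | None = None
    p_loss: float | None = None
    n_resamples: int | None = None
    seed: int | None = None

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.gr) and np.isnan(self.lr))


def weighted_distribution(table: QbicTable, sig: Signature) -> WeightedDistribution:
    """Reweight a table's per-class distributions by a signature."""
    return WeightedDistribution(sig.probs.copy(), table.flank, table.experiment_id, sig.name)


def bh_mask(pvalues: np.ndarray, fdr: float) -> np.ndarray:
    """Boolean mask of hypotheses rejected by Benjamini-Hochberg at level ``fdr``."""
    reject, *_ = multipletests(np.ravel(pvalues), alpha=fdr, method="fdr_bh")
    return reject.reshape(np.shape(pvalues))


def fdr_threshold(table: QbicTable, fdr: float = 0.1) -> float:
    """The score-magnitude threshold induced by BH FDR on a table's p-values.

    BH is applied jointly to all p-values; T is the minimum |score| among
    passing changes, so {|score| >= T} is the passing set (p decreases in
    |score|).  Raises :class:`NoSignificantTailError` if nothing passes.
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    reject = bh_mask(table.pvalues, fdr)
    if not reject.any():
        raise NoSignificantTailError(
            f"no change in table {table.experiment_id} passes BH FDR < {fdr}"
        )
    return float(np.abs(table.scores[reject]).min())


def _tail_counts(table: QbicTable, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-class counts of changes in the positive and negative tails."""
    pos = (table.scores >= T).sum(axis=1)
    neg = (table.scores <= -T).sum(axis=1)
    return pos, neg


def tail_areas(dist: WeightedDistribution, table: QbicTable, T: float) -> TailAreas:
    """Mass of a weighted distribution in the two significant tails."""
    if dist.experiment_id != table.experiment_id:
        raise ValueError(
            f"distribution provenance {dist.experiment_id!r} does not match table "
            f"{table.experiment_id!r}"
        )
    pos, neg = _tail_counts(table, T)
    mass = dist.mass_per_change()
    return TailAreas(T, float(pos @ mass), float(neg @ mass))


def gain_loss_ratios(table: QbicTable, sig: Signature, fdr: float = 0.1) -> GainLossResult:
    """GR and LR of one (experiment, signature) pair.

    A tail empty under the baseline makes the corresponding ratio undefined
    (NaN), and a table with no BH-passing change at all yields NaN for both,
    flagged via ``defined`` — never silently 0 or 1.
    """
    try:
        T = fdr_threshold(table, fdr)
    except NoSignificantTailError:
        logger.warning("table %s: no significant tail at FDR %g", table.experiment_id, fdr)
        return GainLossResult(table.experiment_id, table.tf_name, sig.name, np.nan, np.nan, np.nan)
    base = tail_areas(weighted_distribution(table, uniform_signature()), table, T)
    obs = tail_areas(weighted_distribution(table, sig), table, T)
    gr = obs.area_pos / base.area_pos if base.area_pos > 0 else np.nan
    lr = obs.area_neg / base.area_neg if base.area_neg > 0 else np.nan
    return GainLossResult(table.experiment_id, table.tf_name, sig.name, gr, lr, T)


def resample_significance(
    table: QbicTable,
    sig: Signature,
    n_mutations: int = 10_000,
    n_reps: int = 1_000,
    seed: int | None = None,
    fdr: float = 0.1,
) -> tuple[float, float]:
    """Empirical p-values for the tail-mass excess of a signature.

    Tests the null that area(D'_Pos) - area(D_Pos) (and the negative-tail
    analogue) is no larger than expected when ``n_mutations`` mutations are
    drawn with equal class frequencies.  Each replicate draws class counts
    from the uniform multinomial, normalizes them to a pseudo-signature and
    recomputes the tail-mass difference; the add-one estimator
    (1 + #{null >= observed}) / (n_reps + 1) is returned for each tail.
    """
    if n_mutations < 1 or n_reps < 1:
        raise ValueError("n_mutations and n_reps must be >= 1")
    T = fdr_threshold(table, fdr)
    pos, neg = _tail_counts(table, T)
    w_pos = pos / table.n_per_class  # per-class conditional tail mass
    w_neg = neg / table.n_per_class
    base_probs = np.full(N_CLASSES, 1.0 / N_CLASSES)
    obs_gain = float((sig.probs - base_probs) @ w_pos)
    obs_loss = float((sig.probs - base_probs) @ w_neg)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, base_probs, size=n_reps) / n_mutations
    null_gain = (counts - base_probs) @ w_pos
    null_loss = (counts - base_probs) @ w_neg
    p_gain = (1 + int((null_gain >= obs_gain).sum())) / (n_reps + 1)
    p_loss = (1 + int((null_loss >= obs_loss).sum())) / (n_reps + 1)
    return p_gain, p_loss


def evaluate_pair(
    table: QbicTable,
    sig: Signature,
    fdr: float = 0.1,
    n_mutations: int = 10_000,
    n_resamples: int = 1_000,
    seed: int | None = None,
) -> GainLossResult:
    """GR/LR plus resampling significance for one (experiment, signature) pair."""
    res = gain_loss_ratios(table, sig, fdr)
    if res.defined:
        p_gain, p_loss = resample_significance(table, sig, n_mutations, n_resamples, seed, fdr)
        res = replace(res, p_gain=p_gain, p_loss=p_loss, n_resamples=n_resamples, seed=seed)
    return res


def results_frame(results: list[GainLossResult]) -> pd.DataFrame:
    """Long-format frame: tf, experiment, signature, GR, LR, p_gain, p_loss."""
    return pd.DataFrame(
        {
            "tf": [r.tf_name for r in results],
            "experiment": [r.experiment_id for r in results],
            "signature": [r.signature_name for r in results],
            "GR": [r.gr for r in results],
            "LR": [r.lr for r in results],
            "p_gain": [r.p_gain for r in results],
            "p_loss": [r.p_loss for r in results],
        }
    )


def aggregate_tf(
    results: "list[GainLossResult] | pd.DataFrame",
    experiment_to_tf: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-TF GR/LR (and p-values): the median over a TF's experiments.

    The standard median is used (mean of the middle two for even counts).
    ``experiment_to_tf`` overrides the tf column when the experiments carry
    no TF names of their own.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df.copy()
    if experiment_to_tf is not None:
        df["tf"] = df["experiment"].map(experiment_to_tf)
        if df["tf"].isna().any():
            missing = df.loc[df["tf"].isna(), "experiment"].unique()
            raise ValueError(f"experiments with no TF mapping: {list(missing)}")
    if df.empty:
        raise ValueError("no results to aggregate")
    value_cols = [c for c in ("GR", "LR", "p_gain", "p_loss") if c in df.columns]
    return df.groupby(["tf", "signature"], as_index=False)[value_cols].median()


def classify_gain_loss(
    per_tf: pd.DataFrame, alpha: float = 0.05
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Split (tf, signature) pairs into gain- and loss-of-binding sets.

    A pair is gain-of-binding when its resampled p_gain < alpha (the excess
    positive-tail mass is significant), loss-of-binding analogously; a pair
    may be in neither set.
    """
    gain = {
        (r.tf, r.signature)
        for r in per_tf.itertuples()
        if r.p_gain is not None and not pd.isna(r.p_gain) and r.p_gain < alpha
    }
    loss = {
        (r.tf, r.signature)
        for r in per_tf.itertuples()
        if r.p_loss is not None and not pd.isna(r.p_loss) and r.p_loss < alpha
    }
    return gain, loss


# ---------------------------------------------------------------------------
# Clustering of the GR/LR matrix


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_newick: str | None
    col_newick: str | None


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def cluster_gr_lr_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of a GR/LR matrix on both axes.

    Agglomerative clustering with complete linkage on Euclidean distance,
    deterministic given input order.  Missing entries are imputed as 1 (no
    effect) with a logged count.  Degenerate axes (single row or column) get
    identity orderings.
    """
    values = matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.warning("imputing %d missing GR/LR entries as 1 for clustering", n_missing)
        values = np.where(np.isnan(values), 1.0, values)

    def one_axis(data, labels):
        if data.shape[0] < 2:
            return list(labels), None, None
        Z = hierarchy.linkage(data, method="complete", metric="euclidean")
        order = hierarchy.leaves_list(Z)
        return [labels[i] for i in order], Z, linkage_to_newick(Z, list(labels))

    row_order, row_Z, row_nwk = one_axis(values, list(matrix.index))
    col_order, col_Z, col_nwk = one_axis(values.T, list(matrix.columns))
    return ClusterResult(row_order, col_order, row_Z, col_Z, row_nwk, col_nwk)
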