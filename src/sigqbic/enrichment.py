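"""Fisher-exact gene-set enrichment of gain-/loss-of-binding TF sets.

A local reimplementation of the standard over-representation test: for each
gene set, a one-sided Fisher exact test on the 2x2 table (query-in-set,
query-not-in-set, set-rest, background-rest), with Benjamini-Hochberg
q-values across sets.  The background defaults to the union of the
collection's sets; callers analysing TF subsets should pass the assayed-TF
universe explicitly.  Gene symbols are matched exactly after upper-casing;
no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from gseapy.parser import read_gmt as _read_gmt
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DEFAULT_Q = 0.005


def _clean(genes) -> frozenset[str]:
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


@dataclass
class GeneSetCollection:
    """Named gene sets plus an explicit background universe."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.sets = {n: _clean(s) for n, s in self.sets.items() if s}
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        if not self.background:
            self.background = frozenset().union(*self.sets.values())
        else:
            self.background = _clean(self.background)

    @classmethod
    def from_gmt(cls, path, background=None) -> "GeneSetCollection":
        """Load a GMT file (name, description, tab-separated symbols)."""
        sets = {str(n): _clean(g) for n, g in _read_gmt(str(path)).items()}
        return cls(sets, _clean(background) if background is not None else frozenset())


def enrich(
    query_tfs,
    collection: GeneSetCollection,
    q_threshold: float = DEFAULT_Q,
) -> pd.DataFrame:
    """Over-representation of a query gene set in each set of a collection.

    Returns one row per gene set: (set_name, n_set, overlap, p, q,
    significant, overlapping_genes), sorted by p.  ``p`` is the one-sided
    Fisher exact (hypergeometric upper-tail) probability; ``q`` is the BH
    adjusted value across all sets of the collection.  A query disjoint from
    the background is an error naming the missing symbols.
    """
    query = _clean(query_tfs)
    if not query:
        raise ValueError("empty query")
    bg = collection.background
    in_bg = query & bg
    if not in_bg:
        raise ValueError(
            f"query is disjoint from the background universe; missing symbols include "
            f"{sorted(query)[:5]}"
        )
    n_bg = len(bg)
    rows = []
    for name, genes in collection.sets.items():
        genes = genes & bg
        overlap = in_bg & genes
        a = len(overlap)
        b = len(in_bg) - a
        c = len(genes) - a
        d = n_bg - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, len(genes), a, float(p), ",".join(sorted(overlap))))
    df = pd.DataFrame(rows, columns=["set_name", "n_set", "overlap", "p", "overlapping_genes"])
    _, q, *_ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] < q_threshold
    return df[
        ["set_name", "n_set", "overlap", "p", "q", "significant", "overlapping_genes"]
    ].sort_values("p", kind="stable", ignore_index=True)
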