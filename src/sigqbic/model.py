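"""Model/Results interface over the signature x binding-change workflow.

``SignatureQbic`` is constructed from data (score tables and a signature
catalog); ``fit()`` evaluates every (experiment, signature) pair — gain and
loss ratios with resampling significance — and returns a
``SignatureQbicResults`` carrying the long-format estimates, the per-TF
matrices, classification into gain-/loss-of-binding pairs, clustering and a
``summary()`` table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from .qbic_table import QbicTable, read_qbic_table
from .signature_io import Signature, read_signature_catalog


class SignatureQbic:
    """Joint model of mutational signatures and per-TF binding-change tables.

    Parameters
    ----------
    tables : list of QbicTable
        One complete score/p-value table per PBM experiment.
    signatures : list of Signature
        The signature catalog to evaluate.
    experiment_to_tf : dict, optional
        Overrides the tables' own TF names when aggregating experiments.
    """

    def __init__(
        self,
        tables: list[QbicTable],
        signatures: list[Signature],
        experiment_to_tf: dict[str, str] | None = None,
    ):
        if not tables or not signatures:
            raise ValueError("need at least one table and one signature")
        self.tables = list(tables)
        self.signatures = list(signatures)
        self.experiment_to_tf = experiment_to_tf

    @classmethod
    def from_paths(
        cls,
        table_paths: list[tuple],
        catalog_path,
        experiment_to_tf: dict[str, str] | None = None,
        **reader_kwargs,
    ) -> "SignatureQbic":
        """Build from (prediction_path, pvalue_path) pairs and a catalog file."""
        tables = [read_qbic_table(p, q, **reader_kwargs) for p, q in table_paths]
        return cls(tables, read_signature_catalog(catalog_path), experiment_to_tf)

    def fit(
        self,
        fdr: float = 0.1,
        alpha: float = 0.05,
        n_resamples: int = 1_000,
        n_mutations: int = 10_000,
        seed: int | None = None,
    ) -> "SignatureQbicResults":
        """Evaluate GR/LR and resampling significance for every pair.

        Each (experiment, signature) pair gets its own child seed spawned
        deterministically from ``seed``, so results are reproducible and
        independent of evaluation order.
        """
        results = []
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(self.tables) * len(self.signatures))
        k = 0
        for table in self.tables:
            for sig in self.signatures:
                child_seed = int(children[k].generate_state(1)[0] % (2**31))
                k += 1
                results.append(
                    core.evaluate_pair(
                        table, sig, fdr=fdr, n_mutations=n_mutations,
                        n_resamples=n_resamples, seed=child_seed,
                    )
                )
        return SignatureQbicResults(self, core.results_frame(results), fdr, alpha, seed)


class SignatureQbicResults:
    """Fitted gain/loss ratios with significance, aggregation and clustering."""

    def __init__(self, model: SignatureQbic, long: pd.DataFrame, fdr, alpha, seed):
        self.model = model
        self.long = long
        self.fdr = fdr
        self.alpha = alpha
        self.seed = seed
        self.per_tf = core.aggregate_tf(long, model.experiment_to_tf)

    @property
    def gr_matrix(self) -> pd.DataFrame:
        """Per-TF median GR, TFs x signatures."""
        return self.per_tf.pivot(index="tf", columns="signature", values="GR")

    @property
    def lr_matrix(self) -> pd.DataFrame:
        return self.per_tf.pivot(index="tf", columns="signature", values="LR")

    def gain_loss_sets(self, alpha: float | None = None):
        """(gain, loss) sets of (tf, signature) pairs at level alpha."""
        return core.classify_gain_loss(self.per_tf, self.alpha if alpha is None else alpha)

    def cluster(self) -> core.ClusterResult:
        """Complete-linkage Euclidean clustering of [GR | LR] per-TF matrices."""
        combined = pd.concat(
            [self.gr_matrix.add_suffix(":GR"), self.lr_matrix.add_suffix(":LR")], axis=1
        )
        return core.cluster_gr_lr_matrix(combined.T)

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        gain, loss = self.gain_loss_sets()
        lines = [
            "Signature x binding-change fit",
            "=" * 46,
            f"experiments: {len(self.model.tables):>6}",
            f"signatures:  {len(self.model.signatures):>6}",
            f"FDR for tails: {self.fdr:g}   alpha: {self.alpha:g}   seed: {self.seed}",
            f"pairs evaluated: {len(self.long)}  (undefined: {int(self.long['GR'].isna().sum())})",
            f"gain-of-binding pairs: {len(gain)}   loss-of-binding pairs: {len(loss)}",
            "",
            "Per-TF median gain/loss ratios:",
            self.per_tf.to_string(
                index=False, float_format=lambda v: f"{v:.4g}", max_rows=40
            ),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write long results, GR/LR matrices and cluster orderings as TSV/Newick."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["long"] = outdir / "gr_lr_long.tsv"
        self.long.to_csv(paths["long"], sep="\t", index=False, float_format="%.10g")
        paths["gr"] = outdir / "gr_matrix.tsv"
        self.gr_matrix.to_csv(paths["gr"], sep="\t", float_format="%.10g")
        paths["lr"] = outdir / "lr_matrix.tsv"
        self.lr_matrix.to_csv(paths["lr"], sep="\t", float_format="%.10g")
        if min(self.gr_matrix.shape) >= 1 and len(self.per_tf):
            cl = self.cluster()
            paths["cluster"] = outdir / "cluster_orders.tsv"
            pd.DataFrame(
                {
                    "axis": ["row"] * len(cl.row_order) + ["col"] * len(cl.col_order),
                    "label": cl.row_order + cl.col_order,
                }
            ).to_csv(paths["cluster"], sep="\t", index=False)
            for which, nwk in (("rows", cl.row_newick), ("cols", cl.col_newick)):
                if nwk is not None:
                    p = outdir / f"dendrogram_{which}.nwk"
                    p.write_text(nwk + "\n")
                    paths[f"newick_{which}"] = p
        gain, loss = self.gain_loss_sets()
        paths["classification"] = outdir / "gain_loss_pairs.json"
        paths["classification"].write_text(
            json.dumps(
                {"gain": sorted(map(list, gain)), "loss": sorted(map(list, loss))}, indent=2
            )
        )
        return paths
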