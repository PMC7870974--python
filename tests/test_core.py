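"""Oracle and property tests for the weighted-tail statistic."""

import numpy as np
import pandas as pd
import pytest

from sigqbic import core
from sigqbic import mutation_model as mm
from sigqbic.qbic_table import QbicTable
from sigqbic.signature_io import Signature, uniform_signature
from sigqbic.synthetic import synth_signature


# ---------------------------------------------------------------------------
# Independent oracles (deliberately scalar / per-change)


def bh_reject_by_hand(pvalues, alpha):
    """Step-up Benjamini-Hochberg on a flat list, straight from the definition."""
    p = sorted((v, i) for i, v in enumerate(pvalues))
    m = len(p)
    k_star = 0
    for k, (v, _) in enumerate(p, start=1):
        if v <= k * alpha / m:
            k_star = k
    reject = [False] * m
    for v, i in p[:k_star]:
        reject[i] = True
    return reject


def gr_lr_by_hand(table, sig, fdr=0.1):
    """GR/LR by looping over every individual change of the table."""
    entries = []  # (class index, score, p)
    for mc in mm.CLASSES:
        dist = table.class_distribution(mc)
        for s, p in zip(dist.scores, dist.pvalues):
            entries.append((mc.index, float(s), float(p)))
    reject = bh_reject_by_hand([e[2] for e in entries], fdr)
    passing = [e for e, r in zip(entries, reject) if r]
    assert passing, "oracle expects a non-empty significant set"
    T = min(abs(s) for _, s, _ in passing)
    n_per = table.n_per_class
    n_tot = table.n_changes
    base_pos = base_neg = w_pos = w_neg = 0.0
    for ci, s, _ in entries:
        if s >= T:
            base_pos += 1 / n_tot
            w_pos += sig.probs[ci] / n_per
        elif s <= -T:
            base_neg += 1 / n_tot
            w_neg += sig.probs[ci] / n_per
    return w_pos / base_pos, w_neg / base_neg, T


# ---------------------------------------------------------------------------


class TestUniformIdentity:
    def test_gr_and_lr_are_exactly_one_for_any_table(self, taat_table, gccg_table, tiny_table):
        for table in (taat_table, gccg_table, tiny_table):
            res = core.gain_loss_ratios(table, uniform_signature())
            assert res.gr == 1.0
            assert res.lr == 1.0

    def test_weighted_distribution_masses(self, tiny_table, random_sig):
        dist = core.weighted_distribution(tiny_table, random_sig)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-9)
        per_change = dist.mass_per_change()
        mc = mm.MutationClass.from_label("TCA>TTA")
        assert per_change[mc.index] == pytest.approx(
            random_sig["TCA>TTA"] / tiny_table.n_per_class
        )
        uni = core.weighted_distribution(tiny_table, uniform_signature())
        np.testing.assert_allclose(
            uni.mass_per_change(), np.full(96, 1.0 / tiny_table.n_changes), rtol=0, atol=1e-18
        )


class TestConvexity:
    def test_gr_is_linear_in_signature_mixtures(self, taat_table):
        rng = np.random.default_rng(2024)
        s1 = Signature("s1", rng.dirichlet(np.full(96, 1.0)))
        s2 = Signature("s2", rng.dirichlet(np.full(96, 1.0)))
        g1 = core.gain_loss_ratios(taat_table, s1)
        g2 = core.gain_loss_ratios(taat_table, s2)
        for lam in (0.0, 0.25, 0.5, 0.9, 1.0):
            mix = Signature("mix", lam * s1.probs + (1 - lam) * s2.probs)
            gm = core.gain_loss_ratios(taat_table, mix)
            assert gm.gr == pytest.approx(lam * g1.gr + (1 - lam) * g2.gr, abs=1e-9)
            assert gm.lr == pytest.approx(lam * g1.lr + (1 - lam) * g2.lr, abs=1e-9)


class TestOracleEquivalence:
    def test_vectorized_gr_lr_matches_per_change_summation(self, tiny_table, random_sig):
        gr_o, lr_o, T_o = gr_lr_by_hand(tiny_table, random_sig)
        res = core.gain_loss_ratios(tiny_table, random_sig)
        assert res.threshold == pytest.approx(T_o, abs=0)
        assert res.gr == pytest.approx(gr_o, abs=1e-12)
        assert res.lr == pytest.approx(lr_o, abs=1e-12)

    def test_point_mass_signature_against_oracle(self, tiny_table):
        probs = np.zeros(96)
        probs[mm.MutationClass.from_label("TCA>TTA").index] = 1.0
        point = Signature("point", probs)
        gr_o, lr_o, _ = gr_lr_by_hand(tiny_table, point)
        res = core.gain_loss_ratios(tiny_table, point)
        assert res.gr == pytest.approx(gr_o, abs=1e-12)
        assert res.lr == pytest.approx(lr_o, abs=1e-12)


class TestFdrThreshold:
    def test_bh_helper_matches_hand_application_on_ten_pvalues(self):
        pvalues = [0.001, 0.001, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        mask = core.bh_mask(np.array(pvalues), 0.1)
        assert mask.tolist() == bh_reject_by_hand(pvalues, 0.1)
        assert mask.sum() == 2  # only the two smallest pass at FDR 0.1

    def test_threshold_is_min_passing_score_magnitude(self):
        # flank-0 table: one change per class, hand-settable values
        scores = np.linspace(-3, 3, 96).reshape(96, 1)
        pvalues = np.full((96, 1), 0.8)
        pvalues[np.abs(scores) > 2.5] = 1e-4
        table = QbicTable("toy", "toy", scores, pvalues, flank=0)
        by_hand = bh_reject_by_hand(table.pvalues.ravel().tolist(), 0.1)
        expected_T = min(abs(s) for s, r in zip(table.scores.ravel(), by_hand) if r)
        assert core.fdr_threshold(table, 0.1) == pytest.approx(expected_T)

    def test_lowering_fdr_never_lowers_threshold(self, taat_table):
        t_strict = core.fdr_threshold(taat_table, 0.01)
        t_loose = core.fdr_threshold(taat_table, 0.1)
        assert t_strict >= t_loose

    def test_all_pvalues_one_is_a_no_tail_condition(self):
        scores = np.linspace(-3, 3, 96).reshape(96, 1)
        table = QbicTable("flat", "flat", scores, np.ones((96, 1)), flank=0)
        with pytest.raises(core.NoSignificantTailError):
            core.fdr_threshold(table)
        res = core.gain_loss_ratios(table, uniform_signature())
        assert not res.defined
        assert np.isnan(res.gr) and np.isnan(res.lr)


class TestTailAreas:
    def test_uniform_area_is_the_tail_fraction(self):
        # 96 x 16 toy: exactly 100 of 1536 changes at score 5, rest at 0.1
        rng = np.random.default_rng(1)
        scores = np.full((96, 16), 0.1)
        flat = scores.ravel()
        flat[rng.choice(flat.size, 100, replace=False)] = 5.0
        scores = flat.reshape(96, 16)
        table = QbicTable("cnt", "cnt", scores, np.full((96, 16), 0.9), flank=1)
        dist = core.weighted_distribution(table, uniform_signature())
        areas = core.tail_areas(dist, table, T=2.0)
        assert areas.area_pos == pytest.approx(100 / 1536)
        assert areas.area_neg == 0.0

    def test_signature_with_no_mass_on_tail_classes_has_zero_area(self, tiny_table):
        T = core.fdr_threshold(tiny_table)
        pos_classes = np.flatnonzero((tiny_table.scores >= T).any(axis=1))
        probs = np.zeros(96)
        off = [i for i in range(96) if i not in set(pos_classes)]
        probs[off] = 1 / len(off)
        sig = Signature("offtail", probs)
        areas = core.tail_areas(core.weighted_distribution(tiny_table, sig), tiny_table, T)
        assert areas.area_pos == 0.0

    def test_provenance_mismatch_rejected(self, tiny_table, taat_table):
        dist = core.weighted_distribution(taat_table, uniform_signature())
        with pytest.raises(ValueError, match="provenance"):
            core.tail_areas(dist, tiny_table, 1.0)


class TestResampling:
    def test_uniform_signature_is_null_centred(self, taat_table):
        p_gain, p_loss = core.resample_significance(
            taat_table, uniform_signature(), n_mutations=1000, n_reps=400, seed=1
        )
        assert p_gain > 0.2 and p_loss > 0.2

    def test_point_mass_on_top_tail_class_is_maximally_significant(self, taat_table):
        T = core.fdr_threshold(taat_table)
        pos, _ = core._tail_counts(taat_table, T)
        probs = np.zeros(96)
        probs[int(pos.argmax())] = 1.0
        point = Signature("top", probs)
        n_reps = 499
        p_gain, _ = core.resample_significance(
            taat_table, point, n_mutations=10_000, n_reps=n_reps, seed=2
        )
        assert p_gain == pytest.approx(1 / (n_reps + 1))

    def test_seeded_determinism_and_seed_sensitivity(self, taat_table, ctot_sig):
        a = core.resample_significance(taat_table, ctot_sig, 1000, 300, seed=5)
        b = core.resample_significance(taat_table, ctot_sig, 1000, 300, seed=5)
        c = core.resample_significance(taat_table, ctot_sig, 1000, 300, seed=6)
        assert a == b
        assert abs(a[0] - c[0]) <= 2 / np.sqrt(300)


class TestAggregation:
    def test_median_over_experiments(self):
        df = pd.DataFrame(
            {
                "tf": ["X"] * 3 + ["Y"] * 2 + ["Z"],
                "experiment": [f"e{i}" for i in range(6)],
                "signature": ["s"] * 6,
                "GR": [1.0, 2.0, 4.0, 1.0, 3.0, 7.0],
                "LR": [0.5] * 6,
                "p_gain": [0.01] * 6,
                "p_loss": [1.0] * 6,
            }
        )
        agg = core.aggregate_tf(df).set_index("tf")
        assert agg.loc["X", "GR"] == 2.0  # odd count: middle value
        assert agg.loc["Y", "GR"] == 2.0  # even count: mean of middle two
        assert agg.loc["Z", "GR"] == 7.0  # single experiment: identity

    def test_unmapped_experiment_is_an_error(self):
        df = pd.DataFrame(
            {"tf": ["?"], "experiment": ["e0"], "signature": ["s"], "GR": [1.0],
             "LR": [1.0], "p_gain": [0.5], "p_loss": [0.5]}
        )
        with pytest.raises(ValueError, match="no TF mapping"):
            core.aggregate_tf(df, experiment_to_tf={"other": "X"})


class TestClassification:
    def test_all_pvalues_one_gives_empty_sets(self):
        df = pd.DataFrame(
            {"tf": ["A", "B"], "signature": ["s", "s"], "GR": [2.0, 0.5],
             "LR": [0.5, 2.0], "p_gain": [1.0, 1.0], "p_loss": [1.0, 1.0]}
        )
        gain, loss = core.classify_gain_loss(df)
        assert gain == set() and loss == set()

    def test_significant_pairs_split_by_side(self):
        df = pd.DataFrame(
            {"tf": ["A", "B"], "signature": ["s", "s"], "GR": [2.0, 0.5],
             "LR": [0.5, 2.0], "p_gain": [0.002, 0.9], "p_loss": [0.9, 0.002]}
        )
        gain, loss = core.classify_gain_loss(df, alpha=0.05)
        assert gain == {("A", "s")} and loss == {("B", "s")}


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        mat = pd.DataFrame(np.ones((4, 3)), index=list("abcd"), columns=list("xyz"))
        cl = core.cluster_gr_lr_matrix(mat)
        assert cl.row_linkage[:, 2].max() == 0.0
        assert sorted(cl.row_order) == list("abcd")

    def test_two_separated_blocks_stay_contiguous(self):
        rng = np.random.default_rng(0)
        block_a = rng.normal(0, 0.01, (3, 4))
        block_b = rng.normal(10, 0.01, (3, 4))
        mat = pd.DataFrame(np.vstack([block_a, block_b]), index=list("abcdef"))
        order = core.cluster_gr_lr_matrix(mat).row_order
        pos = {lab: i for i, lab in enumerate(order)}
        assert max(pos[l] for l in "abc") < min(pos[l] for l in "def") or max(
            pos[l] for l in "def"
        ) < min(pos[l] for l in "abc")

    def test_four_point_dendrogram_matches_hand_computation(self):
        # 1-d points 0, 1, 10, 12: complete linkage merges (0,1) at 1, (10,12)
        # at 2, then everything at max distance 12
        mat = pd.DataFrame({"v": [0.0, 1.0, 10.0, 12.0]}, index=list("abcd"))
        cl = core.cluster_gr_lr_matrix(mat)
        heights = sorted(cl.row_linkage[:, 2])
        assert heights == [1.0, 2.0, 12.0]

    def test_missing_entries_imputed_as_one(self, caplog):
        mat = pd.DataFrame([[1.0, np.nan], [1.0, 1.0], [5.0, 5.0]], index=list("abc"))
        with caplog.at_level("WARNING"):
            cl = core.cluster_gr_lr_matrix(mat)
        assert "imputing" in caplog.text
        # with nan -> 1, rows a and b are identical
        assert cl.row_linkage[0, 2] == 0.0

    def test_single_row_degenerates_to_identity(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["only"])
        cl = core.cluster_gr_lr_matrix(mat)
        assert cl.row_order == ["only"] and cl.row_linkage is None

    def test_newick_output_parses_with_the_right_leaves(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        mat = pd.DataFrame(np.random.default_rng(3).normal(size=(5, 3)), index=list("abcde"))
        cl = core.cluster_gr_lr_matrix(mat)
        tree = Phylo.read(StringIO(cl.row_newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")
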