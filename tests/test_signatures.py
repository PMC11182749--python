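"""DE, signature definition and rank-based scoring vs direct oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grnrewire import (
    SignatureDefinition,
    define_signature_from_de,
    rank_signature_score,
    regulator_signature,
    wilcoxon_de,
)

from conftest import make_grn
from test_grn import make_adata


def two_group_adata(xa: np.ndarray, xb: np.ndarray, genes=None):
    lognorm = np.vstack([xa, xb])
    genes = genes or [f"g{i}" for i in range(lognorm.shape[1])]
    return make_adata(lognorm, genes, states=["A"] * len(xa) + ["B"] * len(xb))


class TestWilcoxonDE:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        block = rng.uniform(0, 2, size=(5, 10))
        adata = two_group_adata(block, block)
        de = wilcoxon_de(adata, "A", "B")
        assert np.allclose(de["logFC"], 0.0)
        assert (de["pvalue"] == 1.0).all()

    def test_swapping_groups_negates_logfc(self):
        rng = np.random.default_rng(1)
        adata = two_group_adata(
            rng.uniform(0, 2, (20, 8)), rng.uniform(1, 3, (20, 8))
        )
        ab = wilcoxon_de(adata, "A", "B")
        ba = wilcoxon_de(adata, "B", "A")
        assert np.allclose(ab["logFC"], -ba["logFC"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_p_matches_exact_enumeration_n4(self):
        rng = np.random.default_rng(2)
        xa = rng.uniform(0, 1, size=(4, 3))
        xb = rng.uniform(0.2, 1.2, size=(4, 3))
        de = wilcoxon_de(two_group_adata(xa, xb), "A", "B")
        for j, gene in enumerate(de.index):
            pooled = np.concatenate([xa[:, j], xb[:, j]])
            assert len(np.unique(pooled)) == 8  # no ties
            ranks = stats.rankdata(pooled)
            u_obs = ranks[:4].sum() - 4 * 5 / 2
            count = 0
            total = 0
            for combo in itertools.combinations(range(8), 4):
                u = ranks[list(combo)].sum() - 4 * 5 / 2
                total += 1
                if min(u, 16 - u) <= min(u_obs, 16 - u_obs):
                    count += 1
            assert de.loc[gene, "pvalue"] == pytest.approx(count / total, abs=1e-12)

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(3)
        adata = two_group_adata(
            rng.uniform(0, 1, (10, 6)), rng.uniform(0, 1, (10, 6))
        )
        de = wilcoxon_de(adata, "A", "B")
        assert np.allclose(de["padj"], np.minimum(de["pvalue"] * 6, 1.0))

    def test_planted_twofold_shift_detected(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 2, size=(200, 50))
        shifted = base.copy()
        shifted[100:, 0] += 1.0  # 2-fold on the log scale convention
        adata = make_adata(
            shifted, [f"g{i}" for i in range(50)],
            states=["B"] * 100 + ["A"] * 100,
        )
        de = wilcoxon_de(adata, "A", "B")
        assert de.iloc[0]["padj"] < 0.05 and de.iloc[0]["logFC"] > 0.5
        assert (de.iloc[1:]["padj"] > 0.05).all()

    def test_small_group_raises(self):
        adata = two_group_adata(np.ones((2, 3)), np.ones((5, 3)))
        with pytest.raises(ValueError, match=">= 3 cells"):
            wilcoxon_de(adata, "A", "B")


class TestDefineSignature:
    de = pd.DataFrame(
        {
            "logFC": [1.0, 0.6, 0.4, -0.8, 0.9],
            "padj": [0.01, 0.2, 0.01, 0.01, 0.04],
        },
        index=[f"g{i}" for i in range(5)],
    )

    def test_hand_table(self):
        sig = define_signature_from_de(self.de)
        assert set(sig.genes) == {"g0", "g4"}

    def test_down_direction(self):
        sig = define_signature_from_de(self.de, direction="down")
        assert set(sig.genes) == {"g3"}

    def test_empty_pass_set_raises(self):
        with pytest.raises(ValueError, match="review thresholds"):
            define_signature_from_de(self.de, logfc_min=5.0)

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(5)
        de = pd.DataFrame(
            {"logFC": rng.normal(0.6, 0.5, 200), "padj": rng.uniform(0, 0.2, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        tight = set(define_signature_from_de(de, logfc_min=0.5, padj_max=0.03).genes)
        loose_fc = set(define_signature_from_de(de, logfc_min=0.2, padj_max=0.03).genes)
        loose_p = set(define_signature_from_de(de, logfc_min=0.5, padj_max=0.1).genes)
        assert tight <= loose_fc and tight <= loose_p

    def test_empty_definition_rejected(self):
        with pytest.raises(ValueError):
            SignatureDefinition("empty", ())


class TestRegulatorSignature:
    def scores(self):
        rows = []
        for i in range(6):
            rows.append((f"T{i}", "KO", float(i), float(-5 + i)))
            rows.append((f"T{i}", "OE", float(10 - i), float(-i)))
        return pd.DataFrame(
            rows, columns=["tf", "mode", "sum_positive", "sum_negative"]
        )

    def test_top1_with_two_strong_targets(self):
        grn = make_grn([("T0", "g1", 0.5), ("T0", "g2", -0.4), ("T0", "g3", 0.05)])
        sig = regulator_signature(self.scores(), grn, top_n=1)
        assert set(sig.genes) == {"T0", "g1", "g2"}

    def test_connectivity_floor_keeps_tfs_only(self):
        grn = make_grn([("T0", "g1", 0.05)])
        sig = regulator_signature(self.scores(), grn, top_n=2)
        assert set(sig.genes) == {"T0", "T1"}

    def test_matches_sort_filter_union_oracle(self):
        rng = np.random.default_rng(6)
        tfs = [f"T{i}" for i in range(12)]
        rows = []
        for tf in tfs:
            for mode in ("KO", "OE"):
                rows.append((tf, mode, rng.uniform(0, 5), -rng.uniform(0, 5)))
        scores = pd.DataFrame(
            rows, columns=["tf", "mode", "sum_positive", "sum_negative"]
        )
        edges = [
            (rng.choice(tfs), f"g{i}", float(rng.normal()))
            for i in range(60)
        ]
        grn = make_grn(edges)
        for polarity in ("positive", "negative"):
            sig = regulator_signature(scores, grn, polarity=polarity, top_n=4)
            oe = scores[scores["mode"] == "OE"].set_index("tf")
            ko = scores[scores["mode"] == "KO"].set_index("tf")
            if polarity == "positive":
                rank = np.maximum(oe["sum_positive"], -ko["sum_negative"])
            else:
                rank = np.maximum(-oe["sum_negative"], ko["sum_positive"])
            top = set(rank.sort_values(ascending=False).head(4).index)
            targets = {
                t for r, t, c in edges if r in top and abs(c) > 0.1
            }
            assert set(sig.genes) == top | targets

    def test_bad_polarity_raises(self):
        with pytest.raises(ValueError):
            regulator_signature(self.scores(), make_grn([("T0", "g", 1.0)]),
                                polarity="sideways")


class TestRankSignatureScore:
    def test_top_ranked_genes_score_one(self):
        lognorm = np.tile(np.arange(20, 0, -1, dtype=float), (5, 1))
        adata = make_adata(lognorm, [f"g{i}" for i in range(20)])
        sig = SignatureDefinition("s", ("g0", "g1", "g2"))
        score = rank_signature_score(adata, sig, r_max=10)
        assert np.allclose(score, 1.0)

    def test_hand_computation_capped_ranks(self):
        # 10 genes; both signature genes ranked beyond r_max=5 -> capped at 6
        # U' = (6 + 6) - 2*3/2 = 9, score = 1 - 9 / (2*5) = 0.1
        lognorm = np.arange(10, 0, -1, dtype=float)[None, :]
        adata = make_adata(lognorm, [f"g{i}" for i in range(10)])
        sig = SignatureDefinition("s", ("g8", "g9"))
        score = rank_signature_score(adata, sig, r_max=5)
        assert score.iloc[0] == pytest.approx(0.1)

    def test_matches_direct_capped_mwu_oracle(self):
        rng = np.random.default_rng(7)
        lognorm = rng.uniform(0, 5, size=(30, 200))
        genes = [f"g{i}" for i in range(200)]
        adata = make_adata(lognorm, genes)
        sig_genes = tuple(rng.choice(genes, size=12, replace=False))
        r_max = 50
        got = rank_signature_score(adata, SignatureDefinition("s", sig_genes), r_max)
        cols = [genes.index(g) for g in sorted(set(sig_genes))]
        for c in range(30):
            ranks = stats.rankdata(-lognorm[c])
            capped = np.minimum(ranks[cols], r_max + 1)
            n = len(cols)
            u = capped.sum() - n * (n + 1) / 2
            want = min(max(1 - u / (n * r_max), 0.0), 1.0)
            assert got.iloc[c] == pytest.approx(want)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        lognorm = rng.uniform(0, 3, size=(10, 80))
        genes = [f"g{i}" for i in range(80)]
        sig = SignatureDefinition("s", tuple(genes[:7]))
        a = rank_signature_score(make_adata(lognorm, genes), sig, r_max=40)
        b = rank_signature_score(
            make_adata(np.exp(lognorm) * 3 + 1, genes), sig, r_max=40
        )
        assert np.allclose(a, b)

    def test_degrading_a_signature_gene_never_raises_score(self):
        rng = np.random.default_rng(9)
        lognorm = rng.uniform(1, 3, size=(8, 60))
        genes = [f"g{i}" for i in range(60)]
        sig = SignatureDefinition("s", tuple(genes[:5]))
        before = rank_signature_score(make_adata(lognorm, genes), sig, r_max=30)
        worse = lognorm.copy()
        worse[:, 0] = 0.0
        after = rank_signature_score(make_adata(worse, genes), sig, r_max=30)
        assert (after <= before + 1e-12).all()

    def test_validation(self):
        lognorm = np.ones((5, 10))
        adata = make_adata(lognorm, [f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="r_max"):
            rank_signature_score(adata, SignatureDefinition("s", ("g0",)), r_max=10)
        with pytest.raises(ValueError, match="no gene"):
            rank_signature_score(adata, SignatureDefinition("s", ("zz",)), r_max=5)
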