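"""Anchored co-dependency screen and candidate funnel."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codepnet import (
    DependencyTruth,
    MatrixTable,
    ValidationError,
    candidate_filter,
    codependency_concordance,
    gen_dependency_matrix,
    gen_scn_annotation,
    pearson_with_p,
    screen,
    spearman_with_p,
)


class TestCorrelationPrimitives:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 5.0]
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_oracle(self):
        """Centered cross-product 4 over sqrt(5*5) = 0.8; ranks equal values
        here so Spearman agrees."""
        r, p, n = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12) and n == 4
        rho, _, _ = spearman_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_spearman_rank_invariance(self):
        rho, _, _ = spearman_with_p([1, 2, 3], [10, 100, 1000])
        r, _, _ = pearson_with_p([1, 2, 3], [10, 100, 1000])
        assert rho == pytest.approx(1.0) and r < 1.0

    def test_matches_scipy_with_missing(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            x[rng.random(n) < 0.15] = np.nan
            mask = np.isfinite(x)
            if mask.sum() < 4:
                continue
            r, p, m = pearson_with_p(x, y)
            rr, pp = stats.pearsonr(x[mask], y[mask])
            assert r == pytest.approx(rr, abs=1e-12)
            assert p == pytest.approx(pp, abs=1e-12)
            assert m == mask.sum()

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError):
            pearson_with_p([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            spearman_with_p([2, 2, 2], [1, 2, 3])


def _planted_screen_matrix(seed: int = 11):
    """46-line HI screen with 5 genes planted at rho 0.9 among 500."""
    ann = gen_scn_annotation(46, 10, 2.0, 0.0, 0.2, seed=seed)
    genes = ["ANCHOR"] + [f"P{i}" for i in range(5)] + [f"G{i:03d}" for i in range(494)]
    truth = DependencyTruth.build(
        genes, "ANCHOR", rho_hi={f"P{i}": 0.9 for i in range(5)})
    dep = gen_dependency_matrix(truth, ann, seed=seed)
    hi_lines = list(ann.table.index[ann.table["truth_group"] == "HI"])
    return dep, hi_lines


class TestScreen:
    def test_planted_genes_rank_top(self):
        dep, hi_lines = _planted_screen_matrix()
        tab = screen(dep, "ANCHOR", hi_lines)
        ranks = tab.loc[[f"P{i}" for i in range(5)], "rank_positive"]
        assert (ranks <= 10).all()

    def test_anchor_excluded_from_output(self):
        dep, hi_lines = _planted_screen_matrix()
        tab = screen(dep, "ANCHOR", hi_lines)
        assert "ANCHOR" not in tab.index

    def test_all_constant_genes_logged(self):
        df = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1], [2, 2, 2, 2]],
            index=pd.Index(["ANCHOR", "C1", "C2"], name="gene"),
            columns=list("abcd"), dtype=float)
        tab = screen(MatrixTable(df), "ANCHOR", list("abcd"), min_n=3)
        assert tab.empty
        assert tab.attrs["excluded"] == {"C1": "undefined_correlation",
                                         "C2": "undefined_correlation"}

    def test_permutation_equivariance(self):
        dep, hi_lines = _planted_screen_matrix()
        tab1 = screen(dep, "ANCHOR", hi_lines)
        shuffled = list(np.random.default_rng(5).permutation(hi_lines))
        tab2 = screen(dep, "ANCHOR", shuffled)
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_min_n_exclusion(self):
        dep, hi_lines = _planted_screen_matrix()
        sparse = dep.data.copy()
        sparse.loc["G000", hi_lines[:40]] = np.nan  # leaves 6 < min_n pairs
        tab = screen(MatrixTable(sparse), "ANCHOR", hi_lines, min_n=10)
        assert "G000" not in tab.index
        assert tab.attrs["excluded"]["G000"] == "n_below_min"

    def test_anchor_absent(self):
        dep, hi_lines = _planted_screen_matrix()
        with pytest.raises(ValidationError):
            screen(dep, "NOT_A_GENE", hi_lines)

    def test_power_at_moderate_effect(self):
        """Planted rho 0.412 at n=46 is detected at alpha 0.05 in > 75% of
        replicates (the screen's working regime)."""
        ann = gen_scn_annotation(46, 5, 2.0, 0.0, 0.2, seed=0)
        genes = ["ANCHOR"] + [f"G{i:03d}" for i in range(120)]
        truth = DependencyTruth.build(
            genes, "ANCHOR", rho_hi={f"G{i:03d}": 0.412 for i in range(120)})
        dep = gen_dependency_matrix(truth, ann, seed=20)
        hi = list(ann.table.index[ann.table["truth_group"] == "HI"])
        tab = screen(dep, "ANCHOR", hi)
        assert (tab["pearson_p"] < 0.05).mean() > 0.75


def _mock_codep_table(rows: dict) -> pd.DataFrame:
    """rows: gene -> (r, p, rank_or_None)."""
    df = pd.DataFrame(
        {
            "pearson_r": {g: v[0] for g, v in rows.items()},
            "pearson_p": {g: v[1] for g, v in rows.items()},
        }
    ).rename_axis("gene")
    df["rank_positive"] = pd.array(
        [rows[g][2] for g in df.index], dtype="Int64")
    return df


class TestCandidateFilter:
    HI = _mock_codep_table({
        "TF1": (0.8, 1e-4, 1), "TF2": (0.7, 1e-3, 2), "TF3": (0.6, 1e-3, 3),
        "TF4": (0.5, 1e-2, 4), "TF5": (0.45, 2e-2, 5), "TF6": (0.4, 3e-2, 6),
        "TF7": (0.1, 0.5, None), "OTH": (0.9, 1e-5, 7),
    })
    LO = _mock_codep_table({
        "TF1": (0.4, 1e-3, 1), "TF2": (0.3, 1e-2, 2), "TF3": (0.35, 1e-2, 3),
        "TF4": (-0.1, 0.2, None), "TF5": (0.02, 0.8, None),
        "TF6": (-0.02, 0.9, None), "TF7": (0.0, 0.99, None),
        "OTH": (0.5, 1e-4, 4),
    })

    def test_six_minus_three_funnel(self):
        """6 TFs pass HI; 3 are significant-positive in LO -> 3 candidates."""
        report = candidate_filter(self.HI, self.LO,
                                  [f"TF{i}" for i in range(1, 7)], top_k=100)
        assert report.candidates == ("TF4", "TF5", "TF6")
        assert set(report.table.loc[["TF1", "TF2", "TF3"], "excluded_by"]) \
            == {"lo_codependency"}

    def test_disjoint_tf_list(self):
        report = candidate_filter(self.HI, self.LO, ["TF7"], top_k=100)
        assert report.candidates == ()
        assert report.table.at["TF7", "excluded_by"] == "significance"

    def test_rank_boundary(self):
        report = candidate_filter(self.HI, self.LO, ["TF6"], top_k=5)
        assert report.candidates == ()
        assert report.table.at["TF6", "excluded_by"] == "rank"

    def test_empty_tf_list_rejected(self):
        with pytest.raises(ValidationError):
            candidate_filter(self.HI, self.LO, [])

    def test_provenance_columns(self):
        report = candidate_filter(self.HI, self.LO, ["TF1", "TF4"], top_k=100)
        row = report.table.loc["TF4"]
        assert bool(row["selected"]) and row["r_hi"] == 0.5 and row["r_lo"] == -0.1


class TestConcordance:
    def test_identical_inputs_agree(self):
        r_a, r_b, agree = codependency_concordance(
            TestCandidateFilter.HI, TestCandidateFilter.HI, "TF1")
        assert agree and r_a == r_b

    def test_opposite_planted_signs(self):
        flipped = TestCandidateFilter.HI.copy()
        flipped["pearson_r"] = -flipped["pearson_r"]
        _, _, agree = codependency_concordance(TestCandidateFilter.HI, flipped, "TF1")
        assert not agree

    def test_simulated_rnai_vs_crispr_concordance(self):
        """Two independent screens planting rho 0.4 agree in sign in >= 95%
        of replicates."""
        ann = gen_scn_annotation(46, 5, 2.0, 0.0, 0.2, seed=5)
        genes = ["ANCHOR", "TGT"] + [f"G{i}" for i in range(30)]
        truth = DependencyTruth.build(genes, "ANCHOR", rho_hi={"TGT": 0.4})
        hi = list(ann.table.index[ann.table["truth_group"] == "HI"])
        agree = 0
        for rep in range(100):
            t1 = screen(gen_dependency_matrix(truth, ann, seed=1000 + rep),
                        "ANCHOR", hi)
            t2 = screen(gen_dependency_matrix(truth, ann, seed=5000 + rep),
                        "ANCHOR", hi)
            agree += codependency_concordance(t1, t2, "TGT")[2]
        assert agree >= 95

    def test_missing_gene(self):
        with pytest.raises(ValidationError):
            codependency_concordance(TestCandidateFilter.HI,
                                     TestCandidateFilter.LO, "NOPE")
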