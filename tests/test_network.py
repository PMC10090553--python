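"""Correlation gene networks, signatures, cross-state and differential ranking."""
import numpy as np
import pandas as pd
import pytest

from codepnet import (
    CohortBlockSpec,
    GeneNetwork,
    MatrixTable,
    ValidationError,
    annotate_extremes,
    build_network,
    correlation_matrix,
    cross_state_assessment,
    differential_profile,
    extract_signature,
    gen_cohort_expression,
)

from conftest import random_matrix


def _net(coeffs: dict, anchor: str = "ANCHOR", cohort: str = "A") -> GeneNetwork:
    coeffs = {anchor: 1.0, **coeffs}
    return GeneNetwork(cohort=cohort, anchor=anchor,
                       coefficients=pd.Series(coeffs, dtype=float))


class TestBuildNetwork:
    def test_anchor_self_correlation(self):
        m = random_matrix(10, 20, seed=1)
        net = build_network(m, "G0000")
        assert net.coefficients["G0000"] == 1.0

    def test_affine_copy_of_anchor(self):
        m = random_matrix(3, 15, seed=2)
        df = m.data.copy()
        df.loc["G0001"] = 2.5 * df.loc["G0000"] + 7.0
        net = build_network(MatrixTable(df), "G0000")
        assert net.coefficients["G0001"] == pytest.approx(1.0, abs=1e-12)

    def test_planted_block_recovery(self):
        genes = ["ANCHOR"] + [f"B{i}" for i in range(4)] + [f"S{i}" for i in range(20)]
        assignments = {g: ("blk" if g == "ANCHOR" or g.startswith("B") else g)
                       for g in genes}
        rho = {"blk": 0.9, **{g: 0.0 for g in genes if not (g == "ANCHOR" or g.startswith("B"))}}
        expr = gen_cohort_expression(CohortBlockSpec(assignments, rho), 1000, seed=3)
        net = build_network(expr, "ANCHOR")
        assert (net.coefficients[[f"B{i}" for i in range(4)]] > 0.8).all()

    def test_constant_anchor_rejected(self):
        df = random_matrix(4, 10, seed=4).data.copy()
        df.loc["G0000"] = 1.0
        with pytest.raises(ValidationError):
            build_network(MatrixTable(df), "G0000")

    def test_constant_gene_dropped_with_reason(self):
        df = random_matrix(4, 10, seed=5).data.copy()
        df.loc["G0003"] = -2.0
        net = build_network(MatrixTable(df), "G0000")
        assert "G0003" not in net.coefficients.index
        assert net.dropped == ("G0003",)

    def test_sample_permutation_invariance(self):
        m = random_matrix(15, 25, seed=6)
        net1 = build_network(m, "G0002")
        perm = list(np.random.default_rng(0).permutation(m.col_ids))
        net2 = build_network(m.subset_cols(perm), "G0002")
        pd.testing.assert_series_equal(net1.coefficients, net2.coefficients)

    def test_agrees_with_all_pairs_matrix(self):
        """Anchor-wise computation equals the corresponding row of the
        explicit (symmetric) all-pairs correlation matrix."""
        m = random_matrix(30, 12, seed=7, missing_rate=0.1)
        full = correlation_matrix(m)
        assert np.allclose(full.values, full.values.T, equal_nan=True)
        for anchor in ["G0000", "G0017"]:
            net = build_network(m, anchor)
            row = full.loc[anchor, net.coefficients.index.drop(anchor)]
            got = net.coefficients.drop(anchor)
            assert np.allclose(got.to_numpy(), row.to_numpy(), atol=1e-12)

    def test_spearman_method(self):
        m = random_matrix(5, 30, seed=8)
        df = m.data.copy()
        df.loc["G0001"] = np.exp(df.loc["G0000"])  # monotone, nonlinear
        net = build_network(MatrixTable(df), "G0000", method="spearman")
        assert net.coefficients["G0001"] == pytest.approx(1.0, abs=1e-12)


class TestSignature:
    def test_strict_boundary(self):
        net = _net({"G1": 0.71, "G2": 0.70, "G3": 0.69})
        sig = extract_signature([net], 0.7)
        assert sig.members == ("G1",)

    def test_two_anchor_intersection(self):
        n1 = _net({"G1": 0.9, "G2": 0.8}, anchor="A1")
        n2 = _net({"G1": 0.8, "G2": 0.6, "A1": 0.2}, anchor="A2")
        sig = extract_signature([n1, n2], 0.7)
        assert sig.members == ("G1",)

    def test_anchors_excluded_from_members(self):
        n1 = _net({"A2": 0.95, "G1": 0.9}, anchor="A1")
        n2 = _net({"A1": 0.95, "G1": 0.9}, anchor="A2")
        assert extract_signature([n1, n2], 0.7).members == ("G1",)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            coeffs = {f"G{i}": float(r) for i, r in
                      enumerate(rng.uniform(-1, 1, size=20))}
            net = _net(coeffs)
            tight = set(extract_signature([net], 0.9).members)
            loose = set(extract_signature([net], 0.7).members)
            assert tight <= loose

    def test_cutoff_range_checked(self):
        with pytest.raises(ValidationError):
            extract_signature([_net({"G1": 0.5})], 1.0)

    def test_mixed_cohorts_rejected(self):
        with pytest.raises(ValidationError):
            extract_signature([_net({"G1": 0.9}, cohort="A"),
                               _net({"G1": 0.9}, anchor="A2", cohort="B")], 0.7)


class TestCrossState:
    def test_identical_cohorts_fully_congruent(self):
        net = _net({"G1": 0.9, "G2": 0.8, "G3": 0.75})
        sig = extract_signature([net], 0.7)
        other = _net({"G1": 0.9, "G2": 0.8, "G3": 0.75}, cohort="B")
        out = cross_state_assessment(sig, [other])
        assert out.at["ANCHOR", "fraction_below"] == 0.0

    def test_enumeration(self):
        sig = extract_signature(
            [_net({"G1": 0.9, "G2": 0.85, "G3": 0.8, "G4": 0.75})], 0.7)
        other = _net({"G1": 0.8, "G2": 0.6, "G3": 0.5, "G4": 0.71}, cohort="B")
        out = cross_state_assessment(sig, [other])
        assert out.at["ANCHOR", "fraction_below"] == 0.5
        assert out.at["ANCHOR", "min"] == 0.5 and out.at["ANCHOR", "max"] == 0.8

    def test_disjoint_raises(self):
        sig = extract_signature([_net({"G1": 0.9})], 0.7)
        other = _net({"H1": 0.2}, cohort="B")
        with pytest.raises(ValidationError):
            cross_state_assessment(sig, [other])


class TestDifferentialProfile:
    def test_identity_gives_zero_deltas(self):
        net = _net({"G1": 0.5, "G2": -0.2})
        prof = differential_profile(net, _net({"G1": 0.5, "G2": -0.2}, cohort="B"))
        assert (prof.deltas == 0.0).all()

    def test_extreme_bound_ranks_first(self):
        b = _net({"G1": 0.9, "G2": 0.1}, cohort="B")
        a = _net({"G1": -0.9, "G2": 0.1}, cohort="A")
        prof = differential_profile(b, a)
        assert prof.deltas["G1"] == pytest.approx(1.8)
        assert prof.table.at["G1", "rank"] == 1

    def test_deltas_bounded(self):
        rng = np.random.default_rng(10)
        b = _net({f"G{i}": float(r) for i, r in enumerate(rng.uniform(-1, 1, 50))},
                 cohort="B")
        a = _net({f"G{i}": float(r) for i, r in enumerate(rng.uniform(-1, 1, 50))},
                 cohort="A")
        d = differential_profile(b, a).deltas
        assert d.between(-2, 2).all()

    def test_anchor_mismatch(self):
        with pytest.raises(ValidationError):
            differential_profile(_net({"G1": 0.1}, anchor="X"),
                                 _net({"G1": 0.1}, anchor="Y"))

    def test_common_gene_restriction(self):
        b = _net({"G1": 0.5, "G2": 0.5}, cohort="B")
        a = _net({"G1": 0.0, "G3": 0.5}, cohort="A")
        prof = differential_profile(b, a)
        assert set(prof.table.index) == {"ANCHOR", "G1"}


class TestAnnotateExtremes:
    def _profile(self, deltas: dict):
        b = _net({g: 0.0 for g in deltas}, cohort="B")
        a = _net({g: -d for g, d in deltas.items()}, cohort="A")
        return differential_profile(b, a)

    def test_disjoint_set(self):
        prof = self._profile({f"G{i}": (10 - i) / 10 for i in range(10)})
        assert annotate_extremes(prof, ["ZZZ"], 3)[:2] == (0, 0)

    def test_enumeration(self):
        prof = self._profile({f"G{i}": (10 - i) / 10 for i in range(10)})
        c_top, c_bot, m_top, m_bot = annotate_extremes(prof, ["G0", "G9"], 3)
        assert (c_top, c_bot) == (1, 1)
        assert m_top == ("G0",) and m_bot == ("G9",)

    def test_top_n_too_large(self):
        prof = self._profile({f"G{i}": i / 10 for i in range(10)})
        with pytest.raises(ValidationError):
            annotate_extremes(prof, ["G0"], 8)

    def test_null_expectation_hypergeometric(self):
        """With random sets, the mean top-window count matches
        |set| * top_n / N within 3 SE."""
        from scipy.stats import hypergeom
        n_genes, set_size, top_n, n_draws = 80, 12, 20, 1000
        prof = self._profile({f"G{i:02d}": i / 100 for i in range(n_genes)})
        n_prof = prof.n_common  # includes the anchor
        rng = np.random.default_rng(13)
        genes = [g for g in prof.table.index]
        counts = [annotate_extremes(prof, rng.choice(genes, set_size, replace=False),
                                    top_n)[0] for _ in range(n_draws)]
        expected = set_size * top_n / n_prof
        se = np.sqrt(hypergeom(n_prof, set_size, top_n).var() / n_draws)
        assert np.mean(counts) == pytest.approx(expected, abs=3 * se)
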