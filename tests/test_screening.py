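"""Comprehensive-evaluation chain: coefficients, PCA, membership, weights, D."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ktscreen as kt
from ktscreen.screening import CLASS_LABELS


def _panel_from_values(rows):
    return pd.DataFrame(rows, columns=["genotype", "trait", "treatment", "replicate", "value"])


class TestSummarize:
    def test_constant_values_have_zero_cv(self):
        rows = [(f"g{i}", "SL", trt, 1, 10.0) for i in range(3) for trt in ("CK", "LK")]
        out = kt.summarize_traits(_panel_from_values(rows))
        row = out.query("trait == 'SL' and treatment == 'CK'").iloc[0]
        assert row["mean"] == 10.0 and row["sd"] == 0.0 and row["cv_pct"] == 0.0

    def test_two_values_sample_sd(self):
        rows = [("g1", "SL", "CK", 1, 8.0), ("g2", "SL", "CK", 1, 12.0),
                ("g1", "SL", "LK", 1, 8.0), ("g2", "SL", "LK", 1, 12.0)]
        out = kt.summarize_traits(_panel_from_values(rows))
        row = out.query("treatment == 'CK'").iloc[0]
        assert row["mean"] == pytest.approx(10.0)
        assert row["sd"] == pytest.approx(np.sqrt(8.0))  # n-1 denominator
        assert row["cv_pct"] == pytest.approx(28.2842712, abs=1e-6)

    def test_reported_sd_mean_pair_reproduces_reported_cv(self):
        # A two-genotype panel constructed to have mean 18.01 and SD 4.81,
        # the shoot-length control row of a published 543-genotype summary,
        # must reproduce its printed CV of 26.71%.
        mean, sd = 18.01, 4.81
        delta = sd / np.sqrt(2)
        rows = [("g1", "SL", t, 1, mean - delta) for t in ("CK", "LK")] + [
            ("g2", "SL", t, 1, mean + delta) for t in ("CK", "LK")
        ]
        out = kt.summarize_traits(_panel_from_values(rows))
        row = out.query("treatment == 'CK'").iloc[0]
        assert 100 * row["sd"] / row["mean"] == pytest.approx(26.71, abs=0.005)


class TestToleranceCoefficients:
    def test_equal_means_give_unit_coefficient(self):
        rows = [("g1", "T", trt, r, 5.0) for trt in ("CK", "LK") for r in (1, 2)]
        coeff = kt.tolerance_coefficients(_panel_from_values(rows))
        assert coeff.loc["g1", "T"] == pytest.approx(1.0)

    def test_population_pseudo_genotype_ratio(self):
        rows = [("pop", "SL", "CK", 1, 18.01), ("pop", "SL", "LK", 1, 14.89)]
        coeff = kt.tolerance_coefficients(_panel_from_values(rows))
        assert coeff.loc["pop", "SL"] == pytest.approx(14.89 / 18.01, abs=1e-9)

    def test_coefficient_above_one_allowed(self):
        # K-utilization-efficiency traits rise under stress (0.99 -> 2.61).
        rows = [("g", "SKUE", "CK", 1, 0.99), ("g", "SKUE", "LK", 1, 2.61)]
        coeff = kt.tolerance_coefficients(_panel_from_values(rows))
        assert coeff.loc["g", "SKUE"] == pytest.approx(2.61 / 0.99)

    def test_zero_ck_mean_names_genotype_and_trait(self):
        rows = [("gX", "T", "CK", 1, 0.0), ("gX", "T", "LK", 1, 1.0)]
        with pytest.raises(ValueError, match="gX.*T"):
            kt.tolerance_coefficients(_panel_from_values(rows))

    def test_missing_treatment_rejected(self):
        rows = [("g1", "T", "CK", 1, 1.0)]
        with pytest.raises(ValueError, match="missing LK"):
            kt.tolerance_coefficients(_panel_from_values(rows))


def _brute_force_pca(X):
    """Independent oracle: eigendecomposition of the correlation matrix.

    Only the declared sign convention is shared with the implementation;
    eigenvalues, loadings and scores are computed by a different route.
    """
    from ktscreen.screening import _sign_flip

    R = np.corrcoef(X, rowvar=False)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    for j in range(vec.shape[1]):
        if _sign_flip(vec[:, j]):
            vec[:, j] *= -1
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / sd
    scores = Z @ vec
    return eig, vec, scores


class TestComprehensivePca:
    def test_two_perfectly_correlated_traits(self, rng):
        x = rng.normal(1, 0.2, 30)
        coeff = pd.DataFrame({"a": x, "b": 2 * x})
        ev = kt.comprehensive_pca(coeff)
        assert ev.n_retained == 1
        assert ev.contributions[0] == pytest.approx(100.0)

    def test_independent_traits_split_contribution_evenly(self, rng):
        coeff = pd.DataFrame(rng.normal(1, 0.1, (5000, 4)), columns=list("abcd"))
        ev = kt.comprehensive_pca(coeff, retention_rule="fixed", n_components=4)
        assert np.allclose(ev.contributions_all, 25.0, atol=2.0)

    def test_matches_bruteforce_eigendecomposition(self, rng):
        X = rng.normal(0, 1, (50, 13))
        coeff = pd.DataFrame(X, columns=[f"t{j}" for j in range(13)])
        ev = kt.comprehensive_pca(coeff, retention_rule="fixed", n_components=13)
        eig, vec, scores = _brute_force_pca(X)
        assert np.allclose(ev.eigenvalues, eig, atol=1e-8)
        assert np.allclose(ev.scores.to_numpy(), scores, atol=1e-8)
        assert np.allclose(ev.loadings.to_numpy(), vec, atol=1e-8)

    def test_constant_column_rejected_by_name(self, rng):
        coeff = pd.DataFrame({"a": rng.normal(1, 0.1, 10), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            kt.comprehensive_pca(coeff)


class TestMembershipWeightsD:
    def test_min_maps_to_zero_and_max_to_one(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=20)})
        u = kt.membership(scores)
        assert u.loc[scores["PC1"].idxmin(), "PC1"] == 0.0
        assert u.loc[scores["PC1"].idxmax(), "PC1"] == 1.0

    def test_midpoint_maps_to_half(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0, 2.0]})
        assert kt.membership(scores)["PC1"].tolist() == [0.0, 0.5, 1.0]

    def test_affine_invariance(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=50)})
        shifted = scores * 3.7 - 11.0
        pd.testing.assert_frame_equal(kt.membership(scores), kt.membership(shifted))

    def test_degenerate_component_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kt.membership(pd.DataFrame({"PC1": [1.0, 1.0]}))

    def test_weights_from_reported_contribution_rates(self):
        pj = [24.21, 21.85, 17.27, 16.53, 9.83]
        w = kt.weights(pj)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, np.array(pj) / 89.69, atol=1e-12)
        assert np.round(w, 4).tolist() == [0.2699, 0.2436, 0.1926, 0.1843, 0.1096]

    def test_equal_contributions_equal_weights(self):
        assert np.allclose(kt.weights([5.0, 5.0, 5.0]), 1 / 3)

    def test_single_component_weight_is_one(self):
        assert kt.weights([42.0]).tolist() == [1.0]

    def test_nonpositive_contributions_rejected(self):
        with pytest.raises(ValueError):
            kt.weights([10.0, 0.0])

    def test_d_value_arithmetic_and_bounds(self):
        u = pd.DataFrame({"PC1": [0.2, 1.0, 0.0], "PC2": [0.4, 1.0, 0.0]})
        d = kt.d_value(u, np.array([0.5, 0.5]))
        assert d.tolist() == pytest.approx([0.3, 1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        u = pd.DataFrame({"PC1": [0.2]})
        with pytest.raises(ValueError, match="weights"):
            kt.d_value(u, np.array([0.5, 0.5]))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_d_value_dominance_monotonicity(self, seed):
        r = np.random.default_rng(seed)
        n, m = 8, 4
        u = r.uniform(size=(n, m))
        u_dom = np.clip(u + r.uniform(0, 0.3, size=(n, m)), 0, 1)
        w = kt.weights(r.uniform(0.1, 30, size=m))
        d_lo = kt.d_value(pd.DataFrame(u), w)
        d_hi = kt.d_value(pd.DataFrame(u_dom), w)
        assert (d_hi >= d_lo - 1e-12).all()


class TestClassify:
    def test_four_point_masses_recovered_exactly(self):
        d = pd.Series(
            np.repeat([0.9, 0.6, 0.35, 0.1], [5, 10, 12, 8]),
            index=[f"g{i}" for i in range(35)],
        )
        # jitter within groups far below separation so points are distinct
        d += np.linspace(0, 0.01, 35)
        cls = kt.classify(d)
        assert list(cls.class_counts.values()) == [5, 10, 12, 8]
        means = list(cls.class_mean_d.values())
        assert all(a > b for a, b in zip(means, means[1:]))
        assert tuple(cls.class_counts) == CLASS_LABELS

    def test_degenerate_equal_d_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kt.classify(pd.Series(np.ones(10)))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="classify"):
            kt.classify(pd.Series([0.1, 0.2]), k=4)

    def test_planted_tiers_recovered_on_panel(self):
        spec = kt.TraitGenSpec(
            n_genotypes=543, seed=5, tolerance_tiers=kt.DEFAULT_TIERS_543
        )
        panel, truth = kt.generate_trait_panel(spec)
        ev = kt.evaluate(kt.tolerance_coefficients(panel))
        cls = kt.classify(ev.d)
        tiers = pd.Series(truth.tier_labels).loc[ev.d.index]
        top = cls.labels[tiers == 0]
        assert (top == "tolerant").mean() >= 0.9


class TestSelectExtremes:
    def test_count_bound_at_543(self, rng):
        d = pd.Series(rng.uniform(size=543), index=[f"g{i}" for i in range(543)])
        sel = kt.select_extremes(d)
        assert len(sel.tolerant) <= int(np.ceil(543 * 0.01))
        assert len(sel.sensitive) <= int(np.ceil(543 * 0.01))

    def test_uniform_grid_upper_percentile_is_maximum(self):
        d = pd.Series(np.arange(1.0, 101.0), index=[f"g{i}" for i in range(100)])
        sel = kt.select_extremes(d, upper_pct=99.0)
        assert sel.tolerant == ("g99",)

    def test_lower_pct_zero_gives_empty_sensitive_set(self, rng):
        d = pd.Series(rng.uniform(size=150), index=[f"g{i}" for i in range(150)])
        sel = kt.select_extremes(d, lower_pct=0.0)
        assert sel.sensitive == ()

    def test_inverted_percentiles_rejected(self, rng):
        d = pd.Series(rng.uniform(size=120))
        with pytest.raises(ValueError):
            kt.select_extremes(d, upper_pct=1.0, lower_pct=99.0)


class TestConsensus:
    def test_intersection_across_stages(self):
        s1 = kt.SelectionResult(("A", "B"), ("X",), 0.9, 0.1)
        s2 = kt.SelectionResult(("B", "C"), ("Y",), 0.9, 0.1)
        out = kt.cross_stage_consensus({"seedling": s1, "mature": s2})
        tol = out["tolerant"]
        assert list(tol.index[tol["consensus"]]) == ["B"]
        sens = out["sensitive"]
        assert not sens["consensus"].any()

    def test_two_stage_tolerant_consensus_table(self):
        seedling = kt.SelectionResult(
            ("Kenong9204", "Henong6119", "Han6172", "Jimai38", "Heng7228"), (), 0.9, 0.1
        )
        mature = kt.SelectionResult(
            ("Kenong9204", "Henong6119", "Cangmai119", "Henong2552", "Henong9204"),
            (),
            0.9,
            0.1,
        )
        out = kt.cross_stage_consensus({"seedling": seedling, "mature": mature})
        consensus = set(out["tolerant"].index[out["tolerant"]["consensus"]])
        assert consensus == {"Kenong9204", "Henong6119"}

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            kt.cross_stage_consensus({"only": kt.SelectionResult((), (), 0, 0)})


def test_pipeline_permutation_invariance(small_panel):
    """Permuting genotype row order permutes D values identically."""
    panel, _ = small_panel
    ev = kt.evaluate(kt.tolerance_coefficients(panel))
    shuffled = panel.sample(frac=1.0, random_state=7).reset_index(drop=True)
    ev2 = kt.evaluate(kt.tolerance_coefficients(shuffled))
    pd.testing.assert_series_equal(
        ev.d.sort_index(), ev2.d.sort_index(), atol=1e-10, rtol=0
    )
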