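import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from famvar.cohort import CountMatrix
from famvar.expression import (
    DEConfig,
    bh_fdr,
    build_design,
    estimate_dispersion,
    filter_low_counts,
    fit_nb_de,
    integrate_expression,
    tmm_factors,
    _irls_nb,
)
from famvar.synthetic import SimConfig, simulate_counts


def matrix_from(counts, groups):
    samples = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame({"group": groups}, index=samples)
    return CountMatrix(
        pd.DataFrame(counts, columns=samples,
                     index=[f"g{i}" for i in range(counts.shape[0])]),
        meta,
    )


class TestCpmFilter:
    def _matrix(self, n_pass):
        # 20 samples of 1e6 library size; a gene at exactly 1 CPM in n_pass
        counts = np.full((2, 20), 50_000)
        gene = np.zeros(20, dtype=int)
        gene[:n_pass] = 1  # 1 count in a 1e6-ish library -> ~1 CPM
        counts = np.vstack([counts, gene])
        groups = ["aneurysm"] * 12 + ["control"] * 8
        return matrix_from(counts, groups)

    def test_boundary_inclusive_at_min_samples(self):
        m = self._matrix(n_pass=8)
        kept = filter_low_counts(m, DEConfig(min_samples=8))
        assert "g2" in kept.genes

    def test_below_min_samples_dropped(self):
        m = self._matrix(n_pass=7)
        kept = filter_low_counts(m, DEConfig(min_samples=8))
        assert "g2" not in kept.genes

    def test_min_samples_defaults_to_smallest_group(self):
        m = self._matrix(n_pass=8)
        assert "g2" in filter_low_counts(m, DEConfig()).genes

    def test_cpm_scale_invariance(self, rng):
        counts = rng.poisson(30, size=(50, 10))
        groups = ["aneurysm"] * 5 + ["control"] * 5
        a = filter_low_counts(matrix_from(counts, groups), DEConfig())
        b = filter_low_counts(matrix_from(counts * 10, groups), DEConfig())
        assert a.genes == b.genes

    def test_zero_library_sample_rejected(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[:, :3] = 5
        m = matrix_from(counts, ["aneurysm"] * 2 + ["control"] * 2)
        with pytest.raises(ValueError, match="zero total counts"):
            filter_low_counts(m, DEConfig(min_samples=1))


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 6))
        np.testing.assert_allclose(tmm_factors(counts), np.ones(6), atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(20, size=(500, 8)) + 1
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_composition_shift_compensated(self, rng):
        """A sample whose library is inflated by a composition shift (a
        minority of genes hugely overexpressed) gets a factor below 1, so
        its effective library size is corrected downward."""
        base = rng.poisson(100, size=(1000, 6)) + 1
        spiked = base.copy()
        spiked[:200, 0] *= 4  # 20% of genes at 4x inflates the library ~1.6x
        f = tmm_factors(spiked)
        assert f[0] < 0.80
        assert (f[1:] > 1.0).all()  # others compensate upward (geomean 1)


@pytest.fixture(scope="module")
def design():
    groups = ["aneurysm"] * 15 + ["control"] * 15
    meta = pd.DataFrame({"group": groups},
                        index=[f"s{i}" for i in range(30)])
    X, _ = build_design(meta, ("group",))
    return X


class TestDispersion:
    def test_poisson_data_gives_near_zero_dispersion(self, design):
        cfg = SimConfig(seed=21, n_genes=3000, dispersion=0.0,
                        n_aneurysm=15, n_control=15)
        m, _ = simulate_counts(cfg)
        y = m.values().astype(float)
        common, _ = estimate_dispersion(y, design, np.log(y.sum(axis=0)))
        assert common <= 0.01

    def test_true_dispersion_recovered(self, design):
        cfg = SimConfig(seed=22, n_genes=5000, dispersion=0.2,
                        n_aneurysm=15, n_control=15)
        m, _ = simulate_counts(cfg)
        y = m.values().astype(float)
        common, tagwise = estimate_dispersion(y, design, np.log(y.sum(axis=0)))
        assert 0.15 <= common <= 0.25
        assert 0.15 <= np.median(tagwise) <= 0.25

    def test_infinite_prior_df_collapses_tagwise_to_common(self, design, rng):
        counts = rng.negative_binomial(10, 10 / (10 + 50), size=(200, 30))
        offset = np.log(counts.sum(axis=0).astype(float))
        common, tagwise = estimate_dispersion(
            counts, design, offset, prior_df=1e9
        )
        np.testing.assert_allclose(tagwise, common, rtol=1e-6)

    def test_collinear_design_names_columns(self):
        meta = pd.DataFrame(
            {"group": ["aneurysm"] * 4 + ["control"] * 4,
             "rupture": ["ruptured"] * 4 + ["control"] * 4,
             "age": [50] * 8, "sex": ["male"] * 8},
            index=[f"s{i}" for i in range(8)],
        )
        X, names = build_design(meta, ("group", "rupture"))
        with pytest.raises(ValueError, match="rupture"):
            estimate_dispersion(np.ones((5, 8)), X, np.zeros(8),
                                design_names=names)


class TestGlmAgainstStatsmodels:
    def test_poisson_limit_matches_statsmodels(self, rng):
        """At phi -> 0 the NB IRLS engine reduces to a Poisson GLM."""
        n = 40
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        offset = np.log(rng.uniform(1e6, 2e6, size=n))
        beta_true = np.array([-12.0, 0.7, 0.2])
        y = rng.poisson(np.exp(X @ beta_true + offset))[None, :].astype(float)
        beta, mu, ll, conv = _irls_nb(y, X, offset, np.zeros(1))
        ref = sm.GLM(y[0], X, family=sm.families.Poisson(),
                     offset=offset).fit()
        np.testing.assert_allclose(beta[0], ref.params, atol=1e-6)
        assert ll[0] == pytest.approx(ref.llf, abs=1e-6)

    def test_nb_fixed_alpha_matches_statsmodels(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        offset = np.full(n, np.log(1e6))
        phi = 0.2
        r = 1 / phi
        mu = np.exp(-9.0 + 1.0 * X[:, 1] + offset)
        y = rng.negative_binomial(r, r / (r + mu))[None, :].astype(float)
        beta, _, ll, _ = _irls_nb(y, X, offset, np.array([phi]))
        ref = sm.GLM(y[0], X, family=sm.families.NegativeBinomial(alpha=phi),
                     offset=offset).fit()
        np.testing.assert_allclose(beta[0], ref.params, atol=1e-5)
        assert ll[0] == pytest.approx(ref.llf, abs=1e-4)


class TestLrt:
    def test_null_type_one_error_calibrated(self):
        cfg = SimConfig(seed=23, n_genes=4000, dispersion=0.1,
                        n_aneurysm=20, n_control=20)
        m, _ = simulate_counts(cfg)
        res = fit_nb_de(m, DEConfig(covariates=("group",)))
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_planted_logfc_recovered(self):
        cfg = SimConfig(seed=24, n_genes=1500, dispersion=0.1,
                        n_aneurysm=30, n_control=30, n_planted=40)
        m, truth = simulate_counts(cfg)
        res = fit_nb_de(m, DEConfig(covariates=("group",)))
        est = res.loc[list(truth.planted_de_genes), "logfc"]
        assert float(est.mean()) == pytest.approx(2.0, abs=0.1)
        assert res.loc[list(truth.planted_de_genes), "fdr"].max() < 0.05

    def test_full_covariate_design_runs(self):
        cfg = SimConfig(seed=25, n_genes=400, dispersion=0.1)
        m, _ = simulate_counts(cfg)
        res = fit_nb_de(m, DEConfig())
        assert res["converged"].mean() > 0.95
        ok = res.dropna(subset=["p_value"])
        assert (ok["fdr"] >= ok["p_value"] - 1e-12).all()


class TestBh:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2]))[0] == 0.2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, ps):
        from oracles import oracle_bh

        p = np.array(ps)
        np.testing.assert_allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=100)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestIntegrate:
    def _candidates(self):
        from famvar.cascade import CandidateRecord
        from famvar.cohort import AnnotationBundle, VariantRecord
        from famvar.segregation import SegregationResult

        def cand(gene):
            v = VariantRecord("1", 100 + hash(gene) % 1000, "G", "A", {})
            seg = SegregationResult("A", v.key, True, True, True, 0, False)
            return CandidateRecord(
                variant=v, bundle=AnnotationBundle(gene=gene),
                segregation={"A": seg}, families_segregating={"A"},
                cross_family_definite=False, unaffected_carrier_count=0,
            )

        return [cand("TMEM132B"), cand("AGMAT"), cand("NOEXPR")]

    def _de_table(self):
        return pd.DataFrame(
            {"logfc": [-2.626, -0.127], "p_value": [0.0001, 0.8],
             "fdr": [0.023, 0.952], "dispersion": [0.1, 0.1],
             "mean_expression": [10.0, 20.0], "converged": [True, True]},
            index=pd.Index(["TMEM132B", "AGMAT"], name="gene"),
        )

    def test_sole_gene_below_threshold_flagged(self):
        cands = self._candidates()
        integrate_expression(cands, self._de_table())
        flagged = [c.gene for c in cands if c.differentially_expressed]
        assert flagged == ["TMEM132B"]
        tm = next(c for c in cands if c.gene == "TMEM132B")
        assert tm.fdr == pytest.approx(0.023)

    def test_absent_gene_marked_not_available(self):
        cands = self._candidates()
        integrate_expression(cands, self._de_table())
        miss = next(c for c in cands if c.gene == "NOEXPR")
        assert not miss.expression_available and miss.fdr is None

    def test_zero_threshold_flags_nothing(self):
        cands = self._candidates()
        integrate_expression(cands, self._de_table(), fdr_threshold=0.0)
        assert not any(c.differentially_expressed for c in cands)
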