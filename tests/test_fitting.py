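import numpy as np
import pytest

from tskallometry import (
    AllometricDataset,
    ConsequentSet,
    FuzzyPartition,
    GeneratorSpec,
    TSKModel,
    VarianceModel,
    fit_consequents_ls,
    fit_consequents_rls,
    fit_ml,
    fit_tama,
    fit_tsk,
    fit_tsk_at_q,
    generate,
    tsk_output,
)
from tskallometry.fitting import GEOMETRIC, HOMOSCEDASTIC, LOG_LINEAR_HET, _design


def make_model(theta, lam, intercept, slope):
    return TSKModel(
        partition=FuzzyPartition(theta=np.asarray(theta), lam=np.asarray(lam)),
        consequents=ConsequentSet(
            intercept=np.asarray(intercept), slope=np.asarray(slope)
        ),
    )


class TestTskOutput:
    def test_identical_consequents_collapse_to_line(self, rng):
        """Partition of unity: any blend of one line is that line."""
        model = make_model([0.0, 2.0, 5.0], [1.0, 0.5, 2.0], [1.5] * 3, [-0.3] * 3)
        u = rng.uniform(-3, 8, size=50)
        np.testing.assert_allclose(tsk_output(u, model), 1.5 - 0.3 * u, atol=1e-12)

    def test_single_rule_is_its_consequent(self):
        model = make_model([1.0], [0.7], [2.0], [0.5])
        assert tsk_output(3.0, model) == pytest.approx(2.0 + 0.5 * 3.0)

    def test_matches_weighted_power_rearrangement(self, rng):
        """The blend equals ln(b1^(1-w2) b2^w2) + (a1(1-w2)+a2 w2) u."""
        model = make_model([0.0, 2.0], [1.0, 2.0], [0.3, -0.8], [1.1, 0.6])
        u = rng.uniform(-4, 6, size=100)
        w2 = model.partition.firing(u)[:, 1]
        b1, b2 = np.exp(model.consequents.intercept)
        a1, a2 = model.consequents.slope
        expected = np.log(b1 ** (1 - w2) * b2**w2) + (a1 * (1 - w2) + a2 * w2) * u
        np.testing.assert_allclose(tsk_output(u, model), expected, atol=1e-10)


class TestLeastSquares:
    def test_exact_recovery_on_noiseless_data(self):
        truth = make_model([1.0, 4.0], [0.8, 0.8], [-1.0, -2.0], [0.9, 1.3])
        u = np.linspace(-1, 6, 200)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(truth.predict(u)))
        est = fit_consequents_ls(ds, truth.partition)
        np.testing.assert_allclose(est.intercept, truth.consequents.intercept, atol=1e-8)
        np.testing.assert_allclose(est.slope, truth.consequents.slope, atol=1e-8)

    def test_single_rule_reduces_to_ols(self, biphasic_data):
        ds, _ = biphasic_data
        part = FuzzyPartition(theta=[0.0], lam=[1.0])
        est = fit_consequents_ls(ds, part)
        tama = fit_tama(ds)
        assert est.intercept[0] == pytest.approx(tama.ln_beta, abs=1e-8)
        assert est.slope[0] == pytest.approx(tama.alpha, abs=1e-8)

    def test_matches_pseudoinverse_solve(self, rng):
        part = FuzzyPartition(theta=[-0.5, 1.5], lam=[0.6, 1.1])
        u = rng.uniform(-2, 3, size=50)
        v = rng.normal(size=50)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(v))
        est = fit_consequents_ls(ds, part)
        X = _design(u, part)
        coef = np.linalg.pinv(X) @ v
        np.testing.assert_allclose(
            np.concatenate([est.intercept, est.slope]), coef, atol=1e-10
        )

    def test_rls_converges_to_batch(self, rng):
        part = FuzzyPartition(theta=[0.0, 3.0], lam=[1.0, 1.0])
        u = rng.uniform(-2, 5, size=300)
        v = 0.5 + 1.2 * u + rng.normal(0, 0.2, size=300)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(v))
        batch = fit_consequents_ls(ds, part)
        rec = fit_consequents_rls(ds, part)
        np.testing.assert_allclose(rec.intercept, batch.intercept, atol=1e-4)
        np.testing.assert_allclose(rec.slope, batch.slope, atol=1e-4)

    def test_dead_rule_raises_named_error(self, rng):
        part = FuzzyPartition(theta=[0.0, 500.0], lam=[1.0, 1.0])
        u = rng.uniform(-2, 2, size=40)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(u))
        with pytest.raises(ValueError, match=r"rule\(s\) \[2\]"):
            fit_consequents_ls(ds, part)

    def test_too_few_observations_rejected(self):
        part = FuzzyPartition(theta=[0.0, 1.0], lam=[1.0, 1.0])
        ds = AllometricDataset(x=np.array([1.0, 2.0, 3.0]), y=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="n >= 2q"):
            fit_consequents_ls(ds, part)


class TestMaximumLikelihood:
    def test_homoscedastic_ml_equals_ls(self, biphasic_data):
        ds, _ = biphasic_data
        part = FuzzyPartition(theta=[1.8, 6.2], lam=[1.35, 1.35])
        ls = fit_consequents_ls(ds, part)
        cons, var, nll = fit_ml(ds, part, HOMOSCEDASTIC)
        np.testing.assert_allclose(cons.intercept, ls.intercept, atol=1e-8)
        np.testing.assert_allclose(cons.slope, ls.slope, atol=1e-8)
        assert var.kind == HOMOSCEDASTIC and var.sigma > 0
        assert np.isfinite(nll)

    def test_heteroscedastic_parameter_recovery(self):
        """(sigma, k) of the log-linear scale recovered at n=10,000."""
        spec = GeneratorSpec(
            noise=LOG_LINEAR_HET, sigma=3.0, k=0.5, n=10_000, u_range=(0.5, 8.0), seed=3
        )
        ds, _ = generate(spec)
        part = spec.truth_model().partition
        cons, var, nll = fit_ml(ds, part, LOG_LINEAR_HET)
        # Monte-Carlo tolerance: 3 coarse standard errors at this n.
        assert var.sigma == pytest.approx(3.0, abs=0.45)
        assert var.k == pytest.approx(0.5, abs=0.15)
        np.testing.assert_allclose(cons.slope, spec.alpha, rtol=0.06)

    def test_het_nll_never_exceeds_hom_nll(self, biphasic_data):
        """The homoscedastic scale is nested in the log-linear family."""
        ds, _ = biphasic_data
        part = FuzzyPartition(theta=[1.8, 6.2], lam=[1.35, 1.35])
        _, _, nll_hom = fit_ml(ds, part, HOMOSCEDASTIC)
        _, _, nll_het = fit_ml(ds, part, LOG_LINEAR_HET)
        assert nll_het <= nll_hom + 1e-6

    def test_variance_model_guards(self):
        with pytest.raises(ValueError):
            VarianceModel(kind="homoscedastic", sigma=0.5, k=0.3)
        vm = VarianceModel(kind=LOG_LINEAR_HET, sigma=1.5, k=0.2)
        with pytest.raises(ValueError):
            vm.sd(np.array([-10.0]))  # sigma + k*u < 1 there


class TestTama:
    def test_exact_line(self):
        u = np.linspace(0.1, 3.0, 30)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(1.0 + 2.0 * u))
        fit = fit_tama(ds)
        assert fit.alpha == pytest.approx(2.0, abs=1e-10)
        assert fit.ln_beta == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_matches_closed_form_ols(self, rng):
        u = rng.uniform(0, 4, size=10)
        v = 0.5 + 1.1 * u + rng.normal(0, 0.3, size=10)
        ds = AllometricDataset(x=np.exp(u), y=np.exp(v))
        fit = fit_tama(ds)
        slope = np.cov(u, v, ddof=1)[0, 1] / np.var(u, ddof=1)
        intercept = v.mean() - slope * u.mean()
        assert fit.alpha == pytest.approx(slope, rel=1e-10)
        assert fit.ln_beta == pytest.approx(intercept, rel=1e-10)
        # R^2 equals the squared Pearson correlation of v with fitted v.
        r = np.corrcoef(v, fit.predict(u))[0, 1]
        assert fit.r2 == pytest.approx(r**2, rel=1e-10)

    def test_constant_covariate_rejected(self):
        ds = AllometricDataset(x=np.full(5, 2.0), y=np.exp(np.arange(5.0) + 1))
        with pytest.raises(ValueError, match="constant"):
            fit_tama(ds)


class TestFitTskPipeline:
    def test_single_phase_data_reduces_to_tama(self):
        """On loglinear data the pipeline selects q=1 and matches OLS."""
        spec = GeneratorSpec(
            theta=(4.0,), lam=(1.0,), alpha=(1.05,), ln_beta=(-0.5,),
            sigma=0.25, n=2000, u_range=(0.0, 8.0), seed=11,
        )
        ds, _ = generate(spec)
        rep = fit_tsk(ds, r_a=1.1)
        assert rep.q == 1
        assert len(rep.breakpoints) == 0
        tama = fit_tama(ds)
        assert rep.model.consequents.slope[0] == pytest.approx(tama.alpha, abs=1e-8)
        assert rep.model.consequents.intercept[0] == pytest.approx(tama.ln_beta, abs=1e-8)

    def test_biphasic_cohort_data_yields_two_phases(self):
        spec = GeneratorSpec(n=3000, seed=5, u_dist="cohorts")
        ds, truth = generate(spec)
        rep = fit_tsk_at_q(ds, target_q=2)
        assert rep.q == 2
        assert len(rep.breakpoints) == 1
        assert rep.breakpoints.points[0] == pytest.approx(truth["breakpoints_u"][0], abs=0.15)

    def test_deterministic(self):
        spec = GeneratorSpec(n=500, seed=2)
        ds, _ = generate(spec)
        r1 = fit_tsk(ds, r_a=0.5)
        r2 = fit_tsk(ds, r_a=0.5)
        np.testing.assert_array_equal(r1.model.partition.theta, r2.model.partition.theta)
        np.testing.assert_array_equal(
            r1.model.consequents.slope, r2.model.consequents.slope
        )

    def test_model_json_round_trip(self, biphasic_data):
        ds, _ = biphasic_data
        rep = fit_tsk(ds, r_a=0.5)
        clone = TSKModel.from_dict(rep.model.to_dict())
        u = np.linspace(0.5, 7.5, 11)
        np.testing.assert_allclose(clone.predict(u), rep.model.predict(u), rtol=1e-12)

    def test_space_family_consistency_enforced(self):
        from tskallometry.partition import COMPOSITE_LOGNORMAL

        part = FuzzyPartition(theta=[0.0], lam=[1.0], family=COMPOSITE_LOGNORMAL)
        cons = ConsequentSet(intercept=[0.0], slope=[1.0])
        with pytest.raises(ValueError, match="membership family"):
            TSKModel(partition=part, consequents=cons, space=GEOMETRIC)
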