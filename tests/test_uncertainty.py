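"""Uncertainty propagation: priors, resampling, frequentist, Bayesian."""

import numpy as np
import pandas as pd
import pytest

import panelprev as pp
from conftest import make_controls, truth_centred_priors


class TestPriors:
    def test_beta_shapes_from_controls(self):
        controls = pp.ControlData(
            pd.DataFrame(
                {"n_pos": [100.0], "k_pos": [80.0], "n_neg": [400.0], "k_neg": [399.0]},
                index=pd.Index(["sero3"], name="component_id"),
            )
        )
        priors = pp.PerformancePrior.from_controls(controls, ["sero3"])
        assert (priors.spec["sero3"].a, priors.spec["sero3"].b) == (400.0, 2.0)
        assert (priors.sens["sero3"].a, priors.sens["sero3"].b) == (81.0, 21.0)
        assert priors.provenance == "from_controls"

    def test_missing_controls_rejected(self):
        controls = pp.ControlData(
            pd.DataFrame(
                {"n_neg": [400.0], "k_neg": [399.0]},
                index=pd.Index(["a"], name="component_id"),
            )
        )
        with pytest.raises(ValueError, match="lacks pos control"):
            pp.PerformancePrior.from_controls(controls, ["a"])

    def test_degenerate_prior_sampling(self):
        prior = pp.BetaPrior(point=0.9975)
        assert prior.is_degenerate
        assert (prior.sample(np.random.default_rng(0), 10) == 0.9975).all()
        with pytest.raises(ValueError):
            prior.logpdf(np.array([0.5]))

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            pp.BetaPrior(a=-1.0, b=2.0)
        with pytest.raises(ValueError):
            pp.BetaPrior(a=1.0, b=2.0, point=0.5)


class TestResampling:
    def test_degenerate_priors_centre_on_panel_estimator(self, ipd_panel):
        """With point-mass priors at truth and exact expected counts the
        replicate median sits on the panel estimator's point and the
        interval width is pure count-resampling noise, shrinking with m."""
        prev, profiles = ipd_panel
        priors = pp.PerformancePrior.fixed(profiles)
        widths = []
        for m in (4000, 64000):
            ap = pp.ApparentPrevalence.expected(prev, profiles, m)
            point = pp.panel_prevalence_estimate(ap, profiles).point
            est = pp.resampling_interval(ap, priors, reps=4000, seed=1)["panel"]
            assert est.point == pytest.approx(point, abs=0.02)
            widths.append(est.upper - est.lower)
        assert widths[1] < widths[0] / 2

    def test_deterministic_given_seed(self, ipd_panel):
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        priors = truth_centred_priors(prev.component_ids)
        a = pp.resampling_interval(ap, priors, seed=9)
        b = pp.resampling_interval(ap, priors, seed=9)
        assert a["panel"].point == b["panel"].point
        assert a["panel"].lower == b["panel"].lower

    def test_quantiles_converge_with_reps(self, ipd_panel):
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        priors = truth_centred_priors(prev.component_ids)
        small = [
            pp.resampling_interval(ap, priors, reps=200, seed=s)["panel"].upper
            for s in range(8)
        ]
        large = [
            pp.resampling_interval(ap, priors, reps=8000, seed=s)["panel"].upper
            for s in range(8)
        ]
        assert np.std(large) < np.std(small) / 2

    def test_underpowered_panel_raises(self, ipd_panel):
        """Priors straddling the uninformative boundary make most replicates
        undefined; the procedure refuses rather than report a spurious
        interval."""
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        vague = pp.PerformancePrior(
            sens={c: pp.BetaPrior(a=2.0, b=2.0) for c in prev.component_ids},
            spec={c: pp.BetaPrior(a=2.0, b=2.0) for c in prev.component_ids},
        )
        with pytest.raises(pp.EstimateUndefinedError):
            pp.resampling_interval(ap, vague, seed=0)

    def test_reps_floor(self, ipd_panel):
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        with pytest.raises(ValueError):
            pp.resampling_interval(
                ap, truth_centred_priors(prev.component_ids), reps=10, seed=0
            )

    def test_coverage_of_panel_truth(self):
        """Scaled-down coverage study: resampling intervals with
        truth-centred priors cover the realised panel prevalence at or above
        the nominal level."""
        priors = truth_centred_priors(pp.IPD_LIKE_WEIGHTS)
        cover = 0
        n_rep = 200
        for i in range(n_rep):
            cohort = pp.simulate_cohort(pp.ScenarioConfig(seed=60_000 + i))
            est = pp.resampling_interval(
                cohort.apparent_prevalence(), priors, reps=500, seed=i
            )["panel"]
            cover += est.lower <= cohort.panel_truth_prev <= est.upper
        assert cover / n_rep > 0.90


class TestFrequentist:
    def test_perfect_controls_centre_on_truth(self, ipd_panel):
        """Huge error-free control groups leave only binomial positivity
        noise: the interval centres on truth with near-binomial width."""
        prev, profiles = ipd_panel
        m = 4000
        ap = pp.ApparentPrevalence.expected(prev, profiles, m)
        controls = make_controls(
            prev.component_ids, n_pos=10**6, k_pos=8 * 10**5,
            n_neg=10**6, k_neg=997500,
        )
        est = pp.frequentist_interval(ap, controls)["panel"]
        assert est.point == pytest.approx(0.10, abs=0.002)
        binomial_width = 2 * 1.96 * np.sqrt(0.1256 * (1 - 0.1256) / m) / 0.82
        assert est.upper - est.lower < 2 * binomial_width

    @pytest.mark.parametrize(
        "n_neg, low, high",
        [
            # negative-control group large enough that the specificity
            # variance is estimated reliably: coverage is nominal
            (800, 0.91, 0.99),
            # 100 error-free negative controls estimate zero specificity
            # variance, so the Wald interval mildly undercovers here
            (100, 0.88, 0.97),
        ],
    )
    def test_single_test_coverage(self, n_neg, low, high):
        """Empirical coverage of the adjusted single-test interval at p=2%,
        sens 80%, spec 99.75%."""
        rng = np.random.default_rng(314)
        p, sens, spec, m = 0.02, 0.8, 0.9975, 1000
        cover, total = 0, 500
        for _ in range(total):
            truth = rng.random(m) < p
            res = np.where(truth, rng.random(m) < sens, rng.random(m) < 1 - spec)
            row = pd.Series(
                {
                    "n_pos": 100.0, "k_pos": float(rng.binomial(100, sens)),
                    "n_neg": float(n_neg),
                    "k_neg": float(rng.binomial(n_neg, spec)),
                }
            )
            try:
                est = pp.panelprev._lang_reiczigel_single(
                    float(res.sum()), m, row, 0.95
                )
            except pp.UninformativeTestError:
                continue
            cover += est.lower <= p <= est.upper
        assert low <= cover / total <= high

    def test_performance_uncertainty_widens_interval(self, ipd_panel):
        """The panel interval with finite control groups is never narrower
        than the same interval with performance uncertainty removed."""
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        noisy = pp.frequentist_interval(
            ap, make_controls(prev.component_ids)
        )["panel"]
        precise = pp.frequentist_interval(
            ap,
            make_controls(
                prev.component_ids, n_pos=10**8, k_pos=8 * 10**7,
                n_neg=10**8, k_neg=99750000,
            ),
        )["panel"]
        assert noisy.upper - noisy.lower > precise.upper - precise.lower

    def test_missing_controls_directs_to_resampling(self, ipd_panel):
        prev, profiles = ipd_panel
        ap = pp.ApparentPrevalence.expected(prev, profiles, 4000)
        with pytest.raises(ValueError, match="resampling_interval"):
            pp.frequentist_interval(ap, pp.ControlData.empty())

    def test_single_component_bundle(self, profile):
        ap = pp.ApparentPrevalence(
            ("c1",), np.array([pp.apparent_from_true(0.02, profile) * 4000]), 4000
        )
        bundle = pp.frequentist_interval(ap, make_controls(["c1"]))
        assert bundle["panel"].point == bundle["components"]["c1"].point


class TestControlPrecisionVsSampleSize:
    def test_better_controls_beat_more_subjects(self):
        """Characterising the test well narrows panel intervals more than
        doubling the cohort does under poorly known performance."""
        ids = list(pp.IPD_LIKE_WEIGHTS)
        poor = truth_centred_priors(ids, sens_ess=30.0, spec_ess=100.0)
        good = truth_centred_priors(ids, sens_ess=300.0, spec_ess=4000.0)

        def width(n_subjects, priors, seed):
            cohort = pp.simulate_cohort(
                pp.ScenarioConfig(seed=seed, n_subjects=n_subjects)
            )
            est = pp.resampling_interval(
                cohort.apparent_prevalence(), priors, reps=1000, seed=seed
            )["panel"]
            return est.upper - est.lower

        seeds = range(5)
        poor_doubled = np.mean([width(8000, poor, 700 + s) for s in seeds])
        good_fixed = np.mean([width(4000, good, 700 + s) for s in seeds])
        assert good_fixed < poor_doubled


class TestOverdispersion:
    def test_panel_counts_overdispersed_vs_binomial(self):
        """Across replicate studies with performance drawn from its
        uncertainty distribution, panel positive counts have variance above
        the binomial variance at the same mean."""
        rng = np.random.default_rng(5)
        prev = pp.scale_distribution(pp.default_ipd_like_weights(), 0.10)
        m, reps = 4000, 3000
        sens = rng.beta(0.8 * 100, 0.2 * 100, size=(reps, 20))
        spec = rng.beta(0.9975 * 800, 0.0025 * 800, size=(reps, 20))
        ap_n = prev.p * sens + (1 - prev.p) * (1 - spec)
        ap_panel = 1 - np.prod(1 - ap_n, axis=1)
        counts = rng.binomial(m, ap_panel)
        p_bar = counts.mean() / m
        assert counts.var() > 1.5 * m * p_bar * (1 - p_bar)


class TestBayesian:
    def test_parameter_recovery_small_panel(self):
        """Posterior group interval covers the true any-subtype prevalence
        on a 5-component panel with truth-centred priors."""
        weights = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        profiles = tuple(
            pp.ComponentProfile(f"c{i+1}", 0.8, 0.9975) for i in range(5)
        )
        cfg = pp.ScenarioConfig(
            seed=303, n_subjects=4000, weights=weights,
            target_panel_prev=0.08, profiles=profiles,
        )
        cohort = pp.simulate_cohort(cfg)
        priors = truth_centred_priors([p.component_id for p in profiles])
        out = pp.bayesian_estimate(
            cohort.apparent_prevalence(), priors,
            groups=[pp.PanelDefinition("all", tuple(p.component_id for p in profiles))],
            seed=404,
        )
        est = out["groups"]["all"]
        assert est.lower <= cohort.panel_truth_prev <= est.upper
        assert est.point == pytest.approx(0.08, abs=0.025)
        for comp in out["components"].values():
            assert comp.diagnostics["rhat"] < 1.05
            assert comp.diagnostics["ess"] > 400

    def test_tight_priors_concentrate_on_corrected_positivity(self, profile):
        """With near-certain performance priors the posterior prevalence
        concentrates on the misclassification-corrected positivity."""
        m, p = 4000, 0.05
        ap_value = pp.apparent_from_true(p, profile)
        ap = pp.ApparentPrevalence(("c1",), np.array([round(ap_value * m)]), m)
        priors = truth_centred_priors(["c1"], sens_ess=10**6, spec_ess=10**6)
        out = pp.bayesian_estimate(ap, priors, seed=7)
        rg = pp.rogan_gladen(ap.ap[0], profile).point
        assert out["components"]["c1"].point == pytest.approx(rg, abs=0.005)

    def test_degenerate_priors_rejected(self, profile):
        ap = pp.ApparentPrevalence(("c1",), np.array([100.0]), 4000)
        with pytest.raises(ValueError, match="proper"):
            pp.bayesian_estimate(
                ap, pp.PerformancePrior.fixed([profile]), seed=1
            )

    def test_nonconvergence_detected(self):
        """Deliberately truncated chains fail the effective-sample-size
        gate and raise rather than return unreliable intervals."""
        ap = pp.ApparentPrevalence(("c1",), np.array([40.0]), 4000)
        priors = truth_centred_priors(["c1"])
        with pytest.raises(pp.ConvergenceError):
            pp.bayesian_estimate(ap, priors, seed=2, n_warmup=20, n_steps=10)

    def test_miscentred_specificity_prior_breaks_recovery(self):
        """A confidently wrong specificity prior (centred 0.98 when truth is
        0.9975) over-corrects and the posterior interval misses truth: the
        correction is only as good as the performance assumptions."""
        weights = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        profiles = tuple(
            pp.ComponentProfile(f"c{i+1}", 0.8, 0.9975) for i in range(5)
        )
        cfg = pp.ScenarioConfig(
            seed=905, n_subjects=4000, weights=weights,
            target_panel_prev=0.08, profiles=profiles,
        )
        cohort = pp.simulate_cohort(cfg)
        ids = [p.component_id for p in profiles]
        wrong = pp.PerformancePrior(
            sens={c: pp.BetaPrior(a=0.8 * 1000, b=0.2 * 1000) for c in ids},
            spec={c: pp.BetaPrior(a=0.98 * 4000, b=0.02 * 4000) for c in ids},
        )
        out = pp.bayesian_estimate(
            cohort.apparent_prevalence(), wrong,
            groups=[pp.PanelDefinition("all", tuple(ids))], seed=905,
        )
        est = out["groups"]["all"]
        assert not (est.lower <= cohort.panel_truth_prev <= est.upper)

    def test_deterministic_given_seed(self):
        ap = pp.ApparentPrevalence(("c1",), np.array([40.0]), 4000)
        priors = truth_centred_priors(["c1"])
        a = pp.bayesian_estimate(ap, priors, seed=3, n_warmup=200, n_steps=300,
                                 ess_min=50)
        b = pp.bayesian_estimate(ap, priors, seed=3, n_warmup=200, n_steps=300,
                                 ess_min=50)
        assert a["components"]["c1"].point == b["components"]["c1"].point


class TestMethodAgreement:
    def test_three_methods_agree_on_large_cohort(self):
        """On a large simulated cohort with well-centred performance
        information the resampling, frequentist and Bayesian point estimates
        agree."""
        cfg = pp.ScenarioConfig(seed=808, n_subjects=50_000)
        cohort = pp.simulate_cohort(cfg)
        ap = cohort.apparent_prevalence()
        ids = list(ap.component_ids)
        profiles = list(cfg.profiles)

        rg = pp.panel_prevalence_estimate(ap, profiles).point
        res = pp.resampling_interval(
            ap, truth_centred_priors(ids, sens_ess=10**5, spec_ess=10**6),
            reps=2000, seed=1,
        )["panel"].point
        freq = pp.frequentist_interval(
            ap, make_controls(ids, n_pos=10**5, k_pos=8 * 10**4,
                              n_neg=10**6, k_neg=997500),
        )["panel"].point
        assert res == pytest.approx(rg, abs=0.01)
        assert freq == pytest.approx(rg, abs=0.01)
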