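"""MLE/MAP/EAP estimators against grid-search and fine-quadrature oracles."""

import numpy as np
import pytest

from adlcat import (
    Estimator,
    estimate,
    estimate_eap,
    estimate_map,
    estimate_mle,
    log_likelihood,
    reliability_from_sem,
)
from adlcat.estimation import THETA_BOUND

from conftest import dichotomous, random_gpcm

GRID = np.arange(-4.0, 4.0 + 5e-5, 1e-4)


def loglik_grid(responses):
    from adlcat.irt import BankDesign

    design = BankDesign.from_items([it for it, _ in responses])
    x = np.array([x for _, x in responses])
    return design.log_likelihood(GRID, x)


def random_pattern(rng, n_items=8):
    items = [random_gpcm(rng, item_id=f"i{j}") for j in range(n_items)]
    responses = [(it, int(rng.integers(0, it.max_score + 1))) for it in items]
    # avoid all-extreme patterns, which have no interior MLE
    if all(x == 0 for _, x in responses):
        responses[0] = (responses[0][0], 1)
    if all(x == it.max_score for it, x in responses):
        responses[0] = (responses[0][0], 0)
    return responses


class TestMle:
    def test_single_item_extreme_pattern_hits_boundary(self):
        est = estimate_mle([(dichotomous(0.0), 1)])
        assert est.at_boundary and est.theta == THETA_BOUND

    def test_symmetric_pattern_estimates_zero(self):
        est = estimate_mle([(dichotomous(-1.0), 1), (dichotomous(1.0), 0)])
        assert est.theta == pytest.approx(0.0, abs=1e-6)
        assert not est.at_boundary and est.converged

    def test_mixed_pattern_matches_grid_argmax(self, cadl):
        responses = [
            (cadl.item("BI 2: bathing"), 1),
            (cadl.item("FAI 6: local shopping"), 0),
            (cadl.item("BI 10: climbing stairs"), 1),
            (cadl.item("FAI 4: light housework"), 0),
            (cadl.item("BI 4: dressing"), 1),
        ]
        est = estimate_mle(responses)
        assert est.theta == pytest.approx(GRID[np.argmax(loglik_grid(responses))], abs=2e-4)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError, match="at least one response"):
            estimate_mle([])

    def test_oracle_agreement_on_random_patterns(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            responses = random_pattern(rng)
            est = estimate_mle(responses)
            oracle = GRID[np.argmax(loglik_grid(responses))]
            if not est.at_boundary:
                assert est.theta == pytest.approx(float(oracle), abs=1e-3)


class TestMap:
    def test_empty_pattern_returns_prior_mode(self):
        est = estimate_map([])
        assert est.theta == 0.0 and est.n_items == 0

    def test_single_item_fixed_point(self):
        # posterior mode of one correct coin-flip item solves 1 - sigma(t) = t
        est = estimate_map([(dichotomous(0.0), 1)])
        assert est.theta == pytest.approx(0.4010581, abs=1e-5)

    def test_shrinks_toward_prior_mode(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            responses = random_pattern(rng)
            mle, mp = estimate_mle(responses), estimate_map(responses)
            if not mle.at_boundary:
                assert abs(mp.theta) <= abs(mle.theta) + 1e-9

    def test_oracle_agreement_on_random_patterns(self):
        rng = np.random.default_rng(43)
        prior = -0.5 * GRID**2
        for _ in range(25):
            responses = random_pattern(rng)
            oracle = GRID[np.argmax(loglik_grid(responses) + prior)]
            assert estimate_map(responses).theta == pytest.approx(float(oracle), abs=1e-3)


class TestEap:
    def test_empty_pattern_prior_summary(self):
        est = estimate_eap([])
        assert est.theta == pytest.approx(0.0, abs=1e-12)
        # truncated standard normal on [-4, 4] has SD just under 1
        assert est.sem == pytest.approx(0.9996, abs=1e-3)

    def test_symmetric_pattern_estimates_zero(self):
        est = estimate_eap([(dichotomous(-1.0), 1), (dichotomous(1.0), 0)])
        assert est.theta == pytest.approx(0.0, abs=1e-9)

    def test_matches_fine_grid_posterior_mean(self):
        rng = np.random.default_rng(44)
        fine = np.linspace(-4, 4, 100_001)
        prior = -0.5 * fine**2
        from adlcat.irt import BankDesign

        for _ in range(20):
            responses = random_pattern(rng)
            design = BankDesign.from_items([it for it, _ in responses])
            x = np.array([x for _, x in responses])
            log_post = design.log_likelihood(fine, x) + prior
            post = np.exp(log_post - log_post.max())
            post /= post.sum()
            oracle_mean = float(post @ fine)
            oracle_sd = float(np.sqrt(post @ (fine - oracle_mean) ** 2))
            est = estimate_eap(responses)
            assert est.theta == pytest.approx(oracle_mean, abs=1e-3)
            assert est.sem == pytest.approx(oracle_sd, abs=2e-3)


class TestAcrossMethods:
    def test_flat_prior_limit_recovers_mle(self, adl_male):
        # with a nearly flat prior the MAP/EAP machinery reduces to MLE
        responses = [(adl_male[i], x) for i, x in [(0, 1), (25, 1), (31, 2), (12, 0), (5, 1)]]
        mle = estimate_mle(responses)

        from adlcat.irt import BankDesign

        design = BankDesign.from_items([it for it, _ in responses])
        x = np.array([x for _, x in responses])
        wide = np.linspace(-4, 4, 400_001)
        ll = design.log_likelihood(wide, x)  # flat prior == raw likelihood
        assert wide[np.argmax(ll)] == pytest.approx(mle.theta, abs=1e-4)

    def test_dispatch_by_name(self):
        responses = [(dichotomous(-1.0), 1), (dichotomous(1.0), 0)]
        for name in ("MLE", "MAP", "EAP"):
            est = estimate(responses, name)
            assert est.method is Estimator(name)
            assert est.theta == pytest.approx(0.0, abs=1e-5)

    def test_log_likelihood_consistent_with_estimates(self):
        responses = [(dichotomous(0.3), 1), (dichotomous(-0.2), 0), (dichotomous(1.1), 1)]
        mle = estimate_mle(responses)
        assert log_likelihood(mle.theta, responses) >= log_likelihood(mle.theta + 0.05, responses)
        assert log_likelihood(mle.theta, responses) >= log_likelihood(mle.theta - 0.05, responses)


class TestReliability:
    def test_stop_threshold_sem(self):
        assert reliability_from_sem(np.sqrt(0.1)) == pytest.approx(0.90, abs=1e-12)

    def test_unit_sem_gives_zero(self):
        assert reliability_from_sem(1.0) == 0.0

    def test_strictly_decreasing_in_sem(self):
        sems = np.linspace(0.05, 2.0, 50)
        rels = [reliability_from_sem(s) for s in sems]
        assert np.all(np.diff(rels) < 0)

    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reliability_from_sem(0.0)
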