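"""Gaussian-mixture EM, MAP assignment and assignment regions."""

import math

import numpy as np
import pytest

from adrfilter.mixture import (
    SD_FLOOR,
    ClusterRegion,
    MixtureModel,
    assignment_regions,
    em_fit,
    log_likelihood,
    map_assign,
)


@pytest.fixture(scope="module")
def three_component_sample():
    """5000 draws from pi=(0.5,0.3,0.2), mu=(5,10,0), sigma=(20,60,300)."""
    rng = np.random.default_rng(42)
    comp = rng.choice(3, size=5000, p=[0.5, 0.3, 0.2])
    mu = np.array([5.0, 10.0, 0.0])
    sd = np.array([20.0, 60.0, 300.0])
    return rng.normal(mu[comp], sd[comp])


class TestEmFit:
    def test_k1_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 9.0, -3.0, 0.5])
        fit = em_fit(x, K=1)
        model = fit.model
        assert model.weights == (1.0,)
        assert model.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert model.sds[0] == pytest.approx(x.std(), rel=1e-9)  # population SD

    def test_monotone_loglik_and_convergence(self, three_component_sample):
        fit = em_fit(three_component_sample, K=3)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-9).all()
        assert fit.converged

    def test_responsibilities_normalize(self, three_component_sample):
        fit = em_fit(three_component_sample, K=3)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_canonical_order_ascending_sd(self, three_component_sample):
        model = em_fit(three_component_sample, K=3).model
        assert list(model.sds) == sorted(model.sds)

    def test_insufficient_data_fatal(self):
        with pytest.raises(ValueError, match="insufficient"):
            em_fit([1.0, 2.0, 3.0], K=2)

    def test_identical_points_hit_variance_floor(self, caplog):
        fit = em_fit([7.0] * 10, K=1)
        assert fit.model.means[0] == pytest.approx(7.0)
        assert fit.model.sds[0] == pytest.approx(SD_FLOOR)

    def test_reference_implementation_agreement(self, three_component_sample):
        """Converged log-likelihood matches an independent reference fit
        started from the same parameters, within 1e-6."""
        sklearn = pytest.importorskip("sklearn.mixture")
        from adrfilter.mixture import _quantile_init

        x = three_component_sample
        q = _quantile_init(np.asarray(x), 3)
        ref = sklearn.GaussianMixture(
            n_components=3, covariance_type="full", tol=1e-12, max_iter=5000,
            reg_covar=0.0,
            weights_init=np.array(q.weights),
            means_init=np.array(q.means)[:, None],
            precisions_init=(1.0 / np.array(q.sds) ** 2)[:, None, None],
        ).fit(np.asarray(x)[:, None])
        ours = em_fit(x, K=3, tol=1e-15, max_iter=5000)
        assert ours.loglik_trace[-1] == pytest.approx(ref.lower_bound_ * len(x), abs=1e-6)


class TestLogLikelihood:
    def test_standard_normal_at_zero(self):
        model = MixtureModel(weights=(1.0,), means=(0.0,), sds=(1.0,))
        assert log_likelihood(model, [0.0]) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_direct_summation_oracle(self):
        model = MixtureModel(weights=(0.2, 0.5, 0.3), means=(-3.0, 0.0, 10.0), sds=(1.0, 5.0, 40.0))
        x = [-7.0, -1.0, 0.0, 2.5, 8.0, 30.0, -100.0, 55.0, 0.1, 3.3]
        direct = sum(
            math.log(
                sum(
                    w * math.exp(-0.5 * ((xi - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
                    for w, m, s in zip(model.weights, model.means, model.sds)
                )
            )
            for xi in x
        )
        assert log_likelihood(model, x) == pytest.approx(direct, abs=1e-10)

    def test_density_monotonicity(self):
        model = MixtureModel(weights=(0.9, 0.1), means=(0.0, 50.0), sds=(5.0, 5.0))
        at_mean = log_likelihood(model, [0.0])
        far = log_likelihood(model, [0.0 - 10 * 5.0])
        assert at_mean > far


class TestMapAssign:
    def test_tie_breaks_to_lowest_index(self):
        model = MixtureModel(weights=(0.5, 0.5), means=(0.0, 0.0), sds=(2.0, 2.0))
        assert map_assign(model, 1.7) == 0

    def test_small_sd_wins_at_shared_mean(self):
        model = MixtureModel(weights=(0.5, 0.5), means=(0.0, 0.0), sds=(1.0, 10.0))
        assert map_assign(model, 0.0) == 0  # pi/sigma larger for the tight one

    def test_closed_form_boundary_equal_means(self):
        """For equal means the decision boundary is at
        mu ± sqrt(2 s1² s2²/(s2²−s1²) · ln(pi1 s2/(pi2 s1)))."""
        pi1, pi2, s1, s2, mu = 0.6, 0.4, 3.0, 12.0, 5.0
        model = MixtureModel(weights=(pi1, pi2), means=(mu, mu), sds=(s1, s2))
        b = math.sqrt(
            2 * s1**2 * s2**2 / (s2**2 - s1**2) * math.log(pi1 * s2 / (pi2 * s1))
        )
        eps = 1e-6
        assert map_assign(model, mu + b - eps) == 0
        assert map_assign(model, mu + b + eps) == 1
        assert map_assign(model, mu - b + eps) == 0
        assert map_assign(model, mu - b - eps) == 1


class TestAssignmentRegions:
    def test_k1_covers_domain(self):
        model = MixtureModel(weights=(1.0,), means=(0.0,), sds=(1.0,))
        (region,) = assignment_regions(model, (-10.0, 10.0))
        assert region.intervals == ((-10.0, 10.0),)

    def test_nested_topology_equal_means(self):
        """sigma1<sigma2<sigma3 with one mean: inner interval, flanking
        union of two intervals, outer tails."""
        model = MixtureModel(weights=(0.4, 0.35, 0.25), means=(0.0, 0.0, 0.0), sds=(15.0, 70.0, 400.0))
        regions = assignment_regions(model, (-1300.0, 1550.0))
        assert len(regions[0].intervals) == 1           # tight: inner interval
        assert len(regions[1].intervals) == 2           # middle: two flanks
        assert len(regions[2].intervals) == 2           # wide: both tails
        lo0, hi0 = regions[0].intervals[0]
        assert lo0 < 0 < hi0
        assert regions[2].intervals[0][0] == -1300.0
        assert regions[2].intervals[1][1] == 1550.0

    def test_partition_no_gaps_no_overlaps(self):
        model = MixtureModel(
            weights=(0.5, 0.3, 0.2), means=(5.0, 10.0, 0.0), sds=(20.0, 60.0, 300.0)
        )
        regions = assignment_regions(model, (-1000.0, 1000.0))
        ivals = sorted(iv for r in regions for iv in r.intervals)
        assert ivals[0][0] == -1000.0 and ivals[-1][1] == 1000.0
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            assert b1 == pytest.approx(a2)

    def test_agrees_with_grid_scan(self):
        model = MixtureModel(
            weights=(0.5, 0.3, 0.2), means=(5.0, 10.0, 0.0), sds=(20.0, 60.0, 300.0)
        )
        regions = assignment_regions(model, (-1000.0, 1000.0))
        grid = np.linspace(-1000.0, 1000.0, 10_000)
        assigned = map_assign(model, grid)
        for x, k in zip(grid, assigned):
            containing = [r.cluster_index for r in regions if r.contains(x)]
            assert k in containing  # boundary points may belong to two regions

    def test_rounded_reporting(self):
        region = ClusterRegion(cluster_index=0, intervals=((-56.4, 77.5),))
        assert region.rounded() == ((-56, 78),)


def test_model_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        MixtureModel(weights=(0.5, 0.4), means=(0.0, 1.0), sds=(1.0, 1.0))
    with pytest.raises(ValueError, match="sds"):
        MixtureModel(weights=(1.0,), means=(0.0,), sds=(0.0,))
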