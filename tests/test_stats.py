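import numpy as np
import pandas as pd
import pytest

from netsort import (
    degree_association,
    hypergeom_test,
    layer_profile,
    randomization_test,
)
from netsort.errors import FitError, ValidationError
from netsort.synthetic import PlantedSpec, gen_layer_properties, gen_planted_bowtie

from .oracles import brute_hypergeom, exact_rt_pvalue


class TestRandomizationTest:
    def test_identical_constant_groups_p_one(self):
        for alt in ("greater", "less", "two_sided"):
            res = randomization_test([3, 3, 3], [3, 3, 3], alternative=alt,
                                     n_resamples=500, seed=0)
            assert res.p == 1.0

    def test_exhaustive_separated_groups(self):
        res = randomization_test([10, 11, 12], [0, 1, 2], alternative="greater",
                                 exact=True)
        assert res.n_resamples == 20
        assert res.p == pytest.approx(1 / 20)

    @pytest.mark.parametrize("alt", ["greater", "less", "two_sided"])
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_independent_enumeration(self, alt, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 6)).tolist()
        b = rng.normal(size=rng.integers(2, 6)).tolist()
        res = randomization_test(a, b, alternative=alt, exact=True)
        assert res.p == pytest.approx(exact_rt_pvalue(a, b, alt))

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.8, 1, 5).tolist()
        b = rng.normal(0, 1, 5).tolist()
        exact = randomization_test(a, b, alternative="greater", exact=True).p
        mc = randomization_test(a, b, alternative="greater",
                                n_resamples=20000, seed=4).p
        assert mc == pytest.approx(exact, abs=0.02)

    def test_uniform_under_exchangeability(self):
        # P(p <= alpha) ~= alpha for exchangeable groups, via exact p-values
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(2000):
            pool = rng.normal(size=10)
            res = randomization_test(pool[:5], pool[5:],
                                     alternative="greater", exact=True)
            pvals.append(res.p)
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1):
            assert np.mean(pvals <= alpha) == pytest.approx(alpha, abs=0.02)

    def test_missing_values_dropped(self):
        res = randomization_test([1.0, np.nan, 2.0], [0.0, 1.0],
                                 n_resamples=100, seed=0)
        assert res.n_a == 2 and res.n_b == 2

    def test_empty_after_missing_removal_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            randomization_test([np.nan, np.nan], [1.0, 2.0])

    def test_auto_alternative_records_direction(self):
        res = randomization_test([5, 6], [0, 1], n_resamples=100, seed=1)
        assert res.alternative == "greater"
        res = randomization_test([0, 1], [5, 6], n_resamples=100, seed=1)
        assert res.alternative == "less"


class TestHypergeomTest:
    def test_documented_example(self):
        res = hypergeom_test(k=4, K=5, n=4, N=10, direction="enrichment")
        assert res.p == pytest.approx(5 / 210)

    def test_zero_successes(self):
        assert hypergeom_test(0, 3, 4, 10, "enrichment").p == pytest.approx(1.0)
        res = hypergeom_test(0, 3, 4, 10, "depletion")
        assert res.p == pytest.approx(brute_hypergeom(0, 3, 4, 10, "depletion"))

    def test_full_selection_forced(self):
        res = hypergeom_test(k=5, K=5, n=10, N=10, direction="enrichment")
        assert res.p == pytest.approx(1.0)
        assert hypergeom_test(5, 5, 10, 10, "depletion").p == pytest.approx(1.0)

    def test_bounds_validated(self):
        with pytest.raises(ValidationError):
            hypergeom_test(k=6, K=5, n=6, N=10)
        with pytest.raises(ValidationError):
            hypergeom_test(k=0, K=11, n=5, N=10)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 13))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        lo, hi = max(0, n + K - N), min(n, K)
        k = int(rng.integers(lo, hi + 1))
        for direction in ("enrichment", "depletion"):
            assert hypergeom_test(k, K, n, N, direction).p == pytest.approx(
                brute_hypergeom(k, K, n, N, direction)
            )


class TestDegreeAssociation:
    def test_identity_correlation_one(self):
        degrees = list(range(1, 21))
        rho, p = degree_association(degrees, degrees, n_permutations=200, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.01

    def test_antiranked_minus_one(self):
        x = list(range(20))
        rho, _ = degree_association(x, x[::-1], n_permutations=100, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_independent_pairs_small_rho(self):
        rng = np.random.default_rng(8)
        rho, p = degree_association(rng.normal(size=200), rng.normal(size=200),
                                    n_permutations=500, seed=9)
        assert abs(rho) < 0.15
        assert p > 0.05

    def test_constant_property_errors(self):
        with pytest.raises(FitError):
            degree_association([1.0] * 10, list(range(10)))

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValidationError):
            degree_association([1, 2], [1, 2])


@pytest.fixture(scope="module")
def profile_net():
    return gen_planted_bowtie(
        PlantedSpec(n_top=8, n_core=6, n_bottom=8, n_peripheral=2, n_substrates=12,
                    p_top_core=0.4, p_core_core=0.4, p_core_bottom=0.4,
                    p_enzyme_substrate=0.3),
        seed=21,
    )


class TestLayerProfile:
    def test_constant_property_flat_zero_width(self, profile_net):
        net, _ = profile_net
        prop = pd.Series({n: 7.5 for n in net.enzymes})
        res = layer_profile(net, prop, "dnpr", n_reps=30, seed=1, n_swaps=50)
        for layer in res.layers:
            assert res.observed[layer] == pytest.approx(7.5)
            assert res.null_mean[layer] == pytest.approx(7.5)
            assert res.ci_low[layer] == pytest.approx(7.5)
            assert res.ci_high[layer] == pytest.approx(7.5)

    def test_random_property_flat_under_dnpr(self, profile_net):
        net, _ = profile_net
        rng = np.random.default_rng(5)
        prop = pd.Series({n: float(rng.normal()) for n in sorted(net.enzymes)})
        res = layer_profile(net, prop, "dnpr", n_reps=100, seed=2, n_swaps=50)
        spread = max(res.null_mean.values()) - min(res.null_mean.values())
        width = max(res.ci_high[l] - res.ci_low[l] for l in res.layers)
        assert spread < width  # near-flat relative to replicate noise

    def test_out_degree_under_dpr_observed_inside_ci(self, profile_net):
        net, _ = profile_net
        from netsort.graph import topology

        outd = topology(net).out_degrees()
        prop = pd.Series({n: float(outd[n]) for n in net.enzymes})
        res = layer_profile(net, prop, "dpr", n_reps=100, seed=3, n_swaps=100)
        inside = sum(
            res.ci_low[l] - 1e-9 <= res.observed[l] <= res.ci_high[l] + 1e-9
            for l in res.layers
        )
        assert inside >= 2

    def test_invalid_scheme_errors(self, profile_net):
        net, _ = profile_net
        prop = pd.Series({n: 1.0 for n in net.enzymes})
        with pytest.raises(ValidationError):
            layer_profile(net, prop, "bogus", n_reps=2, seed=0)


class TestGeneratedPropertyPower:
    def test_separated_means_detected(self):
        _, truth = gen_planted_bowtie(
            PlantedSpec(n_top=25, n_core=25, n_bottom=25, n_peripheral=0,
                        n_substrates=0),
            seed=3,
        )
        prop = gen_layer_properties(
            truth, {"top": (10.0, 1.0), "core": (0.0, 1.0), "bottom": (0.0, 1.0)},
            seed=4,
        )
        res = randomization_test(
            prop.reindex(sorted(truth.top)), prop.reindex(sorted(truth.core)),
            n_resamples=2000, alternative="greater", seed=5,
        )
        assert res.p < 0.01
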