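import numpy as np
import pytest
from scipy.stats import norm

from costbo.acquisition import (
    AcquisitionValues,
    BatchProposal,
    CostPolicy,
    PoolExhausted,
    SearchOptions,
    adjusted_alpha,
    batch_norm,
    compute_alpha,
    exhaustive_batch_argmax,
    experiment_cost,
    propose_batch,
    scaling_factor,
    _make_proposal,
)
from costbo.chem import KernelHyperparams
from costbo.ledger import initialize_ledger
from costbo.surrogate import FitSettings, fit_surrogate, posterior_predict

from util import cand, comp, fp, random_candidates


def closed_form_ei(mu, sigma, best):
    """Analytic expected improvement oracle."""
    if sigma <= 0:
        return max(0.0, mu - best)
    z = (mu - best) / sigma
    return sigma * (z * norm.cdf(z) + norm.pdf(z))


def _fixed_settings(noise=1e-8, scale=1.0, ls=0.5):
    return FitSettings(
        optimize=False,
        hyperparams=KernelHyperparams(output_scale=scale, lengthscales=np.array([ls])),
        noise_variance=noise,
    )


def _alpha_values(values):
    cands = [cand(i, [comp(f"L{i}", bits={i})]) for i in range(len(values))]
    return AcquisitionValues(
        alpha=np.asarray(values, float), candidates=tuple(cands), mc_samples=1, seed=0
    )


class TestComputeAlpha:
    def test_nonnegative_and_seeded(self):
        rng = np.random.default_rng(0)
        train = random_candidates(rng, 6, yields=True)
        pool = random_candidates(rng, 8, yields=True)
        model = fit_surrogate(train, [c.yield_observed for c in train], _fixed_settings(1e-4))
        a1 = compute_alpha(model, pool, mc_samples=256, seed=5)
        a2 = compute_alpha(model, pool, mc_samples=256, seed=5)
        assert np.all(a1.alpha >= 0)
        assert np.array_equal(a1.alpha, a2.alpha)

    def test_best_observed_point_has_near_zero_alpha(self):
        rng = np.random.default_rng(1)
        train = random_candidates(rng, 5, yields=True)
        ys = [c.yield_observed for c in train]
        best = train[int(np.argmax(ys))]
        twin = cand(99, best.compounds, [(c.name, c.value) for c in best.conditions])
        model = fit_surrogate(train, ys, _fixed_settings(1e-8))
        a = compute_alpha(model, [twin], mc_samples=2000, seed=0)
        assert a.alpha[0] < 1e-3 * model.y_scale

    def test_matches_closed_form_ei(self):
        # derived oracle: with one near-noiseless training point the incumbent
        # is deterministic and MC noisy EI must converge to analytic EI
        rng = np.random.default_rng(2)
        for trial in range(5):
            bits_t = set(map(int, rng.choice(24, size=6, replace=False)))
            bits_c = set(map(int, rng.choice(24, size=6, replace=False)))
            t = cand(0, [comp("T", bits=bits_t, n_bits=24)], [], 50.0)
            c = cand(1, [comp("C", bits=bits_c, n_bits=24)], [])
            model = fit_surrogate([t, t], [40.0, 60.0], _fixed_settings(1e-6, scale=2.0))
            post = posterior_predict(model, [c])
            expected = closed_form_ei(post.mu[0], post.sigma[0], 50.0)
            a = compute_alpha(model, [c], mc_samples=100_000, seed=trial)
            assert a.alpha[0] == pytest.approx(expected, rel=0.02, abs=1e-4)

    def test_rejects_bad_mc_samples(self):
        rng = np.random.default_rng(3)
        train = random_candidates(rng, 3, yields=True)
        model = fit_surrogate(train, [c.yield_observed for c in train], _fixed_settings(1e-4))
        with pytest.raises(ValueError):
            compute_alpha(model, train, mc_samples=0, seed=0)
        with pytest.raises(ValueError):
            compute_alpha(model, [], mc_samples=10, seed=0)


class TestExperimentCost:
    def test_all_owned_is_free(self):
        lig = comp("L", price=50.0)
        led = initialize_ledger([lig], charge_initial=False)
        assert experiment_cost(cand(0, [lig]), led) == 0.0

    def test_single_unowned_term(self):
        led = initialize_ledger([])
        assert experiment_cost(cand(0, [comp("L", price=50.0)]), led) == 50.0

    def test_within_batch_sharing(self):
        led = initialize_ledger([])
        shared = comp("L", price=50.0)
        first, second = cand(0, [shared]), cand(1, [shared])
        assert experiment_cost(first, led, []) == 50.0
        assert experiment_cost(second, led, [first]) == 0.0


class TestScalingFactor:
    def test_lambda_zero(self):
        assert scaling_factor(_alpha_values([1.0, 2.0]), [3.0], lam=0.0) == 0.0

    def test_formula(self):
        assert scaling_factor(_alpha_values([2.0, 1.0]), [4.0, 4.0], lam=1.0) == pytest.approx(0.5)

    def test_inverse_proportional_to_prices(self):
        a = _alpha_values([2.0])
        s1 = scaling_factor(a, [4.0], lam=1.5)
        s2 = scaling_factor(a, [8.0], lam=1.5)
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_prices_rejected(self):
        with pytest.raises(ZeroDivisionError, match="zero"):
            scaling_factor(_alpha_values([1.0]), [0.0, 0.0], lam=1.0)


class TestAdjustedAlpha:
    def test_zero_cost(self):
        assert adjusted_alpha(1.3, 0.0, 2.0) == 1.3

    def test_can_go_negative(self):
        assert adjusted_alpha(1.0, 4.0, 0.5) == pytest.approx(-1.0)

    def test_zero_scaling_identity(self):
        for a in (0.0, 0.7, 5.0):
            assert adjusted_alpha(a, 123.0, 0.0) == a


class TestBatchNorm:
    def _proposal(self, alphas, prices, S, shared=False):
        if shared:
            shared_comp = comp("X", price=prices[0])
            cands = [cand(i, [shared_comp]) for i in range(len(alphas))]
        else:
            cands = [cand(i, [comp(f"C{i}", price=p)]) for i, p in enumerate(prices)]
        led = initialize_ledger([])
        a = {c.index: al for c, al in zip(cands, alphas)}
        return _make_proposal(cands, a, led, S)

    def test_raw_sum(self):
        p = self._proposal([1, 2, 3, 4, 5], [0] * 5, S=0.0)
        assert batch_norm(p, adjusted=False) == 15.0

    def test_shared_compound_charged_once(self):
        p = self._proposal([1, 2, 3, 4, 5], [7.0] * 5, S=1.0, shared=True)
        assert batch_norm(p, adjusted=True) == pytest.approx(15.0 - 7.0)

    def test_adjusted_never_exceeds_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = self._proposal(
                rng.uniform(0, 3, 4), rng.uniform(0, 10, 4), S=float(rng.uniform(0, 2))
            )
            assert batch_norm(p, adjusted=True) <= batch_norm(p, adjusted=False) + 1e-12

    def test_order_invariance_of_adjustment(self):
        shared = comp("X", price=9.0)
        other = comp("Y", price=4.0)
        c0, c1, c2 = cand(0, [shared]), cand(1, [shared, other]), cand(2, [other])
        led = initialize_ledger([])
        a = {0: 1.0, 1: 2.0, 2: 3.0}
        norms = {
            _make_proposal(order, a, led, S=0.5).adjusted_norm
            for order in ([c0, c1, c2], [c2, c1, c0], [c1, c0, c2])
        }
        assert len(norms) == 1


def _random_instance(rng, n_pool=12, n_compounds=6):
    compounds = [comp(f"C{i}", price=float(rng.uniform(1, 40))) for i in range(n_compounds)]
    pool = []
    for i in range(n_pool):
        k = int(rng.integers(1, 3))
        members = [compounds[j] for j in rng.choice(n_compounds, size=k, replace=False)]
        pool.append(cand(i, members))
    owned = [c for c in compounds if rng.random() < 0.3]
    led = initialize_ledger(owned, charge_initial=False)
    alpha = AcquisitionValues(
        alpha=rng.uniform(0, 2, n_pool), candidates=tuple(pool), mc_samples=1, seed=0
    )
    prices = [c.price for c in compounds]
    return pool, led, alpha, prices


class TestProposeBatch:
    def test_no_costs_picks_top_alpha(self):
        rng = np.random.default_rng(0)
        pool = [cand(i, [comp(f"C{i}", price=0.0)]) for i in range(6)]
        a = AcquisitionValues(
            alpha=np.array([0.1, 0.9, 0.3, 0.8, 0.2, 0.5]),
            candidates=tuple(pool),
            mc_samples=1,
            seed=0,
        )
        led = initialize_ledger([])
        prop = propose_batch(
            None, pool, led, CostPolicy(lam=0.0), n_e=2, alpha=a, prices=[1.0]
        )
        assert prop.indices == (1, 3)

    def test_cost_aware_vs_plain_selection(self):
        # two singleton "batches": (alpha 3, cost 0) vs (alpha 4, cost 2), S=1
        free = comp("F", price=0.0)
        priced = comp("P", price=2.0)
        pool = [cand(0, [free]), cand(1, [priced])]
        led = initialize_ledger([])
        a = AcquisitionValues(
            alpha=np.array([3.0, 4.0]), candidates=tuple(pool), mc_samples=1, seed=0
        )
        # lam chosen so S = lam*max alpha/avg p = 1 -> adjusted 3.0 vs 2.0
        lam = 1.0 * np.mean([0.0, 2.0]) / 4.0
        aware = propose_batch(
            None, pool, led, CostPolicy(lam=lam), n_e=1, alpha=a, prices=[0.0, 2.0]
        )
        plain = propose_batch(
            None, pool, led, CostPolicy(lam=0.0), n_e=1, alpha=a, prices=[0.0, 2.0]
        )
        assert aware.indices == (0,)
        assert plain.indices == (1,)

    def test_pool_exhaustion_signal(self):
        pool = [cand(0, [comp("A")])]
        with pytest.raises(PoolExhausted):
            propose_batch(None, pool, initialize_ledger([]), CostPolicy(), n_e=2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        # derived oracle: exhaustive enumeration over all C(12,3) batches
        rng = np.random.default_rng(seed)
        pool, led, alpha, prices = _random_instance(rng)
        lam = float(rng.uniform(0.2, 2.0))
        prop = propose_batch(
            None,
            pool,
            led,
            CostPolicy(lam=lam),
            n_e=3,
            search=SearchOptions(shortlist_size=50),
            alpha=alpha,
            prices=prices,
        )
        S = scaling_factor(alpha, prices, lam)
        a_by_idx = {c.index: float(v) for c, v in zip(alpha.candidates, alpha.alpha)}
        oracle = exhaustive_batch_argmax(pool, a_by_idx, led, S, n_e=3)
        assert prop.adjusted_norm == pytest.approx(oracle.adjusted_norm, abs=1e-9)
        assert prop.indices == oracle.indices

    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_monotone_incremental_cost(self, seed):
        rng = np.random.default_rng(100 + seed)
        pool, led, alpha, prices = _random_instance(rng, n_pool=10)
        costs = []
        for lam in (0.0, 0.5, 1.0, 2.0, 5.0):
            prop = propose_batch(
                None, pool, led, CostPolicy(lam=lam), n_e=3, alpha=alpha, prices=prices
            )
            costs.append(prop.incremental_cost)
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_selected_batch_beats_searched_alternatives(self):
        rng = np.random.default_rng(7)
        pool, led, alpha, prices = _random_instance(rng)
        prop = propose_batch(
            None, pool, led, CostPolicy(lam=1.0), n_e=3, alpha=alpha, prices=prices
        )
        S = scaling_factor(alpha, prices, 1.0)
        a_by_idx = {c.index: float(v) for c, v in zip(alpha.candidates, alpha.alpha)}
        oracle = exhaustive_batch_argmax(pool, a_by_idx, led, S, n_e=3)
        assert prop.adjusted_norm >= oracle.adjusted_norm - 1e-9
        assert prop.adjusted_norm <= prop.raw_norm + 1e-12
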