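"""Cost-adjusted batch acquisition.

Per-candidate acquisition values are Monte-Carlo noisy expected improvement
(improvement of the candidate's latent draw over the per-draw maximum of the
latent function at the observed inputs).  Each value is then penalized by
the inventory-dependent price of the reagents the experiment needs,

    alpha_hat_j = alpha_j - S * c(e_j),      S = lam * max{alpha} / avg{p},

where c sums the prices of compounds that are neither owned nor introduced
by an earlier member of the same batch.  The batch maximizing the sum of
adjusted values is selected; with lam = 0 this reduces exactly to ranking
by raw acquisition values (standard batch BO).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import ExperimentCandidate
from .ledger import InventoryLedger
from .surrogate import SurrogateModel, posterior_cov, posterior_joint, posterior_predict

__all__ = [
    "AcquisitionValues",
    "CostPolicy",
    "BatchProposal",
    "PoolExhausted",
    "compute_alpha",
    "experiment_cost",
    "scaling_factor",
    "adjusted_alpha",
    "batch_norm",
    "propose_batch",
    "SearchOptions",
]


class PoolExhausted(Exception):
    """Raised when fewer untested candidates remain than the batch size."""


@dataclass
class AcquisitionValues:
    """Non-negative acquisition value per untested candidate."""

    alpha: np.ndarray
    candidates: Tuple[ExperimentCandidate, ...]
    mc_samples: int
    seed: int

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if len(self.alpha) != len(self.candidates):
            raise ValueError("alpha / candidate count mismatch")


@dataclass
class CostPolicy:
    """Cost weight lam and the current scaling value S (lam = 0 => S = 0 => plain BO)."""

    lam: float = 1.0
    scaling: float = 0.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class BatchProposal:
    experiments: Tuple[ExperimentCandidate, ...]
    raw_norm: float
    adjusted_norm: float
    incremental_cost: float
    purchases: Tuple[str, ...] = ()

    @property
    def indices(self) -> Tuple[int, ...]:
        return tuple(c.index for c in self.experiments)


@dataclass
class SearchOptions:
    """Batch-search controls: shortlist size and swap refinement."""

    shortlist_size: int = 50
    max_swap_rounds: int = 20


def compute_alpha(
    model: SurrogateModel,
    pool: Sequence[ExperimentCandidate],
    observed: Optional[Sequence[ExperimentCandidate]] = None,
    mc_samples: int = 512,
    seed: int = 0,
) -> AcquisitionValues:
    """Monte-Carlo noisy expected improvement for each pool candidate.

    Joint posterior draws are taken over (observed inputs, candidate); the
    incumbent of each draw is the max over the observed inputs.  Common
    random numbers are shared across candidates for variance reduction.
    """
    pool = tuple(pool)
    if not pool:
        raise ValueError("pool must be non-empty")
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    observed = tuple(observed) if observed is not None else model.train_candidates

    mu_t, C_tt = posterior_joint(model, observed)
    post_p = posterior_predict(model, pool)
    C_pt = posterior_cov(model, pool, observed)

    # factorize the observed-block covariance once
    w, V = np.linalg.eigh(0.5 * (C_tt + C_tt.T))
    w = np.clip(w, 0.0, None)
    L_t = V * np.sqrt(w)

    rng = np.random.default_rng(seed)
    Z_t = rng.standard_normal((mc_samples, len(observed)))
    F_t = mu_t[None, :] + Z_t @ L_t.T                      # draws at observed inputs
    incumbent = F_t.max(axis=1)                            # noisy incumbent per draw

    # conditional draw of each candidate given the observed-block draw
    w_floor = max(w.max(initial=0.0) * 1e-12, 1e-300)
    w_inv = np.zeros_like(w)
    np.divide(1.0, w, out=w_inv, where=w > w_floor)
    A = (C_pt @ V) * w_inv[None, :]                        # pool x n_eig
    cond_mean = post_p.mu[:, None] + (A @ V.T) @ (F_t - mu_t[None, :]).T  # pool x S
    cond_var = post_p.sigma**2 - np.einsum("ij,ij->i", A * w[None, :], A)
    cond_sd = np.sqrt(np.clip(cond_var, 0.0, None))

    eps = rng.standard_normal(mc_samples)                  # shared across candidates
    draws = cond_mean + cond_sd[:, None] * eps[None, :]
    improvement = np.clip(draws - incumbent[None, :], 0.0, None)
    alpha = improvement.mean(axis=1)
    return AcquisitionValues(alpha=alpha, candidates=pool, mc_samples=mc_samples, seed=seed)


def experiment_cost(
    candidate: ExperimentCandidate,
    ledger: InventoryLedger,
    earlier_in_batch: Sequence[ExperimentCandidate] = (),
) -> float:
    """Price of the compounds the experiment needs that are not yet covered.

    A compound is free when it is owned in the ledger or appears in an
    earlier member of the same batch.
    """
    covered: Set[str] = set(ledger.owned)
    for earlier in earlier_in_batch:
        covered.update(c.id for c in earlier.compounds)
    cost = 0.0
    for comp in candidate.compounds:
        if comp.id not in covered:
            cost += comp.price
            covered.add(comp.id)
    return cost


def scaling_factor(alpha: AcquisitionValues, prices: Sequence[float], lam: float) -> float:
    """S = lam * max{alpha} / avg{p}; S = 0 when lam = 0."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0.0:
        return 0.0
    if len(alpha.alpha) == 0:
        raise ValueError("alpha must be non-empty")
    prices = np.asarray(list(prices), dtype=np.float64)
    avg_p = float(prices.mean()) if prices.size else 0.0
    if avg_p <= 0:
        raise ZeroDivisionError(
            "average compound price is zero: the cost adjustment is meaningless; "
            "set lam = 0 or supply positive prices"
        )
    return lam * float(alpha.alpha.max()) / avg_p


def adjusted_alpha(alpha_j: float, cost_j: float, S: float) -> float:
    """alpha_hat = alpha - S * cost; may be negative (no clipping)."""
    return alpha_j - S * cost_j


def _batch_cost_and_purchases(
    experiments: Sequence[ExperimentCandidate], ledger: InventoryLedger
) -> Tuple[float, Tuple[str, ...]]:
    """Total new money a batch needs; each unowned compound charged once."""
    covered: Set[str] = set(ledger.owned)
    cost = 0.0
    purchases: List[str] = []
    for cand in experiments:
        for comp in cand.compounds:
            if comp.id not in covered:
                cost += comp.price
                covered.add(comp.id)
                purchases.append(comp.id)
    return cost, tuple(purchases)


def _make_proposal(
    experiments: Sequence[ExperimentCandidate],
    alpha_by_index: dict,
    ledger: InventoryLedger,
    S: float,
) -> BatchProposal:
    raw = float(sum(alpha_by_index[c.index] for c in experiments))
    cost, purchases = _batch_cost_and_purchases(experiments, ledger)
    return BatchProposal(
        experiments=tuple(experiments),
        raw_norm=raw,
        adjusted_norm=raw - S * cost,
        incremental_cost=cost,
        purchases=purchases,
    )


def batch_norm(batch: BatchProposal, adjusted: bool = False) -> float:
    """Sum of raw acquisition values, or the cost-adjusted sum."""
    return batch.adjusted_norm if adjusted else batch.raw_norm


def propose_batch(
    model: SurrogateModel,
    pool: Sequence[ExperimentCandidate],
    ledger: InventoryLedger,
    policy: CostPolicy,
    n_e: int = 5,
    search: Optional[SearchOptions] = None,
    seed: int = 0,
    mc_samples: int = 512,
    alpha: Optional[AcquisitionValues] = None,
    prices: Optional[Sequence[float]] = None,
) -> BatchProposal:
    """Select the batch of ``n_e`` pool candidates maximizing the adjusted norm.

    Search: shortlist the top-M candidates by individually cost-adjusted
    value, build the batch greedily (within-batch cost zeroing recomputed
    after each pick), then pairwise-swap refine.  With lam = 0 this is exact
    top-``n_e`` selection by raw acquisition value.  Ties break on candidate
    index.  Raises :class:`PoolExhausted` when the pool is too small.
    """
    pool = tuple(pool)
    if len(pool) < n_e:
        raise PoolExhausted(f"pool has {len(pool)} candidates, batch size is {n_e}")
    search = search or SearchOptions()

    if alpha is None:
        alpha = compute_alpha(model, pool, mc_samples=mc_samples, seed=seed)
    alpha_by_index = {c.index: float(a) for c, a in zip(alpha.candidates, alpha.alpha)}

    if policy.lam == 0.0:
        S = 0.0
    else:
        if prices is None:
            seen: Set[str] = set()
            prices = []
            for cand in pool + model.train_candidates:
                for comp in cand.compounds:
                    if comp.id not in seen:
                        seen.add(comp.id)
                        prices.append(comp.price)
        S = scaling_factor(alpha, prices, policy.lam)
    policy.scaling = S

    # deterministic order: adjusted value under current inventory, then index
    def solo_key(c: ExperimentCandidate):
        a_hat = adjusted_alpha(alpha_by_index[c.index], experiment_cost(c, ledger), S)
        return (-a_hat, c.index)

    ranked = sorted(pool, key=solo_key)
    shortlist = ranked[: max(search.shortlist_size, n_e)]

    # greedy construction with within-batch cost dedup
    batch: List[ExperimentCandidate] = []
    remaining = list(shortlist)
    for _ in range(n_e):
        best_c, best_key = None, None
        for c in remaining:
            a_hat = adjusted_alpha(
                alpha_by_index[c.index], experiment_cost(c, ledger, batch), S
            )
            key = (-a_hat, c.index)
            if best_key is None or key < best_key:
                best_c, best_key = c, key
        batch.append(best_c)
        remaining.remove(best_c)

    def adj_norm(members: Sequence[ExperimentCandidate]) -> float:
        raw = sum(alpha_by_index[c.index] for c in members)
        cost, _ = _batch_cost_and_purchases(members, ledger)
        return raw - S * cost

    # swap refinement over the shortlist: single swaps, then pair swaps
    # (cost coupling via shared compounds can require inserting two
    # candidates at once before any single swap helps)
    current = adj_norm(batch)
    for _ in range(search.max_swap_rounds):
        improved = False
        for i in range(len(batch)):
            for c in remaining:
                trial = batch.copy()
                trial[i] = c
                val = adj_norm(trial)
                if val > current + 1e-12:
                    remaining.append(batch[i])
                    batch = trial
                    remaining.remove(c)
                    current = val
                    improved = True
        if not improved and n_e >= 2 and len(remaining) >= 2:
            for i, j in itertools.combinations(range(n_e), 2):
                for c1, c2 in itertools.combinations(remaining, 2):
                    trial = batch.copy()
                    trial[i], trial[j] = c1, c2
                    val = adj_norm(trial)
                    if val > current + 1e-12:
                        remaining.extend([batch[i], batch[j]])
                        batch = trial
                        remaining.remove(c1)
                        remaining.remove(c2)
                        current = val
                        improved = True
                        break
                if improved:
                    break
        if not improved:
            break

    batch.sort(key=lambda c: c.index)
    return _make_proposal(batch, alpha_by_index, ledger, S)


def exhaustive_batch_argmax(
    pool: Sequence[ExperimentCandidate],
    alpha_by_index: dict,
    ledger: InventoryLedger,
    S: float,
    n_e: int,
) -> BatchProposal:
    """Brute-force argmax of the adjusted norm over all size-``n_e`` subsets.

    Intended for oracle testing on small pools; ties break on the sorted
    index tuple.
    """
    best: Optional[BatchProposal] = None
    best_key = None
    for combo in itertools.combinations(sorted(pool, key=lambda c: c.index), n_e):
        prop = _make_proposal(combo, alpha_by_index, ledger, S)
        key = (-prop.adjusted_norm, prop.indices)
        if best_key is None or key < best_key:
            best, best_key = prop, key
    return best
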