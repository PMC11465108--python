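"""Campaign orchestration: cost-aware BO, standard BO, and random sampling.

Each iteration fits the surrogate on everything observed so far, scores the
untested pool, selects a batch, charges any newly needed compounds to the
inventory ledger, and looks the yields up from the design-space table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .acquisition import (
    BatchProposal,
    CostPolicy,
    SearchOptions,
    _batch_cost_and_purchases,
    compute_alpha,
    propose_batch,
)
from .ledger import initialize_ledger
from .surrogate import FitSettings, fit_surrogate

__all__ = [
    "CampaignConfig",
    "IterationRecord",
    "RunTrace",
    "EnsembleSummary",
    "run_campaign",
    "run_ensemble",
    "spend_at_threshold",
]

POLICIES = ("cibo", "bo", "random")


@dataclass
class CampaignConfig:
    policy: str = "cibo"
    lam: float = 1.0
    batch_size: int = 5
    n_iterations: int = 20
    seed: int = 0
    stop_yield: Optional[float] = None
    hard_stop: bool = False
    charge_initial: bool = True
    mc_samples: int = 512
    shortlist_size: int = 50
    gp_restarts: int = 3
    gp_optimize: bool = True

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.stop_yield is not None and not (0 <= self.stop_yield <= 100):
            raise ValueError("stop_yield must lie in [0, 100]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class IterationRecord:
    iteration: int
    batch_indices: Tuple[int, ...]
    best_yield: float
    cumulative_spend: float
    purchases: Tuple[str, ...] = ()
    raw_norm: Optional[float] = None
    adjusted_norm: Optional[float] = None
    alpha_max: Optional[float] = None


@dataclass
class RunTrace:
    config: CampaignConfig
    records: List[IterationRecord] = field(default_factory=list)
    terminal_iteration: Optional[int] = None
    exhausted: bool = False

    @property
    def best_yields(self) -> np.ndarray:
        return np.array([r.best_yield for r in self.records])

    @property
    def spends(self) -> np.ndarray:
        return np.array([r.cumulative_spend for r in self.records])

    @property
    def observed_indices(self) -> List[int]:
        out: List[int] = []
        for r in self.records:
            out.extend(r.batch_indices)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "best_yield": [r.best_yield for r in self.records],
                "cumulative_spend": [r.cumulative_spend for r in self.records],
                "batch_indices": [";".join(map(str, r.batch_indices)) for r in self.records],
                "purchases": [";".join(r.purchases) for r in self.records],
            }
        )

    def to_json_summary(self) -> str:
        return json.dumps(
            {
                "policy": self.config.policy,
                "lam": self.config.lam,
                "seed": self.config.seed,
                "batch_size": self.config.batch_size,
                "n_iterations_run": len(self.records) - 1,
                "final_best_yield": float(self.records[-1].best_yield),
                "total_spend": float(self.records[-1].cumulative_spend),
                "terminal_iteration": self.terminal_iteration,
                "exhausted": self.exhausted,
            },
            indent=2,
        )


@dataclass
class EnsembleSummary:
    mean_best_yield: np.ndarray
    std_best_yield: np.ndarray
    mean_spend: np.ndarray
    std_spend: np.ndarray
    spend_at_threshold_per_run: Optional[List[Optional[float]]]
    traces: List[RunTrace]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.mean_best_yield)),
                "mean_best_yield": self.mean_best_yield,
                "std_best_yield": self.std_best_yield,
                "mean_spend": self.mean_spend,
                "std_spend": self.std_spend,
            }
        )


def _iteration_seed(master_seed: int, iteration: int, stream: int) -> int:
    """Counter-based sub-seed derivation, independent per (iteration, stream)."""
    ss = np.random.SeedSequence([master_seed, iteration, stream])
    return int(ss.generate_state(1)[0])


def run_campaign(space, init_subset: Sequence[int], config: CampaignConfig) -> RunTrace:
    """Run one seeded campaign on a lookup design space.

    ``init_subset`` indexes the candidates observed before iteration one;
    their compounds seed the inventory (charged unless
    ``config.charge_initial`` is False, each compound once).
    """
    by_index = {c.index: c for c in space.candidates}
    unknown = [i for i in init_subset if i not in by_index]
    if unknown:
        raise ValueError(f"init_subset references unknown candidate indices: {unknown}")
    if not init_subset:
        raise ValueError("init_subset must be non-empty")

    init = [by_index[i] for i in init_subset]
    init_ids = set(init_subset)
    pool = [c for c in space.candidates if c.index not in init_ids]

    init_compounds = {}
    for cand in init:
        for comp in cand.compounds:
            init_compounds.setdefault(comp.id, comp)
    ledger = initialize_ledger(init_compounds.values(), charge_initial=config.charge_initial)

    observed = list(init)
    observed_yields = [c.yield_observed for c in init]
    trace = RunTrace(config=config)
    best = max(observed_yields)
    trace.records.append(
        IterationRecord(
            iteration=0,
            batch_indices=tuple(sorted(init_subset)),
            best_yield=best,
            cumulative_spend=ledger.cumulative_spend(),
            purchases=tuple(p.compound_id for p in ledger.purchases),
        )
    )
    if config.stop_yield is not None and best >= config.stop_yield:
        trace.terminal_iteration = 0
        if config.hard_stop:
            return trace

    all_prices = [c.price for c in space.compounds.values()]
    search = SearchOptions(shortlist_size=config.shortlist_size)

    for it in range(1, config.n_iterations + 1):
        if len(pool) < config.batch_size:
            trace.exhausted = True
            break

        if config.policy == "random":
            rng = np.random.default_rng(_iteration_seed(config.seed, it, stream=2))
            picks = rng.choice(len(pool), size=config.batch_size, replace=False)
            members = sorted((pool[i] for i in picks), key=lambda c: c.index)
            cost, purchases = _batch_cost_and_purchases(members, ledger)
            batch = BatchProposal(
                experiments=tuple(members),
                raw_norm=float("nan"),
                adjusted_norm=float("nan"),
                incremental_cost=cost,
                purchases=purchases,
            )
        else:
            settings = FitSettings(
                optimize=config.gp_optimize,
                n_restarts=config.gp_restarts,
                seed=_iteration_seed(config.seed, it, stream=0),
            )
            model = fit_surrogate(observed, observed_yields, settings)
            alpha = compute_alpha(
                model,
                pool,
                mc_samples=config.mc_samples,
                seed=_iteration_seed(config.seed, it, stream=1),
            )
            if config.policy == "bo":
                # pure-BO path: rank by raw acquisition value, no cost code
                alpha_by_index = {c.index: float(a) for c, a in zip(alpha.candidates, alpha.alpha)}
                ranked = sorted(pool, key=lambda c: (-alpha_by_index[c.index], c.index))
                members = sorted(ranked[: config.batch_size], key=lambda c: c.index)
                raw = float(sum(alpha_by_index[c.index] for c in members))
                cost, purchases = _batch_cost_and_purchases(members, ledger)
                batch = BatchProposal(
                    experiments=tuple(members),
                    raw_norm=raw,
                    adjusted_norm=raw,
                    incremental_cost=cost,
                    purchases=purchases,
                )
            else:
                policy = CostPolicy(lam=config.lam)
                batch = propose_batch(
                    model,
                    pool,
                    ledger,
                    policy,
                    n_e=config.batch_size,
                    search=search,
                    alpha=alpha,
                    prices=all_prices,
                )

        ledger.commit_batch(batch, iteration=it)
        batch_ids = set(batch.indices)
        pool = [c for c in pool if c.index not in batch_ids]
        for cand in batch.experiments:
            observed.append(cand)
            observed_yields.append(cand.yield_observed)
        best = max(best, max(c.yield_observed for c in batch.experiments))

        trace.records.append(
            IterationRecord(
                iteration=it,
                batch_indices=batch.indices,
                best_yield=best,
                cumulative_spend=ledger.cumulative_spend(),
                purchases=batch.purchases,
                raw_norm=batch.raw_norm,
                adjusted_norm=batch.adjusted_norm,
            )
        )
        if (
            trace.terminal_iteration is None
            and config.stop_yield is not None
            and best >= config.stop_yield
        ):
            trace.terminal_iteration = it
            if config.hard_stop:
                break
    return trace


def run_ensemble(
    space, init_subset: Sequence[int], config: CampaignConfig, n_runs: int
) -> EnsembleSummary:
    """R campaigns with seeds seed+0..seed+R-1 and identical initialization."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    traces = []
    for r in range(n_runs):
        cfg = CampaignConfig(**{**config.__dict__, "seed": config.seed + r})
        traces.append(run_campaign(space, init_subset, cfg))
    n_iter = min(len(t.records) for t in traces)
    Y = np.stack([t.best_yields[:n_iter] for t in traces])
    S = np.stack([t.spends[:n_iter] for t in traces])
    sat = None
    if config.stop_yield is not None:
        sat = [spend_at_threshold(t, config.stop_yield) for t in traces]
    return EnsembleSummary(
        mean_best_yield=Y.mean(axis=0),
        std_best_yield=Y.std(axis=0),
        mean_spend=S.mean(axis=0),
        std_spend=S.std(axis=0),
        spend_at_threshold_per_run=sat,
        traces=traces,
    )


def spend_at_threshold(trace: RunTrace, threshold: float) -> Optional[float]:
    """Cumulative spend when best yield first reaches ``threshold``; None if never."""
    for rec in trace.records:
        if rec.best_yield >= threshold:
            return rec.cumulative_spend
    return None
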