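"""Inventory ledger: which compounds are owned and what has been paid.

Owned compounds have zero marginal cost; each compound is charged exactly
once, the first time a committed batch needs it.  Stock is never decremented
(quantities are carried as a no-op field for forward compatibility).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Set

from .chem import Compound

__all__ = ["PurchaseRecord", "InventoryLedger", "initialize_ledger"]


@dataclass(frozen=True)
class PurchaseRecord:
    compound_id: str
    price: float
    iteration: int


@dataclass
class InventoryLedger:
    owned: Set[str] = field(default_factory=set)
    purchases: List[PurchaseRecord] = field(default_factory=list)
    initial_owned: Set[str] = field(default_factory=set)
    # forward-compatibility only; stock is never decremented
    quantities: dict = field(default_factory=dict)

    def owns(self, compound_id: str) -> bool:
        return compound_id in self.owned

    def acquire(self, compound: Compound, iteration: int) -> float:
        """Add a compound; returns the amount charged (0 if already owned)."""
        if compound.id in self.owned:
            return 0.0
        self.owned.add(compound.id)
        self.purchases.append(
            PurchaseRecord(compound_id=compound.id, price=compound.price, iteration=iteration)
        )
        return compound.price

    def commit_batch(self, batch, iteration: int) -> float:
        """Charge every unowned compound of a batch proposal exactly once.

        Re-committing the same batch charges nothing (idempotent).
        """
        charged = 0.0
        for cand in batch.experiments:
            for comp in cand.compounds:
                charged += self.acquire(comp, iteration)
        return charged

    def cumulative_spend(self, up_to_iteration: Optional[int] = None) -> float:
        """Sum of purchase prices at iterations <= ``up_to_iteration`` (all if None)."""
        return sum(
            p.price
            for p in self.purchases
            if up_to_iteration is None or p.iteration <= up_to_iteration
        )

    # --- serialization: one JSON purchase record per line ---

    def to_jsonl(self) -> str:
        lines = [json.dumps({"initial_owned": sorted(self.initial_owned)})]
        for p in self.purchases:
            lines.append(
                json.dumps(
                    {"compound_id": p.compound_id, "price": p.price, "iteration": p.iteration}
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "InventoryLedger":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = json.loads(lines[0])
        ledger = cls(initial_owned=set(header["initial_owned"]))
        ledger.owned = set(ledger.initial_owned)
        for ln in lines[1:]:
            rec = json.loads(ln)
            ledger.purchases.append(
                PurchaseRecord(rec["compound_id"], rec["price"], rec["iteration"])
            )
            ledger.owned.add(rec["compound_id"])
        return ledger


def initialize_ledger(
    initial_compounds: Iterable[Compound],
    charge_initial: bool = True,
    iteration: int = 0,
) -> InventoryLedger:
    """Ledger owning the initial compounds, optionally charged as purchases."""
    compounds = list(initial_compounds)
    ids = [c.id for c in compounds]
    seen = set()
    for cid in ids:
        if cid in seen:
            raise ValueError(f"duplicate compound id in initial set: {cid!r}")
        seen.add(cid)
    ledger = InventoryLedger(initial_owned=set(ids))
    if charge_initial:
        for c in compounds:
            ledger.owned.add(c.id)
            ledger.purchases.append(PurchaseRecord(c.id, c.price, iteration))
    else:
        ledger.owned = set(ids)
    return ledger
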