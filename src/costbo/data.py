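"""Design-space tables: CSV reading/writing and synthetic benchmark generation.

A design space is a finite table of candidate experiments (reagent
combination x condition levels) with measured yields serving as a lookup
oracle, plus a compound catalog carrying per-gram prices.

The synthetic generator emulates the shape of published HTE benchmarks: a
full factorial grid over ligands/bases/solvents and numeric conditions with
a logistic yield surface, heterogeneous log-normal prices, and a knob
correlating ligand price with ligand quality (+1 = the best ligand is the
most expensive, the adversarial case).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .chem import (
    ROLE_ORDER,
    Compound,
    ConditionSetting,
    ExperimentCandidate,
    Fingerprint,
    featurize_compound,
)

__all__ = [
    "DesignSpace",
    "SyntheticSpec",
    "SchemaError",
    "read_design_space",
    "write_design_space",
    "generate_synthetic_space",
    "select_initialization",
    "minimal_spend",
]


class SchemaError(ValueError):
    """Raised when a design-space table is missing required columns."""


@dataclass
class DesignSpace:
    candidates: List[ExperimentCandidate]
    compounds: Dict[str, Compound]
    condition_schema: Dict[str, List[float]]
    name: str = "design-space"
    currency: str = "$"

    def __post_init__(self):
        for cand in self.candidates:
            for comp in cand.compounds:
                if comp.id not in self.compounds:
                    raise ValueError(
                        f"candidate {cand.index} references uncataloged compound {comp.id!r}"
                    )
            if cand.yield_observed is None:
                raise ValueError(f"candidate {cand.index} has no measured yield")

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def roles(self) -> Tuple[str, ...]:
        present = {c.role for c in self.compounds.values()}
        return tuple(r for r in ROLE_ORDER if r in present)

    def max_yield(self) -> float:
        return max(c.yield_observed for c in self.candidates)

    def candidate_cost(self, candidate: ExperimentCandidate) -> float:
        seen = set()
        total = 0.0
        for comp in candidate.compounds:
            if comp.id not in seen:
                seen.add(comp.id)
                total += comp.price
        return total


# --------------------------------------------------------------------------
# CSV serialization.  One row per candidate; per role: "<role>" (id),
# "<role>_price", "<role>_smiles", "<role>_fp" ("b1;b2;...|n_bits");
# conditions as "cond_<name>"; measured yield in "yield".  Metadata travels
# in "# key=value" comment lines at the top.
# --------------------------------------------------------------------------

def _fp_to_str(fp: Fingerprint) -> str:
    return ";".join(map(str, sorted(fp.bits))) + "|" + str(fp.n_bits)


def _fp_from_str(s: str) -> Fingerprint:
    bits_s, n_bits = s.split("|")
    bits = frozenset(int(b) for b in bits_s.split(";") if b != "")
    return Fingerprint(bits=bits, n_bits=int(n_bits))


def write_design_space(space: DesignSpace, path) -> None:
    rows = []
    for cand in space.candidates:
        row: Dict[str, object] = {}
        for comp in cand.compounds:
            row[comp.role] = comp.id
            row[f"{comp.role}_price"] = comp.price
            row[f"{comp.role}_smiles"] = comp.structure or ""
            row[f"{comp.role}_fp"] = _fp_to_str(comp.fingerprint)
        for cond in cand.conditions:
            row[f"cond_{cond.name}"] = cond.value
        row["yield"] = cand.yield_observed
        rows.append(row)
    df = pd.DataFrame(rows)
    buf = io.StringIO()
    buf.write(f"# name={space.name}\n")
    buf.write(f"# currency={space.currency}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_design_space(
    table_path,
    schema: Optional[Dict[str, object]] = None,
    n_bits: int = 2048,
    radius: int = 2,
) -> DesignSpace:
    """Read and validate a cost-annotated design-space CSV.

    ``schema`` may override the yield column name (``yield_col``) and the
    condition-column prefix (``cond_prefix``).  Compounds need either an
    explicit fingerprint column or a SMILES column to featurize from.
    """
    schema = schema or {}
    yield_col = schema.get("yield_col", "yield")
    cond_prefix = schema.get("cond_prefix", "cond_")

    meta = {}
    with open(table_path, "r", encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line.lstrip("# ").split("=", 1)
            meta[k.strip()] = v.strip()
        elif not line.startswith("#"):
            break
    df = pd.read_csv(io.StringIO(text), comment="#")

    if yield_col not in df.columns:
        raise SchemaError(f"missing required column(s): [{yield_col!r}]")
    roles = [r for r in ROLE_ORDER if r in df.columns]
    if not roles:
        raise SchemaError("no reagent role column found (expected e.g. 'ligand')")
    missing = [f"{r}_price" for r in roles if f"{r}_price" not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    compounds: Dict[str, Compound] = {}
    fp_cache: Dict[str, Fingerprint] = {}

    def compound_for(row, role) -> Compound:
        cid = str(row[role])
        price = float(row[f"{role}_price"])
        if price < 0:
            raise ValueError(f"negative price {price} for compound {cid!r}")
        if cid in compounds:
            existing = compounds[cid]
            if existing.price != price:
                raise ValueError(f"conflicting prices for compound {cid!r}")
            return existing
        fp_col, smi_col = f"{role}_fp", f"{role}_smiles"
        smiles = None
        if smi_col in df.columns and isinstance(row.get(smi_col), str) and row[smi_col]:
            smiles = row[smi_col]
        if fp_col in df.columns and isinstance(row.get(fp_col), str) and row[fp_col]:
            fp = _fp_from_str(row[fp_col])
        elif smiles:
            if smiles not in fp_cache:
                fp_cache[smiles] = featurize_compound(smiles, n_bits=n_bits, radius=radius)
            fp = fp_cache[smiles]
        else:
            raise SchemaError(
                f"compound {cid!r} has neither a fingerprint nor a SMILES column"
            )
        comp = Compound(id=cid, role=role, fingerprint=fp, price=price, structure=smiles)
        compounds[cid] = comp
        return comp

    cond_cols = [c for c in df.columns if c.startswith(cond_prefix)]
    candidates: List[ExperimentCandidate] = []
    seen_keys = set()
    for i, row in df.iterrows():
        comps = tuple(compound_for(row, r) for r in roles)
        conds = tuple(
            ConditionSetting(name=c[len(cond_prefix):], value=float(row[c])) for c in cond_cols
        )
        key = (tuple(c.id for c in comps), tuple((cn.name, cn.value) for cn in conds))
        if key in seen_keys:
            raise ValueError(f"duplicate (compounds, conditions) row at index {i}")
        seen_keys.add(key)
        candidates.append(
            ExperimentCandidate(
                index=int(i),
                compounds=comps,
                conditions=conds,
                yield_observed=float(row[yield_col]),
            )
        )

    schema_levels: Dict[str, List[float]] = {}
    for c in cond_cols:
        schema_levels[c[len(cond_prefix):]] = sorted(df[c].unique().tolist())
    return DesignSpace(
        candidates=candidates,
        compounds=compounds,
        condition_schema=schema_levels,
        name=meta.get("name", "design-space"),
        currency=meta.get("currency", "$"),
    )


# --------------------------------------------------------------------------
# Synthetic benchmark generation
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    n_ligands: int = 12
    n_bases: int = 4
    n_solvents: int = 3
    temperature_levels: Tuple[float, ...] = (60.0, 90.0, 105.0, 120.0)
    concentration_levels: Tuple[float, ...] = (0.05, 0.1, 0.153)
    fp_bits: int = 64
    # log-normal price model per role: (location of log price, scale of log price)
    ligand_price_log: Tuple[float, float] = (3.5, 1.0)
    base_price_log: Tuple[float, float] = (0.5, 0.5)
    solvent_price_log: Tuple[float, float] = (0.0, 0.5)
    priced_roles: Tuple[str, ...] = ("ligand",)
    quality_scale: float = 2.0
    condition_effect_scale: float = 0.6
    interaction_strength: float = 0.0
    noise_scale: float = 0.0
    price_quality_corr: float = 0.0
    #: reassign the minimum ligand price to the worst-quality ligand so the
    #: "cheapest" initialization is also the low-performing one
    cheap_init_worst: bool = False
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_ligands, self.n_bases, self.n_solvents):
            if n < 1:
                raise ValueError("all reagent counts must be >= 1")
        if not (-1.0 <= self.price_quality_corr <= 1.0):
            raise ValueError("price_quality_corr must lie in [-1, 1]")


def _synthetic_ligand_fps(
    qualities: np.ndarray, fp_bits: int, rng: np.random.Generator
) -> List[Fingerprint]:
    """Quality-ordered overlapping bit windows so kernel similarity tracks quality."""
    n = len(qualities)
    order = np.argsort(qualities)              # rank in quality order
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)
    window = 16
    region = max(fp_bits // 2, 2 * n + window)
    fps = []
    for i in range(n):
        r = rank_of[i]
        base_bits = {(2 * r + k) % min(region, fp_bits) for k in range(window)}
        extra = rng.choice(fp_bits, size=4, replace=False)
        fps.append(Fingerprint(bits=frozenset(base_bits) | set(map(int, extra)), n_bits=fp_bits))
    return fps


def _random_fp(fp_bits: int, rng: np.random.Generator, n_on: int = 12) -> Fingerprint:
    on = rng.choice(fp_bits, size=n_on, replace=False)
    return Fingerprint(bits=frozenset(map(int, on)), n_bits=fp_bits)


def _correlated_prices(
    qualities: np.ndarray, corr: float, log_loc: float, log_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    zq = (qualities - qualities.mean()) / (qualities.std() + 1e-12)
    eps = rng.standard_normal(len(qualities))
    eps = (eps - eps.mean()) / (eps.std() + 1e-12)
    zp = corr * zq + np.sqrt(max(0.0, 1.0 - corr**2)) * eps
    return np.exp(log_loc + log_scale * zp)


def generate_synthetic_space(spec: SyntheticSpec) -> DesignSpace:
    """Full factorial candidate grid with a logistic yield surface; fully seeded."""
    rng = np.random.default_rng(spec.seed)

    qualities = rng.normal(0.0, spec.quality_scale, spec.n_ligands)
    ligand_prices = _correlated_prices(
        qualities, spec.price_quality_corr, *spec.ligand_price_log, rng
    )
    if spec.cheap_init_worst:
        worst = int(np.argmin(qualities))
        cheapest = int(np.argmin(ligand_prices))
        p = ligand_prices.copy()
        p[worst], p[cheapest] = p[cheapest], p[worst]
        ligand_prices = p
    ligand_fps = _synthetic_ligand_fps(qualities, spec.fp_bits, rng)

    base_eff = rng.normal(0.0, spec.condition_effect_scale, spec.n_bases)
    solv_eff = rng.normal(0.0, spec.condition_effect_scale, spec.n_solvents)
    temp_eff = rng.normal(0.0, spec.condition_effect_scale, len(spec.temperature_levels))
    conc_eff = rng.normal(0.0, spec.condition_effect_scale, len(spec.concentration_levels))
    base_prices = np.exp(
        spec.base_price_log[0] + spec.base_price_log[1] * rng.standard_normal(spec.n_bases)
    )
    solv_prices = np.exp(
        spec.solvent_price_log[0]
        + spec.solvent_price_log[1] * rng.standard_normal(spec.n_solvents)
    )

    inter_t = rng.normal(
        0.0, spec.interaction_strength, (spec.n_ligands, len(spec.temperature_levels))
    ) if spec.interaction_strength > 0 else np.zeros(
        (spec.n_ligands, len(spec.temperature_levels))
    )

    ligands = [
        Compound(
            id=f"L{i:02d}",
            role="ligand",
            fingerprint=ligand_fps[i],
            price=float(ligand_prices[i]),
        )
        for i in range(spec.n_ligands)
    ]
    bases = [
        Compound(
            id=f"B{i:02d}",
            role="base",
            fingerprint=_random_fp(spec.fp_bits, rng),
            price=float(base_prices[i]) if "base" in spec.priced_roles else 0.0,
        )
        for i in range(spec.n_bases)
    ]
    solvents = [
        Compound(
            id=f"S{i:02d}",
            role="solvent",
            fingerprint=_random_fp(spec.fp_bits, rng),
            price=float(solv_prices[i]) if "solvent" in spec.priced_roles else 0.0,
        )
        for i in range(spec.n_solvents)
    ]

    candidates = []
    idx = 0
    for li, lig in enumerate(ligands):
        for bi, base in enumerate(bases):
            for si, solv in enumerate(solvents):
                for ti, temp in enumerate(spec.temperature_levels):
                    for ci, conc in enumerate(spec.concentration_levels):
                        u = (
                            qualities[li]
                            + base_eff[bi]
                            + solv_eff[si]
                            + temp_eff[ti]
                            + conc_eff[ci]
                            + inter_t[li, ti]
                        )
                        if spec.noise_scale > 0:
                            u += rng.normal(0.0, spec.noise_scale)
                        y = float(np.clip(100.0 / (1.0 + np.exp(-u)), 0.0, 100.0))
                        candidates.append(
                            ExperimentCandidate(
                                index=idx,
                                compounds=(lig, base, solv),
                                conditions=(
                                    ConditionSetting("temperature", float(temp)),
                                    ConditionSetting("concentration", float(conc)),
                                ),
                                yield_observed=y,
                            )
                        )
                        idx += 1

    catalog = {c.id: c for c in ligands + bases + solvents}
    return DesignSpace(
        candidates=candidates,
        compounds=catalog,
        condition_schema={
            "temperature": sorted(spec.temperature_levels),
            "concentration": sorted(spec.concentration_levels),
        },
        name=f"synthetic-{spec.n_ligands}x{spec.n_bases}x{spec.n_solvents}",
    )


def select_initialization(space: DesignSpace, strategy: str = "cheapest") -> List[int]:
    """Initialization candidate indices.

    Strategies: ``cheapest`` (every candidate using the single cheapest
    ligand; price ties break on compound id), ``named:<compound_id>`` (every
    candidate using that compound), ``indices:<i,j,...>`` (verbatim).
    """
    if strategy.startswith("indices:"):
        return [int(s) for s in strategy[len("indices:"):].split(",") if s != ""]
    if strategy.startswith("named:"):
        cid = strategy[len("named:"):]
        if cid not in space.compounds:
            raise KeyError(f"no compound named {cid!r} in the design space")
    elif strategy == "cheapest":
        ligands = [c for c in space.compounds.values() if c.role == "ligand"]
        if not ligands:
            ligands = list(space.compounds.values())
        cid = min(ligands, key=lambda c: (c.price, c.id)).id
    else:
        raise ValueError(f"unknown initialization strategy {strategy!r}")
    out = [cand.index for cand in space.candidates if cid in cand.compound_ids]
    if not out:
        raise KeyError(f"compound {cid!r} appears in no candidate")
    return out


def minimal_spend(space: DesignSpace, target: float) -> Optional[float]:
    """Least compound cost of any single candidate with yield >= target.

    Returns None when no candidate reaches the target.
    """
    costs = [
        space.candidate_cost(c) for c in space.candidates if c.yield_observed >= target
    ]
    return min(costs) if costs else None
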