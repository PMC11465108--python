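"""Small builders shared across the test suite."""

import numpy as np

from costbo.chem import Compound, ConditionSetting, ExperimentCandidate, Fingerprint


def fp(bits, n_bits=16):
    return Fingerprint(bits=frozenset(bits), n_bits=n_bits)


def comp(cid, role="ligand", bits=(), price=0.0, n_bits=16):
    return Compound(id=cid, role=role, fingerprint=fp(bits, n_bits), price=price)


def cand(index, compounds, conditions=(), yield_observed=None):
    conds = tuple(ConditionSetting(name=n, value=v) for n, v in conditions)
    return ExperimentCandidate(
        index=index, compounds=tuple(compounds), conditions=conds, yield_observed=yield_observed
    )


def random_candidates(rng, n, n_bits=24, with_conditions=True, yields=False):
    """n candidates, one random ligand fingerprint each, optional 1-D condition."""
    out = []
    for i in range(n):
        k = rng.integers(3, 9)
        bits = rng.choice(n_bits, size=k, replace=False)
        c = comp(f"L{i}", bits=set(map(int, bits)), n_bits=n_bits, price=float(rng.uniform(1, 50)))
        conds = [("temperature", float(rng.uniform(0, 100)))] if with_conditions else []
        y = float(rng.uniform(0, 100)) if yields else None
        out.append(cand(i, [c], conds, y))
    return out
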