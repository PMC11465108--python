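"""Molecular featurization and the Tanimoto product kernel.

Reagents are represented as fixed-length binary fingerprints; candidate
experiments concatenate one fingerprint block per reagent role with
min-max-scaled numeric condition values.  The kernel used by the surrogate
is a Jaccard-Tanimoto kernel on the binary blocks multiplied by a
squared-exponential kernel on the scaled conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Fingerprint",
    "Compound",
    "ConditionSetting",
    "ExperimentCandidate",
    "CandidateEncoder",
    "featurize_compound",
    "tanimoto_similarity",
    "tanimoto_matrix",
    "kernel_matrix",
    "encode_candidate",
    "ROLE_ORDER",
]

#: canonical ordering of reagent roles inside the concatenated representation
ROLE_ORDER = ("ligand", "base", "solvent", "other")


@dataclass(frozen=True)
class Fingerprint:
    """A binary substructure fingerprint stored as its set of active bits."""

    bits: frozenset
    n_bits: int

    def __post_init__(self):
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        bits = frozenset(int(b) for b in self.bits)
        if bits and (min(bits) < 0 or max(bits) >= self.n_bits):
            raise ValueError(f"active bit outside [0, {self.n_bits})")
        object.__setattr__(self, "bits", bits)

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.n_bits, dtype=np.float64)
        if self.bits:
            v[sorted(self.bits)] = 1.0
        return v


@dataclass(frozen=True)
class Compound:
    """A purchasable reagent with an identity, structure, fingerprint and price."""

    id: str
    role: str
    fingerprint: Fingerprint
    price: float = 0.0
    structure: Optional[str] = None

    def __post_init__(self):
        if self.role not in ROLE_ORDER:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLE_ORDER}")
        if self.price < 0:
            raise ValueError(f"compound {self.id!r} has negative price {self.price}")


@dataclass(frozen=True)
class ConditionSetting:
    """A numeric, cost-free experimental condition (temperature, time, ...)."""

    name: str
    value: float
    cost_free: bool = True


@dataclass(frozen=True)
class ExperimentCandidate:
    """One point of the discrete design space."""

    index: int
    compounds: Tuple[Compound, ...]
    conditions: Tuple[ConditionSetting, ...] = ()
    yield_observed: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "compounds", tuple(self.compounds))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        y = self.yield_observed
        if y is not None and not (0.0 <= y <= 100.0):
            raise ValueError(f"yield_observed {y} outside [0, 100]")

    @property
    def compound_ids(self) -> Tuple[str, ...]:
        return tuple(c.id for c in self.compounds)


def featurize_compound(structure: str, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Deterministic circular-substructure fingerprint of a SMILES string.

    Raises ``ValueError`` naming the input when the structure does not parse.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure string: {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity |a∩b| / |a∪b|; two empty fingerprints count as 1.0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint sizes differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between rows of two 0/1 matrices.

    All-zero row pairs get similarity 1 (empty/empty convention).
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    out = np.ones_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


class CandidateEncoder:
    """Maps candidates to a (binary block, scaled condition) pair of matrices.

    The binary block concatenates, in :data:`ROLE_ORDER`, the union of the
    fingerprints of each role's compounds.  Conditions are min-max scaled to
    [0, 1] using the supplied per-condition ``(min, max)`` ranges.
    """

    def __init__(
        self,
        role_bits: Mapping[str, int],
        condition_scaling: Mapping[str, Tuple[float, float]],
    ):
        self.roles = tuple(r for r in ROLE_ORDER if r in role_bits)
        self.role_bits = {r: int(role_bits[r]) for r in self.roles}
        self.condition_names = tuple(sorted(condition_scaling))
        self.condition_scaling = {k: (float(lo), float(hi)) for k, (lo, hi) in condition_scaling.items()}
        self._offsets = {}
        off = 0
        for r in self.roles:
            self._offsets[r] = off
            off += self.role_bits[r]
        self.n_binary = off

    @classmethod
    def for_candidates(cls, candidates: Sequence[ExperimentCandidate]) -> "CandidateEncoder":
        """Infer role blocks and condition ranges from a candidate set."""
        role_bits = {}
        cond_vals = {}
        for cand in candidates:
            for comp in cand.compounds:
                nb = comp.fingerprint.n_bits
                if role_bits.setdefault(comp.role, nb) != nb:
                    raise ValueError(f"inconsistent fingerprint size for role {comp.role!r}")
            for cond in cand.conditions:
                cond_vals.setdefault(cond.name, []).append(cond.value)
        scaling = {k: (min(v), max(v)) for k, v in cond_vals.items()}
        return cls(role_bits, scaling)

    def encode_binary(self, candidate: ExperimentCandidate) -> np.ndarray:
        v = np.zeros(self.n_binary, dtype=np.float64)
        for comp in candidate.compounds:
            if comp.role not in self._offsets:
                raise ValueError(f"role {comp.role!r} not covered by encoder")
            if comp.fingerprint.n_bits != self.role_bits[comp.role]:
                raise ValueError(f"fingerprint size mismatch for role {comp.role!r}")
            off = self._offsets[comp.role]
            for b in comp.fingerprint.bits:
                v[off + b] = 1.0
        return v

    def encode_conditions(self, candidate: ExperimentCandidate) -> np.ndarray:
        values = {c.name: c.value for c in candidate.conditions}
        unknown = set(values) - set(self.condition_names)
        if unknown:
            raise ValueError(f"unknown condition name(s): {sorted(unknown)}")
        out = np.empty(len(self.condition_names), dtype=np.float64)
        for i, name in enumerate(self.condition_names):
            if name not in values:
                raise ValueError(f"candidate {candidate.index} missing condition {name!r}")
            lo, hi = self.condition_scaling[name]
            span = hi - lo
            out[i] = 0.0 if span == 0 else (values[name] - lo) / span
        return out

    def encode(self, candidate: ExperimentCandidate) -> np.ndarray:
        return np.concatenate([self.encode_binary(candidate), self.encode_conditions(candidate)])

    def encode_matrix(
        self, candidates: Sequence[ExperimentCandidate]
    ) -> Tuple[np.ndarray, np.ndarray]:
        B = np.stack([self.encode_binary(c) for c in candidates]) if candidates else np.zeros((0, self.n_binary))
        X = (
            np.stack([self.encode_conditions(c) for c in candidates])
            if candidates
            else np.zeros((0, len(self.condition_names)))
        )
        return B, X


def encode_candidate(
    candidate: ExperimentCandidate,
    condition_scaling: Mapping[str, Tuple[float, float]],
) -> np.ndarray:
    """Joint numeric representation: role-blocked fingerprint union + scaled conditions."""
    role_bits = {}
    for comp in candidate.compounds:
        role_bits[comp.role] = comp.fingerprint.n_bits
    enc = CandidateEncoder(role_bits, condition_scaling)
    return enc.encode(candidate)


@dataclass
class KernelHyperparams:
    """Hyperparameters of the Tanimoto x squared-exponential product kernel."""

    output_scale: float = 1.0
    lengthscales: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=np.float64))
        if self.output_scale <= 0:
            raise ValueError("output_scale must be positive")
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")


def _rbf(XA: np.ndarray, XB: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    if XA.shape[1] == 0:
        return np.ones((XA.shape[0], XB.shape[0]))
    ls = np.broadcast_to(lengthscales, (XA.shape[1],))
    A = XA / ls
    B = XB / ls
    d2 = np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :] - 2.0 * (A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-0.5 * d2)


def kernel_matrix(
    encoder: CandidateEncoder,
    candidates_a: Sequence[ExperimentCandidate],
    candidates_b: Sequence[ExperimentCandidate],
    hyperparams: KernelHyperparams,
) -> np.ndarray:
    """Pairwise kernel values k(a, b) = s * Tanimoto(bits) * RBF(conditions)."""
    BA, XA = encoder.encode_matrix(candidates_a)
    BB, XB = encoder.encode_matrix(candidates_b)
    K = tanimoto_matrix(BA, BB) * _rbf(XA, XB, hyperparams.lengthscales)
    return hyperparams.output_scale * K
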