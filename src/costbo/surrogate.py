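"""Gaussian-process surrogate over candidate experiments.

Exact GP regression with the Tanimoto x squared-exponential product kernel
from :mod:`costbo.chem`.  Yields are standardized internally (prior mean =
training mean); hyperparameters are set by multi-restart maximization of the
log marginal likelihood unless frozen in :class:`FitSettings`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize

from .chem import (
    CandidateEncoder,
    ExperimentCandidate,
    KernelHyperparams,
    tanimoto_matrix,
    _rbf,
)

__all__ = [
    "FitSettings",
    "SurrogateModel",
    "SurrogatePosterior",
    "fit_surrogate",
    "posterior_predict",
    "posterior_cov",
    "posterior_joint",
    "posterior_sample",
]

JITTER = 1e-6
MAX_JITTER = 1e-2


@dataclass
class FitSettings:
    """Options controlling hyperparameter fitting."""

    optimize: bool = True
    n_restarts: int = 5
    seed: int = 0
    noise_floor: float = 1e-6
    #: used verbatim when ``optimize`` is False
    hyperparams: Optional[KernelHyperparams] = None
    noise_variance: float = 1e-4
    encoder: Optional[CandidateEncoder] = None


@dataclass
class SurrogatePosterior:
    """Predictive mean and standard deviation per candidate (percent-yield scale)."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class SurrogateModel:
    encoder: CandidateEncoder
    train_candidates: Tuple[ExperimentCandidate, ...]
    train_yields: np.ndarray
    hyperparams: KernelHyperparams
    noise_variance: float
    # standardization constants and cached factorization
    y_mean: float = 0.0
    y_scale: float = 1.0
    _chol: Optional[np.ndarray] = field(default=None, repr=False)
    _alpha: Optional[np.ndarray] = field(default=None, repr=False)
    _B_train: Optional[np.ndarray] = field(default=None, repr=False)
    _X_train: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return len(self.train_candidates)


def _chol_with_jitter(K: np.ndarray, base_jitter: float = JITTER) -> Tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating jitter x10 up to MAX_JITTER."""
    jitter = base_jitter
    I = np.eye(K.shape[0])
    while jitter <= MAX_JITTER:
        try:
            return cholesky(K + jitter * I, lower=True), jitter
        except LinAlgError:
            jitter *= 10.0
    raise LinAlgError(
        "kernel matrix not positive definite after jitter escalation; "
        "check for duplicate training rows with conflicting yields"
    )


def _train_kernel(
    T: np.ndarray, X: np.ndarray, hp: KernelHyperparams, noise: float
) -> np.ndarray:
    K = hp.output_scale * T * _rbf(X, X, hp.lengthscales)
    return K + noise * np.eye(K.shape[0])


def _neg_lml(theta: np.ndarray, T: np.ndarray, X: np.ndarray, y: np.ndarray, d_cond: int) -> float:
    s = np.exp(theta[0])
    ls = np.exp(theta[1 : 1 + d_cond]) if d_cond else np.array([1.0])
    noise = np.exp(theta[-1])
    hp = KernelHyperparams(output_scale=s, lengthscales=ls)
    K = _train_kernel(T, X, hp, noise)
    try:
        L, _ = _chol_with_jitter(K)
    except LinAlgError:
        return 1e12
    a = cho_solve((L, True), y)
    n = len(y)
    return float(0.5 * y @ a + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi))


def fit_surrogate(
    train: Sequence[ExperimentCandidate],
    yields: Sequence[float],
    settings: Optional[FitSettings] = None,
) -> SurrogateModel:
    """Fit the GP surrogate to observed (candidate, yield) pairs.

    Raises ``ValueError`` on an empty training set or out-of-range yields.
    """
    settings = settings or FitSettings()
    train = tuple(train)
    y_raw = np.asarray(yields, dtype=np.float64)
    if len(train) == 0:
        raise ValueError("empty training set; prior-only prediction is a separate path")
    if len(train) != len(y_raw):
        raise ValueError("number of candidates and yields differ")
    if np.any(y_raw < 0) or np.any(y_raw > 100):
        raise ValueError("yields must lie in [0, 100]")

    encoder = settings.encoder or CandidateEncoder.for_candidates(train)
    B, X = encoder.encode_matrix(train)
    T = tanimoto_matrix(B, B)
    d_cond = X.shape[1]

    y_mean = float(y_raw.mean())
    y_scale = float(y_raw.std())
    if y_scale < 1e-12:
        y_scale = 1.0
    y = (y_raw - y_mean) / y_scale

    if settings.optimize:
        rng = np.random.default_rng(settings.seed)
        n_params = 2 + d_cond
        lo = np.full(n_params, np.log(1e-3))
        hi = np.full(n_params, np.log(1e3))
        lo[-1] = np.log(max(settings.noise_floor, 1e-8))
        hi[-1] = np.log(1.0)
        best = None
        x0_default = np.zeros(n_params)
        x0_default[-1] = np.log(1e-2)
        starts = [x0_default] + [
            rng.uniform(lo, hi) for _ in range(max(0, settings.n_restarts - 1))
        ]
        for x0 in starts:
            res = minimize(
                _neg_lml,
                x0,
                args=(T, X, y, d_cond),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        hp = KernelHyperparams(
            output_scale=float(np.exp(theta[0])),
            lengthscales=np.exp(theta[1 : 1 + d_cond]) if d_cond else np.array([1.0]),
        )
        noise = float(max(np.exp(theta[-1]), settings.noise_floor))
    else:
        hp = settings.hyperparams or KernelHyperparams()
        noise = float(max(settings.noise_variance, 0.0))
        if noise <= 0:
            noise = settings.noise_floor

    K = _train_kernel(T, X, hp, noise)
    try:
        L = cholesky(K, lower=True)  # noise term usually suffices as jitter
    except LinAlgError:
        L, _ = _chol_with_jitter(K)
    alpha = cho_solve((L, True), y)
    return SurrogateModel(
        encoder=encoder,
        train_candidates=train,
        train_yields=y_raw,
        hyperparams=hp,
        noise_variance=noise,
        y_mean=y_mean,
        y_scale=y_scale,
        _chol=L,
        _alpha=alpha,
        _B_train=B,
        _X_train=X,
    )


def _cross_kernel(model: SurrogateModel, candidates: Sequence[ExperimentCandidate]) -> np.ndarray:
    B, X = model.encoder.encode_matrix(candidates)
    hp = model.hyperparams
    return hp.output_scale * tanimoto_matrix(B, model._B_train) * _rbf(
        X, model._X_train, hp.lengthscales
    )


def _prior_kernel(
    model: SurrogateModel,
    a: Sequence[ExperimentCandidate],
    b: Sequence[ExperimentCandidate],
) -> np.ndarray:
    hp = model.hyperparams
    BA, XA = model.encoder.encode_matrix(a)
    BB, XB = model.encoder.encode_matrix(b)
    return hp.output_scale * tanimoto_matrix(BA, BB) * _rbf(XA, XB, hp.lengthscales)


def posterior_predict(
    model: SurrogateModel, candidates: Sequence[ExperimentCandidate]
) -> SurrogatePosterior:
    """Latent-function posterior mean/std at the given candidates."""
    candidates = list(candidates)
    Ks = _cross_kernel(model, candidates)
    mu_std = Ks @ model._alpha
    v = cho_solve((model._chol, True), Ks.T)
    var = model.hyperparams.output_scale - np.einsum("ij,ji->i", Ks, v)
    var = np.maximum(var, 0.0)
    mu = model.y_mean + model.y_scale * mu_std
    sigma = model.y_scale * np.sqrt(var)
    return SurrogatePosterior(mu=mu, sigma=sigma)


def posterior_cov(
    model: SurrogateModel,
    candidates_a: Sequence[ExperimentCandidate],
    candidates_b: Optional[Sequence[ExperimentCandidate]] = None,
) -> np.ndarray:
    """Posterior covariance of the latent function between two candidate lists."""
    a = list(candidates_a)
    b = a if candidates_b is None else list(candidates_b)
    Ka = _cross_kernel(model, a)
    Kb = Ka if candidates_b is None else _cross_kernel(model, b)
    Kab = _prior_kernel(model, a, b)
    v = cho_solve((model._chol, True), Kb.T)
    C = Kab - Ka @ v
    return model.y_scale**2 * C


def posterior_joint(
    model: SurrogateModel, candidates: Sequence[ExperimentCandidate]
) -> Tuple[np.ndarray, np.ndarray]:
    """Joint posterior (mean vector, covariance matrix) over the candidates."""
    post = posterior_predict(model, candidates)
    C = posterior_cov(model, candidates)
    return post.mu, C


def posterior_sample(
    model: SurrogateModel,
    candidates: Sequence[ExperimentCandidate],
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Seeded draws from the joint posterior; shape (n_samples, n_candidates)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mean, C = posterior_joint(model, candidates)
    C = 0.5 * (C + C.T)
    try:
        L, _ = _chol_with_jitter(C / max(model.y_scale**2, 1e-300))
        L = L * model.y_scale
    except LinAlgError:
        # degenerate covariance: eigen-clip
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, len(candidates)))
    return mean[None, :] + Z @ L.T
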