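"""Slow Feature Analysis and ICA primitives.

Slow Feature Analysis (SFA) finds, for a multidimensional signal x(t),
functions g_i whose outputs y_i(t) = g_i(x(t)) minimise the slowness
objective Δ(y_i) = ⟨ẏ_i²⟩ under three constraints on the training data:
zero mean, unit variance, and pairwise decorrelation (with outputs ordered
by increasing Δ).  Nonlinearity enters through an optional quadratic
expansion of the input; the optimum is then the solution of a single
generalized symmetric eigenproblem on the pair (derivative covariance,
covariance), solved here via rank-truncated whitening for numerical
robustness with degenerate covariances.

The temporal derivative is estimated by forward differences over the sample
interval dt.  Sign ambiguity is resolved deterministically: each projection
column is flipped so its largest-magnitude coefficient is positive, and
each ICA component so its largest-magnitude training output is positive —
place fields then appear as positive bumps.

The ICA step (used for sparse coding at the network's top) maximises a
non-Gaussianity contrast by fixed-point iteration with symmetric
decorrelation (scikit-learn's FastICA).  The log-cosh contrast is used:
it targets the same super-Gaussian structure as a kurtosis contrast but
stays numerically stable on the heavy-tailed activity distributions the
sparse components themselves produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "SignalBatch",
    "SfaModel",
    "IcaModel",
    "quadratic_expand",
    "expanded_dim",
    "delta_value",
    "fit_sfa",
    "apply_sfa",
    "fit_ica",
    "MomentAccumulator",
    "fit_sfa_from_moments",
]

RANK_RTOL = 1e-10  # eigenvalue truncation, relative to leading covariance eigenvalue


@dataclass
class SignalBatch:
    """T x N array of N signal channels sampled every ``dt`` seconds."""

    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("SignalBatch needs a (T >= 2, N) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SignalBatch values must be finite")


def expanded_dim(n: int) -> int:
    """Dimension after quadratic expansion: n + n(n+1)/2."""
    return n + n * (n + 1) // 2


def quadratic_expand(x: np.ndarray) -> np.ndarray:
    """All monomials x_i followed by all products x_i * x_j with i <= j.

    Works on a single vector or on any (..., n) stack of vectors; the
    ordering of the product terms is row-major over the upper triangle:
    (0,0), (0,1), ..., (0,n-1), (1,1), (1,2), ...
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    iu, ju = np.triu_indices(n)
    return np.concatenate([x, x[..., iu] * x[..., ju]], axis=-1)


def delta_value(y: np.ndarray, dt: float = 1.0) -> float:
    """Slowness Δ(y) = mean squared forward-difference derivative."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two samples")
    dy = np.diff(y, axis=0) / dt
    return float(np.mean(dy**2))


# ---------------------------------------------------------------------------
# moment accumulation (streaming-friendly covariance estimation)


class MomentAccumulator:
    """Accumulates the mean, covariance and derivative covariance of an
    expanded signal over chunks, so large pooled-patch batches never need to
    be materialised at once.

    Derivative chunks must be forward differences of *consecutive* samples
    divided by dt; chunk boundaries are the caller's responsibility.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self._n = 0
        self._sum = np.zeros(dim)
        self._outer = np.zeros((dim, dim))
        self._dn = 0
        self._douter = np.zeros((dim, dim))

    def add_samples(self, z: np.ndarray) -> None:
        z = np.asarray(z, dtype=float).reshape(-1, self.dim)
        self._n += len(z)
        self._sum += z.sum(axis=0)
        self._outer += z.T @ z

    def add_derivatives(self, dz: np.ndarray) -> None:
        dz = np.asarray(dz, dtype=float).reshape(-1, self.dim)
        self._dn += len(dz)
        self._douter += dz.T @ dz

    @property
    def n_samples(self) -> int:
        return self._n

    def moments(self):
        if self._n < 2 or self._dn < 1:
            raise ValueError("not enough samples accumulated")
        mean = self._sum / self._n
        cov = self._outer / self._n - np.outer(mean, mean)
        dcov = self._douter / self._dn
        return mean, cov, dcov


@dataclass
class SfaModel:
    """Fitted SFA stage: optional quadratic expansion, centering, projection."""

    input_dim: int
    expansion: str  # "linear" | "quadratic"
    mean_vector: np.ndarray  # (M,) mean of the expanded signal
    projection: np.ndarray  # (M, k)
    delta_values: np.ndarray  # (k,) ascending
    dt: float = 1.0
    extras: dict = field(default_factory=dict)

    @property
    def n_outputs(self) -> int:
        return self.projection.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input channels, got {x.shape[-1]}"
            )
        z = quadratic_expand(x) if self.expansion == "quadratic" else x
        return (z - self.mean_vector) @ self.projection


def fit_sfa_from_moments(
    mean: np.ndarray, cov: np.ndarray, dcov: np.ndarray, k: int,
    input_dim: int, expansion: str, dt: float = 1.0,
    shrinkage: float = 0.0,
) -> SfaModel:
    """Solve the SFA eigenproblem given the expanded-signal moments.

    Rank deficiency is handled by truncating covariance eigenvalues below
    RANK_RTOL of the leading one; the generalized problem is then an
    ordinary symmetric eigenproblem in the whitened basis.

    ``shrinkage`` adds an isotropic ridge of that fraction of the mean
    signal variance to both covariances — the moment-domain equivalent of
    training with additive white observation noise, which keeps the
    projections from latching onto sample-specific low-variance directions
    when the number of training samples is small relative to the expanded
    dimension.
    """
    cov_s, dcov_s = cov, dcov
    if shrinkage > 0.0:
        lam = shrinkage * float(np.trace(cov)) / cov.shape[0]
        cov_s = cov + lam * np.eye(cov.shape[0])
        dcov_s = dcov + (2.0 * lam / dt**2) * np.eye(cov.shape[0])
    w, v = np.linalg.eigh(cov_s)
    keep = w > RANK_RTOL * w[-1]
    rank = int(keep.sum())
    if rank == 0:
        raise ValueError("degenerate covariance: input is constant")
    if k > rank:
        raise ValueError(f"k={k} exceeds covariance rank {rank}")
    whiten = v[:, keep] / np.sqrt(w[keep])
    m = whiten.T @ dcov_s @ whiten
    d, e = np.linalg.eigh((m + m.T) / 2.0)
    proj = whiten @ e[:, :k]
    if shrinkage > 0.0:
        # restore the exact training constraints (zero mean, unit variance,
        # decorrelation) by symmetric re-whitening against the true
        # covariance; the regularized directions are kept
        b = proj.T @ cov @ proj
        bw, bv = np.linalg.eigh((b + b.T) / 2.0)
        if bw[0] <= RANK_RTOL * max(bw[-1], 1.0):
            raise ValueError("shrunk solution degenerate on the true covariance")
        proj = proj @ (bv / np.sqrt(bw)) @ bv.T
        d = np.einsum("ik,ij,jk->k", proj, dcov, proj)
        order = np.argsort(d)
        proj, d = proj[:, order], d[order]
    # deterministic sign: largest-magnitude coefficient positive
    idx = np.argmax(np.abs(proj), axis=0)
    signs = np.sign(proj[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    proj *= signs
    return SfaModel(
        input_dim=input_dim,
        expansion=expansion,
        mean_vector=np.asarray(mean, dtype=float),
        projection=proj,
        delta_values=np.asarray(d[:k], dtype=float),
        dt=dt,
    )


def fit_sfa(batch: SignalBatch, k: int, expansion: str = "linear") -> SfaModel:
    """Fit SFA on a training batch.

    The k outputs on the training data have zero mean, unit variance, are
    pairwise decorrelated, and come ordered by ascending Δ-value.
    """
    if expansion not in ("linear", "quadratic"):
        raise ValueError("expansion must be 'linear' or 'quadratic'")
    x = batch.values
    z = quadratic_expand(x) if expansion == "quadratic" else x
    acc = MomentAccumulator(z.shape[1])
    acc.add_samples(z)
    acc.add_derivatives(np.diff(z, axis=0) / batch.dt)
    mean, cov, dcov = acc.moments()
    return fit_sfa_from_moments(mean, cov, dcov, k, x.shape[1], expansion, batch.dt)


def apply_sfa(model: SfaModel, batch: SignalBatch) -> SignalBatch:
    """Apply fitted slow-feature functions to a new batch."""
    return SignalBatch(model.transform(batch.values), batch.dt)


# ---------------------------------------------------------------------------
# ICA sparse coding


@dataclass
class IcaModel:
    """Linear unmixing into independent components (sparse coding stage)."""

    input_dim: int
    mean_vector: np.ndarray  # (N,)
    unmixing: np.ndarray  # (n_components, N)
    n_components: int
    converged: bool = True

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.input_dim:
            raise ValueError("dimension mismatch")
        return (x - self.mean_vector) @ self.unmixing.T


def fit_ica(
    batch: SignalBatch,
    n_components: int = 32,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> IcaModel:
    """Fit the sparse-coding unmixing by fixed-point ICA (log-cosh contrast).

    Outputs are decorrelated with unit variance on the training data, and
    each component is sign-aligned so its largest-magnitude training value
    is positive.  Non-convergence is reported via ``converged`` (the best
    iterate is still returned).
    """
    x = batch.values
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds channel count")
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            s = ica.fit_transform(x)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                s = ica.fit_transform(x)
    unmixing = ica.components_.copy()
    peaks = np.abs(s).argmax(axis=0)
    signs = np.sign(s[peaks, np.arange(s.shape[1])])
    signs[signs == 0] = 1.0
    unmixing *= signs[:, None]
    return IcaModel(
        input_dim=x.shape[1],
        mean_vector=ica.mean_.copy(),
        unmixing=unmixing,
        n_components=n_components,
        converged=converged,
    )
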