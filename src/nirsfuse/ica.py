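"""Blind source separation and artifact rejection for channel data.

The recording model is x = A s: each channel mixes statistically independent,
non-Gaussian sources through an unknown mixing matrix A.  Estimating the
unmixing matrix W (effectively the pseudo-inverse of A) recovers the sources
s = W x; artifact components are zeroed and the remainder back-projected to
give the cleaned channel data.

FastICA (symmetric fixed-point iteration on whitened data) is implemented
natively here.  Alternative algorithms (Picard, extended Infomax) plug in
through :func:`register_ica_backend` behind the same :class:`ICAModel`
contract.

Because the rejection criterion is inherently heuristic, the default flags
components with large excess kurtosis (spike-like artifacts); it is fully
pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "ICAModel",
    "center_whiten",
    "fastica_fit",
    "unmix",
    "mix",
    "reject_and_reconstruct",
    "default_rejection",
    "clean_channels",
    "register_ica_backend",
    "FastICA",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last delta."""

    def __init__(self, msg: str, last_delta: float):
        super().__init__(msg)
        self.last_delta = last_delta


@dataclass
class ICAModel:
    """Fitted unmixing/mixing pair with the whitening transform that produced it.

    ``unmixing`` maps whitened data to sources; the composite channel-space
    filter is ``unmixing @ whitener``.  ``mixing`` maps sources back to
    (centred) channel space.
    """

    unmixing: np.ndarray  # (n_components, n_components) on whitened data
    mixing: np.ndarray  # (n_channels, n_components)
    whitener: np.ndarray  # (n_components, n_channels)
    channel_means: np.ndarray  # (n_channels,)
    method: str = "fastica"
    seed: int | None = None
    n_iter: int = 0
    tol_reached: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.whitener.shape[1]

    def channel_filter(self) -> np.ndarray:
        """W_total such that s = W_total (x - mean)."""
        return self.unmixing @ self.whitener


def center_whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre rows and whiten: Z = K (X - mean) with cov(Z) = I.

    X is channel-by-sample.  Uses the eigendecomposition of the sample
    covariance; a rank-deficient covariance is an error (reduce the
    requested component count instead).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("center_whiten needs a 2-D matrix with >= 2 channels")
    n_ch, n_s = X.shape
    if n_s <= n_ch:
        raise ValueError(f"need more samples ({n_s}) than channels ({n_ch}) to whiten")
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    cov = (Xc @ Xc.T) / n_s
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending: row 0 = largest variance
    if evals[-1] < 1e-12 * evals[0]:
        raise ValueError(
            "covariance is rank deficient (duplicate or constant channels); "
            "reduce n_components or drop the degenerate channels"
        )
    whitener = (evecs / np.sqrt(evals)).T  # rows scaled by 1/sqrt(eigenvalue)
    return whitener @ Xc, whitener, means


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W
    evals, evecs = np.linalg.eigh(W @ W.T)
    return evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T @ W


_NONLINEARITIES: dict[str, Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]] = {
    "logcosh": lambda u: (np.tanh(u), 1.0 - np.tanh(u) ** 2),
    "cube": lambda u: (u**3, 3.0 * u**2),
    "exp": lambda u: (u * np.exp(-(u**2) / 2), (1 - u**2) * np.exp(-(u**2) / 2)),
}


def fastica_fit(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    nonlinearity: str = "logcosh",
) -> ICAModel:
    """Fit symmetric fixed-point FastICA on channel-by-sample data.

    Deterministic for a fixed seed.  Raises :class:`ConvergenceError` with
    the last iteration delta if ``max_iter`` is exhausted.
    """
    X = np.asarray(X, dtype=float)
    n_ch = X.shape[0]
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError(f"n_components ({n_components}) exceeds channel count ({n_ch})")
    if nonlinearity not in _NONLINEARITIES:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}; choose from {sorted(_NONLINEARITIES)}")
    g = _NONLINEARITIES[nonlinearity]

    Z, whitener, means = center_whiten(X)
    Z = Z[:n_components] if n_components < n_ch else Z
    whitener = whitener[:n_components] if n_components < n_ch else whitener
    n_s = Z.shape[1]

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n_components, n_components)))

    delta = np.inf
    for it in range(1, max_iter + 1):
        gu, gpu = g(W @ Z)
        W_new = (gu @ Z.T) / n_s - np.diag(gpu.mean(axis=1)) @ W
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"FastICA did not converge in {max_iter} iterations (last delta {delta:.3g}); "
            "sources may be Gaussian or max_iter too small",
            delta,
        )

    # mixing: pseudo-inverse of the composite channel-space filter
    mixing = np.linalg.pinv(W @ whitener)
    return ICAModel(
        unmixing=W,
        mixing=mixing,
        whitener=whitener,
        channel_means=means,
        method="fastica",
        seed=seed,
        n_iter=it,
        tol_reached=delta,
        meta={"nonlinearity": nonlinearity, "tol": tol},
    )


def unmix(model: ICAModel, X: np.ndarray) -> np.ndarray:
    """Source activations s = W K (X - mean) for channel-by-sample X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != model.n_channels:
        raise ValueError(f"X has {X.shape[0]} channels but model expects {model.n_channels}")
    return model.channel_filter() @ (X - model.channel_means[:, None])


def mix(model: ICAModel, S: np.ndarray) -> np.ndarray:
    """Back-project sources to channel space and restore channel means."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] != model.n_components:
        raise ValueError(f"S has {S.shape[0]} components but model expects {model.n_components}")
    return model.mixing @ S + model.channel_means[:, None]


def reject_and_reconstruct(model: ICAModel, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero masked (artifact) components and reconstruct the channel data."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (model.n_components,):
        raise ValueError(f"mask length {mask.size} != component count {model.n_components}")
    S = unmix(model, X)
    S[mask] = 0.0
    return mix(model, S)


def default_rejection(sources: np.ndarray, kurtosis_threshold: float = 5.0) -> np.ndarray:
    """Flag components whose excess kurtosis exceeds the threshold.

    Spike and step artifacts concentrate energy in few samples and are
    strongly leptokurtic; oscillatory physiology is platykurtic (a pure
    sinusoid has excess kurtosis -1.5) and survives.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.shape[0] < 1:
        raise ValueError("need at least one component")
    k = stats.kurtosis(sources, axis=1, fisher=True, bias=True)
    return k > kurtosis_threshold


def clean_channels(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    method: str = "fastica",
    kurtosis_threshold: float = 5.0,
) -> tuple[np.ndarray, ICAModel, np.ndarray]:
    """Fit ICA, reject high-kurtosis components, reconstruct.

    Convenience wrapper returning (cleaned data, model, rejection mask).  On
    non-convergence the data are returned unchanged with a warning — an
    unconverged unmixing matrix would inject, not remove, structure.
    """
    if method != "fastica":
        backend = _ICA_BACKENDS.get(method)
        if backend is None:
            raise NotImplementedError(
                f"ICA method {method!r} has no registered backend; register one "
                "with register_ica_backend() or use 'fastica'"
            )
        model = backend(X, n_components=n_components, seed=seed, tol=tol, max_iter=max_iter)
    else:
        try:
            model = fastica_fit(X, n_components=n_components, seed=seed, tol=tol, max_iter=max_iter)
        except ConvergenceError as e:
            warnings.warn(f"ICA not converged ({e}); returning data unchanged", RuntimeWarning)
            return np.asarray(X, dtype=float).copy(), None, None  # type: ignore[return-value]
    S = unmix(model, X)
    mask = default_rejection(S, kurtosis_threshold=kurtosis_threshold)
    return reject_and_reconstruct(model, X, mask), model, mask


_ICA_BACKENDS: dict[str, Callable[..., ICAModel]] = {}


def register_ica_backend(name: str, fit_fn: Callable[..., ICAModel]) -> None:
    """Register an alternative ICA fit (e.g. picard, infomax) by name."""
    _ICA_BACKENDS[name] = fit_fn


# ---------------------------------------------------------------------------
# scikit-learn estimator facade

try:  # pragma: no cover - import guard only
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object  # type: ignore[assignment]
    TransformerMixin = object  # type: ignore[assignment]


class FastICA(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper over the native FastICA fit.

    Follows sklearn orientation: ``X`` is (n_samples, n_features/channels),
    ``transform`` returns (n_samples, n_components) source activations.

    Attributes set by :meth:`fit`: ``model_`` (the :class:`ICAModel`),
    ``components_`` (composite channel-space unmixing filter),
    ``mixing_``, ``mean_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_components: int | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
        nonlinearity: str = "logcosh",
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.nonlinearity = nonlinearity
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.model_ = fastica_fit(
            X.T,
            n_components=self.n_components,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
            nonlinearity=self.nonlinearity,
        )
        self.components_ = self.model_.channel_filter()
        self.mixing_ = self.model_.mixing
        self.mean_ = self.model_.channel_means
        self.n_iter_ = self.model_.n_iter
        return self

    def transform(self, X):
        return unmix(self.model_, np.asarray(X, dtype=float).T).T

    def inverse_transform(self, S):
        return mix(self.model_, np.asarray(S, dtype=float).T).T
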