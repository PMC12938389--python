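"""Seven entropy estimators for single-channel epoch segments.

All estimators take a 1-D signal ``x`` (and an :class:`EntropyConfig`) and
return a scalar in nats (log-energy entropy is in log-energy units).  The
template-matching estimators (approximate, sample, fuzzy) use embedding
dimension m, Chebyshev distance and tolerance r = r_tol x SD(x) (population
SD); permutation entropy uses ordinal patterns of order m_perm with delay
tau; singular spectrum entropy is the Shannon entropy of the normalized
singular values of the lagged (Hankel) trajectory matrix; envelope entropy
is the Shannon entropy of the normalized Hilbert amplitude envelope; log
energy entropy is the summed log of squared amplitudes.

Conventions (documented because published variants differ):

* approximate entropy includes self-matches (Pincus);
* sample entropy counts pairs among the first N-m templates for both
  template lengths and is undefined (NaN) when no matches exist;
* fuzzy entropy mean-centers templates and uses membership
  exp(-(d/r)^fuzzy_power), with N-m templates at both lengths;
* permutation-entropy ties are broken by index order (stable argsort);
* singular-value probabilities use sigma (not sigma^2) normalization by
  default.

``batch_*`` helpers evaluate one metric over a stack of equal-length
signals; they are exact equivalents of the scalar functions and exist
because feature extraction over a cohort is the hot path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from . import _kernels

METRICS: tuple[str, ...] = (
    "singular_spectrum",
    "approximate",
    "sample",
    "fuzzy",
    "permutation",
    "envelope",
    "log_energy",
)

_EPS = float(np.finfo(np.float64).tiny)  # guards log(0) in log-energy entropy


class DegenerateSignal(ValueError):
    pass


@dataclass(frozen=True)
class EntropyConfig:
    """Estimator parameters (defaults follow the analysis protocol)."""

    m_embed: int = 2
    r_tol: float = 0.15
    m_perm: int = 6
    tau: int = 1
    sse_window: int = 500
    fuzzy_power: float = 2.0
    segment: str = "full_epoch"  # or "post_stimulus"
    r_mode: str = "sd"  # "sd": r = r_tol * SD(x); "absolute": r = r_tol
    sse_weights: str = "sigma"  # or "sigma_squared"
    normalize_perm: bool = False

    def __post_init__(self) -> None:
        if self.m_embed < 1:
            raise ValueError("m_embed must be >= 1")
        if self.r_mode == "sd" and not 0 < self.r_tol < 1:
            raise ValueError("r_tol must be in (0, 1) when r_mode='sd'")
        if self.m_perm < 2:
            raise ValueError("m_perm must be >= 2")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.sse_window < 2:
            raise ValueError("sse_window must be >= 2")
        if self.segment not in ("full_epoch", "post_stimulus"):
            raise ValueError("segment must be 'full_epoch' or 'post_stimulus'")
        if self.r_mode not in ("sd", "absolute"):
            raise ValueError("r_mode must be 'sd' or 'absolute'")
        if self.sse_weights not in ("sigma", "sigma_squared"):
            raise ValueError("sse_weights must be 'sigma' or 'sigma_squared'")


DEFAULT_CONFIG = EntropyConfig()


def _as_batch(x: np.ndarray) -> np.ndarray:
    X = np.asarray(x, dtype=np.float64)
    return X[None, :] if X.ndim == 1 else X


def _tolerances(X: np.ndarray, cfg: EntropyConfig) -> np.ndarray:
    if cfg.r_mode == "absolute":
        return np.full(X.shape[0], float(cfg.r_tol))
    return cfg.r_tol * X.std(axis=-1)  # population SD


def _shannon(p: np.ndarray, axis: int = -1) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=axis)


# -- singular spectrum ------------------------------------------------------

def batch_singular_spectrum(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    X = _as_batch(X)
    n = X.shape[-1]
    L = cfg.sse_window
    if n <= L:
        raise ValueError(f"signal length {n} must exceed sse_window {L}")
    traj = sliding_window_view(X, L, axis=-1)  # (B, K, L): rows are lagged windows
    # singular values via the Gram matrix of the smaller side; the entropy of
    # the normalized spectrum is insensitive to the sqrt(eps)-level error this
    # introduces on near-zero singular values (their p ln p terms vanish)
    K = traj.shape[-2]
    if L <= K:
        gram = np.matmul(traj.transpose(0, 2, 1), traj)
    else:
        gram = np.matmul(traj, traj.transpose(0, 2, 1))
    lam = np.linalg.eigvalsh(gram)
    s = np.sqrt(np.clip(lam[..., ::-1], 0.0, None))
    if cfg.sse_weights == "sigma_squared":
        s = s**2
    tot = s.sum(axis=-1, keepdims=True)
    if np.any(tot == 0):
        raise DegenerateSignal("all-zero signal has no singular spectrum")
    return _shannon(s / tot)


def singular_spectrum_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Shannon entropy of normalized singular values of the trajectory matrix."""
    return float(batch_singular_spectrum(x, cfg)[0])


# -- approximate / sample / fuzzy ------------------------------------------

def batch_apen_sampen(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> tuple[np.ndarray, np.ndarray]:
    """(ApEn, SampEn) over a batch; the two share one template-pair sweep."""
    X = np.ascontiguousarray(_as_batch(X))
    if X.shape[-1] <= cfg.m_embed + 1:
        raise ValueError("signal too short for the embedding dimension")
    return _kernels.apen_sampen_batch(X, cfg.m_embed, _tolerances(X, cfg))


def batch_approximate(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    return batch_apen_sampen(X, cfg)[0]


def approximate_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """ApEn(m, r): Phi^m - Phi^(m+1), self-matches included."""
    return float(batch_approximate(x, cfg)[0])


def batch_sample(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    return batch_apen_sampen(X, cfg)[1]


def sample_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """SampEn(m, r) = -ln(A/B); NaN when no template pairs match."""
    return float(batch_sample(x, cfg)[0])


def batch_fuzzy(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    X = np.ascontiguousarray(_as_batch(X))
    if X.shape[-1] <= cfg.m_embed + 1:
        raise ValueError("signal too short for the embedding dimension")
    m = cfg.m_embed
    B = X.shape[0]
    n = X.shape[-1] - m
    n_pairs = n * (n - 1) // 2
    u = np.empty((B, 2, n_pairs))
    _kernels.fuzzy_dists(X, m, _tolerances(X, cfg), u)
    z = u * u if cfg.fuzzy_power == 2.0 else u**cfg.fuzzy_power
    phi = np.exp(-z).mean(axis=-1)  # one vectorized exp over the batch
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(phi[:, 0]) - np.log(phi[:, 1])
    return np.where((phi <= 0).any(axis=1), np.nan, out)


def fuzzy_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """FuzzyEn(m, r): ln phi^m - ln phi^(m+1) with exponential membership."""
    return float(batch_fuzzy(x, cfg)[0])


# -- permutation ------------------------------------------------------------

def batch_permutation(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    X = _as_batch(X)
    m, tau = cfg.m_perm, cfg.tau
    n = X.shape[-1]
    if n < (m - 1) * tau + 1:
        raise ValueError("signal too short for the permutation order")
    idx = np.arange(n - (m - 1) * tau)[:, None] + np.arange(m)[None, :] * tau
    emb = X[:, idx]  # (B, W, m)
    patterns = np.argsort(emb, axis=-1, kind="stable")
    radix = np.asarray([m**k for k in range(m)], dtype=np.int64)
    ids = (patterns * radix).sum(axis=-1)  # injective permutation code
    # run-length count of sorted codes, all rows at once (runs cannot cross
    # row boundaries because every row start is forced to be a boundary)
    B, W = ids.shape
    flat = np.sort(ids, axis=-1).ravel()
    boundary = np.empty(B * W, dtype=bool)
    boundary[0] = True
    boundary[1:] = flat[1:] != flat[:-1]
    boundary[::W] = True
    starts = np.flatnonzero(boundary)
    counts = np.diff(np.append(starts, B * W))
    q = counts / W
    out = np.bincount(starts // W, weights=-q * np.log(q), minlength=B)
    if cfg.normalize_perm:
        out /= math.log(math.factorial(m))
    return out


def permutation_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Shannon entropy of ordinal-pattern frequencies (ties by index order)."""
    return float(batch_permutation(x, cfg)[0])


# -- envelope ---------------------------------------------------------------

def batch_envelope(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    X = _as_batch(X)
    if X.shape[-1] < 8:
        raise ValueError("signal too short for an amplitude envelope")
    env = np.abs(hilbert(X, axis=-1))
    tot = env.sum(axis=-1, keepdims=True)
    if np.any(tot == 0):
        raise DegenerateSignal("all-zero signal has no envelope")
    return _shannon(env / tot)


def envelope_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Shannon entropy of the normalized Hilbert amplitude envelope.

    Maximal (ln N) for a constant envelope; small for an impulse-like one.
    """
    return float(batch_envelope(x, cfg)[0])


# -- log energy -------------------------------------------------------------

def batch_log_energy(X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    X = _as_batch(X)
    return np.log(X**2 + _EPS).sum(axis=-1)


def log_energy_entropy(x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Sum over samples of ln(x_j^2), guarded against zeros."""
    return float(batch_log_energy(x, cfg)[0])


_BATCH = {
    "singular_spectrum": batch_singular_spectrum,
    "approximate": batch_approximate,
    "sample": batch_sample,
    "fuzzy": batch_fuzzy,
    "permutation": batch_permutation,
    "envelope": batch_envelope,
    "log_energy": batch_log_energy,
}

_SCALAR = {
    "singular_spectrum": singular_spectrum_entropy,
    "approximate": approximate_entropy,
    "sample": sample_entropy,
    "fuzzy": fuzzy_entropy,
    "permutation": permutation_entropy,
    "envelope": envelope_entropy,
    "log_energy": log_energy_entropy,
}


def effective_config(cfg: EntropyConfig, n_samples: int) -> EntropyConfig:
    """Clamp the SSE window for short segments (with a warning).

    The configured window is meant for full-length epochs; on shorter
    segments it is shrunk to 2N/3 so the trajectory matrix keeps a
    non-degenerate number of columns.
    """
    if cfg.sse_window < n_samples:
        return cfg
    new_L = max(2, (2 * n_samples) // 3)
    warnings.warn(
        f"sse_window {cfg.sse_window} >= segment length {n_samples}; shrunk to {new_L}",
        stacklevel=2,
    )
    return replace(cfg, sse_window=new_L)


def compute_metric(metric: str, X: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Evaluate one named metric over a (batch, samples) array."""
    if metric not in _BATCH:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRICS}")
    return _BATCH[metric](X, cfg)


def compute_entropy(metric: str, x: np.ndarray, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    return float(_SCALAR[metric](x, cfg))
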