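"""Probability model for per-complex blink counts in SMLM molecular counting.

A photoswitchable fluorophore emits a geometrically distributed number of
blinks before photobleaching, with support B >= 1 (a detected fluorophore
blinks at least once).  Writing the characteristic number of blinks as
``lam``, the single-fluorophore law is

    Pr(B = b) = (1 - e^{-1/lam}) e^{-(b-1)/lam},   b >= 1,

a 1-truncated geometric distribution with success probability
``1 - e^{-1/lam}`` and mean ``1 / (1 - e^{-1/lam})``.  The total blink
count of a complex carrying N independent fluorophores is then negative
binomial with support B >= N:

    p(B | N) = C(B-1, N-1) (e^{1/lam} - 1)^N e^{-B/lam}.

An ensemble of complexes of 1..h labeled subunits with fractions
pi_1..pi_h produces the finite mixture

    p(B) = sum_k pi_k p(B | k),

whose weights and ``lam`` are jointly estimable from blink counts alone
(see :mod:`blinkmix.em`).  All probability arithmetic is carried out in
log space: B routinely reaches hundreds for large ``lam`` and N, where
direct products underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DegenerateModelError

__all__ = [
    "BlinkDataset",
    "MixtureParams",
    "Responsibilities",
    "negbinom_log_pmf",
    "mixture_pmf",
    "mixture_log_pmf",
    "log_likelihood",
    "labeled_mixture_pmf",
]

_WEIGHT_TOL = 1e-8


@dataclass(frozen=True)
class BlinkDataset:
    """Observed blink counts, one per detected macromolecular complex.

    Parameters
    ----------
    counts
        Sequence of positive integers; ``counts[i]`` is the total number
        of blinks emitted by complex ``i`` before photobleaching.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("blink counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 1):
            bad = np.nonzero(counts < 1)[0]
            raise ValueError(
                f"blink counts must be >= 1 (a detected complex blinks at "
                f"least once); offending record indices: {bad[:10].tolist()}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def size(self) -> int:
        """Number of complexes N_T."""
        return int(self.counts.size)

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True)
class MixtureParams:
    """A candidate mixture model: oligomer orders 1..h, weights, and lam.

    ``weights[k-1]`` is the fraction pi_k of complexes with k labeled
    subunits; ``lam`` is the characteristic number of blinks of a single
    fluorophore.
    """

    h: int
    weights: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        if not (isinstance(self.h, (int, np.integer)) and self.h >= 1):
            raise ValueError("h must be a positive integer")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.h,):
            raise ValueError(f"weights must have length h={self.h}")
        if np.any(w < -_WEIGHT_TOL) or np.any(w > 1 + _WEIGHT_TOL):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError("lam must be a positive real")
        object.__setattr__(self, "h", int(self.h))
        object.__setattr__(self, "weights", np.clip(w, 0.0, 1.0))
        object.__setattr__(self, "lam", float(self.lam))


@dataclass(frozen=True)
class Responsibilities:
    """Posterior matrix r of shape (N_T, h): ``r[i, k-1]`` is the
    probability that complex i has k subunits given its blink count."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.size == 0:
            raise ValueError("responsibilities must be a non-empty 2-D matrix")
        if np.any(r < -_WEIGHT_TOL):
            raise ValueError("responsibilities must be non-negative")
        if not np.allclose(r.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("responsibility rows must sum to 1")
        object.__setattr__(self, "r", r)

    @property
    def n_complexes(self) -> int:
        return self.r.shape[0]

    @property
    def h(self) -> int:
        return self.r.shape[1]


def _validate_positive_int(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError(f"{name} must be integer-valued")
        arr = arr.astype(np.int64)
    if np.any(arr < 1):
        raise ValueError(f"{name} must be >= 1")
    return arr


def negbinom_log_pmf(B, N, lam: float):
    """Log-probability of observing B total blinks from N fluorophores.

    Evaluates ``log p(B|N)`` for the negative-binomial blink law with the
    binomial coefficient computed via log-gamma.  Returns ``-inf`` for
    B < N (a complex with N fluorophores emits at least N blinks).

    Parameters broadcast; scalars in give a scalar out.
    """
    if not (np.isscalar(lam) and np.isfinite(lam) and lam > 0):
        raise ValueError("lam must be a positive real")
    B = _validate_positive_int(B, "B")
    N = _validate_positive_int(N, "N")
    B_, N_ = np.broadcast_arrays(B, N)
    B_ = B_.astype(np.int64)
    N_ = N_.astype(np.int64)
    log_coef = gammaln(B_) - gammaln(N_) - gammaln(B_ - N_ + 1)
    out = log_coef + N_ * np.log(np.expm1(1.0 / lam)) - B_ / lam
    out = np.where(B_ < N_, -np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def _component_log_pmf(counts: np.ndarray, h: int, lam: float) -> np.ndarray:
    """Matrix of log p(B_i | k) for k = 1..h; shape (len(counts), h)."""
    B = counts[:, None]
    k = np.arange(1, h + 1)[None, :]
    log_coef = gammaln(B) - gammaln(k) - gammaln(B - k + 1)
    out = log_coef + k * np.log(np.expm1(1.0 / lam)) - B / lam
    return np.where(B < k, -np.inf, out)


def mixture_log_pmf(B, params: MixtureParams):
    """Log of the mixture probability sum_k pi_k p(B|k), via log-sum-exp."""
    scalar_in = np.ndim(B) == 0
    B = np.atleast_1d(_validate_positive_int(B, "B"))
    logp = _component_log_pmf(B, params.h, params.lam)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)[None, :]
    out = logsumexp(logp + logw, axis=1)
    if scalar_in:
        return float(out[0])
    return out


def mixture_pmf(B, params: MixtureParams):
    """Mixture probability of observing B blinks from the ensemble."""
    out = np.exp(mixture_log_pmf(np.atleast_1d(B), params))
    if np.ndim(B) == 0:
        return float(out[0])
    return out


def log_likelihood(data: BlinkDataset, params: MixtureParams) -> float:
    """Total log-likelihood sum_i log[sum_k pi_k p(B_i|k)] of the mixture.

    If some record has zero probability under every positively weighted
    component (e.g. pi_1 = 0 while a count of 1 is present), returns
    ``-inf`` and raises no exception; the offending records are reported
    in a warning.
    """
    if not isinstance(data, BlinkDataset):
        data = BlinkDataset(np.asarray(data))
    per_record = mixture_log_pmf(data.counts, params)
    per_record = np.atleast_1d(per_record)
    if np.any(np.isneginf(per_record)):
        import warnings

        bad = np.nonzero(np.isneginf(per_record))[0]
        warnings.warn(
            f"{bad.size} record(s) have zero mixture probability "
            f"(first indices: {bad[:5].tolist()}); log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    return float(per_record.sum())


def labeled_mixture_pmf(B, true_weights, lam: float, theta: float):
    """Mixture pmf under imperfect labeling.

    ``true_weights`` are the underlying protomer fractions pi'_1..pi'_h;
    each subunit carries an active fluorophore independently with
    probability ``theta``, so a k-mer presents k' <= k detected labels
    with binomial probability q(k'|k).  Complexes with zero detected
    labels are unobservable, hence the renormalization.  Equivalent to
    :func:`mixture_pmf` evaluated at the apparent weights.
    """
    from .labeling import apparent_weights

    true_weights = np.asarray(true_weights, dtype=float)
    if not (0 < theta <= 1):
        raise ValueError("theta must lie in (0, 1]")
    apparent = apparent_weights(true_weights, theta)
    params = MixtureParams(h=len(apparent), weights=apparent, lam=lam)
    return mixture_pmf(B, params)
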