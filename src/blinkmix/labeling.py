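"""Binomial labeling-efficiency model and its inversion.

With labeling efficiency ``theta``, each subunit of a k-mer carries an
active fluorophore independently, so the number of detected labels N on
a k-subunit complex is Binomial(k, theta):

    q(N | k) = C(k, N) (1 - theta)^(k - N) theta^N.

Complexes with zero detected labels are invisible, so the apparent
(detected-label-class) fractions pi relate to the true protomer
fractions pi' through a renormalized binomial thinning:

    pi_k' = sum_{k >= k'} pi'_k q(k' | k) / (1 - sum_k pi'_k q(0 | k)).

The EM fit (on observed blink counts) recovers the apparent weights;
this module maps them back to the true fractions.  Closed forms are
implemented for mixtures up to dimers and up to trimers, and a generic
triangular linear solve handles any maximum order (and cross-checks the
closed forms).  Inversions of noisy EM estimates can land slightly
outside the simplex; negative raw outputs are clipped to zero and
renormalized, with the ``clipped`` flag set.

``theta`` is always a known input, obtained from control experiments; it
is never estimated from the blink data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import binom

from .errors import DegenerateModelError, SingularCorrectionError

__all__ = [
    "CorrectedWeights",
    "binomial_label_pmf",
    "thinning_matrix",
    "apparent_weights",
    "correct_weights",
    "correct_weights_dimer",
    "correct_weights_trimer",
    "correct",
]


@dataclass(frozen=True)
class CorrectedWeights:
    """True protomer fractions recovered from apparent weights.

    ``clipped`` is True when the raw inversion left the simplex (a
    negative fraction) and the result was clipped and renormalized.
    """

    true_weights: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("corrected weights must form a simplex vector")
        object.__setattr__(self, "true_weights", w)


def _check_theta(theta: float) -> float:
    if not (np.isfinite(theta) and 0 < theta <= 1):
        raise ValueError("theta must lie in (0, 1]")
    return float(theta)


def _check_simplex(w, name: str = "weights") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError(f"{name} must be a non-empty vector")
    if np.any(w < -1e-8) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return np.clip(w, 0.0, None)


def binomial_label_pmf(N: int, h: int, theta: float) -> float:
    """Probability that a complex of h subunits carries N active labels."""
    theta = _check_theta(theta)
    if not (0 <= N <= h):
        raise ValueError(f"N must satisfy 0 <= N <= h, got N={N}, h={h}")
    return float(binom.pmf(N, h, theta))


def thinning_matrix(h: int, theta: float) -> np.ndarray:
    """Upper-triangular matrix M with M[k'-1, k-1] = q(k'|k), 1 <= k' <= k <= h."""
    theta = _check_theta(theta)
    kp = np.arange(1, h + 1)[:, None]
    k = np.arange(1, h + 1)[None, :]
    return np.where(kp <= k, binom.pmf(kp, k, theta), 0.0)


def apparent_weights(true_weights, theta: float) -> np.ndarray:
    """Forward map: true protomer fractions -> apparent detected-label fractions.

    The output sums to 1 by construction (the renormalization divides by
    the total observable mass ``1 - sum_k pi'_k q(0|k)``).
    """
    pw = _check_simplex(true_weights, "true_weights")
    theta = _check_theta(theta)
    M = thinning_matrix(len(pw), theta)
    x = M @ pw
    total = x.sum()
    if total <= 0:
        raise DegenerateModelError("no observable mass: all species unlabeled")
    return x / total


def _finalize(raw: np.ndarray) -> CorrectedWeights:
    if np.any(raw < 0):
        warnings.warn(
            f"labeling correction produced negative fraction(s) {raw.round(4).tolist()}; "
            "clipped to 0 and renormalized",
            RuntimeWarning,
            stacklevel=3,
        )
        clipped = np.clip(raw, 0.0, None)
        s = clipped.sum()
        if s <= 0:
            raise SingularCorrectionError("all corrected fractions non-positive")
        return CorrectedWeights(clipped / s, clipped=True)
    return CorrectedWeights(raw / raw.sum(), clipped=False)


def correct_weights(apparent, theta: float) -> CorrectedWeights:
    """Generic inversion of the thinning map for any maximum order h.

    The forward map is projective-linear, ``pi = M pi' / (s . pi')`` with
    column sums ``s`` of M, so the inverse is a triangular solve followed
    by renormalization.
    """
    pi = _check_simplex(apparent, "apparent")
    theta = _check_theta(theta)
    M = thinning_matrix(len(pi), theta)
    try:
        x = solve_triangular(M, pi, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - theta>0 keeps M regular
        raise SingularCorrectionError(str(exc)) from exc
    if x.sum() <= 0:
        raise SingularCorrectionError("inverted weights have non-positive total mass")
    return _finalize(x / x.sum())


def correct_weights_dimer(apparent, theta: float) -> CorrectedWeights:
    """Closed-form inversion for a monomer/dimer mixture (h = 2)."""
    pi = _check_simplex(apparent, "apparent")
    if pi.size != 2:
        raise ValueError("dimer correction expects a length-2 apparent vector")
    theta = _check_theta(theta)
    if pi[1] <= 0:
        return correct_weights(pi, theta)
    q11 = binomial_label_pmf(1, 1, theta)
    q12 = binomial_label_pmf(1, 2, theta)
    q22 = binomial_label_pmf(2, 2, theta)
    p2 = q11 / (q11 - q12 + (pi[0] / pi[1]) * q22)
    return _finalize(np.array([1.0 - p2, p2]))


def correct_weights_trimer(apparent, theta: float) -> CorrectedWeights:
    """Closed-form inversion for a monomer/dimer/trimer mixture (h = 3)."""
    pi = _check_simplex(apparent, "apparent")
    if pi.size != 3:
        raise ValueError("trimer correction expects a length-3 apparent vector")
    theta = _check_theta(theta)
    q11 = binomial_label_pmf(1, 1, theta)
    q12 = binomial_label_pmf(1, 2, theta)
    q13 = binomial_label_pmf(1, 3, theta)
    q22 = binomial_label_pmf(2, 2, theta)
    q23 = binomial_label_pmf(2, 3, theta)
    q33 = binomial_label_pmf(3, 3, theta)
    p1, p2, p3 = pi
    gamma = p3 * (q11 * (q22 - q23) + q12 * q23 - q13 * q22) + q33 * (
        p2 * (q11 - q12) + p1 * q22
    )
    if abs(gamma) < 1e-14:
        raise SingularCorrectionError(
            "trimer correction is singular for these apparent weights"
        )
    pp3 = p3 * q11 * q22 / gamma
    pp2 = q11 * (p2 * q33 - p3 * q23) / gamma
    return _finalize(np.array([1.0 - pp2 - pp3, pp2, pp3]))


def correct(apparent, theta: float) -> CorrectedWeights:
    """Dispatch to the closed form for h <= 3, the generic solve otherwise."""
    pi = np.asarray(apparent, dtype=float)
    if pi.size == 1:
        _check_simplex(pi, "apparent")
        _check_theta(theta)
        return CorrectedWeights(np.array([1.0]), clipped=False)
    if pi.size == 2:
        return correct_weights_dimer(pi, theta)
    if pi.size == 3:
        return correct_weights_trimer(pi, theta)
    return correct_weights(pi, theta)
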