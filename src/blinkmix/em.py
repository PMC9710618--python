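"""Expectation-maximization fitting of the blink-count mixture.

The latent variables are the per-complex oligomer orders.  Each EM cycle
computes posterior responsibilities

    r_k^(i) = pi_k p(B_i | k) / sum_k' pi_k' p(B_i | k'),

then refreshes the weights as column means of r and the blinking
parameter by the closed-form root of the score equation,

    lam = 1 / log[ sum_ik r_k^(i) B_i / sum_ik (r_k^(i) B_i - k r_k^(i)) ],

which jointly maximize the expected complete-data log-likelihood (the
objective separates in the weights and lam, so one E-step followed by
one simultaneous refresh of both is a standard EM cycle and the observed
log-likelihood never decreases).

Internally the fit aggregates the data by unique blink count, which
makes an iteration O(U x h) for U distinct counts rather than
O(N_T x h); results are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DegenerateDataError, DegenerateModelError
from .model import (
    BlinkDataset,
    MixtureParams,
    Responsibilities,
    _component_log_pmf,
)

__all__ = ["EMConfig", "FitResult", "e_step", "update_weights", "m_step_lambda", "fit_em"]


@dataclass(frozen=True)
class EMConfig:
    """Convergence and initialization settings for the EM fit.

    tol
        Relative log-likelihood change below which the fit is declared
        converged.
    max_iter
        Iteration cap; hitting it sets ``converged=False`` on the result.
    n_restarts
        Number of additional randomized initializations tried on top of
        the default one; the fit with the highest final log-likelihood
        wins.  Mixture likelihoods are multimodal, so a few restarts
        guard against poor local optima.
    seed
        Seed for the restart randomization.
    lam_bounds
        Clamp interval for the lam update, guarding against numerical
        escape on degenerate data.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 5
    seed: int | None = None
    lam_bounds: tuple[float, float] = (1e-3, 1e3)

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")
        lo, hi = self.lam_bounds
        if not (0 < lo < hi):
            raise ValueError("lam_bounds must satisfy 0 < min < max")


@dataclass
class FitResult:
    """Outcome of one EM fit.

    ``aic`` is filled by :mod:`blinkmix.selection`; ``loglik_trace``
    records the observed log-likelihood at each iteration of the winning
    run (useful for monotonicity diagnostics).
    """

    params: MixtureParams
    loglik: float
    n_iter: int
    converged: bool
    responsibilities: Responsibilities
    restarts_used: int = 0
    aic: float | None = None
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def e_step(data: BlinkDataset, params: MixtureParams) -> Responsibilities:
    """Posterior responsibilities of each oligomer order for each complex.

    Rows sum to 1; entries for k > B_i are exactly zero (a k-mer cannot
    emit fewer than k blinks).
    """
    logp = _component_log_pmf(data.counts, params.h, params.lam)
    with np.errstate(divide="ignore"):
        a = logp + np.log(params.weights)[None, :]
    norm = logsumexp(a, axis=1)
    if np.any(np.isneginf(norm)):
        bad = np.nonzero(np.isneginf(norm))[0]
        raise DegenerateModelError(
            f"record(s) {bad[:10].tolist()} (counts "
            f"{data.counts[bad[:10]].tolist()}) have zero probability under "
            f"every positively weighted component"
        )
    r = np.exp(a - norm[:, None])
    return Responsibilities(r)


def update_weights(r: Responsibilities) -> np.ndarray:
    """Mixture weights as the column means of the responsibility matrix."""
    mat = r.r if isinstance(r, Responsibilities) else np.asarray(r, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("responsibility matrix must be non-empty and 2-D")
    return mat.mean(axis=0)


def m_step_lambda(
    data: BlinkDataset,
    r: Responsibilities,
    lam_bounds: tuple[float, float] | None = None,
) -> float:
    """Closed-form maximum-likelihood update of lam given responsibilities.

    Raises :class:`DegenerateDataError` when the denominator
    ``sum_ik (r_k^(i) B_i - k r_k^(i))`` is non-positive, i.e. every
    blink count equals its (soft-)assigned component size and no excess
    blinking remains to estimate lam from.
    """
    mat = r.r if isinstance(r, Responsibilities) else np.asarray(r, dtype=float)
    B = data.counts.astype(float)
    num = float(mat.sum(axis=1) @ B)
    k = np.arange(1, mat.shape[1] + 1)
    den = num - float((mat * k).sum())
    if den <= 0:
        raise DegenerateDataError(
            "every blink count equals its assigned component size; "
            "lam is not identifiable from these data"
        )
    lam = 1.0 / np.log(num / den)
    if lam_bounds is not None:
        lo, hi = lam_bounds
        if lam < lo or lam > hi:
            warnings.warn(
                f"lam update {lam:.4g} outside bounds [{lo:g}, {hi:g}]; clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            lam = float(np.clip(lam, lo, hi))
    return float(lam)


def _default_lam0(counts: np.ndarray) -> float:
    """Method-of-moments lam from the sample mean under a pure-monomer model."""
    bbar = float(counts.mean())
    if bbar <= 1.0:
        return 1.0
    return 1.0 / np.log(bbar / (bbar - 1.0))


def _run_em(
    u: np.ndarray,
    w: np.ndarray,
    h: int,
    pi0: np.ndarray,
    lam0: float,
    config: EMConfig,
) -> tuple[np.ndarray, float, float, int, bool, np.ndarray]:
    """Run one EM chain on unique counts ``u`` with multiplicities ``w``."""
    n = w.sum()
    pi = pi0.copy()
    lam = lam0
    ks = np.arange(1, h + 1, dtype=float)
    # lam-independent pieces of log p(B|k): binomial coefficient and support mask
    B = u.astype(float)[:, None]
    log_coef = gammaln(B) - gammaln(ks)[None, :] - gammaln(B - ks[None, :] + 1.0)
    log_coef = np.where(B < ks[None, :], -np.inf, log_coef)
    wu = w * u  # per-unique-count total blinks
    num = float(wu.sum())
    trace = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for n_iter in range(1, config.max_iter + 1):
            a = log_coef + ks * np.log(np.expm1(1.0 / lam)) - B / lam + np.log(pi)
            amax = a.max(axis=1)
            finite = amax > -np.inf
            if not finite.all():
                bad = np.nonzero(~finite)[0]
                raise DegenerateModelError(
                    f"blink count(s) {u[bad[:10]].tolist()} have zero probability "
                    f"under every positively weighted component"
                )
            r = np.exp(a - amax[:, None])
            rowsum = r.sum(axis=1)
            ll = float(w @ (np.log(rowsum) + amax))
            trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
                converged = True
                break
            ll_prev = ll
            r /= rowsum[:, None]
            pi = w @ r / n
            den = num - float(w @ (r @ ks))
            if den <= 0:
                raise DegenerateDataError(
                    "every blink count equals its assigned component size; "
                    "lam is not identifiable from these data"
                )
            lam = float(np.clip(1.0 / np.log(num / den), *config.lam_bounds))
    return pi, lam, trace[-1], n_iter, converged, np.asarray(trace)


def fit_em(
    data: BlinkDataset,
    h: int,
    config: EMConfig | None = None,
    init: MixtureParams | None = None,
) -> FitResult:
    """Fit an h-component blink-count mixture by EM.

    Alternates the responsibility computation with the closed-form
    weight and lam refresh until the relative log-likelihood change
    drops below ``config.tol`` or ``config.max_iter`` is reached.  The
    default initialization (uniform weights; lam from the monomer
    method of moments) is always tried; ``config.n_restarts``
    randomized initializations are added, and the highest final
    log-likelihood wins (ties broken toward smaller lam).

    Parameters
    ----------
    data
        Observed blink counts.
    h
        Maximum oligomer order of the candidate model.
    config
        EM settings; defaults to ``EMConfig()``.
    init
        Optional explicit starting point used instead of the default
        initialization (restarts are still added on top).
    """
    if config is None:
        config = EMConfig()
    if not isinstance(data, BlinkDataset):
        data = BlinkDataset(np.asarray(data))
    if h < 1:
        raise ValueError("h must be >= 1")
    counts = data.counts
    if counts.max() < h:
        warnings.warn(
            f"maximum blink count {counts.max()} is below h={h}; the largest "
            f"component(s) have no support in these data",
            RuntimeWarning,
            stacklevel=2,
        )

    u, w = np.unique(counts, return_counts=True)
    w = w.astype(float)

    lam_mom = _default_lam0(counts)
    starts: list[tuple[np.ndarray, float]] = []
    if init is not None:
        if init.h != h:
            raise ValueError("init.h must equal h")
        starts.append((init.weights.copy(), init.lam))
    else:
        starts.append((np.full(h, 1.0 / h), lam_mom))
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_restarts):
        pi0 = rng.dirichlet(np.ones(h))
        lam0 = lam_mom * rng.uniform(0.5, 2.0)
        starts.append((pi0, float(np.clip(lam0, *config.lam_bounds))))

    best = None
    for pi0, lam0 in starts:
        pi, lam, ll, n_iter, converged, trace = _run_em(u, w, h, pi0, lam0, config)
        cand = (ll, -lam, pi, n_iter, converged, trace)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    ll, neg_lam, pi, n_iter, converged, trace = best
    params = MixtureParams(h=h, weights=pi / pi.sum(), lam=-neg_lam)
    resp = e_step(data, params)
    return FitResult(
        params=params,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        responsibilities=resp,
        restarts_used=config.n_restarts,
        loglik_trace=trace,
    )
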