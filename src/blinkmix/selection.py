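"""AIC scoring and selection among candidate mixture orders.

The number of free parameters of an h-component blink mixture is k = h:
h - 1 free weights (they sum to 1) plus the blinking parameter lam.  The
default score is ``AIC = 2k - L`` with L the mixture log-likelihood —
note the single factor on L — matching the counting convention this
method was published with; the textbook form ``2k - 2L`` is available
via ``form="standard"``.  The two differ only in how strongly likelihood
gains are weighed against the per-component penalty, which can shift
selection boundaries for borderline mixtures.

A low AIC supports a model but is not definitive: candidates within
ΔAIC < 2 of the winner are reported as near-ties, and with small trimer
fractions the under-parameterized monomer/dimer model can win even when
the data contain trimers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .em import EMConfig, FitResult, fit_em
from .model import BlinkDataset

__all__ = ["ModelComparison", "aic", "select_model"]

_TIE_TOL = 1e-9


def aic(fit: FitResult, h: int, form: str = "paper") -> float:
    """AIC score of a converged fit with k = h free parameters."""
    if not np.isfinite(fit.loglik):
        raise ValueError("AIC requires a finite log-likelihood")
    if form == "paper":
        return 2.0 * h - fit.loglik
    if form == "standard":
        return 2.0 * h - 2.0 * fit.loglik
    raise ValueError(f"unknown AIC form {form!r}; use 'paper' or 'standard'")


@dataclass
class ModelComparison:
    """Fits of h = 1..h_max with their AIC scores and the selected order.

    ``near_ties`` lists candidate orders whose AIC is within 2 of the
    winner — a warning that the data do not firmly discriminate.
    """

    candidates: list[tuple[int, FitResult]]
    aic_values: np.ndarray
    selected_h: int
    near_ties: list[int] = field(default_factory=list)

    @property
    def selected(self) -> FitResult:
        for h, fit in self.candidates:
            if h == self.selected_h:
                return fit
        raise LookupError(f"no candidate with h={self.selected_h}")


def select_model(
    data: BlinkDataset,
    h_max: int,
    config: EMConfig | None = None,
    aic_form: str = "paper",
) -> ModelComparison:
    """Fit mixtures of order 1..h_max and select the minimum-AIC model.

    Exact ties are broken toward the smaller order (parsimony).  A
    candidate whose fit fails is excluded with a warning rather than
    aborting the comparison.
    """
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    candidates: list[tuple[int, FitResult]] = []
    scores: list[float] = []
    for h in range(1, h_max + 1):
        try:
            fit = fit_em(data, h, config=config)
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            warnings.warn(
                f"candidate h={h} failed to fit ({exc}); excluded from selection",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        fit.aic = aic(fit, h, form=aic_form)
        candidates.append((h, fit))
        scores.append(fit.aic)
    if not candidates:
        raise RuntimeError("every candidate model failed to fit")
    scores_arr = np.asarray(scores)
    best_idx = 0
    for i in range(1, len(candidates)):
        if scores_arr[i] < scores_arr[best_idx] - _TIE_TOL:
            best_idx = i
    selected_h = candidates[best_idx][0]
    near = [
        h
        for (h, _), s in zip(candidates, scores_arr)
        if h != selected_h and s - scores_arr[best_idx] < 2.0
    ]
    return ModelComparison(
        candidates=candidates,
        aic_values=scores_arr,
        selected_h=selected_h,
        near_ties=near,
    )
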