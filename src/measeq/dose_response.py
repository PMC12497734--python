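"""Baseline normalisation and Hill-equation dose-response fitting.

Network firing under increasing antagonist concentrations is summarised by
the mean firing rate normalised to the drug-free baseline, and the resulting
inhibition curve r(c) = bottom + (top - bottom) / (1 + (c / IC50)^n) is fitted
by least squares on log-concentration to extract the half-maximal inhibitory
concentration IC50 and the Hill slope n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "normalize_to_baseline", "fit_hill", "hill_curve"]


@dataclass(frozen=True)
class DoseResponseFit:
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    ic50: float
    hill_n: float
    top: float
    bottom: float
    residual_norm: float
    converged: bool

    def predict(self, c: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(c, float), self.ic50, self.hill_n,
                          self.top, self.bottom)


def hill_curve(c: np.ndarray, ic50: float, n: float,
               top: float = 1.0, bottom: float = 0.0) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** n)


def normalize_to_baseline(mfr_per_condition: Sequence[float],
                          baseline_mfr: float) -> list[float]:
    """Responses as fractions of the baseline firing rate (baseline -> 1)."""
    if baseline_mfr <= 0:
        raise ValueError("baseline MFR must be positive")
    return [float(m) / float(baseline_mfr) for m in mfr_per_condition]


def fit_hill(concentrations: Sequence[float], responses: Sequence[float],
             fixed_top: float | None = 1.0,
             fixed_bottom: float | None = 0.0) -> DoseResponseFit:
    """Least-squares Hill fit on log10 concentration with decade multi-start.

    Asymptotes default to fixed (1 and 0: responses are baseline-normalised
    and full block is assumed at saturation); pass ``None`` to free them.
    Unidentifiable data (flat responses, or no IC50 inside a wide bracket of
    the sampled range) yields ``converged=False`` rather than a silent
    answer.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise ValueError("concentrations and responses differ in length")
    if c.size < 4:
        raise ValueError("need at least 4 concentration points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    span = np.log10(c.max() / c.min())
    if span < 2:
        raise ValueError("concentrations must span at least 2 decades")

    logc = np.log10(c)
    free_top = fixed_top is None
    free_bottom = fixed_bottom is None

    def unpack(theta):
        ic50 = 10.0 ** theta[0]
        n = theta[1]
        k = 2
        top = theta[k] if free_top else fixed_top
        k += free_top
        bottom = theta[k] if free_bottom else fixed_bottom
        return ic50, n, top, bottom

    def resid(theta):
        ic50, n, top, bottom = unpack(theta)
        return hill_curve(c, ic50, n, top, bottom) - r

    starts = np.arange(np.floor(logc.min()) - 1, np.ceil(logc.max()) + 1.5, 1.0)
    lo = [logc.min() - 3, 1e-3] + [-1.0] * free_top + [-1.0] * free_bottom
    hi = [logc.max() + 3, 20.0] + [2.0] * free_top + [2.0] * free_bottom

    best = None
    for s in starts:
        theta0 = [s, 1.0] + [1.0] * free_top + [0.0] * free_bottom
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    flat = (r.max() - r.min()) < 0.1
    if best is None or flat:
        ic50, n, top, bottom = unpack(best.x) if best is not None else (np.nan,) * 4
        return DoseResponseFit(tuple(c), tuple(r), float(ic50), float(n),
                               float(top), float(bottom),
                               float(np.nan if best is None else np.sqrt(2 * best.cost)),
                               converged=False)

    ic50, n, top, bottom = unpack(best.x)
    # an IC50 pinned far outside the sampled range is not identified
    inside = logc.min() - 2 <= np.log10(ic50) <= logc.max() + 2
    converged = bool(best.success and inside and n > 0)
    return DoseResponseFit(tuple(c), tuple(r), float(ic50), float(n),
                           float(top), float(bottom),
                           float(np.sqrt(2 * best.cost)), converged)
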