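"""MTT viability, IC50 dose-response fitting and cancer-vs-normal comparison.

The MTT assay reads formazan absorbance at 570 nm with a 690 nm plate
background; viability of a treated well is expressed relative to the
untreated control after blank (medium-only) subtraction.  Survival curves
over a dose series are summarized by the IC50 — the concentration
reducing viability to 50% of control — fitted with a four-parameter
logistic (4PL) on log10 concentration, falling back to log-linear
interpolation between the doses bracketing 50% when the fit cannot
converge.  Replicate IC50s of extract-vs-cell-line pairs are compared
with an unpaired (pooled-variance) two-sided t-test and the usual
significance stars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DEFAULT_DOSES",
    "DoseResponse",
    "IC50Estimate",
    "GroupComparison",
    "FourParameterLogistic",
    "viability_percent",
    "four_param_logistic",
    "fit_ic50",
    "viability_from_plate",
    "compare_groups",
    "significance_tier",
]

#: Serial extract concentrations (ug/ml) of the standard assay design.
DEFAULT_DOSES: tuple[float, ...] = (100.0, 25.0, 6.3, 1.6, 0.4)


@dataclass
class DoseResponse:
    """One survival curve: dose series with per-dose mean viability (%)."""

    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must align")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        d = np.diff(self.concentrations)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("concentrations must be strictly monotone")
        if len(self.concentrations) < 4:
            raise ValueError("need >=4 concentrations for a 4-parameter fit")


@dataclass
class IC50Estimate:
    """IC50 with curve parameters, the method used, and replicate spread."""

    ic50: float
    top: float
    bottom: float
    hill: float
    method: str  # "4pl" or "interpolation"
    extrapolated: bool = False
    sd: float = 0.0
    replicate_ic50s: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sided t-test summary with significance tier."""

    t_statistic: float
    df: int
    p_value: float
    tier: str  # ns / * / ** / ***
    flag: str = ""


def viability_percent(
    well: tuple[float, float],
    control: tuple[float, float],
    blank: tuple[float, float],
) -> tuple[float, bool]:
    """Percent viability of one well relative to the untreated control.

    Each argument is an (A570 signal, A690 background) pair; control and
    blank are plate averages.  corrected = signal - background, and
    viability = 100 * (well_corr - blank_corr) / (control_corr - blank_corr),
    clipped below at 0.  Returns (percent, clipped_flag).
    """
    well_corr = well[0] - well[1]
    control_corr = control[0] - control[1]
    blank_corr = blank[0] - blank[1]
    denom = control_corr - blank_corr
    if denom <= 0:
        raise ValueError(
            "control corrected absorbance must exceed blank (assay failure)"
        )
    pct = 100.0 * (well_corr - blank_corr) / denom
    if pct < 0:
        return 0.0, True
    return pct, False


def four_param_logistic(conc, ic50: float, hill: float, top: float, bottom: float):
    """Descending 4PL survival curve evaluated at concentrations ``conc``.

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill); at c = ic50 the
    curve passes through the midpoint of top and bottom.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


class FourParameterLogistic(RegressorMixin, BaseEstimator):
    """Scikit-learn-style estimator for the descending 4PL survival curve.

    ``fit(concentrations, viability)`` estimates (ic50, hill, top, bottom)
    by bounded least squares on log10 concentration; the fitted IC50 is
    exposed as ``ic50_``.  The top is constrained to at most ``top_max``
    (default 120%) and the bottom to at least ``bottom_min`` (default -5%)
    to stabilize 5-point fits.  When the optimizer cannot converge the
    estimator falls back to log-linear interpolation between the doses
    bracketing 50% viability and records ``method_ = "interpolation"``.
    """

    def __init__(self, top_max: float = 120.0, bottom_min: float = -5.0):
        self.top_max = top_max
        self.bottom_min = bottom_min

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        via = np.asarray(y, dtype=float).ravel()
        curve = DoseResponse(conc, via)  # validates
        order = np.argsort(curve.concentrations)
        c = curve.concentrations[order]
        v = curve.viability[order]

        self.extrapolated_ = not (v.min() <= 50.0 <= v.max())
        fitted = self._fit_4pl(c, v)
        if fitted is not None:
            self.ic50_, self.hill_, self.top_, self.bottom_ = fitted
            self.method_ = "4pl"
        else:
            ic50 = self._interpolate(c, v)
            if ic50 is None:
                raise RuntimeError(
                    "IC50 estimation failed: no 4PL convergence and no doses "
                    "bracketing 50% viability"
                )
            self.ic50_ = ic50
            self.hill_, self.top_, self.bottom_ = np.nan, np.nan, np.nan
            self.method_ = "interpolation"
        if self.extrapolated_ and self.method_ == "4pl" and v.min() > 50.0:
            # all viabilities above 50%: IC50 lies beyond the tested range
            self.ic50_ = max(self.ic50_, float(c.max()))
        return self

    def _fit_4pl(self, c, v):
        p0 = [float(np.sqrt(c.min() * c.max())), 1.0, float(min(v.max(), self.top_max)),
              float(max(v.min(), self.bottom_min))]
        bounds = ([c.min() / 1e3, 0.05, 0.0, self.bottom_min],
                  [c.max() * 1e3, 20.0, self.top_max, 100.0])
        p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, *bounds)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    four_param_logistic, c, v, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            return None
        ic50, hill, top, bottom = popt
        if not np.isfinite(ic50) or ic50 <= 0:
            return None
        return float(ic50), float(hill), float(top), float(bottom)

    @staticmethod
    def _interpolate(c, v):
        logc = np.log10(c)
        for i in range(len(c) - 1):
            lo, hi = sorted((v[i], v[i + 1]))
            if lo <= 50.0 <= hi and v[i] != v[i + 1]:
                frac = (50.0 - v[i]) / (v[i + 1] - v[i])
                return float(10 ** (logc[i] + frac * (logc[i + 1] - logc[i])))
        return None

    def predict(self, X):
        return four_param_logistic(
            np.asarray(X, dtype=float).ravel(),
            self.ic50_, self.hill_, self.top_, self.bottom_,
        )


def fit_ic50(
    concentrations: Sequence[float],
    viability: Sequence[float] | Sequence[Sequence[float]],
) -> IC50Estimate:
    """Estimate the IC50 of a survival curve (optionally per replicate).

    ``viability`` may be a single mean curve or a (replicates x doses)
    array; with replicates, each replicate is fitted separately and the
    IC50 is reported as mean +/- sd over the replicate fits.
    """
    via = np.asarray(viability, dtype=float)
    if via.ndim == 1:
        est = FourParameterLogistic().fit(concentrations, via)
        return IC50Estimate(
            ic50=est.ic50_, top=est.top_, bottom=est.bottom_, hill=est.hill_,
            method=est.method_, extrapolated=est.extrapolated_,
            sd=0.0, replicate_ic50s=(est.ic50_,),
        )
    fits = [FourParameterLogistic().fit(concentrations, row) for row in via]
    ic50s = np.array([f.ic50_ for f in fits])
    ref = fits[int(np.argmin(np.abs(ic50s - np.median(ic50s))))]
    return IC50Estimate(
        ic50=float(ic50s.mean()), top=ref.top_, bottom=ref.bottom_, hill=ref.hill_,
        method=ref.method_, extrapolated=any(f.extrapolated_ for f in fits),
        sd=float(ic50s.std(ddof=1)) if len(ic50s) > 1 else 0.0,
        replicate_ic50s=tuple(float(x) for x in ic50s),
    )


def viability_from_plate(plate) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate viability curves from a tidy plate table.

    ``plate`` is a DataFrame with columns well, role (treated/control/blank),
    dose, a570, a690, replicate.  Control and blank wells are averaged over
    the whole plate; treated wells are reduced with
    :func:`viability_percent`.  Returns (doses descending-as-given,
    viability array of shape (replicates, doses)).
    """
    import pandas as pd  # tidy-table helper only

    plate = pd.DataFrame(plate)
    ctrl = plate[plate["role"] == "control"]
    blank = plate[plate["role"] == "blank"]
    if ctrl.empty or blank.empty:
        raise ValueError("plate must contain control and blank wells")
    control = (ctrl["a570"].mean(), ctrl["a690"].mean())
    blank_avg = (blank["a570"].mean(), blank["a690"].mean())
    treated = plate[plate["role"] == "treated"]
    doses = list(dict.fromkeys(treated["dose"]))  # preserve plate order
    reps = sorted(treated["replicate"].unique())
    via = np.zeros((len(reps), len(doses)))
    for i, rep in enumerate(reps):
        for j, dose in enumerate(doses):
            rows = treated[(treated["replicate"] == rep) & (treated["dose"] == dose)]
            vals = [
                viability_percent((r.a570, r.a690), control, blank_avg)[0]
                for r in rows.itertuples()
            ]
            via[i, j] = float(np.mean(vals))
    return np.asarray(doses, dtype=float), via


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star notation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    ic50_replicates_a: Sequence[float], ic50_replicates_b: Sequence[float]
) -> GroupComparison:
    """Unpaired pooled-variance (Student's) two-sided t-test of two groups."""
    a = np.asarray(ic50_replicates_a, dtype=float)
    b = np.asarray(ic50_replicates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, df, 1.0, "ns", flag="zero variance, equal means")
        return GroupComparison(np.inf if a.mean() > b.mean() else -np.inf, df, 0.0,
                               "***", flag="zero variance, unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(float(t), df, float(p), significance_tier(float(p)))
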