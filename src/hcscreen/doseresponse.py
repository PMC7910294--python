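"""Four-parameter logistic (4PL) dose-response machinery.

Used twice in the pipeline: calibrating the IL-1beta stimulus (finding the
EC50 of the induced CCL2 / ICAM-1 response and choosing a submaximal working
concentration) and fitting multiplex immunoassay standard curves for
back-calculating analyte concentrations.

The curve is parameterized increasing in dose::

    f(x) = bottom + (top - bottom) / (1 + (ec50 / x)**hill),   hill > 0

so f(0) = bottom, f(inf) = top and f(ec50) = (top + bottom) / 2 exactly.
Inhibition is represented downstream as activity ratios, never as a
descending curve.  Fitting is nonlinear least squares on log-dose
(internally the EC50 is estimated on the log scale); a zero-concentration
standard point anchors the bottom asymptote and needs no special casing
because f(0) = bottom in this parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateCurveError, FitError

# detection flags for batch back-calculation
OK = "ok"
BELOW_LOD = "below_lod"
ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class FourPL:
    """An increasing four-parameter logistic curve."""

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self):
        if not self.top > self.bottom:
            raise ValueError(f"need top > bottom, got {self.top} <= {self.bottom}")
        if not self.ec50 > 0:
            raise ValueError(f"need ec50 > 0, got {self.ec50}")
        if not self.hill > 0:
            raise ValueError(f"need hill > 0, got {self.hill}")

    def __call__(self, x):
        """Response at dose ``x`` (scalar or array); f(0) = bottom."""
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            r = self.bottom + (self.top - self.bottom) / (
                1.0 + (self.ec50 / np.where(x > 0, x, np.nan)) ** self.hill)
        r = np.where(x > 0, r, self.bottom)
        return float(r) if r.ndim == 0 else r

    predict = __call__

    def inverse(self, y: float) -> float:
        """Dose producing response ``y``; requires bottom < y < top.

        x = ec50 * ((top - bottom)/(y - bottom) - 1)**(-1/hill)
        """
        if not self.bottom < y < self.top:
            raise ValueError(
                f"response {y} outside open range ({self.bottom}, {self.top})")
        ratio = (self.top - self.bottom) / (y - self.bottom) - 1.0
        return self.ec50 * ratio ** (-1.0 / self.hill)

    def fractional_response(self, x) -> float:
        """(f(x) - bottom) / (top - bottom): position within the window."""
        f = self(x)
        return (f - self.bottom) / (self.top - self.bottom)

    def as_tuple(self):
        return (self.bottom, self.top, self.ec50, self.hill)


def _model(logx_safe, bottom, top, log_ec50, hill):
    # logx_safe is log(x) with -inf for x == 0; the logistic in log-dose
    # space sends -inf to bottom automatically
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + np.exp(-hill * (logx_safe - log_ec50)))


class FourPLModel:
    """Nonlinear least-squares 4PL model for one dose-response series.

    Parameters
    ----------
    dose : array-like, concentrations >= 0 (zero anchors the bottom)
    response : array-like, same length, finite

    ``fit()`` returns a :class:`FourPLResults` carrying the fitted
    :class:`FourPL` curve, standard errors, residuals and diagnostics.
    """

    def __init__(self, dose, response):
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        if dose.shape != response.shape or dose.ndim != 1:
            raise ValueError("dose and response must be 1-D and the same length")
        if np.any(dose < 0):
            raise ValueError("doses must be >= 0")
        if not np.all(np.isfinite(response)):
            raise ValueError("responses must be finite")
        n_pos = len(np.unique(dose[dose > 0]))
        if n_pos < 5:
            raise ValueError(f"need >= 5 distinct positive doses, got {n_pos}")
        # sort by dose: the fit itself is permutation-invariant, sorting just
        # makes initialization bookkeeping simple
        order = np.argsort(dose, kind="stable")
        self.dose = dose[order]
        self.response = response[order]

    # -- initialization ---------------------------------------------------
    def _start(self):
        y = self.response
        x = self.dose
        b0, t0 = float(np.min(y)), float(np.max(y))
        span = t0 - b0
        if span < 1e-12 * max(abs(t0), 1.0):
            raise DegenerateCurveError(
                f"response range {span:g} too flat to fit a logistic")
        half = b0 + span / 2.0
        pos = x > 0
        xp, yp = x[pos], y[pos]
        # dose bracketing the half-range crossing
        above = yp >= half
        if above.any() and (~above).any():
            i = int(np.argmax(above))
            ec0 = float(np.sqrt(xp[max(i - 1, 0)] * xp[i]))
        else:
            ec0 = float(np.exp(np.mean(np.log(xp))))
        return b0, t0, ec0

    def fit(self, maxfev: int = 10000) -> "FourPLResults":
        b0, t0, ec0 = self._start()
        span = t0 - b0
        # a zero-concentration point anchors the bottom asymptote: represent
        # it at a log-dose low enough that the logistic term underflows to 0
        with np.errstate(divide="ignore"):
            logx = np.where(self.dose > 0, np.log(self.dose), -700.0)
        p0 = (b0, t0, np.log(ec0), 1.0)
        lo = (-np.inf, -np.inf, -np.inf, 1e-3)
        hi = (np.inf, np.inf, np.inf, 50.0)
        try:
            popt, pcov = curve_fit(
                _model, logx, self.response, p0=p0, bounds=(lo, hi),
                maxfev=maxfev, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except RuntimeError as e:
            raise FitError(f"4PL fit did not converge: {e}") from e
        bottom, top, log_ec50, hill = popt
        if top <= bottom:  # fitter wandered into a descending curve
            raise FitError("fit produced top <= bottom; data may be decreasing")
        curve = FourPL(float(bottom), float(top), float(np.exp(log_ec50)), float(hill))
        fitted = curve(self.dose)
        resid = self.response - fitted
        return FourPLResults(
            model=self, curve=curve, params=np.asarray(popt),
            cov_params=np.asarray(pcov), resid=resid, fitted=fitted)


class FourPLResults:
    """Results of a 4PL fit: the curve, uncertainties and diagnostics."""

    param_names = ("bottom", "top", "log_ec50", "hill")

    def __init__(self, model, curve, params, cov_params, resid, fitted):
        self.model = model
        self.curve = curve
        self.params = params
        self.cov_params = cov_params
        self.resid = resid
        self.fitted = fitted
        self.converged = True

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of (bottom, top, log_ec50, hill)."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    @property
    def ec50(self) -> float:
        return self.curve.ec50

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid ** 2))

    def predict(self, dose):
        return self.curve(dose)

    def summary(self) -> str:
        lines = ["4PL dose-response fit",
                 f"  n obs: {len(self.model.dose)}    RSS: {self.rss:.6g}"]
        est = dict(zip(self.param_names, self.params))
        se = dict(zip(self.param_names, self.bse))
        for name in ("bottom", "top"):
            lines.append(f"  {name:<9} {est[name]:>12.6g}  (se {se[name]:.3g})")
        lines.append(f"  {'ec50':<9} {self.curve.ec50:>12.6g}  "
                     f"(se of log ec50 {se['log_ec50']:.3g})")
        lines.append(f"  {'hill':<9} {est['hill']:>12.6g}  (se {se['hill']:.3g})")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot data and fitted curve on a log-dose axis (positive doses)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.dose
        pos = x > 0
        ax.semilogx(x[pos], self.model.response[pos], "o", label="data")
        grid = np.geomspace(x[pos].min(), x[pos].max(), n_grid)
        ax.semilogx(grid, self.curve(grid), "-", label="4PL fit")
        ax.axvline(self.curve.ec50, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("dose")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def fit_4pl(doses, responses, **kwargs) -> FourPLResults:
    """Functional wrapper: ``FourPLModel(doses, responses).fit()``."""
    return FourPLModel(doses, responses).fit(**kwargs)


def inverse_4pl(curve: FourPL, y: float) -> float:
    """Strict inverse; raises outside (bottom, top). See also back_calculate."""
    return curve.inverse(y)


def back_calculate(curve: FourPL, signals, top_censor: float | None = None):
    """Batch inverse with detection flags instead of exceptions.

    Readings at/below the bottom asymptote are flagged ``below_lod`` (no
    numeric value); readings at/above the top asymptote are flagged
    ``above_range`` and, if ``top_censor`` is given (e.g. the top standard
    concentration), censored at that value rather than extrapolated.

    Returns ``(concentrations, flags)`` arrays.
    """
    signals = np.atleast_1d(np.asarray(signals, dtype=float))
    conc = np.full(signals.shape, np.nan)
    flags = np.full(signals.shape, OK, dtype=object)
    below = signals <= curve.bottom
    above = signals >= curve.top
    ok = ~below & ~above
    flags[below] = BELOW_LOD
    flags[above] = ABOVE_RANGE
    if top_censor is not None:
        conc[above] = top_censor
    conc[ok] = [curve.inverse(float(y)) for y in signals[ok]]
    return conc, flags


def pick_stimulation_dose(curves, candidate_doses, min_fraction: float = 0.5) -> float:
    """Choose a submaximal stimulus working concentration.

    Returns the lowest candidate dose whose fractional response
    ``(f(x) - bottom)/(top - bottom)`` reaches ``min_fraction`` (inclusive)
    on *every* channel's fitted curve.  A working point near half-maximum
    leaves headroom to detect both induction and attenuation of the
    response.

    ``curves`` may be a sequence of :class:`FourPL` or a mapping of channel
    name to curve.
    """
    if hasattr(curves, "values"):
        curves = list(curves.values())
    else:
        curves = list(curves)
    if not curves:
        raise ValueError("need at least one fitted curve")
    doses = sorted(float(d) for d in candidate_doses)
    if not doses or doses[0] <= 0:
        raise ValueError("candidate doses must be positive")
    table = {}
    for d in doses:
        fracs = [c.fractional_response(d) for c in curves]
        table[d] = min(fracs)
        if table[d] >= min_fraction - 1e-12:
            return d
    detail = ", ".join(f"{d:g}: {f:.3f}" for d, f in table.items())
    raise ValueError(
        f"no candidate dose reaches fractional response {min_fraction} on all "
        f"channels (worst-channel fraction per dose: {detail})")
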