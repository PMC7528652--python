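"""Multiple-turnover slicer kinetics: the burst-and-steady-state model.

An enzyme at concentration E converts substrate through a fast first
turnover (burst) followed by slower steady-state cycling limited by product
release:

    E + S --a--> E.P --b--> E + P

Product accumulation follows the closed form

    F(t) = E * a^2/(a+b)^2 * (1 - exp(-(a+b) t)) + E * a*b/(a+b) * t

with burst rate ``a`` (reported as k1, per minute) and steady-state rate
``b`` (k2, per minute).  ``F`` and ``E`` share units (nM of product when E
is in nM).  Fitting is bounded nonlinear least squares with a multi-start
grid, in the statsmodels style: ``BurstModel(times, F, E).fit()`` returns a
:class:`BurstFitResults` with estimates, standard errors and a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: default multi-start grid for (a, b), per minute
START_GRID_A = (0.01, 0.1, 1.0, 10.0)
START_GRID_B = (0.001, 0.01, 0.1)


def burst_model(t, E: float, a: float, b: float):
    """Closed-form burst-and-steady-state product accumulation F(t).

    Vectorized over ``t``.  The degenerate limit a = b = 0 (no catalysis)
    returns identically zero.
    """
    t = np.asarray(t, dtype=float)
    if E <= 0:
        raise ValueError("enzyme concentration E must be positive")
    if a < 0 or b < 0:
        raise ValueError("rate constants must be non-negative")
    s = a + b
    if s == 0:
        return np.zeros_like(t)
    return E * (a / s) ** 2 * (1.0 - np.exp(-s * t)) + E * (a * b / s) * t


def fraction_product(product, substrate, intermediate=0.0):
    """F_p = product / (product + substrate [+ degradation intermediate]).

    Signals must be non-negative; an all-zero denominator yields NaN (the
    point is undefined, flagged rather than raised so time courses with an
    empty first lane survive).
    """
    p = np.asarray(product, dtype=float)
    s = np.asarray(substrate, dtype=float)
    i = np.asarray(intermediate, dtype=float)
    if (p < 0).any() or (s < 0).any() or (i < 0).any():
        raise ValueError("signals must be non-negative")
    denom = p + s + i
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def fraction_bound(nitrocellulose, nylon):
    """Fraction bound from a layered filter-binding assay.

    Protein-bound RNA is caught by the nitrocellulose membrane, free RNA by
    the nylon membrane underneath: fraction bound = nc / (nc + nylon).
    Both-zero signals yield NaN.
    """
    nc = np.asarray(nitrocellulose, dtype=float)
    ny = np.asarray(nylon, dtype=float)
    if (nc < 0).any() or (ny < 0).any():
        raise ValueError("signals must be non-negative")
    denom = nc + ny
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, nc / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class BurstFitResults:
    """Estimates from fitting the burst model to one time course."""

    k1: float                  # burst rate a, per minute
    k2: float                  # steady-state rate b, per minute
    k1_se: float
    k2_se: float
    E: float
    rss: float
    n_obs: int
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    start: tuple[float, float] = (np.nan, np.nan)

    @property
    def params(self) -> dict[str, float]:
        return {"k1": self.k1, "k2": self.k2}

    @property
    def bse(self) -> dict[str, float]:
        return {"k1": self.k1_se, "k2": self.k2_se}

    def summary(self) -> str:
        lines = [
            "Burst-and-steady-state fit",
            "==========================",
            f"observations: {self.n_obs}    E (fixed): {self.E:g} nM",
            f"residual sum of squares: {self.rss:.6g}",
            "",
            f"{'param':<6}{'estimate':>12}{'std err':>12}",
            f"{'k1':<6}{self.k1:>12.5g}{self.k1_se:>12.3g}",
            f"{'k2':<6}{self.k2:>12.5g}{self.k2_se:>12.3g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0, 1, 200) * (self._times.max() if self._times.size else 1.0)
        ax.plot(self._times, self._F, "o", label="data")
        ax.plot(t, burst_model(t, self.E, self.k1, self.k2), "-", label="fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("product F(t)")
        ax.legend()
        return ax

    _times: np.ndarray = field(default=None, repr=False)
    _F: np.ndarray = field(default=None, repr=False)


class BurstModel:
    """Burst-kinetics model bound to one observed time course.

    Parameters
    ----------
    times, F : array-like
        Time points (minutes) and product signal; at least 4 points.
    E : float
        Enzyme concentration (nM), fixed during the fit by default.
    """

    def __init__(self, times, F, E: float, float_E: bool = False):
        self.times = np.asarray(times, dtype=float)
        self.F = np.asarray(F, dtype=float)
        if self.times.size != self.F.size:
            raise ValueError("times and F must have equal length")
        if self.times.size < 4:
            raise ValueError("need at least 4 time points to fit two rates")
        if E <= 0:
            raise ValueError("E must be positive")
        self.E = float(E)
        self.float_E = bool(float_E)  # fit E too, seeded at the given value

    @classmethod
    def from_timecourse(cls, tc) -> "BurstModel":
        return cls(tc.times, tc.F, tc.E)

    def fit(self, starts=None) -> BurstFitResults:
        """Bounded least squares over a multi-start (a, b) grid.

        Each start runs a trust-region fit with non-negativity bounds; the
        solution with the lowest residual sum of squares wins.  Standard
        errors come from the Jacobian-based covariance at the optimum.
        Raises RuntimeError if no start converges.
        """
        if starts is None:
            starts = [(a0, b0) for a0 in START_GRID_A for b0 in START_GRID_B]
        if self.float_E:
            f = lambda t, a, b, E: burst_model(t, E, a, b)
            p0s = [(a0, b0, self.E) for a0, b0 in starts]
            bounds = ([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf])
        else:
            f = lambda t, a, b: burst_model(t, self.E, a, b)
            p0s = list(starts)
            bounds = ([0.0, 0.0], [np.inf, np.inf])
        best = None
        for p0 in p0s:
            try:
                popt, pcov = curve_fit(
                    f, self.times, self.F, p0=p0, bounds=bounds, maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = self.F - f(self.times, *popt)
            rss = float(resid @ resid)
            if best is None or rss < best[2]:
                best = (popt, pcov, rss, resid, tuple(p0[:2]))
        if best is None:
            raise RuntimeError(
                "burst fit failed to converge from every start in the grid; "
                f"tried {len(p0s)} starts on {self.times.size} points"
            )
        popt, pcov, rss, resid, start = best
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        res = BurstFitResults(
            k1=float(popt[0]), k2=float(popt[1]),
            k1_se=float(se[0]), k2_se=float(se[1]),
            E=float(popt[2]) if self.float_E else self.E,
            rss=rss, n_obs=int(self.times.size),
            fitted=self.F - resid, residuals=resid, start=start,
        )
        res._times = self.times
        res._F = self.F
        return res


def fit_burst(timecourse, E: float | None = None) -> BurstFitResults:
    """Convenience wrapper: fit the burst model to a time course."""
    E = timecourse.E if E is None else E
    return BurstModel(timecourse.times, timecourse.F, E).fit()
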