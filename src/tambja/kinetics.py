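"""Transport-assay kinetics: Hill dose–response and initial-rate extraction.

Two small nonlinear models describe the chloride-efflux assay:

* :class:`HillModel` — end-of-assay efflux (%) as a function of carrier
  loading x (mol% carrier/lipid), ``y = ymax * x^n / (EC50^n + x^n)``.  The
  EC50 is the loading that releases 50% of the encapsulated chloride within
  the 300 s assay window; n is the Hill cooperativity coefficient.  ymax is
  fixed at 100% by default because detergent lysis defines complete release.

* :class:`EffluxDecayModel` — a single efflux trace y(t) rising
  asymptotically to a plateau, ``y = a - b * c^t`` with 0 < c < 1, whose
  initial rate is the closed form ``k_ini = -b * ln(c)`` (% s^-1).

Both fits use deterministic multi-start Levenberg–Marquardt style least
squares (8 starts on a log-spaced grid, ties broken by lowest SSE then
lowest EC50) so repeated runs are bit-identical.

Logarithms are base 10 throughout the package, matching log P conventions;
the potency scale is ``log10(1/EC50)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError

__all__ = [
    "HillModel",
    "HillResults",
    "EffluxDecayModel",
    "AsymptoticResults",
    "fit_hill",
    "fit_kini",
    "impute_ec50_from_kini",
    "ImputationResult",
    "log_potency",
]

_N_STARTS = 8


def log_potency(ec50: float) -> float:
    """Potency transform log10(1/EC50); requires EC50 > 0."""
    ec50 = float(ec50)
    if not np.isfinite(ec50) or ec50 <= 0:
        raise InputError(f"ec50 must be a positive finite number, got {ec50!r}")
    return float(-np.log10(ec50))


# ---------------------------------------------------------------------------
# Hill dose–response
# ---------------------------------------------------------------------------

@dataclass
class HillResults:
    """Fitted Hill curve: EC50 (mol%), Hill n, plateau ymax (%), and SSE."""

    ec50: float
    hill_n: float
    ymax: float
    ymax_fixed: bool
    residual_sse: float
    n_obs: int

    def predict(self, loadings) -> np.ndarray:
        x = np.asarray(loadings, dtype=float)
        return self.ymax * x**self.hill_n / (self.ec50**self.hill_n + x**self.hill_n)

    def summary(self) -> str:
        tag = "fixed" if self.ymax_fixed else "fitted"
        return (
            "Hill dose-response fit\n"
            f"  EC50     {self.ec50:.6g} mol%\n"
            f"  n        {self.hill_n:.4g}\n"
            f"  ymax     {self.ymax:.4g} % ({tag})\n"
            f"  SSE      {self.residual_sse:.4g} %^2   (n = {self.n_obs})"
        )


class HillModel:
    """Hill dose–response model for end-of-assay chloride efflux.

    Parameters
    ----------
    loadings : array-like
        Carrier loadings, mol% compound to lipid; positive, >= 4 distinct.
    responses : array-like
        % chloride release at the end of the assay; non-negative.
    """

    def __init__(self, loadings, responses):
        x = np.asarray(loadings, dtype=float)
        y = np.asarray(responses, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InputError("loadings and responses must be 1-D of equal length")
        if np.unique(x).size < 4:
            raise InputError("need at least 4 distinct loadings for a Hill fit")
        if np.any(x <= 0):
            raise InputError("loadings must be positive")
        if np.any(y < 0):
            raise InputError("responses must be non-negative")
        if np.all(y == 0):
            raise InputError("all responses are zero; Hill curve is unidentifiable")
        self.loadings = x
        self.responses = y

    def fit(self, fix_ymax: float | None = 100.0) -> HillResults:
        """Least-squares Hill fit; ``fix_ymax=None`` fits the plateau too."""
        x, y = self.loadings, self.responses
        lx = np.log(x)

        def resid(theta):
            log_ec50, log_n = theta[0], theta[1]
            ymax = theta[2] if fix_ymax is None else fix_ymax
            n = np.exp(log_n)
            # Hill curve in log space: 1/(1 + exp(n*(log ec50 - log x)))
            frac = 1.0 / (1.0 + np.exp(np.clip(n * (log_ec50 - lx), -500, 500)))
            return ymax * frac - y

        starts = np.log(np.geomspace(x.min(), x.max(), _N_STARTS))
        best = None
        for s in starts:
            theta0 = [s, 0.0] + ([max(y.max(), 1.0)] if fix_ymax is None else [])
            try:
                sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun**2))
            cand = (sse, float(np.exp(sol.x[0])), sol)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            raise FitError("Hill fit did not converge from any start")
        sse, ec50, sol = best
        hill_n = float(np.exp(sol.x[1]))
        ymax = float(sol.x[2]) if fix_ymax is None else float(fix_ymax)
        if not (0 < ec50 < np.inf) or not (0 < hill_n < np.inf):
            raise FitError("Hill fit converged to non-physical parameters")
        return HillResults(ec50, hill_n, ymax, fix_ymax is not None, sse, len(x))


def fit_hill(loadings, responses, fix_ymax: float | None = 100.0) -> HillResults:
    """Convenience wrapper: build a :class:`HillModel` and fit it."""
    return HillModel(loadings, responses).fit(fix_ymax=fix_ymax)


# ---------------------------------------------------------------------------
# Asymptotic efflux trace and k_ini
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticResults:
    """Fitted asymptotic trace y = a - b*c^t and the derived initial rate.

    ``kini`` is exactly ``-b * ln(c)`` of the fitted parameters, in % s^-1.
    """

    a: float
    b: float
    c: float
    residual_sse: float
    n_obs: int

    @property
    def kini(self) -> float:
        return float(-self.b * np.log(self.c))

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.a - self.b * self.c**t

    def summary(self) -> str:
        return (
            "Asymptotic efflux fit  y = a - b*c^t\n"
            f"  a (plateau)  {self.a:.4g} %\n"
            f"  b            {self.b:.4g} %\n"
            f"  c            {self.c:.6g}\n"
            f"  k_ini        {self.kini:.6g} % s^-1   (n = {self.n_obs})"
        )


class EffluxDecayModel:
    """Single chloride-efflux trace fitted to ``y = a - b*c^t``.

    ``c`` is parameterised internally as ``c = exp(-exp(theta))`` so the
    (0, 1) constraint holds smoothly; ``b`` as ``exp(beta)`` to stay
    positive.
    """

    def __init__(self, times, efflux, loading: float | None = None):
        t = np.asarray(times, dtype=float)
        y = np.asarray(efflux, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InputError("times and efflux must be 1-D of equal length")
        if t.size < 5:
            raise InputError("need at least 5 trace points")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if np.ptp(y) == 0:
            raise InputError("constant efflux trace; decay rate unidentifiable")
        self.times = t
        self.efflux = y
        self.loading = loading

    def fit(self) -> AsymptoticResults:
        t, y = self.times, self.efflux
        span = t[-1] - t[0]

        def resid(theta):
            a, log_b, th = theta
            c = np.exp(-np.exp(th))
            return a - np.exp(log_b) * c**t - y

        a0 = float(y.max())
        b0 = max(float(y.max() - y.min()), 1e-3)
        # decay-rate starts spanning half-lives from ~span/50 to ~5*span
        rates = np.geomspace(np.log(2) / (5 * span), np.log(2) * 50 / span, _N_STARTS)
        best = None
        for r in rates:
            theta0 = [a0, np.log(b0), np.log(r)]
            try:
                sol = least_squares(resid, theta0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol)
            if sse <= 1e-18 * max(1.0, float(np.sum(y**2))):
                break  # exact fit reached; later starts cannot improve
        if best is None:
            raise FitError("asymptotic trace fit did not converge from any start")
        sse, sol = best
        a = float(sol.x[0])
        b = float(np.exp(sol.x[1]))
        c = float(np.exp(-np.exp(sol.x[2])))
        if not (0 < c < 1):
            raise FitError("fitted decay base outside (0, 1)")
        return AsymptoticResults(a, b, c, sse, t.size)


def fit_kini(times, efflux, loading: float | None = None) -> AsymptoticResults:
    """Fit ``y = a - b*c^t`` to a trace; ``.kini`` gives ``-b ln c``."""
    return EffluxDecayModel(times, efflux, loading).fit()


# ---------------------------------------------------------------------------
# EC50 imputation from the initial rate
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Predicted EC50 plus the calibration line it came from."""

    ec50: float
    slope: float
    intercept: float
    r: float
    n_calibration: int
    form: str

    def summary(self) -> str:
        return (
            f"EC50 imputation ({self.form} calibration, n = {self.n_calibration})\n"
            f"  predicted EC50  {self.ec50:.6g} mol%\n"
            f"  slope {self.slope:.4g}  intercept {self.intercept:.4g}  "
            f"r {self.r:.4g}"
        )


def impute_ec50_from_kini(calibration, kini: float, form: str = "loglog") -> ImputationResult:
    """Predict an EC50 from an initial rate via a calibration regression.

    The default (and recommended) form regresses log10(EC50) on log10(k_ini)
    over calibration records with both quantities measured (imputed EC50s are
    excluded), then back-transforms the prediction.  ``form`` may also be
    ``"semilog"`` (log10(EC50) on k_ini) or ``"linear"``.

    Parameters
    ----------
    calibration : CompoundTable
        Must contain >= 3 usable records.
    kini : float
        Query initial rate, % s^-1; must be positive.
    """
    if kini is None or not np.isfinite(kini) or kini <= 0:
        raise InputError(f"query kini must be positive, got {kini!r}")
    if form not in ("loglog", "semilog", "linear"):
        raise InputError(f"unknown calibration form {form!r}")
    df = calibration.data
    ok = (
        df["ec50_molpct"].notna()
        & df["kini_pct_per_s"].notna()
        & (df["ec50_molpct"] > 0)
        & (df["kini_pct_per_s"] > 0)
        & ~df["ec50_imputed"]
    )
    ec50 = df.loc[ok, "ec50_molpct"].to_numpy(float)
    ki = df.loc[ok, "kini_pct_per_s"].to_numpy(float)
    if ec50.size < 3:
        raise InputError(
            f"need >= 3 calibration records with measured ec50 and kini, got {ec50.size}"
        )
    if form == "loglog":
        xv, yv, q = np.log10(ki), np.log10(ec50), np.log10(kini)
    elif form == "semilog":
        xv, yv, q = ki, np.log10(ec50), float(kini)
    else:
        xv, yv, q = ki, ec50, float(kini)
    slope, intercept = np.polyfit(xv, yv, 1)
    r = float(np.corrcoef(xv, yv)[0, 1])
    pred = slope * q + intercept
    value = float(pred if form == "linear" else 10.0**pred)
    return ImputationResult(value, float(slope), float(intercept), r, int(ec50.size), form)
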