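"""Suitability-trait regression: best-form selection and lag comparison.

Links habitat suitability to 20-year DBH growth, annual ring increments and
wood basic density.  Six candidate functional forms (linear, quadratic,
cubic, logarithmic, exponential, power) are fitted by least squares; the
winner minimises the small-sample-corrected information criterion (AICc),
with ties going to the form with fewer parameters.  The lag analysis pools
(growth, suitability) pairs across sites and years at lag 0 (current-year)
and lag 1 (previous-year) and compares linear-fit R-squared values —
a stronger lag-1 fit indicates a lagged climatic effect on radial growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

FORMS = ("linear", "quadratic", "cubic", "logarithmic", "exponential", "power")


class DegenerateRegressorError(ValueError):
    """The regressor is constant; no slope is identifiable."""


def _aicc(sse: float, n: int, n_coef: int) -> float:
    k = n_coef + 1  # + residual variance
    if n - k - 1 <= 0 or sse <= 0:
        return np.inf if sse > 0 else -np.inf
    return n * np.log(sse / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def _poly_fit(x, y, deg):
    coefs = np.polynomial.polynomial.polyfit(x, y, deg)
    return tuple(coefs), lambda xx, c=coefs: np.polynomial.polynomial.polyval(xx, c)


def _log_fit(x, y):
    c, pred = _poly_fit(np.log(x), y, 1)
    return c, lambda xx, c=c: c[0] + c[1] * np.log(xx)


def _exp_fit(x, y):
    if np.all(y > 0):
        b0 = np.polynomial.polynomial.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(b0[0])), float(b0[1]))
    else:
        p0 = (max(float(np.mean(y)), 1e-6), 0.0)
    popt, _ = curve_fit(lambda xx, a, b: a * np.exp(b * xx), x, y, p0=p0,
                        maxfev=20000)
    return tuple(popt), lambda xx, p=popt: p[0] * np.exp(p[1] * xx)


def _power_fit(x, y):
    if np.all(y > 0):
        b0 = np.polynomial.polynomial.polyfit(np.log(x), np.log(y), 1)
        p0 = (float(np.exp(b0[0])), float(b0[1]))
    else:
        p0 = (max(float(np.mean(y)), 1e-6), 1.0)
    popt, _ = curve_fit(lambda xx, a, b: a * np.power(xx, b), x, y, p0=p0,
                        maxfev=20000)
    return tuple(popt), lambda xx, p=popt: p[0] * np.power(xx, p[1])


_FITTERS = {
    "linear": (lambda x, y: _poly_fit(x, y, 1), 2, None),
    "quadratic": (lambda x, y: _poly_fit(x, y, 2), 3, None),
    "cubic": (lambda x, y: _poly_fit(x, y, 3), 4, None),
    "logarithmic": (_log_fit, 2, "x>0"),
    "exponential": (_exp_fit, 2, None),
    "power": (_power_fit, 2, "x>0"),
}


def evaluate_form(form: str, coefs, x):
    """Evaluate a fitted functional form at new abscissae.

    Domain violations (log/power at x <= 0) yield NaN rather than raising.
    """
    x = np.asarray(x, dtype=float)
    c = coefs
    if form in ("linear", "quadratic", "cubic"):
        return np.polynomial.polynomial.polyval(x, np.asarray(c))
    with np.errstate(invalid="ignore", divide="ignore"):
        if form == "logarithmic":
            return np.where(x > 0, c[0] + c[1] * np.log(np.where(x > 0, x, 1.0)), np.nan)
        if form == "exponential":
            return c[0] * np.exp(c[1] * x)
        if form == "power":
            return np.where(x > 0, c[0] * np.power(np.where(x > 0, x, 1.0), c[1]), np.nan)
    raise ValueError(f"unknown form {form!r}")


@dataclass
class FormFit:
    """One candidate form's least-squares fit and selection statistics."""

    form: str
    coefs: tuple
    r_squared: float
    adj_r_squared: float
    aicc: float
    n_coef: int
    note: str = ""


@dataclass
class TraitLinkResults:
    """Winning form plus the full per-form report for one trait."""

    trait_name: str
    form: str
    coefs: tuple
    r_squared: float
    adj_r_squared: float
    aicc: float
    lag: int
    report: list[FormFit] = field(default_factory=list)
    slope_se: float | None = None  # linear form only
    n_obs: int = 0

    def predict(self, x):
        return evaluate_form(self.form, self.coefs, x)

    def slope_conf_int(self, alpha: float = 0.05):
        """Two-sided confidence interval for the linear slope."""
        if self.form != "linear" or self.slope_se is None:
            raise ValueError("slope interval is defined for the linear form only")
        from scipy.stats import t

        b = self.coefs[1]
        half = t.ppf(1.0 - alpha / 2.0, self.n_obs - 2) * self.slope_se
        return b - half, b + half

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        rows = [[f.form,
                 ", ".join(f"{c:.4g}" for c in f.coefs) if f.coefs else "-",
                 f"{f.r_squared:.4f}" if np.isfinite(f.r_squared) else "-",
                 f"{f.aicc:.2f}" if np.isfinite(f.aicc) else "-",
                 "selected" if f.form == self.form else f.note]
                for f in self.report]
        tbl = SimpleTable(rows, headers=["form", "coefficients", "R^2", "AICc", ""])
        head = (f"Trait link: {self.trait_name} ~ suitability (lag {self.lag})\n"
                f"selected form: {self.form}, R^2 = {self.r_squared:.4f}, "
                f"adj R^2 = {self.adj_r_squared:.4f}, n = {self.n_obs}")
        return head + "\n" + str(tbl)


class TraitLinkModel:
    """Best-form regression of a trait on habitat suitability.

    statsmodels-style: construct from per-site arrays, call :meth:`fit` to
    obtain :class:`TraitLinkResults`.
    """

    def __init__(self, suitability, trait, forms=FORMS, trait_name: str = "trait",
                 lag: int = 0):
        self.x = np.asarray(suitability, dtype=float)
        self.y = np.asarray(trait, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("suitability and trait must be equal-length 1-D")
        if len(self.x) < 5:
            raise ValueError("need at least 5 sites")
        if np.ptp(self.x) == 0:
            raise DegenerateRegressorError("suitability is constant across sites")
        self.forms = tuple(forms)
        self.trait_name = trait_name
        self.lag = lag

    def fit(self) -> TraitLinkResults:
        x, y, n = self.x, self.y, len(self.x)
        sst = float(((y - y.mean()) ** 2).sum())
        report: list[FormFit] = []
        for form in self.forms:
            fitter, n_coef, domain = _FITTERS[form]
            if domain == "x>0" and np.any(x <= 0):
                report.append(FormFit(form, (), np.nan, np.nan, np.inf, n_coef,
                                      note="skipped: requires x > 0"))
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    coefs, predict = fitter(x, y)
            except Exception as exc:  # non-convergent nonlinear fit
                report.append(FormFit(form, (), np.nan, np.nan, np.inf, n_coef,
                                      note=f"skipped: {type(exc).__name__}"))
                continue
            resid = y - predict(x)
            sse = float((resid ** 2).sum())
            r2 = 1.0 - sse / sst if sst > 0 else 1.0
            denom = n - n_coef - 1
            adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan
            report.append(FormFit(form, tuple(float(c) for c in coefs),
                                  r2, adj, _aicc(sse, n, n_coef), n_coef))
        fitted = [f for f in report if f.coefs]
        if not fitted:
            raise RuntimeError("no candidate form could be fitted")
        winner = min(fitted, key=lambda f: (round(f.aicc, 10), f.n_coef))

        slope_se = None
        if winner.form == "linear":
            resid = y - evaluate_form("linear", winner.coefs, x)
            sxx = float(((x - x.mean()) ** 2).sum())
            dof = n - 2
            slope_se = float(np.sqrt((resid ** 2).sum() / dof / sxx)) if dof > 0 else None
        return TraitLinkResults(
            trait_name=self.trait_name, form=winner.form, coefs=winner.coefs,
            r_squared=winner.r_squared, adj_r_squared=winner.adj_r_squared,
            aicc=winner.aicc, lag=self.lag, report=report,
            slope_se=slope_se, n_obs=n)


def fit_trait_model(suitability, trait, forms=FORMS, trait_name: str = "trait",
                    lag: int = 0) -> TraitLinkResults:
    """Convenience wrapper: build and fit a :class:`TraitLinkModel`."""
    return TraitLinkModel(suitability, trait, forms=forms,
                          trait_name=trait_name, lag=lag).fit()


@dataclass
class LagComparison:
    """Which lag explains annual growth better, and by how much."""

    results: dict[int, TraitLinkResults]
    winner: int
    r2_by_lag: dict[int, float]
    delta_r2: float

    def summary(self) -> str:
        lines = [f"lag {k}: R^2 = {v:.4f}" for k, v in sorted(self.r2_by_lag.items())]
        lines.append(f"winner: lag {self.winner} (delta R^2 = {self.delta_r2:.4f})")
        return "\n".join(lines)


def lag_analysis(annual_growth: np.ndarray, annual_suitability: np.ndarray,
                 lags=(0, 1)) -> LagComparison:
    """Pooled linear regression of annual growth on lagged suitability.

    ``annual_growth`` is (sites x T) chronological; ``annual_suitability``
    is (sites x T + max(lags)) chronological, ending in the same final year,
    so the series extends max(lags) years before the first growth year.
    Pairs (growth[s, t], suitability[s, t - k]) are pooled across sites and
    years for each lag k and fitted with the linear form.
    """
    G = np.asarray(annual_growth, dtype=float)
    S = np.asarray(annual_suitability, dtype=float)
    max_lag = max(lags)
    if G.ndim != 2 or S.ndim != 2 or G.shape[0] != S.shape[0]:
        raise ValueError("growth and suitability tables need matching sites")
    if S.shape[1] < G.shape[1] + max_lag:
        raise ValueError(
            f"suitability needs >= {G.shape[1] + max_lag} years for lag {max_lag}")
    if np.ptp(S) == 0:
        raise DegenerateRegressorError("suitability constant across all pairs")
    T = G.shape[1]
    results: dict[int, TraitLinkResults] = {}
    for k in lags:
        offset = max_lag - k
        suit_pairs = S[:, offset:offset + T].ravel()
        results[k] = fit_trait_model(
            suit_pairs, G.ravel(), forms=("linear",),
            trait_name="annual DBH growth", lag=k)
    r2 = {k: r.r_squared for k, r in results.items()}
    winner = max(r2, key=lambda k: r2[k])
    deltas = sorted(r2.values(), reverse=True)
    delta = deltas[0] - deltas[1] if len(deltas) > 1 else 0.0
    return LagComparison(results=results, winner=winner, r2_by_lag=r2,
                         delta_r2=delta)
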