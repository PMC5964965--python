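"""Parabolic QSAR models of anion-transport potency.

The working hypothesis is a parabolic structure–activity relationship: the
transport potency log10(1/EC50) of a carrier rises with its lipophilicity
log P up to a membrane-determined optimum and falls beyond it, because a too
hydrophilic molecule never partitions into the bilayer while a too
hydrophobic one never leaves its core.  The two-term model

    log10(1/EC50) = b0 + b1 * ALOGPs + b2 * ALOGPs^2      (b2 < 0)

has its optimum at ``logP* = -b1 / (2*b2)``.

:class:`QSARModel` is a statsmodels-flavoured model object: build it from a
:class:`~tambja.datasets.CompoundTable` (or raw arrays), call :meth:`fit`,
and get a :class:`QSARResults` carrying coefficients, t-based 95% confidence
intervals, R² and a ``summary()``.  Squared terms are named derived columns
(``"<name>-sq"``) generated on demand, so model specifications stay purely
name-based.

:func:`enumerate_models` is an exhaustive all-subsets search: it fits every
subset of candidate descriptors up to a size cap and ranks the fits by R²
with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import CompoundTable
from .errors import FitError, InputError

__all__ = [
    "QSARModel",
    "QSARResults",
    "design_matrix",
    "enumerate_models",
    "optimum_logp",
]

SQ_SUFFIX = "-sq"


def design_matrix(source, terms) -> tuple[pd.DataFrame, pd.Series | None]:
    """Build the (no-intercept) design matrix for named terms.

    ``source`` is a CompoundTable or a DataFrame of numeric columns.  A term
    ``"<name>-sq"`` is derived as the square of column ``<name>`` when not
    itself present.  For a CompoundTable the special response
    ``log10(1/EC50)`` is returned alongside; ALOGPs is exposed under both its
    schema name ``alogps`` and the conventional ``ALOGPs``.
    """
    if isinstance(source, CompoundTable):
        frame = pd.DataFrame(
            {
                "alogps": source.data["alogps"].to_numpy(float),
                "ALOGPs": source.data["alogps"].to_numpy(float),
                "rt_min": source.data["rt_min"].to_numpy(float),
                "kini_pct_per_s": source.data["kini_pct_per_s"].to_numpy(float),
            },
            index=source.data["compound_id"],
        )
        response = pd.Series(
            source.log_potency().to_numpy(), index=frame.index, name="log_inv_ec50"
        )
    else:
        frame = pd.DataFrame(source).astype(float)
        response = None
    if len(set(terms)) != len(list(terms)):
        raise InputError("duplicate terms in model specification")
    cols = {}
    for term in terms:
        if term in frame.columns:
            cols[term] = frame[term].to_numpy(float)
        elif term.endswith(SQ_SUFFIX) and term[: -len(SQ_SUFFIX)] in frame.columns:
            base = term[: -len(SQ_SUFFIX)]
            cols[term] = frame[base].to_numpy(float) ** 2
        else:
            raise InputError(f"unknown term {term!r}")
    return pd.DataFrame(cols, index=frame.index), response


class QSARResults:
    """Ordinary-least-squares fit of a named-term QSAR model.

    Thin wrapper over a statsmodels OLS results object exposing the fields
    practitioners report: intercept, per-term coefficients, R², and analytic
    95% confidence intervals from the t distribution with
    ``n_obs - n_terms - 1`` degrees of freedom.
    """

    def __init__(self, terms, sm_results, response_name="log_inv_ec50"):
        self.terms = list(terms)
        self.response_name = response_name
        self._sm = sm_results

    @property
    def intercept(self) -> float:
        return float(self._sm.params.iloc[0])

    @property
    def coefficients(self) -> pd.Series:
        return self._sm.params.iloc[1:]

    @property
    def params(self) -> pd.Series:
        """Intercept + coefficients, statsmodels order."""
        return self._sm.params

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def n_obs(self) -> int:
        return int(self._sm.nobs)

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm.resid)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha=alpha)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(design, self.terms)
        return np.asarray(self._sm.predict(sm.add_constant(X, has_constant="add")))

    def optimum_logp(self, variable: str | None = None) -> float:
        return optimum_logp(self, variable)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"QSAR OLS fit: {self.response_name} ~ {' + '.join(self.terms)}",
            f"  n_obs = {self.n_obs}    R^2 = {self.rsquared:.4f}",
            f"  {'term':<14}{'coef':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<14}{self.params[name]:>10.4f}"
                f"{ci.loc[name, 'ci_low']:>10.4f}{ci.loc[name, 'ci_high']:>10.4f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<QSARResults terms={self.terms} R2={self.rsquared:.4f} "
            f"n={self.n_obs}>"
        )


class QSARModel:
    """OLS model of a response against named descriptor terms.

    Parameters
    ----------
    source : CompoundTable or DataFrame
        Data; a CompoundTable supplies the log10(1/EC50) response itself.
    terms : sequence of str
        Descriptor column names; ``"<name>-sq"`` derives a squared column.
    response : array-like, optional
        Required when ``source`` is a plain DataFrame.
    include_imputed : bool
        Whether records with an imputed EC50 enter the fit (default True).
    """

    def __init__(self, source, terms, response=None, include_imputed: bool = True):
        if isinstance(source, CompoundTable) and not include_imputed:
            source = source.without_imputed()
        X, auto_response = design_matrix(source, terms)
        if response is None:
            response = auto_response
        if response is None:
            raise InputError("a response vector is required with a plain DataFrame")
        y = np.asarray(response, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise InputError("response length does not match design rows")
        mask = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
        self.exog = X[mask]
        self.endog = y[mask]
        self.terms = list(terms)
        self.response_name = getattr(response, "name", None) or "y"

    def fit(self) -> QSARResults:
        n, k = self.exog.shape
        if n <= k + 1:
            raise InputError(
                f"need n_obs > n_terms + 1 (got n={n} for {k} terms)"
            )
        Xc = sm.add_constant(self.exog, has_constant="add")
        rank = np.linalg.matrix_rank(Xc.to_numpy(float))
        if rank < Xc.shape[1]:
            collinear = _collinear_terms(Xc)
            raise FitError(f"rank-deficient design; collinear terms: {collinear}")
        res = sm.OLS(self.endog, Xc).fit()
        return QSARResults(self.terms, res, self.response_name)


def _collinear_terms(Xc: pd.DataFrame) -> list[str]:
    """Name columns whose removal restores full rank (greedy scan)."""
    arr = Xc.to_numpy(float)
    full = np.linalg.matrix_rank(arr)
    out = []
    for j, name in enumerate(Xc.columns):
        if name == "const":
            continue
        sub = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(sub) == full:
            out.append(str(name))
    return out


def fit_ols(source, terms, response=None, include_imputed: bool = True) -> QSARResults:
    """One-call OLS fit; see :class:`QSARModel`."""
    return QSARModel(source, terms, response, include_imputed).fit()


__all__.append("fit_ols")


def enumerate_models(
    response,
    matrix: pd.DataFrame,
    max_terms: int,
    candidate_subset=None,
    top_k: int | None = None,
) -> list[QSARResults]:
    """Exhaustive all-subsets OLS over descriptor columns, ranked by R².

    Fits every subset of candidate columns of size 1..``max_terms`` and
    returns the ``top_k`` fits (all, when None) sorted by R² descending with
    lexicographic term-name tie-break, so the ranking is independent of the
    column order of ``matrix``.  Rank-deficient subsets are skipped.
    """
    if max_terms < 1:
        raise InputError("max_terms must be >= 1")
    names = sorted(map(str, matrix.columns))
    if candidate_subset is not None:
        candidate_subset = [str(c) for c in candidate_subset]
        unknown = sorted(set(candidate_subset) - set(names))
        if unknown:
            raise InputError(f"candidate terms absent from matrix: {unknown}")
        names = sorted(candidate_subset)
    y = np.asarray(response, dtype=float)
    fits: list[QSARResults] = []
    for size in range(1, max_terms + 1):
        for combo in combinations(names, size):
            try:
                fits.append(fit_ols(matrix, list(combo), response=y))
            except FitError:
                continue
    fits.sort(key=lambda f: (-f.rsquared, tuple(f.terms)))
    return fits if top_k is None else fits[:top_k]


def optimum_logp(fit: QSARResults, variable: str | None = None) -> float:
    """Vertex ``-b1/(2*b2)`` of a fitted parabola in one descriptor.

    ``variable`` defaults to the unique term whose squared partner
    ``"<variable>-sq"`` is also in the model.  Requires a negative squared
    coefficient (an interior maximum).
    """
    if variable is None:
        pairs = [
            t[: -len(SQ_SUFFIX)]
            for t in fit.terms
            if t.endswith(SQ_SUFFIX) and t[: -len(SQ_SUFFIX)] in fit.terms
        ]
        if len(pairs) != 1:
            raise InputError(
                "could not identify a unique linear + squared term pair; "
                "pass variable= explicitly"
            )
        variable = pairs[0]
    sq = variable + SQ_SUFFIX
    if variable not in fit.terms or sq not in fit.terms:
        raise InputError(f"model lacks the pair ({variable!r}, {sq!r})")
    b1 = float(fit.coefficients[variable])
    b2 = float(fit.coefficients[sq])
    if b2 >= 0:
        raise InputError("squared coefficient is non-negative: no interior maximum")
    return -b1 / (2.0 * b2)
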