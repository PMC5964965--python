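"""Stratified bootstrap confidence intervals for QSAR coefficients.

A parabolic lipophilicity model is pinned down by the few compounds at the
extremes of the log P range; a naive bootstrap frequently resamples datasets
missing those high-leverage points, in which case the best fit degenerates
towards a flat line.  The stratified bootstrap guards against this: records
are binned into low / mid / high lipophilicity strata, and every resample
draws with replacement *within* each stratum, preserving the stratum sizes,
so extreme-log P information is always present.

Percentile (2.5% / 97.5%) intervals are reported per coefficient.  The
resampler is a pure function of its seed: one generator is seeded once and
resample index blocks are drawn stratum-by-stratum in a fixed stratum order,
so a given (data, spec, seed) always yields bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CompoundTable
from .errors import FitError, InputError
from .qsar import design_matrix

__all__ = [
    "StrataDefinition",
    "BootstrapResult",
    "assign_strata",
    "stratified_bootstrap",
]

_RANK_TOL = 1e-9


@dataclass
class StrataDefinition:
    """Half-open bins on one descriptor: [-inf,b1), [b1,b2), ..., [bk,inf)."""

    variable: str = "alogps"
    boundaries: tuple = (2.5, 5.0)

    def __post_init__(self):
        bounds = tuple(float(b) for b in self.boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise InputError("strata boundaries must be strictly ascending")
        self.boundaries = bounds

    @property
    def labels(self) -> list[str]:
        if len(self.boundaries) == 2:
            return ["low", "mid", "high"]
        return [f"s{i}" for i in range(len(self.boundaries) + 1)]


def assign_strata(table: CompoundTable, strata: StrataDefinition | None = None) -> pd.Series:
    """Label each record with its lipophilicity stratum.

    Binning is half-open: a value exactly on a boundary belongs to the upper
    stratum.  Raises on missing stratification values; warns if fewer than
    two strata are populated.
    """
    strata = strata or StrataDefinition()
    values = table.data[strata.variable] if strata.variable in table.data.columns else None
    if values is None:
        raise InputError(f"stratification variable {strata.variable!r} not in table")
    vals = values.to_numpy(float)
    if np.isnan(vals).any():
        bad = table.data.loc[np.isnan(vals), "compound_id"].tolist()
        raise InputError(f"missing {strata.variable!r} for compounds: {bad}")
    idx = np.searchsorted(np.asarray(strata.boundaries), vals, side="right")
    labels = [strata.labels[i] for i in idx]
    if len(set(labels)) < 2:
        warnings.warn(
            "all records fall in a single stratum; stratification has no effect",
            UserWarning,
            stacklevel=2,
        )
    return pd.Series(labels, index=table.data.index, name="stratum")


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for one model specification."""

    terms: list
    param_names: list
    point_estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_resamples: int
    seed: int
    strata: StrataDefinition
    stratum_sizes: dict = field(default_factory=dict)
    n_redraws: int = 0
    samples: np.ndarray | None = None

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ci_low": self.ci_low, "ci_high": self.ci_high}, index=self.param_names
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "strata": {
                "variable": self.strata.variable,
                "boundaries": list(self.strata.boundaries),
            },
            "stratum_sizes": dict(self.stratum_sizes),
            "n_redraws": self.n_redraws,
            "coefficients": {
                name: {
                    "estimate": float(est),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
                for name, est, lo, hi in zip(
                    self.param_names, self.point_estimate, self.ci_low, self.ci_high
                )
            },
        }

    def summary(self) -> str:
        lines = [
            f"Stratified bootstrap ({self.n_resamples} resamples, seed {self.seed}, "
            f"strata on {self.strata.variable} at {list(self.strata.boundaries)})",
            f"  {'term':<14}{'estimate':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name, est, lo, hi in zip(
            self.param_names, self.point_estimate, self.ci_low, self.ci_high
        ):
            lines.append(f"  {name:<14}{est:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        return "\n".join(lines)


def stratified_bootstrap(
    table: CompoundTable,
    terms,
    strata: StrataDefinition | None = None,
    n_resamples: int = 999,
    seed: int = 0,
    include_imputed: bool = True,
    keep_samples: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap of an OLS model, resampling within strata.

    Each of the ``n_resamples`` replicates draws, with replacement and
    independently per stratum, exactly as many records as the stratum holds,
    then refits the model by least squares.  A replicate whose design is
    numerically rank-deficient is redrawn (redraws are counted and capped at
    ``10 * n_resamples``).

    Returns per-coefficient 2.5% / 97.5% percentile bounds (numpy linear
    interpolation), the full-data point estimate, and bookkeeping.
    """
    strata = strata or StrataDefinition()
    if include_imputed is False:
        table = table.without_imputed()
    X, response = design_matrix(table, terms)
    y = np.asarray(response, dtype=float)
    labels = assign_strata(table, strata)

    Xc = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
    param_names = ["const", *X.columns]
    point = _solve_ols(Xc, y)
    if point is None:
        raise FitError("model is rank-deficient on the full data")

    order = [lab for lab in strata.labels if (labels == lab).any()]
    groups = [np.flatnonzero((labels == lab).to_numpy()) for lab in order]
    sizes = {lab: int(g.size) for lab, g in zip(order, groups)}

    rng = np.random.default_rng(seed)
    B = int(n_resamples)
    budget = 10 * B
    coefs = np.empty((B, Xc.shape[1]))
    filled = 0
    n_redraws = 0
    while filled < B:
        draw = min(B - filled, B)
        idx = draw_resample_indices(rng, groups, draw)
        Xb = Xc[idx]  # (draw, n, p)
        yb = y[idx]  # (draw, n)
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bn->bi", Xb, yb)
        ok = _full_rank_mask(XtX)
        n_bad = int((~ok).sum())
        if n_bad:
            n_redraws += n_bad
            if n_redraws > budget:
                raise FitError(
                    f"exceeded redraw budget ({budget}) due to rank-deficient resamples"
                )
        sol = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
        take = min(sol.shape[0], B - filled)
        coefs[filled : filled + take] = sol[:take]
        filled += take

    lo = np.percentile(coefs, 2.5, axis=0)
    hi = np.percentile(coefs, 97.5, axis=0)
    return BootstrapResult(
        terms=list(terms),
        param_names=param_names,
        point_estimate=point,
        ci_low=lo,
        ci_high=hi,
        n_resamples=B,
        seed=int(seed),
        strata=strata,
        stratum_sizes=sizes,
        n_redraws=n_redraws,
        samples=coefs if keep_samples else None,
    )


def draw_resample_indices(rng, groups, n_draw: int) -> np.ndarray:
    """Draw ``n_draw`` resample index rows, with replacement within strata.

    ``groups`` is a list of index arrays, one per stratum, in fixed stratum
    order; each output row holds exactly ``len(g)`` draws from each stratum
    ``g``, so stratum sizes are preserved by construction.
    """
    n = sum(g.size for g in groups)
    idx = np.empty((n_draw, n), dtype=np.intp)
    pos = 0
    for g in groups:
        idx[:, pos : pos + g.size] = g[rng.integers(0, g.size, size=(n_draw, g.size))]
        pos += g.size
    return idx


def _solve_ols(Xc: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    XtX = Xc.T @ Xc
    if not _full_rank_mask(XtX[None, :, :])[0]:
        return None
    return np.linalg.solve(XtX, Xc.T @ y)


def _full_rank_mask(XtX: np.ndarray) -> np.ndarray:
    """True where each (p, p) Gram matrix in the stack is well-conditioned."""
    eig = np.linalg.eigvalsh(XtX)
    scale = np.maximum(eig[:, -1], 1e-300)
    return eig[:, 0] > _RANK_TOL * scale
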