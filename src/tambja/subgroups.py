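"""Structural-subgroup analysis of the lipophilicity parabola.

Tambjamine-type carriers differ at three positions: the ring substituent R4
(OMe or OBn), the enamine substituent R5 (NH or NH-Ph, with rare outliers
such as NH-CH2-Ph and NH-py), and the R6 substituent class (alkyl, halogen,
O-R', ...).  Records are labelled with the composite "R4.R5.R6" string and
the activity parabola is examined per subgroup in two ways:

* :func:`fit_group_quadratics` — an independent quadratic in log P per
  subgroup (groups below a minimum size are skipped, not fitted), giving
  each subgroup its own curvature and optimum log P.

* :class:`SharedCurvatureModel` — one curvature shared by all groups, with
  group-specific intercept offsets shifting the parabola vertically.  This
  encodes the physical reading that curvature and optimum log P are
  properties of the membrane while the substituents set the attainable peak
  activity.  Offsets are either fixed effects under a sum-to-zero
  constraint, or Gaussian random intercepts estimated by profiling the REML
  criterion over the variance ratio (grid scan then golden-section
  refinement; fully deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CompoundTable
from .errors import FitError, InputError
from .qsar import QSARResults, fit_ols

__all__ = [
    "classify_subgroups",
    "fit_group_quadratics",
    "SharedCurvatureModel",
    "SharedCurvatureFit",
    "fit_shared_curvature",
]

_KNOWN_R5 = {"NH", "NH-Ph"}
UNCLASSIFIED = "unclassified"


def classify_subgroups(table: CompoundTable) -> pd.Series:
    """Composite "R4.R5.R6" label per record, or ``"unclassified"``.

    A record lands in the unclassified bucket when any annotation is missing
    or its R5 substituent is outside the two main classes (NH, NH-Ph).
    """
    labels = []
    for _, row in table.data.iterrows():
        r4, r5, r6 = row["r4"], row["r5"], row["r6_class"]
        if r4 is None or r6 is None or r5 not in _KNOWN_R5:
            labels.append(UNCLASSIFIED)
        else:
            labels.append(f"{r4}.{r5}.{r6}")
    return pd.Series(labels, index=table.data.index, name="subgroup")


def fit_group_quadratics(
    table: CompoundTable,
    labels: pd.Series,
    min_group_size: int = 3,
    variable: str = "alogps",
) -> tuple[dict[str, QSARResults], list[str]]:
    """Independent quadratic OLS fit per subgroup.

    Returns (fits, skipped): ``fits`` maps each subgroup of size >=
    ``min_group_size`` to its :class:`QSARResults` for
    ``log10(1/EC50) ~ variable + variable-sq``; ``skipped`` lists smaller
    groups (and the unclassified bucket, which is never fitted).
    """
    fits: dict[str, QSARResults] = {}
    skipped: list[str] = []
    for label in sorted(labels.unique()):
        if label == UNCLASSIFIED:
            continue
        mask = (labels == label).to_numpy()
        if mask.sum() < min_group_size:
            skipped.append(label)
            continue
        sub = table.subset(mask)
        fits[label] = fit_ols(sub, [variable, variable + "-sq"])
    return fits, skipped


@dataclass
class SharedCurvatureFit:
    """One parabola shared by all groups, shifted vertically per group.

    ``global_intercept + group_offsets[g]`` is group *g*'s intercept;
    offsets sum to zero (fixed mode) or are BLUPs of a Gaussian random
    intercept (random mode, with ``offset_variance`` their estimated
    variance).
    """

    beta_linear: float
    beta_quad: float
    global_intercept: float
    group_offsets: dict
    mode: str
    offset_variance: float | None = None
    residual_variance: float | None = None
    n_obs: int = 0

    @property
    def optimum_logp(self) -> float:
        if self.beta_quad >= 0:
            raise InputError("squared coefficient is non-negative: no interior maximum")
        return -self.beta_linear / (2.0 * self.beta_quad)

    def predict(self, logp, group=None) -> np.ndarray:
        x = np.asarray(logp, dtype=float)
        off = self.group_offsets.get(group, 0.0) if group is not None else 0.0
        return self.global_intercept + off + self.beta_linear * x + self.beta_quad * x**2

    def summary(self) -> str:
        lines = [
            f"Shared-curvature parabola ({self.mode}, n = {self.n_obs})",
            f"  intercept  {self.global_intercept:.4f}",
            f"  linear     {self.beta_linear:.4f}",
            f"  quadratic  {self.beta_quad:.4f}",
        ]
        try:
            lines.append(f"  optimum log P  {self.optimum_logp:.4f}")
        except InputError:
            pass
        if self.offset_variance is not None:
            lines.append(f"  offset variance  {self.offset_variance:.4g}")
        for g in sorted(self.group_offsets):
            lines.append(f"  offset[{g}]  {self.group_offsets[g]:+.4f}")
        return "\n".join(lines)


class SharedCurvatureModel:
    """Quadratic-in-log P model with group-specific intercepts.

    Parameters
    ----------
    logp, response : array-like
        Lipophilicity values and log10(1/EC50) responses.
    groups : sequence
        Group label per observation.
    """

    def __init__(self, logp, response, groups):
        x = np.asarray(logp, dtype=float)
        y = np.asarray(response, dtype=float)
        g = np.asarray([str(v) for v in groups])
        if not (x.shape == y.shape == g.shape) or x.ndim != 1:
            raise InputError("logp, response and groups must be 1-D of equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        self.x, self.y, self.g = x[ok], y[ok], g[ok]
        self.group_names = sorted(set(self.g))

    @classmethod
    def from_table(cls, table: CompoundTable, labels: pd.Series, variable: str = "alogps"):
        keep = (labels != UNCLASSIFIED).to_numpy()
        sub = table.subset(keep)
        return cls(
            sub.data[variable].to_numpy(float),
            sub.log_potency().to_numpy(),
            labels[keep].to_numpy(),
        )

    # -- fixed-offsets variant ---------------------------------------------

    def _fit_fixed(self) -> SharedCurvatureFit:
        q = len(self.group_names)
        X = np.column_stack([np.ones_like(self.x), self.x, self.x**2])
        if q == 1:
            res = fit_ols(
                pd.DataFrame({"x": self.x, "x-sq": self.x**2}),
                ["x", "x-sq"],
                response=self.y,
            )
            return SharedCurvatureFit(
                beta_linear=float(res.coefficients["x"]),
                beta_quad=float(res.coefficients["x-sq"]),
                global_intercept=res.intercept,
                group_offsets={self.group_names[0]: 0.0},
                mode="fixed_offsets",
                residual_variance=float(np.sum(res.resid**2) / max(len(self.y) - 3, 1)),
                n_obs=len(self.y),
            )
        # sum-to-zero coding: q-1 deviation columns, last group = -1 on all
        D = np.zeros((len(self.y), q - 1))
        for j, name in enumerate(self.group_names[:-1]):
            D[self.g == name, j] = 1.0
        D[self.g == self.group_names[-1], :] = -1.0
        Xf = np.hstack([X, D])
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise FitError("rank-deficient design in fixed-offsets fit")
        beta, *_ = np.linalg.lstsq(Xf, self.y, rcond=None)
        offsets = {name: float(beta[3 + j]) for j, name in enumerate(self.group_names[:-1])}
        offsets[self.group_names[-1]] = float(-sum(offsets.values()))
        resid = self.y - Xf @ beta
        dof = max(len(self.y) - Xf.shape[1], 1)
        return SharedCurvatureFit(
            beta_linear=float(beta[1]),
            beta_quad=float(beta[2]),
            global_intercept=float(beta[0]),
            group_offsets=offsets,
            mode="fixed_offsets",
            residual_variance=float(resid @ resid / dof),
            n_obs=len(self.y),
        )

    # -- random-intercept variant ------------------------------------------

    def _reml_neg2(self, log_lam: float) -> float:
        """-2 x restricted log-likelihood profiled over the variance ratio."""
        lam = np.exp(log_lam)
        n = len(self.y)
        X = np.column_stack([np.ones_like(self.x), self.x, self.x**2])
        Z = self._indicator()
        V = np.eye(n) + lam * (Z @ Z.T)
        sign, logdet_v = np.linalg.slogdet(V)
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, self.y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = self.y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        p = X.shape[1]
        sigma2 = quad / (n - p)
        sign2, logdet_x = np.linalg.slogdet(XtViX)
        return (n - p) * np.log(sigma2) + logdet_v + logdet_x

    def _indicator(self) -> np.ndarray:
        Z = np.zeros((len(self.y), len(self.group_names)))
        for j, name in enumerate(self.group_names):
            Z[self.g == name, j] = 1.0
        return Z

    def _fit_random(self) -> SharedCurvatureFit:
        sizes = {g: int((self.g == g).sum()) for g in self.group_names}
        if len(self.group_names) < 2 or min(sizes.values()) < 2:
            raise InputError(
                "random-intercept fit needs >= 2 groups with >= 2 points each"
            )
        grid = np.log(np.geomspace(1e-8, 1e4, 49))
        vals = np.array([self._reml_neg2(ll) for ll in grid])
        if not np.all(np.isfinite(vals)):
            raise FitError(f"REML criterion non-finite on grid; trace: {vals.tolist()}")
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        log_lam = _golden_section(self._reml_neg2, lo, hi, tol=1e-10)
        lam = float(np.exp(log_lam))

        n = len(self.y)
        X = np.column_stack([np.ones_like(self.x), self.x, self.x**2])
        Z = self._indicator()
        V = np.eye(n) + lam * (Z @ Z.T)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ np.linalg.solve(V, self.y))
        r = self.y - X @ beta
        sigma2 = float(r @ np.linalg.solve(V, r)) / (n - X.shape[1])
        blup = lam * (Z.T @ np.linalg.solve(V, r))
        offsets = {name: float(b) for name, b in zip(self.group_names, blup)}
        return SharedCurvatureFit(
            beta_linear=float(beta[1]),
            beta_quad=float(beta[2]),
            global_intercept=float(beta[0]),
            group_offsets=offsets,
            mode="random_intercept",
            offset_variance=lam * sigma2,
            residual_variance=sigma2,
            n_obs=n,
        )

    def fit(self, mode: str = "fixed_offsets") -> SharedCurvatureFit:
        if len(self.y) < 6:
            raise InputError("need at least 6 observations")
        if mode == "fixed_offsets":
            return self._fit_fixed()
        if mode == "random_intercept":
            return self._fit_random()
        raise InputError(f"unknown mode {mode!r}")


def fit_shared_curvature(
    table: CompoundTable,
    labels: pd.Series,
    mode: str = "fixed_offsets",
    variable: str = "alogps",
) -> SharedCurvatureFit:
    """Fit the shared-curvature model on the classified records of a table."""
    return SharedCurvatureModel.from_table(table, labels, variable).fit(mode=mode)


def _golden_section(fn, a: float, b: float, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Minimise a unimodal scalar function on [a, b]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fn(c), fn(d)
    for _ in range(max_iter):
        if abs(b - a) < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fn(d)
    return (a + b) / 2.0
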