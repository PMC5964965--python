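"""Synthetic assay data and compound libraries with planted ground truth.

Everything the analysis pipeline consumes can be generated here, so every
stage is testable end-to-end with a known answer:

* :func:`simulate_trace` — a chloride-efflux trace rising asymptotically to
  a plateau, ``y(t) = a - b*c^t`` plus Gaussian noise.
* :func:`simulate_dose_response` — end-of-assay efflux across carrier
  loadings following a Hill law.
* :func:`simulate_library` — a compound library whose potency
  log10(1/EC50) follows a planted quadratic in log P with optional
  group-specific intercept offsets and Gaussian noise, plus decoy
  descriptor columns uncorrelated with the response.

Default library parameters mirror the measured tambjamine series: 43
compounds, log P spanning 1–7.5 drawn stratified into low/mid/high bands
(so the extremes are always represented), EC50s falling in roughly
0.003–0.35 mol%, Hill n in 0.85–1.75.  Noise is additive Gaussian on the
log-potency scale, consistent with fitting log10(1/EC50) by least squares.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CompoundTable
from .errors import InputError

__all__ = [
    "LibraryConfig",
    "simulate_trace",
    "simulate_dose_response",
    "simulate_library",
]


def simulate_trace(
    a: float,
    b: float,
    c: float,
    duration_s: float = 300.0,
    dt: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    loading: float = 0.05,
):
    """Simulate an efflux trace ``y = a - b*c^t`` (+ Gaussian noise).

    Returns ``(times, efflux, loading)``; times run 0..duration at step dt.
    """
    if not (0.0 < c < 1.0):
        raise InputError(f"decay base c must lie in (0, 1), got {c!r}")
    if b <= 0:
        raise InputError("amplitude b must be positive")
    if duration_s < 10 * dt:
        raise InputError("duration must cover at least 10 time steps")
    times = np.arange(0.0, duration_s + dt / 2, dt)
    y = a - b * c**times
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=times.size)
    return times, y, loading


def simulate_dose_response(
    ec50: float,
    hill_n: float,
    loadings,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate end-of-assay efflux across loadings from a Hill law.

    Returns ``(loadings, responses)`` with
    ``response = 100 * x^n / (EC50^n + x^n) + noise``.
    """
    if ec50 <= 0 or hill_n <= 0:
        raise InputError("ec50 and hill_n must be positive")
    x = np.asarray(loadings, dtype=float)
    if x.size == 0:
        raise InputError("loadings must be non-empty")
    if np.any(x <= 0):
        raise InputError("loadings must be positive")
    y = 100.0 * x**hill_n / (ec50**hill_n + x**hill_n)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.size)
    return x, y


@dataclass
class LibraryConfig:
    """Ground-truth parameters for a simulated compound library.

    The quadratic ``true_intercept + true_linear*logP + true_quad*logP^2``
    (plus the group offset and N(0, noise_sd) noise) is the planted
    log10(1/EC50).  Defaults sit at the scale of the measured tambjamine
    series.
    """

    n_compounds: int = 43
    true_intercept: float = -0.58
    true_linear: float = 1.2
    true_quad: float = -0.13
    group_offsets: dict = field(default_factory=dict)
    logp_range: tuple = (1.0, 7.5)
    noise_sd: float = 0.45
    n_decoy_descriptors: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        lo, hi = self.logp_range
        if not hi > lo:
            raise InputError("logp_range must be non-degenerate")
        if self.n_compounds < 6:
            raise InputError("need at least 6 compounds for a fittable library")


def simulate_library(config: LibraryConfig):
    """Generate (CompoundTable, descriptor DataFrame, truth dict).

    log P values are drawn stratified: the range is cut at its 1/3 and 2/3
    points into low/mid/high bands and compounds are spread across bands
    (remainders to the mid band), so high-leverage extremes always exist.
    Initial rates are generated log-log-linear in EC50 (so rate-based EC50
    calibration is exercisable); retention times are affine in log P plus
    noise; decoys are standard normal draws rescaled to plausible
    descriptor ranges.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.logp_range
    cuts = (lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0)
    n_low = cfg.n_compounds // 3
    n_high = cfg.n_compounds // 3
    n_mid = cfg.n_compounds - n_low - n_high
    logp = np.concatenate(
        [
            rng.uniform(lo, cuts[0], n_low),
            rng.uniform(cuts[0], cuts[1], n_mid),
            rng.uniform(cuts[1], hi, n_high),
        ]
    )
    rng.shuffle(logp)

    group_names = sorted(cfg.group_offsets) if cfg.group_offsets else [None]
    groups = [group_names[i % len(group_names)] for i in range(cfg.n_compounds)]
    offsets = np.array(
        [0.0 if g is None else cfg.group_offsets[g] for g in groups]
    )

    potency = (
        cfg.true_intercept
        + cfg.true_linear * logp
        + cfg.true_quad * logp**2
        + offsets
        + (rng.normal(0.0, cfg.noise_sd, cfg.n_compounds) if cfg.noise_sd > 0 else 0.0)
    )
    ec50 = 10.0 ** (-potency)
    # initial rate: log-log line in EC50 (slope -1) with mild scatter
    kini = 10.0 ** (-2.0 - np.log10(ec50) + rng.normal(0.0, 0.05, cfg.n_compounds))
    hill_n = rng.uniform(0.85, 1.75, cfg.n_compounds)
    rt = 6.5 + 1.1 * logp + rng.normal(0.0, 0.25, cfg.n_compounds)

    ids = [str(i + 1) for i in range(cfg.n_compounds)]
    table = CompoundTable(
        pd.DataFrame(
            {
                "compound_id": ids,
                "ec50_molpct": ec50,
                "hill_n": hill_n,
                "kini_pct_per_s": kini,
                "alogps": logp,
                "rt_min": rt,
                "r4": pd.Series([None] * cfg.n_compounds, dtype=object),
                "r5": pd.Series([None] * cfg.n_compounds, dtype=object),
                "r6_class": pd.Series(
                    [g if g is not None else None for g in groups], dtype=object
                ),
                "ec50_imputed": np.zeros(cfg.n_compounds, dtype=bool),
            }
        ),
        provenance=f"simulated(seed={cfg.seed})",
    )

    decoys = {}
    for j in range(cfg.n_decoy_descriptors):
        scale = 10.0 ** rng.uniform(-1, 2)
        shift = rng.uniform(-5, 50)
        decoys[f"decoy_{j:02d}"] = rng.normal(0.0, 1.0, cfg.n_compounds) * scale + shift
    descriptors = pd.DataFrame(
        {"ALOGPs": logp, **decoys}, index=pd.Index(ids, name="compound_id")
    )

    truth = {
        "intercept": cfg.true_intercept,
        "linear": cfg.true_linear,
        "quad": cfg.true_quad,
        "group_offsets": dict(cfg.group_offsets),
        "noise_sd": cfg.noise_sd,
        "logp": logp.tolist(),
        "groups": [g if g is not None else "" for g in groups],
        "seed": cfg.seed,
    }
    return table, descriptors, truth
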