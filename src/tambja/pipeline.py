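"""One-command reproduction of the full QSAR analysis.

:func:`run_pipeline` chains the stages a practitioner would run by hand:
load the compound table (packaged fixture or user CSV) → optionally clean a
descriptor matrix and enumerate candidate models → fit the two-term
parabolic lipophilicity model with analytic confidence intervals →
stratified-bootstrap the same model → optionally fit subgroup models when
substituent annotations are available → write ``models.csv``, ``boot.json``
and a human-readable ``report.md``.

Outputs are deterministic: two runs with the same config and seed produce
byte-identical ``models.csv`` and ``boot.json`` (no timestamps enter those
files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import qsar, subgroups
from .datasets import CompoundTable, load_compound_table, load_descriptor_matrix
from .descriptors import clean_descriptors
from .errors import TambjaError
from .kinetics import log_potency
from .resampling import StrataDefinition, stratified_bootstrap

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("tambja.pipeline")


class PipelineError(TambjaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one serialisable record."""

    compounds: str = "table1"  # path or fixture name
    descriptors: str | None = None
    annotations: str | None = None
    include_imputed: bool = True
    terms: tuple = ("alogps", "alogps-sq")
    strata_boundaries: tuple = (2.5, 5.0)
    n_resamples: int = 999
    seed: int = 0
    max_terms: int = 3
    top_k: int = 20
    variation_threshold: float = 1e-8
    subgroup_mode: str = "fixed_offsets"
    make_figure: bool = False
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "compounds": self.compounds,
            "descriptors": self.descriptors,
            "annotations": self.annotations,
            "include_imputed": self.include_imputed,
            "terms": list(self.terms),
            "strata_boundaries": list(self.strata_boundaries),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "max_terms": self.max_terms,
            "top_k": self.top_k,
            "variation_threshold": self.variation_threshold,
            "subgroup_mode": self.subgroup_mode,
            "out_dir": self.out_dir,
        }


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the analysis described by ``config``; returns a result bundle.

    Writes ``models.csv`` (ranked model table), ``boot.json`` (bootstrap
    intervals), ``report.md`` and ``run.log`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    log.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

    table = _stage("load")(load_compound_table, config.compounds)
    log.info("loaded %d compounds from %s", len(table), table.provenance)
    violations = table.validate()
    if violations:
        raise PipelineError("validate", TambjaError("; ".join(violations)))

    fit_table = table if config.include_imputed else table.without_imputed()

    enumerated = None
    cleaning_report = None
    if config.descriptors is not None:
        matrix = _stage("descriptors")(load_descriptor_matrix, config.descriptors)
        matrix, cleaning_report = _stage("clean")(
            clean_descriptors, matrix, config.variation_threshold
        )
        log.info(
            "descriptor cleaning: %d retained, %d removed",
            len(cleaning_report.retained),
            cleaning_report.n_removed,
        )
        ids = fit_table.data["compound_id"]
        aligned = matrix.loc[[i for i in ids if i in matrix.index]]
        keep = fit_table.data["compound_id"].isin(aligned.index).to_numpy()
        y = np.array([log_potency(v) for v in fit_table.data.loc[keep, "ec50_molpct"]])
        enumerated = _stage("enumerate")(
            qsar.enumerate_models, y, aligned, config.max_terms, None, config.top_k
        )
        log.info("enumerated top-%d models (max %d terms)", len(enumerated), config.max_terms)

    main_fit = _stage("fit")(qsar.fit_ols, fit_table, list(config.terms))
    log.info("main fit: R^2 = %.4f", main_fit.rsquared)

    strata = StrataDefinition(boundaries=config.strata_boundaries)
    boot = _stage("bootstrap")(
        stratified_bootstrap,
        fit_table,
        list(config.terms),
        strata,
        config.n_resamples,
        config.seed,
    )
    log.info("bootstrap: %d resamples, %d redraws", boot.n_resamples, boot.n_redraws)

    subgroup_result = None
    if config.annotations is not None:
        annotated = _stage("annotations")(_merge_annotations, fit_table, config.annotations)
        labels = subgroups.classify_subgroups(annotated)
        group_fits, skipped = _stage("subgroups")(
            subgroups.fit_group_quadratics, annotated, labels
        )
        shared = _stage("subgroups")(
            subgroups.fit_shared_curvature, annotated, labels, config.subgroup_mode
        )
        subgroup_result = {"group_fits": group_fits, "skipped": skipped, "shared": shared}
        log.info("subgroups: %d fitted, %d skipped", len(group_fits), len(skipped))

    _write_models_csv(out / "models.csv", main_fit, enumerated)
    (out / "boot.json").write_text(
        json.dumps(boot.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    _write_report(out / "report.md", config, main_fit, boot, subgroup_result, cleaning_report)
    if config.make_figure:
        _stage("figure")(_plot_parabola, fit_table, main_fit, out / "potency_vs_logp.png")

    return {
        "table": table,
        "fit": main_fit,
        "bootstrap": boot,
        "enumerated": enumerated,
        "cleaning_report": cleaning_report,
        "subgroups": subgroup_result,
        "out_dir": out,
    }


def _merge_annotations(table: CompoundTable, path) -> CompoundTable:
    import pandas as pd

    ann = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"compound_id", "r4", "r5", "r6_class"}
    if not need.issubset(ann.columns):
        raise TambjaError(f"annotation CSV must have columns {sorted(need)}")
    df = table.data.copy()
    ann = ann.set_index("compound_id")
    for col in ("r4", "r5", "r6_class"):
        mapped = df["compound_id"].map(ann[col])
        df[col] = [None if (v is None or v != v or v == "") else v for v in mapped]
    return CompoundTable(df, table.provenance + "+annotations")


def _fmt(x: float) -> str:
    return repr(round(float(x), 12))


def _write_models_csv(path: Path, main_fit, enumerated) -> None:
    rows = ["rank,terms,r_squared,intercept," + ",".join(
        f"coef_{i + 1}" for i in range(max(
            [len(main_fit.terms)] + [len(f.terms) for f in (enumerated or [])]
        ))
    )]
    fits = enumerated if enumerated else [main_fit]
    for rank, f in enumerate(fits, start=1):
        coefs = ",".join(_fmt(c) for c in f.coefficients)
        rows.append(
            f"{rank},{'+'.join(f.terms)},{_fmt(f.rsquared)},{_fmt(f.intercept)},{coefs}"
        )
    path.write_text("\n".join(rows) + "\n")


def _write_report(path, config, fit, boot, subgroup_result, cleaning_report) -> None:
    ci = fit.conf_int()
    lines = [
        "# Anion-transport QSAR report",
        "",
        "## Configuration",
        "```json",
        json.dumps(config.to_dict(), indent=1, sort_keys=True),
        "```",
        "",
        "## Parabolic lipophilicity model",
        "",
        f"Response: log10(1/EC50); terms: {', '.join(fit.terms)}; "
        f"n = {fit.n_obs}; R^2 = {fit.rsquared:.4f}",
        "",
        "| term | coefficient | 2.5% | 97.5% | boot 2.5% | boot 97.5% |",
        "|---|---|---|---|---|---|",
    ]
    for i, name in enumerate(fit.params.index):
        lines.append(
            f"| {name} | {fit.params[name]:.3f} | {ci.iloc[i, 0]:.3f} | "
            f"{ci.iloc[i, 1]:.3f} | {boot.ci_low[i]:.3f} | {boot.ci_high[i]:.3f} |"
        )
    try:
        lines += ["", f"Optimum log P (parabola vertex): {fit.optimum_logp():.3f}"]
    except TambjaError:
        pass
    if cleaning_report is not None:
        lines += [
            "",
            "## Descriptor cleaning",
            f"retained {len(cleaning_report.retained)}, "
            f"removed {cleaning_report.n_removed} "
            f"(incomplete {len(cleaning_report.removed_incomplete)}, "
            f"non-numeric {len(cleaning_report.removed_nonnumeric)}, "
            f"low variation {len(cleaning_report.removed_low_variation)})",
        ]
    if subgroup_result is not None:
        lines += ["", "## Structural subgroups", "```",
                  subgroup_result["shared"].summary(), "```"]
        for name, f in sorted(subgroup_result["group_fits"].items()):
            lines.append(f"- {name}: R^2 = {f.rsquared:.3f}, n = {f.n_obs}")
        if subgroup_result["skipped"]:
            lines.append(f"- skipped (<3 points): {', '.join(subgroup_result['skipped'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def _plot_parabola(table: CompoundTable, fit, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = table.data["alogps"].to_numpy(float)
    y = table.log_potency().to_numpy()
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 200)
    curve = fit.intercept + fit.coefficients.iloc[0] * grid + fit.coefficients.iloc[1] * grid**2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, color="#2a6f97", label="compounds")
    ax.plot(grid, curve, color="#c1121f", label="fitted parabola")
    ax.set_xlabel("ALOGPs")
    ax.set_ylabel("log10(1/EC50)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
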