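"""Pipeline orchestration, descriptive tables, and publication-style output.

``run_pipeline`` ties the stages together: load or simulate a registry,
code pillars and outcomes, descriptive statistics, univariate ACE
decompositions, the quasi-causal model sequence for both outcomes and
their pillar subsets, regression trees, and within-pair difference
descriptives.  Everything is seeded and the run log records every
stage, seed, and omitted-observation count.  Descriptive statistics use
complete cases; the structural models use FIML.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import ace, cart, quasicausal, synth, withinpair
from .pillars import PILLAR_COLUMNS, code_dataset, read_registry
from .quasicausal import PRESETS, QuasiCausalSpec, fit_model, wald_equal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_descriptives", "model_table"]

#: outcome -> (transformed model scale, raw tree/descriptive scale, top-2 preset)
OUTCOME_PLAN = {
    "bmi": ("log_bmi", "bmi", "bmi_top2"),
    "phq": ("sqrt_phq", "phq_total", "phq_top2"),
}


@dataclass
class RunConfig:
    """End-to-end run configuration."""

    input_path: str | None = None
    generator: synth.GeneratorConfig | None = None
    sleep_standard: str = "8h"
    symmetric_fv: bool = False
    model_levels: tuple[int, ...] = (1, 2, 3)
    covariates: tuple[str, ...] = ()
    predictor_mode: str = "observed_count"
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def summarize_descriptives(coded: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: mean (SD) rows and percentage rows,
    overall and stratified by sex.  Complete cases per variable."""
    cols = {}
    for label, sub in (
        ("Total", coded),
        ("Men", coded[coded["sex"] == "male"]),
        ("Women", coded[coded["sex"] == "female"]),
    ):
        col = {}
        col["n"] = len(sub)
        for var, name in (("age", "Age"), ("bmi", "BMI"), ("phq_total", "PHQ-2")):
            v = sub[var].dropna() if var in sub else pd.Series(dtype=float)
            col[name] = f"{v.mean():.1f} ({v.std():.1f})" if len(v) else ""
        if "race" in sub:
            r = sub["race"].dropna()
            col["Race (% White)"] = (
                f"{100 * (r == 'White').mean():.1f}" if len(r) else ""
            )
        for pcol in PILLAR_COLUMNS:
            v = sub[pcol].dropna()
            col[f"% {pcol}"] = f"{100 * v.mean():.1f}" if len(v) else ""
        np_ = sub["n_pillars"].dropna()
        for k in range(6):
            col[f"% {k} pillars"] = (
                f"{100 * (np_ == k).mean():.1f}" if len(np_) else ""
            )
        cols[label] = col
    return pd.DataFrame(cols)


def model_table(fits: dict, alpha: float = 0.05) -> str:
    """Markdown table of b_p / b_f estimates with significance bolding.

    ``fits`` maps row labels to QuasiCausalFit objects.  Bolding at the
    given alpha is presentational; p-values are emitted numerically.
    """
    lines = ["| model | parameter | estimate (SE) | p |", "|---|---|---|---|"]
    for label, fit in fits.items():
        for name in fit.param_names:
            base = name.split(":")[-1]
            if base not in ("b_p", "b_f"):
                continue
            est, se = fit.params[name], fit.se[name]
            _, p = fit.z_and_p(name)
            cell = f"{est:.3f} ({se:.3f})"
            if np.isfinite(p) and p < alpha:
                cell = f"**{cell}**"
            lines.append(f"| {label} | {name} | {cell} | {p:.3f} |")
    return "\n".join(lines)


def _fit_sequence(coded, scale_col, preset_name, cfg: RunConfig):
    """Models 1..3 for the all-pillar and top-2 predictor sets."""
    fits = {}
    for pillars in ("all", preset_name):
        for level in cfg.model_levels:
            spec = QuasiCausalSpec(
                outcome=scale_col,
                pillars=pillars,
                model_level=level,
                predictor_mode=cfg.predictor_mode,
                covariates=cfg.covariates if level == 3 else (),
                groups=("female", "male"),
            )
            fit = fit_model(spec, coded)
            key = f"{pillars}:model{level}"
            fits[key] = fit
            if level == 2:
                try:
                    fits[key].wald = wald_equal(fit, "female:b_p", "male:b_p")
                except (KeyError, ValueError, np.linalg.LinAlgError):
                    pass
    return fits


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle and writes
    JSON/CSV/markdown outputs plus a run log under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {"seed": cfg.seed, "stages": []}
    t_start = time.time()

    def stage(name):
        log["stages"].append({"stage": name, "t": round(time.time() - t_start, 2)})
        logger.info("stage: %s", name)

    stage("load")
    if cfg.input_path is not None:
        raw = read_registry(cfg.input_path)
    elif cfg.generator is not None:
        raw = synth.generate_registry(cfg.generator, seed=cfg.seed)
    else:
        raise ValueError("either input_path or generator required")

    stage("code")
    coded = code_dataset(raw, cfg.sleep_standard, cfg.symmetric_fv)
    coded.to_csv(outdir / "coded.csv", index=False)
    log["omitted"] = {
        "bmi_missing": int(coded["bmi"].isna().sum()),
        "phq_missing": int(coded["phq_total"].isna().sum()),
        "n_pillars_missing": int(coded["n_pillars"].isna().sum()),
    }

    stage("descriptives")
    desc = summarize_descriptives(coded)
    desc.to_csv(outdir / "descriptives.csv")

    stage("ace")
    ace_results = {}
    for trait in ("log_bmi", "sqrt_phq"):
        ace_results[trait] = ace.fit_ace_continuous(coded, trait).to_dict()
    ace_results["n_pillars"] = ace.fit_ace_ordinal(
        coded, "n_pillars", n_categories=6
    ).to_dict()
    with open(outdir / "ace.json", "w") as fh:
        json.dump(ace_results, fh, indent=1)

    stage("quasicausal")
    qc_results = {}
    tables = []
    for short, (scale_col, _, preset) in OUTCOME_PLAN.items():
        fits = _fit_sequence(coded, scale_col, preset, cfg)
        qc_results[short] = {k: f.to_dict() for k, f in fits.items()}
        tables.append(f"## {short}\n\n" + model_table(fits, cfg.alpha))
    with open(outdir / "quasicausal.json", "w") as fh:
        json.dump(qc_results, fh, indent=1)
    (outdir / "tables.md").write_text("\n\n".join(tables))

    stage("tree")
    tree_results = {}
    for short, (_, raw_col, _) in OUTCOME_PLAN.items():
        tree = cart.fit_regression_tree(
            coded, raw_col, list(PILLAR_COLUMNS), seed=cfg.seed
        )
        imp = cart.variable_importance(tree)
        tree_results[short] = {
            "tree": tree.to_dict(),
            "importance": imp.round(2).to_dict(),
            "rendering": tree.render(),
        }
    with open(outdir / "trees.json", "w") as fh:
        json.dump(tree_results, fh, indent=1)

    stage("diffs")
    diff_results = {}
    for short, (_, raw_col, _) in OUTCOME_PLAN.items():
        table = withinpair.difference_table(coded, raw_col)
        table.to_csv(outdir / f"diffs_{short}.csv", index=False)
        diff_results[short] = table

    stage("done")
    log["runtime_s"] = round(time.time() - t_start, 2)
    with open(outdir / "log.json", "w") as fh:
        json.dump(log, fh, indent=1)

    return {
        "coded": coded,
        "descriptives": desc,
        "ace": ace_results,
        "quasicausal": qc_results,
        "trees": tree_results,
        "diffs": diff_results,
        "log": log,
    }
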