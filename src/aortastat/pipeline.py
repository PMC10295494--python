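"""End-to-end orchestration: cohort in (real or simulated), report bundle out.

A run produces, under ``output_dir``:

* ``cohort.csv`` — the cohort analysed (simulated ones are written too)
* ``derived.csv`` — input columns plus the eight derived index columns
* ``descriptives.csv`` / ``descriptives_categorical.csv``
* ``comparisons_eat_by_aorta.csv`` — EAT measures across aortic median splits
* ``comparisons_aorta_by_eat.csv`` — aortic indices across EAT median splits
* ``correlations.csv`` — EAT x aorta correlation grid
* ``roc_report.csv`` — sensitivity/specificity/accuracy per predictor/outcome
* ``roc/<predictor>__<outcome>.txt`` — fpr, tpr, threshold coordinates
* ``tables.md`` — all tables rendered to markdown (2-decimal moments,
  3-decimal rates, significance as "<alpha" / "ns")
* ``summary.json`` — machine-readable superset of every rendered number

Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import analysis, roc as roc_mod, simulate
from .indices import BSA_METHODS, STIFFNESS_INTERPRETATIONS, IndexConfig, derive_frame
from .io import read_cohort_frame, write_cohort
from .records import DERIVED_COLUMNS

log = logging.getLogger("aortastat")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline options; every enum field mirrors a CLI flag."""

    seed: int = 0
    cohort_path: str | None = None  # None => simulate
    n: int = 97
    bsa_method: str = "du_bois"
    stiffness_interpretation: str = "log_of_ratio"
    correlation_flavour: str = "pearson"
    t_test_variant: str = "pooled"
    roc_criterion: str = "max_accuracy"
    alpha: float = 0.05
    output_dir: str = "aortastat_run"
    skip_invalid: bool = False

    def __post_init__(self):
        if not (0 < self.alpha <= 0.5):
            raise ValueError(f"alpha must be in (0, 0.5], got {self.alpha}")
        for value, allowed in [
            (self.bsa_method, BSA_METHODS),
            (self.stiffness_interpretation, STIFFNESS_INTERPRETATIONS),
            (self.correlation_flavour, ("pearson", "spearman")),
            (self.t_test_variant, ("pooled", "welch")),
            (self.roc_criterion, roc_mod.OPERATING_CRITERIA),
        ]:
            if value not in allowed:
                raise ValueError(f"{value!r} not in {allowed}")

    def index_config(self) -> IndexConfig:
        return IndexConfig(
            bsa_method=self.bsa_method,
            stiffness_interpretation=self.stiffness_interpretation,
        )


def _round_df(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    return df.round(decimals)


def _sig(p: float, alpha: float) -> str:
    return f"<{alpha:g}" if p < alpha else "ns"


def _markdown(summary: dict, alpha: float) -> str:
    """Render every report table from the JSON summary (and only from it)."""
    lines = ["# Cohort analysis report", ""]
    lines.append("## Descriptive statistics (mean ± SD)")
    lines.append("")
    lines.append("| variable | mean | SD |")
    lines.append("| --- | --- | --- |")
    for var, row in summary["descriptives"]["continuous"].items():
        sd = row["sd"]
        sd_s = "—" if sd is None else f"{sd:.2f}"
        lines.append(f"| {var} | {row['mean']:.2f} | {sd_s} |")
    lines.append("")
    for cat, counts in summary["descriptives"]["categorical"].items():
        lines.append(f"### {cat}")
        lines.append("")
        lines.append("| level | n | % |")
        lines.append("| --- | --- | --- |")
        for level, row in counts.items():
            lines.append(f"| {level} | {row['n']} | {row['percent']:.1f} |")
        lines.append("")

    for key, title in [
        ("comparisons_eat_by_aorta", "EAT measures across aortic median splits"),
        ("comparisons_aorta_by_eat", "Aortic indices across EAT median splits"),
    ]:
        lines.append(f"## {title}")
        lines.append("")
        lines.append(
            "| split variable | median | outcome | ≥ Me mean ± SD (n) | < Me mean ± SD (n) | test | p |"
        )
        lines.append("| --- | --- | --- | --- | --- | --- | --- |")
        for c in summary[key]:
            lines.append(
                f"| {c['split_variable']} | {c['split_median']:.2f} | {c['outcome_variable']} "
                f"| {c['mean_ge']:.2f} ± {c['sd_ge']:.2f} ({c['n_ge']}) "
                f"| {c['mean_lt']:.2f} ± {c['sd_lt']:.2f} ({c['n_lt']}) "
                f"| {c['test_used']} | {_sig(c['p_value'], alpha)} |"
            )
        lines.append("")

    lines.append("## EAT–aorta correlations")
    lines.append("")
    cols = summary["correlations"]["columns"]
    lines.append("| |" + "|".join(cols) + "|")
    lines.append("| --- |" + "|".join("---" for _ in cols) + "|")
    for r, row in summary["correlations"]["values"].items():
        lines.append("| " + r + " |" + "|".join(f"{row[c]:.2f}" for c in cols) + "|")
    lines.append("")

    lines.append("## ROC prediction of adverse aortic status")
    lines.append("")
    lines.append("| predictor | threshold | outcome | AUC | sensitivity | specificity | accuracy |")
    lines.append("| --- | --- | --- | --- | --- | --- | --- |")
    for r in summary["roc"]:
        lines.append(
            f"| {r['predictor']} ≥ {r['threshold']:.2f} | {r['threshold']:.2f} "
            f"| {r['outcome_variable']} {'≥' if r['outcome_direction'] == 'ge_median' else '<'} Me "
            f"| {r['auc']:.3f} | {r['sensitivity']:.3f} | {r['specificity']:.3f} | {r['accuracy']:.3f} |"
        )
    lines.append("")
    lines.append(
        f"{summary['n_tests']} hypothesis tests performed at α = {alpha:g}; "
        "no multiple-testing correction applied."
    )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle. Returns the summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "roc").mkdir(exist_ok=True)

    # -- stage: cohort ----------------------------------------------------
    if config.cohort_path is None:
        spec = simulate.default_spec(n=config.n, seed=config.seed)
        cohort = simulate.generate(spec).frame
        source = f"simulated(n={config.n}, seed={config.seed})"
    else:
        cohort = read_cohort_frame(config.cohort_path, skip_invalid=config.skip_invalid)
        source = str(config.cohort_path)
    write_cohort(cohort, out / "cohort.csv")
    digest = hashlib.md5((out / "cohort.csv").read_bytes()).hexdigest()
    log.info("stage=cohort source=%s n=%d md5=%s", source, len(cohort), digest)

    # -- stage: derive ----------------------------------------------------
    derived = derive_frame(cohort, config.index_config())
    derived.to_csv(out / "derived.csv", index=False, float_format="%.12g")
    log.info("stage=derive columns=%d", len(derived.columns))

    # -- stage: analyze ---------------------------------------------------
    desc = analysis.descriptive_table(derived)
    eat_by_ao = analysis.subgroup_table(
        derived, analysis.AO_VARIABLES, analysis.EAT_VARIABLES,
        alpha=config.alpha, t_variant=config.t_test_variant,
    )
    ao_by_eat = analysis.subgroup_table(
        derived, analysis.EAT_VARIABLES, analysis.AO_VARIABLES,
        alpha=config.alpha, t_variant=config.t_test_variant,
    )
    corr = analysis.correlation_table(derived, method=config.correlation_flavour)
    log.info("stage=analyze comparisons=%d", len(eat_by_ao) + len(ao_by_eat))

    # -- stage: roc -------------------------------------------------------
    roc_results = roc_mod.prediction_report(derived, criterion=config.roc_criterion)
    roc_frame = roc_mod.report_to_frame(roc_results)
    for r in roc_results:
        coords = pd.DataFrame(
            {"fpr": r.curve.fpr, "tpr": r.curve.tpr, "threshold": r.curve.thresholds}
        )
        coords.to_csv(
            out / "roc" / f"{r.predictor}__{r.outcome_variable}.txt",
            index=False, sep="\t", float_format="%.6g",
        )
    log.info("stage=roc results=%d", len(roc_results))

    # -- stage: report ----------------------------------------------------
    # output_dir is a run location, not an analysis parameter: identical
    # analyses into different directories must produce identical summaries
    summary = {
        "config": {k: v for k, v in asdict(config).items() if k != "output_dir"},
        "cohort": {"n": int(len(cohort)), "source": source, "md5": digest},
        "descriptives": {
            "continuous": {
                var: {
                    "mean": float(row["mean"]),
                    "sd": None if pd.isna(row["sd"]) else float(row["sd"]),
                }
                for var, row in desc["continuous"].iterrows()
            },
            "categorical": {
                cat: {
                    str(level): {"n": int(row["n"]), "percent": float(row["percent"])}
                    for level, row in table.iterrows()
                }
                for cat, table in desc["categorical"].items()
            },
        },
        "comparisons_eat_by_aorta": analysis.comparisons_to_frame(eat_by_ao).to_dict("records"),
        "comparisons_aorta_by_eat": analysis.comparisons_to_frame(ao_by_eat).to_dict("records"),
        "correlations": {
            "columns": list(corr.columns),
            "values": {r: {c: float(corr.loc[r, c]) for c in corr.columns} for r in corr.index},
        },
        "roc": roc_frame.to_dict("records"),
        "n_tests": len(eat_by_ao) + len(ao_by_eat),
    }

    _round_df(desc["continuous"], 6).to_csv(out / "descriptives.csv")
    cat_rows = []
    for cat, table in desc["categorical"].items():
        for level, row in table.iterrows():
            cat_rows.append(
                {"variable": cat, "level": level, "n": int(row["n"]), "percent": row["percent"]}
            )
    pd.DataFrame(cat_rows).to_csv(out / "descriptives_categorical.csv", index=False)
    analysis.comparisons_to_frame(eat_by_ao).to_csv(
        out / "comparisons_eat_by_aorta.csv", index=False, float_format="%.6g"
    )
    analysis.comparisons_to_frame(ao_by_eat).to_csv(
        out / "comparisons_aorta_by_eat.csv", index=False, float_format="%.6g"
    )
    corr.to_csv(out / "correlations.csv", float_format="%.6g")
    roc_frame.to_csv(out / "roc_report.csv", index=False, float_format="%.6g")
    (out / "tables.md").write_text(_markdown(summary, config.alpha))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("stage=report dir=%s", out)
    return summary


__all__ = ["RunConfig", "run_pipeline", "DERIVED_COLUMNS"]
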