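"""End-to-end orchestration: simulate -> process -> metrics -> stats.

``run_all`` drives a full synthetic-cohort analysis from one configuration:
cohort simulation, SUV conversion and 10-s resampling, clearance metrics at
both the 5-min split and the 2-min sensitivity split, the group-statistics
battery, a Markdown report and a reproducibility manifest.  Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clearance_metrics import (CAROTID_SPLIT_S, DEFAULT_SPLIT_S,
                                SENSITIVITY_SPLIT_S, summarize_cohort)
from .group_stats import (TacMatrix, chi_square_2x2, mann_whitney,
                          pointwise_group_tests, rm_anova_group_time,
                          spearman)
from .synthetic_cohort import (CohortConfig, all_turbinates_tac,
                               generate_cohort, write_cohort)
from .tac_processing import GRID_STEP_S, resample_10s, to_suv

__all__ = ["RunConfig", "run_all", "report", "cohort_uniform_tacs"]

#: panels carried through the ANOVA / pointwise stages
_PANEL_REGIONS = ("lof", "all_turbinates", "carotid")


@dataclass
class RunConfig:
    """One run's parameters: study conditions plus analysis thresholds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    tissue_split_s: float = DEFAULT_SPLIT_S
    carotid_split_s: float = CAROTID_SPLIT_S
    sensitivity_split_s: float = SENSITIVITY_SPLIT_S
    t75_fraction: float = 0.75
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for s in (self.tissue_split_s, self.carotid_split_s,
                  self.sensitivity_split_s):
            if abs(s / GRID_STEP_S - round(s / GRID_STEP_S)) > 1e-9:
                raise ValueError("split thresholds must lie on the 10-s grid")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        cohort_kwargs = obj.get("cohort", {})
        known = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(cohort_kwargs) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        if "effect" in cohort_kwargs:
            cohort_kwargs["effect"] = {k: tuple(v) for k, v in
                                       cohort_kwargs["effect"].items()}
        cohort = CohortConfig(**cohort_kwargs)
        top = {k: v for k, v in obj.items() if k != "cohort"}
        return cls(cohort=cohort, **top)


def cohort_uniform_tacs(cohort, include_all_turbinates: bool = True):
    """SUV-convert and resample every subject's TACs onto the 10-s grid.

    Returns ``list[(meta, dict region -> UniformTAC)]``; the combined
    All-turbinates curve is aggregated at TAC level (volume-weighted mean of
    the three turbinate curves) before conversion.
    """
    out = []
    for meta, tacs in cohort:
        tacs = dict(tacs)
        if include_all_turbinates and "all_turbinates" not in tacs:
            tacs["all_turbinates"] = all_turbinates_tac(tacs)
        uniform = {r: resample_10s(to_suv(t, meta)) for r, t in tacs.items()}
        out.append((meta, uniform))
    return out


def _tac_matrix(uniform_cohort, region: str, i0: int = 0,
                i1: int | None = None) -> TacMatrix:
    values = np.vstack([u[region].suv[i0:i1] for _, u in uniform_cohort])
    groups = np.array([m.amyloid for m, _ in uniform_cohort])
    times = uniform_cohort[0][1][region].times_s[i0:i1]
    return TacMatrix(values=values, groups=groups, times_s=times)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _group_values(df: pd.DataFrame, meta_by_id, region: str, column: str):
    sub = df[df.region == region]
    neg = sub[[meta_by_id[s].amyloid == "negative" for s in sub.subject_id]]
    pos = sub[[meta_by_id[s].amyloid == "positive" for s in sub.subject_id]]
    return neg[column].to_numpy(), pos[column].to_numpy()


def _safe_test(fn, *args):
    try:
        r = fn(*args)
        return {"statistic": r.statistic, "p_value": r.p_value,
                "method": r.method, "approach": r.approach,
                "n_per_group": list(r.n_per_group)}
    except ValueError as exc:
        return {"statistic": None, "p_value": None, "error": str(exc)}


def _anova_dict(table) -> dict:
    return {name: {"F": e.F, "df1": e.df1, "df2": e.df2,
                   "epsilon": e.epsilon, "df1_gg": e.df1_gg,
                   "df2_gg": e.df2_gg, "p_value": e.p_value}
            for name, e in table.effects().items()}


def _clearance_stats(df: pd.DataFrame, meta_by_id) -> dict:
    """Per-region group comparisons of the clearance summaries."""
    out = {}
    for region in sorted(df.region.unique()):
        entry = {}
        for col in ("auc_total", "auc_influx", "auc_egress", "t75_s",
                    "egress_influx_ratio"):
            neg, pos = _group_values(df, meta_by_id, region, col)
            entry[col] = _safe_test(mann_whitney, neg, pos)
            entry[col]["mean_neg"] = float(np.mean(neg))
            entry[col]["mean_pos"] = float(np.mean(pos))
        out[region] = entry
    return out


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full synthetic pipeline and write all artifacts to outdir.

    Artifacts: subjects.csv, tacs_<id>.csv, clearance.csv (tissue split),
    clearance_split120.csv (sensitivity split), stats_summary.json,
    report.md, manifest.json.  Returns the stats summary dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config.cohort)
    write_cohort(cohort, config.cohort, out)
    meta_by_id = {m.subject_id: m for m, _ in cohort}
    uniform = cohort_uniform_tacs(cohort)

    all_uniform = [u for _, byreg in uniform for u in byreg.values()]
    clearance = summarize_cohort(all_uniform, split_s=config.tissue_split_s,
                                 carotid_split_s=config.carotid_split_s)
    clearance.to_csv(out / "clearance.csv", index=False)
    clearance_sens = summarize_cohort(all_uniform,
                                      split_s=config.sensitivity_split_s,
                                      carotid_split_s=config.carotid_split_s)
    clearance_sens.to_csv(
        out / f"clearance_split{config.sensitivity_split_s:.0f}.csv",
        index=False)

    summary = _compute_stats(config, cohort, uniform, clearance,
                             clearance_sens)
    with open(out / "stats_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    with open(out / "stats_summary.json") as fh:
        summary_loaded = json.load(fh)
    (out / "report.md").write_text(report(summary_loaded))

    manifest = {
        "package_version": __version__,
        "seed": config.cohort.seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": _jsonable({
            "tissue_split_s": config.tissue_split_s,
            "carotid_split_s": config.carotid_split_s,
            "sensitivity_split_s": config.sensitivity_split_s,
            "alpha": config.alpha,
            "n_neg": config.cohort.n_neg,
            "n_pos": config.cohort.n_pos,
            "noise_scale": config.cohort.noise_scale,
        }),
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _compute_stats(config, cohort, uniform, clearance, clearance_sens) -> dict:
    meta_by_id = {m.subject_id: m for m, _ in cohort}
    metas = [m for m, _ in cohort]
    neg = [m for m in metas if m.amyloid == "negative"]
    pos = [m for m in metas if m.amyloid == "positive"]

    demographics = {
        "n_negative": len(neg), "n_positive": len(pos),
        "age": _safe_test(mann_whitney, [m.age_y for m in neg],
                          [m.age_y for m in pos]),
        "weight": _safe_test(mann_whitney, [m.weight_kg for m in neg],
                             [m.weight_kg for m in pos]),
        "sex": _safe_test(chi_square_2x2, [
            [sum(m.sex == "F" for m in neg), sum(m.sex == "M" for m in neg)],
            [sum(m.sex == "F" for m in pos), sum(m.sex == "M" for m in pos)],
        ]),
        "apoe_e4": _safe_test(chi_square_2x2, [
            [sum(m.apoe_e4 == "noncarrier" for m in neg),
             sum(m.apoe_e4 == "carrier" for m in neg)],
            [sum(m.apoe_e4 == "noncarrier" for m in pos),
             sum(m.apoe_e4 == "carrier" for m in pos)],
        ]),
    }

    # brain-nose correlations over the whole sample
    ordered = sorted(meta_by_id)
    def region_col(df, region, col):
        sub = df[df.region == region].set_index("subject_id")
        return sub.loc[ordered, col].to_numpy()

    correlations = {}
    for col in ("auc_total", "t75_s", "auc_egress"):
        correlations[f"lof_vs_all_turbinates_{col}"] = _safe_test(
            spearman, region_col(clearance, "lof", col),
            region_col(clearance, "all_turbinates", col))

    # repeated-measures ANOVAs on the TAC panels
    split_idx = int(round(config.tissue_split_s / GRID_STEP_S))
    anovas = {}
    pointwise = {}
    for region in ("lof", "all_turbinates"):
        full = _tac_matrix(uniform, region)
        influx = _tac_matrix(uniform, region, 0, split_idx + 1)
        egress = _tac_matrix(uniform, region, split_idx, None)
        anovas[region] = {
            "full": _anova_dict(rm_anova_group_time(full)),
            "influx": _anova_dict(rm_anova_group_time(influx)),
            "egress": _anova_dict(rm_anova_group_time(egress)),
        }
        _, p_adj, sig = pointwise_group_tests(full, alpha=config.alpha)
        pointwise[region] = {
            "n_timepoints": int(full.values.shape[1]),
            "n_significant": int(sig.size),
            "significant_times_s": (full.times_s[sig].tolist()
                                    if full.times_s is not None else []),
        }
    carotid_full = _tac_matrix(uniform, "carotid")
    anovas["carotid"] = {"full": _anova_dict(rm_anova_group_time(carotid_full))}

    group_comparisons = _clearance_stats(clearance, meta_by_id)

    # Split-threshold sensitivity: direction of the influx/egress segment
    # group effects at the main vs the 2-min split.  The egress/influx
    # ratio is defined at the main split only and is not part of this
    # comparison.
    sensitivity = {}
    for region in ("lof", "all_turbinates"):
        entry = {}
        for col in ("auc_influx", "auc_egress"):
            neg_m, pos_m = _group_values(clearance, meta_by_id, region, col)
            neg_s, pos_s = _group_values(clearance_sens, meta_by_id, region, col)
            d_main = float(np.mean(neg_m) - np.mean(pos_m))
            d_sens = float(np.mean(neg_s) - np.mean(pos_s))
            entry[col] = {
                "mean_diff_neg_minus_pos_split_main": float(d_main),
                "mean_diff_neg_minus_pos_split_sensitivity": float(d_sens),
                "same_direction": bool(np.sign(d_main) == np.sign(d_sens)),
            }
        sensitivity[region] = entry

    return {
        "alpha": config.alpha,
        "splits_s": {"tissue": config.tissue_split_s,
                     "carotid": config.carotid_split_s,
                     "sensitivity": config.sensitivity_split_s},
        "demographics": demographics,
        "correlations": correlations,
        "anova": anovas,
        "pointwise": pointwise,
        "group_comparisons": group_comparisons,
        "split_sensitivity": sensitivity,
    }


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------

def _fmt(v, nd=4):
    if v is None:
        return "NA"
    return f"{v:.{nd}g}" if isinstance(v, float) else str(v)


def report(summary: dict) -> str:
    """Render the stats summary as a Markdown report.

    Deterministic function of the (JSON-serializable) summary alone, so a
    report regenerated from a saved ``stats_summary.json`` is byte-identical
    to the original.
    """
    lines: list[str] = ["# Cohort clearance report", ""]
    demo = summary["demographics"]
    lines += ["## Demographics",
              "",
              f"Amyloid-negative n = {demo['n_negative']}, "
              f"amyloid-positive n = {demo['n_positive']}.",
              "",
              "| measure | test | statistic | p |",
              "|---|---|---|---|"]
    for key in ("age", "weight", "sex", "apoe_e4"):
        t = demo[key]
        lines.append(f"| {key} | {t.get('method', 'NA')} | "
                     f"{_fmt(t.get('statistic'))} | {_fmt(t.get('p_value'))} |")
    lines += ["", "## Brain-nose correlations", "",
              "| pair | rho | p |", "|---|---|---|"]
    for key, t in sorted(summary["correlations"].items()):
        lines.append(f"| {key} | {_fmt(t.get('statistic'))} | "
                     f"{_fmt(t.get('p_value'))} |")
    lines += ["", "## Repeated-measures ANOVA (group x time, "
                  "Greenhouse-Geisser corrected)", ""]
    for region, panels in sorted(summary["anova"].items()):
        lines += [f"### {region}", "",
                  "| panel | effect | F | df (GG) | epsilon | p |",
                  "|---|---|---|---|---|---|"]
        for panel, effects in sorted(panels.items()):
            for name in ("group", "time", "interaction"):
                e = effects[name]
                lines.append(
                    f"| {panel} | {name} | {_fmt(e['F'])} | "
                    f"({_fmt(e['df1_gg'], 5)}, {_fmt(e['df2_gg'], 6)}) | "
                    f"{_fmt(e['epsilon'])} | {_fmt(e['p_value'])} |")
        lines.append("")
    lines += ["## Pointwise group differences (FDR-corrected)", ""]
    for region, pw in sorted(summary["pointwise"].items()):
        lines.append(f"- {region}: {pw['n_significant']} of "
                     f"{pw['n_timepoints']} timepoints significant at "
                     f"alpha = {summary['alpha']}")
    lines += ["", "## Group comparisons of clearance summaries", "",
              "| region | measure | mean Ab- | mean Ab+ | p |",
              "|---|---|---|---|---|"]
    for region, entry in sorted(summary["group_comparisons"].items()):
        for col, t in sorted(entry.items()):
            lines.append(f"| {region} | {col} | {_fmt(t.get('mean_neg'))} | "
                         f"{_fmt(t.get('mean_pos'))} | {_fmt(t.get('p_value'))} |")
    lines += ["", "## Split-threshold sensitivity", ""]
    for region, entry in sorted(summary["split_sensitivity"].items()):
        agree = all(v["same_direction"] for v in entry.values())
        lines.append(f"- {region}: group-effect directions "
                     f"{'agree' if agree else 'DIFFER'} between the "
                     f"{summary['splits_s']['tissue']:.0f}-s and "
                     f"{summary['splits_s']['sensitivity']:.0f}-s splits")
    lines.append("")
    return "\n".join(lines)
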