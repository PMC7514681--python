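"""End-to-end orchestration: simulate -> preprocess -> MSE -> stats -> classify.

A run is fully determined by (config, seed): every output table is written
deterministically and the manifest echoes the configuration needed to
reproduce it. Stage failures abort the run with a stage-named error and
remove any partially written outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierReport, evaluate_medium
from .entropy import MseParams, MseProfile, multiscale_entropy
from .io import read_sessions, write_sessions
from .preprocessing import FilterSpec, preprocess_session
from .stats import GroupTestResult, bonferroni, friedman_test, spearman_correlation, wilcoxon_pair
from .synthetic import CohortSpec, NirsSession, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "profiles_for_sessions",
    "profiles_to_frame",
    "stats_from_summary",
    "classify_from_summary",
]

STAGE_ORDER = ("simulate", "preprocess", "mse", "stats", "classify")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    cohort: CohortSpec | str = field(default_factory=CohortSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    sbf_components: int = 3
    mse: MseParams = field(default_factory=MseParams)
    analysis_channel: str = "L3"
    fatigue_cut: float = 4.0
    output_dir: str = "nirsmse_run"
    seed: int | None = None
    skip_preprocessing: bool = False
    sampling_rate_hz: float = 10.0  # used when cohort is a CSV path

    def resolved_cohort(self) -> CohortSpec | str:
        """Apply the run-level seed override to a simulated cohort."""
        if isinstance(self.cohort, CohortSpec) and self.seed is not None:
            return dataclasses.replace(self.cohort, seed=self.seed)
        return self.cohort


def load_config(source: str | Path | Mapping) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file or an equivalent mapping."""
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    kwargs: dict = {}
    cohort = data.get("cohort")
    if isinstance(cohort, str):
        kwargs["cohort"] = cohort
    elif isinstance(cohort, Mapping):
        c = dict(cohort)
        for key in ("media",):
            if key in c:
                c[key] = tuple(c[key])
        kwargs["cohort"] = CohortSpec(**c)
    if "filter" in data:
        kwargs["filter"] = FilterSpec(**data["filter"])
    if "mse" in data:
        m = dict(data["mse"])
        if "scales" in m:
            m["scales"] = tuple(m["scales"])
        kwargs["mse"] = MseParams(**m)
    for key in ("sbf_components", "analysis_channel", "fatigue_cut",
                "output_dir", "seed", "skip_preprocessing", "sampling_rate_hz"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def profiles_for_sessions(
    sessions: Sequence[NirsSession],
    params: MseParams,
    channel: str,
) -> list[tuple[NirsSession, MseProfile]]:
    """MSE profile of the analysis channel's task segment, per session."""
    out = []
    for s in sessions:
        profile = multiscale_entropy(s.channel(channel, "task"), params, channel=channel)
        out.append((s, profile))
    return out


def profiles_to_frame(pairs: Sequence[tuple[NirsSession, MseProfile]]) -> pd.DataFrame:
    """Tidy per-scale table: participant, medium, channel, scale, sampen."""
    rows = []
    for s, p in pairs:
        for tau, val in p.values.items():
            rows.append({
                "participant_id": s.participant_id,
                "medium": s.medium,
                "channel": p.channel,
                "scale": tau,
                "sampen": val,
                "averaged_mse": p.averaged_mse,
                "fatigue_score": s.fatigue_score,
            })
    return pd.DataFrame(rows)


def summary_frame(pairs: Sequence[tuple[NirsSession, MseProfile]]) -> pd.DataFrame:
    """One row per session: averaged MSE and fatigue."""
    rows = [{
        "participant_id": s.participant_id,
        "medium": s.medium,
        "averaged_mse": p.averaged_mse,
        "fatigue_score": s.fatigue_score,
    } for s, p in pairs]
    return pd.DataFrame(rows)


def stats_from_summary(summary: pd.DataFrame, media: Sequence[str]) -> list[GroupTestResult]:
    """Friedman across media, post hoc Wilcoxon pairs (Bonferroni over the
    pairs), and a per-medium Spearman against fatigue (Bonferroni over media)."""
    media = [m for m in media if m in set(summary["medium"])]
    wide = summary.pivot(index="participant_id", columns="medium", values="averaged_mse")
    wide = wide[media]
    results: list[GroupTestResult] = []

    fried = friedman_test(wide.to_numpy())
    fried.p_corrected = fried.p_raw  # single omnibus test, no correction
    fried.note = " vs ".join(media)
    results.append(fried)

    pair_list = list(itertools.combinations(media, 2))
    pair_results = []
    for m1, m2 in pair_list:
        res = wilcoxon_pair(wide[m1].to_numpy(), wide[m2].to_numpy())
        res.note = f"{m1} vs {m2}" + (f" ({res.note})" if res.note else "")
        pair_results.append(res)
    for res, p_c in zip(pair_results, bonferroni([r.p_raw for r in pair_results],
                                                 len(pair_list))):
        res.p_corrected = p_c
    results.extend(pair_results)

    sp_results = []
    for m in media:
        sub = summary[summary["medium"] == m]
        x = sub["averaged_mse"].to_numpy(dtype=float)
        y = sub["fatigue_score"].to_numpy(dtype=float)
        res = spearman_correlation(x, y)
        res.note = f"averaged MSE vs fatigue, {m}"
        sp_results.append(res)
    for res, p_c in zip(sp_results, bonferroni([r.p_raw for r in sp_results], len(media))):
        res.p_corrected = p_c
    results.extend(sp_results)
    return results


def classify_from_summary(
    summary: pd.DataFrame,
    media: Sequence[str],
    fatigue_cut: float = 4.0,
) -> list[ClassifierReport]:
    reports = []
    for m in media:
        sub = summary[(summary["medium"] == m) & summary["fatigue_score"].notna()]
        pairs = list(zip(sub["averaged_mse"], sub["fatigue_score"].astype(int)))
        reports.append(evaluate_medium(pairs, medium=m, fatigue_cut=fatigue_cut))
    return reports


def _stats_records(results: Sequence[GroupTestResult]) -> list[dict]:
    return [{
        "test": r.test_name,
        "statistic": r.statistic,
        "n": r.n,
        "df": r.df,
        "p_raw": r.p_raw,
        "p_corrected": r.p_corrected,
        "effect_size": r.effect_size,
        "note": r.note,
    } for r in results]


def _classifier_records(reports: Sequence[ClassifierReport]) -> list[dict]:
    return [{
        "medium": r.medium,
        "boundary": r.boundary,
        "accuracy_pct": round(r.accuracy_pct, 2),
        "tp": r.counts.tp,
        "tn": r.counts.tn,
        "fp": r.counts.fp,
        "fn": r.counts.fn,
        "precision": None if math.isnan(r.precision) else round(r.precision, 2),
        "recall": None if math.isnan(r.recall) else round(r.recall, 2),
        "f1": None if math.isnan(r.f1) else round(r.f1, 2),
        "undefined_metrics": r.undefined_metrics,
        "chance_level_pct": r.chance_level_pct,
        "in_sample": r.in_sample,
    } for r in reports]


def _config_echo(config: RunConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    return plain(config)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact bundle to ``output_dir``.

    Returns a dict with the in-memory results (sessions, profiles, summary,
    stats, classifier reports, manifest).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_text(name: str, text: str) -> None:
        p = out_dir / name
        p.write_text(text)
        written.append(p)

    try:
        # --- simulate / load -------------------------------------------------
        try:
            cohort = config.resolved_cohort()
            if isinstance(cohort, CohortSpec):
                sessions = generate_cohort(cohort)
                simulated = True
                media = list(cohort.media)
            else:
                sessions = read_sessions(cohort, sampling_rate_hz=config.sampling_rate_hz)
                simulated = False
                media = list(dict.fromkeys(s.medium for s in sessions))
            if not sessions:
                raise ValueError("no sessions to analyze")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc

        if simulated:
            p = out_dir / "sessions.csv"
            write_sessions(sessions, p)
            written.append(p)

        # --- preprocess ------------------------------------------------------
        try:
            if config.skip_preprocessing:
                processed = list(sessions)
            else:
                processed = [
                    preprocess_session(s, config.filter, config.sbf_components)
                    for s in sessions
                ]
        except Exception as exc:
            raise PipelineError("preprocess", str(exc)) from exc

        # --- mse -------------------------------------------------------------
        try:
            pairs = profiles_for_sessions(processed, config.mse, config.analysis_channel)
            profiles_df = profiles_to_frame(pairs)
            summary = summary_frame(pairs)
        except Exception as exc:
            raise PipelineError("mse", str(exc)) from exc
        p = out_dir / "mse_profiles.csv"
        profiles_df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

        # --- stats -----------------------------------------------------------
        try:
            stat_results = stats_from_summary(summary, media)
        except Exception as exc:
            raise PipelineError("stats", str(exc)) from exc
        stats_records = _stats_records(stat_results)
        _write_text("stats.json", json.dumps(stats_records, indent=2, sort_keys=True))
        pd.DataFrame(stats_records).to_csv(out_dir / "stats.csv", index=False)
        written.append(out_dir / "stats.csv")

        # --- classify --------------------------------------------------------
        try:
            reports = classify_from_summary(summary, media, config.fatigue_cut)
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        cls_records = _classifier_records(reports)
        _write_text("classifier.json", json.dumps(cls_records, indent=2, sort_keys=True))
        table = pd.DataFrame([{
            "Medium": r["medium"],
            "Accuracy": f"{r['accuracy_pct']:.2f}%",
            "TP": r["tp"], "TN": r["tn"], "FP": r["fp"], "FN": r["fn"],
            "Precision": r["precision"], "Recall": r["recall"], "F1-Score": r["f1"],
        } for r in cls_records])
        table.to_csv(out_dir / "classifier_table.csv", index=False)
        written.append(out_dir / "classifier_table.csv")

        # --- manifest --------------------------------------------------------
        excluded = sorted({
            s.participant_id for s in sessions if s.fatigue_score is None
        })
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_order": list(STAGE_ORDER),
            "config": _config_echo(config),
            "simulated": simulated,
            "n_sessions": len(sessions),
            "n_profiles": len(pairs),
            "n_stat_tests": len(stats_records),
            "n_classifier_reports": len(cls_records),
            "participants_without_fatigue": excluded,
            "undefined_entropy_scales": {
                f"{s.participant_id}/{s.medium}": pr.undefined_scales
                for s, pr in pairs if pr.undefined_scales
            },
        }
        _write_text("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return {
        "sessions": sessions,
        "processed": processed,
        "profiles": pairs,
        "profiles_df": profiles_df,
        "summary": summary,
        "stats": stat_results,
        "classifier_reports": reports,
        "manifest": manifest,
        "output_dir": out_dir,
    }
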