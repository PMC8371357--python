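"""Exclusion pipeline and the pre-registered + exploratory analysis battery.

Consumes the three event tables (participants, grid clicks, anagram events)
from real logs or from :mod:`searchprime.simulate`, applies the seven
pre-registered exclusion criteria, and runs

* the manipulation check (dispersion measure by condition, Welch t + d),
* the primary one-sided test of delta-t (clustered > dispersed) with the
  TOST equivalence test at d = +-0.36, and
* the exploratory battery: sequential-step manipulation check, paired
  resource-contingent comparisons, per-letter-set wear-out tests,
  grid-time and points analyses, cross-domain correlations, and bigram
  similarity.

Reports are plain dicts (JSON-serializable) plus a Markdown rendering.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .anagrams import (
    AnagramSession,
    Visit,
    WordEvent,
    mean_letterset_time,
    session_bigram_similarity,
)
from .spatial import (
    ClickSequence,
    GridSearchRecord,
    participant_contingent_means,
    participant_dispersion,
    participant_mean_step,
)

REQUIRED_PARTICIPANT_COLUMNS = [
    "participant_id",
    "condition",
    "comprehension_fails_anagram",
    "comprehension_fails_grid",
    "inactivity_warnings_post_anagram",
    "inactivity_warnings_grid",
    "max_inactivity_during_warning",
    "post_instruction_time",
    "words_pre",
    "words_post",
    "completed",
]

#: criterion id -> (description, predicate on a participant row)
EXCLUSION_CRITERIA = {
    "1": ("anagram comprehension failed >2 times", lambda r: r.comprehension_fails_anagram > 2),
    "2": ("grid comprehension failed >2 times", lambda r: r.comprehension_fails_grid > 2),
    "3": ("fewer than 20 words in a phase", lambda r: r.words_pre < 20 or r.words_post < 20),
    "4": ("two inactivity warnings in post-test anagram", lambda r: r.inactivity_warnings_post_anagram >= 2),
    "5": ("two inactivity warnings in grid task", lambda r: r.inactivity_warnings_grid >= 2),
    "6": ("inactive >=100 s during a warning", lambda r: r.max_inactivity_during_warning >= 100),
    "7": (">150 s on post-test instructions", lambda r: r.post_instruction_time > 150),
    "incomplete": ("did not complete the experiment", lambda r: not r.completed),
}


@dataclass
class ExclusionReport:
    triggered: dict  # participant_id -> list of criterion ids
    counts: dict  # criterion id -> count
    retained_n: dict  # condition -> retained count

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class SchemaError(ValueError):
    pass


@dataclass
class StudyData:
    """Event tables plus per-participant derived objects."""

    participants: pd.DataFrame
    clicks: pd.DataFrame
    anagram: pd.DataFrame

    @classmethod
    def from_csv(cls, participants, clicks, anagram) -> "StudyData":
        return cls(pd.read_csv(participants), pd.read_csv(clicks), pd.read_csv(anagram))

    @classmethod
    def from_tables(cls, tables) -> "StudyData":
        return cls(tables.participants, tables.clicks, tables.anagram)


def _check_schema(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {missing}")


def apply_exclusions(participants: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Evaluate all exclusion criteria for every participant (criteria are
    independent, so order cannot matter) and return the retained table plus
    a full per-participant trigger report."""
    _check_schema(participants, REQUIRED_PARTICIPANT_COLUMNS, "participants")
    triggered: dict[str, list[str]] = {}
    counts = {cid: 0 for cid in EXCLUSION_CRITERIA}
    for row in participants.itertuples(index=False):
        hits = [cid for cid, (_, pred) in EXCLUSION_CRITERIA.items() if pred(row)]
        if hits:
            triggered[str(row.participant_id)] = hits
            for cid in hits:
                counts[cid] += 1
    keep = ~participants["participant_id"].astype(str).isin(triggered)
    retained = participants[keep].reset_index(drop=True)
    retained_n = retained.groupby("condition")["participant_id"].count().to_dict()
    return retained, ExclusionReport(triggered, counts, retained_n)


def grid_records(clicks: pd.DataFrame, participant_ids=None) -> dict[str, GridSearchRecord]:
    """Assemble per-participant GridSearchRecords from the click-event table."""
    _check_schema(
        clicks, ["participant_id", "condition", "grid_index", "trial", "row", "col", "payoff"], "clicks"
    )
    records: dict[str, GridSearchRecord] = {}
    keep = set(map(str, participant_ids)) if participant_ids is not None else None
    for (pid, cond), part in clicks.groupby(["participant_id", "condition"], sort=True):
        pid = str(pid)
        if keep is not None and pid not in keep:
            continue
        seqs = []
        for _, grid in part.sort_values("trial").groupby("grid_index", sort=True):
            seqs.append(
                ClickSequence(
                    grid["row"].to_numpy(), grid["col"].to_numpy(), grid["payoff"].to_numpy()
                )
            )
        records[pid] = GridSearchRecord(pid, str(cond), seqs)
    return records


def anagram_sessions(anagram: pd.DataFrame, participant_ids=None) -> dict[str, dict[str, AnagramSession]]:
    """Rebuild AnagramSessions (per participant, per phase) from event rows."""
    _check_schema(
        anagram, ["participant_id", "phase", "letterset_index", "event", "word", "correct", "time_s"],
        "anagram",
    )
    keep = set(map(str, participant_ids)) if participant_ids is not None else None
    out: dict[str, dict[str, AnagramSession]] = {}
    for (pid, phase), part in anagram.groupby(["participant_id", "phase"], sort=True):
        pid = str(pid)
        if keep is not None and pid not in keep:
            continue
        visits = []
        for idx, ev in part.sort_values("time_s", kind="stable").groupby("letterset_index", sort=True):
            enter = ev.loc[ev["event"] == "enter", "time_s"]
            exit_ = ev.loc[ev["event"] == "exit", "time_s"]
            subs = ev[ev["event"] == "submit"]
            words = [
                WordEvent(str(w) if pd.notna(w) else "", _as_bool(c), float(t))
                for w, c, t in zip(subs["word"], subs["correct"], subs["time_s"])
            ]
            visits.append(
                Visit(int(idx), float(enter.iloc[0]), float(exit_.iloc[0]), words)
            )
        visits.sort(key=lambda v: v.enter_time)
        out.setdefault(pid, {})[str(phase)] = AnagramSession(str(phase), visits)
    return out


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v) and not pd.isna(v)


def participant_metrics(data: StudyData, retained: pd.DataFrame) -> pd.DataFrame:
    """One row per retained participant with every derived measure used by
    the analyses; undefined measures are NaN (skip-not-impute)."""
    records = grid_records(data.clicks, retained["participant_id"])
    sessions = anagram_sessions(data.anagram, retained["participant_id"])
    rows = []
    for prow in retained.itertuples(index=False):
        pid = str(prow.participant_id)
        rec = records.get(pid)
        sess = sessions.get(pid, {})
        pre, post = sess.get("pre"), sess.get("post")
        after_hit, after_miss = (
            participant_contingent_means(rec) if rec else (math.nan, math.nan)
        )
        t_a1 = mean_letterset_time(pre) if pre else math.nan
        t_a2 = mean_letterset_time(post) if post else math.nan
        post_set_times = {}
        if post is not None:
            for k in range(1, 7):
                post_set_times[f"post_set_{k}_time"] = (
                    post.visits[k - 1].dwell if k - 1 < len(post.visits) else math.nan
                )
        rows.append(
            dict(
                participant_id=pid,
                condition=str(prow.condition),
                dispersion=participant_dispersion(rec) if rec else math.nan,
                mean_step=participant_mean_step(rec) if rec else math.nan,
                step_after_hit=after_hit,
                step_after_miss=after_miss,
                t_a1=t_a1,
                t_a2=t_a2,
                delta_t=t_a2 - t_a1,
                bigram_pre=session_bigram_similarity(pre) if pre else math.nan,
                bigram_post=session_bigram_similarity(post) if post else math.nan,
                grid_time_s=float(getattr(prow, "grid_time_s", math.nan)),
                total_points=float(getattr(prow, "total_points", math.nan)),
                **post_set_times,
            )
        )
    return pd.DataFrame(rows)


def _summaries(metrics: pd.DataFrame, column: str):
    out = {}
    for cond in ("clustered", "dispersed"):
        vals = metrics.loc[metrics["condition"] == cond, column].dropna()
        if len(vals) < 2:
            return None
        out[cond] = stats.GroupSummary.from_sample(vals)
    return out


def _welch_block(metrics, column, alternative="two_sided") -> dict | None:
    g = _summaries(metrics, column)
    if g is None:
        return None
    test = stats.welch_from_summaries(g["clustered"], g["dispersed"], alternative)
    es = stats.cohens_d_from_summaries(g["clustered"], g["dispersed"])
    return {
        "groups": {c: dataclasses.asdict(s) for c, s in g.items()},
        "welch": dataclasses.asdict(test),
        "effect": dataclasses.asdict(es),
    }


def run_preregistered(data: StudyData, alpha: float = 0.05, bound_d: float = 0.36) -> dict:
    """Exclusions, manipulation check, primary one-sided Welch test on
    delta-t (clustered > dispersed) and the TOST equivalence test."""
    retained, report = apply_exclusions(data.participants)
    for cond in ("clustered", "dispersed"):
        if report.retained_n.get(cond, 0) < 2:
            raise ValueError(f"fewer than 2 retained participants in {cond} condition")
    metrics = participant_metrics(data, retained)
    n_missing_dt = int(metrics["delta_t"].isna().sum())

    out = {
        "exclusions": report.to_dict(),
        "n_delta_t_missing": n_missing_dt,
        "manipulation_check": _welch_block(metrics, "dispersion"),
        "primary": _welch_block(metrics, "delta_t", alternative="greater"),
    }
    g = _summaries(metrics.dropna(subset=["delta_t"]), "delta_t")
    if g is not None:
        out["tost"] = dataclasses.asdict(
            stats.tost_from_summaries(g["clustered"], g["dispersed"], bound_d, alpha)
        )
    return out


def run_exploratory(data: StudyData) -> dict:
    """The exploratory battery; sub-analyses with insufficient data are
    reported as skipped rather than failing the run."""
    retained, _ = apply_exclusions(data.participants)
    metrics = participant_metrics(data, retained)
    out: dict = {}

    def guarded(key, fn):
        try:
            out[key] = fn()
        except (ValueError, KeyError) as exc:
            out[key] = {"skipped": str(exc)}

    # (a) sequential-step manipulation check
    guarded("step_manipulation_check", lambda: _welch_block(metrics, "mean_step"))

    # (b) within-condition paired contingent comparisons (after-miss - after-hit)
    def contingent():
        block = {}
        for cond in ("clustered", "dispersed"):
            sub = metrics[metrics["condition"] == cond]
            diffs = (sub["step_after_miss"] - sub["step_after_hit"]).dropna()
            block[cond] = {
                "n": int(len(diffs)),
                "mean_after_hit": float(sub["step_after_hit"].mean()),
                "mean_after_miss": float(sub["step_after_miss"].mean()),
                "paired_t": dataclasses.asdict(stats.paired_t(diffs)),
                "paired_d": dataclasses.asdict(stats.paired_d(diffs)),
            }
        return block

    guarded("contingent_steps", contingent)

    # (c) wear-out: pre-test mean vs k-th post-test letter-set, k = 1..6
    def wearout():
        block = {}
        for k in range(1, 7):
            col = f"post_set_{k}_time"
            if col not in metrics:
                block[str(k)] = {"skipped": "no post-test letter-set times"}
                continue
            m = metrics.assign(wear=metrics[col] - metrics["t_a1"]).dropna(subset=["wear"])
            b = _welch_block(m, "wear")
            block[str(k)] = b if b is not None else {"skipped": "insufficient data"}
        return block

    guarded("wearout", wearout)

    # (d) grid-task time: group comparison and regressions on delta-t
    def gridtime():
        m = metrics.dropna(subset=["grid_time_s", "delta_t"])
        if len(m) < 4 or m["grid_time_s"].isna().all():
            raise ValueError("grid-task durations unavailable")
        block = {"group_comparison": _welch_block(m, "grid_time_s")}
        fit1 = stats.ols(m["delta_t"], m["grid_time_s"].to_numpy(), names=["grid_time_s"])
        cond = (m["condition"] == "clustered").astype(float).to_numpy()
        fit2 = stats.ols(
            m["delta_t"],
            np.column_stack([cond, m["grid_time_s"].to_numpy()]),
            names=["condition_clustered", "grid_time_s"],
        )
        block["ols_delta_t_on_time"] = _ols_dict(fit1)
        block["ols_delta_t_on_condition_time"] = _ols_dict(fit2)
        return block

    guarded("grid_time", gridtime)

    # (e) cross-domain correlations: each spatial measure vs t_A1 and t_A2
    def correlations():
        block = {}
        for spatial_col in ("dispersion", "mean_step"):
            for time_col in ("t_a1", "t_a2"):
                m = metrics.dropna(subset=[spatial_col, time_col])
                r, ci, p = stats.pearson_r(m[spatial_col], m[time_col])
                block[f"{spatial_col}_vs_{time_col}"] = {
                    "r": r, "ci_low": ci[0], "ci_high": ci[1], "p": p, "n": int(len(m)),
                }
        return block

    guarded("correlations", correlations)

    # (f) points earned: group comparison and covariate regression
    def points():
        m = metrics.dropna(subset=["total_points", "delta_t"])
        if len(m) < 4 or m["total_points"].isna().all():
            raise ValueError("point totals unavailable")
        block = {"group_comparison": _welch_block(m, "total_points")}
        cond = (m["condition"] == "clustered").astype(float).to_numpy()
        fit = stats.ols(
            m["delta_t"],
            np.column_stack([cond, m["total_points"].to_numpy()]),
            names=["condition_clustered", "total_points"],
        )
        block["ols_delta_t_on_condition_points"] = _ols_dict(fit)
        return block

    guarded("points", points)

    # (g) bigram similarity in the post-test, with pre-test covariate
    def bigram():
        m = metrics.dropna(subset=["bigram_post"])
        block = {"group_comparison": _welch_block(m, "bigram_post")}
        m2 = m.dropna(subset=["bigram_pre"])
        cond = (m2["condition"] == "clustered").astype(float).to_numpy()
        fit = stats.ols(
            m2["bigram_post"],
            np.column_stack([cond, m2["bigram_pre"].to_numpy()]),
            names=["condition_clustered", "bigram_pre"],
        )
        block["ols_post_on_condition_pre"] = _ols_dict(fit)
        return block

    guarded("bigram_similarity", bigram)
    return out


def _ols_dict(fit) -> dict:
    return {
        "coef": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.bse.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "n": int(fit.nobs),
        "r_squared": float(fit.rsquared),
    }


def run_all(data: StudyData, alpha: float = 0.05, bound_d: float = 0.36, config: dict | None = None) -> dict:
    report = {
        "settings": {"alpha": alpha, "bound_d": bound_d, **(config or {})},
        "preregistered": run_preregistered(data, alpha, bound_d),
        "exploratory": run_exploratory(data),
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write report.json (machine-readable, round-trips bit-exactly) and a
    Markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(_sanitize(report), indent=1, sort_keys=True))
    md_path = out / "report.md"
    md_path.write_text(_render_markdown(report))
    return json_path, md_path


def _sanitize(obj):
    """NaN -> None and numpy scalars -> Python scalars for strict JSON."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _fmt_block(name: str, block: dict | None) -> list[str]:
    lines = [f"### {name}", ""]
    if not block:
        lines += ["(not available)", ""]
        return lines
    if "skipped" in block:
        lines += [f"skipped: {block['skipped']}", ""]
        return lines
    if "groups" in block:
        for cond, g in block["groups"].items():
            lines.append(f"- {cond}: n={g['n']}, M={g['mean']:.3f}, sd={g['sd']:.3f}")
    if "welch" in block:
        w = block["welch"]
        lines.append(
            f"- Welch t({w['df']:.1f}) = {w['statistic']:.3f}, p = {w['p']:.4g} ({w['alternative']})"
        )
    if "effect" in block:
        e = block["effect"]
        lines.append(f"- d = {e['d']:.3f}, CI95 [{e['ci_low']:.3f}, {e['ci_high']:.3f}]")
    lines.append("")
    return lines


def _render_markdown(report: dict) -> str:
    lines = ["# Study report", ""]
    pre = report.get("preregistered", {})
    if pre:
        lines += ["## Pre-registered analyses", ""]
        exc = pre.get("exclusions", {})
        if exc:
            lines.append(f"- retained n per condition: {exc.get('retained_n')}")
            lines.append(f"- exclusions per criterion: {exc.get('counts')}")
            lines.append("")
        lines += _fmt_block("Manipulation check (dispersion)", pre.get("manipulation_check"))
        lines += _fmt_block("Primary test (delta-t, clustered > dispersed)", pre.get("primary"))
        t = pre.get("tost")
        if t:
            lines += [
                "### Equivalence test (TOST)",
                "",
                f"- bounds d = +-{t['bound_d']}, t_lower = {t['t_lower']:.3f}, "
                f"t_upper = {t['t_upper']:.3f}, p = {t['p_tost']:.4g}, "
                f"equivalent: {t['equivalent']}",
                "",
            ]
    if report.get("exploratory"):
        lines += ["## Exploratory analyses", ""]
        for key, block in report["exploratory"].items():
            if isinstance(block, dict) and ("groups" in block or "skipped" in block):
                lines += _fmt_block(key, block)
            else:
                lines += [f"### {key}", "", "```json",
                          json.dumps(_sanitize(block), indent=1), "```", ""]
    return "\n".join(lines)
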