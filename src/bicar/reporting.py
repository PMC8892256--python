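"""Longitudinal progress series and healthy-vs-patient group comparison.

Progress: per-parameter time series over a subject's sessions with weekly
(ISO calendar week) aggregates, mirroring the week-by-week follow-up view of
the evaluation software.  Group comparison: per-parameter means and
dispersions for a baseline group A (e.g. healthy) and a group B (e.g.
post-stroke), the percent excess of B's admission means over A's means
(rounded to integer percent), and paired admission-vs-discharge Wilcoxon
signed-rank tests within group B at significance 0.05.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bieval import PerformanceReport, PARAMETER_FIELDS

__all__ = [
    "ProgressSeries",
    "GroupComparison",
    "progress_history",
    "group_compare",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ProgressSeries:
    """Time series of one parameter over a subject's sessions."""

    parameter: str
    points: list  # (ISO date string, value)
    weekly: list  # (ISO "YYYY-Www", mean of that week's sessions)
    n_missing: int = 0


@dataclass
class GroupComparison:
    """Per-parameter group statistics and paired admission/discharge tests."""

    group_A_mean: dict
    group_A_sd: dict
    group_B_admission_mean: dict
    group_B_admission_sd: dict
    group_B_discharge_mean: dict
    group_B_discharge_sd: dict
    percent_excess: dict           # int %, B admission vs A, per parameter
    paired_p_values: dict          # parameter -> Wilcoxon p (None if untestable)
    significant: dict              # parameter -> p < 0.05
    n_A: int = 0
    n_B: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _parse_date(s: str) -> _dt.datetime:
    return _dt.datetime.fromisoformat(s)


def progress_history(
    reports: Sequence[PerformanceReport],
) -> dict[str, ProgressSeries]:
    """Per-parameter session series and ISO-week means for one subject.

    Reports must already be sorted by session date (raises otherwise);
    sessions with an undefined parameter are skipped and counted.
    """
    if not reports:
        raise ValueError("need at least one report")
    dates = [_parse_date(r.session_date) for r in reports]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("reports must be sorted by session date")
    out: dict[str, ProgressSeries] = {}
    for param in PARAMETER_FIELDS:
        pts, missing = [], 0
        weeks: dict[str, list] = {}
        for r, d in zip(reports, dates):
            v = getattr(r, param)
            if v is None:
                missing += 1
                continue
            pts.append((r.session_date, float(v)))
            iso = d.isocalendar()
            weeks.setdefault(f"{iso[0]}-W{iso[1]:02d}", []).append(float(v))
        weekly = [(wk, float(np.mean(vs))) for wk, vs in sorted(weeks.items())]
        out[param] = ProgressSeries(param, pts, weekly, missing)
    return out


def _by_subject(reports: Sequence[PerformanceReport]) -> dict[str, list]:
    groups: dict[str, list] = {}
    for r in reports:
        groups.setdefault(r.subject_id, []).append(r)
    for sid in groups:
        groups[sid].sort(key=lambda r: _parse_date(r.session_date))
    return groups


def _mean_sd(values: list) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def group_compare(
    group_a: Sequence[PerformanceReport],
    group_b: Sequence[PerformanceReport],
) -> GroupComparison:
    """Compare a baseline group A with a treatment group B.

    For group B, each subject's first session by date is the *admission*
    report and the last the *discharge* report.  The percent excess is
    ``round(100 * (B_admission - A) / A)`` per parameter; paired two-sided
    Wilcoxon signed-rank tests compare admission vs discharge across B's
    subjects (omitted when fewer than two subjects or all differences zero).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    subj_b = _by_subject(group_b)
    admissions = [sess[0] for sess in subj_b.values()]
    discharges = [sess[-1] for sess in subj_b.values()]

    a_mean, a_sd = {}, {}
    adm_mean, adm_sd, dis_mean, dis_sd = {}, {}, {}, {}
    excess, pvals, signif = {}, {}, {}
    for param in PARAMETER_FIELDS:
        a_vals = [float(getattr(r, param)) for r in group_a if getattr(r, param) is not None]
        adm_vals = [float(getattr(r, param)) for r in admissions if getattr(r, param) is not None]
        dis_vals = [float(getattr(r, param)) for r in discharges if getattr(r, param) is not None]
        a_mean[param], a_sd[param] = _mean_sd(a_vals)
        adm_mean[param], adm_sd[param] = _mean_sd(adm_vals)
        dis_mean[param], dis_sd[param] = _mean_sd(dis_vals)
        if a_mean[param] not in (None, 0.0) and adm_mean[param] is not None:
            excess[param] = int(
                round(100.0 * (adm_mean[param] - a_mean[param]) / a_mean[param])
            )
        else:
            excess[param] = None
        p = None
        paired = [
            (float(getattr(adm, param)), float(getattr(dis, param)))
            for adm, dis in zip(admissions, discharges)
            if getattr(adm, param) is not None and getattr(dis, param) is not None
        ]
        if len(paired) >= 2:
            x = np.array([a for a, _ in paired])
            y = np.array([b for _, b in paired])
            if np.any(x != y):
                p = float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
        pvals[param] = p
        signif[param] = (p is not None) and (p < SIGNIFICANCE_LEVEL)

    return GroupComparison(
        group_A_mean=a_mean,
        group_A_sd=a_sd,
        group_B_admission_mean=adm_mean,
        group_B_admission_sd=adm_sd,
        group_B_discharge_mean=dis_mean,
        group_B_discharge_sd=dis_sd,
        percent_excess=excess,
        paired_p_values=pvals,
        significant=signif,
        n_A=len(group_a),
        n_B=len(subj_b),
    )
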