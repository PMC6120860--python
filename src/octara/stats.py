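"""Cohort-level statistics for longitudinal OCT-A quantification.

The battery mirrors the analysis plan of a two-visit observational cohort:
inter-grader Pearson reliability with averaging of the two grader series,
per-eye change-over-time rates, one-sample t-tests of the mean rates against
zero, paired t-tests between visits and between the superficial and deep
plexus, and a bivariate Pearson correlation grid of EZ line width and BCVA
against every OCT-A readout at each visit. All tests are two-sided with
significance declared at p < 0.05; no multiple-testing correction is applied
by default (an optional Benjamini–Hochberg adjustment is available), which
matches common practice for this kind of exploratory correlation grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05

#: metric columns of the tidy eye×visit table, in reporting order
METRIC_COLUMNS = (
    "pd_scp_pct",
    "pd_dcp_pct",
    "faz_scp_mm2",
    "faz_dcp_mm2",
    "cc_mgv",
    "ez_width_um",
    "bcva_logmar",
)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class PearsonResult(NamedTuple):
    r: float
    p: float


def one_sample_t(values, null_mean: float = 0.0) -> TTestResult:
    """Two-sided one-sample Student's t-test against ``null_mean``."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValueError(
            f"zero variance: all {x.size} values equal {x[0]}; t undefined"
        )
    res = sps.ttest_1samp(x, null_mean)
    return TTestResult(float(res.statistic), x.size - 1, float(res.pvalue))


def paired_t(values_a, values_b) -> TTestResult:
    """Two-sided paired Student's t-test (≡ one-sample test on differences)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_r(x, y) -> PearsonResult:
    """Sample Pearson correlation with two-sided p from the t transform."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError("series must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(xa, ya)
    return PearsonResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class GraderPair:
    """Two independent graders' series, their reliability, and the average."""

    grader_a: np.ndarray
    grader_b: np.ndarray
    pearson: PearsonResult
    averaged: np.ndarray
    metric: str | None = None


def grader_merge(a, b, metric: str | None = None) -> GraderPair:
    """Inter-grader Pearson r plus the element-wise mean used downstream."""
    aa = np.asarray(a, dtype=np.float64)
    bb = np.asarray(b, dtype=np.float64)
    if aa.shape != bb.shape:
        raise ValueError("grader series must have equal length")
    if np.array_equal(aa, bb):
        r = PearsonResult(1.0, 0.0)  # identical graders: perfect reliability
    else:
        r = pearson_r(aa, bb)
    return GraderPair(aa, bb, r, (aa + bb) / 2.0, metric=metric)


def _to_wide(visits: pd.DataFrame) -> pd.DataFrame:
    """One row per eye with <metric>_v1 / _v2 / _rate columns and dt."""
    required = {"eye_id", "visit", "dt_years"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visits table lacks columns {sorted(missing)}")
    metrics = [m for m in METRIC_COLUMNS if m in visits.columns]
    v1 = visits[visits["visit"] == 1].set_index("eye_id")
    v2 = visits[visits["visit"] == 2].set_index("eye_id")
    eyes = v1.index.intersection(v2.index)
    wide = pd.DataFrame(index=eyes)
    wide["dt_years"] = v2.loc[eyes, "dt_years"].astype(float)
    for m in metrics:
        wide[f"{m}_v1"] = pd.to_numeric(v1.loc[eyes, m], errors="coerce")
        wide[f"{m}_v2"] = pd.to_numeric(v2.loc[eyes, m], errors="coerce")
        wide[f"{m}_rate"] = (wide[f"{m}_v2"] - wide[f"{m}_v1"]) / wide["dt_years"]
    return wide


def _metric_row(wide: pd.DataFrame, m: str) -> dict:
    sub = wide[[f"{m}_v1", f"{m}_v2", f"{m}_rate"]].dropna()
    n = len(sub)
    row = {
        "metric": m,
        "n": n,
        "visit1_mean": np.nan,
        "visit1_sd": np.nan,
        "visit2_mean": np.nan,
        "visit2_sd": np.nan,
        "visits_paired_p": np.nan,
        "rate_mean": np.nan,
        "rate_sd": np.nan,
        "rate_sem": np.nan,
        "rate_one_sample_p": np.nan,
        "status": "ok",
    }
    if n < 2:
        row["status"] = "insufficient_data"
        return row
    v1, v2, rate = sub[f"{m}_v1"], sub[f"{m}_v2"], sub[f"{m}_rate"]
    row.update(
        visit1_mean=v1.mean(),
        visit1_sd=v1.std(ddof=1),
        visit2_mean=v2.mean(),
        visit2_sd=v2.std(ddof=1),
        rate_mean=rate.mean(),
        rate_sd=rate.std(ddof=1),
        rate_sem=rate.std(ddof=1) / np.sqrt(n),
    )
    try:
        row["visits_paired_p"] = paired_t(v2, v1).p
        row["rate_one_sample_p"] = one_sample_t(rate).p
    except ValueError as err:
        row["status"] = f"undefined: {err}"
        log.warning("metric %s: %s", m, err)
    return row


# SCP-vs-DCP paired comparisons reported alongside the per-metric summary
_PLEXUS_PAIRS = (
    ("pd_scp_pct", "pd_dcp_pct", "perfusion_density"),
    ("faz_scp_mm2", "faz_dcp_mm2", "faz_area"),
)


def build_tables(
    visits: pd.DataFrame, alpha: float = ALPHA, fdr: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary and correlation tables from a tidy eye×visit table.

    Returns ``(summary, correlations)``: per-metric visit means ± SD, paired
    visit-1-vs-visit-2 p, mean rate ± SEM with its one-sample p, SCP-vs-DCP
    paired comparisons (values per visit and rates), and the Pearson grid of
    EZ width / BCVA against the OCT-A readouts at each visit. Complete-case
    per analysis, with the n used always reported. Dispersion convention:
    SD for visit-level means, SEM for rates (SD also included).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    wide = _to_wide(visits)
    if len(wide) < 2:
        raise ValueError("need at least 2 eyes with both visits")
    metrics = [m for m in METRIC_COLUMNS if f"{m}_v1" in wide.columns]
    dropped = [m for m in metrics if wide[[f"{m}_v1", f"{m}_v2"]].dropna().empty]
    for m in dropped:
        log.warning("metric %s has no complete cases; dropped", m)
    metrics = [m for m in metrics if m not in dropped]

    summary = pd.DataFrame([_metric_row(wide, m) for m in metrics])

    comparisons = []
    for scp, dcp, label in _PLEXUS_PAIRS:
        if scp not in metrics or dcp not in metrics:
            continue
        for what in ("v1", "v2", "rate"):
            sub = wide[[f"{scp}_{what}", f"{dcp}_{what}"]].dropna()
            entry = {
                "comparison": f"{label}_scp_vs_dcp_{what}",
                "n": len(sub),
                "scp_mean": sub[f"{scp}_{what}"].mean(),
                "dcp_mean": sub[f"{dcp}_{what}"].mean(),
                "paired_p": np.nan,
            }
            try:
                entry["paired_p"] = paired_t(
                    sub[f"{scp}_{what}"], sub[f"{dcp}_{what}"]
                ).p
            except ValueError as err:
                log.warning("comparison %s: %s", entry["comparison"], err)
            comparisons.append(entry)
    if comparisons:
        comp = pd.DataFrame(comparisons)
        comp.insert(0, "metric", "comparison")
        summary = pd.concat([summary, comp], ignore_index=True)

    responses = [m for m in ("ez_width_um", "bcva_logmar") if m in metrics]
    predictors = [m for m in metrics if m not in responses]
    rows = []
    for resp in responses:
        for pred in predictors:
            for visit in (1, 2):
                sub = wide[[f"{resp}_v{visit}", f"{pred}_v{visit}"]].dropna()
                row = {
                    "response": resp,
                    "predictor": pred,
                    "visit": visit,
                    "n": len(sub),
                    "r": np.nan,
                    "p": np.nan,
                }
                try:
                    res = pearson_r(sub.iloc[:, 0], sub.iloc[:, 1])
                    row["r"], row["p"] = res.r, res.p
                except ValueError as err:
                    log.warning(
                        "correlation %s ~ %s visit %d: %s", resp, pred, visit, err
                    )
                rows.append(row)
    correlations = pd.DataFrame(rows)
    if fdr is not None:
        if fdr != "bh":
            raise ValueError("only 'bh' adjustment is supported")
        ok = correlations["p"].notna()
        adj = np.full(len(correlations), np.nan)
        adj[ok.to_numpy()] = sps.false_discovery_control(
            correlations.loc[ok, "p"].to_numpy(), method="bh"
        )
        correlations["p_adjusted"] = adj
        correlations["significant"] = correlations["p_adjusted"] < alpha
    else:
        correlations["significant"] = correlations["p"] < alpha
    return summary, correlations
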