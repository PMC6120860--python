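"""Parameter-recovery experiments validating the whole pipeline.

Because no patient scans are available, the pipeline is validated end to end
by simulation: a cohort is drawn with known true yearly rates, rendered to
image files, quantified back through the binarize → FAZ → metrics path, and
summarized by the statistics battery; the recovered cohort-mean rates are
then compared with the generator's configured truth. Correlation recovery
and test calibration run in table-only mode (no images).
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import quantify_manifest
from .stats import build_tables, one_sample_t, pearson_r
from .synthetic import CohortSpec, generate_cohort, sample_bivariate

#: visits-table column carrying each metric measured by the image pipeline
RATE_METRICS = (
    "pd_scp_pct",
    "pd_dcp_pct",
    "faz_scp_mm2",
    "faz_dcp_mm2",
    "cc_mgv",
    "ez_width_um",
    "bcva_logmar",
)


def recover_cohort_rates(seed: int, n_eyes: int = 28) -> dict[str, float]:
    """Simulate, render, re-measure and summarize one full cohort.

    Returns the recovered cohort-mean yearly rate per metric, as estimated
    by the statistics battery from the quantified visits table.
    """
    cs = CohortSpec(n_eyes=n_eyes, rng_seed=int(seed))
    with tempfile.TemporaryDirectory() as td:
        generate_cohort(cs, out_dir=td)
        manifest = pd.read_csv(Path(td) / "manifest.csv")
        visits, _ = quantify_manifest(manifest, root=td)
    summary, _ = build_tables(visits)
    rows = summary.set_index("metric")
    return {m: float(rows.loc[m, "rate_mean"]) for m in RATE_METRICS if m in rows.index}


def averaged_recovery(
    seeds: np.ndarray | list[int], n_eyes: int = 28
) -> dict[str, float]:
    """Mean recovered cohort rate per metric, averaged over seeded cohorts."""
    per_seed = [recover_cohort_rates(s, n_eyes=n_eyes) for s in seeds]
    return {
        m: float(np.mean([d[m] for d in per_seed if m in d]))
        for m in RATE_METRICS
    }


def recover_correlation(
    rho: float,
    marginal_x: tuple[float, float],
    marginal_y: tuple[float, float],
    n: int,
    seed: int,
) -> float:
    """Sample Pearson r from an exact bivariate-normal draw (table-only)."""
    x, y = sample_bivariate(
        n, marginal_x[0], marginal_x[1], marginal_y[0], marginal_y[1], rho, seed
    )
    return pearson_r(x, y).r


def null_rejection_rate(
    n_reps: int = 1000, n: int = 28, sd: float = 1.0, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of zero-mean rate cohorts rejected by the one-sample test.

    Calibration check for the non-progressing metric class (e.g. the
    choriocapillaris): with true rate 0, the rejection fraction must sit at
    the nominal test size.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rates = rng.normal(0.0, sd, n)
        if one_sample_t(rates).p < alpha:
            hits += 1
    return hits / n_reps


def significant_fraction(
    mean: float,
    sem: float,
    n: int = 28,
    n_reps: int = 200,
    p_threshold: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts whose mean-rate test reaches p ≤ threshold.

    Per-eye true rates are drawn N(mean, (sem·√n)²), the distribution implied
    when the reported ± of a cohort rate is its standard error.
    """
    rng = np.random.default_rng(seed)
    sd = sem * np.sqrt(n)
    hits = 0
    for _ in range(n_reps):
        rates = rng.normal(mean, sd, n)
        if one_sample_t(rates).p <= p_threshold:
            hits += 1
    return hits / n_reps
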