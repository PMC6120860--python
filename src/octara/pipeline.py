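"""End-to-end quantification: image(s) in, tidy eye×visit table out.

Chains the preprocessing recipe (red channel → auto or fixed threshold →
binarize), FAZ delineation (automated surrogate by default, manual masks
when supplied) and the per-visit metrics, applying the cohort bookkeeping
rules: one eye per patient (best mean scan quality, ties to the right eye),
eyes with scan quality below 7/10 excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .faz import FazMask, faz_auto, load_faz_mask
from .metrics import choriocapillaris_mgv, ez_width, perfusion_density
from .preprocess import (
    Angiogram,
    ThresholdBounds,
    VesselMask,
    auto_threshold_default,
    binarize,
    load_angiogram,
)

log = logging.getLogger(__name__)

QUALITY_MIN = 7  # scans below 7/10 signal strength are excluded


@dataclass(frozen=True)
class AngiogramMeasurement:
    pd_pct: float
    faz_mm2: float
    bounds: ThresholdBounds
    vessels: VesselMask
    faz: FazMask


def measure_angiogram(
    a: Angiogram,
    bounds: ThresholdBounds | None = None,
    faz: FazMask | None = None,
    r_close: int = 2,
) -> AngiogramMeasurement:
    """Binarize one angiogram and measure PD and FAZ area.

    ``bounds=None`` applies the default auto-threshold; ``faz=None`` runs
    the automated center flood-fill surrogate.
    """
    if bounds is None:
        bounds = auto_threshold_default(a)
    vessels = binarize(a, bounds)
    if faz is None:
        faz = faz_auto(vessels, r_close=r_close)
    return AngiogramMeasurement(
        perfusion_density(vessels, faz), faz.area_mm2, bounds, vessels, faz
    )


def _parse_threshold(threshold: str) -> ThresholdBounds | None:
    if threshold == "auto":
        return None
    lo, hi = threshold.split(":")
    return ThresholdBounds(int(lo), int(hi), mode="fixed")


def _select_eyes(manifest: pd.DataFrame) -> pd.DataFrame:
    """One eye per patient: best mean quality, ties resolved to the right eye."""
    if "patient_id" not in manifest.columns:
        return manifest
    keep = []
    for pat, grp in manifest.groupby("patient_id", sort=True):
        eyes = grp.groupby("eye_id")["quality"].mean()
        if len(eyes) > 1:
            best = eyes.max()
            tied = sorted(eyes[eyes == best].index)
            right = [e for e in tied if e.upper().endswith("OD")]
            chosen = right[0] if right else tied[0]
            log.info("patient %s: selected %s among %s", pat, chosen, list(eyes.index))
        else:
            chosen = eyes.index[0]
        keep.append(chosen)
    return manifest[manifest["eye_id"].isin(keep)]


def quantify_manifest(
    manifest: pd.DataFrame,
    root: str | Path = ".",
    threshold: str = "auto",
    faz_mode: str = "auto",
    field_mm: float = 3.0,
    ez_scan_mm: float = 9.0,
    quality_min: float = QUALITY_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every eye×visit listed in a manifest.

    The manifest is tidy (one row per file) with columns ``eye_id``,
    ``visit``, ``kind`` (scp | dcp | cc | ez), ``path``, and optionally
    ``patient_id``, ``visit_date``, ``quality``, ``bcva_logmar`` and
    ``faz_path``. Returns ``(visits, exclusions)``; per-image failures are
    recorded and skipped, and more than 50% failures raises.
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    root = Path(root)
    bounds = _parse_threshold(threshold)
    manifest = _select_eyes(manifest)

    exclusions = []
    if "quality" in manifest.columns:
        bad = manifest.groupby("eye_id")["quality"].min()
        for eye in bad[bad < quality_min].index:
            exclusions.append(
                {"eye_id": eye, "reason": f"signal strength below {quality_min}/10"}
            )
            log.warning("excluding %s: scan quality below %s/10", eye, quality_min)
        manifest = manifest[~manifest["eye_id"].isin([e["eye_id"] for e in exclusions])]

    rows: dict[tuple[str, int], dict] = {}
    n_fail = 0
    for rec in manifest.itertuples(index=False):
        key = (rec.eye_id, int(rec.visit))
        row = rows.setdefault(
            key,
            {
                "eye_id": rec.eye_id,
                "visit": int(rec.visit),
                "visit_date": getattr(rec, "visit_date", None),
                "bcva_logmar": getattr(rec, "bcva_logmar", np.nan),
            },
        )
        path = root / rec.path
        try:
            kind = rec.kind.lower()
            if kind in ("scp", "dcp"):
                a = load_angiogram(path, kind.upper(), field_mm=field_mm)
                faz = None
                if faz_mode == "manual":
                    faz = load_faz_mask(root / rec.faz_path, a.scale_mm_per_px)
                meas = measure_angiogram(a, bounds=bounds, faz=faz)
                row[f"pd_{kind}_pct"] = meas.pd_pct
                row[f"faz_{kind}_mm2"] = meas.faz_mm2
            elif kind == "cc":
                a = load_angiogram(path, "choriocapillaris", field_mm=field_mm)
                row["cc_mgv"] = choriocapillaris_mgv(a)
            elif kind == "ez":
                profile = np.loadtxt(path, skiprows=1)
                row["ez_width_um"] = ez_width(profile, scan_mm=ez_scan_mm)
            else:
                raise ValueError(f"unknown manifest kind {rec.kind!r}")
        except Exception as err:  # row-level failure; the run continues
            n_fail += 1
            log.error("%s (%s v%s): %s", path, rec.eye_id, rec.visit, err)
            exclusions.append(
                {"eye_id": rec.eye_id, "reason": f"{rec.kind}: {err}"}
            )
    if n_fail > 0.5 * len(manifest):
        raise RuntimeError(f"{n_fail}/{len(manifest)} images failed to quantify")

    visits = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["eye_id"], r["visit"])))
    if "visit_date" in visits.columns and visits["visit_date"].notna().all():
        dates = pd.to_datetime(visits["visit_date"])
        d1 = visits.assign(d=dates).pivot(index="eye_id", columns="visit", values="d")
        dt = ((d1[2] - d1[1]).dt.days / 365.25).rename("dt_years")
        visits = visits.merge(dt, on="eye_id")
    return visits, pd.DataFrame(exclusions, columns=["eye_id", "reason"])
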