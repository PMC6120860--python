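"""Per-visit quantitative readouts.

Four measurements summarize each eye-visit: perfusion density of a capillary
plexus (percent of analyzed pixels classified as vessel, FAZ excluded from
numerator and denominator), FAZ area (see :mod:`octara.faz`), the mean gray
value of the unprocessed choriocapillaris slab (a proxy for choroidal blood
flow), and the ellipsoid-zone line width measured on a 9-mm horizontal
foveal reflectivity profile. Progression is the per-eye change over time:
(follow-up − baseline) / interval, negative meaning decline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d

from .faz import FazMask
from .preprocess import Angiogram, VesselMask

log = logging.getLogger(__name__)


@dataclass
class EyeVisit:
    """All measurements for one eye at one visit; missing fields are None."""

    eye_id: str
    visit: int
    visit_date: str | None = None
    dt_years: float | None = None
    pd_scp_pct: float | None = None
    pd_dcp_pct: float | None = None
    faz_scp_mm2: float | None = None
    faz_dcp_mm2: float | None = None
    cc_mgv: float | None = None
    ez_width_um: float | None = None
    bcva_logmar: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def perfusion_density(vessels: VesselMask, faz: FazMask | None = None) -> float:
    """Vessel pixels over analyzed pixels, as a percentage.

    FAZ pixels are excluded from both counts (FAZ takes precedence over the
    vessel label where the two masks overlap), so
    ``PD = 100 · |vessel ∧ ¬FAZ| / (|all| − |FAZ|)``. With no FAZ this is
    the plain vessel fraction.
    """
    vmask = vessels.mask
    if faz is None:
        return 100.0 * vmask.sum() / vmask.size
    if faz.mask.shape != vmask.shape:
        raise ValueError("FAZ mask dimensions do not match vessel mask")
    denom = vmask.size - faz.faz_px
    if denom == 0:
        raise ValueError("empty denominator: FAZ covers the entire image")
    num = int((vmask & ~faz.mask).sum())
    return 100.0 * num / denom


def choriocapillaris_mgv(a: Angiogram) -> float:
    """Mean gray value of the unprocessed choriocapillaris slab."""
    if a.slab != "choriocapillaris":
        raise ValueError(f"MGV is defined on the choriocapillaris slab, got {a.slab}")
    if a.processed:
        raise ValueError("MGV requires unprocessed image")
    return float(a.pixels.mean(dtype=np.float64))


def ez_width_manual(
    left_px: int, right_px: int, length_px: int, scan_mm: float = 9.0
) -> float:
    """EZ width from grader-marked boundary columns, inclusive of both ends."""
    if not (0 <= left_px < right_px < length_px):
        raise ValueError("require 0 <= left < right < length")
    return (right_px - left_px + 1) * (scan_mm * 1000.0 / length_px)


def ez_width(profile: np.ndarray, scan_mm: float = 9.0) -> float:
    """EZ width from a 1-D reflectivity profile, in µm.

    The profile is smoothed with a 5-sample moving average; the width is the
    longest contiguous run above half-maximum contrast that contains the
    profile's peak. Flat profiles return 0 with a warning.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 16:
        raise ValueError("need a 1-D profile of at least 16 samples")
    smooth = uniform_filter1d(p, size=5, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo <= 1e-9:
        log.warning("flat reflectivity profile: EZ width reported as 0")
        return 0.0
    above = smooth >= lo + (hi - lo) / 2.0
    peak = int(np.argmax(smooth))
    # contiguous run of half-max pixels containing the peak
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak
    while end < p.size - 1 and above[end + 1]:
        end += 1
    run = end - start + 1
    return run * (scan_mm * 1000.0 / p.size)


def change_over_time(visit1_value: float, visit2_value: float, dt_years: float) -> float:
    """(follow-up − baseline) / interval; negative = decline."""
    if not dt_years > 0:
        raise ValueError("follow-up interval must be positive")
    return (visit2_value - visit1_value) / dt_years
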