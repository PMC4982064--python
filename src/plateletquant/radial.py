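"""Radial CD63 distribution within platelets (surface-accumulation readout).

For each sufficiently circular platelet, concentric rings from the mask
centroid outward collect the *normalized integrated density* — the sum of
pixel values in a ring divided by the number of pixels in it.  The platelet
edge is the ring where the tubulin (marginal band) density peaks; radii are
normalized by that edge distance and densities by their per-platelet maximum,
so platelets of different sizes and brightnesses become comparable.  In HPS
platelets, CD63 mis-sorts to the plasma membrane, which shows up as the
normalized CD63 curve rising toward radius 1; the scalar
:func:`surface_accumulation_index` condenses that pattern to one number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .imops import ImagePlane, ParameterError
from .segmentation import InputError, PlateletRecord

logger = logging.getLogger("plateletquant")


class DegenerateProfileError(ValueError):
    """A radial profile is identically zero and cannot be normalized."""


@dataclass(frozen=True)
class DistributionConfig:
    """Radial-distribution parameters.

    A fixed ring count (default 20) keeps profiles commensurable across
    platelet sizes before normalization.  ``smoother`` applies to cohort
    aggregation only: 'loess' (statsmodels lowess, span = fraction of grid
    points), 'spline' (smoothing spline), or 'none'.
    """

    min_circularity_strict: float = 0.85
    n_rings: int = 20
    smoother: str = "loess"
    smoother_span: float = 0.3
    profile_reach: float = 1.3  # max profiling radius in units of equivalent radius

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_circularity_strict <= 1.0:
            raise ParameterError("min_circularity_strict must be in [0, 1]")
        if self.n_rings < 3:
            raise ParameterError("n_rings must be >= 3")
        if self.smoother not in ("spline", "loess", "none"):
            raise ParameterError("smoother must be 'spline', 'loess' or 'none'")


@dataclass(frozen=True)
class RadialProfile:
    """Normalized radial density profile of one platelet, one channel."""

    platelet_id: int
    channel: str  # 'cd63' or 'tubulin'
    n_rings: int
    raw_density: np.ndarray
    norm_radius: np.ndarray
    norm_density: np.ndarray
    edge_ring: int
    subject_id: str = ""
    image_id: str = ""


def select_circular(
    platelets: list[PlateletRecord], cfg: DistributionConfig = DistributionConfig()
) -> list[PlateletRecord]:
    """Platelets passing the stricter circularity cut (order preserved)."""
    return [p for p in platelets if p.metrics.circularity > cfg.min_circularity_strict]


def radial_profile(
    img: ImagePlane,
    center_px: tuple[float, float],
    max_radius_px: float,
    n_rings: int,
) -> np.ndarray:
    """Mean intensity in ``n_rings`` concentric rings out to ``max_radius_px``.

    Ring ``r`` collects pixels with ``floor(n_rings * dist / max_radius) == r``;
    pixels at or beyond ``max_radius_px`` are ignored.  Empty rings yield 0
    (logged as a warning).
    """
    r0, c0 = center_px
    if not (0 <= r0 < img.height_px and 0 <= c0 < img.width_px):
        raise InputError("profile center outside image")
    if not max_radius_px > 0:
        raise ParameterError("max_radius_px must be positive")
    rr, cc = np.ogrid[: img.height_px, : img.width_px]
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    idx = np.floor(n_rings * dist / max_radius_px).astype(np.int64)
    inside = idx < n_rings
    sums = np.bincount(idx[inside], weights=img.pixels[inside], minlength=n_rings)
    counts = np.bincount(idx[inside], minlength=n_rings)
    if (counts == 0).any():
        logger.warning("radial_profile: %d empty ring(s) set to 0",
                       int((counts == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return dens


def find_edge_ring(tubulin_profile: np.ndarray) -> int:
    """Index of the maximum-density tubulin ring; ties break outward."""
    prof = np.asarray(tubulin_profile, dtype=float)
    if prof.size == 0:
        raise InputError("empty profile")
    if not (prof > 0).any():
        raise DegenerateProfileError("all-zero tubulin profile")
    # outermost occurrence of the maximum
    return int(prof.size - 1 - np.argmax(prof[::-1]))


def normalize_profile(
    raw: np.ndarray, edge_ring: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize radii by the edge-ring distance and densities by their max.

    Ring centres sit at ``(i + 0.5)`` ring-widths, so
    ``norm_radius[i] = (i + 0.5) / (edge_ring + 0.5)`` puts the edge ring at
    exactly 1; rings beyond the edge keep ``norm_radius > 1``.
    """
    raw = np.asarray(raw, dtype=float)
    if not 0 <= edge_ring < raw.size:
        raise ParameterError("edge_ring out of range")
    mx = raw.max()
    if not mx > 0:
        raise DegenerateProfileError("all-zero profile cannot be normalized")
    i = np.arange(raw.size, dtype=float)
    norm_radius = (i + 0.5) / (edge_ring + 0.5)
    return norm_radius, raw / mx


def profile_platelet(
    platelet: PlateletRecord,
    tubulin: ImagePlane,
    cd63: ImagePlane,
    cfg: DistributionConfig = DistributionConfig(),
) -> dict[str, RadialProfile]:
    """Both channel profiles of one platelet, sharing the tubulin edge ring.

    The profiling center is the filled-mask centroid; the profiling reach is
    ``cfg.profile_reach`` times the equivalent radius so the marginal band and
    just-outside-surface signal are captured.
    """
    center = platelet.metrics.centroid_px
    max_r_px = (
        cfg.profile_reach
        * platelet.metrics.equivalent_radius_um
        * 1000.0
        / tubulin.pixel_size_nm
    )
    raw_tub = radial_profile(tubulin, center, max_r_px, cfg.n_rings)
    raw_cd = radial_profile(cd63, center, max_r_px, cfg.n_rings)
    edge = find_edge_ring(raw_tub)
    out: dict[str, RadialProfile] = {}
    for channel, raw in (("tubulin", raw_tub), ("cd63", raw_cd)):
        nr, nd = normalize_profile(raw, edge)
        out[channel] = RadialProfile(
            platelet_id=platelet.platelet_id,
            channel=channel,
            n_rings=cfg.n_rings,
            raw_density=raw,
            norm_radius=nr,
            norm_density=nd,
            edge_ring=edge,
            subject_id=platelet.subject_id,
            image_id=platelet.image_id,
        )
    return out


def _smooth(grid: np.ndarray, y: np.ndarray, cfg: DistributionConfig) -> np.ndarray:
    if cfg.smoother == "none" or cfg.smoother_span <= 0:
        return y
    if cfg.smoother == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(y, grid, frac=min(max(cfg.smoother_span, 2.0 / len(grid)), 1.0),
                    return_sorted=False)
        return np.asarray(sm, dtype=float)
    from scipy.interpolate import UnivariateSpline

    # smoothing factor scaled by span and residual scale of the curve
    s = cfg.smoother_span * float(np.var(y)) * len(grid)
    spl = UnivariateSpline(grid, y, s=s, k=3)
    return spl(grid)


def aggregate_group_profiles(
    profiles: list[RadialProfile],
    group_of: Mapping[str, str],
    cfg: DistributionConfig = DistributionConfig(),
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject and per-group mean normalized CD63 curves on a common grid.

    Each platelet's (norm_radius, norm_density) curve is linearly interpolated
    onto the grid; a subject curve is the smoothed mean over its platelets and
    a group curve is the mean of subject curves (subjects, not pooled
    platelets, are the statistical unit).  Subjects with zero profiles are
    excluded with a warning.

    Returns ``(subject_curves, group_curves)``; long-format DataFrames with
    columns (subject_id|group, norm_radius, norm_density).
    """
    if grid is None:
        grid = np.linspace(0.0, cfg.profile_reach, 53)
    by_subject: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        y = np.interp(grid, p.norm_radius, p.norm_density)
        by_subject.setdefault(p.subject_id, []).append(y)

    subject_rows = []
    group_curves: dict[str, list[np.ndarray]] = {}
    for sid in sorted(group_of):
        curves = by_subject.get(sid, [])
        if not curves:
            logger.warning("subject %s has no radial profiles; excluded", sid)
            continue
        mean_curve = _smooth(grid, np.mean(curves, axis=0), cfg)
        group_curves.setdefault(group_of[sid], []).append(mean_curve)
        subject_rows.append(
            pd.DataFrame({"subject_id": sid, "norm_radius": grid,
                          "norm_density": mean_curve})
        )

    group_rows = [
        pd.DataFrame({"group": g, "norm_radius": grid,
                      "norm_density": np.mean(cs, axis=0)})
        for g, cs in sorted(group_curves.items())
    ]
    subject_df = pd.concat(subject_rows, ignore_index=True) if subject_rows \
        else pd.DataFrame(columns=["subject_id", "norm_radius", "norm_density"])
    group_df = pd.concat(group_rows, ignore_index=True) if group_rows \
        else pd.DataFrame(columns=["group", "norm_radius", "norm_density"])
    return subject_df, group_df


def surface_accumulation_index(
    profile: RadialProfile, band: tuple[float, float] = (0.8, 1.0)
) -> float:
    """Ratio of mean normalized density in the surface band to the interior.

    1.0 for a flat profile, > 1 when CD63 piles up near the surface (the HPS
    phenotype), < 1 when signal is concentrated at the centre.  Returns +inf
    when the interior mean is zero but the band is not.
    """
    lo, hi = band
    if not lo < hi:
        raise InputError("empty surface band")
    nr = profile.norm_radius
    in_band = (nr >= lo) & (nr <= hi)
    interior = nr < lo
    if not in_band.any() or not interior.any():
        raise InputError("band selects no rings at this ring count")
    band_mean = float(profile.norm_density[in_band].mean())
    int_mean = float(profile.norm_density[interior].mean())
    if int_mean == 0.0:
        return float("inf") if band_mean > 0 else float("nan")
    return band_mean / int_mean
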