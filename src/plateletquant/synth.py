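"""Synthetic two-channel platelet fields with exhaustive ground truth.

The generator emulates the statistical structure of super-resolution (SIM)
platelet images that the analysis assumes: annular tubulin marginal bands at
platelet perimeters (diameters drawn uniformly from 2–5 um, ring widths sized
so band areas overlap the observed 2.3–3.1 um^2), punctate ~150-nm CD63
granules inside platelets with Poisson per-platelet counts, an optional
surface-biased placement mode that mimics the HPS mis-sorting phenotype,
uneven background illumination, additive Gaussian noise, sub-threshold debris
blobs and deliberately touching platelet pairs.  Ground truth (masks,
centroids, per-platelet granule counts and surface flags) is recorded from the
geometry *before* any blurring or noise, so it is unaffected by the imaging
model.  All randomness flows from the config seed: the same seed reproduces
bit-identical images and truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imops import BinaryMask, ImagePlane, ParameterError
from .stats import SubjectCounts


class PlacementError(RuntimeError):
    """The requested number of platelets cannot be placed without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic image model.

    Geometry defaults mirror the biology: platelet diameters 2–5 um, marginal
    band width 250 nm (band areas then span ~1.4–3.7 um^2, overlapping the
    measured 2.3–3.1 um^2), granule diameter 150 nm, pixel size 40 nm and a
    60-nm PSF sigma (SIM-scale ~120-nm resolution, so granules stay
    resolvable).  ``granule_lambda`` defaults to the control-cohort mean of
    6.8 CD63 objects per platelet; ``surface_fraction`` is 0 for control-like
    fields and ~0.6 for an HPS-like surface bias.  Granule centres keep a
    minimum separation of twice the granule diameter so counts are
    recoverable by construction.
    """

    field_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 40.0
    n_platelets: int = 6
    platelet_diameter_um: tuple[float, float] = (2.0, 5.0)
    ring_width_nm: float = 250.0
    granule_lambda: float = 6.8
    granule_diameter_nm: float = 150.0
    granule_min_sep_nm: float = 300.0
    surface_fraction: float = 0.0
    psf_sigma_nm: float = 60.0
    background: tuple[str, float] = ("quadratic", 10.0)
    noise_sd: float = 5.0
    tubulin_amp: float = 120.0
    cd63_amp: float = 150.0
    n_debris: int = 2
    touching_pairs: int = 0
    overdispersion: float | None = None  # negative-binomial k; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.ring_width_nm <= 0 \
                or self.granule_diameter_nm <= 0 or self.psf_sigma_nm < 0:
            raise ParameterError("geometric parameters must be positive")
        if not 0.0 <= self.surface_fraction <= 1.0:
            raise ParameterError("surface_fraction must be in [0, 1]")
        lo, hi = self.platelet_diameter_um
        if not 0 < lo <= hi:
            raise ParameterError("invalid platelet diameter range")
        if self.background[0] not in ("none", "ramp", "quadratic"):
            raise ParameterError("background type must be none/ramp/quadratic")


@dataclass
class GroundTruth:
    """Everything the generator knows about a field, pre-blur/noise."""

    platelet_masks: list[BinaryMask]
    platelet_centroids: list[tuple[float, float]]
    platelet_radii_px: list[float]
    ring_radii_um: list[float]
    ring_areas_um2: list[float]
    granule_centers_px: list[tuple[float, float]]
    granule_owner: list[int]  # platelet index per granule
    per_platelet_count: np.ndarray
    surface_flags: list[bool]
    debris_centers_px: list[tuple[float, float]]

    def to_jsonable(self) -> dict:
        """JSON-serializable geometry summary (masks omitted; reconstructible
        from centroids and radii)."""
        return {
            "platelet_centroids": [list(c) for c in self.platelet_centroids],
            "platelet_radii_px": list(map(float, self.platelet_radii_px)),
            "ring_radii_um": list(map(float, self.ring_radii_um)),
            "ring_areas_um2": list(map(float, self.ring_areas_um2)),
            "granule_centers_px": [list(c) for c in self.granule_centers_px],
            "granule_owner": list(map(int, self.granule_owner)),
            "per_platelet_count": [int(c) for c in self.per_platelet_count],
            "surface_flags": list(map(bool, self.surface_flags)),
            "debris_centers_px": [list(c) for c in self.debris_centers_px],
        }


def _disc_mask(shape: tuple[int, int], center: tuple[float, float],
               radius_px: float) -> BinaryMask:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _place_discs(rng: np.random.Generator, cfg: SynthConfig,
                 ) -> tuple[list[tuple[float, float]], list[float]]:
    """Centers and radii (px) for singles plus touching pairs; singles do not
    overlap anything, pair members overlap each other by design."""
    h, w = cfg.field_px
    lo_um, hi_um = cfg.platelet_diameter_um
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def radius_px() -> float:
        return rng.uniform(lo_um, hi_um) / 2.0 * 1000.0 / cfg.pixel_size_nm

    def fits(c: tuple[float, float], r: float, gap: float = 6.0) -> bool:
        if not (r + gap < c[0] < h - r - gap and r + gap < c[1] < w - r - gap):
            return False
        return all(np.hypot(c[0] - c2[0], c[1] - c2[1]) > r + r2 + gap
                   for c2, r2 in zip(centers, radii))

    n_single = cfg.n_platelets - 2 * cfg.touching_pairs
    if n_single < 0:
        raise ParameterError("touching_pairs exceeds n_platelets / 2")
    for _ in range(n_single):
        for _try in range(2000):
            r = radius_px()
            if 2 * r >= min(h, w):  # cannot fit at any position
                continue
            c = (rng.uniform(r, h - r), rng.uniform(r, w - r))
            if fits(c, r):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PlacementError("could not place platelet without overlap")
    for _ in range(cfg.touching_pairs):
        for _try in range(2000):
            r1, r2 = radius_px(), radius_px()
            if 2 * r1 >= min(h, w) or 2 * r2 >= min(h, w):
                continue
            c1 = (rng.uniform(r1, h - r1), rng.uniform(r1, w - r1))
            theta = rng.uniform(0, 2 * np.pi)
            d = 0.75 * (r1 + r2)  # overlap by less than one radius
            c2 = (c1[0] + d * np.sin(theta), c1[1] + d * np.cos(theta))
            if fits(c1, r1) and all(
                np.hypot(c2[0] - cc[0], c2[1] - cc[1]) > r2 + rr + 6.0
                for cc, rr in zip(centers, radii)
            ) and r2 + 6.0 < c2[0] < h - r2 - 6.0 and r2 + 6.0 < c2[1] < w - r2 - 6.0:
                centers.extend([c1, c2])
                radii.extend([r1, r2])
                break
        else:
            raise PlacementError("could not place touching pair")
    return centers, radii


def _draw_count(rng: np.random.Generator, cfg: SynthConfig) -> int:
    if cfg.granule_lambda <= 0:
        return 0
    if cfg.overdispersion is None:
        return int(rng.poisson(cfg.granule_lambda))
    k = cfg.overdispersion
    p = k / (k + cfg.granule_lambda)
    return int(rng.negative_binomial(k, p))


def _place_granules(
    rng: np.random.Generator, cfg: SynthConfig, center: tuple[float, float],
    radius_px: float, count: int,
) -> tuple[list[tuple[float, float]], list[bool]]:
    """Granule centres inside one platelet: interior-uniform or rim-banded."""
    min_sep = cfg.granule_min_sep_nm / cfg.pixel_size_nm
    pts: list[tuple[float, float]] = []
    flags: list[bool] = []
    for _ in range(count):
        for _try in range(500):
            on_surface = rng.random() < cfg.surface_fraction
            if on_surface:
                # area-uniform radius in the rim band 0.9–1.05 R
                u = rng.random()
                rfrac = np.sqrt(0.9**2 + u * (1.05**2 - 0.9**2))
            else:
                # area-uniform in the interior disc (<= 0.85 R, clear of the rim)
                rfrac = 0.85 * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            p = (center[0] + rfrac * radius_px * np.sin(theta),
                 center[1] + rfrac * radius_px * np.cos(theta))
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
                pts.append(p)
                flags.append(on_surface)
                break
        else:
            # dense platelet: accept the last candidate rather than drop count
            pts.append(p)
            flags.append(on_surface)
    return pts, flags


def _paint_disc(img: np.ndarray, center: tuple[float, float], radius_px: float,
                amp: float) -> None:
    r0 = max(int(center[0] - radius_px) - 1, 0)
    r1 = min(int(center[0] + radius_px) + 2, img.shape[0])
    c0 = max(int(center[1] - radius_px) - 1, 0)
    c1 = min(int(center[1] + radius_px) + 2, img.shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    sel = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
    img[r0:r1, c0:c1][sel] += amp


def _background(cfg: SynthConfig) -> np.ndarray:
    h, w = cfg.field_px
    kind, amp = cfg.background
    if kind == "none" or amp == 0:
        return np.zeros((h, w))
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    if kind == "ramp":
        return amp * cc / max(w - 1, 1)
    # quadratic bowl centred on the field
    q = ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) / ((h / 2) ** 2 + (w / 2) ** 2)
    return amp * q


def generate_field(cfg: SynthConfig) -> tuple[ImagePlane, ImagePlane, GroundTruth]:
    """Render one two-channel field and its ground truth.

    Returns ``(tubulin, cd63, truth)``; truth reflects the pre-blur geometry.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_px
    centers, radii = _place_discs(rng, cfg)

    ring_w_px = cfg.ring_width_nm / cfg.pixel_size_nm
    gran_r_px = cfg.granule_diameter_nm / 2.0 / cfg.pixel_size_nm

    tub = np.zeros((h, w))
    cd = np.zeros((h, w))
    masks: list[BinaryMask] = []
    ring_radii_um: list[float] = []
    ring_areas: list[float] = []
    granule_centers: list[tuple[float, float]] = []
    owners: list[int] = []
    flags: list[bool] = []
    counts = np.zeros(len(centers), dtype=int)

    for i, (c, r) in enumerate(zip(centers, radii)):
        outer = _disc_mask((h, w), c, r)
        inner = _disc_mask((h, w), c, r - ring_w_px)
        ring = outer & ~inner
        tub[ring] += cfg.tubulin_amp
        masks.append(outer)
        um = cfg.pixel_size_nm / 1000.0
        ring_radii_um.append(r * um)
        ring_areas.append(float(ring.sum()) * um * um)

        n = _draw_count(rng, cfg)
        counts[i] = n
        pts, fl = _place_granules(rng, cfg, c, r, n)
        for p in pts:
            _paint_disc(cd, p, gran_r_px, cfg.cd63_amp)
        granule_centers.extend(pts)
        owners.extend([i] * len(pts))
        flags.extend(fl)

    debris_centers: list[tuple[float, float]] = []
    for _ in range(cfg.n_debris):
        for _try in range(500):
            r = rng.uniform(3.0, 8.0)  # px: area well below the 2 um^2 filter
            c = (rng.uniform(r, h - r), rng.uniform(r, w - r))
            if all(np.hypot(c[0] - cc[0], c[1] - cc[1]) > r + rr + 8.0
                   for cc, rr in zip(centers, radii)):
                _paint_disc(tub, c, r, 0.7 * cfg.tubulin_amp)
                debris_centers.append(c)
                break

    truth = GroundTruth(
        platelet_masks=masks,
        platelet_centroids=centers,
        platelet_radii_px=radii,
        ring_radii_um=ring_radii_um,
        ring_areas_um2=ring_areas,
        granule_centers_px=granule_centers,
        granule_owner=owners,
        per_platelet_count=counts,
        surface_flags=flags,
        debris_centers_px=debris_centers,
    )

    sigma = cfg.psf_sigma_nm / cfg.pixel_size_nm
    bg = _background(cfg)
    out = []
    for raw in (tub, cd):
        img = ndi.gaussian_filter(raw, sigma=sigma, mode="nearest") if sigma > 0 else raw
        img = img + bg + rng.normal(0.0, cfg.noise_sd, size=(h, w))
        out.append(np.clip(img, 0.0, None))
    tubulin = ImagePlane(pixels=out[0], pixel_size_nm=cfg.pixel_size_nm)
    cd63 = ImagePlane(pixels=out[1], pixel_size_nm=cfg.pixel_size_nm)
    return tubulin, cd63, truth


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from a master seed."""
    return int(np.random.SeedSequence(entropy=master_seed,
                                      spawn_key=(index,)).generate_state(1)[0]
               % (2**31))


def generate_cohort(
    control_cfg: SynthConfig,
    patient_cfg: SynthConfig,
    n_controls: int,
    n_patients: int,
    seed: int,
    outdir: str | Path,
    images_per_subject: int = 1,
    batch_id: str = "batch01",
) -> pd.DataFrame:
    """Write a synthetic cohort (TIFFs + truth JSON + manifest CSV) to disk.

    Mirrors the study design (7 controls / 3 patients by default usage); each
    subject gets a deterministic child seed so the whole cohort is a pure
    function of ``seed``.  Returns the manifest DataFrame with columns
    (subject_id, group, image_path, batch_id).
    """
    from .io import write_image  # local import: io depends on synth types only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    subjects = [("control", i) for i in range(n_controls)] + \
               [("patient", i) for i in range(n_patients)]
    for k, (grp, i) in enumerate(subjects):
        sid = f"{grp}{i + 1:02d}"
        base = control_cfg if grp == "control" else patient_cfg
        for j in range(images_per_subject):
            s = subject_seed(seed, k * 1000 + j)
            cfg = replace(base, seed=s)
            tubulin, cd63, truth = generate_field(cfg)
            img_path = outdir / f"{sid}_img{j + 1}.tif"
            write_image(img_path, cd63=cd63, tubulin=tubulin)
            with open(outdir / f"{sid}_img{j + 1}_truth.json", "w") as fh:
                json.dump(truth.to_jsonable(), fh)
            rows.append({"subject_id": sid, "group": grp,
                         "image_path": str(img_path), "batch_id": batch_id})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def sample_cohort_counts(
    n_controls: int = 7,
    n_patients: int = 3,
    control_lambda: float = 6.8,
    patient_lambda: float = 2.4,
    n_platelets: int = 281,
    seed: int = 0,
) -> list[SubjectCounts]:
    """Draw per-platelet granule counts for a cohort without rendering images.

    Defaults reproduce the study conditions: 7 controls at a mean of 6.8 CD63
    objects per platelet, 3 HPS patients at 2.4, ~281 platelets per subject,
    Poisson counts.
    """
    rng = np.random.default_rng(seed)
    out: list[SubjectCounts] = []
    for i in range(n_controls):
        out.append(SubjectCounts(f"control{i + 1:02d}", "control",
                                 rng.poisson(control_lambda, n_platelets)))
    for i in range(n_patients):
        out.append(SubjectCounts(f"patient{i + 1:02d}", "patient",
                                 rng.poisson(patient_lambda, n_platelets)))
    return out
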