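"""File I/O: calibrated multi-page TIFFs, manifests and run configuration.

Channel convention (overridable): page/channel 0 = CD63 (488 nm excitation),
channel 1 = tubulin (561 nm).  Pixel size comes from the TIFF resolution tags
(written in pixels-per-centimetre) or an explicit override; an uncalibrated
image without an override is an error, never a silent default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .granules import GranuleSegConfig
from .imops import ImagePlane
from .radial import DistributionConfig
from .segmentation import PlateletSegConfig


class ImageReadError(IOError):
    """File unreadable or not a TIFF."""


class ChannelLayoutError(ValueError):
    """Page count incompatible with the declared channel layout."""


class CalibrationError(ValueError):
    """No pixel size in metadata and no override supplied."""


DEFAULT_CHANNEL_MAP = {"cd63": 0, "tubulin": 1}


def write_image(path: str | Path, cd63: ImagePlane, tubulin: ImagePlane) -> None:
    """Write a 2-channel (optionally z-stacked later) calibrated TIFF."""
    px_cm = 1e7 / cd63.pixel_size_nm  # pixels per centimetre
    data = np.stack([cd63.pixels, tubulin.pixels]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
    )


def _pixel_size_from_tags(page: tifffile.TiffPage) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = Fraction(int(num), int(den))
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        nm_per_unit = 1e7
    elif unit == 2:  # inch
        nm_per_unit = 2.54e7
    else:
        return None
    return float(nm_per_unit / px_per_unit)


def read_image(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size_nm: float | None = None,
) -> tuple[list[ImagePlane], list[ImagePlane]]:
    """Read a multi-page TIFF into (tubulin stack, cd63 stack).

    Pages are interpreted as channel-major: for a file with 2 channels and Z
    planes, page ``z * n_channels + channel`` (tifffile's natural order for a
    (Z, C, Y, X) or (C, Y, X) array).  Raises :class:`CalibrationError` when
    the file carries no resolution tags and no ``pixel_size_nm`` override is
    given.
    """
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            tag_px = _pixel_size_from_tags(tf.pages[0])
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise ImageReadError(f"cannot read TIFF {path}: {exc}") from exc

    px = pixel_size_nm if pixel_size_nm is not None else tag_px
    if px is None:
        raise CalibrationError(f"{path}: no resolution tags and no pixel-size "
                               "override")

    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:  # (Z, C, Y, X)
        planes = data.reshape(-1, *data.shape[-2:])
        n_ch = data.shape[1]
    elif data.ndim == 3:
        planes = data
        n_ch = len(channel_map)
    else:
        raise ChannelLayoutError(f"{path}: unsupported TIFF dimensionality "
                                 f"{data.ndim}")
    if len(planes) % n_ch != 0:
        raise ChannelLayoutError(f"{path}: {len(planes)} pages not divisible by "
                                 f"{n_ch} channels")
    needed = max(channel_map.values()) + 1
    if n_ch < needed:
        raise ChannelLayoutError(f"{path}: channel map needs {needed} channels, "
                                 f"file has {n_ch}")

    def stack(ch: int) -> list[ImagePlane]:
        return [ImagePlane(pixels=planes[z * n_ch + ch].astype(np.float64),
                           pixel_size_nm=float(px))
                for z in range(len(planes) // n_ch)]

    return stack(channel_map["tubulin"]), stack(channel_map["cd63"])


# ---------------------------------------------------------------------------
# manifest and run configuration
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "group", "image_path", "batch_id"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Subject manifest CSV: subject_id, group, image_path, batch_id."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = set(df["group"]) - {"control", "patient"}
    if bad:
        raise ValueError(f"manifest has unknown group labels: {sorted(bad)}")
    return df[MANIFEST_COLUMNS]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; round-trips through YAML."""

    platelet: PlateletSegConfig = field(default_factory=PlateletSegConfig)
    granule: GranuleSegConfig = field(default_factory=GranuleSegConfig)
    distribution: DistributionConfig = field(default_factory=DistributionConfig)
    stats_alpha: float = 0.01
    readout_k: int = 4
    pixel_size_nm_override: float | None = None
    output_dir: str = "plateletquant_out"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "platelet": asdict(self.platelet),
            "granule": asdict(self.granule),
            "distribution": asdict(self.distribution),
            "stats_alpha": self.stats_alpha,
            "readout_k": self.readout_k,
            "pixel_size_nm_override": self.pixel_size_nm_override,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            platelet=PlateletSegConfig(**doc.get("platelet", {})),
            granule=GranuleSegConfig(**doc.get("granule", {})),
            distribution=DistributionConfig(**doc.get("distribution", {})),
            stats_alpha=doc.get("stats_alpha", 0.01),
            readout_k=doc.get("readout_k", 4),
            pixel_size_nm_override=doc.get("pixel_size_nm_override"),
            output_dir=doc.get("output_dir", "plateletquant_out"),
            log_level=doc.get("log_level", "INFO"),
        )
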