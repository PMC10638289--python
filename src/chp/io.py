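"""File I/O and run configuration.

Images come in as PNG or TIFF pairs: an 8-bit photomicrograph plus a
mask image of identical dimensions whose nonzero pixels mark the nucleus
(masks stand in for manual nucleus extraction).  RGB input is converted
to 8-bit brightness, by default with the Rec.601 luma weights; 16-bit
input is rescaled to 8-bit with a warning.  Features travel as CSV with
a fixed schema; a missing HV is an empty field, never "NaN" text.

Coordinate convention throughout the package: row-major, origin at the
top-left, 0-based indices; bounding boxes are inclusive pixel extents.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .features import LABELS, FeatureRecord

logger = logging.getLogger("chp")

FEATURE_COLUMNS = ["nucleus_id", "label", "b1max", "hv", "bi", "ns", "ns2", "density", "predicted"]

RGB_MODES = ("luma601", "mean", "channel:r", "channel:g", "channel:b")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline constants; file values are overridden by CLI flags."""

    hole_threshold: int = 5
    bi_target: int = 127
    b1max_cutoff: float = 25.0
    density_cutoff: float = 0.05
    hv_cutoff: float | None = None
    rgb_to_gray: str = "luma601"
    um_per_pixel: float | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if self.rgb_to_gray not in RGB_MODES:
            raise ValueError(f"rgb_to_gray must be one of {RGB_MODES}")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat TOML file of RunConfig keys; unknown keys are errors."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _to_gray8(arr: np.ndarray, mode: str) -> np.ndarray:
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(float)
        if mode == "luma601":
            g = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
            arr = np.floor(g + 0.5)  # round half up
        elif mode == "mean":
            arr = np.floor(rgb.mean(axis=-1) + 0.5)
        else:  # channel:r|g|b
            arr = rgb[..., "rgb".index(mode[-1])]
    if arr.dtype == np.uint16 or (arr.size and arr.max() > 255):
        logger.warning("16-bit input rescaled to 8-bit")
        arr = np.floor(arr.astype(float) * (255.0 / 65535.0) + 0.5)
    return arr.astype(np.uint8)


def read_nucleus(image_path, mask_path, config: RunConfig | None = None):
    """Load an image + mask pair into a NucleusImage."""
    from .profile import NucleusImage

    config = config or RunConfig()
    inten = _to_gray8(iio.imread(image_path), config.rgb_to_gray)
    mask_arr = iio.imread(mask_path)
    if mask_arr.ndim == 3:
        mask_arr = mask_arr[..., :3].max(axis=-1)
    if inten.shape != mask_arr.shape:
        raise ValueError(
            f"dimension mismatch: image {inten.shape} vs mask {mask_arr.shape}"
        )
    mask = mask_arr != 0
    if not mask.any():
        raise ValueError(f"mask {mask_path} has no inside pixel")
    return NucleusImage(inten, mask)


def write_nucleus(nucleus, image_path, mask_path) -> None:
    """Write the intensity image and the 0/255 mask as 8-bit images."""
    iio.imwrite(image_path, nucleus.intensity)
    iio.imwrite(mask_path, np.where(nucleus.mask, 255, 0).astype(np.uint8))


def write_features(records, path, predicted: dict[str, str] | None = None) -> None:
    """Write feature records to CSV under the fixed schema."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    predicted = predicted or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FEATURE_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.nucleus_id,
                    r.label if r.label is not None else "",
                    r.b1max,
                    r.hv if r.hv is not None else "",
                    r.bi,
                    repr(r.ns),
                    repr(r.ns2),
                    repr(r.density),
                    predicted.get(r.nucleus_id, ""),
                ]
            )


def read_features(path) -> tuple[list[FeatureRecord], dict[str, str]]:
    """Read a feature CSV back; returns (records, predicted-label map)."""
    records: list[FeatureRecord] = []
    predicted: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != FEATURE_COLUMNS:
            raise ValueError(f"unexpected feature CSV header: {reader.fieldnames}")
        for row in reader:
            label = row["label"] or None
            if label is not None and label not in LABELS:
                raise ValueError(f"unknown label {label!r} in {path}")
            records.append(
                FeatureRecord(
                    nucleus_id=row["nucleus_id"],
                    b1max=int(row["b1max"]),
                    hv=int(row["hv"]) if row["hv"] != "" else None,
                    bi=int(row["bi"]),
                    ns=float(row["ns"]),
                    ns2=float(row["ns2"]),
                    density=float(row["density"]),
                    label=label,
                )
            )
            if row["predicted"]:
                predicted[row["nucleus_id"]] = row["predicted"]
    return records, predicted


def read_labels(path) -> dict[str, str]:
    """Read a nucleus_id,label CSV into a map; labels are validated."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"]
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r} in {path}")
            out[row["nucleus_id"]] = label
    return out


def write_profile_curve(profile, path) -> None:
    """Dump a 256-row t,b1 CSV of one homology profile."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "b1"])
        for t, b1 in enumerate(profile.b1_curve):
            w.writerow([t, b1])
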