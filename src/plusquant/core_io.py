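"""Domain types, raster/label I/O, optic-disc geometry and run configuration.

Conventions used throughout the package:

* images are 2-D arrays indexed ``(row, col)``, 0-based;
* distances are Euclidean, in pixel units;
* vessel masks are boolean; any nonzero intensity on disk counts as vessel
  (masks are authored binary but 1-vs-255 encodings both occur in the wild).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("plusquant")

PLUS = "Plus"
NONPLUS = "nonPlus"
VALID_LABELS = frozenset({PLUS, NONPLUS})


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Every tunable of the pipeline, keyed by dotted name.  Values here are the
#: package defaults; a YAML config file may override any subset but unknown
#: keys are rejected.
DEFAULT_CONFIG: dict[str, object] = {
    "spline.spacing_px": 15.0,
    "spline.smoothing": 0.0,
    "spline.refine_subpixel": True,
    "curvature.n_samples": 200,
    "curvature.savgol_window_px": 50.0,
    "curvature.savgol_order": 5,
    "skeleton.min_branch_len": 10,
    "skeleton.min_segment_len": 30,
    "caliber.fraction": 1.0 / 3.0,
    "caliber.halfwidth_convention": False,
    "density.dilation_radius_px": 25,
    "zone.membership_threshold": 0.5,
    "svm.C": 1.0,
    "svm.gamma": "scale",
    "cv.folds": 10,
    "cv.repeats": 10,
    "cv.legacy_leaky": False,
    "nca.k": 5,
    "nca.regularization": 1.0,
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Immutable bag of pipeline tunables, echoed into every output artifact."""

    values: Mapping[str, object] = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    def with_overrides(self, **dotted: object) -> "RunConfig":
        unknown = set(dotted) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(self.values)
        merged.update(dotted)
        return replace(self, values=merged)

    def to_dict(self) -> dict[str, object]:
        return dict(self.values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a YAML file of either dotted or nested keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = _flatten(raw)
        unknown = set(flat) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys in {path}: {sorted(unknown)}")
        merged = dict(DEFAULT_CONFIG)
        merged.update(flat)
        return cls(values=merged)


def _flatten(tree: Mapping, prefix: str = "") -> dict[str, object]:
    flat: dict[str, object] = {}
    for key, value in tree.items():
        name = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean raster: vessel mask, skeleton, or zone membership."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"mask must be a nonempty 2-D grid, got shape {grid.shape}")
        object.__setattr__(self, "grid", grid.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())

    def pixel_coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) coordinates of true pixels."""
        return np.argwhere(self.grid)


@dataclass(frozen=True)
class OpticDiscSpec:
    """Optic-disc location and size in pixel units."""

    center: tuple[float, float]  # (row, col)
    disc_diameter: float

    def __post_init__(self) -> None:
        if not self.disc_diameter > 0:
            raise ValueError(f"disc_diameter must be > 0, got {self.disc_diameter}")

    def validate_for(self, shape: tuple[int, int]) -> None:
        r, c = self.center
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"disc center {self.center} outside image bounds {shape}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "center_row": int(round(self.center[0])),
                    "center_col": int(round(self.center[1])),
                    "disc_diameter_px": float(self.disc_diameter),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "OpticDiscSpec":
        data = json.loads(Path(path).read_text())
        return cls(
            center=(float(data["center_row"]), float(data["center_col"])),
            disc_diameter=float(data["disc_diameter_px"]),
        )


@dataclass(frozen=True)
class ZoneSpec:
    """A named region of the image (entire image or the 5DD annulus)."""

    membership: BinaryMask
    label: str  # "entire_image" | "fiveDD"


@dataclass(frozen=True)
class RaterLabelTable:
    """Per-image binary Plus/non-Plus labels keyed by (image, rater, session)."""

    records: pd.DataFrame  # columns: image_id, rater_id, session_id, label

    def __post_init__(self) -> None:
        df = self.records
        required = ["image_id", "rater_id", "session_id", "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"label table missing columns {missing}")
        bad = df.loc[~df["label"].isin(VALID_LABELS)]
        if len(bad):
            raise ValueError(
                "unrecognized labels (must be Plus/nonPlus) in rows: "
                f"{bad.index.tolist()} -> {sorted(bad['label'].unique())}"
            )
        keys = df[["image_id", "rater_id", "session_id"]]
        dup = keys.duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate (image_id, rater_id, session_id) rows: {df.index[dup].tolist()}"
            )

    def raters(self, session_id: object) -> list:
        sub = self.records[self.records["session_id"] == session_id]
        return sorted(sub["rater_id"].unique().tolist())

    def sessions(self) -> list:
        return sorted(self.records["session_id"].unique().tolist())

    def label_vector(self, rater_id: object, session_id: object) -> pd.Series:
        """Labels of one rater in one session, indexed by image_id."""
        sub = self.records[
            (self.records["rater_id"] == rater_id)
            & (self.records["session_id"] == session_id)
        ]
        return sub.set_index("image_id")["label"].sort_index()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-channel PNG/TIFF raster as a boolean vessel mask.

    Any nonzero intensity maps to vessel.  Multi-channel images are accepted
    only if all channels agree (an unambiguous binarization); otherwise an
    error naming the file is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        binarized = arr != 0
        if not (binarized == binarized[..., :1]).all():
            raise ValueError(f"multi-channel image without unambiguous binarization: {path}")
        arr = arr[..., 0]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return BinaryMask(arr != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel image (vessel = 255)."""
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_labels(path: str | Path) -> RaterLabelTable:
    """Read a rater-label CSV with columns image_id, rater_id, session_id, label."""
    df = pd.read_csv(path, dtype={"label": str})
    return RaterLabelTable(records=df)


def write_labels(table: RaterLabelTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Optic-disc geometry
# ---------------------------------------------------------------------------


def make_5dd_zone(disc: OpticDiscSpec, shape: tuple[int, int]) -> ZoneSpec:
    """Annulus from the optic-disc border to 5 disc diameters beyond it.

    A pixel at Euclidean distance ``d`` from the disc center is a member iff
    ``r_disc < d <= r_disc + 5 * disc_diameter`` with ``r_disc`` the disc
    radius; the disc interior is excluded.  The annulus is clipped to the
    image bounds; an entirely-outside zone yields an empty membership with a
    warning.
    """
    disc.validate_for(shape)
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(rows - disc.center[0], cols - disc.center[1])
    r_disc = disc.disc_diameter / 2.0
    membership = (d > r_disc) & (d <= r_disc + 5.0 * disc.disc_diameter)
    if not membership.any():
        logger.warning("5DD zone for disc at %s lies entirely outside the image", disc.center)
    return ZoneSpec(membership=BinaryMask(membership), label="fiveDD")


def entire_image_zone(shape: tuple[int, int]) -> ZoneSpec:
    return ZoneSpec(membership=BinaryMask(np.ones(shape, dtype=bool)), label="entire_image")


# ---------------------------------------------------------------------------
# Reference standard
# ---------------------------------------------------------------------------


def reference_standard(table: RaterLabelTable, session_id: object) -> pd.Series:
    """Per-image majority label over an odd number of raters in one session.

    No tie-breaking rule exists for an even rater count, so that case is an
    error, as is any image not labeled by every rater of the session.
    """
    raters = table.raters(session_id)
    if len(raters) == 0:
        raise ValueError(f"no labels for session {session_id!r}")
    if len(raters) % 2 == 0:
        raise ValueError(
            f"majority vote requires an odd rater count, got {len(raters)} in session {session_id!r}"
        )
    vectors = {r: table.label_vector(r, session_id) for r in raters}
    image_ids = sorted(set().union(*[set(v.index) for v in vectors.values()]))
    for r, v in vectors.items():
        missing = set(image_ids) - set(v.index)
        if missing:
            raise ValueError(f"rater {r!r} missing labels for images {sorted(missing)}")
    votes = pd.DataFrame({r: v.reindex(image_ids) for r, v in vectors.items()})
    n_plus = (votes == PLUS).sum(axis=1)
    majority = pd.Series(
        np.where(n_plus * 2 > len(raters), PLUS, NONPLUS), index=votes.index, name="label"
    )
    return majority
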