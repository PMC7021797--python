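"""Shared data model, file I/O and pipeline configuration.

All internal coordinates are nanometres, times are seconds, densities are
localizations/µm² (converted only at summaries).  Frames and stacks are
0-based everywhere; the ThunderSTORM CSV dialect adds the 1-based ``id``
and ``frame`` columns that tool expects.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("llstorm")

#: Allowed frame-of-reference tags, in pipeline order.  A table only ever
#: moves forward through these (acquisition → scan_corrected → biological);
#: the explicit inverse transform is the single documented exception.
FRAME_KINDS = ("acquisition", "scan_corrected", "biological")

#: Mandatory columns of a localization table.
CORE_COLUMNS = (
    "x", "y", "z", "frame", "stack", "frame_in_stack",
    "photons", "background", "sigma_x", "sigma_y",
)
#: Optional columns carried through when present.
OPTIONAL_COLUMNS = ("s", "uncertainty_xy", "uncertainty_z", "z_valid")


# ---------------------------------------------------------------------------
# Localization table
# ---------------------------------------------------------------------------

@dataclass
class LocalizationTable:
    """One row per blink localization.

    ``data`` holds the columns of :data:`CORE_COLUMNS` (plus any of
    :data:`OPTIONAL_COLUMNS`); ``frame_kind`` tags the frame of reference of
    (x, y, z).  In the acquisition frame x/y are camera coordinates and z is
    the astigmatic depth relative to the light-sheet/focal centre; in the
    biological frame (x', y', z') z' is height above the coverslip.
    """

    data: pd.DataFrame
    frame_kind: str = "acquisition"

    def __post_init__(self) -> None:
        if self.frame_kind not in FRAME_KINDS:
            raise ValueError(f"unknown frame_kind {self.frame_kind!r}")
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.data.copy(), self.frame_kind)

    def advanced(self, data: pd.DataFrame, new_kind: str) -> "LocalizationTable":
        """Return a new table in ``new_kind``, enforcing forward transitions."""
        if FRAME_KINDS.index(new_kind) <= FRAME_KINDS.index(self.frame_kind):
            raise ValueError(
                f"frame_kind may only advance: {self.frame_kind!r} → {new_kind!r}"
            )
        return LocalizationTable(data, new_kind)

    def validate(self, frames_per_stack: int | None = None) -> None:
        """Check the table invariants, raising ``ValueError`` on violation."""
        d = self.data
        if len(d) == 0:
            return
        if (d["photons"] < 0).any():
            raise ValueError("photons must be >= 0")
        if (d["sigma_x"] <= 0).any() or (d["sigma_y"] <= 0).any():
            raise ValueError("sigma_x and sigma_y must be > 0")
        if frames_per_stack is not None:
            if (d["frame_in_stack"] < 0).any() or (
                d["frame_in_stack"] >= frames_per_stack
            ).any():
                raise ValueError("frame_in_stack out of [0, frames_per_stack)")
            if (
                d["frame"] != d["stack"] * frames_per_stack + d["frame_in_stack"]
            ).any():
                raise ValueError(
                    "frame != stack * frames_per_stack + frame_in_stack"
                )


def localization_table(
    x, y, z, frame, *,
    stack=None, frame_in_stack=None, photons=None, background=None,
    sigma_x=None, sigma_y=None, frame_kind: str = "acquisition",
    frames_per_stack: int | None = None, **extra,
) -> LocalizationTable:
    """Convenience constructor from column arrays.

    When ``frames_per_stack`` is given, ``stack`` and ``frame_in_stack`` are
    derived from the global frame index; otherwise they default to a single
    stack.  Unspecified photometric columns get neutral defaults.
    """
    x = np.asarray(x, float)
    n = len(x)
    frame = np.asarray(frame, int)
    if frames_per_stack is not None:
        stack = frame // frames_per_stack
        frame_in_stack = frame % frames_per_stack
    if stack is None:
        stack = np.zeros(n, int)
        frame_in_stack = frame
    cols = {
        "x": x,
        "y": np.asarray(y, float),
        "z": np.asarray(z, float),
        "frame": frame,
        "stack": np.asarray(stack, int),
        "frame_in_stack": np.asarray(frame_in_stack, int),
        "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons, float),
        "background": np.zeros(n) if background is None else np.asarray(background, float),
        "sigma_x": np.full(n, 150.0) if sigma_x is None else np.asarray(sigma_x, float),
        "sigma_y": np.full(n, 150.0) if sigma_y is None else np.asarray(sigma_y, float),
    }
    for k, v in extra.items():
        cols[k] = np.asarray(v)
    return LocalizationTable(pd.DataFrame(cols), frame_kind)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF movie as (frames × rows × cols, metadata).

    Metadata surfaces the pixel size (nm) when resolution tags are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF stack: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) == 0:
                raise ValueError("zero pages")
            arr = tf.asarray()
            meta: dict = {"n_pages": len(tf.pages)}
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    # resolution stored as pixels per unit; RESUNIT 3 = cm
                    unit = page.tags.get("ResolutionUnit")
                    scale = 1e7 if (unit is not None and unit.value == 3) else 2.54e7
                    meta["pixel_size_nm"] = scale * den / num
    except tifffile.TiffFileError as exc:
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D page sequence, got shape {arr.shape}")
    return arr, meta


def write_stack(path, stack: np.ndarray) -> None:
    """Write a frames × rows × cols array as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(path, stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# Localization CSV (native + ThunderSTORM dialect)
# ---------------------------------------------------------------------------

_TS_COLUMNS = {
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "photons": "intensity [photon]",
    "background": "offset [photon]",
    "sigma_x": "sigma1 [nm]",
    "sigma_y": "sigma2 [nm]",
    "uncertainty_xy": "uncertainty [nm]",
}


def write_localizations(table: LocalizationTable, path, dialect: str = "native") -> None:
    """Write a localization table as CSV.

    ``native`` emits every column plus the ``frame_kind`` tag; ``thunderstorm``
    emits the column names ThunderSTORM expects (1-based id and frame).
    """
    if dialect == "native":
        df = table.data.copy()
        df["frame_kind"] = table.frame_kind
        df.to_csv(path, index=False)
    elif dialect == "thunderstorm":
        d = table.data
        out = pd.DataFrame({"id": np.arange(1, len(d) + 1)})
        out["frame"] = d["frame"].to_numpy() + 1
        for col, ts in _TS_COLUMNS.items():
            if col in d.columns:
                out[ts] = d[col].to_numpy()
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_localizations(
    path, dialect: str = "native", frames_per_stack: int | None = None
) -> LocalizationTable:
    """Read a localization CSV written in ``native`` or ``thunderstorm`` dialect.

    A ThunderSTORM table without a z column is read as 2D data: z is filled
    with 0 and flagged via ``z_valid = False``.  ``frames_per_stack`` lets the
    reader reconstruct stack indices for ThunderSTORM tables (which cannot
    store them); by default all rows go to stack 0.
    """
    df = pd.read_csv(path)
    if dialect == "native":
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        if "frame_kind" in df.columns:
            kinds = df.pop("frame_kind")
            kind = str(kinds.iloc[0]) if len(kinds) else "acquisition"
            if len(kinds) and (kinds != kind).any():
                raise ValueError(f"{path}: mixed frame_kind values")
        else:
            kind = "acquisition"
        return LocalizationTable(df, kind)
    if dialect == "thunderstorm":
        for needed in ("x [nm]", "y [nm]", "frame"):
            if needed not in df.columns:
                raise ValueError(f"{path}: missing mandatory column {needed!r}")
        frame = df["frame"].to_numpy(int) - 1
        n = len(df)
        if "z [nm]" in df.columns:
            z = df["z [nm]"].to_numpy(float)
            z_valid = np.ones(n, bool)
        else:
            logger.warning("%s: no z column; treating as 2D data (z=0)", path)
            z = np.zeros(n)
            z_valid = np.zeros(n, bool)
        kwargs = {}
        for col, ts in _TS_COLUMNS.items():
            if ts in df.columns and col not in ("x", "y", "z"):
                kwargs[col] = df[ts].to_numpy(float)
        return localization_table(
            df["x [nm]"].to_numpy(float), df["y [nm]"].to_numpy(float), z, frame,
            frames_per_stack=frames_per_stack, z_valid=z_valid, **kwargs,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _default_geometry():
    from .geometry import AcquisitionGeometry

    return AcquisitionGeometry()


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Defaults follow the acquisition described for the instrument where stated
    (2 µm × 2 µm window / 0.2 µm step, ≥20-frame tracks, first five MSD lag
    points, 1.5 s FRAP interval with three pre-bleach frames) and documented
    package choices elsewhere.
    """

    geometry: "object" = field(default_factory=_default_geometry)
    # localization filters
    min_photons: float = 500.0
    axial_halfwidth: float = 700.0        # nm; half the illuminated sheet range
    # spot detection / fitting
    detection_threshold: float = 4.0      # multiples of robust noise sd
    min_separation: int = 4               # px between accepted candidates
    roi_size: int = 13                    # px, odd
    camera_offset: float = 100.0          # counts
    camera_gain: float = 1.0              # counts per photon
    # density
    window_size: float = 2000.0           # nm
    step: float = 200.0                   # nm
    render_pixel: float = 20.0            # nm
    # tracking
    max_disp: float = 500.0               # nm per frame
    memory: int = 1                       # frames
    min_track_len: int = 20               # frames
    n_fit_points: int = 5
    # precision (blink-event grouping)
    group_radius: float = 100.0           # nm
    max_gap: int = 1                      # frames
    # frap
    frame_interval: float = 1.5           # s
    n_prebleach: int = 3
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "min_photons", "axial_halfwidth", "detection_threshold",
            "window_size", "step", "render_pixel", "max_disp",
            "group_radius", "frame_interval", "camera_gain",
        )
        for key in positive:
            if getattr(self, key) <= 0 and key != "min_photons":
                raise ValueError(f"config key {key!r} must be > 0")
        if self.min_photons < 0:
            raise ValueError("config key 'min_photons' must be >= 0")
        if self.n_fit_points < 2:
            raise ValueError("config key 'n_fit_points' must be >= 2")
        if self.min_track_len < 2:
            raise ValueError("config key 'min_track_len' must be >= 2")
        if self.roi_size % 2 != 1:
            raise ValueError("config key 'roi_size' must be odd")
        if self.memory < 0 or self.max_gap < 1 or self.n_prebleach < 1:
            raise ValueError("config keys memory/max_gap/n_prebleach out of range")


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file of flat keys.

    Geometry parameters may appear under a ``geometry:`` mapping or as top
    level keys.  Absent keys take the documented defaults; invariant
    violations raise ``ValueError`` naming the offending key.
    """
    from .geometry import AcquisitionGeometry

    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        raw = {**raw, **overrides}

    geo_fields = {f.name for f in dataclasses.fields(AcquisitionGeometry)}
    cfg_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    geo_kwargs = dict(raw.pop("geometry", {}) or {})
    cfg_kwargs = {}
    for key, value in raw.items():
        if key in geo_fields:
            geo_kwargs[key] = value
        elif key in cfg_fields:
            cfg_kwargs[key] = value
        else:
            logger.warning("ignoring unknown config key %r", key)
    unknown = set(geo_kwargs) - geo_fields
    if unknown:
        raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
    geometry = AcquisitionGeometry(**geo_kwargs)
    return PipelineConfig(geometry=geometry, **cfg_kwargs)
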