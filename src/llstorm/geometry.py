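"""Acquisition geometry: scan-shift correction, deskew/rotation to the
coverslip frame, and experimental localization-precision estimation.

The sample is stage-scanned through the light sheet in a sawtooth: within one
stack the scan coordinate advances by ``scan_step`` per frame and resets at
each stack start.  The camera frame (x, y) is inclined by the deskew angle α
relative to the coverslip, so acquisition coordinates (x, y, z) map to the
biological frame (x', y', z') by a rotation about the camera x-axis composed
with the scan translation s along y'::

    x' = x
    y' = s + y·cos α − z·sin α
    z' =     y·sin α + z·cos α

The per-frame transform is rigid (unit-determinant rotation + translation),
so pairwise distances within a frame and point counts are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config_io import LocalizationTable

logger = logging.getLogger("llstorm")


@dataclass
class AcquisitionGeometry:
    """Instrument and scan parameters defining the coordinate transform.

    Defaults follow the described acquisition: 103.8 nm pixels, 40 nm scan
    step, 1001 frames per stack, ~1.4 µm sheet thickness, 20 ms exposure.
    The deskew angle is not printed for the instrument; 32.45° is the
    conventional lattice light-sheet detection inclination and is an explicit
    package default — override it for other instruments.
    """

    pixel_size: float = 103.8        # nm
    scan_step: float = 40.0          # nm per frame
    frames_per_stack: int = 1001
    n_stacks: int = 1
    deskew_angle: float = 32.45      # degrees between camera y-axis and coverslip
    sheet_thickness: float = 1400.0  # nm
    exposure: float = 0.02           # s

    def __post_init__(self) -> None:
        if not (0.0 < self.deskew_angle < 90.0):
            raise ValueError("deskew_angle must lie in (0, 90) degrees")
        if self.scan_step <= 0:
            raise ValueError("scan_step must be > 0")
        if self.frames_per_stack < 1:
            raise ValueError("frames_per_stack must be >= 1")
        if self.pixel_size <= 0 or self.sheet_thickness <= 0 or self.exposure <= 0:
            raise ValueError("pixel_size, sheet_thickness and exposure must be > 0")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")

    @property
    def total_frames(self) -> int:
        """Frames in the full acquisition plan (frames_per_stack × n_stacks)."""
        return self.frames_per_stack * self.n_stacks

    @property
    def stack_scan_extent(self) -> float:
        """Scan range of one stack in nm: (frames_per_stack − 1) · scan_step."""
        return (self.frames_per_stack - 1) * self.scan_step

    @property
    def angle_rad(self) -> float:
        return np.deg2rad(self.deskew_angle)


@dataclass
class PrecisionEstimate:
    """Per-dimension experimental localization precision (nm), pooled over
    repeated localizations of individual blinking events."""

    sigma_x: float
    sigma_y: float
    sigma_z: float
    n_events: int
    n_localizations: int
    frame_kind: str

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma_x, self.sigma_y, self.sigma_z)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def correct_scan_shift(table: LocalizationTable, geometry: AcquisitionGeometry) -> LocalizationTable:
    """Record the known sawtooth scan shift for every localization.

    Adds the scan coordinate column ``s = frame_in_stack · scan_step`` (which
    resets to 0 at each stack start); coordinates are untouched.  The shift
    itself is applied by :func:`deskew_rotate`.
    """
    if table.frame_kind != "acquisition":
        raise ValueError("correct_scan_shift expects an acquisition-frame table")
    fis = table.data["frame_in_stack"].to_numpy()
    if len(fis) and fis.max() >= geometry.frames_per_stack:
        raise ValueError(
            f"frame_in_stack {fis.max()} >= frames_per_stack {geometry.frames_per_stack}"
        )
    if len(fis) and fis.min() < 0:
        raise ValueError("negative frame_in_stack")
    data = table.data.copy()
    data["s"] = fis * float(geometry.scan_step)
    return table.advanced(data, "scan_corrected")


def deskew_rotate(table: LocalizationTable, geometry: AcquisitionGeometry) -> LocalizationTable:
    """Rotate scan-corrected localizations into the biological frame.

    Applies the affine map in the module docstring row-wise; the scan
    coordinate ``s`` is kept so the transform stays invertible.
    """
    if table.frame_kind != "scan_corrected":
        raise ValueError("deskew_rotate expects a scan_corrected table")
    if "s" not in table.data.columns:
        raise ValueError("missing scan coordinate column 's'; run correct_scan_shift")
    ca, sa = np.cos(geometry.angle_rad), np.sin(geometry.angle_rad)
    d = table.data
    y, z, s = d["y"].to_numpy(), d["z"].to_numpy(), d["s"].to_numpy()
    data = d.copy()
    data["y"] = s + y * ca - z * sa
    data["z"] = y * sa + z * ca
    return table.advanced(data, "biological")


def invert_deskew(table: LocalizationTable, geometry: AcquisitionGeometry) -> LocalizationTable:
    """Exact algebraic inverse of :func:`deskew_rotate` (for round trips)."""
    if table.frame_kind != "biological":
        raise ValueError("invert_deskew expects a biological-frame table")
    if "s" not in table.data.columns:
        raise ValueError("missing scan coordinate column 's'")
    ca, sa = np.cos(geometry.angle_rad), np.sin(geometry.angle_rad)
    d = table.data
    yp, zp, s = d["y"].to_numpy(), d["z"].to_numpy(), d["s"].to_numpy()
    data = d.copy()
    data["y"] = (yp - s) * ca + zp * sa
    data["z"] = -(yp - s) * sa + zp * ca
    # deliberate backward transition: the documented inverse operation
    return LocalizationTable(data, "scan_corrected")


# ---------------------------------------------------------------------------
# Experimental localization precision from blinking events
# ---------------------------------------------------------------------------

def estimate_precision(
    table: LocalizationTable,
    group_radius: float = 100.0,
    max_gap: int = 1,
) -> PrecisionEstimate:
    """Estimate per-dimension precision from repeated blink localizations.

    Localizations in consecutive frames (gaps ≤ ``max_gap`` frames) lying
    within ``group_radius`` nm of each other are grouped into blinking
    events; the precision per dimension is the pooled within-event standard
    deviation over events with ≥ 2 members.  This is the only place the
    pipeline merges consecutive localizations (density analysis deliberately
    applies no overcounting correction).
    """
    from .tracking import link_localizations

    if len(table) < 2:
        raise ValueError("need at least 2 localizations")
    events = [
        tr for tr in link_localizations(table, max_disp=group_radius, memory=max_gap - 1)
        if len(tr.frames) >= 2
    ]
    if not events:
        raise ValueError(
            "no multi-localization blinking events found; "
            "increase group_radius or max_gap"
        )
    ss = np.zeros(3)
    dof = 0
    n_loc = 0
    for tr in events:
        dev = tr.xyz - tr.xyz.mean(axis=0)
        ss += (dev**2).sum(axis=0)
        dof += len(tr.frames) - 1
        n_loc += len(tr.frames)
    sig = np.sqrt(ss / dof)
    return PrecisionEstimate(
        sigma_x=float(sig[0]), sigma_y=float(sig[1]), sigma_z=float(sig[2]),
        n_events=len(events), n_localizations=n_loc, frame_kind=table.frame_kind,
    )
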