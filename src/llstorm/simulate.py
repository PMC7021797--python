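"""Synthetic ground-truth scenes, blinking-emitter movies under sawtooth
sample scanning, Brownian trajectories and FRAP traces.

The scene is the minimal adherent-cell geometry exhibiting the three membrane
regions quantified downstream: two spherical-cap cells on a coverslip whose
caps are clipped at the mid-plane where they would overlap, leaving a flat
contact wall per cell.  Emitters are a Poisson point process on each membrane
patch at region-specific surface densities (basal disc, apical cap, and the
two apposed interface walls); because two membranes meet at the interface,
the projected interface density is ≈ twice the per-membrane value, as for
contacting cells.

Image formation uses the same astigmatic elliptical-Gaussian model the
localizer fits: widths σx(z), σy(z) from an :class:`AstigCalibration`,
Poisson photon statistics, Poisson background, then a linear camera
offset/gain and optional Gaussian read noise.  During scanned acquisition
the sheet sits at the camera focal plane; an emitter is excitable in a frame
only if its distance to the sheet plane is at most half the sheet thickness.

All stochastic outputs are reproducible bit-for-bit given (seed, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config_io import LocalizationTable, localization_table
from .frap import FrapTrace, normalize_trace, recovery_model
from .geometry import AcquisitionGeometry
from .localize import AstigCalibration, _pixel_profile

logger = logging.getLogger("llstorm")

UM = 1000.0  # nm per µm


@dataclass
class SceneSpec:
    """Two adjacent spherical-cap cells on a coverslip, with emitter
    densities per membrane region and imaging/camera parameters.

    Densities are emitters per µm² of membrane area; the localization
    densities the pipeline measures are these times the mean localizations
    per emitter set by the blinking kinetics.  The default densities are of
    the order implied by the measured receptor localization densities once a
    blinking yield of a few localizations per label is divided out; the
    kinetic constants themselves are free parameters of the simulation
    (memoryless activation, geometric on-time, single bleach).
    """

    cap_radius_um: float = 8.0
    cap_height_um: float = 6.4
    center_separation_um: float = 11.2
    center_x_um: float = 0.0
    center_y_um: float = 19.5          # midpoint between the two cell centres
    rho_basal: float = 54.0            # emitters / µm²
    rho_apical: float = 140.0
    rho_interface: float = 140.0       # per membrane; two membranes meet at the wall
    interface_distance_nm: float = 50.0
    mean_photons: float = 1500.0       # per blink per frame
    background: float = 10.0           # photons / pixel
    mean_on_frames: float = 3.0        # geometric on-time mean
    activation_rate: float = 0.005     # per emitter per excitable frame
    camera_offset: float = 100.0       # counts
    camera_gain: float = 1.0           # counts / photon
    read_noise: float = 0.0            # counts rms

    def __post_init__(self) -> None:
        if min(self.rho_basal, self.rho_apical, self.rho_interface) < 0:
            raise ValueError("densities must be >= 0")
        if not 0 < self.cap_height_um <= 2 * self.cap_radius_um:
            raise ValueError("cap height must lie in (0, 2·radius]")
        if not 0 <= self.activation_rate <= 1:
            raise ValueError("activation_rate must lie in [0, 1]")
        if self.mean_on_frames < 1:
            raise ValueError("mean_on_frames must be >= 1")


@dataclass
class GroundTruth:
    """Emitter positions (nm, biological frame) with membrane-region labels."""

    positions: np.ndarray   # (n, 3) nm
    labels: np.ndarray      # (n,) in {"basal", "apical", "interface"}
    cell: np.ndarray        # (n,) 0 or 1

    def __len__(self) -> int:
        return len(self.positions)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _scene_nm(scene: SceneSpec):
    """Scene geometry in nm: radius, sphere-centre height, cell centres, mid-plane."""
    R = scene.cap_radius_um * UM
    h = scene.cap_height_um * UM
    zc = h - R                                    # sphere centre height (can be < 0)
    sep = scene.center_separation_um * UM
    x0 = scene.center_x_um * UM
    ymid = scene.center_y_um * UM
    centers = np.array([
        [x0, ymid - sep / 2, zc],
        [x0, ymid + sep / 2, zc],
    ])
    wall_r = np.sqrt(max(R**2 - (sep / 2) ** 2, 0.0)) if sep < 2 * R else 0.0
    return R, zc, centers, ymid, wall_r


# ---------------------------------------------------------------------------
# Ground-truth emitters
# ---------------------------------------------------------------------------

def sample_membrane_emitters(scene: SceneSpec, seed=0) -> GroundTruth:
    """Sample emitters as Poisson point processes on the membrane regions.

    Spherical surfaces are sampled by thinning a full-sphere Poisson process
    (so per-region counts are exactly Poisson with mean ρ · region area
    without computing clipped areas); basal discs and interface walls are
    sampled on their discs directly.  A membrane point counts as interface
    when it lies within ``interface_distance_nm`` of the other cell's
    membrane; basal points (coverslip contact) keep the basal label.
    """
    rng = _rng(seed)
    R, zc, centers, ymid, wall_r = _scene_nm(scene)
    overlap = wall_r > 0

    def dist_to_other(p: np.ndarray, other: int) -> np.ndarray:
        d_sph = np.abs(np.linalg.norm(p - centers[other], axis=1) - R)
        if not overlap:
            return d_sph
        rad = np.hypot(p[:, 0] - centers[other][0], p[:, 2] - centers[other][2])
        d_wall = np.hypot(np.maximum(rad - wall_r, 0.0), p[:, 1] - ymid)
        return np.minimum(d_sph, d_wall)

    def sphere_points(cell: int, rho: float) -> np.ndarray:
        if rho <= 0:
            return np.empty((0, 3))
        area_um2 = 4 * np.pi * (R / UM) ** 2
        n = rng.poisson(rho * area_um2)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p = centers[cell] + R * u
        side = p[:, 1] <= ymid if cell == 0 else p[:, 1] >= ymid
        return p[(p[:, 2] > 0) & side]

    def disc_points(n: int, center: np.ndarray, radius: float, axes=(0, 1)) -> np.ndarray:
        r = radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        p = np.tile(center, (n, 1))
        p[:, axes[0]] += r * np.cos(th)
        p[:, axes[1]] += r * np.sin(th)
        return p

    pos_list, lab_list, cell_list = [], [], []
    for cell in range(2):
        other = 1 - cell
        # apical: full-sphere process at ρ_apical, keep non-interface points
        p = sphere_points(cell, scene.rho_apical)
        if len(p):
            keep = dist_to_other(p, other) > scene.interface_distance_nm
            pos_list.append(p[keep])
            lab_list.append(np.full(keep.sum(), "apical"))
            cell_list.append(np.full(keep.sum(), cell))
        # interface on the sphere: independent process at ρ_interface, keep
        # only points near the other cell
        p = sphere_points(cell, scene.rho_interface)
        if len(p):
            keep = dist_to_other(p, other) <= scene.interface_distance_nm
            pos_list.append(p[keep])
            lab_list.append(np.full(keep.sum(), "interface"))
            cell_list.append(np.full(keep.sum(), cell))
        # basal disc at the coverslip
        if scene.rho_basal > 0:
            a = np.sqrt(max(R**2 - zc**2, 0.0))
            if a > 0:
                n = rng.poisson(scene.rho_basal * np.pi * (a / UM) ** 2)
                p = disc_points(n, np.array([centers[cell][0], centers[cell][1], 0.0]), a)
                side = p[:, 1] <= ymid if cell == 0 else p[:, 1] >= ymid
                p = p[side]
                pos_list.append(p)
                lab_list.append(np.full(len(p), "basal"))
                cell_list.append(np.full(len(p), cell))
        # contact wall (this cell's flat membrane at the mid-plane)
        if overlap and scene.rho_interface > 0:
            n = rng.poisson(scene.rho_interface * np.pi * (wall_r / UM) ** 2)
            p = disc_points(n, np.array([centers[cell][0], ymid, zc]), wall_r, axes=(0, 2))
            p = p[p[:, 2] > 0]
            pos_list.append(p)
            lab_list.append(np.full(len(p), "interface"))
            cell_list.append(np.full(len(p), cell))
    if pos_list:
        positions = np.concatenate(pos_list)
        labels = np.concatenate(lab_list)
        cells = np.concatenate(cell_list).astype(int)
    else:
        positions = np.empty((0, 3))
        labels = np.empty(0, dtype="<U9")
        cells = np.empty(0, int)
    return GroundTruth(positions, labels, cells)


# ---------------------------------------------------------------------------
# Blinking kinetics
# ---------------------------------------------------------------------------

def simulate_blinking(
    truth,
    n_frames: int,
    mean_on_frames: float = 3.0,
    activation_rate: float = 0.005,
    seed=0,
) -> list[np.ndarray]:
    """Per-frame active-emitter index sets under memoryless blinking.

    Each emitter activates with probability ``activation_rate`` per frame
    while dark, stays on for a Geometric(``1/mean_on_frames``) number of
    frames, then bleaches (no dark-state recurrence).  ``mean_on_frames`` may
    be ``inf`` for emitters that never bleach.  ``truth`` is a
    :class:`GroundTruth` or an emitter count.
    """
    n_emitters = len(truth) if isinstance(truth, GroundTruth) else int(truth)
    rng = _rng(seed)
    active: list[list[int]] = [[] for _ in range(n_frames)]
    if activation_rate > 0 and n_emitters:
        g = rng.geometric(activation_rate, size=n_emitters) - 1  # activation frame
        if np.isinf(mean_on_frames):
            L = np.full(n_emitters, n_frames, dtype=np.int64)
        else:
            L = rng.geometric(1.0 / mean_on_frames, size=n_emitters)
        for e in range(n_emitters):
            if g[e] >= n_frames:
                continue
            for f in range(g[e], min(g[e] + L[e], n_frames)):
                active[f].append(e)
    return [np.asarray(a, int) for a in active]


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------

def _stamp_spot(img: np.ndarray, row: float, col: float,
                sx_px: float, sy_px: float, photons: float) -> None:
    """Add one pixel-integrated elliptical Gaussian to an expectation image."""
    ny, nx = img.shape
    hx = int(np.ceil(4 * sx_px + 1))
    hy = int(np.ceil(4 * sy_px + 1))
    c0, c1 = max(int(col) - hx, 0), min(int(col) + hx + 1, nx)
    r0, r1 = max(int(row) - hy, 0), min(int(row) + hy + 1, ny)
    if c0 >= c1 or r0 >= r1:
        return
    Ex = _pixel_profile(c1 - c0, col - c0, sx_px)[0]
    Ey = _pixel_profile(r1 - r0, row - r0, sy_px)[0]
    img[r0:r1, c0:c1] += photons * np.outer(Ey, Ex)


def render_frame(
    emitters: np.ndarray,
    geometry: AcquisitionGeometry,
    calibration: AstigCalibration,
    scene: SceneSpec,
    shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    photons: np.ndarray | None = None,
) -> np.ndarray:
    """Render one camera frame from acquisition-frame emitter positions.

    ``emitters`` is (n, 3) of (x, y, z) nm in the acquisition frame; pixel
    positions are (x/pixel_size + origin_col, y/pixel_size + origin_row).
    Widths come from the calibration at each emitter's z; emitters outside
    the calibrated z range are skipped with a logged count.  With ``rng``
    None the noise-free expectation (offset + gain·signal) is returned;
    otherwise per-blink photon counts are Poisson(mean_photons) unless given
    explicitly, pixels get Poisson shot noise on signal + background, and the
    camera offset/gain (+ optional Gaussian read noise) is applied last.
    """
    emitters = np.asarray(emitters, float).reshape(-1, 3)
    ny, nx = shape
    E = np.zeros((ny, nx))
    n_skipped = 0
    if photons is None:
        if rng is None:
            photons = np.full(len(emitters), scene.mean_photons)
        else:
            photons = rng.poisson(scene.mean_photons, size=len(emitters)).astype(float)
    for (x, y, z), N in zip(emitters, photons):
        if not (calibration.z_min <= z <= calibration.z_max):
            n_skipped += 1
            continue
        sx = calibration.sigma_x(z) / geometry.pixel_size
        sy = calibration.sigma_y(z) / geometry.pixel_size
        _stamp_spot(E, y / geometry.pixel_size + origin[0],
                    x / geometry.pixel_size + origin[1], sx, sy, N)
    if n_skipped:
        logger.info("render_frame: %d emitter(s) outside calibration z range", n_skipped)
    E += scene.background
    if rng is None:
        counts = scene.camera_offset + scene.camera_gain * E
    else:
        counts = scene.camera_offset + scene.camera_gain * rng.poisson(E)
        if scene.read_noise > 0:
            counts = counts + rng.normal(0.0, scene.read_noise, size=counts.shape)
    return counts


# ---------------------------------------------------------------------------
# Scanned acquisition
# ---------------------------------------------------------------------------

@dataclass
class ScanAcquisition:
    """A simulated sawtooth-scanned movie plus its truth channel.

    ``records`` has one row per rendered emitter-frame pair with the
    acquisition-frame coordinates at that frame — the ground truth against
    which localization recall and the sheet-visibility bound are checked.
    ``origin`` is the (row, col) pixel of acquisition coordinate (0, 0).
    ``movie`` is empty when the acquisition was simulated with
    ``render=False``; :meth:`iter_frames` then renders frames lazily (the
    pixel-noise stream is identical either way), which keeps memory constant
    for long acquisitions.
    """

    movie: np.ndarray       # (frames, ny, nx) uint16, possibly empty
    truth: GroundTruth
    records: pd.DataFrame
    origin: tuple[float, float]
    geometry: AcquisitionGeometry
    n_stacks: int
    scene: SceneSpec | None = None
    calibration: AstigCalibration | None = None
    noise_seed: int | None = None
    shape: tuple[int, int] | None = None

    @property
    def total_frames(self) -> int:
        return self.geometry.frames_per_stack * self.n_stacks

    def iter_frames(self):
        """Yield camera frames (uint16) one at a time, in frame order."""
        rng = np.random.default_rng(self.noise_seed)
        by_frame = dict(iter(self.records.groupby("frame"))) if len(self.records) else {}
        for fr in range(self.total_frames):
            g = by_frame.get(fr)
            if g is None:
                em, ph = np.empty((0, 3)), np.empty(0)
            else:
                em = g[["x", "y", "z"]].to_numpy()
                ph = g["photons"].to_numpy()
            frame = render_frame(em, self.geometry, self.calibration, self.scene,
                                 self.shape, origin=self.origin, rng=rng, photons=ph)
            yield np.clip(frame, 0, 65535).astype(np.uint16)


def simulate_scan_acquisition(
    scene: SceneSpec,
    geometry: AcquisitionGeometry,
    n_stacks: int,
    seed=0,
    calibration: AstigCalibration | None = None,
    shape: tuple[int, int] | None = None,
    render: bool = True,
) -> ScanAcquisition:
    """Simulate a blinking movie under sawtooth sample scanning.

    Frame f of every stack places the light sheet at scan coordinate
    s = f·scan_step (resetting each stack); an emitter at biological
    (x', y', z') has acquisition coordinates x = x',
    y = (y' − s)·cos α + z'·sin α, z = −(y' − s)·sin α + z'·cos α, and is
    excitable only while |z| ≤ sheet_thickness/2.  Blinking activation runs
    per excitable frame (dye activation requires illumination), so every
    membrane point receives the same expected number of localizations.
    Total frames = n_stacks · frames_per_stack.  With ``render=False`` only
    the truth channel is produced (no movie), which is cheap at any scale.
    """
    rng = _rng(seed)
    calibration = calibration or AstigCalibration.from_defocus_model()
    truth = sample_membrane_emitters(scene, rng)
    F = geometry.frames_per_stack
    step = geometry.scan_step
    alpha = geometry.angle_rad
    sa, ca = np.sin(alpha), np.cos(alpha)
    half_sheet = geometry.sheet_thickness / 2.0
    win = half_sheet / sa                       # scan half-window of excitability

    P = truth.positions
    s_star = P[:, 1] - P[:, 2] * (ca / sa)      # scan position of sheet passage
    f_lo = np.ceil((s_star - win) / step).astype(int).clip(0, F - 1)
    f_hi = np.floor((s_star + win) / step).astype(int).clip(0, F - 1)
    k_e = (f_hi - f_lo + 1).clip(min=0)
    k_e[(s_star + win < 0) | (s_star - win > (F - 1) * step)] = 0

    rec: dict[str, list] = {k: [] for k in
                            ("emitter", "frame", "stack", "frame_in_stack",
                             "x", "y", "z", "photons", "label")}
    per_frame: dict[int, list[int]] = {}
    for e in range(len(P)):
        if k_e[e] <= 0:
            continue
        K = int(k_e[e]) * n_stacks
        G = int(rng.geometric(scene.activation_rate)) if scene.activation_rate > 0 else K + 1
        if G > K:
            continue
        q, r = divmod(G - 1, int(k_e[e]))
        g = q * F + f_lo[e] + r
        if np.isinf(scene.mean_on_frames):
            L = K
        else:
            L = int(rng.geometric(1.0 / scene.mean_on_frames))
        end = min(g + L - 1, q * F + f_hi[e])   # sheet leaves or dye bleaches
        for fr in range(g, end + 1):
            per_frame.setdefault(fr, []).append(e)
            fis = fr % F
            s = fis * step
            dy = P[e, 1] - s
            rec["emitter"].append(e)
            rec["frame"].append(fr)
            rec["stack"].append(fr // F)
            rec["frame_in_stack"].append(fis)
            rec["x"].append(P[e, 0])
            rec["y"].append(dy * ca + P[e, 2] * sa)
            rec["z"].append(-dy * sa + P[e, 2] * ca)
            rec["photons"].append(float(rng.poisson(scene.mean_photons)))
            rec["label"].append(truth.labels[e])
    records = pd.DataFrame(rec)

    # field of view sized from the scene: camera y spans ~[−win·cosα, z'max/sinα + win·cosα]
    px = geometry.pixel_size
    margin = 8
    if shape is None:
        if len(P):
            x_lo, x_hi = P[:, 0].min(), P[:, 0].max()
            y_hi = P[:, 2].max() / sa + win * ca
        else:
            x_lo = x_hi = y_hi = 0.0
        nx = int(np.ceil((x_hi - x_lo) / px)) + 2 * margin
        ny = int(np.ceil((y_hi + win * ca) / px)) + 2 * margin
        origin = (margin + win * ca / px, margin - x_lo / px)
        shape = (ny, nx)
    else:
        origin = (margin, margin)

    noise_seed = int(rng.integers(2**31))
    acq = ScanAcquisition(
        np.empty((0,) + tuple(shape), np.uint16), truth, records, origin,
        geometry, n_stacks, scene=scene, calibration=calibration,
        noise_seed=noise_seed, shape=tuple(shape),
    )
    if render:
        acq.movie = np.stack(list(acq.iter_frames()))
    return acq


# ---------------------------------------------------------------------------
# Brownian trajectories
# ---------------------------------------------------------------------------

def simulate_trajectories(
    n: int,
    D,                       # (3,) µm²/s, per dimension
    dt: float,
    n_frames: int,
    noise,                   # (3,) nm rms localization noise per dimension
    seed=0,
    spacing_nm: float = 4000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n Brownian 3D trajectories sampled every ``dt`` seconds.

    Per-dimension increments are Gaussian with variance 2·D_r·dt; the noisy
    copy adds i.i.d. Gaussian localization noise σ_r per sample.  Start
    positions sit on a sparse grid (``spacing_nm``) so trajectories are
    linkable without identity confusion.  Returns (true, noisy) arrays of
    shape (n, n_frames, 3) in nm.
    """
    D = np.asarray(D, float)
    noise = np.asarray(noise, float)
    if (D < 0).any() or dt <= 0:
        raise ValueError("D components must be >= 0 and dt > 0")
    rng = _rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    starts = np.zeros((n, 3))
    starts[:, 0] = gx.ravel()[:n] * spacing_nm
    starts[:, 1] = gy.ravel()[:n] * spacing_nm
    step_sd = np.sqrt(2.0 * D * dt) * UM      # nm
    incr = rng.normal(size=(n, n_frames - 1, 3)) * step_sd
    true = np.concatenate(
        [np.zeros((n, 1, 3)), np.cumsum(incr, axis=1)], axis=1
    ) + starts[:, None, :]
    noisy = true + rng.normal(size=true.shape) * noise
    return true, noisy


def trajectories_to_table(positions: np.ndarray) -> LocalizationTable:
    """Flatten (n, frames, 3) trajectory positions into a localization table."""
    n, F, _ = positions.shape
    flat = positions.reshape(n * F, 3)
    frames = np.tile(np.arange(F), n)
    return localization_table(flat[:, 0], flat[:, 1], flat[:, 2], frames)


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def simulate_frap(
    tau: float,
    mobile_fraction: float,
    bleach_depth: float = 0.7,
    n_prebleach: int = 3,
    frame_interval: float = 1.5,
    total_time: float = 120.0,
    noise: float = 0.0,
    seed=0,
) -> FrapTrace:
    """Simulate a normalized FRAP trace with single-exponential recovery.

    Pre-bleach frames sit at 1.0; from the bleach the trace follows
    I(t) = I₀ + MF·(1 − I₀)·(1 − exp(−(t − t_bleach)/τ)) with
    I₀ = 1 − bleach_depth, plus Gaussian noise of the given sd.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    rng = _rng(seed)
    n = int(round(total_time / frame_interval))
    t = frame_interval * np.arange(n)
    i0 = 1.0 - bleach_depth
    raw = np.ones(n)
    post = t >= t[n_prebleach]
    raw[post] = recovery_model(t[post], tau, mobile_fraction, i0, t[n_prebleach])
    if noise > 0:
        raw = raw + rng.normal(0.0, noise, size=n)
    return normalize_trace(raw, 0.0, n_prebleach, frame_interval, t=t)
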