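"""Astigmatic single-molecule localization.

Spots are detected with a difference-of-Gaussians band-pass, fitted with an
elliptical-Gaussian PSF model by maximum likelihood under Poisson noise, and
assigned an axial position by inverting a bead-stack calibration of the
defocus curves σx(z), σy(z).

The elliptical-Gaussian model is a deliberate fidelity trade-off: it replaces
spline-interpolated experimental PSF models with the standard closed-form
astigmatism model, which is sufficient for the geometry, density and
precision analyses downstream and fully self-consistent with the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import yaml
from scipy.optimize import brentq, minimize
from scipy.special import erf

from .config_io import LocalizationTable, PipelineConfig, localization_table

logger = logging.getLogger("llstorm")

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Astigmatism calibration
# ---------------------------------------------------------------------------

@dataclass
class AstigCalibration:
    """Defocus curves σx(z), σy(z) as quartic polynomials (nm vs nm).

    ``coef_x``/``coef_y`` are ``np.polyval`` coefficient vectors.  The
    calibration is rejected on construction unless both widths are positive
    and σx − σy is strictly monotone with a usable range (otherwise the z
    assignment would be ambiguous).  ``z0`` is the crossing point σx = σy.
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    z_min: float
    z_max: float
    z0: float = field(default=np.nan)
    min_astig: float = 10.0  # nm; required range of σx − σy

    def __post_init__(self) -> None:
        self.coef_x = np.asarray(self.coef_x, float)
        self.coef_y = np.asarray(self.coef_y, float)
        if not self.z_min < self.z_max:
            raise ValueError("invalid calibration z range")
        z = np.linspace(self.z_min, self.z_max, 257)
        sx, sy = np.polyval(self.coef_x, z), np.polyval(self.coef_y, z)
        if (sx <= 0).any() or (sy <= 0).any():
            raise ValueError("calibration widths must be positive over the z range")
        diff = sx - sy
        steps = np.diff(diff)
        if not ((steps > 0).all() or (steps < 0).all()):
            raise ValueError("σx − σy is not strictly monotone: ambiguous calibration")
        if diff.max() - diff.min() < self.min_astig:
            raise ValueError(
                f"astigmatism range {diff.max() - diff.min():.1f} nm < "
                f"{self.min_astig} nm: no usable astigmatism"
            )
        if np.isnan(self.z0):
            dcoef = np.polysub(self.coef_x, self.coef_y)
            if diff[0] * diff[-1] < 0:
                self.z0 = float(
                    brentq(lambda zz: np.polyval(dcoef, zz), self.z_min, self.z_max)
                )
            else:  # crossing outside calibrated range
                self.z0 = float(z[np.argmin(np.abs(diff))])
                logger.warning("σx = σy crossing lies outside the calibrated range")
        self._grid: tuple | None = None

    def sigma_x(self, z):
        return np.polyval(self.coef_x, z)

    def sigma_y(self, z):
        return np.polyval(self.coef_y, z)

    def _sqrt_grid(self):
        """1 nm lookup grid of (z, √σx, √σy) for the z assignment."""
        if self._grid is None:
            z = np.arange(self.z_min, self.z_max + 0.5, 1.0)
            self._grid = (z, np.sqrt(self.sigma_x(z)), np.sqrt(self.sigma_y(z)))
        return self._grid

    @classmethod
    def from_defocus_model(
        cls,
        sigma0: float = 140.0,
        gamma: float = 250.0,
        depth: float = 600.0,
        z_range: tuple[float, float] = (-750.0, 750.0),
    ) -> "AstigCalibration":
        """Build a calibration from the standard astigmatic defocus model
        σx,y(z) = σ0·√(1 + ((z ± γ)/d)²), fitted with quartic polynomials.

        σ0 is the in-focus width (nm), γ the focal-plane offset introduced by
        the cylindrical lens (nm) and d the effective depth of field (nm).
        """
        z = np.linspace(z_range[0], z_range[1], 201)
        sx = sigma0 * np.sqrt(1.0 + ((z + gamma) / depth) ** 2)
        sy = sigma0 * np.sqrt(1.0 + ((z - gamma) / depth) ** 2)
        return cls(np.polyfit(z, sx, 4), np.polyfit(z, sy, 4), z_range[0], z_range[1])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "coef_x": [float(c) for c in self.coef_x],
                    "coef_y": [float(c) for c in self.coef_y],
                    "z_min": float(self.z_min),
                    "z_max": float(self.z_max),
                    "z0": float(self.z0),
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "AstigCalibration":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["coef_x"], d["coef_y"], d["z_min"], d["z_max"], d.get("z0", np.nan))


def calibrate_astigmatism(
    bead_stack: np.ndarray,
    z_step: float,
    pixel_size: float,
    roi_size: int = 15,
    detection_threshold: float = 5.0,
    degree: int = 4,
) -> AstigCalibration:
    """Fit σx(z), σy(z) defocus curves from a bead z-stack.

    Beads are detected in the central plane, refitted in every plane, widths
    pooled across beads per plane and the pooled curves fitted with
    polynomials of the given degree.  Requires ≥ 9 planes and ≥ 1 bead; a
    symmetric (non-astigmatic) PSF or non-monotone σx − σy is rejected.
    """
    stack = np.asarray(bead_stack, float)
    n_planes = stack.shape[0]
    if n_planes < 9:
        raise ValueError(f"need >= 9 z planes for calibration, got {n_planes}")
    z = (np.arange(n_planes) - (n_planes - 1) / 2.0) * z_step
    beads = detect_spots(stack[n_planes // 2], threshold=detection_threshold,
                         min_separation=roi_size)
    if len(beads) == 0:
        raise ValueError("no beads detected in the central plane")
    half = roi_size // 2
    H, W = stack.shape[1:]
    sx_planes, sy_planes = [], []
    for k in range(n_planes):
        sxs, sys = [], []
        for r, c in beads:
            if not (half <= r < H - half and half <= c < W - half):
                continue
            roi = stack[k, r - half:r + half + 1, c - half:c + half + 1]
            fit = fit_spot(roi)
            if fit.converged and fit.photons > 0:
                sxs.append(fit.sigma_x)
                sys.append(fit.sigma_y)
        if not sxs:
            raise ValueError(f"no bead converged in plane {k} (z = {z[k]:.0f} nm)")
        sx_planes.append(np.mean(sxs) * pixel_size)
        sy_planes.append(np.mean(sys) * pixel_size)
    coef_x = np.polyfit(z, np.asarray(sx_planes), degree)
    coef_y = np.polyfit(z, np.asarray(sy_planes), degree)
    return AstigCalibration(coef_x, coef_y, float(z[0]), float(z[-1]))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_spots(
    frame: np.ndarray,
    threshold: float = 4.0,
    min_separation: int = 4,
    dog_sigmas: tuple[float, float] = (1.2, 2.4),
) -> np.ndarray:
    """Find candidate spot pixels in a photon-scaled 2D frame.

    Difference-of-Gaussians band-pass, then 8-connected local maxima above
    ``threshold`` robust noise standard deviations (1.4826·MAD), kept in
    decreasing brightness with at least ``min_separation`` pixels between
    accepted candidates.  Returns an (n, 2) array of (row, col); may be empty.
    """
    f = np.asarray(frame, float)
    dog = ndi.gaussian_filter(f, dog_sigmas[0]) - ndi.gaussian_filter(f, dog_sigmas[1])
    med = np.median(dog)
    noise = 1.4826 * np.median(np.abs(dog - med))
    thr = med + threshold * max(noise, 1e-12)
    is_max = (dog == ndi.maximum_filter(dog, size=3)) & (dog > thr)
    cand = np.argwhere(is_max)
    if len(cand) == 0:
        return cand.reshape(0, 2)
    order = np.argsort(dog[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    kept: list[np.ndarray] = []
    for rc in cand:
        if all(np.abs(rc - k).max() >= min_separation for k in kept):
            kept.append(rc)
    return np.array(kept, int)


# ---------------------------------------------------------------------------
# Elliptical-Gaussian MLE fit
# ---------------------------------------------------------------------------

@dataclass
class SpotFit:
    """Result of a single-spot fit, in units of the supplied pixel size
    (x, y relative to the ROI origin pixel centre)."""

    x: float
    y: float
    sigma_x: float
    sigma_y: float
    photons: float
    background: float
    converged: bool
    residual_norm: float


def _pixel_profile(n: int, c: float, s: float):
    """Integrated 1D Gaussian per pixel and its derivatives wrt centre/width.

    Pixel i spans [i − 0.5, i + 0.5]; returns (E, dE/dc, dE/ds), each length n.
    """
    t = np.arange(n + 1) - 0.5
    u = (t - c) / (_SQRT2 * s)
    cdf = 0.5 * erf(u)
    g = np.exp(-u * u) / (_SQRT2PI * s)           # Gaussian density at edges
    E = cdf[1:] - cdf[:-1]
    dEdc = g[:-1] - g[1:]
    h = ((t - c) / s) * g
    dEds = h[:-1] - h[1:]
    return E, dEdc, dEds


def fit_spot(roi: np.ndarray, init: dict | None = None, pixel_size: float = 1.0) -> SpotFit:
    """Maximum-likelihood elliptical-Gaussian fit of one ROI.

    The model is N·Gx(x0, σx)·Gy(y0, σy) + b with pixel-integrated Gaussian
    profiles, maximized under the Poisson likelihood with an analytic
    gradient.  Non-converged fits are returned flagged, never dropped.
    Raises on all-zero or non-finite ROIs.
    """
    k = np.asarray(roi, float)
    if k.ndim != 2:
        raise ValueError("ROI must be 2D")
    if not np.isfinite(k).all():
        raise ValueError("ROI contains non-finite pixels")
    if k.sum() <= 0:
        raise ValueError("all-zero ROI")
    k = np.clip(k, 0.0, None)
    ny, nx = k.shape

    border = np.concatenate([k[0], k[-1], k[1:-1, 0], k[1:-1, -1]])
    b0 = max(float(np.median(border)), 1e-3)
    sig = np.clip(k - b0, 0.0, None)
    tot = sig.sum()
    if tot > 0:
        y0 = float((sig.sum(axis=1) * np.arange(ny)).sum() / tot)
        x0 = float((sig.sum(axis=0) * np.arange(nx)).sum() / tot)
    else:
        y0, x0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    theta0 = np.array([
        x0, y0,
        (init or {}).get("sigma_x", 1.4),
        (init or {}).get("sigma_y", 1.4),
        max(tot, 10.0),
        b0,
    ])
    if init:
        theta0[0] = init.get("x", theta0[0])
        theta0[1] = init.get("y", theta0[1])

    def nll_grad(theta):
        cx, cy, sx, sy, N, b = theta
        Ex, dExdc, dExds = _pixel_profile(nx, cx, sx)
        Ey, dEydc, dEyds = _pixel_profile(ny, cy, sy)
        shape = np.outer(Ey, Ex)
        mu = np.clip(N * shape + b, 1e-12, None)
        nll = float((mu - k * np.log(mu)).sum())
        w = 1.0 - k / mu
        grad = np.array([
            N * float((w * np.outer(Ey, dExdc)).sum()),
            N * float((w * np.outer(dEydc, Ex)).sum()),
            N * float((w * np.outer(Ey, dExds)).sum()),
            N * float((w * np.outer(dEyds, Ex)).sum()),
            float((w * shape).sum()),
            float(w.sum()),
        ])
        return nll, grad

    bounds = [
        (-2.0, nx + 1.0), (-2.0, ny + 1.0),
        (0.4, max(nx, ny)), (0.4, max(nx, ny)),
        (1e-3, None), (1e-6, None),
    ]
    res = minimize(
        nll_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-9},
    )
    cx, cy, sx, sy, N, b = res.x
    Ex = _pixel_profile(nx, cx, sx)[0]
    Ey = _pixel_profile(ny, cy, sy)[0]
    mu = N * np.outer(Ey, Ex) + b
    resid = float(np.sqrt(np.mean((k - mu) ** 2)))
    inside = (-0.5 <= cx <= nx - 0.5) and (-0.5 <= cy <= ny - 0.5)
    return SpotFit(
        x=cx * pixel_size, y=cy * pixel_size,
        sigma_x=sx * pixel_size, sigma_y=sy * pixel_size,
        photons=float(N), background=float(b),
        converged=bool(res.success and inside), residual_norm=resid,
    )


# ---------------------------------------------------------------------------
# z assignment
# ---------------------------------------------------------------------------

def assign_z(
    sigma_x: float,
    sigma_y: float,
    calibration: AstigCalibration,
    max_residual: float = 2.0,
) -> tuple[float, bool]:
    """Assign the axial position from fitted widths via the calibration.

    Minimizes (√σx − √σx_cal(z))² + (√σy − √σy_cal(z))² on a 1 nm grid with
    parabolic refinement; ties break toward smaller |z|.  The assignment is
    invalid when the minimum sits at the range boundary or the √σ-space
    residual exceeds ``max_residual`` (width pair outside the achievable set).
    """
    if not (np.isfinite(sigma_x) and np.isfinite(sigma_y)) or sigma_x <= 0 or sigma_y <= 0:
        return float("nan"), False
    z, rx, ry = calibration._sqrt_grid()
    d = (np.sqrt(sigma_x) - rx) ** 2 + (np.sqrt(sigma_y) - ry) ** 2
    dmin = d.min()
    ties = np.flatnonzero(d <= dmin + 1e-12)
    i = int(ties[np.argmin(np.abs(z[ties]))])
    if i == 0 or i == len(z) - 1:
        return float(z[i]), False
    # parabolic refinement through the three grid points around the minimum
    d0, d1, d2 = d[i - 1], d[i], d[i + 1]
    denom = d0 - 2 * d1 + d2
    shift = 0.5 * (d0 - d2) / denom if denom > 0 else 0.0
    z_hat = float(z[i] + np.clip(shift, -1.0, 1.0))
    valid = bool(np.sqrt(dmin) <= max_residual)
    return z_hat, valid


# ---------------------------------------------------------------------------
# Movie localization and filtering
# ---------------------------------------------------------------------------

def localize_movie(
    stack,
    calibration: AstigCalibration,
    config: PipelineConfig,
) -> LocalizationTable:
    """Detect → fit → assign z on every frame of a camera movie.

    ``stack`` is a frames × rows × cols array or any iterable of 2D frames
    (e.g. a lazy renderer), so long acquisitions need never be held in
    memory.  Camera counts are converted to photons with the configured
    offset/gain.  The output is an acquisition-frame table with frame/stack
    indices derived from the configured frames_per_stack; deterministic
    given its inputs.  Per-spot failures are skipped with a logged count,
    never silently.
    """
    geo = config.geometry
    px = geo.pixel_size
    half = config.roi_size // 2
    n_skipped = 0
    recs: list[tuple] = []
    for fidx, raw in enumerate(stack):
        img = (np.asarray(raw, float) - config.camera_offset) / config.camera_gain
        np.clip(img, 0.0, None, out=img)
        H, W = img.shape
        cands = detect_spots(img, config.detection_threshold, config.min_separation)
        for r, c in cands:
            if not (half <= r < H - half and half <= c < W - half):
                n_skipped += 1
                continue
            roi = img[r - half:r + half + 1, c - half:c + half + 1]
            try:
                fit = fit_spot(roi)
            except ValueError:
                n_skipped += 1
                continue
            if not fit.converged or fit.photons <= 0:
                n_skipped += 1
                continue
            sx_nm, sy_nm = fit.sigma_x * px, fit.sigma_y * px
            z_nm, z_ok = assign_z(sx_nm, sy_nm, calibration)
            recs.append((
                (c - half + fit.x) * px, (r - half + fit.y) * px, z_nm,
                fidx, fit.photons, fit.background, sx_nm, sy_nm, z_ok,
            ))
    if n_skipped:
        logger.info("localize_movie: skipped %d candidate(s)", n_skipped)
    if not recs:
        return localization_table([], [], [], [], frames_per_stack=geo.frames_per_stack)
    a = np.array([r[:8] for r in recs], float)
    return localization_table(
        a[:, 0], a[:, 1], a[:, 2], a[:, 3].astype(int),
        photons=a[:, 4], background=a[:, 5], sigma_x=a[:, 6], sigma_y=a[:, 7],
        frames_per_stack=geo.frames_per_stack,
        z_valid=np.array([r[8] for r in recs], bool),
    )


def filter_localizations(
    table: LocalizationTable,
    min_photons: float = 500.0,
    axial_halfwidth: float = 700.0,
) -> tuple[LocalizationTable, int]:
    """Apply the photon and axial-range filters to an acquisition-frame table.

    Keeps rows with photons ≥ ``min_photons`` and |z| ≤ ``axial_halfwidth``
    (the half-range illuminated by the light sheet).  Rows whose z assignment
    was flagged invalid (``z_valid`` column) are also discarded.  Returns the
    filtered table together with the number of discarded rows, so input =
    output + discarded always holds.
    """
    if table.frame_kind != "acquisition":
        raise ValueError("filter_localizations expects an acquisition-frame table")
    d = table.data
    keep = (d["photons"] >= min_photons) & (np.abs(d["z"]) <= axial_halfwidth)
    if "z_valid" in d.columns:
        keep &= d["z_valid"].astype(bool)
    n_discarded = int((~keep).sum())
    if n_discarded:
        logger.info("filter_localizations: discarded %d of %d rows", n_discarded, len(d))
    return LocalizationTable(d[keep].reset_index(drop=True), table.frame_kind), n_discarded
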