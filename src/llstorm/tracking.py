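"""Single-particle tracking: trajectory linking and per-dimension
ensemble-MSD diffusion analysis.

Per-frame 3D localizations are linked frame-to-frame by minimizing the total
squared displacement over candidate pairs within a search radius (the
Crocker–Grier objective, solved exactly per frame pair with the Hungarian
algorithm), with gap closing up to a configurable memory.  Diffusion
constants are estimated per dimension r ∈ {x, y, z} by an ordinary
least-squares fit of the ensemble mean square displacement at small lags::

    ⟨Δr²⟩(τ) = o + 2 D τ

where the offset o reflects the squared static localization error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config_io import LocalizationTable

logger = logging.getLogger("llstorm")

_FORBIDDEN = 1e12  # finite stand-in for a disallowed assignment (nm²)


@dataclass
class Trajectory:
    """One linked track: strictly increasing frames, positions in nm."""

    id: int
    frames: np.ndarray      # (n,) int
    t: np.ndarray           # (n,) s
    xyz: np.ndarray         # (n, 3) nm


@dataclass
class MSDResult:
    """Ensemble MSD per dimension with per-lag pair counts."""

    lag_frames: np.ndarray  # (L,) int
    tau: np.ndarray         # (L,) s, strictly increasing
    msd: np.ndarray         # (L, 3) nm²
    counts: np.ndarray      # (L,) pairs contributing per lag


@dataclass
class DiffusionFit:
    """Per-dimension linear MSD fit: D in µm²/s, offset in nm²."""

    D: np.ndarray           # (3,) µm²/s
    offset: np.ndarray      # (3,) nm²
    se_D: np.ndarray        # (3,) µm²/s
    se_offset: np.ndarray   # (3,) nm²
    n_fit_points: int


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_localizations(
    table: LocalizationTable,
    max_disp: float,
    memory: int = 0,
    dt: float | None = None,
) -> list[Trajectory]:
    """Link a localization table into trajectories.

    Frame-to-frame assignments minimize the total squared displacement among
    candidate pairs within ``max_disp`` nm (each unlinked end costs
    max_disp²); unmatched localizations start or end tracks, and a track may
    survive up to ``memory`` missed frames.  ``dt`` (s per frame) fills the
    trajectory time axis; default 1 s/frame.  Singleton tracks are returned
    too so no localization is silently dropped.
    """
    dt = 1.0 if dt is None else float(dt)
    d = table.data.sort_values("frame", kind="stable")
    frames = d["frame"].to_numpy(int)
    pos = d[["x", "y", "z"]].to_numpy(float)
    penalty = float(max_disp) ** 2

    active: list[dict] = []
    done: list[dict] = []
    for f in np.unique(frames):
        pts = pos[frames == f]
        frs = np.full(len(pts), f)
        still, cand = [], []
        for tr in active:
            (cand if f - tr["frames"][-1] <= memory + 1 else done).append(tr)
        active = cand
        n, m = len(cand), len(pts)
        new_idx = list(range(m))
        if n and m:
            last = np.array([tr["xyz"][-1] for tr in cand])
            d2 = cdist(last, pts, "sqeuclidean")
            cost = np.full((n + m, m + n), _FORBIDDEN)
            cost[:n, :m] = np.where(d2 <= penalty, d2, _FORBIDDEN)
            cost[:n, m:] = _FORBIDDEN
            cost[np.arange(n), m + np.arange(n)] = penalty
            cost[n:, :m] = _FORBIDDEN
            cost[n + np.arange(m), np.arange(m)] = penalty
            cost[n:, m:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            new_idx = []
            linked = set()
            for i, j in zip(rows, cols):
                if i < n and j < m and cost[i, j] < penalty:
                    cand[i]["frames"].append(f)
                    cand[i]["xyz"].append(pts[j])
                    linked.add(j)
            new_idx = [j for j in range(m) if j not in linked]
        for j in new_idx:
            active.append({"frames": [f], "xyz": [pts[j]]})
    done.extend(active)
    out = []
    for tid, tr in enumerate(done):
        fr = np.asarray(tr["frames"], int)
        out.append(Trajectory(tid, fr, fr * dt, np.asarray(tr["xyz"], float)))
    return out


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def compute_msd(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged per-dimension MSD of one trajectory.

    For lag k, averages (r_{i+k} − r_i)² over all ordered sample pairs
    separated by exactly k frames (overlapping pairs included).  Returns
    (lag_frames, msd (L, 3) in nm², counts); lags with no pairs are absent.
    """
    f, P = traj.frames, traj.xyz
    if len(f) < 2:
        raise ValueError("trajectory needs >= 2 samples")
    lags, msds, counts = [], [], []
    for k in range(1, int(f[-1] - f[0]) + 1):
        j = np.searchsorted(f, f + k)
        ok = (j < len(f))
        ok[ok] &= f[j[ok]] == f[np.flatnonzero(ok)] + k
        if not ok.any():
            continue
        disp = P[j[ok]] - P[ok]
        lags.append(k)
        msds.append((disp**2).mean(axis=0))
        counts.append(int(ok.sum()))
    return np.asarray(lags, int), np.asarray(msds, float), np.asarray(counts, int)


def ensemble_msd(
    trajectories: list[Trajectory],
    min_track_len: int = 20,
    dt: float = 1.0,
) -> MSDResult:
    """Ensemble MSD over all tracks with at least ``min_track_len`` samples.

    The ensemble value at each lag is the pair-count-weighted mean of the
    per-track time-averaged MSDs (equivalently, the mean over all pairs of
    all qualifying tracks).  ``dt`` converts lag frames to lag time.
    """
    qual = [tr for tr in trajectories if len(tr.frames) >= min_track_len]
    if not qual:
        raise ValueError(f"no tracks with >= {min_track_len} samples")
    acc: dict[int, np.ndarray] = {}
    cnt: dict[int, int] = {}
    for tr in qual:
        lags, msd, counts = compute_msd(tr)
        for k, m, c in zip(lags, msd, counts):
            acc[k] = acc.get(k, 0.0) + m * c
            cnt[k] = cnt.get(k, 0) + c
    lags = np.array(sorted(acc), int)
    msd = np.array([acc[k] / cnt[k] for k in lags])
    counts = np.array([cnt[k] for k in lags], int)
    return MSDResult(lags, lags * dt, msd, counts)


def fit_diffusion(
    msd: MSDResult,
    n_fit_points: int = 5,
    weights: str | None = None,
) -> DiffusionFit:
    """Fit ⟨Δr²⟩(τ) = o + 2Dτ on the first ``n_fit_points`` lags per dimension.

    The fit is unweighted ordinary least squares by default (the small-lag
    points are the most reliable); ``weights="counts"`` enables a pair-count
    weighted variant.  D is returned in µm²/s, the offset in nm².  A negative
    offset on noisy data is reported as-is with a warning, not clamped.
    """
    if n_fit_points < 2:
        raise ValueError("n_fit_points must be >= 2")
    if len(msd.tau) < n_fit_points:
        raise ValueError(
            f"need >= {n_fit_points} lag points, got {len(msd.tau)}"
        )
    tau = msd.tau[:n_fit_points]
    w = msd.counts[:n_fit_points].astype(float) if weights == "counts" else np.ones(n_fit_points)
    D = np.empty(3)
    off = np.empty(3)
    se_D = np.full(3, np.nan)
    se_off = np.full(3, np.nan)
    sw = w.sum()
    tbar = (w * tau).sum() / sw
    sxx = (w * (tau - tbar) ** 2).sum()
    for r in range(3):
        y = msd.msd[:n_fit_points, r]
        ybar = (w * y).sum() / sw
        slope = (w * (tau - tbar) * (y - ybar)).sum() / sxx  # nm²/s
        intercept = ybar - slope * tbar
        D[r] = 0.5 * slope * 1e-6
        off[r] = intercept
        dof = n_fit_points - 2
        if dof > 0:
            resid = y - (intercept + slope * tau)
            s2 = (w * resid**2).sum() / dof
            se_D[r] = 0.5 * np.sqrt(s2 / sxx) * 1e-6
            se_off[r] = np.sqrt(s2 * (1.0 / sw + tbar**2 / sxx))
    if (off < 0).any():
        logger.warning("fit_diffusion: negative MSD offset fitted (noisy data)")
    return DiffusionFit(D, off, se_D, se_off, n_fit_points)
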