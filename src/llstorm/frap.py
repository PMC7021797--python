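"""FRAP trace normalization and recovery fitting.

Fluorescence recovery after photobleaching traces (default: one frame every
1.5 s for 120 s, bleach after three pre-bleach images) are normalized to the
background-subtracted pre-bleach mean and fitted with a single-exponential
recovery model::

    I(t) = I₀ + MF · (1 − I₀) · (1 − exp(−(t − t_bleach)/τ))

where I₀ is the post-bleach floor, MF the mobile fraction and τ the recovery
time constant.  The single-exponential model is the package's choice of the
simplest recovery law characterized by (τ, MF); diffusion-equation FRAP
models are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("llstorm")


@dataclass
class FrapTrace:
    """A normalized FRAP intensity trace.

    The bleach step sits between frames ``bleach_index − 1`` and
    ``bleach_index`` (so ``bleach_index == n_prebleach``); the normalized
    pre-bleach mean is exactly 1.
    """

    t: np.ndarray            # (n,) s, strictly increasing
    raw: np.ndarray          # (n,) arbitrary units
    background: float
    normalized: np.ndarray   # (n,)
    bleach_index: int
    n_prebleach: int


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters."""

    tau: float               # s
    mobile_fraction: float   # clipped into [0, 1] with a warning
    i0: float                # post-bleach floor (normalized units)
    residual_norm: float
    converged: bool


def normalize_trace(
    raw,
    background: float = 0.0,
    n_prebleach: int = 3,
    frame_interval: float = 1.5,
    t=None,
) -> FrapTrace:
    """Normalize a raw FRAP trace to its background-subtracted pre-bleach mean.

    I_norm(t) = (raw − background) / mean(prebleach − background); adding the
    same constant to raw and background leaves the result unchanged.  Times
    default to a uniform grid at ``frame_interval``.
    """
    raw = np.asarray(raw, float)
    if raw.ndim != 1 or len(raw) < n_prebleach + 2:
        raise ValueError(f"need >= n_prebleach + 2 = {n_prebleach + 2} frames")
    t = frame_interval * np.arange(len(raw)) if t is None else np.asarray(t, float)
    if len(t) != len(raw) or (np.diff(t) <= 0).any():
        raise ValueError("times must match the trace and be strictly increasing")
    pre = raw[:n_prebleach].mean() - background
    if pre <= 0:
        raise ValueError("pre-bleach mean does not exceed the background")
    return FrapTrace(
        t=t, raw=raw, background=float(background),
        normalized=(raw - background) / pre,
        bleach_index=n_prebleach, n_prebleach=n_prebleach,
    )


def recovery_model(t, tau, mobile_fraction, i0, t_bleach=0.0):
    """Single-exponential recovery curve on post-bleach times."""
    return i0 + mobile_fraction * (1.0 - i0) * (1.0 - np.exp(-(t - t_bleach) / tau))


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares fit of the recovery model to the post-bleach trace.

    Requires ≥ 5 post-bleach points.  Non-convergence is flagged, not raised;
    a mobile fraction fitting outside [0, 1] is clipped with a warning.
    """
    tb = trace.bleach_index
    t_post = trace.t[tb:]
    y_post = trace.normalized[tb:]
    if len(t_post) < 5:
        raise ValueError("need >= 5 post-bleach points")
    t_bleach = trace.t[tb]
    i0_init = float(y_post[0])
    plateau = float(np.mean(y_post[-max(3, len(y_post) // 5):]))
    mf_init = (plateau - i0_init) / (1.0 - i0_init) if i0_init < 0.999 else 1.0
    mf_init = float(np.clip(mf_init, 0.0, 1.0)) if np.isfinite(mf_init) else 1.0
    span = t_post[-1] - t_post[0]
    converged = True
    try:
        popt, _ = curve_fit(
            lambda t, tau, mf, i0: recovery_model(t, tau, mf, i0, t_bleach),
            t_post, y_post,
            p0=[max(span / 8.0, 1e-3), mf_init, min(i0_init, 0.999)],
            bounds=([1e-6, 0.0, -0.5], [np.inf, 1.5, 1.0]),
            maxfev=10000,
        )
        tau, mf, i0 = popt
    except RuntimeError:
        logger.warning("fit_recovery: optimizer did not converge")
        tau, mf, i0 = max(span / 8.0, 1e-3), mf_init, i0_init
        converged = False
    if mf > 1.0:
        logger.warning("fit_recovery: mobile fraction %.3f > 1 clipped to 1", mf)
        mf = 1.0
    resid = y_post - recovery_model(t_post, tau, mf, i0, t_bleach)
    return FrapFit(
        tau=float(tau), mobile_fraction=float(mf), i0=float(i0),
        residual_norm=float(np.sqrt(np.mean(resid**2))), converged=converged,
    )
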