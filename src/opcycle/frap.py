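"""Normalization and exponential fitting of FRAP and FLIP traces.

FRAP: a short bleach pulse in a nuclear spot; recovery of spot fluorescence
reports the freely diffusing (mobile) fraction of the tagged histone and
its exchange half-time T1/2 = ln2 / k.  FLIP: continuous bleaching of one
spot; loss of fluorescence in a distal region reports the same mobile pool
from the other direction.

Normalization follows the double + full-scale scheme standard in FRAP
analysis tools: background subtraction, division by a reference region
(cancelling shared acquisition bleaching), scaling so the pre-bleach mean
is 1, then full-scale rescaling so the first post-bleach frame is 0 and a
complete recovery reaches 1.  After full-scale normalization the fitted
plateau of ``A (1 - exp(-k t))`` *is* the mobile fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "FrapResult",
    "DegenerateReferenceError",
    "NoBleachError",
    "normalize_frap",
    "fit_recovery",
    "analyze_frap",
    "analyze_flip",
    "detect_bleach_index",
]

MIN_POSTBLEACH_FRAMES = 5


class DegenerateReferenceError(ValueError):
    """Reference ROI does not exceed background everywhere."""


class NoBleachError(ValueError):
    """First post-bleach value is not below the pre-bleach mean."""


@dataclass(frozen=True)
class FrapTrace:
    """Raw photobleaching series.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    before it are pre-bleach.  ``roi`` is the bleached (FRAP) or distal
    (FLIP) region, ``reference`` an unbleached nuclear region, and
    ``background`` a non-nuclear region, all in arbitrary fluorescence
    units on a common time base ``t`` (seconds).
    """

    t: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.roi) == len(self.reference) == len(self.background) == n):
            raise ValueError("trace columns must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 3 <= self.bleach_index <= n - MIN_POSTBLEACH_FRAMES:
            raise ValueError(
                "need >= 3 pre-bleach and >= "
                f"{MIN_POSTBLEACH_FRAMES} post-bleach frames"
            )

    @property
    def t_post(self) -> np.ndarray:
        """Time since the first post-bleach frame (seconds)."""
        return self.t[self.bleach_index :] - self.t[self.bleach_index]


@dataclass(frozen=True)
class FrapResult:
    """Fitted mobile fraction and exchange kinetics."""

    mobile_fraction: float
    t_half: float
    rate_k: float
    r_squared: float
    converged: bool
    k_identifiable: bool = True

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction

    @property
    def mobile_fraction_clipped(self) -> float:
        """Mobile fraction clipped into [0, 1] for reporting."""
        return min(max(self.mobile_fraction, 0.0), 1.0)


def detect_bleach_index(roi: np.ndarray, window: int = 5) -> int:
    """Locate the first post-bleach frame from the ROI series.

    Uses a windowed step statistic — the drop between the mean of the
    ``window`` frames before a candidate frame and the ``window`` frames
    from it on — which finds both the abrupt FRAP drop and the onset of
    the gradual FLIP decay in the presence of frame noise.
    """
    roi = np.asarray(roi, dtype=float)
    n = len(roi)
    diffs = np.diff(roi)
    # Abrupt (FRAP-style) bleach: one drop far above the frame-to-frame
    # noise floor, located exactly.
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    i_drop = int(np.argmin(diffs)) + 1
    if -diffs[i_drop - 1] > 8 * (mad + 1e-12) and 3 <= i_drop <= n - MIN_POSTBLEACH_FRAMES:
        return i_drop
    # Gradual (FLIP-style) onset: first frame where the windowed step
    # (mean of the window before minus mean of the window after) reaches
    # half its eventual peak.
    w = max(1, min(window, n // 4))
    lo, hi = max(3, w), n - max(MIN_POSTBLEACH_FRAMES, w) + 1
    steps = np.array(
        [roi[i - w : i].mean() - roi[i : i + w].mean() for i in range(lo, hi)]
    )
    return lo + int(np.argmax(steps >= steps.max() / 2))


def normalize_frap(trace: FrapTrace) -> np.ndarray:
    """Double + full-scale normalization of a FRAP trace.

    Returns the full series (pre- and post-bleach) on the full-scale
    axis: the first post-bleach frame maps to 0 and complete recovery to
    the pre-bleach level maps to 1.  Multiplying both ROI and reference by
    a shared decay (acquisition bleaching) leaves the output unchanged.
    """
    ref = trace.reference - trace.background
    if np.any(ref <= 0):
        raise DegenerateReferenceError("reference <= background somewhere")
    ratio = (trace.roi - trace.background) / ref
    pre_mean = ratio[: trace.bleach_index].mean()
    if pre_mean <= 0:
        raise DegenerateReferenceError("non-positive pre-bleach signal")
    double = ratio / pre_mean
    first_post = double[trace.bleach_index]
    if first_post >= 1.0:
        raise NoBleachError("first post-bleach value is not below pre-bleach mean")
    return (double - first_post) / (1.0 - first_post)


def _recovery(t: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * (1.0 - np.exp(-k * t))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_recovery(normalized: np.ndarray, t: np.ndarray) -> FrapResult:
    """Fit ``A (1 - exp(-k t))`` to a post-bleach recovery series.

    ``normalized`` and ``t`` are the post-bleach samples on the full-scale
    axis with ``t`` starting at 0.  The plateau ``A`` is the mobile
    fraction; ``t_half = ln2 / k``.  Non-convergence is flagged in the
    result, never raised.
    """
    y = np.asarray(normalized, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(y) < MIN_POSTBLEACH_FRAMES:
        raise ValueError(f"need >= {MIN_POSTBLEACH_FRAMES} post-bleach frames")

    # Plateau guess from the last decile; rate guess from the half-rise time.
    n_tail = max(1, len(y) // 10)
    a0 = float(np.mean(y[-n_tail:]))
    if a0 <= 1e-6:
        # Flat series: no recovery, rate not identifiable.
        return FrapResult(
            mobile_fraction=max(a0, 0.0),
            t_half=math.inf,
            rate_k=0.0,
            r_squared=_r_squared(y, np.full_like(y, a0)),
            converged=True,
            k_identifiable=False,
        )
    above = np.nonzero(y >= a0 / 2)[0]
    t_half0 = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2) / t_half0

    # Multi-start over the rate guess: noisy traces have a shallow
    # degenerate minimum at (A -> bound, k -> 0) that a single start can
    # fall into.  Keep the start with the lowest residual sum of squares.
    best: tuple[float, float, float] | None = None
    for k_start in (k0, k0 / 10, k0 * 10):
        try:
            popt, _ = curve_fit(
                _recovery,
                t,
                y,
                p0=[min(max(a0, 1e-3), 1.2), k_start],
                bounds=([0.0, 1e-12], [1.2, np.inf]),
                maxfev=10000,
                xtol=1e-10,
                ftol=1e-10,
            )
            ssr = float(np.sum((y - _recovery(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, float(popt[0]), float(popt[1]))
        except RuntimeError:
            continue
    if best is not None:
        _, a, k = best
        converged = True
    else:
        a, k, converged = a0, k0, False

    return FrapResult(
        mobile_fraction=a,
        t_half=math.log(2) / k if k > 0 else math.inf,
        rate_k=k,
        r_squared=_r_squared(y, _recovery(t, a, k)),
        converged=converged,
    )


def _double_normalize(trace: FrapTrace) -> np.ndarray:
    ref = trace.reference - trace.background
    if np.any(ref <= 0):
        raise DegenerateReferenceError("reference <= background somewhere")
    ratio = (trace.roi - trace.background) / ref
    pre_mean = ratio[: trace.bleach_index].mean()
    if pre_mean <= 0:
        raise DegenerateReferenceError("non-positive pre-bleach signal")
    return ratio / pre_mean


def _floor_recovery(t: np.ndarray, b: float, f: float, k: float) -> np.ndarray:
    return b + (1.0 - b) * f * (1.0 - np.exp(-k * t))


def analyze_frap(trace: FrapTrace) -> FrapResult:
    """Normalize a FRAP trace and fit its post-bleach recovery.

    The bleach floor is fitted jointly with the mobile fraction and rate
    on the double-normalized series, ``b + (1-b) F (1 - exp(-k t))``,
    rather than read off the single (noisy) first post-bleach frame; on a
    noise-free trace this is identical to full-scale normalization
    followed by :func:`fit_recovery`.
    """
    norm = _double_normalize(trace)
    first_post = norm[trace.bleach_index]
    if first_post >= 1.0:
        raise NoBleachError("first post-bleach value is not below pre-bleach mean")
    y = norm[trace.bleach_index :]
    t = trace.t_post
    if len(y) < MIN_POSTBLEACH_FRAMES:
        raise ValueError(f"need >= {MIN_POSTBLEACH_FRAMES} post-bleach frames")

    b0 = float(np.clip(first_post, 0.0, 0.95))
    n_tail = max(1, len(y) // 10)
    tail = float(np.mean(y[-n_tail:]))
    f0 = float(np.clip((tail - b0) / max(1.0 - b0, 1e-6), 1e-3, 1.0))
    if tail - b0 <= 1e-6 and np.ptp(y) < 1e-9:
        return FrapResult(
            mobile_fraction=0.0,
            t_half=math.inf,
            rate_k=0.0,
            r_squared=1.0,
            converged=True,
            k_identifiable=False,
        )
    half_level = b0 + (tail - b0) / 2
    above = np.nonzero(y >= half_level)[0]
    t_half0 = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2) / t_half0

    best: tuple[float, float, float, float] | None = None
    for k_start in (k0, k0 / 10, k0 * 10):
        try:
            popt, _ = curve_fit(
                _floor_recovery,
                t,
                y,
                p0=[b0, f0, k_start],
                bounds=([0.0, 0.0, 1e-12], [0.999, 1.2, np.inf]),
                maxfev=10000,
                xtol=1e-10,
                ftol=1e-10,
            )
            ssr = float(np.sum((y - _floor_recovery(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, *(float(v) for v in popt))
        except RuntimeError:
            continue
    if best is None:
        return FrapResult(
            mobile_fraction=f0, t_half=math.log(2) / k0, rate_k=k0,
            r_squared=_r_squared(y, _floor_recovery(t, b0, f0, k0)),
            converged=False,
        )
    _, b, f, k = best
    return FrapResult(
        mobile_fraction=f,
        t_half=math.log(2) / k if k > 0 else math.inf,
        rate_k=k,
        r_squared=_r_squared(y, _floor_recovery(t, b, f, k)),
        converged=True,
        k_identifiable=k > 0,
    )


def _flip_decay(t: np.ndarray, immobile: float, mobile: float, k: float) -> np.ndarray:
    return immobile + mobile * np.exp(-k * t)


def analyze_flip(trace: FrapTrace) -> FrapResult:
    """Fit the distal-ROI decay of a FLIP experiment.

    Normalization is background subtraction, reference division and
    pre-bleach scaling only (no full-scale step: the distal signal starts
    at the pre-bleach level and decays).  The fitted model is
    ``immobile + mobile * exp(-k t)``; a large mobile amplitude means
    rapid nucleus-wide fluorescence loss.
    """
    ref = trace.reference - trace.background
    if np.any(ref <= 0):
        raise DegenerateReferenceError("reference <= background somewhere")
    ratio = (trace.roi - trace.background) / ref
    pre_mean = ratio[: trace.bleach_index].mean()
    if pre_mean <= 0:
        raise DegenerateReferenceError("non-positive pre-bleach signal")
    y = ratio[trace.bleach_index :] / pre_mean
    t = trace.t_post
    if len(y) < MIN_POSTBLEACH_FRAMES:
        raise ValueError(f"need >= {MIN_POSTBLEACH_FRAMES} post-bleach frames")

    mobile0 = float(np.clip(y[0] - np.mean(y[-max(1, len(y) // 10) :]), 1e-3, 1.0))
    if mobile0 <= 2e-3 and np.ptp(y) < 1e-9:
        # Flat trace: nothing bleaches out of the distal region.
        return FrapResult(
            mobile_fraction=0.0,
            t_half=math.inf,
            rate_k=0.0,
            r_squared=1.0,
            converged=True,
            k_identifiable=False,
        )
    drop_half = y[0] - mobile0 / 2
    below = np.nonzero(y <= drop_half)[0]
    t_half0 = t[below[0]] if len(below) and t[below[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2) / t_half0

    try:
        popt, _ = curve_fit(
            _flip_decay,
            t,
            y,
            p0=[float(np.clip(y[-1], 0, 1.2)), mobile0, k0],
            bounds=([0.0, 0.0, 1e-12], [1.2, 1.2, np.inf]),
            maxfev=10000,
            xtol=1e-10,
            ftol=1e-10,
        )
        immobile, mobile, k = (float(v) for v in popt)
        converged = True
    except RuntimeError:
        immobile, mobile, k, converged = float(y[-1]), mobile0, k0, False

    return FrapResult(
        mobile_fraction=mobile,
        t_half=math.log(2) / k if k > 0 else math.inf,
        rate_k=k,
        r_squared=_r_squared(y, _flip_decay(t, immobile, mobile, k)),
        converged=converged,
    )
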