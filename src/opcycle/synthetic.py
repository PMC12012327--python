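"""Seeded generators for every input the inference modules consume.

The population simulator realizes the steady-state assumption behind
cumulative-labeling inference: an asynchronous cohort in which each cycling
cell's position is uniform on its cycle, a fraction ``1 - g`` per
subpopulation is quiescent, and on division exactly one daughter is
retained so the counted population stays stationary (a modelling
assumption, not biology — it is what makes the linear labeling-index model
exact).  Photobleaching traces and motif-annotated peak universes are
generated from closed forms with planted ground truths, so every estimator
in the package can be checked against known parameters.

All generators take an integer seed; stochastic helpers derive child seeds
deterministically from it via ``child_seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cellcycle import LabelingCurvePoint, PopulationSpec, PulseChaseObservation
from .frap import FrapTrace

__all__ = [
    "CellState",
    "FrapSimParams",
    "PeakUniverseParams",
    "child_seed",
    "simulate_cohort",
    "run_cumulative_edu",
    "run_pulse_chase",
    "generate_frap_trace",
    "generate_flip_trace",
    "frap_ideal_recovery",
    "flip_ideal_decay",
    "generate_peak_universe",
]


def child_seed(seed: int, tag: str) -> int:
    """Deterministic child seed (< 2^31) for a named stochastic step."""
    return (int(seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class CellState:
    """One simulated cell: cycling or quiescent, with a cycle position."""

    cycling: bool
    cycle_position: float | None
    edu_positive: bool
    subpopulation_index: int

    def __post_init__(self) -> None:
        if self.cycling and self.cycle_position is None:
            raise ValueError("cycling cells need a cycle_position")
        if not self.cycling and self.cycle_position is not None:
            raise ValueError("quiescent cells have no cycle_position")


def simulate_cohort(spec: PopulationSpec, n_cells: int, seed: int) -> list[CellState]:
    """Draw an asynchronous steady-state cohort.

    Each cell is assigned a subpopulation by weight, is quiescent with
    probability ``1 - g`` of its subpopulation, and if cycling gets a
    cycle position uniform on ``[0, t_c)``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    rng = np.random.default_rng(seed)
    weights = np.array([s.weight for s in spec.subpopulations])
    sub_idx = rng.choice(len(weights), size=n_cells, p=weights)
    u_cycle = rng.random(n_cells)
    u_pos = rng.random(n_cells)
    cells: list[CellState] = []
    for i in range(n_cells):
        sub = spec.subpopulations[sub_idx[i]]
        cycling = u_cycle[i] < sub.growth_fraction
        pos = float(u_pos[i] * sub.phases.t_c) if cycling else None
        cells.append(
            CellState(
                cycling=cycling,
                cycle_position=pos,
                edu_positive=False,
                subpopulation_index=int(sub_idx[i]),
            )
        )
    return cells


def _time_to_s_entry(position: float, s_start: float, t_s: float, t_c: float) -> float:
    """Hours until the cell next enters (or is already inside) S-phase."""
    if s_start <= position < s_start + t_s:
        return 0.0
    return (s_start - position) % t_c


def _passes_through_s(
    position: float, duration: float, s_start: float, t_s: float, t_c: float
) -> bool:
    """Does the trajectory over ``duration`` hours intersect S-phase?"""
    return _time_to_s_entry(position, s_start, t_s, t_c) <= duration


def run_cumulative_edu(
    cohort: Sequence[CellState],
    spec: PopulationSpec,
    times: Sequence[float],
    pulse_window: float | None = None,
    seed: int | None = None,
) -> list[LabelingCurvePoint]:
    """Score the cohort under continuous label availability.

    The label is available from time 0 up to ``min(t, pulse_window)`` for
    each requested sampling time ``t`` (``pulse_window=None`` means the
    label stays available throughout, the cumulative protocol).  A cell is
    scored label-positive at ``t`` if any part of its trajectory during
    label availability lies in S-phase.  Division re-enters the cell at
    position 0 with label retained, so the counted population is constant
    across ``times``.

    Labeling is deterministic given the cohort: all sampling noise comes
    from the randomness of cohort positions.
    """
    if len(times) == 0:
        raise ValueError("times must be nonempty")
    if any(t < 0 for t in times):
        raise ValueError("times must be >= 0")
    points = []
    for t in times:
        avail = t if pulse_window is None else min(t, pulse_window)
        n_labeled = 0
        for cell in cohort:
            if not cell.cycling:
                continue
            ph = spec.subpopulations[cell.subpopulation_index].phases
            if _passes_through_s(cell.cycle_position, avail, ph.s_start, ph.t_s, ph.t_c):
                n_labeled += 1
        points.append(LabelingCurvePoint(t=float(t), n_total=len(cohort), n_labeled=n_labeled))
    return points


def run_pulse_chase(
    cohort: Sequence[CellState],
    spec: PopulationSpec,
    t_chase: float,
    pulse_window: float = 0.0,
    seed: int | None = None,
) -> PulseChaseObservation:
    """Pulse-chase protocol: label S-phase cells, chase, score mitoses.

    Cells in S-phase at any point during ``[0, pulse_window]`` become
    label-positive (``pulse_window=0`` is an instantaneous pulse).  Every
    cell then advances by ``t_chase`` hours; a cell is pH3+ iff its
    position at that moment lies in M-phase.  Returns counts among the
    label-positive cells.
    """
    if t_chase <= 0:
        raise ValueError("t_chase must be > 0")
    n_edu = 0
    n_edu_ph3 = 0
    for cell in cohort:
        if not cell.cycling:
            continue
        ph = spec.subpopulations[cell.subpopulation_index].phases
        if not _passes_through_s(cell.cycle_position, pulse_window, ph.s_start, ph.t_s, ph.t_c):
            continue
        n_edu += 1
        pos = (cell.cycle_position + t_chase) % ph.t_c
        if ph.m_start <= pos < ph.t_c and ph.t_m > 0:
            n_edu_ph3 += 1
    return PulseChaseObservation(t_chase=t_chase, n_edu=n_edu, n_edu_ph3=n_edu_ph3)


@dataclass(frozen=True)
class FrapSimParams:
    """Ground-truth parameters of a simulated photobleaching experiment.

    ``mobile_fraction`` is the freely exchanging pool, ``rate_k`` its
    exchange rate (per second), ``bleach_depth`` the ROI intensity
    immediately after the bleach relative to pre-bleach,
    ``acquisition_bleach_rate`` a slow shared decay of all fluorescence
    from imaging itself, and ``noise_sd`` the additive Gaussian noise as a
    fraction of pre-bleach intensity.
    """

    mobile_fraction: float = 0.5
    rate_k: float = 0.1
    bleach_depth: float = 0.3
    acquisition_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    n_prebleach: int = 10
    n_postbleach: int = 124
    frame_interval: float = 0.5
    background_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not 0.0 < self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must lie in (0, 1)")
        for name in ("rate_k", "acquisition_bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_prebleach < 3 or self.n_postbleach < 5:
            raise ValueError("need >= 3 pre-bleach and >= 5 post-bleach frames")


def frap_ideal_recovery(params: FrapSimParams, t_post: np.ndarray) -> np.ndarray:
    """Noise-free ROI recovery (relative to pre-bleach, no acquisition decay)."""
    b = params.bleach_depth
    return b + params.mobile_fraction * (1.0 - b) * (
        1.0 - np.exp(-params.rate_k * np.asarray(t_post, dtype=float))
    )


def flip_ideal_decay(params: FrapSimParams, t_post: np.ndarray) -> np.ndarray:
    """Noise-free distal-ROI decay under continuous bleaching."""
    mf = params.mobile_fraction
    return (1.0 - mf) + mf * np.exp(-params.rate_k * np.asarray(t_post, dtype=float))


def _assemble_trace(
    params: FrapSimParams, roi_ideal: np.ndarray, t: np.ndarray, seed: int
) -> FrapTrace:
    rng = np.random.default_rng(seed)
    decay = np.exp(-params.acquisition_bleach_rate * t)
    bg = params.background_level
    roi = bg + roi_ideal * decay
    reference = bg + 1.0 * decay
    background = np.full_like(t, bg)
    if params.noise_sd > 0:
        # The bleach ROI is a small region; reference and background ROIs
        # average many more pixels, so their relative noise is much lower.
        roi = roi + rng.normal(0, params.noise_sd, len(t))
        reference = reference + rng.normal(0, params.noise_sd / 4, len(t))
        background = background + rng.normal(0, params.noise_sd / 4, len(t))
    return FrapTrace(
        t=t,
        roi=roi,
        reference=reference,
        background=background,
        bleach_index=params.n_prebleach,
    )


def _frame_times(params: FrapSimParams) -> np.ndarray:
    n = params.n_prebleach + params.n_postbleach
    return np.arange(n) * params.frame_interval


def generate_frap_trace(params: FrapSimParams, seed: int) -> FrapTrace:
    """Simulate a FRAP trace with a planted mobile fraction and rate.

    Pre-bleach frames sit at the full pre-bleach intensity; the bleach
    drops the ROI instantaneously to ``bleach_depth``, and recovery
    approaches ``bleach_depth + mobile_fraction * (1 - bleach_depth)``
    with rate ``rate_k``.  ROI and reference share the acquisition-bleach
    decay, so double normalization cancels it exactly.
    """
    t = _frame_times(params)
    t_post = t[params.n_prebleach :] - t[params.n_prebleach]
    ideal = np.concatenate(
        [np.ones(params.n_prebleach), frap_ideal_recovery(params, t_post)]
    )
    return _assemble_trace(params, ideal, t, seed)


def generate_flip_trace(params: FrapSimParams, seed: int) -> FrapTrace:
    """Simulate a FLIP distal-ROI trace under continuous spot bleaching.

    The mobile pool exchanges through the bleached spot and is lost with
    rate ``rate_k``; the immobile pool is untouched, so the distal signal
    decays to ``1 - mobile_fraction``.
    """
    t = _frame_times(params)
    t_post = t[params.n_prebleach :] - t[params.n_prebleach]
    ideal = np.concatenate(
        [np.ones(params.n_prebleach), flip_ideal_decay(params, t_post)]
    )
    return _assemble_trace(params, ideal, t, seed)


@dataclass(frozen=True)
class PeakUniverseParams:
    """Planted motif frequencies for a synthetic differential-peak universe."""

    n_foreground: int = 5000
    n_background: int = 5000
    motif_probs_foreground: Mapping[str, float] = field(
        default_factory=lambda: {"CTCF": 0.10, "SOX10": 0.26, "EBOX": 0.30}
    )
    motif_probs_background: Mapping[str, float] = field(
        default_factory=lambda: {"CTCF": 0.01, "SOX10": 0.15, "EBOX": 0.19}
    )
    interval_length: int = 500
    chrom: str = "chr1"
    chrom_size: int = 150_000_000

    def __post_init__(self) -> None:
        if self.n_foreground <= 0 or self.n_background <= 0:
            raise ValueError("peak counts must be > 0")
        if set(self.motif_probs_foreground) != set(self.motif_probs_background):
            raise ValueError("foreground and background must list the same motifs")
        for probs in (self.motif_probs_foreground, self.motif_probs_background):
            for motif, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"motif probability for {motif} not in [0, 1]")

    @property
    def motifs(self) -> list[str]:
        return list(self.motif_probs_foreground)


def _draw_peaks(
    params: PeakUniverseParams,
    n: int,
    probs: Mapping[str, float],
    prefix: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    starts = np.sort(
        rng.integers(0, params.chrom_size - params.interval_length, size=n)
    )
    df = pd.DataFrame(
        {
            "chrom": params.chrom,
            "start": starts,
            "end": starts + params.interval_length,
            "name": [f"{prefix}_{i}" for i in range(n)],
            "score": 0,
            "strand": ".",
        }
    )
    for motif in params.motifs:
        df[motif] = rng.random(n) < probs[motif]
    return df


def generate_peak_universe(
    params: PeakUniverseParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (foreground, background) motif-annotated peak tables.

    BED-style 0-based half-open intervals with one boolean column per
    motif, drawn independently at the planted probabilities.
    """
    rng = np.random.default_rng(seed)
    fg = _draw_peaks(params, params.n_foreground, params.motif_probs_foreground, "fg", rng)
    bg = _draw_peaks(params, params.n_background, params.motif_probs_background, "bg", rng)
    return fg, bg
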