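"""Instrument model and protocol drivers.

``measure_events`` turns a population into a flow-cytometry-like event table
(one event per clump). ``apply_gate`` implements percentile tail gates.
``run_protocol`` drives the twice-daily selection-synchrony schedule and its
unsynchronized and free-run controls; ``run_lineage_protocol`` follows single
founder cells through the microtiter imaging-and-split protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .metrics import OscillationScore, f75_f25
from .oscillator import Population, init_population
from .params import OscillatorParams

__all__ = [
    "GateSpec",
    "ScheduleSpec",
    "ProtocolResult",
    "measure_events",
    "apply_gate",
    "run_protocol",
    "noise_envelope",
    "count_detectable_cycles",
    "run_lineage_protocol",
    "LineageRun",
]

EVENT_COLUMNS = ["event_id", "yfp", "rfp", "pulse_width", "n_cells", "clump_label"]


def _ln_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def measure_events(
    pop: Population,
    seed: Optional[int] = None,
    n_events: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Measure one FACS event per clump.

    yfp = n_cells * yfp_per_cell_mean * noise, rfp analogous, and
    pulse_width = pw_scale * n_cells**pw_exponent * noise; per-cell
    intensity never depends on phase or time. If ``n_events`` is given and
    the population has more clumps, a random subset of clumps is measured
    (the stream an instrument sees in a fixed acquisition window).
    """
    if pop.n_cells == 0:
        raise ValueError("cannot measure an empty population")
    if rng is None:
        rng = pop.rng if seed is None else np.random.default_rng(seed)
    p = pop.params
    sizes = pop.clump_sizes()
    labels = np.arange(sizes.size)
    if n_events is not None and n_events < labels.size:
        labels = rng.choice(labels, size=n_events, replace=False)
        labels.sort()
    n = sizes[labels].astype(float)
    k = labels.size
    return pd.DataFrame(
        {
            "event_id": np.arange(k),
            "yfp": n * p.yfp_per_cell_mean * _ln_noise(rng, p.intensity_cv, k),
            "rfp": n * p.rfp_per_cell_mean * _ln_noise(rng, p.intensity_cv, k),
            "pulse_width": p.pw_scale
            * n**p.pw_exponent
            * _ln_noise(rng, p.pw_noise_cv, k),
            "n_cells": n.astype(int),
            "clump_label": labels,
        }
    )


@dataclass(frozen=True)
class GateSpec:
    """A percentile tail gate on one channel.

    ``tail="dim"`` keeps the ``ceil(fraction * N)`` lowest-channel events,
    ``"bright"`` the highest, ``"all"`` everything (fraction ignored). Ties
    are broken by event_id so a gate is deterministic.
    """

    channel: str = "yfp"
    tail: str = "dim"
    fraction: float = 0.06

    def __post_init__(self):
        if self.channel not in ("yfp", "rfp", "pulse_width"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.tail not in ("dim", "bright", "all"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.tail != "all" and not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")


def apply_gate(events: pd.DataFrame, gate: GateSpec) -> pd.DataFrame:
    """Select the gated tail of an event table (rows kept in input order)."""
    if len(events) == 0:
        raise ValueError("cannot gate an empty event table")
    if gate.tail == "all":
        return events.copy()
    k = math.ceil(gate.fraction * len(events))
    values = events[gate.channel].to_numpy()
    ids = events["event_id"].to_numpy()
    order = np.lexsort((ids, values))  # ascending channel, ties by event_id
    chosen = order[:k] if gate.tail == "dim" else order[-k:]
    return events.iloc[np.sort(chosen)]


@dataclass(frozen=True)
class ScheduleSpec:
    """Ordered (growth interval, action) slots making up one day.

    The default alternates a 10-hr interval ending in selection of the
    brightest events with a 14-hr interval ending in selection of the
    dimmest; the intervals sum to the 24-hr period.
    """

    steps: Tuple[Tuple[float, str], ...] = (
        (10.0, "select_bright"),
        (14.0, "select_dim"),
    )

    def __post_init__(self):
        known = {"select_dim", "select_bright", "collect_all", "dilute_only"}
        for interval, action in self.steps:
            if interval <= 0:
                raise ValueError("schedule intervals must be positive")
            if action not in known:
                raise ValueError(f"unknown action {action!r}")

    @property
    def day_length(self) -> float:
        return sum(interval for interval, _ in self.steps)


@dataclass
class ProtocolResult:
    """Scores per recorded timepoint, the raw event tables, and snapshots."""

    scores: pd.DataFrame
    event_tables: List[pd.DataFrame] = field(default_factory=list)
    snapshots: List[pd.DataFrame] = field(default_factory=list)


def _select(pop: Population, events: pd.DataFrame, gate: GateSpec) -> None:
    selected = apply_gate(events, gate)
    pop.keep_clumps(selected["clump_label"].to_numpy())


def run_protocol(
    pop: Population,
    schedule: Optional[ScheduleSpec] = None,
    mode: str = "synchronize",
    days: int = 3,
    gate_fraction: float = 0.06,
    seed: Optional[int] = None,
    *,
    free_run_after: int = 3,
    channel: str = "yfp",
    n_events: int = 10_000,
    keep_cells: int = 1_000,
    dt: float = 0.25,
    record_snapshots: bool = False,
    score_log_scale: bool = True,
) -> ProtocolResult:
    """Drive the twice-daily FACS schedule on ``pop`` (mutated in place).

    Modes
    -----
    ``synchronize``
        At each scheduled time, record the event table, gate the scheduled
        tail (dim or bright ``gate_fraction``), keep the selected clumps,
        and regrow.
    ``unsynchronized``
        Identical manipulations and times, but every event passes the sorter
        (collect_all) and the culture is simply diluted.
    ``free_run``
        Synchronize for ``free_run_after`` days, then switch to dilute_only
        at the same times for the remaining days.

    The population is primed with an unrecorded action at time zero (the
    dimmest-tail selection that starts each synchronization cycle, or a plain
    dilution for the unsynchronized control), then the event table is
    recorded immediately before each scheduled action; exactly
    ``len(schedule.steps) * days`` tables are recorded. After every action
    the culture is cut back to ``keep_cells`` cells (whole clumps) so it
    stays in exponential phase.

    With ``score_log_scale`` (default) the F75/F25 score is computed on
    log10-transformed intensity and pulse width — the scale FACS
    distributions are displayed and bounded on — which keeps the min-max
    quartile thresholds from being pinned by a single extreme event. Gating
    is rank-based and unaffected by the choice.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if mode not in ("synchronize", "unsynchronized", "free_run"):
        raise ValueError(f"unknown mode {mode!r}")
    schedule = schedule or ScheduleSpec()
    if seed is not None:
        pop.rng = np.random.default_rng(seed)

    def effective_action(scheduled: str, day: int) -> str:
        if mode == "unsynchronized":
            return "collect_all"
        if mode == "free_run" and day >= free_run_after:
            return "dilute_only"
        return scheduled

    def apply_action(action: str, events: pd.DataFrame) -> None:
        if action in ("select_dim", "select_bright"):
            tail = "dim" if action == "select_dim" else "bright"
            _select(pop, events, GateSpec(channel, tail, gate_fraction))
        # collect_all / dilute_only: every clump passes
        if pop.n_cells > keep_cells:
            pop.dilute_to_count(keep_cells)

    # unrecorded priming action at time zero
    priming = "select_dim" if mode in ("synchronize", "free_run") else "collect_all"
    apply_action(
        effective_action(priming, 0) if mode == "free_run" else priming,
        measure_events(pop, n_events=n_events),
    )

    rows = []
    result = ProtocolResult(scores=pd.DataFrame())
    for day in range(days):
        for interval, scheduled in schedule.steps:
            pop.run(interval, dt=dt)
            events = measure_events(pop, n_events=n_events)
            action = effective_action(scheduled, day)
            try:
                if score_log_scale:
                    score = f75_f25(
                        (np.log10(events["yfp"]), np.log10(events["pulse_width"]))
                    )
                else:
                    score = f75_f25(events)
            except DegenerateInputError:
                score = OscillationScore(0, 0, float("nan"))
            rows.append(
                {
                    "time_hr": pop.time,
                    "day": day,
                    "slot": scheduled,
                    "action": action,
                    "f25": score.f25,
                    "f75": score.f75,
                    "log_ratio": score.log_ratio,
                    "n_events": len(events),
                }
            )
            result.event_tables.append(events)
            if record_snapshots:
                result.snapshots.append(pop.to_frame())
            apply_action(action, events)
    result.scores = pd.DataFrame(rows)
    return result


def daily_amplitudes(scores: pd.DataFrame, after_time: float = 0.0) -> pd.Series:
    """Per-day oscillation amplitude: score before the bright-selection slot
    minus score before the dim-selection slot (positive when the culture is
    clumped at the clump-phase timepoint and dispersed at the other)."""
    rows = scores[scores["time_hr"] > after_time]
    out = {}
    for day, day_rows in rows.groupby("day"):
        bright = day_rows[day_rows["slot"] == "select_bright"]["log_ratio"]
        dim = day_rows[day_rows["slot"] == "select_dim"]["log_ratio"]
        if len(bright) and len(dim):
            out[day] = float(bright.iloc[0] - dim.iloc[0])
    return pd.Series(out, dtype=float)


def noise_envelope(unsynchronized_scores: pd.DataFrame, q: float = 0.95) -> float:
    """Amplitude noise envelope from an unsynchronized control run.

    The control is passaged at the same 10:14-hr times without selection, so
    its daily amplitudes (see :func:`daily_amplitudes`) reflect measurement
    noise plus any systematic slot asymmetry of the protocol. Returns the
    ``q``-quantile of their absolute values: the largest daily swing the
    control produces by chance.
    """
    amp = daily_amplitudes(unsynchronized_scores).to_numpy(float)
    amp = amp[np.isfinite(amp)]
    if amp.size == 0:
        raise DegenerateInputError("no finite daily amplitudes in control run")
    return float(np.quantile(np.abs(amp), q))


def count_detectable_cycles(
    scores: pd.DataFrame,
    envelope: float,
    *,
    after_time: float = 0.0,
) -> int:
    """Count days whose oscillation-score cycle beats the noise envelope.

    A day counts as one detectable cycle when its peak-to-trough amplitude
    (bright-slot score minus dim-slot score) exceeds ``envelope``. Only rows
    with ``time_hr > after_time`` are considered, e.g. the free-run portion
    of a record.
    """
    amp = daily_amplitudes(scores, after_time=after_time)
    return int((amp > envelope).sum())


# --------------------------------------------------------------------------
# single-lineage microtiter protocol


@dataclass
class Well:
    """One microtiter well: its founder, imaging times and mean areas."""

    well_id: int
    parent_id: int  # -1 for the root well
    day: int
    times: np.ndarray
    mean_area: np.ndarray
    founder_size: int
    children: List[int] = field(default_factory=list)


@dataclass
class LineageRun:
    wells: List[Well]

    def leaf_series(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """Concatenated root-to-leaf (times, mean_area) series, one per leaf."""
        by_id = {w.well_id: w for w in self.wells}
        leaves = [w for w in self.wells if not w.children]
        out = []
        for leaf in leaves:
            chain = [leaf]
            while chain[0].parent_id >= 0:
                chain.insert(0, by_id[chain[0].parent_id])
            times = np.concatenate([w.times for w in chain])
            areas = np.concatenate([w.mean_area for w in chain])
            out.append((times, areas))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for t, a in zip(w.times, w.mean_area):
                rows.append(
                    {
                        "well_id": w.well_id,
                        "parent_id": w.parent_id,
                        "day": w.day,
                        "time_hr": t,
                        "mean_area": a,
                        "founder_size": w.founder_size,
                    }
                )
        return pd.DataFrame(rows)


def _mean_sampled_area(
    pop: Population, rng: np.random.Generator, sample_fraction: float
) -> float:
    p = pop.params
    sizes = pop.clump_sizes()
    k = max(1, math.ceil(sample_fraction * sizes.size))
    chosen = rng.choice(sizes.size, size=k, replace=False) if k < sizes.size else slice(None)
    return float(np.mean(p.area_scale * sizes[chosen] ** (2.0 / 3.0)))


def run_lineage_protocol(
    params: OscillatorParams,
    images_every: float = 3.5,
    split_every: float = 24.0,
    n_children: int = 3,
    days: int = 3,
    seed: Optional[int] = None,
    *,
    dt: float = 0.25,
    sample_fraction: float = 0.5,
    founder_phase: Optional[float] = None,
) -> LineageRun:
    """Follow single-founder lineages through imaging-and-split passaging.

    A single cell founds the root well. Every ``images_every`` hours the mean
    two-dimensional clump area (``area_scale * n**(2/3)``, averaged over at
    least ``sample_fraction`` of randomly chosen objects) is recorded. After
    ``split_every`` hours, ``n_children`` objects — single cells or whole
    clumps — are picked uniformly at random as founders of child wells, and
    the process repeats for ``days`` rounds (1 + 3 + 9 wells with defaults).
    The founder's phase is drawn uniformly unless ``founder_phase`` is given;
    no FACS synchronization is ever applied, so any sustained periodicity in
    the area series is autonomous.
    """
    if images_every <= 0 or split_every <= 0 or n_children < 1 or days < 1:
        raise ValueError("protocol parameters must be positive")
    rng = np.random.default_rng(seed)
    image_offsets = np.arange(0.0, split_every - 1e-9, images_every)

    root_phase = (
        rng.uniform(0.0, params.period) if founder_phase is None else founder_phase
    )
    wells: List[Well] = []
    next_id = 0

    # queue entries: (parent_id, day, founder arrays dict incl. internal bonds)
    queue = [
        (
            -1,
            0,
            {
                "phase": np.array([root_phase]),
                "lineage": np.array([0], np.int64),
                "cfp": np.array([False]),
                "wall": np.array([False]),
                "genotype": np.array([0], np.int64),
                "bonds": np.empty((2, 0), np.int64),
            },
        )
    ]
    while queue:
        parent_id, day, founder = queue.pop(0)
        pop = Population(params, rng=rng, time=day * split_every)
        pop._append_cells(
            founder["phase"].size,
            phase=founder["phase"],
            lineage=founder["lineage"],
            cfp=founder["cfp"],
            wall=founder["wall"],
            genotype=founder["genotype"],
            birth_time=day * split_every,
        )
        pop.bonds = founder["bonds"].copy()
        pop._invalidate()
        well = Well(
            well_id=next_id,
            parent_id=parent_id,
            day=day,
            times=day * split_every + image_offsets,
            mean_area=np.empty(image_offsets.size),
            founder_size=int(founder["phase"].size),
        )
        next_id += 1
        t_local = 0.0
        for i, t_img in enumerate(image_offsets):
            if t_img > t_local:
                pop.run(t_img - t_local, dt=dt)
                t_local = t_img
            well.mean_area[i] = _mean_sampled_area(pop, rng, sample_fraction)
        pop.run(split_every - t_local, dt=dt)
        wells.append(well)
        if parent_id >= 0:
            next(w for w in wells if w.well_id == parent_id).children.append(
                well.well_id
            )
        if day + 1 < days:
            labels = pop.clump_labels
            clump_ids = rng.choice(
                int(labels.max()) + 1, size=min(n_children, int(labels.max()) + 1),
                replace=False,
            )
            for label in clump_ids:
                mask = labels == label
                local = np.full(pop.n_cells, -1, np.int64)
                local[mask] = np.arange(int(mask.sum()))
                if pop.bonds.shape[1]:
                    keep = mask[pop.bonds[0]] & mask[pop.bonds[1]]
                    sub_bonds = local[pop.bonds[:, keep]]
                else:
                    sub_bonds = np.empty((2, 0), np.int64)
                queue.append(
                    (
                        well.well_id,
                        day + 1,
                        {
                            "phase": pop.phase[mask].copy(),
                            "lineage": pop.lineage[mask].copy(),
                            "cfp": pop.cfp[mask].copy(),
                            "wall": pop.wall[mask].copy(),
                            "genotype": pop.genotype[mask].copy(),
                            "bonds": sub_bonds,
                        },
                    )
                )
    return LineageRun(wells)
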