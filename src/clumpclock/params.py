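"""Parameters of the phase-gated adhesion oscillator and the instrument model.

The simulated cell population carries a minimal phase oscillator: each cell
has an internal phase that advances with wall-clock time, modulo a ~24-hr
period. While a mother's phase lies inside the *adhesive window* at the start
of the period, newborn daughters stay bonded to her, building a lineage-based
clump; outside the window, daughters bud off as singletons and existing
mother-daughter bonds break with a constant per-bond hazard, fragmenting
clumps back toward single cells. This is the simplest model that produces the
observed daily alternation between a single-cell phase and a multicellular
phase.

Fluorescence and pulse width are instrument-level quantities: total intensity
of a FACS event scales with the number of cells in the clump (per-cell
intensity is phase-independent), and pulse width scales like a clump
diameter, ``n_cells**(1/3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass
class OscillatorParams:
    """Tunable parameters of the oscillator simulation.

    Parameters
    ----------
    period : float
        Oscillator period in hours. Default 24.
    adhesive_window : float
        Hours at the start of each period during which a dividing mother
        retains her daughter (bonded). Default 10, matching the 10-hr
        single-cell-to-clump arm of the twice-daily selection schedule.
    doubling_time : float
        Mean hours per division. Default 2.0 (roughly six divisions in the
        shorter growth interval). May be ``inf`` to disable division. Must be
        at least ``period / 16``: one day corresponds to at most 16 divisions.
    doubling_cv : float
        Coefficient of variation of per-cell division intervals; used only in
        the deterministic division mode (lognormal per-cell intervals).
    phase_jitter_sd : float
        SD (hours) of Gaussian jitter added to a daughter's inherited phase at
        each division. Default 0.75: populations desynchronize over about a
        week untreated yet free-run for several cycles after synchronization.
    fragmentation_rate : float
        Per-bond per-hour breakage hazard, active only while the bond's mother
        cell is outside the adhesive window. Default 0.3 (bond half-life
        ~2.3 hr), so clumps decay to mostly singletons within the 14-hr
        dispersal arm.
    division_mode : str
        ``"hazard"``: each cell divides with rate ``ln 2 / doubling_time`` so
        the population doubles every ``doubling_time`` in expectation.
        ``"deterministic"``: each cell divides at fixed multiples of its own
        division interval (useful for exact-count tests).
    max_tracked_clump : int
        Safety cap on clump size; exceeding it raises, guarding against
        runaway growth from misconfigured windows.
    yfp_per_cell_mean, rfp_per_cell_mean : float
        Mean fluorescence per cell, arbitrary units. Per-cell intensity never
        depends on phase or time; cyclical FACS intensity comes entirely from
        changes in cell association.
    intensity_cv : float
        Multiplicative lognormal CV of event fluorescence.
    pw_exponent, pw_scale, pw_noise_cv : float
        Pulse-width model: ``pw = pw_scale * n_cells**pw_exponent * noise``.
        The default exponent 1/3 makes pulse width diameter-like.
    area_scale : float
        Scale of the imaged two-dimensional clump area,
        ``area = area_scale * n_cells**(2/3)`` (projected area of a compact
        three-dimensional clump).
    """

    period: float = 24.0
    adhesive_window: float = 10.0
    doubling_time: float = 2.0
    doubling_cv: float = 0.0
    phase_jitter_sd: float = 0.75
    fragmentation_rate: float = 0.3
    division_mode: str = "hazard"
    max_tracked_clump: int = 20000
    yfp_per_cell_mean: float = 100.0
    rfp_per_cell_mean: float = 100.0
    intensity_cv: float = 0.15
    pw_exponent: float = 1.0 / 3.0
    pw_scale: float = 10.0
    pw_noise_cv: float = 0.05
    area_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if not 0 < self.adhesive_window < self.period:
            raise ValueError(
                "adhesive_window must lie strictly between 0 and period, "
                f"got {self.adhesive_window} (period {self.period})"
            )
        min_doubling = self.period / 16.0  # at most 16 divisions per period
        if not self.doubling_time >= min_doubling:
            raise ValueError(
                f"doubling_time must be >= period/16 = {min_doubling:g} hr, "
                f"got {self.doubling_time}"
            )
        for name in (
            "doubling_cv",
            "phase_jitter_sd",
            "fragmentation_rate",
            "intensity_cv",
            "pw_noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("yfp_per_cell_mean", "rfp_per_cell_mean", "pw_scale", "area_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.division_mode not in ("hazard", "deterministic"):
            raise ValueError(f"unknown division_mode {self.division_mode!r}")
        if self.max_tracked_clump < 1:
            raise ValueError("max_tracked_clump must be >= 1")

    @property
    def division_rate(self) -> float:
        """Per-cell division rate (per hour) in hazard mode: ln2/doubling_time."""
        if math.isinf(self.doubling_time):
            return 0.0
        return math.log(2.0) / self.doubling_time

    def in_window(self, phase):
        """Vectorized test: is a phase inside the adhesive window [0, w)?"""
        return phase < self.adhesive_window

    def replace(self, **kwargs) -> "OscillatorParams":
        """Return a copy with the given fields replaced (re-validated)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return OscillatorParams(**current)
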