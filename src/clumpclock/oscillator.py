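"""Agent-based simulator of a clump-forming oscillator population.

Cells are stored in parallel numpy arrays; mother-daughter adhesion bonds in
an edge list. A clump is a connected component of the bond graph, labeled on
demand. All stochastic draws go through one ``numpy.random.Generator`` owned
by the population, so a run is fully determined by its seed.

Operations mutate the population in place and also return it, so calls chain.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .params import OscillatorParams

__all__ = [
    "Population",
    "init_population",
    "step",
    "sonicate",
    "readhere",
    "dilute",
    "label_walls",
    "density_after_doublings",
]


class Population:
    """A population of phase-bearing cells partitioned into clumps.

    Attributes (parallel arrays, one entry per cell)
    ------------------------------------------------
    cell_id : int64, unique and stable across the population's lifetime
    lineage : int64, founder identity; inherited by daughters
    phase : float64 in [0, period)
    cfp : bool, constitutive CFP subclone marker; inherited
    wall : bool, covalent cell-wall label; set only by :meth:`label_walls`,
        never inherited (a daughter's wall is entirely new)
    genotype : int64 reference into an external genotype table; inherited
    birth_time : float64, hours
    div_interval : float64, per-cell division interval (deterministic mode)

    ``bonds`` is a ``(2, B)`` int array of cell *indices*; row 0 is the
    mother-side endpoint (whose phase gates breakage), row 1 the daughter.
    """

    def __init__(
        self,
        params: OscillatorParams,
        *,
        volume_ml: float = 1.0,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        time: float = 0.0,
    ):
        if volume_ml <= 0:
            raise ValueError("volume_ml must be positive")
        self.params = params
        self.volume_ml = float(volume_ml)
        self.time = float(time)
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.cell_id = np.empty(0, dtype=np.int64)
        self.lineage = np.empty(0, dtype=np.int64)
        self.phase = np.empty(0, dtype=np.float64)
        self.cfp = np.empty(0, dtype=bool)
        self.wall = np.empty(0, dtype=bool)
        self.genotype = np.empty(0, dtype=np.int64)
        self.birth_time = np.empty(0, dtype=np.float64)
        self.div_interval = np.empty(0, dtype=np.float64)
        self.bonds = np.empty((2, 0), dtype=np.int64)
        self._next_id = 0
        self._labels: Optional[np.ndarray] = None

    @classmethod
    def from_clump_sizes(
        cls,
        sizes,
        params: OscillatorParams,
        *,
        phase: float = 0.0,
        seed: Optional[int] = None,
        volume_ml: float = 1.0,
    ) -> "Population":
        """Build a population with the given clump sizes (bonded chains).

        Every cell gets the stated phase; clump ``i`` gets lineage ``i``.
        Convenient for constructing exact instrument-model inputs.
        """
        sizes = np.asarray(sizes, int)
        if sizes.size == 0 or (sizes < 1).any():
            raise ValueError("sizes must be a nonempty list of counts >= 1")
        pop = cls(params, volume_ml=volume_ml, seed=seed)
        total = int(sizes.sum())
        lineage = np.repeat(np.arange(sizes.size), sizes)
        pop._append_cells(
            total,
            phase=np.full(total, float(phase)),
            lineage=lineage,
            cfp=np.zeros(total, bool),
            wall=np.zeros(total, bool),
            genotype=np.zeros(total, np.int64),
            birth_time=0.0,
        )
        bonds = []
        start = 0
        for s in sizes:
            idx = np.arange(start, start + s)
            if s > 1:
                bonds.append(np.stack([idx[:-1], idx[1:]]))
            start += s
        if bonds:
            pop.bonds = np.concatenate(bonds, axis=1)
        pop._invalidate()
        return pop

    # ------------------------------------------------------------------ views

    @property
    def n_cells(self) -> int:
        return self.cell_id.size

    @property
    def density(self) -> float:
        """Cells per ml under the implied culture volume."""
        return self.n_cells / self.volume_ml

    @property
    def clump_labels(self) -> np.ndarray:
        """Connected-component label per cell (computed lazily, cached)."""
        if self._labels is None:
            n = self.n_cells
            if self.bonds.shape[1] == 0:
                self._labels = np.arange(n, dtype=np.int64)
            else:
                data = np.ones(self.bonds.shape[1], dtype=np.int8)
                graph = coo_matrix(
                    (data, (self.bonds[0], self.bonds[1])), shape=(n, n)
                )
                _, labels = connected_components(graph, directed=False)
                self._labels = labels.astype(np.int64)
            sizes = np.bincount(self._labels)
            if sizes.size and sizes.max() > self.params.max_tracked_clump:
                raise RuntimeError(
                    f"clump size {int(sizes.max())} exceeds max_tracked_clump="
                    f"{self.params.max_tracked_clump}; check window/rate settings"
                )
        return self._labels

    @property
    def n_clumps(self) -> int:
        labels = self.clump_labels
        return 0 if labels.size == 0 else int(labels.max()) + 1

    def clump_sizes(self) -> np.ndarray:
        """Cell count of each clump, indexed by clump label."""
        return np.bincount(self.clump_labels, minlength=self.n_clumps)

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: ids, clump membership, phase and flags."""
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "clump_id": self.clump_labels,
                "lineage_id": self.lineage,
                "phase": self.phase,
                "cfp_positive": self.cfp,
                "wall_labeled": self.wall,
                "genotype_id": self.genotype,
                "birth_time": self.birth_time,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    # ------------------------------------------------------------- internals

    def _invalidate(self) -> None:
        self._labels = None

    def _draw_div_intervals(self, n: int) -> np.ndarray:
        p = self.params
        if math.isinf(p.doubling_time):
            return np.full(n, np.inf)
        if p.doubling_cv == 0:
            return np.full(n, p.doubling_time)
        sigma = math.sqrt(math.log1p(p.doubling_cv**2))
        return p.doubling_time * self.rng.lognormal(-0.5 * sigma**2, sigma, n)

    def _append_cells(
        self, n: int, *, phase, lineage, cfp, wall, genotype, birth_time
    ) -> np.ndarray:
        """Append n cells; returns their indices."""
        idx = np.arange(self.n_cells, self.n_cells + n)
        self.cell_id = np.concatenate(
            [self.cell_id, np.arange(self._next_id, self._next_id + n)]
        )
        self._next_id += n
        self.phase = np.concatenate([self.phase, np.asarray(phase, float)])
        self.lineage = np.concatenate([self.lineage, np.asarray(lineage, np.int64)])
        self.cfp = np.concatenate([self.cfp, np.asarray(cfp, bool)])
        self.wall = np.concatenate([self.wall, np.asarray(wall, bool)])
        self.genotype = np.concatenate([self.genotype, np.asarray(genotype, np.int64)])
        self.birth_time = np.concatenate(
            [self.birth_time, np.full(n, float(birth_time))]
        )
        self.div_interval = np.concatenate(
            [self.div_interval, self._draw_div_intervals(n)]
        )
        self._invalidate()
        return idx

    def subset(self, mask: np.ndarray) -> "Population":
        """Keep only cells where ``mask`` is True (in place); remaps bonds.

        Bonds with a removed endpoint are dropped.
        """
        mask = np.asarray(mask, bool)
        index_map = np.full(self.n_cells, -1, dtype=np.int64)
        index_map[mask] = np.arange(int(mask.sum()))
        for name in (
            "cell_id",
            "lineage",
            "phase",
            "cfp",
            "wall",
            "genotype",
            "birth_time",
            "div_interval",
        ):
            setattr(self, name, getattr(self, name)[mask])
        if self.bonds.shape[1]:
            keep = mask[self.bonds[0]] & mask[self.bonds[1]]
            self.bonds = index_map[self.bonds[:, keep]]
        self._invalidate()
        return self

    def keep_clumps(self, labels_to_keep) -> "Population":
        """Retain whole clumps whose label is in ``labels_to_keep``."""
        wanted = np.zeros(self.n_clumps, dtype=bool)
        wanted[np.asarray(labels_to_keep, dtype=np.int64)] = True
        return self.subset(wanted[self.clump_labels])

    # ------------------------------------------------------------ operations

    def step(self, dt: float) -> "Population":
        """Advance the population by ``dt`` hours.

        Phases advance by ``dt`` (mod period). Cells divide according to the
        division model; a daughter bonds to her mother iff the mother's phase
        is inside the adhesive window, otherwise she becomes a new singleton
        clump. Daughters inherit lineage, CFP state and genotype, and the
        mother's phase plus Gaussian jitter; the wall label is never
        inherited. Each bond whose mother cell sits outside the window breaks
        independently with probability ``1 - exp(-fragmentation_rate * dt)``.
        Cell count never decreases.
        """
        p = self.params
        if not dt > 0:
            raise ValueError(f"dt must be positive, got {dt}")
        if dt > p.doubling_time / 4:
            raise ValueError(
                f"dt={dt} too coarse for doubling_time={p.doubling_time}; "
                "require dt <= doubling_time/4"
            )
        t_new = self.time + dt
        self.phase = np.mod(self.phase + dt, p.period)

        # divisions
        n = self.n_cells
        if p.division_mode == "hazard":
            # P(divide in dt) = 2**(dt/tau) - 1, so E[N(t)] = N0 * 2**(t/tau)
            # exactly under repeated steps of equal dt
            prob = (
                math.expm1(p.division_rate * dt)
                if p.division_rate > 0
                else 0.0
            )
            dividers = (
                np.flatnonzero(self.rng.random(n) < prob)
                if prob > 0
                else np.empty(0, np.int64)
            )
        else:
            age_old = self.time - self.birth_time
            age_new = t_new - self.birth_time
            with np.errstate(invalid="ignore"):
                dividers = np.flatnonzero(
                    np.floor(age_new / self.div_interval)
                    > np.floor(age_old / self.div_interval)
                )
        m = dividers.size
        if m:
            mother_phase = self.phase[dividers]
            jitter = (
                self.rng.normal(0.0, p.phase_jitter_sd, m)
                if p.phase_jitter_sd > 0
                else 0.0
            )
            daughter_idx = self._append_cells(
                m,
                phase=np.mod(mother_phase + jitter, p.period),
                lineage=self.lineage[dividers],
                cfp=self.cfp[dividers],
                wall=np.zeros(m, bool),
                genotype=self.genotype[dividers],
                birth_time=t_new,
            )
            adhesive = p.in_window(mother_phase)
            if adhesive.any():
                new_bonds = np.stack([dividers[adhesive], daughter_idx[adhesive]])
                self.bonds = np.concatenate([self.bonds, new_bonds], axis=1)

        # fragmentation: bonds whose mother is outside the window break
        if self.bonds.shape[1] and p.fragmentation_rate > 0:
            exposed = ~p.in_window(self.phase[self.bonds[0]])
            p_break = -math.expm1(-p.fragmentation_rate * dt)
            breaking = exposed & (self.rng.random(self.bonds.shape[1]) < p_break)
            if breaking.any():
                self.bonds = self.bonds[:, ~breaking]

        self.time = t_new
        self._invalidate()
        return self

    def run(self, hours: float, dt: float = 0.25) -> "Population":
        """Step repeatedly for ``hours`` (last step shortened to land exactly)."""
        remaining = float(hours)
        while remaining > 1e-9:
            h = min(dt, remaining)
            self.step(h)
            remaining -= h
        return self

    def sonicate(self) -> "Population":
        """Break every bond: all clumps become singletons, cells unchanged."""
        self.bonds = np.empty((2, 0), dtype=np.int64)
        self._invalidate()
        return self

    def readhere(
        self,
        duration: float,
        stick_prob: float,
        seed: Optional[int] = None,
        n_rounds: int = 1,
    ) -> "Population":
        """Let sonicated cells re-adhere to random partners.

        Models the mixing experiment: after sonication, cells currently in
        the adhesive phase are randomly paired for ``n_rounds`` encounter
        rounds over ``duration`` hours and each pair bonds with probability
        ``stick_prob`` — partners are not restricted to kin, so re-adhered
        clumps may mix lineages and CFP states. Requires an all-singleton
        population (call :meth:`sonicate` first).
        """
        if self.bonds.shape[1]:
            raise ValueError("readhere requires an all-singleton population")
        if not 0 <= stick_prob <= 1:
            raise ValueError("stick_prob must be in [0, 1]")
        if duration <= 0:
            raise ValueError("duration must be positive")
        rng = self.rng if seed is None else np.random.default_rng(seed)
        if stick_prob == 0:
            return self
        adhesive = np.flatnonzero(self.params.in_window(self.phase))
        new_bonds = []
        for _ in range(max(1, n_rounds)):
            perm = rng.permutation(adhesive)
            k = perm.size // 2
            if k == 0:
                break
            u, v = perm[:k], perm[k : 2 * k]
            hit = rng.random(k) < stick_prob
            if hit.any():
                new_bonds.append(np.stack([u[hit], v[hit]]))
        if new_bonds:
            self.bonds = np.concatenate([self.bonds, *new_bonds], axis=1)
        self._invalidate()
        return self

    def dilute(self, target_density: float, seed: Optional[int] = None) -> "Population":
        """Subsample whole clumps, unbiased in phase, to ~``target_density``."""
        if not target_density < self.density:
            raise ValueError(
                f"target density {target_density} must be below current "
                f"density {self.density}"
            )
        return self.dilute_to_count(int(round(target_density * self.volume_ml)), seed)

    def dilute_to_count(self, n_target: int, seed: Optional[int] = None) -> "Population":
        """Keep a random subset of whole clumps totalling ~``n_target`` cells."""
        if n_target < 1:
            raise ValueError("n_target must be >= 1")
        if n_target >= self.n_cells:
            raise ValueError("target cell count must be below current count")
        rng = self.rng if seed is None else np.random.default_rng(seed)
        sizes = self.clump_sizes()
        order = rng.permutation(sizes.size)
        cumulative = np.cumsum(sizes[order])
        n_keep = int(np.searchsorted(cumulative, n_target, side="right"))
        n_keep = max(1, n_keep)
        return self.keep_clumps(order[:n_keep])

    def label_walls(self) -> "Population":
        """Covalently label every current cell's wall; daughters stay unlabeled."""
        self.wall = np.ones(self.n_cells, dtype=bool)
        return self


def init_population(
    n_cells: int,
    params: OscillatorParams,
    phase_mode: str = "uniform",
    seed: Optional[int] = None,
    *,
    phase: float = 0.0,
    volume_ml: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Create ``n_cells`` singleton clumps (an asynchronous or clamped stock).

    ``phase_mode="uniform"`` draws phases uniformly on [0, period), emulating
    a thawed asynchronous stock; ``phase_mode="delta"`` sets every phase to
    ``phase``.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    pop = Population(params, volume_ml=volume_ml, seed=seed, rng=rng)
    if phase_mode == "uniform":
        phases = pop.rng.uniform(0.0, params.period, n_cells)
    elif phase_mode == "delta":
        if not 0 <= phase < params.period:
            raise ValueError("delta phase must lie in [0, period)")
        phases = np.full(n_cells, float(phase))
    else:
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    pop._append_cells(
        n_cells,
        phase=phases,
        lineage=np.arange(n_cells),
        cfp=np.zeros(n_cells, bool),
        wall=np.zeros(n_cells, bool),
        genotype=np.zeros(n_cells, np.int64),
        birth_time=0.0,
    )
    return pop


# Thin functional wrappers over the Population methods.

def step(pop: Population, dt: float) -> Population:
    return pop.step(dt)


def sonicate(pop: Population) -> Population:
    return pop.sonicate()


def readhere(
    pop: Population, duration: float, stick_prob: float, seed: Optional[int] = None
) -> Population:
    return pop.readhere(duration, stick_prob, seed)


def dilute(pop: Population, target_density: float, seed: Optional[int] = None) -> Population:
    return pop.dilute(target_density, seed)


def label_walls(pop: Population) -> Population:
    return pop.label_walls()


def density_after_doublings(start_density: float, n_doublings: float) -> float:
    """Closed-form density after a number of doublings: ``d0 * 2**n``.

    Growth bookkeeping for exponential-phase checks, e.g. a single cell at
    10 cells/ml undergoing at most 16 divisions in 24 hr stays far below the
    3e7 cells/ml end of mid-log growth.
    """
    if start_density <= 0:
        raise ValueError("start_density must be positive")
    return start_density * 2.0**n_doublings
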