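"""Allele trajectories through an experimental evolution.

A discrete-generation haploid Wright-Fisher model tracks oscillator lineages
inside an evolving population: each lineage acquires its causal mutations at
configured times and gains a per-generation fitness advantage once its set is
complete, while drift acts through multinomial resampling. Measured
trajectories emulate Sanger peak-height frequency calls, which carry roughly
10% accuracy and cannot detect alleles below 10% frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "LineageSpec",
    "simulate_lineage_frequencies",
    "sanger_measure",
    "measure_trajectory",
    "count_independent_origins",
]


@dataclass(frozen=True)
class LineageSpec:
    """One oscillator lineage: locus -> arrival day of its mutation.

    The lineage enters the population (one founder individual by default) at
    its earliest arrival day and becomes fitter than background once every
    mutation in ``arrivals`` has occurred.
    """

    arrivals: Dict[str, float]
    initial_freq: Optional[float] = None  # default: 1/pop_size at first arrival

    @property
    def first_arrival(self) -> float:
        return min(self.arrivals.values())


def simulate_lineage_frequencies(
    causal_sets: Sequence[LineageSpec],
    days: int,
    pop_size: int = 100_000,
    selection_strength: float = 0.05,
    seed: Optional[int] = None,
    generations_per_day: int = 6,
) -> pd.DataFrame:
    """Simulate per-locus true-frequency series over an evolution.

    Parameters
    ----------
    causal_sets : sequence of LineageSpec
        One entry per oscillator lineage; the number of lineages is
        ``len(causal_sets)``.
    days : int
        Length of the evolution in days.
    pop_size : int
        Constant haploid population size (default 1e5).
    selection_strength : float
        Per-generation fitness advantage ``s`` of a lineage whose causal set
        is complete.
    generations_per_day : int
        Default 6 — roughly six divisions between successive selections.

    Returns a long DataFrame (day, locus, true_freq) where a locus's
    frequency is the summed frequency of lineages that carry it, recorded
    once per day. Loci are absent (frequency 0) before their arrival day.
    """
    if days < 1 or pop_size < 2 or generations_per_day < 1:
        raise ValueError("days, pop_size and generations_per_day must be positive")
    if selection_strength < 0:
        raise ValueError("selection_strength must be >= 0")
    rng = np.random.default_rng(seed)
    lineages = list(causal_sets)
    n_lin = len(lineages)
    loci = sorted({locus for lin in lineages for locus in lin.arrivals})

    # class 0 = non-oscillator background; classes 1..n = lineages
    counts = np.zeros(n_lin + 1, dtype=np.int64)
    counts[0] = pop_size
    arrived: List[Set[str]] = [set() for _ in lineages]
    records = []

    def record(day: float) -> None:
        freqs = counts / pop_size
        for locus in loci:
            f = sum(
                freqs[i + 1]
                for i, lin in enumerate(lineages)
                if locus in arrived[i]
            )
            records.append({"day": day, "locus": locus, "true_freq": f})

    record(0.0)
    for gen in range(1, days * generations_per_day + 1):
        day = gen / generations_per_day
        for i, lin in enumerate(lineages):
            for locus, arrival in lin.arrivals.items():
                if locus in arrived[i] or arrival > day:
                    continue
                if not arrived[i] and counts[i + 1] == 0:
                    # lineage founded out of the background population
                    init = lin.initial_freq
                    n0 = 1 if init is None else max(1, round(init * pop_size))
                    n0 = min(n0, int(counts[0]))
                    counts[0] -= n0
                    counts[i + 1] += n0
                arrived[i].add(locus)
        fitness = np.ones(n_lin + 1)
        for i, lin in enumerate(lineages):
            if arrived[i] == set(lin.arrivals):
                fitness[i + 1] = 1.0 + selection_strength
        weights = counts * fitness
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("population went extinct")
        counts = rng.multinomial(pop_size, weights / total)
        if gen % generations_per_day == 0:
            record(day)
    return pd.DataFrame(records)


def _sanger_sigma(noise_sd_at_half: float) -> float:
    # measured = mut/(mut+wt); at f=0.5 d(measured)/d(log peak ratio) = 1/4 and
    # the log ratio of two independent lognormals has SD sigma*sqrt(2)
    return noise_sd_at_half / (0.25 * math.sqrt(2.0))


def sanger_measure(
    true_freq: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    noise_sd_at_half: float = 0.05,
    detection_limit: float = 0.10,
) -> float:
    """Sanger peak-height frequency call; ``nan`` when below detection.

    Mutant and wild-type electropherogram peak heights are proportional to
    ``true_freq`` and ``1 - true_freq``, each with multiplicative lognormal
    noise calibrated so the measured frequency has SD ``noise_sd_at_half``
    at a true frequency of 0.5 (the "roughly 10%" accuracy envelope). The
    call is ``mut / (mut + wt)``; values below ``detection_limit`` (default
    10%) are censored to ``nan`` (not detected).
    """
    if not 0 <= true_freq <= 1:
        raise ValueError(f"true_freq must be in [0, 1], got {true_freq}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = _sanger_sigma(noise_sd_at_half)
    if sigma == 0:
        measured = float(true_freq)
    else:
        mut = true_freq * rng.lognormal(-0.5 * sigma**2, sigma)
        wt = (1.0 - true_freq) * rng.lognormal(-0.5 * sigma**2, sigma)
        measured = 1.0 if (mut + wt) == 0 else float(mut / (mut + wt))
    return measured if measured >= detection_limit else float("nan")


def measure_trajectory(
    true_freqs: pd.DataFrame,
    seed: Optional[int] = None,
    noise_sd_at_half: float = 0.05,
    detection_limit: float = 0.10,
) -> pd.DataFrame:
    """Apply :func:`sanger_measure` to a (day, locus, true_freq) table.

    Adds ``measured_freq`` (nan when not detected) and ``detected`` columns.
    """
    rng = np.random.default_rng(seed)
    measured = np.array(
        [
            sanger_measure(
                f,
                rng=rng,
                noise_sd_at_half=noise_sd_at_half,
                detection_limit=detection_limit,
            )
            for f in true_freqs["true_freq"]
        ]
    )
    out = true_freqs.copy()
    out["measured_freq"] = measured
    out["detected"] = ~np.isnan(measured)
    return out


def count_independent_origins(allele_classes_per_population: Sequence) -> int:
    """Lower bound on independently evolved oscillators.

    Each entry is the set of distinct allele classes observed at a focal
    locus among cycling isolates of one population (the wild-type allele
    counts as its own class). Classes are never merged across populations —
    identical-by-state alleles in different populations still arose
    independently — so the bound is the summed class count. For example, one
    population carrying two mutant alleles plus wild type and another
    carrying one mutant plus wild type give 3 + 2 = 5 independent origins.
    """
    classes = list(allele_classes_per_population)
    if not classes:
        raise ValueError("need at least one population")
    total = 0
    for s in classes:
        s = set(s)
        if not s:
            raise ValueError("each population's allele-class set must be nonempty")
        total += len(s)
    return total
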