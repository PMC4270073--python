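"""Bulk-segregant analysis: cross, sporulate, select, sequence, call.

The mapping procedure crosses an evolved oscillator clone to its ancestor,
puts the diploid through meiosis, selects the resulting spores in bulk for
the oscillation phenotype, and sequences the surviving pool. Loci whose
evolved allele is present in at least 95% of the selected pool are called
putative causal mutations; neutral mutations that merely hitchhiked during
evolution segregate at ~50%. The exact binomial tail quantifies how unlikely
an observed deviation from 50% would be for a non-causal locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import beta

from .errors import EmptyPoolError

__all__ = [
    "LocusSpec",
    "SporePool",
    "cross_and_sporulate",
    "select_pool",
    "sequence_pool",
    "call_causal",
    "binom_dev_p",
    "subtrait_score",
    "clopper_pearson",
]


@dataclass(frozen=True)
class LocusSpec:
    """A segregating locus: its name, causality, and subtrait directions.

    ``subtrait_effects`` maps a trait name (e.g. "single_cells",
    "constitutive_clumps") to "favored", "disfavored" or "neutral" — the
    direction selection on that subtrait pushes the evolved allele.
    """

    name: str
    causal: bool = False
    subtrait_effects: Dict[str, str] = field(default_factory=dict)


@dataclass
class SporePool:
    """Genotype counts over n biallelic loci (bit 1 = evolved allele).

    ``genotypes`` holds the distinct bit-vectors (as int64 bitmasks, locus i
    on bit i) and ``counts`` the number of spores of each.
    """

    loci: Tuple[LocusSpec, ...]
    genotypes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        if (self.counts < 0).any():
            raise ValueError("genotype counts must be >= 0")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    @property
    def causal_mask(self) -> int:
        return sum(1 << i for i, l in enumerate(self.loci) if l.causal)

    def allele_freq(self) -> np.ndarray:
        """Evolved-allele frequency per locus (order of ``loci``)."""
        if self.size == 0:
            raise EmptyPoolError("empty pool has no allele frequencies")
        bits = (self.genotypes[:, None] >> np.arange(self.n_loci)) & 1
        return (bits * self.counts[:, None]).sum(axis=0) / self.size

    def allele_counts(self) -> np.ndarray:
        bits = (self.genotypes[:, None] >> np.arange(self.n_loci)) & 1
        return (bits * self.counts[:, None]).sum(axis=0)


def cross_and_sporulate(
    evolved_loci: Sequence[LocusSpec],
    n_spores: int,
    seed: Optional[int] = None,
) -> SporePool:
    """Meiosis of the evolved x ancestor diploid: draw ``n_spores`` spores.

    Loci are treated as unlinked, so each spore inherits each evolved allele
    independently with probability 1/2 and all 2^n genotypes are possible.
    """
    loci = tuple(evolved_loci)
    if n_spores < 1:
        raise ValueError("n_spores must be >= 1")
    if not 1 <= len(loci) <= 62:
        raise ValueError("need between 1 and 62 loci")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n_spores, len(loci)), dtype=np.int64)
    masks = bits @ (np.int64(1) << np.arange(len(loci), dtype=np.int64))
    genotypes, counts = np.unique(masks, return_counts=True)
    return SporePool(loci, genotypes, counts)


def select_pool(
    pool: SporePool,
    predicate: Optional[Callable[[int], bool]] = None,
) -> SporePool:
    """Phenotype-select a spore pool.

    The default predicate is the strictest reading of the reconstruction
    result: a spore oscillates (survives selection) iff it carries the
    evolved allele at *every* causal locus. Alternative predicates (any-k,
    penetrance models) can be passed as a callable on the genotype bitmask.
    """
    if pool.size == 0:
        raise EmptyPoolError("cannot select from an empty pool")
    if predicate is None:
        causal = pool.causal_mask
        keep = (pool.genotypes & causal) == causal
    else:
        keep = np.fromiter(
            (bool(predicate(int(g))) for g in pool.genotypes),
            dtype=bool,
            count=pool.genotypes.size,
        )
    if not keep.any():
        raise EmptyPoolError("selection left no surviving spores")
    return SporePool(pool.loci, pool.genotypes[keep], pool.counts[keep])


def sequence_pool(
    pool: SporePool,
    mean_depth: float,
    seed: Optional[int] = None,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Pooled sequencing of the spool's genomic DNA.

    Per-locus depth is Poisson(``mean_depth``) and the evolved-allele read
    count is Binomial(depth, f') where f' folds in a symmetric per-read
    error rate (0 by default). Returns a pileup table (locus, depth,
    alt_reads).
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    freq = pool.allele_freq()
    p = freq * (1 - error_rate) + (1 - freq) * error_rate
    depth = rng.poisson(mean_depth, size=pool.n_loci)
    alt = rng.binomial(depth, p)
    return pd.DataFrame(
        {"locus": [l.name for l in pool.loci], "depth": depth, "alt_reads": alt}
    )


def binom_dev_p(depth: int, alt_reads: int) -> float:
    """Exact one-sided binomial tail probability under p = 1/2.

    For ``alt_reads >= depth/2`` this is P(X >= alt_reads | depth, 1/2); for
    smaller counts the symmetric lower tail P(X <= alt_reads). Computed by
    direct summation of log binomial coefficients (log-space, no normal
    approximation), stable for depths up to ~1e6.
    """
    depth = int(depth)
    alt_reads = int(alt_reads)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must lie in [0, depth]")
    if alt_reads >= depth / 2:
        k = np.arange(alt_reads, depth + 1)
    else:
        k = np.arange(0, alt_reads + 1)
    log_terms = (
        gammaln(depth + 1)
        - gammaln(k + 1)
        - gammaln(depth - k + 1)
        - depth * math.log(2.0)
    )
    return float(np.exp(logsumexp(log_terms)))


def call_causal(pileup: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """Classify loci from a pooled pileup.

    A locus is called causal when its estimated evolved-allele frequency
    ``alt_reads / depth`` is at or above ``threshold`` (default 0.95). Each
    call carries ``p_dev``, the exact binomial tail probability of its
    deviation from the neutral expectation of 1/2. Zero-depth loci are
    flagged uncallable rather than dropped.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    depth = pileup["depth"].to_numpy(int)
    alt = pileup["alt_reads"].to_numpy(int)
    callable_ = depth >= 1
    freq = np.where(callable_, alt / np.where(callable_, depth, 1), np.nan)
    p_dev = np.array(
        [binom_dev_p(d, a) if d >= 1 else np.nan for d, a in zip(depth, alt)]
    )
    return pd.DataFrame(
        {
            "locus": pileup["locus"],
            "depth": depth,
            "alt_reads": alt,
            "freq_hat": freq,
            "p_dev": p_dev,
            "is_causal": callable_ & (freq >= threshold),
            "callable": callable_,
        }
    )


def clopper_pearson(k: int, n: int, ci_level: float = 0.99) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1 - ci_level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def subtrait_score(
    start_pool: SporePool,
    selected_pool: SporePool,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Per-locus selection direction under a subtrait selection.

    Compares each locus's evolved-allele frequency in the selected pool to
    its starting frequency: ``selected_for`` when the exact binomial CI at
    ``ci_level`` around the selected frequency lies wholly above the start
    frequency, ``selected_against`` when wholly below, else ``neutral``.
    """
    if start_pool.size == 0 or selected_pool.size == 0:
        raise EmptyPoolError("both pools must be nonempty")
    if tuple(l.name for l in start_pool.loci) != tuple(
        l.name for l in selected_pool.loci
    ):
        raise ValueError("pools must cover the same loci in the same order")
    start = start_pool.allele_freq()
    k = selected_pool.allele_counts()
    n = selected_pool.size
    rows = []
    for locus, f0, ki in zip(start_pool.loci, start, k):
        lo, hi = clopper_pearson(int(ki), n, ci_level)
        if lo > f0:
            call = "selected_for"
        elif hi < f0:
            call = "selected_against"
        else:
            call = "neutral"
        rows.append(
            {
                "locus": locus.name,
                "start_freq": f0,
                "selected_freq": ki / n,
                "ci_low": lo,
                "ci_high": hi,
                "classification": call,
            }
        )
    return pd.DataFrame(rows)
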