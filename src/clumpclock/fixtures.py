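"""Small deterministic datasets for tests and demos.

All files are plain CSV, generated from the package's own simulators, and
byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .config import child_seed
from .facs import measure_events
from .oscillator import init_population
from .params import OscillatorParams
from .segregant import LocusSpec, cross_and_sporulate

__all__ = ["make_fixtures"]


def make_fixtures(seed: int, out_dir) -> Dict[str, Path]:
    """Write a tiny event table, a 4-locus spore pool, and a 2-cycle score
    series under ``out_dir``; returns the paths keyed by fixture name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = child_seed(seed, "fixtures")
    paths: Dict[str, Path] = {}

    # event table: a small population simulated into mixed clump sizes
    params = OscillatorParams()
    pop = init_population(40, params, phase_mode="uniform", seed=base)
    pop.run(12.0)
    events = measure_events(pop, seed=base + 1)
    paths["events"] = out / "events.csv"
    events.to_csv(paths["events"], index=False, float_format="%.6f")

    # 4-locus spore pool (2 causal, 2 neutral) from a simulated meiosis
    loci = [
        LocusSpec("mutA", causal=True),
        LocusSpec("mutB", causal=True),
        LocusSpec("neuC"),
        LocusSpec("neuD"),
    ]
    pool = cross_and_sporulate(loci, 500, seed=base + 2)
    paths["loci"] = out / "loci.csv"
    pd.DataFrame(
        {"name": [l.name for l in loci], "causal": [l.causal for l in loci]}
    ).to_csv(paths["loci"], index=False)
    paths["spore_pool"] = out / "spore_pool.csv"
    pd.DataFrame(
        {
            "genotype": [
                format(int(g), f"0{pool.n_loci}b")[::-1] for g in pool.genotypes
            ],
            "count": pool.counts,
        }
    ).to_csv(paths["spore_pool"], index=False)

    # 2-cycle oscillation score series (noisy cosine, 3.5-hr sampling)
    rng = np.random.default_rng(base + 3)
    times = np.arange(0.0, 48.0 + 1e-9, 3.5)
    values = np.cos(2 * np.pi * times / 24.0) + rng.normal(0, 0.05, times.size)
    paths["scores"] = out / "scores.csv"
    pd.DataFrame({"time_hr": times, "log_ratio": values}).to_csv(
        paths["scores"], index=False, float_format="%.6f"
    )
    return paths
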