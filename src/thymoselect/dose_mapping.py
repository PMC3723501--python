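"""Mapping relative agonist RNA expression to the peptide replacement fraction g.

The titration experiment controls agonist abundance through an inducible
transgene and reports it as RNA expression relative to controls; the models
work with g, the fraction of presented peptides replaced by agonist.  The
relation is unknown but should be monotone, approximately linear (on a log
scale) at low expression, and saturate below 1 (endogenous peptides compete
for MHC loading and dendritic cells present no agonist).  A Hill-type
sigmoid in RNA has exactly these properties:

    g(rna) = g_max / (1 + (rho50 / rna)^steepness),   g(0) = 0,

with rho50 the expression level at half-maximal replacement and
``steepness`` the slope of log g versus log RNA at low expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MappingParams:
    """Parameters of the sigmoid RNA -> g mapping."""

    g_max: float
    rho50: float
    steepness: float

    def __post_init__(self):
        if not 0.0 < self.g_max <= 1.0:
            raise ValueError(f"g_max must lie in (0, 1], got {self.g_max}")
        if not self.rho50 > 0.0:
            raise ValueError(f"rho50 must be positive, got {self.rho50}")
        if not self.steepness > 0.0:
            raise ValueError(f"steepness must be positive, got {self.steepness}")


def map_rna_to_g(mp: MappingParams, rna):
    """Replacement fraction g at relative RNA expression `rna` (>= 0)."""
    rna_arr = np.asarray(rna, dtype=float)
    if np.any(rna_arr < 0):
        raise ValueError("rna must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(rna_arr > 0, mp.rho50 / np.maximum(rna_arr, 1e-300), np.inf)
        out = np.where(rna_arr > 0, mp.g_max / (1.0 + ratio**mp.steepness), 0.0)
    return float(out) if np.ndim(rna) == 0 else out


# default exploration ranges for the mapping parameters; they bracket
# saturating replacement fractions from well below 1% up to tens of percent
DEFAULT_RANGES = {
    "g_max": (1e-3, 0.5),
    "rho50": (1.0, 1e3),
    "steepness": (0.5, 2.0),
}


def sample_mapping_params(param_ranges: dict | None, n_samples: int,
                          seed: int) -> list[MappingParams]:
    """Log-uniform draws of (g_max, rho50, steepness) triples."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = dict(DEFAULT_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for key, (lo, hi) in ranges.items():
        if not 0 < lo <= hi:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        vals = {}
        for key in ("g_max", "rho50", "steepness"):
            lo, hi = ranges[key]
            vals[key] = float(lo * np.exp(rng.uniform(0.0, np.log(hi / lo)))) if hi > lo else float(lo)
        out.append(MappingParams(**vals))
    return out


def mapping_envelope(param_ranges: dict | None, n_samples: int, seed: int,
                     rna_grid: Sequence[float] | None = None
                     ) -> tuple[list[MappingParams], pd.DataFrame]:
    """Family of mapping curves over log-uniform parameter draws.

    Returns the sampled parameter triples and a tidy table with one row per
    (sample, rna) pair; deterministic for a fixed seed.
    """
    if rna_grid is None:
        rna_grid = np.geomspace(0.1, 1e4, 60)
    rna_grid = np.asarray(rna_grid, dtype=float)
    samples = sample_mapping_params(param_ranges, n_samples, seed)
    frames = []
    for i, mp in enumerate(samples):
        frames.append(pd.DataFrame({
            "sample": i,
            "rna": rna_grid,
            "g": map_rna_to_g(mp, rna_grid),
            "g_max": mp.g_max,
            "rho50": mp.rho50,
            "steepness": mp.steepness,
        }))
    return samples, pd.concat(frames, ignore_index=True)
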