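"""Synthetic dose-response datasets with the structure of the agonist
titration experiment.

The emulated design: a panel of animals expressing an inducible agonist
peptide in the thymus at graded levels (measured as RNA expression relative
to controls, spanning roughly three orders of magnitude), plus control
animals without induction.  Per animal the observed quantities are the
absolute conventional and regulatory lineage counts, modelled as

    count = round( K * P_fate(g(rna)) * 10^eps ),   eps ~ Normal(0, noise_sd_log10)

with K the precursor scaling constant and multiplicative lognormal
measurement noise (scatter is roughly symmetric on a log axis).  Controls
are generated at g = 0.  Every dataset is bit-reproducible from its seed
and carries its generating truth alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration_fitting import (
    ControlFractions,
    calibrate_thresholds_nsum,
    calibrate_two_phase,
)
from .dose_mapping import MappingParams, map_rna_to_g
from .fate_models import TwoPhaseParams, fate_probs_nsum, two_phase_agonist
from .signal_model import (
    EncounterModel,
    Thresholds,
    agonist_strength_from_percentile,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a generated dataset.

    generating_model is "nsum" (needs encounter_model, thresholds, n) or
    "two_phase" (needs two_phase, agonist zones).  Defaults emulate the
    titration experiment: 24 induced animals with RNA levels log-uniform
    over three orders of magnitude, 4 controls, multiplicative count noise
    of 0.15 on the log10 scale.
    """

    generating_model: str
    mapping: MappingParams
    K: float
    seed: int
    encounter_model: Optional[EncounterModel] = None
    thresholds: Optional[Thresholds] = None
    n: Optional[float] = None
    two_phase: Optional[TwoPhaseParams] = None
    zoneA: str = "reg"
    zoneB: str = "deletion"
    noise_sd_log10: float = 0.15
    n_animals: int = 24
    n_controls: int = 4
    rna_range: tuple[float, float] = (1.0, 1000.0)

    def __post_init__(self):
        if self.generating_model not in ("nsum", "two_phase"):
            raise ValueError("generating_model must be 'nsum' or 'two_phase'")
        if self.generating_model == "nsum" and (
                self.encounter_model is None or self.thresholds is None
                or self.n is None):
            raise ValueError("nsum truth needs encounter_model, thresholds, n")
        if self.generating_model == "two_phase" and self.two_phase is None:
            raise ValueError("two_phase truth needs two_phase params")
        lo, hi = self.rna_range
        if not (0 < lo < hi):
            raise ValueError("rna_range must satisfy 0 < low < high")
        if self.n_animals < 2:
            raise ValueError("need at least 2 induced animals")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be non-negative")

    def fate_probs(self, g: float):
        if self.generating_model == "nsum":
            return fate_probs_nsum(self.encounter_model.with_g(g),
                                   self.thresholds, self.n)
        return two_phase_agonist(self.two_phase, g, self.zoneA, self.zoneB)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["rna_range"] = list(self.rna_range)
        return d


def default_nsum_truth(seed: int, N: int = 3, n: float = 1000.0,
                       frac_conv: float = 0.85, frac_reg: float = 0.03,
                       s_tim_percentile: float = 0.999,
                       mapping: MappingParams | None = None,
                       K: float = 1e5, **kwargs) -> SyntheticTruth:
    """N-sum truth with thresholds calibrated to control fractions and the
    agonist at a high contact-strength percentile (rise-then-fall regime)."""
    cf = ControlFractions(frac_conv, frac_reg)
    base = EncounterModel(N=N)
    th = calibrate_thresholds_nsum(cf, n, base)
    model = replace(base, s_tim=agonist_strength_from_percentile(base, s_tim_percentile))
    if mapping is None:
        # saturating replacement fraction past the reg-lineage turnover of the
        # default model, so the emulated titration shows the rise-then-fall
        mapping = MappingParams(g_max=0.2, rho50=30.0, steepness=1.0)
    return SyntheticTruth(generating_model="nsum", mapping=mapping, K=K,
                          seed=seed, encounter_model=model, thresholds=th,
                          n=n, **kwargs)


def default_two_phase_truth(seed: int, nA: float = 20.0, nB: float = 980.0,
                            d_A: float = 1e-3, frac_conv: float = 0.85,
                            frac_reg: float = 0.01,
                            mapping: MappingParams | None = None,
                            K: float = 1e5, **kwargs) -> SyntheticTruth:
    """Two-phase truth calibrated to control fractions (agonist: reg zone in
    phase A, deletion zone in phase B).

    The rise-then-fall of the regulatory lineage requires the phase-A commit
    gain (~ nA * frac_conv) to exceed the agonist deletion of the baseline
    reg mass (~ nB * frac_reg); the defaults (control reg fraction 1%,
    phase-A share 2%) satisfy this, mirroring the titration data's shape.
    """
    cf = ControlFractions(frac_conv, frac_reg)
    tp = calibrate_two_phase(cf, nA, nB, d_A)
    if mapping is None:
        # the two-phase turnover sits at g ~ 1/nB; span it within the RNA range
        mapping = MappingParams(g_max=0.01, rho50=100.0, steepness=1.0)
    return SyntheticTruth(generating_model="two_phase", mapping=mapping, K=K,
                          seed=seed, two_phase=tp, **kwargs)


def generate_dataset(truth: SyntheticTruth) -> pd.DataFrame:
    """Generate one dose-response dataset from its truth record.

    RNA levels are log-uniform over rna_range; expected counts are
    K * P_fate at g = g(rna); observed counts are the expectations
    perturbed by 10^eps noise and rounded (floored at 0).  Controls are
    generated at g = 0.
    """
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.rna_range
    rna = np.exp(rng.uniform(np.log(lo), np.log(hi), size=truth.n_animals))
    rna.sort()
    rows = []
    expected_any = False
    for i, r in enumerate(rna):
        g = map_rna_to_g(truth.mapping, r)
        fp = truth.fate_probs(g)
        exp_conv, exp_reg = truth.K * fp.conv, truth.K * fp.reg
        expected_any = expected_any or exp_conv >= 1 or exp_reg >= 1
        eps = rng.normal(0.0, truth.noise_sd_log10, size=2)
        rows.append({
            "animal_id": f"ind{i:03d}", "rna_relative": float(r),
            "is_control": 0,
            "tconv_count": int(max(0, round(exp_conv * 10.0 ** eps[0]))),
            "treg_count": int(max(0, round(exp_reg * 10.0 ** eps[1]))),
        })
    fp0 = truth.fate_probs(0.0)
    for i in range(truth.n_controls):
        eps = rng.normal(0.0, truth.noise_sd_log10, size=2)
        rows.append({
            "animal_id": f"ctl{i:03d}", "rna_relative": 0.0, "is_control": 1,
            "tconv_count": int(max(0, round(truth.K * fp0.conv * 10.0 ** eps[0]))),
            "treg_count": int(max(0, round(truth.K * fp0.reg * 10.0 ** eps[1]))),
        })
    if not expected_any:
        import warnings
        warnings.warn("all expected induced counts are below 1")
    return pd.DataFrame(rows)


def noise_free_means(truth: SyntheticTruth, rna: Sequence[float]) -> pd.DataFrame:
    """Expected (noise-free) counts K * P over an RNA grid."""
    rows = []
    for r in np.asarray(rna, dtype=float):
        g = map_rna_to_g(truth.mapping, r) if r > 0 else 0.0
        fp = truth.fate_probs(g)
        rows.append({"rna_relative": r, "g": g,
                     "tconv_mean": truth.K * fp.conv,
                     "treg_mean": truth.K * fp.reg})
    return pd.DataFrame(rows)


def control_fractions_of(truth: SyntheticTruth) -> ControlFractions:
    """The generating model's own selection fractions at g = 0."""
    fp0 = truth.fate_probs(0.0)
    return ControlFractions(fp0.conv, fp0.reg)


def make_recovery_suite(truth: SyntheticTruth, n_replicates: int,
                        master_seed: int | None = None):
    """Replicate datasets sharing the truth parameters but distinct seeds.

    Seeds are spawned deterministically from the master seed (default: the
    truth's own seed).  Returns (list of (dataset, truth) pairs, manifest).
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    master = truth.seed if master_seed is None else master_seed
    rng = np.random.default_rng(master)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    pairs = []
    manifest_rows = []
    for i, s in enumerate(seeds):
        t = replace(truth, seed=int(s))
        pairs.append((generate_dataset(t), t))
        manifest_rows.append({"replicate": i, "seed": int(s),
                              "generating_model": truth.generating_model})
    return pairs, pd.DataFrame(manifest_rows)


def write_dataset(df: pd.DataFrame, path: str | Path,
                  truth: SyntheticTruth | None = None) -> None:
    """Write the dataset CSV, with an optional truth JSON sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth.to_json_dict(), indent=2,
                                      default=float))


def read_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
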