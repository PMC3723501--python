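"""Whole-development fate probabilities for the candidate selection models.

A thymocyte makes at most n encounters.  A deletion-zone signal terminates
development at any encounter; a reg-zone signal marks the cell for the
regulatory lineage (the mark survives unless the cell is later deleted);
a cell that passes positive selection without a reg mark becomes a
conventional T cell; a cell whose every encounter stays below the positive
selection threshold dies by neglect.  Because deletion is absorbing and the
reg mark is order-free, the fate probabilities have closed forms in the
per-encounter zone probabilities (p0, p1, p2, p3):

    neglect = p0^n
    conv    = (p0+p1)^n - p0^n
    reg     = (p0+p1+p2)^n - (p0+p1)^n
    deleted = 1 - (p0+p1+p2)^n

Three model classes reuse this composition:

* the one-hit model: N = 1 contact per encounter, static thresholds;
* the N-sum model: each encounter sums N proximal contacts, so the
  per-encounter zone probabilities come from the N-fold sum distribution;
* the two-phase model: N = 1 with TCR sensitivity differing between an
  early and a late developmental phase, so the same ligand can map to
  different zones in phase A and phase B.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_model import (
    ZONES,
    CategoryProbs,
    EncounterModel,
    Thresholds,
    category_probs,
    category_probs_grid,
)

FATES = ("neglect", "conv", "reg", "deleted")


@dataclass(frozen=True)
class FateProbs:
    """Probabilities of the four developmental outcomes; sums to 1."""

    neglect: float
    conv: float
    reg: float
    deleted: float

    def as_array(self) -> tuple[float, float, float, float]:
        return (self.neglect, self.conv, self.reg, self.deleted)


@dataclass(frozen=True)
class TwoPhaseParams:
    """Encounter budgets and per-phase zone probabilities for phases A and B.

    nA and nB may be real-valued (powers are well defined); d_A, the
    per-encounter deletion probability from endogenous ligands in the
    low-sensitivity phase, is an alias of probsA.p3.
    """

    nA: float
    nB: float
    probsA: CategoryProbs
    probsB: CategoryProbs

    def __post_init__(self):
        if self.nA < 0 or self.nB < 0 or self.nA + self.nB <= 0:
            raise ValueError("need nA >= 0, nB >= 0, nA + nB > 0")

    @property
    def d_A(self) -> float:
        return self.probsA.p3

    def swapped(self) -> "TwoPhaseParams":
        return TwoPhaseParams(self.nB, self.nA, self.probsB, self.probsA)


def _compose(p0, p1, p2, n):
    """Order-free fate composition; accepts scalars or arrays."""
    s0 = np.asarray(p0, dtype=float)
    s1 = s0 + p1
    s2 = s1 + p2
    neglect = s0**n
    conv = s1**n - neglect
    reg = s2**n - s1**n
    deleted = 1.0 - s2**n
    return neglect, conv, reg, deleted


def fate_probs_onehit(p: CategoryProbs, n: float) -> FateProbs:
    """Fate probabilities after a budget of n encounters with static zone
    probabilities p (the one-hit composition; n >= 1)."""
    if n < 1:
        raise ValueError("encounter budget n must be >= 1")
    neg, conv, reg, dele = _compose(p.p0, p.p1, p.p2, n)
    return FateProbs(float(neg), float(conv), float(reg), float(dele))


def mix_agonist(p: CategoryProbs, g: float, zone: str) -> CategoryProbs:
    """Superimpose an agonist point mass of weight g on the zone it falls in:
    every component is scaled by (1 - g) and g is added to `zone`."""
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {ZONES}, got {zone!r}")
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"g must lie in [0, 1], got {g}")
    comps = [(1.0 - g) * c for c in p.as_array()]
    comps[ZONES.index(zone)] += g
    return CategoryProbs(*comps)


def conv_agonist_law(n: float, g: float, baseline_conv: float) -> float:
    """Conventional-lineage selection probability under agonist expression in
    the p0 = 0 regime with the agonist at or above the reg threshold:
    P(conv | g) = (1 - g)^n * P(conv | 0), independent of the thresholds."""
    return (1.0 - g) ** n * baseline_conv


def fate_probs_nsum(model: EncounterModel, th: Thresholds, n: float,
                    method: str = "auto") -> FateProbs:
    """Fate probabilities in the N-sum model: zone probabilities from the
    N-contact encounter distribution (at the model's agonist fraction g),
    composed over a budget of n encounters."""
    p = category_probs(model, th, method=method)
    return fate_probs_onehit(p, n)


def fate_probs_two_phase(tp: TwoPhaseParams) -> FateProbs:
    """Closed-form fate probabilities for the two-phase model.

    With survX = (1-p3X)^nX and noRegX = (1-p2X-p3X)^nX the fates factor
    across phases; the output is invariant under swapping the phases.
    """
    pA, pB = tp.probsA, tp.probsB
    survA = (1.0 - pA.p3) ** tp.nA
    survB = (1.0 - pB.p3) ** tp.nB
    noRegA = (1.0 - pA.p2 - pA.p3) ** tp.nA
    noRegB = (1.0 - pB.p2 - pB.p3) ** tp.nB
    negA = pA.p0 ** tp.nA
    negB = pB.p0 ** tp.nB
    deleted = 1.0 - survA * survB
    reg = survA * survB - noRegA * noRegB
    conv = noRegA * noRegB - negA * negB
    neglect = negA * negB
    return FateProbs(neglect, conv, reg, deleted)


def two_phase_agonist(tp: TwoPhaseParams, g: float, zoneA: str = "reg",
                      zoneB: str = "deletion") -> FateProbs:
    """Fate probabilities with agonist fraction g mixed into each phase at
    its own zone (defaults encode the increasing-sensitivity scenario:
    agonist triggers reg commitment early, deletion late)."""
    mixed = TwoPhaseParams(
        tp.nA, tp.nB,
        mix_agonist(tp.probsA, g, zoneA),
        mix_agonist(tp.probsB, g, zoneB),
    )
    return fate_probs_two_phase(mixed)


def scan_agonist_dose(model_kind: str, params, g_grid: Sequence[float],
                      method: str = "auto") -> pd.DataFrame:
    """Dose-response scan: one FateProbs row per agonist fraction g.

    model_kind "nsum": params = (EncounterModel, Thresholds, n).
    model_kind "two_phase": params = (TwoPhaseParams, zoneA, zoneB).
    """
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.ndim != 1 or len(g_grid) == 0:
        raise ValueError("g_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(g_grid) <= 0):
        raise ValueError("g_grid must be strictly increasing")
    if np.any((g_grid < 0) | (g_grid > 1)):
        raise ValueError("g values must lie in [0, 1]")
    rows = []
    if model_kind == "nsum":
        model, th, n = params
        probs = category_probs_grid(model, th, g_grid, method=method)
        neg, conv, reg, dele = _compose(probs[:, 0], probs[:, 1], probs[:, 2], n)
        rows = np.stack([neg, conv, reg, dele], axis=1)
    elif model_kind == "two_phase":
        tp, zoneA, zoneB = params
        rows = np.array([
            two_phase_agonist(tp, g, zoneA, zoneB).as_array() for g in g_grid
        ])
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    out = pd.DataFrame(rows, columns=list(FATES))
    out.insert(0, "g", g_grid)
    out.insert(0, "model", model_kind)
    return out


def _monotone_verdict(y: np.ndarray, tol: float = 1e-12) -> dict:
    d = np.diff(y)
    imax = int(np.argmax(y))
    return {
        "non_decreasing": bool(np.all(d >= -tol)),
        "non_increasing": bool(np.all(d <= tol)),
        "interior_maximum": bool(
            0 < imax < len(y) - 1
            and y[imax] > y[0] + tol and y[imax] > y[-1] + tol),
    }


def onehit_rejection_check(p: CategoryProbs, n: float,
                           g_grid: Sequence[float]) -> dict:
    """Monotonicity audit of the one-hit (N=1, static thresholds) model.

    For each possible zone placement of the agonist signal, scans reg(g)
    over g_grid and reports whether it is monotone.  For strongly selecting
    baselines (conv fraction large, reg fraction small — the calibrated
    regime) reg(g) is monotone in every zone, so the one-hit model cannot
    produce the rise-then-fall of the regulatory lineage seen in the
    titration data; this is the model-rejection argument.

    Also reports, for the reg-zone placement, whether the stepwise increase
    in reg is at least the stepwise decline in conv.
    """
    g_grid = np.asarray(g_grid, dtype=float)
    report = {}
    for zone in ZONES:
        fates = np.array([
            fate_probs_onehit(mix_agonist(p, g, zone), n).as_array()
            for g in g_grid
        ])
        reg = fates[:, 2]
        verdict = _monotone_verdict(reg)
        verdict["monotone"] = verdict["non_decreasing"] or verdict["non_increasing"]
        if zone == "reg":
            conv = fates[:, 1]
            verdict["reg_rise_covers_conv_decline"] = bool(
                np.all(np.diff(reg) + np.diff(conv) >= -1e-12))
        report[zone] = verdict
    report["all_monotone"] = all(report[z]["monotone"] for z in ZONES)
    return report


def partial_vs_full_agonist(tp: TwoPhaseParams, g_grid: Sequence[float],
                            partial_zones: tuple[str, str] = ("conv", "deletion"),
                            full_zones: tuple[str, str] = ("reg", "deletion")) -> dict:
    """Compare a partial and a full agonist under the two-phase model.

    The partial agonist is too weak to trigger reg commitment in the
    low-sensitivity phase A (default zone conv) but deletes in the sensitive
    phase B; the full agonist triggers reg commitment in A and deletion in
    B.  Reports, per agonist, whether deletion increases with g and whether
    reg(g) has an interior maximum.  The two-phase model yields
    (partial: deletion up, no reg increase; full: reg rise-then-fall).
    """
    out = {}
    for label, (zA, zB) in (("partial", partial_zones), ("full", full_zones)):
        scan = scan_agonist_dose("two_phase", (tp, zA, zB), g_grid)
        reg = scan["reg"].to_numpy()
        dele = scan["deleted"].to_numpy()
        out[label] = {
            "deletion_increasing": bool(np.all(np.diff(dele) >= -1e-12)),
            "reg_non_increasing": bool(np.all(np.diff(reg) <= 1e-12)),
            "reg_interior_maximum": bool(
                reg.argmax() not in (0, len(reg) - 1) and reg.max() > reg[0] + 1e-12),
            "scan": scan,
        }
    out["discriminates"] = (
        out["partial"]["deletion_increasing"]
        and not out["partial"]["reg_interior_maximum"]
        and out["full"]["reg_interior_maximum"]
    )
    return out


def nsum_partial_full_sweep(n_draws: int, seed: int,
                            g_grid: Sequence[float] | None = None,
                            method: str = "auto") -> pd.DataFrame:
    """Sweep random static-threshold N-sum parameterizations, pairing each
    with a weaker (partial) and a stronger (full) agonist, and record which
    qualitative dose-response patterns each produces.

    A static N-sum model cannot produce the partial pattern (deletion up
    with no reg increase) and the full pattern (reg interior maximum)
    simultaneously: a partial agonist that pushes the encounter distribution
    past the deletion threshold implies the stronger agonist does too, so
    reg(g) cannot rise.  The returned table has one row per parameter draw
    with boolean pattern columns; `both_patterns` should never be True.
    """
    from .calibration_fitting import ControlFractions, calibrate_thresholds_nsum

    if g_grid is None:
        g_grid = np.linspace(0.0, 0.2, 41)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_draws):
        N = int(rng.integers(2, 6))
        n = float(rng.choice([100.0, 1000.0]))
        frac_conv = rng.uniform(0.5, 0.95)
        frac_reg = rng.uniform(0.005, min(0.1, 0.98 - frac_conv))
        cf = ControlFractions(frac_conv, frac_reg)
        base = EncounterModel(N=N)
        th = calibrate_thresholds_nsum(cf, n, base, method=method)
        # two contact strengths spanning weak to saturating recognition; the
        # weaker is the partial agonist, the stronger the full agonist
        u = 1.0 - 10.0 ** rng.uniform(-5.0, -1.3, size=2)
        pct_partial, pct_full = float(np.min(u)), float(np.max(u))
        from .signal_model import agonist_strength_from_percentile
        patterns = {}
        for label, pct in (("partial", pct_partial), ("full", pct_full)):
            model = replace(base, s_tim=agonist_strength_from_percentile(base, pct))
            scan = scan_agonist_dose("nsum", (model, th, n), g_grid, method=method)
            reg = scan["reg"].to_numpy()
            dele = scan["deleted"].to_numpy()
            patterns[label + "_deletion_up"] = bool(np.all(np.diff(dele) >= -1e-12))
            patterns[label + "_reg_no_increase"] = bool(np.all(np.diff(reg) <= 1e-9))
            patterns[label + "_reg_interior_max"] = bool(
                reg.argmax() not in (0, len(reg) - 1) and reg.max() > reg[0] + 1e-9)
        patterns["both_patterns"] = (
            patterns["partial_deletion_up"] and patterns["partial_reg_no_increase"]
            and patterns["full_reg_interior_max"])
        rows.append({"draw": i, "N": N, "n": n, "frac_conv": frac_conv,
                     "frac_reg": frac_reg, "pct_partial": pct_partial,
                     "pct_full": pct_full, **patterns})
    return pd.DataFrame(rows)


def predict_efficiency_vs_affinity(model_kind: str, params,
                                   clone_shifts: Sequence[float],
                                   g: float = 0.01,
                                   method: str = "auto") -> pd.DataFrame:
    """Regulatory-lineage selection probability for TCR clones whose agonist
    (self-ligand) contact strength is shifted on the log scale.

    model_kind "nsum": params = (EncounterModel, Thresholds, n); the shift
    multiplies s_tim by exp(shift).
    model_kind "two_phase": params = (TwoPhaseParams, EncounterModel,
    Thresholds_A, Thresholds_B, s_tim); the shifted strength is classified
    into a zone per phase via the phase thresholds, and the expected share
    of reg commitments occurring in phase A is also returned.
    """
    rows = []
    if model_kind == "nsum":
        model, th, n = params
        for shift in clone_shifts:
            shifted = replace(model, s_tim=model.s_tim * float(np.exp(shift)), g=g)
            fp = fate_probs_nsum(shifted, th, n, method=method)
            rows.append({"shift": shift, "reg": fp.reg})
    elif model_kind == "two_phase":
        tp, thA, thB, s_tim = params
        for shift in clone_shifts:
            s = s_tim * float(np.exp(shift))
            zA, zB = thA.zone_of(s), thB.zone_of(s)
            fp = two_phase_agonist(tp, g, zA, zB)
            mixedA = mix_agonist(tp.probsA, g, zA)
            mixedB = mix_agonist(tp.probsB, g, zB)
            survA = (1.0 - mixedA.p3) ** tp.nA
            survB = (1.0 - mixedB.p3) ** tp.nB
            noRegA = (1.0 - mixedA.p2 - mixedA.p3) ** tp.nA
            commitA = (survA - noRegA) * survB
            share = commitA / fp.reg if fp.reg > 0 else np.nan
            rows.append({"shift": shift, "reg": fp.reg, "phase_A_commit_share": share})
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return pd.DataFrame(rows)
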