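"""Per-cell Monte-Carlo simulation of sequential encounters.

This is the brute-force oracle for the closed-form fate probabilities: each
cell draws its encounter categories (or raw summed contact strengths)
independently and sequentially, deletion terminates development at the
encounter where it occurs, a reg-zone signal marks the cell, and at budget
exhaustion the fate resolves reg > conv > neglect from the recorded flags.

Two modes are exposed:

``category``
    Encounter categories are drawn directly from pre-resolved zone
    probabilities.  This isolates the fate-composition logic from the
    signal-strength distribution.

``strength``
    Each encounter draws N raw contact strengths (agonist / null /
    lognormal endogenous mixture), sums them and classifies the sum against
    the thresholds.  This exercises the signal model end to end.

Simulation draws a full (cells x encounters) matrix per chunk from a single
seeded generator, so results do not depend on execution order; fates are
then resolved by vectorised first-occurrence scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fate_models import FATES, FateProbs, TwoPhaseParams
from .signal_model import EncounterModel, Thresholds


@dataclass(frozen=True)
class CellTrace:
    """Realised trajectory of one simulated thymocyte."""

    fate: str
    encounters_used: int
    commit_index: Optional[int] = None  # encounter of the first reg-zone signal
    phase_of_commit: Optional[str] = None

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"fate must be one of {FATES}")
        if self.commit_index is not None and self.commit_index > self.encounters_used:
            raise ValueError("commit_index cannot exceed encounters_used")


@dataclass
class CohortSummary:
    """Aggregate fate fractions of a simulated cohort with binomial SEs."""

    cells: int
    counts: dict
    fractions: dict
    standard_errors: dict
    commit_indices: np.ndarray  # first reg-signal encounter of reg-fated cells
    commit_phases: np.ndarray
    mean_encounters_used: float

    def as_fate_probs(self) -> FateProbs:
        return FateProbs(*(self.fractions[f] for f in FATES))


def _first_true_index(mask: np.ndarray) -> np.ndarray:
    """Per-row index of the first True, or n_cols where none (1-based later)."""
    n_cols = mask.shape[1]
    any_true = mask.any(axis=1)
    idx = np.where(any_true, mask.argmax(axis=1), n_cols)
    return idx


def _resolve_fates(cat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fates from a (cells x n) category matrix.

    Returns (fate codes 0..3 indexing FATES, encounters_used, commit_index
    with -1 for cells that never received a reg-zone signal before the
    decision point).
    """
    n = cat.shape[1]
    t3 = _first_true_index(cat == 3)  # 0-based index of first deletion signal
    t2 = _first_true_index(cat == 2)
    deleted = t3 < n
    reg = (~deleted) & (t2 < n)
    all_neglect = (cat == 0).all(axis=1)
    neglect = (~deleted) & (~reg) & all_neglect
    fate = np.full(cat.shape[0], 1, dtype=np.int8)  # default conv
    fate[neglect] = 0
    fate[reg] = 2
    fate[deleted] = 3
    used = np.where(deleted, t3 + 1, n)
    commit = np.where((t2 < n) & (t2 < used), t2 + 1, -1)  # 1-based
    # a reg mark only counts if it happened before deletion; deletion always wins
    return fate, used, commit


def _draw_categories(rng, cells: int, n: int, probs: np.ndarray) -> np.ndarray:
    edges = np.cumsum(probs)[:-1]
    u = rng.uniform(size=(cells, n))
    return np.searchsorted(edges, u, side="right").astype(np.int8)


def _draw_strength_categories(rng, cells: int, n: int, model: EncounterModel,
                              th: Thresholds) -> np.ndarray:
    g, fn, _ = model.contact_probs
    u = rng.uniform(size=(cells, n, model.N))
    ln = np.exp(rng.normal(model.mu_log, model.sigma_log,
                           size=(cells, n, model.N)))
    contacts = np.where(u < g, model.s_tim, np.where(u < g + fn, 0.0, ln))
    s = contacts.sum(axis=2)
    cat = np.full(s.shape, 0, dtype=np.int8)
    cat[s >= th.a] = 1
    cat[s >= th.b] = 2
    cat[s >= th.c] = 3
    return cat


def _category_matrix(rng, cells, spec) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw the (cells x budget) category matrix for one chunk.

    spec is ("category", probs: CategoryProbs, n) or
    ("strength", model, thresholds, n) or
    ("two_phase", TwoPhaseParams)  (integer budgets; phase A first).
    Returns the matrix and, for two-phase, the per-encounter phase labels.
    """
    kind = spec[0]
    if kind == "category":
        _, probs, n = spec
        return _draw_categories(rng, cells, int(n),
                                np.array(probs.as_array())), None
    if kind == "strength":
        _, model, th, n = spec
        return _draw_strength_categories(rng, cells, int(n), model, th), None
    if kind == "two_phase":
        tp: TwoPhaseParams = spec[1]
        nA, nB = int(round(tp.nA)), int(round(tp.nB))
        parts = []
        if nA:
            parts.append(_draw_categories(rng, cells, nA,
                                          np.array(tp.probsA.as_array())))
        if nB:
            parts.append(_draw_categories(rng, cells, nB,
                                          np.array(tp.probsB.as_array())))
        phases = np.concatenate([np.repeat("A", nA), np.repeat("B", nB)])
        return np.concatenate(parts, axis=1), phases
    raise ValueError(f"unknown simulation spec {kind!r}")


def simulate_cell(spec, seed: int) -> CellTrace:
    """Simulate a single thymocyte; see :func:`simulate_cohort` for specs."""
    rng = np.random.default_rng(seed)
    cat, phases = _category_matrix(rng, 1, spec)
    fate, used, commit = _resolve_fates(cat)
    commit_index = int(commit[0]) if commit[0] > 0 else None
    phase = None
    if commit_index is not None and phases is not None:
        phase = str(phases[commit_index - 1])
    return CellTrace(FATES[fate[0]], int(used[0]), commit_index, phase)


def simulate_cohort(spec, cells: int, seed: int,
                    chunk_cells: int = 20_000,
                    return_traces: bool = False):
    """Simulate a cohort of independent thymocytes.

    ``spec`` selects the model and mode:

    * ``("category", CategoryProbs, n)`` — static zone probabilities,
      budget n;
    * ``("strength", EncounterModel, Thresholds, n)`` — raw N-contact sums
      classified by thresholds;
    * ``("two_phase", TwoPhaseParams)`` — integer phase budgets, phase A
      first (the fate law is order-invariant).

    Returns a :class:`CohortSummary`, plus a trace DataFrame when
    ``return_traces`` is set.  Reproducible for a fixed seed; a cohort of M
    cells is M independent cells in law.
    """
    if cells < 1:
        raise ValueError("cells must be >= 1")
    # keep per-chunk draw matrices bounded (~tens of MB)
    if spec[0] == "strength":
        _, model, _, n = spec
        chunk_cells = min(chunk_cells, max(1, 4_000_000 // (int(n) * model.N)))
    elif spec[0] == "category":
        chunk_cells = min(chunk_cells, max(1, 20_000_000 // int(spec[2])))
    else:
        tp = spec[1]
        chunk_cells = min(chunk_cells,
                          max(1, 20_000_000 // max(1, int(tp.nA + tp.nB))))
    rng = np.random.default_rng(seed)
    counts = np.zeros(4, dtype=np.int64)
    used_total = 0
    commits = []
    commit_phases = []
    traces = [] if return_traces else None
    done = 0
    phases = None
    while done < cells:
        k = min(chunk_cells, cells - done)
        cat, phases = _category_matrix(rng, k, spec)
        fate, used, commit = _resolve_fates(cat)
        counts += np.bincount(fate, minlength=4)
        used_total += int(used.sum())
        has_commit = (commit > 0) & (fate == 2)
        commits.append(commit[has_commit])
        if phases is not None:
            commit_phases.append(phases[commit[has_commit] - 1])
        if return_traces:
            for i in range(k):
                ci = int(commit[i]) if commit[i] > 0 else None
                ph = str(phases[ci - 1]) if (ci and phases is not None) else None
                traces.append((done + i, FATES[fate[i]], int(used[i]), ci, ph))
        done += k
    fractions = {f: counts[i] / cells for i, f in enumerate(FATES)}
    ses = {f: float(np.sqrt(p * (1 - p) / cells)) for f, p in fractions.items()}
    summary = CohortSummary(
        cells=cells,
        counts={f: int(counts[i]) for i, f in enumerate(FATES)},
        fractions=fractions,
        standard_errors=ses,
        commit_indices=np.concatenate(commits) if commits else np.array([], dtype=int),
        commit_phases=(np.concatenate(commit_phases)
                       if commit_phases else np.array([], dtype="U1")),
        mean_encounters_used=used_total / cells,
    )
    if return_traces:
        df = pd.DataFrame(traces, columns=[
            "cell_id", "fate", "encounters_used", "commit_index",
            "phase_of_commit"])
        return summary, df
    return summary
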