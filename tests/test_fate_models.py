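"""Fate composition closed forms, agonist mixing, and qualitative scans."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thymoselect import (
    CategoryProbs,
    ControlFractions,
    EncounterModel,
    Thresholds,
    TwoPhaseParams,
    calibrate_thresholds_nsum,
    calibrate_two_phase,
    conv_agonist_law,
    fate_probs_nsum,
    fate_probs_onehit,
    fate_probs_two_phase,
    mix_agonist,
    onehit_rejection_check,
    partial_vs_full_agonist,
    predict_efficiency_vs_affinity,
    scan_agonist_dose,
    two_phase_agonist,
)
from thymoselect.signal_model import category_probs

from conftest import calibrated_category_probs, random_category_probs


def enumerate_onehit(p: CategoryProbs, n: int) -> dict:
    """Independent oracle: exhaustive enumeration of all 4^n category
    sequences with the sequential fate rules (deletion absorbs, a reg-zone
    signal marks the cell, conv needs at least one above-positive signal)."""
    probs = p.as_array()
    out = dict.fromkeys(("neglect", "conv", "reg", "deleted"), 0.0)
    for seq in itertools.product(range(4), repeat=n):
        weight = math.prod(probs[cat] for cat in seq)
        fate = None
        reg_mark = False
        pos_mark = False
        for cat in seq:
            if cat == 3:
                fate = "deleted"  # encounters after the first deletion signal
                break             # never happen; their weight marginalises out
            reg_mark = reg_mark or cat == 2
            pos_mark = pos_mark or cat >= 1
        if fate is None:
            fate = "reg" if reg_mark else ("conv" if pos_mark else "neglect")
        out[fate] += weight
    return out


def enumerate_two_phase(tp: TwoPhaseParams) -> dict:
    """Oracle for integer phase budgets: enumeration over phase-labelled
    category sequences."""
    nA, nB = int(tp.nA), int(tp.nB)
    pA, pB = tp.probsA.as_array(), tp.probsB.as_array()
    out = dict.fromkeys(("neglect", "conv", "reg", "deleted"), 0.0)
    for seq in itertools.product(range(4), repeat=nA + nB):
        weight = math.prod((pA if i < nA else pB)[cat]
                           for i, cat in enumerate(seq))
        fate = None
        reg_mark = False
        pos_mark = False
        for cat in seq:
            if cat == 3:
                fate = "deleted"
                break
            reg_mark = reg_mark or cat == 2
            pos_mark = pos_mark or cat >= 1
        if fate is None:
            fate = "reg" if reg_mark else ("conv" if pos_mark else "neglect")
        out[fate] += weight
    return out


class TestOnehitComposition:
    def test_degenerate(self):
        assert fate_probs_onehit(CategoryProbs(1, 0, 0, 0), 7).as_array() == (1, 0, 0, 0)
        assert fate_probs_onehit(CategoryProbs(0, 0, 0, 1), 1).deleted == 1.0

    def test_worked_example(self):
        fp = fate_probs_onehit(CategoryProbs(0, 0.9, 0.08, 0.02), 2)
        assert fp.neglect == 0.0
        assert fp.conv == pytest.approx(0.81, abs=1e-12)
        assert fp.reg == pytest.approx(0.98**2 - 0.81, abs=1e-12)
        assert fp.deleted == pytest.approx(1 - 0.9604, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_matches_enumeration_oracle(self, rng, n):
        for _ in range(5):
            p = random_category_probs(rng)
            fp = fate_probs_onehit(p, n)
            oracle = enumerate_onehit(p, n)
            for fate in oracle:
                assert getattr(fp, fate) == pytest.approx(oracle[fate], abs=1e-12)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.integers(1, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_probabilities_conserve(self, raw, n):
        w = np.array(raw) / sum(raw)
        fp = fate_probs_onehit(CategoryProbs(*w), n)
        assert abs(sum(fp.as_array()) - 1.0) < 1e-12
        assert all(v >= -1e-15 for v in fp.as_array())


class TestAgonistMixing:
    def test_identity_and_saturation(self):
        p = CategoryProbs(0.1, 0.7, 0.15, 0.05)
        assert mix_agonist(p, 0.0, "reg").as_array() == p.as_array()
        assert mix_agonist(p, 1.0, "reg").as_array() == (0, 0, 1, 0)

    def test_worked_example(self):
        mixed = mix_agonist(CategoryProbs(0, 0.9, 0.08, 0.02), 0.1, "reg")
        np.testing.assert_allclose(mixed.as_array(), (0, 0.81, 0.172, 0.018),
                                   atol=1e-12)

    @pytest.mark.parametrize("zone", ["reg", "deletion"])
    def test_conv_law_matches_composition(self, zone):
        """With p0 = 0 and the agonist at/above the reg threshold the
        conventional lineage obeys P(conv|g) = (1-g)^n P(conv|0) exactly,
        independent of the thresholds."""
        p = CategoryProbs(0, 0.9, 0.08, 0.02)
        for n in (1, 3, 10, 100):
            baseline = fate_probs_onehit(p, n).conv
            for g in np.linspace(0, 1, 11):
                law = conv_agonist_law(n, g, baseline)
                direct = fate_probs_onehit(mix_agonist(p, g, zone), n).conv
                assert direct == pytest.approx(law, abs=1e-12)

    def test_conv_law_examples(self):
        assert conv_agonist_law(5, 0.0, 0.7) == 0.7
        assert conv_agonist_law(1, 0.5, 0.9) == pytest.approx(0.45)


class TestNsumModel:
    def test_single_contact_reduces_to_mixing(self):
        th = Thresholds(-math.inf, 2.0, 12.0)
        base = EncounterModel(N=1, s_tim=5.0)
        for g in (0.0, 0.05, 0.3):
            fp = fate_probs_nsum(base.with_g(g), th, 50)
            p0 = category_probs(base, th)
            fp2 = fate_probs_onehit(mix_agonist(p0, g, th.zone_of(5.0)), 50)
            np.testing.assert_allclose(fp.as_array(), fp2.as_array(), atol=1e-10)

    def test_calibration_roundtrip_at_baseline(self, control_fractions):
        m = EncounterModel(N=3)
        th = calibrate_thresholds_nsum(control_fractions, 1000.0, m)
        fp = fate_probs_nsum(m, th, 1000.0)
        assert fp.conv == pytest.approx(0.85, abs=1e-9)
        assert fp.reg == pytest.approx(0.03, abs=1e-9)

    def test_reg_interior_maximum_in_calibrated_regime(self, control_fractions):
        """Signal integration over N=3 contacts turns the agonist titration
        into a rise-then-fall of the regulatory lineage while the
        conventional lineage falls and deletion grows monotonically."""
        from thymoselect import agonist_strength_from_percentile

        base = EncounterModel(N=3)
        th = calibrate_thresholds_nsum(control_fractions, 100.0, base)
        model = replace(base, s_tim=agonist_strength_from_percentile(base, 0.999))
        scan = scan_agonist_dose("nsum", (model, th, 100.0),
                                 np.linspace(0, 0.05, 51))
        reg = scan["reg"].to_numpy()
        imax = reg.argmax()
        assert 0 < imax < len(reg) - 1
        assert reg[imax] > reg[0] and reg[imax] > reg[-1]
        assert np.all(np.diff(scan["conv"]) <= 1e-12)
        assert np.all(np.diff(scan["deleted"]) >= -1e-12)


class TestTwoPhaseModel:
    def test_degenerate_phase_reduces_to_onehit(self):
        pB = CategoryProbs(0.05, 0.8, 0.1, 0.05)
        tp = TwoPhaseParams(0.0, 6.0, CategoryProbs(0, 1, 0, 0), pB)
        fp = fate_probs_two_phase(tp)
        fp2 = fate_probs_onehit(pB, 6)
        np.testing.assert_allclose(fp.as_array(), fp2.as_array(), atol=1e-12)

    def test_worked_example_and_enumeration(self):
        tp = TwoPhaseParams(2.0, 2.0,
                            CategoryProbs(0, 0.98, 0, 0.02),
                            CategoryProbs(0, 0.9, 0.08, 0.02))
        fp = fate_probs_two_phase(tp)
        assert fp.deleted == pytest.approx(1 - 0.98**2 * 0.98**2, abs=1e-12)
        assert fp.reg == pytest.approx(0.98**4 - 0.98**2 * 0.81, abs=1e-12)
        assert fp.conv == pytest.approx(0.98**2 * 0.81, abs=1e-12)
        oracle = enumerate_two_phase(tp)
        for fate in oracle:
            assert getattr(fp, fate) == pytest.approx(oracle[fate], abs=1e-12)

    def test_order_invariance_exact(self, rng):
        for _ in range(20):
            tp = TwoPhaseParams(float(rng.uniform(0, 50)),
                                float(rng.uniform(1, 2000)),
                                random_category_probs(rng),
                                random_category_probs(rng))
            a = fate_probs_two_phase(tp)
            b = fate_probs_two_phase(tp.swapped())
            assert a.as_array() == b.as_array()

    def test_agonist_degenerate_cases(self, rng):
        tp = TwoPhaseParams(5.0, 20.0, random_category_probs(rng),
                            random_category_probs(rng))
        assert (two_phase_agonist(tp, 0.0).as_array()
                == fate_probs_two_phase(tp).as_array())
        assert two_phase_agonist(tp, 1.0, "reg", "deletion").deleted == 1.0

    def test_calibrated_rise_then_fall(self):
        cf = ControlFractions(0.85, 0.01)
        tp = calibrate_two_phase(cf, 20.0, 980.0, 1e-3)
        scan = scan_agonist_dose("two_phase", (tp, "reg", "deletion"),
                                 np.linspace(0, 0.02, 101))
        reg = scan["reg"].to_numpy()
        imax = reg.argmax()
        assert 0 < imax < len(reg) - 1
        assert np.all(np.diff(scan["conv"]) <= 1e-12)
        assert np.all(np.diff(scan["deleted"]) >= -1e-12)


class TestScans:
    def test_single_point_grid_is_baseline(self, rng):
        p = random_category_probs(rng)
        tp = TwoPhaseParams(3.0, 10.0, p, random_category_probs(rng))
        scan = scan_agonist_dose("two_phase", (tp, "reg", "deletion"), [0.0])
        np.testing.assert_allclose(
            scan[["neglect", "conv", "reg", "deleted"]].iloc[0].to_numpy(),
            fate_probs_two_phase(tp).as_array(), atol=1e-12)

    def test_onehit_zone_monotonicity(self, rng):
        """One-hit dose responses: an agonist in the reg zone only adds reg
        signals (reg non-decreasing, gain >= conv loss); in the deletion zone
        it only deletes (reg non-increasing, deleted non-decreasing)."""
        g_grid = np.linspace(0, 1, 50)
        for _ in range(10):
            p, n = calibrated_category_probs(rng)
            fates_reg = np.array([
                fate_probs_onehit(mix_agonist(p, g, "reg"), n).as_array()
                for g in g_grid])
            assert np.all(np.diff(fates_reg[:, 2]) >= -1e-12)
            assert np.all(np.diff(fates_reg[:, 2]) + np.diff(fates_reg[:, 1])
                          >= -1e-12)
            fates_del = np.array([
                fate_probs_onehit(mix_agonist(p, g, "deletion"), n).as_array()
                for g in g_grid])
            assert np.all(np.diff(fates_del[:, 2]) <= 1e-12)
            assert np.all(np.diff(fates_del[:, 3]) >= -1e-12)

    def test_rejection_check_verdicts(self, rng):
        p, n = calibrated_category_probs(rng)
        report = onehit_rejection_check(p, n, np.linspace(0, 1, 200))
        assert report["reg"]["non_decreasing"]
        assert report["reg"]["reg_rise_covers_conv_decline"]
        assert report["deletion"]["non_increasing"]
        assert report["all_monotone"]
        assert not report["reg"]["interior_maximum"]

    def test_partial_vs_full_discrimination(self):
        cf = ControlFractions(0.85, 0.01)
        tp = calibrate_two_phase(cf, 20.0, 980.0, 1e-3)
        rep = partial_vs_full_agonist(tp, np.linspace(0, 0.01, 101))
        assert rep["partial"]["deletion_increasing"]
        assert rep["partial"]["reg_non_increasing"]
        assert not rep["partial"]["reg_interior_maximum"]
        assert rep["full"]["reg_interior_maximum"]
        assert rep["discriminates"]
        # without agonist the two scans coincide
        row_p = rep["partial"]["scan"].iloc[0]
        row_f = rep["full"]["scan"].iloc[0]
        for col in ("neglect", "conv", "reg", "deleted"):
            assert row_p[col] == row_f[col]


class TestEfficiencyVsAffinity:
    def test_nsum_ordering_and_baseline(self, control_fractions):
        from thymoselect import agonist_strength_from_percentile

        base = EncounterModel(N=3)
        th = calibrate_thresholds_nsum(control_fractions, 100.0, base)
        model = replace(base, s_tim=agonist_strength_from_percentile(base, 0.99))
        table = predict_efficiency_vs_affinity(
            "nsum", (model, th, 100.0), [-8.0, 0.0, 0.5], g=0.01)
        regs = table["reg"].to_numpy()
        assert regs[1] <= regs[2] + 1e-12
        # far below the positive threshold the agonist acts as a null
        # contact; reg approaches (but does not exactly equal) the
        # endogenous-only baseline since 1% of contacts are silenced
        baseline = fate_probs_nsum(model.with_g(0.0), th, 100.0).reg
        assert regs[0] == pytest.approx(baseline, rel=0.05)

    def test_two_phase_commit_share(self):
        cf = ControlFractions(0.85, 0.01)
        tp = calibrate_two_phase(cf, 20.0, 980.0, 1e-3)
        m = EncounterModel(N=1)
        thB = Thresholds(-math.inf, 2.0, 10.0)
        thA = Thresholds(-math.inf, 6.0, 30.0)  # less sensitive early phase
        table = predict_efficiency_vs_affinity(
            "two_phase", (tp, thA, thB, 12.0), [-3.0, 0.0, 0.7], g=0.002)
        regs = table["reg"].to_numpy()
        assert np.all(np.isfinite(regs))
        # at shift 0 the ligand is reg-zone in A, deletion-zone in B: all
        # agonist-driven commits happen in phase A
        shares = table["phase_A_commit_share"].to_numpy()
        assert 0.0 <= shares[1] <= 1.0
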