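# thymoselect

Stochastic models of thymocyte fate decisions during thymic selection.

Developing T cells in the thymus sample self peptide–MHC (pMHC) ligands and,
depending on the strength of the TCR signals they receive, die by neglect,
mature into conventional CD4 T cells (T_conv), divert into the Foxp3+
regulatory lineage (T_reg), or are deleted. Experiments that titrate a
cognate agonist peptide in the thymic epithelium show a characteristic
signature: T_conv numbers fall monotonically with agonist expression while
T_reg numbers first rise, then fall. `thymoselect` implements and compares
candidate mechanisms for this behaviour, for modellers and quantitative
immunologists who want to fit, simulate or extend them.

## Models

Every model assumes a strict signal-strength hierarchy of fates
(neglect < T_conv < T_reg < deletion) with thresholds a ≤ b ≤ c, an
encounter budget of at most n encounters per thymocyte, deletion absorbing
at any encounter, and a T_reg mark that survives unless the cell is later
deleted. With per-encounter zone probabilities (p0, p1, p2, p3) the fates
have closed forms:

    P(neglect) = p0^n
    P(T_conv)  = (p0+p1)^n − p0^n
    P(T_reg)   = (p0+p1+p2)^n − (p0+p1)^n
    P(deleted) = 1 − (p0+p1+p2)^n

* **One-hit model** — each encounter is a single TCR–pMHC contact with
  static thresholds. Its T_reg dose response is monotone in the agonist
  fraction g for every threshold placement (in the strongly selecting
  calibrated regime), so it cannot produce the observed rise-then-fall —
  the package's model-rejection argument.
* **N-sum model** — each encounter sums N temporally proximal contact
  signals. Single-contact strengths are lognormal (median 1) for
  endogenous peptides, 0 for a null fraction f, and a point mass s_tim for
  the agonist at fraction g; the encounter distribution is the binomial
  mixture of shifted lognormal-sum convolutions. For N ≥ 2 the agonist
  shifts the whole encounter distribution rightward, transiently filling
  the T_reg window: rise-then-fall.
* **Two-phase model** — single contacts, but TCR sensitivity differs
  between a developmental phase A (budget nA, low sensitivity) and phase B
  (budget nB): the same agonist commits cells to T_reg early but deletes
  them late. Fates factor across phases and are invariant to phase order.
  This model additionally explains why a partial agonist enhances deletion
  without boosting T_reg while a full agonist does both.

Agonist abundance is linked to the measured quantity (relative RNA
expression) through a saturating Hill-type mapping
g(RNA) = g_max / (1 + (ρ50/RNA)^s). Thresholds (or phase-B zone
probabilities) are calibrated exactly from control-animal selection
fractions; counts are K × fate probability with a scaling constant K from
control T_conv counts. Fits minimise the residual sum of squares of log10
counts; models are compared by AIC, with ΔAIC ≤ 2 defining approximate 95%
confidence sets. A per-cell Monte-Carlo simulator provides an independent
oracle for all closed forms, and a synthetic-data generator emulates the
titration experiment for parameter-recovery studies.

## Worked example

```python
import numpy as np
from thymoselect import (ControlFractions, EncounterModel,
                         agonist_strength_from_percentile,
                         calibrate_thresholds_nsum, scan_agonist_dose)

cf = ControlFractions(frac_conv=0.85, frac_reg=0.03)   # control mice
base = EncounterModel(N=3)                             # 3 contacts/encounter
th = calibrate_thresholds_nsum(cf, n=100.0, model=base)
model = EncounterModel(N=3, s_tim=agonist_strength_from_percentile(base, 0.999))
scan = scan_agonist_dose("nsum", (model, th, 100.0), np.linspace(0, 0.05, 6))
print(scan.round(4))
```

prints

```
  model     g  neglect    conv     reg  deleted
0  nsum  0.00      0.0  0.8500  0.0300   0.1200
1  nsum  0.01      0.0  0.7046  0.0746   0.2208
2  nsum  0.02      0.0  0.5539  0.0989   0.3472
3  nsum  0.03      0.0  0.4133  0.1046   0.4821
4  nsum  0.04      0.0  0.2928  0.0965   0.6107
5  nsum  0.05      0.0  0.1971  0.0804   0.7225
```

Reading the columns: at g = 0 the model reproduces the control fractions
(85% T_conv, 3% T_reg, 12% deleted) by construction. As the agonist
replaces 1–5% of presented peptides, T_conv falls and deletion rises
monotonically, while the T_reg probability peaks near g ≈ 0.03 at roughly
3.5 times its baseline before declining — the titration signature that
rejects the one-hit model.

The same pipeline is scriptable from the shell:

```bash
thymoselect synth config.yaml --out data.csv        # synthetic dataset + truth
thymoselect fit config.yaml data.csv --model both --out-prefix results/fit
thymoselect scan config.yaml --out scan.csv         # dose-response + shape flags
```

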