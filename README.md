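# aslcalib

Arterial spin labeling (ASL) perfusion calibration as a reusable, fully
synthetic-testable pipeline:

* **`aslcalib.phantom`** — digital concentric-shell brain phantom
  (ventricular/sulcal CSF, WM, GM) with PVE maps and complete voxelwise
  ground truth: CBF, ATT, aBV, equilibrium magnetization, T1, T2*,
  partition coefficient, and a multiplicative coil bias field.
* **`aslcalib.acquisition` / `aslcalib.simulate`** — multi-TI PASL
  (Q2TIPS-style bolus truncation, presaturation) and multi-PLD pCASL
  (background-suppressed, separate TR = 6 s calibration scan) forward
  simulation of control/label series with per-slice timing offsets.
* **`aslcalib.kinetic`** — general kinetic model (single well-mixed tissue
  compartment plus an intravascular arterial box-car) with closed-form
  signals for both labeling schemes, and voxelwise bounded nonlinear
  least-squares fitting of relative CBF, ATT, and aBV.
* **`aslcalib.m0t`** — the three tissue-M0 strategies: long-TR calibration
  scan (with/without T1 correction), control averaging at a fixed TI
  (with/without recovery correction, configurable presaturation
  efficiency), and voxelwise saturation-recovery fitting (M0t, T1t, A).
* **`aslcalib.m0a`** — arterial-M0 derivation: reference-tissue (CSF/WM/GM
  masks at restrictive/extensive PVE thresholds, optional ventricle
  intersection, data-driven bias-field correction) and voxelwise
  (PVE-weighted T2*/lambda extrapolation, in-plane median smoothing, three
  lambda variants).
* **`aslcalib.analysis`** — absolute CBF calibration
  (`CBF = CBF_rel / (alpha * M0a) * 6000`), GM summaries, inter-/intra-
  subject coefficients of variation, jackknife-resampled pairwise method
  comparison, and a one-option-at-a-time post-processing sweep.

Note on fitting: the kinetic and saturation-recovery fits use bounded
trust-region least squares, not the Bayesian (BASIL-style) estimators used
in some published pipelines. When the arterial and tissue compartments
share a transit time and all in-bolus samples share one bolus duration,
(f, ATT, aBV) lie on an exact ridge; a tiny scale-equivariant shrinkage on
aBV selects a deterministic solution (see `aslcalib.kinetic.fit_voxel`).

## CLI

```bash
aslcalib simulate --config cfg.yaml --out session/ --seed 1
aslcalib fit --in session/ --out maps/
aslcalib m0t --in session/ --method satrec --out session/m0t
aslcalib m0a --in session/ --m0t session/m0t --method voxel --out session/m0a
aslcalib compare --in session/ --perf maps/ --m0t-method satrec --out report/
```

`cfg.yaml` may override the phantom (`phantom: {grid_shape: [24, 24, 6]}`)
and acquisition (`sequence: PASL`, `acquisition: {n_repeats: 4}`) defaults.
Volumes are written as NIfTI-1 with JSON sidecars.

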