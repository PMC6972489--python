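"""Tissue equilibrium magnetization (M0t) generation.

Three strategies are implemented:

* ``m0t_longtr``  — separate long-TR scan, optionally corrected for the
  residual T1 saturation at that TR;
* ``m0t_ctravg`` — repeat-averaged control images at one fixed TI,
  optionally corrected for presaturation recovery;
* ``m0t_satrec`` — per-voxel three-parameter saturation-recovery fit
  ``M0t * (1 - A * exp(-t/T1t))`` to the multi-TI control curve, which also
  yields T1t and presaturation-efficiency maps.

All corrections use slice-time-corrected recovery times: on an ascending
2D readout the superior slices are read several hundred milliseconds after
the nominal TI, which matters at the short TIs of the schedule.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from . import constants as C
from .maps import M0Map
from .phantom import TissueMaps
from .simulate import AslDataset


def tr_for_recovery(fraction: float, t1_s: float) -> float:
    """TR at which ``1 - exp(-TR/T1)`` reaches ``fraction``.

    Useful to reason about when the long-TR T1 correction becomes
    negligible for a given tissue (e.g. near-complete CSF recovery).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if t1_s <= 0:
        raise ValueError("t1_s must be positive")
    return -t1_s * float(np.log(1.0 - fraction))


def pve_weighted_t1(tissue: TissueMaps) -> np.ndarray:
    """Per-voxel tissue T1 (s) as the PVE-weighted Table-style combination
    of the GM/WM/CSF constants."""
    return tissue.weighted(*C.T1_TISSUE_S)


def m0t_longtr(calib: M0Map, tissue: TissueMaps,
               t1_correction: bool = True,
               tr_s: float | None = None) -> M0Map:
    """Correct a long-TR calibration scan to equilibrium magnetization.

    Divides by ``1 - exp(-TR/T1)`` voxelwise using the PVE-weighted tissue
    T1 (identity when ``t1_correction`` is off). Refuses to amplify by more
    than 20x (recovery fraction below 0.05 inside the brain).
    """
    tr = calib.meta.get("calib_tr_s") if tr_s is None else tr_s
    if tr is None or tr <= 0:
        raise ValueError("calibration TR must be positive")
    values = np.asarray(calib.values, dtype=float)
    meta = {"t1_correction": t1_correction, "calib_tr_s": tr,
            "te_ms": calib.meta.get("te_ms")}
    if t1_correction:
        t1 = pve_weighted_t1(tissue)
        rec = np.where(t1 > 0, 1.0 - np.exp(-tr / np.maximum(t1, 1e-9)), 1.0)
        if np.any(rec[tissue.brain_mask] < 0.05):
            raise ValueError(
                f"TR={tr} s gives a recovery fraction below 0.05 in the "
                "brain; the correction would amplify noise more than 20x")
        values = values / rec
    return M0Map(values=values, kind="M0t", method="LongTR", meta=meta)


def m0t_ctravg(ds: AslDataset, tissue: TissueMaps,
               ti_choice_s: float | None = None,
               t1_correction: bool = True,
               A: float = C.PRESAT_EFFICIENCY_A) -> M0Map:
    """Average control images at one TI, with optional recovery correction.

    The correction divides by ``1 - A * exp(-t_eff/T1)`` per voxel, with
    ``t_eff`` the slice-time-corrected TI and T1 the PVE-weighted tissue
    value. ``ti_choice_s`` defaults to the longest acquired TI.
    """
    if ds.acq.background_suppression:
        raise ValueError("control averaging requires non-background-"
                         "suppressed data")
    tis = np.asarray(ds.acq.ti_or_pld_s, dtype=float)
    if ti_choice_s is None:
        ti_choice_s = float(tis[-1])
    k = int(np.argmin(np.abs(tis - ti_choice_s)))
    if abs(tis[k] - ti_choice_s) > 1e-6:
        raise ValueError(f"TI {ti_choice_s} s was not acquired "
                         f"(available: {list(tis)})")

    ctrl = ds.mean_control()[..., k]
    meta = {"ti_s": float(tis[k]), "t1_correction": t1_correction,
            "A": A, "te_ms": ds.acq.te_ms}
    if t1_correction:
        t1 = pve_weighted_t1(tissue)
        t_rec = ds.control_recovery_times()[k]          # per slice
        rec = np.ones_like(ctrl)
        for s in range(ds.n_slices):
            t1s = t1[:, :, s]
            rec[:, :, s] = np.where(
                t1s > 0,
                1.0 - A * np.exp(-t_rec[s] / np.maximum(t1s, 1e-9)), 1.0)
        ctrl = ctrl / rec
    return M0Map(values=ctrl, kind="M0t", method="CtrAvg", meta=meta)


def _satrec_curve(x, t):
    m0, t1, a = x
    return m0 * (1.0 - a * np.exp(-t / t1))


def satrec_fit_voxel(times: np.ndarray, signal: np.ndarray,
                     estimate_A: bool = True,
                     init=(None, 1.3, 0.9)):
    """Fit ``M0t*(1 - A*exp(-t/T1t))`` to one voxel's control curve.

    Returns ``(m0t, t1t, A, rss, converged)``. With ``estimate_A`` off, A
    is fixed at 1.0 (two-parameter fit).
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    m0_init = init[0] if init[0] is not None else max(float(signal.max()),
                                                     1e-9)
    if estimate_A:
        x0 = np.array([m0_init, init[1], init[2]])
        lb, ub = [1e-12, 0.2, 0.0], [np.inf, 6.0, 1.2]

        def resid(x):
            return _satrec_curve(x, times) - signal
    else:
        x0 = np.array([m0_init, init[1]])
        lb, ub = [1e-12, 0.2], [np.inf, 6.0]

        def resid(x):
            return _satrec_curve((x[0], x[1], 1.0), times) - signal

    sol = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    rss = float(np.sum(sol.fun ** 2))
    if estimate_A:
        m0, t1, a = sol.x
    else:
        (m0, t1), a = sol.x, 1.0
    return float(m0), float(t1), float(a), rss, bool(sol.success)


class SatRecFit:
    """Voxelwise saturation-recovery fit results (M0t, T1t, A, RSS)."""

    def __init__(self, shape):
        self.m0t = np.zeros(shape)
        self.t1t = np.zeros(shape)
        self.a = np.zeros(shape)
        self.rss = np.zeros(shape)
        self.converged = np.zeros(shape, dtype=bool)


def m0t_satrec(ds: AslDataset, tissue: TissueMaps | None = None,
               estimate_A: bool = True,
               mask: np.ndarray | None = None) -> tuple[M0Map, SatRecFit]:
    """Saturation-recovery M0t estimation from the multi-TI control series.

    Requires a presaturation sequence with at least 3 distinct TIs. The
    fitted T1t map doubles as the tissue-contrast reference downstream.
    Non-converged voxels are flagged, not zeroed.
    """
    if not ds.acq.presaturation or ds.acq.background_suppression:
        raise ValueError("saturation recovery requires a presaturation "
                         "sequence without background suppression")
    if len(ds.acq.ti_or_pld_s) < 3:
        raise ValueError("at least 3 distinct TIs are required")

    ctrl = ds.mean_control()
    shape = ctrl.shape[:3]
    t_rec = ds.control_recovery_times()
    if mask is None:
        mask = (tissue.brain_mask if tissue is not None
                else np.any(ctrl != 0, axis=3))

    fit = SatRecFit(shape)
    for i, j, k in zip(*np.nonzero(mask)):
        m0, t1, a, rss, ok = satrec_fit_voxel(
            t_rec[:, k], ctrl[i, j, k], estimate_A=estimate_A)
        fit.m0t[i, j, k], fit.t1t[i, j, k], fit.a[i, j, k] = m0, t1, a
        fit.rss[i, j, k], fit.converged[i, j, k] = rss, ok

    a_used = float(np.median(fit.a[mask])) if np.any(mask) else 1.0
    m0map = M0Map(values=fit.m0t, kind="M0t", method="SatRec",
                  meta={"estimate_A": estimate_A, "A_median": a_used,
                        "te_ms": ds.acq.te_ms,
                        "n_tis": len(ds.acq.ti_or_pld_s)})
    return m0map, fit
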