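"""Forward simulation of ASL control/label series and calibration scans.

The simulator is the oracle for the whole pipeline: given a phantom's
ground truth it produces the raw 4D series the processing stages consume.

Static (control) signal:

* presaturation sequences (PASL):
  ``bias * M0t * (1 - A * exp(-t_eff / T1))`` with t_eff the slice-time-
  corrected inversion time;
* background-suppressed pCASL: ``bias * M0t * bs_factor`` — a single
  static attenuation stands in for the suppression pulse train (the
  perfusion difference signal is left unattenuated, a documented
  simplification).

The label volume is the control minus the kinetic-model difference signal
``bias * alpha * M0a * forward_signal(...)``; Gaussian noise is added
independently per volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionParams
from .kinetic import KineticParams, forward_signal
from .maps import M0Map
from .phantom import GroundTruth, TissueMaps
from . import constants as C


@dataclass
class AslDataset:
    """A 4D stack of control/label volumes with per-volume metadata.

    ``data`` has shape (x, y, z, n_volumes); ``vol_time_s``,
    ``vol_kind`` ("control"/"label") and ``vol_ti_index`` describe each
    volume. Effective (slice-time-corrected) times are derived on demand.
    """

    data: np.ndarray
    vol_time_s: np.ndarray
    vol_kind: np.ndarray
    vol_ti_index: np.ndarray
    acq: AcquisitionParams

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def effective_times(self) -> np.ndarray:
        """(n_times, n_slices) kinetic-model times per slice."""
        return self.acq.effective_times(self.n_slices)

    def control_recovery_times(self) -> np.ndarray:
        """(n_times, n_slices) saturation-recovery times of the control
        images (nominal TI plus slice offset; PASL presaturation only)."""
        tis = np.asarray(self.acq.ti_or_pld_s, dtype=float)[:, None]
        offs = np.arange(self.n_slices)[None, :] * self.acq.slice_time_ms / 1e3
        return tis + offs

    def bolus_durations(self) -> np.ndarray:
        return self.acq.bolus_durations()

    def mean_control(self) -> np.ndarray:
        """Repeat-averaged control images, shape (x, y, z, n_times)."""
        return self._mean_by_ti("control")

    def mean_diff(self) -> np.ndarray:
        """Repeat-averaged control-label difference, (x, y, z, n_times)."""
        return self._mean_by_ti("control") - self._mean_by_ti("label")

    def _mean_by_ti(self, kind: str) -> np.ndarray:
        n_ti = len(self.acq.ti_or_pld_s)
        out = np.empty(self.data.shape[:3] + (n_ti,))
        sel_kind = self.vol_kind == kind
        for k in range(n_ti):
            sel = sel_kind & (self.vol_ti_index == k)
            out[..., k] = self.data[..., sel].mean(axis=3)
        return out


def _static_signal(truth: GroundTruth, acq: AcquisitionParams,
                   t_rec: np.ndarray) -> np.ndarray:
    """Noise-free static tissue signal, (x, y, z, n_times)."""
    shape = truth.m0t_map.shape
    n_times = t_rec.shape[0]
    m0t = (truth.bias_field * truth.m0t_map)[..., None]
    if acq.background_suppression:
        return np.broadcast_to(m0t * acq.bs_factor,
                               shape + (n_times,)).copy()
    if not acq.presaturation:
        return np.broadcast_to(m0t, shape + (n_times,)).copy()
    t1 = truth.t1_map
    out = np.empty(shape + (n_times,))
    a = truth.presat_efficiency_a
    for k in range(n_times):
        for s in range(shape[2]):
            rec = 1.0 - a * np.exp(
                -t_rec[k, s] / np.maximum(t1[:, :, s], 1e-9))
            rec = np.where(t1[:, :, s] > 0, rec, 0.0)
            out[:, :, s, k] = m0t[:, :, s, 0] * rec
    return out


def _difference_signal(truth: GroundTruth, acq: AcquisitionParams,
                       t_eff: np.ndarray) -> np.ndarray:
    """Noise-free kinetic difference signal, (x, y, z, n_times)."""
    shape = truth.cbf_map.shape
    n_times = t_eff.shape[0]
    taus = acq.bolus_durations()
    amp = acq.alpha * truth.m0a_signal * truth.bias_field
    f = truth.cbf_map / C.CBF_UNIT_FACTOR       # mL/g/s
    out = np.zeros(shape + (n_times,))
    for k in range(n_times):
        for s in range(shape[2]):
            t1t = truth.t1_map[:, :, s]
            p = KineticParams(f_rel=f[:, :, s], att=truth.att_map[:, :, s],
                              abv=truth.abv_map[:, :, s],
                              t1_tissue=np.where(t1t > 0, t1t, 1.0),
                              att_art=truth.att_map[:, :, s])
            dm = forward_signal(t_eff[k, s], p, acq.sequence, tau=taus[k])
            out[:, :, s, k] = amp[:, :, s] * np.where(t1t > 0, dm, 0.0)
    return out


def simulate_asl_series(truth: GroundTruth, tissue: TissueMaps,
                        acq: AcquisitionParams, noise_sd: float = 0.0,
                        seed: int = 0) -> AslDataset:
    """Simulate a full control/label series for one session.

    Independent Gaussian noise of standard deviation ``noise_sd`` (signal
    units) is added to every volume; identical seeds give bit-identical
    datasets.
    """
    if truth.cbf_map.shape != tissue.pve_gm.shape:
        raise ValueError("ground truth and tissue maps must share the grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if acq.background_suppression and not acq.presaturation:
        warnings.warn(
            "background-suppressed controls carry no recovery information; "
            "control-averaging / saturation-recovery M0t methods will not "
            "be usable on this dataset", stacklevel=2)

    n_slices = truth.cbf_map.shape[2]
    t_eff = acq.effective_times(n_slices)
    tis = np.asarray(acq.ti_or_pld_s, dtype=float)
    t_rec = tis[:, None] + np.arange(n_slices)[None, :] \
        * acq.slice_time_ms / 1e3

    static = _static_signal(truth, acq, t_rec)
    dm = _difference_signal(truth, acq, t_eff)

    rng = np.random.default_rng(seed)
    vols, times, kinds, ti_idx = [], [], [], []
    for k in range(len(tis)):
        for _ in range(acq.n_repeats):
            ctrl = static[..., k]
            lbl = static[..., k] - dm[..., k]
            if noise_sd > 0:
                ctrl = ctrl + rng.normal(0.0, noise_sd, ctrl.shape)
                lbl = lbl + rng.normal(0.0, noise_sd, lbl.shape)
            vols.extend([ctrl, lbl])
            times.extend([tis[k], tis[k]])
            kinds.extend(["control", "label"])
            ti_idx.extend([k, k])

    return AslDataset(data=np.stack(vols, axis=-1),
                      vol_time_s=np.asarray(times),
                      vol_kind=np.asarray(kinds),
                      vol_ti_index=np.asarray(ti_idx), acq=acq)


def simulate_calibration_scan(truth: GroundTruth, acq: AcquisitionParams,
                              noise_sd: float = 0.0,
                              seed: int = 0) -> M0Map:
    """Simulate the separate long-TR reference scan (never suppressed).

    Voxel value is ``bias * M0t * (1 - exp(-TR_calib / T1))`` plus noise.
    """
    if acq.calib_tr_s is None or acq.calib_tr_s <= 0:
        raise ValueError("acq.calib_tr_s must be set and positive")
    t1 = truth.t1_map
    rec = np.where(t1 > 0, 1.0 - np.exp(-acq.calib_tr_s /
                                        np.maximum(t1, 1e-9)), 0.0)
    img = truth.bias_field * truth.m0t_map * rec
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return M0Map(values=img, kind="M0t", method="LongTR-raw",
                 meta={"calib_tr_s": acq.calib_tr_s,
                       "t1_corrected": False, "te_ms": acq.te_ms})
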