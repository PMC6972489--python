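"""Digital perfusion phantom with full ground truth.

The phantom is a concentric-shell "brain": CSF-filled ventricles at the
centre, a WM shell around them, a GM rim, and a thin layer of sulcal CSF,
embedded in background. Binary tissue labels are blurred into partial-volume
estimate (PVE) maps, and every quantity needed by the downstream pipeline
(CBF, ATT, aBV, equilibrium magnetization, T1, T2*, partition coefficient,
coil bias field) is stored as a voxelwise ground-truth map.

Conventions
-----------
* Intensive tissue properties (T1, T2*, lambda, ATT) of mixed voxels are
  tissue-fraction-normalized PVE-weighted averages of the per-tissue
  constants.
* Extensive quantities (CBF, aBV, M0t) scale with the tissue fraction.
* The tissue equilibrium signal is ``m0_blood * lambda * exp(-TE/T2*)``
  scaled by the tissue fraction, so that both reference-tissue and voxelwise
  arterial-M0 derivations are exact on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import constants as C

# tissue_layout label values
BACKGROUND = 0
GM_LABEL = 1
WM_LABEL = 2
VENTRICLE_LABEL = 3
SULCAL_CSF_LABEL = 4

_LABEL_NAMES = {
    GM_LABEL: "GM",
    WM_LABEL: "WM",
    VENTRICLE_LABEL: "CSF-ventricle",
    SULCAL_CSF_LABEL: "CSF-sulcal",
}

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class ConfigurationError(ValueError):
    """Raised when a phantom specification cannot produce a valid phantom."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition-independent signal and ground-truth parameters.

    ``shell_radii`` are normalized elliptical radii (fractions of the
    half-field-of-view) delimiting ventricle / WM / GM / sulcal-CSF shells.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 6)
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 5.0)
    pve_blur_fwhm_mm: float = 3.0
    shell_radii: tuple[float, float, float, float] = (0.28, 0.55, 0.80, 0.90)
    te_ms: float = 19.0
    m0_blood: float = 1000.0
    t2star_blood_ms: float = C.T2STAR_BLOOD_MS
    presat_efficiency_a: float = C.PRESAT_EFFICIENCY_A
    bias_peak_to_trough: float = 1.0
    cbf_gm: float = 60.0
    cbf_wm: float = 20.0
    att_gm_s: float = 0.7
    att_wm_s: float = 1.1
    att_csf_s: float = 1.0
    abv_gm: float = 0.01
    abv_wm: float = 0.003
    seed: int = 0


@dataclass
class TissueMaps:
    """PVE maps plus the discrete label volume they were derived from."""

    pve_gm: np.ndarray
    pve_wm: np.ndarray
    pve_csf: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    @property
    def pve_sum(self) -> np.ndarray:
        return self.pve_gm + self.pve_wm + self.pve_csf

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels with any appreciable tissue content."""
        return self.pve_sum > 0.1

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.labels == VENTRICLE_LABEL

    def pve(self, tissue: str) -> np.ndarray:
        return {"GM": self.pve_gm, "WM": self.pve_wm, "CSF": self.pve_csf}[tissue]

    def weighted(self, gm: float, wm: float, csf: float,
                 normalize: bool = True) -> np.ndarray:
        """PVE-weighted combination of per-tissue constants.

        With ``normalize`` the weights are divided by the tissue fraction so
        the value stays an intensive property at the brain edge; voxels with
        no tissue content get 0.
        """
        out = gm * self.pve_gm + wm * self.pve_wm + csf * self.pve_csf
        if normalize:
            s = self.pve_sum
            out = np.divide(out, s, out=np.zeros_like(out), where=s > 0)
        return out


@dataclass
class GroundTruth:
    """Voxelwise truth for every quantity the pipeline estimates."""

    cbf_map: np.ndarray          # mL/100 g/min
    att_map: np.ndarray          # s
    abv_map: np.ndarray          # fraction
    m0t_map: np.ndarray          # signal units (at TE)
    t1_map: np.ndarray           # s
    t2star_map: np.ndarray       # ms
    lambda_map: np.ndarray       # mL/g (tissue-fraction normalized)
    bias_field: np.ndarray       # multiplicative, mean 1 over brain
    presat_efficiency_a: float
    m0_blood: float
    te_ms: float
    t2star_blood_ms: float

    @property
    def m0a_signal(self) -> float:
        """Arterial equilibrium signal at the acquisition TE."""
        return self.m0_blood * float(
            np.exp(-self.te_ms / self.t2star_blood_ms))


def _tissue_labels(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    hx, hy, hz = nx * dx / 2.0, ny * dy / 2.0, nz * dz / 2.0
    gx, gy, gz = np.meshgrid(x / hx, y / hy, z / hz, indexing="ij")
    rho = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)

    r_vent, r_wm, r_gm, r_csf = spec.shell_radii
    labels = np.full(spec.grid_shape, BACKGROUND, dtype=np.int16)
    labels[rho <= r_csf] = SULCAL_CSF_LABEL
    labels[rho <= r_gm] = GM_LABEL
    labels[rho <= r_wm] = WM_LABEL
    labels[rho <= r_vent] = VENTRICLE_LABEL
    return labels


def make_bias_field(grid_shape, voxel_size_mm, peak_to_trough: float,
                    brain_mask: np.ndarray) -> np.ndarray:
    """Smooth multiplicative coil-sensitivity field, mean 1 over the brain.

    A centred inverted paraboloid (quadratic bowl) scaled so that max/min
    over the brain equals ``peak_to_trough``. The quadratic shape spreads
    the curvature evenly over the field of view, like the broad sensitivity
    roll-off of a multi-channel head coil.
    """
    if peak_to_trough < 1.0:
        raise ConfigurationError("peak_to_trough must be >= 1")
    if peak_to_trough == 1.0:
        return np.ones(grid_shape)
    nx, ny, nz = grid_shape
    dx, dy, dz = voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    hx, hy, hz = nx * dx / 2.0, ny * dy / 2.0, nz * dz / 2.0
    gx, gy, gz = np.meshgrid(x / hx, y / hy, z / hz, indexing="ij")
    bump = -(gx ** 2 + gy ** 2 + gz ** 2)
    # after shifting the trough to 1, scale so max/min == peak_to_trough
    b_lo, b_hi = bump[brain_mask].min(), bump[brain_mask].max()
    if b_hi - b_lo <= 0:
        raise ConfigurationError(
            "bias profile too flat over the brain for this peak-to-trough")
    amp = (peak_to_trough - 1.0) / (b_hi - b_lo)
    f = np.maximum(1.0 + amp * (bump - b_lo), 0.05)
    f /= f[brain_mask].mean()
    return f


def make_phantom(spec: PhantomSpec) -> tuple[TissueMaps, GroundTruth]:
    """Build PVE maps and voxelwise ground truth from a phantom spec.

    Raises
    ------
    ConfigurationError
        If the geometry leaves any tissue class empty or the grid is too
        small in-plane.
    """
    if min(spec.grid_shape[:2]) < 16:
        raise ConfigurationError("grid must be at least 16 voxels in-plane")

    labels = _tissue_labels(spec)
    for lab, name in _LABEL_NAMES.items():
        if not np.any(labels == lab):
            raise ConfigurationError(
                f"tissue class {name!r} is empty for this geometry")

    ind_gm = (labels == GM_LABEL).astype(float)
    ind_wm = (labels == WM_LABEL).astype(float)
    ind_csf = ((labels == VENTRICLE_LABEL)
               | (labels == SULCAL_CSF_LABEL)).astype(float)

    if spec.pve_blur_fwhm_mm > 0:
        sigma_vox = [spec.pve_blur_fwhm_mm / _FWHM_TO_SIGMA / v
                     for v in spec.voxel_size_mm]
        ind_gm = gaussian_filter(ind_gm, sigma_vox)
        ind_wm = gaussian_filter(ind_wm, sigma_vox)
        ind_csf = gaussian_filter(ind_csf, sigma_vox)

    tissue = TissueMaps(pve_gm=ind_gm, pve_wm=ind_wm, pve_csf=ind_csf,
                        labels=labels, voxel_size_mm=spec.voxel_size_mm)

    t1 = tissue.weighted(*C.T1_TISSUE_S)
    t2star = tissue.weighted(*C.T2STAR_TISSUE_MS)
    lam = tissue.weighted(*C.LAMBDA_TISSUE)
    att = tissue.weighted(spec.att_gm_s, spec.att_wm_s, spec.att_csf_s)
    cbf = tissue.weighted(spec.cbf_gm, spec.cbf_wm, 0.0, normalize=False)
    abv = tissue.weighted(spec.abv_gm, spec.abv_wm, 0.0, normalize=False)

    pve_sum = tissue.pve_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.where(t2star > 0, np.exp(-spec.te_ms / np.maximum(t2star, 1e-6)), 0.0)
    m0t = spec.m0_blood * lam * decay * pve_sum

    bias = make_bias_field(spec.grid_shape, spec.voxel_size_mm,
                           spec.bias_peak_to_trough, tissue.brain_mask)

    truth = GroundTruth(
        cbf_map=cbf, att_map=att, abv_map=abv, m0t_map=m0t, t1_map=t1,
        t2star_map=t2star, lambda_map=lam, bias_field=bias,
        presat_efficiency_a=spec.presat_efficiency_a,
        m0_blood=spec.m0_blood, te_ms=spec.te_ms,
        t2star_blood_ms=spec.t2star_blood_ms)
    return tissue, truth
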