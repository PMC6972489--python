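"""Arterial equilibrium magnetization (M0a) derivation from an M0t map.

Two families of methods:

* reference tissue (RT-CSF / RT-WM / RT-GM): a single scalar M0a from the
  masked mean of M0t, corrected for the T2* difference between the
  reference tissue and arterial blood and divided by the reference-tissue
  partition coefficient;
* voxelwise: per-voxel extrapolation with PVE-weighted T2* and partition
  coefficient, followed by in-plane median smoothing.

Also provides the data-driven bias-field estimator used to approximate the
coil sensitivity profile for the RT methods, and the partition-coefficient
map variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .maps import M0Map
from .phantom import TissueMaps

SMOOTHING_KERNELS = {"3x3": 3, "5x5": 5, "none": 0}


@dataclass(frozen=True)
class RtMaskSpec:
    """Reference-tissue mask recipe (tissue, PVE threshold, ventricle
    intersection for the CSF variants)."""

    tissue: str = "CSF"                       # "CSF" | "WM" | "GM"
    pve_threshold: float = 0.9                # 0.9 restrictive, 0.6 extensive
    intersect_ventricles: bool = True         # CSF only

    def __post_init__(self):
        if self.tissue not in ("CSF", "WM", "GM"):
            raise ValueError(f"unknown reference tissue {self.tissue!r}")


@dataclass(frozen=True)
class CalibOptions:
    """One point in the calibration post-processing option grid, plus the
    per-tissue constants it relies on."""

    lambda_variant: str = "pve"               # "pve" | "avg" | "tspec"
    smoothing: str = "3x3"                    # "3x3" | "5x5" | "none"
    bias_correction: bool = True
    te_ms: float = 19.0
    t2star_blood_ms: float = C.T2STAR_BLOOD_MS
    alpha: float = C.ALPHA_PASL
    t1_tissue_s: tuple = C.T1_TISSUE_S
    t2star_tissue_ms: tuple = C.T2STAR_TISSUE_MS
    lambda_tissue: tuple = C.LAMBDA_TISSUE
    in_plane_voxel_mm: float = 3.5
    m0a_floor_frac: float = 0.1

    def __post_init__(self):
        if self.lambda_variant not in ("pve", "avg", "tspec"):
            raise ValueError(f"unknown lambda variant "
                             f"{self.lambda_variant!r}")
        if self.smoothing not in SMOOTHING_KERNELS:
            raise ValueError(f"unknown smoothing option {self.smoothing!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        _check_te_ms(self.te_ms)

    @property
    def smoothing_kernel_voxels(self) -> int:
        return SMOOTHING_KERNELS[self.smoothing]

    @property
    def smoothing_extent_mm(self) -> float:
        """Physical in-plane extent of the median kernel (the 'FWHM' the
        option grid is labeled with)."""
        return self.smoothing_kernel_voxels * self.in_plane_voxel_mm


def _check_te_ms(te_ms: float) -> None:
    # guard against passing TE in seconds (0 is allowed: no T2* weighting)
    if te_ms != 0.0 and not 1.0 <= te_ms <= 200.0:
        raise ValueError(
            f"te_ms={te_ms} is outside the plausible range [1, 200] ms — "
            "check that TE is given in milliseconds, not seconds")


def lambda_map(tissue: TissueMaps, variant: str = "pve",
               lambdas: tuple = C.LAMBDA_TISSUE) -> np.ndarray:
    """Partition-coefficient volume for one of the three variants.

    ``pve``: PVE-weighted sum; ``avg``: constant equal-weight GM/WM mean;
    ``tspec``: the constant of the majority tissue per voxel (ties resolved
    GM > WM > CSF). Voxels with no tissue content are set to NaN.
    """
    lg, lw, lc = lambdas
    no_tissue = tissue.pve_sum <= 0
    if variant == "pve":
        lam = lg * tissue.pve_gm + lw * tissue.pve_wm + lc * tissue.pve_csf
    elif variant == "avg":
        lam = np.full(tissue.pve_gm.shape, 0.5 * lg + 0.5 * lw)
    elif variant == "tspec":
        stacked = np.stack([tissue.pve_gm, tissue.pve_wm, tissue.pve_csf])
        # argmax returns the first maximum -> GM > WM > CSF priority
        idx = np.argmax(stacked, axis=0)
        lam = np.choose(idx, [lg, lw, lc]).astype(float)
    else:
        raise ValueError(f"unknown lambda variant {variant!r}")
    return np.where(no_tissue, np.nan, lam)


def _poly_basis(shape, order: int) -> np.ndarray:
    """Monomials x^i y^j z^k with total degree <= order, on [-1, 1] coords,
    flattened to (n_voxels, n_terms)."""
    coords = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
              for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((gx ** i) * (gy ** j) * (gz ** k))
    return np.stack([c.ravel() for c in cols], axis=1)


def estimate_bias_field(m0t: M0Map | np.ndarray, tissue: TissueMaps,
                        order: int = 3) -> np.ndarray:
    """Estimate the multiplicative coil-sensitivity field from an M0t map.

    Log-domain least squares: log(M0t) inside the brain is regressed on a
    3D polynomial surface plus the three PVE maps (which absorb the
    per-tissue intensity levels). The exponentiated polynomial part,
    normalized to mean 1 over the brain, is returned as the bias field.
    """
    values = np.asarray(m0t.values if isinstance(m0t, M0Map) else m0t,
                        dtype=float)
    brain = tissue.brain_mask & (values > 0)
    # fit only where one tissue dominates: there log intensity is a
    # per-tissue constant plus the log bias, so the polynomial part cannot
    # absorb mixing structure
    pves = np.stack([tissue.pve_gm, tissue.pve_wm, tissue.pve_csf])
    majority = np.argmax(pves, axis=0)
    fit_mask = brain & (np.max(pves, axis=0) >= 0.9)
    if fit_mask.sum() < 20:
        raise ValueError("too few near-pure brain voxels to estimate a "
                         "bias field")
    poly = _poly_basis(values.shape, order)[:, 1:]   # tissue intercepts
    onehot = np.stack([(majority == t).ravel().astype(float)
                       for t in range(3)], axis=1)
    X = np.concatenate([poly, onehot], axis=1)
    flat = fit_mask.ravel()
    y = np.log(values.ravel()[flat])
    beta, *_ = np.linalg.lstsq(X[flat], y, rcond=None)
    log_bias = (poly @ beta[:poly.shape[1]]).reshape(values.shape)
    bias = np.exp(log_bias)
    bias /= bias[brain].mean()
    return bias


def build_rt_mask(tissue: TissueMaps, spec: RtMaskSpec) -> np.ndarray:
    """Binary reference-tissue mask from PVE thresholding.

    CSF masks may additionally be intersected with the phantom ventricle
    labels (the stand-in for an atlas ventricle mask).
    """
    mask = tissue.pve(spec.tissue) >= spec.pve_threshold
    if spec.tissue == "CSF" and spec.intersect_ventricles:
        mask = mask & tissue.ventricle_mask
    if not np.any(mask):
        raise ValueError(
            f"empty {spec.tissue} mask at threshold "
            f"{spec.pve_threshold}; consider the extensive option "
            "(threshold 0.6, no ventricle intersection)")
    return mask


def m0a_reference_tissue(m0t: M0Map, mask: np.ndarray, opts: CalibOptions,
                         tissue_kind: str) -> M0Map:
    """Scalar M0a from the masked M0t mean (reference-tissue method).

    ``M0a = <M0t>_rt * exp(TE*(1/T2*_rt - 1/T2*_a)) / lambda_rt``.
    """
    idx = {"GM": 0, "WM": 1, "CSF": 2}[tissue_kind]
    t2_rt = opts.t2star_tissue_ms[idx]
    lam_rt = opts.lambda_tissue[idx]
    _check_te_ms(opts.te_ms)
    values = np.asarray(m0t.values, dtype=float)
    if not np.any(mask):
        raise ValueError("reference-tissue mask is empty")
    mean_m0t = float(values[mask].mean())
    factor = float(np.exp(opts.te_ms * (1.0 / t2_rt
                                        - 1.0 / opts.t2star_blood_ms)))
    m0a = mean_m0t * factor / lam_rt
    return M0Map(values=m0a, kind="M0a", method=f"RT-{tissue_kind}",
                 meta={"n_mask_voxels": int(mask.sum()),
                       "mean_m0t": mean_m0t, "t2star_rt_ms": t2_rt,
                       "lambda_rt": lam_rt, "te_ms": opts.te_ms,
                       "t2star_blood_ms": opts.t2star_blood_ms,
                       "bias_correction": opts.bias_correction,
                       "m0t_method": m0t.method})


def masked_median_filter(values: np.ndarray, mask: np.ndarray,
                         size: int) -> np.ndarray:
    """In-plane median filter over brain-masked neighborhoods.

    For every masked voxel, the median of the in-plane ``size x size``
    neighbors that are themselves inside the mask; out-of-mask voxels are
    never mixed in (no zero bleed-in at edges).
    """
    if size == 0:
        return values.copy()
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    r = size // 2
    stack = []
    work = np.where(mask, values, np.nan)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            shifted = np.full_like(work, np.nan)
            src_i = slice(max(0, -di), values.shape[0] - max(0, di))
            dst_i = slice(max(0, di), values.shape[0] - max(0, -di))
            src_j = slice(max(0, -dj), values.shape[1] - max(0, dj))
            dst_j = slice(max(0, dj), values.shape[1] - max(0, -dj))
            shifted[dst_i, dst_j, :] = work[src_i, src_j, :]
            stack.append(shifted)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(np.stack(stack, axis=0), axis=0)
    out = values.copy()
    out[mask] = med[mask]
    return out


def m0a_voxelwise(m0t: M0Map, tissue: TissueMaps,
                  opts: CalibOptions) -> M0Map:
    """Voxelwise M0a map: per-voxel T2* and lambda extrapolation from M0t.

    ``M0a(i) = M0t(i) * exp(TE*(1/T2*_t(i) - 1/T2*_a)) / lambda_t(i)``
    with PVE-weighted tissue T2* and the configured lambda variant, then
    median-smoothed in-plane. Voxels below ``m0a_floor_frac`` of the brain
    median are set to NaN so the later division cannot blow up.
    """
    _check_te_ms(opts.te_ms)
    values = np.asarray(m0t.values, dtype=float)
    lam = lambda_map(tissue, opts.lambda_variant, opts.lambda_tissue)
    t2t = tissue.weighted(*opts.t2star_tissue_ms)
    mask = tissue.brain_mask
    with np.errstate(all="ignore"):
        factor = np.exp(opts.te_ms * (1.0 / np.maximum(t2t, 1e-9)
                                      - 1.0 / opts.t2star_blood_ms))
        m0a = np.where(mask & np.isfinite(lam) & (lam > 0) & (t2t > 0),
                       values * factor / lam, np.nan)
    m0a = masked_median_filter(m0a, mask & np.isfinite(m0a),
                               opts.smoothing_kernel_voxels)
    valid = np.isfinite(m0a) & mask
    if np.any(valid):
        floor = opts.m0a_floor_frac * np.nanmedian(m0a[valid])
        m0a = np.where(valid & (m0a >= floor), m0a, np.nan)
    return M0Map(values=m0a, kind="M0a", method="Voxel",
                 meta={"lambda_variant": opts.lambda_variant,
                       "smoothing": opts.smoothing,
                       "smoothing_extent_mm": opts.smoothing_extent_mm,
                       "te_ms": opts.te_ms,
                       "t2star_blood_ms": opts.t2star_blood_ms,
                       "m0t_method": m0t.method})
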