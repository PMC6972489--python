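"""Absolute CBF calibration, GM summaries, reproducibility metrics and the
post-processing option sweep.

``CBF = CBF_rel / (alpha * M0a) * 6000`` converts the fitted relative
perfusion amplitude to mL/100 g/min; the reference-tissue path divides by
one scalar, the voxelwise path divides voxel by voxel (masked voxels
propagate as NaN, never infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as C
from .kinetic import PerfusionMaps
from .maps import M0Map
from .m0a import (CalibOptions, RtMaskSpec, build_rt_mask,
                  estimate_bias_field, m0a_reference_tissue, m0a_voxelwise)
from .m0t import m0t_ctravg, m0t_longtr, m0t_satrec
from .phantom import TissueMaps


@dataclass
class CbfResult:
    """Absolute CBF map plus its GM summary and full option provenance."""

    cbf_map: np.ndarray           # mL/100 g/min, NaN where masked
    gm_mean: float
    gm_median: float
    options: dict
    subject_id: str = ""
    session_id: str = ""


def gm_summary(cbf_map: np.ndarray, tissue: TissueMaps,
               pve_threshold: float = 0.9) -> tuple[float, float]:
    """Mean and median CBF over the GM mask (PVE_GM >= threshold)."""
    mask = (tissue.pve_gm >= pve_threshold) & np.isfinite(cbf_map)
    if not np.any(mask):
        raise ValueError("GM mask is empty at this threshold")
    vals = cbf_map[mask]
    return float(vals.mean()), float(np.median(vals))


def calibrate_cbf(perf: PerfusionMaps, m0a: M0Map, alpha: float,
                  tissue: TissueMaps | None = None,
                  gm_pve_threshold: float = 0.9,
                  subject_id: str = "", session_id: str = "") -> CbfResult:
    """Convert relative perfusion to absolute CBF (mL/100 g/min)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    m0a_vals = np.asarray(m0a.values, dtype=float)
    if m0a.is_scalar:
        if not np.isfinite(m0a_vals) or m0a_vals <= 0:
            raise ValueError("scalar M0a must be positive and finite")
        cbf = perf.cbf_rel / (alpha * float(m0a_vals)) * C.CBF_UNIT_FACTOR
    else:
        if m0a_vals.shape != perf.cbf_rel.shape:
            raise ValueError("M0a map and perfusion maps must share a grid")
        with np.errstate(all="ignore"):
            cbf = np.where(np.isfinite(m0a_vals) & (m0a_vals > 0),
                           perf.cbf_rel / (alpha * m0a_vals)
                           * C.CBF_UNIT_FACTOR, np.nan)
    gm_mean = gm_median = float("nan")
    if tissue is not None:
        gm_mean, gm_median = gm_summary(cbf, tissue, gm_pve_threshold)
    return CbfResult(cbf_map=cbf, gm_mean=gm_mean, gm_median=gm_median,
                     options={"alpha": alpha, "m0a": m0a.provenance()},
                     subject_id=subject_id, session_id=session_id)


# ---------------------------------------------------------------------------
# reproducibility metrics

@dataclass
class ReproReport:
    """Coefficients of variation (percent) of GM summary CBF."""

    cv_inter: float
    cv_intra: float
    n_subjects: int
    n_sessions: int


def _as_subject_matrix(gm_values) -> np.ndarray:
    """Coerce input to a (subjects, sessions) float matrix."""
    if isinstance(gm_values, pd.DataFrame):
        wide = gm_values.pivot_table(index="subject", columns="session",
                                     values="value")
        mat = wide.to_numpy(dtype=float)
    else:
        mat = np.asarray(gm_values, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a (subjects, sessions) matrix")
    return mat


def cv_metrics(gm_values) -> ReproReport:
    """Inter- and intra-subject coefficients of variation, in percent.

    ``cv_intra``: per-subject across-session SD over the subject mean,
    averaged over subjects. ``cv_inter``: SD of subject means over the
    grand mean. Sample SDs (ddof=1) are used throughout.
    """
    mat = _as_subject_matrix(gm_values)
    n_sub, n_ses = mat.shape
    if n_sub < 2:
        raise ValueError("at least 2 subjects are required")
    if n_ses < 2:
        raise ValueError("cv_intra is undefined with a single session")
    subj_means = mat.mean(axis=1)
    cv_intra = float(np.mean(mat.std(axis=1, ddof=1) / subj_means) * 100.0)
    cv_inter = float(subj_means.std(ddof=1) / subj_means.mean() * 100.0)
    return ReproReport(cv_inter=cv_inter, cv_intra=cv_intra,
                       n_subjects=n_sub, n_sessions=n_ses)


def jackknife_compare(gm_values_by_method: dict, metric: str = "cv_intra",
                      alpha_level: float = 0.05) -> pd.DataFrame:
    """Pairwise comparison of CV metrics via leave-one-subject-out
    resampling.

    For every method, one CV replicate is computed per left-out subject;
    methods are then compared with paired t tests on the replicates.
    Returns a tidy frame with one row per method pair.
    """
    replicates = {}
    for name, vals in gm_values_by_method.items():
        mat = _as_subject_matrix(vals)
        n = mat.shape[0]
        if n < 3:
            raise ValueError("jackknife needs at least 3 subjects")
        reps = []
        for drop in range(n):
            sub = np.delete(mat, drop, axis=0)
            rep = cv_metrics(sub)
            reps.append(getattr(rep, metric))
        replicates[name] = np.asarray(reps)

    rows = []
    names = list(replicates)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = replicates[names[i]], replicates[names[j]]
            diff = a - b
            if np.allclose(diff, 0.0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(a, b)
            rows.append({"method_a": names[i], "method_b": names[j],
                         "metric": metric,
                         "mean_a": float(a.mean()),
                         "mean_b": float(b.mean()),
                         "t": float(t_stat), "p": float(p),
                         "significant": bool(p < alpha_level),
                         "n_replicates": len(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full calibration runs and the option sweep

RT_METHODS = ("rt-csf", "rt-wm", "rt-gm")
M0A_METHODS = RT_METHODS + ("voxel",)

_DEFAULT_RT_MASKS = {
    "rt-csf": RtMaskSpec("CSF", 0.9, intersect_ventricles=True),
    "rt-wm": RtMaskSpec("WM", 0.9, intersect_ventricles=False),
    "rt-gm": RtMaskSpec("GM", 0.9, intersect_ventricles=False),
}


def run_calibration(perf: PerfusionMaps, m0t: M0Map, tissue: TissueMaps,
                    m0a_method: str, opts: CalibOptions,
                    rt_mask: RtMaskSpec | None = None,
                    gm_pve_threshold: float = 0.9,
                    subject_id: str = "", session_id: str = "") -> CbfResult:
    """One full M0a derivation + CBF calibration for a fitted session.

    For the reference-tissue methods the data-driven bias field is (by
    default) estimated from the M0t map and divided out of both M0t and
    the relative CBF map before calibration; the voxelwise method needs no
    such correction.
    """
    m0a_method = m0a_method.lower()
    if m0a_method not in M0A_METHODS:
        raise ValueError(f"unknown M0a method {m0a_method!r}")

    if m0a_method == "voxel":
        m0a = m0a_voxelwise(m0t, tissue, opts)
        result = calibrate_cbf(perf, m0a, opts.alpha, tissue,
                               gm_pve_threshold, subject_id, session_id)
    else:
        tissue_kind = m0a_method.split("-")[1].upper()
        rt_mask = rt_mask or _DEFAULT_RT_MASKS[m0a_method]
        m0t_use, perf_use = m0t, perf
        if opts.bias_correction:
            bias = estimate_bias_field(m0t, tissue)
            m0t_use = M0Map(values=np.asarray(m0t.values) / bias,
                            kind=m0t.kind, method=m0t.method,
                            meta={**m0t.meta, "bias_corrected": True})
            perf_use = perf.scaled(bias)
        mask = build_rt_mask(tissue, rt_mask)
        m0a = m0a_reference_tissue(m0t_use, mask, opts, tissue_kind)
        result = calibrate_cbf(perf_use, m0a, opts.alpha, tissue,
                               gm_pve_threshold, subject_id, session_id)
    result.options.update({"m0a_method": m0a_method,
                           "m0t_method": m0t.method,
                           "bias_correction": opts.bias_correction,
                           "lambda_variant": opts.lambda_variant,
                           "smoothing": opts.smoothing})
    return result


def _m0t_variants(ds, tissue, m0t_method: str):
    """(label, M0Map) pairs: default first, then one-option deviations."""
    m0t_method = m0t_method.lower()
    if m0t_method == "satrec":
        return [("default", m0t_satrec(ds, tissue)[0]),
                ("A_fixed_100", m0t_satrec(ds, tissue,
                                           estimate_A=False)[0])]
    if m0t_method == "ctravg":
        tis = ds.acq.ti_or_pld_s
        long_ti, short_ti = float(tis[-1]), float(min(
            tis, key=lambda t: abs(t - 0.8)))
        return [
            ("default", m0t_ctravg(ds, tissue, long_ti)),
            ("short_TI", m0t_ctravg(ds, tissue, short_ti)),
            ("no_T1_correction", m0t_ctravg(ds, tissue, long_ti,
                                            t1_correction=False)),
            ("A_100", m0t_ctravg(ds, tissue, long_ti, A=1.0)),
        ]
    raise ValueError(f"unknown M0t method {m0t_method!r}")


def _longtr_variants(calib, tissue):
    return [("default", m0t_longtr(calib, tissue)),
            ("no_T1_correction", m0t_longtr(calib, tissue,
                                            t1_correction=False))]


def _m0a_option_points(m0a_method: str, base: CalibOptions):
    """(label, opts, rt_mask_spec|None) one-option deviations vs default."""
    if m0a_method == "voxel":
        return [("default", base, None),
                ("smooth_5x5", replace(base, smoothing="5x5"), None),
                ("no_smoothing", replace(base, smoothing="none"), None),
                ("lambda_avg", replace(base, lambda_variant="avg"), None),
                ("lambda_tspec", replace(base, lambda_variant="tspec"),
                 None)]
    points = [("default", base, None),
              ("no_bias_correction",
               replace(base, bias_correction=False), None)]
    if m0a_method == "rt-csf":
        points.insert(1, ("intermediate_mask", base,
                          RtMaskSpec("CSF", 0.6, True)))
        points.insert(2, ("extensive_mask", base,
                          RtMaskSpec("CSF", 0.6, False)))
    else:
        tk = m0a_method.split("-")[1].upper()
        points.insert(1, ("extensive_mask", base,
                          RtMaskSpec(tk, 0.6, False)))
    return points


def option_sweep(ds, tissue: TissueMaps, perf: PerfusionMaps,
                 m0t_method: str = "satrec", calib_scan: M0Map | None = None,
                 base_opts: CalibOptions | None = None,
                 subject_id: str = "s01",
                 session_id: str = "ses1") -> pd.DataFrame:
    """GM CBF for the default pipeline and every single-option deviation.

    One row per (M0a method, varied option); ``delta_pct`` is the percent
    change of GM-mean CBF relative to that M0a method's default row.
    Deviations of the M0t options are swept at the default M0a options.
    """
    base = base_opts or CalibOptions(te_ms=ds.acq.te_ms,
                                     alpha=ds.acq.alpha)
    if m0t_method.lower() == "longtr":
        if calib_scan is None:
            raise ValueError("LongTR sweep requires a calibration scan")
        m0t_points = _longtr_variants(calib_scan, tissue)
    else:
        m0t_points = _m0t_variants(ds, tissue, m0t_method)

    rows = []
    for m0a_method in M0A_METHODS:
        # vary the M0t option at default M0a options
        for label, m0t in m0t_points:
            res = run_calibration(perf, m0t, tissue, m0a_method, base,
                                  subject_id=subject_id,
                                  session_id=session_id)
            rows.append((m0a_method, f"m0t:{label}", res))
        # vary the M0a options at the default M0t map
        default_m0t = m0t_points[0][1]
        for label, opts, rt_mask in _m0a_option_points(m0a_method, base):
            if label == "default":
                continue   # identical to the m0t:default row
            res = run_calibration(perf, default_m0t, tissue, m0a_method,
                                  opts, rt_mask=rt_mask,
                                  subject_id=subject_id,
                                  session_id=session_id)
            rows.append((m0a_method, f"m0a:{label}", res))

    records = []
    defaults = {m: next(r for mm, lbl, r in rows
                        if mm == m and lbl == "m0t:default")
                for m in M0A_METHODS}
    for m0a_method, label, res in rows:
        ref = defaults[m0a_method].gm_mean
        records.append({
            "subject": subject_id, "session": session_id,
            "sequence": ds.acq.sequence, "m0t_method": m0t_method,
            "m0a_method": m0a_method, "option": label,
            "gm_mean_cbf": res.gm_mean, "gm_median_cbf": res.gm_median,
            "delta_pct": (res.gm_mean - ref) / ref * 100.0,
        })
    return pd.DataFrame(records)
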