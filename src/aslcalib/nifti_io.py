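"""NIfTI-1 + JSON-sidecar serialization of datasets and result maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionParams
from .kinetic import PerfusionMaps
from .phantom import GroundTruth, TissueMaps
from .simulate import AslDataset


def save_nifti(path: str | Path, data: np.ndarray,
               voxel_size_mm=(3.5, 3.5, 5.0)) -> None:
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _acq_sidecar(acq: AcquisitionParams) -> dict:
    return {
        "sequence": acq.sequence,
        "ti_or_pld_list_s": list(map(float, acq.ti_or_pld_s)),
        "te_ms": acq.te_ms, "tr_s": acq.tr_s,
        "slice_time_ms": acq.slice_time_ms,
        "n_repeats": acq.n_repeats,
        "label_duration_s": acq.label_duration_s,
        "alpha": acq.alpha,
        "background_suppression": acq.background_suppression,
        "presaturation": acq.presaturation,
        "bs_factor": acq.bs_factor,
        "calib_tr_s": acq.calib_tr_s,
        "bolus_durations_s": [float(x) for x in acq.bolus_durations()],
    }


def save_dataset(ds: AslDataset, out_dir: str | Path,
                 voxel_size_mm=(3.5, 3.5, 5.0)) -> None:
    """Write a series as asl.nii.gz-free plain NIfTI plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(out / "asl.nii", ds.data, voxel_size_mm)
    sidecar = _acq_sidecar(ds.acq)
    sidecar["volumes"] = {
        "time_s": [float(t) for t in ds.vol_time_s],
        "kind": [str(k) for k in ds.vol_kind],
        "ti_index": [int(i) for i in ds.vol_ti_index],
    }
    (out / "asl.json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(in_dir: str | Path) -> AslDataset:
    path = Path(in_dir)
    sidecar = json.loads((path / "asl.json").read_text())
    vols = sidecar.pop("volumes")
    acq = AcquisitionParams(
        sequence=sidecar["sequence"],
        ti_or_pld_s=tuple(sidecar["ti_or_pld_list_s"]),
        te_ms=sidecar["te_ms"], tr_s=sidecar["tr_s"],
        slice_time_ms=sidecar["slice_time_ms"],
        n_repeats=sidecar["n_repeats"],
        label_duration_s=sidecar["label_duration_s"],
        background_suppression=sidecar["background_suppression"],
        presaturation=sidecar["presaturation"],
        bs_factor=sidecar["bs_factor"],
        calib_tr_s=sidecar["calib_tr_s"], alpha=sidecar["alpha"])
    return AslDataset(data=load_nifti(path / "asl.nii"),
                      vol_time_s=np.asarray(vols["time_s"]),
                      vol_kind=np.asarray(vols["kind"]),
                      vol_ti_index=np.asarray(vols["ti_index"]), acq=acq)


def save_tissue(tissue: TissueMaps, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("pve_gm", "pve_wm", "pve_csf"):
        save_nifti(out / f"{name}.nii", getattr(tissue, name),
                   tissue.voxel_size_mm)
    save_nifti(out / "labels.nii", tissue.labels.astype(float),
               tissue.voxel_size_mm)
    (out / "tissue.json").write_text(json.dumps(
        {"voxel_size_mm": list(tissue.voxel_size_mm)}, indent=2))


def load_tissue(in_dir: str | Path) -> TissueMaps:
    path = Path(in_dir)
    meta = json.loads((path / "tissue.json").read_text())
    return TissueMaps(
        pve_gm=load_nifti(path / "pve_gm.nii"),
        pve_wm=load_nifti(path / "pve_wm.nii"),
        pve_csf=load_nifti(path / "pve_csf.nii"),
        labels=load_nifti(path / "labels.nii").astype(np.int16),
        voxel_size_mm=tuple(meta["voxel_size_mm"]))


def save_ground_truth(truth: GroundTruth, out_dir: str | Path,
                      voxel_size_mm=(3.5, 3.5, 5.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cbf_map", "att_map", "abv_map", "m0t_map", "t1_map",
                 "t2star_map", "lambda_map", "bias_field"):
        save_nifti(out / f"truth_{name}.nii", getattr(truth, name),
                   voxel_size_mm)
    (out / "truth.json").write_text(json.dumps(
        {"presat_efficiency_a": truth.presat_efficiency_a,
         "m0_blood": truth.m0_blood, "te_ms": truth.te_ms,
         "t2star_blood_ms": truth.t2star_blood_ms}, indent=2))


def save_perfusion(perf: PerfusionMaps, out_dir: str | Path,
                   voxel_size_mm=(3.5, 3.5, 5.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cbf_rel", "att", "abv", "fit_rss"):
        save_nifti(out / f"{name}.nii", getattr(perf, name), voxel_size_mm)
    save_nifti(out / "converged.nii", perf.converged.astype(float),
               voxel_size_mm)
    frac = float(perf.converged.mean())
    (out / "fit_report.json").write_text(json.dumps(
        {"n_times": perf.n_times, "convergence_fraction": frac}, indent=2))


def load_perfusion(in_dir: str | Path) -> PerfusionMaps:
    path = Path(in_dir)
    report = json.loads((path / "fit_report.json").read_text())
    return PerfusionMaps(
        cbf_rel=load_nifti(path / "cbf_rel.nii"),
        att=load_nifti(path / "att.nii"),
        abv=load_nifti(path / "abv.nii"),
        fit_rss=load_nifti(path / "fit_rss.nii"),
        converged=load_nifti(path / "converged.nii") > 0.5,
        n_times=report["n_times"])
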