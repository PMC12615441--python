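"""Dataset and configuration I/O.

One HDF5 file per patient with layout::

    /fids      complex float, axes (x, y, z, t)
    /b0_map    Hz per voxel
    /mask      bool
    /labels    int8 compartment codes (see simulate.LABELS)
    /truth/ph, /truth/mg, /truth/ion
    attrs: acquisition parameters and patient labels

Voxel coordinates are 0-based, axis order (x, y, z, t).  ROI label volumes
can additionally be exported as NIfTI integer volumes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .simulate import AcquisitionSpec, CohortDesign, GroundTruth, MrsiDataset, PatientSpec
from .chemistry import BiochemState

__all__ = [
    "save_patient",
    "load_patient",
    "export_labels_nifti",
    "design_from_yaml",
    "design_to_yaml",
]


def save_patient(path, dataset: MrsiDataset, truth: GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=dataset.fids)
        f.create_dataset("b0_map", data=dataset.b0_map)
        f.create_dataset("mask", data=dataset.mask)
        f.create_dataset("labels", data=truth.labels)
        g = f.create_group("truth")
        g.create_dataset("ph", data=truth.ph)
        g.create_dataset("mg", data=truth.mg)
        g.create_dataset("ion", data=truth.ion)
        acq = dataset.acq
        f.attrs.update({
            "bandwidth": acq.bandwidth, "n_points": acq.n_points,
            "larmor_freq": acq.larmor_freq, "matrix": acq.matrix,
            "nominal_res": acq.nominal_res,
            "patient_id": truth.patient_id, "grade": truth.grade,
            "idh": truth.idh if truth.idh is not None else "NA",
        })


def load_patient(path) -> tuple[MrsiDataset, GroundTruth]:
    with h5py.File(path, "r") as f:
        acq = AcquisitionSpec(
            bandwidth=float(f.attrs["bandwidth"]),
            n_points=int(f.attrs["n_points"]),
            larmor_freq=float(f.attrs["larmor_freq"]),
            matrix=tuple(int(m) for m in f.attrs["matrix"]),
            nominal_res=float(f.attrs["nominal_res"]),
        )
        dataset = MrsiDataset(
            fids=f["fids"][()], acq=acq,
            b0_map=f["b0_map"][()], mask=f["mask"][()].astype(bool),
        )
        idh = str(f.attrs["idh"])
        truth = GroundTruth(
            ph=f["truth/ph"][()], mg=f["truth/mg"][()], ion=f["truth/ion"][()],
            labels=f["labels"][()],
            patient_id=str(f.attrs["patient_id"]),
            grade=str(f.attrs["grade"]),
            idh=None if idh == "NA" else idh,
        )
    return dataset, truth


def export_labels_nifti(truth: GroundTruth, path, voxel_size_cm: float = 1.25) -> None:
    """Write the compartment label volume as an integer NIfTI."""
    import nibabel as nib

    affine = np.diag([voxel_size_cm * 10] * 3 + [1.0])  # mm
    img = nib.Nifti1Image(truth.labels.astype(np.int16), affine)
    nib.save(img, str(path))


# -- cohort design YAML ----------------------------------------------------

def design_to_yaml(design: CohortDesign, path) -> None:
    doc = {
        "matrix": list(design.matrix),
        "noise_sigma": design.noise_sigma,
        "amp_scale_sd": design.amp_scale_sd,
        "jitter_ph": design.jitter_ph,
        "jitter_mg": design.jitter_mg,
        "jitter_ion": design.jitter_ion,
        "b0_ppm": design.b0_ppm,
        "patients": [
            {"id": p.patient_id, "grade": p.grade, "idh": p.idh}
            for p in design.patients
        ],
        "compartment_biochem": {
            comp: {"ph": s.ph, "mg_fraction": s.mg_fraction, "ion": s.ion}
            for comp, s in design.compartment_biochem.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def design_from_yaml(path) -> CohortDesign:
    doc = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    for key in ("noise_sigma", "amp_scale_sd", "jitter_ph", "jitter_mg",
                "jitter_ion", "b0_ppm", "brain_frac", "tumor_frac",
                "edema_frac", "tumor_offset_frac"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "matrix" in doc:
        kwargs["matrix"] = tuple(int(m) for m in doc["matrix"])
        kwargs["acq"] = AcquisitionSpec(matrix=kwargs["matrix"])
    if "patients" in doc:
        kwargs["patients"] = tuple(
            PatientSpec(p["id"], p["grade"], p.get("idh")) for p in doc["patients"]
        )
    if "compartment_biochem" in doc:
        kwargs["compartment_biochem"] = {
            comp: BiochemState(v["ph"], v["mg_fraction"], v["ion"])
            for comp, v in doc["compartment_biochem"].items()
        }
    return CohortDesign(**kwargs)
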