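"""CRLB-based voxel quality assurance, ROI mean shifts, and grouping.

A voxel enters the analysis only if the amplitude CRLBs of all four
analysis resonances (Pi, γ-, α-, β-ATP) are strictly below the threshold
(default 35 %); non-converged or incompletely quantified voxels fail.
Per-patient ROI means of the four shifts are then grouped two ways:
by tumor sub-compartment (HGG-CE, HGG-EDM, LGG-NCE, NAWM) and by IDH
status (WT vs mut on whole-tumor means, the unclassified patient shown
separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amares import FitResult
from .simulate import ANALYSIS_RESONANCES, LABELS, GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftSignature",
    "fits_to_frame",
    "qa_mask",
    "roi_mean_shifts",
    "group_by_scheme",
    "SHIFT_COLUMNS",
]

#: tidy-table column per analysis resonance
SHIFT_COLUMNS = {"Pi": "d_pi", "gATP": "d_gamma", "aATP": "d_alpha", "bATP": "d_beta"}


@dataclass(frozen=True)
class ShiftSignature:
    """The (δPi, δγ, δα, δβ) quadruple rel. PCr; the α-referenced triple
    used by the look-up inversion is always recomputed from these four."""

    d_pi: float
    d_gamma: float
    d_alpha: float
    d_beta: float

    @property
    def rel_alpha(self) -> tuple[float, float, float]:
        return (
            self.d_pi - self.d_alpha,
            self.d_gamma - self.d_alpha,
            self.d_beta - self.d_alpha,
        )


def fits_to_frame(results: list[FitResult], coords: np.ndarray) -> pd.DataFrame:
    """Long-format table of per-voxel, per-resonance fit results.

    ``coords`` is (n_voxels, 3) of voxel indices aligned with ``results``.
    Shifts are stored re-referenced to the fitted PCr position.
    """
    rows = []
    for (i, j, k), fit in zip(np.asarray(coords), results):
        rel = fit.shifts_rel_pcr()
        for idx, name in enumerate(fit.names):
            rows.append((
                int(i), int(j), int(k), name,
                float(fit.amplitude[idx]), float(rel[idx]),
                float(fit.damping[idx]), float(fit.phase[idx]),
                float(fit.crlb_amp_pct[idx]), float(fit.crlb_shift_ppm[idx]),
                bool(fit.converged), float(fit.noise_sd),
            ))
    return pd.DataFrame(rows, columns=[
        "i", "j", "k", "resonance", "amplitude", "shift_ppm", "damping",
        "phase", "crlb_amp_pct", "crlb_shift_ppm", "converged", "noise_sd",
    ])


def qa_mask(frame: pd.DataFrame, threshold_pct: float = 35.0) -> pd.DataFrame:
    """Per-voxel QA decision.

    Returns a frame with columns i, j, k, qa_pass.  A voxel passes iff the
    amplitude CRLBs of Pi, γ-, α- and β-ATP are all *strictly below*
    ``threshold_pct`` (a CRLB equal to the threshold fails), the fit
    converged, and none of the four CRLBs is missing.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    sub = frame[frame["resonance"].isin(ANALYSIS_RESONANCES)]
    out = []
    for (i, j, k), grp in sub.groupby(["i", "j", "k"], sort=True):
        ok = len(grp) == len(ANALYSIS_RESONANCES)
        if ok and not grp["converged"].all():
            ok = False
            logger.debug("voxel (%d,%d,%d) failed QA: fit not converged", i, j, k)
        if ok:
            crlbs = grp["crlb_amp_pct"].to_numpy()
            if np.any(~np.isfinite(crlbs)):
                ok = False
                logger.debug("voxel (%d,%d,%d) failed QA: missing CRLB", i, j, k)
            elif not np.all(crlbs < threshold_pct):
                ok = False
        out.append((i, j, k, ok))
    return pd.DataFrame(out, columns=["i", "j", "k", "qa_pass"])


def _tumor_labels(grade: str) -> list[int]:
    if grade == "LGG":
        return [LABELS["NCE"]]
    return [LABELS["CE"], LABELS["EDM"]]  # HGG and the unclassified patient


def roi_mean_shifts(
    frame: pd.DataFrame,
    truth: GroundTruth,
    qa: pd.DataFrame,
) -> pd.DataFrame:
    """Per-ROI unweighted arithmetic means of the four shifts over
    QA-passing voxels, one row per ROI.

    ROIs are the compartments present in the label volume plus WHT (the
    union of the patient's tumor compartments).  An ROI with no passing
    voxels is omitted (missing, not zero) with a warning.
    """
    wide = (
        frame[frame["resonance"].isin(ANALYSIS_RESONANCES)]
        .pivot_table(index=["i", "j", "k"], columns="resonance", values="shift_ppm")
        .reset_index()
        .merge(qa, on=["i", "j", "k"], how="left")
    )
    wide["qa_pass"] = wide["qa_pass"].fillna(False)
    labels_flat = truth.labels[
        wide["i"].to_numpy(), wide["j"].to_numpy(), wide["k"].to_numpy()
    ]
    wide["label"] = labels_flat

    rois: dict[str, list[int]] = {
        name: [code]
        for name, code in LABELS.items()
        if name != "background" and np.any(labels_flat == code)
    }
    rois["WHT"] = _tumor_labels(truth.grade)

    rows = []
    for roi, codes in rois.items():
        sel = wide[wide["label"].isin(codes)]
        passing = sel[sel["qa_pass"]]
        if len(passing) == 0:
            logger.warning(
                "patient %s: ROI %s has no QA-passing voxels — reported missing",
                truth.patient_id, roi,
            )
            continue
        rows.append({
            "patient": truth.patient_id,
            "grade": truth.grade,
            "idh": truth.idh if truth.idh is not None else "NA",
            "roi": roi,
            "d_pi": passing["Pi"].mean(),
            "d_gamma": passing["gATP"].mean(),
            "d_alpha": passing["aATP"].mean(),
            "d_beta": passing["bATP"].mean(),
            "n_voxels_before_qa": len(sel),
            "n_voxels_after_qa": len(passing),
        })
    return pd.DataFrame(rows)


def group_by_scheme(table: pd.DataFrame, scheme: str) -> dict[str, pd.DataFrame]:
    """Group per-patient ROI means by one of the two study schemes.

    ``scheme="compartment"`` → {HGG-CE, HGG-EDM, LGG-NCE, NAWM}; the
    unclassified patient is excluded from the tumor groups but contributes
    to NAWM.  ``scheme="idh"`` → {WT, mut} of whole-tumor (WHT) means, with
    the unclassified patient returned under "unclassified" for separate
    display.
    """
    if scheme == "compartment":
        groups = {
            "HGG-CE": table[(table["grade"] == "HGG") & (table["roi"] == "CE")],
            "HGG-EDM": table[(table["grade"] == "HGG") & (table["roi"] == "EDM")],
            "LGG-NCE": table[(table["grade"] == "LGG") & (table["roi"] == "NCE")],
            "NAWM": table[table["roi"] == "NAWM"],
        }
    elif scheme == "idh":
        wht = table[table["roi"] == "WHT"]
        groups = {
            "WT": wht[wht["idh"] == "WT"],
            "mut": wht[wht["idh"] == "mut"],
            "unclassified": wht[wht["grade"] == "unclassified"],
        }
    else:
        raise ValueError(f"unknown grouping scheme: {scheme!r}")
    for name, grp in groups.items():
        if len(grp) == 0:
            logger.warning("grouping scheme %s: group %s is empty", scheme, name)
    return {name: grp.reset_index(drop=True) for name, grp in groups.items()}
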