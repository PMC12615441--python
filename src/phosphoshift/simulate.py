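"""Synthetic ³¹P-MRSI cohort generator.

Produces desk-scale synthetic datasets — complex time-domain FIDs on a 3D
voxel grid, a B0 offset map, a brain mask, compartment labels and the
per-voxel biochemical ground truth — with the statistical structure the
downstream analysis assumes: glioma patients with compartment-dependent
pH / MgATP-bound fraction / ionic-strength surrogate, grouped by grade
(HGG/LGG) and IDH status, plus one unclassified (pleomorphic) patient.

Each metabolite is a singlet Lorentzian line; a voxel FID is::

    s(t_n) = Σ_k A_k · exp(i(2π(f_k + b0)·t_n + φ_k)) · exp(−d_k·t_n)

with f_k = δ_k · larmor_freq (ppm × MHz = Hz), t_n = n / bandwidth.
Chemical shifts of Pi and the ATP resonances derive from the voxel's
biochemical state through :mod:`phosphoshift.chemistry`; the remaining
resonances sit at fixed literature-typical positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .chemistry import BiochemState, ShiftConstants, atp_shifts_from_state, pi_shift_from_ph

__all__ = [
    "AcquisitionSpec",
    "ResonanceSpec",
    "MrsiDataset",
    "GroundTruth",
    "CohortDesign",
    "PatientSpec",
    "LABELS",
    "ANALYSIS_RESONANCES",
    "default_resonances",
    "synthesize_fid",
    "add_noise",
    "make_patient",
    "make_cohort",
]

#: integer encoding of compartment labels in label volumes
LABELS = {"background": 0, "NAWM": 1, "CE": 2, "EDM": 3, "NCE": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: the four resonances whose shifts carry the analysis
ANALYSIS_RESONANCES = ("Pi", "gATP", "aATP", "bATP")


@dataclass(frozen=True)
class AcquisitionSpec:
    """MRSI acquisition geometry and spectral axis.

    ``larmor_freq`` is in MHz (³¹P at 7 T ≈ 120.76 MHz); the dwell time is
    1/bandwidth and the ppm axis references PCr = 0 ppm, downfield positive.
    """

    bandwidth: float = 5000.0     # Hz
    n_points: int = 1024
    larmor_freq: float = 120.76   # MHz
    matrix: tuple[int, int, int] = (8, 8, 8)
    nominal_res: float = 1.25     # cm, metadata only

    def __post_init__(self) -> None:
        if self.n_points < 256:
            raise ValueError("n_points must be ≥ 256")
        if any(m < 4 for m in self.matrix):
            raise ValueError("matrix dims must be ≥ 4")
        if self.bandwidth <= 0 or self.larmor_freq <= 0:
            raise ValueError("bandwidth and larmor_freq must be positive")

    @property
    def dwell(self) -> float:
        return 1.0 / self.bandwidth

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) / self.bandwidth


@dataclass(frozen=True)
class ResonanceSpec:
    """One singlet resonance of the spectral model."""

    name: str
    base_shift: float   # ppm rel. PCr
    amplitude: float    # arbitrary units, ≥ 0
    damping: float      # Hz, Lorentzian decay rate
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be ≥ 0")
        if self.damping <= 0:
            raise ValueError(f"{self.name}: damping must be > 0")


# (name, shift ppm rel PCr, relative amplitude, damping Hz)
_DEFAULT_TABLE = [
    ("PCr", 0.00, 1.00, 20.0),
    ("gATP", -2.48, 0.55, 35.0),
    ("aATP", -7.52, 0.60, 35.0),
    ("bATP", -16.15, 0.50, 45.0),
    ("Pi", 4.85, 0.35, 30.0),
    ("ePi", 5.25, 0.08, 30.0),
    ("PE", 6.78, 0.25, 35.0),
    ("PC", 6.24, 0.15, 35.0),
    ("GPC", 2.95, 0.30, 30.0),
    ("GPE", 3.50, 0.20, 30.0),
    ("DPG", 5.70, 0.10, 50.0),
    ("MPL", 2.06, 0.15, 60.0),
    ("NADH", -8.31, 0.10, 40.0),
    ("UDPG", -9.80, 0.05, 40.0),
]


def default_resonances() -> list[ResonanceSpec]:
    """The default in-vivo ³¹P spectral model (PCr, the three ATP
    resonances, intra-/extracellular Pi, the phosphomonoesters PE and PC,
    the phosphodiesters GPC and GPE, DPG, MPL, NAD(H) and UDPG)."""
    return [ResonanceSpec(n, s, a, d) for n, s, a, d in _DEFAULT_TABLE]


@dataclass
class MrsiDataset:
    """FID grid plus acquisition metadata.

    ``fids`` has axes (x, y, z, t); ``b0_map`` is in Hz per voxel and zero
    outside ``mask``.
    """

    fids: np.ndarray
    acq: AcquisitionSpec
    b0_map: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.fids.shape[:3] != self.mask.shape or self.b0_map.shape != self.mask.shape:
            raise ValueError("fids, b0_map and mask grids are misaligned")
        if not np.all(np.isfinite(self.fids)):
            raise ValueError("fids contain non-finite values")
        if np.any(self.b0_map[~self.mask] != 0):
            raise ValueError("b0_map must be zero outside the mask")


@dataclass
class GroundTruth:
    """Per-voxel biochemical truth and labels for one patient."""

    ph: np.ndarray
    mg: np.ndarray
    ion: np.ndarray
    labels: np.ndarray            # ints per LABELS
    patient_id: str
    grade: str                    # "HGG" | "LGG" | "unclassified"
    idh: str | None               # "WT" | "mut" | None

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {LABELS["background"], LABELS["NAWM"]}
        if self.grade == "HGG" and LABELS["NCE"] in present:
            raise ValueError("NCE labels are restricted to LGG patients")
        if self.grade == "LGG" and present & {LABELS["CE"], LABELS["EDM"]}:
            raise ValueError("CE/EDM labels are restricted to HGG patients")

    def state_at(self, idx: tuple[int, int, int]) -> BiochemState:
        return BiochemState(float(self.ph[idx]), float(self.mg[idx]), float(self.ion[idx]))


def synthesize_fid(
    resonances: list[ResonanceSpec],
    acq: AcquisitionSpec,
    b0_offset: float = 0.0,
) -> np.ndarray:
    """Noiseless complex FID of a superposition of Lorentzian singlets."""
    t = acq.times
    fid = np.zeros(acq.n_points, dtype=complex)
    for r in resonances:
        f_hz = r.base_shift * acq.larmor_freq
        if abs(f_hz) > acq.bandwidth / 2:
            raise ValueError(
                f"resonance {r.name} at {r.base_shift} ppm ({f_hz:.0f} Hz) "
                f"aliases outside ±{acq.bandwidth / 2:.0f} Hz"
            )
        fid += r.amplitude * np.exp(
            1j * (2 * np.pi * (f_hz + b0_offset) * t + r.phase) - r.damping * t
        )
    return fid


def add_noise(fid: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Add circular complex Gaussian noise, SD ``sigma`` per channel.

    ``seed`` may be an int or a numpy Generator; identical seeds give
    identical output.  ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    if sigma == 0:
        return fid
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, fid.shape) + 1j * rng.normal(0.0, sigma, fid.shape)
    return fid + noise


# -- cohort design ---------------------------------------------------------

@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    grade: str          # "HGG" | "LGG" | "unclassified"
    idh: str | None     # "WT" | "mut" | None


def _default_patients() -> tuple[PatientSpec, ...]:
    pats = [PatientSpec(f"P{i + 1:02d}", "HGG", "WT") for i in range(7)]
    pats.append(PatientSpec("P08", "HGG", "mut"))
    pats.append(PatientSpec("P09", "LGG", "mut"))
    pats.append(PatientSpec("P10", "LGG", "mut"))
    pats.append(PatientSpec("P11", "unclassified", None))
    return tuple(pats)


def _default_biochem() -> dict[str, BiochemState]:
    # Encodes the study's qualitative pattern: tumor shifted downfield
    # (higher pH/Mg in CE), β-ATP comparably shifted in LGG-NCE and HGG-CE
    # (slightly higher Mg-bound fraction in NCE), lower Ion in LGG/IDH-mut.
    return {
        "NAWM": BiochemState(ph=7.00, mg_fraction=0.80, ion=0.15),
        "EDM": BiochemState(ph=7.05, mg_fraction=0.82, ion=0.15),
        "CE": BiochemState(ph=7.15, mg_fraction=0.90, ion=0.15),
        "NCE": BiochemState(ph=7.05, mg_fraction=0.91, ion=0.13),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort.

    The default emulates the study population: 11 patients — 8 HGG
    (7 IDH-WT, 1 IDH-mut), 2 LGG (IDH-mut) and 1 unclassified — on a
    desk-scale 6×6×6 grid.  ``noise_sigma`` is the complex-channel noise SD
    in the units of the resonance amplitude table (PCr = 1 at t = 0); the
    default puts the amplitude CRLBs of the four analysis resonances around
    the 35 % QA threshold so that quality assurance is exercised.
    Per-patient biochemical jitter (SDs ``jitter_ph``/``jitter_mg``/
    ``jitter_ion``) adds between-patient variability; per-voxel amplitude
    scaling (lognormal, ``amp_scale_sd`` in log units) spreads the CRLBs.
    """

    patients: tuple[PatientSpec, ...] = field(default_factory=_default_patients)
    matrix: tuple[int, int, int] = (6, 6, 6)
    acq: AcquisitionSpec = field(default_factory=lambda: AcquisitionSpec(matrix=(6, 6, 6)))
    compartment_biochem: dict = field(default_factory=_default_biochem)
    constants: ShiftConstants = field(default_factory=ShiftConstants)
    noise_sigma: float = 0.45
    amp_scale_sd: float = 0.20
    jitter_ph: float = 0.02
    jitter_mg: float = 0.003
    jitter_ion: float = 0.005
    b0_ppm: float = 0.05
    brain_frac: float = 0.46      # brain ellipsoid semi-axes, fraction of dim
    tumor_frac: float = 0.22      # CE / NCE ellipsoid semi-axes
    edema_frac: float = 0.34      # outer radius of the EDM shell (HGG)
    tumor_offset_frac: float = 0.16  # tumor center offset along x

    def __post_init__(self) -> None:
        if self.acq.matrix != self.matrix:
            object.__setattr__(self, "acq", replace(self.acq, matrix=self.matrix))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        for comp in ("NAWM", "CE", "EDM", "NCE"):
            if comp not in self.compartment_biochem:
                raise ValueError(f"compartment_biochem missing entry for {comp}")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    acc = np.zeros(shape)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def _segment(design: CohortDesign, grade: str) -> tuple[np.ndarray, np.ndarray]:
    """Brain mask and compartment label volume for one patient."""
    shape = design.matrix
    center = tuple((m - 1) / 2 for m in shape)
    brain = _ellipsoid(shape, center, tuple(design.brain_frac * m for m in shape))
    labels = np.where(brain, LABELS["NAWM"], LABELS["background"]).astype(np.int8)
    t_center = (center[0] + design.tumor_offset_frac * shape[0], center[1], center[2])
    tumor = _ellipsoid(shape, t_center, tuple(design.tumor_frac * m for m in shape)) & brain
    if grade == "LGG":
        labels[tumor] = LABELS["NCE"]
    else:  # HGG and the unclassified patient share a CE+EDM structure
        shell = _ellipsoid(shape, t_center, tuple(design.edema_frac * m for m in shape)) & brain
        labels[shell & ~tumor] = LABELS["EDM"]
        labels[tumor] = LABELS["CE"]
    return brain, labels


def _patient_rng(master_seed: int, patient_index: int, stage: int) -> np.random.Generator:
    """Counter-scheme sub-seed: (master, patient, stage) so adding a patient
    never perturbs another patient's draws."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), patient_index, stage]))


_STAGE_JITTER, _STAGE_B0, _STAGE_AMP, _STAGE_NOISE = 0, 1, 2, 3


def make_patient(
    design: CohortDesign,
    patient_index: int,
    master_seed: int,
) -> tuple[MrsiDataset, GroundTruth]:
    """Synthesize one patient's dataset and ground truth."""
    spec = design.patients[patient_index]
    acq = design.acq
    shape = design.matrix
    brain, labels = _segment(design, spec.grade)

    # per-patient biochemical jitter, shared across that patient's voxels
    jit = _patient_rng(master_seed, patient_index, _STAGE_JITTER)
    offsets = {
        comp: (
            jit.normal(0.0, design.jitter_ph),
            jit.normal(0.0, design.jitter_mg),
            jit.normal(0.0, design.jitter_ion),
        )
        for comp in ("NAWM", "CE", "EDM", "NCE")
    }

    ph = np.zeros(shape)
    mg = np.zeros(shape)
    ion = np.zeros(shape)
    for comp, base in design.compartment_biochem.items():
        sel = labels == LABELS[comp]
        if not np.any(sel):
            continue
        dph, dmg, dion = offsets[comp]
        ph[sel] = base.ph + dph
        mg[sel] = np.clip(base.mg_fraction + dmg, 0.0, 1.0)
        ion[sel] = max(0.0, base.ion + dion)

    b0_rng = _patient_rng(master_seed, patient_index, _STAGE_B0)
    b0 = b0_rng.uniform(-design.b0_ppm, design.b0_ppm, shape) * acq.larmor_freq
    b0 = gaussian_filter(b0, sigma=1.0)
    b0[~brain] = 0.0

    amp_rng = _patient_rng(master_seed, patient_index, _STAGE_AMP)
    amp_scale = np.exp(amp_rng.normal(0.0, design.amp_scale_sd, shape))

    base_res = default_resonances()
    fids = np.zeros(shape + (acq.n_points,), dtype=complex)
    for idx in np.argwhere(brain):
        i, j, k = (int(v) for v in idx)
        state = BiochemState(ph[i, j, k], mg[i, j, k], ion[i, j, k])
        d_pi = pi_shift_from_ph(state.ph, design.constants, ion=state.ion)
        d_g, d_a, d_b = atp_shifts_from_state(state, design.constants)
        voxel_shifts = {"Pi": d_pi, "gATP": d_g, "aATP": d_a, "bATP": d_b}
        res = [
            replace(
                r,
                base_shift=voxel_shifts.get(r.name, r.base_shift),
                amplitude=r.amplitude * amp_scale[i, j, k],
            )
            for r in base_res
        ]
        fids[i, j, k] = synthesize_fid(res, acq, b0_offset=b0[i, j, k])

    if design.noise_sigma > 0:
        noise_rng = _patient_rng(master_seed, patient_index, _STAGE_NOISE)
        fids = add_noise(fids, design.noise_sigma, noise_rng)

    dataset = MrsiDataset(fids=fids, acq=acq, b0_map=b0, mask=brain)
    truth = GroundTruth(
        ph=ph, mg=mg, ion=ion, labels=labels,
        patient_id=spec.patient_id, grade=spec.grade, idh=spec.idh,
    )
    return dataset, truth


def make_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
) -> list[tuple[MrsiDataset, GroundTruth]]:
    """Synthesize the full cohort; reproducible under ``seed``."""
    design = design or CohortDesign()
    return [make_patient(design, i, seed) for i in range(len(design.patients))]
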