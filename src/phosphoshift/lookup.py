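"""Grid look-up inversion of chemical-shift signatures.

Builds a table over (pH, MgATP-bound fraction, Ion) whose nodes hold the
forward-model α-referenced shift triple (δPi−δα, δγ−δα, δβ−δα), and
inverts measured triples by exhaustive nearest-neighbour search in shift
space (unweighted Euclidean metric; ties broken deterministically toward
the lowest pH, then Mg, then Ion).  α-ATP referencing insulates the
inversion from errors in the PCr reference.  The conventional
Henderson–Hasselbalch pH from the Pi–PCr shift alone is provided for
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .chemistry import BiochemState, ShiftConstants, ph_from_pi_shift

__all__ = [
    "LookupTable",
    "default_axes",
    "build_table",
    "invert",
    "ph_conventional",
    "condition_report",
    "save_table",
    "load_table",
    "LookupInverter",
]

MAX_NODES = 10_000_000


def default_axes() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Default grid: pH 6.0–7.8 step 0.01, Mg fraction 0–1 step 0.01,
    Ion 0.00–0.40 step 0.01 (181 × 101 × 41 nodes)."""
    ph = np.round(np.arange(600, 781) * 0.01, 2)
    mg = np.round(np.arange(0, 101) * 0.01, 2)
    ion = np.round(np.arange(0, 41) * 0.01, 2)
    return ph, mg, ion


@dataclass
class LookupTable:
    """Axes, per-node α-referenced triples, and the constants fingerprint."""

    ph_axis: np.ndarray
    mg_axis: np.ndarray
    ion_axis: np.ndarray
    triples: np.ndarray        # (n_ph, n_mg, n_ion, 3)
    fingerprint: str

    def __post_init__(self) -> None:
        for name, ax in (("ph", self.ph_axis), ("mg", self.mg_axis), ("ion", self.ion_axis)):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        if not np.all(np.isfinite(self.triples)):
            raise ValueError("table triples must be finite")
        if self.triples.shape != (len(self.ph_axis), len(self.mg_axis), len(self.ion_axis), 3):
            raise ValueError("triples shape does not match axes")

    @property
    def n_nodes(self) -> int:
        return len(self.ph_axis) * len(self.mg_axis) * len(self.ion_axis)

    def steps(self) -> tuple[float, float, float]:
        """Grid step per axis (0 for singleton axes)."""
        return tuple(
            float(np.max(np.diff(ax))) if len(ax) > 1 else 0.0
            for ax in (self.ph_axis, self.mg_axis, self.ion_axis)
        )


def _forward_triples(ph, mg, ion, constants: ShiftConstants) -> np.ndarray:
    """Vectorized forward model on a meshgrid; exactly matches the scalar
    chemistry functions at every node."""
    c = constants
    ph_g, mg_g, ion_g = np.meshgrid(ph, mg, ion, indexing="ij")
    d_pi = c.delta_acid_pi + (c.delta_base_pi - c.delta_acid_pi) / (
        1.0 + 10.0 ** (c.pka - ph_g)
    ) + c.ion_coef_pi * (ion_g - c.ion_ref)
    dph = ph_g - c.ph_ref
    dion = ion_g - c.ion_ref
    d_g = c.delta_free_gamma + mg_g * (c.delta_mg_gamma - c.delta_free_gamma) \
        + c.ph_coef_gamma * dph + c.ion_coef_gamma * dion
    d_a = c.delta_free_alpha + mg_g * (c.delta_mg_alpha - c.delta_free_alpha) \
        + c.ph_coef_alpha * dph + c.ion_coef_alpha * dion
    d_b = c.delta_free_beta + mg_g * (c.delta_mg_beta - c.delta_free_beta) \
        + c.ph_coef_beta * dph + c.ion_coef_beta * dion
    return np.stack([d_pi - d_a, d_g - d_a, d_b - d_a], axis=-1)


def build_table(
    constants: ShiftConstants = ShiftConstants(),
    ph_axis: np.ndarray | None = None,
    mg_axis: np.ndarray | None = None,
    ion_axis: np.ndarray | None = None,
) -> LookupTable:
    """Evaluate the forward model on the grid; deterministic."""
    d_ph, d_mg, d_ion = default_axes()
    ph = np.asarray(ph_axis if ph_axis is not None else d_ph, dtype=float)
    mg = np.asarray(mg_axis if mg_axis is not None else d_mg, dtype=float)
    ion = np.asarray(ion_axis if ion_axis is not None else d_ion, dtype=float)
    n_nodes = len(ph) * len(mg) * len(ion)
    if n_nodes > MAX_NODES:
        raise ValueError(f"grid of {n_nodes} nodes exceeds the {MAX_NODES} limit")
    triples = _forward_triples(ph, mg, ion, constants)
    return LookupTable(ph, mg, ion, triples, constants.fingerprint())


@dataclass(frozen=True)
class InversionResult:
    ph: float
    mg_fraction: float
    ion: float
    residual: float            # ppm, Euclidean distance at the best node
    out_of_model: bool

    def state(self) -> BiochemState:
        return BiochemState(self.ph, self.mg_fraction, self.ion)


def invert(
    triple,
    table: LookupTable,
    residual_gate: float = 0.1,
) -> InversionResult:
    """Nearest table node to an α-referenced shift triple.

    Exhaustive search, unweighted Euclidean metric; the first minimum in
    (pH, Mg, Ion) C-order wins ties, i.e. lowest pH, then Mg, then Ion.
    A residual above ``residual_gate`` (ppm) flags the result
    out-of-model rather than raising.
    """
    triple = np.asarray(triple, dtype=float)
    if triple.shape != (3,):
        raise ValueError("triple must have exactly 3 components")
    flat = table.triples.reshape(-1, 3)
    d2 = np.einsum("ij,ij->i", flat - triple, flat - triple)
    best = int(np.argmin(d2))     # first occurrence = lexicographic tie-break
    n_mg, n_ion = len(table.mg_axis), len(table.ion_axis)
    i_ph, rem = divmod(best, n_mg * n_ion)
    i_mg, i_ion = divmod(rem, n_ion)
    residual = float(np.sqrt(d2[best]))
    return InversionResult(
        ph=float(table.ph_axis[i_ph]),
        mg_fraction=float(table.mg_axis[i_mg]),
        ion=float(table.ion_axis[i_ion]),
        residual=residual,
        out_of_model=residual > residual_gate,
    )


def ph_conventional(d_pi: float, constants: ShiftConstants = ShiftConstants()) -> float:
    """pH from the Pi–PCr shift difference alone (modified
    Henderson–Hasselbalch); delegates to the chemistry inverse."""
    return ph_from_pi_shift(d_pi, constants)


def condition_report(
    table: LookupTable,
    constants: ShiftConstants = ShiftConstants(),
    cond_limit: float = 1e3,
) -> dict:
    """Identifiability report: condition number of the 3×3 Jacobian
    ∂(triple)/∂(pH, Mg, Ion) at each pH node (the Jacobian is independent
    of Mg and Ion under the affine model); nodes above ``cond_limit``
    are flagged as numerically confounded."""
    c = constants
    ln10 = np.log(10.0)
    conds = np.empty(len(table.ph_axis))
    for i, ph in enumerate(table.ph_axis):
        u = 10.0 ** (c.pka - ph)
        hh_slope = ln10 * (c.delta_base_pi - c.delta_acid_pi) * u / (1.0 + u) ** 2
        jac = np.array([
            [hh_slope - c.ph_coef_alpha,
             -(c.delta_mg_alpha - c.delta_free_alpha),
             c.ion_coef_pi - c.ion_coef_alpha],
            [c.ph_coef_gamma - c.ph_coef_alpha,
             (c.delta_mg_gamma - c.delta_free_gamma) - (c.delta_mg_alpha - c.delta_free_alpha),
             c.ion_coef_gamma - c.ion_coef_alpha],
            [c.ph_coef_beta - c.ph_coef_alpha,
             (c.delta_mg_beta - c.delta_free_beta) - (c.delta_mg_alpha - c.delta_free_alpha),
             c.ion_coef_beta - c.ion_coef_alpha],
        ])
        conds[i] = np.linalg.cond(jac)
    return {
        "ph_axis": table.ph_axis.copy(),
        "condition": conds,
        "flagged_ph": table.ph_axis[conds > cond_limit].copy(),
    }


def save_table(table: LookupTable, path) -> None:
    """Serialize as .npz with a JSON sidecar carrying the fingerprint."""
    np.savez(
        path,
        ph_axis=table.ph_axis, mg_axis=table.mg_axis,
        ion_axis=table.ion_axis, triples=table.triples,
    )
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"fingerprint": table.fingerprint, "n_nodes": table.n_nodes}, fh)


def load_table(path) -> LookupTable:
    data = np.load(path)
    sidecar = str(path)[:-4] + ".json" if str(path).endswith(".npz") else str(path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    return LookupTable(
        ph_axis=data["ph_axis"], mg_axis=data["mg_axis"], ion_axis=data["ion_axis"],
        triples=data["triples"], fingerprint=meta["fingerprint"],
    )


class LookupInverter(BaseEstimator):
    """scikit-learn-style inverter: ``fit()`` builds the table from the
    constants; ``predict(X)`` maps (n, 3) α-referenced triples to (n, 3)
    columns (pH, Mg fraction, Ion).  ``residuals_`` and ``out_of_model_``
    of the last prediction are kept as fitted attributes."""

    def __init__(
        self,
        constants: ShiftConstants | None = None,
        residual_gate: float = 0.1,
    ):
        self.constants = constants
        self.residual_gate = residual_gate

    def fit(self, X=None, y=None):
        self.table_ = build_table(self.constants or ShiftConstants())
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "table_"):
            raise RuntimeError("LookupInverter must be fit() before predict()")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), 3))
        residuals = np.empty(len(X))
        flags = np.empty(len(X), dtype=bool)
        for n, triple in enumerate(X):
            r = invert(triple, self.table_, residual_gate=self.residual_gate)
            out[n] = (r.ph, r.mg_fraction, r.ion)
            residuals[n] = r.residual
            flags[n] = r.out_of_model
        self.residuals_ = residuals
        self.out_of_model_ = flags
        return out
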