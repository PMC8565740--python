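"""Weighted-repulsion model of growth-cone extension direction.

Each growth cone is pushed away from its two flanking heels: for R3 the
repulsion vectors are the unit vectors from the R2 heel to the R3 heel (v1)
and from the R4 heel to the R3 heel (v2); for R4 they run from R5 to R4 (v1)
and from R3 to R4 (v2).  The predicted extension direction is the direction
of the weighted sum

    vp = alpha * v1 + beta * v2,

with the equal-repulsion model fixing alpha = beta = 0.5.  Weights are fitted
independently per cell type by ordinary least squares without intercept,
regressing the measured direction (encoded as a unit vector, both Cartesian
components stacked) on the stacked components of v1 and v2, using pooled
early-extension measurements (22-26 hrs by default) from bundles passing a
shape-symmetry filter.

All vectors live in the bundle's rigidly aligned frame (C at the origin,
C->T4 along +x, chirality applied), where unit vectors are comparable across
bundles; angles are reported in wedge units via each bundle's own angular
scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .annotations import BundleAnnotation
from .errors import CollinearityError, IndeterminateDirectionError
from .frame import StandardFrame, align_raw, build_frame
from .growthcone import GrowthConeMeasurement

DEFAULT_SYMMETRY_THRESHOLD = 0.5
DEFAULT_POOLED_TIMES = (22.0, 24.0, 26.0)


@dataclass
class RepulsionInput:
    """One growth cone's repulsion geometry and measured direction.

    ``v1``/``v2`` are unit vectors in the aligned bundle frame;
    ``measured_angle`` is in wedge units.  The bundle's wedge angles ride
    along so angles convert to vectors without re-deriving the frame.
    """

    v1: np.ndarray
    v2: np.ndarray
    measured_angle: float
    bundle_id: str
    time_hrs_apf: float
    cell_type: str
    wedge_t3: float
    wedge_t3p: float
    #: magnitude of the measured extension vector.  1.0 treats the
    #: measurement as a pure direction; a generator emitting data from the
    #: vector-sum model supplies |alpha*v1 + beta*v2| so the regression is
    #: exactly linear in the weights.
    measured_magnitude: float = 1.0

    def __post_init__(self):
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        for v in (self.v1, self.v2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError("repulsion vectors must be unit vectors")

    @property
    def asymmetry(self) -> float:
        return _asymmetry(self.wedge_t3, self.wedge_t3p)

    def _wedge_to_rad(self, theta: float) -> float:
        return theta * (self.wedge_t3 if theta >= 0 else self.wedge_t3p)

    def _rad_to_wedge(self, phi: float) -> float:
        return phi / (self.wedge_t3 if phi >= 0 else self.wedge_t3p)

    @property
    def measured_unit(self) -> np.ndarray:
        phi = self._wedge_to_rad(self.measured_angle)
        return np.array([np.cos(phi), np.sin(phi)])

    @property
    def measured_vector(self) -> np.ndarray:
        return self.measured_magnitude * self.measured_unit


@dataclass
class RepulsionFit:
    """Fitted repulsion weights for one cell type."""

    cell_type: str
    alpha: float
    beta: float
    r_squared: float
    n_bundles: int


def _asymmetry(w3: float, w3p: float) -> float:
    return abs(w3 - w3p) / max(w3, w3p)


def asymmetry_ratio(frame: StandardFrame) -> float:
    """Bundle shape asymmetry: |w3 - w3p| / max(w3, w3p), in [0, 1)."""
    return _asymmetry(frame.wedge_t3, frame.wedge_t3p)


def repulsion_vectors(bundle: BundleAnnotation, cell_type: str,
                      frame: StandardFrame | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(v1, v2) unit vectors for one cell in the aligned bundle frame."""
    if cell_type == "R3":
        src1, dst, src2 = 2, 3, 4
    elif cell_type == "R4":
        src1, dst, src2 = 5, 4, 3
    else:
        raise ValueError(f"cell_type must be R3 or R4, got {cell_type!r}")
    bundle.require(heels=(src1, dst, src2))
    aligned = align_raw(bundle, frame).set_index("label")
    heel = lambda i: aligned.loc[f"R{i}", ["x", "y"]].to_numpy(dtype=float)
    v1 = heel(dst) - heel(src1)
    v2 = heel(dst) - heel(src2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise IndeterminateDirectionError(
            f"bundle {bundle.bundle_id}: coincident heels for {cell_type}")
    return v1 / n1, v2 / n2


def build_inputs(bundles: Iterable[BundleAnnotation],
                 measurements: Iterable[GrowthConeMeasurement]
                 ) -> list[RepulsionInput]:
    """Pair measured growth-cone angles with their bundle's repulsion
    geometry.  Measurements flagged ambiguous are dropped."""
    by_bundle: dict[str, BundleAnnotation] = {b.bundle_id: b for b in bundles}
    frames: dict[str, StandardFrame] = {}
    out = []
    for m in measurements:
        if m.front.ambiguous or m.bundle_id not in by_bundle:
            continue
        b = by_bundle[m.bundle_id]
        if m.bundle_id not in frames:
            frames[m.bundle_id] = build_frame(b)
        frame = frames[m.bundle_id]
        v1, v2 = repulsion_vectors(b, m.cell_type, frame)
        out.append(RepulsionInput(
            v1=v1, v2=v2, measured_angle=m.front.rel_angle,
            bundle_id=m.bundle_id, time_hrs_apf=m.time_hrs_apf,
            cell_type=m.cell_type, wedge_t3=frame.wedge_t3,
            wedge_t3p=frame.wedge_t3p))
    return out


def predict_angle(inp: RepulsionInput, alpha: float, beta: float) -> float:
    """Standardized angular coordinate of the weighted vector sum's
    direction."""
    if alpha == 0 and beta == 0:
        raise ValueError("(alpha, beta) must not both be zero")
    vp = alpha * inp.v1 + beta * inp.v2
    norm = np.linalg.norm(vp)
    if norm < 1e-9:
        raise IndeterminateDirectionError(
            f"bundle {inp.bundle_id}: alpha*v1 + beta*v2 has near-zero norm")
    phi = float(np.arctan2(vp[1], vp[0]))
    return inp._rad_to_wedge(phi)


def fit_weights(inputs: Sequence[RepulsionInput], cell_type: str,
                symmetry_threshold: float = DEFAULT_SYMMETRY_THRESHOLD,
                times: Sequence[float] | None = DEFAULT_POOLED_TIMES,
                ) -> RepulsionFit:
    """Least-squares repulsion weights for one cell type.

    Inputs are restricted to the pooled early time points and to bundles
    passing the symmetry filter (asymmetry <= threshold).  The measured
    extension vector's components are stacked and regressed on the stacked
    components of (v1, v2) without intercept; R^2 is the coefficient of
    determination on the stacked components.

    Note the weights' absolute scale is identifiable only through the
    measured magnitudes: pure directions (magnitude 1) determine the
    alpha/beta ratio exactly but let the normalization of the target
    deflate or inflate the pair jointly.
    """
    sel = [i for i in inputs
           if i.cell_type == cell_type
           and (times is None or i.time_hrs_apf in set(times))
           and i.asymmetry <= symmetry_threshold]
    if len(sel) < 3:
        raise ValueError(
            f"need >= 3 surviving inputs for {cell_type}, got {len(sel)}")
    X = np.vstack([np.column_stack([i.v1, i.v2]) for i in sel])  # (2n, 2)
    y = np.concatenate([i.measured_vector for i in sel])
    if np.linalg.matrix_rank(X) < 2:
        raise CollinearityError(
            f"{cell_type}: repulsion design matrix is rank-deficient")
    model = LinearRegression(fit_intercept=False).fit(X, y)
    return RepulsionFit(
        cell_type=cell_type,
        alpha=float(model.coef_[0]),
        beta=float(model.coef_[1]),
        r_squared=float(model.score(X, y)),
        n_bundles=len(sel),
    )


def evaluate_models(inputs: Sequence[RepulsionInput],
                    fits: Sequence[RepulsionFit]) -> pd.DataFrame:
    """Absolute predicted-vs-measured angle differences, per input, for the
    equal (alpha = beta = 0.5) and fitted (weighted) models."""
    by_type = {f.cell_type: f for f in fits}
    rows = []
    for i in inputs:
        fit = by_type.get(i.cell_type)
        for model_name, (a, b) in (
                ("equal", (0.5, 0.5)),
                ("weighted", (fit.alpha, fit.beta) if fit else (None, None))):
            if a is None:
                continue
            diff = abs(predict_angle(i, a, b) - i.measured_angle)
            rows.append({"bundle_id": i.bundle_id,
                         "time_hrs_apf": i.time_hrs_apf,
                         "cell_type": i.cell_type, "model": model_name,
                         "abs_angle_diff": diff})
    return pd.DataFrame(rows, columns=["bundle_id", "time_hrs_apf",
                                       "cell_type", "model",
                                       "abs_angle_diff"])


def fit_to_json(fits: Sequence[RepulsionFit], path,
                symmetry_threshold: float = DEFAULT_SYMMETRY_THRESHOLD,
                times: Sequence[float] = DEFAULT_POOLED_TIMES) -> None:
    import json

    payload = [{
        "cell_type": f.cell_type, "alpha": f.alpha, "beta": f.beta,
        "r_squared": f.r_squared, "n_bundles": f.n_bundles,
        "symmetry_threshold": symmetry_threshold,
        "times_pooled": list(times),
    } for f in fits]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
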