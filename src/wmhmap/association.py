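"""Voxel-wise regularized association between WMH evolution and RSSI location.

The predictor matrix is high-dimensional and sparse: one column per in-mask
voxel, entries in {-1, 0, +1} coding WMH regression / no change / progression
for each subject (or {0,1} WMH presence in baseline mode).  A ridge-penalized
support-vector regression (epsilon-insensitive loss, squared-norm penalty on
the voxel weights only) is fit by stochastic gradient descent, with the RSSI
location code (plus unpenalized age) as the response.  The regularization
strength defaults to 1/47.

Because the prose conventions for such models are ambiguous in two respects,
both options are implemented behind flags: the model orientation (location as
response over voxel predictors, or per-voxel responses over location + age,
see :func:`fit_voxelwise_inverse`) and the numeric coding of location (raw
proforma integer or a one-vs-rest indicator, see :func:`encode_response`).

The fitted signed weight field, split into positive and negative maps, is the
association map; for display both halves are rescaled to 50% of their own
maximum (a pure visualization step).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import sparse

from .locations import location_to_int
from .volumetrics import CODE_PROGRESSED, CODE_REGRESSED, EvolutionMap


@dataclasses.dataclass
class ChangeFeatureMatrix:
    """Sparse subject x voxel matrix of WMH change (or presence) codes."""

    subject_ids: list[str]
    voxel_index: np.ndarray        # (p, 3) in-mask voxel coordinates, row order = columns
    values: sparse.csr_matrix      # n_subjects x p, entries in {-1, 0, +1} (or {0,1})
    grid_dims: tuple[int, int, int]
    voxel_dims_mm: tuple[float, float, float]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_grid(self, column_values: np.ndarray) -> np.ndarray:
        """Scatter a per-column vector back onto the 3D grid (zeros elsewhere)."""
        out = np.zeros(self.grid_dims, dtype=np.float64)
        out[tuple(self.voxel_index.T)] = column_values
        return out


@dataclasses.dataclass
class AssociationMap:
    """Signed per-voxel association weights with their sign-split halves."""

    weights: np.ndarray            # 3D signed coefficient field
    intercept: float
    covariate_weights: dict
    voxel_dims_mm: tuple[float, float, float]
    hyperparameters: dict

    @property
    def positive_map(self) -> np.ndarray:
        return np.maximum(self.weights, 0.0)

    @property
    def negative_map(self) -> np.ndarray:
        return np.maximum(-self.weights, 0.0)


def build_change_features(
    evolution_maps: dict[str, EvolutionMap],
    analysis_mask: np.ndarray,
) -> ChangeFeatureMatrix:
    """Assemble the sparse evolution feature matrix from per-subject maps.

    Entry (subject, voxel) is +1 where WMH progressed, -1 where it regressed,
    0 otherwise.  Column order is C-order over the analysis-mask voxels.
    """
    mask = np.asarray(analysis_mask).astype(bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    ids = list(evolution_maps)
    ref = evolution_maps[ids[0]]
    if mask.shape != ref.grid_dims:
        raise ValueError("analysis mask not congruent with evolution maps")
    voxel_index = np.argwhere(mask)
    rows = []
    for sid in ids:
        emap = evolution_maps[sid]
        if emap.grid_dims != ref.grid_dims or not np.allclose(
            emap.voxel_dims_mm, ref.voxel_dims_mm
        ):
            raise ValueError(f"evolution map for {sid!r} not grid-congruent")
        codes = emap.codes[mask]
        row = np.zeros(len(codes), dtype=np.int8)
        row[codes == CODE_PROGRESSED] = 1
        row[codes == CODE_REGRESSED] = -1
        rows.append(sparse.csr_matrix(row))
    values = sparse.vstack(rows).tocsr()
    return ChangeFeatureMatrix(
        subject_ids=ids,
        voxel_index=voxel_index,
        values=values,
        grid_dims=ref.grid_dims,
        voxel_dims_mm=ref.voxel_dims_mm,
    )


def build_presence_features(
    masks: dict[str, np.ndarray], analysis_mask: np.ndarray,
    voxel_dims_mm: tuple[float, float, float],
) -> ChangeFeatureMatrix:
    """Baseline-mode feature matrix: {0,1} WMH presence per voxel."""
    region = np.asarray(analysis_mask).astype(bool)
    if not region.any():
        raise ValueError("analysis mask is empty")
    ids = list(masks)
    voxel_index = np.argwhere(region)
    rows = [sparse.csr_matrix(np.asarray(masks[sid])[region].astype(np.int8))
            for sid in ids]
    values = sparse.vstack(rows).tocsr()
    grid = np.asarray(masks[ids[0]]).shape
    return ChangeFeatureMatrix(ids, voxel_index, values, grid, tuple(voxel_dims_mm))


def encode_response(
    cohort: pd.DataFrame,
    mode: str = "location_code",
    region: str | None = None,
) -> np.ndarray:
    """Numeric response vector from RSSI location.

    ``location_code`` emits the proforma integer of the primary (largest)
    cluster, 0 for no RSSI; ``location_indicator`` emits 1 where the primary
    cluster lies in ``region`` else 0.  A constant vector is degenerate and
    raises.
    """
    primaries = []
    for sid, vol, codes in zip(
        cohort["subject_id"], cohort["rssi_volume_ml"], cohort["rssi_location_codes"]
    ):
        if vol > 0 and len(codes) == 0:
            raise ValueError(f"subject {sid!r} has RSSI but no resolvable location")
        primaries.append(codes[0] if codes else None)
    if mode == "location_code":
        y = np.array([location_to_int(c) for c in primaries], dtype=np.float64)
    elif mode == "location_indicator":
        if region is None:
            raise ValueError("location_indicator mode requires a region")
        y = np.array([1.0 if (c is not None and c[0] == region) else 0.0
                      for c in primaries])
    else:
        raise ValueError(f"unknown encoding mode: {mode!r}")
    if np.unique(y).size == 1:
        raise ValueError("degenerate response: all subjects encode identically")
    return y


def fit_sgd_ridge(
    features: ChangeFeatureMatrix,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
    lam: float = 1.0 / 47.0,
    epsilon: float | None = None,
    epochs: int = 50,
    seed: int = 0,
    loss: str = "epsilon_insensitive",
    eta0: float | None = None,
    decay: float | None = None,
    average: bool = True,
    fit_intercept: bool = True,
) -> AssociationMap:
    """Ridge-penalized SVM-style regression over sparse voxel features via SGD.

    Minimizes ``mean(loss) + lam * ||w||^2 / 2`` over the voxel weights; the
    intercept and covariate coefficients (e.g. age) are unpenalized.  Loss is
    epsilon-insensitive by default, with epsilon defaulting to IQR(response)
    / 13.49 (the dispersion convention of common SVR implementations); a
    squared-loss mode exists for validation against the closed-form ridge
    estimator.  Fully deterministic for a fixed seed: one sample per step,
    fixed shuffling per epoch, step size eta0 / (1 + decay * t), and (by
    default) averaging of the iterates over the second half of the run.
    """
    y = np.asarray(response, dtype=np.float64)
    n, p = features.values.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != number of subjects {n}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in response")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if loss not in ("epsilon_insensitive", "squared"):
        raise ValueError(f"unknown loss {loss!r}")

    X = features.values.toarray().astype(np.float64)
    if covariates is None:
        C = np.zeros((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must match number of subjects")

    if epsilon is None:
        if loss == "squared":
            epsilon = 0.0
        else:
            q1, q3 = np.percentile(y, [25, 75])
            epsilon = max((q3 - q1) / 13.49, 1e-12)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    row_norm2 = (X**2).sum(axis=1) + (C**2).sum(axis=1) + 1.0
    if eta0 is None:
        # the squared-loss (validation) mode needs a small step: the averaged
        # iterate's reshuffling bias is linear in the step size
        scale = 0.1 if loss == "squared" else 0.5
        eta0 = scale / (row_norm2.max() + lam)
    if decay is None:
        decay = 1.0 / (n * max(epochs, 1))

    rng = np.random.default_rng(seed)
    w = np.zeros(p)
    wc = np.zeros(C.shape[1])
    b = 0.0
    t = 0
    total_steps = epochs * n
    avg_start = total_steps // 2
    w_avg = np.zeros(p)
    wc_avg = np.zeros(C.shape[1])
    b_avg = 0.0
    n_avg = 0

    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            eta = eta0 / (1.0 + decay * t)
            pred = X[i] @ w + (C[i] @ wc if wc.size else 0.0) + b
            r = pred - y[i]
            if loss == "squared":
                g = r
            else:
                g = 0.0 if abs(r) <= epsilon else float(np.sign(r))
            w *= (1.0 - eta * lam)
            if g != 0.0:
                w -= eta * g * X[i]
                if wc.size:
                    wc -= eta * g * C[i]
                if fit_intercept:
                    b -= eta * g
            t += 1
            if average and t > avg_start:
                w_avg += w
                wc_avg += wc
                b_avg += b
                n_avg += 1

    if average and n_avg > 0:
        w, wc, b = w_avg / n_avg, wc_avg / n_avg, b_avg / n_avg

    weights_grid = features.to_grid(w)
    return AssociationMap(
        weights=weights_grid,
        intercept=float(b),
        covariate_weights={f"cov{i}": float(v) for i, v in enumerate(wc)},
        voxel_dims_mm=features.voxel_dims_mm,
        hyperparameters={
            "lambda": lam, "epsilon": float(epsilon), "epochs": epochs,
            "seed": seed, "loss": loss, "eta0": float(eta0),
            "decay": float(decay), "average": average,
        },
    )


def fit_voxelwise_inverse(
    features: ChangeFeatureMatrix,
    location: np.ndarray,
    age: np.ndarray,
    lam: float = 1.0 / 47.0,
) -> AssociationMap:
    """Inverted-orientation model: each voxel's change code regressed on location.

    For every voxel independently, ridge regression of the voxel feature on
    [location, age, 1] (penalty on the location and age coefficients); the
    map stores the per-voxel location coefficient.  Closed form, vectorized
    across voxels.
    """
    Y = features.values.toarray().astype(np.float64)     # n x p
    X = np.column_stack([
        np.asarray(location, float), np.asarray(age, float), np.ones(len(location))
    ])
    n = X.shape[0]
    pen = np.diag([lam * n, lam * n, 0.0])
    W = np.linalg.solve(X.T @ X + pen, X.T @ Y)           # 3 x p
    return AssociationMap(
        weights=features.to_grid(W[0]),
        intercept=0.0,
        covariate_weights={},
        voxel_dims_mm=features.voxel_dims_mm,
        hyperparameters={"lambda": lam, "orientation": "voxelwise_response"},
    )


def rescale_for_display(
    amap: AssociationMap, fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rescale the sign-split maps to ``fraction`` of their own maxima.

    Each half is divided by (fraction x its maximum) and clipped to [0,1]; a
    value at half-maximum therefore displays as 1.0.  Returns
    (positive_display, negative_display, degenerate_flag); the flag is set
    when a half is all-zero (that half is returned as zeros).  Visualization
    only — never fed back into statistics.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    out = []
    degenerate = False
    for half in (amap.positive_map, amap.negative_map):
        peak = float(half.max())
        if peak == 0.0:
            degenerate = True
            out.append(np.zeros_like(half))
        else:
            out.append(np.clip(half / (fraction * peak), 0.0, 1.0))
    return out[0], out[1], degenerate
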