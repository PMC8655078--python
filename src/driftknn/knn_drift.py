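"""driftCorrectKNN: drift correction by thresholded nearest-neighbor cost minimization.

The method exploits the repeated blinking of fluorophores in dSTORM /
DNA-PAINT style acquisitions.  A good drift model projects every
localization to t = 0 so that re-blinks of the same emitter collapse onto
each other; the quality of a candidate model is measured by the
thresholded sum of nearest-neighbor distances

    sumNND = sum_i min(d_i, l)

where d_i is the Euclidean distance from projected localization i to its
nearest neighbor and l saturates the contribution of false pairings.
Within a dataset the drift is modelled as a constant-free polynomial in
frame number (default linear); between datasets as a constant shift
(default), fitted in sequence against the corrected first dataset.  All
coordinates and thresholds are in pixels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .localization_io import LocalizationTable, resegment, reassemble

__all__ = [
    "CostParams",
    "DriftModel",
    "FitDiagnostics",
    "CostLandscape",
    "thresholded_nnd_sum",
    "project_to_t0",
    "intra_cost",
    "fit_intra",
    "inter_cost",
    "fit_inter",
    "drift_correct_knn",
    "cost_landscape",
]

logger = logging.getLogger("driftknn")

#: Nearest-neighbor saturation thresholds (pixels).
DEFAULT_L_INTRA = 1.0
DEFAULT_L_INTER = 2.0

#: Derivative-free simplex (Nelder–Mead) settings, fminsearch-style.
OPTIMIZER_XATOL = 1e-6
OPTIMIZER_FATOL = 1e-6
OPTIMIZER_MAXITER = 2000


@dataclass(frozen=True)
class CostParams:
    """Thresholds and polynomial orders of the two cost functions.

    ``l_intra`` (1 px) saturates false pairings caused by blinking within a
    dataset; ``l_inter`` (2 px) the sparser mismatches between whole
    datasets.  The intra model is a degree-``intra_degree`` polynomial in
    frame number with zero constant term; the inter model is always a
    constant shift.
    """

    l_intra: float = DEFAULT_L_INTRA
    l_inter: float = DEFAULT_L_INTER
    intra_degree: int = 1

    def __post_init__(self) -> None:
        if self.l_intra <= 0 or self.l_inter <= 0:
            raise ValueError("thresholds must be > 0")
        if self.intra_degree < 1:
            raise ValueError("intra_degree must be >= 1")


@dataclass
class FitDiagnostics:
    converged: bool
    n_iterations: int
    n_evaluations: int
    initial_cost: float
    final_cost: float


@dataclass
class DriftModel:
    """Per-dataset drift model: intra polynomial + inter constant shift.

    ``intra_coeffs[d, dim, p]`` is the coefficient of f**(p+1) for dataset
    d (pixels/frame**(p+1)); the constant term is fixed at zero so the
    model vanishes at the first frame of each dataset.
    ``inter_shift[d, dim]`` is the constant offset of dataset d relative to
    dataset 0 (pixels); ``inter_shift[0]`` is identically zero.
    Total drift at (dataset d, frame f) = inter_shift[d] + sum_p
    intra_coeffs[d, :, p] * f**(p+1).
    """

    intra_coeffs: np.ndarray  # (n_datasets, ndim, degree)
    inter_shift: np.ndarray  # (n_datasets, ndim)
    intra_degree: int
    is_3d: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intra_coeffs = np.asarray(self.intra_coeffs, float)
        self.inter_shift = np.asarray(self.inter_shift, float)
        if self.intra_coeffs.shape[2] != self.intra_degree:
            raise ValueError("intra_coeffs last axis must match intra_degree")
        if self.n_datasets > 0 and not np.all(self.inter_shift[0] == 0.0):
            raise ValueError("inter_shift of dataset 0 must be zero")

    @property
    def n_datasets(self) -> int:
        return self.intra_coeffs.shape[0]

    @property
    def ndim(self) -> int:
        return 3 if self.is_3d else 2

    def drift_at(self, dataset: np.ndarray, frame: np.ndarray) -> np.ndarray:
        """Model drift (pixels), shape (n, ndim), at given (dataset, frame) pairs."""
        dataset = np.asarray(dataset, np.int64)
        frame = np.asarray(frame, float)
        out = self.inter_shift[dataset].copy()
        fp = frame[:, None]
        for p in range(self.intra_degree):
            out += self.intra_coeffs[dataset, :, p] * fp ** (p + 1)
        return out

    def curve(self, frames_per_dataset: int, n_frames_total: int) -> np.ndarray:
        """Evaluate the model on every global frame; shape (n_frames_total, ndim)."""
        gf = np.arange(n_frames_total)
        d = np.minimum(gf // frames_per_dataset, self.n_datasets - 1)
        f = gf - d * frames_per_dataset
        return self.drift_at(d, f)

    # -- serialization -----------------------------------------------------
    def to_dict(self, pixel_size_nm: float | None = None) -> dict:
        return {
            "intra_degree": self.intra_degree,
            "is_3d": self.is_3d,
            "pixel_size_nm": pixel_size_nm,
            "datasets": [
                {
                    "dataset": d,
                    "intra_coeffs": self.intra_coeffs[d].tolist(),
                    "inter_shift": self.inter_shift[d].tolist(),
                }
                for d in range(self.n_datasets)
            ],
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path: str | Path, pixel_size_nm: float | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(pixel_size_nm), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "DriftModel":
        coeffs = np.array([ds["intra_coeffs"] for ds in d["datasets"]], float)
        shifts = np.array([ds["inter_shift"] for ds in d["datasets"]], float)
        return cls(coeffs, shifts, d["intra_degree"], d["is_3d"],
                   diagnostics=d.get("diagnostics", {}))

    @classmethod
    def from_json(cls, path: str | Path) -> "DriftModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- cost primitives -------------------------------------------------------

def thresholded_nnd_sum(
    query_points: np.ndarray,
    reference: np.ndarray | cKDTree,
    l: float,
    exclude_self: bool = False,
) -> float:
    """Thresholded sum of nearest-neighbor distances, sum_i min(d_i, l).

    ``reference`` may be a point array or a pre-built :class:`cKDTree`
    (the inter-dataset path builds the reference tree once and reuses it).
    With ``exclude_self=True`` query and reference must be the same point
    set in the same order; the i-th point's own entry is excluded from its
    search *by index*, so coincident distinct points still count at
    distance zero.
    """
    if l <= 0:
        raise ValueError("threshold l must be > 0")
    query_points = np.asarray(query_points, float)
    n = len(query_points)
    if n == 0:
        return 0.0
    if exclude_self:
        if n < 2:
            return n * l  # every point saturates: no other point to pair with
        tree = reference if isinstance(reference, cKDTree) else cKDTree(query_points)
        dist, idx = tree.query(query_points, k=2)
        own = idx[:, 0] == np.arange(n)
        d = np.where(own, dist[:, 1], dist[:, 0])
    else:
        tree = reference if isinstance(reference, cKDTree) else cKDTree(reference)
        d, _ = tree.query(query_points, k=1)
    return float(np.minimum(d, l).sum())


def project_to_t0(positions: np.ndarray, frames: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Remove modelled intra-dataset drift: corrected = observed − sum_p a_p f**p.

    ``coeffs`` has shape (ndim, degree); coeffs[:, p-1] multiplies f**p
    (constant term absent by construction).
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, float))
    positions = np.asarray(positions, float)
    frames = np.asarray(frames, float)
    drift = np.zeros_like(positions)
    fp = frames[:, None]
    for p in range(coeffs.shape[1]):
        drift += coeffs[None, :, p].reshape(1, -1) * fp ** (p + 1)
    return positions - drift


def intra_cost(
    positions: np.ndarray, frames: np.ndarray, coeffs: np.ndarray, l_intra: float
) -> float:
    """Cost of an intra-dataset drift model: self sumNND of the t=0 projection.

    The spatial index is rebuilt on every call because every point moves
    with the trial coefficients.
    """
    proj = project_to_t0(positions, frames, coeffs)
    return thresholded_nnd_sum(proj, proj, l_intra, exclude_self=True)


def inter_cost(
    reference_tree: cKDTree, target_points: np.ndarray, shift: np.ndarray, l_inter: float
) -> float:
    """Cost of a constant inter-dataset shift.

    The target dataset (already intra-corrected) is moved by ``shift`` and
    queried against the fixed k-d tree of the corrected first dataset — a
    single tree decomposition serves all trial shifts and all datasets.
    """
    target_points = np.asarray(target_points, float)
    if len(target_points) == 0:
        return 0.0
    return thresholded_nnd_sum(target_points + np.asarray(shift, float), reference_tree, l_inter)


# -- simplex fits ----------------------------------------------------------

def _nelder_mead(fun, x0: np.ndarray, initial_step: np.ndarray) -> tuple[np.ndarray, FitDiagnostics]:
    """Nelder–Mead with an explicit initial simplex scaled to the problem.

    The default fminsearch-style simplex perturbs each coordinate by 5%
    (or an absolute 2.5e-4 at zero), far below the funnel width of these
    cost landscapes when starting from the zero initial guess; an explicit
    per-coordinate step keeps the first reflections inside the funnel.
    """
    x0 = np.asarray(x0, float)
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += initial_step[i]
    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": OPTIMIZER_XATOL,
            "fatol": OPTIMIZER_FATOL,
            "maxiter": OPTIMIZER_MAXITER,
            "initial_simplex": simplex,
        },
    )
    f0 = fun(x0)
    # Nelder-Mead tracks the best vertex, but guard the contract explicitly:
    # the returned parameters never cost more than the initial guess.
    if res.fun > f0:
        x, fbest = x0, f0
    else:
        x, fbest = res.x, float(res.fun)
    diag = FitDiagnostics(
        converged=bool(res.success),
        n_iterations=int(res.nit),
        n_evaluations=int(res.nfev),
        initial_cost=float(f0),
        final_cost=fbest,
    )
    if not res.success:
        logger.warning("simplex did not converge after %d iterations", res.nit)
    return x, diag


def fit_intra(
    positions: np.ndarray,
    frames: np.ndarray,
    degree: int,
    l_intra: float,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Fit the intra-dataset drift polynomial by simplex minimization of
    the self sumNND, initialized at zero coefficients.

    Returns ``coeffs`` of shape (ndim, degree).  A dataset with fewer than
    two localizations has no pairings to constrain the model; zero
    coefficients are returned with a warning.
    """
    positions = np.asarray(positions, float)
    ndim = positions.shape[1]
    if len(positions) < 2:
        warnings.warn("fewer than 2 localizations in dataset; returning zero drift")
        zero = np.zeros((ndim, degree))
        return zero, FitDiagnostics(True, 0, 0, 0.0, 0.0)

    frames = np.asarray(frames, float)
    fmax = max(float(frames.max()), 1.0)

    def objective(theta: np.ndarray) -> float:
        return intra_cost(positions, frames, theta.reshape(ndim, degree), l_intra)

    x0 = np.zeros(ndim * degree)
    # per-coefficient step producing ~0.5 px displacement at the dataset's last frame
    step = np.empty(ndim * degree)
    for dim in range(ndim):
        for p in range(degree):
            step[dim * degree + p] = 0.5 / fmax ** (p + 1)
    x, diag = _nelder_mead(objective, x0, step)
    return x.reshape(ndim, degree), diag


def fit_inter(
    reference_tree: cKDTree,
    target_points: np.ndarray,
    init_shift: np.ndarray,
    l_inter: float,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Fit the constant inter-dataset shift by simplex minimization.

    ``init_shift`` follows the initialization policy of the caller: zero
    when brightfield registration kept datasets aligned, else the
    accumulated end-of-dataset drift of the previous dataset.
    """
    target_points = np.asarray(target_points, float)
    ndim = target_points.shape[1]
    if len(target_points) == 0:
        warnings.warn("empty target dataset; returning initial shift")
        return np.asarray(init_shift, float), FitDiagnostics(True, 0, 0, 0.0, 0.0)

    def objective(shift: np.ndarray) -> float:
        return inter_cost(reference_tree, target_points, shift, l_inter)

    step = np.full(ndim, 0.25)  # px; well inside the l_inter funnel
    x, diag = _nelder_mead(objective, np.asarray(init_shift, float), step)
    return x, diag


# -- full pipeline ---------------------------------------------------------

def drift_correct_knn(
    table: LocalizationTable,
    params: CostParams | None = None,
    registration_used: bool = True,
    frames_per_dataset_override: Optional[int] = None,
    original_frames_per_dataset: Optional[int] = None,
) -> tuple[LocalizationTable, DriftModel]:
    """Full post-processing drift correction.

    1. fit the intra-dataset polynomial for every dataset and project each
       dataset to its own t = 0;
    2. for datasets 1..D−1 in order, fit a constant shift against the
       corrected *first* dataset (one k-d tree, built once), initialized
       at zero when ``registration_used`` else at the accumulated drift of
       the previously corrected dataset;
    3. return the corrected table (observed − model) and the model.

    ``frames_per_dataset_override`` re-chunks the global frame sequence
    before correction and restores the original scheme afterwards; the
    returned model refers to the override chunking.
    """
    params = params or CostParams()
    mapping = None
    work = table
    if frames_per_dataset_override is not None:
        work, mapping = resegment(table, frames_per_dataset_override,
                                  original_frames_per_dataset)

    ndim = work.ndim
    n_ds = work.n_datasets
    degree = params.intra_degree
    coords = work.coords()
    frames = work.frames()
    datasets = work.datasets()

    intra = np.zeros((n_ds, ndim, degree))
    shifts = np.zeros((n_ds, ndim))
    diagnostics: dict = {"intra": {}, "inter": {}}
    ds_last_frame = np.zeros(n_ds)

    for d in range(n_ds):
        sel = datasets == d
        if sel.sum() < 2:
            logger.warning("dataset %d has <2 localizations; skipping intra fit", d)
            diagnostics["intra"][d] = None
            continue
        coeffs, diag = fit_intra(coords[sel], frames[sel], degree, params.l_intra)
        intra[d] = coeffs
        ds_last_frame[d] = frames[sel].max()
        diagnostics["intra"][d] = diag.__dict__
        logger.info("intra fit dataset %d: cost %.4f -> %.4f (%d evals)",
                    d, diag.initial_cost, diag.final_cost, diag.n_evaluations)

    # apply intra corrections
    corrected = coords.copy()
    for d in range(n_ds):
        sel = datasets == d
        corrected[sel] = project_to_t0(coords[sel], frames[sel], intra[d])

    # sequential inter fits against the corrected first dataset
    if n_ds > 1:
        ref_sel = datasets == 0
        ref_tree = cKDTree(corrected[ref_sel])
        for d in range(1, n_ds):
            sel = datasets == d
            if sel.sum() == 0:
                logger.warning("dataset %d empty; skipping inter fit", d)
                diagnostics["inter"][d] = None
                continue
            if registration_used:
                init = np.zeros(ndim)
            else:
                # accumulated drift at the end of the previous dataset:
                # its inter shift plus its intra polynomial at its last frame
                prev = d - 1
                init = shifts[prev] + _poly_eval(intra[prev], ds_last_frame[prev])
            shift, diag = fit_inter(ref_tree, corrected[sel], -init, params.l_inter)
            # fit_inter finds the shift moving dataset d onto dataset 0,
            # i.e. the negative of the dataset's drift offset.
            shifts[d] = -shift
            diagnostics["inter"][d] = diag.__dict__
            logger.info("inter fit dataset %d: cost %.4f -> %.4f (%d evals)",
                        d, diag.initial_cost, diag.final_cost, diag.n_evaluations)
            corrected[sel] = corrected[sel] + shift

    model = DriftModel(intra, shifts, degree, is_3d=work.is_3d, diagnostics=diagnostics)
    out = work.with_coords(corrected)
    if mapping is not None:
        out = reassemble(out, mapping)
    return out, model


def _poly_eval(coeffs: np.ndarray, f: float) -> np.ndarray:
    """Evaluate the constant-free polynomial sum_p coeffs[:, p] f**(p+1)."""
    out = np.zeros(coeffs.shape[0])
    for p in range(coeffs.shape[1]):
        out += coeffs[:, p] * f ** (p + 1)
    return out


# -- landscape export ------------------------------------------------------

@dataclass
class CostLandscape:
    """Dense cost grid over candidate shifts/rates, for visualization."""

    axes: list[np.ndarray]  # one 1D array of candidate values per dimension
    cost: np.ndarray  # shape = tuple(len(a) for a in axes)
    which: str  # "intra" or "inter"

    def argmin(self) -> np.ndarray:
        idx = np.unravel_index(np.argmin(self.cost), self.cost.shape)
        return np.array([self.axes[i][j] for i, j in enumerate(idx)])

    def to_frame(self) -> pd.DataFrame:
        grids = np.meshgrid(*self.axes, indexing="ij")
        cols = {f"p{i}": g.ravel() for i, g in enumerate(grids)}
        cols["cost"] = self.cost.ravel()
        return pd.DataFrame(cols)


def cost_landscape(
    table: LocalizationTable,
    which: str,
    grid: Sequence[np.ndarray],
    params: CostParams | None = None,
    target_dataset: int = 1,
) -> CostLandscape:
    """Evaluate the intra (linear-rate) or inter (constant-shift) cost on a
    dense parameter grid — one value per spatial dimension.

    For ``which="intra"`` the grid axes are linear drift rates (px/frame)
    of dataset 0; for ``which="inter"`` they are constant shifts (px)
    applied to ``target_dataset`` against raw dataset 0.
    """
    params = params or CostParams()
    if which not in ("intra", "inter"):
        raise ValueError("which must be 'intra' or 'inter'")
    axes = [np.asarray(a, float) for a in grid]
    if len(axes) != table.ndim:
        raise ValueError("need one grid axis per spatial dimension")
    shape = tuple(len(a) for a in axes)
    cost = np.empty(shape)
    if which == "intra":
        ds = table.dataset_slice(0)
        pos, frm = ds.coords(), ds.frames()
        for idx in np.ndindex(shape):
            theta = np.array([axes[i][j] for i, j in enumerate(idx)])[:, None]
            cost[idx] = intra_cost(pos, frm, theta, params.l_intra)
    else:
        ref = table.dataset_slice(0).coords()
        tgt = table.dataset_slice(target_dataset).coords()
        tree = cKDTree(ref)
        for idx in np.ndindex(shape):
            shift = np.array([axes[i][j] for i, j in enumerate(idx)])
            cost[idx] = inter_cost(tree, tgt, shift, params.l_inter)
    return CostLandscape(axes=axes, cost=cost, which=which)
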