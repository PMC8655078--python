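"""Synthetic SMLM data: emitter fields, blinking kinetics, drift curves,
localization rendering, and smooth brightfield test stacks.

The generators emulate the statistical structure of dSTORM / DNA-PAINT
acquisitions at the localization level: emitters are fixed points (on a
uniform field, a star-shaped domain, or 40 nm rings), each blinking as an
alternating renewal process with exponential off/on durations (rates
K_on, K_off per frame), and each on-frame yields one localization
scattered around the true position by Gaussian noise.  Camera-frame
physics (PSF rendering, photon shot noise, MLE fitting) is deliberately
not modelled; its net effect on localizations is emulated by the
configurable (optionally anisotropic) Gaussian scatter.

All generator outputs are pure functions of their arguments and the seed.
Physical units are nm; rendered localization tables are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .localization_io import DEFAULT_PIXEL_SIZE_NM, LocalizationTable

__all__ = [
    "EmitterField",
    "BlinkTraces",
    "DriftCurve",
    "SimConfig",
    "gen_uniform_emitters",
    "gen_star_emitters",
    "gen_ring_pair_3d",
    "gen_multi_ring_3d",
    "gen_blink_traces",
    "kon_for_lambda",
    "expected_events_per_emitter",
    "expected_pairs",
    "gen_drift_constant",
    "gen_drift_polynomial",
    "gen_drift_spline",
    "render_localizations",
    "gen_brightfield_stack",
    "SimulatedStage",
]

# Duty-cycle defaults: slow activation, fast bleaching back to dark.
DEFAULT_K_ON = 0.0005  # per frame
DEFAULT_K_OFF = 1.0  # per frame
DEFAULT_NOISE_SIGMA_NM = 10.0
DEFAULT_RING_DIAMETER_NM = 40.0
DEFAULT_RING_DENSITY_PER_PX = 1000.0  # fluorophores per pixel of contour length


@dataclass
class EmitterField:
    """Ground-truth emitter positions (nm), 2D or 3D."""

    positions: np.ndarray  # (n, 2) or (n, 3), nm
    structure_label: str
    roi_nm: float

    @property
    def n_emitters(self) -> int:
        return len(self.positions)

    @property
    def is_3d(self) -> bool:
        return self.positions.shape[1] == 3


@dataclass
class BlinkTraces:
    """On-intervals of every emitter, flat representation.

    ``emitter[i]`` owns the interval ``[t_start[i], t_end[i])`` in
    fractional frame time, clipped to ``[0, n_frames]``.  Intervals of one
    emitter are disjoint and ordered.
    """

    emitter: np.ndarray  # (n_events,) int
    t_start: np.ndarray  # (n_events,) float
    t_end: np.ndarray  # (n_events,) float
    n_emitters: int
    n_frames: int

    @property
    def n_events(self) -> int:
        return len(self.emitter)

    def events_per_emitter(self) -> np.ndarray:
        counts = np.zeros(self.n_emitters, np.int64)
        np.add.at(counts, self.emitter, 1)
        return counts

    def intervals_of(self, i: int) -> list[tuple[float, float]]:
        sel = self.emitter == i
        return list(zip(self.t_start[sel], self.t_end[sel]))

    def on_fraction(self) -> float:
        """Time-averaged fraction of emitters in the on state."""
        total_on = float((self.t_end - self.t_start).sum())
        return total_on / (self.n_emitters * self.n_frames)


@dataclass
class DriftCurve:
    """Cumulative per-frame drift offsets in nm over the full acquisition."""

    offsets: np.ndarray  # (n_frames, ndim), nm
    kind: str
    #: spline generators record their (frame, value) nodes per axis here
    nodes: Optional[list] = None

    @property
    def n_frames(self) -> int:
        return len(self.offsets)

    @property
    def ndim(self) -> int:
        return self.offsets.shape[1]

    def at(self, frames: np.ndarray) -> np.ndarray:
        return self.offsets[np.asarray(frames, np.int64)]


@dataclass
class SimConfig:
    """Bundle of simulation parameters; serialized alongside every output."""

    roi_nm: float = 25_600.0
    n_frames: int = 1000
    frames_per_dataset: int = 1000
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    k_on: float = DEFAULT_K_ON
    k_off: float = DEFAULT_K_OFF
    noise_sigma_nm: float = DEFAULT_NOISE_SIGMA_NM
    noise_sigma_z_nm: Optional[float] = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d


# -- emitter fields --------------------------------------------------------

def gen_uniform_emitters(roi_nm: float, density_per_nm2: float,
                         rng: np.random.Generator) -> EmitterField:
    """Poisson-distributed emitters, i.i.d. uniform over a square ROI."""
    if density_per_nm2 < 0:
        raise ValueError("density must be >= 0")
    n = rng.poisson(density_per_nm2 * roi_nm**2)
    pos = rng.uniform(0.0, roi_nm, size=(n, 2))
    return EmitterField(pos, "uniform", roi_nm)


def star_predicate(xy_nm: np.ndarray, roi_nm: float, n_wedges: int) -> np.ndarray:
    """Membership test of the Siemens-star domain: alternating angular
    wedges about the ROI center; even-indexed wedges are filled."""
    c = roi_nm / 2.0
    ang = np.arctan2(xy_nm[:, 1] - c, xy_nm[:, 0] - c) % (2 * np.pi)
    wedge = np.floor(ang / (2 * np.pi / n_wedges)).astype(int)
    return wedge % 2 == 0


def gen_star_emitters(roi_nm: float, density_per_nm2: float, n_wedges: int = 8,
                      rng: np.random.Generator | None = None) -> EmitterField:
    """Emitters confined to a star-shaped (Siemens-star) domain.

    Realized by thinning a uniform Poisson process over the full ROI with
    the wedge mask, so the density *inside* the star equals
    ``density_per_nm2`` exactly in expectation.
    """
    if n_wedges < 2 or n_wedges % 2:
        raise ValueError("n_wedges must be even and >= 2")
    rng = rng or np.random.default_rng()
    n = rng.poisson(density_per_nm2 * roi_nm**2)
    cand = rng.uniform(0.0, roi_nm, size=(n, 2))
    keep = star_predicate(cand, roi_nm, n_wedges)
    return EmitterField(cand[keep], "star", roi_nm)


def _ring(center_nm: Sequence[float], diameter_nm: float, z_nm: float,
          density_per_px: float, pixel_size_nm: float,
          rng: np.random.Generator) -> np.ndarray:
    circumference_px = np.pi * diameter_nm / pixel_size_nm
    n = rng.poisson(density_per_px * circumference_px)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    r = diameter_nm / 2.0
    return np.column_stack([
        center_nm[0] + r * np.cos(theta),
        center_nm[1] + r * np.sin(theta),
        np.full(n, z_nm),
    ])


def gen_ring_pair_3d(
    rng: np.random.Generator,
    diameter_nm: float = DEFAULT_RING_DIAMETER_NM,
    separation_nm: float = 80.0,
    density_per_px: float = DEFAULT_RING_DENSITY_PER_PX,
    center_nm: Sequence[float] = (0.0, 0.0, 0.0),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    roi_nm: float = 1000.0,
) -> EmitterField:
    """Two coaxial rings separated along z — a DNA-PAINT nanorod mimic.

    Emitters sit exactly on the circles (radius ``diameter_nm/2``) at
    uniform angles, with Poisson counts of mean ``density_per_px`` per
    pixel of contour length; z takes the two values center ± separation/2.
    """
    cz = center_nm[2]
    pts = np.vstack([
        _ring(center_nm, diameter_nm, cz - separation_nm / 2, density_per_px,
              pixel_size_nm, rng),
        _ring(center_nm, diameter_nm, cz + separation_nm / 2, density_per_px,
              pixel_size_nm, rng),
    ])
    return EmitterField(pts, "ring_pair", roi_nm)


def gen_multi_ring_3d(
    rng: np.random.Generator,
    n_pairs: int = 10,
    roi_nm: float = 2000.0,
    separation_nm: float = 80.0,
    **kwargs,
) -> EmitterField:
    """Several ring pairs at random (x, y, z) centers across the ROI."""
    fields = []
    for _ in range(n_pairs):
        center = (rng.uniform(0, roi_nm), rng.uniform(0, roi_nm),
                  rng.uniform(-roi_nm / 8, roi_nm / 8))
        fields.append(gen_ring_pair_3d(rng, separation_nm=separation_nm,
                                       center_nm=center, roi_nm=roi_nm, **kwargs))
    pts = np.vstack([f.positions for f in fields])
    return EmitterField(pts, "multi_ring", roi_nm)


# -- blinking kinetics -----------------------------------------------------

def expected_events_per_emitter(n_frames: int, k_on: float, k_off: float) -> float:
    """Renewal-theory mean number of on-events per emitter, lambda =
    n_frames * K_on K_off / (K_on + K_off)."""
    return n_frames * k_on * k_off / (k_on + k_off)


def kon_for_lambda(lambda_: float, n_frames: int, k_off: float = DEFAULT_K_OFF) -> float:
    """Invert the renewal rate: the K_on giving ``lambda_`` expected events."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be > 0")
    mean_cycle = n_frames / lambda_  # = 1/K_on + 1/K_off
    inv_kon = mean_cycle - 1.0 / k_off
    if inv_kon <= 0:
        raise ValueError("lambda_ too large for this n_frames / K_off")
    return 1.0 / inv_kon


def expected_pairs(lambda_: float) -> float:
    """Expected blink-event pairs per emitter, ⟨N_p⟩ = λ²/2.

    Closed form of E[C(k, 2)] for k ~ Poisson(λ): each emitter with k
    events contributes k(k−1)/2 usable pairings to the intra cost.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    return lambda_**2 / 2.0


def gen_blink_traces(
    n_emitters: int,
    n_frames: int,
    k_on: float = DEFAULT_K_ON,
    k_off: float = DEFAULT_K_OFF,
    rng: np.random.Generator | None = None,
) -> BlinkTraces:
    """Alternating-renewal blinking: every emitter starts dark and cycles
    off ~ Exp(mean 1/K_on) → on ~ Exp(mean 1/K_off) → off ...

    Exponential holding times make the dark phase memoryless, so starting
    each trace in the dark state is equivalent to a random phase.
    Intervals are generated in vectorized batches and clipped to the
    acquisition window [0, n_frames].
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    rng = rng or np.random.default_rng()

    lam = expected_events_per_emitter(n_frames, k_on, k_off)
    batch = max(4, int(np.ceil(lam + 6 * np.sqrt(lam) + 4)))

    ems: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    pending = np.arange(n_emitters)
    t_base = np.zeros(n_emitters)
    while len(pending):
        m = len(pending)
        off = rng.exponential(1.0 / k_on, size=(m, batch))
        on = rng.exponential(1.0 / k_off, size=(m, batch))
        cyc = off + on
        t_on = t_base[pending, None] + np.cumsum(cyc, axis=1) - on
        t_off = t_on + on
        valid = t_on < n_frames
        if np.any(valid):
            em_idx = np.broadcast_to(pending[:, None], t_on.shape)[valid]
            ems.append(em_idx)
            starts.append(np.maximum(t_on[valid], 0.0))
            ends.append(np.minimum(t_off[valid], float(n_frames)))
        # emitters whose last generated cycle still ends before n_frames need more
        t_final = t_base[pending] + cyc.sum(axis=1)
        unfinished = t_final < n_frames
        t_base[pending[unfinished]] = t_final[unfinished]
        pending = pending[unfinished]

    if ems:
        emitter = np.concatenate(ems)
        t_start = np.concatenate(starts)
        t_end = np.concatenate(ends)
        order = np.lexsort((t_start, emitter))
        emitter, t_start, t_end = emitter[order], t_start[order], t_end[order]
    else:
        emitter = np.empty(0, np.int64)
        t_start = t_end = np.empty(0)
    return BlinkTraces(emitter, t_start, t_end, n_emitters, n_frames)


# -- drift curves ----------------------------------------------------------

def gen_drift_constant(n_frames: int, rate_nm_per_frame: Sequence[float]) -> DriftCurve:
    """Constant-rate cumulative drift: offset(f) = rate · f."""
    rate = np.asarray(rate_nm_per_frame, float)
    f = np.arange(n_frames)[:, None]
    return DriftCurve(f * rate[None, :], "constant")


def gen_drift_polynomial(
    n_frames: int, alpha: Sequence[float], beta: Sequence[float] | None = None
) -> DriftCurve:
    """Polynomial cumulative drift: offset(f) = α f + β f² per axis (nm)."""
    alpha = np.asarray(alpha, float)
    beta = np.zeros_like(alpha) if beta is None else np.asarray(beta, float)
    f = np.arange(n_frames, dtype=float)[:, None]
    kind = "linear" if np.all(beta == 0) else "quadratic"
    return DriftCurve(f * alpha[None, :] + f**2 * beta[None, :], kind)


def gen_drift_spline(
    n_frames: int,
    mean_nodes: float = 35.0,
    amplitude_nm: float = 100.0,
    ndim: int = 3,
    rng: np.random.Generator | None = None,
) -> DriftCurve:
    """Smooth, slowly oscillating drift: a cubic spline per axis through
    Poisson(mean_nodes) nodes with uniform values in ±amplitude.

    Node frames partition [0, n_frames−1] with jittered spacing around the
    average interval n_frames/(n_nodes+1); both endpoints are pinned to
    node positions so the spline interpolates over the whole acquisition
    and never extrapolates.  A draw below 4 nodes is redrawn (a cubic
    spline needs at least 4 points).  Natural boundary conditions and a
    redraw of node values whenever the interpolant overshoots beyond
    1.5 × amplitude keep the curve within the stated range up to mild
    spline overshoot, emulating slowly oscillating thermal/mechanical
    drift rather than wild excursions.
    """
    if amplitude_nm <= 0:
        raise ValueError("amplitude_nm must be > 0")
    rng = rng or np.random.default_rng()
    offsets = np.empty((n_frames, ndim))
    nodes: list = []
    frames = np.arange(n_frames, dtype=float)
    for dim in range(ndim):
        n_nodes = 0
        while n_nodes < 4:
            n_nodes = rng.poisson(mean_nodes)
        interval = n_frames / (n_nodes + 1)
        # jittered partition of interior node times; endpoints pinned;
        # snapped to whole frames so the curve interpolates its node
        # values exactly on the frame grid
        t = np.arange(1, n_nodes - 1) * (n_frames - 1) / (n_nodes - 1)
        t = t + rng.uniform(-0.3, 0.3, max(n_nodes - 2, 0)) * interval
        t = np.concatenate([[0.0], np.sort(t), [float(n_frames - 1)]])
        t = np.unique(np.clip(np.round(t), 0.0, n_frames - 1))
        for _ in range(100):
            vals = rng.uniform(-amplitude_nm, amplitude_nm, len(t))
            curve = CubicSpline(t, vals, bc_type="natural")(frames)
            if np.abs(curve).max() <= 1.5 * amplitude_nm:
                break
        offsets[:, dim] = curve
        nodes.append((t.copy(), vals.copy()))
    return DriftCurve(offsets, "spline", nodes=nodes)


# -- localization rendering ------------------------------------------------

def render_localizations(
    field: EmitterField,
    traces: BlinkTraces,
    drift: DriftCurve | None,
    noise_sigma_nm: float = DEFAULT_NOISE_SIGMA_NM,
    frames_per_dataset: int = 1000,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    rng: np.random.Generator | None = None,
    noise_sigma_z_nm: Optional[float] = None,
) -> tuple[LocalizationTable, "GroundTruth"]:
    """Turn blink traces into a localization table (pixel units).

    One localization is emitted per (emitter, frame) with nonzero on-time
    overlap: position = true + drift(frame) + N(0, σ) per axis, with an
    optionally larger axial σ to emulate the poorer z precision of
    astigmatic 3D fitting.  Frame/dataset indices follow
    ``frames_per_dataset``; the returned ground truth carries per-row
    emitter ids, event ids, true positions and true drift for evaluation.
    """
    rng = rng or np.random.default_rng()
    ndim = field.positions.shape[1]
    if drift is not None and drift.ndim != ndim:
        raise ValueError("drift dimensionality does not match emitter field")

    # expand events -> frames with overlap
    f0 = np.floor(traces.t_start).astype(np.int64)
    f1 = np.ceil(traces.t_end).astype(np.int64)
    f1 = np.minimum(np.maximum(f1, f0 + 1), traces.n_frames)
    counts = f1 - f0
    ev_idx = np.repeat(np.arange(traces.n_events), counts)
    frame = f0[ev_idx] + _ranges(counts)
    em = traces.emitter[ev_idx]

    true_pos = field.positions[em]
    pos = true_pos.astype(float).copy()
    if drift is not None:
        pos = pos + drift.at(frame)
    if noise_sigma_nm > 0 or noise_sigma_z_nm:
        sig = np.full(ndim, float(noise_sigma_nm))
        if ndim == 3 and noise_sigma_z_nm is not None:
            sig[2] = noise_sigma_z_nm
        pos = pos + rng.normal(0.0, 1.0, pos.shape) * sig[None, :]

    px = pos / pixel_size_nm
    dataset = frame // frames_per_dataset
    frame_in_ds = frame - dataset * frames_per_dataset
    table = LocalizationTable.from_arrays(
        x=px[:, 0], y=px[:, 1],
        z=px[:, 2] if ndim == 3 else None,
        frame=frame_in_ds, dataset=dataset,
    )
    gt = GroundTruth(
        emitter=em, event=ev_idx, global_frame=frame,
        true_position_nm=true_pos.astype(float),
        drift_nm=drift.at(frame) if drift is not None else np.zeros_like(pos),
    )
    return table, gt


def _ranges(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for an array of counts."""
    total = int(counts.sum())
    out = np.ones(total, np.int64)
    idx = np.cumsum(counts)[:-1]
    out[0] = 0
    out[idx] = -(counts[:-1] - 1)
    return np.cumsum(out)


@dataclass
class GroundTruth:
    """Per-row simulation truth aligned with a rendered table."""

    emitter: np.ndarray
    event: np.ndarray
    global_frame: np.ndarray
    true_position_nm: np.ndarray
    drift_nm: np.ndarray


# -- synthetic brightfield stacks -----------------------------------------

@dataclass
class _BlobField:
    centers: np.ndarray  # (n, 3) voxel coords (y, x, z)
    sigmas: np.ndarray  # (n, 3) voxel widths
    amplitudes: np.ndarray  # (n,)

    def sample(self, shape: tuple[int, int, int], offset_vox: np.ndarray) -> np.ndarray:
        """Evaluate the blob field on the voxel grid, with the *content*
        shifted by ``offset_vox`` (so a feature at c appears at c + offset)."""
        ny, nx, nz = shape
        yy = np.arange(ny, dtype=float)
        xx = np.arange(nx, dtype=float)
        zz = np.arange(nz, dtype=float)
        vol = np.zeros(shape)
        for c, s, a in zip(self.centers + offset_vox, self.sigmas, self.amplitudes):
            gy = np.exp(-0.5 * ((yy - c[0]) / s[0]) ** 2)
            gx = np.exp(-0.5 * ((xx - c[1]) / s[1]) ** 2)
            gz = np.exp(-0.5 * ((zz - c[2]) / s[2]) ** 2)
            vol += a * gy[:, None, None] * gx[None, :, None] * gz[None, None, :]
        return vol


def _make_blob_field(shape, n_blobs, rng) -> _BlobField:
    # Many fine blobs give the cross-correlation a sharp, well-isolated
    # peak (cell-like texture); few broad blobs leave scene cross-terms
    # that visibly bias the 3-point parabola refinement.
    ny, nx, nz = shape
    centers = np.column_stack([
        rng.uniform(0.15 * ny, 0.85 * ny, n_blobs),
        rng.uniform(0.15 * nx, 0.85 * nx, n_blobs),
        rng.uniform(0.15 * nz, 0.85 * nz, n_blobs),
    ])
    sigmas = np.column_stack([
        rng.uniform(1.2, 2.0, n_blobs),
        rng.uniform(1.2, 2.0, n_blobs),
        rng.uniform(1.0, 1.6, n_blobs),
    ])
    amplitudes = rng.uniform(0.5, 1.5, n_blobs)
    return _BlobField(centers, sigmas, amplitudes)


def gen_brightfield_stack(
    shape: tuple[int, int, int] = (64, 64, 21),
    n_blobs: int = 150,
    shift_nm: Sequence[float] = (0.0, 0.0, 0.0),
    noise_level: float = 0.0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    z_step_nm: float = 100.0,
    rng: np.random.Generator | None = None,
    blob_field: _BlobField | None = None,
):
    """Smooth random Gaussian-blob z-stack with an exact (sub-voxel)
    content shift — a desk-scale stand-in for real cell brightfield
    images.  Returns (ImageStack, blob_field); pass the same
    ``blob_field`` back to render a shifted view of the *same* scene.
    """
    from .brightfield_registration import ImageStack

    rng = rng or np.random.default_rng()
    bf = blob_field or _make_blob_field(shape, n_blobs, rng)
    shift_nm = np.asarray(shift_nm, float)  # (x, y, z)
    offset_vox = np.array([
        shift_nm[1] / pixel_size_nm,  # y
        shift_nm[0] / pixel_size_nm,  # x
        shift_nm[2] / z_step_nm,  # z
    ])
    vol = bf.sample(shape, offset_vox) + 1.0  # DC offset, like a lamp background
    if noise_level > 0:
        vol = vol + rng.normal(0.0, noise_level, vol.shape)
    z_positions = np.arange(shape[2]) * z_step_nm
    stack = ImageStack(vol, z_positions, pixel_size_nm=pixel_size_nm,
                       z_step_nm=z_step_nm)
    return stack, bf


class SimulatedStage:
    """Desk-scale stand-in for a piezo stage + brightfield camera.

    Holds a true sample offset (nm).  ``move_by`` applies a commanded move
    with optional multiplicative error; ``acquire_stack`` renders the blob
    scene displaced by the current offset, with optional image noise.
    """

    def __init__(
        self,
        shape: tuple[int, int, int] = (64, 64, 21),
        initial_offset_nm: Sequence[float] = (0.0, 0.0, 0.0),
        move_error: float = 0.0,
        noise_level: float = 0.0,
        pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
        z_step_nm: float = 100.0,
        seed: int = 0,
    ) -> None:
        self.rng = np.random.default_rng(seed)
        self.shape = shape
        self.offset_nm = np.asarray(initial_offset_nm, float).copy()
        self.move_error = move_error
        self.noise_level = noise_level
        self.pixel_size_nm = pixel_size_nm
        self.z_step_nm = z_step_nm
        self.blob_field = _make_blob_field(shape, 150, self.rng)
        self.moves: list[np.ndarray] = []

    def reference_stack(self):
        stack, _ = gen_brightfield_stack(
            self.shape, shift_nm=(0, 0, 0), noise_level=self.noise_level,
            pixel_size_nm=self.pixel_size_nm, z_step_nm=self.z_step_nm,
            rng=self.rng, blob_field=self.blob_field)
        return stack

    def acquire_stack(self):
        stack, _ = gen_brightfield_stack(
            self.shape, shift_nm=self.offset_nm, noise_level=self.noise_level,
            pixel_size_nm=self.pixel_size_nm, z_step_nm=self.z_step_nm,
            rng=self.rng, blob_field=self.blob_field)
        return stack

    def move_by(self, dx_nm: float, dy_nm: float, dz_nm: float) -> None:
        move = np.array([dx_nm, dy_nm, dz_nm], float)
        if self.move_error > 0:
            move = move * (1.0 + self.rng.uniform(-self.move_error,
                                                  self.move_error, 3))
        self.offset_nm += move
        self.moves.append(move)
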