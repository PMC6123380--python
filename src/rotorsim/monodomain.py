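"""Anisotropic monodomain reaction–diffusion solver on 2D sheets.

Solves C_m ∂V/∂t = ∇·(σ(x)∇V) − I_ion + I_stim with no-flux boundaries on a
regular grid: finite differences (flux-form 5-point stencil, centered
9-point cross terms where fibers are rotated), explicit Euler diffusion,
operator-split against the ionic kernels.  Fibrotic nodes carry the fibrotic
ionic variant and scaled conductivities.

Conductivities are effective diffusivities in cm²/s; the solver works in
cm and ms internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import config
from .cell_models import CellParams, IntegrationError, _initial, _kernel
from .substrate import TissueGrid

__all__ = [
    "ConductivityField",
    "Stimulus",
    "EpisodeRecord",
    "default_conductivity",
    "apply_fibrotic_conductivity",
    "line_stimulus",
    "disc_stimulus",
    "run_monodomain",
    "measure_cv",
    "calibrate_conductivity",
    "save_episode",
    "load_episode",
]


class StabilityError(RuntimeError):
    """Explicit-diffusion stability bound violated; the run is refused."""


class MeasurementError(RuntimeError):
    """A conduction-velocity measurement precondition failed."""


class CalibrationError(RuntimeError):
    """Conductivity calibration failed to bracket or converge."""


@dataclass
class ConductivityField:
    """Per-node longitudinal/transverse effective diffusivities (cm²/s)."""

    sigma_L: np.ndarray
    sigma_T: np.ndarray

    def __post_init__(self):
        if self.sigma_L.shape != self.sigma_T.shape:
            raise ValueError("sigma_L and sigma_T must share a shape")
        if not (self.sigma_T > 0).all():
            raise ValueError("sigma_T must be > 0 everywhere")
        if not (self.sigma_L >= self.sigma_T).all():
            raise ValueError("sigma_L must be >= sigma_T everywhere")

    def copy(self) -> "ConductivityField":
        return ConductivityField(self.sigma_L.copy(), self.sigma_T.copy())

    def scaled(self, factor: float) -> "ConductivityField":
        return ConductivityField(self.sigma_L * factor, self.sigma_T * factor)


@dataclass
class Stimulus:
    """One stimulus: a node mask driven for ``duration_ms`` from ``t_start_ms``
    at ``amplitude_ma_cm2`` (converted to pA/pF by the configured gain)."""

    mask: np.ndarray
    t_start_ms: float
    duration_ms: float = 5.0
    amplitude_ma_cm2: float = 0.3

    @property
    def amplitude_pa_pf(self) -> float:
        return self.amplitude_ma_cm2 * config.STIM_GAIN_PA_PF_PER_MA_CM2


@dataclass
class EpisodeRecord:
    """Stored result of one tissue simulation."""

    vm_movie: np.ndarray          # (nt, ny, nx) mV, float32
    times_ms: np.ndarray          # (nt,)
    lat: np.ndarray               # (ny, nx) first −60 mV upward crossing, ms
    stim_log: list
    duration_ms: float
    dt_ms: float
    snapshot_ms: float
    h_cm: float

    @property
    def n_frames(self) -> int:
        return self.vm_movie.shape[0]


def default_conductivity(grid: TissueGrid,
                         sigma_l: float = config.DEFAULT_SIGMA_L,
                         ratio: float = config.DEFAULT_SIGMA_RATIO,
                         ) -> ConductivityField:
    """Uniform calibrated conductivity over a grid (no fibrotic scaling)."""
    sL = np.full(grid.shape, sigma_l)
    return ConductivityField(sL, sL / ratio)


def apply_fibrotic_conductivity(cond: ConductivityField, grid: TissueGrid,
                                long_scale: float = config.FIBROTIC_SCALE_L,
                                trans_scale: float = config.FIBROTIC_SCALE_T,
                                ) -> ConductivityField:
    """Scale conductivity at fibrotic nodes (structural remodeling)."""
    if not (0 < long_scale <= 1 and 0 < trans_scale <= 1):
        raise ValueError("scales must be in (0, 1]")
    out = cond.copy()
    m = grid.fibrosis_mask
    out.sigma_L[m] *= long_scale
    out.sigma_T[m] *= trans_scale
    # keep the invariant sigma_L >= sigma_T
    np.maximum(out.sigma_L, out.sigma_T, out=out.sigma_L)
    return out


def line_stimulus(grid: TissueGrid, edge: str = "left", width_nodes: int = 3,
                  t_start_ms: float = 0.0, **kw) -> Stimulus:
    mask = np.zeros(grid.shape, dtype=bool)
    if edge == "left":
        mask[:, :width_nodes] = True
    elif edge == "right":
        mask[:, -width_nodes:] = True
    elif edge == "bottom":
        mask[:width_nodes, :] = True
    elif edge == "top":
        mask[-width_nodes:, :] = True
    else:
        raise ValueError(f"unknown edge {edge!r}")
    return Stimulus(mask=mask, t_start_ms=t_start_ms, **kw)


def disc_stimulus(grid: TissueGrid, x_cm: float, y_cm: float,
                  radius_mm: float = 1.5, t_start_ms: float = 0.0,
                  **kw) -> Stimulus:
    yy, xx = np.mgrid[:grid.ny, :grid.nx]
    r_cm = radius_mm * 0.1
    d2 = (xx * grid.h_cm - x_cm) ** 2 + (yy * grid.h_cm - y_cm) ** 2
    mask = d2 <= r_cm ** 2
    if not mask.any():
        raise ValueError("stimulus disc lies outside the grid")
    return Stimulus(mask=mask, t_start_ms=t_start_ms, **kw)


def _tensor_components(grid: TissueGrid, cond: ConductivityField):
    """Per-node diffusion tensor in cm²/ms from fiber angle and sigma."""
    a = grid.fiber_angle
    c, s = np.cos(a), np.sin(a)
    sL = cond.sigma_L * 1e-3
    sT = cond.sigma_T * 1e-3
    dxx = sL * c * c + sT * s * s
    dyy = sL * s * s + sT * c * c
    dxy = (sL - sT) * c * s
    return dxx, dyy, dxy


def _diffusion(V, dxx, dyy, dxy, h_cm, has_cross):
    """∇·(D∇V) with no-flux boundaries (flux form for the axis terms)."""
    Vp = np.pad(V, 1, mode="edge")
    # axis fluxes with face-averaged coefficients
    fe = 0.5 * (dxx + np.pad(dxx, ((0, 0), (0, 1)), mode="edge")[:, 1:])
    fw = 0.5 * (dxx + np.pad(dxx, ((0, 0), (1, 0)), mode="edge")[:, :-1])
    fn = 0.5 * (dyy + np.pad(dyy, ((0, 1), (0, 0)), mode="edge")[1:, :])
    fs = 0.5 * (dyy + np.pad(dyy, ((1, 0), (0, 0)), mode="edge")[:-1, :])
    out = (fe * (Vp[1:-1, 2:] - V) - fw * (V - Vp[1:-1, :-2])
           + fn * (Vp[2:, 1:-1] - V) - fs * (V - Vp[:-2, 1:-1])) / h_cm ** 2
    if has_cross:
        gx = (Vp[1:-1, 2:] - Vp[1:-1, :-2]) / (2 * h_cm)
        gy = (Vp[2:, 1:-1] - Vp[:-2, 1:-1]) / (2 * h_cm)
        px = np.pad(dxy * gy, 1, mode="edge")
        py = np.pad(dxy * gx, 1, mode="edge")
        out = out + ((px[1:-1, 2:] - px[1:-1, :-2])
                     + (py[2:, 1:-1] - py[:-2, 1:-1])) / (2 * h_cm)
    return out


def _build_scal(grid: TissueGrid, params_map, fibrotic_params):
    """Per-node conductance-scaling matrix and the model kind."""
    if isinstance(params_map, CellParams):
        region_params = {r: params_map for r in range(1, grid.n_regions + 1)}
    else:
        region_params = dict(params_map)
    models = {p.model for p in region_params.values()}
    if fibrotic_params is not None:
        models.add(fibrotic_params.model)
    if len(models) != 1:
        raise ValueError("all cell variants in one run must share a model kind")
    model = models.pop()
    any_params = next(iter(region_params.values()))
    nscal = len(any_params.scal_names)
    n = grid.nx * grid.ny
    scal = np.ones((nscal, n))
    labels = grid.region_labels.ravel()
    for r, p in region_params.items():
        scal[:, labels == r] = p.scal_vector()[:, None]
    if fibrotic_params is not None:
        fm = grid.fibrosis_mask.ravel()
        scal[:, fm] = fibrotic_params.scal_vector()[:, None]
    return scal, model, any_params


def run_monodomain(grid: TissueGrid, cond: ConductivityField,
                   params_map, stimuli: list[Stimulus],
                   duration_ms: float, dt_ms: float | None = None,
                   snapshot_ms: float = config.DEFAULT_SNAPSHOT_MS,
                   fibrotic_params: CellParams | None = None,
                   no_reaction: bool = False) -> EpisodeRecord:
    """Simulate one episode and return the voltage movie + activation map.

    ``params_map`` is a single ``CellParams`` applied everywhere or a dict
    mapping region label → ``CellParams``; nodes under the fibrosis mask use
    ``fibrotic_params`` when given.  ``no_reaction=True`` runs pure diffusion
    (for conservation checks).  LAT is the first upward crossing of −60 mV
    per node.
    """
    scal, model, base_params = _build_scal(grid, params_map, fibrotic_params)
    if dt_ms is None:
        dt_ms = (config.DEFAULT_DT_MS if model == "detailed"
                 else config.DEFAULT_DT_REDUCED_MS)

    h = grid.h_cm
    dmax = max(cond.sigma_L.max(), cond.sigma_T.max()) * 1e-3
    dt_limit = h * h / (4.0 * dmax)
    if dt_ms > dt_limit:
        raise StabilityError(
            f"dt={dt_ms} ms violates the explicit-diffusion bound "
            f"h²/(4σ) = {dt_limit:.4f} ms; reduce dt or conductivity")
    for st in stimuli:
        if st.mask.shape != grid.shape:
            raise ValueError("stimulus mask must match the grid shape")

    dxx, dyy, dxy = _tensor_components(grid, cond)
    has_cross = bool(np.abs(dxy).max() > 1e-15)

    n = grid.nx * grid.ny
    S = _initial(base_params, n)
    kern = _kernel(base_params)
    V2d = S[0].reshape(grid.shape)

    n_steps = int(round(duration_ms / dt_ms))
    snap_every = max(1, int(round(snapshot_ms / dt_ms)))
    n_frames = n_steps // snap_every + 1
    movie = np.empty((n_frames, grid.ny, grid.nx), dtype=np.float32)
    times = np.empty(n_frames)
    movie[0] = V2d
    times[0] = 0.0
    frame = 1

    lat = np.full(grid.shape, np.nan)
    thr = config.LAT_THRESHOLD_MV
    below = V2d < thr

    stim_buf = np.zeros(n)
    for step in range(n_steps):
        t = step * dt_ms
        stim_buf[:] = 0.0
        for st in stimuli:
            if st.t_start_ms <= t < st.t_start_ms + st.duration_ms:
                stim_buf[st.mask.ravel()] += st.amplitude_pa_pf
        if not no_reaction:
            kern(S, stim_buf, dt_ms, scal)
        elif stim_buf.any():
            S[0] += dt_ms * stim_buf
        V2d = S[0].reshape(grid.shape)
        V2d += dt_ms * _diffusion(V2d, dxx, dyy, dxy, h, has_cross)

        above = V2d >= thr
        newly = below & above & np.isnan(lat)
        if newly.any():
            lat[newly] = t + dt_ms
        below = ~above

        if (step + 1) % snap_every == 0:
            movie[frame] = V2d
            times[frame] = t + dt_ms
            frame += 1
        if (step + 1) % 1000 == 0 and not np.isfinite(V2d).all():
            i, j = np.argwhere(~np.isfinite(V2d))[0]
            raise IntegrationError(
                f"non-finite Vm at t={t + dt_ms:.2f} ms, node ({i},{j})")

    if not np.isfinite(movie[:frame]).all():
        raise IntegrationError("non-finite Vm in recorded movie")
    return EpisodeRecord(vm_movie=movie[:frame], times_ms=times[:frame],
                         lat=lat, stim_log=stimuli, duration_ms=duration_ms,
                         dt_ms=dt_ms, snapshot_ms=snapshot_ms, h_cm=h)


def measure_cv(record: EpisodeRecord, grid: TissueGrid,
               direction=(1.0, 0.0), min_r2: float = 0.9) -> float:
    """Plane-wave conduction speed (cm/s) by least-squares LAT regression.

    Uses nodes whose projected position along ``direction`` lies between 25%
    and 75% of the propagation axis (excluding stimulus and boundary
    artifacts) and, transversely, the central half of the sheet.  ``min_r2``
    is the cleanliness gate on the fit: keep the default for uniform slabs,
    lower it for heterogeneous (fibrotic) media where LAT is legitimately
    scattered around the mean front.
    """
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    yy, xx = np.mgrid[:grid.ny, :grid.nx]
    px = xx * grid.h_cm
    py = yy * grid.h_cm
    proj = px * d[0] + py * d[1]
    perp = -px * d[1] + py * d[0]

    lo, hi = np.quantile(proj, [0.25, 0.75])
    p_lo, p_hi = np.quantile(perp, [0.25, 0.75])
    sel = (proj >= lo) & (proj <= hi) & (perp >= p_lo) & (perp <= p_hi)
    lat = record.lat
    sel &= np.isfinite(lat)
    if sel.sum() < 10:
        raise MeasurementError("too few activated nodes in measurement band")

    x = proj[sel]
    t = lat[sel]
    slope, intercept = np.polyfit(x, t, 1)
    if slope <= 0:
        raise MeasurementError("non-monotone LAT along the propagation axis")
    resid = t - (slope * x + intercept)
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot > 0 and 1.0 - np.sum(resid ** 2) / ss_tot < min_r2:
        raise MeasurementError("LAT field is not a clean planar wavefront")
    return 1000.0 / slope    # ms/cm -> cm/s


def _slab_cv(grid: TissueGrid, cond: ConductivityField, params_map,
             cv_guess_cm_s: float, dt_ms=None, fibrotic_params=None) -> float:
    """Plane-wave CV along x from a left-edge line stimulus."""
    width_cm = grid.extent_cm[0]
    duration = min(1000.0, 1.3 * width_cm / max(cv_guess_cm_s, 5.0) * 1000.0)
    rec = run_monodomain(grid, cond, params_map,
                         [line_stimulus(grid, "left")], duration_ms=duration,
                         dt_ms=dt_ms, fibrotic_params=fibrotic_params)
    return measure_cv(rec, grid, (1.0, 0.0))


def calibrate_conductivity(grid: TissueGrid, target_cv_cm_s: float,
                           tolerance_cm_s: float, cond: ConductivityField,
                           params_map, dt_ms: float | None = None,
                           max_iter: int = 30) -> tuple[ConductivityField, dict]:
    """Scale conductivity globally until plane-wave CV matches the target.

    Monotone bisection on a global multiplier of (sigma_L, sigma_T); the
    measured CV and final multiplier are returned in the info dict.  The
    input field is returned unchanged (0 iterations) if it already meets
    the tolerance.
    """
    if not 5.0 <= target_cv_cm_s <= 120.0:
        raise ValueError("target CV must be within [5, 120] cm/s")
    cv0 = _slab_cv(grid, cond, params_map, target_cv_cm_s, dt_ms)
    if abs(cv0 - target_cv_cm_s) <= tolerance_cm_s:
        return cond, {"cv": cv0, "scale": 1.0, "iterations": 0}

    # diffusion scaling: CV ~ sqrt(sigma) -> good initial bracket
    s_mid = (target_cv_cm_s / cv0) ** 2
    lo, hi = 0.5 * s_mid, 2.0 * s_mid
    cv_lo = _slab_cv(grid, cond.scaled(lo), params_map, target_cv_cm_s, dt_ms)
    cv_hi = _slab_cv(grid, cond.scaled(hi), params_map, target_cv_cm_s, dt_ms)
    it = 2
    while not (cv_lo <= target_cv_cm_s <= cv_hi):
        if it >= max_iter:
            raise CalibrationError(
                f"no bracket after {it} evaluations; last bracket "
                f"[{lo:.4f}, {hi:.4f}] -> CV [{cv_lo:.2f}, {cv_hi:.2f}]")
        if cv_lo > target_cv_cm_s:
            lo *= 0.5
            cv_lo = _slab_cv(grid, cond.scaled(lo), params_map,
                             target_cv_cm_s, dt_ms)
        else:
            hi *= 2.0
            cv_hi = _slab_cv(grid, cond.scaled(hi), params_map,
                             target_cv_cm_s, dt_ms)
        it += 1
    while it < max_iter:
        mid = 0.5 * (lo + hi)
        cv_mid = _slab_cv(grid, cond.scaled(mid), params_map,
                          target_cv_cm_s, dt_ms)
        it += 1
        if abs(cv_mid - target_cv_cm_s) <= tolerance_cm_s:
            return cond.scaled(mid), {"cv": cv_mid, "scale": mid,
                                      "iterations": it}
        if cv_mid < target_cv_cm_s:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no convergence in {max_iter} evaluations; last bracket "
        f"[{lo:.4f}, {hi:.4f}]")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_episode(record: EpisodeRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("vm_movie", data=record.vm_movie,
                         chunks=(1,) + record.vm_movie.shape[1:])
        f.create_dataset("times_ms", data=record.times_ms)
        f.create_dataset("lat", data=record.lat)
        f.attrs["duration_ms"] = record.duration_ms
        f.attrs["dt_ms"] = record.dt_ms
        f.attrs["snapshot_ms"] = record.snapshot_ms
        f.attrs["h_cm"] = record.h_cm
        f.attrs["n_stimuli"] = len(record.stim_log)


def load_episode(path) -> EpisodeRecord:
    with h5py.File(path, "r") as f:
        return EpisodeRecord(
            vm_movie=f["vm_movie"][...], times_ms=f["times_ms"][...],
            lat=f["lat"][...], stim_log=[],
            duration_ms=float(f.attrs["duration_ms"]),
            dt_ms=float(f.attrs["dt_ms"]),
            snapshot_ms=float(f.attrs["snapshot_ms"]),
            h_cm=float(f.attrs["h_cm"]))
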