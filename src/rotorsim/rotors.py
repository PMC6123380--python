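"""Phase-singularity detection and re-entrant-driver bookkeeping.

The activation phase of each node is the temporal analytic-signal (Hilbert)
phase of the mean-subtracted voltage over an analysis window — by default
the final 1,000 ms of an episode, so that transient instability right after
induction is disregarded.  Phase singularities are found per frame by the
topological-charge criterion on 2×2 plaquettes (closed-loop wrapped phase
difference of ±2π), linked into trajectories by greedy nearest-neighbor
matching, filtered by the persistence rule (≥2 rotations and ≥200 ms), and
assigned to the tissue region containing the majority of the trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from . import config
from .monodomain import EpisodeRecord
from .substrate import TissueGrid

__all__ = [
    "PhaseField",
    "PSPoint",
    "RDRecord",
    "compute_phase",
    "find_singularities",
    "track_trajectories",
    "filter_persistent",
    "assign_region",
    "detect_drivers",
]


@dataclass
class PhaseField:
    """Per-node phase in (−π, π] over an analysis window.

    ``phase`` is ``(nt, ny, nx)``; quiescent nodes are NaN (excluded from
    the singularity search).  ``frame_ms`` is the frame interval.
    """

    phase: np.ndarray
    times_ms: np.ndarray
    window: tuple[float, float]
    h_cm: float

    @property
    def frame_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass
class PSPoint:
    """One phase singularity: grid-unit position, time, topological charge."""

    x: float
    y: float
    t: float
    chirality: int


@dataclass
class RDRecord:
    """A tracked re-entrant driver (persistent phase-singularity trajectory)."""

    trajectory: list[PSPoint]
    duration: float
    n_rotations: float
    chirality: int
    region: int | None = None

    @property
    def is_persistent(self) -> bool:
        return (self.n_rotations >= config.MIN_ROTATIONS
                and self.duration >= config.MIN_DURATION_MS)

    def to_json(self) -> str:
        return json.dumps({
            "trajectory": [[p.x, p.y, p.t] for p in self.trajectory],
            "duration": self.duration, "n_rotations": self.n_rotations,
            "chirality": self.chirality, "region": self.region})


#: voltage standard deviation below which a node counts as quiescent (mV)
_QUIESCENT_STD_MV = 1.0


def compute_phase(record: EpisodeRecord,
                  window_ms: float = config.ANALYSIS_WINDOW_MS) -> PhaseField:
    """Analytic-signal phase of the mean-subtracted voltage movie.

    The window is the final ``window_ms`` of the episode.  Requires the
    movie sampling interval to be at most 5 ms.
    """
    if window_ms > record.times_ms[-1] - record.times_ms[0] + 1e-9:
        raise ValueError("analysis window exceeds the episode")
    frame_ms = float(record.times_ms[1] - record.times_ms[0])
    if frame_ms > 5.0 + 1e-9:
        raise ValueError("movie sampling interval must be <= 5 ms")
    t_end = record.times_ms[-1]
    sel = record.times_ms >= t_end - window_ms - 1e-9
    vm = record.vm_movie[sel].astype(float)
    times = record.times_ms[sel]
    centered = vm - vm.mean(axis=0)
    quiescent = vm.std(axis=0) < _QUIESCENT_STD_MV
    phase = np.angle(hilbert(centered, axis=0))
    phase[:, quiescent] = np.nan
    return PhaseField(phase=phase, times_ms=times,
                      window=(float(t_end - window_ms), float(t_end)),
                      h_cm=record.h_cm)


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def find_singularities_frame(phase2d: np.ndarray, t: float) -> list[PSPoint]:
    """Topological-charge search over all 2×2 plaquettes of one frame."""
    p = phase2d
    # circulation around each plaquette, counter-clockwise
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])
    circ = d1 + d2 + d3 + d4
    with np.errstate(invalid="ignore"):
        charge = np.round(circ / (2 * np.pi))
    hits = np.argwhere(np.nan_to_num(np.abs(charge)) >= 1)
    return [PSPoint(x=float(j) + 0.5, y=float(i) + 0.5, t=t,
                    chirality=int(np.sign(charge[i, j])))
            for i, j in hits]


def find_singularities(phase: PhaseField, t: float) -> list[PSPoint]:
    """Phase singularities at the frame nearest to time ``t`` (ms)."""
    idx = int(np.argmin(np.abs(phase.times_ms - t)))
    return find_singularities_frame(phase.phase[idx],
                                    float(phase.times_ms[idx]))


def singularities_by_frame(phase: PhaseField) -> list[list[PSPoint]]:
    return [find_singularities_frame(phase.phase[i], float(phase.times_ms[i]))
            for i in range(phase.phase.shape[0])]


def track_trajectories(ps_by_frame: list[list[PSPoint]],
                       max_link_mm: float = config.MAX_LINK_MM,
                       max_gap_frames: int = config.MAX_GAP_FRAMES,
                       h_cm: float = 0.035) -> list[list[PSPoint]]:
    """Greedy nearest-neighbor linking of same-chirality singularities.

    Points within ``max_link_mm`` of a live trajectory head extend it; gaps
    up to ``max_gap_frames`` frames are bridged; unmatched points start new
    trajectories.
    """
    max_link_nodes = max_link_mm * 0.1 / h_cm
    done: list[list[PSPoint]] = []
    live: list[list[PSPoint]] = []     # trajectories still eligible
    gap: list[int] = []                # frames since each live head matched
    for frame_idx, points in enumerate(ps_by_frame):
        unmatched = list(points)
        # candidate (distance, live-trajectory, point) pairs, greedy by distance
        pairs = []
        for li, traj in enumerate(live):
            head = traj[-1]
            for pi, p in enumerate(unmatched):
                if p.chirality != head.chirality:
                    continue
                d = np.hypot(p.x - head.x, p.y - head.y)
                if d <= max_link_nodes * (gap[li] + 1):
                    pairs.append((d, li, pi))
        pairs.sort(key=lambda z: z[0])
        used_l, used_p = set(), set()
        for d, li, pi in pairs:
            if li in used_l or pi in used_p:
                continue
            live[li].append(unmatched[pi])
            gap[li] = 0
            used_l.add(li)
            used_p.add(pi)
        # age out unmatched live trajectories
        keep_live, keep_gap = [], []
        for li, traj in enumerate(live):
            if li in used_l:
                keep_live.append(traj)
                keep_gap.append(0)
            elif gap[li] + 1 <= max_gap_frames:
                keep_live.append(traj)
                keep_gap.append(gap[li] + 1)
            else:
                done.append(traj)
        live, gap = keep_live, keep_gap
        for pi, p in enumerate(unmatched):
            if pi not in used_p:
                live.append([p])
                gap.append(0)
    return done + live


def count_rotations(traj: list[PSPoint], phase: PhaseField,
                    probe_radius_mm: float = config.ROTATION_PROBE_RADIUS_MM,
                    n_probe: int = 16) -> float:
    """Rotations completed over a trajectory's lifetime.

    Total unwrapped phase accumulated at probe points on a ring of
    ``probe_radius_mm`` around the trajectory centroid, averaged over the
    ring, divided by 2π.  Ring counting is robust to tip meander.
    """
    cx = float(np.mean([p.x for p in traj]))
    cy = float(np.mean([p.y for p in traj]))
    r_nodes = probe_radius_mm * 0.1 / phase.h_cm
    t0, t1 = traj[0].t, traj[-1].t
    sel = (phase.times_ms >= t0 - 1e-9) & (phase.times_ms <= t1 + 1e-9)
    if sel.sum() < 2:
        return 0.0
    ny, nx = phase.phase.shape[1:]
    angles = np.linspace(0, 2 * np.pi, n_probe, endpoint=False)
    acc = []
    for a in angles:
        i = int(round(cy + r_nodes * np.sin(a)))
        j = int(round(cx + r_nodes * np.cos(a)))
        if not (0 <= i < ny and 0 <= j < nx):
            continue
        series = phase.phase[sel, i, j]
        if np.isnan(series).any():
            continue
        unwrapped = np.unwrap(series)
        acc.append(abs(unwrapped[-1] - unwrapped[0]))
    if not acc:
        return 0.0
    return float(np.mean(acc) / (2 * np.pi))


def filter_persistent(trajectories: list[list[PSPoint]], phase: PhaseField,
                      min_rotations: float = config.MIN_ROTATIONS,
                      min_duration_ms: float = config.MIN_DURATION_MS,
                      ) -> list[RDRecord]:
    """Keep trajectories meeting the persistence rule (duration and
    rotation count); returns RDRecords, unassigned to regions."""
    out = []
    for traj in trajectories:
        duration = traj[-1].t - traj[0].t
        if duration < min_duration_ms:
            continue
        n_rot = count_rotations(traj, phase)
        if n_rot < min_rotations:
            continue
        out.append(RDRecord(trajectory=traj, duration=float(duration),
                            n_rotations=n_rot,
                            chirality=traj[0].chirality))
    return out


def assign_region(rd: RDRecord, grid: TissueGrid) -> int:
    """Region containing the majority of the trajectory.

    Ties: the mode of the temporally later half decides; remaining ties go
    to the lowest region id.
    """
    labels = [int(grid.region_labels[min(int(round(p.y)), grid.ny - 1),
                                    min(int(round(p.x)), grid.nx - 1)])
              for p in rd.trajectory]
    region = _majority(labels)
    rd.region = region
    return region


def _majority(labels: list[int]) -> int:
    counts: dict[int, int] = {}
    for lb in labels:
        counts[lb] = counts.get(lb, 0) + 1
    top = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    # tie-break on the later half of the trajectory
    later = labels[len(labels) // 2:]
    lcounts = {r: later.count(r) for r in tied}
    ltop = max(lcounts.values())
    return min(r for r, c in lcounts.items() if c == ltop)


def detect_drivers(record: EpisodeRecord, grid: TissueGrid,
                   window_ms: float = config.ANALYSIS_WINDOW_MS,
                   min_rotations: float = config.MIN_ROTATIONS,
                   min_duration_ms: float = config.MIN_DURATION_MS,
                   ) -> list[RDRecord]:
    """Full chain: phase → singularities → tracking → persistence → region."""
    phase = compute_phase(record, window_ms)
    ps = singularities_by_frame(phase)
    trajs = track_trajectories(ps, h_cm=record.h_cm)
    rds = filter_persistent(trajs, phase, min_rotations, min_duration_ms)
    for rd in rds:
        assign_region(rd, grid)
    return rds
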