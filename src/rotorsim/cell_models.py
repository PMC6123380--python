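"""Single-cell ionic kinetics.

The physiological workhorse is a human atrial action-potential model of the
Courtemanche–Ramirez–Nattel family, with chronic-AF and fibrotic-region
variants expressed as multiplicative conductance scalings (reduced I_CaL,
I_to, I_Kur and doubled I_K1 for AF remodeling; additional loss of I_Na,
I_CaL and I_K1 in fibrosis-affected myocytes).  A 3-variable Fenton–Karma
model is exposed behind the same interface for fast tissue-scale tests; it
supports stable spiral waves at a fraction of the cost.

State is held as a ``(n_state, n_nodes)`` array so that single-cell and
tissue code share the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import _kernels

__all__ = [
    "CellParams",
    "CellState",
    "APMetrics",
    "available_variants",
    "make_variant",
    "step_cell",
    "pace_cell",
]

#: hard ceiling on the detailed-model step, ms (stability of forward Euler)
MAX_DT_DETAILED = 0.05


class IntegrationError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


@dataclass(frozen=True)
class CellParams:
    """A named ionic-model variant.

    ``conductance_scalings`` multiply the baseline maximal conductances; the
    ``model`` field selects the detailed or the reduced kernel.
    """

    variant: str
    conductance_scalings: dict[str, float]
    Cm: float = 100.0
    model: str = "detailed"

    def __post_init__(self):
        for name, s in self.conductance_scalings.items():
            if s <= 0:
                raise ValueError(f"scaling {name!r} must be > 0, got {s}")

    @property
    def scal_names(self) -> tuple[str, ...]:
        return (_kernels.CRN_SCAL_NAMES if self.model == "detailed"
                else _kernels.FK_SCAL_NAMES)

    def scal_vector(self) -> np.ndarray:
        """Scaling factors in kernel order."""
        return np.array([self.conductance_scalings.get(nm, 1.0)
                         for nm in self.scal_names])


@dataclass
class CellState:
    """Membrane state: voltage (mV), gates in [0, 1], concentrations (mM)."""

    Vm: float
    gates: np.ndarray
    concentrations: np.ndarray
    model: str = "detailed"

    @classmethod
    def resting(cls, params: CellParams) -> "CellState":
        S = _initial(params, 1)
        return cls.from_array(S, params.model)

    @classmethod
    def from_array(cls, S: np.ndarray, model: str) -> "CellState":
        if model == "detailed":
            return cls(float(S[0, 0]), S[_kernels.CRN_GATES, 0].copy(),
                       S[_kernels.CRN_CONCS, 0].copy(), model)
        return cls(float(S[0, 0]), S[1:, 0].copy(), np.empty(0), model)

    def to_array(self) -> np.ndarray:
        n = 1 + self.gates.size + self.concentrations.size
        S = np.empty((n, 1))
        S[0, 0] = self.Vm
        S[1:1 + self.gates.size, 0] = self.gates
        if self.concentrations.size:
            S[1 + self.gates.size:, 0] = self.concentrations
        return S


@dataclass
class APMetrics:
    """Validation metrics for one paced beat."""

    apd90: float        # ms
    rmp: float          # mV
    dvdt_max: float     # mV/ms
    captured: bool = True

    def to_csv_row(self) -> str:
        return f"{self.apd90:.3f},{self.rmp:.3f},{self.dvdt_max:.3f},{int(self.captured)}"


def _load_variant_table() -> dict:
    text = resources.files("rotorsim.data").joinpath("variants.yaml").read_text()
    return yaml.safe_load(text)


_VARIANTS = _load_variant_table()


def available_variants() -> list[str]:
    return sorted(_VARIANTS)


def make_variant(name: str) -> CellParams:
    """Parameter set for a named variant.

    Raises ``KeyError`` listing the known variants for an unknown name.
    """
    try:
        block = _VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; available: {', '.join(available_variants())}"
        ) from None
    return CellParams(variant=name,
                      conductance_scalings=dict(block["scalings"]),
                      Cm=float(block.get("Cm", 100.0)),
                      model=block.get("model", "detailed"))


def _initial(params: CellParams, n: int) -> np.ndarray:
    if params.model == "detailed":
        return _kernels.crn_initial_state(n)
    return _kernels.fk_initial_state(n)


def _kernel(params: CellParams):
    return _kernels.crn_step if params.model == "detailed" else _kernels.fk_step


def _check_finite(S: np.ndarray, model: str) -> None:
    if np.isfinite(S).all():
        return
    names = (_kernels.CRN_STATE_NAMES if model == "detailed"
             else _kernels.FK_STATE_NAMES)
    bad = np.where(~np.isfinite(S))[0]
    raise IntegrationError(
        f"non-finite state after step: {names[int(bad[0])]}")


def step_cell(state: CellState, params: CellParams, i_stim: float,
              dt: float) -> CellState:
    """Advance a single cell one time step.

    Gates use the Rush–Larsen exponential scheme; voltage and concentrations
    use forward Euler.  ``i_stim`` is a depolarizing current density in
    pA/pF.  For the detailed model ``dt`` must not exceed 0.05 ms.
    """
    if params.model == "detailed" and dt > MAX_DT_DETAILED:
        raise ValueError(f"dt={dt} ms exceeds {MAX_DT_DETAILED} ms limit "
                         "for the detailed model")
    S = state.to_array()
    scal = params.scal_vector()[:, None]
    _kernel(params)(S, np.array([float(i_stim)]), dt, scal)
    _check_finite(S, params.model)
    return CellState.from_array(S, params.model)


def pace_cell(params: CellParams, cycle_length: float, n_beats: int,
              dt: float = 0.02, stim_amplitude: float = 30.0,
              stim_duration: float = 2.0) -> APMetrics:
    """Pace a cell ``n_beats`` times and report metrics of the final beat.

    Returns an ``APMetrics`` with ``captured=False`` (and NaN apd90) if the
    final stimulus fails to elicit an upstroke; loss of capture is a result,
    not an exception.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    S = _initial(params, 1)
    scal = params.scal_vector()[:, None]
    kern = _kernel(params)
    n_per_cl = int(round(cycle_length / dt))
    n_stim = max(1, int(round(stim_duration / dt)))
    stim_on = np.array([float(stim_amplitude)])
    stim_off = np.zeros(1)

    # run all but the last beat without recording
    for _ in range(n_beats - 1):
        for i in range(n_per_cl):
            kern(S, stim_on if i < n_stim else stim_off, dt, scal)
    _check_finite(S, params.model)

    # record the final beat
    vm = np.empty(n_per_cl + 1)
    vm[0] = S[0, 0]
    for i in range(n_per_cl):
        kern(S, stim_on if i < n_stim else stim_off, dt, scal)
        vm[i + 1] = S[0, 0]
    _check_finite(S, params.model)
    return ap_metrics_from_trace(vm, dt)


def ap_metrics_from_trace(vm: np.ndarray, dt: float) -> APMetrics:
    """APD90, resting potential and max upstroke velocity from one beat."""
    rmp = float(vm[0])
    dvdt = np.diff(vm) / dt
    dvdt_max = float(dvdt.max())
    peak_idx = int(vm.argmax())
    peak = float(vm[peak_idx])
    amplitude = peak - rmp
    if dvdt_max < 5.0 or amplitude < 20.0:
        return APMetrics(apd90=float("nan"), rmp=rmp, dvdt_max=dvdt_max,
                         captured=False)
    v90 = peak - 0.9 * amplitude
    below = np.where(vm[peak_idx:] <= v90)[0]
    if below.size == 0:
        apd90 = float("nan")     # did not repolarize within the window
    else:
        # measure from upstroke (max dV/dt) to 90% repolarization
        up_idx = int(dvdt.argmax())
        apd90 = (peak_idx + below[0] - up_idx) * dt
    return APMetrics(apd90=float(apd90), rmp=rmp, dvdt_max=dvdt_max)
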