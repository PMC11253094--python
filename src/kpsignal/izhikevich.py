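"""Izhikevich spiking-neuron model: regime registry and fixed-step simulation.

The model reduces a biophysical neuron to two coupled ODEs for the membrane
potential ``v`` (mV) and a recovery variable ``u``::

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with an after-spike reset applied whenever ``v`` reaches 30 mV: ``v <- c``,
``u <- u + d``.  Twenty published parameter sets (``a, b, c, d, I``) reproduce
the canonical firing regimes (tonic spiking, bursting, accommodation, ...);
these waveforms serve as neuromorphic electrical stimuli for bio-hybrid
substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IzhikevichParams",
    "StimulusWaveform",
    "SimulationDivergedError",
    "REGIMES",
    "regime_params",
    "simulate_izhikevich",
]

SPIKE_THRESHOLD_MV = 30.0
DEFAULT_DT_MS = 0.25
DEFAULT_V0_MV = -65.0


class SimulationDivergedError(RuntimeError):
    """Raised when the Euler integration produces a non-finite state."""

    def __init__(self, step: int, t_ms: float):
        self.step = step
        self.t_ms = t_ms
        super().__init__(
            f"Izhikevich integration diverged (non-finite state) at step {step} "
            f"(t = {t_ms:g} ms); reduce dt or the input current."
        )


@dataclass(frozen=True)
class IzhikevichParams:
    """One firing-regime parameter set.

    a : recovery time scale (1/ms), b : recovery sensitivity, c : after-spike
    reset potential (mV), d : after-spike recovery increment, I : constant
    input current (model units).
    """

    regime_name: str
    a: float
    b: float
    c: float
    d: float
    I: float


# The 20 canonical firing regimes: name -> (a, b, c, d, I).
_REGIME_TABLE: Mapping[str, tuple[float, float, float, float, float]] = {
    "tonic spiking": (0.02, 0.2, -65, 6, 14),
    "phasic spiking": (0.02, 0.25, -65, 6, 0.5),
    "tonic bursting": (0.02, 0.2, -50, 2, 15),
    "phasic bursting": (0.02, 0.25, -55, 0.05, 0.6),
    "mixed mode": (0.02, 0.2, -55, 4, 10),
    "spike frequency adaptation": (0.01, 0.2, -65, 8, 30),
    "class 1": (0.02, -0.1, -55, 6, 0),
    "class 2": (0.2, 0.26, -65, 0, 0),
    "spike latency": (0.02, 0.2, -65, 6, 7),
    "subthreshold oscillations": (0.05, 0.26, -60, 0, 0),
    "resonator": (0.1, 0.26, -60, -1, 0),
    "integrator": (0.02, -0.1, -55, 6, 0),
    "rebound spike": (0.03, 0.25, -60, 4, 0),
    "rebound burst": (0.03, 0.25, -52, 0, 0),
    "threshold variability": (0.03, 0.25, -60, 4, 0),
    "bistability": (1, 1.5, -60, 0, -65),
    "DAP": (1, 0.2, -60, -21, 0),
    "accommodation": (0.02, 1, -55, 4, 0),
    "inhibition-induced spiking": (-0.02, -1, -60, 8, 80),
    "inhibition-induced bursting": (-0.026, -1, -45, 0, 80),
}

REGIMES: Mapping[str, IzhikevichParams] = {
    name: IzhikevichParams(name, *row) for name, row in _REGIME_TABLE.items()
}


def regime_params(name: str) -> IzhikevichParams:
    """Look up one of the 20 published regime parameter sets by name.

    Raises
    ------
    KeyError
        If ``name`` is not a known regime; the message lists the valid names.
    """
    if not isinstance(name, str) or not name:
        raise KeyError("regime name must be a non-empty string")
    try:
        return REGIMES[name]
    except KeyError:
        valid = ", ".join(sorted(REGIMES))
        raise KeyError(f"unknown regime {name!r}; valid regimes: {valid}") from None


@dataclass
class StimulusWaveform:
    """A sampled stimulus voltage trace.

    ``sample_interval`` is in the unit named by ``time_unit`` ("ms" for
    model-rate waveforms, "s" for recording-rate ones).  ``spike_times``
    are reset-event times in the same unit, strictly increasing.
    """

    sample_interval: float
    values: np.ndarray
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    time_unit: str = "ms"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.values) * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sample_interval


def simulate_izhikevich(
    params: IzhikevichParams,
    duration: float,
    dt: float = DEFAULT_DT_MS,
    input_override: Sequence[float] | None = None,
    v0: float = DEFAULT_V0_MV,
    u0: float | None = None,
) -> StimulusWaveform:
    """Integrate the model with fixed-step forward Euler.

    Parameters
    ----------
    params : IzhikevichParams
        Regime parameters; ``params.I`` is the constant drive unless
        ``input_override`` supplies a per-step current series (e.g. a ramp
        for the accommodation regime).
    duration, dt : float
        Simulated span and step, both in ms.  The trace has
        ``floor(duration/dt)`` samples.
    v0, u0 : float
        Initial state; ``u0`` defaults to ``b * v0``.

    Returns
    -------
    StimulusWaveform
        Millisecond-rate ``v`` trace with spike apices clipped to the 30 mV
        reset threshold, and the reset-event times in ms.

    Notes
    -----
    Deterministic: identical inputs give bit-identical output.  Reported
    ``v`` never exceeds 30 mV — the overshooting Euler step is recorded as
    exactly the threshold so the reset is a testable trace property.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(duration / dt)
    current = None
    if input_override is not None:
        current = np.asarray(input_override, dtype=float)
        if current.shape != (n,):
            raise ValueError(
                f"input_override must have length duration/dt = {n}, got {current.shape}"
            )

    v = float(v0)
    u = params.b * v0 if u0 is None else float(u0)
    trace = np.empty(n)
    spike_times: list[float] = []
    a, b = params.a, params.b
    for k in range(n):
        I = params.I if current is None else current[k]
        v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u_new = u + dt * a * (b * v - u)
        if not (np.isfinite(v_new) and np.isfinite(u_new)):
            raise SimulationDivergedError(k, k * dt)
        if v_new >= SPIKE_THRESHOLD_MV:
            trace[k] = SPIKE_THRESHOLD_MV
            spike_times.append((k + 1) * dt)
            v = params.c
            u = u_new + params.d
        else:
            trace[k] = v_new
            v, u = v_new, u_new

    return StimulusWaveform(
        sample_interval=dt,
        values=trace,
        spike_times=np.asarray(spike_times),
        time_unit="ms",
        meta={"regime": params.regime_name, "v0": v0, "u0": params.b * v0 if u0 is None else u0},
    )
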