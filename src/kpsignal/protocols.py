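"""Piecewise-constant stimulation protocols and audio-derived stimuli.

The protocol battery mirrors common neuromorphic stimulation patterns:
millisecond pulses imitating single spikes, 100 ms bursts probing refractory
effects, stepped-frequency trains revealing resonance, hyperpolarizing
pre-pulses before test spikes, and oscillatory pulse packets.  Audio
waveforms (e.g. owl vocalizations) are resampled and rescaled into voltage
stimuli for acoustic-to-electrical transduction experiments.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as _signal

from .izhikevich import StimulusWaveform

__all__ = ["PROTOCOL_KINDS", "build_pulse_protocol", "audio_to_stimulus"]

PROTOCOL_KINDS = (
    "pulse_train",
    "burst",
    "stepped_frequency",
    "hyperpolarizing_prepulse",
    "oscillatory_packet",
)


def _require_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")


def _pulse_block(amplitude, width_ms, n, gap_ms, resolution_ms):
    _require_nonneg(width_ms=width_ms, gap_ms=gap_ms, n=n)
    w = int(round(width_ms / resolution_ms))
    g = int(round(gap_ms / resolution_ms))
    block = np.zeros((w + g) * int(n))
    for i in range(int(n)):
        block[i * (w + g) : i * (w + g) + w] = amplitude
    return block


def build_pulse_protocol(
    kind: str, resolution_ms: float = 1.0, **spec: float
) -> StimulusWaveform:
    """Build a named piecewise-constant protocol waveform.

    Parameters
    ----------
    kind : str
        One of ``pulse_train``, ``burst``, ``stepped_frequency``,
        ``hyperpolarizing_prepulse``, ``oscillatory_packet``.
    resolution_ms : float
        Sample interval of the generated waveform.
    **spec
        Kind-specific parameters, all amplitudes in mV, widths/gaps in ms:

        - pulse_train: ``amplitude, width_ms, n, gap_ms``
        - burst: same fields, default ``width_ms=100``
        - stepped_frequency: ``freqs_hz`` (sequence), ``step_duration_s``,
          ``amplitude, width_ms`` — within each step, ``f`` pulses per second
          evenly spaced
        - hyperpolarizing_prepulse: ``prepulse_mv, prepulse_ms`` then
          ``amplitude, width_ms, n, gap_ms`` test pulses
        - oscillatory_packet: ``amplitude, freq_hz, cycles, packets, gap_ms``
          square-wave packets separated by silent gaps

    The total duration is the sum of the specified segments.
    """
    if resolution_ms <= 0:
        raise ValueError("resolution_ms must be > 0")
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}; valid: {PROTOCOL_KINDS}")

    if kind in ("pulse_train", "burst"):
        width = spec.get("width_ms", 100.0 if kind == "burst" else 1.0)
        values = _pulse_block(
            spec["amplitude"], width, spec.get("n", 1), spec.get("gap_ms", 0.0),
            resolution_ms,
        )
    elif kind == "stepped_frequency":
        freqs = np.asarray(spec["freqs_hz"], dtype=float)
        step_s = float(spec["step_duration_s"])
        width = float(spec.get("width_ms", 1.0))
        _require_nonneg(step_duration_s=step_s, width_ms=width)
        if np.any(freqs < 0):
            raise ValueError("frequencies must be >= 0")
        step_samples = int(round(step_s * 1000.0 / resolution_ms))
        w = max(1, int(round(width / resolution_ms)))
        chunks = []
        for f in freqs:
            chunk = np.zeros(step_samples)
            n_pulses = int(round(f * step_s))
            for i in range(n_pulses):
                start = int(round(i * step_samples / max(n_pulses, 1)))
                chunk[start : start + w] = spec["amplitude"]
            chunks.append(chunk)
        values = np.concatenate(chunks) if chunks else np.zeros(0)
    elif kind == "hyperpolarizing_prepulse":
        pre_ms = float(spec.get("prepulse_ms", 100.0))
        _require_nonneg(prepulse_ms=pre_ms)
        pre = np.full(int(round(pre_ms / resolution_ms)), float(spec["prepulse_mv"]))
        pulses = _pulse_block(
            spec.get("amplitude", 0.0), spec.get("width_ms", 1.0),
            spec.get("n", 0), spec.get("gap_ms", 0.0), resolution_ms,
        )
        values = np.concatenate([pre, pulses])
    else:  # oscillatory_packet
        freq = float(spec["freq_hz"])
        cycles = int(spec.get("cycles", 5))
        packets = int(spec.get("packets", 1))
        gap_ms = float(spec.get("gap_ms", 0.0))
        _require_nonneg(freq_hz=freq, gap_ms=gap_ms, cycles=cycles, packets=packets)
        half = max(1, int(round(1000.0 / freq / 2.0 / resolution_ms)))
        one_packet = np.tile(
            np.concatenate([np.full(half, spec["amplitude"]),
                            np.full(half, -spec["amplitude"])]),
            cycles,
        )
        gap = np.zeros(int(round(gap_ms / resolution_ms)))
        values = np.concatenate([np.concatenate([one_packet, gap])
                                 for _ in range(packets)]) if packets else np.zeros(0)

    return StimulusWaveform(
        sample_interval=resolution_ms, values=values, time_unit="ms",
        meta={"protocol": kind, "spec": dict(spec), "resolution_ms": resolution_ms},
    )


def audio_to_stimulus(
    samples: np.ndarray,
    source_rate: float,
    target_rate: float,
    peak_mv: float,
) -> StimulusWaveform:
    """Convert an audio amplitude series into a voltage stimulus.

    The series is resampled from ``source_rate`` to ``target_rate``
    (polyphase filtering at the exact rational ratio) and linearly rescaled
    so that ``max |value| == peak_mv``.  A zero-mean input stays zero-mean
    under the linear rescale.

    Raises
    ------
    ValueError
        For non-positive rates/peak or an all-zero input (the rescale is
        undefined).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if source_rate <= 0 or target_rate <= 0 or peak_mv <= 0:
        raise ValueError("source_rate, target_rate and peak_mv must be > 0")

    if source_rate == target_rate:
        resampled = samples.copy()
    else:
        ratio = Fraction(target_rate / source_rate).limit_denominator(10**6)
        resampled = _signal.resample_poly(samples, ratio.numerator, ratio.denominator)

    peak = np.max(np.abs(resampled))
    if peak == 0:
        raise ValueError("input signal is identically zero; rescaling is undefined")
    values = resampled * (peak_mv / peak)
    return StimulusWaveform(
        sample_interval=1.0 / target_rate, values=values, time_unit="s",
        meta={"source_rate_hz": source_rate, "target_rate_hz": target_rate,
              "peak_mv": peak_mv},
    )
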