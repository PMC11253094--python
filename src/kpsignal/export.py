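"""Writers/readers for the pipeline's tabular artifacts.

All text output uses the strict dialect: comma delimiter, '.' decimal
separator, UTF-8, one header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hebbian import EnergyLandscape
from .izhikevich import StimulusWaveform
from .mi import MIMatrix
from .spikes import SpikeEvent

__all__ = [
    "write_waveform_csv",
    "write_spikes_csv",
    "write_mi_csv",
    "read_mi_csv",
    "write_landscape_csv",
    "write_json",
    "save_heatmap",
]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def write_waveform_csv(wf: StimulusWaveform, path: str | Path) -> None:
    """CSV with header ``time_ms,voltage_mV`` (model rate) or ``time_s,voltage_mV``."""
    col = "time_ms" if wf.time_unit == "ms" else "time_s"
    pd.DataFrame({col: wf.times, "voltage_mV": wf.values}).to_csv(
        path, index=False, float_format="%.9g")


def write_spikes_csv(events: list[SpikeEvent], path: str | Path) -> None:
    """CSV with header ``index,time_s,amplitude_mV``, one row per spike."""
    pd.DataFrame({
        "index": np.arange(len(events)),
        "time_s": [e.time for e in events],
        "amplitude_mV": [e.amplitude for e in events],
    }).to_csv(path, index=False, float_format="%.9g")


def write_mi_csv(m: MIMatrix, path: str | Path) -> None:
    """Square CSV with channel labels as header row and first column."""
    pd.DataFrame(m.values, index=m.channels, columns=m.channels).to_csv(
        path, float_format="%.9g")


def read_mi_csv(path: str | Path) -> MIMatrix:
    df = pd.read_csv(path, index_col=0)
    return MIMatrix(values=df.to_numpy(dtype=float),
                    channels=list(df.columns), bins=0)


def write_landscape_csv(ls: EnergyLandscape, path: str | Path) -> None:
    """Long-format CSV ``activity1,activity2,energy``."""
    ls.to_long_frame().to_csv(path, index=False, float_format="%.9g")


def save_heatmap(m: MIMatrix, path: str | Path, title: str = "MI (bits)") -> None:
    """Basic MI heatmap export (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(m.values, cmap="viridis")
    ax.set_xticks(range(len(m.channels)), m.channels, rotation=45)
    ax.set_yticks(range(len(m.channels)), m.channels)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
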