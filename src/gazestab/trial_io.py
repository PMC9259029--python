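"""Plain-text I/O for trials and metric tables.

Trial CSVs carry the columns ``time_s``, ``theta_thorax_deg``,
``theta_head_thorax_deg`` with the metadata (stimulus spec + labels) embedded
as ``#``-prefixed JSON header lines, so a single file round-trips a trial.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .response_metrics import TrialMetrics
from .synthetic_data import StimulusSpec, Trial, TrialMeta

__all__ = [
    "TRIAL_COLUMNS",
    "write_trial",
    "read_trial",
    "metrics_frame",
    "write_metrics",
    "read_metrics",
]

TRIAL_COLUMNS = ("time_s", "theta_thorax_deg", "theta_head_thorax_deg")

METRICS_COLUMNS = (
    "trial_id",
    "gain",
    "phase_xcorr_deg",
    "phase_fft_deg",
    "epsilon",
    "coherence",
    "stim_amplitude_deg",
    "resp_amplitude_deg",
    "flags",
)


def write_trial(
    trial: Trial, path: str | Path, spec: StimulusSpec | None = None
) -> None:
    path = Path(path)
    header = {"meta": trial.meta.__dict__}
    if spec is not None:
        header["stimulus"] = {
            "frequency": spec.frequency,
            "amplitude": spec.amplitude,
            "n_cycles": spec.n_cycles,
            "sample_rate": spec.sample_rate,
            "ramp_endpoints": spec.ramp_endpoints,
        }
    lines = [f"# {key}: {json.dumps(value)}" for key, value in header.items()]
    frame = pd.DataFrame(
        {
            "time_s": trial.time,
            "theta_thorax_deg": trial.theta_thorax,
            "theta_head_thorax_deg": trial.theta_head_thorax,
        }
    )
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_trial(path: str | Path) -> tuple[Trial, StimulusSpec | None]:
    """Read a trial CSV; returns the trial and the embedded spec if present."""
    path = Path(path)
    header: dict = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, payload = line[1:].strip().partition(":")
            header[key.strip()] = json.loads(payload)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial file {path} missing columns: {missing}")
    meta = TrialMeta(**header["meta"]) if "meta" in header else TrialMeta(0.0, 0.0)
    trial = Trial(
        time=frame["time_s"].to_numpy(),
        theta_thorax=frame["theta_thorax_deg"].to_numpy(),
        theta_head_thorax=frame["theta_head_thorax_deg"].to_numpy(),
        meta=meta,
    )
    spec = StimulusSpec(**header["stimulus"]) if "stimulus" in header else None
    return trial, spec


def metrics_frame(
    metrics: Sequence[TrialMetrics], trial_ids: Sequence[str]
) -> pd.DataFrame:
    if len(metrics) != len(trial_ids):
        raise ValueError("metrics and trial_ids must have equal length")
    return pd.DataFrame(
        {
            "trial_id": list(trial_ids),
            "gain": [m.gain for m in metrics],
            "phase_xcorr_deg": [m.phase_xcorr for m in metrics],
            "phase_fft_deg": [m.phase_fft for m in metrics],
            "epsilon": [m.epsilon for m in metrics],
            "coherence": [m.coherence for m in metrics],
            "stim_amplitude_deg": [m.stim_amplitude for m in metrics],
            "resp_amplitude_deg": [m.resp_amplitude for m in metrics],
            "flags": [";".join(m.flags) for m in metrics],
        }
    )


def write_metrics(
    metrics: Sequence[TrialMetrics], trial_ids: Sequence[str], path: str | Path
) -> None:
    metrics_frame(metrics, trial_ids).to_csv(path, index=False, float_format="%.10g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"metrics file {path} missing columns: {missing}")
    return frame
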