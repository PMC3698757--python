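"""CSV/YAML readers and writers with provenance headers.

Analysis outputs are plain CSV with a short ``#``-prefixed provenance header
(package version, seed, config hash) so every file can be traced to the run
that produced it; readers skip those lines. Waveforms travel as two-column
CSV (ISO timestamp, pressure in mmHg) with a YAML sidecar carrying the sample
rate, schedule, preset name and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import Waveform
from .errors import DataError
from .schedule import LightDarkSchedule


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# telebp {__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_waveform(wf: Waveform, path, extra_sidecar: dict | None = None) -> Path:
    """Write a waveform as (iso-timestamp, pressure) CSV plus a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    times = wf.start + pd.to_timedelta(np.arange(wf.samples.size) / wf.sample_rate, unit="s")
    df = pd.DataFrame(
        {
            "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "pressure_mmHg": np.round(wf.samples, 4),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "sample_rate": wf.sample_rate,
        "start": str(wf.start),
        "animal": wf.animal,
        "schedule": {
            "dark_onset_hour": wf.schedule.dark_onset_hour,
            "dark_hours": wf.schedule.dark_hours,
        },
    }
    sidecar.update(extra_sidecar or {})
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def read_waveform(path) -> Waveform:
    """Read a waveform CSV; the YAML sidecar is required for the sample rate."""
    path = Path(path)
    side = path.with_suffix(".yaml")
    if not side.exists():
        raise DataError(f"missing waveform sidecar {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    df = pd.read_csv(path)
    if "pressure_mmHg" not in df.columns:
        raise DataError(f"{path} is not a waveform CSV (no pressure_mmHg column)")
    sched = LightDarkSchedule(**meta.get("schedule", {}))
    return Waveform(
        df["pressure_mmHg"].to_numpy(dtype=float),
        sample_rate=float(meta["sample_rate"]),
        start=pd.Timestamp(meta["start"]),
        schedule=sched,
        animal=meta.get("animal", path.stem),
    )


def write_ground_truth(gt, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(gt.to_dict(), fh, sort_keys=False, default_flow_style=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
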