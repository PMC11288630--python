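"""Plain-text readers and writers for the package's data products.

Formats are deliberately simple: spike tables are tidy CSV (one spike per
row), POR matrices are 0/1 CSV with locust row labels and ``# key=value``
header comments, ground truth and fitted models are JSON, configurations
are YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .behavior import PORMatrix
from .protocol import StimulusProtocol
from .spikes import SpikeTrain
from .synth import GroundTruth, OdorSpec, SyntheticConfig

SPIKE_COLUMNS = ["pn_id", "odor", "condition", "trial", "spike_time_s"]


def write_spike_table(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    """Write spike trains as tidy CSV: pn_id, odor, condition, trial,
    spike_time_s (one spike per row)."""
    rows = []
    for train in trains:
        for t in train.times:
            rows.append((train.pn_id, train.odor, train.condition, train.trial, t))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_table(
    path: str | Path, trial_duration: float | None = None
) -> list[SpikeTrain]:
    """Read a tidy spike table back into :class:`SpikeTrain` objects."""
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    trains = []
    keys = ["pn_id", "odor", "condition", "trial"]
    for (pn_id, odor, condition, trial), group in df.groupby(keys, sort=True):
        times = np.sort(group["spike_time_s"].to_numpy(dtype=float))
        trains.append(
            SpikeTrain(
                times=times,
                pn_id=str(pn_id),
                odor=str(odor),
                condition=str(condition),
                trial=int(trial),
                duration=trial_duration,
            )
        )
    return trains


def write_por_matrix(matrix: PORMatrix, path: str | Path) -> None:
    """Write a POR matrix as 0/1 CSV with ``# key=value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# odor={matrix.odor}\n")
        fh.write(f"# condition={matrix.condition}\n")
        fh.write(f"# concentration={matrix.concentration}\n")
        cols = ",".join(f"trial{j + 1}" for j in range(matrix.n_trials))
        fh.write(f"locust_id,{cols}\n")
        for locust_id, row in zip(matrix.locust_ids, matrix.values):
            fh.write(locust_id + "," + ",".join(str(int(v)) for v in row) + "\n")


def read_por_matrix(path: str | Path) -> PORMatrix:
    """Read a POR matrix written by :func:`write_por_matrix`."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, skiprows=body_start)
    locust_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=int)
    return PORMatrix(
        values=values,
        odor=meta.get("odor", ""),
        condition=meta.get("condition", "control"),
        concentration=float(meta.get("concentration", 1.0)),
        locust_ids=locust_ids,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    record = {
        "pn_ids": list(truth.pn_ids),
        "odor_names": list(truth.odor_names),
        "true_weights": truth.true_weights.tolist(),
        "base_rates": truth.base_rates.tolist(),
        "response_type_map": truth.response_type_map.astype(str).tolist(),
        "true_p_por": {f"{odor}|{cond}": p for (odor, cond), p in truth.true_p_por.items()},
    }
    Path(path).write_text(json.dumps(record, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    record = json.loads(Path(path).read_text())
    true_p = {}
    for key, p in record["true_p_por"].items():
        odor, _, cond = key.partition("|")
        true_p[(odor, cond)] = float(p)
    return GroundTruth(
        true_weights=np.asarray(record["true_weights"], dtype=float),
        response_type_map=np.asarray(record["response_type_map"], dtype=object),
        base_rates=np.asarray(record["base_rates"], dtype=float),
        odor_names=tuple(record["odor_names"]),
        pn_ids=tuple(record["pn_ids"]),
        true_p_por=true_p,
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["odor_set"] = [asdict(o) for o in config.odor_set]
    d["protocol"] = asdict(config.protocol)
    return d


def write_config(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_config(path: str | Path) -> SyntheticConfig:
    """Load a synthetic-experiment configuration from YAML (or JSON)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping) -> SyntheticConfig:
    raw = dict(raw)
    if "odor_set" in raw:
        raw["odor_set"] = tuple(OdorSpec(**o) for o in raw["odor_set"])
    if "protocol" in raw:
        raw["protocol"] = StimulusProtocol(**raw["protocol"])
    return SyntheticConfig(**raw)


def write_json(record: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
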