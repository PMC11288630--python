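"""End-to-end orchestration: simulate → spike statistics → classification →
behavior → ensemble → decoder, with a reproducibility manifest.

All stage outputs are plain text (CSV/JSON) in the run directory; the
manifest records the package version, the seed, a hash of the resolved
configuration and a hash of every numeric output, so re-running an
unchanged configuration byte-reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import compare_conditions, por_probability
from .classify import classify_response, robustness_fractions
from .decoder import PORDecoder, order_units_by_contrast
from .ensemble import (
    build_population_matrix,
    binwise_correlation,
    cross_condition_correlation,
    pca_trajectories,
)
from .io import (
    config_to_dict,
    write_config,
    write_ground_truth,
    write_json,
    write_por_matrix,
    write_spike_table,
)
from .spikes import CONTROL, SEROTONIN, bin_spikes, pool_isis
from .synth import SyntheticConfig, SyntheticExperiment, generate_experiment

STAGES = ("simulate", "ephys", "classify", "behavior", "ensemble", "decode")


class StageError(RuntimeError):
    """A pipeline stage failed or a required upstream stage was disabled."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, validated before any stage runs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str | Path = "neuropor_run"
    stages: tuple[str, ...] = STAGES
    psth_bin_width: float = 0.2
    decoder_bin_width: float = 0.05
    k_sd: float = 6.5
    amplification_gain: float = 1.5
    test_direction: str = "greater"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise StageError(f"unknown stages: {sorted(unknown)}")
        if self.test_direction not in ("greater", "less"):
            raise StageError("test_direction must be 'greater' or 'less'")
        for name, value in (
            ("psth_bin_width", self.psth_bin_width),
            ("decoder_bin_width", self.decoder_bin_width),
        ):
            if value <= 0:
                raise StageError(f"{name} must be positive")
        if self.k_sd < 0 or self.amplification_gain < 1:
            raise StageError("k_sd must be >= 0 and amplification_gain >= 1")


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(stage: str, config: RunConfig, have: dict) -> None:
    if stage not in config.stages:
        raise StageError(
            f"stage {stage!r} is disabled but a downstream stage needs its output"
        )
    if stage not in have:
        raise StageError(f"stage {stage!r} did not produce its output")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "neuropor",
        "version": __version__,
        "seed": config.synthetic.seed,
        "config_hash": _hash_obj(
            {**config_to_dict(config.synthetic), "run": {
                "stages": list(config.stages),
                "psth_bin_width": config.psth_bin_width,
                "decoder_bin_width": config.decoder_bin_width,
                "k_sd": config.k_sd,
                "amplification_gain": config.amplification_gain,
                "test_direction": config.test_direction,
            }}
        ),
        "stages": {},
        "outputs": {},
    }
    have: dict = {}
    proto = config.synthetic.protocol

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for f in files:
            manifest["outputs"][f.name] = _hash_file(f)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        if stage == "simulate":
            exp = generate_experiment(config.synthetic)
            have["simulate"] = exp
            write_config(config.synthetic, out / "config.yaml")
            write_spike_table(exp.trains, out / "spikes.csv")
            write_ground_truth(exp.truth, out / "ground_truth.json")
            por_files = []
            for (odor, cond), matrix in exp.por.items():
                f = out / f"por_{odor}_{cond}.csv"
                write_por_matrix(matrix, f)
                por_files.append(f)
            record(stage, t0, [out / "config.yaml", out / "spikes.csv",
                               out / "ground_truth.json", *por_files])

        elif stage == "ephys":
            _require("simulate", config, have)
            exp: SyntheticExperiment = have["simulate"]
            binned: dict[str, dict[str, object]] = {}
            isi_rows = []
            for condition in (CONTROL, SEROTONIN):
                recs = exp.recordings(condition)
                for (pn_id, odor), trains in recs.items():
                    resp = bin_spikes(trains, config.psth_bin_width, proto.trial_duration)
                    binned.setdefault(f"{pn_id}|{odor}", {})[condition] = resp
                # ISIs: spontaneous window only, pooled across odors and trials
                by_pn: dict[str, list] = {}
                for (pn_id, _odor), trains in recs.items():
                    for train in trains:
                        t0b, t1b = proto.baseline_window
                        times = train.times[(train.times >= t0b) & (train.times < t1b)]
                        by_pn.setdefault(pn_id, []).append(
                            replace(train, times=times, duration=None)
                        )
                for pn_id, trains in by_pn.items():
                    summary = pool_isis(trains)
                    isi_rows.append(
                        {
                            "pn_id": pn_id,
                            "condition": condition,
                            "n_isis": summary.isis.size,
                            "median_isi_s": summary.median_isi,
                        }
                    )
            have["ephys"] = binned
            isi_df = pd.DataFrame(isi_rows).sort_values(["pn_id", "condition"])
            isi_df.to_csv(out / "isi_summary.csv", index=False, float_format="%.6f")
            record(stage, t0, [out / "isi_summary.csv"])

        elif stage == "classify":
            _require("ephys", config, have)
            rows = []
            classes = {CONTROL: [], SEROTONIN: []}
            for unit_id, by_cond in have["ephys"].items():
                for condition, resp in by_cond.items():
                    cls = classify_response(resp, proto, k_sd=config.k_sd)
                    classes[condition].append(cls)
                    rows.append(
                        {
                            "unit": unit_id,
                            "condition": condition,
                            "label": cls.label,
                            "threshold": cls.threshold,
                            "baseline_mean": cls.baseline_mean,
                            "baseline_sd": cls.baseline_sd,
                        }
                    )
            have["classify"] = classes
            pd.DataFrame(rows).to_csv(out / "classification.csv", index=False,
                                      float_format="%.6f")
            rob = robustness_fractions(classes[CONTROL], classes[SEROTONIN])
            write_json(
                {
                    "fraction_on_maintained": rob.fraction_on_maintained,
                    "fraction_off_maintained": rob.fraction_off_maintained,
                    "fraction_nonresponsive_maintained": rob.fraction_nonresponsive_maintained,
                    "n_on": rob.n_on,
                    "n_off": rob.n_off,
                    "n_nonresponsive": rob.n_nonresponsive,
                },
                out / "robustness.json",
            )
            record(stage, t0, [out / "classification.csv", out / "robustness.json"])

        elif stage == "behavior":
            _require("simulate", config, have)
            exp = have["simulate"]
            stats = {}
            for odor in exp.config.odor_names:
                before = exp.por[(odor, CONTROL)]
                after = exp.por[(odor, SEROTONIN)]
                test = compare_conditions(before, after, config.test_direction)
                stats[odor] = {
                    "p_por_control": por_probability(before),
                    "p_por_5HT": por_probability(after),
                    "t_statistic": test.t_statistic,
                    "p_value": test.p_value,
                    "direction": test.direction,
                    "n_locusts": test.n,
                }
            have["behavior"] = stats
            write_json(stats, out / "behavior_stats.json")
            record(stage, t0, [out / "behavior_stats.json"])

        elif stage == "ensemble":
            _require("ephys", config, have)
            pop = build_population_matrix(have["ephys"], protocol=proto)
            traj = pca_trajectories(pop)
            corr = binwise_correlation(pop)
            xcorr = cross_condition_correlation(pop)
            on_sl = pop.window_slice(proto.on_window)
            base_sl = pop.window_slice(proto.baseline_window)
            summary = {
                "n_units": pop.n_units,
                "n_bins": pop.n_bins,
                "explained_variance_pc1": float(traj.explained_variance_ratio[0]),
                "explained_variance_pc2": float(traj.explained_variance_ratio[1]),
                "mean_on_correlation": corr.mean_block(on_sl, on_sl),
                "cross_condition_on_correlation": xcorr.mean_block(on_sl, on_sl),
                "cross_condition_spontaneous_correlation": xcorr.mean_block(base_sl, base_sl),
            }
            have["ensemble"] = summary
            pd.DataFrame(
                {
                    "time_s": np.arange(pop.n_bins) * pop.bin_width,
                    "pc1": traj.coords[:, 0],
                    "pc2": traj.coords[:, 1],
                }
            ).to_csv(out / "pca_trajectory.csv", index=False, float_format="%.6f")
            write_json(summary, out / "ensemble_summary.json")
            record(stage, t0, [out / "pca_trajectory.csv", out / "ensemble_summary.json"])

        elif stage == "decode":
            _require("simulate", config, have)
            _require("behavior", config, have)
            exp = have["simulate"]
            recs = {}
            for (pn_id, odor), trains in exp.recordings(CONTROL).items():
                recs.setdefault(pn_id, {})[odor] = trains
            por_probs = {
                odor: have["behavior"][odor]["p_por_control"]
                for odor in exp.config.odor_names
            }
            model = PORDecoder.from_recordings(
                recs,
                por_probs,
                grand_mean=exp.config.grand_mean_por,
                bin_width=config.decoder_bin_width,
                protocol=proto,
            )
            res = model.fit()
            have["decode"] = res
            write_json(res.to_dict(), out / "decoder_model.json")
            pred_rows = []
            deltas = res.amplification_experiment(config.amplification_gain)
            for odor, (pred, obs) in res.predicted_vs_observed().items():
                pred_rows.append(
                    {
                        "odor": odor,
                        "predicted_p_por": pred,
                        "observed_p_por": obs,
                        "delta_p_por_amplified": deltas[odor],
                    }
                )
            pd.DataFrame(pred_rows).to_csv(
                out / "decoder_predictions.csv", index=False, float_format="%.6f"
            )
            odors = exp.config.odor_names
            if len(odors) >= 2:
                order = order_units_by_contrast(res.model.design, odors[0], odors[-1])
                pd.DataFrame(
                    {
                        "rank": np.arange(order.size),
                        "unit": np.asarray(res.unit_ids)[order],
                        "weight": res.weights[order],
                    }
                ).to_csv(out / "unit_ordering.csv", index=False, float_format="%.6f")
            (out / "summary.txt").write_text(res.summary() + "\n")
            record(stage, t0, [out / "decoder_model.json", out / "decoder_predictions.csv",
                               out / "summary.txt"])

    # exclude per-stage timing from the reproducibility digest
    manifest["manifest_hash"] = _hash_obj(
        {"config": manifest["config_hash"], "outputs": manifest["outputs"]}
    )
    write_json(manifest, out / "manifest.json")
    return manifest
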