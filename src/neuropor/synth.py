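"""Seeded synthetic experiments with the statistical structure of the study.

The generator emulates paired control / serotonin (5HT) recordings from
antennal-lobe projection neurons (PNs) together with palp-opening-response
(POR) sessions, so that every downstream analysis is testable without any
recorded data. What it reproduces:

* 40 s trials with a 4 s odor pulse at t = 10 s; 5 electrophysiology trials
  and 10 behavioral trials per odorant;
* spontaneous spiking that becomes burstier under 5HT at matched mean rate
  (two-state Markov-modulated Poisson process);
* odor-evoked ON and OFF responses whose magnitude — never their timing — is
  multiplied by a uniform gain under 5HT;
* POR outcomes drawn from a ground-truth signed linear readout of population
  activity: odorants loading on positive-weight PNs raise p(POR) above the
  grand mean, odorants loading on negative-weight PNs lower it.

Every quantity is reproducible from one master seed via named substreams, so
a dataset is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .behavior import PORMatrix
from .protocol import BEHAVIOR_PROTOCOL, StimulusProtocol
from .spikes import CONTROL, SEROTONIN, SpikeTrain

ON, OFF, NONE = "ON", "OFF", "none"
RESPONSE_TYPES = (ON, OFF, NONE)
VALENCES = ("appetitive", "aversive", "neutral")

#: Burst-state dwell time of the spontaneous-activity burst process, seconds.
BURST_DWELL_S = 0.15


class SyntheticConfigError(ValueError):
    """Raised for generator configurations that violate their invariants."""


@dataclass(frozen=True)
class OdorSpec:
    """One odorant: label, behavioral valence and its control-condition
    target POR probability (the signed readout is calibrated to hit it)."""

    name: str
    valence: str
    target_por: float

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise SyntheticConfigError(f"unknown valence {self.valence!r}")
        if not 0.0 <= self.target_por <= 1.0:
            raise SyntheticConfigError("target_por must lie in [0, 1]")


#: Default decoder odor panel: a strongly appetitive green-leaf volatile
#: (hexanol), a near-median aggregation pheromone (benzaldehyde) and an
#: aversive pesticide component (linalool), at the study's POR levels.
DEFAULT_ODORS = (
    OdorSpec("HEX", "appetitive", 0.62),
    OdorSpec("BZA", "neutral", 0.40),
    OdorSpec("LOOL", "aversive", 0.29),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a synthetic experiment.

    Parameters
    ----------
    n_pn : int
        Number of projection neurons (89 matches the extracellular dataset
        used by the decoder).
    odor_set : tuple of OdorSpec
        Odor panel with valences and target control POR probabilities.
    baseline_rate : float
        Mean spontaneous firing rate, Hz; individual PNs are jittered
        ±40% around it.
    burstiness : float
        Spontaneous-regime burstiness under 5HT (≥ 1; 1 = Poisson-like).
        The control condition is always 1.
    response_amplitude : float
        Added firing rate (Hz) inside a responsive PN's ON or OFF window.
    gain_5ht : float
        Multiplicative amplification (≥ 1) of evoked-response amplitude
        under 5HT.
    frac_on, frac_off : float
        Fractions of PNs with ON / OFF responses per odorant.
    valence_bias : float
        Probability that an ON responder to an appetitive odorant is drawn
        from the positive-weight pool (aversive → negative pool).
    grand_mean_por : float
        Mean POR probability across odorants and locusts; the readout's
        output baseline.
    n_locusts, n_behavior_trials : int
        Behavioral session size.
    behavior_noise : float
        SD of the per-locust probability offset (probability scale).
    protocol : StimulusProtocol
        Electrophysiology trial timing (5 × 40 s trials, odor at 10–14 s).
    decoder_bin_width : float
        Bin width (s) at which the ground-truth readout is defined.
    seed : int
        Master seed; all substreams derive from it.
    """

    n_pn: int = 89
    odor_set: tuple[OdorSpec, ...] = DEFAULT_ODORS
    baseline_rate: float = 3.0
    burstiness: float = 3.0
    response_amplitude: float = 15.0
    gain_5ht: float = 1.5
    frac_on: float = 0.35
    frac_off: float = 0.15
    valence_bias: float = 0.8
    grand_mean_por: float = 0.43
    n_locusts: int = 23
    n_behavior_trials: int = 10
    behavior_noise: float = 0.02
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    decoder_bin_width: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pn < 1:
            raise SyntheticConfigError("n_pn must be >= 1")
        if not self.odor_set:
            raise SyntheticConfigError("odor_set must be non-empty")
        if self.burstiness < 1:
            raise SyntheticConfigError("burstiness must be >= 1")
        if self.gain_5ht < 1:
            raise SyntheticConfigError("gain_5ht must be >= 1")
        if self.baseline_rate <= 0 or self.response_amplitude < 0:
            raise SyntheticConfigError("rates must be positive")
        if not 0.0 <= self.grand_mean_por <= 1.0:
            raise SyntheticConfigError("grand_mean_por must lie in [0, 1]")
        if self.frac_on + self.frac_off > 1.0:
            raise SyntheticConfigError("frac_on + frac_off must be <= 1")
        if not 0.0 <= self.valence_bias <= 1.0:
            raise SyntheticConfigError("valence_bias must lie in [0, 1]")
        if self.behavior_noise < 0:
            raise SyntheticConfigError("behavior_noise must be >= 0")
        if self.n_locusts < 1 or self.n_behavior_trials < 1:
            raise SyntheticConfigError("behavioral session sizes must be >= 1")

    @property
    def odor_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.odor_set)

    @property
    def pn_ids(self) -> tuple[str, ...]:
        return tuple(f"pn{i + 1:03d}" for i in range(self.n_pn))


@dataclass
class GroundTruth:
    """What the generator knows and the analyses must recover."""

    true_weights: np.ndarray
    response_type_map: np.ndarray  # (n_pn, n_odors) of {ON, OFF, none}
    base_rates: np.ndarray  # per-PN spontaneous rate, Hz
    odor_names: tuple[str, ...]
    pn_ids: tuple[str, ...]
    true_p_por: dict[tuple[str, str], float]  # (odor, condition) -> p

    def response_type(self, pn_index: int, odor: str) -> str:
        return str(self.response_type_map[pn_index, self.odor_names.index(odor)])


def _rng(seed: int, *tags: int) -> np.random.Generator:
    """Named substream of the master seed (one per PN/odor/condition/trial)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(tags)))


def sample_baseline_train(
    rate: float,
    burstiness: float,
    duration: float,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Spontaneous spike train at a given mean rate and burstiness.

    ``burstiness = 1`` gives a homogeneous Poisson process. For
    ``burstiness = b > 1`` the rate switches between a burst state (rate
    ``b × rate``, long-run occupancy ``1/(b + 1)``) and a quiet state at rate
    ``rate / b``, so the long-run mean rate is exactly ``rate`` while a
    fraction ``b/(b + 1)`` of spikes falls inside bursts; dwell times are
    exponential with burst dwell :data:`BURST_DWELL_S`. Burstier trains have
    the same mean rate but a smaller median inter-spike interval.
    """
    if rate <= 0 or duration <= 0:
        raise SyntheticConfigError("rate and duration must be positive")
    if burstiness < 1:
        raise SyntheticConfigError("burstiness must be >= 1")
    if burstiness == 1.0:
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n))
        return SpikeTrain(times=np.unique(times), duration=duration)

    b = float(burstiness)
    p_burst = 1.0 / (b + 1.0)  # long-run burst-state occupancy
    rate_burst = b * rate
    rate_quiet = rate / b
    dwell_burst = BURST_DWELL_S
    dwell_quiet = dwell_burst * (1.0 - p_burst) / p_burst

    # Alternate exponential dwells, Poisson spikes within each segment.
    times: list[np.ndarray] = []
    t = 0.0
    in_burst = bool(rng.random() < p_burst)
    while t < duration:
        dwell = rng.exponential(dwell_burst if in_burst else dwell_quiet)
        seg_end = min(t + dwell, duration)
        seg_rate = rate_burst if in_burst else rate_quiet
        if seg_rate > 0 and seg_end > t:
            n = rng.poisson(seg_rate * (seg_end - t))
            if n:
                times.append(rng.uniform(t, seg_end, size=n))
        t = seg_end
        in_burst = not in_burst
    all_times = np.unique(np.concatenate(times)) if times else np.empty(0)
    return SpikeTrain(times=all_times, duration=duration)


def sample_evoked_train(
    protocol: StimulusProtocol,
    base_rate: float,
    response_type: str,
    amplitude: float,
    gain: float,
    burstiness: float,
    rng: np.random.Generator,
) -> SpikeTrain:
    """One trial: spontaneous activity plus an odor-locked response.

    A responsive PN adds an independent Poisson process at rate
    ``gain × amplitude`` inside its ON window (during the pulse) or OFF
    window (the equal interval after pulse offset). Gain scales magnitude
    only; the response window is fixed by ``response_type``.
    """
    if response_type not in RESPONSE_TYPES:
        raise SyntheticConfigError(f"unknown response_type {response_type!r}")
    if amplitude < 0:
        raise SyntheticConfigError("amplitude must be >= 0")
    if gain < 1:
        raise SyntheticConfigError("gain must be >= 1")
    base = sample_baseline_train(base_rate, burstiness, protocol.trial_duration, rng)
    if response_type == NONE or amplitude == 0:
        return base
    window = protocol.on_window if response_type == ON else protocol.off_window
    t0, t1 = window
    n = rng.poisson(gain * amplitude * (t1 - t0))
    extra = rng.uniform(t0, t1, size=n)
    times = np.unique(np.concatenate([base.times, extra]))
    return SpikeTrain(times=times, duration=protocol.trial_duration)


def _assign_response_map(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Response-type map and the latent positive/negative pool assignment.

    Each PN belongs to a latent pool (+1 positive, −1 negative, alternating
    so the pools are balanced). ON responders to an appetitive odorant are
    drawn from the positive pool with probability ``valence_bias`` (aversive
    → negative pool; neutral → either), which is what segregates the
    behavioral readout into neuron / anti-neuron ensembles.
    """
    rng = _rng(config.seed, 0, 0)
    n_pn, odors = config.n_pn, config.odor_set
    pools = np.where(np.arange(n_pn) % 2 == 0, 1, -1)
    rng.shuffle(pools)
    resp = np.full((n_pn, len(odors)), NONE, dtype=object)
    n_on = int(round(config.frac_on * n_pn))
    n_off = int(round(config.frac_off * n_pn))
    for j, odor in enumerate(odors):
        preferred = {"appetitive": 1, "aversive": -1, "neutral": 0}[odor.valence]
        weights = np.ones(n_pn)
        if preferred != 0:
            bias = config.valence_bias
            weights = np.where(pools == preferred, bias, 1.0 - bias)
        weights = weights / weights.sum()
        chosen = rng.choice(n_pn, size=min(n_on + n_off, n_pn), replace=False, p=weights)
        resp[chosen[:n_on], j] = ON
        resp[chosen[n_on:], j] = OFF
    return resp, pools


def expected_stimulus_counts(
    config: SyntheticConfig,
    truth_map: np.ndarray,
    base_rates: np.ndarray,
    gain: float = 1.0,
) -> np.ndarray:
    """Expected mean spike count per decoder bin during the odor pulse.

    Shape (n_pn, n_odors). Only ON responders are elevated inside the pulse;
    OFF responses fall outside it and contribute baseline counts here.
    """
    rates = np.tile(base_rates[:, None], (1, len(config.odor_set)))
    rates = rates + gain * config.response_amplitude * (truth_map == ON)
    return rates * config.decoder_bin_width


def _calibrate_weights(
    config: SyntheticConfig, truth_map: np.ndarray, base_rates: np.ndarray
) -> np.ndarray:
    """Ground-truth weights: the minimum-norm signed readout that maps each
    odorant's expected stimulus-window population vector exactly onto its
    target POR offset from the grand mean (control condition)."""
    R = expected_stimulus_counts(config, truth_map, base_rates, gain=1.0)
    d = np.array([o.target_por - config.grand_mean_por for o in config.odor_set])
    # min-norm solution of Rᵀ w = d (n_odors ≪ n_pn, R full column rank)
    w = R @ np.linalg.solve(R.T @ R, d)
    return w


def build_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Derive the complete ground truth (rates, response map, weights, true
    POR probabilities per condition) from the configuration alone."""
    rate_rng = _rng(config.seed, 0, 1)
    base_rates = config.baseline_rate * rate_rng.uniform(0.6, 1.4, size=config.n_pn)
    truth_map, _pools = _assign_response_map(config)
    weights = _calibrate_weights(config, truth_map, base_rates)
    true_p: dict[tuple[str, str], float] = {}
    for condition, gain in ((CONTROL, 1.0), (SEROTONIN, config.gain_5ht)):
        R = expected_stimulus_counts(config, truth_map, base_rates, gain=gain)
        p = np.clip(config.grand_mean_por + R.T @ weights, 0.0, 1.0)
        for j, odor in enumerate(config.odor_names):
            true_p[(odor, condition)] = float(p[j])
    return GroundTruth(
        true_weights=weights,
        response_type_map=truth_map,
        base_rates=base_rates,
        odor_names=config.odor_names,
        pn_ids=config.pn_ids,
        true_p_por=true_p,
    )


def generate_por(
    truth: GroundTruth,
    population_responses: Mapping[tuple[str, str], np.ndarray],
    grand_mean_por: float,
    n_locusts: int,
    n_trials: int,
    noise: float,
    rng: np.random.Generator,
) -> dict[tuple[str, str], PORMatrix]:
    """Bernoulli POR matrices from the signed linear readout.

    For each (odor, condition), the success probability is
    ``clip(grand_mean + w*·r + locust_offset, 0, 1)`` where ``r`` is that
    condition's population response vector (gain-amplified under 5HT) and
    the locust offset is Gaussian with SD ``noise``.
    """
    if n_locusts < 1 or n_trials < 1:
        raise SyntheticConfigError("n_locusts and n_trials must be >= 1")
    out: dict[tuple[str, str], PORMatrix] = {}
    for (odor, condition), r in population_responses.items():
        r = np.asarray(r, dtype=float)
        if r.shape != truth.true_weights.shape:
            raise SyntheticConfigError("population response length != n_pn")
        p = grand_mean_por + float(truth.true_weights @ r)
        p_locust = np.clip(p + rng.normal(0.0, noise, size=n_locusts), 0.0, 1.0)
        draws = rng.random((n_locusts, n_trials)) < p_locust[:, None]
        out[(odor, condition)] = PORMatrix(
            values=draws.astype(int), odor=odor, condition=condition
        )
    return out


def sample_por_matrix(
    p: float,
    n_locusts: int,
    n_trials: int,
    rng: np.random.Generator,
    odor: str = "",
    condition: str = CONTROL,
    noise: float = 0.0,
) -> PORMatrix:
    """i.i.d. Bernoulli POR matrix at a fixed probability (optionally with a
    per-locust Gaussian offset) — a null generator for calibration checks."""
    if not 0.0 <= p <= 1.0:
        raise SyntheticConfigError("p must lie in [0, 1]")
    p_locust = np.clip(p + rng.normal(0.0, noise, size=n_locusts), 0.0, 1.0)
    draws = rng.random((n_locusts, n_trials)) < p_locust[:, None]
    return PORMatrix(values=draws.astype(int), odor=odor, condition=condition)


@dataclass
class SyntheticExperiment:
    """A complete paired control/5HT dataset with its ground truth."""

    config: SyntheticConfig
    truth: GroundTruth
    trains: list[SpikeTrain]
    por: dict[tuple[str, str], PORMatrix]

    @property
    def protocol(self) -> StimulusProtocol:
        return self.config.protocol

    def recordings(
        self, condition: str, odor: str | None = None
    ) -> dict[tuple[str, str], list[SpikeTrain]]:
        """Group trains as ``{(pn_id, odor): [trial trains...]}``."""
        out: dict[tuple[str, str], list[SpikeTrain]] = {}
        for train in self.trains:
            if train.condition != condition:
                continue
            if odor is not None and train.odor != odor:
                continue
            out.setdefault((train.pn_id, train.odor), []).append(train)
        for trains in out.values():
            trains.sort(key=lambda tr: tr.trial)
        return out


def generate_experiment(
    config: SyntheticConfig,
    conditions: Sequence[str] = (CONTROL, SEROTONIN),
) -> SyntheticExperiment:
    """Generate spike trains and POR matrices for all requested conditions.

    Control and 5HT spontaneous activity are generated independently (their
    fine structure decorrelates under 5HT); evoked responses share the
    response-type map, with amplitude multiplied by ``gain_5ht`` and
    spontaneous burstiness raised under 5HT. Fully reproducible from
    ``config.seed``.
    """
    for condition in conditions:
        if condition not in (CONTROL, SEROTONIN):
            raise SyntheticConfigError(f"unknown condition {condition!r}")
    truth = build_ground_truth(config)
    proto = config.protocol
    trains: list[SpikeTrain] = []
    cond_params = {CONTROL: (1.0, 1.0), SEROTONIN: (config.gain_5ht, config.burstiness)}
    for ci, condition in enumerate(conditions):
        gain, burstiness = cond_params[condition]
        for pi, pn_id in enumerate(config.pn_ids):
            for oi, odor in enumerate(config.odor_names):
                rtype = str(truth.response_type_map[pi, oi])
                for trial in range(proto.n_trials):
                    rng = _rng(config.seed, 1, pi, oi, 2 if condition == SEROTONIN else 1, trial)
                    bare = sample_evoked_train(
                        proto,
                        truth.base_rates[pi],
                        rtype,
                        config.response_amplitude,
                        gain,
                        burstiness,
                        rng,
                    )
                    trains.append(
                        replace(bare, pn_id=pn_id, odor=odor, condition=condition, trial=trial)
                    )
    responses: dict[tuple[str, str], np.ndarray] = {}
    for condition in conditions:
        gain = cond_params[condition][0]
        R = expected_stimulus_counts(config, truth.response_type_map, truth.base_rates, gain)
        for j, odor in enumerate(config.odor_names):
            responses[(odor, condition)] = R[:, j]
    por = generate_por(
        truth,
        responses,
        config.grand_mean_por,
        config.n_locusts,
        config.n_behavior_trials,
        config.behavior_noise,
        _rng(config.seed, 2),
    )
    return SyntheticExperiment(config=config, truth=truth, trains=trains, por=por)
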