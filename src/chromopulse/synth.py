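"""Synthetic single-cell datasets with the statistical structure of
time-lapse reporter imaging.

The generator stands in for microscopy data: each cell is a stochastic model
trajectory sampled hourly over ~33 h (two pre-stimulus frames), converted to
fluorescence through a per-cell lognormal gain, offset by a per-cell
baseline, and corrupted with additive Gaussian frame noise.  Ground-truth
latent trajectories and per-cell parameters are retained so every feature
extractor can be scored against construction.

The condition-suite generator mirrors a full stimulation design matrix:
five constant concentrations (0.1, 1, 3, 10, 20 ng/ml, 'plate'), four
durations at 10 ng/ml (1, 4, 8 h and constant, 'chip'), and the two-pulse
protocol, with a plate/chip gain difference so the platform scaling step is
exercised.  It does not emulate imaging artifacts (segmentation error,
tracking loss, photobleaching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deterministic import Condition, ConditionData, integrate
from .params import AdaptationParams, GeneKinetics, StimulusProtocol
from .stochastic import StochasticConfig, EnsembleResult, ensemble
from .traces import TraceMatrix

__all__ = [
    "NoiseModel",
    "SyntheticPopulation",
    "gen_population",
    "gen_condition_suite",
    "CONCENTRATION_SERIES",
    "DURATION_SERIES",
]

# the stimulation design matrix the generator emulates
CONCENTRATION_SERIES = (0.1, 1.0, 3.0, 10.0, 20.0)  # ng/ml, constant, plate
DURATION_SERIES = (1.0, 4.0, 8.0, None)  # hours of 10 ng/ml on chip; None = constant


@dataclass
class NoiseModel:
    """Measurement model mapping molecule counts to fluorescence.

    fluor = gain_i * counts + baseline_i + eps, with per-cell
    gain_i ~ lognormal(median ``gain``, shape ``gain_cv``), per-cell
    baseline_i ~ Normal(baseline_mean, baseline_mean * baseline_cv)
    truncated at zero, and per-frame eps ~ Normal(0, additive_sd).
    """

    baseline_mean: float = 20.0
    baseline_cv: float = 0.2
    additive_sd: float = 2.0
    gain: float = 1.0
    gain_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_mean, self.baseline_cv, self.additive_sd) < 0 or self.gain <= 0:
            raise ValueError("noise parameters must be nonnegative and gain > 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(baseline_mean=0.0, baseline_cv=0.0, additive_sd=0.0, gain=1.0, gain_cv=0.0)


@dataclass
class SyntheticPopulation:
    """A generated dataset plus its ground truth."""

    traces: TraceMatrix
    counts: EnsembleResult  # latent stochastic trajectories
    gains: np.ndarray
    baselines: np.ndarray
    noise: NoiseModel
    seed: int


def gen_population(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    protocol: StimulusProtocol,
    n_cells: int = 500,
    noise: NoiseModel | None = None,
    seed: int = 0,
    metadata: dict | None = None,
) -> SyntheticPopulation:
    """Generate a synthetic single-cell population under one protocol.

    Hourly sampling with two pre-stimulus frames; the same seed reproduces
    the dataset exactly.  With a degenerate noise model (all zero, gain 1)
    the output equals the stochastic counts.
    """
    noise = noise or NoiseModel.noiseless()
    cfg = StochasticConfig(n_cells=n_cells, seed=seed, horizon=protocol.horizon)
    ens = ensemble(kin, adapt, protocol, cfg)
    rng = np.random.default_rng(np.random.SeedSequence((seed, noise.seed, 0x5E1)))
    if noise.gain_cv > 0:
        gains = noise.gain * rng.lognormal(0.0, noise.gain_cv, size=n_cells)
    else:
        gains = np.full(n_cells, noise.gain)
    baselines = np.clip(
        rng.normal(noise.baseline_mean, noise.baseline_mean * noise.baseline_cv, size=n_cells),
        0.0,
        None,
    )
    prot = ens.species("P").astype(float)
    values = gains[:, None] * prot + baselines[:, None]
    if noise.additive_sd > 0:
        values = values + rng.normal(0.0, noise.additive_sd, size=values.shape)
    tm = TraceMatrix(
        time=ens.time,
        values=values,
        stimulus_onsets=protocol.pulse_onsets,
        metadata=dict(metadata or {}, seed=seed),
    )
    return SyntheticPopulation(tm, ens, gains, baselines, noise, seed)


def condition_grid(horizon: float = 31.0, cxcl10_plate_mask_h: float | None = None) -> list[Condition]:
    """The standard 5-concentration + 4-duration + two-pulse condition set.

    ``cxcl10_plate_mask_h`` restricts the plate conditions' fit mask to the
    first N hours (used for reporters whose late plate signal is dominated
    by effects outside the model).
    """
    conds: list[Condition] = []
    plate_mask = None if cxcl10_plate_mask_h is None else [(-2.0, cxcl10_plate_mask_h)]
    for conc in CONCENTRATION_SERIES:
        conds.append(
            Condition(
                label=f"conc_{conc:g}",
                protocol=StimulusProtocol.constant(conc, horizon=horizon),
                platform="plate",
                fit_mask=plate_mask,
            )
        )
    for dur in DURATION_SERIES:
        if dur is None:
            proto = StimulusProtocol.constant(10.0, horizon=horizon)
            label = "dur_constant"
        else:
            proto = StimulusProtocol.pulse(0.0, dur, 10.0, horizon=horizon)
            label = f"dur_{dur:g}h"
        conds.append(Condition(label=label, protocol=proto, platform="chip"))
    conds.append(
        Condition(
            label="two_pulse",
            protocol=StimulusProtocol.two_pulse(horizon=horizon),
            platform="chip",
        )
    )
    return conds


def gen_condition_suite(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    seed: int = 0,
    mode: str = "ode",
    n_cells: int = 500,
    plate_gain: float = 2.0,
    chip_gain: float = 1.0,
    horizon: float = 31.0,
    include_two_pulse: bool = True,
    cxcl10_plate_mask_h: float | None = None,
) -> dict:
    """Mean traces (and optionally populations) for the full design matrix.

    ``mode='ode'`` produces noiseless deterministic mean curves (the input
    the fitting procedure assumes); ``mode='stochastic'`` produces ensemble
    means with finite-sample noise and returns the populations too.  Plate
    and chip conditions carry different gains so the platform-scaling step
    of data preparation is exercised; the true plate/chip factor is
    ``plate_gain / chip_gain``.
    """
    if mode not in ("ode", "stochastic"):
        raise ValueError("mode must be 'ode' or 'stochastic'")
    conds = condition_grid(horizon=horizon, cxcl10_plate_mask_h=cxcl10_plate_mask_h)
    if not include_two_pulse:
        conds = [c for c in conds if c.label != "two_pulse"]
    t = np.arange(-2.0, np.floor(horizon) + 1)
    dataset: list[ConditionData] = []
    populations: dict[str, SyntheticPopulation] = {}
    for i, cond in enumerate(conds):
        g = plate_gain if cond.platform == "plate" else chip_gain
        if mode == "ode":
            traj = integrate(kin, adapt, cond.protocol, t)
            mean = g * traj["P"]
        else:
            pop = gen_population(
                kin, adapt, cond.protocol, n_cells=n_cells,
                noise=NoiseModel(baseline_mean=0.0, baseline_cv=0.0, additive_sd=0.0,
                                 gain=g, gain_cv=0.0),
                seed=int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31)),
                metadata={"condition": cond.label, "platform": cond.platform},
            )
            populations[cond.label] = pop
            mean = pop.traces.mean_trace()
        dataset.append(ConditionData(cond, t, mean))
    out = {"dataset": dataset, "true_chip_scale": plate_gain / chip_gain, "time": t}
    if mode == "stochastic":
        out["populations"] = populations
    return out
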