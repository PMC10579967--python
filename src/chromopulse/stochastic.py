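"""Direct Gillespie simulation of single cells under time-varying stimulus.

The stochastic model uses the same species and reactions as the deterministic
one, with integer molecule counts: chromatin opening/closing/initiation/
de-initiation (propensities k1*TF*C, k2*OU, k3*TF*OU, k4*OI), mRNA synthesis
and decay (k5*OI, deltaM*M), protein synthesis and decay (k6*M, deltaP*P),
and — when adaptation is enabled — regulator mRNA/protein synthesis and decay.

The TF activity is re-evaluated from the current stimulus level and regulator
count at every reaction event, and the simulation is advanced (without firing
a reaction) to each protocol switch point, where propensities are refreshed.
Propensities are held constant between events: an approximation that is
accurate here because reaction times are much shorter than the timescale on
which the TF changes.

Per-cell RNG streams are derived from the master seed with a counter-based
scheme (``numpy.random.SeedSequence``), so ensembles are order-independent
and the same master seed reproduces the same ensemble bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import equilibrate
from .params import AdaptationParams, GeneKinetics, ModelState, StimulusProtocol
from .traces import TraceMatrix

try:  # compiled core; the pure-Python body is numba-compatible
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f


__all__ = ["StochasticConfig", "gillespie_run", "ensemble", "two_pulse_experiment", "EnsembleResult"]

# packed parameter vector layout for the compiled core
_NPAR = 18


def _pack_params(kin: GeneKinetics, adapt: AdaptationParams) -> np.ndarray:
    p = np.zeros(_NPAR)
    p[0:8] = (kin.k1, kin.k2, kin.k3, kin.k4, kin.k5, kin.k6, kin.deltaM, kin.deltaP)
    p[8] = kin.alpha
    p[9] = kin.Kd
    p[10] = 1.0 if adapt.enabled else 0.0
    p[11:18] = (
        adapt.a_regM,
        adapt.a_regP,
        adapt.delta_regM,
        adapt.delta_regP,
        adapt.reg_thr,
        adapt.c1,
        adapt.c2,
    )
    return p


@njit(cache=False)
def _core(p, bp, levels, rec_times, x0, seed):  # pragma: no cover - exercised via wrapper
    """Direct-method SSA over piecewise-constant stimulus intervals.

    ``bp``/``levels``: interval breakpoints (len m+1) and the stimulus level on
    each of the m intervals, spanning [rec_times[0] if earlier, t_end].
    Records the current state at every requested time (right-continuous
    convention: a sample at an event time sees the pre-event state).
    """
    np.random.seed(seed)
    x = x0.copy()
    n_rec = rec_times.shape[0]
    out = np.zeros((n_rec, 7), dtype=np.int64)
    t = bp[0]
    t_end = bp[bp.shape[0] - 1]
    seg = 0
    rec_i = 0
    a = np.zeros(12)
    while True:
        while seg + 2 < bp.shape[0] and t >= bp[seg + 1]:
            seg += 1
        ifng = levels[seg]
        seg_end = bp[seg + 1]
        # TF from current stimulus and regulator count
        tf = math.tanh(p[8] * (ifng + p[9]))
        if p[10] > 0.5:
            tf = tf / (1.0 + (x[6] / p[15]) ** p[16])
        a[0] = p[0] * tf * x[0]  # C -> OU
        a[1] = p[1] * x[1]  # OU -> C
        a[2] = p[2] * tf * x[1]  # OU -> OI
        a[3] = p[3] * x[2]  # OI -> OU
        a[4] = p[4] * x[2]  # mRNA synthesis
        a[5] = p[6] * x[3]  # mRNA decay
        a[6] = p[5] * x[3]  # protein synthesis
        a[7] = p[7] * x[4]  # protein decay
        if p[10] > 0.5:
            if tf > 0.0:
                h = tf ** p[17]
                a[8] = p[11] * h / (1.0 + h)  # regM synthesis
            else:
                a[8] = 0.0
            a[9] = p[13] * x[5]  # regM decay
            a[10] = p[12] * x[5]  # regP synthesis
            a[11] = p[14] * x[6]  # regP decay
        atot = 0.0
        for i in range(12):
            atot += a[i]
        if atot > 0.0:
            dt = -math.log(np.random.random()) / atot
            t_next = t + dt
        else:
            t_next = seg_end
        if t_next >= seg_end:
            while rec_i < n_rec and rec_times[rec_i] < seg_end:
                for j in range(7):
                    out[rec_i, j] = x[j]
                rec_i += 1
            t = seg_end
            if t >= t_end:
                break
            continue
        while rec_i < n_rec and rec_times[rec_i] < t_next:
            for j in range(7):
                out[rec_i, j] = x[j]
            rec_i += 1
        t = t_next
        # select and fire a reaction
        r = np.random.random() * atot
        acc = 0.0
        k = 11
        for i in range(12):
            acc += a[i]
            if r < acc:
                k = i
                break
        if k == 0:
            x[0] -= 1
            x[1] += 1
        elif k == 1:
            x[1] -= 1
            x[0] += 1
        elif k == 2:
            x[1] -= 1
            x[2] += 1
        elif k == 3:
            x[2] -= 1
            x[1] += 1
        elif k == 4:
            x[3] += 1
        elif k == 5:
            x[3] -= 1
        elif k == 6:
            x[4] += 1
        elif k == 7:
            x[4] -= 1
        elif k == 8:
            x[5] += 1
        elif k == 9:
            x[5] -= 1
        elif k == 10:
            x[6] += 1
        else:
            x[6] -= 1
    while rec_i < n_rec:
        for j in range(7):
            out[rec_i, j] = x[j]
        rec_i += 1
    return out


def _breakpoints(protocol: StimulusProtocol, t_start: float, t_end: float):
    pts = [t_start]
    for s in protocol.switch_times():
        if t_start < s < t_end:
            pts.append(float(s))
    pts.append(t_end)
    bp = np.array(sorted(set(pts)))
    levels = np.array([protocol.ifng_at(0.5 * (a + b)) for a, b in zip(bp[:-1], bp[1:])])
    return bp, levels


def sample_initial_state(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    rng: np.random.Generator,
    ifng_basal: float = 0.0,
) -> np.ndarray:
    """Integer resting state: multinomial rounding of the equilibrated
    chromatin fractions and Poisson rounding of the other species."""
    st = equilibrate(kin, adapt, ifng_basal)
    probs = np.array([st.C, st.OU, st.OI]) / kin.n_loci
    chrom = rng.multinomial(kin.n_loci, probs)
    rest = rng.poisson([st.M, st.P, st.regM, st.regP])
    return np.concatenate([chrom, rest]).astype(np.int64)


@dataclass
class StochasticConfig:
    """Ensemble settings: replicate count, master seed, horizon (h), record
    grid (default hourly with two pre-stimulus frames, mimicking imaging),
    and an optional molecule-count scaling applied to mRNA/protein units."""

    n_cells: int = 1000
    seed: int = 0
    horizon: float = 31.0
    pre_frames: int = 2
    record_grid: np.ndarray | None = None
    count_scaling: float = 1.0
    resample_initial: bool = True

    def grid(self) -> np.ndarray:
        if self.record_grid is not None:
            return np.asarray(self.record_grid, dtype=float)
        return np.arange(-self.pre_frames, math.floor(self.horizon) + 1, dtype=float)


@dataclass
class EnsembleResult:
    """Recorded integer trajectories of an ensemble: ``states`` has shape
    (n_cells, n_timepoints, 7) in the order (C, OU, OI, M, P, regM, regP)."""

    time: np.ndarray
    states: np.ndarray
    seeds: np.ndarray
    protocol: StimulusProtocol
    metadata: dict = field(default_factory=dict)

    _SPECIES = {"C": 0, "OU": 1, "OI": 2, "M": 3, "P": 4, "regM": 5, "regP": 6}

    def species(self, name: str) -> np.ndarray:
        return self.states[:, :, self._SPECIES[name]]

    def mean(self, name: str = "P") -> np.ndarray:
        return self.species(name).mean(axis=0)

    def sd(self, name: str = "P", ddof: int = 1) -> np.ndarray:
        return self.species(name).std(axis=0, ddof=ddof)

    def sem(self, name: str = "P") -> np.ndarray:
        return self.sd(name) / math.sqrt(self.states.shape[0])

    def trace_matrix(self, name: str = "P") -> TraceMatrix:
        return TraceMatrix(
            time=self.time,
            values=self.species(name).astype(float),
            stimulus_onsets=self.protocol.pulse_onsets,
            metadata=dict(self.metadata, species=name),
        )


def gillespie_run(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    protocol: StimulusProtocol,
    seed: int,
    record_grid: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single stochastic trajectory; returns (time, states[(n_t, 7)]).

    The same seed always yields a bit-identical trajectory.  ``x0`` defaults
    to an integer state sampled from the basal steady state with an RNG
    derived from ``seed``.
    """
    rec = (
        np.asarray(record_grid, dtype=float)
        if record_grid is not None
        else np.arange(-2.0, math.floor(protocol.horizon) + 1)
    )
    ss = np.random.SeedSequence(seed)
    init_words = ss.generate_state(2)
    if x0 is None:
        x0 = sample_initial_state(kin, adapt, np.random.default_rng(init_words[0]))
    x0 = np.asarray(x0, dtype=np.int64)
    if x0[:3].sum() != kin.n_loci:
        raise ValueError("initial chromatin counts must sum to n_loci")
    bp, levels = _breakpoints(protocol, min(rec[0], 0.0), max(rec[-1], protocol.horizon))
    states = _core(_pack_params(kin, adapt), bp, levels, rec, x0, init_words[1])
    return rec, states


def ensemble(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    protocol: StimulusProtocol,
    cfg: StochasticConfig,
) -> EnsembleResult:
    """Ensemble of independent single-cell trajectories.

    Each cell gets its own counter-derived seed pair (initial-state RNG and
    SSA stream); two calls with the same master seed return identical arrays.
    """
    if cfg.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    kin_s = kin if cfg.count_scaling == 1.0 else kin.replace(k5=kin.k5 * cfg.count_scaling)
    rec = cfg.grid()
    words = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_cells).reshape(-1, 2)
    bp, levels = _breakpoints(protocol, min(rec[0], 0.0), max(rec[-1], protocol.horizon))
    p = _pack_params(kin_s, adapt)
    states = np.empty((cfg.n_cells, rec.size, 7), dtype=np.int64)
    fixed_x0 = None
    if not cfg.resample_initial:
        fixed_x0 = sample_initial_state(kin_s, adapt, np.random.default_rng(words[0, 0]))
    for i in range(cfg.n_cells):
        x0 = (
            fixed_x0
            if fixed_x0 is not None
            else sample_initial_state(kin_s, adapt, np.random.default_rng(words[i, 0]))
        )
        states[i] = _core(p, bp, levels, rec, x0, words[i, 1])
    return EnsembleResult(
        time=rec,
        states=states,
        seeds=words[:, 1].copy(),
        protocol=protocol,
        metadata={"master_seed": cfg.seed, "n_cells": cfg.n_cells},
    )


def two_pulse_experiment(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    cfg: StochasticConfig,
    pulse: float = 4.0,
    gap: float = 10.0,
    ifng: float = 10.0,
    window_after_off: float = 9.0,
) -> tuple[EnsembleResult, np.ndarray]:
    """Two-pulse stimulation ensemble with per-cell, per-pulse amplitudes.

    Default protocol: two 4-h pulses of 10 ng/ml with a 10-h off period.  For
    each cell and pulse the protein amplitude change is measured within the
    window from pulse onset to ``window_after_off`` hours after the pulse end
    (window max minus the value at pulse onset), so each pulse is scored
    independently of the previous one.  Returns (ensemble, amplitudes) with
    ``amplitudes`` of shape (n_cells, 2).
    """
    protocol = StimulusProtocol.two_pulse(pulse=pulse, gap=gap, ifng=ifng, horizon=cfg.horizon)
    res = ensemble(kin, adapt, protocol, cfg)
    from .features import pulse_amplitude_window

    prot = res.species("P").astype(float)
    amps = np.empty((prot.shape[0], 2))
    for j, onset in enumerate(protocol.pulse_onsets):
        end = onset + pulse + window_after_off
        for i in range(prot.shape[0]):
            amps[i, j] = pulse_amplitude_window(prot[i], res.time, onset, end).amplitude
    return res, amps
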