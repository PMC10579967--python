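"""Model parameters, stimulus protocols, and their (de)serialization.

The model describes induction of an interferon-gamma (IFNg) response gene
through a three-state chromatin cycle (closed -> open-uninitiated ->
open-initiated), transcription from initiated loci, and translation.  The
transcription-factor (TF) activity driving opening and initiation is a
saturating function of the extracellular IFNg concentration and is optionally
suppressed by an induced negative regulator (signal adaptation).

Time is in hours throughout; stimulus onset defines experiment time zero.
Concentrations of IFNg are in ng/ml.  In the reference scaling one
deterministic concentration unit corresponds to one molecule per cell volume,
so deterministic trajectories and stochastic molecule counts share an axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GeneKinetics",
    "AdaptationParams",
    "StimulusProtocol",
    "ModelState",
    "STATE_NAMES",
    "load_config",
    "dump_config",
]

STATE_NAMES = ("C", "OU", "OI", "M", "P", "regM", "regP")


@dataclass
class GeneKinetics:
    """Per-gene kinetic and input-function parameters.

    Rates are first-order (1/h) except the synthesis rates ``k5`` (mRNA per
    initiated locus per hour) and ``k6`` (protein per mRNA per hour).  ``alpha``
    (per ng/ml) and ``Kd`` (ng/ml) shape the saturating TF input
    tanh(alpha * (ifng + Kd)); a positive ``Kd`` gives a small basal TF
    activity at zero stimulus.  ``n_loci`` is the number of chromatin copies
    of the gene per cell (two for a diploid locus).
    """

    k1: float  # chromatin opening rate per unit TF, 1/h
    k2: float  # chromatin closing rate, 1/h
    k3: float  # transcription initiation rate per unit TF, 1/h
    k4: float  # de-initiation rate, 1/h
    k5: float  # mRNA synthesis rate per initiated locus, molecules/h
    k6: float  # translation rate per mRNA, molecules/h
    deltaM: float  # mRNA degradation rate, 1/h
    deltaP: float  # protein degradation rate, 1/h
    alpha: float  # TF input steepness, per ng/ml
    Kd: float  # TF input offset, ng/ml
    n_loci: int = 2

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "deltaM", "deltaP", "alpha", "Kd"):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneKinetics.{name} must be nonnegative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    def replace(self, **kw) -> "GeneKinetics":
        d = asdict(self)
        d.update(kw)
        return GeneKinetics(**d)


@dataclass
class AdaptationParams:
    """Negative-feedback regulator of the TF (signal adaptation).

    The TF induces a regulator mRNA (regM) with a saturating production term
    a_regM * TF^c2 / (1 + TF^c2); the regulator protein (regP) is translated
    from regM and suppresses TF activity by the factor
    1 / (1 + (regP/reg_thr)^c1).  With ``enabled`` False the TF reduces
    exactly to the plain tanh input and the regulator species stay at zero.
    """

    a_regM: float = 0.0  # regulator mRNA max synthesis rate, molecules/h
    a_regP: float = 0.0  # regulator translation rate, molecules/h per regM
    delta_regM: float = 1.0  # regulator mRNA degradation, 1/h
    delta_regP: float = 1.0  # regulator protein degradation, 1/h
    reg_thr: float = 1.0  # half-suppression scale, molecules
    c1: float = 1.0  # suppression Hill exponent
    c2: float = 1.0  # regulator-production Hill exponent
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.enabled:
            for name in ("a_regM", "a_regP", "delta_regM", "delta_regP", "reg_thr", "c1", "c2"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"AdaptationParams.{name} must be > 0 when enabled")

    @classmethod
    def disabled(cls) -> "AdaptationParams":
        return cls(enabled=False)

    def replace(self, **kw) -> "AdaptationParams":
        d = asdict(self)
        d.update(kw)
        return AdaptationParams(**d)


@dataclass
class StimulusProtocol:
    """Piecewise-constant IFNg concentration versus time.

    ``segments`` is an ordered list of ``(t_start, t_end, ifng)`` triples in
    hours / ng/ml; the concentration outside every segment is zero.  ``t0``
    is the stimulus onset that defines experiment time zero and ``horizon``
    the total simulated duration after onset.
    """

    segments: list[tuple[float, float, float]]
    t0: float = 0.0
    horizon: float = 31.0

    def __post_init__(self) -> None:
        segs = sorted((float(a), float(b), float(c)) for a, b, c in self.segments)
        for (a, b, c) in segs:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) has nonpositive length")
            if c < 0:
                raise ValueError("IFNg concentration must be >= 0")
        for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ValueError("stimulus segments overlap")
        self.segments = segs

    # -- queries ----------------------------------------------------------
    def ifng_at(self, t: float) -> float:
        """IFNg concentration at time ``t`` (segment value, else 0)."""
        for (a, b, c) in self.segments:
            if a <= t < b:
                return c
        return 0.0

    def ifng(self, t) -> np.ndarray:
        """Vectorised concentration query on an array of times."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for (a, b, c) in self.segments:
            out[(t >= a) & (t < b)] = c
        return out

    def switch_times(self) -> np.ndarray:
        """Sorted unique times at which the concentration may jump."""
        pts = sorted({a for a, _, _ in self.segments} | {b for _, b, _ in self.segments})
        return np.asarray(pts, dtype=float)

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, ifng: float, horizon: float = 31.0) -> "StimulusProtocol":
        return cls(segments=[(0.0, horizon, ifng)], horizon=horizon)

    @classmethod
    def pulse(cls, t_on: float, t_off: float, ifng: float, horizon: float = 31.0) -> "StimulusProtocol":
        return cls(segments=[(t_on, t_off, ifng)], horizon=horizon)

    @classmethod
    def two_pulse(
        cls,
        pulse: float = 4.0,
        gap: float = 10.0,
        ifng: float = 10.0,
        horizon: float = 31.0,
    ) -> "StimulusProtocol":
        """Two equal pulses separated by ``gap`` hours off (default 4 h on,
        10 h off, 4 h on at 10 ng/ml)."""
        s1 = (0.0, pulse, ifng)
        s2 = (pulse + gap, 2 * pulse + gap, ifng)
        return cls(segments=[s1, s2], horizon=horizon)

    @property
    def pulse_onsets(self) -> list[float]:
        return [a for a, _, _ in self.segments]

    @classmethod
    def from_string(cls, text: str, horizon: float = 31.0) -> "StimulusProtocol":
        """Parse a shorthand protocol string.

        Supported forms: ``"constant:10"``, ``"pulse:0-4:10"``,
        ``"twopulse:0-4,14-18:10"``.
        """
        parts = text.strip().split(":")
        kind = parts[0].lower()
        if kind == "constant":
            if len(parts) != 2:
                raise ValueError(f"bad protocol string {text!r}")
            return cls.constant(float(parts[1]), horizon=horizon)
        if kind in ("pulse", "twopulse"):
            if len(parts) != 3:
                raise ValueError(f"bad protocol string {text!r}")
            ifng = float(parts[2])
            segs = []
            for rng in parts[1].split(","):
                a, b = rng.split("-")
                segs.append((float(a), float(b), ifng))
            if kind == "pulse" and len(segs) != 1:
                raise ValueError(f"'pulse' expects one interval: {text!r}")
            if kind == "twopulse" and len(segs) != 2:
                raise ValueError(f"'twopulse' expects two intervals: {text!r}")
            return cls(segments=segs, horizon=horizon)
        raise ValueError(f"unknown protocol kind {kind!r} in {text!r}")


@dataclass
class ModelState:
    """Full model state: chromatin loci (C, OU, OI), mRNA (M), protein (P)
    and the adaptation regulator species (regM, regP).

    The three chromatin components always sum to ``n_loci`` (conservation);
    deterministic states are fractional, stochastic states integer counts.
    """

    C: float
    OU: float
    OI: float
    M: float = 0.0
    P: float = 0.0
    regM: float = 0.0
    regP: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.C, self.OU, self.OI, self.M, self.P, self.regM, self.regP], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ModelState":
        return cls(*[float(x) for x in arr])

    def validate(self, n_loci: int | None = None, atol: float = 1e-6) -> None:
        arr = self.to_array()
        if np.any(arr < -atol):
            raise ValueError(f"negative state component: {self}")
        if n_loci is not None and abs(self.C + self.OU + self.OI - n_loci) > atol:
            raise ValueError(
                f"chromatin conservation violated: C+OU+OI={self.C + self.OU + self.OI} != {n_loci}"
            )


# ---------------------------------------------------------------------------
# config file round trip

def dump_config(
    path,
    kinetics: GeneKinetics | None = None,
    adaptation: AdaptationParams | None = None,
    protocol: StimulusProtocol | None = None,
    extra: dict | None = None,
) -> None:
    """Write parameters/protocol to a YAML config (keys match field names)."""
    doc: dict = {}
    if kinetics is not None:
        doc["kinetics"] = asdict(kinetics)
    if adaptation is not None:
        doc["adaptation"] = asdict(adaptation)
    if protocol is not None:
        doc["protocol"] = {
            "segments": [list(s) for s in protocol.segments],
            "t0": protocol.t0,
            "horizon": protocol.horizon,
        }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    """Read a YAML config written by :func:`dump_config`; returns a dict with
    ``kinetics`` / ``adaptation`` / ``protocol`` objects where present."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: dict = dict(doc)
    if "kinetics" in doc:
        out["kinetics"] = GeneKinetics(**doc["kinetics"])
    if "adaptation" in doc:
        out["adaptation"] = AdaptationParams(**doc["adaptation"])
    if "protocol" in doc:
        p = doc["protocol"]
        if isinstance(p, str):
            out["protocol"] = StimulusProtocol.from_string(p)
        else:
            out["protocol"] = StimulusProtocol(
                segments=[tuple(s) for s in p["segments"]],
                t0=p.get("t0", 0.0),
                horizon=p.get("horizon", 31.0),
            )
    return out
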