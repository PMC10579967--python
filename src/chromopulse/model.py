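"""TF input function, deterministic right-hand side, and steady states.

The deterministic model for one gene follows a three-state chromatin cycle
with mRNA and protein::

    dC/dt   = k2*OU - k1*TF*C
    dOU/dt  = k1*TF*C - k2*OU - k3*TF*OU + k4*OI
    dOI/dt  = k3*TF*OU - k4*OI
    dM/dt   = k5*OI - deltaM*M
    dP/dt   = k6*M - deltaP*P

with TF = tanh(alpha*(ifng + Kd)) without adaptation.  With adaptation two
regulator species are integrated alongside::

    dregM/dt = a_regM * TF^c2 / (1 + TF^c2) - delta_regM*regM
    dregP/dt = a_regP*regM - delta_regP*regP

and the TF becomes tanh(alpha*(ifng + Kd)) / (1 + (regP/reg_thr)^c1), a
negative feedback that makes the TF rise and then relax toward a lower
plateau under sustained stimulus.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import AdaptationParams, GeneKinetics, ModelState, StimulusProtocol

__all__ = ["tf_level", "ode_rhs", "steady_state_chromatin", "equilibrate", "steady_state"]


def tf_level(
    ifng: float,
    kin: GeneKinetics,
    adapt: AdaptationParams | None = None,
    regP: float = 0.0,
):
    """Dimensionless TF activity at stimulus ``ifng`` and regulator level ``regP``.

    Returns tanh(alpha*(ifng+Kd)), divided by 1 + (regP/reg_thr)^c1 when
    adaptation is enabled.  Monotone nondecreasing in ``ifng`` and
    nonincreasing in ``regP``.  Accepts scalars or arrays.
    """
    ifng = np.asarray(ifng, dtype=float)
    regP = np.asarray(regP, dtype=float)
    if np.any(ifng < 0):
        raise ValueError("ifng must be >= 0")
    if np.any(regP < 0):
        raise ValueError("regP must be >= 0")
    base = np.tanh(kin.alpha * (ifng + kin.Kd))
    if adapt is not None and adapt.enabled:
        base = base / (1.0 + (regP / adapt.reg_thr) ** adapt.c1)
    if base.ndim == 0:
        return float(base)
    return base


def _reg_production(tf: float, adapt: AdaptationParams) -> float:
    """Saturating regulator-mRNA production a_regM * TF^c2 / (1 + TF^c2)."""
    if tf <= 0.0:
        return 0.0
    h = tf**adapt.c2
    return adapt.a_regM * h / (1.0 + h)


def ode_rhs(
    t: float,
    state: np.ndarray,
    kin: GeneKinetics,
    adapt: AdaptationParams,
    protocol: StimulusProtocol,
) -> np.ndarray:
    """Time derivative of the 7-component state (C, OU, OI, M, P, regM, regP).

    The regulator derivatives are identically zero when adaptation is
    disabled; the chromatin derivatives always sum to zero.
    """
    C, OU, OI, M, P, regM, regP = state
    ifng = protocol.ifng_at(t)
    tf = tf_level(ifng, kin, adapt, max(regP, 0.0))
    open_flux = kin.k1 * tf * C - kin.k2 * OU
    init_flux = kin.k3 * tf * OU - kin.k4 * OI
    dC = -open_flux
    dOU = open_flux - init_flux
    dOI = init_flux
    dM = kin.k5 * OI - kin.deltaM * M
    dP = kin.k6 * M - kin.deltaP * P
    if adapt.enabled:
        dregM = _reg_production(tf, adapt) - adapt.delta_regM * regM
        dregP = adapt.a_regP * regM - adapt.delta_regP * regP
    else:
        dregM = 0.0
        dregP = 0.0
    return np.array([dC, dOU, dOI, dM, dP, dregM, dregP])


def steady_state_chromatin(kin: GeneKinetics, tf: float) -> tuple[float, float, float]:
    """Stationary chromatin occupancies (C, OU, OI) at constant TF activity.

    Detailed balance of the linear chain gives OU/C = k1*tf/k2 and
    OI/OU = k3*tf/k4, normalised to ``n_loci``.  At tf = 0 (or a degenerate
    chain with no return rates) all loci are closed.
    """
    if tf < 0:
        raise ValueError("tf must be >= 0")
    n = float(kin.n_loci)
    if tf == 0.0:
        return (n, 0.0, 0.0)
    # ratios; handle k2/k4 == 0 (absorbing open/initiated states)
    if kin.k2 == 0.0:
        if kin.k1 * tf > 0:
            if kin.k4 == 0.0:
                return (0.0, 0.0, n) if kin.k3 * tf > 0 else (0.0, n, 0.0)
            r2 = kin.k3 * tf / kin.k4
            return (0.0, n / (1 + r2), n * r2 / (1 + r2))
        return (n, 0.0, 0.0)
    r1 = kin.k1 * tf / kin.k2
    if kin.k4 == 0.0:
        return (0.0, 0.0, n) if kin.k3 * tf > 0 else (n / (1 + r1), n * r1 / (1 + r1), 0.0)
    r2 = kin.k3 * tf / kin.k4
    z = 1.0 + r1 + r1 * r2
    return (n / z, n * r1 / z, n * r1 * r2 / z)


def steady_state(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    ifng: float,
) -> ModelState:
    """Full steady state under a constant stimulus, solved algebraically.

    Without adaptation the TF is fixed and every species has a closed form.
    With adaptation the self-consistent TF solves the scalar fixed-point
    equation TF = base / (1 + (regP*(TF)/reg_thr)^c1), which is monotone and
    therefore has a unique root found by bisection.
    """
    if ifng < 0:
        raise ValueError("ifng must be >= 0")
    base = np.tanh(kin.alpha * (ifng + kin.Kd))

    def reg_p_star(tf: float) -> float:
        regM = _reg_production(tf, adapt) / adapt.delta_regM
        return adapt.a_regP * regM / adapt.delta_regP

    if adapt.enabled and base > 0.0:
        def resid(tf: float) -> float:
            return tf * (1.0 + (reg_p_star(tf) / adapt.reg_thr) ** adapt.c1) - base

        # resid(0) = -base < 0, resid(base) >= 0; root in (0, base]
        tf = brentq(resid, 0.0, base, xtol=1e-14, rtol=8.9e-16)
        regM = _reg_production(tf, adapt) / adapt.delta_regM
        regP = adapt.a_regP * regM / adapt.delta_regP
    else:
        tf = float(base)
        regM = 0.0
        regP = 0.0
    C, OU, OI = steady_state_chromatin(kin, tf)
    M = kin.k5 * OI / kin.deltaM if kin.deltaM > 0 else 0.0
    P = kin.k6 * M / kin.deltaP if kin.deltaP > 0 else 0.0
    return ModelState(C, OU, OI, M, P, regM, regP)


def equilibrate(
    kin: GeneKinetics,
    adapt: AdaptationParams,
    ifng_basal: float = 0.0,
    tol: float = 1e-9,
) -> ModelState:
    """Pre-stimulus resting state under constant basal stimulus.

    Uses the algebraic steady state and verifies that the ODE residual at the
    returned state is below ``tol`` (relative to the fastest rate).
    """
    st = steady_state(kin, adapt, ifng_basal)
    proto = StimulusProtocol.constant(ifng_basal, horizon=1.0)
    resid = ode_rhs(0.0, st.to_array(), kin, adapt, proto)
    scale = 1.0 + np.abs(st.to_array()).max()
    if np.abs(resid).max() > max(tol * scale, 1e-7):
        raise RuntimeError(
            f"equilibrate: residual {np.abs(resid).max():.3g} above tolerance"
        )
    return st
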