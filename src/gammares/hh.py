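"""Hodgkin-Huxley channel kinetics and membrane right-hand side.

The Na and K channels use the classical squid-axon rate functions in the
modern voltage convention (resting potential near -65 mV), displaced
along the voltage axis so that the complete membrane -- leak plus the
sodium window current plus the steady-state potassium current, with the
conductance maxima G_Na = 120 mS/cm^2 and G_K = 36 mS/cm^2 -- rests at
the leak reversal of -70 mV.  A single common displacement cannot do
this (the steady-state K current at -70 mV always exceeds the Na window
current), so the two channels are shifted independently: +5 mV for Na,
which puts the firing threshold near -55 mV, and +12.5814 mV for K,
solved so that the net steady-state current vanishes at -70 mV exactly.

Everything here is plain vectorised numpy; the production integrator in
:mod:`gammares.engine` samples these functions into lookup tables.
Units: mV, ms, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import numpy as np

from .params import NeuronParameters


def _exprel_inv(x):
    """x / (1 - exp(-x)) with its removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, safe / (1.0 - np.exp(-safe)))


def rate_constants(v, params: NeuronParameters):
    """Gating rate constants (1/ms) at membrane potential ``v`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.
    """
    u = np.asarray(v, dtype=float) - params.na_kinetics_shift
    w = np.asarray(v, dtype=float) - params.k_kinetics_shift
    alpha_m = _exprel_inv((u + 40.0) / 10.0)
    beta_m = 4.0 * np.exp(-(u + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(u + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
    alpha_n = 0.1 * _exprel_inv((w + 55.0) / 10.0)
    beta_n = 0.125 * np.exp(-(w + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_state_gating(v, params: NeuronParameters):
    """Equilibrium gating values (m_inf, h_inf, n_inf) at potential ``v``."""
    am, bm, ah, bh, an, bn = rate_constants(v, params)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def gating_time_constants(v, params: NeuronParameters):
    """Gating relaxation times (tau_m, tau_h, tau_n) in ms at ``v``."""
    am, bm, ah, bh, an, bn = rate_constants(v, params)
    return 1.0 / (am + bm), 1.0 / (ah + bh), 1.0 / (an + bn)


def membrane_currents(v, m, h, n, g_exc, g_inh, params: NeuronParameters):
    """Total membrane current density (uA/cm^2, outward positive)."""
    g_l = 1e3 * params.leak_conductance  # S/cm^2 -> mS/cm^2
    g_na = 1e3 * params.na_max_conductance * m**3 * h
    g_k = 1e3 * params.k_max_conductance * n**4
    return (
        g_l * (v - params.leak_reversal)
        + g_na * (v - params.na_reversal)
        + g_k * (v - params.k_reversal)
        + g_exc * (v - params.exc_reversal)
        + g_inh * (v - params.inh_reversal)
    )


def membrane_derivatives(state, params: NeuronParameters, g_exc, g_inh):
    """Time derivatives of the membrane state.

    ``state`` is a dict with per-neuron arrays ``V`` (mV) and gating
    variables ``m``, ``h``, ``n``; ``g_exc``/``g_inh`` are the total
    excitatory (recurrent + feedforward) and inhibitory synaptic
    conductances in mS/cm^2.  Returns a dict of derivatives (mV/ms and
    1/ms).  Raising g_exc strictly increases dV/dt whenever V < V_E, and
    raising g_inh strictly decreases it whenever V > V_I.
    """
    v = np.atleast_1d(np.asarray(state["V"], dtype=float))
    m = np.atleast_1d(np.asarray(state["m"], dtype=float))
    h = np.atleast_1d(np.asarray(state["h"], dtype=float))
    n = np.atleast_1d(np.asarray(state["n"], dtype=float))
    g_exc = np.atleast_1d(np.asarray(g_exc, dtype=float))
    g_inh = np.atleast_1d(np.asarray(g_inh, dtype=float))
    for name, arr in (("V", v), ("m", m), ("h", h), ("n", n)):
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise FloatingPointError(
                f"non-finite membrane state {name!r} at neuron index {bad}"
            )
    if np.any(g_exc < 0) or np.any(g_inh < 0):
        raise ValueError("synaptic conductances must be non-negative")

    c = 1e6 * params.membrane_capacitance  # F/cm^2 -> uF/cm^2
    i_total = membrane_currents(v, m, h, n, g_exc, g_inh, params)
    am, bm, ah, bh, an, bn = rate_constants(v, params)
    return {
        "V": -i_total / c,
        "m": am * (1.0 - m) - bm * m,
        "h": ah * (1.0 - h) - bh * h,
        "n": an * (1.0 - n) - bn * n,
    }


def resting_state(params: NeuronParameters, n_neurons: int = 1):
    """Membrane state at the resting potential (gating at equilibrium)."""
    v = params.leak_reversal
    m, h, n = steady_state_gating(v, params)
    ones = np.ones(n_neurons)
    return {"V": v * ones, "m": m * ones, "h": h * ones, "n": n * ones}


def build_gating_tables(params: NeuronParameters, dt: float,
                        v_min: float = -120.0, v_max: float = 60.0,
                        dv: float = 0.01):
    """Sample gating steady states and per-step decay factors on a V grid.

    Returns ``(v_min, inv_dv, table)`` where ``table`` has shape
    ``(n_points, 6)`` with columns ``m_inf, exp(-dt/tau_m), h_inf,
    exp(-dt/tau_h), n_inf, exp(-dt/tau_n)``.  Used by the exponential-
    Euler integrator; linear interpolation on a 0.01 mV grid is accurate
    to well below the integrator's own truncation error.
    """
    grid = np.arange(v_min, v_max + dv / 2, dv)
    m_inf, h_inf, n_inf = steady_state_gating(grid, params)
    tau_m, tau_h, tau_n = gating_time_constants(grid, params)
    table = np.empty((grid.size, 6))
    table[:, 0] = m_inf
    table[:, 1] = np.exp(-dt / tau_m)
    table[:, 2] = h_inf
    table[:, 3] = np.exp(-dt / tau_h)
    table[:, 4] = n_inf
    table[:, 5] = np.exp(-dt / tau_n)
    return v_min, 1.0 / dv, table
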