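"""Adaptive exponential integrate-and-fire (AdEx) granule-cell model.

Membrane equation (units: mV, ms, nS, pF, pA):

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
              - g_AMPA(t) (V - E_exc) - g_NMDA(t) * u(V) * (V - E_exc)
              - g_tonic (V - E_inh) - w + I_inj
    tau_w dw/dt = a (V - E_L) - w

where u(V) is the NMDA Mg-unblock sigmoid.  When V crosses the spike
cutoff, a spike is recorded, V is reset to V_r, w is incremented by b, and
integration of V is suspended for the absolute refractory period.

Integration is forward Euler at a fixed step (default 50 us).  The core
integrator is vectorized over an arbitrary number of independent traces
(cells x runs x conditions) sharing one parameter set, which is what makes
the network simulations tractable; `simulate_gc` is the single-trace
wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stimulus import SpikeTrain
from .synapse import ConductanceTrainPair, MgBlockParams

__all__ = [
    "GCModelParams",
    "SimConfig",
    "simulate_gc",
    "simulate_gc_multi",
    "simulate_current_steps",
    "detect_spikes",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GCModelParams:
    """AdEx parameters for one condition (defaults: generic granule cell)."""

    capacitance: float = 3.0          # pF
    leak_conductance: float = 0.7     # nS
    leak_reversal: float = -80.0      # mV (E_L)
    threshold_slope: float = 2.0      # mV (Delta_T)
    rheobase_threshold: float = -46.0  # mV (V_T)
    adaptation_coupling: float = 0.1  # nS (a)
    spike_triggered_adaptation: float = 3.0  # pA (b)
    adaptation_tau: float = 100.0     # ms (tau_w)
    reset_potential: float = -78.0    # mV (V_r)
    spike_cutoff: float = 0.0         # mV
    refractory: float = 1.5           # ms
    tonic_inhibition: float = 0.45    # nS (g_tonic)
    inhibitory_reversal: float = -75.0  # mV (E_inh)
    excitatory_reversal: float = 0.0  # mV (E_exc)

    def __post_init__(self):
        if min(self.capacitance, self.leak_conductance, self.adaptation_tau) <= 0:
            raise ValueError("capacitance, leak conductance, tau_w must be > 0")
        if self.tonic_inhibition < 0:
            raise ValueError("tonic inhibition must be >= 0")
        if self.reset_potential >= self.spike_cutoff:
            raise ValueError("reset potential must be below the spike cutoff")

    def with_tonic_delta(self, delta_nS: float) -> "GCModelParams":
        """Shift the tonic inhibitory conductance, floored at zero."""
        return replace(self, tonic_inhibition=max(0.0, self.tonic_inhibition + delta_nS))


@dataclass(frozen=True)
class SimConfig:
    dt: float = 5e-5          # s
    duration: float = 1.0     # s
    initial_V: float = -80.0  # mV
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def simulate_gc_multi(model: GCModelParams,
                      g_ampa: np.ndarray, g_nmda: np.ndarray,
                      injected_current, cfg: SimConfig,
                      mg: MgBlockParams = MgBlockParams(),
                      record_v: bool = False):
    """Integrate many independent traces that share one parameter set.

    g_ampa, g_nmda: (n_traces, n_steps) conductance arrays in nS.
    injected_current: scalar or (n_traces,) in pA.

    Returns (V, spikes) where V is the (n_traces, n_steps) voltage array if
    ``record_v`` else None, and spikes is a list of per-trace spike-time
    arrays (seconds, threshold-crossing sample convention).
    """
    g_ampa = np.atleast_2d(np.asarray(g_ampa, dtype=float))
    g_nmda = np.atleast_2d(np.asarray(g_nmda, dtype=float))
    n_traces, n_steps = g_ampa.shape
    if g_nmda.shape != g_ampa.shape:
        raise ValueError("conductance arrays must have identical shape")
    if n_steps < cfg.n_steps:
        raise ValueError("drive does not cover the simulated duration")
    n_steps = cfg.n_steps

    dt_ms = cfg.dt * 1e3
    I = np.broadcast_to(np.asarray(injected_current, dtype=float), (n_traces,)).copy()

    V = np.full(n_traces, cfg.initial_V)
    w = np.zeros(n_traces)
    refrac_left = np.zeros(n_traces, dtype=np.int64)
    refrac_steps = max(1, int(round(model.refractory / dt_ms)))

    mg_ratio = mg.mg_concentration / mg.half_block_concentration
    inv_slope = 1.0 / mg.voltage_slope
    C = model.capacitance
    gL = model.leak_conductance
    EL = model.leak_reversal
    DT = model.threshold_slope
    VT = model.rheobase_threshold
    a = model.adaptation_coupling
    b = model.spike_triggered_adaptation
    tw = model.adaptation_tau
    Vr = model.reset_potential
    Vcut = model.spike_cutoff
    gt = model.tonic_inhibition
    Ei = model.inhibitory_reversal
    Ee = model.excitatory_reversal

    V_out = np.empty((n_traces, n_steps)) if record_v else None
    spike_steps: list[list] = [[] for _ in range(n_traces)]

    for step in range(n_steps):
        unblock = 1.0 / (1.0 + mg_ratio * np.exp(-V * inv_slope))
        # exponential spike-initiation term, clipped to avoid overflow
        exp_arg = np.minimum((V - VT) / DT, (Vcut - VT) / DT + 5.0)
        I_ion = (-gL * (V - EL) + gL * DT * np.exp(exp_arg)
                 - g_ampa[:, step] * (V - Ee)
                 - g_nmda[:, step] * unblock * (V - Ee)
                 - gt * (V - Ei) - w + I)
        dV = dt_ms * I_ion / C
        dw = dt_ms * (a * (V - EL) - w) / tw

        active = refrac_left == 0
        V = np.where(active, V + dV, Vr)
        w = w + dw
        refrac_left = np.maximum(refrac_left - 1, 0)

        crossed = active & (V >= Vcut)
        if np.any(crossed):
            idx = np.nonzero(crossed)[0]
            for i in idx:
                spike_steps[i].append(step)
            V[crossed] = Vr
            w[crossed] += b
            refrac_left[crossed] = refrac_steps
        if record_v:
            V_out[:, step] = np.where(crossed, Vcut, V)
        if not np.all(np.isfinite(V)):
            raise IntegrationError(f"non-finite membrane potential at step {step}")

    spikes = [np.asarray(s, dtype=float) * cfg.dt for s in spike_steps]
    return V_out, spikes


def simulate_gc(model: GCModelParams, drive: ConductanceTrainPair,
                mg: MgBlockParams = MgBlockParams(),
                injected_current: float = 0.0,
                cfg: SimConfig = SimConfig()) -> tuple[np.ndarray, SpikeTrain]:
    """Single-cell simulation; returns the voltage trace (mV) and spikes."""
    if abs(drive.dt - cfg.dt) > 1e-12:
        raise ValueError("drive.dt must equal the simulation step")
    V, spikes = simulate_gc_multi(model, drive.g_ampa[None, :],
                                  drive.g_nmda[None, :], injected_current,
                                  cfg, mg, record_v=True)
    return V[0], SpikeTrain(spikes[0], cfg.duration, "gc")


def simulate_current_steps(model: GCModelParams, amplitudes_pA,
                           step_duration: float = 0.2,
                           dt: float = 5e-5,
                           initial_V: float = -80.0) -> "pd.DataFrame":
    """Frequency-current (f-I) curve from tonic current injections.

    Firing frequency is spike count over the full step duration, matching
    the experimental protocol (200 ms steps, counts over the whole step).
    """
    import pandas as pd

    amplitudes = np.asarray(amplitudes_pA, dtype=float)
    if np.any(np.diff(amplitudes) < 0):
        raise ValueError("amplitudes must be sorted ascending")
    cfg = SimConfig(dt=dt, duration=step_duration, initial_V=initial_V)
    zeros = np.zeros((amplitudes.size, cfg.n_steps))
    _, spikes = simulate_gc_multi(model, zeros, zeros, amplitudes, cfg)
    freq = np.array([len(s) for s in spikes]) / step_duration
    return pd.DataFrame({"current_pA": amplitudes, "frequency_Hz": freq})


def detect_spikes(voltage_mV: np.ndarray, dt: float,
                  threshold: float = -20.0,
                  duration: float | None = None) -> SpikeTrain:
    """Spike times from a sampled voltage trace: upward threshold crossings.

    The event time is the first sample at/above threshold (>= comparison),
    so a trace that exactly grazes the threshold counts once.
    """
    v = np.asarray(voltage_mV, dtype=float)
    above = v >= threshold
    crossings = np.nonzero(above & ~np.concatenate(([False], above[:-1])))[0]
    if duration is None:
        duration = v.size * dt
    return SpikeTrain(crossings * dt, duration, "detected")
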