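"""Unitary AMPA/NMDA conductances, short-term plasticity, and train fitting.

The mossy-fiber -> granule-cell synaptic conductance is modelled as the sum
of a fast *direct* AMPA component (release into the cleft), a slower
*spillover* AMPA component (glutamate diffusing from neighbouring release
sites), and an NMDA component gated by voltage-dependent Mg block.  Each
unitary waveform is a product of an exponential rise and a (possibly
multi-component) exponential decay, normalized to its peak amplitude:

    g(t) = A * c * (1 - exp(-t/tau_rise)) * sum_k f_k exp(-t/tau_decay_k)

with c chosen so max_t g(t) = A.  Short-term depression follows an R*P
scheme: the response to spike i is proportional to R_i * P_i, with resources
R depleted by the released fraction at each spike and recovering
exponentially toward 1, and (optionally) release probability P facilitating
transiently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit

from .stimulus import SpikeTrain, generate_regular_train

__all__ = [
    "KineticScheme",
    "STPParams",
    "MgBlockParams",
    "ConductanceTrainPair",
    "SynapseParams",
    "unitary_conductance",
    "stp_factors",
    "mg_block_fraction",
    "build_conductance_trains",
    "fit_conductance_model",
    "fine_tune_stp",
]


@dataclass(frozen=True)
class KineticScheme:
    """One unitary conductance component (times in ms, amplitude in nS)."""

    peak_amplitude: float
    rise_tau: float
    decay_taus: tuple[float, ...]
    decay_fractions: tuple[float, ...] = (1.0,)
    component: str = "direct"

    def __post_init__(self):
        object.__setattr__(self, "decay_taus", tuple(float(t) for t in np.atleast_1d(self.decay_taus)))
        object.__setattr__(self, "decay_fractions", tuple(float(f) for f in np.atleast_1d(self.decay_fractions)))
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.rise_tau <= 0 or any(t <= 0 for t in self.decay_taus):
            raise ValueError("time constants must be > 0")
        if len(self.decay_taus) != len(self.decay_fractions):
            raise ValueError("decay_taus and decay_fractions length mismatch")
        if any(f < 0 or f > 1 for f in self.decay_fractions):
            raise ValueError("decay fractions must lie in [0, 1]")
        if abs(sum(self.decay_fractions) - 1.0) > 1e-9:
            raise ValueError("decay fractions must sum to 1")

    def scaled(self, factor: float) -> "KineticScheme":
        """Same kinetics with the peak amplitude multiplied by ``factor``."""
        return replace(self, peak_amplitude=self.peak_amplitude * factor)


@dataclass(frozen=True)
class STPParams:
    """R*P short-term plasticity (times in ms)."""

    release_fraction: float  # P, fraction of resources released per spike
    recovery_tau: float      # resource recovery time constant
    facilitation_increment: float = 0.0
    facilitation_tau: float = 50.0

    def __post_init__(self):
        if not (0.0 < self.release_fraction <= 1.0):
            raise ValueError("release_fraction must be in (0, 1]")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be > 0")
        if self.facilitation_increment < 0:
            raise ValueError("facilitation_increment must be >= 0")


@dataclass(frozen=True)
class MgBlockParams:
    """Sigmoid voltage dependence of NMDA-receptor Mg unblock.

    unblock(V) = 1 / (1 + ([Mg]/K_half) * exp(-V / slope))
    """

    mg_concentration: float = 1.0      # mM
    half_block_concentration: float = 3.57  # mM
    voltage_slope: float = 16.1        # mV

    def __post_init__(self):
        if min(self.mg_concentration, self.half_block_concentration,
               self.voltage_slope) <= 0:
            raise ValueError("Mg-block parameters must be positive")


@dataclass
class ConductanceTrainPair:
    """Sampled AMPA and (pre-Mg-block) NMDA conductance series in nS."""

    dt: float
    g_ampa: np.ndarray
    g_nmda: np.ndarray

    def __post_init__(self):
        self.g_ampa = np.asarray(self.g_ampa, dtype=float)
        self.g_nmda = np.asarray(self.g_nmda, dtype=float)
        if self.g_ampa.shape != self.g_nmda.shape:
            raise ValueError("g_ampa and g_nmda must have the same shape")
        if np.any(self.g_ampa < 0) or np.any(self.g_nmda < 0):
            raise ValueError("conductances must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.g_ampa.shape[-1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def scaled(self, ampa_scale: float, nmda_scale: float) -> "ConductanceTrainPair":
        return ConductanceTrainPair(self.dt, self.g_ampa * ampa_scale,
                                    self.g_nmda * nmda_scale)


@dataclass(frozen=True)
class SynapseParams:
    """Full synaptic parameter bundle for one genotype."""

    ampa_direct: KineticScheme
    ampa_spillover: KineticScheme
    nmda: KineticScheme
    stp_ampa: STPParams
    stp_nmda: STPParams
    mg: MgBlockParams = MgBlockParams()

    def scaled(self, ampa_scale: float, nmda_scale: float) -> "SynapseParams":
        """Rescale unitary amplitudes (the KO contract: AMPA x0.2, NMDA x1.2)."""
        return replace(
            self,
            ampa_direct=self.ampa_direct.scaled(ampa_scale),
            ampa_spillover=self.ampa_spillover.scaled(ampa_scale),
            nmda=self.nmda.scaled(nmda_scale),
        )


def _shape(scheme: KineticScheme, t_ms: np.ndarray) -> np.ndarray:
    """Unnormalized rise*decay waveform evaluated at t (ms); 0 for t < 0."""
    t = np.maximum(t_ms, 0.0)
    decay = np.zeros_like(t)
    for f, tau in zip(scheme.decay_fractions, scheme.decay_taus):
        decay += f * np.exp(-t / tau)
    out = (1.0 - np.exp(-t / scheme.rise_tau)) * decay
    out[t_ms < 0] = 0.0
    return out


def _peak_value(scheme: KineticScheme) -> float:
    """Maximum of the unnormalized shape, via dense grid + parabolic refine."""
    t_end = 5.0 * (scheme.rise_tau + max(scheme.decay_taus))
    t = np.linspace(0.0, t_end, 4001)
    s = _shape(scheme, t)
    i = int(np.argmax(s))
    if 0 < i < len(t) - 1:
        # one parabolic interpolation step around the grid maximum
        y0, y1, y2 = s[i - 1], s[i], s[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            dt = t[1] - t[0]
            t_pk = t[i] + 0.5 * dt * (y0 - y2) / denom
            return float(max(y1, _shape(scheme, np.array([t_pk]))[0]))
    return float(s[i])


def unitary_conductance(scheme: KineticScheme, time_grid_s: np.ndarray) -> np.ndarray:
    """Unitary conductance waveform (nS) on a uniform time grid in seconds.

    Zero at t = 0, normalized so the waveform's maximum equals the scheme's
    peak amplitude.
    """
    time_grid_s = np.asarray(time_grid_s, dtype=float)
    if scheme.peak_amplitude == 0:
        return np.zeros_like(time_grid_s)
    peak = _peak_value(scheme)
    return scheme.peak_amplitude / peak * _shape(scheme, time_grid_s * 1e3)


def unitary_integral(scheme: KineticScheme) -> float:
    """Closed-form time integral (nS*ms) of the normalized unitary waveform.

    Expanding rise*decay into a sum of exponentials:
    integral = c * sum_k f_k * (tau_dk - 1/(1/tau_dk + 1/tau_r)).
    """
    if scheme.peak_amplitude == 0:
        return 0.0
    c = scheme.peak_amplitude / _peak_value(scheme)
    total = 0.0
    for f, tau in zip(scheme.decay_fractions, scheme.decay_taus):
        total += f * (tau - 1.0 / (1.0 / tau + 1.0 / scheme.rise_tau))
    return c * total


def stp_factors(stp: STPParams, spike_times_s: np.ndarray) -> np.ndarray:
    """Per-spike amplitude scale factors of the R*P scheme (first spike = 1).

    Resources R start at 1 and are depleted by the released fraction at each
    spike, recovering exponentially toward 1 with ``recovery_tau`` between
    spikes.  With facilitation enabled, the effective release probability is
    incremented after each spike and decays back to baseline.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be ordered")
    P = stp.release_fraction
    R, p_eff = 1.0, P
    factors = np.empty(t.size)
    for i in range(t.size):
        if i > 0:
            dt_ms = (t[i] - t[i - 1]) * 1e3
            R = 1.0 - (1.0 - R) * math.exp(-dt_ms / stp.recovery_tau)
            p_eff = P + (p_eff - P) * math.exp(-dt_ms / stp.facilitation_tau)
        factors[i] = R * p_eff / P
        R *= (1.0 - p_eff)
        if stp.facilitation_increment > 0:
            p_eff = min(1.0, p_eff + stp.facilitation_increment * (1.0 - p_eff))
    return factors


def mg_block_fraction(V_mV, params: MgBlockParams = MgBlockParams()):
    """Fraction of NMDA conductance unblocked at membrane potential V (mV)."""
    V = np.asarray(V_mV, dtype=float)
    ratio = params.mg_concentration / params.half_block_concentration
    out = 1.0 / (1.0 + ratio * np.exp(-V / params.voltage_slope))
    return out if out.ndim else float(out)


def _superpose(kernel: np.ndarray, spike_idx: np.ndarray,
               factors: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    klen = kernel.size
    for idx, fac in zip(spike_idx, factors):
        if idx >= n:
            continue
        m = min(klen, n - idx)
        out[idx:idx + m] += fac * kernel[:m]
    return out


def build_conductance_trains(params: SynapseParams, presyn: SpikeTrain,
                             dt: float, duration: float | None = None,
                             ) -> ConductanceTrainPair:
    """Superpose STP-scaled unitary waveforms at each presynaptic spike.

    AMPA = direct + spillover, both scaled by the same per-spike depression
    factors (one presynaptic release process); NMDA uses its own STP.  The
    returned NMDA series is pre-Mg-block.
    """
    if duration is None:
        duration = presyn.duration
    n = int(round(duration / dt))
    t_grid = np.arange(n) * dt
    idx = np.round(presyn.times / dt).astype(int)
    fac_ampa = stp_factors(params.stp_ampa, presyn.times)
    fac_nmda = stp_factors(params.stp_nmda, presyn.times)

    def kernel(scheme: KineticScheme) -> np.ndarray:
        # truncate at 10 decay time constants (relative tail < 5e-5)
        k_dur = min(duration, (scheme.rise_tau + 10.0 * max(scheme.decay_taus)) * 1e-3)
        k_n = int(round(k_dur / dt))
        return unitary_conductance(scheme, t_grid[:k_n])

    g_ampa = (_superpose(kernel(params.ampa_direct), idx, fac_ampa, n)
              + _superpose(kernel(params.ampa_spillover), idx, fac_ampa, n))
    g_nmda = _superpose(kernel(params.nmda), idx, fac_nmda, n)
    return ConductanceTrainPair(dt, g_ampa, g_nmda)


# ---------------------------------------------------------------------------
# fitting


class FitNotConverged(RuntimeError):
    """Raised/flagged when the optimizer reports failure."""


@dataclass
class ConductanceFitResult:
    params: SynapseParams
    residual_norm: float
    success: bool
    message: str = ""


def _params_from_lmfit(p: lmfit.Parameters, template: SynapseParams) -> SynapseParams:
    def upd(scheme: KineticScheme, prefix: str) -> KineticScheme:
        return replace(scheme,
                       peak_amplitude=p[f"{prefix}_amp"].value,
                       rise_tau=p[f"{prefix}_rise"].value,
                       decay_taus=tuple(p[f"{prefix}_dec{k}"].value
                                        for k in range(len(scheme.decay_taus))))
    return replace(template,
                   ampa_direct=upd(template.ampa_direct, "dir"),
                   ampa_spillover=upd(template.ampa_spillover, "spill"),
                   nmda=upd(template.nmda, "nmda"),
                   stp_ampa=replace(template.stp_ampa,
                                    release_fraction=p["P_ampa"].value,
                                    recovery_tau=p["rec_ampa"].value),
                   stp_nmda=replace(template.stp_nmda,
                                    release_fraction=p["P_nmda"].value,
                                    recovery_tau=p["rec_nmda"].value))


def _add_scheme_params(p: lmfit.Parameters, scheme: KineticScheme,
                       prefix: str, vary_kinetics: bool = True) -> None:
    p.add(f"{prefix}_amp", value=max(scheme.peak_amplitude, 1e-4), min=0.0,
          max=50.0)
    p.add(f"{prefix}_rise", value=scheme.rise_tau, min=0.02, max=20.0,
          vary=vary_kinetics)
    for k, tau in enumerate(scheme.decay_taus):
        p.add(f"{prefix}_dec{k}", value=tau, min=0.05, max=500.0,
              vary=vary_kinetics)


def fit_conductance_model(target: ConductanceTrainPair,
                          initial_guess: SynapseParams,
                          presyn: SpikeTrain | None = None,
                          vary_stp: bool = True) -> ConductanceFitResult:
    """Least-squares fit of the synapse model to a target conductance train.

    Fits the component amplitudes, rise and decay time constants (decay
    fractions are held at the initial guess), and optionally the STP
    parameters, minimizing the summed squared residual over both the AMPA
    and NMDA series.  Deterministic given the initial guess.
    """
    if not (np.all(np.isfinite(target.g_ampa)) and np.all(np.isfinite(target.g_nmda))):
        raise ValueError("target contains non-finite samples")
    if presyn is None:
        presyn = generate_regular_train(20, 100.0,
                                        duration=target.n_samples * target.dt)
    if not (target.g_ampa.any() or target.g_nmda.any()):
        zero = initial_guess.scaled(0.0, 0.0)
        return ConductanceFitResult(zero, 0.0, True, "all-zero target")

    p = lmfit.Parameters()
    _add_scheme_params(p, initial_guess.ampa_direct, "dir")
    _add_scheme_params(p, initial_guess.ampa_spillover, "spill")
    _add_scheme_params(p, initial_guess.nmda, "nmda")
    p.add("P_ampa", value=initial_guess.stp_ampa.release_fraction,
          min=0.01, max=1.0, vary=vary_stp)
    p.add("rec_ampa", value=initial_guess.stp_ampa.recovery_tau,
          min=1.0, max=5000.0, vary=vary_stp)
    p.add("P_nmda", value=initial_guess.stp_nmda.release_fraction,
          min=0.01, max=1.0, vary=vary_stp)
    p.add("rec_nmda", value=initial_guess.stp_nmda.recovery_tau,
          min=1.0, max=5000.0, vary=vary_stp)

    duration = target.n_samples * target.dt

    def residual(pars):
        model = build_conductance_trains(_params_from_lmfit(pars, initial_guess),
                                         presyn, target.dt, duration)
        return np.concatenate([model.g_ampa - target.g_ampa,
                               model.g_nmda - target.g_nmda])

    out = lmfit.minimize(residual, p, method="least_squares")
    fitted = _params_from_lmfit(out.params, initial_guess)
    norm = float(np.sqrt(np.sum(out.residual ** 2)))
    return ConductanceFitResult(fitted, norm, bool(out.success),
                                out.message if not out.success else "")


def fine_tune_stp(params: SynapseParams,
                  target_100: ConductanceTrainPair,
                  target_300: ConductanceTrainPair,
                  presyn_100: SpikeTrain | None = None,
                  presyn_300: SpikeTrain | None = None) -> ConductanceFitResult:
    """Refit only the STP parameters jointly on 100 Hz and 300 Hz targets.

    Kinetic parameters (amplitudes, time constants) are held fixed; the
    depression scheme must explain both stimulation frequencies at once.
    """
    if presyn_100 is None:
        presyn_100 = generate_regular_train(
            20, 100.0, duration=target_100.n_samples * target_100.dt)
    if presyn_300 is None:
        presyn_300 = generate_regular_train(
            10, 300.0, duration=target_300.n_samples * target_300.dt)

    p = lmfit.Parameters()
    p.add("P_ampa", value=params.stp_ampa.release_fraction, min=0.01, max=1.0)
    p.add("rec_ampa", value=params.stp_ampa.recovery_tau, min=1.0, max=5000.0)
    p.add("P_nmda", value=params.stp_nmda.release_fraction, min=0.01, max=1.0)
    p.add("rec_nmda", value=params.stp_nmda.recovery_tau, min=1.0, max=5000.0)

    def with_stp(pars) -> SynapseParams:
        return replace(params,
                       stp_ampa=replace(params.stp_ampa,
                                        release_fraction=pars["P_ampa"].value,
                                        recovery_tau=pars["rec_ampa"].value),
                       stp_nmda=replace(params.stp_nmda,
                                        release_fraction=pars["P_nmda"].value,
                                        recovery_tau=pars["rec_nmda"].value))

    def residual(pars):
        m100 = build_conductance_trains(with_stp(pars), presyn_100, target_100.dt,
                                        target_100.n_samples * target_100.dt)
        m300 = build_conductance_trains(with_stp(pars), presyn_300, target_300.dt,
                                        target_300.n_samples * target_300.dt)
        return np.concatenate([m100.g_ampa - target_100.g_ampa,
                               m100.g_nmda - target_100.g_nmda,
                               m300.g_ampa - target_300.g_ampa,
                               m300.g_nmda - target_300.g_nmda])

    out = lmfit.minimize(residual, p, method="least_squares")
    fitted = with_stp(out.params)
    norm = float(np.sqrt(np.sum(out.residual ** 2)))
    return ConductanceFitResult(fitted, norm, bool(out.success),
                                out.message if not out.success else "")
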