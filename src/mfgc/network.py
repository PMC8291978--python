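"""Feedforward mossy-fiber -> granule-cell network model.

Anatomy-constrained geometry: 187 MF terminals and 487 GCs placed uniformly
at random inside a sphere of 80 um diameter, each GC wired to 4 distinct
MFs within its dendritic reach (30 um; nearest-4 fallback).  MF activity
patterns are binary assignments with a target active fraction f and spatial
correlation radius sigma, realized by thresholding a Gaussian random field
with squared-exponential covariance over MF positions.  Active MFs fire
Poisson spikes at 50 Hz during a 30 ms window; GC responses are spike
counts in that window, simulated through the synapse and neuron modules.

The knockout condition is expressed purely as conductance scaling relative
to control: AMPA x 0.2, NMDA x 1.2, tonic inhibitory conductance - 0.16 nS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .neuron import GCModelParams, SimConfig, simulate_gc_multi
from .synapse import (ConductanceTrainPair, KineticScheme, SynapseParams,
                      stp_factors, unitary_conductance)

__all__ = [
    "NetworkGeometry",
    "PatternParams",
    "ResponseMatrix",
    "ConditionScaling",
    "CONTROL_SCALING",
    "KO_SCALING",
    "build_geometry",
    "generate_mf_patterns",
    "simulate_network_responses",
    "active_fraction",
]

N_MF = 187
N_GC = 487
SYNAPSES_PER_GC = 4
SPHERE_DIAMETER = 80.0  # um
DENDRITE_REACH = 30.0   # um


@dataclass(frozen=True)
class ConditionScaling:
    """Conductance scaling of one condition relative to control."""

    ampa_scale: float = 1.0
    nmda_scale: float = 1.0
    tonic_delta: float = 0.0  # nS added to the control tonic conductance

    def __post_init__(self):
        if self.ampa_scale < 0 or self.nmda_scale < 0:
            raise ValueError("conductance scales must be >= 0")


CONTROL_SCALING = ConditionScaling(1.0, 1.0, 0.0)
KO_SCALING = ConditionScaling(0.2, 1.2, -0.16)


@dataclass
class NetworkGeometry:
    mf_positions: np.ndarray   # (N_MF, 3) um
    gc_positions: np.ndarray   # (N_GC, 3) um
    wiring: np.ndarray         # (N_GC, 4) MF indices, distinct per row
    sphere_diameter: float = SPHERE_DIAMETER

    def __post_init__(self):
        if self.mf_positions.shape != (N_MF, 3):
            raise ValueError(f"expected {N_MF} MF positions")
        if self.gc_positions.shape != (N_GC, 3):
            raise ValueError(f"expected {N_GC} GC positions")
        if self.wiring.shape != (N_GC, SYNAPSES_PER_GC):
            raise ValueError(f"expected {SYNAPSES_PER_GC} synapses per GC")
        if any(len(set(row)) != SYNAPSES_PER_GC for row in self.wiring):
            raise ValueError("each GC needs distinct MF partners")


@dataclass(frozen=True)
class PatternParams:
    fraction_active: float
    correlation_radius: float   # um
    n_patterns: int = 640
    mf_rate_active: float = 50.0  # Hz
    window: float = 30e-3         # s
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction_active <= 1.0):
            raise ValueError("fraction_active must be in [0, 1]")
        if self.correlation_radius < 0:
            raise ValueError("correlation_radius must be >= 0")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")


@dataclass
class ResponseMatrix:
    """patterns x units spike counts; optionally carries the spike times."""

    counts: np.ndarray
    unit_kind: str                      # "MF" | "GC"
    condition: str = "control"
    spike_times: list | None = None     # per pattern: list of per-unit arrays

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_patterns(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]


def _uniform_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        ok = cand[np.sum(cand ** 2, axis=1) <= radius ** 2]
        take = min(n - got, ok.shape[0])
        pts[got:got + take] = ok[:take]
        got += take
    return pts


def build_geometry(seed: int = 0) -> NetworkGeometry:
    """Sample positions and wire each GC to 4 distinct MFs within reach."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E65]))
    radius = SPHERE_DIAMETER / 2.0
    mf = _uniform_sphere(rng, N_MF, radius)
    gc = _uniform_sphere(rng, N_GC, radius)
    wiring = np.empty((N_GC, SYNAPSES_PER_GC), dtype=np.int64)
    for i in range(N_GC):
        d = np.sqrt(np.sum((mf - gc[i]) ** 2, axis=1))
        eligible = np.nonzero(d <= DENDRITE_REACH)[0]
        if eligible.size < SYNAPSES_PER_GC:
            eligible = np.argsort(d)[:SYNAPSES_PER_GC]
        wiring[i] = rng.choice(eligible, size=SYNAPSES_PER_GC, replace=False)
    return NetworkGeometry(mf, gc, wiring)


def generate_mf_patterns(geometry: NetworkGeometry,
                         params: PatternParams) -> ResponseMatrix:
    """Binary MF activation patterns with Poisson spiking of active fibers.

    A zero-mean unit-variance Gaussian field with covariance
    exp(-d^2 / (2 sigma^2)) over MF positions is thresholded at the
    (1 - f) standard-normal quantile, giving expected active fraction f and
    correlation length sigma (sigma = 0 reduces to i.i.d. Bernoulli).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x7061]))
    f = params.fraction_active
    sigma = params.correlation_radius
    n_pat = params.n_patterns

    if sigma > 0:
        d2 = np.sum((geometry.mf_positions[:, None, :]
                     - geometry.mf_positions[None, :, :]) ** 2, axis=-1)
        cov = np.exp(-d2 / (2.0 * sigma ** 2)) + 1e-9 * np.eye(N_MF)
        L = np.linalg.cholesky(cov)
        z = (L @ rng.standard_normal((N_MF, n_pat))).T
    else:
        z = rng.standard_normal((n_pat, N_MF))

    if f >= 1.0:
        active = np.ones((n_pat, N_MF), dtype=bool)
    elif f <= 0.0:
        active = np.zeros((n_pat, N_MF), dtype=bool)
    else:
        active = z > ndtri(1.0 - f)

    counts = np.zeros((n_pat, N_MF), dtype=np.int64)
    spike_times: list[list[np.ndarray]] = []
    for p in range(n_pat):
        per_unit: list[np.ndarray] = []
        for m in range(N_MF):
            if active[p, m]:
                n_spk = rng.poisson(params.mf_rate_active * params.window)
                tt = np.sort(rng.uniform(0.0, params.window, size=n_spk))
                # enforce strict ordering for coincident draws
                for k in range(1, tt.size):
                    if tt[k] <= tt[k - 1]:
                        tt[k] = tt[k - 1] + 1e-9
            else:
                tt = np.empty(0)
            per_unit.append(tt)
            counts[p, m] = tt.size
        spike_times.append(per_unit)
    return ResponseMatrix(counts, "MF", "input", spike_times)


def _mf_conductances(synapses: SynapseParams, spike_times, dt: float,
                     n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-MF AMPA/NMDA conductance arrays for one pattern chunk."""
    n_pat = len(spike_times)
    g_a = np.zeros((n_pat, N_MF, n_steps))
    g_n = np.zeros((n_pat, N_MF, n_steps))
    t_grid = np.arange(n_steps) * dt

    def kernel(scheme: KineticScheme) -> np.ndarray:
        return unitary_conductance(scheme, t_grid)

    k_dir = kernel(synapses.ampa_direct)
    k_spill = kernel(synapses.ampa_spillover)
    k_ampa = k_dir + k_spill
    k_nmda = kernel(synapses.nmda)

    for p in range(n_pat):
        for m in range(N_MF):
            tt = spike_times[p][m]
            if tt.size == 0:
                continue
            fac_a = stp_factors(synapses.stp_ampa, tt)
            fac_n = stp_factors(synapses.stp_nmda, tt)
            idx = np.round(tt / dt).astype(int)
            for i, s in enumerate(idx):
                if s >= n_steps:
                    continue
                m_len = n_steps - s
                g_a[p, m, s:] += fac_a[i] * k_ampa[:m_len]
                g_n[p, m, s:] += fac_n[i] * k_nmda[:m_len]
    return g_a, g_n


def simulate_network_responses(geometry: NetworkGeometry,
                               mf_patterns: ResponseMatrix,
                               gc_model: GCModelParams,
                               synapses: SynapseParams,
                               scaling: ConditionScaling = CONTROL_SCALING,
                               cfg: SimConfig | None = None,
                               condition: str = "control",
                               chunk: int = 32) -> ResponseMatrix:
    """GC spike counts for every MF pattern under one conductance scaling.

    Each GC integrates its 4 MF inputs through the synapse model (scaled by
    the condition) over the pattern window, starting from rest.  Patterns
    are processed in chunks, vectorized over patterns x GCs.
    """
    if mf_patterns.spike_times is None:
        raise ValueError("mf_patterns must carry spike times")
    if cfg is None:
        cfg = SimConfig(dt=5e-5, duration=30e-3, initial_V=-80.0)
    syn = synapses.scaled(scaling.ampa_scale, scaling.nmda_scale)
    model = gc_model.with_tonic_delta(scaling.tonic_delta)
    n_steps = cfg.n_steps
    n_pat = mf_patterns.n_patterns
    counts = np.zeros((n_pat, N_GC), dtype=np.int64)

    for start in range(0, n_pat, chunk):
        stop = min(start + chunk, n_pat)
        spikes_chunk = mf_patterns.spike_times[start:stop]
        g_a_mf, g_n_mf = _mf_conductances(syn, spikes_chunk, cfg.dt, n_steps)
        n_chunk = stop - start
        g_a = np.zeros((n_chunk, N_GC, n_steps))
        g_n = np.zeros((n_chunk, N_GC, n_steps))
        for k in range(SYNAPSES_PER_GC):
            g_a += g_a_mf[:, geometry.wiring[:, k], :]
            g_n += g_n_mf[:, geometry.wiring[:, k], :]
        _, spk = simulate_gc_multi(model,
                                   g_a.reshape(-1, n_steps),
                                   g_n.reshape(-1, n_steps),
                                   0.0, cfg, syn.mg)
        n_spk = np.array([len(s) for s in spk]).reshape(n_chunk, N_GC)
        counts[start:stop] = n_spk
    return ResponseMatrix(counts, "GC", condition)


def active_fraction(responses: ResponseMatrix) -> float:
    """Mean fraction of units with at least one spike, across patterns."""
    return float((responses.counts > 0).mean(axis=1).mean())
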