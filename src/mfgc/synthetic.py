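"""Stand-in parameter presets and synthetic fitting targets.

The WT preset bundles the granule-cell AdEx parameters and the unitary
AMPA (direct + spillover) / NMDA kinetic schemes with their short-term
depression parameters.  The knockout preset differs from WT *only* by the
three condition scalings: unitary AMPA conductance x 0.2, NMDA x 1.2, and
tonic inhibitory conductance reduced by 0.16 nS (floored at zero).

The numeric values are documented stand-ins, not measured constants: they
are literature-plausible granule-cell values calibrated once so that the
WT model's maximum firing rate under summed Poisson mossy-fiber drive lies
in the published WT/KO regime (a few hundred Hz).  See docs/methods.md.

`make_reference_conductance_trains` produces pseudo-experimental
grand-average conductance trains (model output plus additive Gaussian
noise, clipped at zero) that serve as known-ground-truth targets for the
synapse fitting stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .network import CONTROL_SCALING, ConditionScaling
from .neuron import GCModelParams
from .stimulus import generate_regular_train
from .synapse import (ConductanceTrainPair, KineticScheme, MgBlockParams,
                      STPParams, SynapseParams, build_conductance_trains)

__all__ = [
    "ConditionPreset",
    "NoiseSpec",
    "default_presets",
    "network_synapses",
    "make_reference_conductance_trains",
    "seed_manifest",
    "save_preset",
    "load_preset",
]

KO_AMPA_SCALE = 0.2
KO_NMDA_SCALE = 1.2
KO_TONIC_DELTA = -0.16  # nS


@dataclass(frozen=True)
class ConditionPreset:
    label: str
    gc_model: GCModelParams
    synapses: SynapseParams
    scaling: ConditionScaling


@dataclass(frozen=True)
class NoiseSpec:
    additive_sd: float = 0.0  # nS
    seed: int = 0

    def __post_init__(self):
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")


# Leak reversal solved so the WT cell, tonic conductance included, rests at
# exactly -80 mV: E_L = (V_rest (g_L + g_tonic) - g_tonic E_inh) / g_L.
_WT_G_L = 0.55      # nS
_WT_G_TONIC = 0.6   # nS
_E_INH = -85.0      # mV
_E_LEAK = (-80.0 * (_WT_G_L + _WT_G_TONIC) - _WT_G_TONIC * _E_INH) / _WT_G_L


def _wt_gc_model() -> GCModelParams:
    return GCModelParams(
        capacitance=3.0,
        leak_conductance=_WT_G_L,
        leak_reversal=_E_LEAK,
        threshold_slope=2.0,
        rheobase_threshold=-46.0,
        adaptation_coupling=0.05,
        spike_triggered_adaptation=0.6,
        adaptation_tau=100.0,
        reset_potential=-70.0,
        spike_cutoff=0.0,
        refractory=1.5,
        tonic_inhibition=_WT_G_TONIC,
        inhibitory_reversal=_E_INH,
        excitatory_reversal=0.0,
    )


def _wt_synapses() -> SynapseParams:
    return SynapseParams(
        ampa_direct=KineticScheme(4.8, 0.15, (0.4, 2.5), (0.8, 0.2), "direct"),
        ampa_spillover=KineticScheme(1.2, 0.5, (2.0, 8.0), (0.6, 0.4),
                                     "spillover"),
        nmda=KineticScheme(2.25, 1.0, (30.0,), (1.0,), "direct"),
        stp_ampa=STPParams(release_fraction=0.35, recovery_tau=135.0),
        stp_nmda=STPParams(release_fraction=0.4, recovery_tau=135.0),
        mg=MgBlockParams(),
    )


def network_synapses() -> SynapseParams:
    """Control-condition synaptic weights for the feedforward network model.

    The network model carries its own synaptic weight setting, independent
    of the single-cell conductance fits: unitary amplitudes are set so the
    control network operates in the canonical sparsening regime (GC active
    fraction below the MF active fraction, population sparseness at or
    above the MF level) while staying responsive to the knockout scalings.
    Kinetics and short-term plasticity are shared with the single-cell
    bundle.
    """
    syn = _wt_synapses()
    return replace(
        syn,
        ampa_direct=replace(syn.ampa_direct, peak_amplitude=1.05),
        ampa_spillover=replace(syn.ampa_spillover, peak_amplitude=0.2625),
        nmda=replace(syn.nmda, peak_amplitude=1.61),
    )


def default_presets(override_file=None) -> dict[str, ConditionPreset]:
    """WT and KO presets; KO = WT under the published condition scalings.

    If ``override_file`` (YAML, same schema as `save_preset`) is given, its
    values replace the WT stand-ins before the KO scaling is applied.
    """
    if override_file is not None:
        wt = load_preset(override_file)
        wt_model, wt_syn = wt.gc_model, wt.synapses
    else:
        wt_model, wt_syn = _wt_gc_model(), _wt_synapses()
    ko_scaling = ConditionScaling(KO_AMPA_SCALE, KO_NMDA_SCALE, KO_TONIC_DELTA)
    wt = ConditionPreset("WT", wt_model, wt_syn, CONTROL_SCALING)
    ko = ConditionPreset(
        "KO",
        wt_model.with_tonic_delta(KO_TONIC_DELTA),
        wt_syn.scaled(KO_AMPA_SCALE, KO_NMDA_SCALE),
        ko_scaling,
    )
    return {"WT": wt, "KO": ko}


PROTOCOLS = {
    "100x20": dict(n_stimuli=20, frequency=100.0),
    "300x10": dict(n_stimuli=10, frequency=300.0),
}


def make_reference_conductance_trains(preset: ConditionPreset,
                                      protocol: str = "100x20",
                                      noise: NoiseSpec = NoiseSpec(),
                                      dt: float = 5e-5,
                                      ) -> ConductanceTrainPair:
    """Pseudo-experimental grand-average conductance train for one protocol.

    Model-generated trains plus seeded additive Gaussian noise (clipped at
    zero, since a conductance is nonnegative).  With zero noise this equals
    `build_conductance_trains` exactly.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; use one of {sorted(PROTOCOLS)}")
    spec = PROTOCOLS[protocol]
    presyn = generate_regular_train(spec["n_stimuli"], spec["frequency"],
                                    onset=5e-3)
    duration = presyn.duration + 50e-3
    clean = build_conductance_trains(preset.synapses, presyn, dt, duration)
    if noise.additive_sd == 0:
        return clean
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 0x6E6F]))
    g_a = np.clip(clean.g_ampa + rng.normal(0, noise.additive_sd,
                                            clean.g_ampa.shape), 0, None)
    g_n = np.clip(clean.g_nmda + rng.normal(0, noise.additive_sd,
                                            clean.g_nmda.shape), 0, None)
    return ConductanceTrainPair(dt, g_a, g_n)


def seed_manifest(experiment: str, n_seeds: int, master_seed: int = 0) -> list[int]:
    """Deterministic, label-separated expansion of a master seed.

    Streams for different experiment labels are separated by hashing the
    label into the seed-sequence entropy, so manifests for different
    experiments are disjoint with overwhelming probability.
    """
    label_key = int.from_bytes(experiment.encode()[:8].ljust(8, b"\0"), "little")
    ss = np.random.SeedSequence([master_seed, label_key % (2 ** 63)])
    rng = np.random.default_rng(ss)
    seeds: list[int] = []
    seen = set()
    while len(seeds) < n_seeds:
        cand = int(rng.integers(0, 2 ** 31))
        if cand not in seen:
            seen.add(cand)
            seeds.append(cand)
    return seeds


# ---------------------------------------------------------------------------
# YAML serialization of presets


def _scheme_dict(s: KineticScheme) -> dict:
    return dict(peak_amplitude=s.peak_amplitude, rise_tau=s.rise_tau,
                decay_taus=list(s.decay_taus),
                decay_fractions=list(s.decay_fractions), component=s.component)


def save_preset(preset: ConditionPreset, path) -> None:
    doc = {
        "label": preset.label,
        "gc_model": asdict(preset.gc_model),
        "synapses": {
            "ampa_direct": _scheme_dict(preset.synapses.ampa_direct),
            "ampa_spillover": _scheme_dict(preset.synapses.ampa_spillover),
            "nmda": _scheme_dict(preset.synapses.nmda),
            "stp_ampa": asdict(preset.synapses.stp_ampa),
            "stp_nmda": asdict(preset.synapses.stp_nmda),
            "mg": asdict(preset.synapses.mg),
        },
        "scaling": asdict(preset.scaling),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_preset(path) -> ConditionPreset:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        syn = doc["synapses"]
        synapses = SynapseParams(
            ampa_direct=KineticScheme(**syn["ampa_direct"]),
            ampa_spillover=KineticScheme(**syn["ampa_spillover"]),
            nmda=KineticScheme(**syn["nmda"]),
            stp_ampa=STPParams(**syn["stp_ampa"]),
            stp_nmda=STPParams(**syn["stp_nmda"]),
            mg=MgBlockParams(**syn.get("mg", {})),
        )
        return ConditionPreset(
            label=doc["label"],
            gc_model=GCModelParams(**doc["gc_model"]),
            synapses=synapses,
            scaling=ConditionScaling(**doc.get("scaling", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed preset file {path}: {exc}") from exc
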