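"""End-to-end single-cell experiments: Poisson rate sweeps and summaries.

The central in-silico protocol: drive one model granule cell with four
independent refractory-Poisson mossy-fiber trains whose rates sum to a
target (10-1000 Hz), for 1 s at a 50 us step, average the firing rate over
10 independent runs per summed rate, and summarize the input-output
relation with a Hill fit.  Variants of the same protocol give the
mechanism decomposition (tonic inhibition restored, WT NMDA conductance,
or both, in the knockout model) and the spike-train comparison measures
(first-spike delay, van Rossum distance, SPIKE-synchronization between the
pooled MF drive and the GC output).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import (MetricParams, first_spike_delay, hill_fit,
                      spike_synchronization, van_rossum_distance)
from .neuron import SimConfig, simulate_gc_multi
from .stimulus import (PoissonDriveSpec, SpikeTrain, generate_poisson_trains,
                       merge_trains)
from .synapse import SynapseParams, build_conductance_trains
from .synthetic import ConditionPreset, seed_manifest

__all__ = [
    "DEFAULT_SUMMED_RATES",
    "rate_sweep",
    "sweep_summary",
    "io_curve",
    "mechanism_variants",
]

DEFAULT_SUMMED_RATES = (10.0, 20.0, 50.0, 100.0, 150.0, 200.0, 300.0, 500.0,
                        700.0, 1000.0)
N_MF_INPUTS = 4
MF_REFRACTORY = 0.6e-3


def _drive_for_run(synapses: SynapseParams, summed_rate: float, seed: int,
                   cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, list[SpikeTrain]]:
    """Summed 4-fiber conductance drive for one run (per-fiber STP)."""
    spec = PoissonDriveSpec(N_MF_INPUTS, summed_rate, cfg.duration,
                            MF_REFRACTORY, seed)
    trains = generate_poisson_trains(spec)
    g_a = np.zeros(cfg.n_steps)
    g_n = np.zeros(cfg.n_steps)
    for tr in trains:
        pair = build_conductance_trains(synapses, tr, cfg.dt, cfg.duration)
        g_a += pair.g_ampa
        g_n += pair.g_nmda
    return g_a, g_n, trains


def rate_sweep(preset: ConditionPreset,
               summed_rates=DEFAULT_SUMMED_RATES,
               n_runs: int = 10,
               master_seed: int = 0,
               cfg: SimConfig = SimConfig(),
               spike_train_metrics: bool = False,
               metric_params: MetricParams = MetricParams()) -> pd.DataFrame:
    """Firing of one model GC vs. summed MF rate, n_runs runs per rate.

    Input seeds are drawn from a manifest keyed only by the master seed and
    run index, *not* by the condition, so WT/KO (and mechanism variants)
    see identical MF spike trains run for run — matched-seed comparisons.

    With ``spike_train_metrics`` the pooled MF train is compared to the GC
    output per run (first-spike delay, van Rossum distance,
    SPIKE-synchronization).
    """
    seeds = seed_manifest("rate_sweep", n_runs, master_seed)
    n_rates = len(summed_rates)
    n_traces = n_rates * n_runs
    g_a = np.empty((n_traces, cfg.n_steps))
    g_n = np.empty((n_traces, cfg.n_steps))
    drives: list[list[SpikeTrain]] = []
    for i, rate in enumerate(summed_rates):
        for j, seed in enumerate(seeds):
            # per-rate offset keeps fibers independent across rates
            a, n, trains = _drive_for_run(preset.synapses, rate,
                                          seed + 7919 * i, cfg)
            g_a[i * n_runs + j] = a
            g_n[i * n_runs + j] = n
            drives.append(trains)
    _, spikes = simulate_gc_multi(preset.gc_model, g_a, g_n, 0.0, cfg,
                                  preset.synapses.mg)
    rows = []
    for i, rate in enumerate(summed_rates):
        for j in range(n_runs):
            k = i * n_runs + j
            gc = SpikeTrain(spikes[k], cfg.duration, "gc")
            row = {
                "summed_rate_Hz": rate,
                "run": j,
                "condition": preset.label,
                "firing_Hz": gc.n_spikes / cfg.duration,
            }
            if spike_train_metrics:
                pooled = merge_trains(drives[k])
                delay = first_spike_delay(0.0, gc)
                row["first_spike_delay_ms"] = np.nan if delay is None else delay
                row["van_rossum"] = van_rossum_distance(pooled, gc,
                                                        metric_params)
                row["spike_sync"] = spike_synchronization(pooled, gc)
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean of each measure per summed rate (averaging the 10 runs)."""
    return (sweep.drop(columns=["run", "condition"])
            .groupby("summed_rate_Hz", as_index=False).mean())


def io_curve(preset: ConditionPreset, **kwargs):
    """Rate sweep -> mean firing per rate -> Hill fit of the I/O relation."""
    sweep = rate_sweep(preset, **kwargs)
    summary = sweep_summary(sweep)
    fit = hill_fit(summary["summed_rate_Hz"], summary["firing_Hz"])
    return fit, summary, sweep


def mechanism_variants(presets: dict[str, ConditionPreset]) -> dict[str, ConditionPreset]:
    """KO-model variants probing the two compensatory mechanisms.

    - 'KO+tonic': the 0.16 nS tonic inhibitory conductance restored.
    - 'KO+wtNMDA': the WT (unscaled) NMDA conductance substituted.
    - 'KO+both': both manipulations combined.
    """
    wt, ko = presets["WT"], presets["KO"]
    tonic_restored = ko.gc_model.with_tonic_delta(0.16)
    wt_nmda = replace(ko.synapses, nmda=wt.synapses.nmda,
                      stp_nmda=wt.synapses.stp_nmda)
    return {
        "KO": ko,
        "KO+tonic": replace(ko, label="KO+tonic", gc_model=tonic_restored),
        "KO+wtNMDA": replace(ko, label="KO+wtNMDA", synapses=wt_nmda),
        "KO+both": replace(ko, label="KO+both", gc_model=tonic_restored,
                           synapses=wt_nmda),
    }
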