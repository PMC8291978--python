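"""Presynaptic drive: refractory Poisson and regular mossy-fiber spike trains.

Mossy fibers are modelled as Poisson processes with a dead time (absolute
refractory period): exponential inter-spike intervals at the nominal rate
plus a fixed refractory offset.  The resulting renewal process has mean ISI
``1/rate + refractory``, so the realised rate is ``rate / (1 + rate *
refractory)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "PoissonDriveSpec",
    "generate_poisson_trains",
    "generate_regular_train",
    "dead_time_rate",
    "write_spike_trains",
    "read_spike_trains",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (s) of one fiber or neuron on [0, duration]."""

    times: np.ndarray
    duration: float
    source_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz over the full duration."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class PoissonDriveSpec:
    """A bundle of independent refractory-Poisson fibers.

    ``total_rate`` is the summed nominal rate over all fibers (the convention
    used for the MF drive, e.g. "4 fibers, 10-1000 Hz summed"); each fiber
    fires at ``total_rate / n_inputs``.
    """

    n_inputs: int
    total_rate: float
    duration: float
    refractory: float = 0.6e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.total_rate < 0:
            raise ValueError("total_rate must be >= 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


def dead_time_rate(nominal_rate: float, refractory: float) -> float:
    """Realised rate of a Poisson process with dead time.

    The renewal ISI is ``refractory + Exp(nominal_rate)`` with mean
    ``refractory + 1/nominal_rate``; the realised rate is its inverse.
    """
    if nominal_rate <= 0:
        return 0.0
    return nominal_rate / (1.0 + nominal_rate * refractory)


def _one_train(rate: float, duration: float, refractory: float,
               rng: np.random.Generator, source_id: str) -> SpikeTrain:
    if rate <= 0 or duration <= 0:
        return SpikeTrain(np.empty(0), duration, source_id)
    # draw in blocks until past the end; expected count + 6 sd margin
    expected = dead_time_rate(rate, refractory) * duration
    block = max(16, int(expected + 6 * np.sqrt(expected + 1)))
    times = []
    t = 0.0
    while t <= duration:
        isis = rng.exponential(1.0 / rate, size=block) + refractory
        cum = t + np.cumsum(isis)
        keep = cum[cum <= duration]
        times.append(keep)
        if cum[-1] > duration:
            break
        t = cum[-1]
    all_times = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(all_times, duration, source_id)


def generate_poisson_trains(spec: PoissonDriveSpec) -> list[SpikeTrain]:
    """Independent refractory-Poisson trains, one per fiber.

    Each fiber gets its own child random stream derived from the master seed,
    so fiber k's spikes do not depend on ``n_inputs``.
    """
    per_fiber = spec.total_rate / spec.n_inputs
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_inputs)
    return [
        _one_train(per_fiber, spec.duration, spec.refractory,
                   np.random.default_rng(child), source_id=f"mf{k}")
        for k, child in enumerate(children)
    ]


def generate_regular_train(n_stimuli: int, frequency: float,
                           onset: float = 0.0, *,
                           duration: float | None = None,
                           source_id: str = "stim") -> SpikeTrain:
    """Fixed-frequency stimulus train: spikes at onset + k/frequency."""
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    times = onset + np.arange(n_stimuli) / frequency
    if duration is None:
        duration = float(times[-1]) + 1.0 / frequency
    return SpikeTrain(times, duration, source_id)


def merge_trains(trains: list[SpikeTrain]) -> SpikeTrain:
    """Pool several trains into one (sorted union of spike times).

    Used e.g. to compare the summed MF drive against the GC output.  Exactly
    coincident spikes across fibers are jittered apart by one nanosecond to
    preserve strict ordering (they are distinct physical events).
    """
    if not trains:
        raise ValueError("need at least one train")
    duration = max(t.duration for t in trains)
    times = np.sort(np.concatenate([t.times for t in trains]))
    if times.size > 1:
        same = np.diff(times) <= 0
        while np.any(same):
            times[1:][same] = times[:-1][same] + 1e-9
            order = np.argsort(times, kind="stable")
            times = times[order]
            same = np.diff(times) <= 0
    times = times[times <= duration]
    return SpikeTrain(times, duration, "pooled")


def write_spike_trains(path, trains: list[SpikeTrain]) -> None:
    """Serialize trains to a two-column delimited text file (id, time_s)."""
    with open(path, "w") as fh:
        fh.write("# source_id\ttime_s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.source_id}\t{t:.9f}\n")


def read_spike_trains(path, duration: float) -> list[SpikeTrain]:
    ids, times = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, t = line.split("\t")
            ids.append(sid)
            times.append(float(t))
    out = []
    for sid in dict.fromkeys(ids):
        tt = np.array([t for s, t in zip(ids, times) if s == sid])
        out.append(SpikeTrain(np.sort(tt), duration, sid))
    return out
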