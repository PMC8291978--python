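"""Input-output curve analysis and spike-train comparison measures.

Firing-rate curves (GC output vs. summed MF input rate) are summarized by a
Hill fit F(x) = F_max / (1 + (x_half/x)^n); the *offset* is x_half and the
*gain* is the slope of the fitted curve over the range where F lies between
2% and 60% of F_max.  Excitability from current steps is summarized by
rheobase and the linear-fit gain of the f-I relationship.

Two spike-train comparison measures are provided:

* van Rossum distance: both trains are convolved with a causal exponential
  kernel exp(-t/tau) (tau = 10 ms by default); the integral of the squared
  difference, multiplied by 1/tau, gives the squared distance.  We return
  its square root (a metric); the integrals are evaluated in closed form
  with truncation at the train duration.

* SPIKE-synchronization (Kreuz et al.): each spike is coincident if its
  nearest partner in the other train falls within an adaptive window equal
  to half the minimum of the surrounding inter-spike intervals of the two
  trains; the measure is the fraction of coincident spikes over both
  trains.  Parameter-free and bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .stimulus import SpikeTrain

__all__ = [
    "HillFit",
    "MetricParams",
    "hill_fit",
    "gain_rheobase",
    "first_spike_delay",
    "van_rossum_distance",
    "spike_synchronization",
]


@dataclass(frozen=True)
class MetricParams:
    van_rossum_tau: float = 10e-3          # s
    hill_gain_band: tuple[float, float] = (0.02, 0.60)

    def __post_init__(self):
        if self.van_rossum_tau <= 0:
            raise ValueError("van_rossum_tau must be > 0")
        lo, hi = self.hill_gain_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("hill_gain_band must be ascending within (0, 1)")


@dataclass
class HillFit:
    f_max: float        # Hz
    x_half: float       # Hz (== offset)
    exponent: float
    gain: float         # slope of the fit over the 2-60% band
    fit_residual: float
    success: bool = True

    @property
    def offset(self) -> float:
        return self.x_half

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            return self.f_max / (1.0 + (self.x_half / x) ** self.exponent)


def hill_fit(input_rates, output_rates,
             params: MetricParams = MetricParams()) -> HillFit:
    """Fit a Hill curve to an input-output relation and derive gain/offset."""
    x = np.asarray(input_rates, dtype=float)
    y = np.asarray(output_rates, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(x <= 0):
        raise ValueError("input rates must be positive")
    if not np.any(y > 0):
        raise ValueError("all-zero outputs: Hill fit is degenerate")

    ymax = float(y.max())
    half_idx = int(np.argmin(np.abs(y - 0.5 * ymax)))
    p = lmfit.Parameters()
    p.add("f_max", value=ymax, min=1e-6)
    p.add("x_half", value=max(x[half_idx], x[0]), min=1e-6)
    p.add("n", value=1.0, min=0.1, max=20.0)

    def residual(pars):
        return pars["f_max"].value / (1.0 + (pars["x_half"].value / x) ** pars["n"].value) - y

    out = lmfit.minimize(residual, p, method="least_squares")
    f_max = float(out.params["f_max"].value)
    x_half = float(out.params["x_half"].value)
    n = float(out.params["n"].value)

    lo, hi = params.hill_gain_band
    # invert the fitted curve at the band edges: F = q*F_max  =>
    # x = x_half / (1/q - 1)^(1/n)
    x_lo = x_half / (1.0 / lo - 1.0) ** (1.0 / n)
    x_hi = x_half / (1.0 / hi - 1.0) ** (1.0 / n)
    xs = np.linspace(x_lo, x_hi, 200)
    ys = f_max / (1.0 + (x_half / xs) ** n)
    gain = float(np.polyfit(xs, ys, 1)[0])

    resid = float(np.sqrt(np.mean(out.residual ** 2)))
    return HillFit(f_max, x_half, n, gain, resid, bool(out.success))


def gain_rheobase(fI) -> dict:
    """Rheobase and gain of a frequency-current curve.

    ``fI`` is the DataFrame from `neuron.simulate_current_steps` (columns
    current_pA, frequency_Hz, amplitudes ascending).  Rheobase is the
    smallest amplitude with nonzero firing; gain is the OLS slope through
    the suprathreshold points (Hz/pA).  A silent curve returns
    ``{"rheobase": None, "gain": None}``.
    """
    I = np.asarray(fI["current_pA"], dtype=float)
    f = np.asarray(fI["frequency_Hz"], dtype=float)
    supra = f > 0
    if not np.any(supra):
        return {"rheobase": None, "gain": None}
    rheobase = float(I[supra][0])
    if supra.sum() >= 2:
        gain = float(np.polyfit(I[supra], f[supra], 1)[0])
    else:
        gain = None
    return {"rheobase": rheobase, "gain": gain}


def first_spike_delay(stimulus_onset: float, spikes: SpikeTrain) -> float | None:
    """Delay (ms) from stimulus onset to the first subsequent spike."""
    after = spikes.times[spikes.times >= stimulus_onset]
    if after.size == 0:
        return None
    return float((after[0] - stimulus_onset) * 1e3)


def van_rossum_distance(a: SpikeTrain, b: SpikeTrain,
                        params: MetricParams = MetricParams(),
                        squared: bool = False) -> float:
    """van Rossum spike-train distance with a causal exponential kernel.

    D^2 = (1/tau) * integral over [0, T] of (f_a - f_b)^2, where f is the
    train convolved with exp(-t/tau).  Cross terms are evaluated in closed
    form: for spikes s, t the kernel overlap integral is
    (tau/2) exp(-|s-t|/tau) (1 - exp(-2 (T - max(s,t))/tau)).
    """
    if abs(a.duration - b.duration) > 1e-12:
        raise ValueError("trains must share the same duration")
    # canonical argument order makes symmetry bitwise exact
    if (a.times.size, tuple(a.times)) > (b.times.size, tuple(b.times)):
        a, b = b, a
    tau = params.van_rossum_tau
    T = a.duration

    def overlap(u: np.ndarray, v: np.ndarray) -> float:
        if u.size == 0 or v.size == 0:
            return 0.0
        du = np.abs(u[:, None] - v[None, :])
        mx = np.maximum(u[:, None], v[None, :])
        return float(np.sum(0.5 * tau * np.exp(-du / tau)
                            * (1.0 - np.exp(-2.0 * (T - mx) / tau))))

    d2 = (overlap(a.times, a.times) + overlap(b.times, b.times)
          - 2.0 * overlap(a.times, b.times)) / tau
    d2 = max(d2, 0.0)
    return d2 if squared else float(np.sqrt(d2))


def _edge_isis(t: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Preceding and following ISI per spike; edges use the [0, T] bounds."""
    prev = np.empty(t.size)
    nxt = np.empty(t.size)
    prev[0] = t[0]
    prev[1:] = np.diff(t)
    nxt[-1] = T - t[-1]
    nxt[:-1] = np.diff(t)
    return prev, nxt


def spike_synchronization(a: SpikeTrain, b: SpikeTrain) -> float:
    """SPIKE-synchronization: fraction of coincident spikes in [0, 1].

    A spike is coincident if its nearest spike in the other train lies
    within half the minimum of the four surrounding inter-spike intervals
    (adaptive, parameter-free window).  Two empty trains are defined as
    perfectly synchronous (no discordant spikes) with a warning.
    """
    ta, tb = a.times, b.times
    if ta.size == 0 and tb.size == 0:
        warnings.warn("both trains empty: synchronization defined as 1")
        return 1.0
    if ta.size == 0 or tb.size == 0:
        return 0.0
    T = max(a.duration, b.duration)
    prev_a, next_a = _edge_isis(ta, T)
    prev_b, next_b = _edge_isis(tb, T)

    def coincident(t1, prev1, next1, t2, prev2, next2) -> int:
        count = 0
        j_near = np.searchsorted(t2, t1)
        for i, t in enumerate(t1):
            j = j_near[i]
            candidates = [k for k in (j - 1, j) if 0 <= k < t2.size]
            k = min(candidates, key=lambda k: abs(t2[k] - t))
            nu = min(prev1[i], next1[i], prev2[k], next2[k])
            if abs(t2[k] - t) < 0.5 * nu:
                count += 1
        return count

    c = (coincident(ta, prev_a, next_a, tb, prev_b, next_b)
         + coincident(tb, prev_b, next_b, ta, prev_a, next_a))
    return c / (ta.size + tb.size)
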