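# Methods

## Scope

`mfgc` models excitation of cerebellar granule cells (GCs) by mossy
fibers (MFs) in two settings: a single conductance-driven GC under
Poisson MF drive, used to compare wild-type (WT) and GluA4-knockout (KO)
synaptic conditions, and a feedforward MF→GC network used to measure how
the knockout changes population coding and downstream learning speed.
All inputs are generated by the package itself; the `synthetic` module
defines the parameter presets and pseudo-experimental fitting targets.

## Granule-cell model

The GC is an adaptive exponential integrate-and-fire (AdEx) neuron:

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T)
              − g_AMPA(t)(V − E_exc) − g_NMDA(t) u(V) (V − E_exc)
              − g_tonic (V − E_inh) − w + I_inj
    τ_w dw/dt = a (V − E_L) − w

with reset `V → V_r`, `w → w + b` and an absolute refractory period on
each spike.  `u(V) = 1/(1 + ([Mg]/K½) e^(−V/s))` is the NMDA Mg-unblock
sigmoid with the standard literature constants [Mg] = 1 mM,
K½ = 3.57 mM, s = 16.1 mV.

Integration is forward Euler at a fixed 50 µs step, with the exponential
spike-initiation term clipped just above the spike cutoff to avoid
overflow.  The integrator is vectorized over independent traces (cells ×
patterns × conditions share one parameter set), which is what makes the
network simulations tractable on one CPU.  Determinism is exact: the
same inputs give bit-identical spike trains.

Known accuracy limits of the fixed-step Euler scheme, established by the
test suite against a 1 µs reference integration: spike *counts* match
(and change by ≤1 when the step is halved on a 1 s, 50 Hz-summed Poisson
benchmark), and the onset-locked first spike agrees to within one 50 µs
bin, but mid-train spike times drift by a few bins because threshold
crossings are sensitive to accumulated integration error.  At summed
drive ≥100 Hz the halved-step count can differ by a few spikes out of
~200; convergence contracts are therefore stated at low-rate drive.

## Synapse model

Each MF→GC connection contributes a fast *direct* AMPA component, a
slower *spillover* AMPA component, and an NMDA component.  A unitary
waveform is a product of an exponential rise and a multi-exponential
decay, normalized to its peak amplitude; the AMPA direct component uses
a bi-exponential decay (0.4/2.5 ms), spillover 2/8 ms, NMDA a single
30 ms decay.  Short-term depression follows an R·P scheme: the response
to spike *i* is proportional to R·P with resources depleted by the
released fraction at each spike and recovering exponentially
(τ_rec = 135 ms); the direct and spillover components share one release
process.  Conductance trains are the linear superposition of per-spike
unitary kernels scaled by their R·P factors; kernels are truncated at
10 decay time constants (relative tail < 5 × 10⁻⁵).

Fitting proceeds in the same two stages as the experimental workflow it
mirrors: bounded nonlinear least squares (via `lmfit`) of the amplitudes
and time constants against a 20-stimulus 100 Hz conductance train, then
joint fine-tuning of the R·P parameters against the 100 Hz and 300 Hz
trains with kinetics held fixed.  The kinetic landscape is nonconvex —
the direct and spillover components overlap — so the fit is documented
to require a same-order-of-magnitude initial guess (~±20%); from much
farther starts the optimizer can trade amplitude between the two AMPA
components.  Decay *fractions* of multi-exponential components are held
at the initial guess.

## Parameter presets (stand-ins)

The quantitative parameter table behind the original single-cell model
is not machine-readable here, so the shipped presets are documented
stand-ins: literature-plausible GC values calibrated once, at desk
scale, so that the WT model's Hill-fit maximum firing rate under summed
Poisson MF drive lies in the published few-hundred-Hz regime and the
three KO scalings (AMPA × 0.2, NMDA × 1.2, tonic − 0.16 nS) reproduce
the published ratio structure.  They are not measured constants, and
absolute rates carry that caveat; ratio and ordering results are the
robust outputs.

* AdEx: C = 3 pF, g_L = 0.55 nS, Δ_T = 2 mV, V_T = −46 mV,
  a = 0.05 nS, b = 0.6 pA, τ_w = 100 ms, V_r = −70 mV, refractory
  1.5 ms, spike cutoff 0 mV.
* Tonic inhibition: 0.6 nS (WT) with E_inh = −85 mV; the KO preset
  differs *only* by the three scalings, so its tonic is 0.44 nS.  E_L is
  solved so the WT cell, tonic included, rests at exactly −80 mV
  (E_L = −74.55 mV); the KO then rests slightly depolarized, as expected
  from reduced shunting.
* Unitary synapse (WT): AMPA direct 4.8 nS, spillover 1.2 nS, NMDA
  2.25 nS; release fractions P = 0.35 (AMPA) and 0.4 (NMDA),
  τ_rec = 135 ms.  The large amplitudes compensate the strong
  steady-state depression at sustained drive: with τ_rec ≫ the ISI, the
  effective per-event conductance at 100–250 Hz per fiber is roughly an
  order of magnitude below the first-pulse value.  This slow-recovery
  regime is a deliberate choice: it makes the summed drive saturate with
  input rate, keeps the cell near threshold even at maximal input, and
  is what renders the maximum firing rate sensitive to the 0.16 nS tonic
  conductance and the NMDA amplitude — the mechanism decomposition the
  single-cell analysis is about.

## Stimulus model

MF spike trains are Poisson processes with a 0.6 ms dead time, realized
as exponential inter-spike intervals plus the refractory offset (renewal
process; realised rate r/(1 + r·t_ref), verified against a brute-force
Monte-Carlo oracle).  The summed rate of the four fibers is split
equally; each fiber draws from its own child random stream so fiber *k*
is invariant to the number of fibers.  The summed-rate constraint holds
in expectation, not per realization.

## Single-cell experiments

The rate sweep drives one GC with four fibers summing 10–1000 Hz
(10 points) for 1 s, 10 runs per rate; input seeds are keyed by run
only, never by condition, so WT/KO and the mechanism variants see
identical spike trains (matched-seed comparisons).  Firing-rate curves
are summarized by a Hill fit F(x) = F_max/(1 + (x_half/x)^n); the
*offset* is x_half and the *gain* is the slope of the fitted curve where
it lies between 2% and 60% of F_max (evaluated on a 200-point dense
resampling of the fit, not on raw data).  Current-step excitability uses
200 ms injections in 5 pA increments; rheobase is the smallest amplitude
with ≥1 spike, gain the least-squares slope through suprathreshold
points.

Spike-train comparisons use the pooled four-fiber MF train against the
GC output.  The van Rossum distance uses a causal 10 ms exponential
kernel; the implementation evaluates the integral of the squared
difference in closed form with truncation at the train end, and returns
the square root, so it is a metric (the squared form is available via a
flag).  SPIKE-synchronization follows the published adaptive-window
definition: a spike is coincident if its nearest partner lies within
half the minimum of the four surrounding inter-spike intervals; edges
use the distance to the train boundaries; two empty trains are defined
as synchronous (value 1) with a warning.  Caveat: for very sparse trains
the adaptive windows become large and the measure saturates toward 1
for *both* genotypes, so the WT/KO contrast is diluted at the lowest
input rates; the summary statistic reported is the mean over the rate
sweep of the per-rate WT/KO ratio.

## Network model

Geometry: 187 MF terminals and 487 GCs uniform in a sphere of 80 µm
diameter; each GC wires to 4 distinct MFs within a 30 µm dendritic
reach (nearest-4 fallback).  MF activity patterns with target active
fraction f and correlation radius σ are made by thresholding a Gaussian
random field with squared-exponential covariance exp(−d²/2σ²) at the
(1−f) quantile; active fibers fire Poisson spikes at 50 Hz in a 30 ms
window, and responses are spike counts in that window starting from
rest (no equilibration).

The network carries its own synaptic weights (AMPA direct 1.05 nS,
spillover 0.26 nS, NMDA 1.61 nS; kinetics and depression shared with
the single-cell bundle).  This is deliberate: the single-cell
amplitudes are calibrated against 1 s steady-state depression, which a
30 ms window never reaches, and using them directly makes nearly every
GC fire (no sparsening).  The network weights are set once so the
control network operates in the canonical sparsening regime — GC active
fraction below the MF active fraction and population sparseness at or
above the MF level — while remaining responsive to the KO scalings.
The KO condition is expressed *only* through the three scalings, applied
to these weights.

## Coding statistics and the perceptron

Population sparseness is the Treves–Rolls statistic
S = (N − (Σxᵢ)²/Σxᵢ²)/(N − 1) per pattern, averaged over patterns
(all-zero patterns are skipped; 1 = one active unit, 0 = uniform).
Total variance is Σᵢ var(vᵢ) across patterns, population convention
(divide by n; ddof switchable).  Population correlation is the mean
off-diagonal entry of the between-unit correlation matrix with
zero-variance units excluded — an approximation chosen because the
upstream definition is not restated in the sources available to this
package.  GC statistics are normalized to the same statistic on the MF
patterns.

Learning speed: a single-layer perceptron with 10 logistic output units
classifies the patterns into 10 random, exactly balanced classes;
training is full-batch delta rule (gradient of the summed squared error,
averaged over patterns, learning rate 0.3), stopping when the RMS output
error reaches 0.2; learning speed is 1/epochs (0 if the criterion is
never reached within 5000 epochs).  Two design choices matter and were
made after measurement:

* Inputs are the spike counts *mean-centered per unit*, not
  standardized and not raw.  Per-unit standardization rescales every GC
  to unit variance and thereby erases exactly the response-magnitude
  difference that distinguishes the conditions (with it, the KO
  sometimes learns *faster*).  Raw positive counts destabilize
  logistic-output gradient descent (weights saturate and the error
  plateaus).  Centering removes the destabilizing common offset while
  preserving each unit's response variance — the condition signal.
* Learning rate 0.3: large enough to converge within the epoch budget
  on MF patterns, small enough that convergence order between
  conditions is not scrambled by oscillation.

All-zero GC patterns are kept in the training set; they carry
class-inconsistent information and legitimately slow learning.

## Problem sizes and reproducibility

Default experiment sizes are desk scale: 10 rates × 10 runs × 1 s for
the single-cell sweeps, and a 3 × 3 (f, σ) grid × 640 patterns × 2
conditions for the network (the test suite uses a 3 × 2 grid).  Every
stochastic experiment is specified by a master seed expanded through
label-separated seed manifests, and reruns bit-identically.

## What the synthetic data does and does not show

The generator emulates the *structure* of the study inputs — regular
and refractory-Poisson stimulus trains, grand-average-like conductance
trains with additive Gaussian noise (clipped at zero), spatially
correlated binary MF patterns — with known ground truth, so the fitting
and analysis stages are testable end-to-end.  It does not emulate
cell-to-cell parameter variability, recording noise correlations,
in-vivo MF rate modulation or bursting, or Golgi-cell feedback; passing
tests therefore demonstrate correctness of the computations and the
internal consistency of the model, not quantitative agreement with any
particular recorded cell.  Absolute firing rates depend on the stand-in
presets; the WT/KO ratios, the mechanism decomposition, and all
matched-seed orderings are the results that survive preset uncertainty.

## Known limitations

* Forward Euler at 50 µs limits spike-time accuracy (see above);
  comparisons are rate- and count-based.
* The Hill-fit offset (x_half) of the KO model is the least stable
  headline number across master seeds (roughly ±3 Hz at n = 10 runs).
* The perceptron is one documented variant of a family; absolute epoch
  counts are not comparable across variants, only the condition
  orderings and MF-normalized ratios are.
* The spillover component shares its release process with the direct
  component; true glomerular spillover pools across terminals and can
  saturate independently.
* NMDA facilitation is available as an option but off by default; the
  depression-only configuration is the one calibrated and tested.
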