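# Methods

## Scaffold geometry

The tissue block stacks, along the depth axis *y*, a cerebellar cortical
volume of 400 × 330 × 400 µm³ (185 µm molecular layer, 15 µm Purkinje-cell
monolayer, 130 µm granular layer; mossy-fiber glomeruli are represented as
points in the granular layer), the cerebellar nuclei (200 × 600 × 200 µm³,
centred beneath the cortex), and an olivary volume of 100 × 200 × 40 µm³
chosen to hold the cortical-to-olivary volume ratio at 66:1, inside the
murine 66–68:1 range.  The transversal plane is *x–z*; the parasagittal
plane *z* = 200 µm splits the cortex into two 200 µm microzones.  Each
microzone plus the position-based halves of the nuclear and olivary
populations forms one microcomplex.

Population counts are fixed (MF 7073, GoC 219, GrC 88164, MLI 1206, PC 69,
DCNp 12, DCNi 12, IO 12; 96,767 total).  Cortical and nuclear somata are
placed uniformly at random in their layers.  The 12 olivary cells —
`floor(15,172 cells/mm³ × 0.0008 mm³)` — are deposited by a self-avoiding
bounded random walk (step 10 µm, boundary reflection, minimum inter-soma
distance 2 r_IO).  Each nuclear interneuron (DCNi) is placed as a
satellite of its projection neuron (DCNp) at a distance drawn uniformly
from [d₁, d₂] with d₁ = r_DCNp + r_DCNi and d₂ = mean pairwise DCNp
distance/4 − r_DCNp − r_DCNi, resampled until it is nearer its parent than
any other DCNp.  Soma radii (DCNp 10, DCNi 5, IO 7.5 µm) are working
assumptions used only by these collision rules.  Microcomplex labels:
cortical neurons by their *z* slab; DCNp and IO by an equal-size *z*-rank
split (ties by index; equivalent to balanced 2-means when the transversal
separation dominates); DCNi inherit their parent's label.

## Connectivity

Each of the 19 pathway rows carries convergence/divergence statistics, a
peak conductance (nS), a delay (ms), an alpha time constant (ms) and a
sign.  Exact-convergence rows (MF-GrC 4, PF-GoC 1600, MLI-PC 20, CF-PC 1,
MF-DCNp 147) realize their in-degree exactly; statistical rows draw
per-target in-degrees from the stated Gaussian, rounded and clipped at 1
(and above by the candidate pool).  Candidate presynaptic partners are
restricted by axis-aligned transversal reaches standing in for axonal and
dendritic spans — e.g. parallel-fiber rows accept any *z* but |Δx| ≤
100–150 µm, ascending-axon rows use tight 30–50 µm windows with each
granule-cell axon contacting at most one target per row, glomerular rows
use 60–150 µm windows.  The reaches are configuration values; only the
convergence/divergence statistics, not morphology-intersection rules, are
enforced.  Olivonuclear loops (IO-DCNp, IO-DCNi, DCNi-IO) are 6 × 6
all-to-all within each microcomplex; climbing fibers are dealt round-robin
so each Purkinje cell has exactly one and each olivary cell contacts 4–8.
Confined rows (PC-DCN, IO-DCN, DCNi-IO, CF-PC, CF-MLI) never cross
microcomplex labels; crosstalk travels only through parallel fibers and
shared mossy-fiber collaterals.  Basket- and stellate-type
molecular-layer interneurons (random half/half split) differ in their
parallel-fiber convergence (1004 vs 1021) and their delay onto Purkinje
cells (4 vs 5 ms).  Climbing-fiber-to-interneuron spillover is modeled as
per-synapse delays drawn once at build time from N(70, 10) ms; the
gap-junction-coupled interneuron subnetworks (GoC-GoC, MLI-MLI) are
approximated as fast chemical synapses with 1 ms delay.  The realized
scaffold totals ≈ 4.18 M synapses, within 1% of the 4,151,182 reference
(the table's means are rounded, and clipping at 1 slightly inflates
low-mean rows).

## Neuron models and integration

EGLIF neurons couple the membrane to an adaptation current (incremented by
A₂ per spike, driven by voltage through k_adap) and a fast depolarizing
current (reset to A₁ per spike); spikes are drawn from an exponential
escape rate λ₀·exp((V−V_th)/ΔV).  The isolated three-variable subthreshold
system is linear; the scalar step API advances it with the exact
matrix-exponential propagator (step-size invariant, verified against a
high-accuracy ODE oracle).  In the network, synaptic input enters as a
total conductance G and reversal drive Σ g·E_rev frozen over the step, and
the membrane uses the exact exponential update with G folded into the
effective leak rate.  This is unconditionally stable for arbitrarily large
conductances — a frozen-*current* update at dt = 1 ms diverges on the 3 pF
granule cell once Golgi inhibition grows — while the spike-triggered
currents advance by exponential splitting with the start-of-step voltage
in the adaptation coupling (O(dt²) cross terms).  During the refractory
period the membrane is clamped at V_r while the currents keep evolving.
The default resolution is dt = 1 ms (delays round to the nearest step,
minimum one step; sub-millisecond τ_α values are handled exactly by the
per-step alpha-filter propagation), configurable down to 0.1 ms.

The LIF control model shares every passive parameter per population and
differs only in its pacemaker current, matched to the same tonic rate by
inverting the closed-form constant-drive LIF rate.  Isolated LIF rates are
assessed at dt = 0.1 ms because the deterministic model quantizes its ISI
to the grid.

## Parameter provenance

Per-population parameter values are placeholder sets produced by this
package's own calibration — synthetic stand-ins, not the original
published single-neuron optimizations.  Passive values are
literature-typical per cell type; pacemaker currents come from the
monotone bisection tuner (`tune_intrinsic_current`); escape-noise and
spike-triggered parameters were calibrated once against the in-vivo
working points and phenotypes: PC 85 Hz tonic with CV_ISI 0.2 and a
complex-spike burst-pause; DCNp 65 Hz with CV_ISI 0.2 and a
release-from-inhibition rebound burst; GoC 10 Hz, MLI 15 Hz, DCNi 25 Hz,
IO ≈ 1 Hz (typical in-vivo rates for these types); granule cells are not
spontaneously active.  Frozen isolated-cell measurements: PC 85.0 Hz /
CV 0.180, DCNp 64.3 Hz / CV 0.205.

## Stimulation protocol

Baseline: 4 Hz Poisson on all mossy fibers for 1 s.  Conditioned stimulus:
40 Hz Poisson for 260 ms on the mossy-fiber bundle inside a cylinder of
radius 150 µm at the centre of the transversal plane spanning the granular
layer (≈ 44% of mossy fibers; counting glomerular territory within a 50 µm
rosette reach, ≈ 80% of glomeruli receive afferent input).  Unconditioned
stimulus: a regular 500 Hz, 10 ms burst — read as a deterministic volley —
forced as suprathreshold spiking of the six microcomplex-1 olivary
neurons, so the CF-PC, CF-MLI and olivonuclear collateral pathways all
carry it; it co-terminates with the conditioned stimulus at 1260 ms.  A
final 500 ms of silence closes the 1760 ms trial.  Membrane potentials are
initialized uniformly between E_L and V_th per neuron, identically for
both models.  Four independent seed streams (placement, connectivity,
simulation, initialization) keep structure and dynamics separable;
repeated runs reuse one network instance with shifted simulation and
initialization seeds.

## Analysis

PSTHs use 5 ms bins normalized to population rate.  Instantaneous rates
convolve spike trains with unit-area Gaussians (σ = 5 ms for PC, 10 ms for
DCNp), truncated at ±4σ and renormalized by the kernel mass inside the
grid so the trace integrates to the spike count.  The response speed
searches the maximum and minimum of a trace in the 100 ms window starting
5 ms after the climbing-fiber burst onset and reports
(max − min)/(t_max − t_min): negative for burst-then-pause, positive for
pause-then-burst, 0 for a flat trace.  Speeds are computed on two routes —
per neuron (the formula's definition) and on the population-mean trace of
microcomplex-1 — and both are reported.  For the 35-cell Purkinje
population the routes agree; for the 6-cell DCNp population the per-neuron
statistic is noisy (single-neuron rate fluctuations at 60 Hz compete with
the rebound within the window), so the EGLIF-vs-LIF significance claim
uses the population-mean route with one value per simulation (n = 5 per
group), and the per-neuron means are still reported for the ordering.
Model comparison uses the two-sample t-test; a permutation test serves as
an independent oracle in the test suite.  The eyeblink decoder drives a
leaky accumulator per microcomplex (update 1.0 per DCNp spike, 10 ms decay)
through a 50-sample moving average (50 ms at dt = 1 ms); the net response
defaults to the baseline-subtracted sum of the two microcomplex signals
(difference selectable).

## What the simulations show — and do not show

With the Table-parameterized scaffold and calibrated placeholder neurons,
the EGLIF network reproduces the qualitative response grammar: Purkinje
baseline ≈ 88 Hz rising ≈ 15 Hz during the conditioned stimulus;
synchronized complex spikes (≈ 600 Hz population bins) followed by a
≈ 20 ms pause and a later spillover-mediated dip; nuclear pause then
rebound; and an eyeblink trace that is faster and sharper than the LIF
network's.  Per-neuron PC speeds run ≈ −19 Hz/ms (EGLIF) versus ≈ −4 Hz/ms
(LIF), p < 10⁻²⁵⁰; DCNp population-mean speeds ≈ +1.4–1.7 versus ≈ +0.5,
p < 0.01.  These magnitudes depend on the placeholder parameter sets; the
published single-neuron optimizations would shift them (the reference
study reports −23.82 ± 1.96 vs −2.25 ± 0.91 and 1.72 ± 0.83 vs 1 ± 0.06),
so only sign, ordering and significance — not exact means — are treated as
reproduction targets.  The synthetic scaffold also does not emulate
morphology-derived connectivity microstructure, dendritic processing,
true gap-junction coupling, or any plasticity; conclusions about learning
or oscillatory dynamics are out of scope.

## Problem sizes and numerical choices

The default full-scale build (96,767 neurons, ≈ 4.18 M synapses) takes
≈ 45 s and one 1760 ms simulation 10–30 s on a single CPU; the test suite
runs the structural checks on one shared build and the dynamics checks on
five paired EGLIF/LIF runs of that same instance, plus a 2%-scale toy
network for fast engine and protocol tests.  Reduced networks clip exact
convergences to their candidate pools and keep even nuclear/olivary counts
so the two-cluster split remains defined.  Delays shorter than the
resolution are rejected at configuration time (spillover delays are
clipped at 1 ms); Gaussian-drawn in-degrees clip at 1; tie-breaks
(clustering, trace extrema) go to the lowest index / earliest time.
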