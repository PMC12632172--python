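# Methods

This note records the models, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Observation model

The loop's scalar observable is the PS fraction: at one composition the
virtual laboratory draws an analyzed-droplet count n uniformly from
[50, 250] (the replicates that land in the imaging field) and a PS count
from Binomial(n, p(c)), where p is a smooth ground-truth function of the
final solute concentrations. Concentrations are a linear view of the
search coordinates: c_i = stock_i · flow_i / total_flow, with a
plain-buffer counter flow topping every composition up to the total
aqueous flow (100 µL/h by default). Search coordinates are flow rates
throughout; ground-truth models operate on concentrations so their
weights carry physical units (per M, per g/L, per %w/w).

Ground-truth kinds: `logistic_linear` (p = logistic(k·(w·c − offset)),
the default), `logistic_radial` (a spherical 0.5-shell), and
`user_table` (multilinear interpolation of a gridded CSV). The shipped
`demo_system_*` fixtures emulate an RNA-homopolymer / salt / crowder
solution set with a monotone boundary crossing the flow window; the 4D
fixture encodes the influence ordering KCl > NaCl > PEG > poly rA with
effect sizes 2.4, 1.2, 0.6, 0.3 over each variable's concentration range
— adjacent effects separated by exactly 2× and every normalized weight
above 0.1, the regime in which discriminant summaries are reliably
recoverable. These fixtures are synthetic; no quantitative agreement
with any real condensate system is claimed.

Design spaces permit per-variable flow bounds whose maxima jointly
exceed the total flow (such compositions are rejected at balancing
time), but campaigns require sum(flow_max) ≤ total_flow so that
independent per-coordinate sampling — the random initial batch and the
acquisition box bounds — can never propose an unbalanceable composition.

## Surrogate

PS fractions are regressed untransformed by a Gaussian process with a
constant (signal-variance) kernel multiplied by an anisotropic Matérn
5/2 kernel. Inputs are scaled to the unit cube internally; length scales
are constrained to [1%, 100%] of each dimension's range (the upper bound
prevents washing a variable out entirely; the lower bound prevents
delta-like overfitting) and reported in flow units. Hyperparameters
maximize the marginal likelihood with up to 25 random restarts seeded
from the campaign seed; campaign refits additionally warm-start from the
previous iteration's hyperparameters, which the restarts may still
override. Targets are mean/variance-normalized, so a constant training
set predicts its own value everywhere.

No white-noise kernel is fitted; a diagonal jitter of 1e-6 stabilizes
the Cholesky factorization. An observation-noise option exists for
campaigns: `noise_level="binomial"` charges each sample its estimated
fraction variance y(1−y)/n. It is off by default, but recommended when
acquisition concentrates samples near the boundary, where replicate
noise is largest: an interpolating GP fitted to such clusters shrinks
its length scales onto the noise and the KL monitor spikes by orders of
magnitude (values above 1e6 were observed in exploit-mode campaigns).

With a single observation the hyperparameters cannot be optimized; the
fit degrades, with a warning, to a prior-mean model. Predictive means
may leave [0, 1] slightly; `clip_probability` provides the clipped
reporting view, while acquisition and KL always use the raw field.

## Acquisition and batching

All four modes are minimized. Exploit is |μ − target| (target 0.5, the
boundary); explore is −σ; hybrid is −σ²/(|μ − target| + ε) with ε = 0.5;
random draws uniformly and bypasses minimization. Minimization runs
Nelder–Mead from the best of 100 uniform probe points; the five polished
starts are chosen greedily down the probe ranking subject to a minimum
scaled separation of 0.1, so distinct basins each get a simplex.
Out-of-bounds simplex proposals are scored at their clipped projection
plus a quadratic distance penalty, and the returned point is clipped.
On fixed-kernel 1D/2D test surrogates this reaches the 201-per-dimension
grid optimum in ≥95% of seeded trials for every model-based mode.

Batches are assembled sequentially: after each selection a Gaussian bump
(width 0.1 of each dimension's range) is added at the selected point and
the penalized landscape is re-minimized. The bump amplitude equals the
dynamic range of the acquisition over the probe points — large enough to
dominate locally and force diversity, small enough not to erase the
landscape globally (an absolute floor of 1 would exceed the hybrid
landscape's range by 10–500× and reduce every batch to space-filling);
a fallback amplitude of 1 covers degenerate flat landscapes. Exact ties
between multistart minima keep the earliest start.

## Convergence monitoring

Between successive iterations the posterior change at every point of a
fixed monitoring grid (21 per dimension by default, endpoints included)
is the closed-form KL divergence between the two Gaussian predictive
distributions, with P the current and Q the previous posterior —
measuring the information added by the newest batch; the assignment is
a package convention since KL is asymmetric. Standard deviations are
floored at 1e-6 before evaluation. The scalar monitor is the root sum
of squares over the grid, deliberately unnormalized to preserve
sensitivity to steep local transitions. Per-dimension traces report the
RSS over the 1D transect through the grid midpoint along each axis; the
kernel length-scale trajectory is logged alongside as a complementary
per-dimension diagnostic (a short length scale flags a steep, influential
variable). Termination requires the RSS to stay below a user threshold
for `patience` consecutive iterations; the check is evaluated every
iteration but acts only when early stopping is enabled (off by default,
so benchmark campaigns always run their full budget).

## Imaging stage

Synthetic micrograph pairs mimic the two fluorescence channels: uniform
bright disks on a noisy background locate droplets; Gaussian puncta
strictly inside PS droplets report condensates. Defaults: 256×256 px at
1.3 µm/px, droplet radii 8–14 µm, 1–3 puncta per PS droplet placed
within half the radius, signal ≈ 20σ above the Gaussian read noise.
Analysis is classical: Gaussian smoothing (σ = 1 px), a global threshold
halfway between the robust (median/MAD) background and the bright
foreground, connected components, border-touching components discarded,
then a radius window (equivalent-disk, µm) and a circularity filter
(4πA/P² with the Crofton perimeter, clipped to 1, minimum 0.8) — the
"symmetry and radius" validity rules. Condensates are local maxima of
the smoothed PS channel above median + 8 robust SDs. A droplet is PS
when a punctum lies within 0.9 × radius of its centre; each punctum
counts for its nearest centre only (ties to the lowest index). The PS
fraction is PS droplets over detected droplets; an empty detection is a
degenerate sample, not a zero.

The learned detectors used on real instruments are deliberately out of
scope; the surrounding contracts (filters, distance check, fraction) are
detector-agnostic so one can be slotted in. At the default noise level
the classical detector is essentially exact (recall 1.0, no false
positives over 50 rendered fields), so image-routed campaigns measure
loop behaviour, not detector robustness; raising `noise_sd` or lowering
intensities degrades it smoothly.

## LDA summaries

Samples are labelled PS when their fraction is ≥ 0.5 (the boundary
target). Inputs are standardized per dimension before fitting the Fisher
discriminant, so weight magnitudes are comparable across solutes;
reported weights have unit Euclidean norm with the sign oriented so the
PS class projects higher, and raw-space coefficients are exported
alongside. The decision value is the equal-prior midpoint of the class
mean projections. With ~200 samples the weakest shipped effect
(normalized weight ≈ 0.11) is sign-recovered in ≈95% of campaigns;
substantially smaller effects or fewer samples make the sign a coin
flip, which is the expected statistical behaviour, not a defect.

## Cost model

Traditional workflow: 10 samples per dimension-1 study and ×10 per added
dimension, 5 min and 100 µL each, researcher present throughout.
Closed-loop platform: fixed budgets of 11 (3D) and 21 (4D) iterations at
7 min and 10 samples each, ~1000 droplets of ~100 pL per sample — all
produced droplets are charged, not only the imaged subset, the
accounting least favourable to the platform — and the researcher attends
only the first iteration. Both are charged 1 g/L of precious material.
Under these defaults a 4D study improves 340× in time and ≈47,600× in
material. The single-innovation presets (automated analysis,
microfluidics-only with its 10×-3D rule for 4D) bracket the comparison
but carry no numeric claims.

## Seeds and reproducibility

A master seed spawns an independent `SeedSequence` per (iteration,
component) — batch selection, observation, fitting, imaging — so any
iteration can be reproduced in isolation and a resumed campaign
continues the exact stream a straight-through run would have used;
resuming replays the warm-started fit chain from the persisted samples.
Campaign logs are plain CSV and byte-identical across reruns with the
same configuration and seed.

## Problem sizes in the shipped studies

The test suite and the acceptance script scale the studies to desk size:
strategy comparisons use the 2D system with 8 iterations × 5 samples and
10 seeds per mode; boundary recovery uses the 3D system with 10
iterations × 10 samples over 20 seeds; LDA recovery uses 200-sample 4D
campaigns over 20 seeds; the imaging round trip renders 50 fields of
20–40 droplets. These sizes were chosen to keep the statistics stable at
interactive runtimes.

## Known limitations

- The hybrid acquisition with ε = 0.5 is exploration-dominated until the
  uncertainty field is nearly flat: its denominator varies at most 2×
  over the design space (|μ − 0.5| ≤ 0.5) while σ² varies by one to two
  orders of magnitude during a short campaign. In the scaled-down 2D
  studies (40 samples), hybrid sampling therefore spreads like explore
  and does not yet concentrate on the boundary the way a longer campaign
  does; exploit shows the boundary-seeking behaviour unambiguously.
- The final-iteration RSS-KL of a short campaign is dominated by
  marginal-likelihood hyperparameter drift between refits rather than by
  the sampling strategy, so single-iteration KL values separate the
  strategies only weakly at this scale; the qualitative decay of the
  trace is the robust signal.
- The virtual laboratory models droplet counts and binomial PS outcomes
  but not condensation kinetics, droplet coalescence, dye partitioning
  or instrument drift; passing its tests shows the loop and analysis are
  correct, not that any particular real system behaves logistically.
- The GP regresses fractions without a link function (matching the
  plain-regression treatment); predictions can leave [0, 1] near sharp
  boundaries and are clipped only for reporting.
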