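# Methods

## Model

The duplex is a one-dimensional lattice of N base pairs; the state of pair
*n* is the reduced transverse stretch y_n = (u_n − v_n)/√2 of its two bases.
The potential energy is

    V(y) = Σ_n D_n (e^{−a_n y_n} − 1)²
         + Σ_bonds (k/2) (1 + ρ e^{−β (y_n + y_{n−1})}) (y_n − y_{n−1})²

The Morse term models hydrogen bonding plus solvent/phosphate repulsion;
(D_n, a_n) depend only on the pair class (A-T vs G-C). The stacking term
couples neighbours; its exponential factor drops from (1+ρ)k/2 to k/2 as
either pair opens, which is what makes opening cooperative and bubbles
long-lived. A two-strand stacking form that distinguishes the u and v
strands (with independent constants K_u, K_v) is exposed for evaluation
(`stacking_potential_full`), but the equation of motion is written and
integrated in y only; the reduced anharmonic form above is the standard
single-coordinate reduction, and the two forms are not numerically
identical — the reduced form is normative here.

Boundary conditions: periodic by default (position 0 couples to N−1), with
an open mode for flanked linear fragments. Flanks are part of the simulated
lattice but excluded from all reported statistics (the `core_span` of an
encoded sequence).

### Parameters

Defaults ship in `src/epbdsim/data/default.params` (editable, flat
key=value), never hard-coded:

| parameter | default | units | meaning |
|---|---|---|---|
| D_AT / D_GC | 0.05 / 0.075 | eV | Morse depth (2 vs 3 hydrogen bonds) |
| a_AT / a_GC | 4.2 / 6.9 | 1/Å | Morse inverse width |
| k_stack | 0.025 | eV/Å² | stacking constant (uniform) |
| ρ, β | 2.0, 0.35 /Å | — | anharmonic stacking strength / range |
| m | 300 | amu | base-pair mass |
| γ | 5.0 | 1/ps | thermostat friction |
| T | 310 | K | setpoint |

These are the canonical two-class EPBD values of the established
literature lineage. The friction γ is a package design choice: 5 ps⁻¹ is
solvent-like moderate damping, near critical damping of the A-T well
(ω_AT ≈ 7.5 ps⁻¹), so the lattice thermalises in ~0.2 ps — comfortably
inside even heavily scaled-down preheating phases — and successive samples
decorrelate quickly. `k_stack` may instead be a per-dinucleotide table
(`k_stack.AG = ...`), the hook for sequence-specific stacking; no table is
shipped because no vetted set of constants is bundled with the package.

Internal units are eV / Å / amu, giving the derived time unit
t₀ = √(amu·Å²/eV) = 10.1805 fs; k_B = 8.617×10⁻⁵ eV/K. User-facing times
are fs (dt), ps (preheat), ns (production).

## Integrator

Midpoint (RK2) discretisation of the second-order Langevin equation. Per
step, one Gaussian force realisation ξ with per-component variance
2 m γ k_B T / dt is drawn and held fixed in both stages:

    f(y, v) = F(y) − m γ v + ξ
    y½ = y + dt/2·v ;  v½ = v + dt/2·f(y, v)/m
    y′ = y + dt·v½  ;  v′ = v + dt·f(y½, v½)/m

The placement of the noise is a design choice (the scheme name alone does
not fix it); it is validated against behaviour, not against a reference
implementation: (i) in the deterministic limit the one-step error is third
order and the energy drift over 10⁴ steps at 1 fs is <10⁻⁴ with
second-order convergence in dt; (ii) the stationary distribution of an
isolated pair matches the Boltzmann quadrature density (KS < 0.02 at 10⁵
samples, 50 K); (iii) the kinetic temperature recovered via equipartition
matches the setpoint within 3 standard errors. For the linear
(Ornstein-Uhlenbeck) part the scheme's stationary velocity variance is
k_B T/m · (1 + O((γ dt)²)), i.e. the temperature bias at γ dt = 0.005 is
negligible.

Initialisation is exactly y = ẏ = 0 (closed helix at rest); preheating
alone provides thermalisation, and no preheating frame is recorded.
Stability: the G-C well has ω dt ≈ 0.015 at dt = 1 fs; the bounded
oscillatory energy error of the midpoint scheme grows with (ω dt)², so
deterministic-limit conservation checks on G-C-rich lattices favour
dt = 0.5 fs. A non-finite state aborts the run with the step index.

Time step: dt is a single user-set quantity, default 1 fs. A dimensionless
step of 2×10⁻⁵ in internal model time units also circulates for this model
family; it is deliberately not silently adopted — set dt explicitly if you
want it.

## Seeding and batching

Each (sequence index, run index) pair owns a `numpy` PCG64 stream spawned
from the root seed via `SeedSequence(entropy=seed, spawn_key=(i, r))`,
consumed strictly in step order. Batched execution stacks runs along a
leading axis and draws each run's noise from its own stream, so results
are bitwise identical however runs and sequences are partitioned (grouped
by length; `batch_size` only bounds group width). Memory scales as
M × n_frames × N doubles; for long campaigns increase the sampling stride
or split the ensemble.

## Statistics

* **Average coordinates**: mean of y over runs and production frames per
  core position; the standard error is the between-run spread of per-run
  time means (robust to within-run correlation).
* **Flipping probability**: fraction of (run, frame) samples with
  y ≥ tr; the comparison is inclusive. Default sweep: five thresholds,
  0.7071–3.5355 Å in 0.7071 Å steps.
* **Bubbles**: at each frame the open mask is y ≥ tr; an event is a
  maximal run of open positions with a fixed (start, length) persisting
  over consecutive frames. Any change of start or length (growth, shrink,
  split, merge) ends the event and starts new ones — the simplest
  well-defined identity rule. P(n, l, tr) = total event lifetime/(t_s·M)
  with t_s the *recorded* duration (n_frames × frame interval), which
  makes a permanently open configuration score exactly 1. τ(n, l, tr) is
  the pooled mean lifetime across all runs (total lifetime / total count);
  cells with no events are NaN (absent), not zero. Default sweeps:
  lengths 3–20 bp, thresholds 0.5–15.0 Å in 0.5 Å steps.
* **Maximal vs containment semantics**: maximal-event quantities are not
  monotone in l or tr by construction, so the *all-open occupancy* tensor
  (fraction of samples with positions n…n+l−1 simultaneously open, no
  maximality) is computed alongside; it is exactly non-increasing in both
  l and tr and bounded by the weakest single-site flipping probability in
  the window. Both tensors are exported, labelled.
* Bubbles never wrap the N→1 junction even under periodic boundaries:
  reported features concern the linear biological sequence.
* Resolution: lifetimes are quantised to the frame interval; events
  shorter than one frame are invisible. Choose the stride accordingly.
* **ML features**: per-position one-hot blocks (base order A, C, G, T,
  position-major) followed by the mean-opening profile — 5 features/bp.

## Synthetic data and what the tests show

All tests run on generated inputs: homopolymers, uniform random sequences,
and wt/mt substitution pairs (A/T-rich background, one dinucleotide
substituted). Under the two-class Hamiltonian with uniform stacking an
A↔T or G↔C swap is dynamically invisible, so the substitution-sensitivity
check substitutes AT→GC, which changes the pair classes at the site; with
sequence-specific stacking constants (the `k_stack` table hook) strand-
preserving substitutions would also become visible. Real genomic sequence
is supplied as ordinary FASTA input.

The generators emulate composition and single-site perturbations; they do
not emulate sequence correlation structure, methylation/damage chemistry,
supercoiling or salt effects. Passing tests therefore demonstrate the
correctness of the mechanics and statistics, and qualitative sequence
sensitivity — not quantitative agreement with any particular measured
promoter profile.

### Scaled problem sizes

The validation suite runs the study protocol at reduced size, chosen once
as the package's own test conditions: thermostat check M=50, 20 ps + 20 ps
(vs the production default M=1000, 200 ps + 1 ns); stationary-density
check 100 runs × 100 ps of an isolated pair (10⁵ samples); substitution
check M=200, 10 ps + 20 ps on 25-bp sequences. At near-critical damping
these lengths are dozens of relaxation times, sufficient for the stated
tolerances (3 SE; KS < 0.02; permutation p < 0.05).

## Known limitations

* The melting-relevant long-time tail (rare large bubbles) needs the full
  1 ns × M=1000 protocol; the scaled checks do not probe it.
* No helicoidal/twist degrees of freedom, no salt dependence, no
  sequence-specific stacking table shipped.
* The midpoint scheme is not symplectic; its deterministic-limit energy
  error is bounded and small at the default step but grows as (ω dt)².
* The whole trajectory tensor is held in memory; stream-processing of
  features is not implemented.
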