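# Methods

`gasport` analyzes how small gas molecules (dioxygen in the motivating
application: the prolyl hydroxylase PHD2 with its HIF-1α substrate peptide)
reach a buried catalytic metal center.  The pipeline takes flooded-gas
trajectories — many non-interacting gas molecules diffusing around a fixed
anchor — and produces event statistics, residue-contact pathway
assignments, grid-based Markov state models (MSMs), and
transition-path-theory (TPT) kinetics.  This note records the models,
parameter choices and numerical decisions, and what the synthetic
validation does and does not establish.

## Coordinates and event tracing

All analysis happens in anchor-relative coordinates: frames are optionally
superposed onto a reference frame by an equal-weight Kabsch fit of
user-supplied reference atoms, then every gas position is expressed as
`gas − anchor`.  We store the gas-minus-metal vector (not the reverse) so
exported state clouds overlay the protein frame directly; distances are
unaffected.  The fit-atom set is configurable because no single choice is
canonical; with no reference atoms the frames are taken as already aligned.

An *access/egress event* is a traced excursion between the outer shell
(`r_outer`, default 20 Å) and the inner catalytic cutoff (`r_inner`,
default 6 Å) at the analysis stride (default 10 ps).  For each maximal
sub-cutoff dwell, the entry is traced backward to the last frame beyond
`r_outer` and the exit forward to the first such frame.  Two dwells whose
separating excursion never reaches the outer shell are merged into one —
otherwise rattling at the 6 Å cutoff would be double-counted.  Dwells with
no outer-shell crossing before the trajectory start (or after its end) are
*censored*: counted, excluded from mean entry/exit times.  Entry time is
`t(first d < r_inner) − t(last d > r_outer)` at the saved stride; the
first-crossing-frame convention is ours, since only the tracing direction
is canonical.

## Contacts, the trapped filter and pathway labels

A contact is any residue atom within 3.5 Å of a gas site in a frame;
frequencies are reported in contacts per nanosecond of traced event time.
For diatomic input both atom sites are checked; the synthetic gas has a
single site.  The trapped ("starred") filter removes residue/event pairs
whose contact *fraction* exceeds 0.75 — a molecule parked on one residue
for most of an event otherwise dominates the contact table.  Only the
offending pair is removed; the event and its other contacts remain, so
starred frequencies are bounded by unfiltered ones.  The report floor is
12 contacts/ns, matching the smallest values worth tabulating; raw
per-pair output always retains everything.

Pathways are user-defined signature residue sets.  An event gets the label
whose signature accumulates the highest summed contact frequency over the
whole traced segment (not just the first contact), ties broken by a
priority rank, zero-contact events labeled `unassigned`.  Overlap
statistics count pairs of events from different molecules whose
outer-to-outer time spans intersect; the window choice (full traced span)
is ours.

## Grid MSMs

Anchor-relative positions sampled at the MSM stride (default 100 ps) are
rounded to the nearest point of a 1 Å grid over a 40 Å cube centered on
the metal — 40³ = 64,000 possible states.  Out-of-cube positions are
wrapped by minimum image with the cube period (default) or clamped to the
face; both modes are implemented and recorded in outputs because the
underlying convention is ambiguous, and clamping makes both ±20 Å faces
distinct (41³ states).

Transition counts use a sliding window at lag τ, skipping pairs that touch
null frames (frames outside traced events when event restriction is on).
The maximum-likelihood transition matrix is the row normalization
`T̂_ij = c_ij / Σ_k c_ik`, which maximizes `∏ T_ij^c_ij`.  The active set
is the largest strongly connected component of the count graph: simply
dropping rows without outgoing counts cascades to an empty set on
path-like event data, because every traced segment ends in a dangling
state.  The stationary distribution π is the leading left eigenvector on
that component, zero elsewhere.  No reversibility (detailed-balance)
constraint is imposed anywhere, including the Bayesian sampler.

Bayesian uncertainty uses per-row conjugate Dirichlet posteriors with a
uniform pseudo-count of 1/N per state (N = active states); the prior is a
convention, so it is exposed as a parameter.  Implied timescales are
`t_k(τ) = −τ/ln|λ_k(τ)|`; eigenvalues with |λ| ≥ 1 are reported as
divergent rather than silently clipped.  The Chapman–Kolmogorov test
compares set-level self-transition probabilities of `T(τ)^k` against
models re-estimated at `kτ`, with 95% bands from the Bayesian samples;
metastable sets come from the leading eigenvectors (sign split for two
sets, k-means above).  Milestoning reduction relabels each frame with the
most recently visited core set, leaving pre-core frames null.

The MSM sink is every visited state within 6.7 Å of the metal — kept
distinct from the 6.0 Å event cutoff because grid rounding can move a
point ~0.5·√3 Å.  Source states are the specific states occupied at event
boundary frames near the 22 Å shell.  On sparse data those exact states
can fall outside the connected set; the pipeline then falls back to the
active states of the outer shell band and logs it.

## TPT kinetics

Committors solve the standard discrete linear systems (backward via the
time-reversed chain `T̃_ij = π_j T_ji / π_i`); reactive flux is
`f_ij = π_i q⁻_i T_ij q⁺_j`, the rate `k = F/(τ Σ_i π_i q⁻_i)`.  The
headline MFPT solves `m = τ·1 + T m` with `m|B = 0`, averaged over the
source set with π-restricted weights (the source-averaging convention is
ours); `1/k` is reported alongside as a companion diagnostic, and the two
agree only approximately.  Unreachable sinks surface as infinite MFPTs.
Linear systems above 2000 unknowns are solved by ILU-preconditioned
LGMRES (residual 1e-10) — an order of magnitude faster than direct
factorization on these grid graphs, at matching accuracy; small systems
use a direct solve.

## Synthetic gas generator

The generator emulates what flooded-gas MD hands to the analysis:
overdamped Euler–Maruyama dynamics `x ← x − D∇U dt + √(2D dt)·ξ` with
reflecting box walls, kT = 1, default D = 1 Å²/ps and dt = 0.01 ps.
Cavities are smooth C¹ wells `U = −depth·S(d/radius)` with the smoothstep
`S(u) = 1 − 3u² + 2u³`, so the force exists everywhere (no rejection
sampling) and vanishes at rim and center.  Molecules are mutually
non-interacting, matching the flooding assumption.  Pseudo-residues are
single atoms on a deterministic Fibonacci lattice over each well surface,
labeled by well id, giving contact classification an unambiguous ground
truth.  A stability check rejects timesteps whose drift per step exceeds
half a well radius.

What the generator does *not* emulate: protein flexibility and gating,
anisotropic tunnels, solvent structure, gas–gas crowding, finite gas size.
Passing the synthetic suites therefore establishes that the estimators
recover known kinetics of a diffusive trap model — not that any particular
protein conclusion is correct.

### First-passage sampling and boundary corrections

`brute_force_mfpt` starts walkers uniformly on a source sphere and absorbs
them at the sink.  Checking absorption only at multiples of dt behaves
like a continuum boundary displaced by ≈0.5826·√(2D dt) (Mannella/Gobet);
we therefore enlarge the absorbing radius by that shift so the sampled
mean converges to the continuum value at practical dt.  Reflecting
boundaries get no shift: specular folding applied every step reproduces
reflected Brownian motion in law, and adding a shift there measurably
overcorrects.  The free-diffusion check against the
closed shell formula `τ = (b³/3D)(1/a − 1/r₀) − (r₀²−a²)/6D` uses
dt = 0.005 ps and 10⁴ walkers, which puts the residual discretization bias
well inside two standard errors.

When the sampler serves as the oracle for an MSM, the semantics must
match instead: a lag-τ model observes first passage at time resolution τ,
and comparing it to sub-step-resolution sampling leaves a systematic
offset that grows with τ (≈60% at τ = 1 ps on the two-well system).  The
`absorb_interval` mode therefore checks absorption every τ with the same
integrator and reflection as the equilibrium simulation, with corrections
off.  Against that matched oracle the two-well MSM MFPT agrees to a few
percent.

### A geometry caveat on traps

A single localized attractive well between source and sink does **not**
reliably slow first passage in 3D: most walkers bypass it, and a well
adjacent to the absorbing zone effectively enlarges the absorber
(capacitance enhancement), cancelling or outweighing retention.  The 1D
radial picture — where a trap always slows passage — only applies when the
trap intercepts the path, i.e. forms (part of) a shell.  The trapping
property test therefore uses an octahedral ring of 4 kT cavities separated
from the sink, where the slowdown is structural; the same arrangement is
what depresses the MSD exponent α below 1.

## Validation study conditions

Fixed conditions, chosen once (sizes set for a single desk CPU and stated
here as the package's own choices):

* **Shell check** — free diffusion, a = 6 Å absorbing, b = 20 Å
  reflecting sphere, start at b, D = 1 Å²/ps, 10⁴ walkers, dt = 0.005 ps;
  agreement within 2 SE of ≈250.4 ps.
* **Two-well system** — 12 Å half-edge box, wells of depth 4 and 3 kT
  (radius 4 Å) at (±7, 0, 0), sink 4 Å, source shell 10 Å; equilibrium
  run of 200 molecules × 5 ns saved at 1 ps; 1 Å grid, lag 2 ps; MSM
  MFPT vs 10⁴ lag-matched first-passage samples, target 15% relative.
  The same trajectory yields the milestoning-vs-full inter-well MFPT
  comparison (cores: 2 Å balls around the well centers) and the
  subdiffusive MSD exponent.
* **Equilibrium recovery** — one 1 kT well (radius 4 Å) in a 10 Å
  half-edge box, 1000 molecules × 2 ns saved at 2 ps (10⁶ frames), 2 Å
  grid; total variation between MSM π and cell-volume-weighted Boltzmann
  weights < 0.05.  Boundary grid cells straddle the walls, so the
  reference weights each state by the in-box fraction of its cell.
* **Markovianity** — a three-state metastable chain sampled exactly;
  CK predictions must lie inside 95% Dirichlet-posterior bands for
  k ≤ 5; the implied-timescale closed form −τ/ln λ₂ is checked to 1e-6
  on an exactly specified two-state matrix.

## Known limitations

* The unconstrained MLE can yield slightly non-reversible matrices on
  finite equilibrium data; committors and π remain well defined, but
  spectra can acquire small imaginary parts (flagged, magnitudes used).
* Event-restricted MSMs on sparse data have small connected sets; kinetics
  then depend on the fallback source/sink selection, which is logged.
* MFPTs from lag-τ models are resolution-bound: they cannot see sub-lag
  sink touches.  Comparisons across lags or against continuum values must
  account for this (see the boundary-correction discussion above).
* The MSD exponent is a fit over a stated window, not a model of anomalous
  diffusion; with trapping, α depends on the window and is reported with
  its fit range.
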