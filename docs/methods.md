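# Methods

## Model tiers

`retronet` maintains two model tiers for the same declared chemistry and
treats their agreement as the package's central correctness contract.

**Mass-action tier.** Each node is a transcriptional component: parent TFs
bind its promoter reversibly, every occupancy state produces the node's TF
at its own rate constant, and free TF decays at δ (gene expression lumped
into one step; mRNA dynamics are out of scope — they sit between the binding
and protein time scales and, at quasi-steady state, leave the reduced
structure unchanged). Multimeric binding is a single lumped step
n·X + P ⇌ C with dissociation constant K in nM^n; no explicit multimer
intermediate species exists. Binding types at a promoter (≤ 2 parents):

- `single` — one parent; states P, C1.
- `independent` — two sites; states P, C1, C2, C12, with the second site's
  on/off rates independent of the first site's occupancy. This choice
  *defines* cycle closure: the two paths to C12 share equilibrium constants,
  so the reaction cycle is thermodynamically consistent by construction.
- `competitive` — one site, two parents; no doubly bound state (its
  production rate α12 is rejected by the schema).
- `cooperative` — sequential: the first listed parent must bind before the
  second; the second-parent-only state does not exist (α2 rejected). The
  schema makes parent order significant for this reason. We forbid a
  second-parent-only production rate rather than allowing a vestigial α2;
  the alternative (a nonzero α2 on a state that cannot be occupied) would be
  meaningless in this scheme.

Off-rate default k_off = 3600 h⁻¹ (~1 s⁻¹, the experimentally typical
TF–DNA unbinding scale), k_on = k_off/K per binding step; ε divides both,
so shrinking ε widens the time-scale separation without moving any
equilibrium. No measured k_on/k_off pair enters any result — only their
ratio K does, plus the qualitative fact that binding is fast.

**Reduced tier.** With binding at quasi-steady state, promoter occupancies
follow a single partition-function form: with activities a_j = x_j^{n_j}/K_j
and binary exponents e_sj marking which parents are bound in state s,
γ_s = p_T · (∏_j a_j^{e_sj}) / Σ_t ∏_j a_j^{e_tj}, where the binding types
differ only in which states exist. Production is H = Σ_s α_s γ_s (the
generalized Hill function). The *node retroactivity* is the Jacobian of
total bound parent amounts (counting n copies per bound n-multimer) with
respect to free parent concentrations, computed analytically from the same
partition function. Total-TF conservation — binding only shuffles TF
between free and bound — gives the reduced model

(I + J(x,u)) ẋ = H(x,u) − diag(δ)x + d(t) − Ju(x,u)·u̇,

with J the sum of node-retroactivity blocks lifted into network coordinates
and Ju the cross-block against exogenous inputs. One engine evaluates this
for an isolated module, a module with inputs, and a wired module/context
pair; the named matrices are block restrictions of J by promoter ownership
and coordinate:

- internal retroactivity R — module promoters, module×module block;
- external retroactivity S — module promoters, module×input block;
- scaling retroactivity S̄ — context promoters, module×module block;
- mixing retroactivity M̄ — context promoters, module×context block;
- context-side counterparts by swapping roles.

Because the joint premultiplier is derived from one conservation identity
over all promoters, the connected reduced model agrees with the mass-action
model by construction; the test suite still verifies this numerically
(below) since it is the one place where an assembly mistake would hide.
For independent binding the off-diagonal node-retroactivity entries cancel
analytically (total bound parent j is p_T a_j/(1+a_j), independent of the
other parent); the implementation zeroes them structurally so the exact-zero
contract holds in floating point.

## Numerical choices

- Reduced RHS solves (I+J)ẋ = b by LU factorization at every evaluation;
  no explicit inverse. A conditioning guard rejects σ_min(I+J) < 1e-12
  (J is built from finite occupancy derivatives; at physiological
  parameters I+J is far from singular).
- Integration: LSODA with rtol 1e-8, atol 1e-9 nM by default (tighter for
  oscillator verdicts), `max_step = 10·dt_out` so that short input pulses
  cannot be stepped over when the system starts at an equilibrium, and a
  BDF fallback for mass-action systems whose multimer activities make LSODA
  fail. Negative excursions are clipped at output only, never inside the
  solver, with a logged warning; excursions beyond 100·atol raise.
- Promoter conservation is asserted on every mass-action output sample
  (drift bound 10·tol·p_T).
- Steady states are roots of the slow field (the premultiplier cannot move
  equilibria given the conditioning guard), via hybrid-Powell with
  multistart on a log-spaced grid, 5 points per dimension over
  [0.01, 10]×(α·p_T/δ) per species, capped at 200 seeded random starts in
  high dimension; duplicate roots merge at 1e-4 relative (the root solver's
  own scatter exceeds 1e-6).
- Response time: first crossing of x0 + φ(x_ss − x0), linear interpolation,
  default φ = 0.5 (exposed as a parameter; all asserted trends are
  φ-independent). The tail must be flat to within 2% of the displacement.
- Oscillation verdicts discard the first 50% of the horizon, split the rest
  into 3 windows, and call *sustained* iff every window's peak-to-peak
  amplitude exceeds 5% of the trajectory range and window amplitudes decay
  by < 5% per window — robust on relaxation-type waveforms where sample-grid
  jitter makes strict non-decrease flicker.
- The robustness metric d samples its region with a seeded Latin hypercube
  (default 256 points) and reports the sampled sup/inf alongside the full
  pointwise profile ‖(I+R+S̄)⁻¹S̄‖₂, so under-sampling is visible rather
  than hidden. d requires structurally zero mixing retroactivity (checked
  from the wiring topology; refused otherwise). In place of the exact
  nonsingularity proviso of the underlying bound we enforce the
  σ_min conditioning guard and surface failures in the report.
- Trajectory discrepancies are normalized by each species' isolated-run
  range, never pointwise values, to avoid division near zero.

## Parameters and the fixture generator

Units are fixed package-wide: nM and hours. The fixture generator samples
log-uniformly (ranges span orders of magnitude) within typical E. coli
values: production rate constant 1–600 h⁻¹ per promoter copy, half-occupancy
concentration 1–1000 nM (so an n-multimer's K is that value to the n-th
power), promoter/gene concentration 2–600 nM (one copy per cell ≈ 2 nM, up
to high-copy plasmids), decay/dilution 0.3–2.5 h⁻¹ (protein lifetime of
order a cell cycle). Binding types are drawn uniformly among the legal
ones; multimerization from {1,…,4}.

The generator emulates random regulatory topologies with physiological
parameter magnitudes. It does not emulate real expression noise, cell-to-
cell variability, growth-rate feedback, shared transcription/translation
resources, or chromosomal context effects — passing tests therefore support
the deterministic, well-mixed, binding-dominated-loading picture only, not
predictions for any particular experimental circuit.

Case-study parameters live in `retronet.casestudies.DEFAULTS`; every value
carries a source note, and each study was placed in the physiological
regime that exhibits the motif's characteristic behavior (for example, the
clock's activator operates at a few nM with single-digit-nM half-activation
so that low-copy DNA already loads it appreciably; the toggle's context
uses high-copy targets so that its pulse-width switching threshold moves
measurably). Quantitative assertions on these studies are trends and
verdicts (orderings, signs, oscillation/switching outcomes), not magnitude
matches.

## Validation strategy

Three independent oracles pin the analytics:

1. **Occupancy**: closed-form γ versus a damped-Newton solve of the binding
   flux fixed point (unit off-rates; equilibria are rate-independent) —
   agreement to 1e-8 of p_T on concentration grids for all four types.
2. **Retroactivity**: analytic Jacobians versus central finite differences
   of the total-bound map over hundreds of random promoter configurations.
3. **Dynamics (master check)**: reduced versus mass-action free-TF
   trajectories for each case-study system at ε ∈ {1, 0.1, 0.01}: the
   discrepancy scales as O(ε) (≈ 1.5e-4 of signal range at worst for ε = 1)
   and must shrink monotonically. Horizons are one to a few characteristic
   times or oscillation periods per system, chosen to probe the dynamics
   without letting limit-cycle phase drift — which grows secularly in any
   long comparison of slightly detuned oscillators — dominate the norm.

The metric's inequality chain ‖ẋ_conn − ẋ_iso‖ ≤ ‖(I+R+S̄)⁻¹S̄‖‖ẋ_iso‖ ≤
d‖ẋ_iso‖ is checked exhaustively on sampled states; the first inequality is
an algebraic identity of the two RHS forms and doubles as a self-test of
matrix assembly.

## Known limitations

- At most two parents per promoter (the catalog above); more general
  combinatorial promoters are rejected at validation.
- Mixing retroactivity makes the metric d inapplicable; the package then
  offers only simulation-based comparison.
- No stochasticity, no mRNA stage, no resource competition, no
  post-translational modification; equilibria of the reduced tier assume
  the conditioning guard holds.
- The equal-perturbation combinatorial-regulation study shows a monotone
  but sublinear growth of the induced transient with target copy number:
  the same load that couples the parents also damps the perturbed parent's
  free excursion. A doubling law would require normalizing to equal free
  excursion instead of equal production-rate pulse.
- `response_time` requires a converged, monotone-displacement trajectory;
  it raises on oscillating or drifting tails rather than guessing.
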