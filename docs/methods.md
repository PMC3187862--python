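# Methods

## Scope and model structure

`ectoflux` models the ectoine subsystem of *Halomonas elongata* as a small
curated stoichiometric network (27 internal metabolites, 30 reactions
including exchanges) analysed at steady state, `S v = 0`, by linear
programming. It is deliberately not a genome-scale reconstruction: it
covers glucose uptake to ectoine export, the degradation loop, and the
cofactor bookkeeping needed to make the ATP balances exact, and nothing
else (no biomass objective, no compartments, no SBML).

Granularity choices:

* **Glycolysis** is lumped into `glc + 2 NAD+ -> 2 PEP + 2 NADH`, which is
  ATP-neutral (the two kinase steps cancel the two phosphorylations). All
  substrate-level ATP formation in the model therefore happens at pyruvate
  kinase, which is exactly where the pathway variants differ.
* **The PEP–pyruvate–oxaloacetate node** is kept at single-reaction
  resolution (PYK, PDH, PPC, MAE, MDH), because the alternative
  anaplerotic routings through this node are the subject of the analysis.
  MAE and MDH are reversible; PPC, PYK, PDH are not.
* **Nitrogen assimilation** is available both as GDH
  (`akg + NH3 + NADH -> glu`, ATP-free) and as GS/GOGAT
  (net `akg + NH3 + ATP + NAD(P)H -> glu`, one ATP per nitrogen).
* **Redox lumping.** NADH and NADPH are treated as one interconvertible
  couple at zero energy cost; with this convention all three pathway ATP
  balances close exactly, and no transhydrogenase energetics need to be
  asserted. NADH carries no ATP value (no oxidative phosphorylation): the
  −2/0/+1 balances are pure substrate-level accounting. Excess redox can
  only leave through an uncoupled `NADHOX` sink, which ships disabled.
* **Acetate re-ligation** by the AMP-forming acetate:CoA ligase is lumped
  with pyrophosphatase and adenylate kinase to a flat cost of 2 ATP per
  acetate (`ace + 2 ATP + CoA -> acCoA + 2 ADP`), which is what makes the
  synthesis/degradation cycle cost two ATP per turn.
* **DoeA isomers.** Ectoine hydrolysis observed in vivo yields both
  N-alpha- and N-gamma-acetyl-DABA, but the N-gamma isomer is simply the
  EctC substrate and re-cyclizes; stoichiometrically that branch is a null
  cycle, so the model routes all DoeA flux to the N-alpha isomer that
  feeds DoeB.
* **Atom bookkeeping** covers carbon and nitrogen only (H, O, P and water
  are not balanced, matching the level at which the pathway chemistry is
  curated). Cofactor pairs carry their real C/N counts so that every
  non-exchange reaction, including the cofactor-coupled ones, is checked
  non-vacuously; the packaged model passes with an empty imbalance list.

Coefficients are stored as exact rationals. The LP layer (scipy HiGHS)
works in floating point with a solver feasibility tolerance of 1e-9;
assertions on reported solutions use 1e-6; yields are reported to six
decimals.

## Scenarios and the three pathway variants

A scenario silences a set of reactions (bounds `[0, 0]`) and restores
another set to the natural bounds implied by reversibility. The built-ins
(`oren`, `gdh`, `malic`, `synthesis`, `cycle`) encode the classic pathway
variants: at fixed glucose uptake 1 and ectoine export 1 the sign-free ATP
drain optimum is −2 (PPC + GS/GOGAT), 0 (PPC + GDH) and +1 (MAE/MDH + GDH).
Maximum molar yield is computed with the drain bounded below by the
maintenance demand *m* (ATP per glucose taken up): the neutral variant
sustains a 100% yield only at *m* = 0, the generating variant up to
*m* = 1. Because no route converts glucose to ATP without making ectoine,
yields in these scenarios are step functions of *m* (1 while the variant's
ATP gain covers the load, 0 — infeasible — beyond).

Degenerate optima are real in this network (at 100% yield with both
anaplerotic routes open, PPC can carry anywhere between 0 and 1 of the
flux); `solve_fba` therefore follows the primary optimization with a
secondary minimization of total absolute flux to return one canonical
representative, while flux variability analysis (per-reaction min/max at a
fixed fraction of the optimum) remains the authoritative description of
the degeneracy.

## Elementary-mode enumeration

"All alternative pathways" is formalized as the elementary flux modes:
steady-state flux patterns respecting irreversibility whose support is
minimal. The enumerator splits reversible reactions, computes the extreme
rays of the pointed cone `{v >= 0, S v = 0}` with the double description
method in exact rational arithmetic (combinatorial adjacency test), merges
the split halves and discards the spurious forward/backward two-cycles. A
guard of 30 active reactions keeps it at desk scale; restrict with a
scenario for anything larger. Correctness is gated in the tests by an
independent brute-force oracle that checks every reaction subset with the
rank criterion (a support T carries a mode iff `rank(S_T) = |T| − 1` and
the kernel generator can be signed to respect irreversibility).

On the synthesis network (degradation and NADHOX closed, both anaplerotic
and both nitrogen routes open) the enumeration returns **seven** elementary
glucose-to-ectoine modes, all total conversions, with net ATP values
{−3, −2, −1, 0, +1}. Besides the three classic variants these include the
fourth pure combination (MAE/MDH anaplerosis with GS/GOGAT, −1) and modes
that run MDH and MAE in reverse as an oxaloacetate→malate→pyruvate
decarboxylation bypassing pyruvate kinase (−1 with GDH, −3 with GS/GOGAT),
plus a mixed-nitrogen mode whose ATP drain is exactly zero. Each of these
is genuinely support-minimal — none contains another's support — so an
exhaustive analysis of this network yields more than the three variants a
by-hand comparison of anaplerosis × nitrogen-assimilation suggests; the
three classic values are recovered as a subset. The extra modes are all
energetically dominated, which is presumably why they are never discussed.

## Cycle energetics and pool dynamics

`cycle_atp_cost` fixes ectoine export and glucose uptake at 0, fixes the
ectoine-hydrolase (DoeA) flux at the requested rate *f* and maximizes the
sign-free ATP drain; the unique solution routes
EctA→EctC→DoeA→DoeB→ACS and needs 2*f* ATP. Glucose uptake is closed in
this computation on purpose: with uptake free, the LP could blend the
cycle with a glucose→acetate overflow through the same doe reactions
(which *generates* ATP at pyruvate kinase) and report an arbitrarily small
net drain; closing the uptake isolates what the cycle itself costs.
Consistently, at any fixed production and cycling setpoint, silencing DoeA
lowers the total ATP demand by exactly 2 per unit of cycle flux — the
qualitative content of the degradation-knockout productivity experiment
(the measured productivities themselves are wet-lab numbers outside this
model's scope).

No kinetic rate law is known for ectoine degradation, so the pool model is
the minimal one that realizes the turnover-time argument: first-order
degradation, `d(pool)/dt = synthesis − k·pool`. The turnover (response)
time is pool/flux; for this linear model it equals the relaxation time
1/k at steady state, and the time to cover 95% of a setpoint step is
ln(20)/k. The integrator is a fixed-step classical Runge–Kutta scheme —
ample for a one-variable linear ODE — and is gated in the tests against
the closed form `pool* + (pool0 − pool*)·exp(−k t)` at 1e-6, not trusted
on its own. The model is illustrative (it shows *how* cycling buys
response speed), not fitted to any measured ectoine kinetics.

## Synthetic networks

The generators provide ground truth the analysis code cannot know:

* **Chains** `EX_in → M1 → … → Mn → EX_out` with per-step ATP coupling
  have maximum yield 1 and net ATP equal to the sum of the step
  coefficients, by construction; the FBA engine must reproduce both.
* **Random networks** (seeded, 5–6 internal species, 9–12 reactions,
  integer coefficients ≤ 2, ~60–70% irreversible) are sized so the
  brute-force subset and LP-pair oracles stay exhaustive; candidates with
  no nonzero steady-state route from uptake to export are rejected and
  resampled so the property suites never pass vacuously. All generators
  are pure functions of their spec, seed included.

These fixtures are deliberately much simpler than real metabolic networks
(no conserved moieties beyond what sampling produces, no compartments, no
thermodynamic information), so passing the oracle suites certifies the
*algorithms* — LP assembly, FVA, mode enumeration — not the biological
fidelity of any particular reconstruction.

## Known limitations

* The packaged network is a curated reconstruction of the pathway
  chemistry at the granularity described above; a finer-grained network
  (explicit NADPH, explicit AMP, respiration) could shift which ATP
  balances are attainable.
* Yields and balances are molar and stoichiometric; no growth, transport
  thermodynamics or salt dependence is modelled.
* The enumeration is exponential-time by design and guarded at 30 active
  reactions.
* The cycle's response-time benefit is demonstrated on the illustrative
  linear pool model, not on measured kinetics.
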