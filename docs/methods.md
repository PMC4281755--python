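# Methods

## Model

Binding kinetics are modelled as a continuous-time Markov chain (CTMC) over
*ligation states*: joint placements of the tracked particles (sodium ions
`Na_a`, `Na_b` and a `substrate`) on the sites Na1, Na1′ (`Na1p`), Na1″
(`Na1pp`), Na2 and S1, or in the extracellular vestibule or bulk. At most
one particle occupies a site; transitions move one particle at a time.
Timelines are generated by exact stochastic simulation (Gillespie): the
dwell in a state is exponential with the state's total exit rate, and the
successor is drawn proportionally to the individual rates. Binding from
solution is pseudo-first-order — a single effective rate absorbs the ion
concentration, because the measured quantity is a single binding rate
constant, not a second-order rate law.

Three mechanism configurations ship as defaults:

- **`binding_cycle`** — vestibule ⇌ Na1″ with k_b = 55 μs⁻¹ and
  k_u = 2.3 μs⁻¹. These are the reciprocals of the measured mean
  first-passage times (0.018 μs to bind, 0.43 μs bound).
- **`na1_exchange`** — Na1 ⇌ Na1′ at 1/0.173 ≈ 5.78 μs⁻¹ and
  1/0.060 ≈ 16.7 μs⁻¹, the measured residence times of the frequent
  Na1/Na1′ exchanges.
- **`full`** — a complete loading + release cycle for two sodium ions and
  one substrate that hard-codes the mechanism's ordering constraints:
  extracellular sodium enters only via Na1″ (no direct EC→Na1, EC→Na1′ or
  EC→Na2 edges); Na1′ is reachable only from Na1 and returns only to Na1;
  substrate release from S1 must precede Na2 release, which exits via
  Na1″. Only the four rates above are anchored to measurements; the
  remaining rates (Na1″→Na1 translocation, arrivals/departures, substrate
  binding and release, Na2 entry/exit) are free parameters at
  order-of-magnitude defaults (0.5–50 μs⁻¹) and are labelled as such in
  `defaults.py`.

The measured rate constants describe the two *sub-processes* in isolation.
They are therefore benchmarked on the dedicated two-state configurations:
in the full mechanism the Na1″ dwell is additionally drained by
translocation to Na1 (a free parameter), so its total exit rate is not
k_u, and measuring "unbinding" there would conflate the two channels. The
full mechanism is used for the checks it is suited to: event ordering,
sequence recovery, ligation bookkeeping.

## Rendering synthetic coordinates

A timeline is rendered at a fixed sampling interval (default 1.25 ns, the
analysis sampling the estimators are designed for). While a particle
occupies a site its position is the site centre plus isotropic Gaussian
jitter (σ = 0.3 Å); in the vestibule it performs a reflected 1-D random
walk along z inside the vestibule z-interval (step σ = 0.8 Å/frame,
lateral jitter σ = 1.5 Å); in bulk it is placed diffusely beyond
`bulk_z_min`. The default site geometry puts S1 at the origin (the z = 0
convention, +z extracellular), Na1 and Na2 3.5 Å to either side, Na1′
3.5 Å from Na1, and Na1″ at (0, 0, 4.5), i.e. 5.7 Å from both Na1 and Na2,
on the extracellular approach; the vestibule spans z ∈ [8, 15] Å and bulk
begins at z = 18 Å. Site centres are validated to be ≥ 3 Å apart and Na1″
to be 5–6 Å from Na1 and Na2.

What the generator emulates: exponential dwell laws, site-centred
positional noise, diffusive vestibule/bulk excursions, dimer statistics
(independent chains A and B with seeds spawned from the run seed), and the
event ordering of the mechanism. What it does not: forces, explicit
water/membrane, realistic diffusive approach paths, correlated subunit
dynamics, or assignment ambiguity (the jitter is small against the site
spacing, so per-frame labels are essentially noiseless). Passing the
round-trip tests therefore demonstrates that the estimators are correct on
data obeying the model's assumptions — not that real trajectories satisfy
those assumptions.

## Site assignment and episodes

A position is assigned to a site when ≥ `min_coordination` of its
coordinating atoms lie within the cutoff (default 3.0 Å — the one distance
shell the source analyses state, used there for pocket-water counting, and
typical of Na–O coordination; synthetic-mode sites are single pseudo-atoms
at the site centres with `min_coordination` 1). If several sites qualify,
the smallest mean coordinating distance wins; means equal within 1e-6 Å
fall back to configuration order, making assignment deterministic.
Otherwise the z-interval decides vestibule vs bulk. Na1 and Na1′ share a
coordinating-residue list; in real mode Na1′ is distinguished by requiring
the Glu290 carboxylate within the cutoff.

Episodes are maximal same-site label runs; the ≥ 50-ns reporting rule for
binding instances is applied as a filter that *drops* sub-threshold runs
(no bridging/smoothing — the simplest reading of the rule; a merge option
was deliberately not added). Kinetic averages (first-passage means, CTMC
estimation, residence times) use *unfiltered* labels: exponential dwells
conditioned on exceeding 50 ns would be biased upward by exactly 50 ns
(memorylessness), e.g. 0.223 μs instead of 0.173 μs for the Na1 residence.

## Kinetics

First-passage times are measured between label predicates: binding is
clocked from vestibule entry to the first Na1″ residency, unbinding from
Na1″ residency start to the first departure to vestibule/bulk. Passages do
not overlap; a passage still open at the end of the series is censored —
excluded from the mean, always counted and reported. All completed
passages are pooled across subunits. Rates are reciprocal MFPTs; the
spread is reported both as the sample SD (ddof = 1) and the standard
error, and display values round to 2 significant figures while full
precision is kept internally.

CTMC rates are maximum-likelihood estimates k̂ᵢⱼ = Nᵢⱼ/Tᵢ (transition
counts over total state dwell). States declared but never visited get NaN
rows — explicitly undefined, never zero.

Event-order tests pair two particles' events (episode ends for releases,
starts for bindings) by an order-preserving one-to-one matching that
maximises the number of pairs and minimises the total time offset; an
occasional undetected event (a dwell shorter than one frame renders zero
frames) then drops one pair instead of shifting every later pairing.
Episodes truncated by the end of the trajectory can be excluded from
release events via the `horizon` argument.

### Discretization effects

Sampling at interval Δ makes dwells shorter than Δ invisible with
probability ≈ Δ/2m (m the mean dwell): ~3.5 % of 18-ns vestibule dwells at
Δ = 1.25 ns. Each missed dwell merges its two neighbours, inflating
frame-grid FPT/dwell means by the same few percent (observed ≈ +3–4 % on
the binding cycle). Timeline-based estimation (`first_passage_times`
accepts a `StateTimeline`) is free of this effect and is what the
statistical recovery tests use; the end-to-end rendered pipeline carries
the small, understood bias.

## Gating observables

Percent opening is the affine map 100·(d − d_closed)/(d_max − d_closed)
of a TM1b–TM10 or TM6a–TM10 probe distance (Val33:C–Asp401:Cα,
Ile245:C–Ile410:Cα in real mode); it is not clipped to [0, 100]. The
reference distances are configuration constants (global, not per-run
maxima — the simpler convention, since the sources do not specify).
Classes: open strictly above 60 %, intermediate on [50, 60] (both
boundaries inclusive, the literal reading of "in the range 50–60 %"),
occluded below 50 %; the vestibule counts as completely open only when
both helices are open. χ₁ is the N–CA–CB–CG dihedral (IUPAC sign, own
atan2 implementation, cross-checked against MDAnalysis in the tests);
classification is by circular distance to −67° (open) vs −164° (occluded),
ties to occluded, the crystallographic starting class. The salt-bridge
classifier uses midpoint boundaries (5.25, 7.65 Å) between the three
crystal-structure reference distances — the references are given, the
boundaries are this package's convention and live in the configuration.
Pocket waters are oxygens within 3 Å of any pocket atom, counted once
(kd-tree; brute-force cross-checked).

In synthetic mode the gating series is generated, not measured: a
vestibule open/closed state machine converts mechanism events into
threshold-crossing edges — the first sodium binding of a closed period
opens the vestibule (water crossing `water_lead` = 15 ns before the 60 %
opening crossing, then opening 25 ns after the binding), substrate binding
closes it after 50 ns, and a substrate release fires the cascade: opening
crossing 45 ns before release, salt-bridge break 25 ns before, χ₁ switch
10 ns before. Edges are realised as 2-ns linear ramps with the threshold
crossing placed exactly at the scheduled time, plus small Gaussian noise
(σ: 1.5 % opening, 1 water, 0.1 Å, 3°) chosen ≥ 10 σ away from the
thresholds at baseline so noise cannot fake a crossing. Two degenerate
situations are rendered as a continuously open vestibule rather than as
colliding ramps: rebinding attempts while already open emit nothing, and
an occluded period too short to resolve (its close directive would overlap
the next release's back-dated cascade) is skipped together with that
release's opening edges. Hydration–opening lags are reported per opening
event as t(opening crosses 60 %) − t(nearest water crossing of 25, the
midpoint of the 15–20 → 30–35 transition); simultaneous crossings report
lag 0.

## Round-trip validation

Ground-truth timelines are quantized to the frame grid before the ≥ 50-ns
filter when comparing site sequences, so both sides apply the identical
observable rule; a continuous-time-filtered truth would disagree for any
dwell within one frame of 50 ns. With that convention the analysis of
rendered trajectories reproduces the generating site sequences exactly,
occupancy fractions to < 2 %, and CTMC rates to < 10 % at 10⁴ events.

## Problem sizes

The acceptance computation simulates two subunits of the binding cycle for
2.4 ms each (~10,400 pooled completed cycles, 1.9 M frames per subunit)
and two subunits of the exchange for 1.3 ms each (~11,000 dwells of each
kind); the statistical tests use single timelines of the same event
counts. These sizes put the standard error of each mean near 1 %, an order
below the few-percent discretization bias discussed above.

## Known limitations

- Real-mode analysis assumes imaged, whole-molecule coordinates; a
  validator warns on frame-to-frame jumps > 5 Å but nothing re-images.
- The EC-vestibule/EC-region boundary is a declared z-interval convention;
  the distinction is qualitative in the source analyses.
- Substrate z-regions label everything below the S1 band as S1 (the
  intracellular side is out of scope for OF-state analyses).
- The "±" values on first-passage statistics are sample SDs; the estimator
  behind published "±" spreads of this kind is rarely stated.
- Censored passages are excluded from means (and counted); with mean
  dwells far below the run length the induced bias is negligible.
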