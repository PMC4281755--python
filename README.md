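# ionflux

Trajectory analysis of sodium- and substrate-binding kinetics in
sodium-coupled transporters, built around the LeuT paradigm, plus a
synthetic trajectory generator that simulates the binding mechanism so
every analysis stage can be validated against known ground truth.

## The scientific problem

LeuT, the bacterial leucine/alanine transporter from *Aquifex aeolicus*, is
the structural model for neurotransmitter:sodium symporters (serotonin,
dopamine, norepinephrine transporters). Its outward-facing (OF) state binds
a substrate at the S1 site and two sodium ions at the crystallographic Na1
and Na2 sites; long unbiased MD simulations additionally resolve a
transient entry site, **Na1″** (coordinated by Asn21, Ser256 and Ser355,
~5–6 Å from both Na1 and Na2), and the Glu290-coordinated **Na1′** site
adjacent to Na1. Extracting the binding mechanism from such trajectories
requires a pipeline of discrete analyses:

- **site assignment** — classify each ion/substrate position per frame into
  Na1, Na1′, Na1″, Na2, S1, the extracellular (EC) vestibule, or bulk, by a
  coordination-distance criterion;
- **episode extraction** — maximal single-site residencies, reported as
  binding instances only when they last ≥ 50 ns;
- **gating metrics** — percent opening of the TM1b and TM6a helices
  (affine normalization of probe distances between an inward-facing closed
  reference, 0 %, and maximal opening, 100 %; open > 60 %, intermediate
  50–60 %, occluded < 50 %), the Phe253 χ₁ rotamer (−67° open / −164°
  occluded), the Arg30–Asp404 salt-bridge class (4.2 / 6.3 / 9.0 Å
  references for direct / water-mediated / none), and pocket hydration
  (waters within 3 Å of the coordinating residues);
- **event kinetics** — first-passage times (FPT), rate constants as
  reciprocal mean FPTs (k = 1/MFPT), ligation-state transition bookkeeping,
  maximum-likelihood CTMC rate estimation (k̂ᵢⱼ = Nᵢⱼ/Tᵢ), substrate
  z-traces (S1 at z = 0, S2 band ~10 Å above), and event-order tests
  (e.g. substrate release precedes Na2 release; water influx precedes
  vestibule opening).

Because μs-scale MD trajectories are rarely shareable, `ionflux` includes a
**mechanism simulator**: ligation states evolve as a continuous-time Markov
chain (exact Gillespie simulation), are rendered into 3-D coordinates
(site-centred Gaussian jitter, vestibule random walk, diffuse bulk), and
are coupled to gating observables with a constructed event ordering. The
generator's default rates are the measured ones: Na1″ binding
k_b = 55 μs⁻¹ (mean vestibule→Na1″ passage 0.018 μs), unbinding
k_u = 2.3 μs⁻¹ (mean bound dwell 0.43 μs), and Na1⇌Na1′ exchange residences
0.173 μs / 0.060 μs. Running the full pipeline on these synthetic
trajectories and recovering the generating rates validates every stage.

## Worked example

Simulate the vestibule ⇌ Na1″ binding cycle as a dimer (two independent
subunits), render it at the 1.25-ns sampling interval, assign sites, and
estimate the binding/unbinding kinetics:

```python
import ionflux as fx
from ionflux.pipeline import kinetics_table

geometry = fx.default_geometry()
chains = fx.run_simulation(fx.binding_cycle_config(), geometry,
                           duration=500_000.0,  # ns
                           seed=42, n_chains=2, with_gating=False)
series = []
for c in chains:
    series.extend(fx.analyze_chain(c.trajectory, geometry, min_dwell=0.0,
                                   chain_id=c.chain_id).series)
print(kinetics_table(series).to_string(index=False))
```

```
      transition    n  mfpt_mean_us  mfpt_sd_us  rate_per_us  censored
vestibule->Na1pp 2166      0.017824    0.017157    56.103089         0
Na1pp->vestibule 2164      0.443442    0.449213     2.255086         2
```

2166 completed vestibule→Na1″ passages give a mean binding FPT of
0.0178 μs, i.e. k_b ≈ 56 μs⁻¹, and the bound dwells give k_u ≈ 2.3 μs⁻¹ —
the reciprocal-MFPT estimator recovers the generating rates (55, 2.3) to
within sampling error; `censored` counts residencies cut off by the end of
the trajectory, which are excluded from the means. Site names use ASCII
primes internally (`Na1p` = Na1′, `Na1pp` = Na1″).

The same pipeline is available from the shell:

```sh
ionflux simulate --mechanism full --duration 200000 --seed 42 --outdir run/
ionflux analyze --frames run/frames_A.tsv --topology run/topology_A.pdb \
                --gating run/gating_A.tsv --outdir analysis/
ionflux report --analysis-dir analysis/
```

`simulate` writes ground-truth state timelines, rendered frames
(TSV/PDB/DCD/XTC) and gating series; `analyze` writes per-frame labels,
dwell-filtered episodes, occupancy fractions, a ligation-transition record
and the kinetics report; `report` prints the per-chain event table (ordered
site visits, e.g. `Na1″ → Na1 → EC`, and TM opening transitions in the
`x → o` notation).

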