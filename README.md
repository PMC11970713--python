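# nmrfold

Structure determination of small metal-binding protein domains from NMR
data, built for the awkward but common situation where a structured (S)
and an unstructured (U) conformation of the same polypeptide coexist in
solution and both contribute resonances.  Standard automated NOESY
assignment then risks interpreting unstructured-form peaks as structural
restraints for the folded form.  `nmrfold` implements:

* **probabilistic NOE assignment** — every cross peak is scored against all
  shift-consistent proton pairs as P = P_F · P_D, where
  P_F = Π_d exp(−Δ_d²/2) with Δ_d = (μ_d − a_d)/√(σ_F² + γ_F²) measures
  agreement with the assigned shifts and
  P_D = k_D Φ(n (r_min − r₀)/√(n² σ_D² + γ_D²)) the probability that the
  pair is close enough (distance r₀ in a template structure, n = 6) to
  produce an observable peak.  Assignment and structure calculation
  alternate over five cycles, stripping candidates with P < P_max/f under
  the schedules f = 50, 50, 20, 10, 5 and σ_D = 0.15, 0.15, 0.15, 0.1, 0.05.
  Peaks with any medium-range unstructured-form assignment possibility are
  excluded up front;
* **restraint generation** — NOE calibration d = d_max (I/I_min)^(−1/6)
  with flat wells of ±0.33 d, ambiguous restraints through the r⁻⁶-summed
  effective distance, β-sheet hydrogen-bond restraints (1.7 ± 0.3 Å,
  at-least-one-edge ambiguity patterns), TALOS-style dihedral wells, and
  trigonal metal-site restraints (explicit: 2.3 Å bonds / 120° / 109.5°
  angles; implicit: 4.0 Å S–S distances);
* **a restrained annealing engine** — reduced-representation torsion-space
  fold search plus Cartesian refinement, with optional NCS-coupled joint
  refinement of the metal-free and metal-bound forms (chosen segments kept
  superimposable, the metal-binding loops free), pool annealing and
  selection of the 10 best models by energy plus a chemical-shift
  pseudo-energy Σ(δ_obs − δ_calc)²;
* **titration analysis** — HSQC peak tracking across a metal titration
  (fast-exchange drift, intermediate-exchange broadening and reappearance),
  the weighted truncated shift statistic
  Δδ_rms = (1/n) Σ χ(|Δδ|/σ, τ), χ(x, τ) = x² for x ≥ 2τ, and binding-site
  ranking;
* **a synthetic ground-truth generator** — a three-strand antiparallel
  sheet with a trigonal tri-sulfur site, two-form shift tables, r⁻⁶ NOESY
  peaks with noise/decoys, and a titration series — so every stage is
  testable against a known answer.

See `docs/methods.md` for the full model description and the numerical
choices.

## Worked example

```python
from nmrfold import synth, engine, ira
from nmrfold.restraints import RestraintSet, make_dihedral_restraints, \
    make_hbond_restraints

truth = synth.make_toy_fold(seed=0)
noise = synth.NoiseModel(seed=1)
shifts = synth.simulate_shifts(truth, noise=noise)
peaks, _ = synth.simulate_noesy(truth, shifts, noise=noise)

top = truth.topology
base = RestraintSet()
base.distances += make_hbond_restraints(truth.beta_probabilities(),
                                        top.residue_indices)
base.dihedrals += make_dihedral_restraints(truth.dihedral_predictions())

def template_engine(noe_rs):
    rs = RestraintSet(distances=list(noe_rs.distances) + list(base.distances),
                      dihedrals=list(base.dihedrals))
    confs = [engine.anneal(top, rs, seed=777 + k,
                           schedule=engine.AnnealSchedule(n_starts=2))
             for k in range(6)]
    return engine.select_ensemble(confs, n_select=3, topology=top)

result = ira.run_cycles(peaks, shifts, template_engine)
for audit in result.audit:
    print(f"cycle {audit.cycle}: f={audit.f:>4} active={audit.n_active:>5} "
          f"unambiguous={audit.n_unambiguous}")
```

prints (five cycles on the default noisy synthetic dataset)

```
cycle 1: f=50.0 active= 3134 unambiguous=46
cycle 2: f=50.0 active=  730 unambiguous=218
cycle 3: f=20.0 active=  627 unambiguous=238
cycle 4: f=10.0 active=  599 unambiguous=248
cycle 5: f= 5.0 active=  550 unambiguous=270
```

— the number of candidate assignments shrinks as the stripping factor
tightens and the template ensembles improve, while the number of
unambiguously assigned peaks grows; ~98% of the assignments surviving the
final cycle correspond to proton pairs that are genuine NOE contacts of
the generating structure.

The same machinery runs from the shell:

```
nmrfold simulate --outdir data --seed 0    # write a synthetic dataset
nmrfold calc     --seed 0                  # assignment cycles + ensemble
nmrfold titrate  --seed 0                  # CSP titration analysis
```

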