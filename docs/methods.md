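# Methods

`nmrfold` determines the solution structure of a small metal-binding domain
from NMR observables in the situation where two conformational forms of the
same polypeptide — a structured form (S) and an unstructured form (U) —
coexist in solution and contribute overlapping resonance sets.  The package
implements the full analysis chain: probabilistic assignment of NOESY cross
peaks, conversion of assignments and predictions into restraints, restrained
annealing of conformer pools (optionally refining the metal-free and
metal-bound forms jointly), ensemble selection, and chemical-shift-perturbation
analysis of a metal titration.  A synthetic-data generator with a fully
known ground truth closes the loop for validation.

## Probabilistic restraint assignment

Every NOESY cross peak is initially compatible with all proton pairs whose
assigned shifts match its position.  A candidate assignment is scored as

    P = P_F · P_D.

**Frequency agreement.**  With μ the assigned shift vector and a the peak
position,

    P_F = Π_d exp(−Δ_d²/2),   Δ_d = (μ_d − a_d) / √(σ_F,d² + γ_F,d²),

a unit-maximum Gaussian kernel over the peak dimensions.  σ_F is the
resonance-specific uncertainty (estimated from repeated observations within
a spin system where available, floored at γ_F/2 otherwise), and γ_F is the
experiment-level uncertainty: 0.2, 0.02, 0.3 and 0.05 ppm for N, H_N, C and
other ¹H respectively.  Only candidates with P_F > 0.07 are considered at
all — under the kernel convention that gate sits at ≈ 2.3 combined
standardized deviations, which is what makes the number meaningful.  (A
density-normalized variant of P_F is available behind a flag.)

**Distance plausibility.**  NOESY intensity falls off as r⁻ⁿ with n = 6,
and a peak is taken to be observable with probability ½ at a distance
ceiling r_min.  With r₀ the candidate's inter-proton distance in a template
structure,

    P_D = k_D · Φ( n (r_min − r₀) / √(n² σ_D² + γ_D²) ),

with Φ the standard normal CDF, γ_D = 1.0 (intensity log-normal spread),
and σ_D the template-distance uncertainty.  Over a template ensemble P_D is
averaged across models.  Before any template exists, class priors by
residue separation are used instead: 1.0 (intra-residue), 0.5 (sequential),
0.3, 0.2, 0.15 (residue difference 2–4) and 0.1 (long range).  k_D = 1 and
r_min defaults to the calibration ceiling d_max = 4.25 Å; neither value is
printed in the method's source description, and only ratios of P matter for
the ranking.

**Candidate space.**  Two physically motivated exclusions apply during
generation: candidates whose two protons map to U-form resonances at
sequence separation ≤ 4 are excluded outright (an unstructured chain
produces essentially only short-range NOEs, so such peaks carry no
information about the structured fold), and candidates pairing an S-form
with a U-form resonance are never generated (the two forms are distinct
molecules in solution; an inter-form NOE is impossible).

**Iterative refinement.**  Assignment and structure calculation alternate
for five cycles.  In each cycle candidates are rescored (cycle 1 with the
class priors, later cycles against the previous cycle's ensemble with that
cycle's σ_D), then stripped: a candidate is removed iff P < P_max/f, the
maximum taken over its peak's active candidates — a strict inequality, so
the best candidate of every peak survives, as do exact ties.  The schedules
are σ_D = 0.15, 0.15, 0.15, 0.1, 0.05 and f = 50, 50, 20, 10, 5: tolerant
first, aggressive once the template is trustworthy.  Stripped candidates
retain their scores for audit; every peak ends as assigned, dropped (no
surviving candidate) or fully excluded, and the audit counts reconcile.

## Restraints

* **NOE distances** — intensity I calibrates to a target d = d_max (I/I_min)^(−1/6)
  with I_min the weakest intensity in the set and d_max = 4.25 Å, so the
  weakest peak maps to the ceiling.  The restraint well is flat over
  ±0.33·d and quadratic outside.  An ambiguous restraint (several candidate
  pairs for one peak) is satisfied through the r⁻⁶-summed effective
  distance r_eff = (Σ r_k⁻⁶)^(−1/6) ≤ min r_k.  Restraints involving
  pseudo-protons get +1.0 Å on the upper bound.
* **Hydrogen bonds** — residues predicted β-sheet with probability > 75%
  contribute two ambiguous restraints each, encoding that at least one
  strand edge is bonded: (1) HN(i)·C′(x) or HN(x)·C′(i−1), (2) HN(i+1)·C′(x)
  or HN(x)·C′(i), x over the modeled range at separation ≥ 2.  C′(j) names
  the carbonyl group of residue j; the 1.7 ± 0.3 Å target is the standard
  amide-proton-to-acceptor-oxygen hydrogen-bond distance and is measured to
  the oxygen (to the carbonyl carbon it would be physically impossible).
* **Dihedrals** — predictions classified Strong become square wells at the
  predicted φ/ψ with half-width twice the prediction spread.
* **Metal coordination** — the trigonal tri-sulfur site supports two modes.
  Explicit: a metal atom with three 2.3 Å metal–S bonds, three 120° S–metal–S
  angles and three 109.5° metal–S–C angles, the metal initialized at the
  sulfur centroid.  Implicit: three pairwise S–S distances at 4.0 Å and no
  metal atom.  The two are mutually consistent: ideal trigonal geometry
  gives S–S = 2·2.3·sin 60° ≈ 3.98 Å.
* **NCS coupling** — a penalty keeping the backbone of chosen segments of
  two co-refined forms superimposable while other segments (the
  metal-binding loops) move freely.

## Structure engine

A reduced representation — backbone N, HN, CA, HA, C′, O, the side-chain
atoms any restraint references, and pseudo-protons for unresolved
methylenes/methyls — with ideal covalent geometry (bonds, angles, trans
amide planarity, L-chirality via signed volumes at CA, soft-sphere
repulsion).  The chirality convention was validated against an external
L-alanine reference structure.

Conformer generation is a two-phase protocol, deterministic under its seed:

1. **Torsion-space fold search.**  The chain is parametrized by φ/ψ (ω held
   trans) and the side-chain χ angles down to any restrained atom, built by
   sequential placement with ideal internal coordinates, so covalent
   geometry is exact by construction and the energy surface in torsion
   space contains only restraint and repulsion terms (with analytic
   gradients obtained by projecting the Cartesian gradient onto the
   rotation axes).  Torsions under dihedral restraints start at their
   targets and are held there while the unrestrained torsions — loops,
   termini, side chains — are folded against the distance restraints with
   a soft-core repulsion ramp, from several random starts; a final round
   releases everything.  The best start by full energy wins.
2. **Cartesian polish.**  A soft-geometry relaxation followed by a full-
   weight L-BFGS quench; the quench energy trace is recorded and is
   monotone nonincreasing.

Coupled two-form refinement anneals both forms, then alternates: superpose
the bound form's coupled backbone segments onto the metal-free form's
(optimal rotation, recomputed each outer round and then frozen), add the
harmonic coupling penalty, quench, and vice versa.  Free segments carry no
penalty.

**Ensemble selection.**  From a pool of annealed conformers the n lowest
(default 10) are selected by total energy plus a chemical-shift
pseudo-energy: the sum of squared differences between observed shifts and
shifts back-calculated from the conformer, each difference scaled by the
per-nucleus weights (1, 10, 4 for H, N, C) so the ¹⁵N terms do not dominate
the sum.  The default back-calculator is the package's own empirical model
(random-coil value + a fixed secondary-structure offset from the
conformer's φ/ψ); any callable with the same signature can be plugged in.

## Chemical-shift-perturbation analysis

The per-residue difference statistic between two states is

    Δδ_rms(res) = (1/n) Σᵢ χ(|δᵢᵃ − δᵢᵇ|/σᵢ, τᵢ),   χ(x, τ) = x² if x ≥ 2τ else 0,

over the residue's n atoms present in both tables, with σ = 1, 10, 4 ppm
for H, N, C and τ the per-atom-class noise floor on the scaled axis
(defaults H_N 0.01977, N 0.01761, C′ 0.01780, other ¹H 0.02620, other ¹³C
0.042974).  The thresholds are re-estimated per dataset as the sample
standard deviation of the scaled differences over residues known to be
unstructured in both states.  As printed the statistic is a truncated mean
of squares despite the conventional "rms" name; a square-root variant is a
flag.  The truncation is applied on the σ-scaled axis — the only reading
under which thresholds of similar magnitude for H_N and N make sense, given
that raw ¹⁵N differences are an order of magnitude larger.

Titration series are tracked point to point by minimizing the total
radius-scaled peak displacement (optimal assignment; ambiguities resolve in
favor of the smallest overall movement, and an unmatched peak costs a fixed
penalty of 3 scaled units).  A greedy nearest-neighbor matcher was tried
first and demonstrably mis-pairs reappearing binding-site peaks whose
shifted positions land near other residues' apo positions.  Peaks absent at
a point are flagged broadened-out; a later match is a reappearance — the
intermediate-exchange signature used to flag binding-site residues.
Binding-site ranking takes the top residues of the endpoint Δδ_rms profile
(zeros never rank).

## Synthetic ground truth

The generator builds a miniature fold with the statistical structure the
analysis assumes: three antiparallel strands (default 6 residues each)
joined by two loops, the second loop carrying three cysteines whose Sγ
atoms form a near-trigonal site.  Construction is itself a torsion-space
loop-closure: strand torsions held at ideal β values while each loop's
torsions are optimized (multistart, both hydrogen-bond parities tried) to
close the next strand's antiparallel H-bond ladder and, for the second
loop, the trigonal site; a final relaxation leaves an essentially
strain-free structure on the package's own geometry model.  The metal-bound
form is re-refined from perturbed loop torsions under explicit coordination
restraints, so the strand core matches the metal-free form while the loops
settle differently.

Shifts: the U form is random coil plus a small dispersion (sd 0.04 ppm for
¹H — the clustered spectrum of an unstructured chain); the S form is the
package's forward model plus a per-resonance structural dispersion at
folded-domain magnitudes (sd 0.45 ppm amide ¹H, 3.5 ppm ¹⁵N, 1.8 ppm ¹³C),
deterministic given the seed.  NOESY peaks are emitted for every proton
pair closer than 5 Å: amide-involving contacts as amide-anchored 3D peaks
(H, H_N, N — the nitrogen-edited experiment), others as 2D H–H peaks;
intensities are k·r⁻⁶ under log-normal noise (sd 0.3), positions carry
per-nucleus jitter (0.008 ppm ¹H, 0.08 ppm ¹⁵N), 5% of peaks are dropped,
and decoys at 10% of the true count are drawn from U-form intra-residue and
sequential pairs.  Every peak carries its generating pair in a side channel
the pipeline never sees.

The titration simulates stoichiometric single-site binding: the bound
fraction follows the exact quadratic solution at K_d = 0.005 (ratios 0 to
1.2); non-site residues drift linearly with the bound fraction (fast
exchange), site residues' peaks are omitted while the bound fraction lies
in (0.2, 0.8) and reappear, strongly shifted, near saturation
(intermediate exchange); U-form intensities scale with the free fraction,
so the unstructured form converts almost completely by the final point.

**What the generator does not emulate:** spectral overlap in the intensity
dimension (peaks never merge), relaxation and lineshape effects, spin
diffusion, solvent exchange, and the full proton inventory of real side
chains (one pseudo-proton per side chain).  Passing the closed-loop tests
therefore demonstrates the pipeline's logic and numerics, not performance
on real spectra.

## Validation metrics and problem sizes

The closed-loop tests run at desk scale: annealing pools of 12 with 10
selected (production NMR protocols select the 10 best from pools of
thousands; what the selection step exercises is the ranking, not the pool
size), per-cycle template ensembles of 3 selected from 6 short anneals,
and the default 33-residue toy.  Structure recovery is measured
as backbone RMSD of the selected ensemble's mean structure to the truth.
Assignment recovery is measured at the contact level: the fraction of
surviving candidates whose proton pair is one of the generator's actual
peak-producing contacts.  The stricter bookkeeping metric — tying each
candidate to the one peak that generated it — saturates near 73% even when
scoring uses the true structure as template, because the final stripping
factor f = 5 deliberately retains spectrally degenerate alternatives that
are themselves genuine sub-cutoff contacts (their own peaks overlap); such
candidates yield correct distance restraints, which is what the assignment
exists to produce.

## Known limitations

* The annealer's fold search leans on dihedral restraints to pin strand
  torsions; with no dihedral restraints at all the multistart search still
  works for small systems (it is how the trigonal-site test refines) but
  scales poorly beyond ~40 residues.
* No torsion dynamics or temperature coupling: barrier crossing relies on
  the multistart and the soft-core ramp rather than momentum.
* The shift back-calculator is intentionally simple; with a real predictor
  plugged in, the pseudo-energy term's scale relative to the restraint
  energies may need re-weighting.
* Single chain, single metal site, trigonal coordination only.
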