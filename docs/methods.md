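# Methods

## Scope and model

`stereobind` treats a compound collection as a set of *stereoisomer
families*: maximal sets of molecules with identical constitution
(atomic connectivity) and different spatial configuration. The questions
it answers are (i) how often stereoisomers of one constitution diverge
in their protein-target binding, and (ii) whether vector descriptors of
molecular structure can recover that divergence. Binding is modelled as
a ternary per-target annotation — 0 no binding, 1 weak, 2 strong — and
continuous 128-dimensional "signature" vectors stand in for learned
bioactivity embeddings.

## Stereoisomer grouping

Standardization is RDKit throughout: canonical SMILES with and without
stereo descriptors, InChIKey, molecular formula, formal charge, isotope
flags. Potential stereo elements are counted with RDKit's stereo
perception and include both tetrahedral centres and double-bond
geometry; a compound is *fully defined* only when every potential
element carries a descriptor. A compound with at least one potential
element and not all of them assigned is *partially defined* — including
the all-unassigned case, which is how racemic registrations appear, so
the exhaustiveness filter removes them.

Candidate groups are buckets on the first (14-character) InChIKey block,
which hashes connectivity. Because that block is a hash, membership
additionally requires equal stereo-stripped canonical SMILES (this
guards against collisions and is itself verified against a brute-force
O(n²) canonical-form comparison in the tests), equal formal charge and
InChIKey protonation character, and no isotope labels. Exact InChIKey
duplicates are collapsed first (lexicographically smallest id kept):
registry duplicates would otherwise fabricate stereoisomer pairs at
distance zero. Groups need ≥ 2 survivors; everything removed carries a
reason code (`partially_defined`, `isotope`, `achiral_duplicate`,
`charge_mismatch`, `protonation_mismatch`, `singleton`, `duplicate`).

## Profile divergence

Two conventions coexist deliberately. *Distinctness* of profiles within
a group uses exact ternary equality — a weak-versus-strong difference at
a single target makes two profiles distinct, matching how ternary
annotations are read. *Distances* use the Jaccard distance over
binarized bound-target sets (value ≥ 1 ⇒ bound); a ternary-weighted
Jaccard would need an arbitrary weighting, and binarization can only
merge profiles, never split them, so the fraction of pairs at Jaccard
> 0 is a lower bound on the ternary-distinct fraction (property-tested).
Pairs whose bound sets are both empty get distance 0 by convention and
are excluded from distributions; well-formed inputs never contain them.
Distribution comparisons are two-sided Mann–Whitney U with tie
correction (SciPy's asymptotic implementation). Random-pair categories
are sampled uniformly without replacement, capped (default 10⁵ per
category) because full enumeration is quadratic and statistically
unnecessary.

## Conformers and descriptors

One conformer per compound: ETKDG (v3) distance-geometry embedding with
explicit hydrogens, MMFF94 relaxation capped at 1000 iterations
(non-convergence accepted — the coordinates are kept; a force-field
setup failure falls back to the unoptimized embedding with a warning),
hydrogens removed before export. Compounds with partially defined
stereochemistry are refused: embedding would silently pick one
configuration. Embedding retries (5, seeded schedule, random coordinates
from the third attempt) keep the operation deterministic per seed.

The 2D baseline is a hashed Morgan fingerprint (radius 2, 2048 bits)
computed on the stereo-stripped constitution, so all stereoisomers of a
constitution are bitwise identical by construction. The 3D descriptor
concatenates:

* **USR moments** (12 values): mean, standard deviation and cube-rooted
  third central moment of the distance distributions from four reference
  points — centroid, atom closest to it, atom farthest from it, atom
  farthest from that.
* **Chirality block** (2 values): over atom quadruples (all when
  C(N,4) ≤ 5000, else a seeded unranked sample of 5000), signed
  tetrahedral volumes normalised by the cubed mean interatomic distance;
  the block is the ratio-normalised first and third moments, each in
  [−1, 1], rescaled to the norm of the moment block so neither block
  dominates the cosine geometry.

Plain distance moments are reflection-invariant and cannot separate
enantiomers; the signed-volume block is odd under reflection, so mirror
conformers of a chiral molecule differ exactly there. Both blocks are
invariant to proper rigid motions (tested at 10⁻⁸). For < 4 atoms or
planar point sets the chirality block is zero. Cosine distance between
bitwise-identical vectors is returned as exactly 0 (the naive formula
leaves ~10⁻¹⁶ residue).

## kNN recapitulation benchmark

The cutoff defining nearest neighbors is the empirical quantile (linear
interpolation) of the reference-space distance distribution at a small
percentile, estimated from up to 10⁶ seeded random pairs (all pairs when
fewer); the fraction of distances strictly below it matches the nominal
tail mass to binomial accuracy. The percentile is global over the
distance distribution, not per evaluated molecule — the cheaper and
simpler reading; a per-molecule variant was considered and not built.
Per repetition (default 10 × 2500 compounds, seeded), positives are
subsample pairs strictly below the cutoff; negatives are uniform
non-positives (random mode) or pairs in the near-miss band
(cutoff, 10 × cutoff] (stringent mode — the band multiplier is a config
knob, default 10). Classes are balanced by downsampling the larger one:
AUROC is rank-based, but balance stabilises small-sample variance.
AUROC uses midrank tie handling (scikit-learn), scoring negative
candidate distance, and is averaged over repetitions. Repetition-level
subsampling is the only resampling: no model is trained here, so no
train/test splitting applies.

## Synthetic library generator

The generator emulates the data regime the pipeline targets — a
target-binding corpus restricted to compounds with experimental
annotations — with full ground truth. Constitutions are assembled from a
fixed template pool (head + chain of substituted tetrahedral
stereocentres + tail), verified with RDKit to expose exactly the
requested number of stereo elements, and checked unique across families
so grouping can never merge two families. Stereoisomers are enumerated
by configuration assignment; meso-style duplicates collapse during
canonicalization. A configured fraction of molecules is re-emitted with
one stereocentre erased, standing in for racemic or partially
characterised registrations.

Default conditions: 200 families, 1–3 stereocentres, 2–3 isomers per
family, 50 targets, base profiles sparse (each target active with
probability 0.15, split weak/strong 0.7/0.3), stereo sensitivity 0.01,
10% undefined entries, 128-dimensional signatures with noise SD 0.02.

**Profile mechanics.** Each stereocentre carries a
Bernoulli(`stereo_sensitivity`) susceptibility mask over targets and a
fixed cyclic mutation step in {1, 2}. An isomer differing from the
family base at centres F mutates target t iff some centre in F is
susceptible at t, taking the value of the lowest susceptible flipped
centre — always different from the base value, uniformly one of the two
alternatives. A pair separated by d centres therefore diverges per
target with probability 1−(1−p)^d: bioactivity divergence is coupled to
stereochemical divergence, which is what makes divergence in principle
visible to a stereo-aware structural descriptor and invisible to a
stereo-blind one. For single-centre families this reduces to independent
per-target mutation with probability p, and the distinct-profile pair
fraction follows the closed form 1−(1−p)^T exactly (the tests' analytic
oracle). With the default p = 0.01 and T = 50, ≈ 39% of enantiomer
pairs carry distinct profiles. A profile mutated to all-zero is repaired
at one base-active target with the non-base nonzero value, preserving
both divergence and the every-compound-binds-something invariant.
Ternary saturation caps perfect pairwise distinctness: at most 3
profiles can differ pairwise at a single target, so the
"sensitivity 1 ⇒ all pairs differ everywhere" guarantee holds for
families of ≤ 3 isomers.

**Signatures.** `family base vector + offset + noise`, the offset a
deterministic function of the profile: direction seeded by the profile's
hash, magnitude 4·√(h/T) for Hamming distance h from the family base.
Identical profiles ⇒ identical offsets ⇒ signatures differing only by
noise; diverged profiles ⇒ separated signatures. This is the synthetic
analogue of signatures inferred from bioactivity.

All randomness derives from one root seed via integer-sequence child
streams per family (and per purpose), so output is deterministic and
independent of evaluation order; library bundles round-trip through
plain-text files byte-identically (floats at 17 significant digits).

**What the generator does not emulate.** Real target identities and
assay provenance; assay sparsity bias and false negatives; correlated
target families (each target mutates independently); conformational
flexibility (one conformer per compound); any relationship between
scaffold chemistry and binding beyond the stereocentre coupling. Passing
tests therefore demonstrate the pipeline's correctness and the
descriptors' geometric contracts, not performance on any real corpus.

## Problem sizes and numerical choices

Test and acceptance runs use libraries of 100–500 molecules, benchmark
subsamples of 300 compounds × 5 repetitions, and 10⁶-sample quantile
checks — sizes at which every contract under test is already sharp.
The geo3d-over-fp2d advantage under stringent negatives is a
statistical expectation: verified stable across generator seeds 1–5 at
the benchmark configuration (margins 0.04–0.15 AUROC), though individual
seeds elsewhere can tie. Tolerances: rigid-motion invariance 10⁻⁸
(float64 rotation error is ~10⁻¹³, leaving two orders of headroom);
mirror-symmetry algebra 10⁻⁹; signature round-trip 10⁻¹²;
identical-signature detection 10⁻⁶ cosine. Tie-breaks in USR reference
point selection use `argmax`/`argmin` first-index semantics; exact ties
occur only for exactly symmetric point sets, where any choice yields the
same moments.

## Known limitations

* The chirality block can be near zero for near-planar chiral conformers,
  weakening enantiomer separation in edge cases (none observed on the
  template pool).
* E/Z-only isomer pairs are grouped like chirality pairs (double-bond
  stereo counts toward the potential-element total); the synthetic
  generator exercises tetrahedral centres only.
* Tautomer standardization is deliberately not applied: it could merge
  structures that differ by more than stereochemistry. Charged and
  isotope-labelled variants are excluded rather than neutralized.
* The stringent-negative band multiplier (default 10) is a convention;
  results for bands far from the cutoff converge to random-negative
  behaviour.
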