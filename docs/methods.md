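# Methods

## The prediction model

`pocketvote` implements a structural-transfer approach to binding-site
prediction. The premise is that templates sharing a fold with the query
model often bind ligands in equivalent pockets, so the evidence for a
binding site is the spatial consensus of many template ligands brought
into the model frame.

The pipeline is deterministic and purely geometric:

1. **Template library.** The template list is read in order; each
   template's HETATM groups are restricted to a configurable list of
   biologically relevant chemical-component codes (waters HOH/WAT/DOD are
   excluded unconditionally). A greedy scan then enforces pairwise
   sequence non-redundancy below 70% identity and caps the library at 40
   templates. Identity is computed from a global alignment (match +1,
   mismatch 0, linear gap −1) and normalised by the shorter sequence, the
   convention of fragment-tolerant redundancy screens; the greedy order
   is the input order, so filtering needs no structural information.
2. **Superposition and gating.** Each template is superposed onto the
   model. The built-in engine seeds residue pairs from the global
   sequence alignment and iterates least-squares (Kabsch) fitting of the
   paired Cα atoms, discarding pairs beyond a cutoff that anneals
   8 → 4 Å, for at most 50 rounds. The fit is scored with the standard
   TM-score normalised by the model length, with
   d0(L) = max(0.5, 1.24·(L−15)^⅓ − 1.8); superpositions below TM 0.4
   are rejected and contribute no ligands. The engine provenance
   (builtin / external TM-align-compatible binary / precomputed
   transform file) is recorded in every result so threshold behaviour is
   attributable. The built-in engine is a sequence-seeded iterative
   superposition, not a fragment-search structure aligner: it is exact
   for rigid or mildly noisy copies (the regime the test fixtures
   exercise) but will under-score analogous folds with shuffled
   topology; the external engine exists for that regime.
3. **Contact clustering.** Accepted templates deposit their ligands in
   the model frame. Two ligands are in contact when any heavy-atom pair
   satisfies dist ≤ r(a) + r(b) + margin. Clusters are the connected
   components of the contact graph — the "continuous masses" of
   ligands — computed with a sparse graph routine and cross-checked in
   the tests against a brute-force breadth-first search. Cluster ids are
   ordered by decreasing size, then smallest member id.
4. **Site selection and voting.** The largest cluster is the predicted
   pocket (ties: more residue contacts against the model, then smallest
   member id). Each residue's vote count is the number of *distinct*
   cluster ligands it touches (set semantics, not atom-contact counts).
   A residue is predicted iff votes ≥ 2 and votes/cluster_size ≥ 25%,
   both inclusive; the fraction test is evaluated as an exact rational
   comparison (votes·q ≥ p·size) so the boundary never suffers float
   error. The member whose centre minimises the summed distance to the
   other members' centres is reported as the centroid ligand.

Only one site is reported — the largest cluster — matching single-site
assessment practice; the other clusters remain available in diagnostics.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| contact margin | 0.5 Å | slack added to van der Waals radii in the contact predicate |
| radius mode | sum_of_radii | `r(a)+r(b)+margin`; `single_radius` uses `max(r)+margin` |
| vdW radii | Bondi (1964) | per-element table; unlisted elements (e.g. Fe) fall back to 1.8 Å |
| TM threshold | 0.40 | template acceptance gate |
| min ligands | 2 | absolute vote minimum |
| min fraction | 0.25 | relative vote minimum (inclusive) |
| redundancy threshold | 0.70 | pairwise identity above which a template is dropped |
| template cap | 40 | maximum library size |
| BDT d0 | 1.0 Å | distance constant of the assessment kernel |

The sum-of-radii contact mode is the default because it is the
physically standard criterion; the single-radius variant is provided as
a configuration option since contact definitions in the literature vary
on this point. The 0.5 Å margin dominates the small differences between
published radius sets, which is why a single default radius for
unlisted transition metals is acceptable.

Hydrogens and deuteriums are kept in the data model but excluded from
all contact mathematics: experimental templates mostly lack them, and
including them would make contacts depend on protonation artifacts.
Alternate locations collapse to the highest-occupancy conformer (ties:
alphabetically first altloc) so geometry is single-conformer and runs
are byte-reproducible.

## Assessment

MCC treats the prediction as a binary classification over the target
sequence; with neutral-residue exclusion enabled (default), residues
annotated as capable of binding an alternative ligand are removed from
both sets and from the universe before counting, and degenerate
confusion tables score 0. BDT sums 1/(1+(D_i/d0)²) over predicted
residues, where D_i is the minimum heavy-atom distance to any observed
residue in the native structure, normalised by max(|P|, |O|): adding
distant spurious residues grows the denominator while contributing ≈ 0,
and omitting true residues shrinks the numerator, so both over- and
under-prediction are penalised. The heavy-atom minimum distance is the
default because it matches the contact definition used by the
predictor; a Cα-only convention can be obtained by supplying Cα-only
native coordinates. Z-scores are computed per target over the groups
that predicted it, with the sample (n−1) standard deviation and no
flooring of negative values; spreads at rounding-noise level
(sd ≤ 10⁻¹²·max(1, |mean|)) are treated as zero variance. The Wilcoxon
signed-rank test drops zero differences, uses the exact null
distribution for ≤ 25 remaining pairs and the normal approximation with
continuity correction above.

## Synthetic fixtures

The fixture generators emulate the *logical* structure of real inputs,
not their physics:

* toy models have ideal-geometry backbones (α-helix parameters, a
  straight strand, or a fixed-step random walk) with Cα spacing
  3.8 ± 0.1 Å and schematic N/C/O placement;
* templates are rigid copies (optionally with Gaussian coordinate
  noise) carrying single-atom ligands placed at exact van der Waals
  offsets from anchor residues;
* contact scenarios realise a requested residue–ligand contact matrix
  by laying each linked ligand chain along a line with consecutive
  spacing (threshold − 0.3 Å) and giving wired residues pseudo
  side-chain atoms on perpendicular rays at (threshold − 0.3 Å).
  Placements stay ≥ 0.3 Å away from the inclusive contact boundary on
  both sides, so outcomes cannot flip on floating-point noise. Link
  graphs are restricted to unions of simple paths; that is sufficient
  to express any connected "continuous mass" and keeps the embedding
  problem trivial, at the cost of not realising cyclic contact
  topologies. Every bundle re-parses its own files and re-derives its
  ground truth through the production clustering/voting code before it
  is returned.

Because fixtures are rigid or mildly noisy copies of the query, passing
tests demonstrate the correctness of the geometry, clustering, voting
and scoring machinery — not the remote-homolog alignment quality that a
fragment-search structure aligner provides on real CASP-style targets.
Benchmark-scale claims on real data would additionally need solved
structures and an external aligner.

## Numerical and design choices

* Contact and voting boundaries are inclusive; the voting fraction uses
  exact integer arithmetic.
* Kabsch fitting enforces a proper rotation (reflections corrected);
  degenerate (<3 points or collinear) inputs raise rather than return a
  garbage transform.
* TM-score normalisation uses the model (target) length; the prediction
  concerns the target's site, and the choice is configurable.
* Cluster/centroid tie-breaks are lexicographic on ligand instance ids
  after the documented primary criteria, making every pipeline output a
  pure function of its inputs (run manifests record config + input
  checksums).
* Residue numbers above 9999 are rejected at write time instead of
  silently wrapping the fixed-column format.
* An empty prediction (no accepted templates, or no relevant ligands)
  is a *successful* run with a machine-readable reason, mirroring the
  distinction between "no prediction" and "failure" in community
  assessments.

## Problem sizes

The shipped test-suite and acceptance-script workloads use 30–130
residue toy models, template libraries of 1–41, ligand pools ≤ 21, 50–100
random rigid motions and 200 random clustering pools. These sizes fully
exercise every code path (the algorithms are O(n²) in ligands and
O(L²) in residues at worst) while keeping the whole suite in the
seconds-to-a-minute range.

## Known limitations

* The built-in aligner needs a sequence signal to seed pairing;
  sequence-free structural analogy is the external engine's job.
* One binding site per target; alternative pockets are reported only as
  diagnostics.
* No mmCIF input, symmetry expansion, or covalent-ligand chemistry.
* The default relevant-ligand list is a pragmatic set of common metals,
  nucleotides, cofactors and small anions; serious use should supply a
  curated list (the algorithm is parameterised by it, and no test
  depends on the default's composition).
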