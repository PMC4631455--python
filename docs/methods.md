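# Methods

## Overview

`thermodesign` assembles multiple-point thermostabilizing mutants from two
independent evidence streams — evolutionary (back-to-consensus analysis of
a multiple sequence alignment) and energetic (consensus of two external
ΔΔG calculators) — with structure- and conservation-based exclusion
filters and an additivity-aware greedy combiner. The package does not
compute ΔΔG itself: energy values are consumed as tables produced by
FoldX- or Rosetta-style backends (or by the synthetic generator), and the
package's contribution is the candidate-selection, filtering, combination
and evaluation logic around them.

Sign convention throughout: ΔΔG in kcal·mol⁻¹, negative = stabilizing.
Mutations are written wtPOSsub (e.g. `C128F`) in 1-based, gap-free query
coordinates.

## Evolution arm

Column frequencies are computed per alignment column mapped to a non-gap
query position. The default gap policy excludes gaps from the denominator
(`exclude_gaps`); `count_gaps` divides by all sequences instead and is
offered because either reading of "fraction of analyzed sequences" is
defensible. Unknown residues (`X`) are never counted under either policy.

* **Simple consensus** (cutoff 0.5): the most frequent residue is the
  consensus if its frequency is ≥ the cutoff (inclusive — "at least 50%");
  a candidate is emitted where it differs from the query wild type.
* **Frequency ratio** (ratio ≤ 0.2, consensus frequency ≥ 0.4, both
  inclusive): the "target" residue in the ratio is the query's wild type,
  i.e. the origin of the proposed substitution.

Frequency ties at the consensus prefer the non-wild-type residue, then
alphabetical order — deterministic and tested. Masks for poorly aligned
regions are user-supplied position ranges; the package does no automatic
alignment-quality scoring. A greedy identity-based redundancy reducer
(drop a sequence whose identity to any kept sequence exceeds the cutoff;
query always kept) stands in for the heavier clustering tool chains used
to prepare production alignments, which are out of scope.

**Conservation grades.** Site-specific evolutionary rates (computed
externally, e.g. by a Bayesian rate-inference tool, or imported from any
two-column TSV) are discretized to grades 1–9 by equal-width binning of
the observed rate range, grade 9 = most conserved bin. The exact
partition used by ConSurf-style tools is not public, so the binning is a
declared convention; externally computed grades can be imported verbatim
and take precedence. A degenerate rate range (constant input, or a single
position) yields the neutral grade 5 everywhere. Positions with grade ≥ 8
(inclusive) are immutable.

**Correlation scores.** The per-position score is the maximum over
partner columns of normalized mutual information, MI / min(H(col_i),
H(col_j)), computed over sequences informative in both columns; constant
columns score 0 by convention, and alignments with < 3 sequences return
all-zero scores with a warning. This is a documented stand-in for
correlated-mutation-analysis scores from dedicated servers; the 0.8
exclusion threshold (inclusive) mirrors the workflow the package
implements, and external scores can be imported instead. The stand-in is
approximate: it captures co-variation strength but not the phylogenetic
corrections specialized tools apply.

## Energy arm

Averaging is hierarchical: replicate runs are averaged within each
structure, then structure means are averaged. By default a mutation must
be present on every expected structure (`require_all_structures=True`);
the relaxed mode averages what is available and warns. Classification
thresholds are strict on the stabilizing side (mean < −1.0 for
FoldX-style, < −2.0 for Rosetta-style; exactly the threshold is neutral)
and strict on the destabilizing side (mean > +0.5). A mutation becomes an
energy candidate only when both tools call it stabilizing, its position
passes the grade and correlation filters, and neither tool calls it
destabilizing (the veto is configurable). Applying the
conservation/correlation filter before or after the energy calls yields
the identical candidate set (property-tested); the pipeline driver
filters first because that is the cheap order when ΔΔG must actually be
computed.

Parser dialects: a generic mutation/structure/ddg TSV; a BuildModel-style
difference file (header line starting `Pdb`, rows
`<structure>_<mutation>_<replicate>.pdb <ddg> …`); and a
ddg_monomer-style predictions file (`ddG: <tag> <value> …`, tag
`<structure>_<mutation>` or bare mutation). The grammars are lenient,
documented in the parser docstring, and exercised by fixtures; malformed
mutation tokens fail with the offending line number.

## Structure filter

Salt bridges are detected geometrically: any Asp/Glu side-chain carboxyl
oxygen within 4.0 Å (inclusive) of a Lys/Arg/His side-chain nitrogen
(NZ; NH1/NH2/NE; ND1/NE2). His counts as positively charged. 4.0 Å is the
conventional screening default for charged-group contacts; both the
cutoff and the atom sets are configurable. Only intra-chain pairs are
considered by default ("intra-molecular"); for oligomers each chain is
analyzed independently and the results unioned. An interaction present in
*at least one* analyzed structure or chain is considered important, and a
candidate whose wild-type residue participates in any retained
interaction is discarded with a machine-readable reason. Optional
stand-ins for broader interaction screening (aliphatic-carbon contacts
< 5.0 Å; aromatic ring-centroid distances 4.5–7.0 Å) are off by default —
the published workflow does not specify which additional interaction
classes drove its manual exclusions, so the package exposes the mechanism
and leaves the judgment to the user. A `charge_preserving_exempt` mode
keeps salt-bridge candidates whose substitution preserves the charge
class. Sequence-to-structure numbering is identity by default; an offset
map handles author numbering.

PDB files are read with gemmi: first model only, waters and hetero
compounds removed, highest-occupancy alternate location kept.

## Combiner

A pair is antagonistic iff its double-mutant ΔΔG (averaged over
structures, from the same ingestion path as singles) is strictly above
−3.0 kcal·mol⁻¹; exactly −3.0 is additive. The fixed constant is used as
the criterion (rather than comparison to the sum of singles); the
sum-based alternative is noted as an open design but not implemented as
default. At each position only the lowest-ΔΔG candidate survives
(`best_per_position`; exact ties break alphabetically by substitution).
The greedy scan then admits candidates from most to least stabilizing —
ranked by the Rosetta-arm mean by default, configurable; ties break on a
secondary ranking then position order — each admitted only if
non-antagonistic with every prior admission. The admitted set is
deterministic given the sorted order and the antagonism relation, and is
always a clique in the additivity graph (re-verified by
`validate_plan`). Greedy admission, not maximum clique, is the prescribed
procedure; a max-clique mode is out of scope. `merge_designs` unions two
plans; a position mutated differently in both is an error by default or
resolved in favor of plan A.

## Benchmark arm

Curation keeps records with |ΔΔG| ≥ 0.5 kcal·mol⁻¹ (inclusive; 0.5 is
roughly the experimental error of the measurement, so smaller effects are
unreliable) and collapses duplicate (protein, mutation) measurements to
the one closest to pH 7 — ties prefer the lower pH, then the smaller
deviation from 25 °C, then the lexicographically smallest record id; a
record with missing pH always loses to one with pH. Curation is
idempotent. Files may declare either sign convention; labels are assigned
after canonicalization to negative-is-stabilizing.

Precision is TP/(TP+FP) and false positive rate FP/(FP+TN); both carry an
explicit undefined marker when their denominator is zero, and
whole-percent rounding (half away from zero) is applied only in reports.
The threshold sweep predicts "stabilizing" at mean ΔΔG strictly below
each threshold on the grid −2.5 … +2.5 step 0.5 (11 thresholds), so the
predicted-positive count is non-decreasing in the threshold. The combined
rule (both tools stabilizing at their defaults, minus grade ≥ 8
positions) is scored by the same machinery; its prediction set is by
construction a subset of each tool's, so its false-positive count never
exceeds either tool's.

## Synthetic data

The generators emulate the three input kinds with planted, recoverable
ground truth; each draws from its own stream derived from the master seed
by a fixed label, so adding a generator never perturbs the others, and a
fixed seed gives byte-identical outputs.

* **Alignments**: 50 sequences by default; background columns carry the
  query residue in ~70% of sequences (dominant wild type ⇒ no spurious
  candidates); planted sites realize a consensus residue at frequency 0.8
  against a wild-type frequency of 0.05, counts rounded half-up and the
  realized frequencies recorded in the returned ground truth.
* **ΔΔG tables**: true single values from a mixture — with probability
  0.25 a stabilizing tail uniform on [−4.5, −2.2] (safely below both
  tools' thresholds), else a near-neutral bulk N(0, 0.6²) — observed per
  (tool, structure, replicate) with Gaussian noise of sd 0.2 over three
  structures and three replicates. Doubles are the sum of singles plus
  the planted epistasis offset (zero when unplanted).
* **Structures**: minimal Asp/Lys residue pairs whose OD1–NZ distance is
  exactly the requested value, successive pairs offset 50 Å so they
  cannot interact.

For end-to-end recovery runs the planted antagonistic pair connects the
best- and worst-ranked true candidates and is only planted when their
true ΔΔG separation is at least 0.3 kcal·mol⁻¹: with a near-tied pair the
"ground-truth additive clique" is not identifiable, because replicate
noise can legitimately flip which member the greedy scan admits first.

What the generators do *not* emulate: phylogenetic correlation between
homologs (rows are exchangeable), alignment gaps in the synthetic MSA,
position-dependent ΔΔG structure, correlated errors between tools, or
realistic protein geometry beyond the placed charged groups. Passing the
recovery tests therefore shows the selection/filtering/combination logic
is correct under its stated model, not that the thresholds are optimal
for real proteins.

## Problem sizes and numerics

Property suites run at fixed sizes chosen to exercise the combinatorics
while keeping the default test run fast: 200 random alignments (length
≤ 30) against the brute-force consensus oracle, 500 random ≤ 12-candidate
instances against an independent greedy oracle, 200 random labeled sets
against direct-count metrics, randomized 30-residue toys against an
all-pairs distance oracle. Frequency sums are checked to 1e-9; the
synthetic salt-bridge distance is reproduced to 1e-6 Å. All boundary
semantics (≥ for consensus/immutability/correlation/curation, strict <
and > for the energy calls and antagonism) follow the workflow's wording
and are pinned by dedicated boundary tests.

## Known limitations

* The conservation grading and correlation scoring are declared stand-ins;
  production use should import externally computed profiles.
* The salt-bridge criterion is a distance screen, not an electrostatics
  calculation; no hydrogens are placed.
* The combiner trusts the backend's double-mutant ΔΔG; it never predicts
  multi-point energies itself.
* The benchmark reader accepts any ProTherm-style table; it does not
  reproduce any particular historical database snapshot.
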