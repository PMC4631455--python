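# thermodesign

Design of thermostable multiple-point protein mutants by combining
energy-based and evolution-based candidate generation with smart filtering
of antagonistic and functionally constrained substitutions.

Engineering a protein for heat tolerance usually means stacking several
stabilizing point mutations — but predictions of single-mutation stability
effects are noisy, and individually stabilizing mutations are often
antagonistic when combined. `thermodesign` implements a conservative hybrid
strategy for users (enzyme engineers, protein designers) who have a query
sequence, an alignment of homologs, one or more crystal structures, and
per-mutation ΔΔG tables from external energy calculators (FoldX- or
Rosetta-style), and want a short list of mutually additive substitutions
worth synthesizing.

## The method

Two candidate streams feed a common combiner:

* **Evolution arm.** From a multiple sequence alignment, back-to-consensus
  candidates are proposed where the query deviates from its homologs:
  either a residue present in ≥ 50% of sequences (*simple consensus*,
  cutoff 0.5), or the most frequent residue with frequency ≥ 0.4 whose
  wild-type/consensus frequency ratio is ≤ 0.2 (*frequency ratio*).
  Poorly aligned regions are masked by the user.
* **Energy arm.** Per-structure ΔΔG predictions (kcal·mol⁻¹, negative =
  stabilizing) are averaged — replicates within a structure, then across
  structures — and a mutation qualifies only if *both* tools call it
  stabilizing (FoldX mean < −1.0; Rosetta mean < −2.0), while ΔΔG > +0.5
  marks it destabilizing. Positions with conservation grade ≥ 8 (on the
  1–9 scale derived from site-specific evolutionary rates) or a
  correlated-mutation score ≥ 0.8 are treated as functionally constrained
  and excluded.
* **Structure filter.** Candidates whose wild-type side chain takes part in
  a salt bridge (acidic carboxyl O within 4.0 Å of a basic side-chain N, in
  any analyzed structure or chain) are discarded.
* **Combiner.** Candidate pairs whose predicted double-mutant
  ΔΔG > −3.0 kcal·mol⁻¹ are antagonistic. After keeping the best mutation
  per position, candidates are admitted greedily from the most stabilizing
  down, each one only if additive with everything already admitted; the
  result is a clique in the additivity graph. Independent designs (one per
  arm) can be merged into a hybrid.
* **Benchmark arm.** Experimental ΔΔG records are curated (|ΔΔG| ≥ 0.5
  kcal·mol⁻¹, duplicate measurements resolved to the one closest to pH 7)
  and any predictor is scored with precision = TP/(TP+FP) and false
  positive rate = FP/(FP+TN) over thresholds −2.5 … +2.5 in steps of 0.5.

## Worked example

Merging a published eight-point energy-arm design of a haloalkane
dehalogenase with the best three-point evolution-arm design:

```python
import thermodesign as td

energy = td.DesignPlan.from_notation(
    "C128F + T148L + A172I + C176F + D198W + V219W + C262L + D266F",
    name="energy", provenance="energy")
evolution = td.DesignPlan.from_notation(
    "E20S + F80R + A155P", name="evolution", provenance="evolution")
hybrid = td.merge_designs(energy, evolution, name="hybrid")
print(len(hybrid), hybrid.notation)
```

prints

```
11 C128F + T148L + A172I + C176F + D198W + V219W + C262L + D266F + E20S + F80R + A155P
```

— an 11-substitution hybrid plan; positions are disjoint so the merge is
conflict-free and provenance per mutation is preserved. The end-to-end
pipeline on a fully synthetic project runs from the shell:

```bash
thermodesign run-all --seed 3 --outdir run/
```

which generates an alignment with three planted consensus deviations plus
matching ΔΔG tables, and reports the assembled design with its admission
order in `run/plan.tsv`.

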