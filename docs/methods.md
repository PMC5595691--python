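# Methods

## Model

`agerank` scores each (compound, species) pair with a bounded empirical
function: five factors in [0, 1] multiplied together, plus four additive
terms, clipped to [0, 1]. The multiplicative core encodes a conjunction of
necessary conditions — a compound must target an aging-relevant protein
AND that protein's binding region must be conserved in the invertebrate
AND the binding site itself must be conserved AND the compound must bind
tightly AND it must reach its target in the animal. The additive terms
(drug-likeness, promiscuity, purchasability, approval status) modulate
rather than gate the score.

Logistic transforms `1/(1 + e^{−(x−l)/s})` turn raw quantities into
factors. The form is fixed by its worked examples: the five quoted
nanomolar affinities (100, 23, 35, 63, 120 nM), converted to pKd and
passed through `logistic(·; 5, 1)`, reproduce all five two-decimal
affinity factors (0.88, 0.93, 0.92, 0.90, 0.87).

### Parameters

| quantity | transform | location | scale | rationale |
|---|---|---|---|---|
| domain similarity (0–1) | logistic | 0.6 | 0.1 | mid-range similarity differences matter most |
| binding affinity (pKd) | logistic | 5 | 1 | centred on 10 µM; nanomolar binders saturate |
| promiscuity (#targets) | logistic/5 | 7 | 1 | only many-target compounds are penalized, cap −0.2 |
| worm bioavailability (predictor score) | logistic·0.8+0.2 | 4 | 2.25 | rescaled to (0.2, 1.0); fly uses constant 0.9 |

All are config fields (`RankingConfig`), as are the ±50-residue contact
window, the k-rounding of the lowest-half site rule, and the factor/term
weights used by `tailored_score`.

## Conservation machinery

Residue similarity is `1 − d/215` with `d` the Grantham physicochemical
distance (215 = the table maximum, Cys–Trp). The 20×20 distance table is
vendored as a TSV with an sha256 guard; ambiguity codes B/Z/X are uniform
averages over their expansions, applied on both sides, and the extended
23×23 similarity matrix ships as a second TSV with a bit-exact
load/dump round trip.

**Gap policy** (not dictated by the formulas themselves): columns where
the *reference* is gapped carry no reference residue and are excluded
from denominators; a gap in the *homologue* counts as a mismatch for
identity and contributes similarity 0. This is the conservative choice —
a deletion at a contact position is evidence against conserved binding,
not missing data. The identity denominator can be switched to
alignment-length counting in the config for comparison.

**Binding-site conservation** averages the k most dissimilar site
positions with k = max(1, floor(N/2)). Floor was chosen because an
11-residue site with a single conservative Tyr→His change then gives
(0.6140 + 4)/5 ≈ 0.923 → 0.92, matching the published worked value for
that case; ceil is available via config and differs only at odd N.

**Scoring regions** for domain conservation are the union of every
annotated domain containing a ligand contact and, for contacts outside
all domains, ±50-residue windows clipped to the sequence; overlapping or
adjacent intervals merge, so a residue is never double-counted.

**Homologue selection** per family and species minimizes binding-site
gap count, breaking ties by higher site similarity, then higher site
identity, then lexicographic member id — making the choice deterministic
and input-order invariant.

## Aging-evidence factor

GO evidence classes map to scores: experimental 0.01 (0.02 via
orthologue), computational 0.15 (0.16), author/curator statement 0.16,
automatic/none 0.28 (0.29); GenAge membership forces 0.01. The published
rendering of the implication formula is typographically ambiguous about
what the final division applies to; this package defaults to
`1 − (ev + 0.1·m)/2` (so a GenAge-backed direct target scores 0.995,
displayed as 1.00) and offers `1 − ev − 0.1·m/2` behind
`RankingConfig.aging_formula`. Neither reading reproduces the one
published 0.98 value for the HSP90α-binding compound from the listed
evidence classes alone, so that cell is not used as a check. Which member
of each x/x+0.01 evidence pair applies is mapped here to
direct-vs-orthologue annotation.

For multi-target compounds, domain conservation, site conservation and
affinity are aggregated by element-wise maximum across targets; aging
implication is aggregated by maximum as well, for consistency (the best
target dominates the rationale for testing the compound). The promiscuity
term counts every distinct aging-associated protein the compound is
crystallized with, regardless of whether that target has an orthologue in
the ranking species.

## Ranking and reports

Compounds sort by descending final score; ties share order by ascending
HET code but receive distinct consecutive ranks (published rankings use
unique ordinal ranks). Distribution cutoffs are the score at rank
min(15, N) and at rank max(1, floor(N/10)). Report cards render as JSON
(full precision, byte-identical round trip), HTML (two-decimal display)
or a 16-column table row; the ranking TSV stores full-precision floats
via shortest round-trip repr, so write→read is lossless.

## Synthetic data generator

`agerank.fixtures.generate_fixtures` emulates a complete input set:
protein families evolved from a random root sequence by per-site
substitution (uniform over the 19 alternatives), with invertebrate
branches at the full rate (default 0.35 per site, giving ~60–70 % global
identity to the reference, the range observed for real kinase
orthologues), mammalian branches at a third of it, and binding-pocket
positions at a fifth of the branch rate — mimicking the empirically
stronger conservation of drug binding sites. Compound annotations draw
molecular weight ~N(400, 120) Da, logP ~N(3, 1.5), donors/acceptors
Poisson(2)/Poisson(6), pKd ~N(7, 0.7), predictor bioavailability scores
~N(4, 2), and realistic purchasability/approval frequencies. A
configurable fraction of families lacks one invertebrate species so the
no-homologue exclusion path is exercised.

What the generator does **not** emulate: alignment gaps (fixtures are
gapless, so column = position; gap handling is covered by unit tests on
hand-built alignments), correlated substitution processes, paralogy, or
any realistic relationship between a compound's structure and its
descriptors. Passing fixture-based tests therefore demonstrates the
arithmetic and plumbing of the pipeline, not biological validity on real
alignments.

Every generated dataset ships with expected score breakdowns computed by
`agerank.oracle`, a deliberately naive straight-line re-derivation of
every formula that shares no code with the pipeline; tests require exact
(bit-level) agreement between the two implementations on all fixtures.
To keep that comparison meaningful, both sides evaluate the logistic as a
single expression and sum the composite as product-plus-term-sum.

## Numerical and degenerate-input choices

* `logistic` underflows to exactly 0 for arguments below −700 scale
  units instead of overflowing.
* Empty scoring regions, empty binding sites and missing worm predictor
  scores raise explicit errors; nothing silently defaults to a neutral
  factor.
* Factors outside [0, 1], negative weights, non-positive Kd and invalid
  category/status strings are rejected at construction time.
* Lipinski boundaries follow the rule text: MW ≥ 500 violates, logP > 5,
  donors > 5, acceptors > 10; internal math is unrounded and rounding to
  two decimals happens only at display time.

## Problem sizes

The default test suite runs families of 300 residues with 5–8 families
and 20–100 compounds; these sizes make every dual-implementation and
property check run in seconds while exercising all code paths. The
published study ranked 697 (fly) and 591 (worm) compounds from 1480
structures; reproducing those counts requires the external databases and
predictor outputs that are inputs, not parts, of this package.

## Known limitations

* MSA construction, domain assignment, affinity and bioavailability
  prediction, and database cross-mapping are consumed as inputs; the
  package cannot be better than the upstream annotations it is fed.
* The aging-implication formula ambiguity above means scores in the
  0.95–1.00 band depend mildly on the chosen reading.
* Identity/similarity percentages are reported against the single
  selected homologue; species with several paralogues collapse to the
  best-site representative.
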