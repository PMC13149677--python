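# Methods

## Screening model

The pipeline treats a processed untargeted metabolomics release as three
aligned tables: a dense features × samples matrix of normalized, finite,
non-negative intensities; a per-feature annotation table assigning each
feature either a structure-level annotation (InChIKey, compound name,
optional chemical-superclass label) or a molecular formula only; and
per-sample metadata carrying a food name, an organism binomial and a
two-level food-ontology classification (level 1: plant / animal / algal
/ fungal product; level 2: finer groups such as dairy). Everything
upstream — peak detection, formula assignment, adduct handling,
normalization — is out of scope and assumed done.

### Formula layer

Formulas are flat neutral compositions. The parser accepts underscores
and Unicode subscript digits as count markers and rejects charges,
isotopes, parentheses and adduct dots; element symbols are tokenized
greedily (two-character symbols before one-character ones) and validated
against the periodic table. Canonical rendering is Hill order; all
set-membership operations key on the canonical string so that spelling
variants of the same composition compare equal.

DBE (double bond equivalents) is C − (H + X)/2 + N/2 + 1 with X the
summed halogen count, evaluated with `fractions.Fraction`: 2·DBE is
always an integer and half-integer values (radical or adduct species)
are reported as-is rather than rounded, because rounding would distort
the DBE distribution whose peak at zero is a diagnostic for saturated
fluorochemicals. The equation carries valence terms only for
C, H, N, O, S, P, F, Cl, Br, I; formulas containing any other element
(salts with K or Na, metals) are marked *excluded* — a value, not an
error — and tallied separately wherever DBE is consumed.

### Xenobiotic call

A formula-only feature is `np_formula_match` iff its canonical formula
is in the union of the three natural-product reference sources,
otherwise `putative_xenobiotic`. The percentage reported for the
xenobiotic pool uses **all** features as denominator (not formula-only
features): that is the convention under which the release-scale
stratification (1,187 of 24,721) prints as 4.8%. Percent rounding is
half-up, applied only at report formatting. Structure-annotated
features are never screened as xenobiotics, even if their formula is
absent from the union — the two branches are disjoint by design.
Unparseable formulas go to an explicit `unclassifiable` side-list, so
the partition identity

    n_np_match + n_xenobiotic + n_unclassifiable = n_formula_only

is enforced, never assumed.

### Structure matching

Matching is exact, case-sensitive equality of the full 27-character
InChIKey. An opt-in mode (`--inchikey-block1`) compares only the
14-character connectivity block; it conflates stereoisomers and is off
by default. Therapeutic-category terms attach only on a pharmaceutical
match; the category map can be restricted to a curated keep-set of 20
broad therapeutic categories, which silently discards non-therapeutic
classifications (industrial uses, chemical descriptors) simply by
omission from the keep-set.

### Novel-producer screen

Scope defaults to compounds matched to the pharmaceutical source;
`all-structure` widens it. "Detection" means intensity strictly greater
than `detect_min` (default 0 — the matrix is dense post-normalization
and carries no detection floor of its own). Prevalence is detections
over the denominator population; the default denominator is plant
samples, with `all` available because the two conventions are both
defensible and the choice materially changes which compounds survive
the 10% cutoff. The threshold is strict (`prevalence > threshold`
excludes). Genus is the first whitespace token of the organism binomial,
case-normalized; single lowercase tokens ("unknown") yield no genus and
such samples can never support a pair. Occurrence lookups try the
compound's InChIKey first and fall back to its canonical formula; genus
comparison is case-insensitive. Pairs deduplicate to unique
(compound, genus), keeping the maximum-intensity supporting sample with
ties broken toward the lexicographically smaller sample id.

### Aggregation

A block is one feature subset × one sample group. Block means include
non-detect zeros (a `--detected-only` style restriction would change the
estimand, not just the estimate, and is deliberately not the default);
block sums conserve the grand total. The log transform is fixed as
log10(x + 1) and applied after aggregation. Top-source rankings average
within foods (replicates collapse to a per-food mean), drop foods with
zero mean, and break ties alphabetically — hence "up to n" rows.
Fluorinated-xenobiotic matrices select each group's top-k features by
within-group mean, take the union as rows, and order rows and columns by
average-linkage hierarchical clustering on Euclidean distances of the
transformed matrix; inputs are label-sorted first so identical matrices
give identical leaf orders. Linkage and metric are plumbing choices,
not claims.

## Synthetic data

The generator emulates the screening-relevant structure of a release,
not its spectra: no m/z, retention or adduct information is simulated.

Defaults define the desk-scale study used throughout the tests: 2,000
features (80 structure-annotated, 1,920 formula-only) × 100 samples
with the release's group proportions (70 plant, 15 animal, 8 algal, 7
fungal); a release-sized preset (24,721 × 500) sits behind
`--full-scale`. Planted counts mirror the screens they exercise: 96
xenobiotic formulas (~4.8% of all features, matching the release-scale
share), 12 of them fluorinated with a low-DBE bias — including the
perfluorooctanesulfonate potassium salt C8F17KO3S, which also exercises
the DBE-exclusion path — roughly half of the remainder chlorinated;
12/5/2 planted drug/food-contact/agrochemical matches with 20 decoy
reference rows per source; 7 novel compound–genus pairs scripted below
the 10% prevalence threshold and 3 decoy compounds above it.

Natural-product formulas are drawn from a CHNO(S,P) grammar with
integer DBE ≥ 0 and H ≤ 2C + 2 + N; every formula used by an np-matched
feature is registered in the fixtures, and every planted xenobiotic
formula is rejection-sampled until absent from the union — planted
truth is constructive, not probabilistic, which is what licenses the
exact sensitivity-and-specificity-1.0 recovery assertions. Likewise,
drug-matched compounds that are neither novel-planted nor decoys
receive occurrence records covering every study genus, so the
novel-producer screen has no false positives by construction.

Intensities are log-normal (meanlog 2.0, sdlog 1.0, arbitrary
normalized units) with Bernoulli sparsity π = 0.65 — a zero fraction in
the range typical of dense normalized food-metabolomics matrices — plus
a ×10 multiplicative effect on drug-matched features in plant samples
(the planted group signal for aggregation tests) and scripted rows for
novel/decoy compounds, a three-feature fluorinated block shared by the
hard-cheese samples, and, when enabled, a near-ubiquitous compound
detected in exactly 63 of 65 animal and 194 of 200 plant samples for
the prevalence arithmetic. Random streams are split per table
(metadata, references, features, matrix, planting) from one seed, so
fixed seed ⇒ byte-identical file trees and enlarging one table does not
perturb the others.

What passing on synthetic data does **not** show: robustness to real
reference-database incompleteness and bias, to InChIKey disagreements
from differing structure standardization, to formula-assignment errors
upstream, or to chemotaxonomic plausibility of "novel" pairs. The
screens are exact set operations; their real-world error is inherited
entirely from their inputs.

## Numerical and degenerate-input choices

* DBE and histogram bin edges are exact rationals end to end; floats
  appear only in intensities and ratios.
* Van Krevelen points are undefined (and counted as skipped) for
  carbon-free formulas.
* Half-up decimal rounding is applied only when formatting reports.
* Empty matrix cells read as 0 with a logged count; duplicate feature
  or sample labels are hard errors, as are misaligned sample ids
  between matrix and metadata (offenders listed).
* Empty feature subsets aggregate to structurally-present zero columns;
  an empty fluorinated pool yields an empty matrix, not an error.
* Clustering falls back to label order for fewer than three items.

## Problem sizes

The default test suite and the acceptance script run the desk-scale
study (2,000 × 100), the release-scale partition arithmetic (24,721
feature records, set membership only), a 10,000-formula DBE oracle
comparison, and a 275-sample prevalence study with a reduced feature
count — sizes chosen so the full validation cycle completes in well
under a minute on a laptop while every screen is still exercised at
planted-truth scale.

## Known limitations

* Formula-level xenobiotic calls are putative by nature: absence from
  reference databases reflects their coverage, and no PFAS-class or
  structure assignment is attempted at formula level.
* Name-based matching, structure standardization/desalting and mass or
  adduct arithmetic are out of scope; matching trusts the provided
  InChIKeys and formulas.
* The novel-producer screen does not assess chemotaxonomic plausibility
  or search literature; it reports database absence only.
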