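# chemtrace

Suspect screening of untargeted food-metabolomics features against
chemical knowledge bases.

Large untargeted LC-MS surveys of foods annotate only a small fraction of
their features at the structure level; the rest carry a molecular formula
at best. `chemtrace` turns that annotation gap into a triage problem for
food chemists and exposomics researchers: which features look like known
drugs, agrochemicals or food-contact chemicals, which formulas cannot
plausibly be natural products, and which known natural products turn up
in food organisms never reported to produce them?

## What it computes

Given a normalized feature × sample intensity matrix, a per-feature
annotation table, per-sample food metadata (organism binomial plus a
two-level food-ontology classification) and plain-text reference tables,
the pipeline runs two branches:

* **Structure branch.** Features carrying an InChIKey are matched by
  exact 27-character key equality against pharmaceutical, food-contact
  and agrochemical reference sets, with curated therapeutic-category
  terms attached to drug matches. A taxonomy-aware screen then flags
  compound–genus pairs: a drug-matched compound detected in a food whose
  organism genus *g* is absent from the aggregated natural-product
  occurrence records is a candidate novel producer, subject to a
  prevalence filter (compounds detected in more than 10% of plant
  samples are discarded as ubiquitous).

* **Formula branch.** A formula-only feature with canonical Hill formula
  *f* is a *putative xenobiotic* iff *f* is absent from the union of
  natural-product reference formulas. The xenobiotic pool is prioritized
  by fluorine content and profiled by degree of unsaturation,

      DBE = C − (H + X)/2 + N/2 + 1,   X = F + Cl + Br + I,

  computed in exact rational arithmetic (formulas containing elements
  outside C, H, N, O, S, P and the halogens are excluded rather than
  forced into the equation), by Van Krevelen coordinates (H/C vs O/C),
  and by heteroatom content.

Ontology-aware aggregation (block means or sums per food group × feature
subset, optional log10(x+1)), per-compound food-source rankings,
detection prevalence, and hierarchically clustered matrices of top
fluorinated xenobiotics round out the reporting layer.

A seed-reproducible synthetic-study generator plants ground truth for
every screen — xenobiotic formulas constructively absent from the
reference union, scripted novel compound–genus pairs below the
prevalence threshold with decoys above it, planted source matches and
group effects — so the entire pipeline is validated end to end by exact
recovery.

## Worked example

```sh
chemtrace simulate --seed 7 --out demo/study
chemtrace screen --annotations demo/study/annotations.tsv \
                 --refs demo/study/refs --out demo/screen
```

prints

```
wrote study: 2000 features x 100 samples -> demo/study
96 putative xenobiotics (4.8% of all features), 12 fluorinated
```

i.e. of the 2,000 features (80 structure-annotated, 1,920 formula-only),
1,824 formula-only features match a natural-product formula and 96 do
not — a 4.8% putative-xenobiotic share of all features — and 12 of the
96 contain fluorine. `demo/screen/screen_summary.json` adds the
heteroatom table (here 42 chlorinated and 26 sulfur-bearing xenobiotic
features, 54 with any halogen) and a `dbe_skipped` count of 1: the
planted perfluorooctanesulfonate potassium salt C8F17KO3S, whose
potassium atom has no term in the DBE equation. The novel-producer
screen on the same study,

```sh
chemtrace novel-producers --features demo/study/features.tsv \
    --annotations demo/study/annotations.tsv \
    --metadata demo/study/metadata.tsv --refs demo/study/refs \
    --out demo/novel.tsv
```

reports `7 novel compound-genus pairs`, each with the supporting sample,
its intensity and the compound's prevalence, e.g.

```
inchikey                      compound_name  genus   best_sample  max_intensity  prevalence
COXISCZGMURUAO-XFDPZFPKKB-N   compound_0005  Allium  S0046        46.1587        0.0143
```

— compound_0005 is detected in an *Allium* food although no occurrence
record lists *Allium* as a producer, and its 1.4% prevalence is well
under the 10% ubiquity cutoff. All seven pairs are exactly the ones the
generator planted.

`chemtrace run --config pipeline.yaml` chains every stage and writes a
manifest with input checksums and per-stage counts; `aggregate`,
`top-sources`, `prevalence` and `fluorinated-heatmap` expose the
reporting operations individually. The same functionality is importable
from Python (`import chemtrace`).

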