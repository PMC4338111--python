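# pathora

Pathway diagrams, omics data overlay and over-representation analysis.

Biologists organize knowledge about cellular processes as *pathway
diagrams*: boxes for genes, proteins and metabolites, arrows for the
conversions, stimulations and inhibitions between them, each box annotated
with a database identifier (e.g. the *KNG1* gene as Entrez Gene 3827).
Given such a diagram collection and an omics experiment — say a
differential-expression table with `log2FC` and `pvalue` columns — two
questions follow:

1. **Which pathways are affected?** Define a boolean *criterion* selecting
   the interesting genes (e.g. `ABS([log2FC]) > 1 AND [pvalue] < 0.05`) and
   rank pathways by how over-represented criterion-positive genes are.
2. **What does the data look like on the diagram?** Paint each data-node
   box with its measurements: continuous values through a color gradient,
   categories through ordered color rules, one box column per data column
   and one box row per measurement.

`pathora` implements this workflow as a library plus a small CLI:

* **GPML I/O** — reads and writes the Graphical Pathway Markup Language
  used by WikiPathways (2013a dialect; 2010a accepted on read). Unknown
  attributes and elements round-trip verbatim; writing is byte-deterministic.
* **Identifier mapping** — a TSV-driven cross-reference table; matching uses
  the full transitive closure, so data keyed in any linked identifier
  system finds its pathway nodes.
* **Dataset import** — delimited text with inferred column types and
  three-valued (Kleene) criterion evaluation: comparisons against missing
  values are *undefined*, and only a definite `true` counts as positive.
* **Over-representation analysis** — the hypergeometric Z-score, gene-level.
* **Visualization** — gradient/rule color schemes rendered with the pathway
  as deterministic SVG (PNG via the optional `cairosvg` extra).
* **Fixtures** — seeded synthetic pathway collections, mapping tables and
  expression datasets, including a *planted enrichment* construction with a
  known answer.

## The statistic

For each pathway, count `total` (distinct annotated genes), `n` (those
measured) and `r` (those meeting the criterion); across the collection
count `N` (measured genes present in at least one pathway — genes in no
pathway are ignored) and `R` (positives among them). Under the
hypergeometric null of drawing the pathway's `n` genes from the `N`-gene
universe with `R` positives,

```
Z = (r − nR/N) / sqrt( n · (R/N) · (1 − R/N) · (1 − (n−1)/(N−1)) )
```

Positive `Z`: more positive genes than expected. Pathways are ranked by `Z`
descending; a degenerate variance (`n = 0`, `n = N`, `R = 0` or `R = N`)
gives an undefined score, reported as `NA` and sorted last. Counting is
gene-level through identifier-equivalence classes: several data rows for
one gene never inflate the counts, and one true row makes its gene
positive.

## Worked example

```python
from pathora import import_data_table, load_mapping_table, run_ora, write_ora_report
from pathora.fixtures import FixtureSpec, generate_collection, generate_dataset

spec = FixtureSpec(seed=7)                      # 20 pathways, pathway 0 planted
collection, idmap_text = generate_collection(spec)
mapper = load_mapping_table(idmap_text)
dataset = import_data_table(generate_dataset(spec, collection),
                            id_column="id", system="SysB")

report = run_ora(collection, dataset, mapper,
                 "ABS([log2FC]) > 1 AND [pvalue] < 0.05")
print(f"N = {report.N} measured genes in pathways, R = {report.R} positive")
for row in report.rows[:3]:
    print(f"{row.pathway_name}\t{row.total}\t{row.n}\t{row.r}\t{row.z:.2f}")
```

prints

```
N = 133 measured genes in pathways, R = 22 positive
Synthetic pathway 000	10	10	9	6.48
Synthetic pathway 003	10	10	4	2.07
Synthetic pathway 014	10	10	3	1.19
```

Pathway 000 is the planted one: 9 of its 10 measured genes pass the
criterion against an expectation of `nR/N = 10·22/133 ≈ 1.65`, hence
`Z ≈ 6.48` — far ahead of the best background pathway. The same analysis
from the shell:

```sh
pathora fixtures --out demo --pathways 20 --seed 7
pathora ora --pathways demo/pathways --data demo/data.tsv \
    --idmap demo/idmap.tsv --system SysB \
    --criterion 'ABS([log2FC]) > 1 AND [pvalue] < 0.05' --out report.tsv
pathora render --pathway demo/pathways/pathway_000.gpml \
    --data demo/data.tsv --idmap demo/idmap.tsv \
    --scheme demo/scheme.json --system SysB --out pathway_000.svg
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — generates
the seeded synthetic world, executes the over-representation analysis,
renders the top-ranked pathway with the demo scheme — and writes its result
JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model, parameters, numerical choices and
the limits of what the synthetic data establishes.
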