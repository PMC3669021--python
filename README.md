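# phenotier

Four-tiered graphs for binary phenotype matrices.

Given a strain × resource 0/1 matrix (e.g. enzyme activities from API ZYM
strips or carbon assimilation from Biolog PM1 plates), `phenotier`:

1. groups strains with identical profiles — and resources with identical
   utilization columns — into **equivalence classes**;
2. ordinates the strains by a **PCA on the Hamming-similarity matrix**
   (similarity = 1 − normalized Hamming distance); classical PCoA of the
   distance matrix is available as an alternative mode;
3. lays everything out as a directed four-tier graph
   *strains → strain classes → resource classes → resources*: strain classes
   sit at their PC1 coordinate (overlapping classes spread apart by a minimal
   spacing ε while non-overlapping geometry is preserved), resource classes
   sit at the barycenter of the strain classes linking to them, and every
   class is annotated with its connection count;
4. writes the result to **GraphML** (optionally with yEd geometry extensions)
   plus a profile table re-ordered to match the graph.

Supporting statistics (per-profile summaries, Pearson/Mantel correlation
between distance matrices, Wilcoxon rank-sum with exact enumeration at small
n) and a synthetic-data generator with planted class structure are included.

## CLI

```sh
# simulate a matrix with planted classes, then build the graph
phenotier simulate --strains 33 --resources 95 --classes 6 --seed 42 --out sim.csv
phenotier graph --input sim.csv --output graph.graphml --table profile.tsv --yed

# continuous OD input, binarized at 10% of the dataset-wide maximum
phenotier graph --input od.csv --continuous --fraction 0.10 --output graph.graphml

# equivalence classes with degrees; ordination coordinates
phenotier classes --input sim.csv --out classes.tsv
phenotier ordinate --input sim.csv --coords coords.csv --variance var.tsv

# correlation between two square distance CSVs (Mantel permutation p included)
phenotier correlate --d1 enzyme_dist.csv --d2 carbon_dist.csv --permutations 999
```

Every subcommand accepts `--config file.toml` whose keys mirror its flags,
and `phenotier -v …` logs the binarization threshold, ε and variance
fractions to stderr.

Input layout: comma-separated text, first row = resource names (first cell
blank), first column = strain names; `--sep $'\t'` switches to TSV.

## Package layout

| module                  | contents                                                    |
|-------------------------|-------------------------------------------------------------|
| `phenotier.io`          | CSV matrix I/O, OD binarization, GraphML writer/reader, profile tables |
| `phenotier.equivalence` | strain/resource partitions, reduced class graph with degrees |
| `phenotier.ordination`  | normalized Hamming distances, similarity PCA, PCoA          |
| `phenotier.layout`      | overlap-separated PC1 placement, barycenters, tiered graph  |
| `phenotier.stats`       | profile summaries, distance-matrix correlation, rank-sum test |
| `phenotier.simulate`    | planted-class binary/bimodal-OD generators with ground truth |
| `phenotier.cli`         | `phenotier graph|classes|ordinate|simulate|correlate`       |
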