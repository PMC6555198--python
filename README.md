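# transtat

Scriptable biostatistics for bulk and single-cell gene-expression matrices:
a library plus a `transtat` command-line tool covering the everyday analysis
loop for RNA-seq count data.

* **I/O** — CSV expression matrices (genes in rows, samples in columns),
  gene-length tables, negative-control gene lists, sample metadata, and
  externally produced differential-expression tables, all with validation.
* **Preprocessing** — low-expression filtering; FPKM/RPKM, TPM,
  upper-quartile, and RUV (control-gene factor) normalization; relative log
  expression (RLE) profiles for sample QC.
* **Distribution fitting** — maximum-likelihood fits of lognormal, Pareto,
  log-logistic, gamma, Weibull, and Burr XII families, ranked by AIC, plus a
  power-law-based low-expression cutoff report.
* **Exploration** — pairwise scatter tables, Pearson/Spearman correlation
  matrices, PCA over samples, seeded k-means.
* **Variability** — per-sample Shannon entropy (Doane-rule binning) and the
  pairwise squared-coefficient-of-variation noise matrix.
* **Clustering** — fold-change or DE-table gene selection, per-gene z-score
  scaling, Ward hierarchical clustering with heatmap layout and per-cluster
  gene lists, and volcano-plot categorization.
* **Fixtures** — a deterministic synthetic-data generator with planted,
  recoverable structure for testing every stage offline.

## Command line

Every subcommand reads/writes plain CSV and records a `run_manifest.json`
(parameters, version, input checksums — no timestamps, so reruns are
byte-identical). Exit codes: 0 success, 1 invalid input, 2 internal error.

```sh
# generate a synthetic bundle to play with
cat > spec.json <<'EOF'
{"seed": 1, "n_genes": 200, "n_samples": 6, "n_controls": 20, "de_fraction": 0.2}
EOF
transtat fixtures --spec spec.json --out bundle/

# filter + TPM normalization with before/after RLE summaries
transtat preprocess --matrix bundle/matrix.csv --lengths bundle/gene_lengths.csv \
    --method tpm --min-value 5 --min-samples 2 --out prep/

# RUV normalization from negative-control genes
transtat preprocess --matrix bundle/matrix.csv --controls bundle/control_genes.csv \
    --method ruv --k 1 --out ruv/

# distribution fitting with AIC ranking for one sample
transtat distfit --matrix bundle/matrix.csv --sample S1 --out fit/

# correlations, PCA, k-means
transtat correlate --matrix bundle/matrix.csv --method spearman --out corr.csv
transtat pca --matrix bundle/matrix.csv --out pca/
transtat kmeans --matrix bundle/matrix.csv --k 2 --seed 1 --out clusters.csv

# entropy + noise
transtat variability --matrix bundle/matrix.csv --out var/

# Ward clustering of fold-change-selected genes, heatmap layout, gene lists
transtat cluster --matrix bundle/matrix.csv --metadata bundle/metadata.csv \
    --cond-a Control --cond-b Treated --min-fold 2 --k 3 --out clust/

# volcano categorization of an external DE table
transtat volcano --de bundle/de_table.csv --p 0.05 --fc 1 --out volcano.csv
```

## Conventions worth knowing

* Low-expression filtering keeps genes **strictly above** the threshold in
  at least the requested number of samples.
* Two-point CV² uses the population variance (divide by 2), so the pair
  (x, 3x) has CV² exactly 0.25.
* Z-scaling uses the sample (n−1) standard deviation; Ward clustering is the
  "Ward.D2" convention (Euclidean distances, Lance–Williams update on
  squared distances).
* Distribution fits exclude zeros (all six supports are strictly positive)
  and report how many were dropped; Pareto fixes its location at the sample
  minimum but counts two parameters in AIC.
* Entropy bins raw values after a log10(x+1) transform by default; pass the
  linear-binning flag to disable.
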