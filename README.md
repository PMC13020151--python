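# xciscape

Analysis pipeline linking the **magnitude of escape from X chromosome
inactivation (XCI)** to the **magnitude of sex-biased gene expression**
across human tissues.

In XX individuals one X is epigenetically silenced, but incompletely: some
genes escape and are expressed from the inactive X (X_i). In females with
fully skewed ("non-mosaic") XCI, allelic expression at heterozygous sites
directly measures X_i output:

    AE = |0.5 - ref_reads / total_reads|        (0 biallelic … 0.5 monoallelic)

with analyses on the escape scale 1-AE, where 1-AE ≥ 0.6 calls an
observation *escaping* and 0.5 ≤ 1-AE < 0.6 *silenced*. Joining these
observations to per-gene×tissue sex effects (β_mash, with local false sign
rate LFSR), the pipeline asks, separately for pseudoautosomal (PAR) and
non-PAR X-linked (NPX) genes:

- Do genes in the same topologically associating domain (TAD) show more
  similar escape than genes in different TADs? (within- vs between-TAD
  pairwise-distance permutation test, adjacency and rank-distance decay,
  sequential ANOVA with Tukey HSD)
- Does the magnitude of escape predict the magnitude of sex bias?
  (quadrant-stratified Spearman correlations of 1-AE against β_mash, per
  gene, per tissue, and across tissue medians)
- Are sex-biased escape genes near regions of same-direction sex-biased
  enhancer activity? (Fisher exact tests over nearest-gene annotations)

Who it is for: anyone with gene-level allelic-expression tables from
skewed-XCI samples (or harmonizable single-cell allelic measures —
X_i/total, X_a/total, X_i/X_a), sex-bias effect tables, TAD intervals and
regulatory-element annotations. A synthetic-data generator emulating all
five input families makes every stage testable without any external data.

## Worked example

Run the whole pipeline on a simulated study (12 PAR + 120 NPX genes,
16 TADs, 8 tissues, 2 skewed-XCI individuals):

```python
from xciscape.cli import run_pipeline

run_pipeline(
    {
        "simulate": {"seed": 7, "n_par_genes": 12, "n_npx_genes": 120,
                     "n_tads": 16, "n_tissues": 8, "n_individuals": 2},
        "tad": {"n_perm": 1000, "seed": 7},
    },
    "demo_out",
)
print(open("demo_out/report.txt").read())
```

which prints (abridged):

```
PAR gene x tissue crosstab (XCI status x bias status):
bias_status  female  male  unbiased
xci_status
silenced          0     0         0
escape            1    80        15
variable          0     0         0

TAD permutation test:
  median within-TAD distance   0.0280
  median between-TAD distance  0.0620
  observed difference          -0.0340
  empirical p (1000 shuffles)  0.0000

Escape-bias quadrant correlations (Spearman rho of 1-AE vs beta):
  PAR_male_escape          rho = -0.278  p = 0.000378  n = 160
  NPX_female_escape        rho = -0.673  p = 9.72e-19  n = 132
  NPX_female_silenced      rho = +0.014  p = 0.833  n = 224
```

Reading the numbers: PAR gene×tissue observations almost all escape XCI
and are predominantly male-biased. Genes within a TAD have much more
similar allelic expression than genes in different TADs (median pair
distance 0.028 vs 0.062); no random reassignment of TAD labels among 1000
produced as extreme a difference, so the empirical p is 0. In the escape
quadrants the correlations are negative: for PAR genes, deeper silencing in
females (lower 1-AE) accompanies stronger male bias (higher β); for NPX
genes, fuller escape (higher 1-AE) accompanies stronger female bias (more
negative β). On the silenced side the association disappears — the
coupling is a property of escaping genes only.

The same stages are available from the shell:

```sh
xciscape simulate --seed 7 --outdir inputs/
xciscape run --config cfg.yaml --outdir out/
xciscape tad-test --tad-bed inputs/tads.bed --values inputs/ae.tsv \
    --genes inputs/genes.tsv --n-perm 1000 --seed 7
```

Every run writes a `manifest.json` with the resolved configuration, seeds,
SHA-256 digests of all inputs and outputs, per-stage record counts and wall
times; re-running the same config reproduces identical digests.

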