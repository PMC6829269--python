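# tcelsig

Estimating how strongly a tissue or tumor is infiltrated by T cells from bulk
gene expression, using a small signature of genes whose expression is
restricted to T cells — no deconvolution software or gene weighting required.

The package is aimed at computational immunologists and tumor-immunology
groups who have log2-scale bulk expression (microarray or RNA-seq) for
purified immune cells, healthy tissues and tumor specimens, and want to

1. **distill a T-cell-restricted signature** from a candidate gene list,
2. **score T-cell infiltration** of any sample with that signature,
3. **stratify patient survival** by infiltration level, and
4. **predict response to anti-PD-1 therapy** from checkpoint expression
   ratios combined with the infiltration score.

A seeded synthetic-corpus generator reproduces the statistical structure
these methods assume, so the whole pipeline can be exercised and tested
without any external download.

## Methods at a glance

**Six-round signature selection.** Starting from candidates, with per-gene
T-cell reference `meanT(g)` (mean log2 expression over all purified T-cell
samples), a gene survives only if:

1. `meanT(g) − mean(g, immune subset) ≥ 3.32` for every non-T immune subset
   (3.32 log2 = ten-fold);
2. `meanT(g) − mean over tissues of mean(g, tissue) ≥ 3.32`;
3. the per-tissue range `max_t mean(g,t) − min_t mean(g,t)` lies in
   [2.5, 8.5] log2;
4. & 5. with `nl/Tc(g,t) = mean(g,t) − meanT(g)` and `M_nl/Tc(t)` its mean
   over the surviving cohort, `max_t [nl/Tc(g,t) − M_nl/Tc(t)] ≤ 3.32`
   (two passes, the cohort mean recomputed between them);
6. the gene is not under-margined (< 3.32 log2) in cell lines from two or
   more distinct parenchymal sources, nor in any non-T immune-derived line.

The packaged `signature_h()` is a 15-gene T-cell-restricted signature
(CD2, CD247, CD28, CD3D, CD3G, CD6, GPR171, GZMK, ICOS, ITK, KLRB1, PYHIN1,
TIGIT, TRAT1, TRBC1) produced by this procedure on a large curated
microarray corpus.

**Infiltration scores** over the signature genes S of a log2 profile x:

- `Ts% = 100 · 2^(mean_{g∈S} [x(g) − meanT(g)])` — percentage of the
  purified-T-cell signal (T cells ≡ 100); log-space averaging makes it a
  geometric mean of per-gene linear ratios.
- `Tav = mean_{g∈S} x(g)` — mean log2 signature expression;
  platform-specific (Tav-array vs Tav-RNAseq).
- `Ts-l2 = mean_{g∈S} [x(g, tumor) − meanHT(g)]` — log2 offset from matched
  healthy tissue; |Ts-l2| ≤ 0.32 ↔ 80–125% of the healthy-tissue signal.

**Survival.** Patients are binned by Tav (default edges 0.125 and 2 outside,
0.5 in between) and compared by Kaplan–Meier curves, the Mantel–Cox log-rank
test and the log-rank hazard ratio `HR = (O_A/E_A)/(O_B/E_B)` with
`CI95 = exp(log HR ± 1.96·√(1/E_A + 1/E_B))`.

**Response rules.** With linear FPKM for PD-1/PD-L1/PD-L2 and
`Tav-RNAseq = mean log2(FPKM+1)` over the signature: signature-1 requires
both ligand/PD-1 ratios in (0.5, 10); signature-2 requires the PD-L1/PD-1
ratio in that window and Tav-RNAseq > 1; signature-3 adds
PD-1/Tav-RNAseq > 0.5. Groups are compared by overall response rate (ORR)
and contingency chi-square.

## Worked example

```python
from tcelsig import (CorpusSpec, GeneSignature, SelectionConfig, generate_corpus,
                     group_means, run_selection, score_samples)

corpus = generate_corpus(CorpusSpec(), seed=7)          # 60 genes, 19 groups
candidates = GeneSignature("candidates", corpus.matrix.gene_ids)
report = run_selection(corpus.matrix, corpus.annotation, candidates,
                       SelectionConfig())
print(report.summary())

stats = group_means(corpus.matrix, corpus.annotation)
scores = score_samples(corpus.matrix, corpus.annotation, report.signature,
                       stats.t_ref, ht_group="colon")
print(scores.loc[["colon_s1", "melanoma_s1", "brain_s1", "T_memory_s1"]].round(3))
```

prints

```
candidates entering selection: 60
  round1_immune: excluded 10
  round2_tissue: excluded 10
  round3_range: excluded 10
  round4_outlier: excluded 10
  round5_outlier: excluded 0
  round6_cellline: excluded 10
surviving genes: 10
  SIG001, SIG002, SIG003, SIG004, SIG005, SIG006, SIG007, SIG008, SIG009, SIG010

             ts_percent    tav           band  ts_l2  infiltrated
sample_id
colon_s1          3.403  5.101        similar  0.106         True
melanoma_s1       8.021  6.338           high  1.343         True
brain_s1          0.219  1.143  extremely_low -3.852        False
T_memory_s1      97.643  9.944           high  4.949         True
```

The corpus plants 10 T-restricted genes plus 50 confounders, each engineered
to violate exactly one selection round; the six rounds exclude each
confounder class at its designed round and recover the planted signature
exactly. Scoring then shows what the numbers mean: a colon specimen sits at
Ts% 3.4 — "similar" to the healthy-tissue reference band (80–125% of
Ts% 3.0) — the melanoma specimen (simulated with an 8% T-cell fraction)
scores Ts% 8.0 and is called infiltrated, near-zero-fraction brain scores
0.2, and a purified T-cell sample scores ≈ 100 by construction.

The same operations are available from the shell:

```sh
tcelsig simulate corpus --seed 7 --out corpus/
tcelsig select --matrix corpus/matrix.tsv --annotation corpus/annotation.tsv \
               --candidates corpus/candidates.gmt --out report/
tcelsig score  --matrix corpus/matrix.tsv --annotation corpus/annotation.tsv \
               --signature report/signature.gmt --ht-group colon --out scores.tsv
tcelsig prognosis --survival survival.tsv --edges 0.125,0.5,2 --out km.json
tcelsig respond --clinical melanoma.tsv --out calls.tsv
```

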