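# mslinc

Discovery and subtype analysis of molecular-subtype-specific long
intergenic noncoding RNAs (MS-lincRNAs) in breast cancer transcriptomes —
implemented as a tested, reusable pipeline exercised end-to-end on
synthetic data with planted ground truth.

Breast cancer is clinically stratified into five molecular subtypes
(luminal A, luminal B HER2±, HER2, triple negative). Novel intergenic
lincRNAs expressed distinctively in one subtype can complement
protein-based subtyping. Starting from a known-gene annotation, an
assembled transcript catalog, an FPKM matrix, methylation beta values and a
PPI edge list, the pipeline:

1. **discovers novel lincRNAs**: candidates ≥ 2000 bp from any known gene,
   mature length ≥ 200 nt, and called noncoding by *both* of two
   coding-potential scorers (Fickett TESTCODE + ORF logistic; in-frame
   hexamer log-likelihood ratio + ORF logistic);
2. **tests differential expression** (Welch's t on log2(FPKM+1), BH) of
   each tumor subtype against adjacent-tissue and normal controls, and
   assigns expression classes I (down in all tumors), II (up in all
   tumors), III (up in luminal tumors only);
3. **links promoter methylation to expression**: CpGs 500–2000 bp from the
   TSS, Pearson correlation at P < 0.01;
4. **builds a coexpression network**: cis pairs (≤ 100 kb) and trans pairs
   (> 1 Mb or different chromosomes), edges at r > 0.6 with P < 1e-5,
   coding–coding edges requiring PPI support, modules by greedy
   cohesiveness w_in/(w_in + w_bound);
5. **selects the "Linctype" marker panel** by staged correlation-based
   feature selection (CFS merit k·r̄_cf / √(k + k(k−1)·r̄_ff) over
   symmetrical uncertainty SU = 2·I(X;Y)/(H(X)+H(Y)), forward best-first
   search): cancer/control stage, six-class stage, per-subtype one-vs-rest
   stage, plus expression extremes;
6. **evaluates the panel**: PCA, k-means (k = 5) against true subtypes,
   Kaplan–Meier curves per cluster and the multi-group log-rank test.

The `mslinc.syndata` module generates every input with recorded ground
truth, emulating a 33-sample design (5 tumor subtypes, 5 matched adjacent
groups, 1 normal group × 3) plus a 250-sample validation cohort — so every
stage is testable without downloads. See `docs/methods.md` for models,
defaults and design decisions.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py            --seed 1   # write synthetic study
python analysis/02_discover_lincrnas.py   --seed 1
python analysis/06_linctype_panel.py      --seed 1
python analysis/07_subtype_evaluation.py  --seed 1
```

`02_discover_lincrnas.py` prints:

```
accepted 50 of 85 candidates
precision 100.0%  recall 100.0%
SElincRNA: 48  MElincRNA: 2
```

All 50 planted lincRNAs are recovered and all 35 decoys rejected — the
audit trail (`results/discovery_audit.tsv`) records which filter rejected
each decoy (10 × distance, 5 × length, 20 × coding potential).

`06_linctype_panel.py` prints:

```
panel: 146 markers
planted markers recovered with correct subtype tag: 25/25
```

so the staged selection finds every planted subtype marker and tags it with
its planted subtype. `07_subtype_evaluation.py` then clusters the
validation cohort on the panel:

```
adjusted Rand index vs truth: 1.000
log-rank across clusters: chi2 = 96.69, df = 4, p = 4.99e-20
```

k-means on the panel reproduces the five planted subtypes exactly, and the
planted survival differences between clusters (hazard ratios spanning
1–8) are detected decisively.

A thin CLI mirrors the main entry points:
`mslinc simulate|discover|panel --help`.

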