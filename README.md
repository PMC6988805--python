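# methsponge

Prediction of DNA methylation-mediated **sponge circRNAs** and their
protein-coding **driver-gene** partners from tumor/normal multi-omics
profiles, with prognostic-index survival stratification.

Circular RNAs can act as competing endogenous RNAs (ceRNAs): by binding
miRNAs at miRNA response elements they de-repress the miRNAs' other
targets. Because circRNAs are co-expressed with their linear host
transcripts, DNA methylation of the circRNA **host gene** is a usable proxy
for circRNA regulation. This package implements an integrative pipeline
that nominates circRNA–driver gene sponge pairs from four data layers —
miRNA expression, gene expression, 450K-style CpG methylation, and
circRNA/miRNA interaction tables — and evaluates the prognostic value of
the nominated circRNAs' host-gene methylation.

The pipeline, in order:

1. **Differential screening** (SAM-style moderated *t* with permutation
   q-values): miRNAs and genes gated at fold change > 2 or < 0.5, circRNA
   host-gene methylation at fold change > 1.5 or < 2/3.
2. **CC network**: circRNAs connect iff they share a differentially
   expressed miRNA (edge weight = shared count).
3. **DMCC network**: CC edges between differentially methylated host genes
   are kept iff their methylation correlates with Pearson *r* > 0.6 **and**
   the correlation beats a 1000-permutation null (edge weight = *r*).
4. **Module mining** (MCODE-style k-core weighting, greedy expansion,
   haircut): module members become candidate circRNAs.
5. **CMD network**: candidate circRNAs × (differentially expressed ∩
   curated driver) genes, linked through shared DE miRNAs; every connected
   (circRNA, driver) pair is a candidate.
6. **Sponge prediction** — a pair is predicted iff all four conditions hold:
   - *P*₁ ≤ 0.05 and *P*₂ ≤ 0.05, where *P*₁ is the one-sided
     Fisher/hypergeometric enrichment of the shared miRNAs
     (point term (a+b)!(c+d)!(a+c)!(b+d)! / (a!b!c!d!n!), summed over
     a′ ≥ a) and *P*₂ the two-sided test of the Pearson correlation *r*
     between host-gene and driver-promoter methylation
     (promoter = TSS−1.5 kb .. TSS+0.5 kb, strand-aware) in tumor samples;
   - *r* > 0 and greater than random (1000 permutations, *p* < 0.05);
   - ≥ 8 unique shared target sites on the driver (same-seed miRNAs occupy
     the same site);
   - driver promoter methylation negatively correlated with driver
     expression (*p* < 0.05).
7. **Survival**: joint Cox fit on the predicted circRNAs' host-gene
   methylation; prognostic index PI = Σᵢ βᵢxᵢ per patient; median-PI split
   into high/low risk; log-rank test and Kaplan–Meier curves.

Because the original data layers are controlled-access downloads, the
package ships a first-class **synthetic-data generator**
(`methsponge.synthetic_data`) that emits every input shape with planted
ground truth — differential features, co-methylated host-gene modules,
true sponge pairs with ≥ 8 unique shared sites, decoy pairs capped at 3
sites, and methylation-driven survival — so that every stage has a
measurable recovery target.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (60 tumor / 30 normal samples, 5 planted sponge pairs
among 64 decoys):

```bash
cd analysis
python 01_simulate.py && python 02_preprocess.py && python 03_screen.py
python 04_networks.py && python 05_cmd_network.py
python 06_predict.py && python 07_survival.py
```

`06_predict.py` prints (abridged):

```
predicted sponge pairs: 5 of 69 candidates
  circ_001 - G001: P1=1.21e-05 r_meth=0.85 perm_p=0.0010 sites=10 r_meth_expr=-0.56
  ...
recall of planted pairs: 5/5
decoys emitted: 0
```

All five planted pairs are recovered: each shares 10 unique target sites
with its driver (≥ 8 required), its host-gene and driver-promoter
methylation are strongly positively correlated (permutation *p* at the
minimum attainable 1/1001), and promoter methylation anti-correlates with
driver expression. None of the 64 decoys — built to share at most 3 unique
sites — is emitted. `07_survival.py` then fits the joint Cox model on the
five host genes and prints the median-PI stratification
(`log-rank statistic 3.28, p = 0.07007` on this cohort; the host-gene
methylation covariates are strongly correlated within modules, which
limits per-gene coefficient stability — see `docs/methods.md`).

The same study runs as one command through the pipeline API or CLI:

```bash
methsponge make-config --seed 1 --out config.yaml
methsponge run --config config.yaml --out-dir run1
```

which writes every intermediate table plus `manifest.json` with SHA-256
hashes of all inputs/outputs (identical config + seed ⇒ identical hashes).

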