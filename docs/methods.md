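# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the pipeline. Nothing
here states a result the tests or `scripts/acceptance.py` do not compute.

## Differential screening

Features are compared between tumor and normal groups with a moderated
statistic d = (x̄_t − x̄_n)/(s + s₀), where s is the two-sample pooled
standard error and the fudge factor s₀ is the 5th percentile of the
per-feature s — a SAM-style stabiliser that keeps near-constant features
from dominating the ranking. q-values come from group-label permutations:
the null |d| distribution is pooled over permutations, FDR(t) = (expected
null count ≥ t)/(observed count ≥ t), and q is the monotone envelope of
FDR over decreasing |d| (so q never decreases as |d| decreases). Fold
changes are ratios of raw group means; a zero normal mean falls back to a
+1 pseudo-count, the same pseudo-count used by the log2(x+1) display
transform.

Gate defaults: expression FC > 2 or FC < 0.5 with q ≤ 0.01; methylation
FC > 1.5 or FC < 2/3 with q ≤ 0.05. The q cut-offs are exposed in config
because the source convention reports q as a percentage; the defaults read
"1" and "5" as 1% and 5% — the only non-vacuous reading — and users can
override either.

## Networks

**CC network.** Bipartite projection: edge (u, v) iff circRNAs u and v
share at least one differentially expressed miRNA; the weight counts
shared miRNAs. `degree_summary` reports a log–log least-squares slope of
the degree survival function as a descriptive heavy-tail statistic, not a
fitted power-law model.

**DMCC network.** A CC edge survives iff both host genes are
differentially methylated and their gene-level methylation satisfies a
conjunction: sample Pearson r > 0.6 AND one-sided permutation p < 0.05,
where the null shuffles one profile's sample order (1000 permutations,
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)). The conjunction is deliberate:
"greater than random" alone would admit weak but significant correlations,
and "r > 0.6" alone would admit spuriously high small-n correlations.
Pairs with fewer than 3 shared non-missing samples are skipped with a
warning.

**Module mining.** An MCODE-style procedure: each node is weighted by
(highest k-core number of its closed neighborhood) × (density of that
core); seeds are visited in decreasing weight (ties broken by node id for
determinism); a seed greedily absorbs unassigned neighbors with weight
≥ (1 − node_score_cutoff) × seed weight, breadth-first; a haircut
iteratively removes members with fewer than two in-module connections;
modules are scored density × size and each node belongs to at most one
module. Defaults (degree cutoff 2, node score cutoff 0.2, k-core 2,
haircut on, fluff off) are the plugin convention; all are exposed in
config. Modules below 3 members are discarded (a 2-node module cannot
survive the haircut).

## Sponge prediction

For each candidate pair, the 2×2 table is built from the CMD network's
miRNA universe (n = CMD miRNAs): a = shared miRNAs; b = the circRNA's
universe miRNAs not shared with this driver; c = the driver's universe
miRNAs not shared with this circRNA; d = n − a − b − c. This
margin-consistent operationalisation makes the verbal definitions
("shared with other drivers / other circRNAs") sum exactly to the
universe. P₁ is the one-sided upper-tail hypergeometric sum over a′ ≥ a —
Fisher's exact test in its enrichment direction, which is the biologically
meaningful side (a sponge pair should share *more* miRNAs than chance).
The implementation uses the scipy hypergeometric survival function; the
test suite checks it against exact-fraction enumeration of every
margin-fixed table with n ≤ 20 at 1e−10.

P₂ is the two-sided t-test of the sample Pearson correlation (1/(n−1)
normalisation) between circRNA host-gene methylation and driver promoter
methylation, computed on tumor samples only — the sponge hypothesis
concerns regulation within the disease cohort, and normal-sample columns
never enter any pair score. A minimum of 10 shared tumor samples is
required (config) for correlation stability.

Unique target sites are distinct site positions on the driver hit by at
least one shared miRNA; miRNAs with the same seed (positions 2–8, 7-mer —
the standard definition) can occupy the same site, and distinctness is by
position, so same-seed copies collapse automatically. The ≥ 8-site gate
and all p-value thresholds are applied to raw per-pair values — the
procedure is a fixed decision rule, not a multiplicity-corrected scan — but
the audit table includes every statistic so users can apply
Benjamini–Hochberg across pairs if they prefer.

## Survival

The Cox proportional-hazards fit (Efron tie handling, via lifelines) is
joint over all selected host genes, per "multivariate" regression. The
prognostic index is PI = Σᵢ βᵢxᵢ; the printed source formula repeats its
first term, which the symbol definitions identify as a typographical
artifact of the general sum. Patients split at the median PI; ties go to
the low-risk group (deterministic, config-exposed). PI is
affine-equivariant — adding a constant to every sample's covariate shifts
all PI equally and leaves the split unchanged — which the tests verify.
Guard rails: fits require more events than covariates, exact
rank-deficiency raises a collinearity error, and a non-converged model
refuses to score.

## Synthetic-data generator

The generator is the package's study bed: it emulates the *shapes* of a
tumor/normal multi-omics cohort and plants known structure; none of its
magnitudes are estimates from real data (the source study reports none),
so they are package choices, fixed once in `SimulationConfig` defaults:

- **Cohort**: 60 tumor / 30 normal samples — a 2:1 design large enough for
  stable correlations at the permutation test's resolution, small enough
  that the full study runs in seconds.
- **Expression**: log-normal, value = 2^(base + Δ·tumor + 0.5·ε) with
  base ~ U(4, 8); planted differential features use Δ = ±log2(effect_fc),
  alternating up/down, with effect_fc = 4 (comfortably past the 2-fold
  gate without being degenerate). Setting effect_fc = 1 removes the effect
  entirely; the screen then discovers at its nominal false-positive rate.
- **Methylation**: per gene, a latent beta per sample; probes are latent +
  N(0, meth_noise_sd = 0.05), clipped to [0, 1] — adjacent CpGs share one
  pattern with one noise knob. Module host genes add a +0.28 tumor shift
  (fold change ≈ 1.7, past the 1.5 gate) and load 0.15 on a shared
  per-module N(0,1) factor against a 0.05 residual, giving within-module
  latent correlations ≈ 0.9 > 0.6. Planted drivers' promoter latents load
  on their partner module's factor, producing the positive host–promoter
  correlation the prediction step requires. The annotation carries
  deliberately bad probes (a missing value, a two-gene probe, chrX/chrY
  probes, a SNP-flagged probe) to exercise the filter chain.
- **Interactions**: each planted pair shares 10 dedicated miRNAs with
  distinct seeds — hence 10 unique sites, clearing the ≥ 8 gate by
  construction; decoy pairs share the ≤ 3 decoy miRNAs of their driver,
  capping them at 3 unique sites. One site position exists per
  (gene, seed), so same-seed miRNAs co-target one site. Non-planted seeds
  draw from a 20-seed pool to exercise seed collisions. Two planted
  modules of 8 circRNAs each are glued into CC cliques by 3 shared module
  miRNAs; with 4 decoy drivers per module circRNA this yields 64 decoy
  candidate pairs alongside the 5 planted ones.
- **Survival**: exponential baseline (rate 1/1500 per day); per-sample
  hazard ∝ exp(β·x_centered) over the planted sponge hosts' latent
  methylation, β = (1.5, −1.5, 1.0, −1.0, 0.8) — mixed signs so risk is a
  genuinely multivariate function. Censoring is an independent competing
  exponential calibrated so each sample is censored with probability
  censor_rate (0.3); the boundary cases 0 and 1 are handled exactly.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: realistic genome coordinates or probe
densities, probe type I/II chemistry and batch effects, count overdispersion
and library-size variation, miRNA-target prediction noise (interactions are
exact by construction), linkage between probes beyond host-gene grouping,
and copy-number/mutation structure. Recovery results demonstrate the
pipeline's correctness on its stated model, not its sensitivity on real
tumor-cohort data.

## Numerical choices

- Promoter window endpoints inclusive at TSS−1500 and TSS+500, mirrored on
  the − strand; inclusivity must be fixed somewhere for reproducibility
  and the tests pin both boundaries on both strands.
- Permutation p-values use the add-one estimator (1 + exceed)/(n_perm + 1),
  never exactly zero.
- File writes are deterministic (sorted rows, shortest-roundtrip floats);
  matrix reads parse floats with correctly-rounded conversion so
  write∘read is the identity at full precision.
- One global seed per run; per-stage sub-seeds derive from
  `SeedSequence((seed, stage_index))`, so stages are independently
  reproducible.
- Degenerate inputs fail loudly: constant vectors in correlations, groups
  with < 2 samples, empty risk groups, more covariates than events.

## Known limitations

- The SAM-style screen is a re-implementation of the general approach, not
  a numerical clone of the SAMR package; q-values agree in calibration
  (tested) but not digit-for-digit with SAMR.
- Within-module host genes are strongly co-methylated by design, so the
  joint Cox fit's per-gene coefficients are unstable (high variance
  inflation) even when the risk stratification itself is informative; the
  analysis reports the log-rank result, not coefficient interpretations.
- The DMCC correlation is computed over all samples of the supplied
  profile; the shared tumor/normal shift of differentially methylated
  genes contributes common variance, which is part of the co-methylation
  signal as defined, not removed.
- P₁'s b/c/d universes are one margin-consistent reading of the verbal
  definitions; the contingency construction is isolated in
  `contingency_for_pair` so alternative universes are a one-function
  change.
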