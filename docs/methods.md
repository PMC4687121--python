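# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout the package.

## Moderated two-group differential expression

For each probeset *g* with group means compared as MUT − WT (or
later − earlier age), the pooled two-sample variance `s²_g` with residual
degrees of freedom `d_g = n1 + n2 − 2` is shrunk towards a prior:

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t_g   = log2FC_g / sqrt(s̃²_g (1/n1 + 1/n2)),   t_g ~ t(d0 + d_g) under H0.

The hyperparameters assume the gene-wise true variances follow a scaled
inverse-chi-square distribution, `σ²_g ~ d0·s0²/χ²_{d0}`, under which
`z = log s²_g` satisfies

    E[z]   = log s0² + ψ(d_g/2) − log(d_g/2) − ψ(d0/2) + log(d0/2)
    Var[z] = ψ'(d_g/2) + ψ'(d0/2)

(ψ, ψ′ digamma/trigamma). `d0` solves `ψ'(d0/2) = Var(z) − ψ'(d_g/2)` by
monotone bisection on [0.1, 10⁶]; `s0²` follows from the mean of `z`. When
the observed dispersion of `z` does not exceed its pure sampling dispersion
the variances are consistent with a common value: `d0 = ∞` is returned, the
posterior variance is `s0²` for every gene and the reference distribution is
standard normal. (The widely used Bioconductor implementation instead caps
the total df at the pooled residual df in this limit; for finite `d0` the
two formulations agree exactly, which a cross-check test verifies against
limma through Rscript.) With `d0 = 0` the statistic reduces to the ordinary
pooled t.

Degenerate case: `s̃² = 0` yields signed-infinite t and p = 0 with a logged
warning (p = 1 when the fold change is also 0). Multiple testing uses
Benjamini–Hochberg step-up, reported as `q`; "nominal" lists threshold
unadjusted p, "FDR" lists threshold `q`. Ranks order by ascending p with
ties broken by descending |log2FC| then probeset id, so ranked lists are
deterministic. `AbsFC = 2^|log2FC|` (reported to 3 decimals) is the
linear-scale magnitude regardless of direction; contrasts are oriented
MUT − WT / later − earlier so "down in the mutant" is a negative log2FC.

## Genotype-over-time screen and trajectory patterns

The screen is a per-probeset two-way fixed-effects ANOVA with genotype, time
(categorical) and their interaction; the reported p is the
extra-sum-of-squares F test of all genotype-containing terms against the
time-only model. It deliberately replaces a dedicated time-course ANOVA
estimator: the downstream use — extract FDR < 0.05 probesets, then tag their
trajectories — depends only on a genotype-involvement screen, and the
two-way ANOVA is exact for that purpose on this balanced design. Data are
treated as pseudo-longitudinal (different animals per age); no
repeated-measures correlation is modelled.

Trajectory tagging correlates each significant probeset's per-time means
(per genotype) with the standardized monotone template over the ordered time
index, calling `up`/`down` by the sign of the winning correlation and `NC`
when the amplitude (max − min of per-time means) is below `min_amp` or
|r| < `r_min`. Defaults `r_min = 0.8`, `min_amp = 0.1` log2: with three
time points |r| ≥ 0.8 excludes strongly non-monotone shapes, and 0.1 log2
(~7 % linear) is below the smallest fold change the analysis would ever
report as meaningful. Constant profiles (undefined correlation) are `NC`;
an exact |r| tie is `NC` (conservative). Raw per-time means are used rather
than model coefficients. Time enters the generator and the templates as the
ordered index (0, 1, 2), not months, because the templates are rank-based.

The 3×3 pattern table counts genes by (WT pattern, MUT pattern); each cell
also tallies the direction (sign of the mean MUT − WT difference across
times). A gene with several probesets is placed in the cell of its
smallest-p probeset; when its probesets disagree on the pattern pair or
direction it still counts in that cell but is excluded from the
direction tallies ("mixed pattern").

## Cross-dataset concordance

Probeset-level results collapse to unique gene ids keeping the entry with
the smallest p (tie: larger |log2FC|, then probeset id) — the collapse rule
for multi-probeset genes is not standardized in the field, so best-p was
chosen and applied uniformly. Genes map to homolog groups; genes of one
species sharing a group are collapsed best-p again *before* cross-mapping,
mirroring the unique-gene-id-then-homolog conversion order. Unmapped genes
are counted and excluded, and lists re-rank by significance.

Top-N overlap is tested by the upper-tail hypergeometric. The universe is an
explicit, reported policy because it is the dominant unstated degree of
freedom in published versions of this comparison: default "intersection"
(homolog groups present in both collapsed lists), alternatives "union" and
fixed N. The permutation alternative resamples the top-A set uniformly from
the universe, `p = (1 + #{overlap ≥ k}) / (reps + 1)`, floored at
1/(reps+1); default 10⁴ replicates matches the smallest p one would quote
as `< 10⁻⁴`.

The concordance profile partitions list B into consecutive rank bins
(default 1000 genes; top-list size K default 200, both per the published
usage of each). Each of A's top-K genes found in B increments its bin's
concordant or discordant count by sign agreement; frequencies are counts/K
and sum with the unmapped fraction to 1 (asserted at 10⁻¹² on every
construction).

## Conditional over-representation

Gene sets live on a DAG with the true-path rule: a gene annotated to a term
belongs to all its ancestors (propagation computed once on load; cycles are
a hard error). Terms are tested children-before-parents with the upper-tail
hypergeometric against a fixed universe; when a term's unadjusted p falls
below the conditioning threshold (default 0.05) its propagated genes are
removed from every ancestor before the ancestor is tested — a single
bottom-up pass, matching the convention of the standard conditional
implementation. Reported Count (significant genes in the term) and Global
(term size) reflect the post-conditioning sets; Count is genes (not
probesets) after collapse. BH across terms is reported as "FDR p".

A discreteness caveat: with small terms/universes the hypergeometric null
cannot attain a size near the nominal 0.05 (the achievable size may be
~0.03), so type-I calibration checks use term sizes large enough
(universe 1000, terms of 100, 200 significant genes) that the attainable
size is ~0.047.

"Genetic similarity" between terms is the Jaccard index of their gene sets
(overlap coefficient available by flag). Term clustering is average-linkage
on 1 − similarity, cut at the coarsest level at which every cluster's mean
pairwise similarity meets the threshold (0.9 and 0.5 are the conventional
display levels); the representative is the cluster's smallest-p term (tie:
largest gene set). Node/edge tables are emitted for external rendering;
edge weights equal the recomputed similarity.

## Genotype × model interaction

Each gene shared between the two studies (matched through homolog groups;
one representative probeset per gene, chosen by smallest plain genotype-t p)
is fitted by least squares on genotype + model + genotype:model with all
ages pooled — pooled because the divergent-gene report is a single
per-model fold-change pair (a per-time variant exists but is off by
default). The interaction F has 1 numerator df, so it equals the squared
coefficient t-test. Each study is median-centred per probeset before the
joint fit; this is cosmetic (any constant offset is absorbed by the model
main effect) but makes the shared-intercept report readable. The divergent
table keeps interaction p below threshold AND |FC_A − FC_B| strictly above
0.20, sorted by descending difference.

## Synthetic-data generator

The generator emulates the paired design: two studies on disjoint probeset
namespaces, 2 genotypes × 3 ages × `replicates_per_cell`, linked by an
ortholog map covering `mappable_fraction` of genes. Expression follows the
same linear model the analysis assumes,

    y = μ_g + β_g·I[MUT] + γ_g·t + δ_g·I[MUT]·t + ε,   ε ~ N(0, σ²_g),

with centred time index t (so the pooled MUT − WT contrast equals β_g),
probe-level baseline offsets ~ N(0, 0.5) for multi-probeset genes, and
σ²_g ~ d0·s0²/χ²_{d0} so the moderation assumptions hold by construction.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_genes` | 5000 | desk-scale version of a ~20k-probeset array |
| `replicates_per_cell` | 5 | matches the ~15 animals/genotype across 3 ages |
| `times` | (6, 12, 18) | the study's ages in months |
| `baseline_mean` | 7.0 log2 | typical post-normalisation array intensity |
| `genotype_effect_size` | N(0.5, 0.15) magnitudes, clipped ≥ 0.05 | published per-gene log2FCs span ~0.1–1.2 |
| `de_fraction` | 0.05 | sparse dysregulation |
| `shared_fraction` / `discordant_fraction` | 0.6 / 0.1 | strongly but not perfectly shared signature |
| `trajectory_mix` | up 0.2 / flat 0.6 / down 0.2 | most genes age-stable |
| `trajectory_slope` | 0.3 log2/step | visible but noise-comparable ageing trend |
| `variance_prior` | d0 = 4, s0² = 0.05 | heavy-tailed gene variances, residual sd ~0.2 |
| `mappable_fraction` | 0.85 | typical cross-platform ortholog coverage |

Shared-signature genes reuse one effect magnitude in both models so the
planted signature is concordant in size as well as sign. The mutant
trajectory equals the wild-type trajectory for non-DE genes and is redrawn
only for DE genes: leaving the two fully independent would give roughly a
third of *all* genes a genotype×time interaction, far denser than the
sparse screens such studies report. All randomness flows from one seed
through named substreams (one per study/component), so adding a generator
does not perturb the draws of another; identical seeds give bit-identical
outputs.

What the generator does **not** emulate: probe-level (pre-normalisation)
effects, batch and sex covariates, correlated gene modules, platform-
specific intensity distributions, or annotation errors in the ortholog map.
Passing tests on this generator therefore demonstrate the statistics are
correct and calibrated under the stated model, not that real-data artefacts
are handled.

## Numerical conventions and problem sizes

TSV everywhere (UTF-8, '.' decimal); statistics serialized to 6 significant
digits, fold-change columns to 3 decimals. Missing expression values are a
hard load error (post-normalisation matrices are complete; silent imputation
would corrupt variance moderation). Multi-mapping probesets are dropped on
load with a logged count. Ranked-list ties and topological-order ties break
by id, so every output is deterministic given its input.

The validation suite and the acceptance script use scaled-down problem
sizes chosen as desk-scale defaults: null calibrations at 5000 genes (per
gene tests) or 400 simulation seeds (overlap test, 800 genes each), prior-df
recovery at 10⁴ genes, dose-response at 20 seeds per shared-fraction level.
Planted-recovery simulations use a per-step slope difference of 1 log2 unit
at residual sd ~0.2 — the signal/noise regime in which a time-course screen
of this design is expected to operate at high power.

## Known limitations

* The hyperprior estimator assumes a common residual df across genes per
  contrast (true for complete two-group designs; unbalanced missingness is
  rejected at load time anyway).
* The conditional enrichment pass is single-sweep bottom-up; it does not
  iterate after parents change status.
* The permutation overlap test permutes only list A's top set; it conditions
  on list B exactly like the hypergeometric null.
* Per-timepoint genotype contrasts estimate variance within that age only;
  pooling variance across ages would gain df at the cost of assuming
  age-constant dispersion (flagged for sensitivity analysis, not default).
* The interaction test is fixed-effects only; no random-effects or
  batch-aware meta-analysis across models.
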