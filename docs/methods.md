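# Methods

## Data model and conventions

All statistics operate on a samples × loci matrix of **counted-allele
dosages** in {0, 1, 2}, with NaN for missing genotypes. The counted allele
of a locus defaults to the first allele observed in file order (PED) or to
REF (VCF); an explicit locus → allele mapping can override it, and every
output header records the convention. All frequency-based statistics here
are invariant to which allele is counted, so the convention matters only
for interchange of frequency tables and panels between sources. Positions
are 1-based; half-missing PED genotypes (one "0" allele) are treated as
fully missing, a conservative choice matching common practice. Group
allele frequencies pool the individuals of a group; a group with zero
non-missing calls at a locus gets an *undefined* (NaN) frequency, never 0,
and loci with any undefined group frequency are excluded from marker
scoring rather than imputed. Samples carry a population label nested in a
continental region; the default region set is the seven continental
regions (Africa, Middle East, Europe, CS Asia, E Asia, Americas, Oceania)
with an optional eighth, Siberia, for northern-Asian populations that fit
none of the seven clusters.

## Marker informativeness

`informativeness` implements the entropy-based informativeness for
assignment of a biallelic locus across K groups, in natural-log units
(divide by ln b to convert to base b). Groups enter unweighted: regional
sample sizes do not weight the mean frequency, so a small reference region
counts as much as a large one. Iₙ is 0 iff all group frequencies are
equal, is bounded by ln K, and is symmetric in the two alleles. δ for a
pair of groups is the absolute counted-allele frequency difference, equal
to half the L1 distance over both alleles. Multiallelic markers are out of
scope.

## Panel selection

The pipeline runs filter → score → cap → prune → claim → reduce, with all
ties broken by (score, locus_id) so reruns are bit-identical.

- **Candidate filter.** Autosomes 1–22 only; allele pairs restricted to
  the strand-unambiguous set {A/C, A/G, T/C, T/G} (A/T and C/G are
  excluded because the strand cannot be resolved from frequency data
  alone); optionally require presence on the genotyping array.
- **Informativeness cap.** The `top_n_by_in` (default 5000) most
  informative loci are kept, ranked by Iₙ with lexicographic tie-break.
- **LD pruning.** Sliding windows of `window_size` SNPs (default 50)
  advancing by `window_step` (default 5), never spanning chromosomes.
  Within a window, the locus with the highest VIF = 1/(1 − R²) is removed
  (ties: the later locus in map order) until all VIFs are at or below
  `vif_threshold` (default 1.5, i.e. R² < 1/3 against its neighbours).
  Only the threshold itself is method-critical; window 50/step 5 are the
  conventional defaults of windowed pruning and are config-exposed.
  Missing dosages are mean-imputed for the regressions only. VIFs come
  from the diagonal of the inverse correlation matrix, with a
  pseudoinverse regression fallback for near-singular windows so a
  perfectly predictable locus reports VIF = ∞. The sliding pass repeats to
  a fixed point, which guarantees the postcondition that *every* window of
  the retained loci satisfies the threshold — a property a single pass
  cannot give, because removals in later windows shift earlier ones.
- **Per-pair claiming.** Group pairs are processed in ascending
  min-group-index order; each pair walks its δ-descending ranking and
  claims the top `per_pair` (default 10) markers not already claimed, so
  with seven regions and abundant markers the union holds exactly
  10 × 21 = 210 distinct loci, each with the claiming pair recorded as
  provenance. An alternative reading — letting a marker count for several
  pairs — would yield a smaller union; disjoint claiming was chosen
  because it makes the pool size predictable and every pair's quota
  explicit.
- **Reduction.** Real multiplex panels are trimmed under assay-chemistry
  constraints that cannot be modelled generically. The surrogate objective
  used here preserves the design intent: maximise, over the retained set,
  the minimum across group pairs of the sum of that pair's three best δ
  values, so no pair is left without several strong markers. Explicitly
  infeasible loci are removed first via the exclusion list. Small
  instances (subset count ≤ 20 000, which covers every panel of ≤ 8 loci)
  are solved exactly by enumeration, taking the lexicographically first
  optimum; larger panels use greedy backward elimination (remove the locus
  whose deletion leaves the highest objective; ties: lower Iₙ, then id).
  The greedy path is a heuristic and can be slightly suboptimal, which is
  why the exact path exists and is what the small-panel tests compare
  against.

## Differentiation statistics

Pairwise F_ST uses the Weir–Cockerham (1984) θ for two groups of diploid
individuals: per locus, variance components a (among groups), b (among
individuals within groups) and c (within individuals, from observed
heterozygosity) are combined across loci as Σa / Σ(a+b+c) (ratio of sums).
Loci where the pooled pair is monomorphic or a group has no calls are
dropped from the sums. Negative estimates — legitimate draws of an
unbiased estimator near zero — are reported as computed, with an optional
floor at zero. Spreadsheet-style AMOVA formulations used by some software
differ in the third decimal; expect small numerical differences when
comparing published tables (±0.01 is a realistic tolerance).

Permutation significance shuffles individuals between the two groups,
keeping sizes fixed, with p = (1 + #{θ* ≥ θ}) / (n_perm + 1), so p is
never exactly 0 and equals 1/(n_perm+1) when the observed split is
unmatched. The Mantel statistic is the Pearson correlation of the strict
lower triangles of two distance matrices; its p-value jointly permutes the
rows and columns of the second matrix and is two-sided on |r|.

## Admixture model and estimation

Individual i's two allele copies at locus l each draw an ancestral cluster
from qᵢ (the admixture vector) and then the counted allele with that
cluster's frequency p_lk. With loci treated as independent — appropriate
for an LD-pruned panel, and the reason no LD is simulated either — the
per-individual log-likelihood is

    ℓ(q) = Σ_l [ g_l ln Σ_k q_k p_lk + (2 − g_l) ln Σ_k q_k (1 − p_lk) ]

over non-missing loci (a sample's missing loci are simply dropped, so
panels with a failed assay remain usable). This is a deterministic
maximum-likelihood replacement for Bayesian MCMC clustering: the estimated
Q matrix is the same quantity, without posterior uncertainty, and exact
reproduction of MCMC-based numbers is a non-goal.

*Supervised* mode fixes p from labelled reference individuals — maximum a
posteriori with pseudocount 0.5 (Jeffreys-like), clamped to
[ε, 1−ε], ε = 10⁻⁶, so no locus can contribute an infinite penalty — and
runs per-sample EM from the uniform simplex point until the log-likelihood
change falls below 10⁻⁷ (max 2000 iterations). Every EM step provably does
not decrease ℓ, and the tests assert this along trajectories.

*Unsupervised* mode alternates the q-sweep with the closed-form frequency
update from allele-origin responsibilities, from Dirichlet(1,…,1) random
starts (default 10 restarts, relative tolerance 10⁻⁶, max 500 iterations),
returning the restart with the best final likelihood. Cluster labels are
arbitrary across runs; `align_replicates` resolves label switching by
exhaustive search over the K! column permutations (K ≤ 10) maximising the
summed inner product with the first run.

Membership-threshold assignment places a sample in a cluster only when its
membership strictly exceeds the cutoff (>0.85 or >0.5 by convention;
strict inequality chosen so a 50/50 sample is unassigned at 0.5). The
0.85-assigned set is always a subset of the 0.5-assigned set.

## PCA and MDS

PCA normalises each locus by the drift-scaled convention standard in
population-structure analysis: centre by 2p̂ and divide by √(p̂(1−p̂)),
where p̂ = (1 + counted-allele count)/(2 + 2n) is the posterior allele
frequency; missing entries become 0 after centring (the locus mean);
monomorphic loci are dropped. Scores come from the SVD; each component is
oriented so its largest-magnitude loading is positive, making output signs
deterministic. Eigenvalues are of the sample covariance (ddof 1) and
proportions are relative to the total across all components.

IBS similarity of two samples is the fraction of allele copies shared over
mutually non-missing loci, s = Σ(2 − |gᵢ − gⱼ|)/(2L); distance is 1 − s.
Classical (Torgerson) MDS double-centres −½·J·D²·J and embeds the top
non-negative eigenpairs; negative eigenvalues (non-Euclidean inputs) are
dropped with a warning.

## Synthetic data

The generator draws, per locus, an ancestral frequency uniform on
(0.1, 0.9) and then each region's frequency from the Balding–Nichols Beta
distribution at that region's divergence F, so the expected fixation index
of a region against the ancestor is F. Genotypes follow the admixture
model generatively; missingness is i.i.d. Bernoulli. Everything is
reproducible bit-for-bit from one seed.

The packaged default scenario uses seven regions at
F = (0.15, 0.03, 0.03, 0.05, 0.10, 0.20, 0.18) — ordered as Africa,
Middle East, Europe, CS Asia, E Asia, Americas, Oceania — with 50 samples
per region, 1% missingness, and two admixed cohorts (Africa–Europe and
Americas–Europe gradients, ancestry fractions 0.05–0.95 in 19 steps).
These divergences qualitatively echo the empirical ordering of continental
F_ST (Eurasian pairs smallest; Africa, the Americas and Oceania most
distinct); they are illustrative, not fitted to any dataset. Because the
Eurasian regions are deliberately close (F = 0.03), a 41-SNP panel
assigns only ~60% of reference individuals at the strict >85% membership
cutoff while ~95% are correct at >50% — reproducing the known behaviour of
compact panels, which separate Eurasian regions weakly. The simulator has
no LD, no demographic history, no genotyping-error model and one
population per region, so passing tests demonstrate estimator correctness
under the stated model, not robustness to real-data artefacts such as
linked markers, clinal structure within regions, or batch effects.

## Numerical and scale choices

- 0·ln 0 := 0 throughout; Iₙ values within 10⁻¹⁵ of 0 are snapped to 0.
- Permutation p-values use the add-one rule and are never 0.
- The test suite and the acceptance script run simulations at a few
  hundred to a few thousand loci and tens of samples per group — sizes at
  which every estimator's sampling error is far smaller than the effects
  asserted, while a full run stays in the tens of seconds.
- Low-admixture insensitivity: at 41 panel-scale loci, an ancestry
  fraction of 0.1 carries roughly 3–4× the relative estimation error of a
  balanced 0.5 mixture. This is asserted as a property (a ratio > 1), not
  as a fixed number, since its magnitude varies with δ and seed.

## Known limitations

- No haplotype or LD-aware likelihoods; panels must be pruned for the
  independence assumption to be reasonable.
- Unsupervised EM finds local optima; restarts mitigate but do not
  guarantee the global maximum.
- No Bayesian uncertainty on Q, no local-ancestry inference, no
  hierarchical AMOVA F-statistics, no Tracy–Widom testing of PCs, no
  projection of new samples onto fixed PCA loadings.
- The reduction objective is a surrogate for assay-chemistry constraints;
  encode real constraints through the exclusion list.
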