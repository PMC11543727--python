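# Methods

`bsrqtl` dissects a *sporadic* (incompletely penetrant) quantitative trait in
a biparental recombinant-inbred-line (RIL) population by combining two
independent mapping arms — a genome-wide linkage (LOD) scan and a
bulked-segregant ΔSNP-index scan — and intersecting their significant
regions to nominate candidate genes. The emulated design is an interspecific
soybean population (cultivar C08 × wild accession W05, ~407 F7:8 lines,
~6400 bin markers) whose multifoliolate-leaf trait is expressed sporadically
per seedling and scored as affected-seedling counts over three replicate
seasons (5, 10 and 20 seedlings per line).

## Synthetic data model

The generator is first-class, tested code: it defines the study conditions
under which every calibration and recovery claim is made.

**Genotypes.** Each line is a two-state Markov chain along each chromosome.
The switch probability between adjacent markers is the selfing-RIL effective
recombination R\* = 2r/(1+2r), with r from Haldane's map function
r = (1 − e^(−d/50))/2 on the cM gap d. This closed form (the fixation limit
of repeated selfing) replaces simulating seven explicit generations; residual
heterozygosity is injected as an independent per-call rate (default 0.01,
about the F7 expectation) rather than tracked mechanistically. Codes:
0 = C08 homozygote, 2 = W05 homozygote, 1 = residual heterozygote.

**Phenotypes.** No penetrance model is available for a sporadic per-seedling
trait, so the package adopts a logistic liability model and flags it as a
stand-in: for line i in replicate j,

    eta_ij = mu + sum_k a_k (x_ik − 1) + rep_j + gamma_ij + eps_ij,
    count_ij ~ Binomial(n_seedlings_j, logistic(eta_ij)),

with gamma ~ N(0, sigma_ge²) (line-by-season interaction) and
eps ~ N(0, sigma_eps²). Defaults: mu = logit(0.2) (a baseline where roughly
one seedling in five is affected, matching a trait that is common but far
from fixed), sigma_ge = sigma_eps = 0.5, replicate shifts ±0.25, and several
planted QTLs of unequal effect (1.2 down to 0.3 liability units). These
choices reproduce the qualitative signatures of the emulated study —
population CV above 50%, replicate correlations around 0.6, broad-sense
heritability in the 0.6–0.85 range — without being fit to any reported
number. What passing tests on this generator do **not** show: robustness to
epistasis, to segregation distortion (wide crosses often show it), to
shared-environment correlation between seedlings of one cup, or to
genotyping error; none of these are modelled.

**Bulks and reads.** Bulks are the k = 30 highest- and lowest-frequency
lines by pooled affected frequency; ties break by line identifier (lines are
ordered by descending frequency then id, MUL takes the first k and TRI the
last k, which keeps the bulks disjoint for k ≤ n/2 and makes them a
partition at k = n/2). Pooled reads per SNP and bulk: the true alt (W05)
frequency is the mean genotype code / 2 over member lines; total depth is
Poisson (default mean 30) and alt reads Binomial with a symmetric error rate
(default 0.001). The map's marker density doubles as the SNP density of the
pooled data, so BSA simulations need a map with ≥ ~10 markers per Mb for the
windowing stage to retain windows.

## Phenotype statistics

The trial model is y_ijk = mu + env_j + g_i + (ge)_ij + eps_ijk with lines
and the interaction random. Components come from the expected-mean-squares
equations of the balanced layout (negative solutions truncated at zero);
broad-sense heritability on an entry-mean basis is

    H² = V_g / (V_g + V_ge/L + V_eps/(R·L)).

With one observation per line × season (R = 1) the interaction and residual
are confounded; V_ge is then reported as 0 with a warning and its mass sits
in V_eps. H² is unaffected because V_ge/L + V_eps/L enters as a sum — the
recovery experiment exercises exactly this. Unbalanced tables (a line
missing from one season) are handled by estimating on the balanced core,
documented as an approximation rather than full REML. The response defaults
to the affected frequency so seasons with 5/10/20 seedlings are comparable;
raw counts are available by flag. BLUPs are the balanced-case shrinkage
mu + s·(ȳ_i − ȳ) with s = V_g/(V_g + V_ge/L + V_eps/(RL)) — rank-preserving,
exact for the balanced model, and the default mapping phenotype.

## Linkage arm

The scan is single-marker regression of the phenotype on genotype code with
LOD = (n/2)·log10(RSS0/RSS1). This is an engine substitution for interval
mapping, documented rather than asserted as equivalent: with ~6400 bin
markers the between-marker gaps are small and imputation adds little. An
exact fit (RSS1 = 0) would give an infinite LOD and is replaced by a
configurable ceiling (default 50); monomorphic markers report LOD 0 with a
flag. Genome-wide significance is the classical permutation approach: the
phenotype vector is shuffled (preserving genotype correlation), and the
(1 − alpha) quantile of the max-LOD distribution over 1000 permutations is
the threshold.

QTL calling extracts peaks greedily per chromosome (leftmost marker of a
plateau wins ties). The support interval spans the contiguous markers with
LOD ≥ peak − 1.5; a second above-threshold marker whose connecting valley
stays within 1.5 of its own LOD is merged into the same QTL. Physical bounds
are rounded outward by one flanking marker. PVE = 100·(1 − 10^(−2·LOD/n)),
which equals the regression R² identically; the additive effect is
(mean of code-0 lines − mean of code-2 lines)/2, so a trait raised by the
wild-parent allele reports a *negative* effect. Replicate-consistent
confidence regions are reduced to the common region (max of starts, min of
ends); disjoint replicate intervals are an error left to the caller.

## Bulked-segregant arm

Per SNP and bulk, index = alt/(alt+ref). Filters follow the QTL-seq
convention for this design: drop SNPs with total depth < 3 in either bulk,
and SNPs with index < 0.3 in *both* bulks. ΔSNP index = index(TRI) −
index(MUL); with MUL enriched for the trait-raising W05 (alt) allele, a true
locus drives Δ negative. Windows of 1 Mbp advance by 10 kbp on a grid
anchored at position 1 of each chromosome; windows holding fewer than 10
SNPs are skipped. Window means are computed directly over member SNPs (not
by prefix-sum differencing) so they agree exactly with a naive oracle.

**Null model for the cutoff.** The 99% cutoff comes from a simulated null
of *unselected* bulks, recomputing the window means in each of the
iterations (100,000 in the publication profile; 2000 in the test profile,
which widens only the Monte-Carlo error of the cutoff estimate). The default
null resamples both layers of noise: bulk composition — each bulk as
``bulk_size`` member haplotypes drawn as linked Markov chains over the
observed SNP positions, using a cM/Mb scale to convert physical gaps to map
distance — and reads, binomially at the observed depths. Composition noise
matters: with 30-line bulks each bulk's allele frequency drifts around 0.5
with sd ≈ 0.09, and linkage makes that drift nearly constant across a 1-Mb
window, so it dominates the window-mean null (sd ≈ 0.13) and does not
average out with SNP count. A null that resamples reads alone
(alt ~ Binomial(depth, 0.5) per SNP independently, available as
``null_model="binomial"``) yields a cutoff several-fold too small (≈ 0.05 vs
≈ 0.3 under the default design) and flags most of a signal-free genome.
Cutoffs are genome-wide and two-sided on |window mean| — loci are reported
in both directions. The composition-aware null needs two inputs the count
table cannot supply (bulk size and a cM/Mb scale); defaults are 30 lines and
5 cM/Mb, and callers with a map should pass the map-derived scale.

Significant-region calling merges retained windows beyond a cutoff whenever
their intervals overlap or abut, separately per direction and chromosome;
the region interval is the union of member windows. Per-iteration
re-application of the SNP-index filter inside the null is skipped (under
f ≈ 0.5 the both-below-0.3 rule fires negligibly often).

## Integration

Linkage and BSA regions intersect pairwise ([max starts, min ends], 1-based
inclusive). Gene membership defaults to any-overlap (≥1 bp; full containment
behind a flag). Variant positions classify strand-aware as genic / upstream
(1 kb beyond the TSS) / downstream (1 kb beyond the TTS) / intergenic, with
no priority collapsing when a position sits near two genes. The expression
filter is strict: FPKM > 1 in every named bulk sample; genes absent from the
matrix are flagged unexpressed with a warning. Reports are sorted by
(chromosome, start, gene id) so identical inputs give byte-identical files.

## Numerical and design notes

* Coordinates are 1-based inclusive internally (published table positions
  map verbatim); BED output converts to 0-based half-open.
* Multiallelic VCF records and indels are dropped, not decomposed — the
  ΔSNP index is defined for two alleles.
* One published QTL interval carries a printed width (0.85 Mb) inconsistent
  with its own printed bounds (0.80 Mb); the coordinate table keeps both and
  width checks treat the printed number there as suspect.
* All stages draw randomness from `numpy.random.default_rng`; experiment
  drivers derive independent child seeds from one master seed via
  `SeedSequence.spawn`, so every result is reproducible from a single
  integer.
* Experiment problem sizes (genomes of 2000–2510 SNPs, 400-line
  populations, 2000-iteration cutoffs, 10–20 seeds) are desk-scale choices
  that keep each study in the seconds-to-minutes range while leaving the
  binomial/Monte-Carlo error small relative to the margins being tested.

## Known limitations

* The liability-logistic penetrance model is a stand-in; the within-line
  variance structure of a real sporadic trait is unknown.
* Marker regression does not interpolate between markers and will misplace
  peaks on sparse maps; use dense maps or accept wider support intervals.
* The unbalanced variance-component fallback (balanced core) discards
  information from incompletely scored lines.
* The composition-aware BSA null assumes unrelated, equally weighted bulk
  members and a uniform cM/Mb scale per chromosome; selection, relatedness
  or recombination-rate variation would mis-calibrate it.
* DEG calling, GO/KEGG enrichment and variant-effect (synonymous vs
  nonsynonymous) annotation are outside the package's scope.
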