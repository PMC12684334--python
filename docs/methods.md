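# Methods

This note documents the models and estimators implemented in
`clonescape`, the defaults and why they were chosen, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Data model

Genotypes are biallelic SNP dosages (0/1/2 copies of the ALT allele,
diploid) in an individuals × loci matrix with a missing-data sentinel;
each individual carries a sampling-site label.  All per-site statistics
are computed within sites.  Filtering removes loci and then individuals
with missingness strictly above 5 % (the conventional cutoff for
reduced-representation SNP panels), then monomorphic loci, iterating to
a fixed point so the filter is idempotent; the order is a package
choice made for determinism.  A per-individual heterozygosity vs
missingness table (with k·MAD outlier flagging, default k = 3) screens
for genotyping artefacts before any diversity statistic is trusted.

## Clone detection

The pairwise distance between individuals is the proportion of allelic
differences: Σ_l |g_a,l − g_b,l| / (2 L_ab) over loci called in both,
so Aa↔AA counts one allelic difference and AA↔aa two.  In a partially
clonal sample this distance distribution is multi-modal: ramet pairs of
one genet differ only through genotyping error and pile up near zero.
The automatic cutoff looks at single-linkage merge heights, restricts
attention to gaps whose lower endpoint lies below `fraction` (default
0.5) of the largest height, and returns the midpoint of the largest
such gap (ties resolved towards the lowest gap).  Contraction then
takes connected components of the graph with edges d ≤ cutoff
(single linkage); each genet is represented by its lowest-missingness
member.  When all genotypes are identical the distribution carries no
gap and the predictor falls back to exact-match contraction
(threshold 0) — without this a monoclonal site would be unanalysable.
Clonal richness is R = (G − 1)/(N − 1).

## Diversity and linkage statistics

Per locus, H_e = 2p(1−p) from the within-site allele frequency and
H_o is the heterozygote fraction; the multilocus inbreeding
coefficient pools loci, F_IS = 1 − ΣH_o/ΣH_e, after excluding
within-site monomorphic loci.  No small-sample correction is applied
by default so that a site consisting of one heterozygous clone yields
exactly −1 (the fixed-heterozygote signature); the 2n/(2n−1)
correction is available as a flag.

The index of association works on per-pair, per-locus dosage distances
d_l = |g_a,l − g_b,l|.  With D = Σ_l d_l, V_O the variance of D over
all pairs and V_E = Σ_l Var(d_l) (population variances throughout):
I_A = V_O/V_E − 1 and r̄_d = (V_O − V_E) / (2 Σ_{l<m} √(V_l V_m)).
The permutation null shuffles each locus column independently across
individuals — destroying inter-locus association while preserving
locus-wise genotype frequencies — with the add-one rule
p = (1 + #{r̄_d⋆ ≥ r̄_d}) / (n_perm + 1); 999 permutations by default.
Missing cells are mean-imputed per locus before the pair distances;
with the 5 % missingness filter upstream this touches few cells.
Ramets are deliberately retained in these statistics: the clone signal
is what they measure.  Note that a *literally monoclonal* site carries
no r̄_d signal at all — its only polymorphism is independent
genotyping error — whereas a fully clonal site with a few coexisting
clones shows the strong LD elevation expected in the field.

## Individual-level structure

PCA mean-imputes missing cells per locus, centres columns, optionally
scales by √(p(1−p)), and orients every component so its
largest-magnitude loading is positive.  Structure analyses are meant
to run on genet-level data (one individual per MLG) to avoid clonal
pseudo-replication; `one_per_genet` performs the reduction.

Ancestry proportions come from a least-squares decomposition of the
one-hot genotype encoding, X ≈ Q F, with Q rows on the K-simplex and F
a 3-genotype simplex per locus and cluster.  Optimisation alternates
projected-gradient steps with monotone backtracking (the objective
never increases, a property the tests assert), from Dirichlet(1)
starts, best of `reps` runs; convergence at relative objective change
< 1e−6 or 500 iterations.  K is chosen by cross-entropy on a 5 %
holdout of masked genotype cells — the fitted genotype probabilities
must predict cells never seen in training.

Neighbour joining runs on the allelic-difference distance matrix
(scikit-bio's implementation behind the module surface); negative
branch lengths are clamped to zero and counted.  Split support is the
proportion of locus-bootstrap replicates (loci resampled with
replacement, distances and NJ recomputed) containing the split.
Near-zero terminal branches are the visual signature of clones.

## Demographic inference

Two-population histories are compared on the joint site frequency
spectrum.  The model space is the canonical 22-scenario set: SI, IM,
AM and SC base histories, each with exponential growth (G, possibly
asymmetric), a two-class effective-size mixture standing in for linked
selection (2N: proportion Q of loci at size factor hrf), and — for
histories with gene flow — a two-class migration mixture standing in
for barrier loci (2m: proportion P of loci at migration factor
me_frac).

Expected spectra come from a structured-coalescent Monte-Carlo engine
(numba-jitted): piecewise-constant deme sizes and backward migration
rates up to the split, a single ancestral deme beyond it; exponential
growth is discretised into 8 piecewise-constant sub-epochs.  The
engine accumulates expected branch lengths by descendant configuration
(rather than dropping mutations), which removes one layer of Monte
Carlo noise; multiplying by θ/2 gives the expected spectrum.  The
engine is validated against msprime and against the θ/i law of the
neutral frequency spectrum.

Fitting maximises a composite Poisson likelihood over jSFS cells
(folded when the observation is folded; the fixed corner cells are
masked), with the spectrum scale θ̂ = Σobs/Σmodel profiled out
analytically.  Because θ̂ absorbs the overall scale, jointly rescaling
all sizes and times (and inversely the migration rates) is an exact
likelihood ridge; the ancestral size is therefore anchored at na = 1
by default — sizes and times are relative to the ancestral
population — and excluded from the free-parameter count.  The count k
includes θ̂, and AIC = 2k − 2 log L; models are ranked by AIC and a
fit is flagged "stronger" only when it beats every competitor by more
than 10 AIC units.

Monte-Carlo expectations enter the likelihood through log ê, which by
Jensen's inequality penalises parameter regions with noisier
estimates (typically migration-rich histories).  The engine therefore
runs in eight fixed-seed batches and the first-order bias
obs·Var(ê)/(2ê²) is added back from the batch variance.  Fixed engine
seeds give common random numbers across parameter evaluations, so the
optimiser sees a smooth surface.

The three-step optimisation per replicate fit: (1) a broad
population-based random search over log-uniform parameter bounds
(differential evolution, Sobol initialisation), (2) Nelder–Mead
refinement, (3) a perturbation restart; the best point over
`n_fits` replicates (default 20) is polished with 5× more genealogies
per evaluation.  Bounds span roughly ±2 orders of magnitude around
neutral expectations (sizes 0.05–20, times 0.05–10, migration
0.1–20 per lineage per 2N_ref generations; mixture proportions
0.05–0.95; the 2m reduction factor 10⁻³–0.2).

Scaled parameters convert to biological units through
N_ref = θ̂/(4μL): sizes in individuals, times in years via a
generation time (default 4 y, appropriate for long-lived fucoid
seaweeds) and per-generation migration rates m = M/(2N_ref).  The
per-bp mutation rate (default 10⁻⁸) and effective sequence length L
are user inputs; the conversion round-trips exactly.

Folding is keyed on the pooled minor-allele count; complementary cell
pairs at exactly half the pooled count are averaged (the average
stored in both cells), which preserves totals and makes folding
idempotent.

## Connectivity

A per-generation dispersal matrix (row-stochastic over habitat sites,
columns = destination) is propagated g generations (default 32) of
stepping-stone dispersal, either as the g-step transition matrix P^g
(default; rows renormalised each step against floating-point drift) or
as the cumulative mean of P¹…P^g — the accumulation rule of
multi-generation connectivity is not uniquely defined, so both
readings are offered and labelled.  The asymmetry summary totals
probability mass out of versus into a site partition (e.g. a marginal
sea).  Heatmap export uses the source-in-columns convention.  The
synthetic dispersal generator is a reflected discretised Gaussian on a
1-D coastline: mean displacement = advection, spread = diffusion;
reflection keeps the unmasked kernel symmetric at zero advection.

## Morphometrics

The undulation index is the margin arc length over the endpoint chord
of a traced branch polyline (1 = flat margin; π/2 for a semicircular
margin), invariant to rigid motions and scaling; individual values
average three branches, mirroring field protocols.  Trait PCA
z-scores traits first.  Site dendrograms use average-linkage
clustering of Euclidean distances on z-scored site trait means
(linkage and distance are configurable; neither is canonical), and
congruence with the genetic-distance dendrogram is reported as the
cophenetic correlation plus the Robinson–Foulds distance — an
operationalisation of "do field morphotypes recover the genetic
structure?".

## Synthetic data: what it shows and what it does not

Generators are pure functions of their seed.  Clonal sites draw genet
base allele frequencies Uniform(0.05, 0.95) so within-site
polymorphism is near-certain (F_IS and r̄_d need polymorphic loci);
genotyping error is an independent per-allele flip, giving replicate
discordance a closed form used as a test oracle; missingness is
completely at random (an optional per-individual multiplier can bias
it).  Metapopulations follow the Balding–Nichols construction, which
realises a target F_ST but no isolation-by-distance or admixture
clines.  Divergence data share the inference engine's coalescent but
are generated by mutation dropping from independent seeds; loci are
unlinked, with no linked selection beyond the explicit 2N/2m mixtures.
Trait tables are Gaussian around lineage means with no
environment-by-lineage interaction.

Passing tests therefore establish internal correctness and
recoverability under these idealised conditions — free recombination
across loci, no allele-frequency ascertainment, MCAR missingness,
known ancestral states for unfolded spectra — not performance on real
reduced-representation data, where linked loci, ascertainment and
reference bias add error the generators do not emulate.

Test problem sizes are chosen desk-scale: sites of 15–50 individuals
and 100–600 loci for clonal statistics, 5×10⁴ unlinked loci and 8
diploids per population for demographic recovery (with 2 replicate
fits and 2000 genealogies per likelihood evaluation), 100 bootstrap
replicates for tree support.  The one documented failure mode of the
recovery harness is the intrinsic ts/m ridge of two-population
models: at these sample sizes the likelihood distinguishes the truth
from a deep-split/weak-migration alternative by only a few units, so
recovery is asserted at a factor-of-two tolerance, not tighter.
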