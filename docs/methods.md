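# Methods

This note records the statistical models the package implements, the
choices made where the underlying procedures are genuinely open, and
what the synthetic studies do and do not demonstrate.

## Bisulfite model and methylation calling

A bisulfite experiment reads an unmethylated cytosine as thymine with
probability `c` (the conversion rate) and as cytosine — i.e. as
methylated — with probability `r = 1 − c` (non-conversion). The
emission model in the simulator is one-sided: a methylated cytosine
always reads methylated, an unmethylated one misreads with probability
`r`. At true methylation level π the observed methylated-read
probability is therefore `π + (1 − π)·r`, and the correction
`ML_corrected = (ML − r)/(1 − r)` is exactly unbiased. This is the
only emission model under which that widely used correction is exact;
adding a symmetric error on the methylated strand would bias it by a
factor `(1 − 2r)/(1 − r)`. `ML_corrected` is clamped to [0, 1] because
sampling noise can push `ML` below `r`.

Note the `r` in the correction formula must be the *non-conversion*
rate: with a conversion rate of ~0.99 plugged in directly the formula
is negative almost everywhere. Configurations therefore accept the
conversion rate `c` (default 0.995, a typical plant WGBS value) and
derive `r = 1 − c`.

The methylated-site caller tests `mC ~ Binomial(mC + umC, r)` one-sided
(upper tail) at α = 0.05 with a per-sample coverage floor of 5; sites
below the floor are excluded, never called unmethylated. Because the
binomial is discrete the caller is conservative: at coverage 30 and
r = 0.005 the realised type-I error is ≈ 0.01 at nominal 0.05.

Context classification follows the plant convention — CG if the next
strand-aware base is G, CHG if base+1 ∈ {A,C,T} and base+2 = G,
otherwise CHH — with minus-strand sites evaluated on the reverse
complement. Sites whose context would require bases beyond the
chromosome end are excluded rather than guessed.

## Allelic CpG genotyping

The methylation support rate `S = mC/(mC + C)` at a single CpG locus
runs from 0 (neither allele methylated) through 0.5 (hemi-methylated)
to 1 (both alleles methylated) and serves as a proxy genotype for
allelic methylation state when parental genomes are unavailable. A
locus is flagged as changed when `|S_treat − S_ctrl|/S_ctrl` strictly
exceeds 0.5. A gain from `S_ctrl = 0` is treated as changed (infinite
ratio); 0 → 0 is unchanged. The classifier is invariant under
proportional scaling of read counts, which the property tests verify.

## DMR scan

Counts are pooled per site within each group (replicates summed); a
site is eligible when its pooled coverage reaches the floor (default 5)
in *both* groups, since both the window test and the region ANOVA need
both groups at every site. Windows of 1000 bp advanced by 100 bp are
materialised wherever they contain at least one eligible site; each is
tested with a two-sided Fisher exact test on the pooled 2×2
methylated/unmethylated table. Significant windows (p < 0.05) are
merged when they overlap or abut (a gap of one unmerged step separates
regions), and each merged region is confirmed by a one-way ANOVA across
the two groups on per-site corrected methylation levels (p < 0.05). No
genome-wide FDR is applied inside DMR calling — the procedure
deliberately mirrors a raw-p candidate screen. Direction is hyper when
the pooled treated level exceeds control.

Resolution: a strong DMR makes every window overlapping it significant,
so calls extend up to window − step ≈ 900 bp beyond each true boundary,
and occasionally further when chance-significant neighbouring windows
chain on. Planted regions in the recovery study are therefore 3 kb —
below ~2.4 kb a 50% reciprocal-overlap recovery criterion is
geometrically unattainable regardless of signal strength.

## ASE pipeline

Variant hygiene reproduces the usual RNA-seq calling filters: biallelic
SNVs only, phred quality ≥ 20, and removal of every member of any run
of ≥ 3 SNPs whose inclusive span is ≤ 35 bases (clustered SNPs are
usually alignment artefacts). The depth floor keeps loci with
REF + ALT > 5 in *both* conditions and is deliberately depth-only, so
deeply covered homozygous-looking loci survive (they can be informative
about genotype transitions). Heterozygosity for transition classes
requires the minor allele at ≥ 2 reads and fraction ≥ 0.1 — a
configurable rule, since no principled threshold exists without a
genotype likelihood model, which is out of scope.

Differential ASE sums replicate counts within condition and applies a
two-sided Fisher exact test to the condition × allele table; the
replicate-summing choice matches condition-level reporting and trades
replicate-variance awareness for power at low depth (a beta-binomial
test is a stated non-goal). The per-gene representative locus is the
depth-maximal SNP inside the 3′ UTR or within 500 bp beyond its outer
boundary (strand-aware, half-open), ties broken to the smallest
coordinate for determinism.

## siRNA clusters

Cluster calling uses a gap-linking rule: consecutive 24-nt reads join a
chain while the inter-read gap is ≤ 75 bp (an approximation to
ShortStack's island definition, configurable), and chains with ≥ 10
reads become clusters. Clusters within 150 bp (inclusive) merge into
loci; merging is idempotent and order-independent. Differential loci
need |log₂ fold change| ≥ 1 on RPM with a 1-RPM pseudocount — without
the pseudocount a fully silenced locus would have an undefined fold
change, and silencing is the dominant observed response — plus a Fisher
exact p < 0.05 on locus-versus-rest counts per library.

## Expression

FPKM = fragments × 10⁹ / (length × library fragments). A DEG requires
all three of: Fisher exact p < 0.05 on pooled fragments versus library
remainders, |log₂FC| ≥ 1 on group-mean FPKM, and FPKM strictly > 5 in
every replicate (the floor is enforced per replicate, the stricter of
the two possible readings). The lncRNA stable-expression filter keeps
features with FPKM > 1 in at least one group and > 0 in the other.

## Interval arithmetic and DMR annotation

All interval logic is 0-based half-open with bedtools semantics: an
overlap requires ≥ 1 shared base, so `[0,100)` and `[100,200)` do not
overlap. A feature is "within" a DMR on ≥ 1 bp overlap — partial
overlap counts, as DMR/siRNA-cluster relationships are typically
partial. Element classes are computed over genes, lncRNAs and siRNA
loci; TE overlaps are recorded separately and do not enter the class
(there is no TE element class in the classification this reproduces).
Meta-feature profiles use 10 upstream, 20 body and 10 downstream bins,
coverage-weighted, with minus-strand features mirrored.

## Mixed-model association

The model is `y = μ + Qβ + g·α + h·δ + u + e` with `g` the 0/1/2
dosage, `h` the heterozygote indicator, `cov(u) = σ_g² K` and
independent residuals. With `K = U D Uᵀ`, rotating by `Uᵀ` makes the
covariance diagonal with weights `w_i = h² d_i + (1 − h²)`; the
heritability `h²` is estimated by REML as a 1-D profile optimisation,
per SNP by default or once under the covariate-only model with the
`p3d` shortcut. The SNP is tested by the exact F test of its two terms
in the whitened regression; `R²` is the SNP share of the whitened
phenotypic sum of squares, guaranteed in [0, 1] by model nesting. With
`K = I` the procedure reduces to ordinary least squares exactly (unit
weights for every `h²`), which the tests verify to 10⁻⁶. Missing
genotypes are dropped casewise with a sub-`K` eigendecomposition;
collinear covariates are dropped with a warning.

Marker QC keeps SNPs with MAF ≥ 0.05, missingness ≤ 0.25 and every
genotype class carried by ≥ 3 individuals — the class rule is the
quantitative reading of "too few individuals in the alternative
genotype class" and also guarantees the decomposition below is
estimable. `K` defaults to the VanRaden relationship matrix of the
filtered markers (mean-imputed); externally estimated `Q`/`K` are
accepted as inputs.

Effects are decomposed from genotype-class means of the
structure-adjusted phenotype: `a = (m_AA − m_aa)/2` oriented so AA is
the major-allele homozygote, `d = m_Aa − (m_AA + m_aa)/2`. The
dominance ratio uses absolute values, `|d|/|a| > 2` strictly defines a
prominently dominant locus, and `a = 0` yields an infinite ratio
(prominent iff `d ≠ 0`). Because of the major-allele orientation the
sign of `a` can differ from a generator's alt-allele parameterisation;
recovery comparisons therefore use `|a|` (and `d`, which is
orientation-invariant). Multiple testing uses Benjamini–Hochberg
q-values (the λ = 0 Storey variant); significance requires both
p < 0.001 and q < 0.10.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *count laws* of each assay under known
truth: binomial methylated reads at Poisson coverage, binomial allelic
counts, uniform 24-nt reads within clusters, Poisson fragments, and
Hardy–Weinberg genotypes with a phenotype built from planted `a`/`d`
effects, a polygenic term with VanRaden covariance, and Gaussian
residuals. Defaults are chosen to be realistic for a poplar leaf
experiment: GC fraction 0.34, baseline methylation CG 0.40 / CHG
0.20 / CHH 0.05, conversion rate 0.995, coverage 30, three replicates
per group, MAF 0.1–0.5, and population sizes of 300–500.

It deliberately omits read-level artefacts: alignment error, mapping
bias toward the reference allele, M-bias, PCR duplicates,
overdispersion between biological replicates, linkage disequilibrium
between simulated SNPs, and genotype-calling error. Passing tests
therefore demonstrate that the *statistics are implemented correctly
and are calibrated under their own assumptions* — not that those
assumptions hold in any particular sequencing dataset. Effects that
hinge on the omitted features (e.g. reference-bias inflation of ASE)
are invisible here.

All generators are deterministic given the configuration seed, each
drawing from an independent stream so adding one assay never perturbs
another; same-seed runs are byte-identical, which the pipeline manifest
checksums verify.

## Reference study sizes

The acceptance studies run at desk scale, chosen once: DMR recovery on
a 1-Mb genome with twenty 3-kb planted regions (ΔML +0.4, coverage 30);
allele-fraction bias over 10⁴ loci at depth 100; effect recovery over
ten replicate populations of n = 500 with a = 0.6, d = 0.9 and residual
SD 1 (errors averaged over replicates, since a single class-mean draw
has SE ≈ 0.09 for `d`); type-I error of the binomial caller and the
Fisher ASE test over 10⁴ null instances; mixed-model null calibration
at n = 300 with 500 SNPs; and the dominance false-flag rate over 20
pure-additive causal SNPs at n = 500.

## Known limitations

* The window Fisher test on pooled counts treats reads within a group
  as exchangeable; replicate overdispersion would inflate significance
  on real data (beta-binomial modelling is a non-goal).
* DMR boundaries are window-quantised and systematically wide by up to
  one window per side.
* The differential-ASE and DEG Fisher tests share the pooling caveat.
* Per-SNP REML refits assume a single genetic variance component; no
  epistasis, haplotype or multi-locus modelling.
* The CLI is a thin convenience layer; programmatic use through the
  library API is the primary interface.
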