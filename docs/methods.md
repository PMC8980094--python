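# Methods

`phylosite` implements the computational core of a multi-site tumor
relatedness analysis for low-mutation-burden, fusion-driven cancers, together
with the gene-set statistics used to prioritize fusion-associated pathways and
drug targets. Because the patient-level data such analyses consume are
controlled-access, the package ships a synthetic clonal-evolution cohort
generator with known ground truth; every stage is validated against that
truth or against independent brute-force oracles.

## Multi-site mutation model

A patient has `k` tumor sites (2–5). Somatic mutations partition into three
clonal categories:

* **trunk** — carried by the founding clone, present in every site with
  cancer cell fraction (CCF) 1.0;
* **branch** — carried by a subclone spanning more than one but not all
  sites;
* **private** — confined to a single site.

The expected variant allele fraction (VAF) of a mutation in a site where it
is present is `0.5 · ρ · CCF` for tumor purity `ρ`, i.e. a heterozygous
mutation at a diploid locus. Subclonal CCFs are drawn from U(0.3, 0.8). At
the default purity 0.4 this puts trunk VAFs at 0.20 and subclonal VAFs at
0.06–0.16, reproducing the empirical pattern that trunk mutations carry
roughly twice the allele fraction of branch/private ones (observed trunk
means ≈ 0.16–0.23 vs branch means ≈ 0.12 in multi-site exome studies of this
tumor type). The model deliberately ignores copy number at mutated loci and
tree-structured nested subclones: neither is identifiable from the consumed
inputs, and the two-parameter model already reproduces the category-level VAF
separation the downstream statistics rely on.

A patient with exactly two sites cannot host a "more than one but not all
sites" subclone, so the branch probability mass is folded into the private
category for such patients. This keeps the *trunk* proportion — the quantity
the pipeline reports — identical across site counts, so the cohort mean of
per-patient trunk fractions estimates the trunk clone proportion regardless
of the site-count mix.

Read counts are simulated at two tiers: depth ~ Poisson(mean) with exome mean
228 and deep-targeted mean 3700; alt reads ~ Binomial(depth, VAF) where the
mutation is present and Binomial(depth, ε) where absent, with per-base error
ε = 0.001. Depth is Poisson rather than fixed because that is the standard
coverage model; the means are the study-design coverages.

## Detection, rescue, classification

Exome-tier detection applies the paired tumor/normal filter: tumor depth
≥ 30, normal depth ≥ 15, tumor VAF ≥ 0.05, normal VAF ≤ 0.01 (all bounds
inclusive, matching the ≥/≤ phrasing of the criteria they implement).
Population-database frequencies that are missing are treated as 0 (a variant
absent from ESP6500/1000 Genomes is novel and passes the `<0.01` rarity
criterion). A normal sample with zero depth contributes normal VAF 0 — no
normal evidence of the allele.

The per-patient presence/absence matrix is the union of detected mutations
over the patient's sites (a mutation enters only if detected somewhere, so no
all-zero rows exist). *Rescue* then re-genotypes every union mutation in
every site at deep coverage: an absent cell flips to present iff deep alt
reads ≥ 5 and deep VAF ≥ 0.01. These two defaults are a design choice, not a
quoted protocol value: at 3700X and ε ≤ 0.005 a truly absent site produces
≥ 37 alt reads (VAF 0.01) with negligible probability, while a truly present
subclonal mutation at VAF ≥ 0.06 clears the rule essentially always. Both
knobs are configurable. Presence can only grow under rescue, so the trunk
fraction is non-decreasing — an invariant the tests check on 100 simulated
patients.

Categories are a pure function of the row: all ones ⇒ trunk, exactly one ⇒
private, otherwise branch. The cohort trunk percentage is reported as the
mean of per-patient fractions (the pooled fraction is also emitted); under
the packaged deep-validation scenario (trunk proportion 0.60) the rescued
cohort mean recovers 60% within sampling noise, which is the package's
headline simulation check. Clonal deconvolution is deliberately not
performed: at ~40 exonic mutations per patient there is too little signal for
subclone inference, and the trunk/branch/private partition does not need it.

## Distances and trees

Sample-to-sample distance is the hamming distance between matrix columns
(count of rows that differ). An all-zero germline column is appended before
computing distances, so a sample's distance to germline equals its number of
alterations; the germline leaf is the rooting ancestor. For copy-number trees
the same machinery runs on the five-level encoded matrix, with missing
coverage treated as diploid (0), consistent with a germline defined as
alteration-free.

Trees are inferred with classical Saitou–Nei neighbor joining. Numerical
choices: the Q criterion is minimized with ties broken by lexicographic order
of the joined leaf-name pairs (making runs deterministic); negative
branch-length estimates are clamped to 0 to preserve the
branch-length-as-alteration-count interpretation; the final three-point and
two-point joins use the standard closed forms. On additive distance matrices
the implementation provably recovers the generating tree; the test suite
checks 100 random 4–6-taxon instances against an independently constructed
random tree (topology via Robinson–Foulds = 0, path lengths to 1e-9) and
cross-checks topologies against scikit-bio's independent NJ implementation.
Both raw hamming distances and NJ-estimated branch lengths are emitted,
since either can be used to draw trunk/branch length diagrams.

## Copy-number toolkit

Coordinates are 1-based inclusive throughout (SEG convention). Integer total
copy number is encoded as 0→−2, 1→−1, 2→0, 3→+1, ≥4→+2. Patient-level
merging computes the breakpoint union per chromosome and assigns each atomic
interval the **unweighted** mean of the log2 ratios of the samples covering
it (sample-specific intervals keep their value). The mean is unweighted
across samples — not length-weighted — because each covering sample
contributes one estimate per interval; a per-base brute-force oracle on toy
chromosomes verifies the merge exactly. Hamming distance on encoded values
counts differing levels categorically (−1 vs +1 contributes 1, not 2);
that is what "hamming" means, and an absolute-difference variant would
change the germline-distance-equals-event-count property.

Gene-level values are assigned from the segment containing the gene midpoint
(configurable to any-overlap mean); midpoint assignment avoids
double-counting boundary-spanning genes. A gene is a recurrent gain (loss)
when its log2 is ≥ +0.25 (≤ −0.25) in at least 4 patients; integration with
differential expression keeps direction-concordant genes only (gains
up-regulated, losses down-regulated) at p < 0.05 and linear fold change
> 1.5. The fold-change bound is interpreted on the linear scale
(|log2FC| > log2 1.5 ≈ 0.585); an analysis that meant log2 units would use a
different bound, and the choice is surfaced as a parameter.

## Gene-set statistics

**GSEA.** The enrichment score is the signed extremum of the difference
between the weighted in-set cumulative distribution (weights |score|^w,
default exponent 1) and the uniform out-of-set one, walking down the ranked
list. The p-value permutes gene-set membership labels (n_perm ≥ 100, default
1000) with a +1 pseudocount: p = (1 + #{|ES*| ≥ |ES|}) / (1 + n_perm).
Membership permutation — not phenotype permutation — is the only scheme
available when the input is a single ranked list rather than a sample-level
expression matrix. Null calibration (uniform p under random scores and
random sets) is verified by KS test at 2000 replicates.

**ssGSEA.** Per sample, genes are ranked by expression; a signature's score
is the summed difference between the rank-weighted in-set empirical CDF
(weights rank^α, α = 0.25) and the uniform out-of-set CDF. The statistic is
rank-based, hence invariant under monotone transforms of expression — a
property the tests assert directly. Generic signature scoring is provided
rather than any trained immune-score coefficient set; the 29-signature
immune panel (or any other) is supplied as a GMT.

**Truncated product.** For p-values p₁..p_L and truncation point τ (default
0.05, the method's canonical choice), W = ∏{p_i ≤ τ} p_i, and the combined
p-value is P(W* ≤ W) under independent uniforms, computed with the exact
closed form

p = Σ_{k=1}^{L} C(L,k) τ^k (1−τ)^{L−k} F_k(min(1, W/τ^k)) + (1−τ)^L · 1{W ≥ 1},

where F_k(x) = x Σ_{s<k} (−ln x)^s / s! is the CDF of a product of k
uniforms; the empty product gives W = 1 and combined p = 1. At τ = 1 the
formula reduces to Fisher's method (verified to 1e-10), and the closed form
is cross-checked against 10⁶-draw Monte Carlo. The combination is applied
per pathway to the association p (GSEA on the network-association ranking)
and the deregulation p (GSEA on the differential-expression ranking).

**ROC/AUC and rank-shift.** AUC uses the Mann–Whitney midrank convention
(ties count ½), so AUC × n_pos × n_neg equals the one-sided rank-sum U
exactly — asserted as an invariant. The rank-shift test is the one-sided
Mann–Whitney test that set genes outrank the rest (scipy's exact/approximate
policy). Drug-target prioritization keeps genes at percentile rank ≤ 15
(inclusive at the boundary), present in the drug–gene interaction table, and
significantly up-regulated (p < 0.05, linear FC > 1.5); percentile rank uses
average ranks over score ties with 0 = most associated.

## Synthetic cohort: what it does and does not emulate

The generator reproduces the features the pipeline's statistics depend on:
multi-site patients with a known trunk/branch/private partition, two-tier
binomial read counts, arm-level shared/private copy-number events on real
hg19 arm boundaries with a 2,000-gene synthetic annotation, expression fold
changes linear in copy-number dosage (log2FC = slope × mean encoded status +
N(0, σ), with a deterministic monotone map from |log2FC| to a p-value — the
two-sided normal tail at the noise scale), and planted gene sets for
enrichment. It does **not** emulate mutational signatures, nested subclone
trees, strand bias or mapping artifacts, focal SCNAs below arm scale, or
realistic gene–pathway structure. Passing tests therefore demonstrate that
the implementation computes its statistics correctly and recovers planted
truth under the stated generative model — not that the model captures every
property of real tumors.

Default scenario sizes ("deep validation"): 20 patients, 2–5 sites, 40
mutations per patient, clone proportions 0.60/0.25/0.15, purity 0.4,
coverages 228X/3700X. Purity and the subclone CCF range are calibrated
choices (no published values exist for them); they were fixed once to
reproduce the observed trunk/branch VAF levels and are not tuned per run.
Test and acceptance runs use 4–100 simulated patients depending on the
property being checked; these sizes keep the full suite under a minute per
file while leaving binomial sampling error well inside the stated
tolerances.

## Degenerate inputs and edge policies

* Two-taxon distance matrices return the single edge; three taxa use the
  closed-form three-point solution (a tie in Q at n = 3 is broken
  lexicographically).
* A category with no present cells is reported as missing, never as mean 0.
* Zero-variance columns make Pearson correlation undefined; reported as
  missing with the pair's overlap count.
* A gene set that does not intersect the ranked list is an error for GSEA
  (and a skipped signature with a warning for ssGSEA).
* Single-sample patients are skipped with a warning in the relatedness
  workflow — a phylogeny is undefined.
* Cells without deep coverage warn and stay unrescued; they never abort a
  patient.

## Known limitations

* The VAF model is site-homogeneous per mutation; real subclones vary in CCF
  across sites, which would blur the trunk/branch VAF separation.
* Trunk-fraction recovery depends on the rescue rule and deep coverage; at
  much lower deep depth or higher error rates the default rule would need
  re-examination.
* The exome capture size is a required user input for mutation rates per Mb;
  no default is assumed.
* NJ is exact for additive distances but, like all distance methods, offers
  no support values; bootstrap support is out of scope.
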