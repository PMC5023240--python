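# Methods

`evomex` re-implements, as a tested pipeline over synthetic data, the
computational analysis of eight replicate *Methylobacterium extorquens* AM1
lineages (F1–F8) evolved for ~600 generations after their formaldehyde
oxidation pathway was re-engineered: the native H₄MPT-dependent pathway was
deleted and replaced by a plasmid-borne (pCM410) glutathione-linked pathway
(*flhA*, *fghA*), producing an engineered ancestor (EM) that grows on
methanol far more slowly than wild type (WT). This note records the models,
defaults and numerical choices, and what the synthetic data do and do not
establish.

## Expression reaction norms

### Model

Each gene's log2 expression is decomposed into two additive effects:

* **acclimation** α = E[log2(EM)] − E[log2(WT)] — the immediate
  physiological response to the engineering;
* **adaptation** ε_l = E[log2(EVO_l)] − E[log2(EM)] — the evolved response
  of lineage *l*.

Significance of each contrast at an adjusted-p threshold *q\** (default
0.05) yields five mutually exclusive categories per locus per lineage:

| α | ε | category |
|---|---|----------|
| n.s. | n.s. | unchanged |
| n.s. | sig. | novel |
| sig. | n.s. | unrestored |
| sig. | sig., sign(ε) = −sign(α) | restored |
| sig. | sig., sign(ε) = sign(α) | reinforced |

"Unchanged" is made explicit so the categories partition the locus universe.
Restored loci get a subtype from the residual α + ε: `full` when
|α + ε| ≤ τ (default τ = 0.5 log2), `partial` when the residual keeps the
sign of α, `over` when evolution overshot past the WT level. τ is the only
free parameter in the subtype rule; 0.5 log2 (√2-fold) is a conventional
"biologically negligible" residual.

Loci physically deleted in a lineage (e.g. by a large IS-mediated deletion)
are excluded from that lineage's classification via a (lineage, locus)
deletion mask; the mask is a two-column table of locus ids rather than a
coordinate interval because classification operates on loci, and the
mutation module's IS-deletion detector already emits the removed-gene list.

### Moderated t statistics

Per-probe two-group statistics use empirical-Bayes variance shrinkage: the
probe-wise pooled variance s²_g (residual df d_g) is squeezed toward a prior
(d₀, s₀²) estimated from the distribution of log s²_g by method of moments
(digamma/trigamma matching, trigamma inverted by Newton iteration), giving
posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and
t = Δmean / (s̃_g √(1/n_a + 1/n_b)) on d₀ + d_g df. When the observed log
variances are no more dispersed than chi-square sampling predicts, d₀ = ∞
and the prior scale is the arithmetic mean of the sample variances. The
implementation agrees with limma's `eBayes` to ~1e-13 in t on a
heteroscedastic fixture (cross-checked in the test suite via Rscript), and
reduces to the ordinary pooled t at d₀ = 0 and to a z-like statistic at
d₀ = ∞ (both asserted numerically).

Probes are assimilated to loci by median effect and Stouffer-combined
p-values signed by each probe's t, so probes disagreeing in direction
cancel; single-probe loci keep their probe statistics exactly. p-values are
Benjamini–Hochberg adjusted across loci within each contrast. The original
microarray study's exact cut-off and multiple-testing handling are not
restated in its methods; q < 0.05 with BH is this package's explicit,
configurable default.

Orientation convention: effects are log2(EM/WT) and log2(EVO/EM), so a
positive ε means the evolved strain increased expression relative to its
ancestor.

## Mutation analysis

Input is breseq-style GenomeDiff, one file per lineage (SNP, INS, DEL, SUB,
MOB, AMP parsed; other entry types carried opaquely). Two filters run in a
fixed, documented order, both idempotent:

1. **marginal calls** — a call is kept only if its mutant read fraction
   exceeds 0.5 (an equal or greater mix of reference reads marks a marginal
   or polymorphic call); records without read-support metadata pass through;
2. **ancestral alleles** — an identical allele (same type, coordinate and
   alternate state) present in ≥ 6 of 8 lineages is attributed to the
   construction of the common ancestor, not to evolution, and removed. The
   threshold is configurable; the same *gene* hit by *different* alleles is
   genuine parallelism and is always retained.

Coding effects: SNPs inside a CDS are classified synonymous / missense /
nonsense by translating the reference and mutated CDS (standard genetic
code; start-codon special cases not modelled). A tandem duplication (AMP)
adding L bp with L ≡ 0 (mod 3) reports an in-frame protein extension of
L/3 amino acids — the rule behind the RNA-polymerase α-subunit linker
extensions (+77 aa in F1, +32 aa in F8, and the 141 bp → +47 aa allele) —
otherwise a frameshift. Intergenic records are assigned to the nearest
downstream gene within 2,500 bp (relation `intergenic-upstream`); the
window default is set so that a regulatory SNP ~2 kb upstream of *gshA*
counts toward that target.

Parallelism is tabulated as a boolean targets × lineages matrix; both coding
and upstream hits count. Two conventions mirror the study's target
definitions: the engineered plasmid is one collective target regardless of
which plasmid gene is hit (`region_targets`), and the two ATP-synthase
subunit loci are merged into one functional target (`target_aliases`).

IS-mediated deletions are recognised when a DEL's endpoints each fall within
100 bp of annotated insertion-sequence copies of the same family and
orientation; the call carries the deletion span and the list of genes fully
contained in it.

## Growth phenotypes

The specific growth rate μ (1/h) is the slope of ln(OD600) vs time in the
exponential phase, found by sliding-window OLS. A window qualifies when it
has ≥ 5 points, r² ≥ 0.99, positive slope, **and a fitted rise of at least
two doublings (2·ln 2)**; the maximum-slope qualifying window is reported.
The rise requirement is the load-bearing choice: with multiplicative
measurement noise of a few percent, short windows can be spuriously steep
yet perfectly linear, and any rule selecting on slope or fit quality alone
can latch onto them (observed errors up to ~60% at μ = 0.02/h under 2%
noise). Noise cannot fake a sustained two-doubling climb, so the rise gate
removes those windows while leaving noiseless curves untouched — recovery on
a clean exponential is exact, and a monotone-decreasing curve yields an
explicit no-fit rather than a number. Under 2% multiplicative noise the
estimator stays within ~4% of truth across μ ∈ {0.02…0.20}/h (the test grid).
Curves that never complete two doublings are reported as no-fit; for very
slow strains the observation window must be long enough (≥ 2·ln2/μ hours).

Relative growth is μ_strain/μ_reference (benefit = fold − 1). Epistasis
between two mutations uses the four-genotype contrast
b(m1|anc) = μ(anc+m1)/μ(anc) − 1 versus b(m1|anc+m2); a negative difference
is diminishing-returns epistasis (e.g. a benefit falling from 57% alone to
44% in an already-improved background gives −0.13), zero corresponds to
multiplicative rates. Group comparisons use Welch's unequal-variance
two-tailed t-test. Oxidative-stress (H₂O₂ disc assay) halo diameters are
normalized to each strain's own pink or white ancestor; protection
= 1 − diameter ratio, reported with SEM over ≥ 3 replicate plates.

## Synthetic data

The generators define the study conditions for every test:

* **Expression**: 2,000 genes, 3 replicates per group, |α| = |ε| = 2.0 log2
  for affected genes, i.i.d. Gaussian replicate noise sd 0.25 log2, category
  proportions 5% novel / 10% restored / 5% unrestored / 3% reinforced / 77%
  unchanged. Effects are additive on the log2 scale (the standard microarray
  model). Replicate count n = 3 is a typical microarray design; the original
  study does not state its per-group replicate number. Restored genes have
  ε = −α exactly; an optional fraction gets partial restoration ε = −cα
  (0 < c < 1) to exercise the subtype logic. Each gene carries one category
  shared by all simulated lineages; per-lineage categories would require
  per-lineage ε jointly constrained by a shared α and are not needed by any
  downstream consumer.
* **Mutations**: multi-type records over a toy single-replicon genome of
  evenly spaced CDSs (whole codons, so translation oracles work) with IS
  copies; options plant identical "ancestral" alleles in every lineage and
  an IS-pair-bounded deletion of configurable span.
* **Growth**: flat lag (default 3 h), logistic approach to od_max with
  maximum specific rate μ, mean-one lognormal multiplicative noise at a
  stated CV. Defaults od0 = 0.01, od_max = 1.0 (~6.6 doublings, typical of
  methanol microtiter growth), hourly reads; the recovery grid observes
  96 h so the slowest strain (0.02/h) completes two doublings.

What passing tests show — and do not. The generators realise the *structure*
of the study's data (two-contrast design, multi-probe loci, mutation
spectrum, lag/exponential/saturation curves) with well-behaved noise. They
do not model probe-level microarray artifacts (spatial effects, dye bias,
intensity-dependent variance), read-level sequencing error, clumping in
OD measurements, or biological correlation between genes. Recovery rates
measured here (e.g. ≥95% of reaction-norm labels at q < 0.05) therefore
certify the statistical machinery under its stated assumptions, not
performance on raw instrument data.

## Packaged fixtures

`src/evomex/data/` carries small text fixtures transcribed from the study's
published summary tables: the per-lineage strain summary (growth relative to
EM, novel-expression counts, mutation tallies), the expected parallel-target
presence matrix, and the expression divergence of the two RNAP-mutant
lineages. The per-lineage GenomeDiff files and the toy GFF3 genome are
synthetic reconstructions that encode the published presence/absence
pattern with invented coordinates and distinct alleles per lineage (so the
ancestral filter correctly retains locus-level parallelism). The
`rpoa_contrasts.tsv` fixture derives its effects from published fold
changes but carries synthetic significance flags, as per-gene p-values were
not published. `evomex reproduce` recomputes the target matrix and the
trajectory calls from these inputs and diffs them against the expected
renderings.

## Determinism

Every generator takes an explicit seed; pipeline stages draw child seeds
from one root generator. Output files carry a provenance header with the
package version, seed and a config hash (output paths excluded from the
hash), and a rerun with the same config and seed is byte-identical.

## Known limitations

* The GenomeDiff dialect covers the fields this pipeline consumes; evidence
  lines are preserved verbatim but not interpreted beyond read counts.
* No array normalization, background or batch correction: the expression
  matrix is assumed already normalized on the log2 scale.
* No fold-change floor is applied on top of significance when classifying
  (the original study's criterion on this point is unstated); one can be
  imposed by filtering the contrast table before classification.
* The growth module intentionally does not fit full logistic/Gompertz
  models or estimate lag/stationary parameters.
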