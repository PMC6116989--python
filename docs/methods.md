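# Methods

## Scope and data model

The package implements a complete association analysis for a two-category
(horned/polled) trait on a population where pedigree is deep but genotyping
is sparse: genomic breeding values are estimated in one step for all animals
(single-step GBLUP), SNP effects are derived from them (weighted single-step
GWAS), additive variance is partitioned into 1 Mb windows, and a
runs-of-homozygosity (ROH) island scan provides an independent line of
evidence. All coordinates are 1-based inclusive internally (PLINK MAP
convention); BED output converts to 0-based half-open in one place
(`plinkio.write_bed`).

## Threshold liability model and Gibbs sampler

Liabilities I follow `I = 1μ + Xa + e` with `a ~ N(0, H σ²ₐ)` and
`e ~ N(0, I σ²ₑ)`; an animal is polled (category 2) iff its liability
exceeds the threshold. Identifiability is fixed the standard way for two
categories: threshold t = 0, μ free, unit total liability variance
(σ²ₐ = h², σ²ₑ = 1 − h²). Variance components are fixed, not estimated; the
default h² = 0.99 follows the source analysis of this design, where the
trait is quasi-Mendelian on the liability scale.

The sampler alternates (i) liabilities from truncated-normal full
conditionals — plain rejection near the bulk, Robert's translated-
exponential rejection in the tail, so category-2 animals with strongly
negative means remain numerically exact; (ii) μ from its Gaussian full
conditional under a flat prior; (iii) each animal effect by single-site
Gibbs using one row of H⁻¹ (numba-compiled; dense H⁻¹ is cheap at the
scales this package targets). GEBV are posterior means of `a`. Defaults:
20,000 cycles, 10% burn-in, thinning 10 (the original real-data setting of
300,000 cycles is a config value, not a code change). Chains are exactly
reproducible given a seed. The Gaussian reduction (observed liabilities)
is validated against the direct mixed-model-equation solution.

## Relationship matrices

* A by the tabular recursion (diagonal 1 + F); A⁻¹ by Henderson rules using
  exact inbreeding from the tabular diagonal, so A⁻¹A = I also on inbred
  pedigrees.
* G* = ZDZ′λ with Z = M − 2p (missing genotypes mean-imputed, preserving
  zero column means), λ = 1/Σ2pᵢ(1−pᵢ); D = I gives the VanRaden method-1
  G. Allele frequencies are computed from the genotyped animals after QC —
  the only observable choice without base-population data.
* H⁻¹ assembled as A⁻¹ plus the genotyped-block correction
  G_b⁻¹ − A₂₂⁻¹ with G_b = (1−β)G* + βA₂₂; blending default β = 0.05
  guarantees invertibility and is exposed in config.

## Weighted single-step GWAS

The iteration is: D = I → build G*, H⁻¹ → GEBV by the threshold-model
sampler → û = DZ′[ZDZ′]⁻¹âg (the λDZ′G*⁻¹âg form is used when the blended
G* inverse is already available; unblended, the two coincide and Zû = âg
holds to numerical precision) → per-SNP variances ûᵢ²2pᵢ(1−pᵢ) → D
normalized so Σdᵢ2pᵢ(1−pᵢ) is conserved → repeat. One reweighting loop
(two passes) is the default, and GEBV are re-estimated inside the loop.
Reweighting sharpens the variance profile: in the replication study the
causal window's share roughly triples after one loop.

Window shares use the empirical (population) variance of the window genetic
values `Z_w û_w` across genotyped animals, divided by the fixed σ²ₐ. Both
window modes are provided: sliding (one window per starting SNP, span
end − start + 1 ≤ 1 Mb — this reproduces SNP-delimited spans such as
878,631–1,873,922) and tiling (disjoint 1 Mb bins). Region reporting uses
sliding mode: windows above the share threshold (default >1%, strict) that
are consecutive in map order merge into a region, and the region total sums
a greedy left-to-right non-overlapping subset of its windows so heavily
overlapping sliding windows are not double-counted. With the published
window table this reproduces the 65.54% total exactly.

## ROH and islands

A reported segment is a maximal SNP interval in which every SNP passes the
window-support rule (≥5% of the covering 50-SNP windows have ≤1
heterozygote and ≤2 missing calls; windows truncate at chromosome edges)
and which satisfies: ≥100 SNPs, span ≥1 Mb, inter-SNP gaps ≤0.5 Mb, density
≥1 SNP/50 kb, ≤1 heterozygote. "Maximal" means not contained in another
passing interval; the detector is verified set-identical to an exhaustive
interval enumerator on random chromosomes. Segment and region lengths are
end − start (the convention under which the published island and consensus
lengths — 2.47 and 1.86 Mb — are exact). The single-heterozygote allowance
applies both inside scanning windows and per segment; the missing-call
allowance per window (2) is a package default, exposed in `RohParams`.

Island calling screens per-SNP ROH incidence (fraction of scanned animals
whose ROH cover the SNP, each animal counted once) against the boxplot
fence Q3 + 1.5·IQR, quartiles by linear interpolation; ≥100 consecutive
outlier SNPs form an island. The fence is computed genome-wide by default:
at desk scale the simulated island occupies ~30% of its 400-SNP chromosome,
which would contaminate a per-chromosome Q3; for a single-chromosome scan
(as in the original design) the two scopes coincide, and
`fence_scope="chromosome"` is available. The ROH scan defaults to the
polled subset, with `all`/`horned` selectable. Constant incidence (zero
IQR and zero range) yields no islands, with a warning.

## Synthetic population

The generator emulates the study conditions at desk scale (about one minute
for the full pipeline): 200 founders plus 4 generations of random mating
(disjoint sire/dam pairs, 2 offspring each) giving 1,000 animals; five
10 Mb autosomes with 400 evenly spaced SNPs (25 kb spacing); founder allele
frequencies uniform on [0.05, 0.5] so QC stays non-degenerate; 40% of
non-founders genotyped with 1% missing calls.

Gene dropping transmits whole haplotypes with recombination (Haldane map
function, 1 cM/Mb), so Mendelian structure matches A and haplotype blocks
survive transmission. The causal locus sits at 1.5 Mb on chromosome 1 —
near the chromosome start, as in the mapped region — with founder allele
frequency 0.20. Every founder haplotype carrying the causal allele also
carries one conserved 3 Mb flanking block (a single mutation origin):
homozygous carriers are therefore homozygous across ~120 consecutive SNPs,
which is what the ROH island detects. The block is set to the major allele
at each flanking SNP; a block drawn from the background frequencies instead
makes every 1 Mb window inside it an equally strong tag of carrier status
and the variance peak loses its center, whereas the major-allele block
keeps per-SNP LD with the causal allele weak away from the locus — a
deliberately simple stand-in for LD decay, since coalescent-realistic
haplotypes are out of scope.

Liability = polygenic value + causal effect + residual. The polygenic part
(variance h² = 0.8) is gene-dropped down the pedigree as founder values
N(0, h²) plus Mendelian sampling N(0, h²/2 · (1 − (F_s + F_d)/2)); the
causal effect is dominant, 8 liability-SD for carriers (an `additive` mode
is available); the residual has variance 1 − h². Total liability-scale
heritability is therefore very high, as in the source analysis. The
threshold is the empirical 1 − 0.137 quantile of the realized liabilities,
so polled prevalence hits the target exactly; with carrier frequency
(~0.34) above the prevalence, the threshold falls inside the carrier
cluster — penetrance is incomplete, consistent with polledness in indicine
cattle not being cleanly one-locus Mendelian, and it keeps
causal-haplotype homozygotes (~4% of animals) frequent enough for the ROH
analysis to see them.

What the generator does **not** emulate: background LD (founders are in
linkage equilibrium away from the causal block), selection and assortative
mating, genotyping-array ascertainment, sex chromosomes, imputation error.
Passing tests therefore demonstrate the machinery and its statistical
behavior under the intended data structure, not performance on real
LD-rich cattle data.

## Numerical choices and degenerate inputs

* Allele frequencies clipped to [1e−8, 1−1e−8] before λ and centering
  (QC normally removes fixed SNPs; the clip guards hand-built inputs).
* Backsolve raises a dedicated error on singular ZDZ′, suggesting blending.
* `normalize_weights` falls back to D = I (with a warning) when all raw
  variances are zero.
* QC applies its rule order (unmapped → sex chromosomes → sample call rate
  → SNP call rate → monomorphic → MAF, strict inequalities) repeatedly to a
  fixed point: removing a SNP can push a borderline sample below the
  call-rate threshold and vice versa, and the fixed point makes the filter
  idempotent. Statistics are recomputed after sample removal.
* Gibbs raises with the cycle index if a draw becomes non-finite.
* Desk-scale problem sizes: the replication study uses 2,000-cycle chains
  (burn-in 400, thinning 10) per pass; a single analysis defaults to
  20,000 cycles. Sizes are config values chosen so a full replication study
  (10 populations × 2 Gibbs passes each) completes in under a minute.

## Known limitations

* Dense H⁻¹ and single-site Gibbs are O(n²) per cycle — fine to a few
  thousand pedigree animals, not for national evaluations (no APY inverse,
  no metafounders).
* Only μ enters as a fixed effect, matching the analysis design; arbitrary
  fixed effects would need an extended incidence structure.
* No genotype imputation: genotypes are taken as (QC-filtered) given.
* Functional enrichment is out of scope; gene annotation is an offline
  overlap against a user-supplied BED file.
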