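# polledgwas

Weighted single-step GWAS (WssGWAS) and runs-of-homozygosity (ROH) analysis
for a binary horned/polled trait on a pedigreed, partially genotyped cattle
population — the analysis design used to map polledness in Nelore cattle to
the centromeric region of chromosome 1.

The package is for quantitative geneticists who want a self-contained,
testable implementation of this analysis chain: a threshold-model animal
model solved by Gibbs sampling under the combined pedigree + genomic
relationship matrix, SNP effects backsolved from breeding values with
iterative reweighting, additive variance partitioned into 1 Mb SNP windows,
and an independent ROH-island scan whose intersection with the GWAS signal
refines the candidate region. Because the commercial data behind the
original study are private, the package ships a synthetic-data generator
that reproduces the study's structure (multi-generation pedigree, partial
genotyping, one dominant causal locus with a conserved founder haplotype,
13.7% polled prevalence) so the whole analysis runs end to end.

## Model

Phenotypes are categories (1 = horned, 2 = polled) linked to a latent
liability

    I = 1μ + Xa + e,    a ~ N(0, H σ²ₐ),   e ~ N(0, I σ²ₑ),

with category 2 observed iff the liability exceeds a threshold (fixed at 0;
μ free). `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]` combines the pedigree
relationship matrix A with the genomic matrix of the genotyped subset.
With centered genotype codes Z, per-SNP weights D and
λ = 1/Σᵢ 2pᵢ(1−pᵢ), the weighted genomic matrix is G* = ZDZ′λ and SNP
effects are backsolved from the genotyped animals' GEBV âg:

    û = λDZ′G*⁻¹ âg = DZ′[ZDZ′]⁻¹ âg,
    σ̂²û,i = ûᵢ² · 2pᵢ(1−pᵢ)   →   next D (normalized to conserve Σ dᵢ2pᵢ(1−pᵢ)),

iterated once (two passes total). The share of additive variance of a 1 Mb
window w of consecutive SNPs is

    100 · var(Σ_{j∈w} z_j û_j) / σ²ₐ,

and windows explaining more than 1% are merged into candidate regions.
ROH are called per animal with the classical seven-parameter sliding-window
scan (50-SNP windows, ≥100 SNPs, ≥1 Mb, ≤0.5 Mb gaps, ≥1 SNP/50 kb, ≤1
heterozygote); SNPs whose ROH incidence across polled animals exceeds the
boxplot fence Q3 + 1.5·IQR over ≥100 consecutive SNPs form an island, and
GWAS ∩ island intersections are the consensus regions.

## Worked example

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_run_pipeline.py --seed 1
```

prints, for the default population (1,000 animals, 320 genotyped at 2,000
SNPs, polled prevalence 0.137):

```
top 1 Mb windows by variance share:
chrom  start_bp  end_bp  snp_count  var_share_pct
    1   1378447 2355890         39      10.089084
    1    776943 1754387         38       9.907628
    1    751881 1729324         38       9.905323
...
1 ROH island(s) in polled animals:
  1:1-3007519  (3.01 Mb)
1 consensus region(s):
  1:1-3007519  (3.01 Mb)
```

The top windows all contain or flank the simulated causal SNP
(chr1:1,500,000); the ROH island in the polled animals spans the conserved
founder haplotype around it, and their intersection is the refined consensus
region — the same logic that narrowed the real study's 3.11 Mb association
region to 1.86 Mb. `analysis/03_causal_recovery.py` repeats the whole chain
on ten fresh populations (top window contains the causal SNP in 10/10, ROH
island overlaps it in 10/10 at seed 1), and `analysis/04_worked_examples.py`
re-derives the published arithmetic: the three >1% windows merge to a
region explaining 47.18 + 14.66 + 3.70 = 65.54% of the additive variance,
and intersecting chr1:878,631–3,987,104 with the island chr1:269,100–2,739,000
gives chr1:878,631–2,739,000 (1.86 Mb).

The same pipeline is scriptable via the `polledgwas` CLI
(`simulate`, `qc`, `gwas`, `roh`, `report`, `all`), e.g.
`polledgwas all --seed 1 --out results/run`.

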