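# Methods

This note records the models, parameter choices and numerical conventions
behind `srnaqtl`, and what the synthetic studies do and do not demonstrate.

## Population model

An immortalized F2 (IMF2) is a panel of hybrids made by paired crosses of
recombinant inbred lines (RILs); each hybrid's genotype at a locus is AA,
Aa or aa (A ≡ the Zhenshan 97 allele), with F2-like expected frequencies
(¼, ½, ¼), but the panel can be regrown indefinitely.

RILs are simulated by single-seed descent from the F1: at each of 8 selfing
generations a meiotic product is drawn per chromosome with crossovers as a
Poisson process (Haldane map function — no interference; interference is
irrelevant to the downstream statistics). After selfing, any residual
heterozygous segment is fixed to a random founder allele, so RILs are fully
homozygous mosaics. Chromosomes assort independently, so with zero
recombination each chromosome — not the whole genome — fixes a single
founder. Crosses are drawn without replacement: each RIL enters at most one
cross when the panel allows, otherwise distinct pairs are sampled (RILs
reused, pairs never repeated).

The bin map is the partition of the genome at the union of all RIL
breakpoints; genotypes are constant within bins for every individual, so
bins serve as the markers for all scans.

### Default and scaled study designs

Defaults emulate the full design: 12 chromosomes with rice-like lengths
(~373 Mb), 196 RILs, 98 hybrids, and a recombination rate (1.06 cM/Mb)
calibrated so the RIL panel carries ≈1556 breakpoints, i.e. ≈1568 bins of
~240 kb.

The validation studies run a scaled design: 3 chromosomes × 20 Mb, a
16-RIL panel behind 98 distinct paired crosses, 10.4 cM/Mb → ≈190 bins.
The small panel is deliberate: each bin boundary is a breakpoint in one
RIL, so the number of hybrids that recombine at a boundary equals that
RIL's usage (~12 here, versus 1 in the full design). Peak localization in
bin units is a random walk whose drift per boundary is proportional to that
number; a panel with single-use RILs cannot localize a one-residual-sd
effect to ±1 bin at n = 98 no matter the effect of interest. The cost of
the small panel is background correlation between chromosomes (bins are
functions of only 16 founder mosaics), which produces occasional ghost
distant QTLs; the permutation threshold operates per trait and remains
calibrated regardless.

## Expression simulation

A planted trait has expected value μ + Σ(a·x + d·z) per hybrid, with
x ∈ {−1, 0, +1} for {aa, Aa, AA} and z = 1[Aa], on the RPM scale
(baseline μ = 10 RPM). Counts are negative-binomial around
mean × (library size / 10⁶) with dispersion 0.2 (variance m + 0.2 m²,
typical sRNA-seq overdispersion); library sizes are uniform on
14.52–27.73 million reads, the observed range of the study libraries.
A Gaussian mode (`noise="normal"`, unit residual sd) feeds the scan
calibration studies, where effect sizes are defined in residual-sd units;
a deterministic mode supports exact-value tests. Mother-gene mRNA tracks
its sRNAs' genetic value through a per-trait coupling coefficient plus
unit Gaussian noise.

What the generator does **not** emulate: sequence content and mapping
artifacts, ncRNA contamination (a sequence blocklist stands in for
database filtering), segregation distortion, residual RIL heterozygosity,
batch effects, and the heavy-tailed abundance distribution of real sRNA
populations. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
property of real libraries.

## Quantification rules

All thresholds are inclusive and central: RPM ≥ 0.6 (sRNA), normalized
count ≥ 6 (cluster), FPKM ≥ 1 (mRNA) define *expressed*; an entity
expressed in ≥ 26 of 98 hybrids ("more than 25") is a trait. Region
assignment is strand-aware (upstream = 2 kb 5′ of the TSS, downstream =
500 bp 3′); when windows of several genes compete the precedence is
genic > upstream > downstream > intergenic, ties to the nearest TSS — the
order is a package decision to make region tallies deterministic. Genic
anchors refine to exon / intron / UTR (exonic but outside every annotated
CDS). Trait anchors are the 5′-most genomic coordinate of the record;
at ≤ 26 nt the choice is immaterial at bin scale but fixed for
reproducibility.

Islands require pooled coverage ≥ 30× over **all** libraries (parents,
hybrid and IMF2s pooled; per-library island calling is not offered);
the merge gap is end-to-start in half-open coordinates, "within 1000 nt"
read as gap ≤ 1000. Cluster membership is by record anchor. Size factors
are the standard median-of-ratios: rows containing any zero are excluded
from factor estimation; the geometric mean runs over all libraries. No
minimum island span is imposed; an optional span filter is available.

## Genome scan

IMF2 genotypes are fully observed per bin, so interval mapping reduces
exactly to marker regression: at a test bin,
LOD = (n/2)·log₁₀(RSS_reduced/RSS_full), the reduced model holding
intercept + cofactors and the full model adding x and z. With all three
classes present the full model equals the three-group-means model, which
makes the scan vectorizable: per bin we precompute an orthonormal basis of
each design (rank-aware, zero-padded) and evaluate all permutations with
one tensor contraction. Bins with fewer than two genotype classes score
LOD 0 and are flagged.

Cofactors: forward stepwise selection on additive codes, at most 3 (n=98),
scored by the extended BIC (per-term penalty ln n + 2 ln n_bins). Plain
BIC ignores that each cofactor is chosen among hundreds of bins and admits
a spurious marker for most null traits; the extended penalty restores the
expected ≥90% empty sets under the null. Cofactors within 10 Mb of the
test bin (same chromosome) are dropped there. Both the count and window
are configurable.

Significance: trait values are permuted across individuals (default 1000
permutations; per-trait RNG substreams derived from the master seed and a
CRC of the trait id), the genome-wide max LOD recorded, the threshold
taken as the (1−α) empirical quantile (method "higher") and the trait
p-value as (1 + #{perm ≥ obs})/(1 + n_perm). Benjamini–Hochberg at
q = 0.05 runs across traits; QTLs are then called within significant
traits at each trait's own threshold. Note the p-value floor
1/(n_perm+1): with few traits, BH can only reject if that floor is below
q·i/m, so small demonstrations need enough permutations.

Peaks are plateau-left local maxima above the threshold; two maxima on a
chromosome are distinct QTLs only when ≥ 5 bins apart **and** separated by
a valley ≥ 1.5 LOD below the lower maximum (conjunctive, because wiggles
on one LOD hill under tight bin-map linkage are not separate loci);
otherwise they collapse to the higher, ties to the lower coordinate.
Support intervals extend while LOD ≥ peak − 1.5, then one bin beyond each
side, clipped at chromosome ends. R² is 1 − RSS/TSS of the single-locus
genotype-means model.

Local vs distant: a QTL is local if the trait anchor lies inside the
support interval's bp span or within 250 kb of the peak bin; anything
else — including any cross-chromosome case — is distant. The source
analysis invokes the 250-kb rule only "in a recombination sparse region"
without operationalizing sparseness; here the fallback applies
unconditionally, a documented deviation that can only make the local call
slightly more permissive.

## Genetic effects and dominance

a = (m_AA − m_aa)/2 and d = m_Aa − (m_AA + m_aa)/2 from unweighted class
means; positive a means the Zhenshan 97 homozygote expresses higher. The
dominance test (h-test) permutes residuals of the additive-only least
squares fit and recomputes d (which is a fixed linear contrast of the
data, and exactly zero on the fitted values) — this isolates dominance
from additive signal; two-sided p with the +1 correction; 1000
permutations, applied at peak bins only. Classification: non-significant
→ none; significant d < 0 → negative dominance, and d < −|a| (heterozygote
below both homozygotes) → negative overdominance; mirrored for positive.

## Hotspots and correlations

Density = items per Mb of bin; a bin is a hotspot when its density
strictly exceeds multiplier × the genome-average density (total items /
total Mb): 3× for traits, 6× for QTLs, 2× for cluster traits. QTLs are
anchored at peak bins only. Runs of adjacent hotspot bins are reported
per chromosome.

Pairwise Pearson correlations are computed within groups (same mother
gene, same cluster, or trait-vs-mother-gene); zero-variance vectors are
skipped and logged. The significance threshold r* is the (1−α) quantile of
|r| between independent standard-normal vectors of the shared sample
length — at n = 98 this converges to the analytic critical value
t₀.₉₇₅,₉₆/√(t²+96) ≈ 0.199 — and is always recomputed rather than
hard-coded. |r| ≥ 0.3 is classed strong (boundary inclusive; the dividing
points are silent on ties). Distant-QTL peak distances are measured
bin-midpoint to bin-midpoint with a 2-Mb cutoff for "nearby".

## Pipeline, determinism and problem sizes

The pipeline runs simulate (or ingest) → filter/quantify → cluster → scan
(with effects) → hotspots → correlations → report, logging record counts
at every stage so the filtering cascade is auditable. All randomness flows
from one master seed; reruns are byte-identical. The simulate stage caches
its fixture bundle keyed by a configuration hash; downstream stages are
cheap at these sizes and always recompute. The CLI is a thin layer over
`srnaqtl.pipeline` with exit codes 0/1/2 (ok / user error / internal).

Validation studies use the scaled design throughout: 200 null traits ×
200 permutations for calibration, 100 planted traits each for local and
distant recovery, 500/200 replicates for dominance type-I/power, 100
random tracks for the cluster oracles. These sizes give Monte-Carlo error
comfortably inside the stated tolerances while the whole suite runs in
well under a minute of scan time.

## Known limitations

- Localization to ±1 bin at one residual-sd is intrinsically limited by
  how many hybrids recombine at each bin boundary (see the population
  section); measured rates on the scaled design are ~0.8.
- Epistasis, multi-QTL joint models and pseudomarker imputation are out of
  scope; scans are single-locus per test position.
- The blocklist filter is a functional stand-in for database-driven ncRNA
  removal, not a curated annotation.
- Cross-chromosome background LD in small RIL panels can produce ghost
  distant QTLs above per-trait thresholds; the full 196-RIL design does
  not share this property.
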