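# Methods

## The scan model

`introscan` assumes two diploid sister species, M and S, sampled in two
contexts: allopatric reference panels (`M_allo`, `S_allo`) that define what
each species looks like away from contact, and one sympatric population
pair (`m1`, `s1`) tested for gene exchange. The population manifest is the
single source of this structure; nothing is inferred from sample names.

All analysis operates on biallelic SNPs. Positions are 1-based internally
(VCF convention); block intervals are converted once, at construction, to
0-based half-open integers so BED emission is a plain column dump.
Missing genotypes are carried explicitly and never imputed: a missing
diploid call removes two haploid copies from every frequency, count and
denominator it would have entered.

### Divergent sites

Per-site differentiation between the allopatric panels uses Hudson's
F<sub>ST</sub> estimator

    F_ST = [ (pa - pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1) ]
           / [ pa(1-pb) + pb(1-pa) ]

with p the alternate-allele frequency and n the called haploid copies in
each pool. Hudson's form is the default because it is well behaved
per-site, unbiased under unequal sample sizes, and exactly 1 at a fixed
difference with complete data — the d-site definition only needs a
monotone, bounded per-site measure. A Weir–Cockerham variance-components
estimator is available behind `estimator="weir_cockerham"` for concordance
checks. Sites where either pool falls below the call-rate floor (default
80% of the pool's maximum copy number) are not scored; negative estimates
are kept (they are informative about sampling noise) and only clamped into
the lowest bin when the spectrum is histogrammed. A **d-site** is a site
with F<sub>ST</sub> strictly above the threshold (default 0.8).

### Site classification

At each d-site the species-diagnostic alleles are the majority alleles of
the two allopatric panels; sites with coincident majorities or an exact
50/50 tie are dropped and logged. The i-allele count of a sympatric pool
is the number of copies of the *other* species' diagnostic allele among
its called genomes. With occurrence threshold n (default 8) and reciprocal
ceiling 1:

* `i_m1`: count in m1 ≥ n and count in s1 ≤ 1;
* `i_s1`: the mirror image;
* `j`: both counts ≤ 1;
* `undefined`: everything else.

The asymmetry requirement guards against remnant shared ancestral
polymorphism masquerading as introgression. Classification additionally
requires at least n called copies in *both* sympatric pools; otherwise the
site is `undefined`. The rationale: a low count backed by few called
copies is missing data, not evidence of absence, and must not create
j-sites (or reciprocal-ceiling passes) out of gaps in coverage. This
guard preserves monotonicity — the i-site set at n = 8 is a subset of the
set at n = 2 — and classification is a pure function of
(count_m1, count_s1, called copies, n, ceiling), so the emitted table is
self-reproducing.

### Blocks

A block of one class is a maximal run of consecutive same-class sites
along the d-site sequence of a contig. Any d-site of a different class
interrupts a run — including `undefined` sites; treating every non-member
d-site as an interrupter is the conservative reading, since an undefined
site is positive evidence that the run's homogeneity is unverified there.
The physical boundary on each side is floor((a+b)/2) between the outermost
member site and the nearest interrupting d-site; floor rounding is
deterministic and sub-bp precision is meaningless. Where no flanking
d-site exists (contig edge), the boundary falls back to the member site
itself rather than the contig end, to avoid inflating blocks with
unassayed sequence. Singleton blocks (one member site) are flagged;
headline i-block statistics exclude them by default, and j-block
summaries report both the "≥ 1 site" and "≥ 2 sites" variants.

### Supporting statistics

* D<sub>xy</sub>: per variant site pa(1−pb)+pb(1−pa), normalized by an
  explicit `accessible_length` — the accessible-genome definition is an
  input, not a guess, because genome-wide per-site values depend entirely
  on it.
* θ<sub>π</sub> per Kb: 1000·Σ 2p(1−p)·n/(n−1) / L.
  θ<sub>w</sub> per Kb: 1000·S/(a<sub>n−1</sub>·L) with
  a<sub>k</sub> = Σ<sub>i≤k</sub> 1/i and n the nominal haploid pool size
  (2 × diploids; per-site missingness is not corrected in the harmonic
  number).
* Patterson's D over a (((P1,P2),P3),O) genealogy:
  Σ(ABBA−BABA)/Σ(ABBA+BABA) on frequencies polarized so the outgroup
  major allele is ancestral; sites with outgroup frequency in (0.2, 0.8)
  are unpolarizable and excluded. Significance by a *weighted* delete-one
  block jackknife (blocks weighted by their ABBA+BABA mass) over
  contiguous genomic blocks, 1 Mb by default. Two practical cautions,
  both verified in the calibration test: blocks must comfortably exceed
  the scale over which genealogies are correlated — within a single short
  region the D signal stays correlated far beyond the LD scale of
  individual sites, and sub-scale blocks understate the SE — and a
  handful of blocks or a handful of informative sites leaves the
  studentized Z heavy-tailed. The null-calibration test therefore
  jackknifes over 20 independently simulated contigs per replicate.
* Modified f<sub>d</sub>: the ABBA−BABA numerator divided by the same
  numerator with the donor frequency max(p2, p3) substituted for both
  P2 and P3 — the expected numerator under complete sharing — reported
  only for windows with D > 0, and NaN otherwise.
* LD decay: squared Pearson correlation of unphased 0/1/2 genotype
  vectors over samples called at both sites, for intra-contig pairs up to
  300 kb (default), averaged in 1 kb distance bins. Empty bins are
  reported as missing, never zero-filled.

## The synthetic-data generators

### Forward secondary-contact simulator

`simulate_rsb` models the recurrent-hybridization-with-selection picture
of speciation with gene flow. Each sympatric deme is a Wright–Fisher
population of N diploids (default 200). Per generation: (1) a
Poisson-sampled number of residents is replaced by pure migrants of the
other species — continuous rate m and episodic pulses compose; (2)
offspring are formed from uniformly drawn parents; (3) each gamete
receives Poisson(genetic length) crossovers placed uniformly on a linear
physical↔genetic map; (4) offspring survive viability selection with
multiplicative fitness (1−s) per heterospecific copy at each speciation
locus. Allopatric demes receive no migrants; since mutation is off and
drift cannot change pure ancestry, they are emitted as fixed individuals.

Ancestry is tracked as integer junction lists per haplotype
(piecewise-constant donor labels), so marker genotypes are generated only
at output and the donor tracts of every sampled haplotype are exact by
construction: species M is fixed for the reference allele and species S
for the alternate at every marker, making each marker a fully divergent
d-site in allopatry. Identical parameters and seed give byte-identical
output.

The simulator reproduces the Markovian junction-theory expectation for
single-pulse admixture — exponential tract lengths with mean
1/((1−f)T) Morgans — within a few percent when drift is weak (verified at
N = 1000–2000). At small N two finite-population effects lengthen tracts
beyond this: junctions are lost by coalescence, and drift makes local
ancestry clumpy, which suppresses new junction formation where ancestry
is concentrated. At N = 200, f = 0.1, T = 50 the mean tract length is
about 1.2× the idealized 1/T — worth remembering when the idealized
formula is used as a yardstick.

### Tract planting

`plant_tracts` generates the exact-ground-truth configuration for
recovery tests: markers on a regular grid (default study condition:
500 bp spacing), 100 disjoint tracts with exponential lengths (mean
5 kb) copied onto 9 of the 10 target-pool haplotypes, and optional
independent symmetric per-call miscalls. Tracts keep one marker spacing
clear of contig ends: a tract boundary beyond the outermost marker is
not localizable by the midpoint rule, so nothing can be claimed about it.
With the marker grid, every recovered block boundary is guaranteed within
half the local inter-marker spacing of the true tract boundary, and the
recovery tests assert exactly that.

### Neutral coalescent scenarios

Where mutation and deep history matter and ancestry tracking does not,
the generators delegate to msprime:

* `simulate_neutral_panmictic` (n = 10 diploids, N<sub>e</sub> = 10⁴,
  500 kb, μ = r = 10⁻⁸): calibration check that θ<sub>π</sub> ≈
  θ<sub>w</sub> within 3 jackknife SEs.
* `simulate_species_pair` (N<sub>e</sub> = 2×10⁴ per deme, split 4×10⁵
  generations ago, 500 kb): with no contact, the allopatric F_ST spectrum
  between the two samples is U-shaped — abundant fixed differences from
  the deep split at the top, abundant low-frequency private variation at
  the bottom, little in between. Adding secondary-contact migration
  yields the admixed high-diversity deme used as the sympatric LD case.
* LD contrast: the allopatric control is a small isolated population
  (N<sub>e</sub> = 5000, mirroring the low diversity of the real
  allopatric panels), whose drift sustains long-range LD; the admixed
  deme (large N<sub>e</sub>, long-standing migration) holds far more
  diversity and long-recombined ancestry, so its r² decay curve sits
  lower beyond 10 kb. "Decays faster" is measured as the mean r² over
  the 10–100 kb tail of the curve, which is robust to the bin
  quantization that makes a single threshold-crossing distance tie.

The L-shaped sympatric spectrum is produced by the forward simulator
itself (continuous bidirectional migration m = 0.01 for 100 generations
homogenizes most divergent markers), matching how the sympatric pair is
actually compared in the scan.

### Selection-islet study condition

The islet demonstration uses s = 0.5 at one locus, a single f = 0.1 pulse,
T = 100 generations, N = 200 diploids, and a genome of 4 chromosomes ×
2 Morgans (2 Mb each) with the locus mid-chromosome-1 — enough unlinked
genome that selective drag leaves the rest of the genome measurably
introgressed while the locus itself is purged. The reported
"genome-wide introgressed ancestry" is the genome-averaged heterospecific
ancestry fraction of the full deme, and its median is taken over
replicates; a per-position median within a replicate would be dominated
by drift losses under a single small pulse and says little about the
islet contrast. Note the purge is strong: the pulse's whole-genome
association with the selected allele costs roughly two thirds of the
introgressed material before recombination frees it.

## Numerical and degenerate-input choices

* Frequencies at sites with zero called copies are NaN ("undefined"),
  never 0; they propagate as unscored.
* F_ST denominator 0 (both pools monomorphic for the same allele) →
  unscored, not 0 or ±inf.
* Patterson's D with Σ(ABBA+BABA) = 0 → NaN, with SE/Z NaN when fewer
  than two jackknife blocks carry signal.
* r² pairs with a zero-variance member are skipped, not zeroed.
* Midpoint rounding is floor; ties in diagnostic-allele majorities drop
  the site rather than guessing.
* The extinction guard in the forward simulator aborts a generation after
  2000·N consecutive viability rejections with an error advising weaker
  selection.

## Problem sizes

The validation suite runs at the study conditions stated above: 1000
random site tables for the scanner-oracle equivalence; 10⁴ random
frequency pairs for the estimator closed form; 100 planted tracts at
500 bp marker spacing; 20 replicates of the neutral-pulse tract-length
check and 50 of the selection islet; single seeds for the qualitative
spectrum, diversity and LD contrasts; 100 replicates of 20 independent
contigs (in rescaled coalescent units, N<sub>e</sub> = 1000,
μ = r = 10⁻⁷) for the null-D calibration. `scripts/acceptance.py`
recomputes the same quantities with 10 and 20 simulator replicates for
the two replicate-based checks.

## Known limitations

* The scan is site/occupancy-based; it does not phase haplotypes and
  does not model genotyping error beyond the call-rate filter.
* θ<sub>w</sub> uses the nominal pool size in the harmonic number, which
  slightly overestimates the normalizer under heavy missingness.
* The forward simulator is not a coalescent engine: allopatric panels
  are emitted as fixed (no within-species polymorphism unless the
  msprime generators are used), and mutation is off by default because
  the d-site structure, not diversity, is the object of study.
* Gene-overlap counting is coordinate overlap only; no functional
  annotation.
* Real data will include structural variation, mapping artifacts and
  population structure within panels that the generators do not emulate;
  passing tests demonstrate correctness of the scan's logic and its
  recovery behaviour under the stated models, not robustness to every
  property of real resequencing data.
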