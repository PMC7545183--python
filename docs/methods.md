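# Methods

## The scans and their estimators

**Windowed F_ST.** Per biallelic site the two-population Weir–Cockerham
(1984) variance components are computed from per-group sample sizes
(non-missing diploid calls), allele frequencies and observed
heterozygosity: *a* (among populations), *b* (among individuals within
populations), *c* (within individuals).  A window's value is the
ratio-of-sums Σa / Σ(a+b+c) over its usable sites — the "weighted"
windowed estimator reported by the standard VCF scan tools.  Sites
monomorphic in the pooled sample, callable in only one group, or with a
pooled sample of a single individual are skipped; windows with no usable
site are missing.  Negative window values are reported, not clamped:
they are informative about estimator noise near zero differentiation.

**Nucleotide diversity.** Per site, expected pairwise differences are
x(n−x)/C(n,2) with x the alternate-allele count among n called alleles;
a window's π divides the per-site sum by the window length in bp, so
monomorphic and uncalled positions dilute π exactly as in the standard
windowed estimators.  The Pi-ratio contrasts the domesticated over the
de-domesticated group (π_DO/π_DE) and is undefined where π_DE = 0.

**Candidate regions.** Thresholds are the empirical 95th percentile of
window values, computed separately for the A&B-subgenome windows and the
D-subgenome windows: tetraploid introgression inflates A&B
differentiation, so a joint threshold would be dominated by one set.

**Permutation null.** Group labels are shuffled jointly over the union
of the two groups with group sizes preserved — samples, not windows, are
the exchangeable units — the genome-wide windowed scan is recomputed,
and the per-partition maximum recorded; 100 replicates by default.  The
observed maximum of an undifferentiated cohort is one more draw from
this null, so it falls inside the 100-replicate range with probability
≈ 99/101 per partition.

**Effective size.** Ne = θ/(4μL) with defaults μ = 6.5×10⁻⁹ per site
per generation and generation time L = 1 year (the conventional wheat
settings).  θ is an input: it comes from the site-frequency spectrum of
the neutral marker set, whose construction is out of scope here.

## Depth statistics

All depth work uses the Normalized Coverage Number, NCN = window mean
depth / genome-wide mean depth per sample, which cancels library size.
PAV calling selects 5 kb windows with self-NCN > 0.8 and other-NCN
< 0.2 (both strict, as printed) and merges selected windows whose gap is
strictly below 10 kb — a gap of exactly 10,000 bp is not merged.  Gene
calls apply the same rule to the gene's base-weighted mean NCN computed
from overlapping windows.  The CNV-index per 100 kb window is mean
NCN(DO) − mean NCN(DE); positive values mean more deletion carriers in
the de-domesticated group by construction.  Per-sample deletion
genotyping reuses the 0.8/0.2 pair on the regional mean NCN — the
regional thresholds are not separately published, so the PAV pair is a
declared package choice — and keeps an explicit `unknown` band rather
than forcing binary calls.

## TE insertion genotyping

Rules are evaluated in a fixed order.  Rule 1: at least two reads
spanning the site with a perfect reference match across the spanning
window → non-insertion.  Rule 2: a soft-clipped read whose clip matches
the TE at 100% identity over more than 10 bp (strict: a 10 bp match is
insufficient) → insertion.  Anything else → unknown.  Two quantities
the published rules leave open are fixed here as declared choices: the
"perfect match" spanning window is site ± 5 bp (mismatches elsewhere in
the read are tolerated), and the clip boundary must fall within 2 bp of
the site.  Clip matching tests both TE strands, so reverse-complemented
evidence classifies identically.  When a sample satisfies both rules,
Rule 1 wins per the stated order and the conflict is flagged on the
call.

## Haplotypes

Gene haplotypes are strings over {ref base, alt base, N} from the
homozygous dosages at SNPs in the gene interval; heterozygous calls
become N (inbred-panel assumption; the alternative of dropping such
samples is a flag).  Samples with more than 50% missing symbols and
genes with fewer than 2 sites are discarded — the published criterion is
only "enough sites / well covered", so these defaults are package
choices.  A haplotype is HA-adapted when it carries a missense alternate
allele and its HA-group frequency strictly exceeds its LA-group
frequency; equal frequencies or absence from both groups leave it
unclassified.  Missense sites are an input list; codon-level effect
prediction is out of scope.

## Mixed-model association

The marker model is y = Wα + xβ + u + ε, u ~ N(0, σ²g K) with VanRaden
kinship K = ZZ'/Σ2p(1−p) on mean-imputed dosages and PC covariates from
the standardized dosage matrix (signs fixed by forcing each component's
largest-magnitude loading positive).  Variance components are estimated
once by REML under the null and reused for every marker (the
P3D/EMMAX approximation; the published tool's internals are not
specified, and at panel scale the approximation is the standard
practice).  Each marker is then a GLS t-test in the eigenspace of K;
with K = I and no covariates this reduces exactly to OLS, which the
tests verify to 1e-8.  Binary phenotypes use the linear model, as the
panel tools do.  Variance explained is the GLS partial R²,
(RSS_null − RSS_marker)/RSS_null — the published variance-explained
formula is unstated, so the package's percentages are this definition
and not comparable to other definitions.  Structural variants enter as
pseudo-genotypes (presence → 1/1, absence → 0/0, unknown → ./.), and
chromosome-local confounding is absorbed by concatenating local-PC and
global-PC covariates with collinear columns dropped.

## Scaffold anchoring

Probe pairs are two 500 bp mates cut every 1000 bp; "insertion size
500 bp" is read as mate-to-mate spacing, so one pair spans 1000 bp
(the alternative outer-gap reading, span 1500 bp, is available via
`span_mode="outer"`).  Reads map by unique exact substring match on
either strand — at desk scale this plays the role of the external
aligner.  A scaffold goes to the chromosome with most mapped reads;
fewer than 22 reads on the best chromosome → chrUn (ties break
lexicographically and are logged).  "Continuously aligned" is ≥5
consecutive probe positions on the same chromosome and strand with
reference positions advancing monotonically within 2× the step; the
first and last such runs give the position key (mean of the two run
means) and the direction.  Pseudomolecules join ordered, oriented
scaffolds with 300 bp N gaps, with an AGP v2.1 table consistent with the
FASTA; chrUn concatenates unplaced scaffolds the same way.

## Synthetic worlds: what they emulate and what they do not

The generator reproduces the *structure* of a resequencing study: a
de-domesticated group of 50 versus a domesticated group of 52 (the
default group sizes), near-homozygous genotypes (2% heterozygosity —
wheat is selfing), 2% missing calls, allele frequencies from a uniform
prior on [0.05, 0.95], and divergent windows where the two group
frequencies are p(1−δ) and p(1−δ)+δ, making the between-group difference
exactly δ.  Depth is Poisson at the read-count level: window reads ~
Poisson(cov × window/read-length × copy), the simplest count model with
the right mean scaling; 150 bp reads and 10× coverage by default.  TE
evidence is noise-free by construction (clips are exact TE substrings).
Scaffold worlds use uniform-random sequence, which makes 500 bp probes
essentially always unique.

Not emulated: linkage disequilibrium (sites are independent draws, so
LD-pruning behaviour on realistic haplotype structure is only exercised
on constructed correlated toys), sequencing error in reads, mapping
bias, GC-dependent coverage, or real wheat sequence.  Passing tests
therefore demonstrate correctness of the estimators and decision rules
under the stated noise models, not robustness to alignment artefacts.

## Numerical choices and problem sizes

Scan benchmarks use 2×50 samples, 5,000 sites over two 2.5 Mb
chromosomes (~100 sites per 100 kb window), one δ = 0.8 window, 20
cohort replicates and 100 permutations — large enough for stable top-5%
thresholds while keeping the full suite around a minute.  REML optimizes
log(σ²e/σ²g) on [−10, 10] by bounded scalar minimization; non-PSD
kinship is ridged by the smallest amount restoring PSD and logged.
Pairwise r² uses pairwise-complete observations and treats constant
vectors as r² = 0; pruning is greedy left-to-right within a 50-site
window, keeping the earlier site, which makes output deterministic.  The
published pruning phrase is ambiguous as written; the conventional
reading (remove one of any pair with r² ≥ 0.4) is implemented.
Filters: MAF keeps sites ≥ threshold; missingness is strict "<" for the
association-panel rule (30%) and "≤" available for the discovery rule
(40%).  All randomness flows from explicit integer seeds;
pipeline stages receive children of one global seed via SeedSequence, so
identical seeds give byte-identical outputs and manifests.

## Known limitations

- Two populations only for F_ST; no haplotype-based selection statistics.
- The P3D approximation understates per-marker variance-component
  uncertainty; exact per-marker REML is not implemented.
- Breakpoint-resolution SV calling, genome-scale alignment, phasing and
  imputation are out of scope; the probe-read matcher requires exact
  substring identity and is not a general aligner.
- The variance-explained percentages depend on the partial-R²
  definition above and on the covariates supplied.
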