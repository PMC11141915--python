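# Methods

## Generative model (karyosim)

A patient is a rooted clone tree. The root is the diploid germline; each
edge carries an ordered event list: whole-chromosome monosomies, driver
point mutations, optionally a whole-genome doubling (WGD), and post-WGD
arm gains. Passenger mutations are drawn per edge with Poisson counts
(separately for nonsynonymous and synonymous classes), positions uniform
over chromosomes weighted by length × current copy number, and uniform
times along the edge; on a WGD edge, passengers with time below `wgd_time`
(default 0.5) — and all inherited mutations and drivers — double in
multiplicity, which is the zygosity signal the timing module exploits.
Monosomies remove the paternal homolog; a WGD doubles both parental
counts; arm gains add one copy of the retained/major haplotype.

The genome is abstract: 22 autosomes with lengths proportional to the
human assembly (units ≈ Mb), fixed p-arm fractions and, by default, 500
evenly spaced germline-heterozygous SNP sites per chromosome. Real arm and
gene tables can be substituted; inference nowhere depends on true hg38
coordinates.

Observation model per region (purity ρ, nominal coverage c): tumor depth
at a site is Poisson with mean c·(ρ·C + 2(1−ρ))/2 (depth proportional to
local DNA content, normalized to a diploid average), normal depth is
Poisson(c); allele counts are binomial at the mixture-expected B-allele
fraction or VAF. The B-allele's parental origin is drawn once per site per
patient, so allelic imbalance is phase-consistent across regions. A
symmetric per-read error rate is available and defaults to 0. One master
seed drives everything; per-region streams are derived by stable hashing,
so adding a region never perturbs existing regions and identical seeds
give bit-identical datasets.

### Default scenario

The default two-clone scenario encodes the canonical aggressive-ChRCC
progression: a classic clone with monosomies {1, 2, 6, 10, 13, 17, 21}
(chromosome 21 is included deterministically; it is configurable) and a
hemizygous TP53-like driver on 17p, then a dedifferentiated child that
acquires a PTEN-like driver on monosomic chromosome 10 and undergoes WGD,
followed by gains of 1q and chromosome 7. Branch rates default to 28
nonsynonymous trunk mutations and 12 extra on the dedifferentiation
branch, so classic samples carry ~28 and dedifferentiated samples ~40.

The post-WGD gains matter beyond realism (dedifferentiated ChRCC genomes
show gains beyond two copies): a genome whose copy numbers are *all even*
is mathematically indistinguishable from its halved version at a remapped
purity — substituting ρ′ = 2ρ/(1+ρ) and halving every copy number leaves
expected logR and logOR exactly invariant. Odd-copy segments break this
halving symmetry and make the WGD state identifiable from copy-number data
alone, exactly as in real WGD tumors, which are never perfect doublings.

### What the simulator does not emulate

No read-level artifacts (mappability, GC bias, FFPE damage), no subclonal
copy number within a region beyond explicit clone mixtures, no
chromosome-level noise in SNP spacing, no X/Y. Passing tests therefore
demonstrate correctness of the inference logic under the stated
statistical model, not robustness to every artifact of real exome data.

## Allele-specific copy number (ascn)

Per-site statistics: logR = log2[(t/n)·(Σn/Σt)] (library-size
normalized), logOR = Haldane-corrected natural-log allelic odds ratio of
tumor vs normal. Sites with normal depth < 10 are dropped.

Segmentation is recursive binary splitting per chromosome on the
bivariate series (logR, |logOR|): the candidate split maximizes the sum of
the two pooled two-sample t² statistics and is accepted above a critical
value; minimum segment 8 sites. Two passes: coarse (critical 60) for the
purity/ploidy fit, fine (critical 35) for the reported segments. The
criticals were calibrated on flat-noise simulations (σ = 0.05, 500 sites)
to a ≤ 5 % whole-genome false-split rate; at these values the observed
rate is 0/100 and a −1 logR step is localized exactly.

Segment allelic imbalance is summarized as
lor = sqrt(max(mean(logOR²) − mean(v), 0)), where v is the delta-method
read-count variance per site — folding |logOR| directly is upward-biased
at balanced states, and this debiased magnitude estimates the latent
|log-odds| on the same scale as the model prediction |ln(b/(1−b))| with
b the expected BAF. Model log-odds are capped at 4.0 (complete imbalance
is finite in data because of the Haldane correction).

The grid fit scans purity 0.05–1.00 (step 0.01) × diploid-logR offset
−1.6–1.6 (step 0.02); each segment takes the integer (major, minor) pair
(total ≤ cn_max = 8; boundary fits flagged) minimizing squared distance in
(logR, lor); the residual is length-weighted. Selection among per-purity
candidates adds a parsimony penalty of `cn_penalty` (default 0.001) per
ploidy unit, applied **only** at the candidate level — per-segment
assignments are unpenalized, so focal aberrations are not shrunk. The
penalty resolves the purity/ploidy ladder (integer rescalings of the whole
genome with remapped purity, which differ in residual only through noise)
toward the least-amplified explanation, and also prevents closely spaced
high-copy states at low purity from overfitting logOR noise. Candidates
with ploidy < 1 are rejected as unphysical; exact ties go to higher
purity; the offset is refined in closed form for the chosen assignment.
A fit in which every segment lands in a single state (e.g. a pure normal)
is flagged low-confidence; fitted purity < 0.3 flags the sample excluded.
Reported ploidy is the length-weighted mean total copy number, labeled as
such.

Calls: WGD when ≥ 50 % (inclusive) of autosomal length has major copy
≥ 2; arm gain/loss when > 50 % (strict) of the arm is above/below
baseline 2 — baseline is 2 regardless of sample ploidy, so hypodiploid
monosomies count as losses; genes inherit the copy number of their
containing fine-pass segment, with larger-overlap and then
farther-from-baseline tie-breaks for breakpoint-spanning genes, and the
applied rule is recorded per gene. Paired differential gene copy number
uses a two-tailed paired t-test with Benjamini–Hochberg adjustment and a
mean fold-change ≥ 2 requirement; a gene identical in every pair is not
testable, while a constant nonzero difference is degenerate-significant
(p = 0), a case scipy reports as NaN and the implementation handles
explicitly.

## Mutation timing (timing)

Somatic calls require VAF ≥ 0.15 (boundary retained) and nonsynonymous
annotation; TMB is the retained count. Multiplicity inverts the VAF model,
m̂ = VAF·(ρ·C + 2(1−ρ))/ρ, rounded and clamped to [1, C]; m̂ < 0.75 flags
subclonal, which removes the variant from timing evidence (drivers are
assumed clonal; the guard protects against simulated edge cases).
Zygosity: total copy 1 → hemizygous (LOH); minor 0 with m = C ≥ 2 →
homozygous; otherwise heterozygous. Ordering per driver across a
patient's samples: homozygous on a minor-0 chromosome in a WGD-positive
sample ⇒ before duplication (whether or not the mutation is also seen
hemizygous pre-WGD); m = 1 on a duplicated chromosome ⇒ after;
contradictory samples collapse to unordered with a conflict note;
homozygosity at C > 2 is accepted but marked extrapolated. Samples with
fitted purity < 0.3 contribute no evidence. The mutation log odds
ln[(alt+0.5)/(ref+0.5)] is a declared convention for overlaying somatic
mutations on B-allele plots; it equals the segment |logOR| only in a pure
tumor, since normal cells contribute reference reads at somatic sites but
both alleles at germline SNPs.

## Phylogeny (phylo)

Mutations are grouped by their presence pattern (the subset of samples
passing the somatic filter). A laminar pattern family is exactly a rooted
containment tree; crossing patterns are detected pairwise (the two-state
analogue of the three-gamete test) and resolved by the documented
*drop-min* policy: iteratively remove the conflicting pattern with the
fewest mutations (ties: smaller pattern, then lexical), logging removals.
This containment construction is this package's formalization of what is
done by hand in practice. Branch length = pattern mutation count; the sum
of branch lengths equals the number of distinct retained mutations minus
dropped ones, asserted exactly. Samples attach under the smallest
containing pattern; the root is the all-sample (MRCA) pattern, created
with length 0 when no mutation is fully shared. Arm-level CN events and
WGD are annotated on the MRCA branch of their carrier samples; when the
carriers do not form a clade the event attaches to the deepest branch
containing all carriers, with a warning — a convention, since no
placement is uniquely implied. Newick export carries attributes both as
`[&…]` comments and in a JSON sidecar; re-import (structure via dendropy,
attributes via sidecar) is lossless.

## Scores (scores)

H-score = integer intensity (0–3) × percent positive (0–100), range
0–300; p53 positivity is strict H > 10. logCPM follows the voom
convention log2[(count + 0.5)/(libsize + 1)·10⁶]. The T effector score is
the mean logCPM over the signature genes present in the matrix; the
signature list is user-supplied (the published list is an external
resource), and absent genes are reported rather than silently dropped.

## Problem sizes

The validation suites use 50 simulated two-region patients (purity
cycling 0.4/0.6/0.8, coverage 100, 500 SNP sites per chromosome), 10
seeds × 3 purities for copy-number recovery, 100 flat-noise genomes and
20 step genomes for segmentation, 5 four-region patients for topology
recovery, and 20 runs × 1000 genes × 6 pairs for differential copy
number — sizes at which every recovery statistic is stable while the full
suite runs in well under a minute.

## Known limitations

Purity and ploidy are reported at grid resolution (0.01); subclonal
(fractional) copy number is out of scope; the WGD call follows the ≥ 50 %
major-copy rule and will miss doublings followed by extensive loss; a
genuinely perfect all-even doubling with no odd-copy segment is
unidentifiable from copy-number data alone (see the ladder discussion)
and would be reported at the lower rung; timing gives point verdicts, not
probabilistic estimates with confidence intervals.
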