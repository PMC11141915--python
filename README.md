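# chromoevo

Multiregion tumor-genomics toolkit for the chromophobe renal cell carcinoma
(ChRCC) dedifferentiation problem: allele-specific somatic copy number,
mutation timing relative to whole-genome doubling (WGD), and per-patient
clone phylogenies — exercised against a built-in clonal-evolution simulator
with full generating truth, so the entire inference stack is testable
without access-controlled patient data.

## The scientific problem

Classic ChRCC is characteristically *hypodiploid*: tumors carry monosomies
of chromosomes 1, 2, 6, 10, 13, 17 and 21. A minority of tumors progress to
an aggressive dedifferentiated state that metastasizes. The genomic
signature of that transition is a sequence of events — an early *TP53*
mutation (hemizygous, because chromosome 17 has a single copy), sometimes a
*PTEN* mutation, then duplication of the remaining chromosomes (WGD). After
WGD a pre-existing hemizygous mutation sits on **both** copies of its
chromosome: total copy number 2, minor copy number 0, multiplicity 2 —
homozygous. A mutation acquired after WGD sits on one copy of two. Zygosity
therefore orders mutations against genome doubling.

The package implements that chain of reasoning end to end:

- **karyosim** — forward simulator: clone trees with monosomies, drivers,
  WGD and post-WGD arm gains; multiregion sampling at chosen purity and
  coverage; Poisson depths and binomial allele counts; full truth emitted.
- **ascn** — per-SNP logR/logOR statistics, two-pass (coarse→fine)
  recursive binary segmentation, and a joint purity/ploidy/integer
  allele-specific copy-number grid fit, with WGD, arm-level and gene-level
  calls plus paired differential gene copy number (BH-adjusted t-tests).
- **timing** — somatic-call filter (VAF ≥ 15 %, nonsynonymous), mutation
  burden (TMB), mutation log odds, multiplicity m̂ = VAF·(ρ·C + 2(1−ρ))/ρ,
  zygosity classification and pre/post-WGD ordering.
- **phylo** — containment phylogenies over binary mutation-presence
  patterns, branch lengths = mutation counts, driver/CN/WGD annotation,
  Newick + JSON export.
- **scores** — IHC H-score (intensity 0–3 × percent positive, threshold
  H > 10 for p53 positivity), voom-convention logCPM and the T effector
  expression score.

Key model formulas (ρ purity, C total copy number, m multiplicity, ψ
ploidy, M/m major/minor copies):

```
VAF  = ρ·f·m / (ρ·C + 2(1−ρ))                       f = clone fraction
BAF  = (ρ·M + (1−ρ)) / (ρ·(M+m̲) + 2(1−ρ))
logR = log2[(ρ·C + 2(1−ρ)) / (ρ·ψ + 2(1−ρ))]
```

## Worked example

```
chromoevo report --seed 7 --out out/
```

runs simulate → fit-cn → time-events → build-tree on the default
two-region patient (classic + dedifferentiated, purity 0.7, coverage 100)
and prints the summary, which for seed 7 reads (abridged):

```json
{
 "samples": {
  "R1_classic": {"purity": 0.7, "ploidy": 1.638, "wgd": false},
  "R2_dediff":  {"purity": 0.7, "ploidy": 3.375, "wgd": true}
 },
 "timing": {
  "PTENL": "mutation_before_duplication",
  "TP53L": "mutation_before_duplication"
 },
 "tmb": {"by_sample": {"R1_classic": 27, "R2_dediff": 40}}
}
```

Reading: the classic region is hypodiploid (ploidy 1.64 — seven
monosomies), the dedifferentiated region has doubled (ploidy 3.38, WGD
flag set because ≥ 50 % of the autosomal genome has major copy number
≥ 2), both drivers are called *before* the duplication (they are
homozygous on minor-copy-0 chromosomes in the WGD sample), and the
dedifferentiated sample carries the higher mutation burden. `out/`
additionally contains the SEG table, the arm-level gain/loss matrix, the
timing table with evidence, and the annotated Newick tree with its JSON
sidecar.

The same stages are available as library calls (`karyosim.simulate_scenario`,
`ascn.fit_cn`, `timing.order_events`, `phylo.build_tree`, …) and as the
CLI verbs `simulate`, `fit-cn`, `time-events`, `build-tree`, `score`,
`report`.

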