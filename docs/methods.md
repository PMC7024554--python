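# Methods

This note documents the quantitative procedures implemented in
`magdissect`, the defaults of the synthetic-community generator, and the
design choices made where the underlying conventions were genuinely open.

## Abundance from DNA coverage

The per-contig fold-coverage is `reads × read_length / contig_length`.
A MAG's average coverage is the **length-weighted** mean over its contigs,
algebraically `read_length × Σ counts / Σ lengths`; an unweighted mean
would let short contigs dominate. Relative abundance divides each MAG's
average coverage by the per-sample sum over all binned MAGs, so columns
are probability vectors (enforced to 1 ± 1e-9 in tests, achieved at
machine precision). Unbinned contigs (MAG id `-`) are excluded from
per-MAG statistics but retained in library-level totals.

Degenerate case: a sample where every MAG has zero coverage has no defined
composition; the column is reported NA with a warning rather than
silently renormalized.

Quality tiers use the MIMAG completeness/contamination thresholds — high:
completeness > 90 and contamination < 5 (both strict); medium:
completeness ≥ 50 (inclusive) and contamination < 10; low otherwise.
rRNA/tRNA inventory criteria are not evaluated because the inputs carry no
RNA-gene annotation. Tier membership never affects the abundance
denominator: composition is over all binned MAGs.

## Activity from RNA

RPKM is `count × 10⁹ / (gene_length × total_mapped)` with `total_mapped`
the sum of RNA counts over **all** genes in the sample, including genes on
unbinned contigs. A per-MAG denominator would make activities
incomparable across genomes; a library-level one is what makes the
relative-activity simplex meaningful. A MAG's activity is the unweighted
arithmetic mean RPKM over all of its protein-coding genes with zeros
included — dropping silent genes would inflate sparsely expressed
genomes and break conservation. Relative activity normalizes per sample
exactly as abundance does. The RNA/DNA ratio is relative activity /
relative abundance, NA where abundance is zero (an abundance-0 MAG with
positive activity is flagged as an inconsistent input pair).

No gene-length floor is applied; genes shorter than the read length are
retained as annotated.

## Process allocation

For a process with signature family F, a carrier MAG's share in sample s
is `Σ RPKM of its F genes / Σ RPKM of all F genes in s`. Multi-copy
families within a MAG are **summed**, not averaged — the process signal is
the family's total transcript output. The default catalog is
methanogenesis → {mcrA} (alpha subunit only; other mcr subunits are
ignored), acetate_uptake → {ack, acs} (pooled, with per-route subtotals),
syntrophy_flag → {fhs}, glycine_cleavage → {gcvP}; symbols match
case-insensitively and the catalog is user-replaceable via a
`process  symbol` table. Shares are ratios of same-sample RPKM values, so
they are invariant under any uniform scaling of a sample's counts.
A sample with zero total signature expression yields NA shares with a
warning; a community with no annotated signature gene at all is an error.

The syntrophy flag defaults to RPKM > 0 (configurable threshold); no
published cutoff exists for "expressed fhs", so the permissive default is
declared rather than inferred.

CH₄ anchoring: `normalize_expression` multiplies every gene's RPKM in
sample s by `ch4_rate(s) / Σ mcrA RPKM(s)`. This is the simplest
transform that ties the methanogenesis marker to the measured process
rate, making cross-sample expression comparable in process units; by
construction the normalized mcrA total equals the CH₄ rate exactly, which
the tests assert at machine precision.

## KEGG modules, the expression filter, auxotrophy

Module activity is the arithmetic mean RPKM over a MAG's genes annotated
to the module; pairs with no member gene are absent, not zero (presence
semantics). The coverage-normalized variant divides by the MAG's average
coverage in the sample — transcription per genome copy rather than per
community. A configurable minimum member-gene fraction (default 0) can
suppress sparsely annotated pairs.

"Highly expressed" genes are those at or above the median RPKM of the
genome's *expressed* (RPKM > 0 strictly) genes in that sample; the median
uses the even-count midpoint average and the boundary is inclusive, so at
least ⌈n/2⌉ of the expressed genes always pass. These conventions are
fixed here for determinism.

An auxotrophy candidate is a (MAG, module) pair where the MAG lacks the
module or never expresses it in any sample, while ≥ 1 other MAG expresses
it; the expressers are reported as potential cross-feeders. Modules
expressed by no MAG are excluded — a community-wide absence cannot be
distinguished from an annotation gap.

## Reporting

Group fractions are sums of member-MAG fractions. The correlation of a
group metric with the CH₄ production rate is the squared Pearson
coefficient over **steady-state** samples only (the `steady` column of
`samples.tsv`, inferred from the timepoint label when absent): the
transitional sample right after a perturbation mixes adaptation states.
Constant inputs return NA; fewer than 3 pairs is an error.

Shift tables compare consecutive timepoints per MAG: replicate means, a
log2 ratio with pseudo-fraction ε = 1e-6 (keeps zero fractions finite
while leaving 4-decimal reporting stable), and a two-sided Welch t-test
across replicate reactors. Reactors are independent biological
replicates, hence Welch rather than a paired test; no multiplicity
correction is applied because the p-values are descriptive, not an
inference procedure.

## The synthetic community generator

The generator emulates the study design the package targets: **79 MAGs**
(5 archaeal methanogens) over **9 samples** = 3 timepoints (before H₂
addition, shortly after, long after) × 3 replicate reactors. Default CH₄
production rates are ~300 / ~350 / ~410 mL CH₄ (L·d)⁻¹ per timepoint
(± 5 reactor-to-reactor s.d.), on the scale of an acetate-fed thermophilic
digester at an organic loading rate of 1 g (L·d)⁻¹ whose yield rises
roughly from 300 to 410 mL g⁻¹ after H₂ supplementation.

- **True abundances** are Dirichlet-distributed per sample. Bacterial
  MAGs use concentration 0.5 (strongly uneven communities, as observed in
  digesters where a dozen genomes hold most of the biomass); archaeal
  MAGs use 2.9, which puts the five methanogens near a quarter of the
  community in expectation (the observed band is roughly 19–37%).
- **DNA counts** are Poisson per contig with mean
  `abundance × mean_dna_depth × n_mags × contig_length / read_length`, so
  the community-average fold-coverage equals `mean_dna_depth` (default
  50×, read length 150 bp) and depth remains interpretable on the
  per-genome coverage scale. Genome copy number is the abundance signal;
  overdispersion is reserved for RNA, where replicate variability
  actually matters to the claims being tested.
- **RNA counts** are negative-binomial per gene (gamma–Poisson mixture,
  variance μ + d·μ²; d = 0 degenerates to Poisson) with means
  proportional to `expression_rate × gene_length`, calibrated so each
  sample's expected library size equals `mean_rna_library_size` (default
  5 × 10⁶). Default dispersion 0.3 is a typical between-replicate value
  for bulk RNA counting.
- **Expression programs**: per-gene log-normal base rates (σ = 1.2)
  with mild per-sample log-normal jitter (σ = 0.2). Non-signature
  archaeal gene rates additionally scale with the sample's CH₄ rate,
  reproducing the methanogen-activity/CH₄ coupling seen in such systems;
  because allocation shares are within-sample ratios, this leaves every
  marker recovery exact.
- **Signature genes**: each archaeal MAG carries exactly one mcrA
  (multi-copy via `mcra_copies`); ack/acs/fhs/gcvP carriers are random
  subsets (defaults 50/40/40/40% of the eligible pool — fhs in ~40% of
  bacteria mirrors communities where about half the bacteria live
  syntrophically). Per process, carrier shares are Dirichlet(1) per
  sample — or pinned via `fixed_methanogenesis_share` — and signature
  gene rates are set proportional to the share, so RPKM-ratio allocation
  recovers them.
- **Planted auxotrophies**: `planted_module` / `planted_absent_mags`
  gives every MAG except the last k one well-expressed gene of a chosen
  module, so the screen's exact recovery is testable through the public
  fixture path.

What the simulator deliberately does **not** model: sequence-level reads
(errors, GC bias), mapping ambiguity and shared contigs (no counting rule
exists for multi-mapped reads between MAGs, so counts are taken as
unambiguous), assembly/binning artifacts, and strain heterogeneity.
Passing recovery tests therefore demonstrates correctness of the
estimators given aligned-count inputs — not robustness to upstream
alignment or binning error.

## Recovery experiments and problem sizes

Estimator-recovery runs (abundance against a pinned
[0.4, 0.3, 0.15, 0.1, 0.05] truth at 2×/10×/20×/50× depth;
methanogenesis shares against [0.7, 0.2, 0.1] at 10⁶ RNA reads; both
averaged over 10 seeds) use `rna_dispersion = 0`. Dispersion models
biological replicate variability that no estimator can remove, so
recovery bands are defined over counting (Poisson) noise; the default
dispersion stays in place for all other fixtures. Recovery communities
are kept small (5–10 MAGs, tens of genes per MAG, 3 samples) — the
estimators are per-sample ratios whose error depends on counts per
entity, not on community size, and the study-scale configuration is
exercised separately by the acceptance script.

## Known limitations

- RPKM is the only expression unit; TPM/TMM/DESeq-style normalizations
  and differential-expression inference are out of scope.
- Module presence is annotation-based; KEGG module definition logic
  (boolean blocks) is not evaluated, so a single annotated member gene
  counts as presence unless a member fraction is configured.
- The CH₄ anchoring assumes mcrA transcription is proportional to
  methane flux across samples; regulatory decoupling would bias the
  normalized units but not the within-sample shares.
- Quality tiers ignore rRNA/tRNA criteria (inputs carry no RNA-gene
  inventory), so "high" here is necessary but not sufficient for the
  full genome-reporting standard.
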