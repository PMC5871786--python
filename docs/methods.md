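# Methods

## The problem being modelled

In multiplexed sequencing on ExAmp-chemistry instruments, a small fraction of
reads is assigned to the wrong co-pooled library ("index hopping"). For
tumour–normal exome pools this imports germline alleles of other individuals
into a tumour sample at low allelic fraction, where they are readily called
as somatic SNVs. `hopaudit` quantifies, for every somatic call, the variant
support in the *pool complement* — the co-multiplexed libraries from other
individuals — and uses it together with a cohort allele-frequency resource to
separate hop-derived artefacts from genuine somatic variation.

## Pool complement and PC-AF

For a call in sample *s*, the complement is every library sharing *s*'s pool
whose individual differs from *s*'s. All co-pooled libraries of the same
individual (notably the matched normal) are excluded: shared germline
variation would otherwise look like contamination support. Libraries dropped
from downstream analysis for QC reasons still belong to complements — they
remain physical contamination sources.

At the call site we sum, over complement libraries, all overlapping reads
(`pc_depth`) and those carrying the variant allele (`pc_alt`); PC-AF is their
ratio. Counts are read counts as tabulated in the pileup; overlapping mate
pairs are not collapsed into fragments. When `pc_depth < min_pc_depth`
(default 20) the PC-AF is *undefined* — an explicit state, never encoded as
zero. At realistic complement depths (a dozen libraries at 150–300X) the
minimum never binds; it guards degenerate inputs such as solo-lane samples
(empty complement, `pc_depth = 0`).

## Classification rules

With cohort alternate-allele frequency `f` and a defined PC-AF:

* `APPARENTLY_TRUE` — `f ≤ 0` (absent from the cohort) **and** PC-AF < 0.01;
* `SUSPECTED_CONTAMINANT` — `f ≥ 0.05` **and** PC-AF ≥ 0.2;
* `AMBIGUOUS` — everything else, including every undefined PC-AF (absence of
  evidence about the complement must not certify a call) and calls with
  `0 < f < 0.05` regardless of PC-AF.

Both the 0.2 and 0.05 bounds are inclusive; the 0.01 bound is strict. The
rules never overlap (0.01 < 0.2 and 0 < 0.05), so each call gets exactly one
label. A sample is flagged *high-contamination* when its estimated
contaminant read fraction is ≥ 0.005; the Spearman correlation between
per-sample suspected-contaminant counts and contamination estimates is
reported with a two-sided, midrank-tie p-value and used descriptively only.

## Contamination estimator

Let marker *i* be a site with population frequency `p ∈ [0.05, 0.95]` where
the host is homozygous (dosage 0 or 2; heterozygous sites are excluded
because host alleles there are indistinguishable from foreign ones). With
contaminant read fraction `c`, the foreign-allele read fraction at a hom-ref
marker has expectation `c·p + e/3` (alt allele; `e` the uniform miscall rate)
and at a hom-alt marker `c·(1−p) + e/3` (ref allele). Pooling markers gives
the method-of-moments estimator

    ĉ = Σᵢ (xᵢ − dᵢ·e/3) / Σᵢ dᵢ·qᵢ ,   clipped to [0, 1],

with foreign-allele count `xᵢ`, depth `dᵢ` and weight `qᵢ` (`pᵢ` or `1−pᵢ`).
A percentile bootstrap over markers (default 200 resamples, seeded) provides
an optional 95% interval. A likelihood model was deliberately not used: the
single-moment estimator is transparent, and its expectation provably does not
depend on how `c` is split among contaminant sources — so parameter-recovery
tests across 1/2/4/7-source admixtures are directly interpretable. (Tools
whose mixture model assumes exactly two contributors can progressively
underestimate multi-source contamination; that behaviour is a property of
those tools and is not reproduced here.)

Host genotypes come from simulation truth or a supplied matched-normal
genotype table; genotype calling from reads is out of scope. A caveat noted
but not asserted: a real contaminant is one individual, not a population
draw, so its genotype correlation across markers inflates estimator variance
at small marker counts (it does not bias the mean across markers).

## Simulator

The generator works at pileup level (per-site base counts), not read
sequences: every consumer of simulated data uses counts only. Defaults
emulate a deep-exome tumour/normal design: 300 reads/site for tumour
libraries and 150 for normals (echoing median coverages of ~315X/~146X),
uniform base-miscall rate 0.001, germline genotypes drawn per site under
Hardy–Weinberg from the cohort frequency, somatic sites planted at
cohort-absent loci with cellular alt fractions uniform in [0.1, 0.5].

Hopping is symmetric and memoryless per read: with probability `h` a read's
assigned library is redrawn from the other pool members, by default
proportionally to their pool fractions (free indexed molecules scale with
library share; the mechanism is not otherwise constrained by data, and a
`uniform` mode is kept for sensitivity checks). No index-pair structure is
modelled, matching effectively single-indexed pools. Read totals are
conserved exactly, and every read keeps its origin library as a truth tag.

Admixtures mix reads at each site from the target (weight `1 − c`) and each
contaminant library (its fraction), with uniform depth across sites — real
libraries have coverage profiles this does not reproduce. `verify_mixture`
recovers each library's share from the origin tags, the in-silico analogue
of validating mixtures by library-specific depth of coverage.

What the simulator does **not** model: PCR duplicates, mapping artefacts,
GC-dependent coverage, indels/SVs, copy-number structure and tumour
subclonality, or quality-score variation. Passing tests therefore show the
method's arithmetic and discrimination logic are correct under the stated
generative model, not that thresholds are optimal for any particular real
cohort.

The naive candidate caller used in end-to-end checks emits a call wherever a
sample shows ≥ 3 reads of a truth alt allele, and (when given the host
individual) suppresses the host's own germline sites — emulating a
matched-normal somatic caller. Without that suppression the end-to-end
precision property cannot hold for any pool-complement method: the host's own
common germline variants carry complement support by construction.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere, including the internal
  pileup TSV.
* SNVs only; indels and other alleles are skipped at VCF ingest (counted in
  the log). Depth is the sum of the AD field, so `AD=10,5` gives depth 15.
* "Absent from the cohort" means frequency ≤ 0 exactly; sites missing from
  the frequency table look up as 0.
* Pool fractions are normalised per pool on load; absent fractions mean
  equal shares (pools are loaded for equal representation in practice).
* Calls whose sample's AD entry is missing in a multi-sample VCF are treated
  as not-called-in-that-sample and skipped; a VCF lacking the AD FORMAT
  definition entirely is an error.
* Mapping/base-quality filtering of complement reads is assumed to have
  happened upstream; ingest accepts pre-filtered pileups.
* All randomness flows through seeded `numpy` generators; identical
  configuration and seed reproduce outputs byte for byte.

## Problem sizes

The test suite and the acceptance script run deliberately desk-scale
configurations chosen as the package's own defaults: admixture recovery uses
5000 markers at 300X over 10 replicates per level (~2 s total); pool
simulations use 300–1400 sites and pools of 2–16 libraries. These sizes put
binomial standard errors well inside the asserted tolerances, which is the
criterion by which they were chosen.
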