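# Methods

## The assay model

A pooled transposon insertion library is a set of clones, each defined by
one insertion site (chromosome, 1-based position, strand of the junction
read). The library is sampled at four timepoints spanning one sexual cycle:

| timepoint | role |
|---|---|
| T1 | initial library |
| T2 | revived, plated pre-sex culture (reference for filtering) |
| T3 | short post-sex outgrowth (one 1:100 dilution, 24 h) |
| T4 | long post-sex outgrowth (serial dilutions, 48 h) |

Selection is modeled multiplicatively per stage. Each gene carries three
survival factors `w_veg_pre`, `w_sex`, `w_veg_post ≥ 0`; a clone whose site
lies inside the gene (introns included, strand ignored) is reweighted by the
stage factor and the pool is renormalized:

    T2 = normalize(T1 · w_veg_pre),  T3 = normalize(T2 · w_sex),
    T4 = normalize(T3 · w_veg_post).

Intergenic clones always carry factor 1. The single `w_sex` deliberately
subsumes mating, meiosis, sporulation and germination survival; no
mating-type switching, microcolony or tetrad structure is modeled. A site
inside overlapping genes takes the product of the owners' factors.

## Fitness statistic and test

For a comparison (pre, post) each retained site gets

    r = log10( max(c_post, 1)/N_post ) − log10( max(c_pre, 1)/N_pre ),

where `c` are unique-UMI counts and `N` the post-filter sample totals. The
one-read floor keeps dropouts finite at the cost of understating their
magnitude; the totals are not re-inflated by the flooring (the correction
would be negligible at realistic depths).

Each gene with ≥ 5 distinct insertion sites is tested against the pooled
intergenic `r` distribution with a two-sided Mann-Whitney U. Two-sided is
chosen because both depletion (sex-required) and enrichment (repressor
candidates) are biologically meaningful; direction is assigned afterwards by
the gene's mean `r` relative to the intergenic mean. Bonferroni multiplies
each raw p by the number of genes actually tested in that comparison;
significance is corrected p < 0.05. Benjamini-Hochberg FDR is available
behind a flag as a documented deviation, never the default.

Hit calling uses the two post-sex comparisons T3/T2 and T4/T2: significant
in at least one, with mean `r` below the null mean in every significant
comparison, ⇒ `required_for_sex`; above ⇒ `repressor_candidate`. When the
two comparisons disagree in direction the more significant one wins and the
gene is flagged `direction_conflict`. The vegetative comparisons T2/T1 and
T4/T3, run through the identical machinery, produce the growth flags; a
significant increase at *both* vegetative steps marks
`growth_advantage_suspect`, the signature of a repressor call explained by
growth rate rather than repression of sex. Treating "increased at both
steps" as a significance call (not merely a positive mean) is this package's
reading of an ambiguous convention.

### Mann-Whitney engine

`scipy.stats.mannwhitneyu` with the exact null distribution when both
samples have ≤ 8 observations and no ties, otherwise the normal
approximation with tie-corrected variance and continuity correction. The
exact two-sided convention is `min(1, 2·min(P(U≤u), P(U≥u)))`; the test
suite verifies it against exhaustive enumeration over rank splits for every
sample-size pair up to 8 vs 8.

## Read model and processing

Read layout (configurable): `[linker][UMI][transposon end][genomic
fragment]`, the fragment starting at the insertion junction on the insertion
strand. Processing requires a perfect, read-start-anchored linker match
(reads failing it are `no_linker`), extracts the UMI, requires a perfect
match to the entire configured transposon terminal sequence (`no_hermes_end`
otherwise), and maps the remaining fragment by exact substring search over
both reference strands: exactly one occurrence ⇒ `mapped_unique` with the
junction base's coordinate (on the minus strand this is the rightmost base
of the forward-strand match); zero ⇒ `unmapped`; several ⇒ `multi_mapped`.
Fragments under 20 nt are reported unmapped — uniqueness of shorter matches
is not meaningful. Exact matching is adequate for the error-free synthetic
reads this package is validated on; for real data the intended extension
point is an external aligner whose per-read calls are ingested through the
same JunctionCall TSV contract.

A site's count in a sample is the number of distinct UMIs among its
uniquely mapped reads (PCR duplicates share site and UMI and collapse to
one); runs are summed per sample, and the site universe is the union over
all samples, zero-filled. The depth filter keeps sites with ≥ 9 unique
products (strictly more than 8) in T2, and all downstream frequencies use
post-filter totals so each sample's retained frequencies sum to 1. Sites
are keyed by (chrom, pos, strand); strand-merged keying is a flag, not the
default.

## Simulator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| genome | 0.5 Mb, 200 genes of 1–2 kb, 40% intergenic | desk-scale stand-in for a yeast chromosome arm with yeast-like gene density |
| placement | uniform over both strands | the transposon shows little insertional bias; a hotspot model exists for robustness checks |
| clones | 13 000 (study geometry) | one insertion per ~38 bp, the density of the filtered real library |
| clone abundance | symmetric Dirichlet, concentration 10 | moderate clone-size dispersion from library growth |
| depth | 5×10⁵–10⁶ unique products/sample | puts the median site at ~30–80 products so ≥ 90% of sites clear the ≤ 8-product filter, as in the real library |
| UMI | 10 nt, distinct per site | ≥ 8 nt makes collisions negligible; drawing distinct UMIs per site makes the round-trip contract exact rather than near-exact |
| PCR duplication | geometric, mean 2 | duplicates per unique product; UMI collapsing must undo it |
| read length | 100 nt | leaves a 49 nt genomic fragment after layout overhead — far above the uniqueness threshold |
| errors | none (uniform substitution optional) | acceptance runs are error-free by design |

Clones are placed at least one read length from chromosome ends so every
junction read carries a full genomic fragment. Multiple sequencing runs are
emulated by splitting emitted reads round-robin; the real assay's multiple
restriction digests and primers are collapsed into one pool. Genic versus
intergenic library composition follows interval length (uniform placement);
the true fraction in a real library is unknown and this is an assumption.

What passing tests therefore show: the pipeline's arithmetic, gating,
mapping, deduplication, filtering and testing are correct under the stated
model, and the test has its nominal error rates under exchangeable neutral
sites. What they do not show: robustness to sequencing error, UMI errors
(no directional-network collapsing is implemented), insertional bias,
chromatin-dependent depth, or mapping ambiguity in repetitive genomes.

## Simulation studies

- **Family-wise error**: 200 replicates of a fully neutral study-geometry
  library at depth 10⁶; the fraction of replicates with ≥ 1
  Bonferroni-significant gene must stay within two Monte-Carlo standard
  errors of 5%. Under full neutrality gene and intergenic sites are
  exchangeable, so the test's validity is a property, not an assumption.
- **Parameter recovery**: 20 sex-required genes (`w_sex = 0.1`), 20
  growth-advantage genes (factor 2 at both vegetative stages), 160 neutral,
  7 replicates at depth 5×10⁵. Reported: sensitivity for sex-required
  genes, both-steps flagging of growth-advantage genes, neutral mis-calls
  in the median replicate, and direction consistency of every detection.
- **Round-trip**: a 100 kb / 50-gene / 5 000-clone library's error-free
  reads are emitted, processed and counted; per-site counts must equal the
  sampled truth at 100% of sites, and the depth filter must match a
  brute-force refilter.

Replicate counts and depths are the package's desk-scale study conditions;
the statistical behavior they probe (error control, rank-test consistency)
does not depend on genome scale.

## Bench assay calculators

Viable spore yield VSY = viable spores recovered / cells plated; each
replicate is normalized by the mean VSY of wild-type replicates from the
same batch (so the wild-type batch mean is exactly 1), and genotypes are
compared with the shared Mann-Whitney engine. Competition assays score
`log10(p1/p0)` of the focal strain's colony fraction; a zero final fraction
yields a flagged `-inf` sentinel that participates in cohort tests by rank
— no pseudo-counts. Category tables use Fisher's exact test: scipy for
2×2, and for 2×k a Freeman-Halton extension that enumerates first-row
configurations under fixed margins and sums the probabilities of tables no
more probable than the observed one (feasible because bench tallies are a
few hundred objects; complexity is the product of column totals). Tetrad
tables (four spores / no visible spores / other) can be collapsed to 2×2
as four-spore versus rest.

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive everywhere; GFF3 output uses feature
  types `gene` and `region`.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give byte-identical FASTQ,
  truth tables and result TSVs. No stage reads the clock for computation.
- Probability comparisons in the Freeman-Halton enumeration use a 1e-9
  relative tolerance to absorb log-space rounding at the "equally probable
  table" boundary.
- Degenerate inputs fail loudly: empty intergenic null, zero sample totals,
  empty Fisher margins, a genome too small for its genes, a library driven
  entirely to zero abundance ("library extinct").
- Genes with < 5 sites are reported as `too_few_sites`, never silently
  dropped.

## Known limitations

Exact-match mapping and perfect-gate filtering are strict stand-ins for
aligner-based processing of real, errorful reads; the statistics operate on
whatever site-count table is supplied, so real-data users should map
externally and enter at the TSV interface. The one-read floor biases strong
depletions toward zero, making reported fold changes conservative.
Essentiality is not called from insertion density; essential-gene handling
is limited to their depletion being visible in the vegetative comparisons.
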