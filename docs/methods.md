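# Methods

This note documents the models and procedures implemented in `mobilome`, the
parameter defaults and why they were chosen, the numerical conventions, and
the limits of what the synthetic benchmarks establish.

## Coordinates and formats

All interval arithmetic is 0-based half-open. BED is emitted 0-based
half-open; GFF3 converts to 1-based inclusive at the writer. Depth input is
auto-detected by column count: 3 columns = depth TSV (1-based positions,
`samtools depth` convention), 4 columns = bedGraph (0-based half-open).
Circularity is a flag on the sequence record; the array scanner and repeat
finder append a bounded wrap of the sequence start so features spanning the
origin are caught, and report them with a `wrapped` flag (coordinates read
modulo L). FASTA/BED/TSV round trips are lossless up to line wrapping.

## Sequence comparison

Identity is always matches / alignment columns, with gap columns in the
denominator; query coverage is the aligned query span / query length.

* **Seeded nucleotide search** (spacers, repeats): exact k-mer seeds
  (k = 10 by default) locate candidate diagonals; on each diagonal every
  query sub-window long enough to satisfy the coverage threshold is scored
  exactly. The seed length is pigeonhole-safe for the 95/95 defaults on
  queries ≥ 21 nt: an accepted window of w ≥ ⌈0.95·q⌉ columns with
  m ≤ ⌊0.05·w⌋ mismatches contains an exact run of ≥ ⌈(w−m)/(m+1)⌉ ≥ 10
  matching columns, so no accepted placement can lack a seed. Matching is
  gap-free by default — spacer/protospacer divergence is dominated by
  substitutions at the identity levels of interest — with a gapped mode
  (DP rescoring of seeded loci) available in the configuration.
* **DP oracle**: an exhaustive Smith–Waterman with linear gaps
  (`dp_local_align_nt`) for small inputs, used to validate the seeded route;
  ties resolve to the first maximal cell in row-major order.
* **Protein local alignment**: affine-gap local alignment with BLOSUM62 and
  BLAST-style gap costs (open 11, extend 1; a gap of length g costs 11+g).
  The pair is canonicalized by (length, lexicographic) order before aligning
  so scores, matches, and identity are symmetric under argument order.
  Alignment fraction is measured against the shorter protein.

## CRISPR array detection

CRT/MinCED-style: slide an exact 8-mer window; a recurrence of the window at
a spacing compatible with one repeat plus one spacer (49–97 bp for the
default bounds: repeats 23–47 nt, spacers 26–50 nt) starts a chain; chains
with ≥ 3 instances are extended column-by-column outward while ≥ 75% of
instances agree with the modal base, with a one-column rescue if the
following column agrees (tolerates isolated substitutions in diverged
instances). Right extension is capped so no inter-repeat gap drops below the
minimum spacer length — a pure tandem repeat otherwise swallows its own
"spacers". Instances missed by the exact-seed chain (seed k-mer mutated) are
recovered by scanning the admissible spacing range on both flanks for
segments within 25% mismatch of the consensus; edge instances that diverge
from the consensus by more than that are pruned (a chance seed match one
period away in the flank can otherwise prepend a junk instance).

Arrays whose spacers are near-identical (mean pairwise identity ≥ 0.80,
measured as best-diagonal matches over the longer spacer) are classified
`tandem`, not CRISPR; with CDS intervals provided, tandem arrays fully inside
one CDS are flagged intragenic. This automates a removal that is often done
by manual inspection; 0.80 separates "spacers are copies of one unit" from
genuine spacer diversity with a wide margin on both sides and is
configurable.

A note on ground truth: in the synthetic generator, spacer bases adjacent to
the repeat are cycled across instances so that no boundary column agrees
across all instances. Without this, the repeat/spacer boundary is genuinely
ill-posed — a column shared by every instance *is* repeat consensus by
definition — and no detector could match the manifest exactly.

## Spacerome and protospacer search

Recruitment accepts an array when its consensus repeat aligns to any host
repeat at ≥ 95% identity over ≥ 95% of the shorter repeat, on either strand.
Spacer dereplication is exact (100% identity) after strand canonicalization
(lexicographic minimum of the spacer and its reverse complement); provenance
is conserved, and the partition counts per dataset are reported. Strand-aware
dedup is available via configuration for comparison.

Before searching, every detected array span (repeats and spacers, end to end)
in the assemblies that contributed spacers is replaced by Ns. N positions
produce no seeds and never count as matches, so "no hit overlaps a masked
interval" holds by construction; it is asserted on every run regardless, and
a hit inside a known array span in any *other* target triggers a warning
naming the array (an un-masked self-match, as happens when an array evades
detection).

## MGE catalogue

Hit-bearing contigs are grouped into candidates. Dereplication links two
contigs when windows tiling the shorter one match the longer at ≥ 95%
identity over ≥ 80% of the windows (containment against the shorter);
clusters are single-linkage connected components, the representative is the
longest member (ties lexicographic). The identity/containment defaults
mirror common genome-dereplication practice and are recorded in run
metadata. The 2.8 kb length floor is applied strictly (< 2,800 bp removed,
2,800 bp retained) after dereplication, to representatives. The summary
table reports lengths in bp and integer-rounded kbp, sorted by length
descending. Manual curation of target neighbourhoods is out of scope; the
warning hook above marks loci needing inspection.

## Genomic repeat landscape

Dispersed duplications are found by self-comparison: shared 16-mers grouped
by diagonal, merged into runs (gap tolerance 3k), scored gap-free, and
reported when ≥ 100 bp at ≥ 95% identity; the self-diagonal and mirrored
pairs are excluded, inverted (reverse-strand) repeats are found against the
reverse complement, and pairs overlapping detected arrays are removed. The
headline statistic is the genomic *footprint*: merged coverage of all repeat
intervals over genome length. The summed-alignment variant (2× summed pair
lengths over genome length) is reported alongside, since "percent repeats"
is stated both ways in the literature.

## Replication model

A circular element whose molecules carry replication bubbles expanding
bidirectionally and symmetrically from a fixed origin o, with bubble progress
f ~ Uniform(0,1) (an unsynchronized steady state), has expected relative copy
number c(u) = 1 + a·(1−u) at normalized circular distance u = d(x,o)/(L/2):
the V shape when linearized with the origin near the element edge. The
log-linear variant c(u) = (1+a)^(1−u) covers exponentially growing
populations; both are fitted and the better SSE wins.

Fitting: coverage is binned at 1 kb over the element and normalized by the
median per-base depth of 20 kb flanks (median, not mean, for robustness to
neighbouring elements; truncated flanks warn). The origin is grid-searched
over bin edges and midpoints; for each candidate the activity has a closed
form, clipped at 0. Model comparison against the flat profile uses BIC with
Gaussian errors (flat: 1 parameter; V: 2). Verdict: `replicating` requires
Δ = BIC_flat − BIC_V ≥ 6 (strong evidence) and element/flank mean coverage
ratio ≥ 1.25; `integrated` requires weak evidence (Δ < 6 or a ≈ 0) and ratio
< 1.25; anything else is `ambiguous`. The ratio floor is set midway between
the integrated expectation (ratio 1) and the weakest activity the classifier
is asked to detect (a = 1, mean ratio 1 + a/2 = 1.5): a floor at 2 would by
construction miss every element with a < 2 no matter how clean the signal.
Both thresholds are configurable.

The molecule-level simulator draws Poisson(a) bubbles per molecule and
realizes depth as Poisson(depth × mean copy number); its empirical mean
matches the closed form within 1% at 10⁵ molecules (checked), making it the
independent oracle for the fitter.

## Gene-flow scaling

Counts per taxon group and genome are fitted against the total gene count G
by ordinary least squares in closed form (normal equations; cross-checked
against statsmodels to machine precision in the tests). G includes all called
genes, unassigned ones included — stated here because the regressor choice
moves the intercepts. Confidence intervals use the t distribution with n−2
degrees of freedom. The archaea:bacteria ratio is reported per genome sorted
by genome size, with zero-bacteria rows flagged rather than dropped. COG
profiles exclude unknown-function genes (category S or no category);
enrichment per group is the fraction excess over the best other group. MGE
gene-length percentages are group sums of gene length over the total, ×100.

Taxon assignment itself is an input: the table schema mirrors an orthology
mapper's export so real runs feed the mapper's output straight in.

## ERP clustering

Pairs are scored by local alignment; an edge requires alignment fraction
≥ 0.80 (of the shorter protein) AND identity × alignment-fraction ≥ 0.24,
both inclusive, both on the 0–1 scale. Families are connected components
(single linkage — the natural reading of a single-cutoff clustering);
singletons are kept. The identity term uses all alignment columns, so the
composite is conservative for gappy alignments. Domain-based manual
regrouping and family consolidations (as done in curated analyses) are
supported through an override table, not automated.

## Synthetic data: what it does and does not establish

The generators are pure functions of (seed, parameters). Defaults: host
genomes of 40 kb with 5 CRISPR arrays (4–7 repeats of 28–40 nt, spacers
30–46 nt) and 3 tandem decoys; 6 MGE contigs of 3.2–9 kb (one deliberately
below the 2.8 kb floor) carrying 1–2 protospacers each, plus exact-duplicate
contigs for the dereplication stage and 4 protospacer-free decoys; uniform
A/C/G/T background; substitution-only mutations. Gene tables: 8 genomes,
planned totals 1,800–4,600 genes (sizes G×1,000 bp, a ~2.5× span), archaeal
counts flat at 900, bacterial slope 0.45 (intercept −300), eukaryotic slope
0.10, unassigned absorbing the remainder; Gaussian noise σ = 30; COG letters
drawn from group-specific weights with information-processing categories
(J/K/L) enriched in the archaeal group, metabolism (C/E/G/P) in the
bacterial, trafficking/cytoskeleton/modification (U/Z/O) in the eukaryotic.
Protein families: tiers at target pairwise identities 1.0/0.6/0.3/0.15 with
an exact per-member substitution count, resampled until realized pairwise
identities are within ±2% of target; inter-family background < 15%.

Benchmarks run on these conditions show that the implementation is correct
and calibrated *under the generative assumptions*: uniform base composition,
substitution-only divergence, non-chimeric contigs, independent Poisson
coverage noise, and well-separated identity tiers. They do not establish
performance on real metagenomes, where repeat families blur the
tandem/CRISPR boundary, coverage has mapping artefacts and strain mixtures,
and protein-identity structure is continuous. Deposited-data headline counts
therefore require the original assemblies and annotation databases and are
not asserted by the test suite.

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` use: 30 replicate genomes (3
arrays each, diverged repeat instances) for detection recall/boundary error;
100 spacer-sized queries × 20 contigs of 5 kb for oracle equivalence; 10⁵
molecules for the law-of-large-numbers check; 100 replicating (a ∈ [1,4],
depth 50–150×) + 100 integrated elements of 20 kb for classifier operating
characteristics; 100 replicate 8-genome tables for CI calibration; and 200
proteins (24 tiered families + background) for the clustering-partition
check. These sizes put every Monte-Carlo estimate's sampling error well
inside the asserted tolerances.
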