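# Methods

## Scope and data model

`panepi` analyzes strand-specific bacterial methylomes across a strain
panel. All coordinates are 1-based inclusive (GFF3-native) end to end;
only the BED exporters convert to 0-based half-open. A methylation call is
a (replicon, position, strand, modification type) tuple pointing at the
modified base itself; a motif occurrence is a window match of an IUPAC
motif on either strand, whose methylated base sits at
`start + modified_index - 1` (plus strand) or
`start + len(motif) - modified_index` (minus strand, leftmost-coordinate
convention). An occurrence is methylated exactly when a call with
compatible type sits on that base. Palindromic motifs therefore contribute
two methylatable occurrences per locus, one per strand, matching
strand-specific kinetic calling. Overlapping occurrences are all retained:
the matching is exhaustive, with no greedy masking. `N` in the genome
never matches any motif position, so unsequenced gaps do not inflate
occurrence totals.

## Region classes

Each replicon is partitioned per strand into CDS (inside a gene on the
accordant strand), nCDS (inside a gene on the discordant strand), US
(within `us_length` bp upstream of a gene start on the accordant strand)
and tIG (everything else), with precedence CDS > nCDS > US > tIG. The
precedence makes the four classes a true partition — required for count
additivity in the frequency tables, and property-tested on random layouts
including nested and overlapping genes. nCDS as "antisense within a gene"
is our reading of the four-class scheme: coding, upstream and intergenic
are strand-accordant notions, and antisense-within-gene is the only
remaining positional class. `us_length` defaults to 300 bp, a conventional
bacterial promoter-proximal window; replicons are linear unless declared
circular, in which case upstream windows wrap the origin.

## Statistics

* **Frequency**: methylated count over total count per group; zero-total
  groups are reported as missing, never as frequency 0.
* **Pan-epigenome**: presence of a motif in a strain defaults to "at
  least one methylated occurrence genome-wide"; a minimum-frequency or
  minimum-count rule is configurable. The count floor exists because
  distinct same-type motifs can genuinely share methylated bases when one
  motif's word embeds another's recognition site, which lets a
  universally active motif deposit a handful of apparent calls on a motif
  the strain does not actually recognize.
* **NRMSD** is RMSD about the mean divided by the mean (coefficient of
  variation). The mean normalizer keeps a high-frequency, low-spread
  motif (GANTC) near zero while range normalization would not separate
  magnitudes; range normalization is available as a config option and the
  choice is recorded in output metadata.
* **Scaling** is a z-score with sample standard deviation; zero-variance
  rows/columns map to zeros with a warning, and scaling is idempotent.
* **PCA** is an eigendecomposition of the covariance (or correlation,
  default) matrix; contributions are squared loadings normalized to 100
  per component. Centering and scaling default to on because region
  frequencies differ in magnitude across motifs. Missing cells are
  imputed to column means with a warning.
* **Group tests** use Kruskal–Wallis followed by Dunn's z on pooled mean
  ranks with tie correction `T = Σ(t³ − t)/(12(N − 1))`; two-sided normal
  p-values, Holm adjustment by default (Bonferroni and
  Benjamini–Hochberg selectable). The rank-based pair is the coherent
  reading of "ANOVA + Dunn post hoc"; the identical-data corner case
  returns H = 0 and p = 1. Pairwise significance is flagged at
  adjusted p < 0.001, the convention used for replicon-comparison
  heatmaps.
* **Clustering** is complete-linkage agglomeration on Euclidean
  distances. Leaves are sorted lexicographically before linkage so that
  tie-breaking is deterministic and input-order-independent. Cophenetic
  matrices come from the merge heights; tree pairs are compared by
  Pearson correlation of aligned upper triangles (Spearman behind a
  flag). An external phylogeny in Newick enters the comparison through
  its patristic tip-to-tip distances.
* **Transfer fold changes**: `log10(ratio(d, r) / ratio(r, r))` with the
  `-Inf` literal serialized for zero-transformant cells; ratios are taken
  as given, with no error propagation, since only point values are
  reported upstream.

## The synthetic panel generator

The generator emulates a 21-strain panel of multipartite genomes at
roughly 1/35 scale: per strain a 100 kb chromosome, 50 kb chromid and
40 kb megaplasmid, plus a 10 kb accessory plasmid in every other strain.
Background sequence is i.i.d. with a configurable GC content (default
0.5); genes are placed without overlap at ~80% coverage with
normally-distributed lengths (mean 900 bp, min 150 bp), random strands,
and exponential gaps.

Methylation is Bernoulli per occurrence, independent across occurrences:
`p = base_p(motif) × region_multiplier × replicon_multiplier`, capped at
0.995. Defaults take `base_p` from the packaged 16-motif reference table
(so GANTC ≈ 0.99 and the rest 0.02–0.19), region multipliers
CDS 1.0 / nCDS 0.9 / US 1.1 / tIG 1.2, and replicon multipliers
chromosome 1.0 / chromid 1.0 / megaplasmid 1.1 / plasmid 0.5 — frequencies
differ by motif, by region and by replicon, with accessory plasmids
hypomethylated. GANTC is declared a *uniform motif*: cell-cycle
methylation is genome-wide, so region and resident-replicon multipliers
do not apply to it, only the plasmid deviation. The presence design makes
ten motifs active in all strains and six in seeded random subsets of
sizes 2, 5, 8, 12, 16 and 19 (no strain-exclusive motif), the structure
the classification stage is meant to recover.

Two scale-down compensations keep the planted design identifiable, both
artifacts of the 35× size reduction rather than of the method:

1. **Occurrence floors.** A motif with p = 0.016 has thousands of sites
   in a 7 Mb genome but would have ~90 here, giving a ~20% chance of zero
   methylated occurrences in a carrier strain. The generator therefore
   plants random concrete words of each motif into the background until
   every motif reaches ~`25/base_p` occurrences per strain, so a carrier
   is essentially never silent (a safety anchor forces one methylated
   occurrence in the astronomically rare remaining case).
2. **Disambiguated modified-base offsets.** The published summary does
   not state which base of each motif is methylated. Under the fallback
   rule (first base compatible with the modification type) some same-type
   motif pairs can place their methylated base on the same genome
   position and strand whatever the surrounding sequence — e.g. every
   RAGCWGCTY word embeds a GCRDB site with an aligned modified cytosine —
   so a core motif's calls would mark shell motifs as methylated in every
   strain and no presence rule could recover the design. The generator
   therefore uses an offset assignment, found by exhaustive search over
   all full and partial pairwise word alignments, under which no two
   same-type motifs can ever share a methylated site. One biological
   compromise is knowingly made: GANTC's methyladenine is really at
   position 2 (CcrM), but only position 3 (the degenerate N) is
   collision-free; nothing downstream depends on the absolute offset.
   Planted words additionally avoid embedding other same-type motifs
   where the degeneracy allows.

Everything is driven by one integer seed through a single PCG64 stream;
reruns are byte-identical, which the tests assert by file hash.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — motif
occurrence counts with planted floors, strand-specific Bernoulli calls
with motif/region/replicon-dependent probabilities, a core/shell presence
design, multipartite replicon classes. It does not emulate sequence
evolution along a phylogeny, kinetic-signal noise, operon structure, GC
skew, or spatially correlated methylation. Passing recovery tests
therefore demonstrates that the pipeline's counting, matching and
classification are correct under the stated sampling model, not that the
model captures every property of real methylomes.

## Verification strategy and problem sizes

Scanning is verified exactly against a brute-force IUPAC-expansion window
oracle (100 random sequences up to 5 kb, all 16 motifs); the region
partition against per-position classification oracles and 1,000 random
layouts; clustering against an exhaustive-search complete-linkage
agglomerator; Dunn's z against a hand-derived two-group value
(≈ 1.964 for (1,2,3) vs (4,5,6)) and a 10,000-replicate null calibration
of the type-I error at α = 0.05. End-to-end recovery uses a full
21-strain panel written to disk and re-read through the file pipeline:
core/shell labels must match the planted design exactly, and per
motif × region methylated counts (pooled over carrier strains) must fall
inside the simultaneous 99% envelope of the design's Poisson-binomial
(normal approximation, Šidák-corrected over the 64 cells — a per-cell 99%
interval over 64 cells would fail somewhere by construction). These sizes
keep the full suite and the acceptance script at about a minute each on
one CPU.

## Known limitations

* The motif-collapse rule (sub-motif containment with aligned modified
  base, subset-wise on IUPAC sets) is one defensible formalization of
  "shared common core sequence"; other rules could merge differently.
* Presence calling from naive counts is vulnerable to embedded-motif
  call sharing whenever true offsets actually collide; with real data the
  per-strain motif lists of the upstream modification caller are the more
  reliable presence source, and the count/frequency floors are the
  mitigation offered here.
* Replicon classes come from an explicit manifest; no alignment-based
  assignment is performed.
* The upstream-window length is a single global constant, not
  operon-aware.
* The transfer module reports point fold changes only; no variance model.
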