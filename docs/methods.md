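# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ribogap`.

## Distances and the barcode gap

All distances are uncorrected p-distances: substitution counts over
compared sites, reported as percent.  No Jukes–Cantor or Kimura correction
is applied (and none is planned): the diagnostic compares raw nucleotide
differences between repeats of the *same* genome with differences between
strains, and a model correction would rescale both without changing the
comparison while hiding the actual mutation counts.

Sites where either sequence carries `-` are excluded pair-by-pair
(pairwise deletion); `N` is excluded the same way by default (toggleable),
since an `N` carries no evidence either way.  Ambiguity codes are scored
under one of two policies:

* **strict** — any symbol difference is a difference.  Default for
  clone/genome comparisons, whose sequences contain no ambiguity codes.
* **set-overlap** — a difference only when the IUPAC expansions are
  disjoint (`R` vs `A` matches, `R` vs `C` differs).  Used whenever a
  consensus or database record with ambiguity codes participates,
  e.g. when screening database hits against a type-strain barcode.

A pair with zero comparable sites raises an error rather than returning 0:
two oppositely truncated repeats have *no* measured distance, and a silent
zero would fabricate identity.  Summary statistics that scan many pairs
(e.g. the simulator's intragenomic maximum) skip such pairs explicitly.

The barcode-gap report covers every unordered taxon pair:
`gap = min_inter − max(max_intra_A, max_intra_B)`, verdict
`gap_present = gap > 0`.  Pairs involving a taxon with fewer than two
members are reported with an undefined intra maximum and flagged, not
dropped.  Database-style screening (`similarity_filter`) aligns each
candidate globally to the query (match +1, mismatch −1, gap −2) before
scoring, mirroring the usual practice of comparing unaligned accessions.

## Secondary-structure classification of variable sites

Structures are inputs (dot-bracket over a reference transcript; bracket
tiers `()`, `[]`, `{}`); no folding is performed.  Sequences are stored in
the DNA view (`U`→`T` on input); pairing logic treats T as U, and all
classification is invariant under the T/U representation.

A column is **variable** when ≥ 2 states occur among gap-free rows and the
minor states together are carried by at least `min_minor_count` sequences
(default 3).  The default deliberately excludes singleton and doubleton
variants, the typical signature of polymerase/amplification error in
cloned material; set it to 1 to keep everything.  Dimorphic columns
(exactly two states) are the SND sites of the trade.

Paired variable sites are read **row-wise**: the classifier sees the set
of (site, partner) base combinations actually carried by individual
sequences, not the two column distributions.  This is what distinguishes a
genuine compensatory base change — two groups of sequences each holding a
different canonical pair, e.g. G·C vs A·U — from coincidental variability
at both columns that produces non-canonical combinations in some rows.
Canonical means Watson–Crick plus the G·U wobble.  Classes:

* `neutral_unpaired` — site not in a helix;
* `wobble_neutral` — one side varies, every carried combination still
  canonical (C↔U opposite G, and the hemi-CBC case G-C→G-U; the
  `hemi_cbc` flag marks variation that toggles between two distinct
  canonical pairings);
* `CBC` — both sides vary, all carried combinations canonical;
* `mismatch` — some sequence carries a non-canonical combination;
* `unanchored` — the reference row is gapped at the column, so no
  structural context exists.

**Pseudogene flagging**: a sequence is flagged when it carries a
non-canonical combination at a *designated* CBC pair.  When the caller
supplies the designated pairs (as the simulator's truth tables do, or as a
user does after inspecting the structure) exactly those are used;
otherwise a pair is auto-designated when the alignment itself shows at
least two distinct canonical combinations there — i.e. the pair is
observed to compensate, so breaking it is evidence of a dead repeat.
Coordinates in reports are emitted both in reference numbering and
loop-local numbering, since published figures use either.

## Trees, neighbour-net and treelikeness

**Neighbour joining** is the standard Saitou–Nei agglomeration.
Determinism: among tied Q-criterion minima the smallest (row, column)
index pair is joined.  Negative branch lengths are clamped to 0 with a
logged warning.  On additive matrices the reconstruction is exact (tested
to 1e-9).

**Neighbour-net** follows the published two-stage agglomeration: cluster
pairs are chosen by the NJ-style criterion on cluster-averaged distances;
inside the chosen pair, the endpoint nodes to link are chosen by the same
criterion with the two clusters expanded to singletons; every 3-chain
x–y–z is immediately reduced to two nodes with the 2/3–1/3 weighting
(d(u,·) = ⅔d(x,·)+⅓d(y,·), d(v,·) = ⅔d(z,·)+⅓d(y,·),
d(u,v) = (d(x,y)+d(x,z)+d(y,z))/3).  The accumulated orderings concatenate
into a circular ordering of all taxa.  One subtlety: at the four-cluster
stage the selection criterion ties *exactly* between complementary pairs
(an algebraic identity), so a naive first-minimum rule makes the output
depend on input order.  Ties (within 1e-9 relative tolerance) are broken
canonically by smallest contained taxon label, which restores invariance
under permutation of the input rows.  The implementation reproduces the
independent R implementation (`phangorn::neighborNet`) to 1e-6 on random
matrices (cross-checked in the test suite via `Rscript`).

Split weights are fitted by non-negative least squares
(`scipy.optimize.nnls`, an active-set method) over all n(n−1)/2 splits
compatible with the circular ordering; splits with weight < 1e-9 are
dropped and the residual norm is reported.  On additive input the fit is
exact and returns precisely the tree splits with branch-length weights; a
4-cycle "box" metric returns both incompatible splits.  With fewer than 4
taxa no incompatible split is expressible and the NJ tree's splits are
returned (`method: nj-fallback` in metadata).

**Delta score**: per quartet, with pairwise sums s1 ≥ s2 ≥ s3,
δ = (s1−s2)/(s1−s3) (0 when s1 = s3).  Mean over all C(n,4) quartets and
per-taxon means; additive ⇒ 0, equal-sided box ⇒ 1.  The **Q-residual** is
mean(((s1−s2)/s̄)²) with s̄ the mean off-diagonal distance.  These replace
eyeballing "how boxy" a splits graph looks with a number.

## Repeat and gene mining

`scan_genome` is a self-contained seed-and-extend search: exact k-mer
seeds (default k = 12) between query and contig are grouped by diagonal
(band ±25); each seed cluster defines a window (cluster diagonal span ±100
bp) in which the query is locally aligned (match +1, mismatch −1, gap −2).
Hit identity = matches / aligned columns; coverage = aligned query span /
query length.  Both strands are searched via the reverse-complemented
query.  Same-strand hits of one query within 50 bp merge, keeping the
higher-scoring extension (mutated repeats fragment naive seeding).
Defaults: report at identity ≥ 0.80 and coverage ≥ 0.30; **complete** iff
coverage ≥ 0.90 (closed boundary), else **truncate** — the threshold is
echoed in every report because "truncate" has no standard definition.
Boundary behaviour worth knowing: a verbatim full-length plant is located
at exact coordinates; for truncated plants a local aligner may wander a
few bases into the flank when chance matches continue the alignment.

`haplotype_groups` single-links aligned copies at ≤ `merge_threshold`
symbol differences (default 0 = identical-sequence classes) and counts
distinguishing positions between group majority consensuses (ties resolve
by fixed base order A<C<G<T, logged).  `gene_copy_report` combines
per-genome copy counts with the mosaic diagnostic: `admixture_signal` is
true when a genome's own gene copies differ from each other by more
substitutions than the closest copy in another genome — copies with
different phylogenetic roots, the signature of a chimeric genome.

## Consensus barcodes and Sanger emulation

`iupac_consensus` calls, per column, every base whose (gap-excluded,
optionally abundance-weighted) proportion reaches `min_proportion`, and
writes the IUPAC code of the called set — di-, tri- or tetramorphic
columns become 2-, 3- or 4-base codes.  If no state reaches the threshold
the majority state is called and the column flagged.  Columns with > 50 %
gap emit `-`, keeping the consensus alignable.  `majority_consensus` is
the threshold-1.0 special case (ties → base order, logged).

`sanger_emulation` is the same computation with repeat abundances as
weights and the threshold read as a basecaller's minor-peak detection
limit: the number of ambiguous positions in the output is exactly the
number of columns whose minor weighted proportion reaches the threshold.
Default detection threshold 0.25 — a 3:1 minority repeat class is just
detectable, a plausible midpoint for dye-terminator traces; the sweep in
`analysis/06` shows how strongly the apparent ambiguity count depends on
this choice (the reason different laboratories deposit different
"taxonomic sequences" for the same strain).

## The simulator

The generator produces the three regimes the diagnosis distinguishes, with
full truth labels; every dataset is byte-reproducible from (config, seed)
(single `numpy` PCG64 stream, fixed traversal order).

*State.* Each strain carries a pool of repeats (common 200-nt unit) and a
set of single-copy genes (300 nt, 3 genes), each element assigned to one
of 20 genome blocks.  The unit's secondary structure is a fixed template:
three hairpins (two 12-bp stems mimicking the D1/D2 hairpin domains, one
10-bp stem), 66 % of positions unpaired; two mid-stem pairs per stem are
*designated* CBC pairs (treated as essential for folding).

*Substitution.* Along each species-tree branch a Gillespie event queue
draws events at exact rates.  Candidate substitutions arise at
`mutation_rate` /site/unit (default 0.03) with transition:transversion
ratio κ = 4 (pyrimidine/purine transitions dominate observed rDNA
variation).  Acceptance depends on structural context: unpaired sites
always accept; at stem sites a change keeping a canonical/wobble pair
accepts with 0.5; at designated pairs a pair-breaking change may instead
trigger a compensated double substitution (probability 0.25) — a true
CBC; remaining pair-breaking changes accept with 0.3 and, at designated
pairs, mark the repeat a pseudogene.  These acceptance values are
calibrated only to reproduce the qualitative pattern (variable sites
enriched in loops, wobble-dominated stems, a minority of broken-pair
pseudogenes); they are not inferred from data.

*Homogenization.* At `homogenization_rate` /repeat/unit a repeat is
overwritten by a uniformly chosen donor from the same tandem array;
dispersed repeats are never overwritten (gene conversion needs physical
proximity).  `conversion_tract` makes the overwrite partial (a fraction of
the unit at a random offset), which is what creates chimeric repeats when
the array contains divergent (e.g. two-parent) copies; the default is a
whole-repeat overwrite.

*Birth-and-death.* Duplication copies a repeat (same array/block),
deletion removes one (never the last), truncation blanks a uniform 10–60 %
terminal fraction (truncated repeats are kept as gap-padded rows, so clone
alignments are alignment-free by construction; genome emission strips the
gaps).

*Hybridization.* Events act on extant tip lineages: the two parental
genomes merge block-wise — each parent's copy of each block is retained
independently with the event's retention probability (default 0.6); a
block losing both copies keeps one random parent (whole-block loss is
lethal); retaining both creates segmental diploidy, i.e. multi-copy genes
of mixed parentage.  The hybrid then evolves for `extra_time`.  Its clones
are deposited under the first parent's taxon label by default, emulating
assignment to the phenotypically closest species.  Hybridization at
internal (ancestral) times is not modelled — events between lineages that
are not both extant tips are rejected — which keeps lineage state
single-pass without changing the diagnostic signal.

*Emission.* Genomes are written as FASTA contigs with random background
(arrayed: one rDNA contig, tandem with 150–400-bp spacers; dispersed:
three contigs, block-routed placement, 20 % of repeats on the minus
strand); truth tables record every placement with origin, status and
block.  A repeat's final status is recomputed from its final sequence
(broken designated pair ⇒ `pseudogene_cbc`; gaps ⇒
`pseudogene_truncated`), so truth and sequence can never disagree.

*Preset study conditions* (`homogenized_config`, `birth_death_config`,
`admixed_config`): the homogenized preset (arrayed, h = 50, mutation 0.04)
realizes concerted evolution — within-genome diversity ≲ 1.5 %, clean
Sanger reads, intact barcode gaps; the birth-death preset (dispersed,
b = 0.3 / d = 0.2 / truncation 0.15) produces heterogeneous pools (5–10 %
intragenomic divergence, matching the magnitude reported for
pulcherrima-clade strains), truncated pseudogenes and ambiguity-laden
Sanger reads; the admixed preset adds a B×C hybridization with mosaic
retention and partial conversion tracts in the merged array, erasing the
parental barcode gap and raising the delta score.  The default species
tree is a 4-taxon clade, `((A:0.6,B:0.6):0.5,(C:0.7,D:0.7):0.4)` time
units.

### What the simulator does and does not emulate

Emulated: multicopy repeats with loop-concentrated, wobble/CBC-constrained
variation; SND sites; truncated pseudogene copies; dispersed vs arrayed
placement; chimeric genomes with block mosaicism and segmental diploidy;
Sanger consensus reads with a detection threshold.  Not emulated:
within-species coalescent variation (one genome per strain), insertions
(only terminal truncation), selection beyond the acceptance filter,
sequencing/basecalling noise, assembly fragmentation or collapse of
near-identical repeats.  Passing tests therefore demonstrate correctness
of the measurement pipeline and the qualitative mechanism-to-signal map,
not quantitative rates in real genomes — on real assemblies, repeat
collapse in particular will *understate* intragenomic diversity.

## Problem sizes and numerics

The test suite and the acceptance script run at deliberately modest sizes
chosen to exercise every code path with comfortable statistical margins:
8-taxon trees (100 replicates) for NJ exactness, 5–8-taxon split systems,
20 matched replicate pairs for the hybridization delta comparison
(4 clones/strain), 25 planted-genome replicates (~3 kb contigs, 350-nt
units) for the scanner, and the three preset datasets (4–5 strains,
6–13 repeats each, 200-nt units).  Key tolerances: NJ additive
reconstruction 1e-9; NNLS split-weight recovery 1e-6 (reporting threshold
1e-9); neighbour-net tie tolerance 1e-9 relative.  Degenerate inputs are
errors, not silent defaults: empty FASTA, duplicate ids, zero comparable
sites, unbalanced dot-brackets, n < 3 trees, queries shorter than the
seed, abundance/record mismatches.

## Known limitations

* Accession-based quantities (ambiguity counts of deposited records,
  clone-set maxima, database percent identities, assembly mining counts)
  require the corresponding GenBank records/assemblies as local FASTA;
  the package computes them from any supplied files but ships none.
* The neighbour-net NNLS fits all O(n²) circular splits over O(n²)
  distance pairs; beyond a few hundred taxa the dense design matrix
  becomes the bottleneck.
* The scanner's local alignment is exact within a seed window, but a
  repeat with no exact k-mer seed (identity well below ~75 % for k = 12)
  is invisible; lower `seed_length` for more diverged queries.
* Hemi-CBC is reported as a flag on `wobble_neutral` rather than a
  separate class: the two are the same single-sided canonical-preserving
  mechanism, and splitting them would double-count sites in summaries.
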