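# Methods

`dolloscan` reconstructs the loss history of a small gene family across a
set of species, from genomic sequence to ancestral gene content.  It was
built around the comparative biology of the vertebrate guanylyl-cyclase
(GC) family — the retinal cyclases GC-E/GC-F (*Gucy2e*/*Gucy2f*) and the
olfactory GC-D (*Gucy2d*) — whose repeated, lineage-specific
pseudogenization makes it a model case for loss-only evolution, but every
stage is generic over gene names, trees and parameters.

## Lesion detection

A gene copy is scanned against an intact reference CDS of the same family.
The scan is strictly reference-based: we do not attempt de novo gene
prediction, only the identification of ORF-inactivating differences.

1. **Quality control.** Extractions with an N fraction above
   `max_n_fraction` (default 0.05) or covering less than `min_coverage`
   (default 0.9) of the reference length are EXCLUDED outright.  Genome
   assemblies with unresolved runs of N or truncated gene regions cannot
   be distinguished from real lesions, so no lesion calls are made on
   them.  Both thresholds are qualitative judgements, not measurements;
   they are configurable.
2. **Alignment.** Target and reference CDS are globally aligned
   (match +1, mismatch −2, gap open −12, extend −3).  Gaps are priced high
   relative to mismatches because indels are rare in coding sequence; with
   cheaper gaps, a pair of compensating ±1 gaps can "explain" a dense
   cluster of substitutions and fabricate frameshifts.  Gap runs are then
   left-aligned (standard indel normalisation) so positions are canonical
   under repeat-context ambiguity.
3. **Frameshifts.** Each maximal gap run whose length is not divisible by
   3 is one FRAMESHIFT lesion at the reference offset of its left edge.
   Two compensating shifts count as two events even though the net frame
   is restored — the intervening peptide is still destroyed — and an
   in-frame (3k) indel is no lesion at all.
4. **Nonsense codons.** The target is projected onto reference codon
   coordinates (deleted bases become N, inserted bases are dropped), which
   restores the reference frame downstream of any indel.  Each premature
   stop in this projection is a NONSENSE lesion at its reference codon
   index; the terminal stop never counts.  Two suppression rules prevent
   one biological event from being counted twice: stops that exist only in
   the shifted frame of a frameshifted region never appear in the
   projection by construction, and stops whose codon overlaps a
   frameshift's reference span (±6 nt) are discarded as junction
   by-products of that frameshift.
5. **Splice sites.** Every intron's terminal dinucleotides, read in
   transcription orientation, must form an accepted (donor, acceptor)
   pair.  The default set {GT–AG, GC–AG, AT–AC} covers the canonical
   major-spliceosome pairs plus the minor (U12) AT–AC introns and is
   configurable.  Introns shorter than 4 nt are reported as TRUNCATION.
6. **Start codon.** A non-ATG first codon is a START_LOSS lesion.  Any
   lesion upstream of the first in-frame ATG within `rescue_window`
   codons (default 60) is flagged `rescuable`, since reinitiation at a
   downstream start could still yield a near-full-length protein.
   Rescuable lesions count toward classification by default
   (`count_rescuable`), reflecting that an annotated alternative start is
   a hypothesis, not an observation.

Lesion positions are nucleotide offsets in the reference CDS, except
NONSENSE positions, which are reference codon indices.

## Pseudogene calling

The calling rule requires redundant evidence before declaring a gene dead,
mirroring careful manual annotation: single apparent lesions are too often
assembly or alignment artifacts.

* no countable lesion → INTACT;
* ≥ `min_lesions_solo` lesions (default 2) → PSEUDOGENE;
* fewer, but at least one lesion *shared* with a closely related species →
  PSEUDOGENE (a lesion present in two relatives at the homologous position
  almost certainly predates their split and is real);
* otherwise → PARTIAL, an intermediate state covering both incipient
  pseudogenization and possible artifacts;
* no sequence → ABSENT; failed QC → EXCLUDED.

Two lesions are "shared" when their kinds match and their reference
positions differ by at most `shared_pos_tolerance` (default 6 nt; codons
for nonsense lesions).  Exact position matching would be brittle against
alignment jitter around indels.  "Closely related" defaults to the leaves
under the species' parent node (`sister_clade`); `k_nearest` (patristic
k-NN, default k=2) and a fixed-radius `distance` mode are provided because
the notion is inherently scale-dependent.

For ancestral reconstruction, statuses collapse to presence/absence:
INTACT and PARTIAL copies still encode an ORF and count as present;
PSEUDOGENE and ABSENT count as absent; EXCLUDED species carry no evidence
and are dropped (default) rather than imputed.

## Dollo reconstruction

An intact gene can be pseudogenized independently many times but is, for
practical purposes, never resurrected; this is Dollo parsimony.  Under a
loss-only model with a present root, the minimal history has a closed
form: an ancestor possessed the gene iff at least one descendant leaf
does, and every present→absent edge is one loss.  `dollo_reconstruct`
implements this in one postorder pass; `brute_force_min_losses`
exhaustively enumerates all admissible internal-state assignments on small
trees and serves as an independent oracle (the two agree on every rooted
binary topology with ≤ 6 leaves under every presence pattern, and on 500
random 7–8-leaf instances — see `tests/test_acceptance.py`).

Losses on internal edges are labelled `stem`: "bottleneck" events
inherited by an entire descendant clade, such as the loss of the second
visual cyclase on the sauropsid stem.  Losses on terminal edges are
`terminal`: recent, species-specific events, such as a fossorial rodent
losing a visual gene on its own branch.  When the input tree carries
branch lengths, each event is annotated with the (parent-depth,
child-depth) interval; the package only echoes input ages and performs no
divergence-time estimation.

A gene absent from every leaf is unidentifiable under a loss-only model
(there is no evidence the root ever had it); this is an error unless the
caller asserts root presence, in which case it is reported as a single
loss spanning all leaves.  Polytomies are handled natively.

## Alignment curation

For users who build protein trees from the scanned genes, `curation`
reimplements classic block-based alignment cleaning with explicit column
provenance.  Four ordered rules: (1) drop all gap-containing columns;
(2) on the survivors, delete every run of more than `max_nonconserved_run`
(default 8) contiguous nonconserved columns; (3) split into blocks at the
deletions and trim each block to flank-grade terminal columns (modal
residue fraction ≥ `flank_min_fraction`, default 0.55); (4) keep blocks of
at least `min_block_length` (default 5) columns.  A column is conserved
when a strict majority (> 0.5) of sequences share its modal residue; both
fractions are configurable since block-filtering tools differ in their
internal thresholds.  With the default thresholds flank-grade implies
conserved, which makes curation idempotent.  The implementation is checked
against an independent, deliberately naive rule-by-rule oracle on random
alignments.

## Orthology verification

Gene identity is confirmed by reciprocal best hit (RBH).  Candidate CDS
pairs are compared by Smith–Waterman local alignment of their translations
over all 3×3 forward frame pairs (all 6×6 via `frames=6`), BLOSUM62,
affine gaps (open 11, extend 1).  At the scale of one gene family,
exhaustive pairwise scoring needs no heuristic seeding and no E-value
statistics; the raw score ranks hits, with ties broken by alignment
length, then identity, then lexicographic id, making results
deterministic.  A hit is confirmed when the best subject's own best hit
back in the query set is the original query.

## The synthetic-data generator

Real inputs to this kind of survey are manually curated genome
extractions that cannot be redistributed; the generator produces datasets
with the same structure and *exact* ground truth.

* **Tree**: Yule (pure-birth) process with `n_species` (default 12)
  extant tips, branch lengths rescaled to unit root height.  The analysis
  consumes topology and relative depth only, so branch-length realism
  beyond ultrametricity is not modelled.
* **Genes**: 3 families by default (named gcD/gcE/gcF), each a random ORF
  of `root_cds_length_codons` (default 360) codons split into `n_exons`
  (default 3) exons — matching the practice of surveying the variable
  first exons of a large gene rather than its full 16-exon span.  Leaf
  proteins fall in the 300–520 aa envelope typical of such queries.
* **Intact evolution**: per-branch Poisson point substitutions at
  `subst_rate` (default 0.05 expected substitutions per site root-to-tip),
  with any hit that would create a premature stop, destroy the start, or
  destroy the terminal stop redrawn.  No indels and no codon model: the
  downstream analysis consumes lesions, not substitution statistics, so a
  richer model would add cost without test power.
* **Loss and pseudogenization**: by default two internal ("stem") branches
  are chosen (never for gcE, whose real-world counterpart is never lost)
  and each receives a shared lesion set of `min_truth_lesions` (default 2)
  — inherited by every descendant leaf, exactly as a real pre-split lesion
  would be — plus Poisson(`post_loss_indel_rate`, default 0.5) private
  lesions per leaf.  Lesions are frameshifting indels (geometric lengths,
  multiples of 3 rejected), nonsense substitutions, and splice-dinucleotide
  edits, placed ≥30 nt apart and away from the start/terminal codons.
  Relaxed constraint after loss is realised through these explicit,
  recorded edits while background substitution stays ORF-constrained; a
  free-drift simulation would create unrecorded stops and make exact
  truth-comparison impossible.
* **Artifacts**: chosen (species, gene) extractions are corrupted with a
  run of Ns covering 25% of the CDS, which must trip the QC stage.
* **Assembly**: each gene copy is embedded in its own contig with random
  flanks and fresh GT..AG introns (76–196 nt), on a random strand.
  Introns are generated, not evolved, so splice-lesion truth is exact.

Everything is deterministic per (`tree_seed`, `seq_seed`).

What passing on this generator does **not** show about real data: the
generator has no paralogs or processed pseudogenes to misidentify (the
RBH stage is exercised separately), no alignment-degrading indel drift in
intact lineages, no annotation errors in exon coordinates, and its
contigs are single-gene.  Results on real genomes will be limited by
assembly and annotation quality in ways the QC thresholds only partially
capture.

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; GFF3's 1-based closed
  intervals are converted at the I/O boundary only.  Minus-strand CDS are
  spliced in ascending genomic order, then reverse-complemented.
* The 6-nt shared-position/matching tolerance absorbs alignment jitter
  around indels.  A known residual: when an indel falls in a repetitive
  or substitution-dense context, the score-optimal (left-aligned) gap
  placement can genuinely sit more than 6 nt from the mutational event;
  in simulation this affects on the order of 0.1% of injected indels.
* Ties in curation's modal-residue count cannot exceed 50% and are
  therefore nonconserved under the strict-majority rule; no tie-break is
  needed.
* `translate` ignores a trailing partial codon; ambiguous codons render X
  and never count as stops, so N-masked regions cannot create nonsense
  calls.
* Problem sizes used by the test suite and the acceptance script —
  exhaustive Dollo checking to 6 leaves plus 500 random 7–8-leaf
  instances, 100 intact-only and 50 lesion-injected replicates of the
  12-species × 3-gene dataset, 200 random curation alignments — were
  chosen as the smallest sets that exercise every code path many times
  over while keeping a full run in the low minutes.

## Known limitations

* Detection is reference-based: a family member too diverged to align
  reliably to the chosen reference will be misreported (usually as
  EXCLUDED via coverage).
* Whole-exon deletions are not given a dedicated lesion type; they
  surface as frameshift and/or coverage evidence.  TRUNCATION is emitted
  only for degenerate (<4 nt) introns.
* PARTIAL is a statement about evidence, not biology: one real lesion and
  one artifact look identical at this level.
* Dollo is the right model only when re-gain is impossible; it will
  overcount losses for gene families with frequent horizontal transfer or
  functional resurrection.
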