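"""Synthetic gene families evolving (and dying) along a species tree.

The generator emulates the data underlying a comparative gene-loss survey:
a small family of multi-exon coding genes evolves along a Yule species
tree; on chosen branches a gene is lost and its descendants accumulate
ORF-inactivating lesions (frameshifting indels, premature stops, splice
dinucleotide disruptions); assembly artefacts (runs of N) can corrupt
chosen extractions.  Every injected event is recorded in a ground-truth
object so detectors and the full pipeline can be scored exactly.

Deliberate simplifications, chosen so the truth stays exact: intact
lineages evolve by ORF-preserving point substitution only (no indels, no
codon model); introns are generated fresh per species rather than evolved,
with canonical GT..AG ends; lesions are injected as explicit edits at
recorded reference coordinates instead of emerging from relaxed
simulation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy

from .formats import (
    GeneModel,
    SequenceRecord,
    write_fasta,
    write_gff3_gene_models,
    write_newick,
)
from .lesions import STOP_CODONS, Lesion, revcomp
from .tree import SpeciesTree, TreeNode

_BASES = "ACGT"
_STOPS = sorted(STOP_CODONS)


@dataclass
class SimConfig:
    n_species: int = 12
    tree_seed: int = 42
    seq_seed: int = 1042
    genes: tuple[str, ...] = ("gcD", "gcE", "gcF")
    root_cds_length_codons: int = 360
    n_exons: int = 3
    subst_rate: float = 0.05  # expected substitutions/site, root to tip
    #: gene -> list of loss-branch child-node labels; None = auto-pick stems
    loss_branches: Optional[dict[str, list[str]]] = None
    n_stem_losses: int = 2
    min_truth_lesions: int = 2
    post_loss_indel_rate: float = 0.5  # expected private lesions per pseudo leaf
    post_loss_stop_bias: float = 0.5  # fraction of injected lesions that are stops
    n_run_rate: float = 0.0  # per-(species,gene) probability of N corruption
    corrupt_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need >= 2 species")
        if self.root_cds_length_codons < 30:
            raise ValueError("root CDS must be >= 30 codons")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        for r in (self.subst_rate, self.post_loss_indel_rate, self.n_run_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    loss_events: list[tuple[str, str]] = field(default_factory=list)  # (gene, child label)
    lesions: dict[tuple[str, str], list[Lesion]] = field(default_factory=dict)
    corrupted: set[tuple[str, str]] = field(default_factory=set)
    pseudo_leaves: dict[str, set[str]] = field(default_factory=dict)  # gene -> leaves

    def true_status(self, species: str, gene: str) -> str:
        if (species, gene) in self.corrupted:
            return "EXCLUDED"
        if species in self.pseudo_leaves.get(gene, set()):
            return "PSEUDOGENE"
        return "INTACT"

    def to_json(self) -> str:
        payload = {
            "loss_events": [list(ev) for ev in self.loss_events],
            "corrupted": sorted(list(p) for p in self.corrupted),
            "pseudo_leaves": {g: sorted(v) for g, v in self.pseudo_leaves.items()},
            "lesions": {
                f"{sp}|{gene}": [
                    {
                        "kind": l.kind,
                        "cds_pos": l.cds_pos,
                        "detail": l.detail,
                        "exon_index": l.exon_index,
                    }
                    for l in lst
                ]
                for (sp, gene), lst in sorted(self.lesions.items())
            },
        }
        return json.dumps(payload, indent=1)


@dataclass
class Dataset:
    """In-memory view of a generated dataset (also written to disk)."""

    config: SimConfig
    tree: SpeciesTree
    references: dict[str, str]  # gene -> root CDS
    cds: dict[tuple[str, str], str]  # (species, gene) -> leaf CDS (post-lesion)
    contigs: dict[tuple[str, str], str]
    models: dict[tuple[str, str], GeneModel]
    exon_boundaries: dict[str, list[int]]  # gene -> CDS offsets of exon ends
    truth: SimTruth


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(n_species: int, seed: int) -> SpeciesTree:
    """Yule (pure-birth) tree with ``n_species`` extant tips, branch lengths
    rescaled to unit root height.  Leaves are named ``sp01..`` in tree
    order, internal nodes ``anc1..`` in postorder.  Deterministic per seed."""
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = random.Random(seed)
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # the process stops at the n-th split, leaving zero-length cherries;
    # run the clock one more exponential waiting time so tips diverge
    extra = rng.expovariate(n_species)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra

    def convert(dnode) -> TreeNode:
        node = TreeNode(length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None

    def walk(node: TreeNode):
        for child in node.children:
            yield from walk(child)
        yield node

    # rescale to unit root height
    depths: dict[int, float] = {}
    height = 0.0
    stack = [(root, 0.0)]
    while stack:
        node, d = stack.pop()
        depths[id(node)] = d
        if node.is_leaf:
            height = max(height, d)
        for child in node.children:
            stack.append((child, d + (child.length or 0.0)))
    for node in walk(root):
        if node.length is not None and height > 0:
            node.length /= height

    leaf_i = anc_i = 0
    for node in walk(root):
        if node.is_leaf:
            leaf_i += 1
            node.label = f"sp{leaf_i:02d}"
        else:
            anc_i += 1
            node.label = f"anc{anc_i}"
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# intact evolution


def random_orf(n_codons: int, rng: random.Random) -> str:
    """ATG + random non-stop codons + terminal stop; length ``n_codons``."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES) for _ in range(3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def _constrained_substitute(seq: list[str], rate_per_branch: float, rng: random.Random) -> None:
    """Apply Poisson-many ORF-preserving point substitutions in place."""
    n = _poisson(rate_per_branch * len(seq), rng)
    n_codons = len(seq) // 3
    for _ in range(n):
        for _try in range(100):
            pos = rng.randrange(len(seq))
            new = rng.choice([b for b in _BASES if b != seq[pos]])
            ci = pos // 3
            codon = seq[3 * ci : 3 * ci + 3]
            codon[pos % 3] = new
            codon_s = "".join(codon)
            if ci == 0:
                continue  # never touch the start codon
            if ci == n_codons - 1:
                if codon_s not in STOP_CODONS:
                    continue  # terminal stop must stay a stop
            elif codon_s in STOP_CODONS:
                continue  # no premature stop in an intact lineage
            seq[pos] = new
            break


def _poisson(lam: float, rng: random.Random) -> int:
    # Knuth's method; lambdas here are small (tens at most)
    if lam <= 0:
        return 0
    l = pow(2.718281828459045, -lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= l:
            return k
        k += 1


def evolve_intact_cds(
    root_cds: str, tree: SpeciesTree, subst_rate: float, seed: int | random.Random
) -> dict[str, str]:
    """Evolve an intact ORF along every branch by constrained substitution;
    returns leaf-label -> cDNA.  All outputs are lesion-free ORFs."""
    if not root_cds.startswith("ATG") or root_cds[-3:] not in STOP_CODONS:
        raise ValueError("root CDS must start with ATG and end with a stop")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    seqs: dict[int, list[str]] = {id(tree.root): list(root_cds)}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        seq = list(seqs[id(node.parent)])
        _constrained_substitute(seq, subst_rate * (node.length or 0.0), rng)
        seqs[id(node)] = seq
        if node.is_leaf:
            out[node.label] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# pseudogenization


def _draw_position(rng: random.Random, length: int, used: list[int], min_gap: int = 30) -> int:
    for _ in range(200):
        pos = rng.randrange(12, length - 30)
        if all(abs(pos - u) >= min_gap for u in used):
            return pos
    raise RuntimeError("could not place a lesion away from existing ones")


def _draw_lesion(
    rng: random.Random,
    length: int,
    used: list[int],
    stop_bias: float,
    intron_positions: list[int],
    used_introns: set[int],
) -> Lesion:
    n_introns = len(intron_positions)
    roll = rng.random()
    if (
        n_introns > 0
        and len(used_introns) < n_introns
        and roll >= stop_bias
        and rng.random() < 0.25
    ):
        intron = rng.choice([i for i in range(n_introns) if i not in used_introns])
        used_introns.add(intron)
        kind = rng.choice(["SPLICE_DONOR", "SPLICE_ACCEPTOR"])
        pos = intron_positions[intron]
        used.append(pos)
        return Lesion(kind=kind, cds_pos=pos, detail=f"intron{intron}", exon_index=intron)
    if roll < stop_bias:
        ci = _draw_position(rng, length, used) // 3
        used.append(ci * 3)
        return Lesion(kind="NONSENSE", cds_pos=ci, detail=rng.choice(_STOPS))
    pos = _draw_position(rng, length, used)
    used.append(pos)
    size = 0
    while size == 0 or size % 3 == 0:
        size = 1 + _geometric(rng, 0.5, cap=8)
    sign = rng.choice(["+", "-"])
    return Lesion(kind="FRAMESHIFT", cds_pos=pos, detail=f"{sign}{size}")


def _geometric(rng: random.Random, p: float, cap: int) -> int:
    k = 0
    while k < cap and rng.random() > p:
        k += 1
    return k


def _apply_lesions(cds: str, lesions: list[Lesion], rng: random.Random) -> str:
    """Apply nonsense/frameshift edits (splice lesions are applied at genome
    assembly).  Edits are applied right-to-left so recorded reference
    coordinates stay valid."""
    seq = list(cds)
    editable = [l for l in lesions if l.kind in ("NONSENSE", "FRAMESHIFT")]
    for les in sorted(editable, key=lambda l: -(l.cds_pos * 3 if l.kind == "NONSENSE" else l.cds_pos)):
        if les.kind == "NONSENSE":
            seq[3 * les.cds_pos : 3 * les.cds_pos + 3] = list(les.detail)
        else:
            size = int(les.detail[1:])
            if les.detail[0] == "-":
                del seq[les.cds_pos : les.cds_pos + size]
            else:
                ins = [rng.choice(_BASES) for _ in range(size)]
                seq[les.cds_pos : les.cds_pos] = ins
    return "".join(seq)


def inject_pseudogenization(
    tree: SpeciesTree,
    gene: str,
    loss_branches: list[str],
    sequences: dict[str, str],
    exon_boundaries: list[int],
    config: SimConfig,
    rng: random.Random,
) -> tuple[dict[str, str], SimTruth]:
    """Overlay inactivating lesions on the leaves below each loss branch.

    Each loss branch receives a shared lesion set (>= ``min_truth_lesions``)
    inherited by every descendant leaf, plus Poisson-many private lesions
    per leaf, so every pseudo-leaf exceeds the solo calling threshold and
    sister species share homologous lesions, as inherited lesions do.
    Returns the updated leaf sequences and the per-gene truth.
    """
    truth = SimTruth()
    intron_positions = exon_boundaries[:-1]  # CDS offsets of intron starts
    # nesting check: a listed branch must not be an ancestor of another
    nodes = {label: tree.find_node(label) for label in loss_branches}
    for a in loss_branches:
        for b in loss_branches:
            if a == b:
                continue
            leaves_a = {l.label for l in SpeciesTree.subtree_leaves(nodes[a])}
            leaves_b = {l.label for l in SpeciesTree.subtree_leaves(nodes[b])}
            if leaves_a & leaves_b:
                raise ValueError(
                    f"loss branches {a!r} and {b!r} overlap for gene {gene!r}"
                )

    out = dict(sequences)
    truth.pseudo_leaves[gene] = set()
    for label in loss_branches:
        truth.loss_events.append((gene, label))
        node = nodes[label]
        leaves = [l.label for l in SpeciesTree.subtree_leaves(node)]
        ref_length = min(len(sequences[l]) for l in leaves)
        shared_used: list[int] = []
        shared_introns: set[int] = set()
        shared = [
            _draw_lesion(
                rng, ref_length, shared_used, config.post_loss_stop_bias,
                intron_positions, shared_introns,
            )
            for _ in range(config.min_truth_lesions)
        ]
        for leaf in sorted(leaves):
            used = list(shared_used)
            used_introns = set(shared_introns)
            private = [
                _draw_lesion(
                    rng, ref_length, used, config.post_loss_stop_bias,
                    intron_positions, used_introns,
                )
                for _ in range(_poisson(config.post_loss_indel_rate, rng))
            ]
            all_lesions = shared + private
            out[leaf] = _apply_lesions(out[leaf], all_lesions, rng)
            truth.lesions[(leaf, gene)] = sorted(
                all_lesions, key=lambda l: (l.cds_pos, l.kind)
            )
            truth.pseudo_leaves[gene].add(leaf)
    return out, truth


# ---------------------------------------------------------------------------
# genome assembly & dataset generation


def _split_exons(length: int, n_exons: int, rng: random.Random) -> list[int]:
    """CDS offsets at which exons end (ascending, excluding 0, including
    ``length``)."""
    if n_exons == 1:
        return [length]
    while True:
        cuts = sorted(
            rng.randrange(30, length - 30) for _ in range(n_exons - 1)
        )
        if all(b - a >= 30 for a, b in zip(cuts, cuts[1:])):
            return cuts + [length]


def _random_seq(n: int, rng: random.Random) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def mask_with_n_run(cds: str, rng: random.Random, fraction: float = 0.25) -> str:
    """Replace a contiguous run covering ``fraction`` of the CDS with Ns,
    emulating an unresolved assembly region."""
    n_mask = max(1, int(fraction * len(cds)))
    start = rng.randrange(0, len(cds) - n_mask + 1)
    return cds[:start] + "N" * n_mask + cds[start + n_mask:]


def _assemble_contig(
    cds: str,
    boundaries: list[int],
    splice_lesions: list[Lesion],
    strand: str,
    rng: random.Random,
) -> tuple[str, list[tuple[int, int]]]:
    """Embed a CDS into a contig with introns and flanks; returns the contig
    and the exon intervals (ascending genomic order)."""
    # exon pieces in transcription order; boundaries are CDS offsets
    starts = [0] + boundaries[:-1]
    pieces = [cds[s:e] for s, e in zip(starts, boundaries)]

    bad_donor = {l.exon_index: "CC" for l in splice_lesions if l.kind == "SPLICE_DONOR"}
    bad_acceptor = {l.exon_index: "CC" for l in splice_lesions if l.kind == "SPLICE_ACCEPTOR"}

    flank5 = _random_seq(rng.randrange(60, 121), rng)
    flank3 = _random_seq(rng.randrange(60, 121), rng)
    region = [flank5]
    exon_spans: list[tuple[int, int]] = []
    cursor = len(flank5)
    for i, piece in enumerate(pieces):
        exon_spans.append((cursor, cursor + len(piece)))
        region.append(piece)
        cursor += len(piece)
        if i < len(pieces) - 1:
            donor = bad_donor.get(i, "GT")
            acceptor = bad_acceptor.get(i, "AG")
            body = _random_seq(rng.randrange(76, 196), rng)
            intron = donor + body + acceptor
            region.append(intron)
            cursor += len(intron)
    region.append(flank3)
    contig = "".join(region)

    if strand == "-":
        total = len(contig)
        contig = revcomp(contig)
        exon_spans = sorted((total - e, total - s) for s, e in exon_spans)
    return contig, exon_spans


def generate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> Dataset:
    """Generate a full dataset (tree, per-species contigs, gene models,
    references, truth); optionally write it to ``out_dir``.

    Layout on disk: ``tree.nwk``, ``reference.fasta``, ``models.gff3``,
    ``genomes/<species>.fasta``, ``truth.json``.
    """
    tree = simulate_tree(config.n_species, config.tree_seed)
    rng = random.Random(config.seq_seed)
    length_nt = config.root_cds_length_codons * 3

    # choose loss branches
    loss_branches = config.loss_branches
    if loss_branches is None:
        candidates = [
            n.label
            for n in tree.postorder()
            if not n.is_leaf
            and n is not tree.root
            and 2 <= len(SpeciesTree.subtree_leaves(n)) <= max(2, config.n_species // 2)
        ]
        loss_branches = {}
        lossy_genes = [g for g in config.genes if g != "gcE"][: config.n_stem_losses]
        if not candidates and config.n_stem_losses > 0:
            raise ValueError("tree has no internal stem branch to place a loss on")
        for gene in lossy_genes:
            loss_branches[gene] = [rng.choice(candidates)]

    references: dict[str, str] = {}
    boundaries: dict[str, list[int]] = {}
    cds: dict[tuple[str, str], str] = {}
    truth = SimTruth()
    for gene in config.genes:
        root_cds = random_orf(config.root_cds_length_codons, rng)
        references[gene] = root_cds
        boundaries[gene] = _split_exons(length_nt, config.n_exons, rng)
        leaf_seqs = evolve_intact_cds(root_cds, tree, config.subst_rate, rng)
        branches = loss_branches.get(gene, [])
        if branches:
            leaf_seqs, gene_truth = inject_pseudogenization(
                tree, gene, branches, leaf_seqs, boundaries[gene],
                config, rng,
            )
            truth.loss_events.extend(gene_truth.loss_events)
            truth.lesions.update(gene_truth.lesions)
            truth.pseudo_leaves.update(gene_truth.pseudo_leaves)
        for sp, seq in leaf_seqs.items():
            cds[(sp, gene)] = seq

    # QC corruption
    corrupt = set(config.corrupt_pairs)
    for sp in tree.leaf_labels():
        for gene in config.genes:
            if config.n_run_rate > 0 and rng.random() < config.n_run_rate:
                corrupt.add((sp, gene))
    truth.corrupted = corrupt

    contigs: dict[tuple[str, str], str] = {}
    models: dict[tuple[str, str], GeneModel] = {}
    for sp in tree.leaf_labels():
        for gene in config.genes:
            strand = rng.choice("+-")
            gene_truth_lesions = truth.lesions.get((sp, gene), [])
            splice = [
                l for l in gene_truth_lesions
                if l.kind in ("SPLICE_DONOR", "SPLICE_ACCEPTOR")
            ]
            seq = cds[(sp, gene)]
            if (sp, gene) in corrupt:
                seq = mask_with_n_run(seq, rng)
            # splits refer to the reference CDS; indels in this copy may
            # have shortened it, so clamp while keeping order
            bnds: list[int] = []
            prev = 0
            for b in boundaries[gene][:-1]:
                b = max(prev + 10, min(b, len(seq) - 10))
                if b <= prev:
                    raise RuntimeError("cannot place exon boundaries in CDS")
                bnds.append(b)
                prev = b
            bnds.append(len(seq))
            contig, exon_spans = _assemble_contig(seq, bnds, splice, strand, rng)
            contigs[(sp, gene)] = contig
            models[(sp, gene)] = GeneModel(
                gene_id=f"{sp}__{gene}",
                species=sp,
                contig=f"{sp}|{gene}",
                strand=strand,
                exons=exon_spans,
            )

    dataset = Dataset(
        config=config,
        tree=tree,
        references=references,
        cds=cds,
        contigs=contigs,
        models=models,
        exon_boundaries=boundaries,
        truth=truth,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: Dataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "genomes").mkdir(exist_ok=True)
    write_newick(ds.tree, out / "tree.nwk")
    write_fasta(
        [SequenceRecord(id=g, seq=s) for g, s in sorted(ds.references.items())],
        out / "reference.fasta",
    )
    write_gff3_gene_models(
        [ds.models[k] for k in sorted(ds.models)], out / "models.gff3"
    )
    for sp in ds.tree.leaf_labels():
        recs = [
            SequenceRecord(id=f"{sp}|{gene}", seq=ds.contigs[(sp, gene)])
            for gene in ds.config.genes
        ]
        write_fasta(recs, out / "genomes" / f"{sp}.fasta")
    (out / "truth.json").write_text(ds.truth.to_json())
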