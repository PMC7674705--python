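"""Detection of ORF-inactivating lesions in a gene copy.

A *lesion* is a mutation that destroys the encoded protein: a frameshifting
indel, a premature (nonsense) stop codon, a disrupted splice-site
dinucleotide, or loss of the start codon.  Detection is reference-based:
the candidate coding sequence is extracted from its genomic context via a
gene model, aligned to an intact reference CDS, and scanned.

Two conventions keep one biological event from being counted twice:

* Frameshifts are counted per *maximal gap run* in the pairwise alignment
  (an indel of length not divisible by 3).  Two compensating shifts count as
  two events even though they restore the net frame — the intervening
  peptide is still destroyed.
* Nonsense codons are read in the frame *restored by the reference
  alignment*: the target is projected onto reference codon coordinates, so
  stop triplets that exist only in the shifted reading frame of a
  frameshifted region are not additionally reported as nonsense lesions.

Lesion ``cds_pos`` is a 0-based nucleotide offset in the spliced CDS
(reference coordinates where an alignment is involved), except NONSENSE
lesions, whose position is the reference codon index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio.Seq import Seq

from .formats import GeneModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: canonical major (GT-AG, GC-AG) and minor-spliceosome (AT-AC) intron ends
DEFAULT_SPLICE_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

LESION_KINDS = (
    "NONSENSE",
    "FRAMESHIFT",
    "SPLICE_DONOR",
    "SPLICE_ACCEPTOR",
    "START_LOSS",
    "TRUNCATION",
)


@dataclass(frozen=True)
class Lesion:
    kind: str
    cds_pos: int
    genomic_pos: Optional[int] = None
    detail: str = ""
    exon_index: Optional[int] = None
    rescuable: bool = False

    def __post_init__(self):
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class QCResult:
    n_fraction: float
    coverage: float
    passed: bool


@dataclass
class ScanParams:
    max_n_fraction: float = 0.05
    min_coverage: float = 0.9
    accepted_splice_pairs: frozenset = DEFAULT_SPLICE_PAIRS
    rescue_window: int = 60  # codons searched for an alternative in-frame start


@dataclass
class LesionReport:
    gene: str
    species: str
    lesions: list[Lesion] = field(default_factory=list)
    qc: Optional[QCResult] = None
    excluded: bool = False

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


# ---------------------------------------------------------------------------
# sequence plumbing

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(contig_seq: str, gene_model: GeneModel) -> str:
    """Splice exons (ascending genomic order) and reverse-complement for
    minus-strand models, yielding the CDS in transcription orientation."""
    for start, end in gene_model.exons:
        if start < 0 or end > len(contig_seq):
            raise ValueError(
                f"{gene_model.gene_id}: exon [{start},{end}) outside contig "
                f"of length {len(contig_seq)}"
            )
    spliced = "".join(contig_seq[s:e] for s, e in gene_model.exons)
    return revcomp(spliced) if gene_model.strand == "-" else spliced


def slice_first_exons(gene_model: GeneModel, k: int) -> GeneModel:
    """Restrict a gene model to its first ``k`` exons in transcription order
    (for minus-strand genes these are the ``k`` highest genomic intervals)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= gene_model.n_exons:
        return gene_model
    if gene_model.strand == "+":
        exons = gene_model.exons[:k]
    else:
        exons = gene_model.exons[-k:]
    return replace(gene_model, exons=list(exons))


def translate(cdna: str) -> str:
    """Standard-code translation; stops rendered ``*``; a trailing partial
    codon is ignored with a warning."""
    usable = len(cdna) - len(cdna) % 3
    if usable != len(cdna):
        logging.getLogger(__name__).warning(
            "translate: ignoring %d trailing nt", len(cdna) - usable
        )
    if not usable:
        return ""
    return str(Seq(cdna[:usable]).translate())


# ---------------------------------------------------------------------------
# individual detectors


def detect_nonsense(cdna: str, codon_offset: int = 0) -> list[Lesion]:
    """One NONSENSE lesion per in-frame premature stop codon.  The terminal
    stop (last complete codon) is never a lesion.  ``cds_pos`` is the codon
    index (plus ``codon_offset``)."""
    if len(cdna) < 3:
        raise ValueError("cdna shorter than one codon")
    n_codons = len(cdna) // 3
    lesions = []
    for i in range(n_codons - 1):
        codon = cdna[3 * i : 3 * i + 3].upper()
        if codon in STOP_CODONS:
            lesions.append(
                Lesion(kind="NONSENSE", cds_pos=i + codon_offset, detail=codon)
            )
    return lesions


def detect_frameshifts(target_row: str, reference_row: str) -> list[Lesion]:
    """Frameshifting indels from two rows of one pairwise alignment.

    Each maximal run of ``-`` in either row whose length is not divisible by
    3 yields one FRAMESHIFT lesion positioned at the reference-CDS offset of
    the run's left edge.  In-frame indels yield nothing.
    """
    if len(target_row) != len(reference_row):
        raise ValueError("alignment rows differ in length")
    lesions = []
    ref_pos = 0
    i = 0
    n = len(target_row)
    while i < n:
        t, r = target_row[i], reference_row[i]
        if t == "-" and r != "-":  # deletion in target
            j = i
            while j < n and target_row[j] == "-" and reference_row[j] != "-":
                j += 1
            run = j - i
            if run % 3 != 0:
                lesions.append(
                    Lesion(kind="FRAMESHIFT", cds_pos=ref_pos, detail=f"-{run}")
                )
            ref_pos += run
            i = j
        elif r == "-" and t != "-":  # insertion in target
            j = i
            while j < n and reference_row[j] == "-" and target_row[j] != "-":
                j += 1
            run = j - i
            if run % 3 != 0:
                lesions.append(
                    Lesion(kind="FRAMESHIFT", cds_pos=ref_pos, detail=f"+{run}")
                )
            i = j
        else:
            if r != "-":
                ref_pos += 1
            i += 1
    return lesions


def check_splice_sites(
    contig_seq: str,
    gene_model: GeneModel,
    accepted_pairs: Iterable[tuple[str, str]] = DEFAULT_SPLICE_PAIRS,
) -> list[Lesion]:
    """Validate the intron-terminal dinucleotides of every intron.

    Each intron (in transcription orientation) must begin and end with a
    (donor, acceptor) pair from ``accepted_pairs``; a deviating side emits a
    SPLICE_DONOR / SPLICE_ACCEPTOR lesion carrying the observed 2-mer.
    Introns shorter than 4 nt emit a TRUNCATION lesion instead.
    """
    accepted = set(accepted_pairs)
    donors = {d for d, _ in accepted}
    acceptors = {a for _, a in accepted}
    lesions = []
    exons_tx = gene_model.exons_in_transcription_order()
    cds_offset = 0
    for i in range(len(exons_tx) - 1):
        exon = exons_tx[i]
        nxt = exons_tx[i + 1]
        cds_offset += exon[1] - exon[0]
        if gene_model.strand == "+":
            intron = contig_seq[exon[1] : nxt[0]]
        else:
            intron = revcomp(contig_seq[nxt[1] : exon[0]])
        exon_idx = (
            i if gene_model.strand == "+" else gene_model.n_exons - 1 - i
        )
        if len(intron) < 4:
            lesions.append(
                Lesion(
                    kind="TRUNCATION",
                    cds_pos=cds_offset,
                    detail=f"intron {i} shorter than 4 nt",
                    exon_index=exon_idx,
                )
            )
            continue
        donor = intron[:2].upper()
        acceptor = intron[-2:].upper()
        if (donor, acceptor) in accepted:
            continue
        if donor not in donors:
            lesions.append(
                Lesion(
                    kind="SPLICE_DONOR",
                    cds_pos=cds_offset,
                    detail=donor,
                    exon_index=exon_idx,
                )
            )
        if acceptor not in acceptors:
            lesions.append(
                Lesion(
                    kind="SPLICE_ACCEPTOR",
                    cds_pos=cds_offset,
                    detail=acceptor,
                    exon_index=exon_idx,
                )
            )
        if donor in donors and acceptor in acceptors:
            # both 2-mers occur in accepted pairs but not as this combination
            lesions.append(
                Lesion(
                    kind="SPLICE_DONOR",
                    cds_pos=cds_offset,
                    detail=f"{donor}..{acceptor}",
                    exon_index=exon_idx,
                )
            )
    return lesions


def detect_start_loss(cdna: str, rescue_window: int = 60) -> list[Lesion]:
    """START_LOSS when the first codon is not ATG.  The lesion is flagged
    ``rescuable`` when an in-frame ATG exists within ``rescue_window``
    codons, since translation could re-initiate downstream."""
    if len(cdna) < 3:
        raise ValueError("cdna shorter than one codon")
    if cdna[:3].upper() == "ATG":
        return []
    rescue_at = _first_inframe_atg(cdna, rescue_window)
    return [
        Lesion(
            kind="START_LOSS",
            cds_pos=0,
            detail=cdna[:3].upper(),
            rescuable=rescue_at is not None,
        )
    ]


def _first_inframe_atg(cdna: str, rescue_window: int) -> Optional[int]:
    """Codon index of the first in-frame ATG at codon 1..rescue_window."""
    limit = min(rescue_window, len(cdna) // 3 - 1)
    for i in range(1, limit + 1):
        if cdna[3 * i : 3 * i + 3].upper() == "ATG":
            return i
    return None


def quality_check(
    extracted_seq: str,
    expected_length: int,
    max_n_fraction: float = 0.05,
    min_coverage: float = 0.9,
) -> QCResult:
    """Exclude poor-quality extractions: too many Ns or too much missing."""
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    if not extracted_seq:
        return QCResult(n_fraction=1.0, coverage=0.0, passed=False)
    n_fraction = extracted_seq.upper().count("N") / len(extracted_seq)
    coverage = min(1.0, len(extracted_seq) / expected_length)
    passed = n_fraction <= max_n_fraction and coverage >= min_coverage
    return QCResult(n_fraction=n_fraction, coverage=coverage, passed=passed)


# ---------------------------------------------------------------------------
# composite scan


def project_to_reference(target_row: str, reference_row: str) -> str:
    """Target sequence in reference coordinates: one character per reference
    base (aligned target base, or ``N`` where the target is deleted);
    insertions in the target are dropped.  This restores the reference
    reading frame downstream of any frameshift."""
    out = []
    for t, r in zip(target_row, reference_row):
        if r == "-":
            continue
        out.append("N" if t == "-" else t)
    return "".join(out)


def scan_gene(
    contig_seq: str,
    gene_model: GeneModel,
    reference_cds: str,
    params: ScanParams | None = None,
) -> LesionReport:
    """Full reference-based lesion scan of one gene copy.

    Order of operations: quality check (failure short-circuits to an
    EXCLUDED report with no lesion calls); CDS extraction; global pairwise
    nucleotide alignment to the reference; frameshift detection on the
    alignment; nonsense detection in the reference-restored frame; splice
    site validation on the genomic model; start-codon check with downstream
    rescue annotation.
    """
    from .orthology import align_nucleotide_global

    params = params or ScanParams()
    report = LesionReport(gene=gene_model.gene_id, species=gene_model.species)

    target_cds = extract_cds(contig_seq, gene_model)
    report.qc = quality_check(
        target_cds,
        expected_length=len(reference_cds),
        max_n_fraction=params.max_n_fraction,
        min_coverage=params.min_coverage,
    )
    if not report.qc.passed:
        report.excluded = True
        return report

    target_row, ref_row = align_nucleotide_global(target_cds, reference_cds)
    lesions = detect_frameshifts(target_row, ref_row)

    projected = project_to_reference(target_row, ref_row)
    stops = detect_nonsense(projected)
    # a stop codon at an indel junction is a by-product of the frameshift,
    # not an independent nonsense event: suppress stops whose codon lies
    # within the alignment-jitter window of a frameshift's reference span
    fs_spans = []
    for les in lesions:
        if les.kind == "FRAMESHIFT":
            size = int(les.detail[1:])
            end = les.cds_pos + (size if les.detail.startswith("-") else 0)
            fs_spans.append((les.cds_pos - 6, end + 6))
    lesions.extend(
        s
        for s in stops
        if not any(lo < 3 * s.cds_pos + 3 and 3 * s.cds_pos < hi for lo, hi in fs_spans)
    )

    if gene_model.n_exons >= 2:
        lesions.extend(
            check_splice_sites(contig_seq, gene_model, params.accepted_splice_pairs)
        )
    lesions.extend(detect_start_loss(target_cds, params.rescue_window))

    # annotate lesions upstream of a usable alternative start as rescuable
    rescue_at = _first_inframe_atg(target_cds, params.rescue_window)
    if rescue_at is not None:
        flagged = []
        for les in lesions:
            nt_pos = les.cds_pos * 3 if les.kind == "NONSENSE" else les.cds_pos
            if nt_pos < rescue_at * 3 and not les.rescuable:
                les = replace(les, rescuable=True)
            flagged.append(les)
        lesions = flagged

    report.lesions = sorted(
        lesions, key=lambda l: (l.cds_pos, l.kind, l.detail)
    )
    return report
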