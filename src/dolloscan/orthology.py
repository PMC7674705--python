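"""Reciprocal-best-hit orthology via translated local alignment.

Candidate coding sequences are compared by Smith-Waterman local alignment
of their translations over all 3x3 forward frame pairs (optionally all 6
frames), scored with BLOSUM62 and affine gaps (open 11, extend 1).  The
best-scoring subject is the hit; orthology is confirmed when the best hit's
own best hit back in the query set is the original query.  Raw alignment
score ranks hits; ties break by alignment length, then identity, then
lexicographic id, so results are deterministic.

Also exports the global nucleotide aligner used by the lesion scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats import SequenceRecord


@dataclass(frozen=True)
class HitScore:
    query_id: str
    subject_id: str
    score: float
    aln_length: int
    identity: float
    frame_query: int = 0
    frame_subject: int = 0


@dataclass(frozen=True)
class RBHResult:
    confirmed: bool
    forward: Optional[HitScore]
    back: Optional[HitScore]

    @property
    def best_back_id(self) -> Optional[str]:
        return self.back.subject_id if self.back else None


# ---------------------------------------------------------------------------
# aligners


@lru_cache(maxsize=None)
def _protein_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=None)
def _nt_aligner() -> Align.PairwiseAligner:
    # global so end gaps register as indels; gaps are priced high relative
    # to mismatches because indels are rare in coding sequence -- a cheap
    # gap pair can otherwise "explain" a dense cluster of substitutions and
    # fabricate compensating frameshifts
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -3
    return aligner


def _left_align_gaps(gapped: list[str], solid: list[str]) -> None:
    """Shift every gap run in ``gapped`` to its leftmost score-equivalent
    position (standard indel normalisation), in place."""
    n = len(gapped)
    i = 0
    while i < n:
        if gapped[i] == "-" and solid[i] != "-":
            j = i
            while j < n and gapped[j] == "-" and solid[j] != "-":
                j += 1
            while (
                i > 0
                and gapped[i - 1] != "-"
                and solid[i - 1] != "-"
                and solid[i - 1] == solid[j - 1]
            ):
                gapped[j - 1] = gapped[i - 1]
                gapped[i - 1] = "-"
                i -= 1
                j -= 1
            i = j
        else:
            i += 1


def align_nucleotide_global(a: str, b: str) -> tuple[str, str]:
    """Global pairwise nucleotide alignment; returns the two gapped rows
    (row for ``a`` first).  Gap runs are left-aligned so indel positions
    are canonical under repeat-context ambiguity."""
    aln = _nt_aligner().align(a.upper(), b.upper())[0]
    row_a, row_b = list(str(aln[0])), list(str(aln[1]))
    _left_align_gaps(row_a, row_b)
    _left_align_gaps(row_b, row_a)
    return "".join(row_a), "".join(row_b)


# ---------------------------------------------------------------------------
# translated scoring


def _frame_translations(nt: str, frames: int) -> list[tuple[int, str]]:
    """Translations of the requested frames; frames 0..2 forward, 3..5 on
    the reverse complement.  Partial trailing codons are dropped."""
    out = []
    seqs = [nt.upper()]
    if frames == 6:
        seqs.append(str(Seq(nt).reverse_complement()).upper())
    for strand_i, seq in enumerate(seqs):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                out.append((strand_i * 3 + f, str(Seq(sub).translate())))
    return out


def translated_score(
    nt_a: str,
    nt_b: str,
    frames: int = 3,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> HitScore:
    """Best local protein alignment over all frame pairs of two nucleotide
    sequences.  Identity is computed over aligned, non-gap columns."""
    if len(nt_a) < 30 or len(nt_b) < 30:
        raise ValueError("sequences must be >= 30 nt for translated scoring")
    if frames not in (3, 6):
        raise ValueError("frames must be 3 or 6")
    aligner = _protein_aligner(matrix, gap_open, gap_extend)
    best: Optional[HitScore] = None
    for fa, prot_a in _frame_translations(nt_a, frames):
        for fb, prot_b in _frame_translations(nt_b, frames):
            alns = aligner.align(prot_a, prot_b)
            if len(alns) == 0:
                continue
            aln = alns[0]
            row_a, row_b = str(aln[0]), str(aln[1])
            pairs = [
                (x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"
            ]
            ident = (
                sum(1 for x, y in pairs if x == y) / len(pairs) if pairs else 0.0
            )
            hit = HitScore(
                query_id=query_id,
                subject_id=subject_id,
                score=float(aln.score),
                aln_length=len(row_a),
                identity=ident,
                frame_query=fa,
                frame_subject=fb,
            )
            if best is None or (hit.score, hit.aln_length, hit.identity) > (
                best.score,
                best.aln_length,
                best.identity,
            ):
                best = hit
    assert best is not None
    return best


def best_hit(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    frames: int = 3,
    **kwargs,
) -> Optional[HitScore]:
    """Highest-scoring subject for ``query``; ties broken by longer
    alignment, higher identity, then lexicographic subject id."""
    best: Optional[HitScore] = None
    for subject in database:
        hit = translated_score(
            query.seq,
            subject.seq,
            frames=frames,
            query_id=query.id,
            subject_id=subject.id,
            **kwargs,
        )
        if best is None:
            best = hit
            continue
        cand = (hit.score, hit.aln_length, hit.identity)
        incumbent = (best.score, best.aln_length, best.identity)
        if cand > incumbent or (
            cand == incumbent and hit.subject_id < best.subject_id
        ):
            best = hit
    return best


def reciprocal_best_hit(
    query_id: str,
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    frames: int = 3,
    **kwargs,
) -> RBHResult:
    """Confirm orthology: the best hit of ``query_id`` in ``set_b`` must
    itself have ``query_id`` as best hit back in ``set_a``."""
    by_id = {r.id: r for r in set_a}
    if query_id not in by_id:
        raise KeyError(f"{query_id!r} not in query set")
    forward = best_hit(by_id[query_id], set_b, frames=frames, **kwargs)
    if forward is None:
        return RBHResult(confirmed=False, forward=None, back=None)
    subject = next(r for r in set_b if r.id == forward.subject_id)
    back = best_hit(subject, set_a, frames=frames, **kwargs)
    confirmed = back is not None and back.subject_id == query_id
    return RBHResult(confirmed=confirmed, forward=forward, back=back)
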