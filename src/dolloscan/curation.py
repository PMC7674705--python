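"""Block-based curation of protein multiple alignments.

Removes ambiguous alignment regions before phylogenetic use, in the style
of classic block-filtering tools, with full column provenance.  Four rules
are applied in order:

1. columns containing a gap are removed (when ``allow_gaps`` is false);
2. on the remaining columns, every maximal run of more than
   ``max_nonconserved_run`` contiguous nonconserved columns is deleted;
3. the surviving stretches form candidate blocks, each trimmed until its
   first and last columns are flank-grade (modal-residue fraction >=
   ``flank_min_fraction``);
4. blocks shorter than ``min_block_length`` are dropped.

A column is *conserved* when its modal residue is shared by a strict
majority (> ``conserved_min_fraction``) of sequences.  ``column_map``
records, for every retained column, its index in the original alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


@dataclass
class CurationParams:
    min_block_length: int = 5
    max_nonconserved_run: int = 8
    flank_min_fraction: float = 0.55
    allow_gaps: bool = False
    conserved_min_fraction: float = 0.5  # strict: fraction must exceed this

    def __post_init__(self):
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")
        if self.max_nonconserved_run < 0:
            raise ValueError("max_nonconserved_run must be >= 0")
        for f in (self.flank_min_fraction, self.conserved_min_fraction):
            if not (0 < f <= 1):
                raise ValueError("fractions must be in (0, 1]")


@dataclass
class CuratedAlignment:
    rows: list[str]
    column_map: list[int] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def classify_column(column: str, params: CurationParams | None = None) -> str:
    """``gap`` / ``conserved`` / ``nonconserved`` for one alignment column."""
    params = params or CurationParams()
    if not column:
        raise ValueError("empty column")
    if not params.allow_gaps and "-" in column:
        return "gap"
    frac = _modal_fraction(column)
    return "conserved" if frac > params.conserved_min_fraction else "nonconserved"


def _modal_fraction(column: str) -> float:
    counts = Counter(c for c in column if c != "-")
    if not counts:
        return 0.0
    return max(counts.values()) / len(column)


def is_flank_grade(column: str, params: CurationParams | None = None) -> bool:
    params = params or CurationParams()
    return _modal_fraction(column) >= params.flank_min_fraction


def curate_alignment(
    msa: list[str], params: CurationParams | None = None
) -> CuratedAlignment:
    """Apply the four curation rules; see module docstring."""
    params = params or CurationParams()
    if len(msa) < 2:
        raise ValueError("need >= 2 aligned sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment")

    columns = ["".join(row[i] for row in msa) for i in range(width)]

    # rule 1: gap clearing
    kept = [
        i for i, col in enumerate(columns)
        if classify_column(col, params) != "gap"
    ]

    # rule 2: delete long nonconserved runs (measured after gap clearing)
    labels = [classify_column(columns[i], params) for i in kept]
    blocks: list[list[int]] = []
    current: list[int] = []
    i = 0
    n = len(kept)
    while i < n:
        if labels[i] == "nonconserved":
            j = i
            while j < n and labels[j] == "nonconserved":
                j += 1
            if j - i > params.max_nonconserved_run:
                # deletion: split candidate blocks here
                if current:
                    blocks.append(current)
                    current = []
            else:
                current.extend(kept[i:j])
            i = j
        else:
            current.append(kept[i])
            i += 1
    if current:
        blocks.append(current)

    # rule 3: trim each block to flank-grade terminal columns
    trimmed: list[list[int]] = []
    for block in blocks:
        lo, hi = 0, len(block) - 1
        while lo <= hi and not is_flank_grade(columns[block[lo]], params):
            lo += 1
        while hi >= lo and not is_flank_grade(columns[block[hi]], params):
            hi -= 1
        if lo <= hi:
            trimmed.append(block[lo : hi + 1])

    # rule 4: minimum block length
    column_map = [
        i for block in trimmed if len(block) >= params.min_block_length
        for i in block
    ]

    rows = ["".join(row[i] for i in column_map) for row in msa]
    return CuratedAlignment(rows=rows, column_map=column_map)
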