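"""Gene status classification from lesion reports.

The calling rule mirrors manual pseudogene annotation practice: a gene copy
is only called a pseudogene when the evidence is redundant — either it
carries more than one independent inactivating lesion, or its single lesion
is shared (same kind, homologous position) with a closely related species,
which implies the lesion predates their split and is real.  A single
private lesion yields the intermediate PARTIAL status (possible ongoing
pseudogenization, or an annotation/assembly artifact).

Statuses:

INTACT      no countable lesion
PARTIAL     lesions present but below the solo threshold and unshared
PSEUDOGENE  >= ``min_lesions_solo`` lesions, or a shared lesion
ABSENT      no sequence found for this species
EXCLUDED    extraction failed quality control
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .lesions import Lesion, LesionReport
from .tree import SpeciesTree

STATUSES = ("INTACT", "PARTIAL", "PSEUDOGENE", "ABSENT", "EXCLUDED")


@dataclass
class ClassificationParams:
    min_lesions_solo: int = 2
    neighbor_mode: str = "sister_clade"  # sister_clade | k_nearest | distance
    k: int = 2
    max_patristic_distance: Optional[float] = None
    shared_pos_tolerance: int = 6  # nt (codons for NONSENSE positions)
    count_rescuable: bool = True

    def __post_init__(self):
        if self.min_lesions_solo < 1:
            raise ValueError("min_lesions_solo must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.shared_pos_tolerance < 0:
            raise ValueError("shared_pos_tolerance must be >= 0")
        if self.neighbor_mode not in {"sister_clade", "k_nearest", "distance"}:
            raise ValueError(f"unknown neighbor_mode {self.neighbor_mode!r}")


@dataclass
class GeneStatusMatrix:
    """Mapping (species, gene) -> status; every pair in the declared
    universe has exactly one status."""

    statuses: dict[tuple[str, str], str] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> str:
        return self.statuses[key]

    @property
    def species(self) -> list[str]:
        return sorted({s for s, _ in self.statuses})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self.statuses})

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                gene: {sp: self.statuses[(sp, gene)] for sp in self.species
                       if (sp, gene) in self.statuses}
                for gene in self.genes
            }
        )
        frame.index.name = "species"
        return frame


# ---------------------------------------------------------------------------


def neighbors(tree: SpeciesTree, species: str, params: ClassificationParams) -> list[str]:
    """Species considered "closely related" to ``species``.

    ``sister_clade``: all other leaves under the species' parent node.
    ``k_nearest``: the k leaves at smallest patristic distance (topological
    when branch lengths are absent).  ``distance``: all leaves within
    ``max_patristic_distance``.
    """
    leaf = tree.find_leaf(species)  # raises KeyError if missing
    if params.neighbor_mode == "sister_clade":
        parent = leaf.parent
        if parent is None:
            return []
        return sorted(
            n.label for n in SpeciesTree.subtree_leaves(parent) if n.label != species
        )
    dists = [
        (tree.patristic_distance(species, other), other)
        for other in tree.leaf_labels()
        if other != species
    ]
    dists.sort()
    if params.neighbor_mode == "k_nearest":
        return [name for _, name in dists[: params.k]]
    if params.max_patristic_distance is None:
        raise ValueError("distance mode requires max_patristic_distance")
    return [name for d, name in dists if d <= params.max_patristic_distance]


def shared_lesion(
    lesion_a: Lesion, lesion_b: Lesion, params: ClassificationParams
) -> bool:
    """Same kind at the homologous position (both positions expressed in the
    shared reference coordinate), within the position tolerance."""
    return (
        lesion_a.kind == lesion_b.kind
        and abs(lesion_a.cds_pos - lesion_b.cds_pos) <= params.shared_pos_tolerance
    )


def _countable(report: LesionReport, params: ClassificationParams) -> list[Lesion]:
    if params.count_rescuable:
        return list(report.lesions)
    return [l for l in report.lesions if not l.rescuable]


def classify(
    lesion_reports: dict[tuple[str, str], Optional[LesionReport]],
    tree: SpeciesTree,
    params: ClassificationParams | None = None,
) -> GeneStatusMatrix:
    """Assign a status to every (species, gene) pair.

    ``lesion_reports`` maps each pair in the universe to its report, or to
    ``None`` when no sequence was found (-> ABSENT).  Reports flagged
    ``excluded`` become EXCLUDED.  Otherwise the calling rule applies:
    0 lesions -> INTACT; >= ``min_lesions_solo`` -> PSEUDOGENE; fewer, but
    with a lesion shared with a close relative -> PSEUDOGENE; else PARTIAL.
    """
    params = params or ClassificationParams()
    matrix = GeneStatusMatrix()
    tree_leaves = set(tree.leaf_labels())
    for (species, gene) in lesion_reports:
        if species not in tree_leaves:
            raise KeyError(f"species {species!r} not a leaf of the tree")

    neighbor_cache: dict[str, list[str]] = {}
    for (species, gene), report in sorted(lesion_reports.items()):
        if report is None:
            matrix.statuses[(species, gene)] = "ABSENT"
            continue
        if report.excluded:
            matrix.statuses[(species, gene)] = "EXCLUDED"
            continue
        lesions = _countable(report, params)
        if not lesions:
            matrix.statuses[(species, gene)] = "INTACT"
            continue
        if len(lesions) >= params.min_lesions_solo:
            matrix.statuses[(species, gene)] = "PSEUDOGENE"
            continue
        # below the solo threshold: look for the same lesion in relatives
        if species not in neighbor_cache:
            neighbor_cache[species] = neighbors(tree, species, params)
        shared = False
        for other in neighbor_cache[species]:
            other_report = lesion_reports.get((other, gene))
            if other_report is None or other_report.excluded:
                continue
            for mine in lesions:
                if any(
                    shared_lesion(mine, theirs, params)
                    for theirs in _countable(other_report, params)
                ):
                    shared = True
                    break
            if shared:
                break
        matrix.statuses[(species, gene)] = "PSEUDOGENE" if shared else "PARTIAL"
    return matrix


def presence_vector(
    matrix: GeneStatusMatrix, gene: str, policy: str = "unknown"
) -> dict[str, str]:
    """Collapse statuses to presence/absence for ancestral reconstruction.

    INTACT and PARTIAL copies still encode an ORF -> present; PSEUDOGENE
    and ABSENT -> absent; EXCLUDED species are mapped to ``unknown`` or
    dropped entirely (``policy="drop"``).
    """
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    out: dict[str, str] = {}
    for (species, g), status in matrix.statuses.items():
        if g != gene:
            continue
        if status in ("INTACT", "PARTIAL"):
            out[species] = "present"
        elif status in ("PSEUDOGENE", "ABSENT"):
            out[species] = "absent"
        else:  # EXCLUDED
            if policy == "drop":
                continue
            out[species] = "unknown"
    return out
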