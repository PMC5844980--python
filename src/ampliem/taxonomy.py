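"""Nearest-reference taxonomy assignment.

Each OTU representative is aligned against every reference sequence; the
lineage of the closest reference is copied onto the OTU provided the
similarity (1 - genetic distance) reaches a global 90% floor.  References
may carry truncated lineages (e.g. down to family only); in that case the
assignment's ``assigned_level`` is the deepest rank available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignmentParams, semiglobal_align

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ReferenceOtu:
    """A reference 16S sequence with an ordered lineage (domain..genus).

    The lineage may be truncated at any rank but is never empty and always
    starts with a domain name.
    """

    id: str
    sequence: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"reference {self.id}: lineage must be non-empty")
        if len(self.lineage) > len(RANKS):
            raise ValueError(f"reference {self.id}: lineage deeper than genus")


@dataclass
class TaxonomyAssignment:
    otu_id: str
    reference_id: str | None
    similarity: float
    lineage: tuple[str, ...]

    @property
    def assigned(self) -> bool:
        return bool(self.lineage)

    @property
    def assigned_level(self) -> str | None:
        """Deepest rank present in the lineage ('lowest level available')."""
        if not self.lineage:
            return None
        return RANKS[len(self.lineage) - 1]


def assign_taxonomy(
    representative: str,
    references: Sequence[ReferenceOtu],
    min_similarity: float = 0.90,
    params: AlignmentParams | None = None,
    otu_id: str = "otu",
) -> TaxonomyAssignment:
    """Assign the lineage of the closest reference (exhaustive best hit).

    Ties on similarity are broken by the lexicographically smallest
    reference id.  Below the similarity floor the OTU stays unassigned
    (empty lineage), with the best hit still reported.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    best_sim, best_ref = -1.0, None
    for ref in references:
        if ref.sequence == representative:
            sim = 1.0
        else:
            sim = semiglobal_align(representative, ref.sequence, params).similarity
        if sim > best_sim or (sim == best_sim and ref.id < best_ref.id):
            best_sim, best_ref = sim, ref
    if best_sim >= min_similarity:
        lineage = tuple(best_ref.lineage)
    else:
        lineage = ()
    return TaxonomyAssignment(
        otu_id=otu_id,
        reference_id=best_ref.id,
        similarity=best_sim,
        lineage=lineage,
    )


def assign_all(
    representatives: dict[str, str],
    references: Sequence[ReferenceOtu],
    min_similarity: float = 0.90,
    params: AlignmentParams | None = None,
) -> dict[str, TaxonomyAssignment]:
    """Assign taxonomy for a mapping otu_id -> representative sequence."""
    return {
        oid: assign_taxonomy(seq, references, min_similarity, params, otu_id=oid)
        for oid, seq in representatives.items()
    }


def read_reference_fasta(path) -> list[ReferenceOtu]:
    """Read references whose headers carry ``id rank1;rank2;...`` lineages."""
    refs = []
    with open(path) as fh:
        rid, lineage, chunks = None, (), []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    refs.append(ReferenceOtu(rid, "".join(chunks), lineage))
                header = line[1:].split(None, 1)
                rid = header[0]
                lineage = tuple(
                    t.strip() for t in header[1].split(";") if t.strip()
                ) if len(header) > 1 else ()
                chunks = []
            else:
                chunks.append(line.strip())
        if rid is not None:
            refs.append(ReferenceOtu(rid, "".join(chunks), lineage))
    return refs


def write_reference_fasta(refs: Sequence[ReferenceOtu], path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.id} {';'.join(r.lineage)}\n{r.sequence}\n")
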