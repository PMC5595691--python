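"""Binding-site mapping and conservation factors over family alignments.

A family couples one reference sequence of known 3D structure (typically
human) with orthologue sequences from the other species of interest, all in
one common alignment frame.  Ligand-contact residues reported for the
structure are mapped through the alignment to score how well the binding
site and its surrounding domains are conserved in each orthologue.

Coordinate conventions: residue positions are 1-based on the ungapped
reference sequence; alignment columns are 1-based as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from agerank.config import LogisticParams, RankingConfig
from agerank.grantham import (
    GAP_CHARS,
    AminoAcidSimilarityMatrix,
    EmptyRegionError,
    default_matrix,
    pairwise_identity,
    pairwise_similarity,
)
from agerank.scoring import logistic

__all__ = [
    "AlignedFamily",
    "BindingSiteContacts",
    "DomainAnnotation",
    "ContactMappingError",
    "SpeciesAbsentError",
    "contacts_to_columns",
    "scoring_regions",
    "domain_conservation",
    "binding_site_conservation",
    "select_homologue",
    "global_identity",
    "site_identity",
]


class ContactMappingError(ValueError):
    """A contact position does not exist on the ungapped reference."""


class SpeciesAbsentError(LookupError):
    """No family member belongs to the requested species; the compound
    cannot be ranked for that species via this family."""


@dataclass
class AlignedFamily:
    """One reference structure sequence plus homologues in a shared frame."""

    family_id: str
    ref_id: str
    aligned_seqs: dict[str, str]
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.ref_id not in self.aligned_seqs:
            raise ValueError(
                f"family {self.family_id}: reference {self.ref_id!r} missing"
            )
        lengths = {len(s) for s in self.aligned_seqs.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"family {self.family_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        missing = set(self.aligned_seqs) - set(self.species_of)
        if missing:
            raise ValueError(
                f"family {self.family_id}: members without species tag: "
                f"{sorted(missing)}"
            )

    @property
    def length(self) -> int:
        return len(self.aligned_seqs[self.ref_id])

    @property
    def ref_aligned(self) -> str:
        return self.aligned_seqs[self.ref_id]

    def ref_ungapped_length(self) -> int:
        return sum(1 for c in self.ref_aligned if c not in GAP_CHARS)

    def members_of(self, species: str) -> list[str]:
        return sorted(
            m
            for m, sp in self.species_of.items()
            if sp == species and m != self.ref_id
        )

    def ref_columns(self) -> list[int]:
        """1-based alignment columns carrying a reference residue."""
        return [
            i + 1 for i, c in enumerate(self.ref_aligned) if c not in GAP_CHARS
        ]


@dataclass
class BindingSiteContacts:
    """Ligand-contact residues of one structure, as residue positions
    (1-based) on the ungapped reference sequence."""

    structure_id: str
    het_code: str
    contact_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = sorted(set(self.contact_positions))
        if pos and pos[0] < 1:
            raise ValueError(
                f"{self.structure_id}/{self.het_code}: positions must be >= 1"
            )
        self.contact_positions = pos


@dataclass
class DomainAnnotation:
    """Structural-domain intervals, 1-based inclusive on the ungapped
    reference sequence."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start < 1 or start > end:
                raise ValueError(f"invalid domain interval ({start}, {end})")
        self.intervals = sorted(self.intervals)


def contacts_to_columns(
    family: AlignedFamily, contacts: BindingSiteContacts
) -> set[int]:
    """Map reference residue positions to 1-based alignment columns."""
    ref = family.ref_aligned
    pos_to_col: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(ref, start=1):
        if ch not in GAP_CHARS:
            residue += 1
            pos_to_col[residue] = col
    columns = set()
    for p in contacts.contact_positions:
        if p not in pos_to_col:
            raise ContactMappingError(
                f"{contacts.structure_id}/{contacts.het_code}: contact {p} "
                f"beyond reference length {residue}"
            )
        columns.add(pos_to_col[p])
    return columns


def _merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:  # overlap or adjacency
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def scoring_regions(
    contacts: BindingSiteContacts,
    domains: DomainAnnotation,
    seq_length: int,
    window: int = 50,
) -> list[tuple[int, int]]:
    """Reference-sequence regions over which domain conservation is scored.

    Every annotated domain containing at least one ligand contact is
    included whole; contacts falling outside all domains contribute a
    +-``window`` residue interval instead, clipped to the sequence.  The
    union is merged (adjacent intervals coalesce) and returned sorted.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pieces: list[tuple[int, int]] = []
    for start, end in domains.intervals:
        if end > seq_length:
            raise ValueError(
                f"domain ({start}, {end}) beyond sequence length {seq_length}"
            )
        if any(start <= p <= end for p in contacts.contact_positions):
            pieces.append((start, end))
    for p in contacts.contact_positions:
        if p > seq_length:
            raise ContactMappingError(
                f"contact {p} beyond sequence length {seq_length}"
            )
        if not any(s <= p <= e for s, e in domains.intervals):
            pieces.append((max(1, p - window), min(seq_length, p + window)))
    return _merge_intervals(pieces)


def _region_columns(family: AlignedFamily, regions: Sequence[tuple[int, int]]) -> list[int]:
    """Alignment columns of the reference residues inside the regions."""
    cols = family.ref_columns()  # cols[i] is the column of residue i+1
    selected: list[int] = []
    for start, end in regions:
        if end > len(cols):
            raise ValueError(
                f"region ({start}, {end}) beyond reference length {len(cols)}"
            )
        selected.extend(cols[start - 1 : end])
    return sorted(set(selected))


def domain_conservation(
    family: AlignedFamily,
    member: str,
    regions: Sequence[tuple[int, int]],
    params: LogisticParams | None = None,
    matrix: AminoAcidSimilarityMatrix | None = None,
) -> float:
    """Domain-conservation factor: logistic-transformed Grantham similarity.

    The mean Grantham-based similarity between reference and member over
    the scoring regions is passed through logistic(x; 0.6, 0.1), which
    stretches the mid-similarity range where conservation differences
    matter most for retained compound binding.
    """
    if not regions:
        raise EmptyRegionError("domain conservation over an empty region set")
    params = params or LogisticParams(0.6, 0.1)
    cols0 = [c - 1 for c in _region_columns(family, regions)]
    sim = pairwise_similarity(
        family.ref_aligned, family.aligned_seqs[member], cols0, matrix
    )
    return logistic(sim, params.location, params.scale)


def site_similarities(
    family: AlignedFamily,
    member: str,
    site_columns: Iterable[int],
    matrix: AminoAcidSimilarityMatrix | None = None,
) -> list[float]:
    """Per-column Grantham similarity at the binding site (member gap -> 0)."""
    m = matrix or default_matrix()
    ref = family.ref_aligned
    hom = family.aligned_seqs[member]
    sims = []
    for col in sorted(site_columns):
        r, h = ref[col - 1], hom[col - 1]
        if r in GAP_CHARS:
            raise ContactMappingError(
                f"site column {col} holds a reference gap"
            )
        sims.append(0.0 if h in GAP_CHARS else m.similarity(r, h))
    return sims


def binding_site_conservation(
    family: AlignedFamily,
    member: str,
    site_columns: Iterable[int],
    matrix: AminoAcidSimilarityMatrix | None = None,
    k_rounding: str = "floor",
) -> float:
    """Binding-site conservation: mean similarity of the least-conserved half.

    Because most binding sites are more than 50% identical, averaging all
    positions would saturate; restricting to the k = max(1, floor(N/2))
    most dissimilar positions keeps the factor sensitive.  ``k_rounding``
    may be "ceil" to round k up for odd site sizes instead.
    """
    sims = site_similarities(family, member, site_columns, matrix)
    if not sims:
        raise EmptyRegionError("binding-site conservation over an empty site")
    n = len(sims)
    if k_rounding == "floor":
        k = max(1, n // 2)
    elif k_rounding == "ceil":
        k = max(1, math.ceil(n / 2))
    else:
        raise ValueError(f"unknown k rounding mode: {k_rounding!r}")
    sims.sort()
    return sum(sims[:k]) / k


def _site_gap_count(family: AlignedFamily, member: str, site_columns) -> int:
    hom = family.aligned_seqs[member]
    return sum(1 for col in site_columns if hom[col - 1] in GAP_CHARS)


def select_homologue(
    family: AlignedFamily,
    species: str,
    site_columns: Iterable[int],
    matrix: AminoAcidSimilarityMatrix | None = None,
) -> str:
    """Representative member of a species: fewest binding-site gaps, then
    highest site similarity, then highest site identity, then first id."""
    site_columns = sorted(site_columns)
    members = family.members_of(species)
    if not members:
        raise SpeciesAbsentError(
            f"family {family.family_id}: no member of species {species!r}"
        )

    def sort_key(m: str):
        gaps = _site_gap_count(family, m, site_columns)
        sims = site_similarities(family, m, site_columns, matrix)
        sim = sum(sims) / len(sims) if sims else 0.0
        cols0 = [c - 1 for c in site_columns]
        ident = (
            pairwise_identity(family.ref_aligned, family.aligned_seqs[m], cols0)
            if cols0
            else 0.0
        )
        return (gaps, -sim, -ident, m)

    return min(members, key=sort_key)


def global_identity(
    family: AlignedFamily, member: str, alignment_denominator: bool = False
) -> int:
    """Whole-sequence identity to the reference, as a rounded percent."""
    frac = pairwise_identity(
        family.ref_aligned,
        family.aligned_seqs[member],
        alignment_denominator=alignment_denominator,
    )
    return round(100 * frac)


def site_identity(
    family: AlignedFamily, member: str, site_columns: Iterable[int]
) -> int:
    """Binding-site identity to the reference, as a rounded percent."""
    cols0 = [c - 1 for c in sorted(site_columns)]
    if not cols0:
        raise EmptyRegionError("site identity over an empty site")
    frac = pairwise_identity(family.ref_aligned, family.aligned_seqs[member], cols0)
    return round(100 * frac)
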