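"""Polymorphic-site detection, variant classification and haplotype reports.

Within a clone library, identical full-length sequences constitute one
haplotype; haplotype 1 is the most common and is taken as the underlying true
sequence of the individual (or species).  Variant sites are read per
haplotype (never per clone) on the coordinate system of the most common
haplotype, classified as insertion / deletion / transition / transversion,
and annotated with poly-A/T homopolymer context — the predominant location
of indel variants in amplicon clone libraries.

A species whose individuals carry dominant haplotypes more divergent than
``max_intra_divergence`` (default 1% p-distance) is split into separate
reporting units, the convention used for putative cryptic species.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .clone_align import CloneLibrary, StarAlignment, pairwise_align, star_align_sequences
from .io_formats import NamedSequence

logger = logging.getLogger(__name__)

__all__ = [
    "Haplotype",
    "VariantSite",
    "UnitSummary",
    "SpeciesSummary",
    "collapse_haplotypes",
    "most_common_haplotype",
    "classify_variant",
    "find_polymorphic_sites",
    "annotate_homopolymer",
    "summarize_species",
    "site_matrix",
    "species_summary_table",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

VARIATION_STYLE_ORDER = ("transversion", "transition", "deletion", "insertion")


@dataclass(frozen=True)
class Haplotype:
    """A distinct full-length sequence with its clone counts."""

    haplotype_id: int  # 1 = most common
    sequence: str
    clone_count: dict[str, int]  # individual_id -> clones
    singleton: bool = False  # exactly one clone in total: probable error (§ annotation only)

    @property
    def total_count(self) -> int:
        return sum(self.clone_count.values())


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic alignment column on common-haplotype coordinates.

    ``position`` is the 1-based reference coordinate; ``sub_index`` is 0 for
    reference columns and k for the k-th insertion column after ``position``
    (rendered "pos.k").  ``types`` maps each alt state to its variant class.
    """

    position: int
    sub_index: int
    ref_state: str
    alt_states: tuple[str, ...]
    types: dict[str, str]
    in_at_homopolymer: bool = False
    tract_base: str | None = None
    tract_length: int | None = None

    @property
    def label(self) -> str:
        return str(self.position) if self.sub_index == 0 else f"{self.position}.{self.sub_index}"


def collapse_haplotypes(
    libraries: CloneLibrary | Sequence[CloneLibrary],
) -> list[Haplotype]:
    """Group primer-trimmed clones by exact sequence identity.

    Accepts one library (per-individual haplotypes) or several (species
    level).  Haplotypes are sorted by total clone count descending, ties by
    lexicographic sequence, and numbered from 1 (the most common).
    """
    if isinstance(libraries, CloneLibrary):
        libraries = [libraries]
    counts: dict[str, Counter] = {}
    n_clones = 0
    for lib in libraries:
        for clone in lib.clones:
            counts.setdefault(clone.seq, Counter())[lib.individual_id] += 1
            n_clones += 1
    ordered = sorted(counts, key=lambda s: (-sum(counts[s].values()), s))
    haps = [
        Haplotype(
            haplotype_id=i + 1,
            sequence=seq,
            clone_count=dict(counts[seq]),
            singleton=sum(counts[seq].values()) == 1,
        )
        for i, seq in enumerate(ordered)
    ]
    assert sum(h.total_count for h in haps) == n_clones
    logger.info("collapse_haplotypes: %d clones -> %d haplotypes", n_clones, len(haps))
    return haps


def most_common_haplotype(haplotypes: Sequence[Haplotype]) -> Haplotype:
    """Haplotype with the highest total clone count; ties resolve to the
    lexicographically smaller sequence (and are visible as equal counts)."""
    if not haplotypes:
        raise ValueError("no haplotypes")
    return min(haplotypes, key=lambda h: (-h.total_count, h.sequence))


def classify_variant(ref_state: str, alt_state: str) -> str:
    """Classify an alt state against the common-haplotype state.

    gap->base is an insertion, base->gap a deletion, A<->G / C<->T a
    transition, any other base pair a transversion.
    """
    if ref_state == alt_state:
        raise ValueError("states must differ")
    if ref_state == "-" and alt_state == "-":
        raise ValueError("double gap is not a variant")
    if ref_state == "-":
        return "insertion"
    if alt_state == "-":
        return "deletion"
    pair = {ref_state, alt_state}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


def find_polymorphic_sites(aln: StarAlignment) -> list[VariantSite]:
    """One :class:`VariantSite` per alignment column with > 1 distinct state.

    States are read across the alignment rows (one row per haplotype);
    positions are reported on the common-haplotype coordinate system.  A
    multi-allelic column yields a single site carrying every alt state.
    """
    ref_row = aln.rows[aln.reference_id]
    sites: list[VariantSite] = []
    row_ids = list(aln.rows)
    for c in range(aln.columns):
        states = {aln.rows[r][c] for r in row_ids}
        if len(states) <= 1:
            continue
        ref_state = ref_row[c]
        alts = tuple(sorted(states - {ref_state}))
        pos, sub = aln.column_map[c]
        sites.append(
            VariantSite(
                position=pos,
                sub_index=sub,
                ref_state=ref_state,
                alt_states=alts,
                types={a: classify_variant(ref_state, a) for a in alts},
            )
        )
    return sites


def _at_tracts(reference: str, min_run: int) -> list[tuple[int, int, str]]:
    """Maximal A- or T-homopolymer runs of length >= min_run as
    (start, end, base) with 1-based inclusive coordinates."""
    tracts = []
    i = 0
    L = len(reference)
    while i < L:
        j = i
        while j < L and reference[j] == reference[i]:
            j += 1
        if reference[i] in "AT" and j - i >= min_run:
            tracts.append((i + 1, j, reference[i]))
        i = j
    return tracts


def annotate_homopolymer(
    aln: StarAlignment, site: VariantSite, min_run: int = 3
) -> VariantSite:
    """Flag a site that lies inside or immediately adjacent to a poly-A/T
    tract of length >= ``min_run`` on the common haplotype."""
    reference = aln.reference_seq
    # an insertion after pos p neighbours both p and p+1 on the reference
    probe = {site.position, site.position + 1} if site.sub_index else {site.position}
    for start, end, base in _at_tracts(reference, min_run):
        if any(start - 1 <= p <= end + 1 for p in probe):
            return replace(
                site, in_at_homopolymer=True, tract_base=base, tract_length=end - start + 1
            )
    return replace(site, in_at_homopolymer=False, tract_base=None, tract_length=None)


@dataclass
class UnitSummary:
    """Polymorphism summary for one reporting unit (normally = the species;
    cryptic-species candidates are split into several units)."""

    unit_id: str
    individual_ids: list[str]
    haplotypes: list[Haplotype]
    sites: list[VariantSite]
    alignment: StarAlignment

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_clones(self) -> int:
        return sum(h.total_count for h in self.haplotypes)

    @property
    def length(self) -> int:
        """Length of the most common haplotype (primer-trimmed)."""
        return len(self.haplotypes[0].sequence)

    @property
    def styles(self) -> tuple[str, ...]:
        observed = {t for s in self.sites for t in s.types.values()}
        return tuple(s for s in VARIATION_STYLE_ORDER if s in observed)


@dataclass
class SpeciesSummary:
    """Species-level polymorphism report with the survey-table columns:
    polymorphism style(s), total polymorphic sites, clone count, and the
    length of the most common haplotype (multi-unit species report their
    per-unit values joined with '/')."""

    species_id: str
    units: list[UnitSummary]

    @property
    def polymorphism_style(self) -> str:
        styles = tuple(
            s
            for s in VARIATION_STYLE_ORDER
            if any(s in u.styles for u in self.units)
        )
        if not styles:
            return "No"
        return ", ".join(s.capitalize() for s in styles)

    @property
    def n_polymorphic_sites(self) -> str:
        return "/".join(str(u.n_sites) for u in self.units)

    @property
    def total_sites(self) -> int:
        return sum(u.n_sites for u in self.units)

    @property
    def n_clones(self) -> int:
        return sum(u.n_clones for u in self.units)

    @property
    def length(self) -> str:
        return "/".join(str(u.length) for u in self.units)

    @property
    def n_haplotypes(self) -> int:
        return sum(len(u.haplotypes) for u in self.units)


def _dominant_divergence(a: str, b: str) -> float:
    """p-distance between two dominant haplotypes (pairwise gap deletion)."""
    ga, gb, _ = pairwise_align(a, b)
    compared = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    diffs = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-" and x != y)
    if compared == 0:
        raise ValueError("no comparable sites between dominant haplotypes")
    return diffs / compared


def _split_units(
    libraries: Sequence[CloneLibrary], max_intra_divergence: float
) -> list[list[CloneLibrary]]:
    """Single-linkage grouping of individuals on dominant-haplotype distance."""
    dominants = [
        most_common_haplotype(collapse_haplotypes(lib)).sequence for lib in libraries
    ]
    n = len(libraries)
    groups: list[list[int]] = []
    assigned = [False] * n
    for i in range(n):
        if assigned[i]:
            continue
        group = [i]
        assigned[i] = True
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for j in range(n):
                if not assigned[j] and _dominant_divergence(
                    dominants[k], dominants[j]
                ) <= max_intra_divergence:
                    assigned[j] = True
                    group.append(j)
                    frontier.append(j)
        groups.append(sorted(group))
    return [[libraries[i] for i in g] for g in groups]


def summarize_species(
    libraries: Sequence[CloneLibrary],
    min_run: int = 3,
    max_intra_divergence: float = 0.01,
) -> SpeciesSummary:
    """Species-level polymorphism summary across individuals.

    Clones are collapsed to haplotypes across the whole reporting unit, a
    star MSA of the haplotype sequences (reference = most common haplotype)
    is scanned for polymorphic columns, and each site is annotated with its
    homopolymer context.  Distinct reference coordinates are counted once,
    however many alt states they carry.
    """
    if not libraries:
        raise ValueError("need at least one clone library")
    species_id = libraries[0].species_id
    if any(lib.species_id != species_id for lib in libraries):
        raise ValueError("libraries from different species")

    units = []
    groups = _split_units(list(libraries), max_intra_divergence)
    for gi, group in enumerate(groups):
        haps = collapse_haplotypes(group)
        common = most_common_haplotype(haps)
        seqs = [NamedSequence(f"hap{h.haplotype_id}", h.sequence) for h in haps]
        aln = star_align_sequences(seqs, reference_seq=common.sequence)
        sites = [
            annotate_homopolymer(aln, s, min_run=min_run)
            for s in find_polymorphic_sites(aln)
        ]
        unit_id = species_id if len(groups) == 1 else f"{species_id}_unit{gi + 1}"
        units.append(
            UnitSummary(
                unit_id=unit_id,
                individual_ids=[lib.individual_id for lib in group],
                haplotypes=haps,
                sites=sites,
                alignment=aln,
            )
        )
    summary = SpeciesSummary(species_id=species_id, units=units)
    logger.info(
        "summarize_species: %s %d clones -> %d unit(s), sites %s",
        species_id,
        summary.n_clones,
        len(units),
        summary.n_polymorphic_sites,
    )
    return summary


def site_matrix(unit: UnitSummary) -> pd.DataFrame:
    """Per-haplotype states at the polymorphic positions.

    Haplotype 1 shows its bases; other haplotypes show '.' where they match
    haplotype 1 and '-' at missing (gap) sites.  Columns are the site labels
    on common-haplotype coordinates, plus the clone count.
    """
    aln = unit.alignment
    label_to_col = {aln.column_label(c): c for c in range(aln.columns)}
    records = []
    ref_row = aln.rows[aln.reference_id]
    for h in unit.haplotypes:
        row_id = f"hap{h.haplotype_id}"
        rec: dict[str, object] = {"haplotype": row_id, "clones": h.total_count}
        for s in unit.sites:
            c = label_to_col[s.label]
            state = aln.rows[row_id][c]
            if h.haplotype_id == 1:
                rec[s.label] = state
            elif state == ref_row[c]:
                rec[s.label] = "."
            elif state == "-":
                rec[s.label] = "-"
            else:
                rec[s.label] = state
        records.append(rec)
    return pd.DataFrame.from_records(records)


def species_summary_table(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    """Survey-style table: one row per species with style / sites / clones /
    length columns."""
    return pd.DataFrame.from_records(
        [
            {
                "species": s.species_id,
                "polymorphism_style": s.polymorphism_style,
                "n_polymorphic_sites": s.n_polymorphic_sites,
                "n_clones": s.n_clones,
                "length": s.length,
                "n_haplotypes": s.n_haplotypes,
            }
            for s in summaries
        ]
    )
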