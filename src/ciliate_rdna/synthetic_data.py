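"""Seeded generators for clone libraries and dPCR/qPCR data.

The generators emulate the statistical structure the analysis modules
assume, so the whole pipeline is testable without any sequencing run:

* clone libraries are near-identical amplicon sets — each cloned molecule is
  one of a small set of designed haplotypes (drawn by frequency, with a
  dominant haplotype), plus clone-level noise: per-base substitutions at
  rate ``p_sub`` and single-base A/T indels inside poly-A/T tracts at rate
  ``p_homo_indel`` per tract.  Every clone records its provenance (true
  haplotype, injected errors) so round-trip tests can separate design from
  noise;

* digital-PCR reactions thin the true per-cell copy number by the loaded
  fraction and dilution (binomial thinning), scatter the surviving
  molecules uniformly over partitions and count occupied partitions;

* qPCR Cq values follow a log-linear standard curve with Gaussian noise.

A packaged benchmark (:func:`table2_benchmark`) builds 13 species whose
designed polymorphic-site counts, variant styles, clone numbers and amplicon
lengths copy the published ciliate mtSSU survey row-for-row.  Benchmark
references descend from a common synthetic ancestor (conserved core plus a
species-specific prefix of a variable region) so they remain alignable
across species for the phylogenetic-congruence checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clone_align import IUPAC_EXPAND, CloneLibrary, revcomp
from .copy_number import PartitionData
from .io_formats import NamedSequence
from .polymorphism import _at_tracts

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceWithTracts",
    "HaplotypeSpec",
    "UnitSpec",
    "SpeciesSimSpec",
    "DpcrSimSpec",
    "CloneProvenance",
    "generate_reference",
    "apply_edits",
    "simulate_clone_library",
    "simulate_dpcr",
    "simulate_qpcr",
    "table2_benchmark",
    "BenchmarkDesign",
    "Benchmark",
    "cell_dimensions_table",
    "MTSSU_PRIMER_FWD",
    "MTSSU_PRIMER_REV",
]

# Broad-range mitochondrial SSU primers (IUPAC degeneracies in the reverse).
MTSSU_PRIMER_FWD = "TGTGCCAGCAGCCGCGGTAA"
MTSSU_PRIMER_REV = "CCCMTACCRGTACCTTGTGT"


@dataclass(frozen=True)
class ReferenceWithTracts:
    sequence: NamedSequence
    #: (start, end, base), 1-based inclusive, for every designed poly-A/T tract
    tracts: tuple[tuple[int, int, str], ...]


def _background(rng: np.random.Generator, n: int, forbid_run: int = 3) -> list[str]:
    """Random sequence in which no A- or T-homopolymer reaches ``forbid_run``."""
    out: list[str] = []
    bases = "ACGT"
    for _ in range(n):
        options = bases
        if len(out) >= forbid_run - 1:
            tail = out[-(forbid_run - 1):]
            if len(set(tail)) == 1 and tail[0] in "AT":
                options = bases.replace(tail[0], "")
        out.append(options[rng.integers(len(options))])
    return out


def generate_reference(
    length: int,
    n_at_tracts: int,
    tract_len_range: tuple[int, int] = (4, 6),
    seed: int = 0,
    min_tract_len: int = 3,
) -> ReferenceWithTracts:
    """A random reference containing exactly ``n_at_tracts`` maximal poly-A/T
    homopolymer tracts with lengths in ``tract_len_range``.

    Flanking composition (forced C/G boundaries, run-limited background)
    guarantees the designed tracts are the only A/T runs reaching
    ``min(tract_len_range)``.  Same seed, same sequence.
    """
    rng = np.random.default_rng(seed)
    lo, hi = tract_len_range
    if lo < min_tract_len:
        raise ValueError("tract lengths must be >= min_tract_len")
    if n_at_tracts == 0:
        seq = "".join(_background(rng, length, forbid_run=min_tract_len))
        return ReferenceWithTracts(NamedSequence("reference", seq), ())
    tract_lens = rng.integers(lo, hi + 1, size=n_at_tracts)
    min_gap = 2
    slack = length - int(tract_lens.sum()) - min_gap * (n_at_tracts + 1)
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_at_tracts} tracts of {lo}-{hi} nt into {length} nt"
        )
    extra = rng.multinomial(slack, np.full(n_at_tracts + 1, 1 / (n_at_tracts + 1)))
    pieces: list[str] = []
    tracts: list[tuple[int, int, str]] = []
    pos = 0
    for i in range(n_at_tracts + 1):
        gap_len = min_gap + int(extra[i])
        gap = _background(rng, gap_len, forbid_run=min_tract_len)
        gap[0] = "CG"[rng.integers(2)]
        gap[-1] = "CG"[rng.integers(2)]
        pieces.append("".join(gap))
        pos += gap_len
        if i < n_at_tracts:
            base = "AT"[rng.integers(2)]
            tl = int(tract_lens[i])
            pieces.append(base * tl)
            tracts.append((pos + 1, pos + tl, base))
            pos += tl
    seq = "".join(pieces)
    assert len(seq) == length
    observed = _at_tracts(seq, min_run=lo)
    assert len(observed) == n_at_tracts, "tract packing postcondition violated"
    return ReferenceWithTracts(NamedSequence("reference", seq), tuple(tracts))


# ---------------------------------------------------------------------------
# clone libraries

Edit = tuple  # ("sub", pos, base) | ("ins", pos, base) | ("del", pos); 1-based


@dataclass(frozen=True)
class HaplotypeSpec:
    hap_id: str
    edits: tuple[Edit, ...]
    frequency: float


@dataclass(frozen=True)
class UnitSpec:
    """One breeding unit: a reference plus designed haplotypes shared by
    ``n_individuals`` individuals (species usually have a single unit;
    cryptic-species benchmarks use two)."""

    reference: str
    haplotypes: tuple[HaplotypeSpec, ...]
    n_individuals: int
    clones_per_individual: int

    def __post_init__(self) -> None:
        total = sum(h.frequency for h in self.haplotypes)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies must sum to 1, got {total}")


@dataclass(frozen=True)
class SpeciesSimSpec:
    """Simulation design for one species' clone libraries."""

    species_id: str
    units: tuple[UnitSpec, ...]
    primer_fwd: str = MTSSU_PRIMER_FWD
    primer_rev: str = MTSSU_PRIMER_REV
    p_sub: float = 1e-4
    p_homo_indel: float = 1e-2
    min_tract_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_sub <= 1 and 0 <= self.p_homo_indel <= 1):
            raise ValueError("error rates must be probabilities")
        for u in self.units:
            if len(u.reference) <= 2 * max(len(self.primer_fwd), len(self.primer_rev)):
                raise ValueError("amplicon must be longer than both primers")


@dataclass(frozen=True)
class CloneProvenance:
    haplotype_id: str
    injected_subs: int
    injected_indels: int


def apply_edits(reference: str, edits: Sequence[Edit]) -> str:
    """Apply substitution/insertion/deletion edits (1-based positions on the
    unedited reference; insertions attach after their position)."""
    seq = list(reference)
    for edit in sorted(edits, key=lambda e: -e[1]):
        op, pos = edit[0], edit[1]
        if op == "sub":
            seq[pos - 1] = edit[2]
        elif op == "del":
            del seq[pos - 1]
        elif op == "ins":
            seq.insert(pos, edit[2])
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return "".join(seq)


def _largest_remainder(freqs: Sequence[float], n: int) -> list[int]:
    """Deterministic integer allocation of n clones to frequencies."""
    raw = [f * n for f in freqs]
    counts = [int(x) for x in raw]
    order = sorted(
        range(len(freqs)), key=lambda i: (-(raw[i] - counts[i]), -freqs[i], i)
    )
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _expand_primer(primer: str, rng: np.random.Generator) -> str:
    out = []
    for ch in primer:
        options = sorted(IUPAC_EXPAND[ch])
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def _mutate_clone(
    seq: str,
    p_sub: float,
    p_homo_indel: float,
    min_tract_len: int,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Clone-level error model: iid substitutions plus single-base indels of
    the tract base at the 3' end of each poly-A/T tract."""
    chars = list(seq)
    n_subs = 0
    if p_sub > 0:
        hits = np.nonzero(rng.random(len(chars)) < p_sub)[0]
        for i in hits:
            others = "ACGT".replace(chars[i], "")
            chars[i] = others[rng.integers(3)]
        n_subs = len(hits)
    mutated = "".join(chars)
    n_indels = 0
    if p_homo_indel > 0:
        edits: list[Edit] = []
        for start, end, base in _at_tracts(mutated, min_tract_len):
            if rng.random() < p_homo_indel:
                if rng.random() < 0.5:
                    edits.append(("del", end))
                else:
                    edits.append(("ins", end, base))
                n_indels += 1
        if edits:
            mutated = apply_edits(mutated, edits)
    return mutated, n_subs, n_indels


def simulate_clone_library(spec: SpeciesSimSpec) -> list[CloneLibrary]:
    """Simulate clone libraries (one :class:`CloneLibrary` per individual).

    Clone counts per haplotype follow the designed frequencies exactly
    (largest-remainder allocation); the rng shuffles clone order and drives
    the error model.  Each clone is primer_fwd + core + revcomp(primer_rev)
    with concrete bases substituted for primer degeneracies.
    """
    rng = np.random.default_rng(spec.seed)
    fwd = _expand_primer(spec.primer_fwd, rng)
    rev_rc = revcomp(_expand_primer(spec.primer_rev, rng))
    libraries: list[CloneLibrary] = []
    ind_no = 0
    for unit in spec.units:
        hap_seqs = {
            h.hap_id: apply_edits(unit.reference, h.edits) for h in unit.haplotypes
        }
        counts = _largest_remainder(
            [h.frequency for h in unit.haplotypes], unit.clones_per_individual
        )
        for _ in range(unit.n_individuals):
            ind_no += 1
            ind_id = f"ind{ind_no}"
            assignment = [
                h.hap_id for h, c in zip(unit.haplotypes, counts) for _ in range(c)
            ]
            rng.shuffle(assignment)
            clones = []
            provenance: dict[str, CloneProvenance] = {}
            for j, hap_id in enumerate(assignment, start=1):
                core, n_subs, n_indels = _mutate_clone(
                    hap_seqs[hap_id],
                    spec.p_sub,
                    spec.p_homo_indel,
                    spec.min_tract_len,
                    rng,
                )
                clone_id = f"{spec.species_id}_{ind_id}_c{j}"
                clones.append(NamedSequence(clone_id, fwd + core + rev_rc))
                provenance[clone_id] = CloneProvenance(hap_id, n_subs, n_indels)
            libraries.append(
                CloneLibrary(
                    species_id=spec.species_id,
                    individual_id=ind_id,
                    clones=clones,
                    provenance=provenance,
                )
            )
    logger.info(
        "simulate_clone_library: %s -> %d individuals, %d clones",
        spec.species_id,
        len(libraries),
        sum(len(l.clones) for l in libraries),
    )
    return libraries


# ---------------------------------------------------------------------------
# dPCR / qPCR

@dataclass(frozen=True)
class DpcrSimSpec:
    """One simulated digital-PCR reaction from a single-cell extract."""

    true_copies_per_cell: float
    n_partitions: int
    fraction_loaded: float = 1.0
    dilution_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_copies_per_cell < 0:
            raise ValueError("true_copies_per_cell must be >= 0")
        if not 0 < self.fraction_loaded <= 1:
            raise ValueError("fraction_loaded must be in (0, 1]")
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        if self.fraction_loaded / self.dilution_factor > 1:
            raise ValueError("cannot load more molecules than the extract holds")


def simulate_dpcr(spec: DpcrSimSpec) -> PartitionData:
    """Binomially thin the cell's copies by fraction/dilution, scatter the
    surviving molecules uniformly over partitions, count occupied ones."""
    rng = np.random.default_rng(spec.seed)
    p_keep = spec.fraction_loaded / spec.dilution_factor
    m = int(rng.binomial(int(round(spec.true_copies_per_cell)), p_keep))
    if m == 0:
        n_positive = 0
    else:
        counts = rng.multinomial(m, np.full(spec.n_partitions, 1 / spec.n_partitions))
        n_positive = int(np.count_nonzero(counts))
    return PartitionData(
        n_partitions=spec.n_partitions,
        n_positive=n_positive,
        fraction_loaded=spec.fraction_loaded,
        dilution_factor=spec.dilution_factor,
        cells_in_extract=1,
    )


def simulate_qpcr(
    copies: float,
    slope: float = -3.32,
    intercept: float = 38.0,
    sd_noise: float = 0.0,
    seed: int | None = None,
) -> float:
    """Cq = intercept + slope*log10(copies) + N(0, sd_noise).

    The default curve (slope -3.32, i.e. ~100% efficiency; intercept 38) is
    synthetic: real runs must supply their own standard curve.
    """
    if copies <= 0:
        raise ValueError("copies must be positive")
    if slope >= 0:
        raise ValueError("slope must be negative")
    cq = intercept + slope * math.log10(copies)
    if sd_noise > 0:
        cq += np.random.default_rng(seed).normal(0.0, sd_noise)
    return float(cq)


# ---------------------------------------------------------------------------
# the 13-species benchmark

@dataclass(frozen=True)
class BenchmarkDesign:
    """Designed truth for one benchmark species, for round-trip checks."""

    species_id: str
    n_individuals: int
    total_clones: int
    expected_sites: tuple[int, ...]  # per reporting unit
    expected_styles: tuple[str, ...]
    expected_lengths: tuple[int, ...]


@dataclass
class Benchmark:
    species_specs: list[SpeciesSimSpec]
    designs: dict[str, BenchmarkDesign]
    outgroups: list[NamedSequence]


# (species, n_individuals, clones/individual, trimmed length,
#  haplotype edit plans, haplotype frequencies)
# Edit tokens: ts/tv = transition/transversion SNP, del/ins = single-base
# indel at the 3' end of the next unused poly-A/T tract.
_BENCHMARK_ROWS = [
    ("Epistylis_sp", 2, 10, 1204, [[], ["ts"]], [0.8, 0.2]),
    ("Paramecium_caudatum", 3, 10, 990,
     [[], ["ts", "del"], ["ins", "ts", "del", "ins"]], [0.7, 0.2, 0.1]),
    ("Paramecium_sp", 3, 30, 1016, [[]], [1.0]),
    ("Tetrahymena_thermophila", 3, 10, 1037, [[]], [1.0]),
    # Favella_ehrenbergii is built specially (two cryptic units), see below
    ("Sterkiella_sp", 3, 10, 1213, [[], ["del", "ins"]], [0.8, 0.2]),
    ("Phacodinium_metchnikoffi", 3, 10, 1047, [[]], [1.0]),
    ("Neobakuella_aenigmatica", 3, 30, 1600, [[]], [1.0]),
    ("Euplotes_vannus", 3, 10, 968, [[]], [1.0]),
    ("Oxytricha_trifallax", 3, 10, 1151,
     [[], ["del", "ins", "del"], ["ins", "del", "ins"]], [0.7, 0.2, 0.1]),
    ("Spirostomum_sp", 3, 30, 977, [[], ["del"], ["ins"]], [0.8, 0.15, 0.05]),
    ("Trithigmostoma_sp", 3, 30, 1024,
     [[], ["ts", "tv", "del", "ins"], ["del", "ins", "ts"], ["tv", "del", "ins"]],
     [0.6, 0.2, 0.13, 0.07]),
    ("Coleps_sp", 3, 30, 959,
     [[], ["del", "ins", "del"], ["ins", "del", "ins"]], [0.7, 0.2, 0.1]),
]

_CORE_LEN = 950
_ANCESTOR_LEN = 1650
# tract slots (start positions, length 5) and SNP slots inside the conserved
# core, identical across species so designed edits always have a target
_TRACT_STARTS = (50, 130, 210, 290, 370, 450, 530, 610, 690, 770)
_TRACT_LEN = 5
_SNP_SLOTS = (860, 872, 884, 896, 908, 920, 932)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _make_ancestor(rng: np.random.Generator) -> str:
    seq = _background(rng, _ANCESTOR_LEN, forbid_run=3)
    for i, start in enumerate(_TRACT_STARTS):
        base = "AT"[i % 2]
        seq[start - 2] = "C"
        for k in range(_TRACT_LEN):
            seq[start - 1 + k] = base
        seq[start - 1 + _TRACT_LEN] = "G"
    return "".join(seq)


def _protected_positions() -> set[int]:
    prot: set[int] = set()
    for start in _TRACT_STARTS:
        prot.update(range(start - 2, start + _TRACT_LEN + 1))  # 0-based zone
    return prot


def _species_reference(
    ancestor: str, length: int, rate: float, rng: np.random.Generator
) -> str:
    """Conserved core + species-specific prefix of the variable region, with
    iid substitutions outside the planted tract zones."""
    if not _CORE_LEN <= length <= _ANCESTOR_LEN:
        raise ValueError("benchmark length outside ancestor bounds")
    seq = list(ancestor[:length])
    protected = _protected_positions()
    for i in range(length):
        if i in protected:
            continue
        if rng.random() < rate:
            seq[i] = "ACGT".replace(seq[i], "")[rng.integers(3)]
    return "".join(seq)


def _design_edits(
    reference: str, plans: list[list[str]]
) -> list[tuple[str, ...]]:
    """Turn edit-token plans into concrete edits, consuming tract and SNP
    slots in order so every designed site has a distinct coordinate."""
    tract_iter = iter(_TRACT_STARTS)
    snp_iter = iter(_SNP_SLOTS)
    out = []
    for plan in plans:
        edits: list[Edit] = []
        for token in plan:
            if token in ("del", "ins"):
                start = next(tract_iter)
                end = start + _TRACT_LEN - 1
                base = reference[start - 1]
                edits.append(("del", end) if token == "del" else ("ins", end, base))
            elif token == "ts":
                pos = next(snp_iter)
                edits.append(("sub", pos, _TRANSITION[reference[pos - 1]]))
            elif token == "tv":
                pos = next(snp_iter)
                edits.append(("sub", pos, _TRANSVERSION[reference[pos - 1]]))
            else:
                raise ValueError(f"unknown edit token {token!r}")
        out.append(tuple(edits))
    return out


def _plan_styles(plans: list[list[str]]) -> tuple[str, ...]:
    token_style = {"ts": "transition", "tv": "transversion",
                   "del": "deletion", "ins": "insertion"}
    seen = {token_style[t] for plan in plans for t in plan}
    return tuple(
        s for s in ("transversion", "transition", "deletion", "insertion") if s in seen
    )


def _find_isolated_c(reference: str, lo: int = 936, hi: int = 950) -> int:
    """1-based position of a cytosine away from any poly-A/T tract."""
    for pos in range(lo, hi):
        if reference[pos - 1] == "C":
            return pos
    for pos in range(800, len(reference)):
        if reference[pos - 1] == "C":
            return pos
    raise RuntimeError("reference contains no cytosine")


def table2_benchmark(seed: int = 316) -> Benchmark:
    """The packaged 13-species benchmark.

    Designed site counts, variant styles, clone numbers and amplicon lengths
    copy the published survey row-for-row; clone libraries are simulated
    noise-free so every polymorphic site is a designed one.  The seed varies
    the concrete sequences but never the designed counts.
    """
    rng = np.random.default_rng(seed)
    ancestor = _make_ancestor(rng)
    species_specs: list[SpeciesSimSpec] = []
    designs: dict[str, BenchmarkDesign] = {}

    for species, n_ind, n_clones, length, plans, freqs in _BENCHMARK_ROWS:
        rate = rng.uniform(0.08, 0.18)
        ref = _species_reference(ancestor, length, rate, rng)
        edits = _design_edits(ref, plans)
        haps = tuple(
            HaplotypeSpec(f"hap{i + 1}", e, f)
            for i, (e, f) in enumerate(zip(edits, freqs))
        )
        unit = UnitSpec(ref, haps, n_ind, n_clones)
        spec = SpeciesSimSpec(
            species_id=species,
            units=(unit,),
            p_sub=0.0,
            p_homo_indel=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        species_specs.append(spec)
        n_sites = sum(len(p) for p in plans)
        designs[species] = BenchmarkDesign(
            species_id=species,
            n_individuals=n_ind,
            total_clones=n_ind * n_clones,
            expected_sites=(n_sites,),
            expected_styles=_plan_styles(plans),
            expected_lengths=(length,),
        )

    # Favella_ehrenbergii: two cryptic units.  Unit A (individuals 1-2):
    # one transition SNP plus a cytosine deletion.  Unit B (individual 3):
    # ~2.5% divergent from unit A, 4 nt longer, one tract deletion.
    rate = rng.uniform(0.08, 0.18)
    ref_a = _species_reference(ancestor, 1604, rate, rng)
    snp_pos = _SNP_SLOTS[0]
    c_pos = _find_isolated_c(ref_a)
    haps_a = (
        HaplotypeSpec("hapA1", (), 0.8),
        HaplotypeSpec(
            "hapA2",
            (("sub", snp_pos, _TRANSITION[ref_a[snp_pos - 1]]), ("del", c_pos)),
            0.2,
        ),
    )
    ref_b = list(ref_a)
    protected = _protected_positions()
    for i in range(len(ref_b)):
        if i not in protected and rng.random() < 0.025:
            ref_b[i] = "ACGT".replace(ref_b[i], "")[rng.integers(3)]
    ref_b = "".join(ref_b) + "GCAG"  # 1608 nt
    t_start = _TRACT_STARTS[0]
    haps_b = (
        HaplotypeSpec("hapB1", (), 0.8),
        HaplotypeSpec("hapB2", (("del", t_start + _TRACT_LEN - 1),), 0.2),
    )
    fav = SpeciesSimSpec(
        species_id="Favella_ehrenbergii",
        units=(UnitSpec(ref_a, haps_a, 2, 10), UnitSpec(ref_b, haps_b, 1, 10)),
        p_sub=0.0,
        p_homo_indel=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    species_specs.insert(4, fav)
    designs["Favella_ehrenbergii"] = BenchmarkDesign(
        species_id="Favella_ehrenbergii",
        n_individuals=3,
        total_clones=30,
        expected_sites=(2, 1),
        expected_styles=("transition", "deletion"),
        expected_lengths=(1604, 1608),
    )

    outgroups = []
    for k in range(3):
        og = list(ancestor)
        for i in range(len(og)):
            if rng.random() < 0.20:
                og[i] = "ACGT".replace(og[i], "")[rng.integers(3)]
        outgroups.append(NamedSequence(f"Outgroup_{k + 1}", "".join(og)))

    total_ind = sum(d.n_individuals for d in designs.values())
    assert total_ind == 38, "benchmark must cover 38 individuals"
    logger.info("table2_benchmark: 13 species, %d individuals", total_ind)
    return Benchmark(species_specs=species_specs, designs=designs, outgroups=outgroups)


def cell_dimensions_table() -> pd.DataFrame:
    """Synthetic cell-dimension table (length, width in um, width:thickness
    ratio, shape class) for the 13 benchmark species.

    The published dimension figure is not machine-readable, so these values
    are plausible synthetic stand-ins for exercising the volume operations;
    they are not measurements.
    """
    rows = [
        ("Epistylis_sp", 120, 40, 1.0, "bell_cone"),
        ("Paramecium_caudatum", 200, 50, 1.2, "cuboid"),
        ("Paramecium_sp", 150, 45, 1.2, "cuboid"),
        ("Tetrahymena_thermophila", 50, 25, 1.2, "cuboid"),
        ("Favella_ehrenbergii", 200, 80, 1.0, "bell_cone"),
        ("Sterkiella_sp", 120, 50, 2.0, "cuboid"),
        ("Phacodinium_metchnikoffi", 90, 50, 1.8, "cuboid"),
        ("Neobakuella_aenigmatica", 110, 40, 2.0, "cuboid"),
        ("Euplotes_vannus", 80, 45, 1.8, "cuboid"),
        ("Oxytricha_trifallax", 110, 40, 2.0, "cuboid"),
        ("Spirostomum_sp", 400, 40, 1.3, "cuboid"),
        ("Trithigmostoma_sp", 70, 35, 2.2, "cuboid"),
        ("Coleps_sp", 55, 25, 1.1, "cuboid"),
    ]
    return pd.DataFrame(
        rows, columns=["species", "length_um", "width_um", "width_thickness_ratio", "shape"]
    )
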