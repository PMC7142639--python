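"""Primer trimming and star multiple alignment of near-identical clones.

Cloned amplicons from a single individual differ from each other by at most a
handful of sites, so a full progressive MSA is unnecessary: every clone is
globally aligned to the modal (most frequent) sequence and insertions are
merged into shared columns.  This "star" construction is exact for
near-identical inputs and — unlike hand alignment in an editor — fully
reproducible.

The pairwise aligner is a global Needleman–Wunsch with linear gap cost and a
fixed tie-break order (diagonal, then up, then left); single-base gaps inside
homopolymer tracts are normalised to the 3'-most equivalent position so that
indel coordinates in downstream variant reports are deterministic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io_formats import NamedSequence

logger = logging.getLogger(__name__)

__all__ = [
    "CloneLibrary",
    "StarAlignment",
    "PrimerTrimError",
    "trim_primers",
    "pairwise_align",
    "build_star_msa",
    "star_align_sequences",
    "iupac_match",
    "revcomp",
]

# IUPAC code -> set of concrete bases it stands for (N -> ACGT).
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


class PrimerTrimError(ValueError):
    """Raised when a primer cannot be located within the mismatch budget."""

    def __init__(self, primer: str, message: str):
        self.primer = primer
        super().__init__(message)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if ``base`` is one of the concrete expansions of ``pattern_char``."""
    return base in IUPAC_EXPAND.get(pattern_char, frozenset())


def _mismatches(window: str, pattern: str) -> int:
    return sum(not iupac_match(p, b) for p, b in zip(pattern, window))


def _best_site(seq: str, pattern: str, from_end: bool) -> tuple[int, int]:
    """Best (start, mismatches) placement of ``pattern`` in ``seq``.

    Ties resolve toward the sequence end the primer belongs to (5' for the
    forward primer, 3' for the reverse one); scanning from that end lets a
    perfect match return immediately.
    """
    k = len(pattern)
    positions = range(len(seq) - k + 1)
    if from_end:
        positions = reversed(positions)
    best = (-1, k + 1)
    for pos in positions:
        mm = _mismatches(seq[pos : pos + k], pattern)
        if mm < best[1]:
            best = (pos, mm)
            if mm == 0:
                break
    return best


def trim_primers(
    clone: NamedSequence, fwd: str, rev: str, max_mismatch: int = 2
) -> NamedSequence:
    """Return the insert strictly between the forward primer site and the
    reverse-complemented reverse-primer site.

    Primer sequences may contain IUPAC ambiguity codes (M = A/C, R = A/G, ...),
    which match any of their expansions at no mismatch cost.  If either primer
    has no placement with at most ``max_mismatch`` mismatches a
    :class:`PrimerTrimError` names the offending primer.
    """
    fwd = fwd.replace(" ", "").upper()
    rev_rc = revcomp(rev.replace(" ", "").upper())
    seq = clone.seq.upper()
    if len(seq) <= len(fwd) + len(rev_rc):
        raise PrimerTrimError("fwd", f"{clone.id}: clone shorter than its primers")
    f_pos, f_mm = _best_site(seq, fwd, from_end=False)
    if f_mm > max_mismatch:
        raise PrimerTrimError(
            "fwd", f"{clone.id}: no fwd primer match within {max_mismatch} mismatches"
        )
    r_pos, r_mm = _best_site(seq, rev_rc, from_end=True)
    if r_mm > max_mismatch:
        raise PrimerTrimError(
            "rev", f"{clone.id}: no rev primer match within {max_mismatch} mismatches"
        )
    core = seq[f_pos + len(fwd) : r_pos]
    if r_pos < f_pos + len(fwd):
        raise PrimerTrimError("rev", f"{clone.id}: primer sites overlap")
    return NamedSequence(clone.id, core)


def _shift_gaps_right(a: list[str], b: list[str]) -> None:
    """Normalise gap placement to the 3'-most score-equivalent position.

    A gap in one row may slide right past the next column whenever the other
    row carries the same base in both columns (i.e. inside a homopolymer
    run); the alignment score is unchanged.  Applied to both rows in place.
    """
    n = len(a)
    changed = True
    while changed:
        changed = False
        for row, other in ((a, b), (b, a)):
            for k in range(n - 1):
                if row[k] == "-" and row[k + 1] != "-" and other[k] == other[k + 1]:
                    row[k], row[k + 1] = row[k + 1], row[k]
                    changed = True


def pairwise_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
) -> tuple[str, str, float]:
    """Global alignment of ``a`` and ``b`` under linear gap cost.

    Returns ``(gapped_a, gapped_b, score)`` for the optimal global alignment.
    Tie-breaking during traceback prefers diagonal, then up (gap in ``b``),
    then left (gap in ``a``), and single-base gaps inside homopolymer runs
    are shifted to the 3'-most equivalent column.  Empty inputs are allowed.
    """
    if match <= mismatch or gap >= 0:
        raise ValueError("require match > mismatch and gap < 0")
    m, n = len(a), len(b)
    H = np.empty((m + 1, n + 1))
    H[0] = gap * np.arange(n + 1)
    if m and n:
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        bv = np.frombuffer(b.encode(), dtype=np.uint8)
        sub = np.where(av[:, None] == bv[None, :], float(match), float(mismatch))
        jg = gap * np.arange(n + 1)
        for i in range(1, m + 1):
            prev = H[i - 1]
            cand = np.empty(n + 1)
            cand[0] = prev[0] + gap  # only 'up' reaches column 0
            cand[1:] = np.maximum(prev[:-1] + sub[i - 1], prev[1:] + gap)
            # resolve the within-row left-gap chain:
            # H[i,j] = max_{k<=j} cand[k] + gap*(j-k)
            H[i] = jg + np.maximum.accumulate(cand - jg)
    else:
        H[:, 0] = gap * np.arange(m + 1)

    # traceback with fixed preference: diagonal, up, left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    out_a.reverse()
    out_b.reverse()
    _shift_gaps_right(out_a, out_b)
    return "".join(out_a), "".join(out_b), float(H[m, n])


@dataclass
class CloneLibrary:
    """The cloned amplicon set for one individual of one species."""

    species_id: str
    individual_id: str
    clones: list[NamedSequence]
    #: optional simulation provenance: clone id -> record of the true
    #: haplotype and any injected errors (filled by the synthetic generator)
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("a clone library needs at least one clone")


@dataclass
class StarAlignment:
    """Multiple alignment of near-identical sequences around a reference.

    ``column_map[c]`` is ``(pos, sub)``: ``pos`` the 1-based coordinate on the
    ungapped reference and ``sub`` 0 for reference columns or k >= 1 for the
    k-th insertion column attached after ``pos`` (label "pos.k"; insertions
    before the first reference base anchor at pos 0).
    """

    reference_id: str
    rows: dict[str, str]
    column_map: list[tuple[int, int]]

    @property
    def columns(self) -> int:
        return len(self.column_map)

    @property
    def reference_seq(self) -> str:
        return self.rows[self.reference_id].replace("-", "")

    def column_label(self, c: int) -> str:
        pos, sub = self.column_map[c]
        return str(pos) if sub == 0 else f"{pos}.{sub}"

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")


def _pick_reference(seqs: Sequence[NamedSequence]) -> str:
    """Modal sequence; ties broken by length (longer) then lexicographic order."""
    counts = Counter(s.seq for s in seqs)
    return min(counts, key=lambda s: (-counts[s], -len(s), s))


def star_align_sequences(
    seqs: Sequence[NamedSequence], reference_seq: str | None = None
) -> StarAlignment:
    """Star MSA of ``seqs``: align each to the reference, merge insertions.

    The reference defaults to the modal sequence.  The row whose sequence
    equals the reference (first such row) names the alignment's reference_id;
    if no row matches, a synthetic "reference" row is added.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ref = reference_seq if reference_seq is not None else _pick_reference(seqs)
    L = len(ref)

    # per row: base aligned to each reference position, plus insertions
    # (strings of inserted bases) keyed by the preceding reference position
    parsed: dict[str, tuple[list[str], dict[int, str]]] = {}
    ref_row_id = None
    for s in seqs:
        if s.seq == ref:
            states = list(ref)
            inserts: dict[int, str] = {}
            if ref_row_id is None:
                ref_row_id = s.id
        else:
            g_ref, g_seq, _ = pairwise_align(ref, s.seq)
            states = []
            inserts = {}
            pos = 0
            for rc, sc in zip(g_ref, g_seq):
                if rc != "-":
                    pos += 1
                    states.append(sc)
                else:
                    inserts[pos] = inserts.get(pos, "") + sc
        parsed[s.id] = (states, inserts)
    if ref_row_id is None:
        ref_row_id = "reference"
        parsed = {ref_row_id: (list(ref), {}), **parsed}

    ins_len = {p: 0 for p in range(L + 1)}
    for _, inserts in parsed.values():
        for p, ins in inserts.items():
            ins_len[p] = max(ins_len[p], len(ins))

    column_map: list[tuple[int, int]] = []
    for k in range(ins_len[0]):
        column_map.append((0, k + 1))
    for p in range(1, L + 1):
        column_map.append((p, 0))
        for k in range(ins_len[p]):
            column_map.append((p, k + 1))

    rows: dict[str, str] = {}
    for rid, (states, inserts) in parsed.items():
        chars: list[str] = []
        ins0 = inserts.get(0, "")
        chars.extend(ins0.ljust(ins_len[0], "-"))
        for p in range(1, L + 1):
            chars.append(states[p - 1])
            ins = inserts.get(p, "")
            chars.extend(ins.ljust(ins_len[p], "-"))
        rows[rid] = "".join(chars)

    aln = StarAlignment(reference_id=ref_row_id, rows=rows, column_map=column_map)
    for s in seqs:
        assert aln.ungapped(s.id) == s.seq, f"ungap invariant broken for {s.id}"
    return aln


def build_star_msa(library: CloneLibrary) -> StarAlignment:
    """Star MSA of a (primer-trimmed) clone library against its modal clone."""
    aln = star_align_sequences(library.clones)
    logger.info(
        "build_star_msa: %s/%s %d clones -> %d columns",
        library.species_id,
        library.individual_id,
        len(library.clones),
        aln.columns,
    )
    return aln
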