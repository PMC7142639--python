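"""Readers and writers for the external formats the pipeline touches.

Everything flows through FASTA (clones, haplotypes, references), TSV with a
header row ('.' decimal separator, scientific notation accepted) and a flat
YAML run configuration.  FASTA dialect: '>' headers, the first
whitespace-delimited token is the record id, the remainder is ignored
metadata — this matches typical Sanger-clone exports.

Every reader preserves input order and never silently drops rows; pipeline
stages log input and output counts at INFO level so clone-count bookkeeping
stays auditable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NamedSequence",
    "RunConfig",
    "FastaFormatError",
    "SchemaError",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "load_config",
]


class FastaFormatError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


class SchemaError(ValueError):
    """Raised when a table is missing required columns."""


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide sequence.

    ``seq`` is over {A,C,G,T,N,-} plus IUPAC ambiguity codes (primers).  An
    empty ``seq`` is allowed only as an explicit degenerate input to the
    alignment operations; FASTA records are always non-empty.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[NamedSequence]:
    """Read a FASTA file into a list of :class:`NamedSequence`.

    Record order is preserved, sequences are upper-cased and whitespace is
    stripped.  A file whose first non-blank line does not start with ``>``
    raises :class:`FastaFormatError` naming the offending line; an empty
    file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaFormatError(
                f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
            )
        break
    records = [
        NamedSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]
    for rec in records:
        if not rec.seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
    logger.info("read_fasta: %s -> %d records", path, len(records))
    return records


def write_fasta(records: Sequence[NamedSequence], path: str | Path) -> Path:
    """Write records as 60-column wrapped FASTA, re-readable by :func:`read_fasta`.

    Ids must be unique within the file.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    path = Path(path)
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")
    logger.info("write_fasta: %d records -> %s", len(records), path)
    return path


def read_table(
    path: str | Path,
    schema: Mapping[str, Callable | type] | None = None,
) -> pd.DataFrame:
    """Read a TSV with header row, coercing columns to the declared types.

    ``schema`` maps column name -> type (e.g. ``float``, ``int``, ``str``).
    All schema columns are required; missing ones raise :class:`SchemaError`
    listing every missing name.  Row order is preserved and no row is ever
    dropped.  Scientific notation ("8.1e5") parses to float.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {missing}")
        for col, typ in schema.items():
            if typ is str:
                continue
            df[col] = df[col].map(lambda v, t=typ: t(v) if v != "" else None)
    logger.info("read_table: %s -> %d rows", path, len(df))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    logger.info("write_table: %d rows -> %s", len(df), path)
    return path


@dataclass
class RunConfig:
    """Flat run configuration for the pipeline.

    ``species`` maps species_id -> per-species settings (paths, clone counts);
    primer sequences may contain IUPAC ambiguity codes.  ``seed`` feeds every
    source of randomness downstream.
    """

    seed: int = 316
    out_dir: str = "results"
    primer_fwd: str = "TGTGCCAGCAGCCGCGGTAA"
    primer_rev: str = "CCCMTACCRGTACCTTGTGT"
    p_sub: float = 1e-4
    p_homo_indel: float = 1e-2
    min_tract_len: int = 3
    max_intra_divergence: float = 0.01
    n_partitions: int = 25000
    fraction_loaded: float = 0.5
    qpcr_slope: float = -3.32
    qpcr_intercept: float = 38.0
    species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, referenced paths checked."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    for sp, entry in cfg.species.items():
        for key in ("clones_fasta", "clone_dir"):
            p = (entry or {}).get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"species {sp}: {key} path {p} does not exist")
    return cfg
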