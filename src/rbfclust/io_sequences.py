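"""Reading, validating and quality-filtering nucleotide sequence collections.

FASTA headers are interpreted as ``symbol|accession``; anything after the
first whitespace is treated as free-text description and ignored. A header
without ``|`` yields a record whose whole token is the gene symbol and whose
accession is empty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FastaFormatError",
    "SequenceRecord",
    "SequenceSet",
    "read_fasta",
    "read_table",
    "write_fasta",
    "deduplicate",
    "filter_quality",
]


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected structure."""


@dataclass(frozen=True)
class SequenceRecord:
    """One gene's identifiers and uppercase nucleotide sequence."""

    gene_symbol: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if any(c.isspace() for c in self.sequence):
            raise ValueError("sequence must not contain whitespace")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple:
        return (self.gene_symbol, self.accession)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with a provenance label."""

    records: list = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _parse_header(header: str) -> tuple:
    token = header.split()[0] if header.split() else ""
    if not token:
        raise FastaFormatError("empty FASTA header")
    if "|" in token:
        symbol, accession = token.split("|", 1)
    else:
        symbol, accession = token, ""
    if not symbol:
        raise FastaFormatError(f"header {header!r} has empty gene symbol")
    return symbol, accession


def read_fasta(path: Union[str, Path]) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaFormatError
        If sequence text precedes the first header, or a record has an
        empty sequence body.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: first non-blank line must start with '>', "
                        f"got {line.strip()[:40]!r}"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise FastaFormatError(f"{path}: empty sequence body for header {rec.description!r}")
        symbol, accession = _parse_header(rec.description)
        records.append(SequenceRecord(symbol, accession, seq))
    return SequenceSet(records=records, provenance=str(path))


def read_table(path: Union[str, Path], sep: str = None) -> SequenceSet:
    """Read a CSV/TSV with columns gene_symbol, accession, sequence."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"gene_symbol", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "accession" not in df.columns:
        df["accession"] = ""
    records = [
        SequenceRecord(row.gene_symbol, row.accession, row.sequence)
        for row in df.itertuples(index=False)
    ]
    return SequenceSet(records=records, provenance=str(path))


def write_fasta(s: SequenceSet, path: Union[str, Path]) -> None:
    """Write records back to FASTA with ``symbol|accession`` headers."""
    bio = []
    for r in s.records:
        header = f"{r.gene_symbol}|{r.accession}" if r.accession else r.gene_symbol
        bio.append(_BioRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(bio, str(path), "fasta")


def deduplicate(s: SequenceSet) -> SequenceSet:
    """Drop later records sharing a (gene_symbol, accession) key; keep the first."""
    seen = set()
    kept = []
    for r in s.records:
        if r.key in seen:
            continue
        seen.add(r.key)
        kept.append(r)
    dropped = len(s.records) - len(kept)
    if dropped:
        logger.info("deduplicate: dropped %d duplicate record(s)", dropped)
    return SequenceSet(records=kept, provenance=s.provenance)


def filter_quality(s: SequenceSet, min_length: int = 1000, max_n_fraction: float = 0.5) -> SequenceSet:
    """Remove short and N-rich sequences.

    Records shorter than *min_length* bases, or with an 'N' fraction strictly
    above *max_n_fraction* (treated as incomplete), are removed. Input order
    is preserved.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = []
    for r in s.records:
        if r.length < min_length:
            continue
        if r.length and r.sequence.count("N") / r.length > max_n_fraction:
            continue
        kept.append(r)
    if s.records and not kept:
        warnings.warn("filter_quality removed all records", stacklevel=2)
    return SequenceSet(records=kept, provenance=s.provenance)
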