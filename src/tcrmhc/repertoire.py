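"""Sequence-family input handling.

Parses FASTA files of TRAV/TRBV genes or HLA alleles with IMGT-style headers,
filters to unique productive entries, and extracts the structurally conserved
regions (CDR loops, TCR-exposed helix residues, peptide contacts) named in a
region-definition config.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "RegionDefinition",
    "parse_family_fasta",
    "filter_productive_unique",
    "extract_regions",
    "load_region_definitions",
]

FAMILIES = ("TRAV", "TRBV", "HLA-I", "HLA-IIa", "HLA-IIb", "KIR", "other")
FUNCTIONALITIES = ("productive", "ORF", "pseudogene")

# IMGT functionality tokens as they appear in pipe-delimited headers:
# "F" (functional/productive), "ORF" (open reading frame), "P" (pseudogene).
# "(F)"/"[F]" mark inferred assignments and are treated the same.
DEFAULT_FUNCTIONALITY_REGEX = r"(?:^|\|)\s*[\[(]?(F|ORF|P)[\])]?\s*(?:\||$)"

_TOKEN_MAP = {"F": "productive", "ORF": "ORF", "P": "pseudogene"}


@dataclass
class SequenceRecord:
    """One gene/allele: identifier, family, functionality and region segments.

    ``segments`` is an ordered mapping region_label -> amino-acid string; it is
    empty until :func:`extract_regions` has been applied, or may be populated
    directly (e.g. by the synthetic generator).
    """

    id: str
    family: str = "other"
    functionality: str = "productive"
    sequence: str = ""
    segments: dict[str, str] = field(default_factory=dict)

    def concatenated_segments(self) -> str:
        return "".join(self.segments.values())

    def __post_init__(self) -> None:
        if self.functionality not in FUNCTIONALITIES:
            raise ValueError(f"unknown functionality {self.functionality!r}")


@dataclass
class RegionDefinition:
    """1-based residue positions of each named region in a family's reference
    numbering."""

    family: str
    regions: dict[str, list[int]]

    def __post_init__(self) -> None:
        for label, positions in self.regions.items():
            if not positions:
                raise ValueError(f"region {label!r}: empty position list")
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(
                    f"region {label!r}: positions must be strictly increasing"
                )
            if min(positions) < 1:
                raise ValueError(f"region {label!r}: positions are 1-based")


class FastaParseError(ValueError):
    pass


def _open_maybe_gzip(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    raw = path.open("rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def parse_family_fasta(
    source,
    family: str = "other",
    functionality_regex: str = DEFAULT_FUNCTIONALITY_REGEX,
) -> list[SequenceRecord]:
    """Parse a FASTA file/stream of one sequence family into records.

    Headers are scanned for an IMGT-style functionality token (``F``, ``ORF``,
    ``P``); records lacking a token default to productive. The identifier is
    the gene/allele name field of a pipe-delimited IMGT header when present,
    otherwise the first whitespace-delimited word. Order of first appearance
    is preserved. Accepts plain or gzip-compressed files.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    handle = _open_maybe_gzip(source)
    pattern = re.compile(functionality_regex)
    records: list[SequenceRecord] = []
    text = handle.read()
    if isinstance(text, bytes):
        text = text.decode()
    if not text.strip():
        raise FastaParseError("empty FASTA input")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FastaParseError(f"malformed FASTA: first line is not a header: {first!r}")
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        header = entry.description
        m = pattern.search(header)
        functionality = _TOKEN_MAP[m.group(1)] if m else "productive"
        fields = [f.strip() for f in header.split("|")]
        # IMGT headers: accession|gene_name|species|functionality|...
        name = fields[1] if len(fields) > 1 and fields[1] else fields[0].split()[0]
        seq = str(entry.seq).upper().replace("*", "").replace(".", "")
        records.append(
            SequenceRecord(id=name, family=family, functionality=functionality,
                           sequence=seq)
        )
    if not records:
        raise FastaParseError("no FASTA entries found")
    return records


def filter_productive_unique(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Keep only productive records; deduplicate on extracted segments.

    Open reading frames and pseudogenes are dropped. Among records whose
    concatenated extracted segments are identical the first is kept (if no
    segments have been extracted yet, uniqueness is judged on the full
    sequence).
    """
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    for rec in records:
        if rec.functionality != "productive":
            continue
        key = rec.concatenated_segments() or rec.sequence
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def extract_regions(
    full_sequence: str,
    definition: RegionDefinition,
    record_id: str = "?",
) -> dict[str, str]:
    """Pull the residues at each region's 1-based positions out of a sequence."""
    segments: dict[str, str] = {}
    n = len(full_sequence)
    for label, positions in definition.regions.items():
        if positions[-1] > n:
            raise IndexError(
                f"record {record_id}: region {label!r} position {positions[-1]} "
                f"exceeds sequence length {n}"
            )
        segments[label] = "".join(full_sequence[p - 1] for p in positions)
    return segments


def apply_region_definition(
    records: Sequence[SequenceRecord], definition: RegionDefinition
) -> list[SequenceRecord]:
    """Extract regions into every record (in place); returns the records."""
    for rec in records:
        rec.segments = extract_regions(rec.sequence, definition, record_id=rec.id)
    return list(records)


def load_region_definitions(path) -> dict[str, RegionDefinition]:
    """Load a YAML/JSON config mapping family -> region -> 1-based positions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        fam: RegionDefinition(family=fam, regions={r: list(p) for r, p in regs.items()})
        for fam, regs in raw.items()
    }


def default_region_definitions() -> dict[str, RegionDefinition]:
    """The shipped region lists (editable conventions, not authoritative)."""
    from importlib.resources import files

    path = files("tcrmhc").joinpath("data/regions_default.yaml")
    raw = yaml.safe_load(path.read_text())
    return {
        fam: RegionDefinition(family=fam, regions={r: list(p) for r, p in regs.items()})
        for fam, regs in raw.items()
    }
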