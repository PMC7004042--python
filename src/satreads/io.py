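"""Readers and writers for the formats the pipeline touches.

Reads come in as FASTA/FASTQ (optionally gzipped); similarity hits in the
LASTZ ``--format=general`` tab-separated dialect; retroelement protein-domain
hits in a DANTE-style GFF3 table.  All coordinates are converted once, at
ingest, to a single internal convention: 0-based, half-open, on the read's
forward strand.  Result tables are written as plain TSV.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The six retroelement protein domains profiled around satellite arrays,
#: in their order within the element (GAG at the 5' end, INT at the 3' end
#: of the gag-pol region).
DOMAINS = ("GAG", "PROT", "RT", "RH", "aRH", "INT")

#: Repeat classes recognised in the reference database.  Satellites, rDNA
#: and telomeric repeats are "array-forming" classes that are merged into
#: oriented arrays; dispersed repeats are coded per hit, with lower priority.
REPEAT_CLASSES = ("satellite", "rDNA", "telomere", "dispersed", "domain")

#: Columns of the LASTZ ``--format=general`` dialect, in file order.
LASTZ_GENERAL_COLUMNS = (
    "name1", "size1", "start1", "length1", "strand1",
    "name2", "size2", "start2", "length2", "strand2",
    "identity", "score",
)


class FormatError(ValueError):
    """A malformed record or row in an input file."""


@dataclass(frozen=True)
class ReadRecord:
    """One long read: identifier plus uppercase sequence."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference repeat sequence in its family's forward orientation."""

    family_id: str
    repeat_class: str
    sequence: str
    priority_rank: int = 0

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """One alignment between a read and a reference repeat.

    Coordinates are 0-based half-open on the read's forward strand.  The
    strand is the orientation of the matched region relative to the
    (forward-oriented) reference family.  Identity is a fraction in [0, 1].
    """

    read_id: str
    read_start: int
    read_end: int
    strand: str
    family_id: str
    ref_length: int
    identity: float
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.read_start < self.read_end:
            raise ValueError(
                f"bad hit interval [{self.read_start}, {self.read_end}) "
                f"on read {self.read_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain similarity hit (GAG/PROT/RT/RH/aRH/INT) on a read."""

    read_id: str
    read_start: int
    read_end: int
    strand: str
    domain: str
    identity: float
    similarity: float
    aln_length_proportion: float
    interruptions: int
    length_proportion: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown protein domain {self.domain!r}")
        if not 0 <= self.read_start < self.read_end:
            raise ValueError(
                f"bad domain interval [{self.read_start}, {self.read_end})"
            )


# ---------------------------------------------------------------------------
# reads


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> str | None:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == "":
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FormatError(f"unrecognised sequence file (starts with {first!r})")


def read_sequences(path: str | Path, min_length: int = 0) -> Iterator[ReadRecord]:
    """Stream reads from FASTA or FASTQ, keeping those >= ``min_length`` bp.

    The format is sniffed from the first character; gzip is transparent.
    Sequences are uppercased; input order is preserved.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        if fmt is None:
            logger.warning("empty sequence file: %s", path)
            return
        seen: set[str] = set()
        for record in SeqIO.parse(handle, fmt):
            seq = str(record.seq).upper()
            if not record.id or not seq:
                raise FormatError(f"malformed record {record.id!r} in {path}")
            if record.id in seen:
                raise FormatError(f"duplicate read id {record.id!r} in {path}")
            seen.add(record.id)
            if len(seq) >= min_length:
                yield ReadRecord(record.id, seq)


def write_fasta(reads: Iterable[ReadRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f">{read.read_id}\n")
            for i in range(0, read.length, width):
                out.write(read.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# reference database


def read_reference_database(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[ReferenceEntry]:
    """Load reference repeats: vanilla FASTA plus a sidecar annotation TSV.

    The sidecar has columns ``family_id``, ``repeat_class``, ``priority_rank``.
    Every FASTA record must be annotated.  Satellite/rDNA/telomere entries
    must outrank (have strictly lower priority_rank than) dispersed entries.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"family_id": str})
    meta = {
        row.family_id: (row.repeat_class, int(row.priority_rank))
        for row in ann.itertuples()
    }
    entries = []
    with _open_text(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id not in meta:
                raise FormatError(f"reference {record.id!r} missing from annotation")
            repeat_class, rank = meta[record.id]
            entries.append(
                ReferenceEntry(record.id, repeat_class, str(record.seq).upper(), rank)
            )
    array_ranks = [e.priority_rank for e in entries
                   if e.repeat_class in ("satellite", "rDNA", "telomere")]
    disp_ranks = [e.priority_rank for e in entries if e.repeat_class == "dispersed"]
    if array_ranks and disp_ranks and max(array_ranks) >= min(disp_ranks):
        raise FormatError(
            "satellite/rDNA/telomere references must have priority_rank strictly "
            "lower than dispersed references"
        )
    return entries


def write_reference_database(
    entries: Iterable[ReferenceEntry],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    entries = list(entries)
    write_fasta(
        [ReadRecord(e.family_id, e.sequence) for e in entries], fasta_path
    )
    pd.DataFrame(
        {
            "family_id": [e.family_id for e in entries],
            "repeat_class": [e.repeat_class for e in entries],
            "priority_rank": [e.priority_rank for e in entries],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


def family_classes(entries: Iterable[ReferenceEntry]) -> dict[str, str]:
    """family_id -> repeat_class mapping, checking within-family consistency."""
    classes: dict[str, str] = {}
    for e in entries:
        if classes.setdefault(e.family_id, e.repeat_class) != e.repeat_class:
            raise ValueError(f"family {e.family_id} has inconsistent repeat classes")
    return classes


# ---------------------------------------------------------------------------
# similarity-hit tables


def _parse_identity(raw: str) -> float:
    """Identity as percent (0-100] or fraction (0-1]; '%' suffix tolerated."""
    value = float(raw.rstrip("%"))
    if value > 1.0:
        value /= 100.0
    if not 0.0 <= value <= 1.0:
        raise FormatError(f"identity {raw!r} out of range")
    return value


def parse_hit_table(
    path: str | Path, dialect: str = "lastz-general"
) -> Iterator[SimilarityHit]:
    """Parse a similarity-hit table into the internal coordinate convention.

    ``lastz-general``: 12 tab-separated columns
    (name1,size1,start1,length1,strand1,name2,size2,start2,length2,strand2,
    identity,score) where sequence 1 is the read and sequence 2 the reference;
    start1 is origin-one on the read's forward strand.  ``lastz-general-0``
    is identical but with origin-zero starts.  A header line starting with
    ``#`` or with ``name1`` is skipped.

    The emitted strand is the orientation of the hit relative to the
    forward-oriented reference: '+' when strand1 == strand2.
    """
    if dialect not in ("lastz-general", "lastz-general-0"):
        raise ValueError(f"unknown dialect {dialect!r}")
    origin = 1 if dialect == "lastz-general" else 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#") or line.split("\t", 1)[0] == "name1":
                continue
            fields = line.split("\t")
            if len(fields) != len(LASTZ_GENERAL_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(LASTZ_GENERAL_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            row = dict(zip(LASTZ_GENERAL_COLUMNS, fields))
            try:
                start = int(row["start1"]) - origin
                length = int(row["length1"])
                ref_length = int(row["size2"])
                score = float(row["score"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if row["strand1"] not in "+-" or row["strand2"] not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand")
            strand = "+" if row["strand1"] == row["strand2"] else "-"
            yield SimilarityHit(
                read_id=row["name1"],
                read_start=start,
                read_end=start + length,
                strand=strand,
                family_id=row["name2"],
                ref_length=ref_length,
                identity=_parse_identity(row["identity"]),
                score=score,
            )


def write_hit_table(
    hits: Iterable[SimilarityHit], path: str | Path, dialect: str = "lastz-general"
) -> None:
    """Write hits back out in the LASTZ-general dialect (round-trip safe)."""
    if dialect not in ("lastz-general", "lastz-general-0"):
        raise ValueError(f"unknown dialect {dialect!r}")
    origin = 1 if dialect == "lastz-general" else 0
    with open(path, "w") as out:
        out.write("#" + "\t".join(LASTZ_GENERAL_COLUMNS) + "\n")
        for h in hits:
            out.write(
                "\t".join(
                    [
                        h.read_id,
                        "0",  # size1 (read length) is not retained internally
                        str(h.read_start + origin),
                        str(h.length),
                        "+",
                        h.family_id,
                        str(h.ref_length),
                        str(origin),
                        str(h.ref_length),
                        h.strand,
                        f"{h.identity:.6f}",
                        f"{h.score:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# protein-domain tables

_DOMAIN_ATTRS = {
    "Name": "domain",
    "Identity": "identity",
    "Similarity": "similarity",
    "Aln_Prop": "aln_length_proportion",
    "Interruptions": "interruptions",
    "Len_Prop": "length_proportion",
}


def parse_domain_table(path: str | Path) -> Iterator[DomainHit]:
    """Parse a DANTE-style GFF3 table of protein-domain hits.

    Nine GFF3 columns; attributes carry ``Name`` (one of GAG, PROT, RT, RH,
    aRH, INT), ``Identity``, ``Similarity``, ``Aln_Prop``, ``Interruptions``
    and ``Len_Prop``.  GFF3 1-based inclusive coordinates are converted to
    the internal 0-based half-open convention.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, _type, start, end, _score, strand, _phase, attrs = fields
            attr_map = {}
            for item in attrs.split(";"):
                if item and "=" in item:
                    key, value = item.split("=", 1)
                    attr_map[key.strip()] = value.strip()
            kwargs = {}
            for key, target in _DOMAIN_ATTRS.items():
                if key not in attr_map:
                    raise FormatError(
                        f"{path}:{lineno}: missing attribute {key!r}"
                    )
                kwargs[target] = attr_map[key]
            try:
                hit = DomainHit(
                    read_id=seqid,
                    read_start=int(start) - 1,
                    read_end=int(end),
                    strand=strand,
                    domain=kwargs["domain"],
                    identity=float(kwargs["identity"]),
                    similarity=float(kwargs["similarity"]),
                    aln_length_proportion=float(kwargs["aln_length_proportion"]),
                    interruptions=int(kwargs["interruptions"]),
                    length_proportion=float(kwargs["length_proportion"]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            yield hit


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for h in hits:
            attrs = (
                f"Name={h.domain};Identity={h.identity:g};"
                f"Similarity={h.similarity:g};Aln_Prop={h.aln_length_proportion:g};"
                f"Interruptions={h.interruptions};Len_Prop={h.length_proportion:g}"
            )
            out.write(
                "\t".join(
                    [
                        h.read_id, "satreads", "protein_domain",
                        str(h.read_start + 1), str(h.read_end), ".",
                        h.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# result tables


def hits_to_frame(hits: Iterable[SimilarityHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.read_id, h.read_start, h.read_end, h.strand, h.family_id,
             h.ref_length, h.identity, h.score)
            for h in hits
        ],
        columns=["read_id", "read_start", "read_end", "strand", "family_id",
                 "ref_length", "identity", "score"],
    )


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
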