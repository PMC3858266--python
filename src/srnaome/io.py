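"""Sequence I/O and the collapsed-read data model.

All sequences are held internally as uppercase DNA (``U`` normalised to
``T`` on ingest) so that hashing and substring matching have one canonical
form.  FASTA/FASTQ parsing is delegated to Biopython's ``SeqIO``; this
module adds the collapsed-FASTA header dialect (``id_count``) and the
reference-catalog header dialect (``category=<x>;family=<y>`` key-value
pairs in the description) used throughout the pipeline.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "RawRead",
    "CollapsedRead",
    "CatalogEntry",
    "ReferenceCatalog",
    "CATEGORIES",
    "revcomp",
    "to_dna",
    "to_rna",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "collapse",
    "merge_collapsed",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "read_catalog_fasta",
    "write_catalog_fasta",
]

#: Closed set of annotation categories, in the default precedence order.
CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "repeat", "mRNA")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def to_dna(seq: str) -> str:
    """Uppercase and normalise ``U`` to ``T`` (the internal alphabet)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Re-emit a DNA-alphabet sequence in RNA flavour (``T`` to ``U``)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RawRead:
    """A single sequencing read, possibly with phred quality scores."""

    identifier: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"read {self.identifier!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.identifier!r}: quality length "
                f"{len(self.quality)} != sequence length {len(self.sequence)}"
            )


@dataclass
class CollapsedRead:
    """A unique sRNA sequence with its per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CatalogEntry:
    id: str
    sequence: str
    category: str
    family: str | None = None
    species: str | None = None


@dataclass
class ReferenceCatalog:
    """A named, categorised set of reference sequences.

    Invariants (checked on construction): entry ids are unique, every
    category belongs to the closed set, and miRNA entries carry a family.
    """

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.id in seen:
                raise FormatError(f"duplicate catalog id {e.id!r}")
            seen.add(e.id)
            if e.category not in CATEGORIES:
                raise FormatError(
                    f"catalog entry {e.id!r}: unknown category {e.category!r}"
                )
            if e.category == "miRNA" and not e.family:
                raise FormatError(f"miRNA catalog entry {e.id!r} lacks a family")

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_category(self, category: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.category == category]

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.category not in out:
                out.append(e.category)
        return out


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, normalize_u: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file as ``(identifier, sequence)`` pairs in file order.

    Sequences are uppercased; ``U`` is converted to ``T`` only when
    ``normalize_u`` is set.  Empty sequences and malformed headers raise
    :class:`FormatError` naming the offending record.
    """
    records: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        if first == "":
            return []
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' FASTA header")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: record {len(records) + 1}: empty header")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r}: empty sequence")
            if normalize_u:
                seq = seq.replace("U", "T")
            records.append((rec.id, seq))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, rna: bool = False
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, optionally in RNA flavour."""
    with _open_text(path, "wt") as handle:
        for ident, seq in records:
            handle.write(f">{ident}\n{to_rna(seq) if rna else seq}\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read phred+33 FASTQ into :class:`RawRead` records.

    Truncated records raise :class:`FormatError` with the record index.
    """
    reads: list[RawRead] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                reads.append(
                    RawRead(
                        identifier=rec.id,
                        sequence=str(rec.seq).upper(),
                        quality=list(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed FASTQ after record {len(reads)}: {exc}"
            ) from exc
    return reads


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            qstr = "".join(chr(q + 33) for q in qual)
            handle.write(f"@{r.identifier}\n{r.sequence}\n+\n{qstr}\n")


def collapse(sequences: Iterable[str], library: str) -> dict[str, CollapsedRead]:
    """Collapse cleaned sequences into unique tags with counts for *library*.

    The sum of counts equals the number of input sequences (conservation).
    Sequences are normalised to the internal DNA alphabet.
    """
    out: dict[str, CollapsedRead] = {}
    for seq in sequences:
        seq = to_dna(seq)
        cr = out.get(seq)
        if cr is None:
            out[seq] = CollapsedRead(seq, {library: 1})
        else:
            cr.counts[library] = cr.counts.get(library, 0) + 1
    return out


def merge_collapsed(
    *collapsed_sets: dict[str, CollapsedRead],
) -> dict[str, CollapsedRead]:
    """Merge per-library collapsed sets, summing counts per sequence."""
    out: dict[str, CollapsedRead] = {}
    for cset in collapsed_sets:
        for seq, cr in cset.items():
            tgt = out.get(seq)
            if tgt is None:
                out[seq] = CollapsedRead(seq, dict(cr.counts))
            else:
                for lib, n in cr.counts.items():
                    tgt.counts[lib] = tgt.counts.get(lib, 0) + n
    return out


def write_collapsed_fasta(
    collapsed: dict[str, CollapsedRead],
    path: str | Path,
    library: str,
    prefix: str = "u",
) -> None:
    """Write one library's collapsed reads in the ``id_count`` dialect.

    Headers look like ``>u1_2301``: a running unique-tag id, an underscore,
    and the read count in *library*.  Sequences with zero count in
    *library* are skipped.  The written order is deterministic
    (descending count, then sequence).
    """
    items = [
        (seq, cr.count(library)) for seq, cr in collapsed.items() if cr.count(library)
    ]
    items.sort(key=lambda x: (-x[1], x[0]))
    with _open_text(path, "wt") as handle:
        for i, (seq, n) in enumerate(items, start=1):
            handle.write(f">{prefix}{i}_{n}\n{seq}\n")


def read_collapsed_fasta(path: str | Path, library: str) -> dict[str, CollapsedRead]:
    """Read collapsed FASTA in the ``id_count`` dialect back into memory.

    Also accepts the count as a separate whitespace token in the
    description (``>u7 15``).  A non-numeric count token raises
    :class:`FormatError`.
    """
    out: dict[str, CollapsedRead] = {}
    for ident_seq in _iter_collapsed(path):
        ident, desc, seq = ident_seq
        token: str | None = None
        if desc:
            token = desc.split()[0]
        elif "_" in ident:
            token = ident.rsplit("_", 1)[1]
        if token is None:
            raise FormatError(f"{path}: header {ident!r}: no count token")
        try:
            n = int(token)
        except ValueError:
            raise FormatError(
                f"{path}: header {ident!r}: count token {token!r} is not an integer"
            ) from None
        if n < 0:
            raise FormatError(f"{path}: header {ident!r}: negative count")
        seq = to_dna(seq)
        cr = out.get(seq)
        if cr is None:
            out[seq] = CollapsedRead(seq, {library: n})
        else:
            cr.counts[library] = cr.counts.get(library, 0) + n
    return out


def _iter_collapsed(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description[len(rec.id) :].strip()
            if not str(rec.seq):
                raise FormatError(f"{path}: record {rec.id!r}: empty sequence")
            yield rec.id, desc, str(rec.seq)


def _parse_kv(description: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in description.replace(" ", ";").split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_catalog_fasta(path: str | Path, default_category: str | None = None) -> ReferenceCatalog:
    """Read a reference catalog from FASTA.

    The category (and optional family/species) is encoded in the header
    description as ``category=<x>;family=<y>`` key-value pairs; a
    *default_category* may be supplied for plain FASTA catalogs.
    """
    entries: list[CatalogEntry] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            kv = _parse_kv(rec.description[len(rec.id) :])
            category = kv.get("category", default_category)
            if category is None:
                raise FormatError(
                    f"{path}: catalog entry {rec.id!r} has no category= tag "
                    "and no default category was given"
                )
            entries.append(
                CatalogEntry(
                    id=rec.id,
                    sequence=to_dna(str(rec.seq)),
                    category=category,
                    family=kv.get("family"),
                    species=kv.get("species"),
                )
            )
    return ReferenceCatalog(entries)


def write_catalog_fasta(catalog: ReferenceCatalog, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for e in catalog:
            tags = [f"category={e.category}"]
            if e.family:
                tags.append(f"family={e.family}")
            if e.species:
                tags.append(f"species={e.species}")
            handle.write(f">{e.id} {';'.join(tags)}\n{e.sequence}\n")
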