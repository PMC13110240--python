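"""Readers and writers for FASTA/FASTQ and the pipeline's TSV tables.

All nucleotide sequences are normalised at ingestion: uppercase, U
converted to T (sequencers emit DNA-space reads; every downstream
first-base "U" test is therefore performed on T).  The alphabet is
restricted to {A, C, G, T, N}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

VALID_BASES = frozenset("ACGTN")

#: Fixed category order for every count table the pipeline emits.
CATEGORY_ORDER: tuple[str, ...] = (
    "piRNA",
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "other_ncRNAs",
    "unknown",
)

#: Roles a reference set can play in the classification cascade.
REFERENCE_ROLES: tuple[str, ...] = (
    "genome",
    "mirna",
    "rrna",
    "trna",
    "snrna",
    "other_ncrna",
    "rrna_rescue",
    "known_pirna",
)


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/TSV input."""


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


def _normalise(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def _check_alphabet(seq: str, context: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"{context}: invalid characters {sorted(bad)} in sequence")


@dataclass(frozen=True)
class SmallRNARead:
    """One sequenced small-RNA read.

    ``sequence`` is DNA-space ({A,C,G,T,N}, U stored as T); ``quality``
    is an optional tuple of per-base Phred scores of identical length.
    """

    read_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        _check_alphabet(self.sequence, f"read {self.read_id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSet:
    """A named FASTA-backed sequence collection with a cascade role."""

    name: str
    role: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.role not in REFERENCE_ROLES:
            raise ConfigError(f"unknown reference role {self.role!r}")
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise FormatError(f"reference set {self.name!r}: duplicate id {rid!r}")
            seen.add(rid)
            if not seq:
                raise FormatError(f"reference set {self.name!r}: empty sequence {rid!r}")
            _check_alphabet(seq, f"reference {rid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CountTable:
    """Per-sample read counts over the seven fixed RNA categories."""

    sample_id: str
    rows: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.rows) != set(CATEGORY_ORDER):
            missing = set(CATEGORY_ORDER) - set(self.rows)
            extra = set(self.rows) - set(CATEGORY_ORDER)
            raise FormatError(
                f"count table {self.sample_id!r}: categories must be exactly "
                f"{list(CATEGORY_ORDER)} (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for cat, n in self.rows.items():
            if not isinstance(n, int) or n < 0:
                raise FormatError(f"count table {self.sample_id!r}: bad count {n!r} for {cat}")

    @classmethod
    def zero(cls, sample_id: str) -> "CountTable":
        return cls(sample_id, {c: 0 for c in CATEGORY_ORDER})

    @property
    def total(self) -> int:
        return sum(self.rows.values())


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and U->T normalised; multi-line records are
    concatenated.  Duplicate ids, empty files and stray leading sequence
    lines raise :class:`FormatError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_seq: list[str] = []

    def flush(line_no: int) -> None:
        if cur_id is None:
            return
        seq = _normalise("".join(cur_seq))
        if not seq:
            raise FormatError(f"{path}:{line_no}: record {cur_id!r} has no sequence")
        _check_alphabet(seq, f"{path} record {cur_id!r}")
        records.append((cur_id, seq))

    with open(path) as fh:
        line_no = 0
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                if cur_id in seen:
                    raise FormatError(f"{path}:{line_no}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                cur_seq = []
            else:
                if cur_id is None:
                    raise FormatError(f"{path}:{line_no}: sequence before first header")
                cur_seq.append(line)
        flush(line_no + 1)
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_fastq(path: str | os.PathLike) -> list[SmallRNARead]:
    """Parse a 4-line-record FASTQ file (Phred+33) into reads.

    An empty file yields an empty list; truncated records or
    quality/sequence length mismatches raise :class:`FormatError`.
    """
    reads: list[SmallRNARead] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count {len(lines)} not divisible by 4)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        line_no = i + 1
        if not header.startswith("@"):
            raise FormatError(f"{path}:{line_no}: expected '@' header, got {header!r}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{line_no + 2}: expected '+' separator")
        read_id = header[1:].split()[0] if header[1:].split() else ""
        if not read_id:
            raise FormatError(f"{path}:{line_no}: empty read id")
        seq = _normalise(seq)
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}:{line_no + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        try:
            reads.append(
                SmallRNARead(read_id, seq, tuple(ord(c) - 33 for c in qual))
            )
        except FormatError as err:
            raise FormatError(f"{path}:{line_no}: {err}") from None
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality
            if qual is None:
                qual = (40,) * len(read.sequence)
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count tables


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    """Write a two-column TSV (category, count) in the fixed category order."""
    with open(path, "w") as fh:
        fh.write(f"category\t{table.sample_id}\n")
        for cat in CATEGORY_ORDER:
            fh.write(f"{cat}\t{table.rows[cat]}\n")


def read_count_table(path: str | os.PathLike) -> CountTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty count table")
    header = lines[0].split("\t")
    if len(header) != 2 or header[0] != "category":
        raise FormatError(f"{path}:1: expected header 'category\\t<sample_id>'")
    sample_id = header[1]
    rows: dict[str, int] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{line_no}: expected 2 columns")
        cat, val = parts
        try:
            rows[cat] = int(val)
        except ValueError:
            raise FormatError(f"{path}:{line_no}: non-integer count {val!r}") from None
    return CountTable(sample_id, rows)


# ---------------------------------------------------------------------------
# Reference bundle loading


def load_reference_bundle(
    paths: Mapping[str, str | os.PathLike],
) -> dict[str, ReferenceSet]:
    """Load the per-role reference FASTAs named in ``paths``.

    ``paths`` maps role names (a subset of :data:`REFERENCE_ROLES`) to
    FASTA files.  Roles absent from the mapping are simply absent from
    the bundle; the cascade skips the corresponding stages and reports
    them as skipped.  An unknown role name raises :class:`ConfigError`.
    """
    bundle: dict[str, ReferenceSet] = {}
    for role, path in paths.items():
        if role not in REFERENCE_ROLES:
            raise ConfigError(
                f"unknown reference role {role!r}; valid roles: {list(REFERENCE_ROLES)}"
            )
        if not os.path.exists(path):
            raise ConfigError(f"reference FASTA for role {role!r} not found: {path}")
        records = tuple(read_fasta(path))
        bundle[role] = ReferenceSet(name=os.path.basename(str(path)), role=role, records=records)
    return bundle
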