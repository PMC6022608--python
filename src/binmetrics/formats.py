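"""Readers and writers for the file formats the tool touches.

The central exchange format is the Bioboxes binning format: a
tab-separated file with optional ``@Key:Value`` header lines, optional
``#`` comment lines, a mandatory ``@@``-prefixed column header naming at
least SEQUENCEID and BINID, and one row per sequence.  Reading is
tolerant (any column order, case-insensitive header keys, stray
whitespace); writing is strict and deterministic so that files
round-trip byte-identically.

Sequence lengths come either from FASTA/FASTQ files (plain or gzipped,
indexed with Bio.SeqIO) or from an in-file ``_LENGTH`` column of the
gold standard.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

from .model import (
    Binning,
    ConfigurationError,
    DuplicateAssignmentError,
    FormatError,
    GoldStandard,
)

logger = logging.getLogger(__name__)

FASTA_EXTENSIONS = (".fasta", ".fa", ".fna", ".fsa")

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | os.PathLike) -> TextIO:
    """Open plain or gzip-compressed text, sniffing by magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _parse_bioboxes_table(path: str | os.PathLike):
    """Parse the raw structure of a Bioboxes binning file.

    Returns (headers, columns, rows) where headers maps lower-cased
    ``@Key`` names to values, columns is the ``@@`` column list, and
    rows are lists of fields aligned to columns.
    """
    headers: dict[str, str] = {}
    columns: list[str] | None = None
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@@"):
                if columns is not None:
                    raise FormatError(
                        f"{path}: second '@@' column header at line {lineno}"
                    )
                columns = [c.strip().upper() for c in line[2:].split("\t")]
                continue
            if line.startswith("@"):
                if columns is not None:
                    raise FormatError(
                        f"{path}: '@' header after the '@@' line at line {lineno}"
                    )
                key, _, value = line[1:].partition(":")
                headers[key.strip().lower()] = value.strip()
                continue
            if columns is None:
                raise FormatError(
                    f"{path}: data row before any '@@' column header "
                    f"at line {lineno}"
                )
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < len(columns):
                raise FormatError(
                    f"{path}: row at line {lineno} has {len(fields)} column(s), "
                    f"header declares {len(columns)}"
                )
            rows.append(fields)
    if columns is None:
        raise FormatError(f"{path}: missing '@@' column header line")
    return headers, columns, rows


def read_bioboxes_binning(
    path: str | os.PathLike,
    *,
    label: str | None = None,
    keep_first: bool = False,
) -> Binning:
    """Read a predicted binning from a Bioboxes binning file.

    The label defaults to the ``@SampleID`` header when present, else
    the file basename without extension.  Extra columns beyond
    SEQUENCEID/BINID are preserved as per-sequence metadata.

    With ``keep_first`` a duplicate sequence id with a conflicting bin
    is downgraded from an error to a warning and the first assignment
    wins.
    """
    headers, columns, rows = _parse_bioboxes_table(path)
    try:
        seq_col = columns.index("SEQUENCEID")
        bin_col = columns.index("BINID")
    except ValueError as exc:
        raise FormatError(
            f"{path}: '@@' header must name SEQUENCEID and BINID "
            f"(got {columns})"
        ) from exc
    extra_cols = [
        (i, name)
        for i, name in enumerate(columns)
        if i not in (seq_col, bin_col)
    ]
    assignment: dict[str, str] = {}
    metadata: dict[str, dict[str, str]] = {}
    dropped_duplicates = 0
    for fields in rows:
        seq_id, bin_id = fields[seq_col], fields[bin_col]
        if seq_id in assignment and assignment[seq_id] != bin_id:
            if not keep_first:
                raise DuplicateAssignmentError(
                    f"{path}: sequence {seq_id!r} assigned to both "
                    f"{assignment[seq_id]!r} and {bin_id!r}"
                )
            dropped_duplicates += 1
            continue
        assignment[seq_id] = bin_id
        if extra_cols:
            metadata[seq_id] = {
                name: fields[i] for i, name in extra_cols if i < len(fields)
            }
    if dropped_duplicates:
        logger.warning(
            "%s: kept first assignment for %d duplicated sequence id(s)",
            path,
            dropped_duplicates,
        )
    if label is None:
        label = headers.get("sampleid") or Path(path).stem
    return Binning(label=label, assignment=assignment, metadata=metadata)


def write_bioboxes_binning(
    binning: Binning,
    path: str | os.PathLike,
    sample_id: str | None = None,
    *,
    version: str = "0.9.0",
) -> None:
    """Write a binning as a Bioboxes binning file.

    Rows are sorted by sequence id so output is deterministic and
    write/read/write is idempotent.
    """
    if not binning.assignment:
        raise ValueError("refusing to write an empty binning")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"@Version:{version}\n")
        fh.write(f"@SampleID:{sample_id if sample_id is not None else binning.label}\n")
        fh.write("@@SEQUENCEID\tBINID\n")
        for seq_id in sorted(binning.assignment):
            fh.write(f"{seq_id}\t{binning.assignment[seq_id]}\n")


def _detect_seq_format(path: str | os.PathLike) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise FormatError(
                    f"{path}: not FASTA or FASTQ (first record starts "
                    f"with {first!r})"
                )
    raise FormatError(f"{path}: empty sequence file")


def index_sequence_lengths(
    paths: Iterable[str | os.PathLike],
) -> dict[str, int]:
    """Index sequence lengths (bp) from FASTA/FASTQ files.

    Format is auto-detected per file; gzip input is transparent.  Ids
    are the header token up to the first whitespace.  Zero-length
    records are excluded with a warning; a duplicate id across files is
    an error.
    """
    lengths: dict[str, int] = {}
    for path in paths:
        fmt = _detect_seq_format(path)
        with _open_text(path) as fh:
            for record in SeqIO.parse(fh, fmt):
                if len(record.seq) == 0:
                    logger.warning(
                        "%s: sequence %r is empty, excluded", path, record.id
                    )
                    continue
                if record.id in lengths:
                    raise FormatError(
                        f"duplicate sequence id {record.id!r} in {path}"
                    )
                lengths[record.id] = len(record.seq)
    return lengths


def read_gold_standard(
    path: str | os.PathLike,
    lengths: Mapping[str, int] | None = None,
) -> GoldStandard:
    """Read the gold-standard sequence-to-genome map.

    The file is in Bioboxes binning format with BINID holding the true
    genome id.  Per-sequence lengths come from the ``lengths`` mapping
    (e.g. built by :func:`index_sequence_lengths`), from an in-file
    ``_LENGTH`` column, or both; when both name a sequence they must
    agree, else the conflict is an error naming the id.
    """
    binning = read_bioboxes_binning(path)
    file_lengths: dict[str, int] = {}
    for seq_id, meta in binning.metadata.items():
        raw = meta.get("_LENGTH")
        if raw is None or raw == "":
            continue
        try:
            file_lengths[seq_id] = int(float(raw))
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad _LENGTH value {raw!r} for sequence {seq_id!r}"
            ) from exc
    if lengths is None and not file_lengths:
        raise ConfigurationError(
            f"{path}: no length source — provide FASTA/FASTQ files or a "
            f"_LENGTH column in the gold standard"
        )
    merged = dict(file_lengths)
    if lengths is not None:
        for seq_id, length in lengths.items():
            if seq_id in merged and merged[seq_id] != length:
                raise ConfigurationError(
                    f"length conflict for sequence {seq_id!r}: _LENGTH column "
                    f"says {merged[seq_id]}, sequence file says {length}"
                )
            merged[seq_id] = length
    relevant = {s: L for s, L in merged.items() if s in binning.assignment}
    return GoldStandard(assignment=dict(binning.assignment), seq_lengths=relevant)


def convert_fasta_bins_dir(directory: str | os.PathLike) -> Binning:
    """Build a binning from a directory of per-bin FASTA files.

    Each FASTA file is one bin; the bin id is the file basename without
    extension.  Sequence lengths are *not* taken from these files — the
    gold standard governs lengths.
    """
    directory = Path(directory)
    fasta_files = sorted(
        p
        for p in directory.iterdir()
        if p.is_file()
        and (p.suffix.lower() in FASTA_EXTENSIONS
             or (p.suffix == ".gz" and Path(p.stem).suffix.lower() in FASTA_EXTENSIONS))
    )
    if not fasta_files:
        raise ConfigurationError(f"{directory}: no FASTA files found")
    assignment: dict[str, str] = {}
    for path in fasta_files:
        bin_id = Path(path.stem).stem if path.suffix == ".gz" else path.stem
        ids = []
        with _open_text(path) as fh:
            for record in SeqIO.parse(fh, "fasta"):
                ids.append(record.id)
        if not ids:
            logger.warning("%s: empty FASTA file, bin %r omitted", path, bin_id)
            continue
        for seq_id in ids:
            if seq_id in assignment:
                raise DuplicateAssignmentError(
                    f"sequence {seq_id!r} appears in bins "
                    f"{assignment[seq_id]!r} and {bin_id!r}"
                )
            assignment[seq_id] = bin_id
    return Binning(label=directory.name, assignment=assignment)


def apply_exclusion_filter(
    gold: GoldStandard,
    exclude: Iterable[str],
) -> GoldStandard:
    """Remove genomes (exact ids or fnmatch patterns) from a gold standard.

    Removed sequences are treated downstream as nonexistent, not as
    unassigned — e.g. bins representing viruses or circular elements can
    be taken out of scope entirely.  A pattern matching nothing is a
    warning, not an error; emptying the gold standard is an error.
    """
    patterns = list(exclude)
    if not patterns:
        return gold
    genomes = sorted(gold.genomes)
    removed: set[str] = set()
    for pat in patterns:
        hits = {g for g in genomes if g == pat or fnmatchcase(g, pat)}
        if not hits:
            logger.warning("exclusion pattern %r matches no genome", pat)
        removed |= hits
    if not removed:
        return gold
    kept_assignment = {
        s: g for s, g in gold.assignment.items() if g not in removed
    }
    if not kept_assignment:
        raise ConfigurationError(
            "exclusion filter removed every genome: empty gold standard"
        )
    kept_lengths = {s: gold.seq_lengths[s] for s in kept_assignment}
    return GoldStandard(assignment=kept_assignment, seq_lengths=kept_lengths)
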