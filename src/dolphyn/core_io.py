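"""Data model and readers/writers for protein sets, peptide libraries, and reactivity tables.

The package works with three kinds of artifacts:

* protein sets (FASTA) — the design substrate, one record per protein or
  protein-cluster representative;
* peptide libraries (TSV) — the designed peptides with provenance back to
  their source proteins; TSV is the canonical format, FASTA export is lossy;
* reactivity tables (CSV/TSV) — peptide x sample matrices of sequencing
  counts, fold changes, p-values and log hit-fold-changes coming out of a
  PhIP-Seq screen.

Coordinates are 0-based, half-open ``[start, start+len)`` everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)


class ValidationError(ValueError):
    """Input violates a data-model invariant (alphabet, uniqueness, shape)."""


class LibraryFormatError(ValueError):
    """A file could not be parsed in the expected format."""


def is_canonical(seq: str) -> bool:
    """True if every character of ``seq`` is a canonical amino acid."""
    return all(c in _AA_SET for c in seq)


def check_canonical(seq: str, where: str = "sequence") -> None:
    """Raise :class:`ValidationError` naming the first non-canonical position."""
    for i, c in enumerate(seq):
        if c not in _AA_SET:
            raise ValidationError(
                f"{where}: non-canonical residue {c!r} at position {i} "
                f"(allowed: {AA_ALPHABET})"
            )


@dataclass
class ProteinRecord:
    """A protein (or protein-cluster representative) to be represented in a library."""

    id: str
    seq: str
    cluster_id: str | None = None
    phage_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.seq = str(self.seq).upper()
        self.phage_ids = frozenset(self.phage_ids)
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if not self.seq:
            raise ValidationError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


class PeptideKind(str, Enum):
    TILE = "tile"
    EPITOPE15 = "epitope15"
    STITCHED = "stitched"
    SCAN_KMER = "scan_kmer"
    SCAN_ALANINE = "scan_alanine"
    WILDTYPE = "wildtype"


#: Expected length (aa) of a default stitched peptide: 3 x 15-mer + 2 x GGGGS.
STITCHED_LENGTH = 3 * 15 + 2 * 5


@dataclass
class PeptideRecord:
    """A library member with provenance to its source protein(s)."""

    id: str
    seq: str
    kind: PeptideKind
    source_protein_ids: tuple[str, ...] = ()
    start: int | None = None

    def __post_init__(self) -> None:
        self.kind = PeptideKind(self.kind)
        self.seq = str(self.seq).upper()
        self.source_protein_ids = tuple(self.source_protein_ids)
        if not self.seq:
            raise ValidationError(f"peptide {self.id!r}: empty sequence")
        if self.kind is PeptideKind.EPITOPE15 and len(self.seq) != 15:
            raise ValidationError(
                f"peptide {self.id!r}: kind=epitope15 requires length 15, got {len(self.seq)}"
            )
        if self.kind is PeptideKind.STITCHED and len(self.seq) != STITCHED_LENGTH:
            raise ValidationError(
                f"peptide {self.id!r}: kind=stitched requires length {STITCHED_LENGTH}, "
                f"got {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_proteins(path: str | Path, skip_noncanonical: bool = False) -> list[ProteinRecord]:
    """Read a protein set from FASTA.

    The header token before the first whitespace is the record id; sequences
    are uppercased. Non-canonical residues (X, B, Z, U, ``*`` ...) are rejected
    unless ``skip_noncanonical`` is set, in which case the record is kept and
    downstream window scans drop the affected 15-mers.
    """
    path = Path(path)
    text_head = path.read_text()[:1024].lstrip()
    if text_head and not text_head.startswith(">"):
        raise LibraryFormatError(f"{path}: not a FASTA file (first record line must start with '>')")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        protein = ProteinRecord(id=rec.id, seq=str(rec.seq))
        if not skip_noncanonical:
            check_canonical(protein.seq, where=f"protein {rec.id!r}")
        records.append(protein)
    return records


def write_proteins(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write a protein set as FASTA."""
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.seq}\n")


_LIBRARY_COLUMNS = ["id", "seq", "kind", "source_protein_ids", "start"]


def write_library(
    peptides: list[PeptideRecord],
    path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Write a peptide library as TSV (canonical) and optionally FASTA (lossy).

    Columns: ``id, seq, kind, source_protein_ids, start``; source protein ids
    are semicolon-joined, a missing start is an empty field.
    ``read_library(write_library(x)) == x``.
    """
    if not peptides:
        raise ValidationError("write_library: empty peptide list")
    rows = [
        {
            "id": p.id,
            "seq": p.seq,
            "kind": p.kind.value,
            "source_protein_ids": ";".join(p.source_protein_ids),
            "start": "" if p.start is None else p.start,
        }
        for p in peptides
    ]
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for p in peptides:
                desc = f"kind={p.kind.value} sources={';'.join(p.source_protein_ids)}"
                fh.write(f">{p.id} {desc}\n{p.seq}\n")


def read_library(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide library TSV written by :func:`write_library`."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise LibraryFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryFormatError(f"{path}: missing columns {missing}")
    peptides = []
    for row in df.itertuples(index=False):
        sources = tuple(s for s in row.source_protein_ids.split(";") if s)
        start = None if row.start == "" else int(row.start)
        peptides.append(
            PeptideRecord(id=row.id, seq=row.seq, kind=row.kind,
                          source_protein_ids=sources, start=start)
        )
    return peptides


def read_matrix(path: str | Path, impute_zero: bool = False) -> pd.DataFrame:
    """Read one peptide x sample numeric matrix from CSV/TSV.

    First column holds the peptide id (often the amino-acid sequence itself),
    remaining columns are samples. Missing cells are an error unless
    ``impute_zero`` is set, in which case they become 0.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise LibraryFormatError(f"{path}: ragged or malformed table ({exc})") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise LibraryFormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        if impute_zero:
            df = df.fillna(0.0)
        else:
            row = df.isna().any(axis=1).idxmax()
            col = df.columns[df.isna().any(axis=0)][0]
            raise LibraryFormatError(
                f"{path}: missing value at row {row!r}, column {col!r} "
                "(pass impute_zero=True to fill with 0)"
            )
    return df


def read_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column membership TSV (e.g. peptide→protein, peptide→phage).

    Multiple rows per key accumulate into a tuple of values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise LibraryFormatError(f"{path}: membership map needs two columns")
    out: dict[str, tuple[str, ...]] = {}
    for key, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[key] = out.get(key, ()) + (val,)
    return out


def write_map(mapping: Mapping[str, Iterable[str]], path: str | Path,
              key_name: str = "peptide_id", value_name: str = "target_id") -> None:
    rows = [(k, v) for k, vals in mapping.items() for v in vals]
    pd.DataFrame(rows, columns=[key_name, value_name]).to_csv(path, sep="\t", index=False)


@dataclass
class ReactivityTable:
    """Peptide x sample matrices from a PhIP-Seq screen.

    ``log_hfc`` is the log2 hit fold change: log2 of the fold change where the
    hit criteria hold (count > 15, fold change > 5, p < 0.001) and 0 elsewhere
    (enforced by :func:`dolphyn.reactivity.call_hits`).
    """

    peptide_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray | None = None
    foldchange: np.ndarray | None = None
    pvalue: np.ndarray | None = None
    log_hfc: np.ndarray | None = None
    peptide_to_proteins: dict[str, tuple[str, ...]] = field(default_factory=dict)
    peptide_to_phages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peptide_ids = list(self.peptide_ids)
        self.sample_ids = list(self.sample_ids)
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValidationError("duplicate peptide ids in reactivity table")
        shape = (len(self.peptide_ids), len(self.sample_ids))
        for name in ("counts", "foldchange", "pvalue", "log_hfc"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m)
            if m.shape != shape:
                raise ValidationError(
                    f"{name} has shape {m.shape}, expected {shape} (peptides x samples)"
                )
            setattr(self, name, m)
        if self.pvalue is not None and ((self.pvalue < 0) | (self.pvalue > 1)).any():
            raise ValidationError("p-values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.peptide_ids), len(self.sample_ids))

    def frame(self, which: str) -> pd.DataFrame:
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"matrix {which!r} not present")
        return pd.DataFrame(m, index=self.peptide_ids, columns=self.sample_ids)

    @classmethod
    def from_frames(cls, **frames: pd.DataFrame | None) -> "ReactivityTable":
        """Build a table from identically indexed DataFrames (counts=, foldchange=, ...)."""
        maps = {
            "peptide_to_proteins": frames.pop("peptide_to_proteins", {}),
            "peptide_to_phages": frames.pop("peptide_to_phages", {}),
        }
        present = {k: v for k, v in frames.items() if v is not None}
        if not present:
            raise ValidationError("at least one matrix is required")
        first = next(iter(present.values()))
        for name, df in present.items():
            if list(df.index) != list(first.index) or list(df.columns) != list(first.columns):
                raise ValidationError(f"matrix {name!r} is not aligned with the others")
        return cls(
            peptide_ids=[str(i) for i in first.index],
            sample_ids=[str(c) for c in first.columns],
            **{k: df.to_numpy(dtype=float) for k, df in present.items()},
            **maps,
        )


def read_reactivity(
    counts: str | Path | None = None,
    foldchange: str | Path | None = None,
    pvalue: str | Path | None = None,
    log_hfc: str | Path | None = None,
    peptide_to_proteins: str | Path | None = None,
    peptide_to_phages: str | Path | None = None,
    impute_zero: bool = False,
) -> ReactivityTable:
    """Assemble a :class:`ReactivityTable` from one or more matrix files."""
    frames = {
        name: (read_matrix(p, impute_zero=impute_zero) if p is not None else None)
        for name, p in {
            "counts": counts, "foldchange": foldchange,
            "pvalue": pvalue, "log_hfc": log_hfc,
        }.items()
    }
    table = ReactivityTable.from_frames(**frames)
    if peptide_to_proteins is not None:
        table.peptide_to_proteins = read_map(peptide_to_proteins)
    if peptide_to_phages is not None:
        table.peptide_to_phages = read_map(peptide_to_phages)
    return table
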