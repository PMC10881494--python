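"""Peptide library designers: uniform tiling and predict/select/stitch.

Two strategies for representing a protein set as a synthesizable peptide
library:

* **Uniform tiling** (the classic PhIP-Seq layout): 56-aa tiles overlapping
  by 28 aa, with a full-length C-terminal tile whenever the protein length is
  not a multiple of the step, giving roughly 2x proteome coverage.
* **Epitope stitching**: every 15-mer window of a protein is scored by the
  epitope classifier; non-overlapping windows with probability > 0.5 are
  selected greedily in descending-probability order, and sets of three are
  stitched into one 55-aa composite peptide separated by GGGGS linkers. With
  n selected epitopes, floor(n/3) peptides are made; the rank-interleaving
  rule places the highest-probability epitope first on the first peptide, the
  second-highest first on the second, and so on, so each stitched peptide
  leads with a strong candidate. Proteins with fewer than three selected
  epitopes are left out of the library — the price of compression.

Coverage credits 56 protein-derived aa per full tile but only 45 per stitched
peptide (3 x 15; linkers and the stop codon are synthesis overhead, not
proteome content).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    PeptideKind,
    PeptideRecord,
    ProteinRecord,
    ValidationError,
    is_canonical,
)

DEFAULT_LINKER = "GGGGS"
EPITOPE_LENGTH = 15


@dataclass
class EpitopeWindow:
    """A scored 15-mer window of a protein."""

    protein_id: str
    start: int
    seq: str
    prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValidationError(f"window probability {self.prob} outside [0, 1]")

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class StitchedPeptide:
    """Three epitope windows joined by linkers into one library peptide."""

    members: tuple[EpitopeWindow, EpitopeWindow, EpitopeWindow]
    linker: str = DEFAULT_LINKER
    group_id: str | None = None
    protein_ids: tuple[str, ...] = ()
    phage_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def seq(self) -> str:
        return self.linker.join(m.seq for m in self.members)

    def __len__(self) -> int:
        return len(self.seq)


def pepsyn_tile(
    protein: ProteinRecord, tile_len: int = 56, overlap: int = 28
) -> list[PeptideRecord]:
    """Uniformly tile a protein with fixed-length overlapping peptides.

    Tiles start at 0, tile_len-overlap, ... while they fit; if the last
    regular tile does not end at the protein's C-terminus, a full tile ending
    exactly at the C-terminus is appended (overlapping the previous tile by
    more than ``overlap``). Proteins shorter than ``tile_len`` yield a single
    short tile covering the whole protein; padding to full length is the
    encoder's concern.
    """
    if overlap >= tile_len:
        raise ValidationError("overlap must be smaller than tile length")
    L = len(protein)
    step = tile_len - overlap
    if L < tile_len:
        starts = [0]
        lengths = [L]
    else:
        starts = list(range(0, L - tile_len + 1, step))
        if starts[-1] + tile_len != L:
            starts.append(L - tile_len)
        lengths = [tile_len] * len(starts)
    return [
        PeptideRecord(
            id=f"{protein.id}|tile|{s}",
            seq=protein.seq[s : s + n],
            kind=PeptideKind.TILE,
            source_protein_ids=(protein.id,),
            start=s,
        )
        for s, n in zip(starts, lengths)
    ]


def dolphyn_select(
    protein: ProteinRecord,
    model,
    threshold: float = 0.5,
    skip_noncanonical: bool = False,
) -> list[EpitopeWindow]:
    """Score all 15-mer windows and greedily pick non-overlapping epitopes.

    All ``L - 14`` windows (stride 1) are scored with
    ``model.predict_proba_many``; windows with probability strictly above
    ``threshold`` are accepted in descending-probability order (ties: smaller
    start), skipping any window overlapping an already accepted one. The
    result is ordered by descending probability. Proteins shorter than 15 aa
    yield an empty list.
    """
    L = len(protein)
    if L < EPITOPE_LENGTH:
        return []
    windows = [
        (s, protein.seq[s : s + EPITOPE_LENGTH]) for s in range(L - EPITOPE_LENGTH + 1)
    ]
    if skip_noncanonical:
        windows = [(s, w) for s, w in windows if is_canonical(w)]
        if not windows:
            return []
    probs = np.asarray(model.predict_proba_many([w for _, w in windows]), dtype=float)
    order = sorted(range(len(windows)), key=lambda i: (-probs[i], windows[i][0]))
    accepted: list[EpitopeWindow] = []
    for i in order:
        if probs[i] <= threshold:
            break
        s = windows[i][0]
        if any(abs(s - a.start) < EPITOPE_LENGTH for a in accepted):
            continue
        accepted.append(EpitopeWindow(protein.id, s, windows[i][1], float(probs[i])))
    return accepted


def dolphyn_stitch(
    windows: Sequence[EpitopeWindow],
    linker: str = DEFAULT_LINKER,
    group_id: str | None = None,
    protein_ids: tuple[str, ...] = (),
    phage_ids: frozenset[str] = frozenset(),
) -> list[StitchedPeptide]:
    """Combine rank-ordered epitopes into stitched peptides.

    With n epitopes sorted by descending probability, np = floor(n/3)
    peptides are made; peptide i holds ranks i, i+np and i+2*np. Fewer than
    three epitopes make no peptide; epitopes of rank >= 3*np stay unused.
    """
    n_pep = len(windows) // 3
    if not protein_ids and windows:
        protein_ids = (windows[0].protein_id,)
    out = []
    for i in range(n_pep):
        trio = (windows[i], windows[i + n_pep], windows[i + 2 * n_pep])
        out.append(
            StitchedPeptide(
                members=trio, linker=linker, group_id=group_id,
                protein_ids=protein_ids, phage_ids=phage_ids,
            )
        )
    return out


def split_stitched(seq: str, linker: str = DEFAULT_LINKER) -> tuple[str, str, str]:
    """Recover the three member 15-mers of a stitched peptide at fixed offsets."""
    k, g = EPITOPE_LENGTH, len(linker)
    if len(seq) != 3 * k + 2 * g:
        raise ValidationError(f"not a stitched peptide of linker {linker!r}: {seq!r}")
    return (seq[:k], seq[k + g : 2 * k + g], seq[2 * (k + g) :])


@dataclass
class ProteinGroup:
    """Proteins whose selected epitope sets are identical, stitched once."""

    group_id: str
    protein_ids: tuple[str, ...]
    windows: tuple[EpitopeWindow, ...]
    phage_ids: frozenset[str] = field(default_factory=frozenset)


def group_shared_epitopes(
    selections: Mapping[str, Sequence[EpitopeWindow]],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[ProteinGroup]:
    """Group proteins sharing their entire selected epitope set.

    Identical 15-mer sequences collapse to one library entry; proteins whose
    selected epitope sequence sets are exactly equal form one group that is
    stitched once, with all protein (and phage) ids retained as provenance.
    Proteins sharing only part of their epitopes stay in separate groups (the
    shared 15-mers are still deduplicated in the flat epitope list).
    """
    by_key: dict[tuple[str, ...], list[str]] = {}
    order: list[tuple[str, ...]] = []
    for pid in selections:
        key = tuple(sorted({w.seq for w in selections[pid]}))
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(pid)
    groups = []
    for gi, key in enumerate(order):
        pids = tuple(by_key[key])
        rep = selections[pids[0]]
        seen: set[str] = set()
        windows = []
        for w in rep:  # keep descending-probability order, dedup identical seqs
            if w.seq not in seen:
                seen.add(w.seq)
                windows.append(w)
        phages: frozenset[str] = frozenset()
        if proteins is not None:
            phages = frozenset().union(*(proteins[p].phage_ids for p in pids))
        groups.append(ProteinGroup(f"g{gi:05d}", pids, tuple(windows), phages))
    return groups


def epitope_records(selections: Mapping[str, Sequence[EpitopeWindow]]) -> list[PeptideRecord]:
    """Flat deduplicated 15-mer epitope library with merged provenance."""
    by_seq: dict[str, list[EpitopeWindow]] = {}
    order: list[str] = []
    for pid in selections:
        for w in selections[pid]:
            if w.seq not in by_seq:
                by_seq[w.seq] = []
                order.append(w.seq)
            by_seq[w.seq].append(w)
    out = []
    for i, seq in enumerate(order):
        ws = by_seq[seq]
        out.append(
            PeptideRecord(
                id=f"epi{i:06d}",
                seq=seq,
                kind=PeptideKind.EPITOPE15,
                source_protein_ids=tuple(dict.fromkeys(w.protein_id for w in ws)),
                start=ws[0].start,
            )
        )
    return out


@dataclass
class LibraryStats:
    """Size, coverage, and compression bookkeeping for a designed library."""

    n_proteins: int
    n_proteins_skipped: int
    total_aa: int
    n_tiles: int
    coverage: float
    compression_ratio: float | None = None


#: Protein-derived amino acids credited per peptide of each kind.
_COVERED_AA = {
    PeptideKind.STITCHED: 3 * EPITOPE_LENGTH,  # linkers excluded
    PeptideKind.EPITOPE15: EPITOPE_LENGTH,
}


def coverage(n_peptides: int, covered_aa_per_peptide: int, total_aa: int) -> float:
    """Library coverage: protein-derived aa in the library over proteome length."""
    if total_aa <= 0:
        raise ValidationError("total_aa must be positive")
    return n_peptides * covered_aa_per_peptide / total_aa


def compression_ratio(n_compressed: int, n_reference: int) -> float:
    """Peptide-count ratio of a compressed design to a reference design."""
    if n_reference <= 0:
        raise ValidationError("reference library must be non-empty")
    return n_compressed / n_reference


def library_stats(
    peptides: Sequence[PeptideRecord],
    proteins: Sequence[ProteinRecord],
    reference_n_tiles: int | None = None,
) -> LibraryStats:
    """Tile counts, coverage and (optionally) compression for one design.

    ``coverage`` credits each peptide with its protein-derived amino acids:
    the tile length for tiles, 45 for stitched peptides, 15 for single
    epitopes. ``reference_n_tiles`` (a competing design's peptide count)
    enables the compression ratio.
    """
    total_aa = sum(len(p) for p in proteins)
    represented = {pid for pep in peptides for pid in pep.source_protein_ids}
    covered = sum(_COVERED_AA.get(p.kind, len(p.seq)) for p in peptides)
    return LibraryStats(
        n_proteins=len(proteins),
        n_proteins_skipped=sum(1 for p in proteins if p.id not in represented),
        total_aa=total_aa,
        n_tiles=len(peptides),
        coverage=covered / total_aa if total_aa else 0.0,
        compression_ratio=(
            compression_ratio(len(peptides), reference_n_tiles)
            if reference_n_tiles is not None
            else None
        ),
    )


def design_library(
    proteins: Sequence[ProteinRecord],
    model,
    threshold: float = 0.5,
    linker: str = DEFAULT_LINKER,
    skip_noncanonical: bool = False,
) -> tuple[list[PeptideRecord], LibraryStats, list[ProteinGroup]]:
    """Full predict/select/group/stitch pipeline over a protein set."""
    protein_map = {p.id: p for p in proteins}
    if len(protein_map) != len(proteins):
        raise ValidationError("duplicate protein ids in input")
    selections = {
        p.id: dolphyn_select(p, model, threshold, skip_noncanonical) for p in proteins
    }
    groups = group_shared_epitopes(selections, protein_map)
    peptides: list[PeptideRecord] = []
    for g in groups:
        for j, sp in enumerate(
            dolphyn_stitch(list(g.windows), linker, g.group_id, g.protein_ids, g.phage_ids)
        ):
            peptides.append(
                PeptideRecord(
                    id=f"{g.group_id}|stitched|{j}",
                    seq=sp.seq,
                    kind=PeptideKind.STITCHED,
                    source_protein_ids=g.protein_ids,
                )
            )
    stats = library_stats(peptides, proteins)
    return peptides, stats, groups


def tile_library(
    proteins: Sequence[ProteinRecord], tile_len: int = 56, overlap: int = 28
) -> tuple[list[PeptideRecord], LibraryStats]:
    """Tile every protein and collect stats."""
    peptides = [t for p in proteins for t in pepsyn_tile(p, tile_len, overlap)]
    return peptides, library_stats(peptides, proteins)
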