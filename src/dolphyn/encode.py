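"""Reverse translation and synthesis-ready oligonucleotide assembly.

Library peptides become 200-nt oligos laid out as

    prefix (16 nt) | 168-nt insert | suffix (16 nt)

where the insert is the reverse-translated peptide plus a stop codon
(stitched 55-mers: 165 + 3 nt) or, for single 15-mers, 5'-padding of random
sequence and three stop codons ahead of the 45-nt coding region so all
sub-libraries share one oligo length. Codons are drawn at random from an
E. coli usage table after discarding codons below a usage threshold
(default 0.1) and renormalizing. EcoRI (GAATTC) and HindIII (AAGCTT) sites —
used to clone inserts into the display vector — are eliminated everywhere
except the designed adapter context, by synonymous codon swaps in coding
sequence and local resampling in random filler.

A variable-length dialect pads short coding inserts 3' with a fixed
glycine/serine-linker-derived sequence up to a target insert length
(120 nt default) instead of random 5' filler.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .core_io import PeptideKind, PeptideRecord, ValidationError

# Approximate E. coli K-12 codon usage (fraction within each amino acid).
# Shipped as the package default; any usage table of the same shape may be
# substituted. Stop codons are keyed '*'.
ECOLI_K12_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGT": 0.38, "CGC": 0.40, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAT": 0.45, "AAC": 0.55},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGT": 0.45, "TGC": 0.55},
    "Q": {"CAA": 0.35, "CAG": 0.65},
    "E": {"GAA": 0.69, "GAG": 0.31},
    "G": {"GGT": 0.34, "GGC": 0.40, "GGA": 0.11, "GGG": 0.15},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.77, "AAG": 0.23},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.12},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15, "AGT": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15},
    "*": {"TAA": 0.61, "TGA": 0.30, "TAG": 0.09},
}

DEFAULT_PREFIX = "AGGAATTCCGCTGCGT"
DEFAULT_SUFFIX = "ATGGTCACAGCTGTGC"
VARIABLE_SUFFIX = "GTCGTGACTGGGAAAC"
#: Fixed 3' padding used by the variable-length dialect (encodes GS linkers).
VARIABLE_PAD = (
    "GCAAGTCCTGCAGCTCCAGCCCCTGCAAGCCCAGCAGCTCCAGCACCAAGTGCACCTGCTGGCGGAGGAGG"
    "TTCTGGCGGGGGCGGGAGC"
)
RESTRICTION_SITES: tuple[str, ...] = ("GAATTC", "AAGCTT")  # EcoRI, HindIII

DEFAULT_INSERT_LEN = 168

_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


def translate(nt: str) -> str:
    """Translate an in-frame DNA string (stops rendered as '*')."""
    if len(nt) % 3:
        raise ValidationError(f"length {len(nt)} is not a multiple of 3")
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))


class CodonTableError(ValidationError):
    pass


@dataclass(frozen=True)
class CodonTable:
    """Usage-weighted codon sampler after threshold filtering.

    Codons with usage below ``threshold`` are discarded and the remaining
    frequencies renormalized; every amino acid (and stop, keyed ``*``) must
    retain at least one codon.
    """

    codons: dict[str, tuple[str, ...]]
    probs: dict[str, tuple[float, ...]]
    threshold: float

    @classmethod
    def from_usage(
        cls,
        usage: dict[str, dict[str, float]] | None = None,
        threshold: float = 0.1,
    ) -> "CodonTable":
        usage = usage if usage is not None else ECOLI_K12_USAGE
        codons: dict[str, tuple[str, ...]] = {}
        probs: dict[str, tuple[float, ...]] = {}
        for aa, table in usage.items():
            kept = sorted(
                ((c, f) for c, f in table.items() if f >= threshold),
                key=lambda t: (-t[1], t[0]),
            )
            if not kept:
                raise CodonTableError(
                    f"amino acid {aa!r} has no codon with usage >= {threshold}"
                )
            total = sum(f for _, f in kept)
            codons[aa] = tuple(c for c, _ in kept)
            probs[aa] = tuple(f / total for _, f in kept)
        return cls(codons=codons, probs=probs, threshold=threshold)

    def sample(self, aa: str, rng: np.random.Generator) -> str:
        try:
            options = self.codons[aa]
        except KeyError:
            raise CodonTableError(f"no codons for residue {aa!r}") from None
        if len(options) == 1:
            return options[0]
        return options[int(rng.choice(len(options), p=self.probs[aa]))]

    def synonyms(self, aa: str) -> tuple[str, ...]:
        """Allowed codons for ``aa``, ordered by descending usage."""
        try:
            return self.codons[aa]
        except KeyError:
            raise CodonTableError(f"no codons for residue {aa!r}") from None


def default_codon_table(threshold: float = 0.1) -> CodonTable:
    return CodonTable.from_usage(ECOLI_K12_USAGE, threshold)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def revtrans(peptide: str, table: CodonTable, seed=0) -> str:
    """Reverse-translate a peptide by sampling usage-weighted codons.

    Deterministic under a fixed seed; translating the result recovers the
    input exactly, and codons below the table's usage threshold never occur.
    """
    rng = _as_rng(seed)
    return "".join(table.sample(aa, rng) for aa in peptide)


@dataclass(frozen=True)
class Region:
    """A named half-open interval of an oligo's full sequence."""

    name: str  # prefix | filler | stops | coding | stop | suffix
    start: int
    end: int


#: Region names counted as the (coding) insert vs. non-coding padding.
_INSERT_NAMES = frozenset({"coding", "stop"})
_PADDING_NAMES = frozenset({"filler", "stops"})
_CODING_NAMES = frozenset({"coding", "stop", "stops"})


@dataclass
class OligoRecord:
    """A synthesis-ready oligo with region annotations over ``full_nt``."""

    peptide_id: str
    full_nt: str
    regions: tuple[Region, ...]

    def _concat(self, names: frozenset[str]) -> str:
        return "".join(self.full_nt[r.start : r.end] for r in self.regions if r.name in names)

    @property
    def prefix(self) -> str:
        return self._concat(frozenset({"prefix"}))

    @property
    def suffix(self) -> str:
        return self._concat(frozenset({"suffix"}))

    @property
    def insert_nt(self) -> str:
        return self._concat(_INSERT_NAMES)

    @property
    def padding_nt(self) -> str:
        return self._concat(_PADDING_NAMES)

    @property
    def coding_nt(self) -> str:
        return self._concat(frozenset({"coding"}))

    def translated(self) -> str:
        """Amino-acid translation of the coding region(s)."""
        return translate(self.coding_nt)


def _build(peptide_id: str, parts: Sequence[tuple[str, str]]) -> OligoRecord:
    regions = []
    pos = 0
    for name, seq in parts:
        regions.append(Region(name, pos, pos + len(seq)))
        pos += len(seq)
    return OligoRecord(peptide_id, "".join(seq for _, seq in parts), tuple(regions))


def encode_stitched(
    peptide_id: str,
    seq: str,
    table: CodonTable,
    seed=0,
    prefix: str = DEFAULT_PREFIX,
    suffix: str = DEFAULT_SUFFIX,
) -> OligoRecord:
    """Encode a 55-aa stitched peptide: 165 nt coding + stop = 168-nt insert."""
    if len(seq) != 55:
        raise ValidationError(f"stitched peptide must be 55 aa, got {len(seq)}")
    rng = _as_rng(seed)
    coding = revtrans(seq, table, rng)
    stop = table.sample("*", rng)
    return _build(peptide_id, [("prefix", prefix), ("coding", coding),
                               ("stop", stop), ("suffix", suffix)])


def pad_epitope15(
    peptide_id: str,
    seq: str,
    table: CodonTable,
    seed=0,
    prefix: str = DEFAULT_PREFIX,
    suffix: str = DEFAULT_SUFFIX,
    insert_len: int = DEFAULT_INSERT_LEN,
) -> OligoRecord:
    """Encode a single 15-mer with 5' padding up to the common insert length.

    Layout: random filler (114 nt) | three stop codons | 45-nt coding region,
    so the insert matches the 168 nt of the stitched and tiled sub-libraries.
    """
    if len(seq) != 15:
        raise ValidationError(f"epitope peptide must be 15 aa, got {len(seq)}")
    rng = _as_rng(seed)
    coding = revtrans(seq, table, rng)
    stops = "".join(table.sample("*", rng) for _ in range(3))
    filler_len = insert_len - len(coding) - len(stops)
    if filler_len < 0:
        raise ValidationError(f"insert_len {insert_len} too short for a 15-mer insert")
    filler = "".join("ACGT"[i] for i in rng.integers(0, 4, filler_len))
    return _build(peptide_id, [("prefix", prefix), ("filler", filler),
                               ("stops", stops), ("coding", coding), ("suffix", suffix)])


def encode_tile(
    peptide_id: str,
    seq: str,
    table: CodonTable,
    seed=0,
    prefix: str = DEFAULT_PREFIX,
    suffix: str = DEFAULT_SUFFIX,
    tile_len: int = 56,
) -> OligoRecord:
    """Encode a 56-aa tile; the insert is 168 nt of coding sequence (no stop)."""
    if len(seq) != tile_len:
        raise ValidationError(f"tile must be {tile_len} aa, got {len(seq)}")
    coding = revtrans(seq, table, _as_rng(seed))
    return _build(peptide_id, [("prefix", prefix), ("coding", coding), ("suffix", suffix)])


def encode_variable(
    peptide_id: str,
    seq: str,
    table: CodonTable,
    seed=0,
    prefix: str = DEFAULT_PREFIX,
    suffix: str = VARIABLE_SUFFIX,
    target_insert_len: int = 120,
    pad_seq: str = VARIABLE_PAD,
) -> OligoRecord:
    """Variable-length dialect: coding + stop, 3'-padded with a fixed linker sequence."""
    rng = _as_rng(seed)
    coding = revtrans(seq, table, rng)
    stop = table.sample("*", rng)
    pad_len = target_insert_len - len(coding) - len(stop)
    if pad_len < 0:
        raise ValidationError(
            f"peptide {peptide_id!r} too long for target insert {target_insert_len} nt"
        )
    if pad_len > len(pad_seq):
        raise ValidationError("padding sequence shorter than required pad length")
    return _build(peptide_id, [("prefix", prefix), ("coding", coding), ("stop", stop),
                               ("filler", pad_seq[:pad_len]), ("suffix", suffix)])


class RecodingError(ValidationError):
    pass


def _find_violation(
    seq: str, regions: tuple[Region, ...], sites: Sequence[str]
) -> tuple[int, str] | None:
    allowed = [(r.start, r.end) for r in regions if r.name in ("prefix", "suffix")]
    for site in sites:
        start = 0
        while True:
            pos = seq.find(site, start)
            if pos < 0:
                break
            span = (pos, pos + len(site))
            if not any(a <= span[0] and span[1] <= b for a, b in allowed):
                return pos, site
            start = pos + 1
    return None


def recode_sites(
    oligo: OligoRecord,
    table: CodonTable,
    sites: Sequence[str] = RESTRICTION_SITES,
    seed=0,
    max_passes: int = 100,
) -> OligoRecord:
    """Remove restriction sites outside the designed adapter context.

    Sites overlapping coding sequence (including stop codons) are removed by
    synonymous codon swaps, tried in descending-usage order, so the peptide
    translation never changes; sites inside random filler are resampled
    locally. Iterates until clean (swaps can create new sites) up to
    ``max_passes``; an unavoidable site raises :class:`RecodingError` naming
    the position.
    """
    rng = _as_rng(seed)
    seq = list(oligo.full_nt)
    coding_regions = [r for r in oligo.regions if r.name in _CODING_NAMES]
    filler_regions = [r for r in oligo.regions if r.name == "filler"]
    for _ in range(max_passes):
        violation = _find_violation("".join(seq), oligo.regions, sites)
        if violation is None:
            return OligoRecord(oligo.peptide_id, "".join(seq), oligo.regions)
        pos, site = violation
        span = (pos, pos + len(site))
        if _fix_by_codon_swap(seq, span, coding_regions, table, site):
            continue
        if _fix_by_filler_resample(seq, span, filler_regions, rng):
            continue
        raise RecodingError(
            f"oligo {oligo.peptide_id!r}: cannot remove site {site} at position {pos}"
        )
    raise RecodingError(
        f"oligo {oligo.peptide_id!r}: still contains forbidden sites after "
        f"{max_passes} passes"
    )


def _fix_by_codon_swap(
    seq: list[str], span: tuple[int, int], coding_regions: list[Region],
    table: CodonTable, site: str,
) -> bool:
    for r in coding_regions:
        if span[1] <= r.start or span[0] >= r.end:
            continue
        first = max(0, (max(span[0], r.start) - r.start) // 3)
        last = (min(span[1], r.end) - 1 - r.start) // 3
        for ci in range(first, last + 1):
            cs = r.start + 3 * ci
            current = "".join(seq[cs : cs + 3])
            aa = CODON_TO_AA[current]
            for alt in table.synonyms(aa):
                if alt == current:
                    continue
                seq[cs : cs + 3] = list(alt)
                window = "".join(seq[max(0, span[0] - 5) : span[1] + 5])
                if site not in window:
                    return True
                seq[cs : cs + 3] = list(current)
    return False


def _fix_by_filler_resample(
    seq: list[str], span: tuple[int, int], filler_regions: list[Region],
    rng: np.random.Generator,
) -> bool:
    touched = False
    for r in filler_regions:
        lo, hi = max(span[0], r.start), min(span[1], r.end)
        for i in range(lo, hi):
            seq[i] = "ACGT"[int(rng.integers(0, 4))]
            touched = True
    return touched


def encode_library(
    peptides: Iterable[PeptideRecord],
    table: CodonTable | None = None,
    seed: int = 0,
    prefix: str = DEFAULT_PREFIX,
    suffix: str = DEFAULT_SUFFIX,
    sites: Sequence[str] = RESTRICTION_SITES,
    recode: bool = True,
) -> list[OligoRecord]:
    """Encode a mixed library; one master seed drives every peptide's draws."""
    table = table or default_codon_table()
    rng = np.random.default_rng(seed)
    out = []
    for p in peptides:
        if p.kind is PeptideKind.STITCHED:
            oligo = encode_stitched(p.id, p.seq, table, rng, prefix, suffix)
        elif p.kind is PeptideKind.EPITOPE15:
            oligo = pad_epitope15(p.id, p.seq, table, rng, prefix, suffix)
        elif len(p.seq) == 56:
            oligo = encode_tile(p.id, p.seq, table, rng, prefix, suffix)
        else:
            raise ValidationError(
                f"peptide {p.id!r} (kind={p.kind.value}, length {len(p.seq)}) has no "
                "fixed-length oligo layout; use encode_variable"
            )
        if recode:
            oligo = recode_sites(oligo, table, sites, rng)
        out.append(oligo)
    return out


def write_oligos(oligos: Sequence[OligoRecord], path, fasta_path=None) -> None:
    """Oligo TSV: id, insert_nt, full_nt, and region annotations."""
    import pandas as pd

    rows = [
        {
            "id": o.peptide_id,
            "insert_nt": o.insert_nt,
            "full_nt": o.full_nt,
            "regions": ";".join(f"{r.name}:{r.start}-{r.end}" for r in o.regions),
        }
        for o in oligos
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for o in oligos:
                fh.write(f">{o.peptide_id}\n{o.full_nt}\n")
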