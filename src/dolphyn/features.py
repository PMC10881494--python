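"""Composition features for short peptides.

A peptide of length L is described by 556 raw counts:

* 20  single amino-acid counts (alphabetical by one-letter code),
* 400 contiguous ordered amino-acid digram counts (row-major, positions i,i+1),
* 11  counts over the DIAMOND reduced alphabet, an 11-group partition of the
  20 amino acids used for seed compression in homology search,
* 121 contiguous ordered DIAMOND-group digram counts,
* 4   side-chain class counts (positive / negative / polar-uncharged / nonpolar).

For a 15-mer the unigram blocks each sum to 15 and the digram blocks to 14;
values are raw counts rather than length-normalised frequencies (equivalent at
fixed length, and exact integers).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

from .core_io import AA_ALPHABET, ValidationError

#: DIAMOND 11-group reduced amino-acid alphabet.
DIAMOND_GROUPS: tuple[str, ...] = (
    "KREDQN", "STA", "ILV", "C", "G", "H", "M", "F", "Y", "W", "P",
)

#: Side-chain classes (name, members). Histidine is counted as positively
#: charged; cysteine and tyrosine as polar-uncharged; glycine as nonpolar.
SIDECHAIN_CLASSES: tuple[tuple[str, str], ...] = (
    ("positive", "KRH"),
    ("negative", "DE"),
    ("polar", "STNQYC"),
    ("nonpolar", "AVLIPFMWG"),
)


def _check_partition(groups: tuple[str, ...], alphabet: str, what: str) -> None:
    joined = "".join(groups)
    if sorted(joined) != sorted(alphabet):
        raise ValidationError(f"{what} is not a partition of the alphabet")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed, ordered definition of the 556-dimensional feature space."""

    aa_alphabet: str = AA_ALPHABET
    diamond_groups: tuple[str, ...] = DIAMOND_GROUPS
    sidechain_classes: tuple[tuple[str, str], ...] = SIDECHAIN_CLASSES

    def __post_init__(self) -> None:
        _check_partition(self.diamond_groups, self.aa_alphabet, "diamond_groups")
        _check_partition(tuple(m for _, m in self.sidechain_classes),
                         self.aa_alphabet, "sidechain_classes")
        if len(self.diamond_groups) != 11:
            raise ValidationError("expected 11 DIAMOND groups")
        if len(self.sidechain_classes) != 4:
            raise ValidationError("expected 4 side-chain classes")

    @property
    def n_aa(self) -> int:
        return len(self.aa_alphabet)

    @property
    def n_groups(self) -> int:
        return len(self.diamond_groups)

    @property
    def n_classes(self) -> int:
        return len(self.sidechain_classes)

    @property
    def n_features(self) -> int:
        return (self.n_aa + self.n_aa ** 2 + self.n_groups
                + self.n_groups ** 2 + self.n_classes)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return _feature_names(self)

    def to_yaml(self, path) -> None:
        doc = {
            "aa_alphabet": self.aa_alphabet,
            "diamond_groups": list(self.diamond_groups),
            "sidechain_classes": [list(pair) for pair in self.sidechain_classes],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            aa_alphabet=doc["aa_alphabet"],
            diamond_groups=tuple(doc["diamond_groups"]),
            sidechain_classes=tuple((n, m) for n, m in doc["sidechain_classes"]),
        )


def default_schema() -> FeatureSchema:
    """The package's fixed default schema (20+400+11+121+4 = 556 features)."""
    return FeatureSchema()


@lru_cache(maxsize=8)
def _feature_names(schema: FeatureSchema) -> tuple[str, ...]:
    aa = schema.aa_alphabet
    names: list[str] = [f"aa_{a}" for a in aa]
    names += [f"pair_{a}{b}" for a in aa for b in aa]
    names += [f"dia_{g}" for g in schema.diamond_groups]
    names += [f"diapair_{g}_{h}" for g in schema.diamond_groups for h in schema.diamond_groups]
    names += [f"sc_{n}" for n, _ in schema.sidechain_classes]
    return tuple(names)


@lru_cache(maxsize=8)
def _lookup_tables(schema: FeatureSchema) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Byte-value lookup tables: aa index, DIAMOND group index, side-chain index."""
    aa_idx = np.full(256, -1, dtype=np.int64)
    for i, a in enumerate(schema.aa_alphabet):
        aa_idx[ord(a)] = i
    group_of = np.full(schema.n_aa, -1, dtype=np.int64)
    for gi, members in enumerate(schema.diamond_groups):
        for a in members:
            group_of[aa_idx[ord(a)]] = gi
    class_of = np.full(schema.n_aa, -1, dtype=np.int64)
    for ci, (_, members) in enumerate(schema.sidechain_classes):
        for a in members:
            class_of[aa_idx[ord(a)]] = ci
    return aa_idx, group_of, class_of


def _encode(seq: str, schema: FeatureSchema) -> np.ndarray:
    aa_idx, _, _ = _lookup_tables(schema)
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = aa_idx[raw]
    if (idx < 0).any():
        pos = int(np.argmax(idx < 0))
        raise ValidationError(
            f"non-canonical residue {seq[pos]!r} at position {pos} in {seq!r}"
        )
    return idx


def extract_features(seq: str, schema: FeatureSchema | None = None) -> np.ndarray:
    """Compute the 556-vector of raw composition counts for one peptide.

    Pure and deterministic; requires length >= 2 and a fully canonical
    sequence. Unigram blocks sum to ``len(seq)``, digram blocks to
    ``len(seq) - 1``.
    """
    schema = schema or default_schema()
    if len(seq) < 2:
        raise ValidationError("peptide must have length >= 2 for digram features")
    idx = _encode(seq, schema)
    _, group_of, class_of = _lookup_tables(schema)
    n_aa, n_g = schema.n_aa, schema.n_groups
    uni = np.bincount(idx, minlength=n_aa)
    pairs = np.bincount(idx[:-1] * n_aa + idx[1:], minlength=n_aa * n_aa)
    g = group_of[idx]
    g_uni = np.bincount(g, minlength=n_g)
    g_pairs = np.bincount(g[:-1] * n_g + g[1:], minlength=n_g * n_g)
    sc = np.bincount(class_of[idx], minlength=schema.n_classes)
    return np.concatenate([uni, pairs, g_uni, g_pairs, sc]).astype(np.float64)


def feature_matrix(seqs, schema: FeatureSchema | None = None) -> np.ndarray:
    """Stack :func:`extract_features` over many peptides into an (n, 556) array."""
    schema = schema or default_schema()
    return np.vstack([extract_features(s, schema) for s in seqs])


def feature_frame(seqs, schema: FeatureSchema | None = None):
    """Feature matrix as a DataFrame with named columns (CSV-exportable)."""
    import pandas as pd

    schema = schema or default_schema()
    return pd.DataFrame(feature_matrix(seqs, schema), index=list(seqs),
                        columns=list(schema.feature_names))
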