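"""Seeded synthetic-data generators for end-to-end testing without downloads.

Every generator is a pure function of a :class:`FixtureSpec` (seed included).
Synthetic "epitopes" follow a composition rule rather than any biological
model: a 15-mer is epitope-like when its count of positively charged residues
(K/R/H) falls in a configurable band, 5-8 by default — the band where real
public epitopes are enriched — so classifier tests are interpretable: the
positive-side-chain count feature is the ground-truth decision variable.
Background sequence is uniform over the 20 amino acids, which makes the
motif rare outside planted sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AA_ALPHABET, ProteinRecord, ReactivityTable, ValidationError

POSITIVE_RESIDUES = "KRH"
_NONPOSITIVE = "".join(a for a in AA_ALPHABET if a not in POSITIVE_RESIDUES)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study: sizes, motif band, spike-ins, noise."""

    seed: int = 0
    # proteome
    n_proteins: int = 30
    min_length: int = 90
    max_length: int = 250
    epitopes_per_protein: int = 3
    # training scan
    n_wildtypes: int = 60
    wildtype_length: int = 56
    n_samples: int = 8
    n_bead_samples: int = 2
    # phage reactivity
    n_phages: int = 12
    peptides_per_phage: int = 30
    n_background_peptides: int = 300
    spike_phages: tuple[str, ...] = ()
    spike_shift: float = 2.0
    background_sd: float = 1.0
    # motif band: positive-side-chain count of an epitope-like 15-mer
    motif_range: tuple[int, int] = (5, 8)


def motif_true(seq: str, motif_range: tuple[int, int] = (5, 8)) -> bool:
    """Does this 15-mer satisfy the synthetic epitope rule?"""
    n = sum(seq.count(a) for a in POSITIVE_RESIDUES)
    return motif_range[0] <= n <= motif_range[1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), n))


def _motif_15mer(rng: np.random.Generator, motif_range: tuple[int, int]) -> str:
    n_pos = int(rng.integers(motif_range[0], motif_range[1] + 1))
    positions = rng.choice(15, size=n_pos, replace=False)
    letters = [
        _NONPOSITIVE[i] for i in rng.integers(0, len(_NONPOSITIVE), 15)
    ]
    for p in positions:
        letters[p] = POSITIVE_RESIDUES[int(rng.integers(0, 3))]
    return "".join(letters)


def make_proteome(spec: FixtureSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteins with motif 15-mers planted at known disjoint positions.

    Returns the proteins and a truth table (protein_id, start, end) of the
    planted windows.
    """
    rng = np.random.default_rng(spec.seed)
    proteins, truth = [], []
    for i in range(spec.n_proteins):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        letters = list(_random_seq(rng, L))
        starts: list[int] = []
        candidates = rng.permutation(L - 15 + 1)
        for s in candidates:
            if all(abs(int(s) - t) >= 15 for t in starts):
                starts.append(int(s))
            if len(starts) == spec.epitopes_per_protein:
                break
        if len(starts) < spec.epitopes_per_protein:
            raise ValidationError(
                f"cannot fit {spec.epitopes_per_protein} disjoint epitopes "
                f"in a {L}-aa protein"
            )
        pid = f"prot{i:04d}"
        for s in sorted(starts):
            letters[s : s + 15] = _motif_15mer(rng, spec.motif_range)
            truth.append({"protein_id": pid, "start": s, "end": s + 15})
        proteins.append(ProteinRecord(id=pid, seq="".join(letters)))
    return proteins, pd.DataFrame(truth, columns=["protein_id", "start", "end"])


@dataclass
class TrainingFixture:
    table: ReactivityTable
    wildtype_map: dict[str, str]
    bead_sample_ids: list[str]
    labels: dict[str, int] = field(default_factory=dict)


def make_training_table(spec: FixtureSpec) -> TrainingFixture:
    """A scan-shaped reactivity table whose labels follow the planted motif.

    Each synthetic wildtype (56 aa) carries one planted motif 15-mer; the
    wildtype's 15-mer windows (step 5, as in a k-mer scan) are the training
    peptides, keyed by their sequence. Motif-true windows receive a positive
    log hit-fold-change in at least two serum samples; all other windows are
    silent everywhere, with seeded mock-IP (bead) counts providing the
    negative-ranking signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    serum = [f"S{j:03d}" for j in range(spec.n_samples)]
    beads = [f"BEADS{j}" for j in range(spec.n_bead_samples)]
    samples = serum + beads

    peptide_ids: list[str] = []
    wildtype_map: dict[str, str] = {}
    labels: dict[str, int] = {}
    rows_hfc, rows_counts = [], []
    for w in range(spec.n_wildtypes):
        wt_id = f"wt{w:04d}"
        letters = list(_random_seq(rng, spec.wildtype_length))
        plant = int(rng.integers(0, spec.wildtype_length - 15 + 1))
        letters[plant : plant + 15] = _motif_15mer(rng, spec.motif_range)
        wt_seq = "".join(letters)
        for s in range(0, spec.wildtype_length - 15 + 1, 5):
            pep = wt_seq[s : s + 15]
            if pep in wildtype_map:
                continue  # sequence collision across wildtypes: keep first
            wildtype_map[pep] = wt_id
            label = int(motif_true(pep, spec.motif_range))
            labels[pep] = label
            hfc = np.zeros(len(samples))
            if label:
                n_react = int(rng.integers(2, spec.n_samples + 1))
                cols = rng.choice(spec.n_samples, size=n_react, replace=False)
                hfc[cols] = rng.uniform(1.0, 5.0, n_react)
            counts = np.concatenate(
                [rng.poisson(5, spec.n_samples), rng.poisson(40, spec.n_bead_samples)]
            )
            peptide_ids.append(pep)
            rows_hfc.append(hfc)
            rows_counts.append(counts)

    table = ReactivityTable(
        peptide_ids=peptide_ids,
        sample_ids=samples,
        counts=np.vstack(rows_counts).astype(float),
        log_hfc=np.vstack(rows_hfc),
    )
    return TrainingFixture(table, wildtype_map, beads, labels)


@dataclass
class PhageFixture:
    table: ReactivityTable
    log2fc: pd.DataFrame
    peptide_to_phages: dict[str, tuple[str, ...]]
    intended_hits: np.ndarray
    spike_phages: tuple[str, ...]


def make_phage_reactivity(spec: FixtureSpec) -> PhageFixture:
    """Counts / fold changes / p-values for a phage sublibrary screen.

    Background log2 fold changes are N(0, background_sd); spike-in phages are
    shifted by ``spike_shift`` in every sample. Counts and p-values are
    generated so that exactly the cells with fold change > 5 satisfy the hit
    criteria, making the generator's intended hit mask recoverable by
    :func:`dolphyn.reactivity.call_hits`. Besides the phage-assigned
    peptides, ``n_background_peptides`` belong to no scored phage — as in a
    real sublibrary, where many peptides map only to phages below the
    25-peptide scoring floor — so the resampling pool is wider than the
    scored sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    phages = [f"phage{j:03d}" for j in range(spec.n_phages)]
    unknown = set(spec.spike_phages) - set(phages)
    if unknown:
        raise ValidationError(f"spike phages not in fixture: {sorted(unknown)}")
    samples = [f"S{j:03d}" for j in range(spec.n_samples)]
    peptide_ids, pep_to_phage = [], {}
    for ph in phages:
        for j in range(spec.peptides_per_phage):
            pid = f"{ph}_pep{j:03d}"
            peptide_ids.append(pid)
            pep_to_phage[pid] = (ph,)
    for j in range(spec.n_background_peptides):
        peptide_ids.append(f"bg_pep{j:04d}")

    n = len(peptide_ids)
    log2fc = rng.normal(0.0, spec.background_sd, (n, spec.n_samples))
    for ph in spec.spike_phages:
        rows = [i for i, p in enumerate(peptide_ids) if pep_to_phage.get(p, (None,))[0] == ph]
        log2fc[rows, :] += spec.spike_shift
    foldchange = np.power(2.0, log2fc)
    intended = foldchange > 5.0
    counts = np.where(
        intended,
        rng.integers(50, 500, (n, spec.n_samples)),
        rng.integers(0, 15, (n, spec.n_samples)),
    ).astype(float)
    pvalue = np.where(intended, 1e-5, rng.uniform(0.01, 1.0, (n, spec.n_samples)))

    table = ReactivityTable(
        peptide_ids=peptide_ids,
        sample_ids=samples,
        counts=counts,
        foldchange=foldchange,
        pvalue=pvalue,
        peptide_to_phages=pep_to_phage,
    )
    frame = pd.DataFrame(log2fc, index=peptide_ids, columns=samples)
    return PhageFixture(table, frame, pep_to_phage, intended, tuple(spec.spike_phages))


def make_labeled_peptides(
    n_per_class: int,
    seed: int = 0,
    motif_range: tuple[int, int] = (5, 8),
    n_wildtypes: int = 40,
) -> "list":
    """Directly generate a balanced, separable labeled set (no reactivity table).

    Positives satisfy the motif band; negatives have a positive-residue count
    outside it. Wildtype ids are assigned round-robin so wildtype-disjoint
    splitting stays exercised.
    """
    from .classifier import LabeledPeptide

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = []
    low, high = motif_range
    outside = [k for k in range(0, 13) if not (low <= k <= high)]
    for i in range(n_per_class):
        wt = f"wt{i % n_wildtypes:04d}"
        out.append(LabeledPeptide(_motif_15mer(rng, motif_range), wt, 1))
        n_pos = int(rng.choice(outside))
        letters = [_NONPOSITIVE[j] for j in rng.integers(0, len(_NONPOSITIVE), 15)]
        for p in rng.choice(15, size=n_pos, replace=False):
            letters[p] = POSITIVE_RESIDUES[int(rng.integers(0, 3))]
        out.append(LabeledPeptide("".join(letters), wt, 0))
    return out
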