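"""Downstream PhIP-Seq scoring: hits, reactive ratios, PhARscore, discovery power.

Hit calling applies three strict thresholds to each peptide x sample cell
(sequencing count > 15, fold change over mock-IP > 5, p < 0.001); qualifying
cells carry log2(fold change) as the log hit-fold-change, all others 0.

The phage aggregate reactivity score (PhARscore) summarizes a sample's
reactivity to one phage: the mean log2 fold change of the phage's peptides is
compared with a null distribution of means of equally many peptides drawn at
random (without replacement within a draw) from the same sublibrary's
peptide pool, and the excess over the resampled null expectation is
expressed in units of the pool's peptide-level standard deviation, so an
exchangeable phage scores near 0 and the score > 1 reactivity cutoff demands
a full pool-SD of aggregate enrichment. Scoring is iterated: after each
round the peptides of strongly reactive phages (score > 1) leave the null
pool, so a handful of dominant phages cannot inflate the null; iteration
stops when no new phage crosses the threshold or after seven rounds. Only
phages represented by at least 25 peptides are scored.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError


@dataclass(frozen=True)
class HitCriteria:
    """Strict thresholds for significant reactivity (all exclusive bounds)."""

    min_count: float = 15.0
    min_fc: float = 5.0
    max_p: float = 0.001


def call_hits(
    counts: np.ndarray,
    foldchange: np.ndarray,
    pvalue: np.ndarray,
    criteria: HitCriteria = HitCriteria(),
) -> np.ndarray:
    """log2 hit-fold-change matrix: log2(fc) where all three criteria hold, else 0."""
    counts = np.asarray(counts, dtype=float)
    foldchange = np.asarray(foldchange, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    if not (counts.shape == foldchange.shape == pvalue.shape):
        raise ValidationError("counts/foldchange/pvalue shapes differ")
    if (counts < 0).any():
        raise ValidationError("negative counts")
    if (foldchange < 0).any():
        raise ValidationError("negative fold changes")
    if ((pvalue < 0) | (pvalue > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    hit = (counts > criteria.min_count) & (foldchange > criteria.min_fc) & (
        pvalue < criteria.max_p
    )
    out = np.zeros_like(foldchange)
    out[hit] = np.log2(foldchange[hit])
    return out


def reactive_ratio(
    log_hfc: np.ndarray,
    scope: str = "any_sample",
    min_fraction: float = 0.01,
) -> float:
    """Fraction of peptides that are reactive.

    ``any_sample``: reactive means log_hfc > 0 in at least one sample.
    ``fraction_of_samples``: reactive in at least ``min_fraction`` of samples.
    """
    m = np.asarray(log_hfc)
    if m.size == 0:
        raise ValidationError("empty matrix")
    positive = m > 0
    if scope == "any_sample":
        return float(positive.any(axis=1).mean())
    if scope == "fraction_of_samples":
        return float((positive.mean(axis=1) >= min_fraction).mean())
    raise ValidationError(f"unknown scope {scope!r}")


@dataclass
class PhARscoreResult:
    sample_id: str
    phage_id: str
    score: float
    n_peptides: int
    iteration: int
    binarized: int


def _null_means(
    pool_values: np.ndarray,
    k: int,
    n_draws: int,
    rng: np.random.Generator,
    block: int = 2000,
) -> np.ndarray:
    """Means of ``n_draws`` random size-k subsets (no replacement within a draw)."""
    m = len(pool_values)
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        b = min(block, n_draws - done)
        u = rng.random((b, m))
        sel = np.argpartition(u, k - 1, axis=1)[:, :k]
        out[done : done + b] = pool_values[sel].mean(axis=1)
        done += b
    return out


def pharscore(
    log2fc: pd.DataFrame,
    peptide_to_phages: Mapping[str, Sequence[str]],
    n_draws: int = 10000,
    seed: int = 0,
    score_cutoff: float = 1.0,
    max_iter: int = 7,
    min_peptides: int = 25,
) -> pd.DataFrame:
    """Iterative resampled aggregate reactivity score, per sample and phage.

    ``log2fc`` is a peptide x sample DataFrame (index: peptide ids) for one
    sublibrary. The score is (observed mean - resampled null mean) / SD of
    the null pool's peptide values, so exchangeable phages score ~0 and
    ``score > cutoff`` requires the phage's peptides to average a full
    pool-SD above the null expectation. Returns a DataFrame with columns
    sample_id, phage_id, score, n_peptides, iteration, binarized; phages
    with fewer than ``min_peptides`` peptides are absent. A phage's own
    peptides never enter its null draws. Deterministic under ``seed`` and
    invariant to the peptide row order (the null pool is sorted by peptide
    id).
    """
    if not isinstance(log2fc, pd.DataFrame):
        raise ValidationError("log2fc must be a peptide x sample DataFrame")
    present = set(map(str, log2fc.index))
    phage_peps: dict[str, list[str]] = {}
    for pep, phages in peptide_to_phages.items():
        if str(pep) not in present:
            continue
        for ph in phages:
            phage_peps.setdefault(str(ph), []).append(str(pep))
    eligible = {
        ph: sorted(set(peps))
        for ph, peps in phage_peps.items()
        if len(set(peps)) >= min_peptides
    }
    pool_ids = sorted(present)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(log2fc.columns))

    rows: list[PhARscoreResult] = []
    for col_i, sample in enumerate(log2fc.columns):
        values = {str(i): float(v) for i, v in log2fc[sample].items()}
        rng = np.random.default_rng(children[col_i])
        flagged: dict[str, tuple[float, int]] = {}
        scores: dict[str, tuple[float, int]] = {}
        removed: set[str] = set()
        for iteration in range(1, max_iter + 1):
            new_flags = []
            for ph in sorted(eligible):
                if ph in flagged:
                    continue
                own = set(eligible[ph])
                null_ids = [p for p in pool_ids if p not in removed and p not in own]
                k = len(own)
                if not null_ids:
                    raise ValidationError(f"empty null pool for phage {ph!r}")
                if len(null_ids) < k:
                    raise ValidationError(
                        f"null pool ({len(null_ids)}) smaller than phage "
                        f"{ph!r} peptide set ({k})"
                    )
                obs = float(np.mean([values[p] for p in eligible[ph]]))
                pool_values = np.array([values[p] for p in null_ids])
                null = _null_means(pool_values, k, n_draws, rng)
                sd = float(pool_values.std())
                if sd == 0.0:
                    warnings.warn(f"phage {ph!r}, sample {sample!r}: degenerate null")
                    score = 0.0
                else:
                    score = (obs - float(null.mean())) / sd
                scores[ph] = (score, iteration)
                if score > score_cutoff:
                    new_flags.append(ph)
            for ph in new_flags:
                flagged[ph] = scores[ph]
                removed.update(eligible[ph])
            if not new_flags:
                break
        for ph in sorted(eligible):
            score, iteration = scores[ph]
            rows.append(
                PhARscoreResult(
                    sample_id=str(sample),
                    phage_id=ph,
                    score=score,
                    n_peptides=len(eligible[ph]),
                    iteration=iteration,
                    binarized=int(score > score_cutoff),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def protein_hits(
    hit_mask: np.ndarray,
    peptide_ids: Sequence[str],
    peptide_to_proteins: Mapping[str, Sequence[str]],
    protein_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Protein x sample reactivity: a protein is hit if any of its peptides is."""
    hit_mask = np.asarray(hit_mask, dtype=bool)
    if protein_ids is None:
        protein_ids = sorted(
            {p for pep in peptide_ids for p in peptide_to_proteins.get(str(pep), ())}
        )
    out = np.zeros((len(protein_ids), hit_mask.shape[1]), dtype=bool)
    index = {p: i for i, p in enumerate(protein_ids)}
    for row, pep in enumerate(peptide_ids):
        for prot in peptide_to_proteins.get(str(pep), ()):
            if prot in index:
                out[index[prot]] |= hit_mask[row]
    return pd.DataFrame(out, index=list(protein_ids))


def protein_discovery_metrics(
    truth_hits: np.ndarray, test_hits: np.ndarray
) -> dict[str, float]:
    """Confusion-matrix metrics of one design's protein calls against another's.

    Cells are protein x sample booleans; the reference design's calls serve
    as ground truth. Precision/recall are NaN when undefined (no predicted /
    no true positives).
    """
    truth = np.asarray(truth_hits, dtype=bool)
    test = np.asarray(test_hits, dtype=bool)
    if truth.shape != test.shape:
        raise ValidationError("truth/test shapes differ")
    tp = int((truth & test).sum())
    fp = int((~truth & test).sum())
    fn = int((truth & ~test).sum())
    tn = int((~truth & ~test).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "accuracy": (tp + tn) / truth.size if truth.size else float("nan"),
    }
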