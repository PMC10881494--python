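"""Scan-library generators and the epitope-footprint analysis.

Two scan designs localize epitopes within 56-aa immunodominant "wildtype"
peptides:

* the k-mer scan tiles each wildtype with sub-peptides of length 15-45
  (step 5 aa between lengths) starting every 5 amino acids — 42 sub-peptides
  per 56-mer in total;
* the alanine scan replaces successive residue triplets with AAA (wildtype
  alanines become glycine, so every scanned position is always mutated).

The footprint analysis aggregates per-position reactivity-difference curves
(alanine variant minus wildtype) across many wildtypes and samples: curves
with a single contiguous dip are centered on their minimum, averaged, and the
width of the shortest centered interval holding 80% of the aggregate
baseline-subtracted dip mass estimates how many positions an epitope spans.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np

from .core_io import ValidationError

DEFAULT_KS: tuple[int, ...] = (15, 20, 25, 30, 35, 40, 45)


@dataclass
class ScanPeptide:
    """One scan-library member derived from a wildtype peptide."""

    wildtype_id: str
    seq: str
    scan_kind: str  # "kmer" | "alanine"
    start: int
    k: int | None = None


def kmer_scan(
    wildtype_id: str,
    seq: str,
    ks: Sequence[int] = DEFAULT_KS,
    step: int = 5,
) -> list[ScanPeptide]:
    """All k-mer windows of a wildtype, each length at starts 0, step, 2*step, ...

    For a 56-mer with the default lengths this yields 9+8+7+6+5+4+3 = 42
    sub-peptides.
    """
    if len(seq) < max(ks):
        raise ValidationError(
            f"wildtype {wildtype_id!r} (length {len(seq)}) shorter than max k {max(ks)}"
        )
    out = []
    for k in ks:
        for start in range(0, len(seq) - k + 1, step):
            out.append(ScanPeptide(wildtype_id, seq[start : start + k], "kmer", start, k))
    return out


def alanine_scan(
    wildtype_id: str,
    seq: str,
    window: int = 3,
    step: int = 1,
) -> list[ScanPeptide]:
    """Triple-alanine scan variants of a wildtype.

    Within each window every residue becomes alanine, except residues that
    already are alanine, which become glycine; everything outside the window
    is unchanged. One variant per window position.
    """
    if len(seq) < window:
        raise ValidationError(f"wildtype {wildtype_id!r} shorter than scan window")
    out = []
    for start in range(0, len(seq) - window + 1, step):
        sub = "".join("G" if c == "A" else "A" for c in seq[start : start + window])
        variant = seq[:start] + sub + seq[start + window :]
        out.append(ScanPeptide(wildtype_id, variant, "alanine", start, None))
    return out


@dataclass
class FootprintSummary:
    """Aggregate of centered single-dip reactivity-difference curves."""

    mean_curve: np.ndarray
    median_curve: np.ndarray
    center: int
    span80: int
    n_used: int
    n_excluded: int


def _single_dip_center(curve: np.ndarray, smooth: int = 3) -> int | None:
    """Center of a single contiguous dip, or None if no dip / multiple dips.

    The dip position is the minimum of a 3-point moving average (ties: the
    middle of the tied run, so flat-bottomed dips center on their midpoint);
    the curve qualifies as single-dip if the smoothed derivative shows exactly
    one negative-to-positive sign-change pair.
    """
    if len(curve) < smooth + 2:
        return None
    s = np.convolve(curve, np.ones(smooth) / smooth, mode="valid")
    d = np.diff(s)
    signs = [k for k, _ in groupby(np.sign(d)) if k != 0]
    down_up = sum(1 for a, b in zip(signs, signs[1:]) if a < 0 < b)
    if not any(k < 0 for k in signs):
        return None  # never descends: no dip
    if down_up != 1:
        return None  # several dips (or dip at the very edge with another)
    mins = np.flatnonzero(np.isclose(s, s.min()))
    return int(mins[len(mins) // 2]) + (smooth - 1) // 2


def footprint(
    curves: Iterable[Sequence[float]],
    mass_fraction: float = 0.8,
    baseline_positions: int = 10,
) -> FootprintSummary:
    """Center single-dip curves, aggregate, and measure the 80% dip span.

    Curves without a single clean dip are excluded with a warning. The
    aggregate mean curve is baseline-subtracted (baseline = median of the
    outermost ``baseline_positions`` aggregated positions, split between the
    two ends) and ``span80`` is the width in positions of the shortest
    interval containing the center that holds ``mass_fraction`` of the total
    dip mass. The result is invariant to translating all curves.
    """
    curves = [np.asarray(c, dtype=float) for c in curves]
    if not curves:
        raise ValidationError("footprint: empty input")
    aligned: list[tuple[np.ndarray, int]] = []
    excluded = 0
    for c in curves:
        dip = _single_dip_center(c)
        if dip is None:
            excluded += 1
            continue
        aligned.append((c, dip))
    if excluded:
        warnings.warn(f"footprint: excluded {excluded} curve(s) without a single clean dip")
    if not aligned:
        raise ValidationError("footprint: no curve shows a single clean dip")

    max_len = max(len(c) for c, _ in aligned)
    width = 2 * max_len - 1
    center = max_len - 1
    grid = np.full((len(aligned), width), np.nan)
    for row, (c, dip) in enumerate(aligned):
        grid[row, center - dip : center - dip + len(c)] = c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_curve = np.nanmean(grid, axis=0)
        median_curve = np.nanmedian(grid, axis=0)

    valid = np.flatnonzero(~np.isnan(mean_curve))
    half = max(1, baseline_positions // 2)
    outer = np.concatenate([valid[:half], valid[-half:]])
    baseline = float(np.median(mean_curve[outer]))
    mass = np.clip(baseline - mean_curve, 0.0, None)
    mass[np.isnan(mean_curve)] = 0.0
    total = mass.sum()
    if total <= 0:
        warnings.warn("footprint: aggregate curve carries no dip mass")
        return FootprintSummary(mean_curve, median_curve, center, 0, len(aligned), excluded)

    need = mass_fraction * total - 1e-9
    best = width
    for i in range(center + 1):
        acc = mass[i : center + 1].sum()
        j = center
        while acc < need and j + 1 < width:
            j += 1
            acc += mass[j]
        if acc >= need:
            best = min(best, j - i + 1)
    return FootprintSummary(mean_curve, median_curve, center, int(best), len(aligned), excluded)
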