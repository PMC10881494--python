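"""Random-forest classification of epitope-containing peptides.

Training data come from a reactivity screen of short sub-peptides ("k-mer
scan" windows of immunodominant wildtype peptides): a 15-mer is a positive
example if two or more serum samples show a positive log hit-fold-change, a
negative example if no sample reacts at all. Negatives are ranked by their
abundance in the mock-IP (beads-only) samples so that peptides absent for
technical reasons are not mistaken for non-epitopes, and the top N are taken
to balance the classes. Because the scan windows of one wildtype are nearly
identical sequences, train/test splits are made at whole-wildtype
granularity so no wildtype contributes to both sides.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .core_io import ValidationError
from .features import FeatureSchema, default_schema, feature_matrix
from .core_io import ReactivityTable


@dataclass
class LabeledPeptide:
    """A training example: peptide sequence, its wildtype of origin, binary label."""

    seq: str
    wildtype_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0/1, got {self.label!r}")


def build_training_set(
    reactivity: ReactivityTable,
    wildtype_map: Mapping[str, str],
    bead_sample_ids: Sequence[str],
    peptide_length: int = 15,
    min_reactive_samples: int = 2,
) -> list[LabeledPeptide]:
    """Construct a balanced labeled set from a scan reactivity table.

    Peptide ids are taken to be the peptide sequences (as in scan reactivity
    tables, where the amino-acid sequence is the row name). Only peptides of
    ``peptide_length`` are considered. Positives react (log_hfc > 0) in at
    least ``min_reactive_samples`` serum samples; negative candidates react in
    none, and are ranked by descending mean mock-IP (bead) count, ties broken
    lexicographically by sequence; the top N are kept, N = number of positives.
    """
    if reactivity.log_hfc is None:
        raise ValidationError("reactivity table needs a log_hfc matrix")
    if reactivity.counts is None:
        raise ValidationError("reactivity table needs bead-sample counts")
    bead_set = set(bead_sample_ids)
    missing = bead_set - set(reactivity.sample_ids)
    if missing:
        raise ValidationError(f"bead samples not in table: {sorted(missing)}")
    serum_cols = [i for i, s in enumerate(reactivity.sample_ids) if s not in bead_set]
    bead_cols = [i for i, s in enumerate(reactivity.sample_ids) if s in bead_set]
    if not serum_cols or not bead_cols:
        raise ValidationError("need at least one serum and one bead sample")

    keep = [i for i, pid in enumerate(reactivity.peptide_ids) if len(pid) == peptide_length]
    hfc = reactivity.log_hfc[np.ix_(keep, serum_cols)]
    bead = reactivity.counts[np.ix_(keep, bead_cols)].mean(axis=1)
    n_reactive = (hfc > 0).sum(axis=1)

    positives, candidates = [], []
    for row, i in enumerate(keep):
        pid = reactivity.peptide_ids[i]
        if n_reactive[row] >= min_reactive_samples:
            positives.append(pid)
        elif n_reactive[row] == 0:
            candidates.append((-bead[row], pid))
    if len(candidates) < len(positives):
        raise ValidationError(
            f"only {len(candidates)} eligible negatives for {len(positives)} positives; "
            "relax the negative criterion or provide more non-reactive peptides"
        )
    candidates.sort()
    negatives = [pid for _, pid in candidates[: len(positives)]]

    def wt(pid: str) -> str:
        try:
            return wildtype_map[pid]
        except KeyError:
            raise ValidationError(f"peptide {pid!r} missing from wildtype map") from None

    return [LabeledPeptide(p, wt(p), 1) for p in positives] + [
        LabeledPeptide(p, wt(p), 0) for p in negatives
    ]


def split_by_wildtype(
    data: Sequence[LabeledPeptide], test_frac: float = 0.05, seed: int = 0
) -> tuple[list[LabeledPeptide], list[LabeledPeptide]]:
    """Split into train/test with disjoint wildtypes.

    Whole wildtypes are accumulated into the test set, in seeded shuffled
    order, until at least ``test_frac`` of the peptides are covered; exact
    fractions are generally unattainable at whole-wildtype granularity.
    """
    wildtypes = sorted({d.wildtype_id for d in data})
    if len(wildtypes) < 2:
        raise ValidationError("cannot split: all peptides share one wildtype")
    rng = np.random.default_rng(seed)
    order = [wildtypes[i] for i in rng.permutation(len(wildtypes))]
    target = test_frac * len(data)
    by_wt: dict[str, int] = {}
    for d in data:
        by_wt[d.wildtype_id] = by_wt.get(d.wildtype_id, 0) + 1
    test_wt: set[str] = set()
    covered = 0
    for wt in order:
        if covered >= target:
            break
        if len(test_wt) == len(wildtypes) - 1:
            break  # keep at least one wildtype in training
        test_wt.add(wt)
        covered += by_wt[wt]
    train = [d for d in data if d.wildtype_id not in test_wt]
    test = [d for d in data if d.wildtype_id in test_wt]
    return train, test


@dataclass
class EpitopeModel:
    """A fitted random forest predicting whether a peptide contains an epitope."""

    forest: RandomForestClassifier
    schema: FeatureSchema
    peptide_length: int
    n_trees: int = 100
    seed: int = 42
    training_manifest: dict = field(default_factory=dict)

    def predict_proba_many(self, seqs: Sequence[str]) -> np.ndarray:
        """Epitope probability (fraction of trees voting positive) per peptide."""
        for s in seqs:
            if len(s) != self.peptide_length:
                raise ValidationError(
                    f"peptide {s!r} has length {len(s)}, model expects {self.peptide_length}"
                )
        X = feature_matrix(seqs, self.schema)
        return self.forest.predict_proba(X)[:, 1]

    def predict_proba(self, seq: str) -> float:
        return float(self.predict_proba_many([seq])[0])

    def oob_scores(self) -> np.ndarray:
        """Out-of-bag positive-class probabilities for the training examples."""
        return self.forest.oob_decision_function_[:, 1]

    def importances(self) -> "list[tuple[str, float]]":
        """(feature name, impurity importance), sorted descending."""
        pairs = list(zip(self.schema.feature_names, self.forest.feature_importances_))
        pairs.sort(key=lambda t: (-t[1], t[0]))
        return pairs

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": "dolphyn-epitope-model/1",
                "forest": self.forest,
                "schema": self.schema,
                "peptide_length": self.peptide_length,
                "n_trees": self.n_trees,
                "seed": self.seed,
                "training_manifest": self.training_manifest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpitopeModel":
        doc = joblib.load(path)
        if doc.get("format") != "dolphyn-epitope-model/1":
            raise ValidationError(f"{path}: not a dolphyn epitope model")
        return cls(
            forest=doc["forest"],
            schema=doc["schema"],
            peptide_length=doc["peptide_length"],
            n_trees=doc["n_trees"],
            seed=doc["seed"],
            training_manifest=doc["training_manifest"],
        )


def train(
    data: Sequence[LabeledPeptide],
    schema: FeatureSchema | None = None,
    n_trees: int = 100,
    seed: int = 42,
) -> EpitopeModel:
    """Train a random forest (default 100 trees, out-of-bag scoring retained).

    Requires at least two examples of each class and peptides of one uniform
    length; reproducible under a fixed seed.
    """
    schema = schema or default_schema()
    labels = np.array([d.label for d in data])
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValidationError("need >= 2 examples of each class")
    lengths = {len(d.seq) for d in data}
    if len(lengths) != 1:
        raise ValidationError(f"peptides must share one length, got {sorted(lengths)}")
    (length,) = lengths
    X = feature_matrix([d.seq for d in data], schema)
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, labels)
    manifest = {
        "n_examples": len(data),
        "n_positive": int((labels == 1).sum()),
        "n_negative": int((labels == 0).sum()),
        "peptide_length": length,
        "n_trees": n_trees,
        "seed": seed,
        "n_features": schema.n_features,
        "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return EpitopeModel(
        forest=forest, schema=schema, peptide_length=length,
        n_trees=n_trees, seed=seed, training_manifest=manifest,
    )


def score_long_peptide(model: EpitopeModel, seq: str) -> float:
    """Score a peptide longer than the model's window.

    The mean predicted probability over all length-``model.peptide_length``
    windows (stride 1) is the peptide's probability score; a 56-mer scored by
    a 15-mer model averages 42 windows.
    """
    k = model.peptide_length
    if len(seq) < k:
        raise ValidationError(f"sequence shorter than model window ({len(seq)} < {k})")
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return float(np.mean(model.predict_proba_many(windows)))


def compute_auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Area under the ROC curve (probability a positive outranks a negative, ties 1/2)."""
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    if len(set(labels.tolist()) & {0, 1}) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def oob_auc(model: EpitopeModel, labels: Sequence[int]) -> float:
    """AUC of the out-of-bag predictions against the training labels."""
    return compute_auc(model.oob_scores(), labels)
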