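"""Subsampling loop turning stable misclassifications into repositioning
candidates.

Repeated 90/10 train/holdout splits yield, for every drug, a distribution
over predicted therapeutic classes.  The most frequent class is the final
prediction; every other predicted class is a repositioning suggestion whose
score is its frequency in the drug's prediction distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .embed import train_svm

log = logging.getLogger(__name__)


@dataclass
class PredictionDistribution:
    """Counts of predicted classes for one drug across holdout iterations."""

    drug_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_eval(self) -> int:
        return sum(self.counts.values())

    def add(self, predicted: str) -> None:
        self.counts[predicted] = self.counts.get(predicted, 0) + 1

    def frequencies(self) -> dict[str, float]:
        n = self.n_eval
        return {c: k / n for c, k in self.counts.items()}


@dataclass(frozen=True)
class RepositioningRecord:
    """One (drug, alternative class) suggestion with its reliability score."""

    drug_id: str
    original_class: str
    predicted_class: str
    score: float
    n_eval: int

    @property
    def is_confirmation(self) -> bool:
        return self.predicted_class == self.original_class


def bootstrap_predict(
    coords: np.ndarray,
    drug_ids: Sequence[str],
    labels: Mapping[str, str],
    iterations: int = 10_000,
    holdout: float = 0.1,
    seed: int = 0,
    stratified: bool = False,
    gamma: float | str = "scale",
    C: float = 1.0,
) -> dict[str, PredictionDistribution]:
    """Accumulate per-drug prediction distributions over random splits.

    Each iteration holds out ``ceil(holdout * n)`` drugs sampled without
    replacement (optionally stratified by class), trains the SVM on the
    rest, and records the predicted class of each held-out drug.  Splits
    whose training part has fewer than two classes are resampled.  Drugs
    never held out after all iterations get targeted extra iterations so
    every drug has at least one prediction.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n != len(drug_ids):
        raise ValueError("coords and drug_ids disagree on cohort size")
    if not 0.0 < holdout < 1.0:
        raise ValueError("holdout must lie strictly between 0 and 1")
    y = np.array([labels[d] for d in drug_ids])
    n_test = int(np.ceil(holdout * n))
    small = {
        c for c, k in zip(*np.unique(y, return_counts=True))
        if k < int(np.ceil(1.0 / holdout))
    }
    if small:
        log.warning(
            "classes likely absent from some training subsets: %s",
            ", ".join(sorted(small)),
        )
    rng = np.random.default_rng(seed)
    dists = {d: PredictionDistribution(drug_id=d) for d in drug_ids}

    def one_iteration(test_idx: np.ndarray) -> bool:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        if len(set(y[mask].tolist())) < 2:
            return False
        clf = train_svm(coords[mask], y[mask], gamma=gamma, C=C)
        for i, pred in zip(test_idx, clf.predict(coords[test_idx])):
            dists[drug_ids[i]].add(str(pred))
        return True

    def sample_test() -> np.ndarray:
        if not stratified:
            return rng.choice(n, size=n_test, replace=False)
        # proportional per-class holdout, remainder filled at random
        test: list[int] = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            k = int(np.floor(holdout * idx.size))
            if k:
                test.extend(rng.choice(idx, size=k, replace=False).tolist())
        rest = np.setdiff1d(np.arange(n), test)
        short = n_test - len(test)
        if short > 0:
            test.extend(rng.choice(rest, size=short, replace=False).tolist())
        return np.array(test[:n_test])

    resampled = 0
    done = 0
    cap = 100 * iterations
    attempts = 0
    while done < iterations:
        attempts += 1
        if attempts > cap:
            raise RuntimeError("too many degenerate training subsets")
        if one_iteration(sample_test()):
            done += 1
        else:
            resampled += 1
    if resampled:
        log.info("resampled %d degenerate split(s)", resampled)

    # top-up: guarantee n_eval >= 1 for every drug
    uncovered = [i for i, d in enumerate(drug_ids) if dists[d].n_eval == 0]
    topped_up = 0
    while uncovered:
        head = np.array(uncovered[:n_test])
        fill = np.setdiff1d(np.arange(n), head)
        extra = rng.choice(fill, size=n_test - head.size, replace=False)
        if one_iteration(np.concatenate([head, extra])):
            topped_up += 1
            uncovered = [i for i, d in enumerate(drug_ids) if dists[d].n_eval == 0]
        if topped_up > n:
            raise RuntimeError("top-up iterations failed to cover all drugs")
    if topped_up:
        log.info("ran %d extra iteration(s) to cover never-held-out drugs", topped_up)
    return dists


def final_prediction(dist: PredictionDistribution) -> tuple[str, float]:
    """Most frequent predicted class and its frequency; ties break
    lexicographically (and are logged)."""
    if dist.n_eval < 1:
        raise ValueError(f"drug {dist.drug_id} was never evaluated")
    top = max(dist.counts.values())
    tied = sorted(c for c, k in dist.counts.items() if k == top)
    if len(tied) > 1:
        log.info(
            "drug %s: tie between %s; keeping %s",
            dist.drug_id, ", ".join(tied), tied[0],
        )
    return tied[0], top / dist.n_eval


def repositioning_report(
    dists: Mapping[str, PredictionDistribution],
    labels: Mapping[str, str],
    min_score: float = 0.0,
    include_confirmations: bool = False,
) -> tuple[list[RepositioningRecord], float]:
    """Scored repositioning suggestions plus the overall mode-prediction
    accuracy.

    One record per (drug, predicted class different from its label) with
    score at least ``min_score``, sorted by descending score then drug id.
    Accuracy is the fraction of drugs whose most frequent prediction equals
    their original class.
    """
    missing = [d for d in labels if d not in dists or dists[d].n_eval == 0]
    if missing:
        raise ValueError(f"no predictions for labelled drug(s): {missing[:5]}")
    records: list[RepositioningRecord] = []
    correct = 0
    for drug_id, original in labels.items():
        dist = dists[drug_id]
        top_class, _ = final_prediction(dist)
        if top_class == original:
            correct += 1
        for cls, freq in dist.frequencies().items():
            if cls == original and not include_confirmations:
                continue
            if freq >= min_score:
                records.append(
                    RepositioningRecord(
                        drug_id=drug_id,
                        original_class=original,
                        predicted_class=cls,
                        score=freq,
                        n_eval=dist.n_eval,
                    )
                )
    records.sort(key=lambda r: (-r.score, r.drug_id, r.predicted_class))
    return records, correct / len(labels)


def class_flow_summary(
    records: Sequence[RepositioningRecord],
) -> dict[tuple[str, str], float]:
    """Score-weighted sum of reclassification events per directed class
    pair, suitable for drawing a repositioning flow network."""
    flows: dict[tuple[str, str], float] = {}
    for rec in records:
        if rec.is_confirmation:
            continue
        key = (rec.original_class, rec.predicted_class)
        flows[key] = flows.get(key, 0.0) + rec.score
    return flows
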