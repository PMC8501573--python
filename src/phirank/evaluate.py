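"""Benchmark evaluation: top-host prediction, taxonomic accuracy, AUC/AUPR.

The protocol mirrors the standard virus-host benchmark design: for each query
virus the highest-scoring host is the prediction; when several hosts tie at
the maximum the prediction counts as correct if the true host is among them.
Accuracy is reported at six taxonomic levels (species through phylum) as the
percentage of viruses whose predicted host shares the level label with a
known host.  Pair-level discrimination is summarised by ROC AUC and the area
under the precision-recall curve, with precision/recall/specificity reported
at the F1-maximising score threshold; non-interacting pairs are all
virus-host pairs absent from the truth set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LEVELS",
    "TaxonomyTable",
    "InteractionTruth",
    "EvalReport",
    "predict_hosts",
    "accuracy_at_level",
    "roc_auc",
    "pr_aupr",
    "best_f1_threshold",
    "evaluate_benchmark",
]

#: Taxonomic levels, narrowest first.
LEVELS = ("species", "genus", "family", "order", "class", "phylum")


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-host lineage at the six levels species..phylum.

    Each lineage is a six-slot tuple aligned with :data:`LEVELS`; a slot may
    be None (missing).  Species must be present for every host the table is
    asked about during evaluation.
    """

    lineages: Mapping[str, tuple[str | None, ...]]

    def __post_init__(self) -> None:
        fixed = {}
        for host, lineage in self.lineages.items():
            lineage = tuple(lineage)
            if len(lineage) != len(LEVELS):
                raise ValueError(
                    f"lineage of {host!r} has {len(lineage)} slots, "
                    f"expected {len(LEVELS)}"
                )
            fixed[host] = tuple(
                (x if x else None) for x in lineage
            )
        object.__setattr__(self, "lineages", fixed)

    def label(self, host_id: str, level: str) -> str | None:
        if level not in LEVELS:
            raise ValueError(f"unknown taxonomic level {level!r}")
        lineage = self.lineages.get(host_id)
        if lineage is None:
            return None
        return lineage[LEVELS.index(level)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        """Read a 7-column TSV: host_id then the six level labels; empty
        field = missing."""
        lineages: dict[str, tuple[str | None, ...]] = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 1 + len(LEVELS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {1 + len(LEVELS)} "
                    f"columns, got {len(fields)}"
                )
            lineages[fields[0].strip()] = tuple(
                f.strip() or None for f in fields[1:]
            )
        return cls(lineages)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for host, lineage in self.lineages.items():
                fh.write(
                    "\t".join((host, *(x or "" for x in lineage))) + "\n"
                )


@dataclass(frozen=True)
class InteractionTruth:
    """Known virus-host interacting pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def hosts_of(self, virus_id: str) -> frozenset[str]:
        return frozenset(h for v, h in self.pairs if v == virus_id)

    def validate_against(self, matrix: ScoreMatrix) -> None:
        viruses = set(matrix.virus_ids)
        hosts = set(matrix.host_ids)
        for v, h in self.pairs:
            if v not in viruses or h not in hosts:
                raise ValueError(
                    f"truth pair ({v!r}, {h!r}) not covered by the matrix"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTruth":
        pairs: set[tuple[str, str]] = set()
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            pairs.add((fields[0].strip(), fields[1].strip()))
        return cls(frozenset(pairs))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for v, h in sorted(self.pairs):
                fh.write(f"{v}\t{h}\n")


@dataclass(frozen=True)
class EvalReport:
    """Summary metrics of one benchmark run."""

    auc: float
    aupr: float
    f1: float
    precision: float
    recall: float
    specificity: float
    threshold: float
    accuracy_by_level: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "auc": self.auc,
            "aupr": self.aupr,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "accuracy_by_level": self.accuracy_by_level,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def predict_hosts(
    matrix: ScoreMatrix,
) -> dict[str, tuple[frozenset[str], float]]:
    """Per-virus top host set: all hosts attaining the row maximum.

    Exact score equality defines the tie set; a row of all-equal scores
    returns every host.
    """
    if not matrix.host_ids:
        raise ValueError("matrix has no hosts")
    out: dict[str, tuple[frozenset[str], float]] = {}
    for vid, row in zip(matrix.virus_ids, matrix.scores):
        top = float(row.max())
        hosts = frozenset(
            h for h, s in zip(matrix.host_ids, row) if s == top
        )
        out[vid] = (hosts, top)
    return out


def accuracy_at_level(
    predictions: Mapping[str, tuple[frozenset[str], float]],
    truth: InteractionTruth,
    taxonomy: TaxonomyTable,
    level: str,
) -> float:
    """Percentage of viruses correct at one taxonomic level.

    A virus counts correct if ANY predicted top host shares the level label
    with ANY of its known hosts.  A missing lineage label on either side
    makes that particular comparison a non-match (logged), never a crash.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown taxonomic level {level!r}")
    if not predictions:
        raise ValueError("no predictions to evaluate")
    correct = 0
    for virus, (pred_hosts, _) in predictions.items():
        true_hosts = truth.hosts_of(virus)
        if not true_hosts:
            raise ValueError(f"virus {virus!r} has no known host in truth")
        true_labels = set()
        for h in true_hosts:
            lab = taxonomy.label(h, level)
            if lab is None:
                logger.warning(
                    "missing %s label for true host %r; treated as non-match",
                    level,
                    h,
                )
            else:
                true_labels.add(lab)
        hit = False
        for h in pred_hosts:
            lab = taxonomy.label(h, level)
            if lab is None:
                logger.warning(
                    "missing %s label for predicted host %r; treated as "
                    "non-match",
                    level,
                    h,
                )
            elif lab in true_labels:
                hit = True
                break
        correct += hit
    return 100.0 * correct / len(predictions)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool | int]
) -> float:
    """Area under the ROC curve (Mann-Whitney formulation; ties count half).

    Equals the probability that a random interacting pair outscores a random
    non-interacting pair.  Requires at least one positive and one negative.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("roc_auc needs both positive and negative scores")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_aupr(scores: Sequence[float], labels: Sequence[bool | int]) -> float:
    """Area under the precision-recall curve by step-wise summation.

    No linear interpolation between operating points (the convention for
    imbalanced interaction benchmarks); a random scorer attains the positive
    prevalence.  Requires at least one positive.
    """
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("pr_aupr needs at least one positive")
    return float(
        average_precision_score(labels, np.asarray(scores, dtype=float))
    )


def _confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, fn, tn


def best_f1_threshold(
    scores: Sequence[float], labels: Sequence[bool | int]
) -> tuple[float, float, float, float]:
    """F1-maximising score threshold and its F1/precision/recall.

    Candidate thresholds are the distinct observed scores plus one value
    above the maximum (predict nothing); a pair is predicted interacting
    when its score is >= the threshold.  Ties in F1 break toward the higher
    (more conservative) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("best_f1_threshold needs at least one positive")
    candidates = sorted(set(scores.tolist()))
    candidates.append(candidates[-1] + 1.0)
    best: tuple[float, float, float, float] | None = None
    for thr in candidates:
        tp, fp, fn, _ = _confusion_at(scores, labels, thr)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        if best is None or f1 >= best[1]:
            best = (thr, f1, precision, recall)
    assert best is not None
    return best


def evaluate_benchmark(
    matrix: ScoreMatrix,
    truth: InteractionTruth,
    taxonomy: TaxonomyTable,
    negative_subsample: int | None = None,
    seed: int | None = None,
) -> EvalReport:
    """Run the full benchmark protocol on a score matrix.

    Positives are the truth pairs; negatives are every other virus-host pair
    in the matrix (optionally subsampled to ``negative_subsample`` pairs for
    quick runs, off by default).
    """
    truth.validate_against(matrix)
    pos_mask = np.zeros(matrix.scores.shape, dtype=bool)
    v_index = {v: i for i, v in enumerate(matrix.virus_ids)}
    h_index = {h: j for j, h in enumerate(matrix.host_ids)}
    for v, h in truth.pairs:
        pos_mask[v_index[v], h_index[h]] = True
    pos_scores = matrix.scores[pos_mask]
    neg_scores = matrix.scores[~pos_mask]
    if negative_subsample is not None and negative_subsample < len(neg_scores):
        rng = np.random.default_rng(seed)
        neg_scores = rng.choice(neg_scores, negative_subsample, replace=False)
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate(
        [np.ones(len(pos_scores), bool), np.zeros(len(neg_scores), bool)]
    )
    auc = roc_auc(scores, labels)
    aupr = pr_aupr(scores, labels)
    thr, f1, precision, recall = best_f1_threshold(scores, labels)
    _, fp, _, tn = _confusion_at(scores, labels, thr)
    specificity = tn / (tn + fp) if tn + fp else 0.0
    predictions = predict_hosts(matrix)
    # restrict level accuracy to viruses with known hosts
    predictions = {
        v: pred for v, pred in predictions.items() if truth.hosts_of(v)
    }
    accuracy = {
        level: accuracy_at_level(predictions, truth, taxonomy, level)
        for level in LEVELS
    }
    return EvalReport(
        auc=auc,
        aupr=aupr,
        f1=f1,
        precision=precision,
        recall=recall,
        specificity=specificity,
        threshold=thr,
        accuracy_by_level=accuracy,
    )
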