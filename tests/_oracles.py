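"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written the slow, obvious way — materialised prefix sets,
exhaustive pairwise comparisons, full threshold scans — and deliberately
shares no code with the package.
"""

from __future__ import annotations

from itertools import count

import numpy as np


def prefix_set(ranks: list[frozenset[str]], d: int) -> frozenset[str]:
    out: set[str] = set()
    for rank in ranks[:d]:
        out |= rank
    return frozenset(out)


def brute_rbo(
    s_ranks: list[frozenset[str]],
    t_ranks: list[frozenset[str]],
    p: float,
    normalize: bool = True,
) -> float:
    """Depth-by-depth evaluation of the truncated rank-biased overlap."""
    n = max(len(s_ranks), len(t_ranks))
    if n == 0:
        return 0.0
    total = 0.0
    for d in range(1, n + 1):
        s = prefix_set(s_ranks, d)
        t = prefix_set(t_ranks, d)
        union = s | t
        a = len(s & t) / len(union) if union else 0.0
        total += p ** (d - 1) * a
    raw = (1 - p) * total
    if normalize:
        raw /= 1 - p**n
    return min(1.0, max(0.0, raw))


def random_tie_ranks(
    rng: np.random.Generator, labels: list[str]
) -> list[frozenset[str]]:
    """Random ranked list over a random subset of labels, random ties."""
    k = int(rng.integers(0, len(labels) + 1))
    chosen = [labels[i] for i in rng.permutation(len(labels))[:k]]
    ranks: list[set[str]] = []
    for lab in chosen:
        if ranks and rng.random() < 0.4:
            ranks[-1].add(lab)
        else:
            ranks.append({lab})
    return [frozenset(r) for r in ranks]


def brute_collapse(
    hits: list[tuple[str, float]], species_map: dict[str, str]
) -> list[frozenset[str]]:
    """Deduplicate species by first appearance, then group equal scores."""
    rep: list[tuple[str, float]] = []
    seen: set[str] = set()
    for subject, score in hits:
        sp = species_map.get(subject, subject)
        if sp not in seen:
            seen.add(sp)
            rep.append((sp, score))
    ranks: list[set[str]] = []
    last = object()
    for sp, score in rep:
        if score == last:
            ranks[-1].add(sp)
        else:
            ranks.append({sp})
        last = score
    return [frozenset(r) for r in ranks]


def brute_auc(pos: list[float], neg: list[float]) -> float:
    """Probability a random positive outscores a random negative, ties half."""
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_best_f1(
    scores: list[float], labels: list[bool]
) -> tuple[float, float, float, float]:
    """Exhaustive threshold scan; ties in F1 go to the higher threshold."""
    candidates = sorted(set(scores)) + [max(scores) + 1.0]
    best = None
    for thr in candidates:
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and not y)
        fn = sum(1 for s, y in zip(scores, labels) if s < thr and y)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        if best is None or f1 >= best[1]:
            best = (thr, f1, precision, recall)
    return best


def brute_aupr(scores: list[float], labels: list[bool]) -> float:
    """Step-wise precision-recall area over descending distinct thresholds."""
    n_pos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and not y)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
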