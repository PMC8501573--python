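"""All-vs-all virus x host interaction score matrices.

The score matrix holds one rank-biased-overlap score per virus-host pair.
The "+viruses" expanded-reference mode — where the similarity-search database
also contains viral sequences, so a virus and host can be linked through
shared similarity to other viruses — is purely a property of the input ranked
lists; the scoring path is identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .ranklists import RankedList
from .rbo import RboParams, rbo

__all__ = ["ScoreMatrix", "score_all", "exclude_self"]


@dataclass(frozen=True)
class ScoreMatrix:
    """Dense virus x host matrix of interaction scores in [0, 1]."""

    virus_ids: tuple[str, ...]
    host_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.virus_ids), len(self.host_ids)):
            raise ValueError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.virus_ids)} viruses x {len(self.host_ids)} hosts"
            )
        if scores.size and not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
            raise ValueError("scores must lie in [0, 1]")

    def row(self, virus_id: str) -> np.ndarray:
        return self.scores[self.virus_ids.index(virus_id)]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: header of host ids, first column of virus ids.

        Floats use repr (shortest round-trip) so downstream evaluation is
        bit-stable.
        """
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("\t".join(("virus_id", *self.host_ids)) + "\n")
            for vid, row in zip(self.virus_ids, self.scores):
                fh.write(
                    vid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ValueError(f"{path}: empty matrix file")
        header = lines[0].split("\t")
        host_ids = tuple(header[1:])
        virus_ids: list[str] = []
        rows: list[list[float]] = []
        for line in lines[1:]:
            fields = line.split("\t")
            virus_ids.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
        return cls(
            tuple(virus_ids),
            host_ids,
            np.array(rows, dtype=float).reshape(len(virus_ids), len(host_ids)),
        )


def _as_ordered_lists(
    lists: Mapping[str, RankedList] | Sequence[RankedList],
) -> list[RankedList]:
    if isinstance(lists, Mapping):
        out = list(lists.values())
    else:
        out = list(lists)
    ids = [rl.query_id for rl in out]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate query id(s) in collection: {dup}")
    return out


def score_all(
    virus_lists: Mapping[str, RankedList] | Sequence[RankedList],
    host_lists: Mapping[str, RankedList] | Sequence[RankedList],
    params: RboParams | None = None,
    workers: int = 1,
) -> ScoreMatrix:
    """Score every virus ranked list against every host ranked list.

    The result is deterministic and independent of execution order; the
    ``workers`` knob only parallelises rows (joblib).
    """
    if params is None:
        params = RboParams()
    viruses = _as_ordered_lists(virus_lists)
    hosts = _as_ordered_lists(host_lists)

    def score_row(virus: RankedList) -> list[float]:
        return [rbo(virus, host, params) for host in hosts]

    if workers > 1 and len(viruses) > 1:
        rows = Parallel(n_jobs=workers)(
            delayed(score_row)(v) for v in viruses
        )
    else:
        rows = [score_row(v) for v in viruses]
    scores = np.array(rows, dtype=float).reshape(len(viruses), len(hosts))
    return ScoreMatrix(
        tuple(v.query_id for v in viruses),
        tuple(h.query_id for h in hosts),
        scores,
    )


def exclude_self(
    virus_lists: Mapping[str, RankedList],
    contig_to_parent: Mapping[str, str],
) -> dict[str, RankedList]:
    """Remove each contig's parent genome label from its own ranked list.

    Used for the incomplete-sequence experiment, where contigs subsampled
    from a phage genome must not be matched back to that full-length genome:
    the parent's label is removed from every rank, emptied ranks are dropped
    and later ranks shift up.  A contig id missing from the mapping is an
    error; a parent label absent from the list leaves it unchanged.
    """
    out: dict[str, RankedList] = {}
    for contig_id, ranked in virus_lists.items():
        if contig_id not in contig_to_parent:
            raise ValueError(f"unknown parent for contig {contig_id!r}")
        out[contig_id] = ranked.without_label(contig_to_parent[contig_id])
    return out
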