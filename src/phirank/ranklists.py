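"""Tie-aware ranked lists of reference species from similarity-search tables.

A similarity search (nucleotide BLAST, or Mash sketch distances) of one query
sequence against a reference database yields a table of (subject, score) hits.
This module turns those tables into *ranked lists*: ordered sequences of rank
sets, where each rank holds one or more reference species whose representative
scores are exactly equal (ties).  Genome-level subjects are collapsed to
species via a genome-to-species map, keeping each species at its first (best)
appearance only.

Ranked lists have four properties that matter downstream: top ranks are more
informative than bottom ranks; two lists need not contain the same species;
lists may differ in length; and several species may share one rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "RankedList",
    "parse_blast_tab",
    "parse_mash_dist",
    "collapse_to_ranks",
    "read_ranklist_file",
    "write_ranklist_file",
    "read_ranklist_dir",
    "write_ranklist_dir",
    "read_species_map",
]

#: Number of columns in the tabular BLAST dialect (outfmt 6/7).
BLAST_TAB_COLUMNS = 12
#: Column index (0-based) of the bit-score in the tabular BLAST dialect.
BLAST_BITSCORE_COLUMN = 11
#: Number of columns in the Mash ``dist`` output.
MASH_COLUMNS = 5


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit: a subject sequence with its bit-score."""

    query_id: str
    subject_id: str
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_id.strip() or not self.subject_id.strip():
            raise ValueError("query_id and subject_id must be non-empty")
        if self.bit_score < 0:
            raise ValueError(f"bit_score must be >= 0, got {self.bit_score}")


@dataclass(frozen=True)
class RankedList:
    """Ordered ranks of reference species labels, best rank first.

    ``ranks`` is a tuple of frozensets.  Each set is one rank; a set with
    more than one label is a tie.  A label appears in at most one rank.
    The list may be empty (a query with no hits at all).
    """

    query_id: str
    ranks: tuple[frozenset[str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ranks", tuple(frozenset(r) for r in self.ranks)
        )
        seen: set[str] = set()
        for i, rank in enumerate(self.ranks):
            if not rank:
                raise ValueError(f"rank {i + 1} of {self.query_id!r} is empty")
            dup = seen & rank
            if dup:
                raise ValueError(
                    f"label(s) {sorted(dup)} appear in more than one rank "
                    f"of {self.query_id!r}"
                )
            seen |= rank

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.ranks)

    def labels(self) -> frozenset[str]:
        """All labels anywhere in the list."""
        out: set[str] = set()
        for rank in self.ranks:
            out |= rank
        return frozenset(out)

    def prefix(self, depth: int) -> frozenset[str]:
        """Union of the first ``min(depth, len)`` rank sets.

        A depth beyond the end of the list contributes the whole list.
        """
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        out: set[str] = set()
        for rank in self.ranks[:depth]:
            out |= rank
        return frozenset(out)

    def without_label(self, label: str) -> "RankedList":
        """Copy with ``label`` removed from every rank.

        Ranks emptied by the removal are dropped; later ranks shift up.
        """
        new_ranks = []
        for rank in self.ranks:
            kept = rank - {label}
            if kept:
                new_ranks.append(kept)
        return RankedList(self.query_id, tuple(new_ranks))


def _split_fields(line: str) -> list[str]:
    # BLAST/Mash tabular output is tab-separated; tolerate runs of whitespace
    # so hand-made fixtures survive.
    if "\t" in line:
        return line.rstrip("\n").split("\t")
    return line.split()


def parse_blast_tab(
    stream: Iterable[str],
    score_column: int = BLAST_BITSCORE_COLUMN,
) -> dict[str, list[tuple[str, float]]]:
    """Parse tabular BLAST output into per-query hit lists.

    Accepts the 12-column outfmt 6/7 dialect (``qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore``); lines
    beginning with ``#`` are comments and skipped.  For each query, each
    subject is kept once with its highest bit-score, and subjects are ordered
    by decreasing score.  Subjects with exactly equal scores keep their input
    order; they become ties when collapsed to ranks.

    Parameters
    ----------
    stream :
        Iterable of text lines.
    score_column :
        0-based index of the score column (default: the bit-score).

    Returns
    -------
    dict mapping query_id to a list of ``(subject_id, bit_score)`` pairs
    ordered by decreasing score.  An empty stream yields an empty dict.
    """
    # per query: subject -> (max score, first-appearance index)
    best: dict[str, dict[str, tuple[float, int]]] = {}
    counter = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = _split_fields(line)
        if len(fields) < BLAST_TAB_COLUMNS:
            raise ValueError(
                f"line {lineno}: expected >= {BLAST_TAB_COLUMNS} columns, "
                f"got {len(fields)}"
            )
        query = fields[0].strip()
        subject = fields[1].strip()
        if not query or not subject:
            raise ValueError(f"line {lineno}: empty query or subject id")
        try:
            score = float(fields[score_column])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: unparseable score {fields[score_column]!r}"
            ) from exc
        per_query = best.setdefault(query, {})
        if subject not in per_query or score > per_query[subject][0]:
            order = per_query[subject][1] if subject in per_query else counter
            per_query[subject] = (score, order)
        counter += 1
    out: dict[str, list[tuple[str, float]]] = {}
    for query, subjects in best.items():
        ordered = sorted(
            subjects.items(), key=lambda kv: (-kv[1][0], kv[1][1])
        )
        out[query] = [(subj, score) for subj, (score, _) in ordered]
    return out


def parse_mash_dist(
    stream: Iterable[str],
) -> dict[str, list[tuple[str, float]]]:
    """Parse Mash ``dist`` output into per-query subject lists.

    Mash emits five columns: reference-ID, query-ID, distance, p-value,
    shared-hashes.  Here the *first* column is treated as the sequence being
    ranked for (the sketch each database genome was compared against) and the
    second column as the database subject, matching a ``mash dist host.msh
    db.fna`` invocation.  Subjects are ordered by increasing distance; equal
    distances keep input order and become ties downstream (pass
    ``higher_is_better=False`` to :func:`collapse_to_ranks`).
    """
    hits: dict[str, list[tuple[str, float, int]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = _split_fields(line)
        if len(fields) < MASH_COLUMNS:
            raise ValueError(
                f"line {lineno}: expected >= {MASH_COLUMNS} columns, "
                f"got {len(fields)}"
            )
        query = fields[0].strip()
        subject = fields[1].strip()
        if not query or not subject:
            raise ValueError(f"line {lineno}: empty query or subject id")
        try:
            dist = float(fields[2])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: unparseable distance {fields[2]!r}"
            ) from exc
        hits.setdefault(query, []).append((subject, dist, lineno))
    out: dict[str, list[tuple[str, float]]] = {}
    for query, rows in hits.items():
        # keep best (smallest) distance per subject, stable among equals
        best: dict[str, tuple[float, int]] = {}
        for subject, dist, order in rows:
            if subject not in best or dist < best[subject][0]:
                kept = best[subject][1] if subject in best else order
                best[subject] = (dist, kept)
        ordered = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1]))
        out[query] = [(subj, dist) for subj, (dist, _) in ordered]
    return out


def collapse_to_ranks(
    hits: Iterable[tuple[str, float]],
    species_map: Mapping[str, str] | None = None,
    query_id: str = "",
    higher_is_better: bool = True,
) -> RankedList:
    """Collapse an ordered hit list into a tie-aware species ranked list.

    Subjects are mapped to species and each species is kept at its first
    (best-scoring) appearance only; this deduplication happens *before* tie
    grouping, so a species is ranked by its best genome even when other
    genomes of the same species score lower.  Consecutive species whose
    representative scores are exactly equal share one rank.

    Parameters
    ----------
    hits :
        ``(subject_id, score)`` pairs ordered best-first: decreasing score
        when ``higher_is_better`` (bit-scores), increasing when not (Mash
        distances).
    species_map :
        Genome/accession label to species label.  A subject absent from the
        map falls back to its own label (with a warning), which keeps
        reference sets that mix prokaryote genomes with unlabelled viral
        sequences uniform.
    query_id :
        Label stored on the resulting :class:`RankedList`.
    higher_is_better :
        Score direction; exact equality defines a tie either way.
    """
    species_map = species_map or {}
    seen: set[str] = set()
    dedup: list[tuple[str, float]] = []
    prev: float | None = None
    for subject, score in hits:
        key = float(score) if higher_is_better else -float(score)
        if prev is not None and key > prev:
            raise ValueError(
                f"hits for {query_id!r} are not ordered best-first "
                f"(score {score} after {prev if higher_is_better else -prev})"
            )
        prev = key
        if subject in species_map:
            species = species_map[subject]
        else:
            if species_map:
                logger.warning(
                    "subject %r not in species map; using it as its own "
                    "species label",
                    subject,
                )
            species = subject
        if species in seen:
            continue
        seen.add(species)
        dedup.append((species, key))
    ranks: list[set[str]] = []
    last_score: float | None = None
    for species, key in dedup:
        if last_score is not None and key == last_score:
            ranks[-1].add(species)
        else:
            ranks.append({species})
        last_score = key
    return RankedList(query_id, tuple(frozenset(r) for r in ranks))


def write_ranklist_file(ranked: RankedList, path: str | Path) -> None:
    """Write one ranked list: one rank per line, tied labels comma-separated."""
    path = Path(path)
    lines = [",".join(sorted(rank)) for rank in ranked.ranks]
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def read_ranklist_file(
    path: str | Path, query_id: str | None = None
) -> RankedList:
    """Read a ranked-list file written by :func:`write_ranklist_file`.

    The query id defaults to the file's stem.  Duplicate labels across lines
    and blank interior lines are errors.
    """
    path = Path(path)
    if query_id is None:
        query_id = path.stem
    text = path.read_text(encoding="utf-8")
    raw_lines = text.split("\n")
    # drop trailing empty strings from the final newline(s)
    while raw_lines and raw_lines[-1] == "":
        raw_lines.pop()
    ranks: list[frozenset[str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.strip():
            raise ValueError(f"{path}: blank interior line {lineno}")
        labels = [lab.strip() for lab in line.split(",")]
        if any(not lab for lab in labels):
            raise ValueError(f"{path}: empty label on line {lineno}")
        for lab in labels:
            if lab in seen:
                raise ValueError(f"{path}: duplicate label {lab!r}")
            seen.add(lab)
        ranks.append(frozenset(labels))
    return RankedList(query_id, tuple(ranks))


def read_ranklist_dir(directory: str | Path) -> dict[str, RankedList]:
    """Read every ``<query_id>.txt`` ranked-list file in a directory."""
    directory = Path(directory)
    out: dict[str, RankedList] = {}
    for path in sorted(directory.glob("*.txt")):
        out[path.stem] = read_ranklist_file(path)
    return out


def write_ranklist_dir(
    lists: Mapping[str, RankedList], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for query_id, ranked in lists.items():
        write_ranklist_file(ranked, directory / f"{query_id}.txt")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping genome/accession id to species label."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        genome, species = fields[0].strip(), fields[1].strip()
        if not genome or not species:
            raise ValueError(f"{path}: line {lineno}: empty field")
        out[genome] = species
    return out
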