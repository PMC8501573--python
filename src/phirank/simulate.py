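"""Synthetic desk-scale benchmarks: planted-host universes and contig draws.

A planted universe emulates the structure of a real virus-host benchmark:
each candidate host has a ranked list of reference species (as a real host
genome would after a similarity search against the reference database), and
each virus's ranked list is a noisy copy of its true host's list.  It does
not emulate sequence-level realism — no genomes are aligned; the noise model
perturbs the lists directly — so it tests the ranking/scoring/evaluation
machinery, not the biology of any particular phage family.

``subsample_contigs`` draws fixed-length fragments from a genome, the input
preparation step of the incomplete-sequence experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evaluate import LEVELS, InteractionTruth, TaxonomyTable
from .ranklists import RankedList, write_ranklist_dir

__all__ = [
    "PlantedUniverse",
    "make_planted_universe",
    "subsample_contigs",
    "emit_blast_like_table",
    "random_ranked_list",
]

#: Contig lengths (bases) of the incomplete-sequence experiment.
CONTIG_LENGTHS = (20000, 10000, 5000, 3000, 1000)
#: Replicates per contig length.
CONTIG_REPLICATES = 10


@dataclass(frozen=True)
class PlantedUniverse:
    """A synthetic benchmark with one known true host per virus."""

    host_lists: dict[str, RankedList]
    virus_lists: dict[str, RankedList]
    truth: InteractionTruth
    taxonomy: TaxonomyTable
    noise: float
    seed: int

    def save(self, directory: str | Path) -> None:
        """Serialise to the on-disk benchmark layout.

        ``host/`` and ``virus/`` ranked-list directories plus ``truth.tsv``
        and ``taxonomy.tsv``.
        """
        directory = Path(directory)
        write_ranklist_dir(self.host_lists, directory / "host")
        write_ranklist_dir(self.virus_lists, directory / "virus")
        self.truth.to_tsv(directory / "truth.tsv")
        self.taxonomy.to_tsv(directory / "taxonomy.tsv")


def _lineage_for(index: int) -> tuple[str, ...]:
    # hosts aggregate into broader taxa by halving: 2 species per genus,
    # 2 genera per family, and so on up to phylum
    return tuple(
        f"{level[0]}{index >> k}" for k, level in enumerate(LEVELS)
    )


def random_ranked_list(
    rng: np.random.Generator,
    pool: Sequence[str],
    list_len: int,
    query_id: str = "",
    tie_prob: float = 0.0,
) -> RankedList:
    """Random tie-structured ranked list drawn from a label pool.

    Takes a random permutation prefix of ``pool`` and merges each adjacent
    pair of ranks with probability ``tie_prob``.
    """
    if list_len > len(pool):
        raise ValueError("list_len exceeds pool size")
    labels = [pool[i] for i in rng.permutation(len(pool))[:list_len]]
    ranks: list[set[str]] = []
    for lab in labels:
        if ranks and tie_prob > 0 and rng.random() < tie_prob:
            ranks[-1].add(lab)
        else:
            ranks.append({lab})
    return RankedList(query_id, tuple(frozenset(r) for r in ranks))


def _perturb(
    rng: np.random.Generator,
    host: RankedList,
    pool: Sequence[str],
    noise: float,
    query_id: str,
) -> RankedList:
    """Noisy copy of a host list.

    Three passes, all at rate ``noise``: each position's label is replaced
    with a random pool label with probability ``noise`` (at noise = 1 the
    copy shares content with its host only by chance); adjacent positions
    swap with probability ``noise/2``; adjacent ranks merge into ties with
    probability ``noise/2``.
    """
    labels = [lab for rank in host.ranks for lab in sorted(rank)]
    present = set(labels)
    for i in range(len(labels)):
        if rng.random() >= noise:
            continue
        # replace with a pool label not already present in this list
        for _ in range(20):
            candidate = pool[rng.integers(len(pool))]
            if candidate not in present:
                present.discard(labels[i])
                present.add(candidate)
                labels[i] = candidate
                break
    for i in range(len(labels) - 1):
        if rng.random() < noise / 2:
            labels[i], labels[i + 1] = labels[i + 1], labels[i]
    ranks: list[set[str]] = []
    for lab in labels:
        if ranks and rng.random() < noise / 2:
            ranks[-1].add(lab)
        else:
            ranks.append({lab})
    return RankedList(query_id, tuple(frozenset(r) for r in ranks))


def make_planted_universe(
    n_hosts: int = 50,
    n_viruses: int = 200,
    pool_size: int = 250,
    list_len: int = 25,
    noise: float = 0.1,
    seed: int = 0,
) -> PlantedUniverse:
    """Build a synthetic benchmark with planted virus-host interactions.

    Each host's ranked list is a random permutation prefix of a shared
    reference species pool; each virus copies its true host's list and is
    perturbed position-wise with probability ``noise`` (label replacement
    from the pool, neighbour swaps, tie merges).  Virus ``i`` interacts
    with host ``i mod n_hosts``.
    Deterministic given ``seed``; all draws flow from one PCG64 generator.
    """
    if min(n_hosts, n_viruses, pool_size, list_len) < 1:
        raise ValueError("all size parameters must be positive")
    if not (0.0 <= noise <= 1.0):
        raise ValueError(f"noise must lie in [0, 1], got {noise}")
    if list_len > pool_size:
        raise ValueError("list_len exceeds pool_size")
    rng = np.random.default_rng(seed)
    pool = [f"sp{i:04d}" for i in range(pool_size)]
    host_ids = [f"host_{i:03d}" for i in range(n_hosts)]
    host_lists = {
        hid: random_ranked_list(rng, pool, list_len, query_id=hid)
        for hid in host_ids
    }
    virus_lists: dict[str, RankedList] = {}
    pairs: set[tuple[str, str]] = set()
    for j in range(n_viruses):
        vid = f"virus_{j:03d}"
        true_host = host_ids[j % n_hosts]
        pairs.add((vid, true_host))
        if noise == 0.0:
            virus_lists[vid] = RankedList(vid, host_lists[true_host].ranks)
        else:
            virus_lists[vid] = _perturb(
                rng, host_lists[true_host], pool, noise, vid
            )
    taxonomy = TaxonomyTable(
        {hid: _lineage_for(i) for i, hid in enumerate(host_ids)}
    )
    return PlantedUniverse(
        host_lists=host_lists,
        virus_lists=virus_lists,
        truth=InteractionTruth(frozenset(pairs)),
        taxonomy=taxonomy,
        noise=noise,
        seed=seed,
    )


def subsample_contigs(
    genome: SeqRecord,
    lengths: Sequence[int] = CONTIG_LENGTHS,
    replicates: int = CONTIG_REPLICATES,
    seed: int = 0,
) -> list[SeqRecord]:
    """Draw random fixed-length contigs from a (linear) genome.

    Start positions are uniform on ``[0, L - length]`` (0-based, half-open;
    no wraparound).  Replicates are independent and may overlap.  A length
    longer than the genome is skipped with a warning; contig ids encode
    parent, length and replicate as ``<parent>|len<length>|rep<r>``.
    """
    seq = str(genome.seq)
    if set(seq.upper()) - set("ACGTNU"):
        warnings.warn(
            f"genome {genome.id}: non-nucleotide characters present",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out: list[SeqRecord] = []
    for length in lengths:
        if length > len(seq):
            warnings.warn(
                f"genome {genome.id} ({len(seq)} bp) shorter than requested "
                f"contig length {length}; skipped",
                stacklevel=2,
            )
            continue
        for rep in range(replicates):
            start = int(rng.integers(0, len(seq) - length + 1))
            out.append(
                SeqRecord(
                    Seq(seq[start : start + length]),
                    id=f"{genome.id}|len{length}|rep{rep}",
                    description=f"start={start}",
                )
            )
    return out


def emit_blast_like_table(
    lists: Mapping[str, RankedList] | PlantedUniverse,
) -> str:
    """Synthesise a 12-column tabular hit table reproducing ranked lists.

    Labels in rank d receive bit-score ``1000 - 5*(d-1)`` (equal within a
    rank, strictly decreasing across ranks), so parsing the table and
    collapsing with an identity species map recovers the original rank
    orders and ties.  A :class:`PlantedUniverse` emits both its virus and
    host queries in one table.
    """
    if isinstance(lists, PlantedUniverse):
        merged: dict[str, RankedList] = {}
        merged.update(lists.virus_lists)
        merged.update(lists.host_lists)
        lists = merged
    rows: list[str] = []
    for query_id, ranked in lists.items():
        for d, rank in enumerate(ranked.ranks):
            score = 1000.0 - 5.0 * d
            for label in sorted(rank):
                rows.append(
                    "\t".join(
                        (
                            query_id,
                            label,
                            "95.000",
                            "500",
                            "10",
                            "2",
                            "1",
                            "500",
                            "1",
                            "500",
                            "1e-100",
                            f"{score:.1f}",
                        )
                    )
                )
    return "".join(row + "\n" for row in rows)
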