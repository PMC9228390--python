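"""Greedy incremental identity clustering with longest-representative election.

This reproduces the clustering semantics widely used for transcriptome
redundancy removal (CD-HIT-style): sequences are sorted by length, the
longest founds the first cluster, and each subsequent sequence joins an
existing cluster when its identity to the representative reaches the
threshold (default 85%), otherwise it founds a new one. Identity is the
number of identical aligned positions of an end-gap-free global alignment
divided by the length of the *shorter* sequence, so a fragment contained
in a longer isoform counts as fully redundant.

Two modes are provided: ``cluster_self`` (redundancy within one set) and
``cluster_cross`` (2D mode: which queries are already represented in a
subject set), run in both directions and united when symmetric overlap is
wanted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "ClusterConfig",
    "Cluster",
    "ClusterSet",
    "pairwise_identity",
    "cluster_self",
    "cluster_cross",
    "redundancy_rate",
    "clstr_format",
    "cluster_tsv",
]

# lexicographic (score, matches) packing: score*SCALE + matches stays exact
# in int64 for sequences far longer than anything a transcriptome yields
_SCALE = 1 << 20
_GAP = _SCALE  # gap costs score -1, adds no match
_MATCH = _SCALE + 1  # match adds score +1 and one matched position


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering parameters.

    identity_threshold : fraction in (0, 1], default 0.85 — the identity
        cap below which two sequences are considered distinct.
    mode : "self" or "cross".
    assignment : "best" joins the best-scoring qualifying representative
        (deterministic regardless of insertion order); "first" joins the
        first qualifying one in founding order.
    word_filter : when true, a conservative shared-3-mer bound skips
        alignments that cannot reach the threshold; it never changes the
        result, only the work done.
    """

    identity_threshold: float = 0.85
    mode: Literal["self", "cross"] = "self"
    assignment: Literal["best", "first"] = "best"
    word_filter: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)

    @property
    def sources(self) -> set[str]:
        return {m.source for m in self.members if m.source is not None}


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    config: ClusterConfig

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_input(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_count(a: np.ndarray, b: np.ndarray) -> int:
    """Matched positions of the optimal end-gap-free alignment.

    Scoring is match +1, mismatch 0, internal gap -1; the unaligned ends
    of both sequences are free. Among all score-optimal alignments the
    one with the most matched positions is taken (lexicographic DP on
    packed (score, matches) integers), which makes the identity count
    path-independent and deterministic.
    """
    if len(a) > len(b):
        a, b = b, a
    n, m = len(a), len(b)
    jg = _GAP * np.arange(1, m + 1, dtype=np.int64)
    prev = np.zeros(m + 1, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        eq = (b == a[i - 1]).astype(np.int64) * _MATCH
        base = np.maximum(prev[:-1] + eq, prev[1:] - _GAP)
        np.maximum(base, 0, out=base)  # free-start floor
        # left-gap chain: cur[j] = max(base[j], cur[j-1] - GAP), cur[0] = 0
        run = np.maximum.accumulate(base + jg) - jg
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = 0
        cur[1:] = np.maximum(base, run)
        best = max(best, cur.max())
        prev = cur
    return int(best) % _SCALE


def pairwise_identity(a: str, b: str) -> float:
    """Identity fraction between two residue strings.

    Identical aligned positions of the optimal end-gap-free global
    alignment divided by the length of the shorter sequence; symmetric,
    in [0, 1]. Containment of a fragment in a longer sequence scores 1.0.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _match_count(_encode(a.upper()), _encode(b.upper()))
    return matches / min(len(a), len(b))


def _kmer_counter(seq: str, k: int = 3) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _word_filter_pass(
    ka: Counter, kb: Counter, short_len: int, threshold: float, k: int = 3
) -> bool:
    """Conservative bound: can the pair still reach ``threshold`` identity?

    An alignment with d non-matching columns destroys at most k shared
    k-mers of the shorter sequence, so a qualifying pair shares at least
    (short_len - k + 1) - k*d of them (counted with multiplicity).
    """
    if short_len < k + 2:
        return True
    max_diffs = int(np.floor((1.0 - threshold) * short_len)) + 1
    needed = (short_len - k + 1) - k * max_diffs
    if needed <= 0:
        return True
    shared = sum((ka & kb).values())
    return shared >= needed


def _sorted_for_clustering(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # length descending, ties by input order (stable sort)
    return sorted(records, key=lambda r: -len(r))


def cluster_self(records: Sequence[SequenceRecord], config: ClusterConfig | None = None) -> ClusterSet:
    """Greedy incremental clustering of one sequence set.

    Records are processed longest-first (ties in input order); each record
    joins the best-scoring existing representative with identity >= the
    threshold (ties to the earlier-founded cluster), else founds a new
    cluster. Because processing is longest-first, every representative is
    the longest member of its cluster.
    """
    if not records:
        raise ValueError("cluster_self requires at least one record")
    config = config or ClusterConfig()
    clusters: list[Cluster] = []
    kmers: list[Counter] = []
    thr = config.identity_threshold
    for rec in _sorted_for_clustering(records):
        rk = _kmer_counter(rec.seq)
        best_i, best_ident = -1, -1.0
        for i, cl in enumerate(clusters):
            if config.word_filter and not _word_filter_pass(rk, kmers[i], len(rec), thr):
                continue
            ident = pairwise_identity(rec.seq, cl.representative.seq)
            if ident >= thr and ident > best_ident:
                best_i, best_ident = i, ident
                if config.assignment == "first":
                    break
        if best_i >= 0:
            clusters[best_i].members.append(rec)
            clusters[best_i].identities[rec.id] = best_ident
        else:
            clusters.append(Cluster(rec, [rec], {rec.id: 1.0}))
            kmers.append(rk)
    return ClusterSet(clusters, config)


def cluster_cross(
    query_set: Sequence[SequenceRecord],
    subject_set: Sequence[SequenceRecord],
    config: ClusterConfig | None = None,
) -> tuple[list[str], list[str]]:
    """2D clustering: which queries are represented in the subject set.

    A query is matched iff its identity to any subject reaches the
    threshold. Returns (matched_query_ids, unmatched_query_ids) in query
    order. Run twice with the roles swapped and unite the matches to
    obtain the symmetric overlap.
    """
    if not query_set or not subject_set:
        raise ValueError("cluster_cross requires non-empty query and subject sets")
    config = config or ClusterConfig(mode="cross")
    thr = config.identity_threshold
    subj_kmers = [_kmer_counter(s.seq) for s in subject_set]
    matched, unmatched = [], []
    for q in query_set:
        qk = _kmer_counter(q.seq)
        hit = False
        for s, sk in zip(subject_set, subj_kmers):
            if config.word_filter and not _word_filter_pass(
                qk, sk, min(len(q), len(s)), thr
            ):
                continue
            if pairwise_identity(q.seq, s.seq) >= thr:
                hit = True
                break
        (matched if hit else unmatched).append(q.id)
    return matched, unmatched


def redundancy_rate(total: int, nonredundant: int) -> float:
    """Percent of redundant sequences, truncated to two decimals.

    ``100 * (total - nonredundant) / total`` — e.g. 17,706 ORFs reduced
    to 13,244 non-redundant ones is 25.20% redundancy. The value is
    truncated (not rounded) at the second decimal, the convention the
    published redundancy tables this mirrors follow (12.3155% prints as
    12.31); integer arithmetic keeps it exact.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= nonredundant <= total):
        raise ValueError("nonredundant must be in [0, total]")
    return ((total - nonredundant) * 10000 // total) / 100.0


def clstr_format(cs: ClusterSet) -> str:
    """Cluster membership in a CD-HIT-like ``.clstr`` text layout."""
    lines = []
    for i, cl in enumerate(cs.clusters):
        lines.append(f">Cluster {i}")
        for j, m in enumerate(cl.members):
            if m.id == cl.representative.id:
                lines.append(f"{j}\t{len(m)}aa, >{m.id}... *")
            else:
                ident = cl.identities.get(m.id, float("nan"))
                lines.append(f"{j}\t{len(m)}aa, >{m.id}... at {100 * ident:.2f}%")
    return "\n".join(lines) + "\n"


def cluster_tsv(cs: ClusterSet) -> str:
    """Membership as TSV: cluster_id, member_id, representative_flag, identity."""
    lines = ["cluster_id\tmember_id\trepresentative\tidentity"]
    for i, cl in enumerate(cs.clusters):
        for m in cl.members:
            rep = int(m.id == cl.representative.id)
            ident = cl.identities.get(m.id, float("nan"))
            lines.append(f"{i}\t{m.id}\t{rep}\t{ident:.4f}")
    return "\n".join(lines) + "\n"
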