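"""Dual toxin prospection: homology screening and profile-model competition.

Two complementary routes flag ORFs of interest. The homology route runs
exact Smith–Waterman local alignment of every ORF against keyword-tagged
reference toxins and keeps hits whose Karlin–Altschul expectation
E = K·m·n·e^(−λS) falls below a cutoff (default 1e−5); a query inherits
the keywords of every retained target, so per-keyword counts can exceed
the number of distinct queries. The profile route scores each ORF
against position-specific log-odds models built from family seed
alignments and assigns it, winner-take-all, to the best-scoring family —
or to none when no model beats the random-sequence null. The two hit
sets are then combined by inclusion–exclusion, with redundancy removed
from the homology set and previously reported sequences subtracted per
strategy, yielding the final ORFs-of-interest count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .cluster import ClusterConfig, cluster_self
from .seqio import SequenceRecord

__all__ = [
    "KEYWORD_VOCABULARY",
    "ScreenConfig",
    "ReferenceSet",
    "FamilyModel",
    "ScreenHit",
    "ProspectionAccounting",
    "local_align",
    "evalue",
    "homology_screen",
    "alignment_background",
    "build_family_model",
    "compete",
    "combine_strategies",
    "hits_tsv",
    "keyword_counts_tsv",
]

KEYWORD_VOCABULARY = frozenset(
    {
        "antimicrobial",
        "antinociceptive",
        "antiparasitic",
        "antiarrhythmic",
        "cytolytic",
        "hemolytic",
        "hyaluronidase",
        "pro-inflammatory",
        "kinin",
        "lectin",
        "necrotic",
        "neurotoxin",
        "neurotransmitter hydrolysis",
        "presynaptic neurotoxin",
        "protease inhibitor",
        "protease",
    }
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScreenConfig:
    """Homology-screen parameters.

    ``evalue_max`` is the retention cutoff. ``matrix``/``gap_open``/
    ``gap_extend`` define the local-alignment scoring (gap_open charges
    the first gap residue, gap_extend each further one). ``lambda_``/``k``
    are the Karlin–Altschul parameters for the scoring system; the
    defaults are the standard gapped-BLOSUM62 values. Effective search
    lengths m, n default to the actual sequence lengths.
    """

    evalue_max: float = 1e-5
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_max <= 0 or self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("evalue_max, lambda_ and k must be positive")


@dataclass
class ReferenceSet:
    """Keyword-tagged reference toxins for the homology route."""

    records: list[SequenceRecord]
    keyword_map: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        for rid, kws in self.keyword_map.items():
            if rid not in ids:
                raise ValueError(f"keyword map references unknown record {rid!r}")
            unknown = set(kws) - KEYWORD_VOCABULARY
            if unknown:
                raise ValueError(f"unknown keyword(s) for {rid!r}: {sorted(unknown)}")

    @classmethod
    def from_tsv(cls, records: Sequence[SequenceRecord], tsv_text: str) -> "ReferenceSet":
        """Parse an ``id <tab> comma-separated-keywords`` map."""
        kmap: dict[str, frozenset[str]] = {}
        for line in tsv_text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, _, kws = line.partition("\t")
            kmap[rid] = frozenset(k.strip() for k in kws.split(",") if k.strip())
        return cls(list(records), kmap)


@dataclass
class FamilyModel:
    """Position-specific log-odds profile built from a family seed alignment."""

    family_name: str
    log_odds: np.ndarray  # (n_match_columns, 20)
    match_columns: list[int]

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


@dataclass(frozen=True)
class ScreenHit:
    query_id: str
    target: str
    score: float
    strategy: Literal["homology", "profile"]
    evalue: float | None = None
    keywords: frozenset[str] = frozenset()
    family: str | None = None
    query_span: tuple[int, int] | None = None  # aligned span on the query


_aligner_cache: dict[tuple, PairwiseAligner] = {}


def _aligner(config: ScreenConfig) -> PairwiseAligner:
    key = (config.matrix, config.gap_open, config.gap_extend)
    if key not in _aligner_cache:
        al = PairwiseAligner(mode="local")
        al.substitution_matrix = substitution_matrices.load(config.matrix)
        al.open_gap_score = -config.gap_open
        al.extend_gap_score = -config.gap_extend
        _aligner_cache[key] = al
    return _aligner_cache[key]


def local_align(
    query: str, target: str, config: ScreenConfig | None = None
) -> tuple[float, tuple[tuple[int, int], tuple[int, int]] | None]:
    """Optimal Smith–Waterman score and aligned span pair.

    Returns ``(raw_score, ((q_start, q_end), (t_start, t_end)))`` with
    0-based half-open spans, or ``(0.0, None)`` when no positive-scoring
    local alignment exists (the empty alignment is the floor).
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    config = config or ScreenConfig()
    al = _aligner(config)
    score = float(al.score(query, target))
    if score <= 0:
        return 0.0, None
    aln = al.align(query, target)[0]
    qa, ta = aln.aligned[0], aln.aligned[1]
    span = ((int(qa[0][0]), int(qa[-1][1])), (int(ta[0][0]), int(ta[-1][1])))
    return score, span


def evalue(raw_score: float, config: ScreenConfig, m: int, n: int) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space lengths must be positive")
    return config.k * m * n * math.exp(-config.lambda_ * raw_score)


def homology_screen(
    orfs: Sequence[SequenceRecord],
    reference: ReferenceSet,
    config: ScreenConfig | None = None,
) -> tuple[list[ScreenHit], dict[str, int]]:
    """Screen ORFs against a keyword-tagged reference by local alignment.

    A hit is retained iff its expectation is at or below
    ``config.evalue_max``. A query inherits the keywords of all its
    retained targets; per-keyword counts count *queries*, so a query
    related to several activities is counted once under each.
    """
    if not orfs or not reference.records:
        raise ValueError("homology_screen requires non-empty ORF and reference sets")
    config = config or ScreenConfig()
    hits: list[ScreenHit] = []
    kw_queries: dict[str, set[str]] = {}
    for orf in orfs:
        for ref in reference.records:
            score, span = local_align(orf.seq, ref.seq, config)
            if score <= 0:
                continue
            e = evalue(score, config, len(orf), len(ref))
            if e <= config.evalue_max:
                kws = reference.keyword_map.get(ref.id, frozenset())
                hits.append(
                    ScreenHit(orf.id, ref.id, score, "homology", evalue=e,
                              keywords=kws, query_span=span[0])
                )
                for kw in kws:
                    kw_queries.setdefault(kw, set()).add(orf.id)
    counts = {kw: len(qs) for kw, qs in sorted(kw_queries.items())}
    return hits, counts


def alignment_background(alignments: Sequence[Sequence[SequenceRecord]]) -> dict[str, float]:
    """Smoothed residue composition of one or more (seed) alignments.

    Pooling every family's seed gives a database-wide background, the
    analogue of the composition BLAST-style statistics assume.
    """
    counts = Counter()
    for aln in alignments:
        for rec in aln:
            counts.update(ch for ch in rec.seq.upper() if ch in AMINO_ACIDS)
    total = sum(counts.values())
    return {aa: (counts[aa] + 1.0) / (total + 20.0) for aa in AMINO_ACIDS}


def build_family_model(
    seed_alignment: Sequence[SequenceRecord],
    family_name: str,
    *,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.25,
) -> FamilyModel:
    """Position-specific log-odds profile from an aligned FASTA.

    Columns where gaps hold the majority are dropped from the match
    states. Per kept column, residue probabilities use
    background-proportional (Dirichlet) pseudocounts with total prior
    mass ``20 * pseudocount`` — under a uniform background this reduces
    to plain +``pseudocount`` additive smoothing. The default prior
    mass (5, from pseudocount 0.25) stays comparable to a small seed,
    so observed columns dominate the prior. Scores are natural-log
    odds against ``background``. The default background is
    the seed's own smoothed composition (see
    :func:`alignment_background`), which keeps composition-matched but
    unrelated sequences at or below the null; pass an explicit table
    (e.g. uniform) to override. Sequence order in the seed does not
    affect the model.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least two sequences")
    ncol = len(seed_alignment[0].seq)
    for rec in seed_alignment:
        if len(rec.seq) != ncol:
            raise ValueError(f"ragged alignment: {rec.id!r} has length {len(rec.seq)} != {ncol}")
    if background is None:
        background = alignment_background([seed_alignment])
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    bg = np.array([background[aa] for aa in AMINO_ACIDS])
    nseq = len(seed_alignment)
    match_cols: list[int] = []
    rows: list[np.ndarray] = []
    for c in range(ncol):
        column = [rec.seq[c].upper() for rec in seed_alignment]
        gaps = sum(1 for ch in column if ch in "-.")
        if gaps * 2 > nseq:
            continue
        counts = 20.0 * pseudocount * bg.copy()
        for ch in column:
            if ch in aa_index:
                counts[aa_index[ch]] += 1.0
        probs = counts / counts.sum()
        rows.append(np.log(probs / bg))
        match_cols.append(c)
    if not rows:
        raise ValueError("alignment has no match columns")
    return FamilyModel(family_name, np.vstack(rows), match_cols)


def _profile_score(seq: str, model: FamilyModel) -> float:
    """Best ungapped placement of the model's match columns along ``seq``."""
    idx = np.array([AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else -1 for ch in seq.upper()])
    L, W = len(idx), model.length
    if L < W:
        return -math.inf
    # unknown residues score the background (log-odds 0)
    padded = np.hstack([model.log_odds, np.zeros((W, 1))])
    best = -math.inf
    for start in range(L - W + 1):
        window = idx[start : start + W]
        s = float(padded[np.arange(W), window].sum())
        if s > best:
            best = s
    return best


def compete(
    seq: str | SequenceRecord, models: Sequence[FamilyModel]
) -> tuple[str | None, float]:
    """Winner-take-all family assignment.

    Scores every model by its best ungapped placement along the
    sequence and returns ``(family_name, score)`` for the argmax, or
    ``(None, best_score)`` when no model scores above 0 (the null).
    Ties go to the lexicographically first family name.
    """
    if not models:
        raise ValueError("compete requires at least one model")
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    best_name, best_score = None, -math.inf
    for model in sorted(models, key=lambda m: m.family_name):
        sc = _profile_score(s, model)
        if sc > best_score:
            best_name, best_score = model.family_name, sc
    if best_score <= 0:
        return None, best_score
    return best_name, best_score


def profile_screen(
    orfs: Sequence[SequenceRecord], models: Sequence[FamilyModel]
) -> tuple[list[ScreenHit], dict[str, int]]:
    """Assign each ORF to its winning family; count queries per family."""
    hits: list[ScreenHit] = []
    fam_counts: Counter = Counter()
    for orf in orfs:
        family, score = compete(orf.seq, models)
        if family is not None:
            hits.append(ScreenHit(orf.id, family, score, "profile", family=family))
            fam_counts[family] += 1
    return hits, dict(sorted(fam_counts.items()))


@dataclass
class ProspectionAccounting:
    """Inclusion–exclusion bookkeeping for the combined screening routes."""

    homology_total: int
    homology_redundant: int
    profile_total: int
    overlap: int
    previously_reported_homology: int
    previously_reported_profile: int
    warnings: list[str] = field(default_factory=list)
    final_ids: list[str] | None = None

    @property
    def homology_nonredundant(self) -> int:
        return self.homology_total - self.homology_redundant

    @property
    def final_count(self) -> int:
        return (
            self.homology_nonredundant
            + self.profile_total
            - self.overlap
            - self.previously_reported_homology
            - self.previously_reported_profile
        )


def combine_strategies(
    homology_hits: Sequence[ScreenHit],
    profile_hits: Sequence[ScreenHit],
    orf_seqs: Mapping[str, str] | None = None,
    cluster_config: ClusterConfig | None = None,
    previously_reported_homology: Sequence[str] | int = (),
    previously_reported_profile: Sequence[str] | int = (),
) -> ProspectionAccounting:
    """Combine the homology and profile routes into a final count.

    Homology queries are deduplicated by redundancy clustering of their
    sequences (when ``orf_seqs`` is given; otherwise ids are taken as
    already non-redundant); the overlap is the set of profile queries
    falling in a homology cluster; previously reported sequences are
    subtracted per strategy. Previously reported ids absent from the
    hits raise a warning entry, not an error. Counts at every step are
    retained on the returned accounting object.
    """
    warnings: list[str] = []
    hom_ids = sorted({h.query_id for h in homology_hits})
    prof_ids = sorted({h.query_id for h in profile_hits})
    if orf_seqs is not None and hom_ids:
        config = cluster_config or ClusterConfig()
        recs = [SequenceRecord(i, orf_seqs[i]) for i in hom_ids]
        cs = cluster_self(recs, config)
        member_to_rep = {
            m.id: cl.representative.id for cl in cs.clusters for m in cl.members
        }
        nr_hom = sorted({member_to_rep[i] for i in hom_ids})
        overlap_ids = sorted(
            {member_to_rep.get(p, p) for p in prof_ids if p in member_to_rep}
        )
    else:
        nr_hom = hom_ids
        overlap_ids = sorted(set(hom_ids) & set(prof_ids))

    def _prev(prev: Sequence[str] | int, pool: set[str], label: str) -> int:
        if isinstance(prev, int):
            return prev
        missing = [p for p in prev if p not in pool]
        if missing:
            warnings.append(f"previously reported {label} ids absent from hits: {missing}")
        return len(set(prev))

    n_prev_hom = _prev(previously_reported_homology, set(hom_ids), "homology")
    n_prev_prof = _prev(previously_reported_profile, set(prof_ids), "profile")

    final_ids: list[str] | None = None
    if not isinstance(previously_reported_homology, int) and not isinstance(
        previously_reported_profile, int
    ):
        prev_all = set(previously_reported_homology) | set(previously_reported_profile)
        final_ids = sorted((set(nr_hom) | set(prof_ids)) - prev_all)

    return ProspectionAccounting(
        homology_total=len(hom_ids),
        homology_redundant=len(hom_ids) - len(nr_hom),
        profile_total=len(prof_ids),
        overlap=len(overlap_ids),
        previously_reported_homology=n_prev_hom,
        previously_reported_profile=n_prev_prof,
        warnings=warnings,
        final_ids=final_ids,
    )


def hits_tsv(hits: Sequence[ScreenHit]) -> str:
    """Hits as TSV: query, target, strategy, score, evalue, query span, keywords/family."""
    lines = ["query\ttarget\tstrategy\tscore\tevalue\tqstart\tqend\tkeywords_or_family"]
    for h in hits:
        tag = h.family if h.strategy == "profile" else ",".join(sorted(h.keywords))
        ev = "" if h.evalue is None else f"{h.evalue:.3g}"
        qs, qe = h.query_span if h.query_span else ("", "")
        lines.append(
            f"{h.query_id}\t{h.target}\t{h.strategy}\t{h.score:.1f}\t{ev}\t{qs}\t{qe}\t{tag}"
        )
    return "\n".join(lines) + "\n"


def keyword_counts_tsv(counts: Mapping[str, int], header: str = "Associated Keyword") -> str:
    lines = [f"{header}\tCount"]
    for k, v in counts.items():
        lines.append(f"{k}\t{v}")
    lines.append(f"Total\t{sum(counts.values())}")
    return "\n".join(lines) + "\n"
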