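"""Ground-truth generator: toxin precursors, pseudo-assemblies, references.

Every pipeline stage is testable without downloads because this module
fabricates the inputs with known answers: (a) toxin precursors built as
rule-compliant signal peptide + pro-peptide ending in a di-basic or PQM
cleavage site + C-terminal mature region carrying a planted
six-cysteine PSM scaffold; (b) per-assembler "views" of the precursor
set with controlled common / pairwise-shared / unique fractions,
point-mutation divergence and within-assembler redundant duplicates,
emulating what three independent de novo assemblers recover from one
transcriptome; and (c) family-structured reference sets with seed
alignments and keyword tags, standing in for curated toxin databases.
Families have a founder mature sequence from which member matures and
reference homologs diverge by point mutation, so both screening routes
have real signal to recover. All randomness flows from one integer
seed; mutations never touch planted cysteine anchors or cleavage-site
residues unless corruption is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .maturation import DIBASIC_PAIRS
from .screen import AMINO_ACIDS, KEYWORD_VOCABULARY, ReferenceSet
from .seqio import SequenceRecord

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_precursors",
    "generate_assembly_views",
    "generate_reference_set",
    "shuffled_decoys",
    "truth_tsv",
]

_HYDROPHOBIC = "LVIF"
# spacer residues avoid C (keeps the planted framework exactly six
# cysteines) and K/R/E (keeps the mature region free of spurious
# di-basic or PQM cleavage sites, so planted boundaries stay exact)
_SPACER_ALPHABET = "".join(aa for aa in AMINO_ACIDS if aa not in "CKRE")
_PSM_GAPS = ((4, 6), (4, 9), (2, 10), (3, 14))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults emulate a small venom-gland prospection: 200 precursors in
    8 toxin families, signal peptides of 15–25 residues, pro-peptides
    of 10–30, mature regions of 40–80 with a planted PSM in every
    toxin family, three assembler views with a 40/30/30%
    common/pairwise/unique split, 2% point divergence between views and
    10% added within-assembler redundancy.
    """

    seed: int = 0
    n_precursors: int = 200
    signal_length: tuple[int, int] = (15, 25)
    propeptide_length: tuple[int, int] = (10, 30)
    mature_length: tuple[int, int] = (40, 80)
    psm_fraction: float = 1.0
    mutation_rate: float = 0.02
    assembly_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    redundancy_fraction: float = 0.1
    n_families: int = 8
    reference_per_family: int = 5
    family_mutation_rate: float = 0.05
    sources: tuple[str, ...] = ("asm1", "asm2", "asm3")

    def __post_init__(self) -> None:
        for lo, hi in (self.signal_length, self.propeptide_length, self.mature_length):
            if lo > hi or lo < 1:
                raise ValueError(f"infeasible length range ({lo},{hi})")
        if self.signal_length[0] < 12:
            raise ValueError("signal peptides shorter than 12 residues break the rule grammar")
        if self.mature_length[0] < 25:
            raise ValueError("mature regions need >= 25 residues to host a PSM")
        fr = self.assembly_fractions
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("assembly_fractions must be non-negative and sum to 1")
        for frac in (self.psm_fraction, self.mutation_rate, self.redundancy_fraction,
                     self.family_mutation_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_families < 1 or self.n_precursors < 1:
            raise ValueError("need at least one family and one precursor")


@dataclass
class TruthRecord:
    """Ground truth for one precursor."""

    id: str
    signal_cleavage_after: int  # 0-based index of the last signal residue
    cleavage_position: int  # first mature residue (precursor coordinates)
    mature_span: tuple[int, int]
    mature_seq: str
    family: str
    has_psm: bool
    psm_anchors: tuple[int, ...] | None  # precursor coordinates
    protected: frozenset[int]  # precursor indices mutations must not touch
    bucket: str | None = None  # common / pair:<a>+<b> / unique:<src>


def _choice(rng: np.random.Generator, alphabet: str, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _make_signal(rng: np.random.Generator, length: int) -> str:
    """Signal whose earliest rule-valid cleavage is its own end.

    M + hydrophobic core + A + hydrophobic + A: the -1/-3 residues are
    small, every earlier candidate fails the small-residue test, and the
    core provides the required hydrophobic run.
    """
    core = _choice(rng, _HYDROPHOBIC, length - 4)
    mid = _HYDROPHOBIC[int(rng.integers(0, 4))]
    return "M" + core + "A" + mid + "A"


def _make_founder_mature(
    rng: np.random.Generator, length: int, with_psm: bool
) -> tuple[str, tuple[int, ...] | None]:
    """A mature region, optionally carrying a PSM at returned anchor indices."""
    if not with_psm:
        return _choice(rng, _SPACER_ALPHABET, length), None
    pad = int(rng.integers(0, 3))
    budget = length - pad - 6 - 1  # residues available for the four gaps
    mins = [lo for lo, _ in _PSM_GAPS]
    gaps: list[int] = []
    for gi, (lo, hi) in enumerate(_PSM_GAPS):
        rest = sum(mins[gi + 1 :])
        hi_eff = min(hi, budget - rest)
        gaps.append(int(rng.integers(lo, hi_eff + 1)))
        budget -= gaps[-1]
    pieces: list[str] = [_choice(rng, _SPACER_ALPHABET, pad)]
    anchors: list[int] = []
    pos = pad
    for gap in (gaps[0], gaps[1], 0, gaps[2], gaps[3], None):
        anchors.append(pos)
        pieces.append("C")
        pos += 1
        if gap is None:
            break
        pieces.append(_choice(rng, _SPACER_ALPHABET, gap))
        pos += gap
    tail = length - pos
    pieces.append(_choice(rng, _SPACER_ALPHABET, tail))
    return "".join(pieces), tuple(anchors)


def _make_propeptide(rng: np.random.Generator, length: int) -> tuple[str, frozenset[int]]:
    """Pro-peptide ending in a di-basic pair or a PQM (E-x-x-R) site.

    Returns the sequence and the local indices of the cleavage-motif
    residues that mutations must not touch.
    """
    if rng.random() < 0.5 and length >= 2:
        body = _choice(rng, _SPACER_ALPHABET, length - 2)
        pair = sorted(DIBASIC_PAIRS)[int(rng.integers(0, len(DIBASIC_PAIRS)))]
        return body + pair, frozenset({length - 2, length - 1})
    body = _choice(rng, _SPACER_ALPHABET, max(0, length - 4))
    mid = _choice(rng, _SPACER_ALPHABET, 2)
    return body + "E" + mid + "R", frozenset({length - 4, length - 1})


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: frozenset[int] = frozenset(),
    alphabet: str = AMINO_ACIDS,
) -> str:
    """Point-mutate ``seq`` at ``rate`` per residue, sparing protected sites."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        choices = [aa for aa in alphabet if aa != out[i]]
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def generate_precursors(
    config: GeneratorConfig,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate toxin precursors with full coordinate-level ground truth.

    Precursors are grouped into families; the first member of a family
    founds its mature sequence and later members carry point-diverged
    copies (anchors and cleavage motifs untouched), so family structure
    is real. Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    founders: dict[str, tuple[str, tuple[int, ...] | None]] = {}
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_precursors):
        family = f"FAM{i % config.n_families}"
        if family not in founders:
            has_psm = rng.random() < config.psm_fraction
            length = int(rng.integers(config.mature_length[0], config.mature_length[1] + 1))
            founders[family] = _make_founder_mature(rng, length, has_psm)
        founder_seq, founder_anchors = founders[family]
        protected_local = frozenset(founder_anchors or ())
        mature = (
            founder_seq
            if len([t for t in truths if t.family == family]) == 0
            else _mutate(rng, founder_seq, config.family_mutation_rate,
                         protected_local, _SPACER_ALPHABET)
        )
        sig_len = int(rng.integers(config.signal_length[0], config.signal_length[1] + 1))
        pro_len = int(rng.integers(config.propeptide_length[0], config.propeptide_length[1] + 1))
        signal = _make_signal(rng, sig_len)
        pro, pro_protect = _make_propeptide(rng, pro_len)
        protein = signal + pro + mature
        m_start = sig_len + pro_len
        protected = (
            {0, sig_len - 1, sig_len - 3}
            | {sig_len + j for j in pro_protect}
            | {m_start + a for a in (founder_anchors or ())}
        )
        pid = f"tox{i:04d}"
        records.append(SequenceRecord(pid, protein))
        truths.append(
            TruthRecord(
                id=pid,
                signal_cleavage_after=sig_len - 1,
                cleavage_position=m_start,
                mature_span=(m_start, len(protein)),
                mature_seq=mature,
                family=family,
                has_psm=founder_anchors is not None,
                psm_anchors=tuple(m_start + a for a in founder_anchors) if founder_anchors else None,
                protected=frozenset(protected),
            )
        )
    return records, truths


def generate_assembly_views(
    records: Sequence[SequenceRecord],
    truths: Sequence[TruthRecord],
    config: GeneratorConfig,
) -> tuple[dict[str, list[SequenceRecord]], list[TruthRecord]]:
    """Per-assembler views with planted common/pairwise/unique structure.

    Each precursor is assigned a bucket by ``assembly_fractions``:
    common precursors appear (point-mutated) in every source, pairwise
    ones in a random pair, unique ones in a single source.
    ``redundancy_fraction`` then adds truncated, mutated duplicates
    within each source. View record ids are ``<source>|<precursor id>``.
    Returns the views and bucket-annotated copies of the truths.
    """
    if not records:
        raise ValueError("generate_assembly_views requires at least one record")
    rng = np.random.default_rng(config.seed + 1)
    sources = list(config.sources)
    n = len(records)
    order = rng.permutation(n)
    n_common = int(round(config.assembly_fractions[0] * n))
    n_pair = int(round(config.assembly_fractions[1] * n))
    buckets: dict[int, tuple[str, list[str]]] = {}
    for rank, idx in enumerate(order):
        if rank < n_common:
            buckets[idx] = ("common", sources)
        elif rank < n_common + n_pair:
            pair = sorted(rng.choice(len(sources), size=2, replace=False))
            chosen = [sources[pair[0]], sources[pair[1]]]
            buckets[idx] = (f"pair:{'+'.join(chosen)}", chosen)
        else:
            src = sources[int(rng.integers(0, len(sources)))]
            buckets[idx] = (f"unique:{src}", [src])
    views: dict[str, list[SequenceRecord]] = {s: [] for s in sources}
    truth_by_id = {t.id: t for t in truths}
    out_truths: list[TruthRecord] = []
    for i, rec in enumerate(records):
        label, targets = buckets[i]
        t = truth_by_id[rec.id]
        out_truths.append(
            TruthRecord(**{**t.__dict__, "bucket": label})
        )
        for src in targets:
            seq = _mutate(rng, rec.seq, config.mutation_rate, t.protected)
            views[src].append(SequenceRecord(f"{src}|{rec.id}", seq, source=src))
    for src in sources:
        base = list(views[src])
        n_dup = int(round(config.redundancy_fraction * len(base)))
        for k in range(n_dup):
            parent = base[int(rng.integers(0, len(base)))]
            keep = int(np.ceil(len(parent.seq) * rng.uniform(0.6, 0.9)))
            seq = _mutate(rng, parent.seq[:keep], config.mutation_rate)
            views[src].append(SequenceRecord(f"{parent.id}__dup{k}", seq, source=src))
    return views, out_truths


def generate_reference_set(
    truths: Sequence[TruthRecord], config: GeneratorConfig
) -> tuple[ReferenceSet, dict[str, list[SequenceRecord]]]:
    """Keyword-tagged reference homologs plus per-family seed alignments.

    Per family, ``reference_per_family`` point-diverged copies of the
    family founder's mature sequence (equal length, so the set is
    trivially aligned and serves directly as the seed alignment). Each
    family is tagged with one or two keywords from the fixed activity
    vocabulary.
    """
    rng = np.random.default_rng(config.seed + 2)
    families: dict[str, TruthRecord] = {}
    for t in truths:
        families.setdefault(t.family, t)  # first member carries the founder mature
    vocab = sorted(KEYWORD_VOCABULARY)
    ref_records: list[SequenceRecord] = []
    keyword_map: dict[str, frozenset[str]] = {}
    alignments: dict[str, list[SequenceRecord]] = {}
    for family in sorted(families):
        founder = families[family]
        protected_local = frozenset(
            a - founder.mature_span[0] for a in (founder.psm_anchors or ())
        )
        n_kw = 1 + int(rng.integers(0, 2))
        kws = frozenset(
            vocab[int(i)] for i in rng.choice(len(vocab), size=n_kw, replace=False)
        )
        members: list[SequenceRecord] = []
        for j in range(config.reference_per_family):
            seq = _mutate(
                rng, founder.mature_seq, config.family_mutation_rate,
                protected_local, _SPACER_ALPHABET,
            )
            rid = f"{family}_ref{j}"
            members.append(SequenceRecord(rid, seq, source=family))
            keyword_map[rid] = kws
        ref_records.extend(members)
        alignments[family] = members
    return ReferenceSet(ref_records, keyword_map), alignments


def shuffled_decoys(
    records: Sequence[SequenceRecord], seed: int = 0
) -> list[SequenceRecord]:
    """Residue-shuffled copies of ``records`` — an empirical null set."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        chars = np.array(list(rec.seq))
        rng.shuffle(chars)
        out.append(SequenceRecord(f"decoy|{rec.id}", "".join(chars)))
    return out


def truth_tsv(truths: Sequence[TruthRecord]) -> str:
    lines = [
        "id\tsignal_cleavage_after\tcleavage_position\tmature_start\tmature_end"
        "\tfamily\thas_psm\tbucket"
    ]
    for t in truths:
        lines.append(
            f"{t.id}\t{t.signal_cleavage_after}\t{t.cleavage_position}"
            f"\t{t.mature_span[0]}\t{t.mature_span[1]}\t{t.family}"
            f"\t{int(t.has_psm)}\t{t.bucket or ''}"
        )
    return "\n".join(lines) + "\n"
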