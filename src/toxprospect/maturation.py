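"""Mature-toxin resolution: signal peptide, pro-peptide cleavage, naming.

Spider-toxin precursors carry an N-terminal secretion signal, a
pro-peptide of variable length, and a C-terminal cysteine-rich mature
region. Maturation proceeds stepwise: (i) detect the signal peptide
(rule-based, or imported from an external predictor); (ii) strip it;
(iii) predict pro-peptide cleavage sites — classical di-basic pairs
(KR/RR/KK/RK) and the processing quadruplet motif (an arginine with a
glutamate among the three preceding residues); (iv–vi) take the mature
span as the homolog-supported region bounded by cleavage sites;
(vii) classify each precursor by signal/pro-peptide presence; and
(viii) count cysteines on the mature peptide. Mature peptides are
finally clustered into paralog groups and given rational names
(activity prefix + "theraphotoxin" + species code + group index +
paralog letter, e.g. U-theraphotoxin-Pv5a).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .cluster import ClusterConfig, cluster_self
from .motifs import CysteineFramework, cysteine_framework
from .seqio import SequenceRecord

__all__ = [
    "SignalPrediction",
    "CleavageSite",
    "ToxinPrecursor",
    "MatureToxin",
    "predict_signal",
    "parse_signal_tsv",
    "predict_prosites",
    "select_homolog_span",
    "resolve_mature",
    "classify_categories",
    "assign_names",
    "mature_report_tsv",
]

# Kyte–Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SMALL_RESIDUES = frozenset("AGSCT")  # allowed at the -1/-3 signal positions
DIBASIC_PAIRS = frozenset({"KR", "RR", "KK", "RK"})

MIN_SIGNAL_LEN = 12
MAX_SIGNAL_LEN = 45
HYDROPHOBIC_RUN_MIN = 6
HYDROPHOBIC_MEAN_MIN = 1.6


@dataclass(frozen=True)
class SignalPrediction:
    present: bool
    cleavage_after: int | None = None  # 0-based index of the last signal residue
    method: Literal["rule", "imported"] = "rule"


@dataclass(frozen=True)
class CleavageSite:
    position: int  # 0-based index of the first mature-side residue
    motif: Literal["dibasic", "PQM"]


@dataclass
class ToxinPrecursor:
    id: str
    protein: str
    signal: SignalPrediction
    prosites: list[CleavageSite] = field(default_factory=list)
    homolog_span: tuple[int, int] | None = None


@dataclass
class MatureToxin:
    precursor_id: str
    mature_seq: str | None
    mature_span: tuple[int, int] | None
    category: Literal["both", "signal_only", "propeptide_only", "neither"]
    framework: CysteineFramework | None
    name: str | None = None
    warnings: list[str] = field(default_factory=list)


def _has_hydrophobic_run(seq: str) -> bool:
    """Uninterrupted hydrophobic stretch within the signal candidate region.

    Looks for a run of >= 6 residues, each with Kyte–Doolittle value
    >= 1.6, starting within positions 2–30 (1-based) of the sequence.
    """
    window = seq[1:30]
    run = 0
    for ch in window:
        if _KD.get(ch, -4.5) >= HYDROPHOBIC_MEAN_MIN:
            run += 1
            if run >= HYDROPHOBIC_RUN_MIN:
                return True
        else:
            run = 0
    return False


def predict_signal(
    seq: str,
    imported: Mapping[str, int | None] | None = None,
    record_id: str | None = None,
) -> SignalPrediction:
    """Rule-based signal-peptide call, overridden by imported predictions.

    Rule mode requires a leading Met, a hydrophobic core (an
    uninterrupted run of >= 6 residues with Kyte–Doolittle >= 1.6 within
    the first 30 positions), and picks the shortest signal length in
    [12, 45) whose -1 and -3 residues are small (A/G/S/C/T). When
    ``imported`` supplies an entry for ``record_id``, that prediction
    (an index of the last signal residue, or ``None`` for absent) takes
    precedence over the rule.
    """
    if imported is not None and record_id is not None and record_id in imported:
        site = imported[record_id]
        if site is None:
            return SignalPrediction(False, method="imported")
        if not (10 <= site < MAX_SIGNAL_LEN) or site >= len(seq) - 1:
            raise ValueError(
                f"imported signal cleavage for {record_id!r} out of range: {site}"
            )
        return SignalPrediction(True, site, method="imported")
    seq = seq.upper()
    if len(seq) < 15 or not seq.startswith("M"):
        return SignalPrediction(False)
    if not _has_hydrophobic_run(seq):
        return SignalPrediction(False)
    for n in range(MIN_SIGNAL_LEN, min(MAX_SIGNAL_LEN, len(seq) - 1)):
        if seq[n - 1] in SMALL_RESIDUES and seq[n - 3] in SMALL_RESIDUES:
            return SignalPrediction(True, n - 1)
    return SignalPrediction(False)


def parse_signal_tsv(text: str) -> dict[str, int | None]:
    """Parse imported predictions: ``id <tab> cleavage_after`` (or ``-``)."""
    out: dict[str, int | None] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        rid, _, val = line.partition("\t")
        out[rid] = None if val.strip() in {"-", "NA", ""} else int(val)
    return out


def predict_prosites(seq_after_signal: str, offset: int = 0) -> list[CleavageSite]:
    """Pro-peptide cleavage sites in a signal-stripped sequence.

    Di-basic: cleavage immediately after any KR/RR/KK/RK pair. PQM
    (processing quadruplet motif): cleavage immediately after an R whose
    three preceding residues include at least one E. Duplicate positions
    merge (di-basic label wins); sites return in ascending order,
    shifted by ``offset`` into precursor coordinates.
    """
    if not seq_after_signal:
        raise ValueError("predict_prosites requires a non-empty sequence")
    s = seq_after_signal.upper()
    sites: dict[int, str] = {}
    for i in range(1, len(s)):
        if s[i - 1 : i + 1] in DIBASIC_PAIRS:
            sites[i + 1] = "dibasic"
    for i, ch in enumerate(s):
        if ch == "R" and i >= 1 and "E" in s[max(0, i - 3) : i]:
            sites.setdefault(i + 1, "PQM")
    return [
        CleavageSite(pos + offset, motif)  # type: ignore[arg-type]
        for pos, motif in sorted(sites.items())
        if pos + offset < len(s) + offset  # cleavage must leave a mature side
    ]


def select_homolog_span(hits: Sequence) -> tuple[int, int] | None:
    """The query span of the best screen hit for one precursor.

    Among hits carrying a ``query_span``, the highest-scoring one wins;
    ties go to the longest span. Returns ``None`` when no hit has a
    span (profile hits, or no hits at all).
    """
    spanned = [h for h in hits if getattr(h, "query_span", None) is not None]
    if not spanned:
        return None
    best = max(spanned, key=lambda h: (h.score, h.query_span[1] - h.query_span[0]))
    return tuple(best.query_span)


def _category(signal_present: bool, has_prosites: bool) -> str:
    if signal_present and has_prosites:
        return "both"
    if signal_present:
        return "signal_only"
    if has_prosites:
        return "propeptide_only"
    return "neither"


def resolve_mature(precursor: ToxinPrecursor) -> MatureToxin:
    """Resolve the mature span of a precursor from its homolog support.

    The signal region (when present) is stripped first. The mature start
    is the greatest cleavage position at or before the homolog span
    start — the signal cleavage itself qualifies; the mature end is the
    smallest cleavage position at or after the homolog span end, else
    the C-terminus. A mature peptide is reported only when the
    N-terminal bound is an actual cleavage or signal site; otherwise the
    record carries its category but no mature sequence. Cysteines are
    counted on the mature peptide.
    """
    seq = precursor.protein
    warnings: list[str] = []
    sig = precursor.signal
    mature_floor = sig.cleavage_after + 1 if sig.present and sig.cleavage_after is not None else 0
    prosites = [s for s in precursor.prosites if s.position > mature_floor]
    category = _category(sig.present, bool(prosites))

    if precursor.homolog_span is None:
        return MatureToxin(precursor.id, None, None, category, None, warnings=warnings)

    h_start, h_end = precursor.homolog_span
    if h_start < mature_floor:
        warnings.append(
            f"homolog span start {h_start} overlaps the signal region; clipped to {mature_floor}"
        )
        h_start = mature_floor
    h_end = min(h_end, len(seq))

    bounds = sorted({s.position for s in prosites} | ({mature_floor} if sig.present else set()))
    starts = [b for b in bounds if b <= h_start]
    if not starts:
        return MatureToxin(precursor.id, None, None, category, None, warnings=warnings)
    m_start = max(starts)
    ends = [s.position for s in prosites if s.position >= h_end]
    m_end = min(ends) if ends else len(seq)
    mature = seq[m_start:m_end]
    framework = cysteine_framework(mature) if mature else None
    return MatureToxin(
        precursor.id, mature or None, (m_start, m_end) if mature else None,
        category, framework, warnings=warnings,
    )


def classify_categories(records: Sequence[MatureToxin]) -> tuple[dict[str, int], dict[str, int]]:
    """Four-way category tally and whole-number percentages."""
    counts = {"both": 0, "signal_only": 0, "propeptide_only": 0, "neither": 0}
    for rec in records:
        counts[rec.category] += 1
    total = len(records)
    percents = {k: (round(100.0 * v / total) if total else 0) for k, v in counts.items()}
    return counts, percents


def _letters(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, 27 -> ab, ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def assign_names(
    mature_records: Sequence[MatureToxin],
    species_code: str = "Pv",
    start_index: int = 5,
    paralog_threshold: float = 0.85,
    activity_prefix: str = "U",
) -> list[MatureToxin]:
    """Rational nomenclature over paralog clusters of mature peptides.

    Mature sequences are clustered at ``paralog_threshold``; each
    cluster gets one index (numbered from ``start_index`` in order of
    first appearance in the input) and its members get letters a, b,
    c, ... (aa, ab, ... past z) in input order. Records without a mature
    sequence pass through unnamed. Deterministic for a fixed input order.
    """
    with_mature = [r for r in mature_records if r.mature_seq]
    if not with_mature:
        return list(mature_records)
    recs = [SequenceRecord(r.precursor_id, r.mature_seq) for r in with_mature]
    cs = cluster_self(recs, ClusterConfig(identity_threshold=paralog_threshold))
    member_to_cluster: dict[str, int] = {}
    for ci, cl in enumerate(cs.clusters):
        for m in cl.members:
            member_to_cluster[m.id] = ci
    # number clusters by first appearance in input order
    cluster_index: dict[int, int] = {}
    member_rank: dict[str, int] = {}
    counters: dict[int, int] = {}
    named: list[MatureToxin] = []
    for rec in mature_records:
        if not rec.mature_seq:
            named.append(rec)
            continue
        ci = member_to_cluster[rec.precursor_id]
        if ci not in cluster_index:
            cluster_index[ci] = start_index + len(cluster_index)
            counters[ci] = 0
        name = (
            f"{activity_prefix}-theraphotoxin-{species_code}"
            f"{cluster_index[ci]}{_letters(counters[ci])}"
        )
        counters[ci] += 1
        named.append(
            MatureToxin(
                rec.precursor_id, rec.mature_seq, rec.mature_span, rec.category,
                rec.framework, name=name, warnings=rec.warnings,
            )
        )
    return named


def mature_report_tsv(records: Sequence[MatureToxin], precursors: Mapping[str, ToxinPrecursor] | None = None) -> str:
    """Per-precursor TSV: category, sites, mature span/sequence, cysteines, name."""
    lines = [
        "id\tcategory\tsignal_cleavage_after\tcleavage_sites\tmature_start\tmature_end"
        "\tmature_seq\tn_cys\todd\tname"
    ]
    for rec in records:
        pre = precursors.get(rec.precursor_id) if precursors else None
        sig = ""
        sites = ""
        if pre is not None:
            sig = "" if pre.signal.cleavage_after is None else str(pre.signal.cleavage_after)
            sites = ";".join(f"{s.position}:{s.motif}" for s in pre.prosites)
        span = rec.mature_span or ("", "")
        fw = rec.framework
        lines.append(
            f"{rec.precursor_id}\t{rec.category}\t{sig}\t{sites}\t{span[0]}\t{span[1]}"
            f"\t{rec.mature_seq or ''}\t{fw.count if fw else ''}"
            f"\t{int(fw.odd) if fw else ''}\t{rec.name or ''}"
        )
    return "\n".join(lines) + "\n"
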