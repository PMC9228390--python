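"""Cysteine-framework analysis and the knottin (ICK) scaffold grammar.

Disulfide-bridged spider-venom peptides are built on the inhibitor
cystine knot: six core cysteines whose spacing follows the primary
structural motif (PSM), C1-X(4,6)-C2-X(4,9)-C3-C4-X(2,10)-C5-X(3,14)-
C6-X(1,16), optionally followed downstream by the extra structural
motif (ESM), C-X-C. PSM presence alone is taken as sufficient evidence
that a peptide can adopt the ion-channel-binding scaffold; the ESM is
recorded separately. Spacers (X) may contain further cysteines — only
the anchor positions are constrained — so frameworks with more than six
cysteines still match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "CysteineFramework",
    "MotifPattern",
    "MotifMatch",
    "PSM",
    "ESM",
    "cysteine_framework",
    "scan_motif",
    "classify_ick",
    "motif_report_tsv",
]


@dataclass(frozen=True)
class CysteineFramework:
    count: int
    positions: tuple[int, ...]
    odd: bool


@dataclass(frozen=True)
class MotifPattern:
    """Alternating fixed-cysteine / bounded-spacer pattern.

    ``spacers`` holds (lo, hi) residue-count bounds between consecutive
    anchor cysteines; ``trailing`` bounds the residues required after the
    last anchor (the PSM demands at least one).
    """

    name: str
    spacers: tuple[tuple[int, int], ...]
    trailing: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.spacers:
            if lo > hi or lo < 0:
                raise ValueError(f"invalid spacer bounds ({lo},{hi}) in {self.name}")
        if self.trailing and (self.trailing[0] > self.trailing[1] or self.trailing[0] < 0):
            raise ValueError(f"invalid trailing bounds in {self.name}")

    @property
    def n_anchors(self) -> int:
        return len(self.spacers) + 1


#: Primary structural motif: C1-X(4,6)-C2-X(4,9)-C3-C4-X(2,10)-C5-X(3,14)-C6-X(1,16)
PSM = MotifPattern("PSM", ((4, 6), (4, 9), (0, 0), (2, 10), (3, 14)), trailing=(1, 16))
#: Extra structural motif: C7-X-C8
ESM = MotifPattern("ESM", ((1, 1),))


@dataclass(frozen=True)
class MotifMatch:
    pattern_name: str
    span: tuple[int, int]
    cysteine_positions: tuple[int, ...]


def cysteine_framework(seq: str) -> CysteineFramework:
    """Count and locate cysteines; flag odd frameworks."""
    if not seq:
        raise ValueError("cysteine_framework requires a non-empty sequence")
    positions = tuple(i for i, ch in enumerate(seq.upper()) if ch == "C")
    return CysteineFramework(len(positions), positions, len(positions) % 2 == 1)


def scan_motif(seq: str, pattern: MotifPattern) -> list[MotifMatch]:
    """All anchor placements of ``pattern`` in ``seq``, leftmost-first.

    Every tuple of cysteine anchors whose inter-anchor spacer lengths
    fall within the pattern's bounds is reported, including overlapping
    placements. Spacer residues are unconstrained (cysteines allowed).
    Matches are ordered by anchor tuple, leftmost first. A match's span
    runs from the first anchor to the end of the trailing spacer (capped
    at the sequence end).
    """
    s = seq.upper()
    cys = [i for i, ch in enumerate(s) if ch == "C"]
    matches: list[MotifMatch] = []

    def extend(anchors: list[int], depth: int) -> None:
        if depth == len(pattern.spacers):
            last = anchors[-1]
            if pattern.trailing is not None:
                lo, hi = pattern.trailing
                avail = len(s) - last - 1
                if avail < lo:
                    return
                end = last + 1 + min(hi, avail)
            else:
                end = last + 1
            matches.append(MotifMatch(pattern.name, (anchors[0], end), tuple(anchors)))
            return
        lo, hi = pattern.spacers[depth]
        prev = anchors[-1]
        for c in cys:
            gap = c - prev - 1
            if gap < lo:
                continue
            if gap > hi:
                break
            extend(anchors + [c], depth + 1)

    for c0 in cys:
        extend([c0], 0)
    return matches


def classify_ick(seq: str, *, esm_anywhere_downstream: bool = True) -> dict[str, bool]:
    """PSM/ESM composition of a mature peptide.

    Returns flags ``has_psm``, ``has_esm_after_psm`` (ESM evaluated on
    the suffix following the first PSM match's sixth anchor cysteine)
    and ``ick_candidate`` (PSM presence is sufficient). When
    ``esm_anywhere_downstream`` is false the ESM must start at the first
    residue after C6 instead of anywhere downstream.
    """
    psm_matches = scan_motif(seq, PSM)
    has_psm = bool(psm_matches)
    has_esm = False
    if has_psm:
        c6 = psm_matches[0].cysteine_positions[-1]
        suffix = seq[c6 + 1 :]
        esm_matches = scan_motif(suffix, ESM)
        if esm_anywhere_downstream:
            has_esm = bool(esm_matches)
        else:
            has_esm = any(m.cysteine_positions[0] == 0 for m in esm_matches)
    return {"has_psm": has_psm, "has_esm_after_psm": has_esm, "ick_candidate": has_psm}


def motif_report_tsv(records: Sequence) -> str:
    """Per-sequence TSV: id, cysteine count, parity, PSM/ESM flags, coordinates."""
    lines = ["id\tn_cys\todd\thas_psm\thas_esm_after_psm\tick_candidate\tpsm_anchors"]
    for rec in records:
        fw = cysteine_framework(rec.seq)
        flags = classify_ick(rec.seq)
        psm = scan_motif(rec.seq, PSM)
        anchors = ";".join(",".join(map(str, m.cysteine_positions)) for m in psm)
        lines.append(
            f"{rec.id}\t{fw.count}\t{int(fw.odd)}\t{int(flags['has_psm'])}"
            f"\t{int(flags['has_esm_after_psm'])}\t{int(flags['ick_candidate'])}\t{anchors}"
        )
    return "\n".join(lines) + "\n"
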