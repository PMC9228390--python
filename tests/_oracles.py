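"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (plain
Python, plain data structures, no imports from toxprospect's numeric
paths and no biopython) so that agreement with the package is a real
two-route check rather than the same code run twice.
"""

from __future__ import annotations

import itertools

# --- alignment -------------------------------------------------------------

def identity_matches_oracle(a: str, b: str) -> int:
    """Max matched positions among score-optimal free-ends alignments.

    Scoring: match +1, mismatch 0, internal gap -1, unaligned ends of
    both sequences free. States are (score, matches) tuples compared
    lexicographically; floor at (0, 0).
    """
    n, m = len(a), len(b)
    H = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    best = (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sc, mt = H[i - 1][j - 1]
            diag = (sc + 1, mt + 1) if a[i - 1] == b[j - 1] else (sc, mt)
            up = (H[i - 1][j][0] - 1, H[i - 1][j][1])
            left = (H[i][j - 1][0] - 1, H[i][j - 1][1])
            H[i][j] = max((0, 0), diag, up, left)
            best = max(best, H[i][j])
    return best[1]


def sw_affine_score_oracle(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Smith–Waterman score with affine gaps (open charges the first gap
    residue, extend the rest); floor 0."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


# --- ORFs ------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def all_complete_orfs_oracle(seq: str) -> list[tuple[str, int, int, int]]:
    """Exhaustive six-frame enumeration of complete (M..stop) ORFs.

    Returns (protein, frame, start, end) with forward-strand 0-based
    half-open coordinates including the stop codon, maximal per start
    (first in-frame stop terminates).
    """
    out = []
    L = len(seq)
    for sign, s in ((1, seq), (-1, seq.translate(_COMPLEMENT)[::-1])):
        for off in range(3):
            frame = sign * (off + 1)
            i = off
            starts: list[int] = []
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                aa = _CODON_TABLE[codon]
                if aa == "M":
                    starts.append(i)
                if aa == "*":
                    for st in starts:
                        protein = "".join(
                            _CODON_TABLE[s[k : k + 3]] for k in range(st, i, 3)
                        )
                        lo, hi = st, i + 3
                        if sign < 0:
                            lo, hi = L - (i + 3), L - st
                        out.append((protein, frame, lo, hi))
                    starts = []
                i += 3
    return out


def longest_orf_oracle(seq: str):
    """Longest complete ORF under the tie-break frame +1..+3,-1..-3 then
    leftmost start on the scanned strand; None if absent."""
    orfs = all_complete_orfs_oracle(seq)
    if not orfs:
        return None
    rank = {f: i for i, f in enumerate([1, 2, 3, -1, -2, -3])}
    L = len(seq)

    def key(o):
        protein, frame, lo, hi = o
        scan_start = lo if frame > 0 else L - hi
        return (-len(protein), rank[frame], scan_start)

    return min(orfs, key=key)


# --- assembly stats --------------------------------------------------------

def n50_oracle(lengths: list[int]) -> int:
    """Sort-and-accumulate N50 over the given contig lengths."""
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return L
    return 0


# --- motifs ----------------------------------------------------------------

def psm_anchor_tuples_oracle(seq: str) -> list[tuple[int, ...]]:
    """All 6-cysteine anchor tuples satisfying the PSM spacer bounds,
    requiring >= 1 residue after the sixth cysteine."""
    bounds = [(4, 6), (4, 9), (0, 0), (2, 10), (3, 14)]
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    out = []
    for tup in itertools.combinations(cys, 6):
        gaps = [tup[k + 1] - tup[k] - 1 for k in range(5)]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, bounds)) and tup[5] < len(seq) - 1:
            out.append(tup)
    return out


# --- clustering ------------------------------------------------------------

def greedy_cluster_oracle(seqs: list[tuple[str, str]], threshold: float):
    """Reference greedy clustering: longest-first, best qualifying
    representative (ties to the earliest-founded cluster).

    ``seqs`` is a list of (id, sequence); returns a list of clusters,
    each a list of member ids with the representative first.
    """
    order = sorted(range(len(seqs)), key=lambda i: -len(seqs[i][1]))
    reps: list[int] = []
    clusters: list[list[str]] = []
    for i in order:
        sid, seq = seqs[i]
        best_c, best_ident = -1, -1.0
        for ci, r in enumerate(reps):
            rep_seq = seqs[r][1]
            matches = identity_matches_oracle(seq, rep_seq)
            ident = matches / min(len(seq), len(rep_seq))
            if ident >= threshold and ident > best_ident:
                best_c, best_ident = ci, ident
        if best_c >= 0:
            clusters[best_c].append(sid)
        else:
            reps.append(i)
            clusters.append([sid])
    return clusters
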