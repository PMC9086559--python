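"""miRanda-style miRNA target-site prediction.

Two ingredients per candidate site: a complementarity alignment score and
a duplex free-energy estimate.  The score is a local (Smith-Waterman,
affine-gap) alignment between the miRNA read 3'->5' and the target read
5'->3', under the miRanda-lineage scheme: Watson-Crick pair +5, G:U
wobble +1, mismatch -3, gap open -9, gap extend -4, with pair/mismatch
contributions at miRNA positions 2-8 from the 5' end (the seed) scaled by
2.  The energy is a nearest-neighbor stacking sum over consecutive paired
columns using the published Watson-Crick stack table (Xia et al. Turner
lab parameters, 37 C) plus a duplex-initiation term; stacks containing a
wobble pair take a single flat value since the alignment scorer, not the
energy model, is what discriminates sites.  Gapped or mismatched columns
contribute nothing and break stacks.

Sites are reported when score > min_score and energy < max_energy (both
strict, matching the published screening conditions score > 140 and
energy < -20 kcal/mol), greedily selected non-overlapping in descending
score order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

# Watson-Crick nearest-neighbor stack free energies, kcal/mol at 37 C
# (Xia et al. 1998 / Turner 2004).  Key: the 5'->3' dinucleotide of one
# strand; the partner strand is its Watson-Crick complement.
WC_STACK = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}
WOBBLE_STACK = -1.2      # flat term for any stack containing a G:U pair
DUPLEX_INIT = 4.09       # duplex initiation penalty, kcal/mol


@dataclass
class ScoringParams:
    """Alignment scoring parameters (miRanda-lineage defaults)."""

    match_wc: float = 5.0
    match_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0      # cost of the first gapped column
    gap_extend: float = -4.0    # cost of each further gapped column
    seed_scale: float = 2.0     # multiplier for miRNA positions seed_start..seed_end
    seed_start: int = 2         # 1-based from the miRNA 5' end
    seed_end: int = 8


@dataclass
class Alignment:
    """An aligned site: miRNA shown 3'->5', target 5'->3'.

    ``columns`` holds one (mir_char, target_char) tuple per alignment
    column in target 5'->3' order, with ``"-"`` for gaps.
    """

    mir_aln: str
    match_line: str
    target_aln: str
    target_start: int  # 1-based inclusive on the target
    target_end: int
    columns: list[tuple[str, str]] = field(default_factory=list)

    def pretty(self) -> str:
        return (f"miRNA  3' {self.mir_aln} 5'\n"
                f"          {self.match_line}\n"
                f"target 5' {self.target_aln} 3'  "
                f"[{self.target_start}-{self.target_end}]")


@dataclass
class TargetHit:
    """One predicted binding site passing both screening thresholds."""

    mirna_id: str
    target_id: str
    score: float
    energy: float
    target_start: int
    target_end: int
    alignment: Alignment


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq or any(c not in "ACGU" for c in seq):
        raise InvalidArgumentError(f"{what} must be non-empty RNA over A/C/G/U")
    return seq


def _pair_kind(mir_base: str, target_base: str) -> str | None:
    if (mir_base, target_base) in WC_PAIRS:
        return "WC"
    if (mir_base, target_base) in WOBBLE_PAIRS:
        return "GU"
    return None


def _substitution_matrix(mirna: str, params: ScoringParams) -> list[dict[str, float]]:
    """Per miRNA position (3'->5' order), score against each target base."""
    L = len(mirna)
    rev = mirna[::-1]  # rev[k] sits at miRNA 5'-position L-k
    table = []
    for k, mb in enumerate(rev):
        pos5 = L - k
        scale = params.seed_scale if params.seed_start <= pos5 <= params.seed_end else 1.0
        row = {}
        for tb in "ACGU":
            kind = _pair_kind(mb, tb)
            if kind == "WC":
                row[tb] = params.match_wc * scale
            elif kind == "GU":
                row[tb] = params.match_wobble * scale
            else:
                row[tb] = params.mismatch * scale
        table.append(row)
    return table


def _dp_matrices(mirna: str, window: str, params: ScoringParams):
    """Gotoh local alignment; returns (M, X, Y) score matrices.

    M: column is a pair/mismatch; X: gap in the miRNA (target base
    unmatched); Y: gap in the target.  Gap convention: a gap of length g
    costs gap_open + (g-1)*gap_extend.
    """
    L, T = len(mirna), len(window)
    sub = _substitution_matrix(mirna, params)
    NEG = -1e9
    M = np.full((L + 1, T + 1), NEG)
    X = np.full((L + 1, T + 1), NEG)
    Y = np.full((L + 1, T + 1), NEG)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    go, ge = params.gap_open, params.gap_extend
    for i in range(1, L + 1):
        row_sub = sub[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, T + 1):
            s = row_sub[window[j - 1]]
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = max(0.0, best_prev + s) if best_prev + s > 0 else 0.0
            Xi[j] = max(Mi[j - 1] + go, Xi[j - 1] + ge)
            Yi[j] = max(Mi1[j] + go, Yi1[j] + ge)
    return M, X, Y


def _traceback(mirna: str, window: str, params: ScoringParams, M, X, Y,
               end_i: int, end_j: int) -> Alignment:
    sub = _substitution_matrix(mirna, params)
    rev = mirna[::-1]
    go, ge = params.gap_open, params.gap_extend
    cols: list[tuple[str, str]] = []
    i, j, state = end_i, end_j, "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] <= 0:
                break
            s = sub[i - 1][window[j - 1]]
            cols.append((rev[i - 1], window[j - 1]))
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if np.isclose(M[i, j], prev):
                state = "M"
            elif np.isclose(X[i, j], prev):
                state = "X"
            elif np.isclose(Y[i, j], prev):
                state = "Y"
            else:  # local start
                break
        elif state == "X":
            cols.append(("-", window[j - 1]))
            if np.isclose(X[i, j], M[i, j - 1] + go):
                state = "M"
            j -= 1
        else:  # Y
            cols.append((rev[i - 1], "-"))
            if np.isclose(Y[i, j], M[i - 1, j] + go):
                state = "M"
            i -= 1
    cols.reverse()
    start_j = end_j - sum(1 for _, tb in cols if tb != "-") + 1
    mir_aln = "".join(mb for mb, _ in cols)
    tgt_aln = "".join(tb for _, tb in cols)
    line = []
    for mb, tb in cols:
        kind = _pair_kind(mb, tb) if "-" not in (mb, tb) else None
        line.append("|" if kind == "WC" else ":" if kind == "GU" else " ")
    return Alignment(mir_aln, "".join(line), tgt_aln, start_j, end_j, cols)


def align_site(mirna: str, window: str, params: ScoringParams | None = None
               ) -> tuple[float, Alignment]:
    """Best local alignment of a miRNA against a target window.

    Returns the optimal score and its alignment (ties resolved toward the
    leftmost, shortest site).  The miRNA must be 19-24 nt and the window
    at least as long as the miRNA.
    """
    params = params or ScoringParams()
    mirna = _check_rna(mirna, "miRNA")
    window = _check_rna(window, "window")
    if not 19 <= len(mirna) <= 24:
        raise InvalidArgumentError(f"miRNA length must be 19..24, got {len(mirna)}")
    if len(window) < len(mirna):
        raise InvalidArgumentError("window shorter than miRNA")
    M, X, Y = _dp_matrices(mirna, window, params)
    end_i, end_j = np.unravel_index(int(np.argmax(M)), M.shape)
    score = float(M[end_i, end_j])
    aln = _traceback(mirna, window, params, M, X, Y, int(end_i), int(end_j))
    return score, aln


def duplex_energy(alignment: Alignment) -> float:
    """Nearest-neighbor duplex free energy of an aligned site, kcal/mol.

    Sum of stack terms over consecutive paired columns plus the duplex
    initiation penalty; unpaired or gapped columns contribute nothing and
    break stacks.  More negative means more stable.
    """
    kinds = []
    for mb, tb in alignment.columns:
        kinds.append(_pair_kind(mb, tb) if "-" not in (mb, tb) else None)
    energy = DUPLEX_INIT
    for c in range(len(kinds) - 1):
        k1, k2 = kinds[c], kinds[c + 1]
        if k1 is None or k2 is None:
            continue
        if k1 == "WC" and k2 == "WC":
            top = alignment.columns[c][1] + alignment.columns[c + 1][1]
            energy += WC_STACK[top]
        else:
            energy += WOBBLE_STACK
    return energy


def perfect_duplex_energy(mirna: str) -> float:
    """Duplex energy of a miRNA bound to its exact full-length complement.

    This is the energy a planted (reverse-complement) site attains: all
    columns Watson-Crick paired, so the nearest-neighbor sum runs over
    every adjacent dinucleotide of the site.
    """
    mirna = _check_rna(mirna, "miRNA")
    site = mirna.translate(str.maketrans("ACGU", "UGCA"))[::-1]
    return DUPLEX_INIT + sum(WC_STACK[site[c:c + 2]] for c in range(len(site) - 1))


def _find_sites(mirna: str, target: str, params: ScoringParams,
                min_score: float) -> list[tuple[float, Alignment]]:
    """All non-overlapping local maxima with score > min_score."""
    M, X, Y = _dp_matrices(mirna, target, params)
    col_best = M.max(axis=0)
    candidates = []
    for j in np.nonzero(col_best > min_score)[0]:
        i = int(M[:, j].argmax())
        aln = _traceback(mirna, target, params, M, X, Y, i, int(j))
        candidates.append((float(M[i, j]), aln))
    # greedy selection: best score first, leftmost on ties
    candidates.sort(key=lambda c: (-c[0], c[1].target_start))
    chosen: list[tuple[float, Alignment]] = []
    taken: list[tuple[int, int]] = []
    for score, aln in candidates:
        if any(aln.target_start <= e and aln.target_end >= s for s, e in taken):
            continue
        chosen.append((score, aln))
        taken.append((aln.target_start, aln.target_end))
    chosen.sort(key=lambda c: c[1].target_start)
    return chosen


def scan_targets(mirnas: dict[str, str], targets: dict[str, str],
                 min_score: float = 140.0, max_energy: float = -20.0,
                 params: ScoringParams | None = None) -> list[TargetHit]:
    """Scan every miRNA against every target sequence.

    Reports non-overlapping sites per (miRNA, target) pair with
    score > min_score AND energy < max_energy (both strict), sorted by
    (target, position, miRNA).  Empty inputs yield an empty list.
    """
    params = params or ScoringParams()
    hits: list[TargetHit] = []
    for target_id in sorted(targets):
        tseq = _check_rna(targets[target_id], f"target {target_id!r}")
        for mir_id in sorted(mirnas):
            mseq = _check_rna(mirnas[mir_id], f"miRNA {mir_id!r}")
            if not 19 <= len(mseq) <= 24:
                raise InvalidArgumentError(f"miRNA {mir_id!r} length must be 19..24")
            if len(tseq) < len(mseq):
                continue
            if min_score == float("inf"):
                continue
            for score, aln in _find_sites(mseq, tseq, params, min_score):
                energy = duplex_energy(aln)
                if energy < max_energy:
                    hits.append(TargetHit(mir_id, target_id, score, energy,
                                          aln.target_start, aln.target_end, aln))
    hits.sort(key=lambda h: (h.target_id, h.target_start, h.mirna_id))
    return hits
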