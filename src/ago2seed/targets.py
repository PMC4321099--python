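"""miRanda-style in silico target-site prediction.

A mature miRNA is aligned, 3'->5', against a 3'UTR read 5'->3' with a local
(Smith-Waterman) dynamic program under complementarity scoring: a
Watson-Crick pair scores as a match, G:U wobble scores weakly positive,
anything else is a mismatch; gaps are affine.  Pair scores at miRNA seed
positions 2-8 are doubled, reflecting the dominant role of seed pairing in
target recognition.  All non-overlapping sites above a score threshold are
reported best-first; overlapping lower-scoring sites are suppressed.

The scoring scheme and its defaults are this package's own definition,
chosen to mimic published miRanda behavior, and are fully configurable via
:class:`ScoringParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequences import (SEED_END, SEED_START, MiRNASeq, UTRSeq, canonicalize,
                        reverse_complement)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair-state characters used in alignment traces
MATCH, WOBBLE, MISMATCH, GAP = "|", ":", ".", "-"


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring parameters (dimensionless, this package's scale)."""

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_start: int = SEED_START   # 1-based miRNA positions whose pair
    seed_end: int = SEED_END       # scores are multiplied ...
    seed_multiplier: float = 2.0   # ... by this factor
    min_score: float = 80.0

    def base_table(self) -> np.ndarray:
        """4x4 pair score table indexed by (miRNA base, UTR base)."""
        t = np.full((4, 4), self.mismatch)
        for a, b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
            t[_BASE_INDEX[a], _BASE_INDEX[b]] = self.match
        for a, b in (("G", "U"), ("U", "G")):
            t[_BASE_INDEX[a], _BASE_INDEX[b]] = self.wobble
        return t

    def pair_state(self, mirna_base: str, utr_base: str) -> str:
        if (mirna_base, utr_base) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
            return MATCH
        if (mirna_base, utr_base) in (("G", "U"), ("U", "G")):
            return WOBBLE
        return MISMATCH

    def position_weights(self, mirna_length: int) -> np.ndarray:
        """Per-position multiplier, indexed by 1-based miRNA position - 1."""
        w = np.ones(mirna_length)
        w[self.seed_start - 1:self.seed_end] = self.seed_multiplier
        return w


DEFAULT_PARAMS = ScoringParams()


@dataclass
class DuplexAlignment:
    """One scored candidate binding site.

    UTR coordinates are 0-based half-open on the 5'->3' UTR;
    ``mirna_start``/``mirna_end`` are 1-based inclusive miRNA positions
    covered by the alignment (seed = 2-8).  ``aligned_mirna`` runs 3'->5' to
    face ``aligned_utr`` (5'->3'); ``trace`` holds one pair-state character
    per alignment column.
    """

    mirna_id: str
    gene_id: str
    utr_start: int
    utr_end: int
    score: float
    trace: str
    seed_matched: bool
    mirna_start: int
    mirna_end: int
    aligned_mirna: str
    aligned_utr: str

    def rescore(self, params: ScoringParams, mirna_length: int) -> float:
        """Re-score the stored trace under ``params`` (invariant check)."""
        weights = params.position_weights(mirna_length)
        total, in_gap = 0.0, False
        # aligned_mirna runs 3'->5': its first consumed base is position mirna_end
        position = self.mirna_end
        for mb, ub, state in zip(self.aligned_mirna, self.aligned_utr, self.trace):
            if state == GAP:
                total += params.gap_extend if in_gap else params.gap_open
                in_gap = True
                if mb != GAP:
                    position -= 1
                continue
            in_gap = False
            table_score = {MATCH: params.match, WOBBLE: params.wobble,
                           MISMATCH: params.mismatch}[state]
            total += table_score * weights[position - 1]
            position -= 1
        return total


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _align_segment(mirna_rev: str, weights_rev: Sequence[float], utr: str,
                   params: ScoringParams):
    """Gotoh local alignment of the reversed miRNA against one UTR segment.

    Returns ``(score, path)`` of the single best local alignment, where
    ``path`` is a list of (i, j, state) steps in alignment order, or
    ``(0.0, [])`` if nothing scores positively.  Ties are broken toward the
    smallest (end column, end row).
    """
    m, n = len(mirna_rev), len(utr)
    table = params.base_table()
    s = table[np.ix_(_encode(mirna_rev), _encode(utr))] * \
        np.asarray(weights_rev)[:, None]
    go, ge = params.gap_open, params.gap_extend
    NEG = float("-inf")
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 open from H, 2 extend
    ptrF = np.zeros((m + 1, n + 1), dtype=np.int8)
    best_score, best_cell = 0.0, None
    for i in range(1, m + 1):
        si = s[i - 1]
        Hi, Hprev = H[i], H[i - 1]
        Ei, Fi, Fprev = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e_open, e_ext = Hi[j - 1] + go, Ei[j - 1] + ge
            e = e_open if e_open >= e_ext else e_ext
            Ei[j] = e
            ptrE[i, j] = 1 if e_open >= e_ext else 2
            f_open, f_ext = Hprev[j] + go, Fprev[j] + ge
            f = f_open if f_open >= f_ext else f_ext
            Fi[j] = f
            ptrF[i, j] = 1 if f_open >= f_ext else 2
            diag = Hprev[j - 1] + si[j - 1]
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if e > h:
                h, p = e, 2
            if f > h:
                h, p = f, 3
            Hi[j] = h
            ptrH[i, j] = p
            if h > best_score:
                best_score, best_cell = h, (i, j)
    if best_cell is None:
        return 0.0, []
    # traceback; steps are ('D'iag | gap-consuming-'U'TR | gap-consuming-'M'iRNA, i, j)
    path = []
    i, j = best_cell
    state = "H"
    while not (state == "H" and ptrH[i, j] == 0):
        if state == "H":
            p = ptrH[i, j]
            if p == 1:
                path.append(("D", i, j))
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":   # gap in miRNA, consume UTR base
            path.append(("U", i, j))
            if ptrE[i, j] == 1:
                state = "H"
            j -= 1
        else:                # gap in UTR, consume miRNA base
            path.append(("M", i, j))
            if ptrF[i, j] == 1:
                state = "H"
            i -= 1
    path.reverse()
    return float(best_score), path


def _path_to_alignment(mirna: MiRNASeq, utr: UTRSeq, path, score: float,
                       utr_offset: int, seed_hits: Sequence[tuple[int, str]],
                       params: ScoringParams) -> DuplexAlignment:
    mirna_rev = mirna.sequence[::-1]
    L = len(mirna.sequence)
    aligned_m, aligned_u, trace = [], [], []
    i_consumed, j_consumed = [], []
    for kind, i, j in path:
        if kind == "D":
            mb, ub = mirna_rev[i - 1], utr.sequence[utr_offset + j - 1]
            aligned_m.append(mb)
            aligned_u.append(ub)
            trace.append(params.pair_state(mb, ub))
            i_consumed.append(i)
            j_consumed.append(j)
        elif kind == "U":    # gap in miRNA opposite a UTR base
            aligned_m.append(GAP)
            aligned_u.append(utr.sequence[utr_offset + j - 1])
            trace.append(GAP)
            j_consumed.append(j)
        else:                # gap in UTR opposite a miRNA base
            aligned_m.append(mirna_rev[i - 1])
            aligned_u.append(GAP)
            trace.append(GAP)
            i_consumed.append(i)
    utr_start = utr_offset + min(j_consumed) - 1
    utr_end = utr_offset + max(j_consumed)
    mirna_start = L - max(i_consumed) + 1
    mirna_end = L - min(i_consumed) + 1
    seed_matched = any(utr_start < off + 7 and off < utr_end
                       for off, _ in seed_hits)
    return DuplexAlignment(
        mirna_id=mirna.id, gene_id=utr.gene_id, utr_start=utr_start,
        utr_end=utr_end, score=score, trace="".join(trace),
        seed_matched=seed_matched, mirna_start=mirna_start,
        mirna_end=mirna_end, aligned_mirna="".join(aligned_m),
        aligned_utr="".join(aligned_u))


def align_duplex(mirna: MiRNASeq, utr: UTRSeq,
                 params: ScoringParams = DEFAULT_PARAMS) -> list[DuplexAlignment]:
    """All non-overlapping duplex sites scoring at least ``params.min_score``.

    Sites are found greedily: the best-scoring local alignment is reported,
    its UTR interval is removed, and the remaining flanks are searched
    recursively.  The returned list is best-first (score desc, then leftmost
    UTR start).
    """
    mirna_rev = mirna.sequence[::-1]
    weights_rev = params.position_weights(len(mirna.sequence))[::-1]
    seed_hits = seed_match_scan(mirna, utr)
    sites: list[DuplexAlignment] = []

    def search(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        score, path = _align_segment(mirna_rev, weights_rev,
                                     utr.sequence[lo:hi], params)
        if not path or score < params.min_score:
            return
        aln = _path_to_alignment(mirna, utr, path, score, lo, seed_hits, params)
        sites.append(aln)
        search(lo, aln.utr_start)
        search(aln.utr_end, hi)

    search(0, len(utr.sequence))
    sites.sort(key=lambda a: (-a.score, a.utr_start))
    return sites


def seed_match_scan(mirna: MiRNASeq, utr: UTRSeq) -> list[tuple[int, str]]:
    """Offsets of exact seed-complementary sites in the UTR.

    Reports 7mer sites (reverse complement of miRNA positions 2-8) and
    7mer-A1 sites (reverse complement of positions 2-7 followed by an A
    opposite position 1).  Offsets are 0-based starts of the 7-nt window.
    """
    site7 = reverse_complement(mirna.seed)
    site_a1 = site7[1:] + "A"
    hits = []
    for kind, site in (("7mer", site7), ("7mer-A1", site_a1)):
        start = utr.sequence.find(site)
        while start != -1:
            hits.append((start, kind))
            start = utr.sequence.find(site, start + 1)
    # a 7mer hit subsumes an A1 hit at the same window
    sevens = {off for off, kind in hits if kind == "7mer"}
    hits = [(off, kind) for off, kind in hits
            if kind == "7mer" or off not in sevens]
    hits.sort()
    return hits


def predict_targets(mirnas: Iterable[MiRNASeq], utrs: Iterable[UTRSeq],
                    params: ScoringParams = DEFAULT_PARAMS
                    ) -> dict[str, list[str]]:
    """Per-miRNA predicted target gene lists.

    A gene is predicted for a miRNA iff it carries at least one duplex site
    with score >= ``params.min_score`` that overlaps an exact seed match.
    Because a qualifying site must overlap a seed match, UTRs with no seed
    hit are skipped without running the full dynamic program.  Lists are
    ordered by (best site score desc, gene id).
    """
    utrs = list(utrs)
    out: dict[str, list[str]] = {}
    for mirna in mirnas:
        scored: list[tuple[float, str]] = []
        for utr in utrs:
            if not seed_match_scan(mirna, utr):
                continue
            sites = [a for a in align_duplex(mirna, utr, params) if a.seed_matched]
            if sites:
                scored.append((max(a.score for a in sites), utr.gene_id))
        scored.sort(key=lambda t: (-t[0], t[1]))
        out[mirna.id] = [g for _, g in scored]
    return out


def write_sites_bed(alignments: Iterable[DuplexAlignment], path) -> None:
    """BED6-compatible site table (gene id stands in for the chromosome)."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.gene_id}\t{a.utr_start}\t{a.utr_end}\t{a.mirna_id}"
                     f"\t{a.score:g}\t+\n")


def write_pair_summary(predicted: Mapping[str, Sequence[str]], path) -> None:
    """Tab-delimited per-(miRNA, gene) summary of predictions."""
    with open(path, "w") as fh:
        fh.write("mirna\tgene\trank\n")
        for mirna in sorted(predicted):
            for rank, gene in enumerate(predicted[mirna], start=1):
                fh.write(f"{mirna}\t{gene}\t{rank}\n")
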