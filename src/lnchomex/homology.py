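"""Motif-pattern scoring between candidate lncRNA homologs.

Two transcripts are compared through their block profiles.  The
motif-pattern similarity score (MPSS) is the maximum, over all monotone
(non-crossing) sets of block pairs, of the summed block similarity scores —
computed by dynamic programming over the |A| x |B| grid with free skips.
The gap penalty score (GPS) measures spacing conservation of the aligned
blocks:

    GPS = sqrt( sum_{i=1}^{n-1} (x_i - y_i)^2 ) / (n - 1)

where x_i and y_i are center-to-center distances between consecutive aligned
blocks in the two transcripts and n is the number of aligned pairs (GPS = 0
when n <= 1).  MPSS significance comes from a permutation null of random
cross-species transcript pairs; GPS significance from re-drawing block
positions uniformly while keeping the pairing.  Both p-values use the
add-one convention and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .motifs import BlockProfile, MotifMatch

#: tolerance for treating two MPSS totals as co-optimal during tie-breaking
_TIE_EPS = 1e-9


def block_similarity(counts_a: Dict[str, int], counts_b: Dict[str, int]) -> float:
    """Sum over motif classes of min(x_i, y_i) / max(x_i, y_i).

    Classes absent from either block contribute nothing (0/0 := 0), so the
    sum effectively runs over the shared classes.  Symmetric in its arguments.
    """
    total = 0.0
    for cls, x in counts_a.items():
        y = counts_b.get(cls, 0)
        if x > 0 and y > 0:
            total += min(x, y) / max(x, y)
    return total


@dataclass(frozen=True)
class BlockAlignment:
    """Optimal monotone matching of two block profiles."""

    pairs: Tuple[Tuple[int, int], ...]
    mpss: float
    gps: float
    dist_a: Tuple[float, ...] = ()
    dist_b: Tuple[float, ...] = ()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _similarity_matrix(a: BlockProfile, b: BlockProfile) -> np.ndarray:
    sim = np.zeros((len(a.blocks), len(b.blocks)))
    for i, ba in enumerate(a.blocks):
        for j, bb in enumerate(b.blocks):
            sim[i, j] = block_similarity(ba.counts, bb.counts)
    return sim


def align_blocks(a: BlockProfile, b: BlockProfile) -> BlockAlignment:
    """Maximum-MPSS monotone matching of the two profiles.

    Skipped blocks are free; only positive-similarity pairs may be aligned
    (a zero-score pair changes nothing and would distort the gap structure).
    Ties between co-optimal alignments are broken by the lexicographically
    smallest pair list.  The tie-break deliberately never looks at block
    spacing: selecting the minimum-GPS alignment among co-optimal matchings
    would bias the observed GPS low relative to the position-shuffle null
    (which keeps the pairing fixed) and make the GPS test anti-conservative.
    """
    na, nb = len(a.blocks), len(b.blocks)
    if na == 0 or nb == 0:
        return BlockAlignment((), 0.0, 0.0)
    sim = _similarity_matrix(a, b)
    ca, cb = a.centers, b.centers
    score = np.full((na, nb), -np.inf)
    prev: List[List[Optional[Tuple[int, int]]]] = [[None] * nb for _ in range(na)]
    for i in range(na):
        for j in range(nb):
            s = sim[i, j]
            if s <= 0.0:
                continue
            best_s: float = s
            best_prev: Optional[Tuple[int, int]] = None
            if i > 0 and j > 0:
                sub = score[:i, :j]
                m = sub.max()
                if np.isfinite(m):
                    # any positive-score predecessor strictly improves on s
                    tied = np.argwhere(sub >= m - _TIE_EPS)
                    pi, pj = tied[0]  # row-major: smallest (i', j')
                    best_s = float(m + s)
                    best_prev = (int(pi), int(pj))
            score[i, j] = best_s
            prev[i][j] = best_prev
    if not np.isfinite(score).any():
        return BlockAlignment((), 0.0, 0.0)
    m = score[np.isfinite(score)].max()
    i, j = (int(v) for v in np.argwhere(score >= m - _TIE_EPS)[0])
    pairs: List[Tuple[int, int]] = []
    cur: Optional[Tuple[int, int]] = (int(i), int(j))
    while cur is not None:
        pairs.append(cur)
        cur = prev[cur[0]][cur[1]]
    pairs.reverse()
    dist_a = tuple(float(ca[q] - ca[p]) for (p, _), (q, _) in zip(pairs, pairs[1:]))
    dist_b = tuple(float(cb[q] - cb[p]) for (_, p), (_, q) in zip(pairs, pairs[1:]))
    aln = BlockAlignment(tuple(pairs), float(m), 0.0, dist_a, dist_b)
    gps = gap_penalty(aln, a, b)
    return BlockAlignment(tuple(pairs), float(m), gps, dist_a, dist_b)


def gap_penalty(alignment: BlockAlignment, a: BlockProfile, b: BlockProfile) -> float:
    """GPS of an alignment: sqrt(sum of squared spacing deviations) / (n - 1)."""
    n = alignment.n_pairs
    if n <= 1:
        return 0.0
    ca, cb = a.centers, b.centers
    ia = np.array([p for p, _ in alignment.pairs])
    ib = np.array([q for _, q in alignment.pairs])
    dx = np.diff(ca[ia])
    dy = np.diff(cb[ib])
    return float(np.sqrt(np.sum((dx - dy) ** 2)) / (n - 1))


# ---------------------------------------------------------------------------
# permutation nulls


class MpssNull:
    """Empirical MPSS null from random cross-species profile pairs."""

    def __init__(self, values: np.ndarray):
        self.values = np.sort(np.asarray(values, dtype=float))

    @property
    def n_perm(self) -> int:
        return int(self.values.size)

    def p_value(self, mpss_obs: float) -> float:
        """(1 + #{null >= obs}) / (n_perm + 1)."""
        ge = self.values.size - np.searchsorted(self.values, mpss_obs - _TIE_EPS, side="left")
        return float((1 + ge) / (self.values.size + 1))


def null_mpss(
    library_a: Sequence[BlockProfile],
    library_b: Sequence[BlockProfile],
    n_perm: int = 100_000,
    seed: int = 0,
) -> MpssNull:
    """Sample MPSS of uniformly drawn cross-species profile pairs."""
    if len(library_a) < 2 or len(library_b) < 2:
        raise InputError("each profile library needs >= 2 profiles")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(library_a), size=n_perm)
    ib = rng.integers(0, len(library_b), size=n_perm)
    vals = np.empty(n_perm)
    for k in range(n_perm):
        vals[k] = align_blocks(library_a[ia[k]], library_b[ib[k]]).mpss
    return MpssNull(vals)


def null_gps(
    a: BlockProfile,
    b: BlockProfile,
    alignment: BlockAlignment,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> float:
    """p-value of the observed GPS under uniform re-draw of block positions.

    Block centers of both profiles are independently re-drawn uniformly
    within the transcript and re-sorted; the alignment pairing is retained
    and GPS recomputed.  Low GPS (conserved spacing) is significant:
    p = (1 + #{null GPS <= obs GPS}) / (n_shuffle + 1).
    """
    n = alignment.n_pairs
    if n < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = gap_penalty(alignment, a, b)
    ia = np.array([p for p, _ in alignment.pairs])
    ib = np.array([q for _, q in alignment.pairs])
    pos_a = np.sort(rng.uniform(0, a.seq_length, size=(n_shuffle, len(a.blocks))), axis=1)
    pos_b = np.sort(rng.uniform(0, b.seq_length, size=(n_shuffle, len(b.blocks))), axis=1)
    dx = np.diff(pos_a[:, ia], axis=1)
    dy = np.diff(pos_b[:, ib], axis=1)
    null = np.sqrt(np.sum((dx - dy) ** 2, axis=1)) / (n - 1)
    return float((1 + int(np.sum(null <= obs + _TIE_EPS))) / (n_shuffle + 1))


# ---------------------------------------------------------------------------
# homolog calling


@dataclass(frozen=True)
class CandidateScore:
    """Scored candidate pair, the unit call_homologs consumes."""

    query_id: str
    target_id: str
    mpss: float
    gps: float
    p_mpss: float
    p_gps: float


@dataclass(frozen=True)
class HomologyCall:
    query_id: str
    target_id: str
    mpss: float
    gps: float
    p_mpss: float
    p_gps: float
    max_mpss_among_candidates: float
    verdict: str  # "coPARSE" or "rejected"
    region_a: Optional[Tuple[int, int]] = None
    region_b: Optional[Tuple[int, int]] = None


def call_homologs(
    candidates: Sequence[CandidateScore],
    alpha: float = 0.05,
    ratio: float = 0.8,
) -> List[HomologyCall]:
    """Apply the homolog-calling thresholds per query lncRNA.

    A pair is called iff both permutation p-values are below ``alpha`` and its
    MPSS exceeds ``ratio`` times the maximum MPSS among the query's candidates.
    """
    by_query: Dict[str, List[CandidateScore]] = {}
    for c in candidates:
        by_query.setdefault(c.query_id, []).append(c)
    calls: List[HomologyCall] = []
    for query, group in by_query.items():
        max_mpss = max(c.mpss for c in group)
        for c in group:
            ok = c.p_mpss < alpha and c.p_gps < alpha and c.mpss > ratio * max_mpss
            calls.append(
                HomologyCall(
                    c.query_id, c.target_id, c.mpss, c.gps, c.p_mpss, c.p_gps,
                    max_mpss, "coPARSE" if ok else "rejected",
                )
            )
    return calls


def homologous_region(
    alignment: BlockAlignment,
    profile_a: BlockProfile,
    profile_b: BlockProfile,
    matches_a: Sequence[MotifMatch],
    matches_b: Sequence[MotifMatch],
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Per-transcript interval from the first to the last aligned motif match.

    The region runs from the start of the first motif match inside the first
    aligned block to the end of the last motif match inside the last aligned
    block.  Returns None when the alignment is empty (undefined region).
    """
    if not alignment.pairs:
        return None

    def region(profile: BlockProfile, matches: Sequence[MotifMatch], idx_first: int, idx_last: int):
        first, last = profile.blocks[idx_first], profile.blocks[idx_last]
        starts = [m.start for m in matches if m.start >= first.start and m.end <= first.end]
        ends = [m.end for m in matches if m.start >= last.start and m.end <= last.end]
        if not starts or not ends:
            raise InputError("aligned block contains no motif matches")
        return (min(starts), max(ends))

    (ia0, ib0), (ia1, ib1) = alignment.pairs[0], alignment.pairs[-1]
    return region(profile_a, matches_a, ia0, ia1), region(profile_b, matches_b, ib0, ib1)
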