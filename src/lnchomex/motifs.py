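"""PWM motif scanning, block clustering and motif-library manipulation.

Transcript sequences are stored in the DNA alphabet (U is normalised to T on
read); scanning is sense-strand only, because inputs are spliced transcript
sequences, not genomic windows.  Match significance is an exact p-value under
the i.i.d. background model, computed from the full null distribution of the
integer-discretised log-odds score (bins of ``SCORE_BIN`` bits), the same
construction FIMO uses.  Positions overlapping N never produce a match: the
log-odds of an undetermined base is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError

BASES = "ACGT"
#: width of the integer score lattice used for exact p-values, in bits
SCORE_BIN = 1e-3

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 4

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_RC)[::-1]


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an ACGTN string to integer codes 0..4; anything else is an error."""
    arr = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sequence[int(np.argmax(arr < 0))]
        raise InputError(f"non-ACGTN character {bad!r} in sequence")
    return arr


def regularize_matrix(matrix: np.ndarray, background: np.ndarray, pseudocount: float) -> np.ndarray:
    """Mix each row with the background so no cell is exactly zero."""
    reg = (matrix + pseudocount * background[None, :]) / (1.0 + pseudocount)
    return reg / reg.sum(axis=1, keepdims=True)


@dataclass(eq=False)
class Pwm:
    """Position weight matrix of one RBP motif in one species.

    ``matrix`` holds per-position base probabilities over (A, C, G, T); rows
    must sum to 1 within 1e-6 (apply :func:`regularize_matrix` upstream).
    """

    motif_id: str
    rbp_name: str
    species: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise InputError("PWM matrix must be width x 4")
        if self.matrix.shape[0] < 1:
            raise InputError("PWM width must be >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise InputError(f"PWM {self.motif_id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise InputError("background must sum to 1")
        if self.pseudocount <= 0:
            raise InputError("pseudocount must be positive")
        self._scoring: Optional[tuple] = None

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Mean information content per column, in bits."""
        p = regularize_matrix(self.matrix, self.background, self.pseudocount)
        return float(np.mean(np.sum(p * np.log2(p / self.background[None, :]), axis=1)))

    # -- exact scoring machinery -------------------------------------------

    def _scoring_tables(self):
        """(float log-odds, integer lattice scores, tail p-values, lattice offset)."""
        if self._scoring is None:
            p = regularize_matrix(self.matrix, self.background, self.pseudocount)
            logodds = np.log2(p / self.background[None, :])
            iscore = np.rint(logodds / SCORE_BIN).astype(np.int64)
            dist = np.array([1.0])
            offset = 0
            for k in range(self.width):
                row = iscore[k]
                lo, hi = int(row.min()), int(row.max())
                new = np.zeros(dist.size + hi - lo)
                for b in range(4):
                    s = int(row[b]) - lo
                    new[s : s + dist.size] += self.background[b] * dist
                dist = new
                offset += lo
            tail = np.cumsum(dist[::-1])[::-1]
            tail = np.minimum(tail, 1.0)
            self._scoring = (logodds, iscore, tail, offset)
        return self._scoring

    def exact_pvalue(self, int_score: int) -> float:
        """P(lattice score >= int_score) under the background model."""
        _, _, tail, offset = self._scoring_tables()
        idx = int_score - offset
        if idx < 0:
            return 1.0
        if idx >= tail.size:
            return 0.0
        return float(tail[idx])


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    motif_class: str
    seq_id: str
    start: int
    end: int
    score: float
    p_value: float


@dataclass(frozen=True)
class MotifBlock:
    """A cluster of overlapping motif matches, summarised per motif class."""

    seq_id: str
    start: int
    end: int
    center: float
    counts: Dict[str, int]

    @property
    def total_matches(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BlockProfile:
    seq_id: str
    seq_length: int
    blocks: Tuple[MotifBlock, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        starts = [b.start for b in self.blocks]
        if starts != sorted(starts):
            raise InputError("blocks must be sorted by start")
        for b in self.blocks:
            if b.start < 0 or b.end > self.seq_length:
                raise InputError("block outside [0, seq_length)")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.blocks], dtype=float)


def scan_motifs(
    pwm: Pwm,
    sequence: str,
    p_threshold: float = 1e-4,
    seq_id: str = "seq",
    motif_class: Optional[str] = None,
) -> List[MotifMatch]:
    """Scan one transcript with one PWM; matches are offsets with p <= p_threshold.

    The score reported is the float log-odds sum in bits; the p-value is exact
    on the ``SCORE_BIN`` lattice (see module docstring).
    """
    enc = encode_sequence(sequence.upper().replace("U", "T"))
    w = pwm.width
    if enc.size < w:
        return []
    logodds, iscore, tail, offset = pwm._scoring_tables()
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    cols = np.arange(w)
    int_scores = iscore[cols[None, :], safe].sum(axis=1)
    float_scores = logodds[cols[None, :], safe].sum(axis=1)
    idx = np.clip(int_scores - offset, 0, tail.size - 1)
    pvals = tail[idx]
    pvals = np.where(int_scores - offset < 0, 1.0, pvals)
    keep = (~has_n) & (pvals <= p_threshold)
    cls = motif_class if motif_class is not None else pwm.rbp_name
    return [
        MotifMatch(pwm.motif_id, cls, seq_id, int(o), int(o) + w,
                   float(float_scores[o]), float(pvals[o]))
        for o in np.flatnonzero(keep)
    ]


def scan_library(
    pwms: Sequence[Pwm], sequence: str, p_threshold: float = 1e-4, seq_id: str = "seq"
) -> List[MotifMatch]:
    """Scan one transcript with a whole motif library."""
    out: List[MotifMatch] = []
    for pwm in pwms:
        out.extend(scan_motifs(pwm, sequence, p_threshold, seq_id=seq_id))
    out.sort(key=lambda m: (m.start, m.end, m.motif_id))
    return out


def cluster_matches(
    matches: Sequence[MotifMatch],
    seq_length: Optional[int] = None,
    seq_id: Optional[str] = None,
) -> BlockProfile:
    """Single-linkage clustering of motif matches into blocks.

    Two matches link iff their overlap is at least half the length of the
    shorter match; a block's interval is the union span of its cluster and its
    counts are per-motif-class match counts.
    """
    matches = sorted(matches, key=lambda m: (m.start, m.end, m.motif_id))
    if seq_id is None:
        seq_id = matches[0].seq_id if matches else "seq"
    if seq_length is None:
        seq_length = max((m.end for m in matches), default=0)
    n = len(matches)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ov = min(matches[i].end, matches[j].end) - max(matches[i].start, matches[j].start)
            if ov <= 0:
                continue
            shorter = min(matches[i].end - matches[i].start, matches[j].end - matches[j].start)
            if ov >= 0.5 * shorter:
                parent[find(i)] = find(j)
    clusters: Dict[int, List[MotifMatch]] = {}
    for i, m in enumerate(matches):
        clusters.setdefault(find(i), []).append(m)
    blocks = []
    for members in clusters.values():
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        counts: Dict[str, int] = {}
        for m in members:
            counts[m.motif_class] = counts.get(m.motif_class, 0) + 1
        blocks.append(MotifBlock(seq_id, start, end, (start + end) / 2.0, counts))
    blocks.sort(key=lambda b: (b.start, b.end))
    return BlockProfile(seq_id, seq_length, tuple(blocks))


@dataclass(frozen=True)
class PwmComparison:
    offset: int
    correlation: float
    p_value: float
    comparable: bool


def pwm_similarity(
    a: Pwm, b: Pwm, n_perm: int = 1000, seed: int = 0, min_overlap: int = 4
) -> PwmComparison:
    """Best ungapped offset of b against a by Pearson correlation of the overlap.

    The correlation is computed over the flattened overlapping sub-matrices
    (4 x overlap values); significance by permuting b's columns ``n_perm``
    times.  Used as the motif-merge criterion (merge at p < 0.001).
    """

    def best_corr(mb: np.ndarray) -> Tuple[float, int]:
        wa, wb = a.width, mb.shape[0]
        best, best_off = -np.inf, 0
        for d in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo, hi = max(0, d), min(wa, d + wb)
            if hi - lo < min_overlap:
                continue
            x = a.matrix[lo:hi].ravel()
            y = mb[lo - d : hi - d].ravel()
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if r > best:
                best, best_off = r, d
        return best, best_off

    obs, off = best_corr(b.matrix)
    if not np.isfinite(obs):
        return PwmComparison(0, float("nan"), float("nan"), False)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(b.width)
        r, _ = best_corr(b.matrix[perm])
        if r >= obs:
            hits += 1
    return PwmComparison(off, obs, (1 + hits) / (n_perm + 1), True)


@dataclass(frozen=True)
class ExtrapolationResult:
    pwm: Pwm
    converged: bool
    n_iter: int
    n_matches: int


def extrapolate_motif(
    pwm: Pwm,
    target_sequences: Sequence[str],
    p_threshold: float = 1e-4,
    blend_weight: float = 0.5,
    max_iter: int = 10,
    tol: float = 0.01,
) -> ExtrapolationResult:
    """Iterative mapping-and-refinement of a motif onto a target sequence set.

    Each round scans the targets with the current PWM, builds a base-count
    matrix from the matched sites and blends it with the current matrix
    (``blend_weight`` on the old motif).  Stops when the largest cell change
    drops below ``tol`` or after ``max_iter`` rounds; a round with zero
    matches returns the last PWM flagged unconverged.
    """
    if not target_sequences:
        raise InputError("target sequence set must be non-empty")
    current = pwm
    n_matches = 0
    for it in range(1, max_iter + 1):
        site_counts = np.zeros_like(current.matrix)
        n_matches = 0
        for si, seq in enumerate(target_sequences):
            seq = seq.upper().replace("U", "T")
            for m in scan_motifs(current, seq, p_threshold, seq_id=str(si)):
                enc = encode_sequence(seq[m.start : m.end])
                site_counts[np.arange(current.width), enc] += 1
                n_matches += 1
        if n_matches == 0:
            return ExtrapolationResult(current, False, it, 0)
        freq = regularize_matrix(
            site_counts / site_counts.sum(axis=1, keepdims=True),
            current.background,
            current.pseudocount,
        )
        blended = blend_weight * current.matrix + (1.0 - blend_weight) * freq
        blended /= blended.sum(axis=1, keepdims=True)
        delta = float(np.abs(blended - current.matrix).max())
        current = Pwm(
            current.motif_id, current.rbp_name, current.species,
            blended, current.background, current.pseudocount,
        )
        if delta < tol:
            return ExtrapolationResult(current, True, it, n_matches)
    return ExtrapolationResult(current, False, max_iter, n_matches)


def mutate_rbp_sites(sequence: str, sites: Iterable[Tuple[int, int]]) -> str:
    """Replace each site's subsequence with its antisense (reverse complement).

    Used to ablate predicted RBP-binding sites in rescue-fragment design while
    preserving length and overall base composition.
    """
    sites = sorted(sites)
    for (s1, e1), (s2, e2) in zip(sites, sites[1:]):
        if e1 > s2:
            raise InputError("sites must be disjoint")
    out = list(sequence)
    for s, e in sites:
        if s < 0 or e > len(sequence) or s >= e:
            raise InputError(f"site [{s},{e}) outside sequence")
        out[s:e] = reverse_complement(sequence[s:e])
    return "".join(out)
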