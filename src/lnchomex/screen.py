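"""Paired-crRNA library design and knockout-screen enrichment.

Design side: Cas12a crRNA candidates are kept when the PAM is TTTV, the GC
content of the 23-nt protospacer lies in [0.2, 0.9], the protospacer carries
no UUUU (TTTT in DNA) run, it occurs exactly once in the genome and every
other locus differs by at least two mismatches.  Off-target checking is an
exhaustive Hamming scan over both strands, viable on toy genomes only — no
index structure is built.

Analysis side: per-crRNA time trends are least-squares cubics on
log2(count + 1) versus day (exact interpolation with four time points); the
trend statistic is the fitted end-to-end change centred by the median over
AAVS1 background rows.  Normalised ascending ranks feed robust rank
aggregation: a gene with sorted guide ranks r_(1) <= ... <= r_(k) gets
rho = min_j P(Beta(j, k - j + 1) <= r_(j)), with permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .motifs import encode_sequence, reverse_complement
from .synteny import GeneLocus

PROTOSPACER_LEN = 23
PAM_LEN = 4


# ---------------------------------------------------------------------------
# crRNA design


@dataclass(frozen=True)
class Crrna:
    """One candidate crRNA target site (PAM + 23-nt protospacer)."""

    crrna_id: str
    chrom: str
    start: int  # protospacer interval, 0-based half-open
    end: int
    strand: str
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise InputError(f"{self.crrna_id}: protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam) != PAM_LEN:
            raise InputError(f"{self.crrna_id}: PAM must be {PAM_LEN} nt")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class CrrnaPair:
    pair_id: str
    gene_id: str
    crrna_1: Crrna
    crrna_2: Crrna
    essential_overlap: bool = False


@dataclass(frozen=True)
class FilterResult:
    accepted: bool
    reasons: Tuple[str, ...]


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _genome_occurrences(genome: Dict[str, str], query: str, max_mm: int) -> List[int]:
    """Mismatch counts (<= max_mm) of every genomic window on either strand."""
    q = encode_sequence(query)
    hits: List[int] = []
    for seq in genome.values():
        for strand_seq in (seq, reverse_complement(seq)):
            enc = encode_sequence(strand_seq)
            if enc.size < q.size:
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, q.size)
            mm = np.count_nonzero(win != q[None, :], axis=1)
            hits.extend(int(v) for v in mm[mm <= max_mm])
    return hits


def filter_crrna(candidate: Crrna, genome: Dict[str, str]) -> FilterResult:
    """Apply the per-crRNA acceptance rules; rejections carry reason codes.

    Reason codes: PAM (not TTTV), GC (outside [0.2, 0.9]), polyU (TTTT run),
    not_unique (exact occurrences != 1), offtarget (another locus within one
    mismatch).
    """
    reasons: List[str] = []
    if not (candidate.pam[:3] == "TTT" and candidate.pam[3] in "ACG"):
        reasons.append("PAM")
    gc = gc_content(candidate.protospacer)
    if not 0.2 <= gc <= 0.9:
        reasons.append("GC")
    if "TTTT" in candidate.protospacer:
        reasons.append("polyU")
    near = _genome_occurrences(genome, candidate.protospacer, max_mm=1)
    exact = sum(1 for mm in near if mm == 0)
    if exact != 1:
        reasons.append("not_unique")
    if sum(1 for mm in near if mm == 1) > 0:
        reasons.append("offtarget")
    return FilterResult(not reasons, tuple(reasons))


def enumerate_crrna_candidates(genome: Dict[str, str]) -> List[Crrna]:
    """All TTTN-PAM sites on both strands of a (toy) genome.

    On the + strand a site is PAM at [p, p+4) followed by the protospacer at
    [p+4, p+27); on the - strand coordinates are reported on the forward
    strand with the protospacer interval preceding the PAM.
    """
    out: List[Crrna] = []
    k = 0
    for chrom, seq in genome.items():
        n = len(seq)
        for p in range(0, n - PAM_LEN - PROTOSPACER_LEN + 1):
            if seq[p : p + 3] == "TTT":
                out.append(Crrna(f"cr{k:05d}", chrom, p + 4, p + 27, "+",
                                 seq[p + 4 : p + 27], seq[p : p + 4]))
                k += 1
        rc = reverse_complement(seq)
        for p in range(0, n - PAM_LEN - PROTOSPACER_LEN + 1):
            if rc[p : p + 3] == "TTT":
                # map back to forward-strand coordinates
                start = n - (p + 27)
                out.append(Crrna(f"cr{k:05d}", chrom, start, start + 23, "-",
                                 rc[p + 4 : p + 27], rc[p : p + 4]))
                k += 1
    return out


def filter_crrna_pairs(
    crrnas: Sequence[Crrna],
    lnc: GeneLocus,
    coding_exons: Sequence[Tuple[str, int, int]],
    essential_spans: Sequence[Tuple[str, int, int]] = (),
) -> List[CrrnaPair]:
    """Enumerate and filter crRNA pairs for one target lncRNA.

    Kept pairs (1) flank the lncRNA TSS (one crRNA on each side), (2) avoid
    every coding-gene exon with both crRNAs and (3) target the nontranscribed
    (template) strand with both crRNAs.  Pairs overlapping an essential-gene
    span are flagged, not dropped.
    """
    tss = lnc.start if lnc.strand == "+" else lnc.end
    template = "-" if lnc.strand == "+" else "+"

    def on_chrom(c: Crrna) -> bool:
        return c.chrom == lnc.chrom

    def hits_exon(c: Crrna) -> bool:
        return any(ch == c.chrom and c.start < e and s < c.end
                   for ch, s, e in coding_exons)

    def hits_essential(c: Crrna) -> bool:
        return any(ch == c.chrom and c.start < e and s < c.end
                   for ch, s, e in essential_spans)

    usable = [c for c in crrnas
              if on_chrom(c) and c.strand == template and not hits_exon(c)]
    pairs: List[CrrnaPair] = []
    k = 0
    for i, c1 in enumerate(usable):
        for c2 in usable[i + 1:]:
            s1 = c1.midpoint - tss
            s2 = c2.midpoint - tss
            if s1 * s2 >= 0:  # same side of the TSS, or sitting on it
                continue
            up, down = (c1, c2) if s1 < 0 else (c2, c1)
            pairs.append(CrrnaPair(
                f"{lnc.gene_id}_p{k:04d}", lnc.gene_id, up, down,
                essential_overlap=hits_essential(up) or hits_essential(down),
            ))
            k += 1
    return pairs


# ---------------------------------------------------------------------------
# screen enrichment


@dataclass
class ScreenTable:
    """Normalised crRNA-pair counts over timepoints.

    ``counts``: rows = crRNA pairs, columns = timepoint x replicate samples;
    ``days``: day of each column; ``gene_ids`` and ``is_control`` align with
    the rows (controls are the AAVS1 background pairs).  Counts are expected
    pre-normalised; raw-looking input (very large column-sum imbalance) only
    triggers a warning, never an error.
    """

    counts: pd.DataFrame
    days: np.ndarray
    gene_ids: pd.Series
    is_control: pd.Series

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        if self.days.size != self.counts.shape[1]:
            raise InputError("days must align with count columns")
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        if not bool(self.is_control.any()):
            raise InputError("at least one control (AAVS1) row is required")
        sums = self.counts.values.sum(axis=0)
        if sums.min() > 0 and sums.max() / sums.min() > 3:
            import warnings

            warnings.warn(
                "column sums differ by >3x; counts may not be normalised",
                stacklevel=2,
            )


def read_screen_table(path) -> ScreenTable:
    """Read a screen count TSV: pair_id, gene_id, is_control, then d<day>_r<rep> columns."""
    df = pd.read_csv(path, sep="\t")
    meta = ["pair_id", "gene_id", "is_control"]
    missing = set(meta) - set(df.columns)
    if missing:
        raise InputError(f"missing columns {sorted(missing)}")
    count_cols = [c for c in df.columns if c not in meta]
    days = []
    for c in count_cols:
        if not c.startswith("d") or "_r" not in c:
            raise InputError(f"count column {c!r} must look like d<day>_r<rep>")
        days.append(int(c[1:].split("_r")[0]))
    return ScreenTable(
        df[count_cols].astype(float).set_axis(df["pair_id"]),
        np.array(days),
        df.set_index("pair_id")["gene_id"],
        df.set_index("pair_id")["is_control"].astype(bool),
    )


def fit_time_trend(table: ScreenTable) -> pd.Series:
    """Control-centred cubic end-to-end change per crRNA pair.

    Fits log2(count + 1) against day with a cubic polynomial (replicates
    pooled into one least-squares fit; with exactly four distinct days the
    fit interpolates the per-day means exactly) and takes fitted(last day) -
    fitted(day 0), centred by the median statistic of the control rows.
    """
    days = np.asarray(table.days, dtype=float)
    if np.unique(days).size < 4:
        raise InputError("cubic fit needs >= 4 distinct timepoints")
    y = np.log2(table.counts.values + 1.0)
    X = np.vander(days, 4, increasing=True)  # columns 1, d, d^2, d^3
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # 4 x n_rows
    lo, hi = days.min(), days.max()
    v_lo = np.array([1.0, lo, lo**2, lo**3])
    v_hi = np.array([1.0, hi, hi**2, hi**3])
    raw = (v_hi - v_lo) @ coef
    center = float(np.median(raw[table.is_control.values]))
    return pd.Series(raw - center, index=table.counts.index, name="trend")


def rank_crrnas(statistics: pd.Series) -> pd.Series:
    """Ascending normalised ranks in (0, 1]; most depleted pair gets 1/N."""
    ranks = sps.rankdata(statistics.values, method="average")
    return pd.Series(ranks / statistics.size, index=statistics.index, name="rank")


def control_relative_ranks(statistics: pd.Series, is_control: pd.Series) -> pd.Series:
    """Each crRNA's quantile within the AAVS1 control statistic distribution.

    r = (1 + #{control statistics <= stat}) / (n_controls + 1), in (0, 1].
    For a crRNA behaving like the background this is uniform regardless of
    how many true hits the library contains, which is what the gene-level
    aggregation needs for calibrated p-values; a global rank over all rows
    (see :func:`rank_crrnas`) is deflated near zero as soon as real hits
    occupy the bottom of the list.
    """
    ctrl = np.sort(statistics.values[is_control.values.astype(bool)])
    if ctrl.size == 0:
        raise InputError("control-relative ranks need >= 1 control row")
    q = (1 + np.searchsorted(ctrl, statistics.values, side="right")) / (ctrl.size + 1)
    return pd.Series(q, index=statistics.index, name="rank")


@dataclass(frozen=True)
class RraResult:
    gene_id: str
    rho: float
    p_value: float
    rank: int
    n_crrnas: int


def rho_score(ranks: Sequence[float]) -> float:
    """min over j of P(Beta(j, k - j + 1) <= r_(j)) for sorted guide ranks."""
    r = np.sort(np.asarray(ranks, dtype=float))
    k = r.size
    j = np.arange(1, k + 1)
    return float(np.min(sps.beta.cdf(r, j, k - j + 1)))


def rra_gene_scores(
    ranks: pd.Series,
    gene_ids: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    include_genes: Optional[Sequence[str]] = None,
) -> List[RraResult]:
    """Gene-level robust rank aggregation with Monte-Carlo null p-values.

    The null for a gene with k guides draws k i.i.d. Uniform(0, 1) ranks —
    the no-association null of the rank-aggregation model itself — and
    recomputes rho, n_perm times per distinct k.  Sampling the null from the
    pooled *observed* ranks instead would contaminate it with the true hits'
    extreme ranks and make every p-value conservative.  p-values use the
    add-one convention; genes are ordered by rho.
    """
    rng = np.random.default_rng(seed)
    groups: Dict[str, np.ndarray] = {
        g: ranks.loc[idx].values
        for g, idx in ranks.groupby(gene_ids).groups.items()
    }
    if include_genes is not None:
        groups = {g: v for g, v in groups.items() if g in include_genes}
    null_sorted: Dict[int, np.ndarray] = {}
    for k in sorted({v.size for v in groups.values()}):
        draws = np.sort(rng.uniform(size=(n_perm, k)), axis=1)
        j = np.arange(1, k + 1)
        rho_null = sps.beta.cdf(draws, j[None, :], (k - j + 1)[None, :]).min(axis=1)
        null_sorted[k] = np.sort(rho_null)
    scored = []
    for g, r in groups.items():
        rho = rho_score(r)
        null = null_sorted[r.size]
        p = (1 + int(np.searchsorted(null, rho, side="right"))) / (n_perm + 1)
        scored.append((g, rho, p, r.size))
    scored.sort(key=lambda t: (t[1], t[0]))
    return [
        RraResult(g, rho, p, rank + 1, k)
        for rank, (g, rho, p, k) in enumerate(scored)
    ]


@dataclass(frozen=True)
class CnvBiasResult:
    correlation: float
    p_value: float
    flagged: bool
    defined: bool


def cnv_bias_check(
    results: Sequence[RraResult],
    cnv: Dict[str, float],
    flag_threshold: float = 0.3,
) -> CnvBiasResult:
    """Spearman correlation of RRA rho scores with per-gene copy number.

    A strong correlation would indicate copy-number-driven dropout bias; the
    flag is raised when |rho_spearman| exceeds ``flag_threshold``.
    """
    pairs = [(r.rho, cnv[r.gene_id]) for r in results if r.gene_id in cnv]
    if len(pairs) < 3:
        raise InputError("need >= 3 genes with CNV values")
    x, y = map(np.asarray, zip(*pairs))
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CnvBiasResult(float("nan"), float("nan"), False, False)
    rho, p = sps.spearmanr(x, y)
    return CnvBiasResult(float(rho), float(p), abs(rho) > flag_threshold, True)
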