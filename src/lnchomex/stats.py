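"""Conservation and enrichment statistics on called homolog sets.

The bespoke content here is the handful of published scores (overlap score,
Jaccard index, common histone modification rate, proportion-style odds
ratio) and the permutation-based enrichment scheme; ordinary hypothesis
tests (Mann-Whitney U, Fisher's exact, Pearson/Spearman) are delegated to
scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InputError


@dataclass(frozen=True)
class PairedCountVector:
    """Per-category paired counts (histone marks, tissues, ...) for two genes."""

    labels: Tuple[str, ...]
    x: Tuple[float, ...]
    y: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise InputError("labels, x and y must have equal lengths")
        if any(v < 0 for v in self.x) or any(v < 0 for v in self.y):
            raise InputError("counts must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    position: int
    allele_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise InputError("allele_frequency outside [0,1]")

    @property
    def is_common(self) -> bool:
        """Common SNP: major alternative allele frequency above 5%."""
        return self.allele_frequency > 0.05


def overlap_score(n1: int, n2: int, m: int) -> float:
    """Annotation-set agreement: 0.5 * (m/n1 + m/n2)."""
    if n1 <= 0 or n2 <= 0:
        raise InputError("n1 and n2 must be positive")
    if m > min(n1, n2):
        raise InputError("m exceeds min(n1, n2)")
    return 0.5 * (m / n1 + m / n2)


def jaccard_index(x: int, y: int, n: int) -> float:
    """Cross-species gene conservation: n / (x + y - n)."""
    if n > min(x, y):
        raise InputError("n exceeds min(x, y)")
    if x + y - n <= 0:
        return 0.0
    return n / (x + y - n)


@dataclass(frozen=True)
class AlignmentHit:
    evalue: float
    hit_length: int
    identity: float  # overall, in [0,1]
    coverage: float = 0.0


def sequence_homology_classify(
    hits: Sequence[AlignmentHit],
    evalue_max: float = 1e-4,
    min_hit_len: int = 50,
    min_identity: float = 0.5,
) -> str:
    """Label a gene pair 'homolog_ss' or 'homolog_nss' from its alignment hits.

    homolog_ss requires at least one hit with E-value < evalue_max, hit
    length strictly > min_hit_len and identity strictly > min_identity.
    """
    for h in hits:
        if h.evalue < evalue_max and h.hit_length > min_hit_len and h.identity > min_identity:
            return "homolog_ss"
    return "homolog_nss"


def is_rbp_homolog(hit: AlignmentHit, min_coverage: float = 0.7, min_identity: float = 0.7) -> bool:
    """RBP homology preset: alignment coverage >= 70% and identity >= 70%."""
    return hit.coverage >= min_coverage and hit.identity >= min_identity


def common_histone_rate(v: PairedCountVector) -> float:
    """Sum of per-mark min(x_i, y_i) over sum of per-mark max(x_i, y_i)."""
    num = sum(min(a, b) for a, b in zip(v.x, v.y))
    den = sum(max(a, b) for a, b in zip(v.x, v.y))
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# motif / nonmotif partition and SNP density


def motif_region_partition(
    transcript_length: int, matches: Sequence
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Split [0, transcript_length) into motif (union of matches) and nonmotif."""
    ivs = sorted((m.start, m.end) for m in matches)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        s, e = max(0, s), min(transcript_length, e)
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    nonmotif: List[Tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            nonmotif.append((cursor, s))
        cursor = e
    if cursor < transcript_length:
        nonmotif.append((cursor, transcript_length))
    return merged, nonmotif


def snp_density(
    intervals: Sequence[Tuple[int, int]], variants: Sequence[VariantRecord]
) -> float:
    """Variants per kilobase of the given intervals."""
    length = sum(e - s for s, e in intervals)
    if length == 0:
        return 0.0
    count = sum(1 for v in variants if any(s <= v.position < e for s, e in intervals))
    return 1000.0 * count / length


def compare_densities(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U between two density samples: (U, p)."""
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


# ---------------------------------------------------------------------------
# permutation enrichment (ClinVar-style)


@dataclass(frozen=True)
class EnrichmentResult:
    enrichment: float
    p_value: float
    observed: int
    null_mean: float
    defined: bool


def interval_enrichment_permutation(
    target_set: Iterable[str],
    universe: Iterable[str],
    annotated_ids: Iterable[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of annotated ids in a target set versus same-size random draws.

    enrichment = observed count / mean count over random draws; p is the
    add-one tail fraction of draws with count >= observed.  The count of
    annotated ids in a uniform same-size draw without replacement is
    hypergeometric, so the null is sampled directly from that distribution.
    """
    universe = set(universe)
    targets = set(target_set)
    annotated = set(annotated_ids) & universe
    if not targets <= universe:
        raise InputError("target set must be a subset of the universe")
    if not annotated:
        return EnrichmentResult(float("nan"), 1.0, 0, 0.0, False)
    observed = len(targets & annotated)
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(len(annotated), len(universe) - len(annotated),
                              len(targets), size=n_perm)
    null_mean = float(null.mean())
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    enr = observed / null_mean if null_mean > 0 else float("nan")
    return EnrichmentResult(enr, p, observed, null_mean, np.isfinite(enr))


# ---------------------------------------------------------------------------
# differential-expression odds ratio


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    p_value: float
    defined: bool


def de_odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Ratio-of-ratios odds ratio (a/b)/(c/d) with two-sided Fisher's exact p.

    a, b: focal genes differentially / normally expressed; c, d: background
    genes differentially / normally expressed.  Zero margins (b or d = 0, or
    c = 0) leave the ratio undefined; the Fisher p is still computed on the
    2x2 table.  No continuity correction is applied — the undefined flag is
    the documented behaviour for degenerate margins.
    """
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b == 0 or d == 0 or c == 0:
        return OddsRatioResult(float("nan"), float(p), False)
    return OddsRatioResult((a / b) / (c / d), float(p), True)


# ---------------------------------------------------------------------------
# tissue specificity


def tissue_specificity(expression: np.ndarray) -> np.ndarray:
    """Tau specificity per gene on log-scaled expression.

    ``expression`` is genes x organs (non-negative).  tau =
    sum(1 - e_i/max(e)) / (k - 1) on e = log2(x + 1); 1 means expression in a
    single organ, 0 uniform expression.  All-zero genes get tau 0.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InputError("expression must be genes x organs with >= 2 organs")
    if (x < 0).any():
        raise InputError("negative expression values")
    e = np.log2(x + 1.0)
    emax = e.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(emax > 0, e / emax, 1.0)
    k = x.shape[1]
    return np.sum(1.0 - frac, axis=1) / (k - 1)


def homolog_specificity_correlation(
    tau_a: Sequence[float], tau_b: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation of tissue-specificity scores across homolog pairs."""
    a = np.asarray(tau_a, dtype=float)
    b = np.asarray(tau_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise InputError("need two equal-length samples of size >= 2")
    if a.std() == 0 or b.std() == 0:
        # degenerate: identical-profile convention r = 1 when vectors equal
        return (1.0, 0.0) if np.allclose(a, b) else (float("nan"), float("nan"))
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
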