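"""Synteny features for candidate lncRNA pairs and the random-forest nominator.

For a candidate pair (gene in species A, gene in species B) and one evidence
class (genomic anchors or one-to-one protein homologs), nine counts are taken
within a fixed flank (default 1 Mb) of each gene: elements near A (m1) and
near B (m2) in the upstream (u), downstream (d) and combined flank
(f = u + d) regions, plus the matched counts m — corresponding pairs whose
two sides fall in same-labelled regions of the two genes.  Three proportion
scores m_r / min(m1_r, m2_r) per evidence class, together with the matched
counts, give the 12 features of the classifier.

Upstream/downstream is oriented by each gene's strand; an element is assigned
to a region by its midpoint.  A proportion with min(m1, m2) = 0 is defined as
0 (the ratio is otherwise undefined for an empty flank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, TrainingError

EVIDENCE_CLASSES = ("anchor", "protein")

#: feature order used everywhere a 12-vector appears
FEATURE_NAMES = [
    "anchor_prop_u", "anchor_prop_d", "anchor_prop_f",
    "protein_prop_u", "protein_prop_d", "protein_prop_f",
    "anchor_m_u", "anchor_m_d", "anchor_m_f",
    "protein_m_u", "protein_m_d", "protein_m_f",
]


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"{self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: bad strand")


@dataclass(frozen=True)
class CorrespondencePair:
    """One-to-one corresponding element pair (anchor segment or protein gene)."""

    pair_id: str
    evidence: str  # "anchor" or "protein"
    locus_a: Locus
    locus_b: Locus
    gene_a: str = ""
    gene_b: str = ""


@dataclass(frozen=True)
class FlankCounts:
    """The nine flank counts for one evidence class."""

    m1_u: int
    m1_d: int
    m2_u: int
    m2_d: int
    m_u: int
    m_d: int

    @property
    def m1_f(self) -> int:
        return self.m1_u + self.m1_d

    @property
    def m2_f(self) -> int:
        return self.m2_u + self.m2_d

    @property
    def m_f(self) -> int:
        return self.m_u + self.m_d


def _flank_side(gene: GeneLocus, locus: Locus, flank_bp: int) -> Optional[str]:
    """'u', 'd' or None by the element midpoint, oriented by gene strand."""
    if locus.chrom != gene.chrom:
        return None
    mid = locus.midpoint
    before = gene.start - flank_bp <= mid < gene.start
    after = gene.end <= mid < gene.end + flank_bp
    if gene.strand == "+":
        return "u" if before else ("d" if after else None)
    return "d" if before else ("u" if after else None)


def flank_counts(
    gene_a: GeneLocus,
    gene_b: GeneLocus,
    correspondences: Sequence[CorrespondencePair],
    flank_bp: int = 1_000_000,
) -> Dict[str, FlankCounts]:
    """Count flank elements per evidence class for one candidate pair."""
    acc = {ev: {"m1_u": 0, "m1_d": 0, "m2_u": 0, "m2_d": 0, "m_u": 0, "m_d": 0}
           for ev in EVIDENCE_CLASSES}
    for c in correspondences:
        if c.evidence not in acc:
            raise InputError(f"unknown evidence class {c.evidence!r}")
        side_a = _flank_side(gene_a, c.locus_a, flank_bp)
        side_b = _flank_side(gene_b, c.locus_b, flank_bp)
        d = acc[c.evidence]
        if side_a is not None:
            d[f"m1_{side_a}"] += 1
        if side_b is not None:
            d[f"m2_{side_b}"] += 1
        if side_a is not None and side_a == side_b:
            d[f"m_{side_a}"] += 1
    return {ev: FlankCounts(**vals) for ev, vals in acc.items()}


def proportion_scores(c: FlankCounts) -> Tuple[float, float, float]:
    """(proportion_u, proportion_d, proportion_f) = m_r / min(m1_r, m2_r)."""

    def prop(m: int, m1: int, m2: int) -> float:
        denom = min(m1, m2)
        return m / denom if denom > 0 else 0.0

    return (
        prop(c.m_u, c.m1_u, c.m2_u),
        prop(c.m_d, c.m1_d, c.m2_d),
        prop(c.m_f, c.m1_f, c.m2_f),
    )


def synteny_features(
    gene_a: GeneLocus,
    gene_b: GeneLocus,
    correspondences: Sequence[CorrespondencePair],
    flank_bp: int = 1_000_000,
) -> np.ndarray:
    """The 12-feature vector for one candidate pair, in FEATURE_NAMES order."""
    counts = flank_counts(gene_a, gene_b, correspondences, flank_bp)
    anc, prot = counts["anchor"], counts["protein"]
    pa, pd_, pf = proportion_scores(anc)
    qa, qd, qf = proportion_scores(prot)
    return np.array([
        pa, pd_, pf, qa, qd, qf,
        anc.m_u, anc.m_d, anc.m_f, prot.m_u, prot.m_d, prot.m_f,
    ], dtype=float)


def build_training_set(
    protein_pairs: Sequence[CorrespondencePair],
    genes_a: Dict[str, GeneLocus],
    genes_b: Dict[str, GeneLocus],
    correspondences: Sequence[CorrespondencePair],
    flank_bp: int = 1_000_000,
    n_negative_ratio: float = 1.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Features and labels from one-to-one protein homologs and random decoys.

    Each positive pair's own correspondence record is removed from the
    evidence before its features are computed (leave-one-out, so a gene never
    counts itself as its own syntenic context).  Negatives are uniformly
    sampled non-homologous gene pairs, n_negative_ratio per positive.
    """
    positives = [p for p in protein_pairs if p.gene_a in genes_a and p.gene_b in genes_b]
    if len(positives) < 20:
        raise TrainingError(f"need >= 20 positive pairs, got {len(positives)}")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for p in positives:
        evidence = [c for c in correspondences if c.pair_id != p.pair_id]
        rows.append(synteny_features(genes_a[p.gene_a], genes_b[p.gene_b], evidence, flank_bp))
        labels.append(1)
    homologous = {(p.gene_a, p.gene_b) for p in positives}
    ids_a = sorted(genes_a)
    ids_b = sorted(genes_b)
    n_neg = int(round(len(positives) * n_negative_ratio))
    made = 0
    while made < n_neg:
        ga = ids_a[rng.integers(len(ids_a))]
        gb = ids_b[rng.integers(len(ids_b))]
        if (ga, gb) in homologous:
            continue
        rows.append(synteny_features(genes_a[ga], genes_b[gb], correspondences, flank_bp))
        labels.append(0)
        made += 1
    return np.array(rows), np.array(labels)


def train_synteny_model(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
) -> RandomForestClassifier:
    """Fit the random-forest synteny classifier (500 trees by default)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise TrainingError("non-finite feature values")
    if len(np.unique(labels)) < 2:
        raise TrainingError("labels are single-class")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(features, labels)
    return model


def predict_syntenic(
    model: RandomForestClassifier,
    features: np.ndarray,
    threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """(probability of synteny, boolean candidate flag at ``threshold``)."""
    probs = model.predict_proba(np.asarray(features, dtype=float))[:, 1]
    return probs, probs >= threshold


def candidate_lnc_pairs(
    lnc_a: Sequence[GeneLocus],
    lnc_b: Sequence[GeneLocus],
    anchors: Sequence[CorrespondencePair],
    flank_bp: int = 1_000_000,
) -> List[Tuple[str, str]]:
    """Pre-filter of the candidate universe: pairs bridged by >= 1 anchor.

    A pair qualifies when some anchor correspondence has its A side within
    ``flank_bp`` of the A lncRNA and its B side within ``flank_bp`` of the
    B lncRNA — avoiding the all-vs-all blowup of the full cross product.
    """

    def near(gene: GeneLocus, locus: Locus) -> bool:
        return _flank_side(gene, locus, flank_bp) is not None

    out = []
    for la in lnc_a:
        for lb in lnc_b:
            for anc in anchors:
                if anc.evidence != "anchor":
                    continue
                if near(la, anc.locus_a) and near(lb, anc.locus_b):
                    out.append((la.gene_id, lb.gene_id))
                    break
    return out
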