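"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of the fixture seed (bit-identical
reruns) and produces the same structures — or writes the same formats — the
analysis modules consume.  Planted motif sites use the PWM consensus rather
than sampled letters, so a recovery failure indicates a pipeline bug, not
sampling noise; planted homolog pairs share an ordered set of motif-class
blocks at jittered positions, decoys carry the same class multiset in
shuffled order at fresh positions, and background transcripts each carry
their own random pattern — emulating a pool of real lncRNAs, all of which
have motif blocks of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .motifs import BASES, BlockProfile, MotifBlock, Pwm
from .screen import ScreenTable
from .synteny import CorrespondencePair, GeneLocus, Locus


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic study conditions, with their defaults."""

    seed: int = 0
    # motif library
    n_motifs: int = 24
    # min width 7: at the default scan threshold 1e-4 the best attainable
    # p-value of a width-w motif is 4**-w, so a planted consensus is only
    # guaranteed detectable for w >= 7
    motif_width_range: Tuple[int, int] = (7, 10)
    consensus_prob: float = 0.91
    # planted homolog pairs
    transcript_length_range: Tuple[int, int] = (1400, 2000)
    n_blocks_range: Tuple[int, int] = (6, 10)
    jitter: int = 20
    # direct random block profiles (permutation-calibration fixtures)
    profile_length: int = 2000
    profile_n_classes: int = 12
    profile_blocks_range: Tuple[int, int] = (8, 12)
    profile_classes_per_block: Tuple[int, int] = (1, 3)
    profile_max_count: int = 6
    # synteny genomes
    flank_bp: int = 1_000_000
    n_segments: int = 8
    segment_length: int = 3_000_000
    anchor_spacing: int = 150_000
    protein_spacing: int = 300_000
    locus_jitter: int = 20_000
    lnc_per_segment: int = 2
    # knockout screen
    n_screen_genes: int = 2000
    crrnas_per_gene: int = 3
    # the control pool anchors every null quantile; ~1,000 AAVS1 pairs keep
    # the relative error of the 5% tail estimate under 10% after the
    # three-guide aggregation (see methods note on screen calibration)
    n_controls: int = 1000
    timepoints: Tuple[int, ...] = (0, 15, 30, 45)
    n_replicates: int = 2
    nb_mean: float = 500.0
    nb_dispersion: float = 10.0
    depletion_lfc: float = -2.0
    frac_depleted: float = 0.05

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named fixture stream."""
        return np.random.default_rng([self.seed, stream])


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# motif library


def make_motif_library(spec: FixtureSpec, species: str = "synthetic") -> List[Pwm]:
    """Random informative PWMs (>= 1 bit/column) with unique ids, one per RBP."""
    rng = spec.rng(1)
    lo, hi = spec.motif_width_range
    pwms = []
    for i in range(spec.n_motifs):
        w = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 4, size=w)
        mat = np.full((w, 4), (1.0 - spec.consensus_prob) / 3.0)
        mat[np.arange(w), consensus] = spec.consensus_prob
        pwms.append(Pwm(f"M{i:03d}", f"RBP{i:03d}", species, mat))
    return pwms


# ---------------------------------------------------------------------------
# planted homolog pairs


@dataclass(frozen=True)
class PlantedPair:
    seq_a: str
    seq_b: str
    motif_ids: Tuple[str, ...]       # planted class order in A
    motif_ids_b: Tuple[str, ...]     # class order in B (shuffled for decoys)
    centers_a: Tuple[int, ...]
    centers_b: Tuple[int, ...]
    decoy: bool


def _spaced_centers(
    rng: np.random.Generator, length: int, n: int, min_sep: int, margin: int
) -> np.ndarray:
    """n sorted positions in [margin, length - margin) at least min_sep apart."""
    room = length - 2 * margin - (n - 1) * min_sep
    if room <= 0:
        raise ValueError("transcript too short for the requested block count")
    u = np.sort(rng.uniform(0, room, size=n))
    return (margin + u + np.arange(n) * min_sep).astype(int)


def _plant(
    rng: np.random.Generator,
    length: int,
    motifs: Sequence[Pwm],
    centers: Sequence[int],
) -> str:
    seq = list(random_sequence(rng, length))
    for pwm, c in zip(motifs, centers):
        s = int(c) - pwm.width // 2
        seq[s : s + pwm.width] = pwm.consensus
    return "".join(seq)


def make_homolog_pair(
    spec: FixtureSpec,
    library: Sequence[Pwm],
    rng: Optional[np.random.Generator] = None,
    decoy: bool = False,
) -> PlantedPair:
    """A transcript pair sharing an ordered block pattern (or a shuffled decoy).

    Both sequences are i.i.d. random background with the same ordered set of
    motif-class blocks embedded; B's positions are jittered by at most
    ``spec.jitter`` nt.  A decoy keeps the class multiset but shuffles the
    class order and re-draws B's positions.
    """
    if rng is None:
        rng = spec.rng(2)
    n = int(rng.integers(*spec.n_blocks_range, endpoint=True))
    idx = rng.choice(len(library), size=n, replace=False)
    motifs = [library[i] for i in idx]
    length = int(rng.integers(*spec.transcript_length_range, endpoint=True))
    max_w = max(p.width for p in motifs)
    min_sep = 2 * max_w + 2 * spec.jitter + 10
    centers_a = _spaced_centers(rng, length, n, min_sep, margin=max_w + spec.jitter + 2)
    seq_a = _plant(rng, length, motifs, centers_a)
    if decoy:
        perm = rng.permutation(n)
        while n > 1 and np.all(perm == np.arange(n)):
            perm = rng.permutation(n)
        motifs_b = [motifs[i] for i in perm]
        centers_b = _spaced_centers(rng, length, n, min_sep, margin=max_w + spec.jitter + 2)
    else:
        motifs_b = motifs
        centers_b = centers_a + rng.integers(-spec.jitter, spec.jitter + 1, size=n)
    seq_b = _plant(rng, length, motifs_b, centers_b)
    return PlantedPair(
        seq_a, seq_b,
        tuple(p.motif_id for p in motifs), tuple(p.motif_id for p in motifs_b),
        tuple(int(c) for c in centers_a), tuple(int(c) for c in centers_b),
        decoy,
    )


def make_background_transcripts(
    spec: FixtureSpec,
    library: Sequence[Pwm],
    n: int,
    rng: Optional[np.random.Generator] = None,
) -> List[str]:
    """Background lncRNA pool: each transcript carries its own random pattern."""
    if rng is None:
        rng = spec.rng(3)
    out = []
    for _ in range(n):
        nb = int(rng.integers(*spec.n_blocks_range, endpoint=True))
        idx = rng.choice(len(library), size=nb, replace=False)
        motifs = [library[i] for i in idx]
        length = int(rng.integers(*spec.transcript_length_range, endpoint=True))
        max_w = max(p.width for p in motifs)
        min_sep = 2 * max_w + 2 * spec.jitter + 10
        centers = _spaced_centers(rng, length, nb, min_sep, margin=max_w + spec.jitter + 2)
        out.append(_plant(rng, length, motifs, centers))
    return out


# ---------------------------------------------------------------------------
# direct random block profiles (pure-null calibration substrate)


def make_random_profile(
    spec: FixtureSpec, rng: np.random.Generator, seq_id: str = "prof"
) -> BlockProfile:
    """A random block profile: random classes, counts and positions."""
    n = int(rng.integers(*spec.profile_blocks_range, endpoint=True))
    centers = np.sort(rng.uniform(20, spec.profile_length - 20, size=n))
    blocks = []
    for k, c in enumerate(centers):
        ncls = int(rng.integers(*spec.profile_classes_per_block, endpoint=True))
        classes = rng.choice(spec.profile_n_classes, size=ncls, replace=False)
        counts = {
            f"C{cls:02d}": int(rng.integers(1, spec.profile_max_count + 1))
            for cls in classes
        }
        blocks.append(MotifBlock(seq_id, int(c) - 10, int(c) + 10, float(c), counts))
    return BlockProfile(seq_id, spec.profile_length, tuple(blocks))


def make_random_profiles(
    spec: FixtureSpec, n: int, rng: Optional[np.random.Generator] = None, prefix: str = "p"
) -> List[BlockProfile]:
    if rng is None:
        rng = spec.rng(4)
    return [make_random_profile(spec, rng, f"{prefix}{i:05d}") for i in range(n)]


# ---------------------------------------------------------------------------
# synteny genomes


@dataclass(frozen=True)
class SyntenyFixture:
    genes_a: Dict[str, GeneLocus]
    genes_b: Dict[str, GeneLocus]
    correspondences: Tuple[CorrespondencePair, ...]
    protein_pairs: Tuple[CorrespondencePair, ...]
    planted_lnc_pairs: Tuple[Tuple[str, str], ...]
    decoy_lnc_pairs: Tuple[Tuple[str, str], ...]


def make_synteny_genomes(spec: FixtureSpec) -> SyntenyFixture:
    """Two toy genomes made of conserved segments.

    Within a segment, anchors and one-to-one protein homologs sit at
    corresponding (jittered) positions in both genomes; planted syntenic
    lncRNA pairs sit at corresponding positions and therefore share their
    flanking correspondences, while decoys pair lncRNAs from different
    segments and share none.
    """
    rng = spec.rng(5)
    genes_a: Dict[str, GeneLocus] = {}
    genes_b: Dict[str, GeneLocus] = {}
    corr: List[CorrespondencePair] = []
    protein_pairs: List[CorrespondencePair] = []
    planted: List[Tuple[str, str]] = []
    lnc_by_segment_a: List[List[str]] = []
    lnc_by_segment_b: List[List[str]] = []
    gap = 500_000
    order_b = rng.permutation(spec.n_segments)  # segment order differs between genomes
    for s in range(spec.n_segments):
        base_a = s * (spec.segment_length + gap)
        base_b = int(order_b[s]) * (spec.segment_length + gap)
        n_anc = spec.segment_length // spec.anchor_spacing
        for k in range(n_anc):
            da = k * spec.anchor_spacing + int(rng.integers(0, spec.locus_jitter))
            db = k * spec.anchor_spacing + int(rng.integers(0, spec.locus_jitter))
            corr.append(CorrespondencePair(
                f"anc_s{s}_{k}", "anchor",
                Locus("chrA", base_a + da, base_a + da + 500),
                Locus("chrB", base_b + db, base_b + db + 500),
            ))
        n_prot = spec.segment_length // spec.protein_spacing
        for k in range(n_prot):
            da = k * spec.protein_spacing + int(rng.integers(0, spec.locus_jitter))
            db = k * spec.protein_spacing + int(rng.integers(0, spec.locus_jitter))
            ga, gb = f"protA_s{s}_{k}", f"protB_s{s}_{k}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes_a[ga] = GeneLocus(ga, "chrA", strand, base_a + da, base_a + da + 5000)
            genes_b[gb] = GeneLocus(gb, "chrB", strand, base_b + db, base_b + db + 5000)
            pair = CorrespondencePair(
                f"prot_s{s}_{k}", "protein",
                Locus("chrA", base_a + da, base_a + da + 5000),
                Locus("chrB", base_b + db, base_b + db + 5000),
                gene_a=ga, gene_b=gb,
            )
            corr.append(pair)
            protein_pairs.append(pair)
        seg_lnc_a, seg_lnc_b = [], []
        for k in range(spec.lnc_per_segment):
            pos = int((k + 1) * spec.segment_length / (spec.lnc_per_segment + 1))
            da = pos + int(rng.integers(0, spec.locus_jitter))
            db = pos + int(rng.integers(0, spec.locus_jitter))
            la, lb = f"lncA_s{s}_{k}", f"lncB_s{s}_{k}"
            genes_a[la] = GeneLocus(la, "chrA", "+", base_a + da, base_a + da + 2000)
            genes_b[lb] = GeneLocus(lb, "chrB", "+", base_b + db, base_b + db + 2000)
            planted.append((la, lb))
            seg_lnc_a.append(la)
            seg_lnc_b.append(lb)
        lnc_by_segment_a.append(seg_lnc_a)
        lnc_by_segment_b.append(seg_lnc_b)
    decoys: List[Tuple[str, str]] = []
    for s in range(spec.n_segments):
        t = (s + 1 + int(rng.integers(0, spec.n_segments - 1))) % spec.n_segments
        if t == s:
            t = (s + 1) % spec.n_segments
        for la, lb in zip(lnc_by_segment_a[s], lnc_by_segment_b[t]):
            decoys.append((la, lb))
    return SyntenyFixture(
        genes_a, genes_b, tuple(corr), tuple(protein_pairs),
        tuple(planted), tuple(decoys),
    )


@dataclass(frozen=True)
class GradedPair:
    """An isolated candidate pair sharing exactly k flanking correspondences."""

    k: int
    gene_a: GeneLocus
    gene_b: GeneLocus
    correspondences: Tuple[CorrespondencePair, ...]


def make_graded_synteny_pairs(
    spec: FixtureSpec,
    k_values: Sequence[int] = tuple(range(11)),
    n_per_k: int = 20,
    n_flank_elements: int = 10,
) -> List[GradedPair]:
    """Candidate pairs with a controlled number of shared flank correspondences.

    Each pair lives on its own chromosome pair with ``n_flank_elements``
    anchors and proteins near each gene (half upstream, half downstream);
    exactly k of them correspond across the pair, the rest pair with loci far
    away.  Used to probe monotonicity of the classifier probability in k.
    """
    rng = spec.rng(6)
    out: List[GradedPair] = []
    pos = 2_000_000
    far = 50_000_000
    uid = 0
    for k in k_values:
        for _ in range(n_per_k):
            ca, cb = f"gp{uid}_a", f"gp{uid}_b"
            ga = GeneLocus(f"gA{uid}", ca, "+", pos, pos + 2000)
            gb = GeneLocus(f"gB{uid}", cb, "+", pos, pos + 2000)
            corr: List[CorrespondencePair] = []
            shared = set(rng.choice(n_flank_elements, size=k, replace=False))
            for ev in ("anchor", "protein"):
                for j in range(n_flank_elements):
                    side = 1 if j % 2 == 0 else -1
                    off = side * int(rng.integers(50_000, spec.flank_bp - 50_000))
                    la = Locus(ca, pos + off, pos + off + 500)
                    if j in shared:
                        off_b = side * int(rng.integers(50_000, spec.flank_bp - 50_000))
                        lb = Locus(cb, pos + off_b, pos + off_b + 500)
                    else:
                        lb = Locus(cb, far + j * 10_000, far + j * 10_000 + 500)
                    corr.append(CorrespondencePair(f"g{uid}_{ev}{j}", ev, la, lb))
                    # balance: an element near B whose partner is far in A
                    if j not in shared:
                        off_b = side * int(rng.integers(50_000, spec.flank_bp - 50_000))
                        corr.append(CorrespondencePair(
                            f"g{uid}_{ev}{j}x", ev,
                            Locus(ca, far + j * 10_000, far + j * 10_000 + 500),
                            Locus(cb, pos + off_b, pos + off_b + 500),
                        ))
            out.append(GradedPair(k, ga, gb, tuple(corr)))
            uid += 1
    return out


# ---------------------------------------------------------------------------
# knockout screen


@dataclass(frozen=True)
class ScreenFixture:
    table: ScreenTable
    depleted_genes: frozenset


def make_screen(spec: FixtureSpec) -> ScreenFixture:
    """Negative-binomial screen counts with planted monotone depletion.

    Planted genes decay log-linearly to ``depletion_lfc`` log2 units at the
    final day (per-crRNA efficiency jittered by +-30%); AAVS1 control rows
    and all other genes are flat in expectation.
    """
    rng = spec.rng(7)
    genes = [f"G{i:04d}" for i in range(spec.n_screen_genes)]
    n_dep = int(round(spec.frac_depleted * spec.n_screen_genes))
    depleted = set(rng.choice(genes, size=n_dep, replace=False))
    days = np.array(
        [d for d in spec.timepoints for _ in range(spec.n_replicates)], dtype=float
    )
    cols = [
        f"d{d}_r{r + 1}" for d in spec.timepoints for r in range(spec.n_replicates)
    ]
    rows, gene_ids, is_control, pair_ids = [], [], [], []
    horizon = float(max(spec.timepoints))

    def sample_row(lfc: float) -> np.ndarray:
        base = spec.nb_mean * 2.0 ** rng.normal(0.0, 0.5)
        mean = base * 2.0 ** (lfc * days / horizon)
        r = spec.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    for g in genes:
        for c in range(spec.crrnas_per_gene):
            eff = rng.uniform(0.7, 1.3) if g in depleted else 0.0
            rows.append(sample_row(spec.depletion_lfc * eff))
            gene_ids.append(g)
            is_control.append(False)
            pair_ids.append(f"{g}_cr{c}")
    for c in range(spec.n_controls):
        rows.append(sample_row(0.0))
        gene_ids.append("AAVS1")
        is_control.append(True)
        pair_ids.append(f"AAVS1_cr{c}")
    idx = pd.Index(pair_ids, name="pair_id")
    table = ScreenTable(
        pd.DataFrame(np.array(rows, dtype=float), index=idx, columns=cols),
        days,
        pd.Series(gene_ids, index=idx, name="gene_id"),
        pd.Series(is_control, index=idx, name="is_control"),
    )
    return ScreenFixture(table, frozenset(depleted))


# ---------------------------------------------------------------------------
# toy genome for crRNA design


@dataclass(frozen=True)
class CrisprFixture:
    genome: Dict[str, str]
    lnc: GeneLocus
    coding_exons: Tuple[Tuple[str, int, int], ...]
    essential_spans: Tuple[Tuple[str, int, int], ...]


def make_crispr_fixture(spec: FixtureSpec, genome_length: int = 6000) -> CrisprFixture:
    """A toy genome with a lncRNA TSS, a coding exon and an essential span."""
    rng = spec.rng(8)
    seq = random_sequence(rng, genome_length)
    mid = genome_length // 2
    lnc = GeneLocus("LNC1", "chrT", "+", mid, min(genome_length - 100, mid + 1500))
    return CrisprFixture(
        {"chrT": seq},
        lnc,
        (("chrT", genome_length // 10, genome_length // 10 + 400),),
        (("chrT", mid + 600, mid + 900),),
    )
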