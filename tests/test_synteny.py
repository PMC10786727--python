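import numpy as np
import pytest

from lnchomex.errors import TrainingError
from lnchomex.synteny import (
    CorrespondencePair, FlankCounts, GeneLocus, Locus, build_training_set,
    flank_counts, proportion_scores, synteny_features, train_synteny_model,
    predict_syntenic,
)

FLANK = 1_000_000


def gene(gid, start, strand="+", chrom="chr1"):
    return GeneLocus(gid, chrom, strand, start, start + 2000)


def corr(pid, ev, pos_a, pos_b, chrom_a="chr1", chrom_b="chr2"):
    return CorrespondencePair(pid, ev, Locus(chrom_a, pos_a, pos_a + 500),
                              Locus(chrom_b, pos_b, pos_b + 500))


def brute_flank_counts(gene_a, gene_b, pairs, flank=FLANK):
    """Independent quadratic-time recount used as the oracle."""

    def side(g, loc):
        if loc.chrom != g.chrom:
            return None
        mid = (loc.start + loc.end) / 2
        if g.start - flank <= mid < g.start:
            return "u" if g.strand == "+" else "d"
        if g.end <= mid < g.end + flank:
            return "d" if g.strand == "+" else "u"
        return None

    res = {}
    for ev in ("anchor", "protein"):
        sub = [p for p in pairs if p.evidence == ev]
        m1u = sum(1 for p in sub if side(gene_a, p.locus_a) == "u")
        m1d = sum(1 for p in sub if side(gene_a, p.locus_a) == "d")
        m2u = sum(1 for p in sub if side(gene_b, p.locus_b) == "u")
        m2d = sum(1 for p in sub if side(gene_b, p.locus_b) == "d")
        mu = sum(1 for p in sub
                 if side(gene_a, p.locus_a) == "u" and side(gene_b, p.locus_b) == "u")
        md = sum(1 for p in sub
                 if side(gene_a, p.locus_a) == "d" and side(gene_b, p.locus_b) == "d")
        res[ev] = FlankCounts(m1u, m1d, m2u, m2d, mu, md)
    return res


class TestFlankCounts:
    def test_empty_flanks_are_all_zero(self):
        ga, gb = gene("a", 5_000_000), gene("b", 5_000_000, chrom="chr2")
        fc = flank_counts(ga, gb, [corr("p1", "anchor", 0, 0)])
        assert fc["anchor"] == FlankCounts(0, 0, 0, 0, 0, 0)

    def test_fully_shared_upstream_flank(self):
        ga, gb = gene("a", 5_000_000), gene("b", 5_000_000, chrom="chr2")
        pairs = [corr(f"p{i}", "anchor", 4_500_000 + i * 1000, 4_500_000 + i * 1000)
                 for i in range(3)]
        fc = flank_counts(ga, gb, pairs)["anchor"]
        assert (fc.m_u, fc.m1_u, fc.m2_u) == (3, 3, 3)

    def test_strand_orientation_flips_labels(self):
        ga = gene("a", 5_000_000, strand="-")
        gb = gene("b", 5_000_000, chrom="chr2")
        fc = flank_counts(ga, gb, [corr("p", "anchor", 4_500_000, 4_500_000)])["anchor"]
        assert fc.m1_d == 1 and fc.m1_u == 0  # left of a '-' gene is downstream
        assert fc.m2_u == 1
        assert fc.m_u == 0 and fc.m_d == 0  # labels differ, no match

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            ga = gene("a", int(rng.integers(2_000_000, 8_000_000)),
                      strand="+-"[rng.integers(2)])
            gb = gene("b", int(rng.integers(2_000_000, 8_000_000)),
                      strand="+-"[rng.integers(2)], chrom="chr2")
            pairs = [
                corr(f"p{i}", ("anchor", "protein")[int(rng.integers(2))],
                     int(rng.integers(0, 10_000_000)), int(rng.integers(0, 10_000_000)))
                for i in range(int(rng.integers(0, 40)))
            ]
            assert flank_counts(ga, gb, pairs) == brute_flank_counts(ga, gb, pairs)

    def test_features_symmetric_under_species_swap(self, rng):
        for _ in range(50):
            ga = gene("a", int(rng.integers(2_000_000, 8_000_000)))
            gb = gene("b", int(rng.integers(2_000_000, 8_000_000)), chrom="chr2")
            pairs = [corr(f"p{i}", "anchor", int(rng.integers(0, 10_000_000)),
                          int(rng.integers(0, 10_000_000)))
                     for i in range(20)]
            fwd = synteny_features(ga, gb, pairs)
            swapped = [CorrespondencePair(p.pair_id, p.evidence, p.locus_b, p.locus_a)
                       for p in pairs]
            rev = synteny_features(gb, ga, swapped)
            np.testing.assert_allclose(fwd, rev)


class TestProportionScores:
    def test_direct_formula(self):
        fc = FlankCounts(m1_u=4, m1_d=0, m2_u=8, m2_d=0, m_u=2, m_d=0)
        assert proportion_scores(fc)[0] == 0.5

    def test_saturated(self):
        fc = FlankCounts(3, 0, 3, 0, 3, 0)
        pu, _, pf = proportion_scores(fc)
        assert pu == 1.0 and pf == 1.0

    def test_empty_flank_convention(self):
        fc = FlankCounts(0, 0, 5, 0, 0, 0)
        assert proportion_scores(fc) == (0.0, 0.0, 0.0)

    def test_f_counts_are_sums(self):
        fc = FlankCounts(2, 3, 4, 1, 1, 1)
        assert fc.m1_f == 5 and fc.m2_f == 5 and fc.m_f == 2


class TestTrainingSet:
    def make_world(self, n=30):
        genes_a, genes_b, pairs = {}, {}, []
        for i in range(n):
            base = 2_000_000 + i * 3_000_000
            ga, gb = f"pA{i}", f"pB{i}"
            genes_a[ga] = GeneLocus(ga, "chr1", "+", base, base + 2000)
            genes_b[gb] = GeneLocus(gb, "chr2", "+", base, base + 2000)
            pairs.append(CorrespondencePair(
                f"pp{i}", "protein",
                Locus("chr1", base, base + 2000), Locus("chr2", base, base + 2000),
                gene_a=ga, gene_b=gb))
            # shared flanking anchors make the true pairs syntenic
            for k in range(4):
                off = (k + 1) * 150_000
                pairs.append(corr(f"anc{i}_{k}", "anchor", base + off, base + off))
        return genes_a, genes_b, pairs

    def test_counts_and_labels(self):
        genes_a, genes_b, pairs = self.make_world()
        prot = [p for p in pairs if p.evidence == "protein"]
        X, y = build_training_set(prot, genes_a, genes_b, pairs, seed=0)
        assert X.shape == (60, 12)
        assert y.sum() == 30 and (y == 0).sum() == 30

    def test_focal_pair_never_counts_itself(self):
        # a protein pair with *no other* correspondences nearby must see all-zero features
        ga = {"pA0": GeneLocus("pA0", "chr1", "+", 5_000_000, 5_002_000)}
        gb = {"pB0": GeneLocus("pB0", "chr2", "+", 5_000_000, 5_002_000)}
        focal = CorrespondencePair("pp0", "protein",
                                   Locus("chr1", 4_900_000, 4_902_000),
                                   Locus("chr2", 4_900_000, 4_902_000),
                                   gene_a="pA0", gene_b="pB0")
        feats = synteny_features(ga["pA0"], gb["pB0"],
                                 [c for c in [focal] if c.pair_id != focal.pair_id])
        assert np.all(feats == 0)

    def test_positive_rows_match_direct_recomputation(self):
        genes_a, genes_b, pairs = self.make_world(25)
        prot = [p for p in pairs if p.evidence == "protein"]
        X, y = build_training_set(prot, genes_a, genes_b, pairs, seed=1)
        for i, p in enumerate(prot):
            expected = synteny_features(
                genes_a[p.gene_a], genes_b[p.gene_b],
                [c for c in pairs if c.pair_id != p.pair_id])
            np.testing.assert_allclose(X[i], expected)

    def test_too_few_positives_is_an_error(self):
        genes_a, genes_b, pairs = self.make_world(5)
        prot = [p for p in pairs if p.evidence == "protein"]
        with pytest.raises(TrainingError):
            build_training_set(prot, genes_a, genes_b, pairs)


class TestModel:
    def test_separable_fixture_is_separated(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0.7, 1.0, size=(40, 12))
        neg = rng.uniform(0.0, 0.3, size=(40, 12))
        X = np.vstack([pos, neg])
        y = np.array([1] * 40 + [0] * 40)
        model = train_synteny_model(X, y, seed=0, n_estimators=100)
        probs, flags = predict_syntenic(model, X)
        assert probs[:40].min() > probs[40:].max()
        assert flags[:40].all() and not flags[40:].any()

    def test_single_class_labels_rejected(self):
        with pytest.raises(TrainingError):
            train_synteny_model(np.zeros((10, 12)), np.ones(10))

    def test_fixed_seed_reproduces_scores(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(60, 12))
        y = (X[:, 0] > 0.5).astype(int)
        p1, _ = predict_syntenic(train_synteny_model(X, y, seed=5, n_estimators=50), X)
        p2, _ = predict_syntenic(train_synteny_model(X, y, seed=5, n_estimators=50), X)
        np.testing.assert_array_equal(p1, p2)
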