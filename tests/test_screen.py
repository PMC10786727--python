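import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lnchomex.errors import InputError
from lnchomex.screen import (
    Crrna, CnvBiasResult, RraResult, ScreenTable, cnv_bias_check,
    enumerate_crrna_candidates, filter_crrna, filter_crrna_pairs,
    fit_time_trend, gc_content, rank_crrnas, rho_score, rra_gene_scores,
)
from lnchomex.synteny import GeneLocus


def embed(genome_seq, protospacer, pam="TTTA", pos=100):
    s = list(genome_seq)
    s[pos : pos + 4] = pam
    s[pos + 4 : pos + 27] = protospacer
    return "".join(s)


def crrna(protospacer, pam="TTTA", start=104, strand="+", chrom="chrT"):
    return Crrna("cr", chrom, start, start + 23, strand, protospacer, pam)


@pytest.fixture()
def proto():
    # GC 10/23, no TTTT run
    return "ACGTACGTACGGCCATGCATGCA"


@pytest.fixture()
def genome(rng, proto):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    return {"chrT": embed(seq, proto)}


class TestFilterCrrna:
    def test_good_candidate_passes(self, genome, proto):
        res = filter_crrna(crrna(proto), genome)
        assert res.accepted, res.reasons

    def test_pam_tttt_rejected(self, genome, proto):
        genome = {"chrT": embed(genome["chrT"], proto, pam="TTTT")}
        res = filter_crrna(crrna(proto, pam="TTTT"), genome)
        assert "PAM" in res.reasons

    def test_gc_bounds(self, genome):
        at_rich = "ATATATATAATATTAATATAATA"
        genome = {"chrT": embed(genome["chrT"], at_rich)}
        res = filter_crrna(crrna(at_rich), genome)
        assert gc_content(at_rich) < 0.2
        assert "GC" in res.reasons

    def test_polyu_rejected(self, genome):
        poly = "ACGTTTTACGGCCATGCATGCAC"
        genome = {"chrT": embed(genome["chrT"], poly)}
        res = filter_crrna(crrna(poly), genome)
        assert "TTTT" in poly and "polyU" in res.reasons

    def test_duplicate_locus_rejected(self, genome, proto):
        seq = genome["chrT"]
        genome = {"chrT": embed(seq, proto, pos=1000)}  # second exact copy
        res = filter_crrna(crrna(proto), genome)
        assert "not_unique" in res.reasons

    def test_one_mismatch_neighbour_rejected(self, genome, proto):
        variant = "G" + proto[1:]
        assert variant != proto
        genome = {"chrT": embed(genome["chrT"], variant, pos=1000)}
        res = filter_crrna(crrna(proto), genome)
        assert "offtarget" in res.reasons


class TestPairFilter:
    def make_crrnas(self, positions, strand="-"):
        out = []
        for i, p in enumerate(positions):
            out.append(Crrna(f"c{i}", "chrT", p, p + 23, strand,
                             "ACGTACGTACGGCCATGCATGCA", "TTTA"))
        return out

    def lnc(self):
        return GeneLocus("LNC1", "chrT", "+", 1000, 2000)

    def test_flanking_pair_is_kept(self):
        pairs = filter_crrna_pairs(self.make_crrnas([900, 1100]), self.lnc(), [])
        assert len(pairs) == 1
        assert pairs[0].crrna_1.start == 900  # upstream first

    def test_same_side_pair_rejected(self):
        assert filter_crrna_pairs(self.make_crrnas([800, 900]), self.lnc(), []) == []

    def test_coding_exon_overlap_rejected(self):
        pairs = filter_crrna_pairs(self.make_crrnas([900, 1100]), self.lnc(),
                                   [("chrT", 890, 930)])
        assert pairs == []

    def test_transcribed_strand_rejected(self):
        pairs = filter_crrna_pairs(self.make_crrnas([900, 1100], strand="+"),
                                   self.lnc(), [])
        assert pairs == []

    def test_essential_overlap_flags_not_drops(self):
        pairs = filter_crrna_pairs(self.make_crrnas([900, 1100]), self.lnc(), [],
                                   essential_spans=[("chrT", 1090, 1130)])
        assert len(pairs) == 1 and pairs[0].essential_overlap


def make_table(rows, days=(0, 15, 30, 45), n_controls=2):
    cols = [f"d{d}_r1" for d in days]
    data, genes, ctrl, ids = [], [], [], []
    for i, (gene, series) in enumerate(rows):
        data.append(series)
        genes.append(gene)
        ctrl.append(gene == "AAVS1")
        ids.append(f"p{i}")
    idx = pd.Index(ids, name="pair_id")
    return ScreenTable(pd.DataFrame(data, index=idx, columns=cols),
                       np.array(days, dtype=float),
                       pd.Series(genes, index=idx),
                       pd.Series(ctrl, index=idx))


class TestTimeTrend:
    def test_constant_series_statistic_is_zero(self):
        rows = [("g1", [100, 100, 100, 100])] + [("AAVS1", [50, 50, 50, 50])] * 2
        trend = fit_time_trend(make_table(rows))
        assert trend["p0"] == pytest.approx(0.0, abs=1e-9)

    def test_four_points_are_interpolated_exactly(self):
        # a known cubic in log2 space is recovered and the endpoint change matches
        days = np.array([0.0, 15.0, 30.0, 45.0])
        coef = np.array([8.0, 0.05, -0.002, 0.00002])
        logc = np.vander(days, 4, increasing=True) @ coef
        counts = 2.0**logc - 1.0
        rows = [("g1", counts), ("AAVS1", [50, 50, 50, 50]),
                ("AAVS1", [80, 80, 80, 80])]
        table = make_table(rows)
        trend = fit_time_trend(table)
        expected = logc[-1] - logc[0]
        assert trend["p0"] == pytest.approx(expected, abs=1e-9)
        # exact interpolation: residuals vanish
        X = np.vander(days, 4, increasing=True)
        fit, *_ = np.linalg.lstsq(X, np.log2(counts + 1.0), rcond=None)
        assert np.abs(X @ fit - logc).max() < 1e-9

    def test_statistic_invariant_to_global_scaling(self, rng):
        rows = [(f"g{i}", rng.uniform(50, 500, size=4)) for i in range(10)]
        rows += [("AAVS1", rng.uniform(50, 500, size=4)) for _ in range(5)]
        t1 = fit_time_trend(make_table(rows))
        scaled = [(g, [4 * v for v in series]) for g, series in rows]
        # multiplying every count+1 by 4 adds 2 to all log-counts: centering removes it
        shifted = [(g, [4 * (v + 1) - 1 for v in series]) for g, series in rows]
        t2 = fit_time_trend(make_table(shifted))
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)

    def test_missing_timepoint_is_an_error(self):
        rows = [("g1", [1, 2, 3]), ("AAVS1", [1, 1, 1])]
        with pytest.raises(InputError):
            fit_time_trend(make_table(rows, days=(0, 15, 30)))


class TestRanks:
    def test_most_depleted_gets_smallest_rank(self):
        s = pd.Series([-3.0, 0.0, 2.0], index=["a", "b", "c"])
        r = rank_crrnas(s)
        assert r["a"] == pytest.approx(1 / 3)
        assert r["c"] == pytest.approx(1.0)

    def test_all_ties_average(self):
        s = pd.Series([1.0] * 4, index=list("abcd"))
        assert set(rank_crrnas(s).round(9)) == {round((4 + 1) / (2 * 4), 9)}

    def test_control_relative_ranks_are_uniform_for_background_rows(self, rng):
        from lnchomex.screen import control_relative_ranks

        stats = pd.Series(rng.normal(size=1000), index=[f"p{i}" for i in range(1000)])
        ctrl = pd.Series([i >= 800 for i in range(1000)], index=stats.index)
        r = control_relative_ranks(stats, ctrl)
        assert r.min() > 0 and r.max() <= 1
        # null rows share the control distribution: quantiles are near-uniform
        assert abs(r[~ctrl].mean() - 0.5) < 0.05
        # the tail probability that the gene-level aggregation relies on
        assert abs((r[~ctrl] <= 0.05).mean() - 0.05) < 0.03

    def test_matches_sort_based_recomputation(self, rng):
        vals = rng.normal(size=200)
        s = pd.Series(vals, index=[f"p{i}" for i in range(200)])
        r = rank_crrnas(s)
        expected = (np.argsort(np.argsort(vals)) + 1) / 200
        np.testing.assert_allclose(np.sort(r.values), np.sort(expected))


class TestRra:
    def test_single_guide_rho_is_its_rank(self):
        assert rho_score([0.2]) == pytest.approx(0.2)

    def test_two_guide_closed_form(self):
        # j=1: 1-(1-r)^2, j=2: r^2  ->  min(0.19, 0.81)
        assert rho_score([0.1, 0.9]) == pytest.approx(0.19)

    def test_dominant_gene_ranks_first(self):
        ranks = pd.Series([0.01, 0.02, 0.5, 0.6, 0.7, 0.9],
                          index=[f"p{i}" for i in range(6)])
        genes = pd.Series(["hit", "hit", "g1", "g1", "g2", "g2"],
                          index=ranks.index)
        res = rra_gene_scores(ranks, genes, n_perm=500, seed=0)
        assert res[0].gene_id == "hit"
        assert res[0].rho == min(r.rho for r in res)
        assert res[0].p_value == min(r.p_value for r in res)

    def test_rho_in_unit_interval_and_monotone(self, rng):
        for _ in range(50):
            r = np.sort(rng.uniform(size=4))
            rho = rho_score(r)
            assert 0 < rho <= 1
            better = r.copy()
            better[2] = better[2] * 0.5
            assert rho_score(better) <= rho + 1e-12


class TestCnv:
    def make_results(self, rhos):
        return [RraResult(f"g{i}", float(r), 0.5, i + 1, 3)
                for i, r in enumerate(rhos)]

    def test_independent_cnv_is_unflagged(self, rng):
        res = self.make_results(rng.uniform(size=300))
        cnv = {f"g{i}": float(v) for i, v in enumerate(rng.normal(2, 0.5, size=300))}
        out = cnv_bias_check(res, cnv)
        assert out.defined and not out.flagged and abs(out.correlation) < 0.15

    def test_induced_confound_is_flagged(self, rng):
        rhos = rng.uniform(size=300)
        res = self.make_results(rhos)
        cnv = {f"g{i}": float(5 - 3 * r + rng.normal(0, 0.1))
               for i, r in enumerate(rhos)}
        out = cnv_bias_check(res, cnv)
        assert out.flagged

    def test_constant_cnv_is_undefined(self):
        res = self.make_results([0.1, 0.5, 0.9])
        out = cnv_bias_check(res, {r.gene_id: 2.0 for r in res})
        assert not out.defined


class TestEnumeration:
    def test_candidates_have_valid_structure(self, genome):
        for c in enumerate_crrna_candidates(genome):
            assert c.pam[:3] == "TTT"
            assert len(c.protospacer) == 23
            seq = genome[c.chrom]
            if c.strand == "+":
                assert seq[c.start : c.end] == c.protospacer
            else:
                from lnchomex.motifs import reverse_complement
                assert reverse_complement(seq[c.start : c.end]) == c.protospacer
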