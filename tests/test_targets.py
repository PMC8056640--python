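import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncflow.models import AnnotationSet, TranscriptModel
from lncflow.targets import (
    TargetPair,
    cis_targets,
    pearson_test,
    span_distance,
    trans_targets,
)


def _gene(gene_id, start, end, chrom="chr1", strand="+"):
    return TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, ((start, end),))


def _lnc(tid, start, end, chrom="chr1", strand="+"):
    mid = (start + end) // 2
    return TranscriptModel(tid, tid, chrom, strand, ((start, mid), (mid + 1, end)))


class TestCisTargets:
    def test_inside_window(self):
        ref = AnnotationSet([_gene("g1", 160_000, 165_000)])
        lnc = _lnc("l1", 100_000, 110_000)
        pairs = cis_targets([lnc], ref)
        assert len(pairs) == 1
        assert pairs[0].distance_bp == 50_000

    def test_beyond_window_excluded(self):
        ref = AnnotationSet([_gene("g1", 260_000, 265_000)])
        assert cis_targets([_lnc("l1", 100_000, 110_000)], ref) == []

    def test_exactly_at_window_included(self):
        ref = AnnotationSet([_gene("g1", 210_000, 215_000)])
        pairs = cis_targets([_lnc("l1", 100_000, 110_000)], ref)
        assert len(pairs) == 1
        assert pairs[0].distance_bp == 100_000

    def test_overlap_gives_distance_zero(self):
        ref = AnnotationSet([_gene("g1", 105_000, 115_000)])
        pairs = cis_targets([_lnc("l1", 100_000, 110_000)], ref)
        assert pairs[0].distance_bp == 0

    def test_other_chromosome_excluded(self):
        ref = AnnotationSet([_gene("g1", 100_000, 110_000, chrom="chr2")])
        assert cis_targets([_lnc("l1", 100_000, 110_000)], ref) == []

    def test_strand_agnostic(self):
        ref = AnnotationSet([_gene("g1", 120_000, 125_000, strand="-")])
        assert len(cis_targets([_lnc("l1", 100_000, 110_000)], ref)) == 1

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(13)
        genes = []
        for i in range(80):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 1_500_000))
            genes.append(_gene(f"g{i}", start, start + int(rng.integers(500, 5000)),
                               chrom=chrom))
        ref = AnnotationSet(genes)
        lncs = []
        for i in range(100):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 1_500_000))
            lncs.append(_lnc(f"l{i}", start, start + int(rng.integers(300, 2000)),
                             chrom=chrom))
        found = {(p.lncrna_id, p.mrna_id, p.distance_bp)
                 for p in cis_targets(lncs, ref)}
        expected = set()
        for l in lncs:
            for g in genes:
                if g.chrom != l.chrom:
                    continue
                d = span_distance(l.start, l.end, g.start, g.end)
                if d <= 100_000:
                    expected.add((l.transcript_id, g.gene_id, d))
        assert found == expected

    def test_planted_cis_pairs_recovered(self, study):
        lnc = [t for t in study.assembled
               if t.transcript_id in study.truth.positional_class]
        found = {(p.lncrna_id, p.mrna_id) for p in cis_targets(lnc, study.reference)}
        assert study.truth.planted_cis_pairs <= found


class TestPearsonTest:
    def test_affine_relation(self):
        x = np.arange(9.0)
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_r_09_n9_matches_t_distribution_oracle(self):
        # construct vectors with sample r exactly 0.9
        rng = np.random.default_rng(1)
        x = rng.normal(size=9)
        e = rng.normal(size=9)
        xs = (x - x.mean()) / x.std()
        es = e - e.mean()
        es -= xs * (es @ xs) / (xs @ xs)  # orthogonalize
        es /= es.std()
        y = 0.9 * xs + np.sqrt(1 - 0.81) * es
        r, p = pearson_test(xs, y)
        assert r == pytest.approx(0.9, abs=1e-12)
        t = 0.9 * np.sqrt(7 / (1 - 0.81))
        expected_p = 2 * stats.t.sf(t, df=7)
        assert p == pytest.approx(expected_p, rel=1e-6)
        assert expected_p == pytest.approx(9.4e-4, rel=0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=9), rng.normal(size=9)
        perm = rng.permutation(9)
        assert pearson_test(x, y) == pytest.approx(pearson_test(x[perm], y[perm]))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test(np.ones(9), np.arange(9.0))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=9), rng.normal(size=9)
            r, p = pearson_test(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)


class TestTransTargets:
    def _expr(self, mat, prefix):
        return pd.DataFrame(
            mat,
            index=[f"{prefix}{i}" for i in range(len(mat))],
            columns=[f"s{j}" for j in range(mat.shape[1])],
        )

    def test_planted_pairs_recovered(self, study, study_fpkm):
        lnc = sorted(study.truth.positional_class)
        mrna = sorted(study.truth.coding_gene_ids)
        pairs = trans_targets(study_fpkm.loc[lnc], study_fpkm.loc[mrna])
        found = {(p.lncrna_id, p.mrna_id) for p in pairs}
        truth = study.truth.planted_trans_pairs
        recall = len(truth & found) / len(truth)
        assert recall >= 0.9

    def test_null_false_positive_rate(self):
        """Independent profiles: joint rule fires well below the p cutoff."""
        rng = np.random.default_rng(8)
        n_pairs = 10_000
        x = np.log10(rng.lognormal(2, 1, size=(n_pairs, 9)) + 0.01)
        y = np.log10(rng.lognormal(2, 1, size=(n_pairs, 9)) + 0.01)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc * xc).sum(1) * (yc * yc).sum(1))
        t = np.abs(r) * np.sqrt(7 / (1 - r * r))
        p = 2 * stats.t.sf(t, df=7)
        rate = float(((np.abs(r) > 0.9) & (p < 0.01)).mean())
        assert rate <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n_pairs)

    def test_boundary_r_excluded(self):
        # y built so that sample r with x is exactly 0.9 on raw scale
        rng = np.random.default_rng(4)
        x = rng.normal(10, 1, size=9)
        e = rng.normal(size=9)
        xs = (x - x.mean()) / x.std()
        es = e - e.mean()
        es -= xs * (es @ xs) / (xs @ xs)
        es /= es.std()
        y = 0.9 * xs + np.sqrt(1 - 0.81) * es
        a = self._expr(x[None, :], "l")
        b = self._expr((y - y.min() + 1.0)[None, :], "m")
        pairs = trans_targets(a, b, log_scale=False)
        assert pairs == []  # strict > 0.9

    def test_no_shared_samples_errors(self):
        a = self._expr(np.ones((1, 9)), "l")
        b = pd.DataFrame(np.ones((1, 9)), index=["m0"],
                         columns=[f"z{j}" for j in range(9)])
        with pytest.raises(ValueError, match="share no sample"):
            trans_targets(a, b)

    def test_emitted_pairs_satisfy_invariants(self, study, study_fpkm):
        lnc = sorted(study.truth.positional_class)
        mrna = sorted(study.truth.coding_gene_ids)
        pairs = trans_targets(study_fpkm.loc[lnc], study_fpkm.loc[mrna])
        for p in pairs:
            assert abs(p.pcc) > 0.9
            assert p.p_value < 0.01


def test_target_pair_invariants_enforced():
    with pytest.raises(ValueError):
        TargetPair("l", "m", "cis", distance_bp=-1)
    with pytest.raises(ValueError):
        TargetPair("l", "m", "trans", pcc=1.5, p_value=0.001)
    with pytest.raises(ValueError):
        TargetPair("l", "m", "chimeric")
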