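"""Peak assignment, training-set construction, DM prior learning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peakprior.annotation import Transcript, cluster_tss_groups
from peakprior.chip import (
    ALPHA_MAX,
    ALPHA_MIN,
    Peak,
    PriorSpec,
    TrainingSet,
    build_training_set,
    compare_prior_sources,
    dm_log_likelihood,
    fit_prior,
    gene_peak_status,
    informativeness_test,
    partition_units,
    read_peaks,
    tss_peak_status,
    tss_signal_rpm,
)


class TestReadPeaks:
    def test_narrowpeak_signal_column(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t900\t1100\t.\t0\t.\t7.5\t-1\t-1\t100\n")
        (peak,) = read_peaks(str(p))
        assert (peak.chrom, peak.start, peak.end, peak.signal) == (
            "chr1",
            900,
            1100,
            7.5,
        )

    def test_bed6_score_column(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t20\tx\t3.0\t+\n")
        (peak,) = read_peaks(str(p), format="bed6")
        assert peak.signal == 3.0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("")
        assert read_peaks(str(p)) == []

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t1100\t900\t.\t0\t.\t7.5\t-1\t-1\t100\n")
        with pytest.raises(ValueError, match=":1"):
            read_peaks(str(p))


def _tx(tid, tss, gid="g", chrom="c"):
    return Transcript(tid, gid, chrom, "+", ((tss, tss + 1000),))


class TestTssPeakStatus:
    def test_window_overlap_boundaries(self):
        t = _tx("t", 1000)
        # window is [500, 1501): a peak starting at 1400 hits, at 1501 misses
        f1 = tss_peak_status([t], [Peak("c", 1400, 1600, 1.0)])[0]
        f2 = tss_peak_status([t], [Peak("c", 1501, 1600, 1.0)])[0]
        assert f1.has_peak and not f2.has_peak

    def test_signal_sums_over_peaks(self):
        t = _tx("t", 1000)
        f = tss_peak_status(
            [t], [Peak("c", 400, 600, 2.0), Peak("c", 900, 1100, 3.0)]
        )[0]
        assert f.signal == 5.0

    def test_other_chromosome_ignored(self):
        t = _tx("t", 1000)
        f = tss_peak_status([t], [Peak("other", 900, 1100, 3.0)])[0]
        assert not f.has_peak

    def test_group_uses_all_member_windows(self):
        ts = [_tx("a", 1000), _tx("b", 1400)]
        (g,) = cluster_tss_groups(ts)
        f = tss_peak_status([g], [Peak("c", 1850, 1950, 1.0)])[0]
        assert f.has_peak  # inside b's window only

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            tss_peak_status([_tx("t", 1000)], [], flank=-1)


class TestTssSignalRpm:
    def test_rpm_formula(self):
        t = _tx("t", 1000)
        reads = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [950, 1050], "end": [980, 1080]}
        )
        rpm = tss_signal_rpm(reads, [t], flank=100, library_depth=10**6)
        assert rpm["t"] == pytest.approx(2.0)

    def test_single_read_at_high_depth(self):
        # one read at a typical deep-library depth lands near 0.022 RPM
        t = _tx("t", 1000)
        reads = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1030]})
        rpm = tss_signal_rpm(reads, [t], flank=100, library_depth=45_500_000)
        assert rpm["t"] == pytest.approx(0.022, rel=0.01)

    def test_read_counted_once_per_group(self):
        ts = [_tx("a", 1000), _tx("b", 1100)]
        (g,) = cluster_tss_groups(ts)
        reads = pd.DataFrame({"chrom": ["c"], "start": [1050], "end": [1080]})
        rpm = tss_signal_rpm(reads, [g], flank=100, library_depth=10**6)
        assert rpm[g.group_id] == pytest.approx(1.0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            tss_signal_rpm(pd.DataFrame(), [_tx("t", 0)], library_depth=0)


class TestBuildTrainingSet:
    def _counts(self, txs):
        return {t.transcript_id: 10.0 for t in txs}

    def test_disjoint_genes_eligible(self):
        txs = [_tx("a", 1000, "g1"), _tx("b", 10000, "g2")]
        groups = cluster_tss_groups(txs)
        peaks = [Peak("c", 950, 1050, 1.0)]
        ts = build_training_set(txs, groups, peaks, self._counts(txs))
        assert sorted(ts.unit_ids) == ["a", "b"]

    def test_overlapping_genes_excluded(self):
        txs = [
            _tx("a", 1000, "g1"),
            _tx("b", 1500, "g2"),  # spans overlap
            _tx("d", 10000, "g3"),
            _tx("e", 20000, "g4"),
        ]
        groups = cluster_tss_groups(txs)
        peaks = [Peak("c", 9950, 10050, 1.0)]
        ts = build_training_set(txs, groups, peaks, self._counts(txs))
        assert sorted(ts.unit_ids) == ["d", "e"]

    def test_overlapping_tss_windows_excluded(self):
        # same gene, two TSS groups whose windows overlap (gap 600 < 1001)
        txs = [
            Transcript("a", "g1", "c", "+", ((1000, 1200),)),
            Transcript("b", "g1", "c", "+", ((1600, 1800),)),
            _tx("d", 10000, "g3"),
            _tx("e", 20000, "g4"),
        ]
        groups = cluster_tss_groups(txs)
        assert len([g for g in groups if g.gene_id == "g1"]) == 2
        peaks = [Peak("c", 9950, 10050, 1.0)]
        ts = build_training_set(txs, groups, peaks, self._counts(txs))
        assert "a" not in ts.unit_ids and "b" not in ts.unit_ids

    def test_empty_training_set_is_an_error(self):
        txs = [_tx("a", 1000, "g1"), _tx("b", 1500, "g2")]
        groups = cluster_tss_groups(txs)
        with pytest.raises(ValueError, match="training set"):
            build_training_set(txs, groups, [], self._counts(txs))


class TestDmLogLikelihood:
    def test_unit_alpha_is_uniform_over_compositions(self):
        # with alpha=1 the DM is uniform over the 3 compositions of N=2
        for counts in ([1.0, 1.0], [2.0, 0.0], [0.0, 2.0]):
            ll = dm_log_likelihood(np.array(counts), np.array([1, 1]), [1.0])
            assert ll == pytest.approx(np.log(1 / 3), abs=1e-9)

    def test_two_partition_value(self):
        # counts (5,0) under alphas (0.60, 0.04): independent log-Gamma oracle
        from scipy.special import gammaln as G

        a1, a2 = 0.60, 0.04
        A = a1 + a2
        expect = (
            G(6) - G(6) - G(1) + G(A) - G(5 + A) + G(5 + a1) - G(a1)
        )
        ll = dm_log_likelihood(np.array([5.0, 0.0]), np.array([1, 2]), [a1, a2])
        assert ll == pytest.approx(expect, abs=1e-12)
        assert ll == pytest.approx(np.log(0.88), abs=5e-3)

    def test_probabilities_sum_to_one(self):
        # exhaustive composition enumeration for small N, K
        for K, alphas in [(2, [0.6, 0.04]), (3, [0.5, 1.5, 2.0])]:
            labels = np.arange(1, K + 1)
            for N in range(1, 7):
                total = 0.0
                for c in itertools.product(range(N + 1), repeat=K):
                    if sum(c) != N:
                        continue
                    total += np.exp(
                        dm_log_likelihood(
                            np.array(c, dtype=float), labels, alphas[:K]
                        )
                    )
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            dm_log_likelihood(np.array([1.0]), np.array([1]), [0.0])


class TestFitPrior:
    def test_underdispersed_counts_drive_alpha_up(self):
        # counts (1,1): DM probability a/(2a+1) increases in a, so the MLE
        # sits on the flat upper plateau; the fit must reach it
        ts = TrainingSet(["a", "b"], np.array([1.0, 1.0]), np.array([1, 1]))
        spec = fit_prior(ts)
        a = spec.alphas[1]
        assert a > 100
        ll_bound = dm_log_likelihood(ts.counts, ts.labels, [ALPHA_MAX])
        assert spec.log_likelihood >= ll_bound - 1e-6

    def test_concentrated_counts_drive_alpha_down(self):
        # counts (5,0): probability increases to 1/2 as a -> 0
        ts = TrainingSet(["a", "b"], np.array([5.0, 0.0]), np.array([1, 1]))
        spec = fit_prior(ts)
        assert spec.alphas[1] == pytest.approx(ALPHA_MIN, rel=1e-3)

    def test_two_partition_nesting(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(5, size=40).astype(float)
        labels2 = np.array([1, 2] * 20)
        ts2 = TrainingSet([f"u{i}" for i in range(40)], counts, labels2)
        ts1 = TrainingSet([f"u{i}" for i in range(40)], counts, np.ones(40, int))
        ll2 = fit_prior(ts2).log_likelihood
        ll1 = fit_prior(ts1, model="no_partition").log_likelihood
        assert ll2 >= ll1 - 1e-6

    def test_recovery_improves_with_training_size(self):
        # median |log(alpha_hat / alpha)| shrinks as units grow
        errors = {}
        for n_units in (50, 200, 1000):
            errs = []
            for s in range(5):
                rng = np.random.default_rng(1234 + s)
                a = np.repeat([0.60, 0.04], n_units // 2)
                th = rng.dirichlet(a)
                counts = rng.multinomial(20_000, th).astype(float)
                ts = TrainingSet(
                    [f"u{i}" for i in range(n_units)],
                    counts,
                    np.repeat([1, 2], n_units // 2),
                )
                spec = fit_prior(ts)
                errs.append(
                    abs(np.log(spec.alphas[1] / 0.60))
                    + abs(np.log(spec.alphas[2] / 0.04))
                )
            errors[n_units] = float(np.median(errs))
        assert errors[1000] < errors[50]


class TestPartitionUnits:
    def _table(self, has_peak, signal=None):
        n = len(has_peak)
        return pd.DataFrame(
            {
                "has_peak": has_peak,
                "signal": signal if signal is not None else [0.0] * n,
            },
            index=[f"u{i}" for i in range(n)],
        )

    def test_two_partition_peak(self):
        t = self._table([True, False, True])
        assert partition_units(t) == {"u0": 1, "u1": 2, "u2": 1}

    def test_no_partition(self):
        t = self._table([True, False])
        assert set(partition_units(t, model="no_partition").values()) == {1}

    def test_signal_quantile_degenerate_error(self):
        t = self._table([True] * 4, signal=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            partition_units(t, model="signal_quantile", k=2)

    def test_signal_quantile_orders_by_signal(self):
        t = self._table([True] * 4, signal=[1.0, 10.0, 2.0, 20.0])
        lab = partition_units(t, model="signal_quantile", k=2)
        assert lab["u0"] == lab["u2"] != lab["u1"] == lab["u3"]

    def test_peak_plus_signal_three_way(self):
        t = self._table([False, True, True, True, True], [0, 1, 2, 3, 4])
        lab = partition_units(t, model="peak_plus_signal")
        assert lab["u0"] == 1
        assert {lab["u1"], lab["u2"]} == {2} and {lab["u3"], lab["u4"]} == {3}

    def test_logistic_combined_separable(self):
        rng = np.random.default_rng(0)
        signal = np.concatenate([rng.uniform(5, 9, 20), rng.uniform(0, 1, 20)])
        t = self._table([True] * 40, signal=list(signal))
        resp = pd.Series(
            [True] * 20 + [False] * 20, index=t.index
        )
        lab = partition_units(t, model="logistic_combined", responses=resp)
        expect = {u: (1 if resp[u] else 2) for u in t.index}
        assert lab == expect


class TestCompareAndInformativeness:
    def _dm_counts(self, alphas_per_unit, N, rng):
        return rng.multinomial(N, rng.dirichlet(alphas_per_unit)).astype(float)

    def test_informative_labels_rank_first(self):
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            rng = np.random.default_rng(600 + s)
            labels = np.repeat([1, 2], 40)
            counts = self._dm_counts(np.repeat([0.60, 0.04], 40), 4000, rng)
            permuted = rng.permutation(labels)
            ranked = compare_prior_sources(
                counts, {"informative": labels, "permuted": permuted}
            )
            wins += ranked[0]["source"] == "informative"
        assert wins >= int(0.95 * n_rep)

    def test_single_candidate_passthrough(self):
        counts = np.array([3.0, 1.0, 0.0, 5.0])
        (rec,) = compare_prior_sources(counts, {"only": np.array([1, 1, 2, 2])})
        assert rec["source"] == "only"

    def test_identical_candidates_tie_lexicographically(self):
        counts = np.array([3.0, 1.0, 0.0, 5.0])
        labels = np.array([1, 1, 2, 2])
        ranked = compare_prior_sources(counts, {"b": labels, "a": labels})
        assert [r["source"] for r in ranked] == ["a", "b"]
        assert ranked[0]["log_likelihood"] == pytest.approx(
            ranked[1]["log_likelihood"], abs=1e-6
        )

    def test_statistic_nonnegative(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4, 30).astype(float)
        labels = np.array([1, 2] * 15)
        res = informativeness_test(counts, labels, n_permutations=99, seed=0)
        assert res["statistic"] >= -1e-9

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            informativeness_test(
                np.ones(10), np.ones(10, int), n_permutations=99
            )


class TestGenePeakStatus:
    def test_categories(self):
        txs = [
            _tx("a1", 1000, "gA"),
            _tx("a2", 5000, "gA"),
            _tx("b1", 20000, "gB"),
            _tx("b2", 25000, "gB"),
            _tx("c1", 40000, "gC"),
        ]
        groups = cluster_tss_groups(txs)
        peaks = [
            Peak("c", 950, 1050, 1.0),
            Peak("c", 4950, 5050, 1.0),
            Peak("c", 19950, 20050, 1.0),
        ]
        feats = tss_peak_status(groups, peaks)
        status = gene_peak_status(groups, feats)
        assert status == {"gA": "all", "gB": "mixed", "gC": "none"}
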