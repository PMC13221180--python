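import numpy as np
import pytest
from scipy import stats

from splicedesign.evaluate import (MutationRecord, NullDistribution,
                                   build_null_distribution,
                                   classification_metrics, kd_mimicry,
                                   marginal_position_effects, metric_a,
                                   motif_insertion_scan, pearson_r,
                                   position_enrichment,
                                   sliding_window_scan)
from splicedesign.oracle import make_design_event, oracle_psi


# ---------------------------------------------------- brute-force oracles
def auroc_pair_counting(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else 0.5 if p == n else 0.0
    return wins / (len(pos) * len(neg))


def auprc_step_integration(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = fp = 0
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += y[i:j].sum()
        fp += (j - i) - y[i:j].sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestMetricA:
    def test_count_rule(self):
        assert metric_a([0.1, 0.5, 0.9], [0.05, 0.9, 0.1]) == \
            pytest.approx(1 / 3)

    def test_perfect(self):
        assert metric_a([0.2, 0.8], [0.2, 0.8]) == 1.0

    def test_boundary_strict(self):
        assert metric_a([0.0], [0.2]) == 0.0  # exactly 0.2 not counted

    def test_permutation_invariant(self, rng):
        p, o = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        assert metric_a(p, o) == metric_a(p[perm], o[perm])


class TestPearson:
    def test_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = classification_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["auroc"] == 1.0 and m["auprc"] == 1.0

    def test_random_scores_near_chance(self, rng):
        aurocs, auprcs = [], []
        for _ in range(100):
            labels = np.array([0, 1] * 25)
            scores = rng.uniform(0, 1, 50)
            m = classification_metrics(scores, labels)
            aurocs.append(m["auroc"])
            auprcs.append(m["auprc"])
        assert abs(np.mean(aurocs) - 0.5) < 0.04
        assert abs(np.mean(auprcs) - 0.5) < 0.06  # ~prevalence

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(10, 120))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        # quantized scores force ties
        scores = np.round(rng.uniform(0, 1, n), 1)
        m = classification_metrics(scores, labels)
        assert m["auroc"] == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-12)
        assert m["auprc"] == pytest.approx(
            auprc_step_integration(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def scan_event(oracle_spec):
    return make_design_event(oracle_spec, seed=33, plant_silencer=False)


def _model_fn(oracle_spec, tissue):
    return lambda windows: oracle_psi(oracle_spec, windows, tissue)


class TestInsertionScan:
    def test_constant_model_zero_everywhere(self, scan_event):
        eff = motif_insertion_scan(lambda w: 0.42, scan_event, "TGCATG",
                                   [(1, 10), (1, 20), (2, 60)])
        np.testing.assert_array_equal(eff, 0.0)

    def test_ignored_position_near_zero(self, oracle_spec, scan_event):
        # insertions in the flanking windows are outside the oracle's
        # motif readout; only site-window overlap could matter
        fn = _model_fn(oracle_spec, oracle_spec.tissues[0])
        eff = motif_insertion_scan(fn, scan_event,
                                   oracle_spec.motifs[1].sequence,
                                   [(0, 5), (3, 90)], seed=4)
        assert np.abs(eff).max() < 0.02


class TestKdMimicry:
    def test_below_threshold_no_change(self, scan_event):
        null = NullDistribution(values=np.array([0.5, 0.6]))
        call, dpsi = kd_mimicry(lambda w: 0.5, scan_event, [(1, 10, 6)],
                                null)
        assert call == "no-change" and dpsi == 0.0

    def test_planted_silencer_scramble_called(self, oracle_spec):
        ev = make_design_event(oracle_spec, seed=11)
        tissue = oracle_spec.tissues[0]
        fn = _model_fn(oracle_spec, tissue)
        sil = oracle_spec.motifs[1].sequence
        pos = ev.windows[1].sequence.find(sil)
        null = build_null_distribution(
            fn, [make_design_event(oracle_spec, s, plant_silencer=False)
                 for s in (1, 2)],
            offsets=[(1, pos)], length=len(sil), reps=5, seed=0)
        call, dpsi = kd_mimicry(fn, ev, [(1, pos, len(sil))], null,
                                seed=1)
        # scrambling a silencer raises inclusion
        assert call == "increase" and dpsi > 0.1


class TestSlidingWindow:
    def test_output_length_and_determinism(self, oracle_spec, scan_event):
        fn = _model_fn(oracle_spec, oracle_spec.tissues[0])
        out1 = sliding_window_scan(fn, scan_event, window=6, reps=1,
                                   seed=3)
        out2 = sliding_window_scan(fn, scan_event, window=6, reps=1,
                                   seed=3)
        assert out1.size == 400 - 6 + 1
        np.testing.assert_array_equal(out1, out2)

    def test_silencer_region_ranks_high(self, oracle_spec):
        ev = make_design_event(oracle_spec, seed=17)
        fn = _model_fn(oracle_spec, oracle_spec.tissues[0])
        out = sliding_window_scan(fn, ev, window=6, reps=3, seed=5)
        sil = oracle_spec.motifs[1].sequence
        pos = 100 + ev.windows[1].sequence.find(sil)  # global coordinate
        mags = np.abs(out)
        thresh = np.nanquantile(mags, 0.9)
        assert np.nanmax(mags[pos - 5:pos + 6]) >= thresh


class TestMarginalEffects:
    def test_single_position_records(self):
        recs = [MutationRecord("e", [(5, "A", "G")], 0.3),
                MutationRecord("e", [(5, "A", "T")], 0.1),
                MutationRecord("e", [(9, "C", "T")], -0.2)]
        df = marginal_position_effects(recs)
        assert set(df.position) == {5, 9}  # others missing, not zero
        assert df.set_index("position").loc[5, "mean_abs_dpsi"] == \
            pytest.approx(0.2)
        assert df.set_index("position").loc[9, "mean_abs_dpsi"] == \
            pytest.approx(0.2)

    def test_split_attribution(self):
        recs = [MutationRecord("e", [(1, "A", "G"), (2, "A", "G")], 0.4)]
        split = marginal_position_effects(recs, "split")
        full = marginal_position_effects(recs, "full")
        assert split.mean_abs_dpsi.tolist() == [0.2, 0.2]
        assert full.mean_abs_dpsi.tolist() == [0.4, 0.4]

    def test_enrichment_matches_exact_binomial(self):
        import pandas as pd
        marginal = pd.DataFrame({
            "position": range(100),
            "mean_abs_dpsi": np.linspace(0, 1, 100),
            "n_mutations": 1})
        selected = list(range(90, 100)) * 3 + [0, 1]
        rep = position_enrichment(selected, marginal)
        assert rep["hits_top"] == 30 and rep["hits_bottom"] == 2
        expected = stats.binomtest(30, 32, 0.5,
                                   alternative="greater").pvalue
        assert rep["pvalue"] == pytest.approx(expected, abs=1e-15)
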