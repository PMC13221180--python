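from functools import lru_cache

import numpy as np
import pytest

from splicedesign.design import (BosConfig, DesignProblem, VaeConfig,
                                 VaeTrainConfig, design_metrics,
                                 event_design_sequence,
                                 genetic_algorithm_baseline, levenshtein,
                                 mutational_corpus, oracle_handle,
                                 random_mutation_baseline, run_bos,
                                 train_vae)
from splicedesign.oracle import make_design_event


# --------------------------------------------------------- levenshtein
def lev_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
    return rec(len(a), len(b))


class TestLevenshtein:
    def test_trivial_cases(self):
        assert levenshtein("ACGT", "ACGT") == 0
        assert levenshtein("ACGT", "ACG") == 1
        assert levenshtein("", "ACG") == 3

    def test_known_pair(self):
        assert levenshtein("GATTACA", "GCATGCT") == \
            lev_recursive("GATTACA", "GCATGCT")

    def test_matches_exhaustive_recursion(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(0, 11, size=2)
            a = "".join(rng.choice(list("ACGT"), n1))
            b = "".join(rng.choice(list("ACGT"), n2))
            assert levenshtein(a, b) == lev_recursive(a, b)


# ------------------------------------------------------------ VAE units
@pytest.fixture(scope="module")
def tiny_vae():
    rng = np.random.default_rng(0)
    start = "".join(rng.choice(list("ACGT"), 80))
    corpus = mutational_corpus(start, 120, 10, seed=1)
    cfg = VaeConfig.tiny(hidden=48, latent_dim=16)
    vae, hist = train_vae(corpus, cfg, VaeTrainConfig(epochs=8, seed=0))
    return vae, corpus, hist


class TestVae:

    def test_reconstruction_improves(self, tiny_vae):
        _, _, hist = tiny_vae
        assert hist["token_accuracy"][-1] > hist["token_accuracy"][0]
        assert hist["recon"][-1] < hist["recon"][0]

    def test_encode_decode_shapes(self, tiny_vae):
        vae, corpus, _ = tiny_vae
        z = vae.encode(corpus[0])
        assert z.shape == (16,)
        out = vae.decode(z)
        assert len(out) == 80 and set(out) <= set("ACGT")

    def test_kl_annealing_recorded(self, tiny_vae):
        _, _, hist = tiny_vae
        assert hist["kl_weight"][0] == 0.0
        assert hist["kl_weight"][-1] > 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="share a length"):
            train_vae(["ACGTACGT", "ACGT"], VaeConfig.tiny())

    def test_deterministic_history(self):
        rng = np.random.default_rng(3)
        start = "".join(rng.choice(list("ACGT"), 40))
        corpus = mutational_corpus(start, 40, 5, seed=2)
        cfg = VaeConfig.tiny(hidden=32, latent_dim=8)
        _, h1 = train_vae(corpus, cfg, VaeTrainConfig(epochs=2, seed=5))
        _, h2 = train_vae(corpus, cfg, VaeTrainConfig(epochs=2, seed=5))
        assert h1["recon"] == h2["recon"]


# ----------------------------------------------------- problem/baselines
@pytest.fixture(scope="module")
def design_problem(oracle_spec):
    event = make_design_event(oracle_spec, seed=3)
    return DesignProblem(
        start_sequence=event_design_sequence(event),
        oracle=oracle_handle(oracle_spec),
        target_condition=oracle_spec.tissues[0],
        maximize=True, tau=30, budget=40, others_band=0.05, seed=0)


class TestRandomBaseline:
    def test_budget_and_lev_bound(self, design_problem):
        res = random_mutation_baseline(design_problem, k=30)
        assert res.n_evaluations == design_problem.budget
        assert len(res.candidates) == design_problem.budget
        assert all(c.lev <= 30 for c in res.candidates)

    def test_kmer_is_single_contiguous_substitution(self, design_problem):
        res = random_mutation_baseline(design_problem, k=6, seed=4)
        start = design_problem.start_sequence
        for c in res.candidates:
            diffs = [i for i, (x, y) in enumerate(zip(start, c.sequence))
                     if x != y]
            if diffs:
                assert max(diffs) - min(diffs) < 6


class TestGaBaseline:
    def test_budget_accounting(self, design_problem):
        res = genetic_algorithm_baseline(design_problem, pop_size=8)
        assert res.n_evaluations == design_problem.budget

    def test_offspring_respect_tau(self, design_problem):
        res = genetic_algorithm_baseline(design_problem, pop_size=8,
                                         seed=9)
        assert all(c.lev <= design_problem.tau for c in res.candidates)

    def test_seeded_reproducible(self, design_problem):
        a = genetic_algorithm_baseline(design_problem, pop_size=8, seed=2)
        b = genetic_algorithm_baseline(design_problem, pop_size=8, seed=2)
        assert [c.sequence for c in a.candidates] == \
            [c.sequence for c in b.candidates]


class TestDesignMetrics:
    def test_success_rate_counting(self, design_problem):
        res = random_mutation_baseline(design_problem, k=3, seed=1)
        m = design_metrics(res, lambda c: False)
        assert m["success_rate"] == 0.0
        m2 = design_metrics(
            res, lambda c: c.objective > -np.inf)
        assert m2["success_rate"] == 1.0

    def test_top20_matches_sort_and_slice(self, design_problem):
        res = random_mutation_baseline(design_problem, k=3, seed=1)
        m = design_metrics(res, lambda c: False)
        objs = sorted(c.objective for c in res.candidates)
        k = int(np.ceil(0.2 * len(objs)))
        np.testing.assert_allclose(m["top20_objectives"], objs[-k:])

    def test_fraction_rule(self, design_problem):
        res = random_mutation_baseline(design_problem, k=3, seed=1)
        crit = lambda c: c.psis[design_problem.target_condition] > \
            np.median([x.psis[design_problem.target_condition]
                       for x in res.candidates])
        m = design_metrics(res, crit)
        assert 0.0 < m["success_rate"] < 1.0


class TestProblemLogic:
    def test_tau_zero_only_exact_decodes_feasible(self, oracle_spec):
        event = make_design_event(oracle_spec, seed=3)
        problem = DesignProblem(
            start_sequence=event_design_sequence(event),
            oracle=oracle_handle(oracle_spec),
            target_condition=oracle_spec.tissues[0], tau=0, budget=5,
            seed=0)
        res = random_mutation_baseline(problem, k=3, seed=0)
        assert all(not c.feasible for c in res.candidates
                   if c.sequence != problem.start_sequence)

    def test_violation_zero_for_start(self, design_problem):
        p = design_problem
        psis = p.oracle(p.start_sequence)
        assert p.violation(p.start_sequence, psis, 0) == 0.0

    def test_invalid_problem_rejected(self, oracle_spec):
        event = make_design_event(oracle_spec, seed=3)
        with pytest.raises(ValueError):
            DesignProblem(start_sequence=event_design_sequence(event),
                          oracle=oracle_handle(oracle_spec),
                          target_condition=oracle_spec.tissues[0],
                          tau=-1, budget=5)


class TestGpSurrogate:
    def test_interpolation_property(self, rng):
        """Exact GP posterior mean reproduces noise-free observations —
        checked against a direct linear-algebra solve."""
        from splicedesign.design import _fit_gp
        z = rng.normal(size=(15, 4))
        y = np.sin(z[:, 0]) + 0.5 * z[:, 1]
        gp = _fit_gp(z, y, seed=0)
        pred = gp.predict(z)
        np.testing.assert_allclose(pred, y, atol=5e-2)
        # direct solve with the fitted kernel reproduces sklearn
        K = gp.kernel_(z)
        alpha = np.linalg.solve(K, y - y.mean())
        direct = K @ alpha + y.mean()
        np.testing.assert_allclose(direct, y, atol=1e-8)


@pytest.fixture(scope="module")
def small_bos(oracle_spec):
    event = make_design_event(oracle_spec, seed=3)
    start = event_design_sequence(event)
    problem = DesignProblem(
        start_sequence=start, oracle=oracle_handle(oracle_spec),
        target_condition=oracle_spec.tissues[0], maximize=True,
        tau=30, budget=40, others_band=0.05, seed=1)
    corpus = mutational_corpus(start, 150, 30, seed=2)
    vae, _ = train_vae(corpus, VaeConfig.tiny(),
                       VaeTrainConfig(epochs=6, seed=0,
                                      reference=start))
    cfg = BosConfig(n_init=10, batch_size=5, n_candidates=64, ard=False)
    return run_bos(problem, vae, cfg), problem


class TestBosLoop:

    def test_budget_exact(self, small_bos):
        res, problem = small_bos
        assert res.n_evaluations == problem.budget
        assert len(res.candidates) == problem.budget

    def test_feasible_candidates_satisfy_tau(self, small_bos):
        res, problem = small_bos
        for c in res.feasible:
            assert levenshtein(c.sequence, problem.start_sequence) \
                <= problem.tau

    def test_audit_reproduces_flags(self, small_bos):
        res, _ = small_bos
        assert res.audit()

    def test_best_so_far_monotone(self, small_bos):
        res, _ = small_bos
        trace = res.best_so_far()
        finite = [x for x in trace if np.isfinite(x)]
        assert all(a <= b + 1e-12 for a, b in zip(finite, finite[1:]))
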