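import itertools

import numpy as np
import pytest

from splicedesign.genomic_io import extract_window
from splicedesign.oracle import (generate_dataset, make_design_event,
                                 oracle_psi, positional_effect_profile,
                                 sample_oracle)


class TestSampleOracle:
    def test_same_seed_identical_spec(self):
        a, b = sample_oracle(3), sample_oracle(3)
        assert a.spec_hash() == b.spec_hash()
        assert sample_oracle(4).spec_hash() != a.spec_hash()

    def test_no_motifs_site_only(self, rng):
        spec = sample_oracle(1, n_motifs=0)
        windows = ["".join(rng.choice(list("ACGT"), 100))
                   for _ in range(4)]
        vals = {t: oracle_psi(spec, windows, t) for t in spec.tissues}
        # without motifs every tissue collapses to the same value
        assert len({round(v, 12) for v in vals.values()}) == 1

    def test_betas_linear_in_tpm(self):
        spec = sample_oracle(2)
        for m in spec.motifs:
            tpms = spec.rbp_tpm.loc[m.regulator]
            betas = [spec.motif_beta(m, t) for t in spec.tissues]
            ratio = np.array(betas) / np.maximum(
                tpms.to_numpy() / spec.tpm_scale, 1e-12)
            np.testing.assert_allclose(ratio, m.slope, rtol=1e-9)


class TestOraclePsi:
    def test_logistic_range_and_monotone_site(self, oracle_spec, rng):
        windows = ["".join(rng.choice(list("ACGT"), 100))
                   for _ in range(4)]
        base = oracle_psi(oracle_spec, windows, oracle_spec.tissues[0])
        assert 0.0 <= base <= 1.0
        # plant the consensus donor at the alt-donor anchor: psi rises
        w = list(windows)
        a = 50
        cons = oracle_spec.donor_model.consensus()
        w[2] = w[2][:a - 3] + cons + w[2][a + 6:]
        up = oracle_psi(oracle_spec, w, oracle_spec.tissues[0])
        assert up > base

    def test_planted_silencer_tissue_specific(self, oracle_spec):
        ev = make_design_event(oracle_spec, seed=9)
        windows = [w.sequence for w in ev.windows]
        tA, tB, tC = oracle_spec.tissues
        psi = {t: oracle_psi(oracle_spec, windows, t)
               for t in oracle_spec.tissues}
        # silencer regulator expressed in tissue A only
        assert psi[tA] < psi[tB] - 0.2
        assert abs(psi[tB] - psi[tC]) < 0.1
        # scrambling the motif equalizes the tissues
        sil = oracle_spec.motifs[1].sequence
        pos = windows[1].find(sil)
        assert pos >= 0
        w2 = list(windows)
        w2[1] = w2[1][:pos] + "A" * len(sil) + w2[1][pos + len(sil):]
        if sil not in w2[1]:
            psi2 = {t: oracle_psi(oracle_spec, w2, t)
                    for t in oracle_spec.tissues}
            assert psi2[tA] > psi[tA] + 0.2
            assert abs(psi2[tB] - psi[tB]) < 0.05

    def test_unknown_tissue_rejected(self, oracle_spec, rng):
        windows = ["A" * 100] * 4
        with pytest.raises(KeyError):
            oracle_psi(oracle_spec, windows, "kidney")


class TestPositionalProfile:
    def test_zero_outside_range(self, oracle_spec):
        m = oracle_spec.motifs[0]
        d, eff = positional_effect_profile(
            oracle_spec, m, oracle_spec.tissues[0], "upstream",
            np.array([0, 10, m.max_distance, m.max_distance + 1, 200]))
        assert eff[3] == 0.0 and eff[4] == 0.0
        assert eff[0] != 0.0

    def test_monotone_decay(self, oracle_spec):
        m = oracle_spec.motifs[1]
        d, eff = positional_effect_profile(
            oracle_spec, m, oracle_spec.tissues[0], "upstream")
        mags = np.abs(eff[: m.max_distance])
        assert np.all(np.diff(mags) <= 1e-12)

    def test_profile_matches_insertion_finite_difference(self,
                                                         oracle_spec):
        """Logit-space profile agrees in rank with brute-force insertion
        effects measured through the oracle."""
        from scipy.stats import spearmanr
        ev = make_design_event(oracle_spec, seed=21, plant_silencer=False)
        windows = [w.sequence for w in ev.windows]
        m = oracle_spec.motifs[1]
        tissue = oracle_spec.tissues[0]
        base = oracle_psi(oracle_spec, windows, tissue)
        # distances >= 24 keep the insertion clear of the acceptor's
        # 23-mer score window (20 intronic bases + planting margin)
        dists = np.arange(24, 44)
        measured = []
        for dist in dists:
            w2 = list(windows)
            start = 50 - dist - len(m.sequence)
            w2[1] = (w2[1][:start] + m.sequence
                     + w2[1][start + len(m.sequence):])
            measured.append(oracle_psi(oracle_spec, w2, tissue) - base)
        _, truth = positional_effect_profile(oracle_spec, m, tissue,
                                             "upstream", dists)
        rho = spearmanr(measured, truth).statistic
        assert rho > 0.95


class TestGenerateDataset:
    def test_shapes_and_bounds(self, small_dataset):
        assert len(small_dataset.events) == 60
        assert len(small_dataset.records) == 180
        assert all(0 <= r.psi <= 1 for r in small_dataset.records)

    def test_bit_reproducible(self, oracle_spec):
        a = generate_dataset(oracle_spec, n_events=10, seed=42)
        b = generate_dataset(oracle_spec, n_events=10, seed=42)
        assert a.genome.contigs == b.genome.contigs
        assert [r.psi for r in a.records] == [r.psi for r in b.records]
        assert a.manifest == b.manifest

    def test_zero_noise_equals_oracle(self, oracle_spec):
        ds = generate_dataset(oracle_spec, n_events=10, seed=1, noise=0)
        for rec in ds.records:
            assert rec.psi == pytest.approx(
                ds.truth[rec.event_id].psi_true[rec.condition], abs=1e-12)

    def test_windows_match_extract_window(self, small_dataset):
        """Stored windows agree with strand-aware extraction from the
        written genome, on both strands."""
        seen = {"+": 0, "-": 0}
        for ev in small_dataset.events[:30]:
            seen[ev.strand] += 1
            for site, win in zip(ev.sites, ev.windows):
                ext = extract_window(small_dataset.genome, site,
                                     width=100,
                                     conservation=small_dataset.conservation)
                assert ext.sequence == win.sequence
                np.testing.assert_allclose(ext.conservation,
                                           win.conservation)
        assert seen["+"] > 0 and seen["-"] > 0

    def test_changing_fraction_in_target_regime(self, oracle_spec):
        ds = generate_dataset(oracle_spec, n_events=400, seed=3)
        psis = {}
        for r in ds.records:
            psis.setdefault(r.event_id, {})[r.condition] = \
                ds.truth[r.event_id].psi_true[r.condition]
        frac = np.mean([
            max(abs(a - b) for a, b in
                itertools.combinations(by.values(), 2)) >= 0.15
            for by in psis.values()])
        assert 0.08 <= frac <= 0.25

    def test_records_written_and_read_back(self, tmp_path, oracle_spec):
        ds = generate_dataset(oracle_spec, n_events=8, seed=2)
        ds.write(tmp_path / "bundle")
        from splicedesign.genomic_io import (read_conservation,
                                             read_genome,
                                             read_quant_table)
        g = read_genome(tmp_path / "bundle" / "genome.fa")
        assert g.contigs == ds.genome.contigs
        recs = read_quant_table(tmp_path / "bundle" / "quant.tsv")
        assert len(recs) == len(ds.records)
        cons = read_conservation(tmp_path / "bundle" /
                                 "conservation.bedgraph", g.lengths)
        for c in cons:
            np.testing.assert_allclose(cons[c], ds.conservation[c],
                                       atol=5e-7, equal_nan=True)
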