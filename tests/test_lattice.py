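"""Lattice Monte Carlo: initialization, update rules, outcome
classification, scans and snapshots."""

import numpy as np
import pytest

from junglegame.core import TOPOLOGY, example1_network, make_network
from junglegame.fixtures import enumerable_lattice
from junglegame.lattice import (
    Lattice,
    NormalizedRates,
    OutcomeLabel,
    classify_outcome,
    init_lattice,
    mc_step,
    one_step_gain_probs,
    parse_snapshot,
    phase_scan,
    run,
    sample_one_step_gains,
    scan_cell_seed,
    snapshot,
)


class TestNormalizedRates:
    def test_normalization_sums_to_one(self):
        rates = NormalizedRates.from_network(example1_network(0.5, 1.2))
        total = sum(rates.k(i, j) for i, j in TOPOLOGY)
        assert total == pytest.approx(1.0)
        # K51 = 1.2 over sum 7.7
        assert rates.k(5, 1) == pytest.approx(1.2 / 7.7)

    def test_override_mode(self):
        rates = NormalizedRates.override(1.0)
        assert rates.provenance == "explicit-override"
        assert all(rates.k(i, j) == 1.0 for i, j in TOPOLOGY)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match="k\\[1,2\\]"):
            NormalizedRates.override({pair: (1.5 if pair == (1, 2) else 0.5)
                                      for pair in TOPOLOGY})

    def test_off_topology_entries_are_zero(self):
        rates = NormalizedRates.override(1.0)
        assert rates.kmat[5, 4] == 0.0  # S5 never invades S4
        with pytest.raises(KeyError):
            rates.k(5, 2)


class TestInitLattice:
    def test_counts_near_uniform(self):
        lat = init_lattice(200, seed=3)
        counts = lat.counts()
        assert counts.sum() == 40_000
        # binomial: mean 8000, sd = sqrt(40000*0.2*0.8) = 80
        assert np.all(np.abs(counts - 8000) < 5 * 80)

    def test_seed_determinism(self):
        assert np.array_equal(init_lattice(50, 9).cells, init_lattice(50, 9).cells)
        assert not np.array_equal(init_lattice(50, 9).cells, init_lattice(50, 10).cells)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            init_lattice(2, seed=0)
        with pytest.raises(ValueError):
            Lattice(np.ones((2, 2), dtype=np.int8))


class TestUpdateRules:
    def test_monoculture_is_absorbing(self):
        lat = Lattice(np.full((10, 10), 3, dtype=np.int8))
        rng = np.random.default_rng(0)
        for _ in range(5):
            mc_step(lat, NormalizedRates.override(1.0), rng)
        assert np.all(lat.cells == 3)

    def test_no_reverse_invasion(self):
        """S5 cannot invade S4 (no 5->4 edge), so in an S4/S5 lattice the
        S5 count never increases."""
        rec = run(NormalizedRates.override(1.0), 12, 50, seed=4,
                  record_every=1, init=enumerable_lattice("two-species-stripe"))
        s5 = rec.counts[:, 4]
        assert np.all(np.diff(s5) <= 0)

    def test_one_invader_exact_gain_probability(self):
        """On the 3x3 one-invader lattice with k12 = 1, an elementary
        update grows S1 exactly when the drawn (site, neighbor) pair spans
        the S1 site: probability 1/9 + (8/9)(1/8) = 2/9."""
        lat = enumerable_lattice("one-invader")
        probs = one_step_gain_probs(lat, NormalizedRates.override(1.0))
        assert probs[0] == pytest.approx(2.0 / 9.0)
        assert np.all(probs[1:] == 0.0)

    def test_one_step_oracle_matches_monte_carlo(self):
        """Empirical single-update gain frequencies agree with exhaustive
        enumeration within 4 sigma over 1e5 trials, for both update
        conventions and non-unit probabilities."""
        n = 100_000
        rates = NormalizedRates.from_network(example1_network(0.5, 1.2))
        for pattern in ("one-invader", "checker-of-three"):
            lat = enumerable_lattice(pattern)
            for conv in (True, False):
                exact = one_step_gain_probs(lat, rates, pair_convention=conv)
                freq = sample_one_step_gains(lat, rates, n, seed=123,
                                             pair_convention=conv)
                sigma = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n)
                assert np.all(np.abs(freq - exact) <= 4 * sigma), (pattern, conv)

    def test_focal_only_halves_pair_gain(self):
        lat = enumerable_lattice("checker-of-three")
        rates = NormalizedRates.override(0.5)
        pair = one_step_gain_probs(lat, rates, pair_convention=True)
        focal = one_step_gain_probs(lat, rates, pair_convention=False)
        assert np.allclose(pair, 2 * focal)


class TestRun:
    def test_bit_for_bit_reproducible(self):
        rates = NormalizedRates.override(1.0)
        a = run(rates, 30, 50, seed=5)
        b = run(rates, 30, 50, seed=5)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.final.cells, b.final.cells)
        assert a.extinction_mcs == b.extinction_mcs

    def test_site_conservation(self):
        rec = run(NormalizedRates.override(1.0), 30, 50, seed=5, record_every=1)
        assert np.all(rec.counts.sum(axis=1) == 900)

    def test_extinction_is_permanent(self):
        rec = run(NormalizedRates.override(1.0), 50, 400, seed=2, record_every=1)
        for sp, t in enumerate(rec.extinction_mcs):
            if t is not None:
                recorded = rec.counts[rec.mcs >= t, sp]
                assert np.all(recorded == 0)

    def test_density_rows_sum_to_one(self):
        rec = run(NormalizedRates.override(1.0), 20, 20, seed=1)
        assert np.allclose(rec.densities.sum(axis=1), 1.0)

    def test_export_header_and_columns(self):
        rec = run(NormalizedRates.override(1.0), 10, 10, seed=1, record_every=5)
        lines = rec.to_text().splitlines()
        assert lines[0] == "# seed = 1"
        assert any(line.startswith("mcs\t") for line in lines)


class TestOutcomes:
    def _record_with_final_counts(self, counts):
        cells = np.concatenate([
            np.full(c, sp + 1, dtype=np.int8) for sp, c in enumerate(counts)
        ])
        L = int(np.sqrt(cells.size))
        lat = Lattice(cells.reshape(L, L))
        return run(NormalizedRates.override(1.0), L, 1, seed=0, init=lat)

    def test_taxonomy(self):
        # build degenerate lattices and classify their (absorbing) outcome
        rec = self._record_with_final_counts([0, 0, 0, 0, 81])
        assert classify_outcome(rec) is OutcomeLabel.ONLY_S5
        rec = self._record_with_final_counts([81, 0, 0, 0, 0])
        assert classify_outcome(rec) is OutcomeLabel.ONLY_S1_OR_S2

    def test_all_five_and_other(self):
        lat = init_lattice(20, 1)
        rec = run(NormalizedRates.override(1.0), 20, 1, seed=1, init=lat)
        assert classify_outcome(rec) is OutcomeLabel.ALL_FIVE
        # survivors {2, 3} fall outside the named taxonomy
        cells = np.array([[2, 3, 2], [3, 2, 3], [2, 3, 2]], dtype=np.int8)
        # S2 invades S3, so freeze by classifying the initial record
        rec = run(NormalizedRates.override({
            pair: (1e-9 if pair == (2, 3) else 1.0) for pair in TOPOLOGY
        }), 3, 1, seed=0, init=Lattice(cells))
        if set(rec.survivors()) == {2, 3}:
            assert classify_outcome(rec) is OutcomeLabel.OTHER

    def test_phase_scan_reproducible_and_labeled(self):
        p_grid = [0.4, 0.8]
        s_grid = [0.3, 1.5]
        a = phase_scan(p_grid, s_grid, L=20, n_mcs=200, base_seed=9)
        b = phase_scan(p_grid, s_grid, L=20, n_mcs=200, base_seed=9)
        assert a.shape == (2, 2)
        assert all(x is y for x, y in zip(a.ravel(), b.ravel()))
        assert all(isinstance(x, OutcomeLabel) for x in a.ravel())

    def test_scan_cell_seed_mixing(self):
        seeds = {scan_cell_seed(1, i, j) for i in range(5) for j in range(5)}
        assert len(seeds) == 25
        assert scan_cell_seed(1, 2, 3) == scan_cell_seed(1, 2, 3)


class TestSnapshot:
    def test_round_trip(self):
        lat = init_lattice(17, seed=8)
        assert np.array_equal(parse_snapshot(snapshot(lat)).cells, lat.cells)

    def test_monoculture_text(self):
        lat = Lattice(np.full((3, 3), 5, dtype=np.int8))
        assert snapshot(lat) == "555\n555\n555\n"

    def test_png_export(self, tmp_path):
        from junglegame.lattice import save_snapshot_png

        path = tmp_path / "snap.png"
        save_snapshot_png(init_lattice(10, 1), str(path))
        assert path.stat().st_size > 0
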