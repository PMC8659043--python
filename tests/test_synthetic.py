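"""Synthetic study generator: determinism, capture model, noise and EEMs."""

import numpy as np
import pytest

from spescreen.eem_fri import fri, fri_retention
from spescreen.feature_io import consensus_filter
from spescreen.recovery_qc import InternalStandard, compute_recovery
from spescreen.synthetic import (
    CartridgeProfile,
    Compound,
    Fluorophore,
    MatrixProfile,
    apply_cartridge_to_eem,
    capture_probability,
    default_matrices,
    generate_compound_pool,
    generate_eem,
    simulate_capture,
    simulate_replicates,
    simulate_study,
    spike_internal_standards,
)

RIVER = default_matrices()["river"]
PURE = default_matrices()["ultrapure"]


def open_cartridge(**kw):
    """A cartridge that captures everything unless overridden."""
    defaults = dict(
        name="open", rt_window_center=17.0, rt_window_width=1e6,
        charge_affinity={c: 1.0 for c in ("neutral", "acidic", "basic")},
        dom_sensitivity=0.0,
    )
    defaults.update(kw)
    return CartridgeProfile(**defaults)


class TestCompoundPool:
    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_compound_pool(0, seed=1)

    def test_seed_determinism(self):
        a = generate_compound_pool(100, seed=1)
        b = generate_compound_pool(100, seed=1)
        assert a == b

    def test_mz_mean_matches_uniform(self):
        # Uniform(50, 1000): mean 525, sd (1000-50)/sqrt(12)
        pool = generate_compound_pool(10000, seed=7)
        mz = np.array([c.mz for c in pool])
        se = (1000 - 50) / np.sqrt(12) / np.sqrt(len(mz))
        assert abs(mz.mean() - 525.0) < 3 * se

    def test_compound_validation(self):
        with pytest.raises(ValueError):
            Compound("x", mz=20.0, rt_true=1.0, charge_class="neutral", base_area=1.0)
        with pytest.raises(ValueError):
            Compound("x", mz=100.0, rt_true=1.0, charge_class="neutral", base_area=0.0)


class TestCapture:
    def test_unit_capture_at_window_center(self):
        c = Compound("x", mz=300.0, rt_true=17.0, charge_class="neutral", base_area=5e4)
        cart = open_cartridge(rt_window_width=2.0)
        captured = simulate_capture([c], cart, PURE, deterministic=True)
        assert captured["x"] == pytest.approx(5e4)

    def test_full_dom_competition_zeroes_capture(self):
        c = Compound("x", mz=300.0, rt_true=17.0, charge_class="neutral", base_area=5e4)
        cart = open_cartridge(dom_sensitivity=1.0)
        effluent = default_matrices()["effluent"]  # doc >= doc_ref
        assert simulate_capture([c], cart, effluent, deterministic=True) == {}

    def test_deterministic_areas_match_formula(self):
        pool = generate_compound_pool(1000, seed=3)
        cart = CartridgeProfile(
            name="c", rt_window_center=10.0, rt_window_width=4.0,
            charge_affinity={"neutral": 1.0, "acidic": 0.5, "basic": 0.2},
            dom_sensitivity=0.5,
        )
        captured = simulate_capture(pool, cart, RIVER, deterministic=True)
        for c in pool[::100]:  # spot-check against the closed-form probability
            g = np.exp(-((c.rt_true - 10.0) ** 2) / (2 * 4.0**2))
            aff = {"neutral": 1.0, "acidic": 0.5, "basic": 0.2}[c.charge_class]
            comp = 1 - 0.5 * min(1.0, RIVER.doc / 7.1)
            assert captured[c.id] == pytest.approx(c.base_area * g * aff * comp)

    def test_dom_sensitivity_monotone(self):
        pool = generate_compound_pool(200, seed=5)
        areas = []
        for s in (0.0, 0.3, 0.6, 0.9):
            cart = open_cartridge(dom_sensitivity=s)
            areas.append(simulate_capture(pool, cart, RIVER, deterministic=True))
        for lo, hi in zip(areas[1:], areas[:-1]):
            assert all(lo[k] <= hi[k] + 1e-12 for k in lo)

    def test_capture_probability_bounded(self):
        pool = generate_compound_pool(200, seed=8)
        cart = open_cartridge(rt_window_width=3.0, dom_sensitivity=0.7)
        for c in pool:
            assert 0.0 <= capture_probability(c, cart, RIVER) <= 1.0


class TestReplicates:
    def test_noise_free_replicates_identical(self):
        pool = generate_compound_pool(50, seed=2)
        captured = simulate_capture(pool, open_cartridge(), PURE, deterministic=True)
        table = simulate_replicates(captured, pool, "S", n_reps=3, cv=0.0, lod=0.0, seed=1)
        for rep in ("r1", "r2", "r3"):
            sub = table.records[table.records["replicate_id"] == rep]
            assert dict(zip(sub["feature_id"], sub["area"])) == pytest.approx(captured)

    def test_lod_censoring(self):
        pool = [Compound("x", mz=300.0, rt_true=17.0, charge_class="neutral", base_area=500.0)]
        captured = {"x": 500.0}
        table = simulate_replicates(captured, pool, "S", cv=0.0, lod=1e3, seed=1)
        assert table.records.empty

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            simulate_replicates({}, [], "S", cv=-0.1)

    def test_replicate_presence_matches_rerun_oracle(self):
        pool = generate_compound_pool(500, seed=11)
        captured = simulate_capture(pool, open_cartridge(), PURE, deterministic=True)
        table = simulate_replicates(captured, pool, "S", cv=0.2, lod=1e4, seed=42)
        # independent re-simulation of the same noise stream
        rng = np.random.default_rng(42)
        expected_full = set()
        for cid in sorted(captured):
            noise = rng.normal(0.0, 0.2, 3)
            if all(max(0.0, captured[cid] * (1 + e)) >= 1e4 for e in noise):
                expected_full.add(cid)
        got = {f.feature_id for f in consensus_filter(table, "S", mz_tol_ppm=1e-9, rt_tol=1e-9)}
        assert got == expected_full


class TestEEM:
    def test_no_fluorophores_zero_grid(self):
        eem = generate_eem([])
        assert not eem.intensity.any()

    def test_peak_at_grid_node_equals_amplitude(self):
        f = Fluorophore("f", ex_center=300.0, em_center=400.0, ex_sigma=10.0,
                        em_sigma=10.0, amplitude=7.5)
        eem = generate_eem([f])
        assert eem.intensity.max() == pytest.approx(7.5)
        i, j = np.unravel_index(eem.intensity.argmax(), eem.intensity.shape)
        assert (eem.ex[i], eem.em[j]) == (300.0, 400.0)

    def test_additivity(self):
        f1 = Fluorophore("a", 260.0, 350.0, 10.0, 15.0, 3.0)
        f2 = Fluorophore("b", 350.0, 500.0, 20.0, 25.0, 5.0)
        both = generate_eem([f1, f2]).intensity
        np.testing.assert_allclose(
            both, generate_eem([f1]).intensity + generate_eem([f2]).intensity
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_eem([], ex_grid=np.array([]), em_grid=np.array([250.0, 252.0]))

    def test_stokes_shift_enforced(self):
        with pytest.raises(ValueError):
            Fluorophore("bad", ex_center=400.0, em_center=300.0, ex_sigma=5.0,
                        em_sigma=5.0, amplitude=1.0)


class TestCartridgeEEM:
    FLUORS = (Fluorophore("only", 330.0, 480.0, 20.0, 25.0, 100.0),)

    def test_total_retention_zeroes_spectrum(self):
        before = generate_eem(self.FLUORS)
        cart = open_cartridge(dom_retention_per_fluorophore={"only": 1.0})
        after = apply_cartridge_to_eem(before, cart, self.FLUORS)
        assert not after.intensity.any()

    def test_zero_retention_is_identity(self):
        before = generate_eem(self.FLUORS)
        cart = open_cartridge(dom_retention_per_fluorophore={"only": 0.0})
        after = apply_cartridge_to_eem(before, cart, self.FLUORS)
        np.testing.assert_allclose(after.intensity, before.intensity)

    def test_partial_retention_scales_volume(self):
        before = generate_eem(self.FLUORS)
        cart = open_cartridge(dom_retention_per_fluorophore={"only": 0.85})
        after = apply_cartridge_to_eem(before, cart, self.FLUORS)
        assert after.intensity.sum() == pytest.approx(0.15 * before.intensity.sum())

    def test_invalid_retention_fraction_rejected(self):
        with pytest.raises(ValueError):
            CartridgeProfile(
                name="bad", rt_window_center=10.0, rt_window_width=2.0,
                dom_retention_per_fluorophore={"only": 1.5},
            )


class TestSpikeRoundTrip:
    STD = InternalStandard(
        name="caffeine-d9", mz=204.1536, rt_window=(4.0, 4.4), reference_area=2e3
    )

    def _spiked_area(self, recovery):
        pool = generate_compound_pool(20, seed=6)
        captured = simulate_capture(pool, open_cartridge(), PURE, deterministic=True)
        table = simulate_replicates(captured, pool, "S", cv=0.0, lod=0.0, seed=1)
        spiked = spike_internal_standards(
            table, [self.STD], {"caffeine-d9": recovery}, concentration_factor=1000.0
        )
        rows = spiked.records[spiked.records["feature_id"] == "IS_caffeine-d9"]
        return rows

    @pytest.mark.parametrize("recovery,expected", [(1.0, 100.0), (0.63, 63.0)])
    def test_round_trip_recovers_truth(self, recovery, expected):
        rows = self._spiked_area(recovery)
        assert len(rows) == 3  # one per replicate
        result = compute_recovery(rows["area"].iloc[0], self.STD, 1000.0)
        assert result.recovery == pytest.approx(expected)

    def test_zero_recovery_absent(self):
        assert self._spiked_area(0.0).empty


class TestStudy:
    def test_study_seed_determinism(self):
        a = simulate_study(seed=9)
        b = simulate_study(seed=9)
        assert a.combined.records.equals(b.combined.records)

    def test_pools_are_extra_samples(self):
        from spescreen.synthetic import StudyConfig

        cfg = StudyConfig(n_compounds=100, n_pools=2)
        study = simulate_study(cfg, seed=4)
        assert {"pool1", "pool2"} <= set(study.tables)

    def test_cartridge_retention_round_trip_region_iii(self):
        study = simulate_study(seed=2)
        cart = study.config.cartridges[0]
        ret = fri_retention(
            fri(study.eems_before[cart.name]), fri(study.eems_after[cart.name])
        )
        truth = 100 * cart.dom_retention_per_fluorophore["fulvic"]
        assert ret["III"] == pytest.approx(truth, abs=1.0)
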