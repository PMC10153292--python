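"""Parameter sampling, initial-condition schemes, and the screen driver."""

import numpy as np
import pandas as pd
import pytest

from segpol import GridSpec, build_grid, load_catalog
from segpol.sampling import (SCHEMES, SamplingConfig, initial_condition,
                             plot_solutions, run_screen, sample_parameters)
from segpol.scoring import default_template


class TestSampleParameters:
    def test_draws_respect_ranges_and_loguniform_median(self):
        cat = load_catalog()
        cfg = SamplingConfig()
        rng = np.random.default_rng(1)
        draws = {n: [] for n in cat.sampled_names}
        for _ in range(10_000):
            ps = sample_parameters(cfg, rng)
            for n in cat.sampled_names:
                draws[n].append(ps[n])
        for n, vals in draws.items():
            lo, hi = cfg.range_of(n)
            vals = np.asarray(vals)
            assert vals.min() >= lo and vals.max() <= hi
            # log-uniform median is sqrt(lo * hi); MC tolerance ~ 4 sigma
            med, expect = np.median(vals), np.sqrt(lo * hi)
            assert abs(np.log(med / expect)) < 4 * np.log(hi / lo) / np.sqrt(4 * 10_000)

    def test_ptc0_hh0_in_1_1000(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ps = sample_parameters(rng=rng)
            assert 1.0 <= ps["PTC0"] <= 1000.0
            assert 1.0 <= ps["HH0"] <= 1000.0

    def test_unsampled_parameters_stay_at_defaults(self):
        ps = sample_parameters(rng=np.random.default_rng(3))
        # translation rates keep their ln2/H tie to the *sampled* half-life
        assert ps["T_en"] == pytest.approx(np.log(2) / ps["H_EN"])

    def test_bad_override_range_rejected(self):
        cfg = SamplingConfig(overrides={"PTC0": (0.0, 10.0)})
        with pytest.raises(ValueError):
            cfg.range_of("PTC0")


class TestInitialConditions:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_all_levels_in_unit_interval(self, scheme, grid_1x4):
        x = initial_condition(scheme, grid_1x4)
        assert x.shape == (132,)
        assert x.min() >= 0.0 and x.max() <= 1.0

    def test_crisp_uses_the_level_vocabulary(self, grid_1x4, model_1x4):
        x = initial_condition("crisp", grid_1x4)
        allowed = {0.0, 0.15, 0.4, 0.9, 0.15 / 6, 0.4 / 6, 0.9 / 6}
        assert {round(v, 12) for v in x} <= {round(a, 12) for a in allowed}
        assert x[model_1x4.species_index("wg", 1)] == 0.9
        assert x[model_1x4.species_index("en", 2)] == 0.9
        assert x[model_1x4.species_index("en", 0)] == 0.15

    def test_derived_species_start_at_zero(self, grid_1x4, model_1x4):
        x = initial_condition("crisp", grid_1x4)
        for c in range(4):
            assert x[model_1x4.species_index("CN", c)] == 0.0
            for s in range(1, 7):
                assert x[model_1x4.species_index("PH", c, s)] == 0.0

    def test_near_target_matches_template_sign_pattern(self, grid_1x4, model_1x4):
        x = initial_condition("near_target", grid_1x4)
        for name, flags in default_template().assignments.items():
            on = [x[model_1x4.species_index(name, c)] for c in range(4) if flags[c]]
            off = [x[model_1x4.species_index(name, c)] for c in range(4) if not flags[c]]
            assert min(on) > max(off)

    def test_unknown_scheme_rejected(self, grid_1x4):
        with pytest.raises(KeyError):
            initial_condition("nonsense", grid_1x4)

    def test_non_1x4_grid_rejected(self):
        with pytest.raises(ValueError):
            initial_condition("crisp", build_grid(GridSpec(2, 3)))


class TestRunScreen:
    def test_same_seed_gives_identical_tallies(self):
        a = run_screen(20, scheme="crisp", seed=77)
        b = run_screen(20, scheme="crisp", seed=77)
        assert (a.hits, a.tries, a.failures) == (b.hits, b.tries, b.failures)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_tallies_are_consistent(self):
        res = run_screen(15, scheme="crisp", seed=5)
        assert res.tries + res.failures == 15
        counts = res.records["outcome"].value_counts()
        assert counts.get("hit", 0) == res.hits
        assert counts.get("failure", 0) == res.failures

    def test_infinite_threshold_makes_every_try_a_hit(self):
        res = run_screen(8, scheme="crisp", seed=9, threshold=np.inf)
        assert res.hits == res.tries

    def test_records_carry_the_48_sampled_parameters(self):
        res = run_screen(3, scheme="crisp", seed=1)
        cat = load_catalog()
        assert set(cat.sampled_names) <= set(res.records.columns)
        for n in cat.sampled_names:
            lo, hi = cat[n].lo, cat[n].hi
            assert res.records[n].between(lo, hi).all()


class TestPlotSolutions:
    def _fake_hits(self, n=6, at_low_end=False):
        cat = load_catalog()
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(n):
            row = {}
            for nm in cat.sampled_names:
                lo, hi = cat[nm].lo, cat[nm].hi
                row[nm] = lo if at_low_end else float(
                    np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append(row)
        return pd.DataFrame(rows)

    def test_low_end_hits_map_to_zero(self):
        table = plot_solutions(self._fake_hits(at_low_end=True))
        hits = table.drop(index=["mean", "sd"])
        assert np.allclose(hits.to_numpy(dtype=float), 0.0)

    def test_mean_sd_rows_match_column_stats(self):
        table = plot_solutions(self._fake_hits())
        hits = table.drop(index=["mean", "sd"])
        np.testing.assert_allclose(table.loc["mean"], hits.mean(), rtol=1e-12)
        np.testing.assert_allclose(table.loc["sd"], hits.std(ddof=1), rtol=1e-12)

    def test_halflives_and_cooperativities_omitted(self):
        cat = load_catalog()
        table = plot_solutions(self._fake_hits())
        excluded = [e.name for e in cat.entries
                    if e.sampled and e.role in ("half-life", "nu")]
        assert len(excluded) == 25  # 13 half-lives + 12 cooperativities
        assert len(table.columns) == 48 - len(excluded)
        assert not set(excluded) & set(table.columns)

    def test_empty_hits_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            table = plot_solutions(pd.DataFrame())
        assert len(table) == 0
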