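import numpy as np
import pandas as pd
import pytest

from traitspace.io import HabitatPool
from traitspace.space import (
    OCTANTS,
    TraitSpace,
    assign_octants,
    build_trait_space,
    centroid_distances,
    delta_cdf,
    distance_summary,
    octant_proportions,
    randomization_test_cdf,
    _delta_cdf_batch,
)
from conftest import make_record


def toy_space(Z, statuses, habitat_id="h1"):
    Z = np.asarray(Z, dtype=float)
    native = np.array([s == "native" for s in statuses])
    return TraitSpace(
        habitat_id=habitat_id,
        species_ids=tuple(f"s{i}" for i in range(len(statuses))),
        Z=Z,
        statuses=tuple(statuses),
        native_centroid=Z[native].mean(axis=0),
        scale_mean=None,
        scale_sd=None,
        mode="raw",
    )


def grid_oracle_delta(native, alien, step=0.005):
    """Independent ΔCDF oracle: right-continuous ECDFs evaluated on a dense
    uniform grid that contains every jump point (inputs are lattice-valued),
    with a plain-Python region scan."""
    xs = np.arange(0.0, 100.0 + step, step)
    Fn = np.searchsorted(np.sort(native), xs, side="right") / len(native)
    Fa = np.searchsorted(np.sort(alien), xs, side="right") / len(alien)
    g = (Fa - Fn)[:-1]
    areas = g * step
    regions, sign, acc = [], 0, 0.0
    for gk, ak in zip(g, areas):
        sk = 0 if abs(gk) < 1e-12 else (1 if gk > 0 else -1)
        if sk != 0 and sign != 0 and sk != sign:
            regions.append(acc)
            acc = 0.0
        if sk != 0:
            sign = sk
        acc += ak
    regions.append(acc)
    regions = np.array(regions)
    if np.abs(regions).sum() < 1e-12:
        return 0.0
    return float(regions[np.argmax(np.abs(regions))])


class TestBuildTraitSpace:
    @pytest.fixture
    def records(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(20):
            status = "native" if i < 12 else ("naturalized" if i < 16 else "invasive")
            recs.append(
                make_record(
                    f"s{i}", status=status,
                    sla=float(10 ** rng.normal(1, 0.2)),
                    height_max=float(10 ** rng.normal(-0.3, 0.4)),
                    seed_weight=float(10 ** rng.normal(0, 0.6)),
                )
            )
        return recs

    def test_raw_mode_standardizes(self, records):
        pool = HabitatPool("h1", "x", frozenset(r.species_id for r in records), True)
        space = build_trait_space(pool, records)
        assert np.all(np.abs(space.Z.mean(axis=0)) < 1e-10)
        assert np.allclose(space.Z.std(axis=0, ddof=1), 1.0, atol=1e-10)
        native = space.status_mask("native")
        assert np.allclose(space.native_centroid, space.Z[native].mean(axis=0))

    def test_species_with_missing_trait_dropped(self, records):
        records[0] = make_record("s0", status="native", sla=None)
        pool = HabitatPool("h1", "x", frozenset(r.species_id for r in records), True)
        space = build_trait_space(pool, records)
        assert "s0" not in space.species_ids

    def test_residual_mode_keeps_scale(self, records):
        ids = [r.species_id for r in records]
        rng = np.random.default_rng(0)
        resid = pd.DataFrame(
            rng.normal(scale=0.7, size=(20, 3)), index=ids,
            columns=["sla", "height_max", "seed_weight"],
        )
        pool = HabitatPool("h1", "x", frozenset(ids), True)
        space = build_trait_space(pool, records, mode="residual", residuals=resid)
        assert np.allclose(space.Z, resid.loc[list(space.species_ids)].to_numpy())

    def test_too_few_natives_rejected(self, records):
        few = [r for r in records if r.status.value != "native"][:6]
        few += [r for r in records if r.status.value == "native"][:2]
        pool = HabitatPool("h1", "x", frozenset(r.species_id for r in few), True)
        with pytest.raises(ValueError, match="native"):
            build_trait_space(pool, few)


class TestOctants:
    def test_caption_mapping_semantics(self):
        # octants I-IV: above-average height; I,II,V,VI: above-average SLA;
        # I,IV,V,VIII: above-average seed weight
        height_above = {k for k, v in OCTANTS.items() if k[1]}
        assert {OCTANTS[k] for k in height_above} == {"I", "II", "III", "IV"}
        sla_above = {OCTANTS[k] for k in OCTANTS if k[0]}
        assert sla_above == {"I", "II", "V", "VI"}
        seed_above = {OCTANTS[k] for k in OCTANTS if k[2]}
        assert seed_above == {"I", "IV", "V", "VIII"}

    def test_extremes_and_tie_rule(self):
        Z = np.array([
            [0.0, 0.0, 0.0],   # native (defines centroid)
            [1.0, 1.0, 1.0],   # above on all -> I
            [-1.0, -1.0, -1.0],  # below on all -> VII
            [0.0, 0.0, 0.0],   # exactly at centroid -> I by >= tie rule
        ])
        space = toy_space(Z, ["native", "invasive", "invasive", "invasive"])
        # centroid is the single native point
        labels = assign_octants(space)
        assert labels[1] == "I"
        assert labels[2] == "VII"
        assert labels[3] == "I"

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(60, 3))
        statuses = ["native"] * 40 + ["naturalized"] * 12 + ["invasive"] * 8
        space = toy_space(Z, statuses)
        counts, props = octant_proportions(assign_octants(space), statuses)
        assert counts.to_numpy().sum() == 60
        assert np.allclose(props.sum(axis=0), 1.0)

    def test_single_species_column(self):
        space = toy_space(
            np.array([[0, 0, 0], [0.5, 0.5, -0.5], [1, 1, -1], [-1, 2, 0]]),
            ["native", "native", "native", "invasive"],
        )
        counts, props = octant_proportions(
            assign_octants(space), space.statuses
        )
        inv = props["invasive"]
        assert inv.sum() == 1.0
        assert (inv > 0).sum() == 1

    def test_uniform_cloud_fills_octants_evenly(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(2000, 3))
        statuses = ["native"] * 2000
        space = toy_space(Z, statuses)
        _, props = octant_proportions(assign_octants(space), statuses)
        assert np.all(np.abs(props["native"] - 1 / 8) < 0.05)


class TestCentroidDistances:
    def test_geometry(self):
        Z = np.array([
            [0.0, 0.0, 0.0],
            [3.0, 4.0, 0.0],
            [0.0, 0.0, 10.0],
        ])
        space = toy_space(Z, ["native", "invasive", "invasive"])
        prof = centroid_distances(space)
        assert prof.distances[0] == 0.0
        assert prof.distances[1] == pytest.approx(5.0)
        assert prof.relative[2] == 100.0
        assert prof.relative[1] == pytest.approx(50.0)

    def test_summary_scales_consistent(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(30, 3))
        statuses = ["native"] * 20 + ["invasive"] * 10
        space = toy_space(Z, statuses)
        prof = centroid_distances(space)
        summ = distance_summary(space, prof).set_index("status")
        dmax = prof.distances.max()
        for status in ("native", "invasive"):
            assert summ.loc[status, "mean_distance_pct"] == pytest.approx(
                summ.loc[status, "mean_distance_sd"] * 100 / dmax
            )


class TestDeltaCDF:
    def test_dominated_alien_negative_no_crossing(self):
        delta, crossings, frac = delta_cdf(
            np.array([10.0, 20.0, 30.0]), np.array([40.0, 100.0])
        )
        assert delta < 0
        assert crossings == 0
        assert frac == 1.0

    def test_identical_groups_zero(self):
        vals = np.array([5.0, 50.0, 100.0])
        delta, crossings, frac = delta_cdf(vals, vals.copy())
        assert delta == 0.0 and crossings == 0 and frac == 1.0

    def test_hand_case_with_crossings(self):
        native = np.array([20.0, 40.0, 60.0])
        alien = np.array([30.0, 90.0])
        delta, crossings, frac = delta_cdf(native, alien)
        # regions: [20,30): -10/3; [30,40): +5/3; [40,90): -55/3
        assert delta == pytest.approx(-55 / 3, abs=1e-9)
        assert crossings == 2
        assert frac == pytest.approx((55 / 3) / (70 / 3), abs=1e-9)
        assert delta == pytest.approx(grid_oracle_delta(native, alien), abs=1e-6)

    def test_antisymmetry_exact_and_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = np.round(rng.uniform(0, 100, rng.integers(2, 15)), 2)
            b = np.round(rng.uniform(0, 100, rng.integers(2, 15)), 2)
            d_ab, _, _ = delta_cdf(a, b)
            d_ba, _, _ = delta_cdf(b, a)
            assert d_ab == -d_ba
            assert abs(d_ab) <= 100.0

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(13)
        n_native, n_alien = 9, 6
        values = np.round(
            rng.uniform(0, 100, size=(300, n_native + n_alien)), 1
        )
        batch = _delta_cdf_batch(values, n_native)
        for b in range(300):
            scalar, _, _ = delta_cdf(values[b, :n_native], values[b, n_native:])
            assert batch[b] == pytest.approx(scalar, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            delta_cdf(np.array([1.0]), np.array([1.0, 2.0]))


class TestRandomizationTestCDF:
    @pytest.fixture
    def shifted_space(self):
        rng = np.random.default_rng(21)
        n_nat, n_inv = 60, 15
        Z = np.vstack([
            rng.normal(size=(n_nat, 3)),
            rng.normal(size=(n_inv, 3)) + np.array([0, 2.0, 0]),
        ])
        return toy_space(Z, ["native"] * n_nat + ["invasive"] * n_inv)

    def test_displaced_alien_group_detected(self, shifted_space):
        res = randomization_test_cdf(
            shifted_space, "invasive_vs_native", n_perm=499, seed=5
        )
        assert res.delta_cdf < 0
        assert res.p <= 0.05

    def test_deterministic_under_seed(self, shifted_space):
        r1 = randomization_test_cdf(shifted_space, "invasive_vs_native",
                                    n_perm=199, seed=9)
        r2 = randomization_test_cdf(shifted_space, "invasive_vs_native",
                                    n_perm=199, seed=9)
        assert r1.p == r2.p and np.array_equal(r1.null, r2.null)

    def test_third_group_held_out(self):
        rng = np.random.default_rng(31)
        Z = np.vstack([
            rng.normal(size=(30, 3)),
            rng.normal(size=(10, 3)),
            rng.normal(size=(8, 3)) + 50.0,  # extreme naturalized group
        ])
        statuses = ["native"] * 30 + ["invasive"] * 10 + ["naturalized"] * 8
        with_third = randomization_test_cdf(
            toy_space(Z, statuses), "invasive_vs_native", n_perm=199, seed=4
        )
        without = randomization_test_cdf(
            toy_space(Z[:40], statuses[:40]), "invasive_vs_native",
            n_perm=199, seed=4,
        )
        assert with_third.delta_cdf == pytest.approx(without.delta_cdf)
        assert with_third.p == without.p

    def test_unknown_comparison_rejected(self, shifted_space):
        with pytest.raises(ValueError):
            randomization_test_cdf(shifted_space, "casual_vs_native")
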