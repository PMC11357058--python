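"""Relative sigma-potential descriptors and feature selection."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pytest

from dessol.sigma import (
    SIGMA_GRID,
    AxisMismatchError,
    DescriptorVector,
    GridLookupError,
    SigmaGrid,
    SigmaRegionPartition,
    SolventSystem,
    interpolate_temperature,
    lookup_grid,
    partition_regions,
    read_sigma_tsv,
    relative_potential,
    select_features,
    subset_r2,
    write_sigma_tsv,
)


def const_grid(compound, mu, T=298.15):
    return SigmaGrid(compound, T, SIGMA_GRID.copy(),
                     np.full(61, float(mu)))


class TestSigmaGridInvariants:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="61"):
            SigmaGrid("x", 298.15, SIGMA_GRID[:-1], np.zeros(60))

    def test_non_increasing_axis_rejected(self):
        sig = SIGMA_GRID.copy()[::-1]
        with pytest.raises(ValueError):
            SigmaGrid("x", 298.15, sig, np.zeros(61))

    def test_nonfinite_mu_rejected(self):
        mu = np.zeros(61)
        mu[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SigmaGrid("x", 298.15, SIGMA_GRID.copy(), mu)

    def test_axis_spacing_is_0001(self):
        assert np.allclose(np.diff(SIGMA_GRID), 0.001, atol=1e-12)
        assert SIGMA_GRID[0] == -0.03 and SIGMA_GRID[-1] == 0.03


class TestSolventSystem:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SolventSystem((("a", 0.5), ("b", 0.4)), "bad", "binary")

    def test_duplicate_components_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SolventSystem((("a", 0.5), ("a", 0.5)), "bad", "binary")


class TestRelativePotential:
    def test_self_difference_is_zero(self):
        g = const_grid("s", 1.7)
        solvent = const_grid("s", 1.7)
        d = relative_potential(g, SolventSystem.neat("s"), [solvent])
        assert np.all(d.relative_mu == 0.0)

    def test_single_component_constant(self):
        solute = const_grid("FA", 0.0)
        solvent = const_grid("w", 2.0)
        d = relative_potential(solute, SolventSystem.neat("w"), [solvent])
        assert np.allclose(d.relative_mu, -2.0)

    def test_two_component_weighted_sum(self):
        # 0.3 * 1.0 + 0.7 * 2.0 = 1.7 -> relative = 0 - 1.7
        solute = const_grid("FA", 0.0)
        sysm = SolventSystem((("a", 0.3), ("b", 0.7)), "mix", "binary")
        d = relative_potential(
            solute, sysm, [const_grid("a", 1.0), const_grid("b", 2.0)]
        )
        assert np.allclose(d.relative_mu, -1.7)

    def test_missing_component_raises_lookup_error(self):
        solute = const_grid("FA", 0.0)
        with pytest.raises(GridLookupError, match="ghost"):
            relative_potential(solute, SolventSystem.neat("ghost"), [solute])

    def test_mixture_linearity(self):
        """Descriptor of a mixture is the convex combination of the
        descriptors of its pure components."""
        rng = np.random.default_rng(0)
        solute = SigmaGrid("FA", 298.15, SIGMA_GRID.copy(),
                           rng.normal(size=61))
        ga = SigmaGrid("a", 298.15, SIGMA_GRID.copy(), rng.normal(size=61))
        gb = SigmaGrid("b", 298.15, SIGMA_GRID.copy(), rng.normal(size=61))
        grids = [ga, gb]
        for w in (0.2, 0.5, 0.9):
            mix = SolventSystem((("a", w), ("b", 1 - w)), "m", "binary")
            d_mix = relative_potential(solute, mix, grids)
            d_a = relative_potential(solute, SolventSystem.neat("a"), grids)
            d_b = relative_potential(solute, SolventSystem.neat("b"), grids)
            assert np.allclose(
                d_mix.relative_mu,
                w * d_a.relative_mu + (1 - w) * d_b.relative_mu,
                atol=1e-9,
            )

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(min_value=-100.0, max_value=100.0))
    def test_solvent_translation_shifts_descriptor(self, shift):
        rng = np.random.default_rng(1)
        mu = rng.normal(size=61)
        solute = SigmaGrid("FA", 298.15, SIGMA_GRID.copy(),
                           rng.normal(size=61))
        base = SigmaGrid("w", 298.15, SIGMA_GRID.copy(), mu)
        shifted = SigmaGrid("w", 298.15, SIGMA_GRID.copy(), mu + shift)
        d0 = relative_potential(solute, SolventSystem.neat("w"), [base])
        d1 = relative_potential(solute, SolventSystem.neat("w"), [shifted])
        assert np.allclose(d1.relative_mu, d0.relative_mu - shift)


def _toy_descriptors(values_by_col, n):
    """DescriptorVectors whose column j takes values_by_col[j]."""
    out = []
    for i in range(n):
        rel = np.array([values_by_col[j][i] for j in range(61)])
        out.append(DescriptorVector(record_id=str(i), relative_mu=rel))
    return out


def brute_force_r2(x, y):
    """Independent oracle: R^2 of the least-squares line via polyfit."""
    if np.ptp(x) == 0:
        return 0.0
    coef = np.polyfit(x, y, 1)
    pred = np.polyval(coef, x)
    sse = np.sum((y - pred) ** 2)
    sst = np.sum((y - np.mean(y)) ** 2)
    return 1.0 - sse / sst if sst > 0 else 0.0


class TestSelectFeatures:
    def test_exact_affine_column_selected(self):
        rng = np.random.default_rng(2)
        cols = {j: rng.normal(size=6) for j in range(61)}
        y = 3.0 * cols[17] - 1.0  # exact affine in column 17
        desc = _toy_descriptors(cols, 6)
        mask = select_features(desc, y, ["DES"] * 6, threshold=0.99)
        assert mask[17]

    def test_toy_set_matches_least_squares_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2.0, 3.9, 6.1, 8.0, 10.1])
        cols = {j: x if j == 30 else np.zeros(5) for j in range(61)}
        desc = _toy_descriptors(cols, 5)
        r2 = subset_r2(desc, y, ["neat"] * 5)
        assert r2["non-DES"][30] == pytest.approx(brute_force_r2(x, y),
                                                  abs=1e-12)
        mask = select_features(desc, y, ["neat"] * 5, threshold=0.4)
        assert mask[30] == (brute_force_r2(x, y) > 0.4)

    def test_threshold_one_gives_empty_mask(self):
        rng = np.random.default_rng(3)
        cols = {j: rng.normal(size=8) for j in range(61)}
        y = rng.normal(size=8)
        desc = _toy_descriptors(cols, 8)
        mask = select_features(desc, y, ["neat"] * 8, threshold=1.0)
        assert not mask.any()

    def test_mask_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n = int(rng.integers(4, 11))
            cols = {j: rng.normal(size=n) for j in range(61)}
            y = rng.normal(size=n)
            tags = rng.choice(["neat", "DES"], size=n).tolist()
            if tags.count("DES") < 3 or n - tags.count("DES") < 3:
                tags = ["neat"] * n
            desc = _toy_descriptors(cols, n)
            mask = select_features(desc, y, tags, threshold=0.4)
            for j in range(61):
                expect = False
                for name in ("neat", "DES"):
                    sel = [i for i, t in enumerate(tags)
                           if (t == "DES") == (name == "DES")]
                    if len(sel) >= 3:
                        r2 = brute_force_r2(
                            np.array([cols[j][i] for i in sel]), y[sel]
                        )
                        expect = expect or r2 > 0.4
                assert mask[j] == expect, f"trial {trial} col {j}"

    def test_affine_response_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        cols = {j: rng.normal(size=10) for j in range(61)}
        y = rng.normal(size=10)
        desc = _toy_descriptors(cols, 10)
        m0 = select_features(desc, y, ["DES"] * 10)
        m1 = select_features(desc, 4.2 * y - 17.0, ["DES"] * 10)
        assert np.array_equal(m0, m1)

    def test_constant_column_contributes_zero(self, caplog):
        cols = {j: np.ones(5) for j in range(61)}
        desc = _toy_descriptors(cols, 5)
        r2 = subset_r2(desc, [1, 2, 3, 4, 5.0], ["neat"] * 5)
        assert np.all(r2["non-DES"] == 0.0)


class TestPartitionRegions:
    def test_all_false_mask(self):
        out = partition_regions(SigmaRegionPartition(), np.zeros(61, bool))
        assert out == {"HBD": [], "HYD": [], "HBA": []}

    def test_sigma_zero_is_hydrophobic(self):
        mask = np.zeros(61, bool)
        mask[30] = True  # sigma = 0
        out = partition_regions(SigmaRegionPartition(), mask)
        assert out["HYD"] == [30] and not out["HBD"] and not out["HBA"]

    def test_one_index_per_region(self):
        mask = np.zeros(61, bool)
        for sigma in (-0.02, 0.0, 0.02):
            mask[np.argmin(np.abs(SIGMA_GRID - sigma))] = True
        out = partition_regions(SigmaRegionPartition(), mask)
        assert [len(out[k]) for k in ("HBD", "HYD", "HBA")] == [1, 1, 1]

    def test_regions_cover_axis_disjointly(self):
        out = partition_regions(SigmaRegionPartition(), np.ones(61, bool))
        allidx = sorted(out["HBD"] + out["HYD"] + out["HBA"])
        assert allidx == list(range(61))


class TestInterpolateTemperature:
    def test_endpoint_returns_input(self):
        lo = const_grid("c", 0.0, T=290.0)
        hi = const_grid("c", 2.0, T=310.0)
        assert interpolate_temperature(lo, hi, 290.0) is lo
        assert interpolate_temperature(lo, hi, 310.0) is hi

    def test_midpoint(self):
        lo = const_grid("c", 0.0, T=290.0)
        hi = const_grid("c", 2.0, T=310.0)
        g = interpolate_temperature(lo, hi, 300.0)
        assert np.allclose(g.mu_values, 1.0)

    def test_quarter_point_linear_arithmetic(self):
        rng = np.random.default_rng(6)
        mu0, mu1 = rng.normal(size=61), rng.normal(size=61)
        lo = SigmaGrid("c", 290.0, SIGMA_GRID.copy(), mu0)
        hi = SigmaGrid("c", 310.0, SIGMA_GRID.copy(), mu1)
        g = interpolate_temperature(lo, hi, 295.0)
        assert np.allclose(g.mu_values, 0.75 * mu0 + 0.25 * mu1)

    def test_extrapolation_guarded(self):
        lo = const_grid("c", 0.0, T=290.0)
        hi = const_grid("c", 2.0, T=310.0)
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_temperature(lo, hi, 320.0)
        g = interpolate_temperature(lo, hi, 320.0, allow_extrapolation=True)
        assert np.allclose(g.mu_values, 3.0)


class TestLookup:
    def test_snap_within_half_kelvin(self):
        g = const_grid("c", 1.0, T=298.15)
        assert lookup_grid([g], "c", 298.4) is g

    def test_interpolates_between_bracketing_grids(self):
        lo = const_grid("c", 0.0, T=290.0)
        hi = const_grid("c", 2.0, T=310.0)
        g = lookup_grid([lo, hi], "c", 300.0)
        assert np.allclose(g.mu_values, 1.0)

    def test_out_of_range_raises(self):
        lo = const_grid("c", 0.0, T=290.0)
        with pytest.raises(GridLookupError):
            lookup_grid([lo], "c", 300.0)


def test_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    g = SigmaGrid("FA", 303.15, SIGMA_GRID.copy(), rng.normal(size=61))
    p = tmp_path / "fa.tsv"
    write_sigma_tsv(g, p)
    back = read_sigma_tsv(p)
    assert back.compound_id == "FA"
    assert back.temperature == 303.15
    assert np.allclose(back.mu_values, g.mu_values, rtol=1e-10)
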