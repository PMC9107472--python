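"""Droplet sampling and vaporization statistics."""

import numpy as np
import pytest

from nanodose.beam import BeamSpec, curve_metrics, ion_survival, let_profile, pristine_bragg, survival_fraction
from nanodose.nucleation import ATM, get_pfc
from nanodose.phantom import (
    BubbleField,
    DropletPopulation,
    Droplets,
    PhantomSpec,
    dilute_to_phantom,
    expansion_factor,
    irradiate,
    sample_droplets,
    spontaneous_probability,
    spontaneous_vaporization,
)


@pytest.fixture(scope="module")
def beam_setup():
    curve = pristine_bragg(180.0, 3.04)
    letc = let_profile(curve)
    return curve, letc, BeamSpec(range=180.0, dose_at_peak=1.0)


class TestDilution:
    def test_reference_concentration(self):
        # 23 ul of the bulk stock into the 40.09 ml gel mix
        assert dilute_to_phantom(7e9, 23.0, 40.09) == pytest.approx(4.0e6, rel=0.01)

    def test_top_concentration(self):
        assert dilute_to_phantom(7e9, 50.0, 40.09) == pytest.approx(8.7e6, rel=0.01)

    def test_zero_volume_added(self):
        assert dilute_to_phantom(7e9, 0.0, 40.09) == 0.0

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            dilute_to_phantom(7e9, 50_000.0, 40.0)


class TestSampleDroplets:
    SPEC = PhantomSpec()

    def test_deterministic(self):
        pop = DropletPopulation(concentration=1e5)
        region = ((0.0, 10.0), (0.0, 10.0), (0.0, 10.0))
        a = sample_droplets(self.SPEC, pop, 7, region=region)
        b = sample_droplets(self.SPEC, pop, 7, region=region)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.diameters_nm, b.diameters_nm)

    def test_zero_concentration(self):
        pop = DropletPopulation(concentration=0.0)
        assert len(sample_droplets(self.SPEC, pop, 0)) == 0

    def test_poisson_count(self):
        """Observed counts stay within 4 sqrt(lambda) of the expectation."""
        pop = DropletPopulation(concentration=2e5)
        region = ((0.0, 10.0), (0.0, 10.0), (0.0, 10.0))  # 1 ml
        lam = 2e5
        for seed in range(5):
            n = len(sample_droplets(self.SPEC, pop, seed, region=region))
            assert abs(n - lam) < 4 * np.sqrt(lam)

    def test_diameter_distribution(self):
        pop = DropletPopulation()
        region = ((0.0, 20.0), (0.0, 20.0), (0.0, 20.0))
        d = sample_droplets(
            PhantomSpec(nd_concentration=1e5),
            DropletPopulation(concentration=2e4),
            11,
            region=region,
        ).diameters_nm
        lo, hi = pop.diameter_bounds_nm
        assert d.min() >= lo and d.max() <= hi
        assert abs(d.mean() - 700.0) < 100.0

    def test_positions_inside_region(self):
        region = ((5.0, 8.0), (1.0, 2.0), (10.0, 30.0))
        drops = sample_droplets(
            self.SPEC, DropletPopulation(concentration=1e5), 3, region=region
        )
        for axis, (lo, hi) in enumerate(region):
            assert drops.positions[:, axis].min() >= lo
            assert drops.positions[:, axis].max() <= hi


class TestSpontaneous:
    def _droplets(self, n, d_nm, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(n, 3)).astype(np.float32)
        return Droplets(pos, np.full(n, d_nm, dtype=np.float32))

    def test_zero_rate(self):
        drops = self._droplets(1000, 700.0)
        field = spontaneous_vaporization(
            drops, rate_params={"base_rate": 0.0}, seed=1
        )
        assert len(field) == 0

    def test_mean_fraction_matches_expectation(self):
        """Monte-Carlo hit fraction agrees with the analytic mean of the
        per-droplet probabilities over the size distribution."""
        pop = DropletPopulation()
        drops = sample_droplets(
            PhantomSpec(),
            DropletPopulation(concentration=5e4),
            5,
            region=((0.0, 20.0), (0.0, 20.0), (0.0, 20.0)),
        )
        params = {"base_rate": 2e-3}
        expected = spontaneous_probability(drops.diameters_nm, 1.0, params).mean()
        hits = [
            len(spontaneous_vaporization(drops, 1.0, params, seed=s))
            for s in range(8)
        ]
        n = len(drops)
        observed = np.mean(hits) / n
        mc_sd = np.sqrt(expected / (n * 8))
        assert abs(observed - expected) < 5 * mc_sd

    def test_large_droplets_vaporize_more(self):
        """Stochastic dominance: 1000 nm droplets beat 200 nm ones."""
        big = self._droplets(10_000, 1000.0)
        small = self._droplets(10_000, 200.0)
        params = {"base_rate": 1e-3}
        for seed in range(3):
            n_big = len(spontaneous_vaporization(big, 1.0, params, seed=seed))
            n_small = len(spontaneous_vaporization(small, 1.0, params, seed=seed))
            assert n_big > n_small

    def test_origin_label(self):
        field = spontaneous_vaporization(
            self._droplets(500, 900.0), rate_params={"base_rate": 0.5}, seed=2
        )
        assert len(field) > 0
        assert set(field.origin) == {"spontaneous"}


class TestIrradiate:
    SPEC = PhantomSpec()

    def _droplets(self, n, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.column_stack(
            [
                rng.uniform(20, 45, n),  # beam axis 166..191: spans the peak
                rng.uniform(0, 26, n),
                rng.uniform(0, 23, n),
            ]
        ).astype(np.float32)
        return Droplets(pos, np.full(n, 700.0, dtype=np.float32))

    def test_zero_dose(self, beam_setup):
        curve, letc, _ = beam_setup
        beam = BeamSpec(range=180.0, dose_at_peak=0.0)
        field = irradiate(
            self._droplets(1000), self.SPEC, curve, letc, beam, seed=0
        )
        assert len(field) == 0

    def test_let_below_threshold_everywhere(self, beam_setup):
        curve, letc, beam = beam_setup
        field = irradiate(
            self._droplets(1000), self.SPEC, curve, letc, beam,
            threshold=1e6, seed=0,
        )
        assert len(field) == 0

    def test_depth_profile_matches_analytic_expectation(self, beam_setup):
        """Binned bubble counts track the closed-form hit probability."""
        curve, letc, beam = beam_setup
        drops = self._droplets(100_000)
        fields = [
            irradiate(
                drops, self.SPEC, curve, letc, beam,
                efficiency=10.0, seed=s,
            )
            for s in range(5)
        ]
        z_all = self.SPEC.beam_axis_of(drops.positions[:, 0].astype(float))
        from nanodose.nucleation import let_threshold
        from nanodose.phantom import calibrated_survival, let_efficiency_ramp

        thr = let_threshold(37.0).LET_threshold
        mean_range, sigma = calibrated_survival(curve, letc, thr)
        area = np.pi * (700e-7 / 2) ** 2
        gate = let_efficiency_ramp(z_all, letc, thr)
        p = 1 - np.exp(
            -10.0 * area * beam.fluence * gate
            * survival_fraction(z_all, mean_range, sigma)
        )
        bins = np.arange(166.0, 191.0, 1.0)
        expected, _ = np.histogram(z_all, bins, weights=p)
        counts = np.zeros(len(bins) - 1)
        for f in fields:
            zb = self.SPEC.beam_axis_of(f.positions[:, 0].astype(float))
            counts += np.histogram(zb, bins)[0]
        counts /= len(fields)
        tol = 4 * np.sqrt(np.maximum(expected, 1.0) / len(fields))
        assert np.all(np.abs(counts - expected) <= tol)

    def test_dose_rate_invariance(self, beam_setup):
        """Identical fluence at 100% vs 50% rate: identical bubble fields."""
        curve, letc, _ = beam_setup
        drops = self._droplets(20_000)
        full = irradiate(
            drops, self.SPEC, curve, letc,
            BeamSpec(range=180.0, dose_at_peak=1.0, dose_rate_fraction=100.0),
            seed=3,
        )
        half = irradiate(
            drops, self.SPEC, curve, letc,
            BeamSpec(range=180.0, dose_at_peak=1.0, dose_rate_fraction=50.0),
            seed=3,
        )
        assert np.array_equal(full.positions, half.positions)

    def test_monotone_in_dose(self, beam_setup):
        curve, letc, _ = beam_setup
        drops = self._droplets(50_000)
        counts = []
        for dose in (0.25, 1.0, 4.0):
            n = sum(
                len(
                    irradiate(
                        drops, self.SPEC, curve, letc,
                        BeamSpec(range=180.0, dose_at_peak=dose),
                        seed=s,
                    )
                )
                for s in range(3)
            )
            counts.append(n)
        assert counts[0] < counts[1] < counts[2]

    def test_spatial_confinement(self, beam_setup):
        """>95% of radiation bubbles lie between the 60%-of-peak proximal
        depth and the distal 10%-of-peak depth."""
        curve, letc, beam = beam_setup
        drops = self._droplets(100_000)
        field = irradiate(
            drops, self.SPEC, curve, letc, beam, efficiency=10.0, seed=4
        )
        zb = self.SPEC.beam_axis_of(field.positions[:, 0].astype(float))
        peak = curve.dose.max()
        z60 = curve.depth[np.flatnonzero(curve.dose >= 0.6 * peak)[0]]
        peak_idx = int(np.argmax(curve.dose))
        distal = curve.dose[peak_idx:]
        z10 = curve.depth[peak_idx + np.flatnonzero(distal < 0.1 * peak)[0]] \
            if np.any(distal < 0.1 * peak) else curve.depth[-1]
        inside = (zb >= z60) & (zb <= z10)
        assert inside.mean() > 0.95

    def test_mismatched_grids_rejected(self, beam_setup):
        curve, letc, beam = beam_setup
        bad = let_profile(pristine_bragg(180.0, 3.04, grid_step=0.1))
        with pytest.raises(ValueError, match="grid"):
            irradiate(self._droplets(10), self.SPEC, curve, bad, beam, seed=0)


class TestExpansionFactor:
    def test_pfb_body_conditions(self):
        f = expansion_factor(get_pfc("perfluorobutane"), 37.0, ATM)
        assert f == pytest.approx(5.5, abs=0.3)

    def test_pressure_scaling(self):
        props = get_pfc("perfluorobutane")
        f1 = expansion_factor(props, 37.0, ATM)
        f2 = expansion_factor(props, 37.0, 2 * ATM)
        assert f2 / f1 == pytest.approx(2 ** (-1 / 3), rel=1e-12)

    def test_override_passthrough(self):
        props = get_pfc("perfluorobutane")
        assert expansion_factor(props, 37.0, ATM, override=10.0) == 10.0
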