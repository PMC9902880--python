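"""Trace photometry and photobleaching step classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirspot.detect import Spot
from mirspot.simulate import Emitter, GroundTruth, ImagingConfig, render_movie
from mirspot.traces import (
    TraceError,
    count_steps,
    estimate_noise_sd,
    extract_trace,
    extract_traces,
    filter_single_molecules,
)


from oracles import exhaustive_segmentation


def _spot(x=16.0, y=16.0):
    return Spot(x=x, y=y, peak_intensity=0.0)


class TestExtractTrace:
    def test_uniform_image_cancels(self):
        data = np.full((6, 32, 32), 250.0)
        trace = extract_trace(data, _spot())
        assert np.allclose(trace.intensities, 0.0)
        assert trace.background_level == pytest.approx(250.0)

    def test_photometry_matches_gaussian_mass(self):
        # noise-free emitter at gain 1: trace = photons × PSF mass in aperture
        img = ImagingConfig(width=32, height=32, n_frames=5, em_gain=1.0,
                            photons_per_frame=400.0, background_photons=0.0,
                            bleach_rate=0.0)
        truth = GroundTruth([Emitter(x=16.0, y=16.0, bleach_frames=(5,))])
        movie = render_movie(truth, img, noise=False)
        trace = extract_trace(movie, _spot())
        # independent oracle: radial integral of the 2-D Gaussian over the
        # aperture disc (pixelation keeps this within a couple of percent)
        r_ap, sigma = 3.0, img.psf_sigma
        mass = 1.0 - math.exp(-(r_ap**2) / (2 * sigma**2))
        assert trace.intensities[0] == pytest.approx(400.0 * mass, rel=0.02)

    def test_bleach_steps_down_to_zero(self):
        img = ImagingConfig(width=32, height=32, n_frames=20, em_gain=1.0,
                            photons_per_frame=400.0, background_photons=0.0,
                            read_noise_sd=0.0)
        truth = GroundTruth([Emitter(x=16.0, y=16.0, bleach_frames=(10,))])
        movie = render_movie(truth, img, noise=False)
        trace = extract_trace(movie, _spot())
        assert np.all(trace.intensities[:10] > 100)
        assert np.allclose(trace.intensities[10:], 0.0, atol=1e-6)

    def test_edge_spot_rejected(self):
        data = np.zeros((5, 32, 32))
        with pytest.raises(TraceError):
            extract_trace(data, _spot(x=2.0, y=16.0))
        spots = [_spot(x=2.0, y=16.0), _spot()]
        traces = extract_traces(data, spots)
        assert traces[0] is None and spots[0].accepted is False
        assert traces[1] is not None

    def test_annulus_geometry_validated(self):
        data = np.zeros((5, 32, 32))
        with pytest.raises(TraceError):
            extract_trace(data, _spot(), aperture_radius=3, annulus_inner=2,
                          annulus_outer=6)


class TestCountSteps:
    def test_constant_trace_one_level(self):
        fit = count_steps(np.full(20, 500.0), noise_sd_estimate=5.0)
        assert fit.n_levels == 1 and fit.change_frames == []

    def test_two_fluorophore_staircase(self, rng):
        y = np.concatenate([np.full(10, 200.0), np.full(10, 100.0), np.zeros(10)])
        y = y + rng.normal(0, 2.0, size=30)
        fit = count_steps(y)
        assert fit.n_levels == 3
        assert fit.change_frames == [10, 20]
        assert fit.n_down == 2 and fit.n_up == 0
        assert fit.reaches_baseline

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError):
            count_steps(np.array([1.0, 2.0, 3.0]))

    @given(st.floats(0.5, 200.0))
    def test_scaling_invariance(self, c):
        rng = np.random.default_rng(7)
        y = np.concatenate([np.full(12, 150.0), np.zeros(12)])
        y = y + rng.normal(0, 4.0, size=24)
        base = count_steps(y, noise_sd_estimate=4.0)
        scaled = count_steps(y * c, noise_sd_estimate=4.0 * c)
        assert scaled.n_levels == base.n_levels
        assert scaled.change_frames == base.change_frames

    def test_monotone_penalty(self, rng):
        for _ in range(20):
            y = rng.normal(0, 1, 30) + np.repeat(
                rng.choice([0, 50, 100], size=3), 10
            )
            levels = [
                count_steps(y, penalty=p).n_levels for p in (0.5, 2.0, 5.0, 20.0, 100.0)
            ]
            assert levels == sorted(levels, reverse=True)

    def test_matches_exhaustive_oracle_on_short_traces(self, rng):
        """Binary segmentation equals brute-force optimum on bleach-like traces."""
        mismatches = 0
        sd = 5.0
        for i in range(200):
            n = int(rng.integers(8, 13))
            n_steps = int(rng.integers(0, 3))
            # change points ≥ 2 frames apart so every level is representable
            while True:
                cps = sorted(rng.choice(range(2, n - 1), size=n_steps,
                                        replace=False)) if n_steps else []
                if all(b - a >= 2 for a, b in zip(cps, cps[1:])):
                    break
            # bleach staircase with step sizes at the assay's SNR (≥ 8σ)
            drops = rng.uniform(8 * sd, 40 * sd, size=n_steps)
            levels = [float(drops[k:].sum()) for k in range(n_steps + 1)]
            y = np.empty(n)
            for lvl, (a, b) in zip(levels, itertools.pairwise([0, *cps, n])):
                y[a:b] = lvl
            y += rng.normal(0, sd, size=n)
            fit = count_steps(y, penalty=5.0, noise_sd_estimate=sd)
            beta = 5.0 * sd**2 * math.log(n)
            oracle = exhaustive_segmentation(y, beta)
            if fit.change_frames != oracle:
                mismatches += 1
        assert mismatches == 0

    def test_noise_sd_estimator(self, rng):
        y = rng.normal(0, 12.0, size=2000)
        assert estimate_noise_sd(y) == pytest.approx(12.0, rel=0.1)
        # robust to a large step
        y[1000:] += 500.0
        assert estimate_noise_sd(y) == pytest.approx(12.0, rel=0.1)


class TestFilterSingleMolecules:
    def _as_traces(self, arrays):
        from mirspot.traces import Trace

        spots = [_spot() for _ in arrays]
        traces = [
            Trace(spot=s, intensities=np.asarray(a, dtype=float), background_level=0.0)
            for s, a in zip(spots, arrays)
        ]
        return spots, traces

    def test_constant_traces_accepted_in_counting_mode(self, rng):
        arrays = [np.full(30, 400.0) + rng.normal(0, 5, 30) for _ in range(5)]
        spots, traces = self._as_traces(arrays)
        accepted = filter_single_molecules(spots, traces, policy="counting")
        assert len(accepted) == 5
        assert all(s.accepted for s in spots)

    def test_two_downward_steps_rejected(self, rng):
        y = np.concatenate([np.full(10, 200.0), np.full(10, 100.0), np.zeros(10)])
        spots, traces = self._as_traces([y + rng.normal(0, 2, 30)])
        assert filter_single_molecules(spots, traces) == []
        assert spots[0].accepted is False

    def test_upward_step_rejected(self, rng):
        y = np.concatenate([np.zeros(15), np.full(15, 200.0)])
        spots, traces = self._as_traces([y + rng.normal(0, 2, 30)])
        assert filter_single_molecules(spots, traces) == []

    def test_single_bleach_accepted_both_modes(self, rng):
        y = np.concatenate([np.full(15, 200.0), np.zeros(15)])
        arrays = [y + rng.normal(0, 2, 30)]
        for policy in ("counting", "validation"):
            spots, traces = self._as_traces(arrays)
            assert len(filter_single_molecules(spots, traces, policy=policy)) == 1

    def test_validation_requires_baseline(self, rng):
        # bleach observed but trace never reaches zero → validation rejects
        y = np.concatenate([np.full(15, 400.0), np.full(15, 150.0)])
        arrays = [y + rng.normal(0, 2, 30)]
        spots, traces = self._as_traces(arrays)
        assert filter_single_molecules(spots, traces, policy="validation") == []
        spots, traces = self._as_traces(arrays)
        assert len(filter_single_molecules(spots, traces, policy="counting")) == 1

    def test_mixed_double_emitter_field_fraction(self):
        """~20% two-fluorophore spots → accepted fraction tracks the mix."""
        img = ImagingConfig(width=32, height=32, n_frames=60, bleach_rate=0.05)
        rng = np.random.default_rng(11)
        n_single, n_double, accepted = 0, 0, 0
        total = 120
        for i in range(total):
            double = rng.uniform() < 0.2
            n_fluor = 2 if double else 1
            bleach = tuple(
                min(60, int(math.ceil(rng.exponential(1 / img.bleach_rate))))
                for _ in range(n_fluor)
            )
            truth = GroundTruth([Emitter(x=16.0, y=16.0, n_fluorophores=n_fluor,
                                         bleach_frames=bleach)])
            movie = render_movie(truth, img, seed=1000 + i)
            spots = [_spot()]
            traces = extract_traces(movie, spots)
            got = filter_single_molecules(spots, traces, policy="counting")
            n_double += double
            n_single += not double
            accepted += len(got)
        # doubles whose two dyes both bleach within the movie are rejected;
        # accepted fraction should sit near 1 − 0.2·P(both bleach) ≈ 0.85
        frac = accepted / total
        assert 0.75 <= frac <= 0.95
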