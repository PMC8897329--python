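"""Sampling statistics of the phase-space source generator.

Each statistical check compares the sampler against an independent closed
form: the multinomial law for angle-bin selection, the uniform/log-uniform/
Maxwellian in-group energy laws, and the r^2 disc CDF for positions.
"""

import math

import numpy as np
import pytest
from scipy import stats

from j45dose.fluence import FluenceComponent, default_group_structure
from j45dose.phase_space import (
    DegenerateSourceError,
    SamplerConfig,
    generate_phase_space,
    place_on_disc,
    sample_angle_bin,
    sample_angle_bins,
    sample_energies,
    sample_energy,
)
from j45dose.quadrature import DirectionBin, direction_vector, ds02_quadrature


def _component_with(q, bin_values):
    """prompt_gamma component with given per-bin total fluence, flat in E."""
    groups = default_group_structure("prompt_gamma")
    vals = np.zeros((q.n_bins, groups.n_groups))
    for b, v in bin_values.items():
        vals[b, :] = v / groups.n_groups
    return FluenceComponent("prompt_gamma", vals, groups)


def _neutron_component(edges, weights_by_group, bin_index, q):
    """delayed_neutron component concentrated in chosen groups of one bin."""
    groups = default_group_structure("delayed_neutron")
    vals = np.zeros((q.n_bins, groups.n_groups))
    for g, w in weights_by_group.items():
        vals[bin_index, g] = w
    return FluenceComponent("delayed_neutron", vals, groups)


class TestAngleSelection:
    def test_single_bin_always_selected(self):
        q = ds02_quadrature("symmetric")
        bi = next(i for i, b in enumerate(q.bins) if b.weight > 0)
        c = _component_with(q, {bi: 1.0})
        rng = np.random.default_rng(0)
        assert all(sample_angle_bin(c, q, rng) == bi for _ in range(50))

    def test_two_bins_follow_weighted_ratio(self):
        q = ds02_quadrature("symmetric")
        contrib = [i for i, b in enumerate(q.bins) if b.weight > 0]
        b1, b2 = contrib[0], contrib[7]
        w1, w2 = q.bins[b1].weight, q.bins[b2].weight
        # arrange weighted fluences in ratio 3:1
        c = _component_with(q, {b1: 3.0 / w1, b2: 1.0 / w2})
        rng = np.random.default_rng(1)
        n = 100_000
        picks = sample_angle_bins(c, q, rng, n)
        k1 = int((picks == b1).sum())
        # exact binomial oracle at p = 3/4
        p = 0.75
        sd = math.sqrt(n * p * (1 - p))
        assert abs(k1 - n * p) < 4 * sd

    def test_zero_weight_bin_never_selected(self):
        q = ds02_quadrature("symmetric")
        start = next(i for i, b in enumerate(q.bins) if b.weight == 0.0)
        contrib = next(i for i, b in enumerate(q.bins) if b.weight > 0)
        # a huge fluence parked on the starting direction is multiplied out
        c = _component_with(q, {start: 1e30, contrib: 1.0})
        rng = np.random.default_rng(2)
        picks = sample_angle_bins(c, q, rng, 100_000)
        assert not np.any(picks == start)

    def test_degenerate_source_rejected(self):
        q = ds02_quadrature("symmetric")
        start = next(i for i, b in enumerate(q.bins) if b.weight == 0.0)
        c = _component_with(q, {start: 1.0})
        with pytest.raises(DegenerateSourceError):
            sample_angle_bin(c, q, np.random.default_rng(0))


class TestEnergySampling:
    def test_gamma_uniform_in_group(self):
        q = ds02_quadrature("symmetric")
        groups = default_group_structure("prompt_gamma")
        # pick the group straddling ~1-2 MeV and force all fluence into it
        g = int(np.searchsorted(groups.edges, 1.0)) - 1
        lo, hi = groups.lower[g], groups.upper[g]
        vals = np.zeros((q.n_bins, groups.n_groups))
        bi = next(i for i, b in enumerate(q.bins) if b.weight > 0)
        vals[bi, g] = 1.0
        c = FluenceComponent("prompt_gamma", vals, groups)
        rng = np.random.default_rng(3)
        e = sample_energies(c, np.full(100_000, bi), SamplerConfig(), rng)
        assert e.min() >= lo and e.max() <= hi
        assert e.mean() == pytest.approx((lo + hi) / 2, rel=3e-3)

    def test_epithermal_log_uniform(self):
        q = ds02_quadrature("symmetric")
        groups = default_group_structure("delayed_neutron")
        bi = next(i for i, b in enumerate(q.bins) if b.weight > 0)
        g = int(np.searchsorted(groups.edges, 1e-5)) - 1
        c = _neutron_component(groups.edges, {g: 1.0}, bi, q)
        rng = np.random.default_rng(4)
        e = sample_energies(c, np.full(100_000, bi), SamplerConfig(), rng)
        lo, hi = groups.lower[g], groups.upper[g]
        # inverse-CDF closed form: median of 1/E on [lo, hi) is sqrt(lo*hi)
        assert np.median(e) == pytest.approx(math.sqrt(lo * hi), rel=2e-2)
        u = np.log(e / lo) / np.log(hi / lo)
        assert stats.kstest(u, "uniform").pvalue > 0.001

    def test_thermal_maxwellian_moment(self):
        q = ds02_quadrature("symmetric")
        groups = default_group_structure("delayed_neutron")
        bi = next(i for i, b in enumerate(q.bins) if b.weight > 0)
        cfg = SamplerConfig()
        kT = cfg.kT_MeV
        # all fluence in groups below the thermal cutoff: the sampled mix of
        # truncated Maxwellians over the full thermal range has mean 3/2 kT
        thermal_groups = {}
        for g in range(groups.n_groups):
            lo, hi = groups.lower[g], groups.upper[g]
            if hi <= cfg.thermal_cutoff:
                # weight by the Maxwellian content of the group
                from scipy.special import gammainc
                thermal_groups[g] = (gammainc(1.5, hi / kT)
                                     - gammainc(1.5, lo / kT))
        c = _neutron_component(groups.edges, thermal_groups, bi, q)
        rng = np.random.default_rng(5)
        e = sample_energies(c, np.full(200_000, bi), cfg, rng)
        assert e.mean() == pytest.approx(1.5 * kT, rel=0.01)

    def test_samples_stay_inside_their_group(self, io_scenario):
        c = io_scenario.components["prompt_neutron"]
        q = io_scenario.quadrature
        rng = np.random.default_rng(6)
        bins = sample_angle_bins(c, q, rng, 20_000)
        e = sample_energies(c, bins, SamplerConfig(), rng)
        assert e.min() >= c.groups.edges[0]
        assert e.max() <= c.groups.edges[-1]

    def test_empty_spectrum_rejected(self):
        q = ds02_quadrature("symmetric")
        groups = default_group_structure("prompt_gamma")
        vals = np.zeros((q.n_bins, groups.n_groups))
        vals[0, 0] = 1.0
        c = FluenceComponent("prompt_gamma", vals, groups)
        with pytest.raises(DegenerateSourceError):
            sample_energy(c, 5, SamplerConfig(), np.random.default_rng(0))


class TestDiscPlacement:
    def test_vertical_bin_case(self):
        b = DirectionBin(mu=0.0, eta=1.0, beta_sign=0, weight=0.1, level=1)
        rng = np.random.default_rng(7)
        pos, dirs = place_on_disc(b, 100.0, rng, 1000)
        np.testing.assert_allclose(dirs, np.tile([0.0, 0.0, 1.0], (1000, 1)))
        np.testing.assert_allclose(pos[:, 2], -100.0, atol=1e-9)

    def test_plane_offset_identity_all_bins(self, asymmetric480):
        rng = np.random.default_rng(8)
        for b in asymmetric480.bins[::17]:
            if b.weight == 0:
                continue
            pos, dirs = place_on_disc(b, 70.0, rng, 200)
            dots = np.einsum("ij,ij->i", pos, dirs)
            assert np.abs(dots + 70.0).max() < 1e-9
            np.testing.assert_allclose(dirs[0], direction_vector(b),
                                       atol=1e-12)

    def test_disc_radial_cdf(self):
        b = DirectionBin(mu=0.6, eta=0.5, beta_sign=1, weight=0.1, level=2)
        rng = np.random.default_rng(9)
        R = 100.0
        pos, dirs = place_on_disc(b, R, rng, 100_000)
        d = dirs[0]
        inplane = pos + R * d          # remove the upstream translation
        r = np.linalg.norm(inplane - np.outer(inplane @ d, d), axis=1)
        # uniform disc: P(r < x) = (x/R)^2
        assert stats.kstest(r / R, lambda x: x**2).pvalue > 0.001

    def test_zero_weight_bin_rejected(self):
        b = DirectionBin(mu=0.0, eta=1.0, beta_sign=0, weight=0.0,
                         level=1, is_starting=True)
        with pytest.raises(ValueError):
            place_on_disc(b, 100.0, np.random.default_rng(0))


class TestGeneratePhaseSpace:
    def test_record_count_and_determinism(self, io_scenario, tmp_path):
        cfg = SamplerConfig(n_particles=1000, seed=13)
        a = generate_phase_space(io_scenario, "delayed_gamma", cfg,
                                 tmp_path / "a.txt")
        generate_phase_space(io_scenario, "delayed_gamma", cfg,
                             tmp_path / "b.txt")
        assert (tmp_path / "a.txt").read_bytes() == \
               (tmp_path / "b.txt").read_bytes()
        batch = a.read()
        assert len(batch) == 1000
        assert batch.ptype == "gamma"

    def test_angle_histogram_matches_weighted_fluence(self, io_scenario,
                                                      tmp_path):
        cfg = SamplerConfig(n_particles=200_000, seed=14)
        q = io_scenario.quadrature
        c = io_scenario.components["prompt_gamma"]
        rng = np.random.default_rng(14)
        picks = sample_angle_bins(c, q, rng, cfg.n_particles)
        wf = q.weights * c.values.sum(axis=1)
        p = wf / wf.sum()
        counts = np.bincount(picks, minlength=q.n_bins)
        keep = p * cfg.n_particles >= 5     # chi-square validity
        chi = stats.chisquare(counts[keep],
                              p[keep] / p[keep].sum() * counts[keep].sum())
        assert chi.pvalue > 0.001

    def test_unknown_component_rejected(self, io_scenario, tmp_path):
        with pytest.raises(KeyError):
            generate_phase_space(io_scenario, "nope", SamplerConfig(),
                                 tmp_path / "x.txt")
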