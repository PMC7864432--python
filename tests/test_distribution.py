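"""Quantile-distance statistic: exactness, equivariance, dominance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rseeg
from rseeg.distribution import EmpiricalPowerDistribution, pddf, pddm

from test_spectral import make_epm


def dist(samples, band="theta"):
    return EmpiricalPowerDistribution(band=band, samples=np.asarray(samples, float))


def dense_grid_pddm(d1, d2, c1, c2, n_grid=10_000):
    """Black-box quadrature oracle: integrate the quantile difference over
    a dense u-grid refined with the order-statistic breakpoints, each cell
    evaluated at its midpoint (the integrand is constant within cells)."""
    brk = np.concatenate(
        [np.linspace(c1, c2, n_grid),
         np.arange(1, d1.n + 1) / d1.n,
         np.arange(1, d2.n + 1) / d2.n]
    )
    brk = np.unique(np.clip(brk, c1, c2))
    mids = 0.5 * (brk[:-1] + brk[1:])
    vals = d1.quantile(mids) - d2.quantile(mids)
    return float(np.sum(vals * np.diff(brk)))


class TestEmpiricalDistribution:
    def test_degenerate_distribution(self):
        d = dist([2.0] * 30)
        assert d.quantile([0.01, 0.5, 1.0]) == pytest.approx(2.0)
        assert d.pdf().sum() == pytest.approx(1.0)

    def test_worked_quantiles_1113(self):
        d = dist([1.0, 1.0, 1.0, 3.0])
        # F(1) = 0.75, F(3) = 1; generalized inverse jumps at 0.75
        assert d.quantile(0.75) == 1.0
        assert d.quantile(0.8) == 3.0
        assert d.quantile(1.0) == 3.0

    def test_pdf_sums_to_one_and_cdf_ends_at_one(self, rng):
        d = dist(rng.normal(size=200))
        assert d.pdf().sum() == pytest.approx(1.0)
        assert d.cdf()[-1] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dist([])

    def test_quantile_domain_checked(self):
        with pytest.raises(ValueError):
            dist([1.0, 2.0]).quantile(0.0)


class TestPddm:
    def test_identical_distributions_give_zero_exactly(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 300))
            d = dist(x)
            assert pddm(d, d) == 0.0

    def test_antisymmetry_bit_exact(self, rng):
        for _ in range(20):
            a, b = dist(rng.normal(size=60)), dist(rng.normal(size=60), "alpha")
            assert pddm(a, b) == -pddm(b, a)

    def test_constant_shift_identity(self, rng):
        x = rng.normal(size=100)
        delta = 1.0
        a, b = dist(x + delta), dist(x, "alpha")
        assert pddm(a, b, 0.95, 1.0) == pytest.approx(delta * 0.05, abs=1e-12)
        assert pddm(a, b, 0.0, 1.0) == pytest.approx(delta, abs=1e-12)

    def test_worked_step_function_example(self):
        theta = dist([1.0, 1.0, 1.0, 3.0])
        alpha = dist([1.0, 1.0, 1.0, 1.0], "alpha")
        assert pddm(theta, alpha, 0.95, 1.0) == pytest.approx(0.10, abs=1e-12)
        assert pddm(theta, alpha, 0.0, 1.0) == pytest.approx(0.50, abs=1e-12)

    def test_invalid_window_rejected(self):
        d = dist([1.0, 2.0])
        with pytest.raises(ValueError):
            pddm(d, d, 0.9, 0.9)
        with pytest.raises(ValueError):
            pddm(d, d, 0.9, 0.5)

    def test_matches_dense_grid_oracle(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(5, 500, size=2)
            a = dist(rng.normal(size=n1) * rng.uniform(0.5, 2.0))
            b = dist(rng.normal(size=n2) + rng.uniform(-1, 1), "alpha")
            c1 = float(rng.uniform(0.0, 0.9))
            c2 = float(rng.uniform(c1 + 0.05, 1.0))
            assert pddm(a, b, c1, c2) == pytest.approx(
                dense_grid_pddm(a, b, c1, c2), abs=1e-9
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=4, max_size=60),
        shift=st.floats(0.0, 3.0),
    )
    def test_stochastic_dominance_property(self, x, shift):
        """If sorted B1 samples pairwise dominate B2's, PDDF >= 0 and
        PDDM >= 0 on every window."""
        b = dist(x, "alpha")
        a = dist(np.asarray(x) + shift)
        u = np.linspace(0.01, 1.0, 97)
        assert (pddf(a, b, u) >= 0).all()
        assert pddm(a, b, 0.95, 1.0) >= 0.0
        assert pddm(a, b, 0.25, 0.75) >= 0.0


class TestBinnedReconstruction:
    def test_binned_cdf_pddm_close_to_exact(self, rng):
        """Reconstructing quantiles from the reporting bins changes PDDM by
        at most one bin width times the window length."""
        x = rng.normal(size=300)
        y = rng.normal(size=300) * 1.3
        a, b = dist(x), dist(y, "alpha")
        lo = min(x.min(), y.min()) - 1e-9
        hi = max(x.max(), y.max())
        edges = a.bin_edges(lo, hi)

        def binned_quantile(d, u):
            cdf = d.cdf(edges)
            idx = np.searchsorted(cdf, u)
            return edges[np.minimum(idx + 1, len(edges) - 1)]

        c1, c2 = 0.95, 1.0
        u = np.linspace(c1 + 1e-9, c2, 2001)
        approx = np.trapezoid(binned_quantile(a, u) - binned_quantile(b, u), u)
        exact = pddm(a, b, c1, c2)
        assert abs(approx - exact) <= a.bin_width * (c2 - c1) + 1e-9


class TestPerChannel:
    def test_antisymmetry_per_channel(self, hc_epm):
        v1, t1 = rseeg.pddm_per_channel(hc_epm, "theta", "alpha")
        v2, t2 = rseeg.pddm_per_channel(hc_epm, "alpha", "theta")
        assert v1 == pytest.approx(-v2)
        assert t1 == pytest.approx(-t2)

    def test_uniform_shift_moves_every_channel_by_delta_times_window(self):
        rng = np.random.default_rng(5)
        lin = 10 ** rng.normal(0.0, 0.3, size=(60, 3, 40))
        epm = make_epm(lin, channels=("T3", "T4", "T5"))
        base, _ = rseeg.pddm_per_channel(epm)
        delta = 0.4  # log10 shift of the theta bins only
        lin_shift = lin.copy()
        lin_shift[:, :, 2:7] *= 10 ** delta
        epm2 = make_epm(lin_shift, channels=("T3", "T4", "T5"))
        shifted, _ = rseeg.pddm_per_channel(epm2)
        assert shifted - base == pytest.approx(delta * 0.05, abs=1e-9)

    def test_bursts_confined_to_masked_channels(self, montage):
        """Sparse theta bursts on T3/T5 raise PDDM95 there and leave the
        other channels essentially unchanged."""
        from dataclasses import replace

        base_p = replace(rseeg.healthy_profile(), subject_cv=0.0)
        burst_p = replace(
            base_p, theta_burst_prob=0.08, theta_burst_gain=6.0,
            burst_channel_mask=("T3", "T5"),
        )
        deltas = []
        for seed in range(6):
            s0 = rseeg.generate_subject(base_p, montage, 60.0, seed=seed)
            s1 = rseeg.generate_subject(burst_p, montage, 60.0, seed=seed)
            v0, _ = rseeg.pddm_per_channel(rseeg.epoch_psd(s0))
            v1, _ = rseeg.pddm_per_channel(rseeg.epoch_psd(s1))
            deltas.append(v1 - v0)
        delta = np.mean(deltas, axis=0)
        masked = [montage.index(c) for c in ("T3", "T5")]
        others = [i for i in range(len(montage.labels)) if i not in masked]
        assert delta[masked].min() > 0.01
        assert np.abs(delta[others]).max() < 0.5 * delta[masked].min()
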