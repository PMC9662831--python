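import numpy as np
import pytest

import parahop as ph
from parahop.simulate import BOUND, CYTOSOLIC, TETHERED, init_state


@pytest.fixture(scope="module")
def no_plasmid_run(fig4_params):
    """20 simulated minutes without a plasmid: binding/unbinding only."""
    p = fig4_params.replace(np=0)
    return p, ph.run(p, duration=1200.0, burn_in=600.0, sampling_interval=60.0,
                     seed=21, para_bins=24)


class TestInitState:
    def test_single_plasmid_starts_mid_nucleoid(self, fig4_params):
        st = init_state(fig4_params, seed=0)
        np.testing.assert_allclose(st.ppos[0], [fig4_params.L / 2, fig4_params.W / 2])
        assert st.time == 0.0
        assert np.all(st.state == CYTOSOLIC)
        assert np.all(st.counters == 0)

    def test_two_plasmids_default_quarter_positions(self, fig4_params):
        p = fig4_params.replace(np=2)
        st = init_state(p, seed=0)
        np.testing.assert_allclose(st.ppos[:, 0], [p.L / 4, 3 * p.L / 4])

    def test_coincident_override_allowed(self, fig4_params):
        p = fig4_params.replace(np=2)
        st = init_state(p, seed=0, plasmid_positions=[(0.3, 0.4), (0.3, 0.4)])
        assert np.all(st.ppos[0] == st.ppos[1])

    def test_position_outside_nucleoid_rejected(self, fig4_params):
        with pytest.raises(ValueError, match="outside"):
            init_state(fig4_params, seed=0,
                       plasmid_positions=[(fig4_params.L + 1.0, 0.4)])


class TestStepInvariants:
    def test_dimer_number_conserved_and_counters_monotone(self, fig4_params):
        p = fig4_params.replace(nA=60)
        st = init_state(p, seed=2)
        prev = 0
        for _ in range(20):
            ph.step(st, p, n_steps=200)
            states = st.state
            assert states.shape[0] == p.nA
            assert np.all((states >= CYTOSOLIC) & (states <= TETHERED))
            total = st.counters.sum()
            assert total >= prev
            prev = total
            assert np.all(st.pos[states != CYTOSOLIC] >= 0)
            assert st.pos[states != CYTOSOLIC, 0].max(initial=0) <= p.L

    def test_tether_state_consistent_with_partner(self, fig4_params):
        p = fig4_params.replace(nA=200)
        st = init_state(p, seed=3)
        ph.step(st, p, n_steps=5000)
        teth = st.state == TETHERED
        assert np.all(st.partner[teth] >= 0)
        assert np.all(st.partner[~teth] == -1)


class TestDeterminism:
    def test_identical_seed_identical_trajectory(self, fig4_params):
        p = fig4_params.replace(nA=100)
        a = ph.run(p, 300.0, 60.0, 60.0, seed=7)
        b = ph.run(p, 300.0, 60.0, 60.0, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.tether_counts, b.tether_counts)
        assert a.counters == b.counters

    def test_different_seed_differs(self, fig4_params):
        p = fig4_params.replace(nA=100)
        a = ph.run(p, 300.0, 60.0, 60.0, seed=7)
        b = ph.run(p, 300.0, 60.0, 60.0, seed=8)
        assert not np.array_equal(a.positions, b.positions)


class TestClosedFormLimits:
    def test_no_plasmid_bound_fraction(self, no_plasmid_run):
        """Steady state: bound fraction = ka/(ka+kd) = 95%."""
        p, traj = no_plasmid_run
        bound = traj.para_kymo.sum(axis=1)
        frac = bound.mean() / p.nA
        # binomial sd per sample ~ sqrt(0.95*0.05/500) ~ 1%
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_pure_diffusion_limit_msd(self):
        """With no ParA the plasmid diffuses freely: MSD = 2*Dp*t per axis."""
        p = ph.make_params(kh=0.1, Dh=0.01, nA=0, L=20.0, W=0.95, Dp=3e-3)
        traj = ph.run(p, duration=2000.0, burn_in=0.0, sampling_interval=1.0,
                      seed=13, plasmid_positions=[(10.0, 0.475)])
        lags, m = ph.msd(traj, lags=[1.0, 2.0, 5.0])
        np.testing.assert_allclose(m, 2 * p.Dp * lags, rtol=0.15)

    def test_single_dimer_stationary_variance(self):
        """A lone bound dimer with no hopping or unbinding fluctuates about
        its home with stationary variance sigma_x^2 (long axis) and
        sigma_y^2 (short axis)."""
        p = ph.make_params(kh=0.0, Dh=0.0, kd=0.0, ka=0.0, nA=1, np=0,
                           L=2.53, W=0.95)
        st = init_state(p, seed=17)
        st.state[0] = BOUND
        st.pos[0] = st.home[0] = (p.L / 2, p.W / 2)
        xs, ys = [], []
        for _ in range(400):
            ph.step(st, p, n_steps=1000)  # 1 s ~ one relaxation time
            xs.append(st.pos[0, 0])
            ys.append(st.pos[0, 1])
        assert np.var(xs) == pytest.approx(p.sigma_x**2, rel=0.25)
        assert np.var(ys) == pytest.approx(p.sigma_y**2, rel=0.25)


class TestEngineEquivalence:
    def test_fast_and_reference_agree_statistically(self, fig4_params):
        """The event-driven engine reproduces the per-step kernel's
        stationary statistics: bound fraction, tether count and the spread
        of the plasmid about mid-nucleoid."""
        p = fig4_params.replace(nA=80)
        fast = ph.run(p, 900.0, 300.0, 10.0, seed=31, engine="fast")
        ref = ph.run(p, 900.0, 300.0, 10.0, seed=31, engine="reference")
        t_fast = fast.tether_counts[:, 0].mean()
        t_ref = ref.tether_counts[:, 0].mean()
        assert t_fast == pytest.approx(t_ref, rel=0.35)
        sd_fast = fast.series(0).std()
        sd_ref = ref.series(0).std()
        assert sd_fast == pytest.approx(sd_ref, rel=0.5)
        events_fast = sum(fast.counters.values())
        events_ref = sum(ref.counters.values())
        assert events_fast == pytest.approx(events_ref, rel=0.25)


class TestReplication:
    def test_copy_inherits_position_but_no_tethers(self, fig4_params):
        p = fig4_params.replace(nA=300)
        st = init_state(p, seed=4)
        ph.step(st, p, n_steps=3000)
        parent_tethers = int(st.tether_counts()[0])
        assert parent_tethers > 0
        ph.replicate_plasmid(st, 0)
        counts = st.tether_counts()
        assert counts[0] == parent_tethers
        assert counts[1] == 0
        np.testing.assert_array_equal(st.ppos[0], st.ppos[1])

    def test_replicating_untethered_plasmid(self, fig4_params):
        st = init_state(fig4_params, seed=4)
        ph.replicate_plasmid(st, 0)
        assert np.all(st.tether_counts() == 0)

    def test_unknown_plasmid_id(self, fig4_params):
        st = init_state(fig4_params, seed=4)
        with pytest.raises(ValueError):
            ph.replicate_plasmid(st, 5)

    def test_replicated_pair_moves_toward_quarter_positions(self):
        """After mid-nucleoid replication the two plasmids segregate toward
        +/- L/4 from mid (the two-plasmid home positions)."""
        p = ph.preset("fig5rep", nA=300)
        finals = []
        for s in range(8):
            traj = ph.run(p, duration=2100.0, burn_in=600.0,
                          sampling_interval=60.0, seed=900 + s,
                          replicate_at=0.0)
            finals.append(np.abs(traj.positions[-8:, :]).mean())
        mean_abs = np.mean(finals)
        assert abs(mean_abs - p.L / 4) < 0.25
        assert mean_abs > 0.35  # clearly separated from mid-nucleoid


class TestAtpAndKymograph:
    def test_zero_duration_rejected(self, small_sim):
        with pytest.raises(ValueError):
            ph.atp_consumption_rate(small_sim, duration=0.0)

    def test_no_plasmid_rate_matches_kd_theta(self, no_plasmid_run):
        """Steady-state turnover: rate = kd * theta = 0.01 * 475 = 4.75/s."""
        p, traj = no_plasmid_run
        assert ph.atp_consumption_rate(traj) == pytest.approx(4.75, rel=0.05)
        assert traj.counters["stimulated_hydrolysis_events"] == 0

    def test_kymograph_single_immobile_dimer(self):
        samples = [np.array([1.0])] * 5
        kym = ph.para_kymograph(samples, n_bins=10, L=2.5)
        assert kym.shape == (5, 10)
        assert np.all(kym.sum(axis=1) == 1)
        assert np.count_nonzero(kym.sum(axis=0)) == 1

    def test_kymograph_rows_sum_to_bound_count(self, no_plasmid_run):
        p, traj = no_plasmid_run
        rows = traj.para_kymo.sum(axis=1)
        assert np.all(rows > 0.9 * 475) and np.all(rows < 1.1 * 475)

    def test_empty_samples_give_zero_rows(self):
        kym = ph.para_kymograph([np.array([])], n_bins=4, L=1.0)
        assert np.all(kym == 0)

    def test_para_profile_sign_flips_with_epsilon(self):
        """Long-lived tethers (low eps) pile ParA up at the plasmid; fast
        ParB-stimulated hydrolysis (high eps) carves a depletion zone."""

        def plasmid_bin_ratio(name, seed, bins=21):
            p = ph.preset(name, nA=300)
            tr = ph.run(p, 1800.0, 600.0, 30.0, seed=seed, para_bins=bins)
            idx = np.clip(((tr.series(0) + p.L / 2) / p.L * bins).astype(int),
                          0, bins - 1)
            at, away = [], []
            for k, b in enumerate(idx):
                row = tr.para_kymo[k]
                at.append(row[b])
                far = np.r_[row[: max(b - 3, 0)], row[b + 4:]]
                if far.size:
                    away.append(far.mean())
            return np.mean(at) / np.mean(away)

        low_eps = np.mean([plasmid_bin_ratio("fig3C", s) for s in (5, 6)])
        high_eps = np.mean([plasmid_bin_ratio("fig3E", s) for s in (5, 6)])
        assert low_eps > 1.3
        assert high_eps < 0.95


class TestRunContract:
    def test_non_commensurate_sampling_rejected(self, fig4_params):
        with pytest.raises(ValueError, match="multiple"):
            ph.run(fig4_params, 100.0, 0.0, 0.0015, seed=0)

    def test_times_and_shapes(self, small_sim):
        traj = small_sim
        assert traj.times.shape[0] == traj.positions.shape[0] == 11
        assert np.all(np.diff(traj.times) == 60.0)
        assert np.all(np.abs(traj.series(0)) <= traj.L / 2)
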