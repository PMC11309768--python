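import numpy as np
import pytest
from scipy.integrate import quad

from dsrbd_dynamics.hard import (NO_EXCHANGE, AdiabaticPulse, ConstantLock,
                                 ExchangeParams, ExchangeFit, BETA,
                                 bm_propagate, build_hs_pulse,
                                 classify_exchange, delta_kex,
                                 dw_ppm_to_rad, fit_two_state,
                                 simulate_hard_rates)

R1RHO_DELAYS = np.array([0, 16, 32, 64, 96, 128]) * 1e-3
R2RHO_DELAYS = np.array([0, 16, 32, 64]) * 1e-3
PULSE_NS = (1, 2, 4, 6, 8)


@pytest.fixture(scope="module")
def pulses():
    return [build_hs_pulse(n) for n in PULSE_NS]


def _noisy_row(row, rng, sigma=0.02):
    return {"R1": row["R1"],
            "R1rho": {k: v * (1 + sigma * rng.standard_normal())
                      for k, v in row["R1rho"].items()},
            "R2rho": {k: v * (1 + sigma * rng.standard_normal())
                      for k, v in row["R2rho"].items()}}


class TestHsPulse:
    def test_edge_symmetry(self, pulses):
        for p in pulses:
            a0 = p.amplitude_at(np.array([0.0]))[0]
            a1 = p.amplitude_at(np.array([p.tp]))[0]
            assert a0 == pytest.approx(a1, rel=1e-9)

    def test_peak_amplitude_at_midpoint(self, pulses):
        for p in pulses:
            assert p.amplitude_at(np.array([p.tp / 2]))[0] \
                == pytest.approx(p.w1max, rel=1e-12)

    def test_mean_amplitude_rises_with_stretching(self, pulses):
        # independent oracle: numeric integral of sech(beta x^n)
        def mean_amp(n):
            val, _ = quad(lambda x: 1.0 / np.cosh(BETA * np.sign(x)
                                                  * abs(x) ** n), -1, 1)
            return val / 2.0

        means = [p.amplitude.mean() / p.w1max for p in pulses]
        oracle = [mean_amp(n) for n in PULSE_NS]
        np.testing.assert_allclose(means, oracle, rtol=1e-3)
        assert all(np.diff(means) > 0)

    def test_offset_sweep_spans_bandwidth(self, pulses):
        for p in pulses:
            off = p.offset_at(np.array([0.0, p.tp]))
            assert off[0] == pytest.approx(-p.bandwidth / 2, rel=1e-6)
            assert off[1] == pytest.approx(p.bandwidth / 2, rel=1e-6)

    @pytest.mark.parametrize("kwargs", [
        {"n": 0}, {"tp": -1e-3}, {"w1max": 0.0}, {"bandwidth": -1.0},
        {"npoints": 16},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n=1, tp=16e-3, w1max=1e4, bandwidth=3e4, npoints=256)
        base.update(kwargs)
        with pytest.raises(ValueError):
            AdiabaticPulse(**base)


class TestExchangeParams:
    def test_detailed_balance(self):
        p = ExchangeParams(pb=0.2, kex=1000.0, dw=100.0)
        assert p.pa + p.pb == pytest.approx(1.0)
        assert p.kab + p.kba == pytest.approx(p.kex)
        assert p.pa * p.kab == pytest.approx(p.pb * p.kba)

    def test_invalid_population(self):
        with pytest.raises(ValueError):
            ExchangeParams(pb=0.7, kex=1000.0, dw=100.0)


class TestPropagator:
    def test_norm_conserved_without_relaxation(self):
        p = ExchangeParams(pb=0.5, kex=0.0, dw=0.0, r1g=0.0, r2g=0.0)
        m0 = np.array([0.0, 0.0, 0.5, 0.0, 0.0, 0.5])
        traj = bm_propagate(p, build_hs_pulse(1), m0, 128e-3)
        norms = np.linalg.norm(traj[:, :3] + traj[:, 3:], axis=1)
        assert np.abs(norms - 1.0).max() <= 1e-8

    def test_norm_never_increases_with_relaxation(self):
        p = ExchangeParams(pb=0.1, kex=2000.0, dw=500.0, r1g=1.5, r2g=11.0)
        m0 = np.array([0.0, 0.0, 0.9, 0.0, 0.0, 0.1])
        traj = bm_propagate(p, build_hs_pulse(4), m0, 128e-3)
        norms = np.linalg.norm(traj, axis=1)
        assert np.all(np.diff(norms) <= 1e-12)

    def test_constant_lock_tilted_decay_closed_form(self):
        # pB -> 0 limit: R = R1 cos^2(theta) + R2 sin^2(theta)
        r1, r2 = 1.5, 11.0
        w1 = 2 * np.pi * 2000.0
        for offc in (2 * np.pi * 1000.0, 2 * np.pi * 3000.0):
            lock = ConstantLock(w1=w1, offset_value=offc, tp=4e-3)
            p = ExchangeParams(pb=1e-6, kex=0.0, dw=0.0, r1g=r1, r2g=r2)
            e = np.array([w1, 0.0, -offc])
            e /= np.linalg.norm(e)
            m0 = np.concatenate([e * (1 - 1e-6), e * 1e-6])
            traj = bm_propagate(p, lock, m0, 64e-3)
            t = np.arange(len(traj)) * 4e-3
            proj = [np.dot(m[:3] + m[3:], e) for m in traj]
            rate = -np.polyfit(t, np.log(proj), 1)[0]
            theta = np.arctan2(w1, abs(offc))
            closed = r1 * np.cos(theta) ** 2 + r2 * np.sin(theta) ** 2
            assert rate == pytest.approx(closed, rel=0.01)

    def test_laguerre_two_state_oracle_on_constant_locks(self):
        # asymptotic (Miloushev-Palmer) R1rho vs direct propagation,
        # within 5% over pB <= 0.2, kex in [500, 5e4]
        r1, r2 = 1.5, 11.0
        w1 = 2 * np.pi * 1500.0
        om_a = 800.0
        dw = 764.0

        def laguerre(pb, kex):
            pa = 1 - pb
            om_b = om_a + dw
            om_bar = pa * om_a + pb * om_b
            wea2 = w1**2 + om_a**2
            web2 = w1**2 + om_b**2
            we2 = w1**2 + om_bar**2
            s2 = w1**2 / we2
            num = s2 * pa * pb * dw**2 * kex
            den = wea2 * web2 / we2 + kex**2 - s2 * pa * pb * dw**2 * (
                1 + 2 * kex**2 * (pa * wea2 + pb * web2)
                / (wea2 * web2 + we2 * kex**2))
            return r1 * (1 - s2) + r2 * s2 + num / den

        for pb in (0.05, 0.2):
            for kex in (500.0, 5000.0, 5e4):
                p = ExchangeParams(pb=pb, kex=kex, dw=dw, r1g=r1, r2g=r2)
                lock = ConstantLock(w1=w1, offset_value=-om_a, tp=8e-3)
                om_bar = (1 - pb) * om_a + pb * (om_a + dw)
                e = np.array([w1, 0.0, om_bar])
                e /= np.linalg.norm(e)
                m0 = np.concatenate([e * (1 - pb), e * pb])
                traj = bm_propagate(p, lock, m0, 64e-3)
                t = np.arange(len(traj)) * 8e-3
                proj = np.abs([np.dot(m[:3] + m[3:], e) for m in traj])
                rate = -np.polyfit(t, np.log(proj), 1)[0]
                assert rate == pytest.approx(laguerre(pb, kex), rel=0.05)

    def test_step_doubling_converges_at_default_npoints(self):
        p = ExchangeParams(pb=0.1, kex=3000.0, dw=500.0, r1g=1.5, r2g=11.0)
        m0 = np.array([0.0, 0.0, 0.9, 0.0, 0.0, 0.1])
        # passes the doubling test at the default discretization
        bm_propagate(p, build_hs_pulse(4), m0, 64e-3,
                     convergence_check=True, convergence_tol=1e-6)

    def test_coarse_discretization_raises_with_advice(self):
        p = ExchangeParams(pb=0.1, kex=3000.0, dw=500.0, r1g=1.5, r2g=11.0)
        m0 = np.array([0.0, 0.0, 0.9, 0.0, 0.0, 0.1])
        with pytest.raises(ValueError, match="npoints"):
            bm_propagate(p, build_hs_pulse(8, npoints=64), m0, 64e-3,
                         convergence_check=True, convergence_tol=1e-12)

    def test_duration_must_be_pulse_multiple(self):
        p = ExchangeParams(pb=0.1, kex=1000.0, dw=100.0)
        with pytest.raises(ValueError, match="multiple"):
            bm_propagate(p, build_hs_pulse(1), np.zeros(6), 17e-3)


class TestSimulateHardRates:
    def test_monotone_dispersion_signature_with_exchange(self, pulses,
                                                         ctx600):
        p = ExchangeParams(pb=0.1, kex=3000.0,
                           dw=dw_ppm_to_rad(2.0, ctx600),
                           r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(p, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        r1rho = [row["R1rho"][f"HS{n}"] for n in PULSE_NS]
        r2rho = [row["R2rho"][f"HS{n}"] for n in PULSE_NS]
        assert all(np.diff(r1rho) > 0)      # R1rho rises HS1 -> HS8
        assert all(np.diff(r2rho) < 0)      # R2rho falls HS1 -> HS8

    def test_invisible_exchange_when_dw_is_zero(self, pulses):
        # dw = 0: exchange cannot affect the rates regardless of kex
        base = ExchangeParams(pb=0.01, kex=0.0, dw=0.0, r1g=1.5, r2g=11.0)
        hidden = ExchangeParams(pb=0.2, kex=5000.0, dw=0.0, r1g=1.5,
                                r2g=11.0)
        row0 = simulate_hard_rates(base, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        row1 = simulate_hard_rates(hidden, pulses, R1RHO_DELAYS,
                                   R2RHO_DELAYS)
        for block in ("R1rho", "R2rho"):
            for hs in row0[block]:
                assert row1[block][hs] == pytest.approx(row0[block][hs],
                                                        rel=1e-6)

    def test_exchange_free_baseline_is_monotone_not_flat(self, pulses):
        # geometric effect only: <sin^2 theta> grows with the stretching
        # factor, so R1rho rises and R2rho falls even without exchange
        p = ExchangeParams(pb=0.01, kex=0.0, dw=0.0, r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(p, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        r1rho = [row["R1rho"][f"HS{n}"] for n in PULSE_NS]
        assert all(np.diff(r1rho) > 0)
        assert row["R1rho"]["HS8"] - row["R1rho"]["HS1"] > 1.0

    def test_delay_not_multiple_of_tp_rejected(self, pulses):
        p = ExchangeParams(pb=0.1, kex=1000.0, dw=100.0)
        with pytest.raises(ValueError, match="multiple"):
            simulate_hard_rates(p, pulses, [0.0, 0.017], R2RHO_DELAYS)


class TestTwoStateFit:
    def test_clean_round_trip_kex_and_exchange_amplitude(self, pulses,
                                                         ctx600):
        truth = ExchangeParams(pb=0.15, kex=8000.0,
                               dw=dw_ppm_to_rad(2.0, ctx600),
                               r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(truth, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        fit = fit_two_state(row, pulses, ctx600, sigma=0.02,
                            grid_shape=(8, 6, 5))
        assert fit.detected
        assert fit.params.kex == pytest.approx(8000.0, rel=0.05)
        # pB and dw individually sit on the fast-exchange ridge; their
        # combination phi_ex = pB (1-pB) dw^2 is what the data determine
        phi_truth = 0.15 * 0.85 * truth.dw**2
        phi_fit = fit.params.pb * (1 - fit.params.pb) * fit.params.dw**2
        assert phi_fit == pytest.approx(phi_truth, rel=0.10)

    def test_clean_round_trip_with_fixed_dw(self, pulses, ctx600):
        truth = ExchangeParams(pb=0.15, kex=8000.0,
                               dw=dw_ppm_to_rad(2.0, ctx600),
                               r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(truth, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        # match the fit discretization to the generator's so the round
        # trip probes the estimator, not the step-size truncation
        fit = fit_two_state(row, pulses, ctx600, sigma=0.02,
                            grid_shape=(8, 6, 1), fix_dw_ppm=2.0,
                            fit_npoints=1024, grid_npoints=96)
        assert fit.detected
        assert fit.params.kex == pytest.approx(8000.0, rel=0.05)
        assert fit.params.pb == pytest.approx(0.15, abs=0.02)
        assert fit.params.r2g == pytest.approx(11.0, rel=0.05)

    def test_noisy_recovery_study_with_fixed_dw(self, pulses, ctx600):
        # kex within x1.5 and pB within 0.05 hold for the replicate
        # medians; individual draws can land on an equally-good
        # alternative basin (fast-exchange identifiability limit)
        truth = ExchangeParams(pb=0.15, kex=8000.0,
                               dw=dw_ppm_to_rad(2.0, ctx600),
                               r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(truth, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        kexs, pbs = [], []
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            fit = fit_two_state(_noisy_row(row, rng), pulses, ctx600,
                                sigma=0.02, grid_shape=(8, 6, 1),
                                fix_dw_ppm=2.0)
            assert fit.detected
            kexs.append(fit.params.kex)
            pbs.append(fit.params.pb)
        assert 1 / 1.5 <= np.median(kexs) / 8000.0 <= 1.5
        assert abs(np.median(pbs) - 0.15) <= 0.05
        within = np.sum((np.array(kexs) >= 8000 / 1.5)
                        & (np.array(kexs) <= 8000 * 1.5))
        assert within >= 4

    def test_exchange_free_data_returns_sentinel(self, pulses, ctx600):
        p = ExchangeParams(pb=0.01, kex=0.0, dw=0.0, r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(p, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        rng = np.random.default_rng(42)
        fit = fit_two_state(_noisy_row(row, rng), pulses, ctx600,
                            sigma=0.02, grid_shape=(6, 5, 4))
        assert not fit.detected
        assert fit.sentinel == NO_EXCHANGE

    def test_seeded_determinism(self, pulses, ctx600):
        truth = ExchangeParams(pb=0.15, kex=8000.0,
                               dw=dw_ppm_to_rad(2.0, ctx600),
                               r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(truth, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        rng = np.random.default_rng(17)
        noisy = _noisy_row(row, rng)
        fits = [fit_two_state(noisy, pulses, ctx600, sigma=0.02,
                              grid_shape=(6, 5, 1), fix_dw_ppm=2.0,
                              mc=8, seed=99) for _ in range(2)]
        assert fits[0].params.kex == fits[1].params.kex
        assert fits[0].params.pb == fits[1].params.pb
        assert fits[0].kex_sigma == fits[1].kex_sigma

    def test_too_few_pulses(self, ctx600):
        with pytest.raises(ValueError):
            fit_two_state({}, [build_hs_pulse(1), build_hs_pulse(8)],
                          ctx600)


class TestBinRecovery:
    def _study(self, ctx, pulses, kex, dw_ppm, n_rep, seed0):
        truth = ExchangeParams(pb=0.15, kex=kex,
                               dw=dw_ppm_to_rad(dw_ppm, ctx),
                               r1g=1.5, r2g=11.0)
        row = simulate_hard_rates(truth, pulses, R1RHO_DELAYS, R2RHO_DELAYS)
        out = []
        for s in range(n_rep):
            rng = np.random.default_rng(seed0 + s)
            fit = fit_two_state(_noisy_row(row, rng), pulses, ctx,
                                sigma=0.02, grid_shape=(8, 6, 1),
                                fix_dw_ppm=dw_ppm)
            out.append(classify_exchange(fit)["kex_class"])
        return out

    def test_slow_bin_recovered(self, pulses, ctx600):
        classes = self._study(ctx600, pulses, 2000.0, 2.0, 4, 60)
        assert classes.count("slow") >= 3

    def test_fast_bin_recovered_majority(self, pulses, ctx600):
        classes = self._study(ctx600, pulses, 15000.0, 2.0, 8, 60)
        assert classes.count("fast") >= 4

    def test_very_fast_regime_classification_stable(self, pulses, ctx600):
        # kex >> omega_1: exchange averages to a near-constant R2 addition,
        # indistinguishable from the exchange-free baseline at this noise;
        # the classification is stable across seeds (consistently 'none')
        classes = self._study(ctx600, pulses, 80000.0, 3.0, 4, 40)
        assert len(set(classes)) == 1


class TestClassification:
    @pytest.mark.parametrize("kex, expected", [
        (4999.0, "slow"),
        (5001.0, "fast"),
        (49999.0, "fast"),
        (60000.0, "very_fast"),
    ])
    def test_kex_bins(self, kex, expected):
        p = ExchangeParams(pb=0.15, kex=kex, dw=100.0)
        assert classify_exchange(p)["kex_class"] == expected

    @pytest.mark.parametrize("pb, expected", [
        (0.05, "<10%"), (0.15, "10-20%"), (0.3, "20-40%"), (0.45, ">40%"),
    ])
    def test_pb_bins(self, pb, expected):
        p = ExchangeParams(pb=pb, kex=1000.0, dw=100.0)
        assert classify_exchange(p)["pb_class"] == expected

    def test_sentinel_maps_to_none(self):
        assert classify_exchange(NO_EXCHANGE)["kex_class"] == "none"
        assert classify_exchange(
            ExchangeFit(detected=False))["kex_class"] == "none"


class TestDeltaKex:
    def _fit(self, kex):
        return ExchangeFit(detected=True,
                           params=ExchangeParams(pb=0.1, kex=kex, dw=100.0))

    def test_induced_and_quenched_flags(self):
        table = delta_kex({1: self._fit(3000.0), 2: self._fit(20000.0)},
                          {1: self._fit(20000.0), 2: self._fit(3000.0)})
        assert table.loc[0, "delta_kex"] == pytest.approx(17000.0)
        assert table.loc[0, "flag"] == "induced"
        assert table.loc[1, "delta_kex"] == pytest.approx(-17000.0)
        assert table.loc[1, "flag"] == "quenched"

    def test_boundary_unflagged(self):
        table = delta_kex({1: self._fit(0.0)}, {1: self._fit(9999.0)})
        assert table.loc[0, "flag"] == ""

    def test_missing_state_marker(self):
        table = delta_kex({1: self._fit(3000.0)}, {2: self._fit(4000.0)})
        assert set(table["flag"]) == {"missing-state"}
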