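"""EFI simulation and transverse-resistance calibration."""

import numpy as np
import pytest

import cochleanet as cn
from cochleanet.calibration import EFIMatrix, rmse_percent
from cochleanet.metrics import SIVProfile


@pytest.fixture(scope="module")
def efi(model, layout):
    return cn.simulate_efi(model, layout)


class TestSimulateEFI:
    def test_offdiagonal_reciprocity(self, efi):
        v = efi.values
        for i in range(16):
            for j in range(i + 1, 16):
                assert v[i, j] == pytest.approx(v[j, i], rel=1e-9)

    def test_row_maximum_at_stimulating_electrode(self, efi):
        # inverted-V rows: each stimulating contact sees the largest
        # trans-impedance at itself
        assert np.all(np.argmax(efi.values, axis=1) == np.arange(16))

    def test_amplitude_invariance(self, model, layout, efi):
        other = cn.simulate_efi(model, layout, amplitude_uA=320.0)
        np.testing.assert_allclose(other.values, efi.values, rtol=1e-12)

    def test_diagonal_flagged_invalid(self, efi):
        assert not efi.diagonal_valid.any()

    def test_entries_positive(self, efi):
        assert np.all(efi.values > 0)


class TestRMSE:
    def test_identical_profiles_zero(self, efi):
        assert rmse_percent(efi, efi) == 0.0

    def test_uniform_offset_closed_form(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(5, 1, size=14)) + 1
        base[7] = base.max() + 1  # unambiguous peak
        a = SIVProfile(wire_positions=np.arange(14.0), values=base)
        # target = normalized sim + 0.05 everywhere, then rescaled so its
        # own normalization reproduces that shift exactly at the peak
        shifted = base / base.max() + 0.05
        b = SIVProfile(wire_positions=np.arange(14.0), values=shifted / shifted.max())
        expected = 100 * np.sqrt(
            np.mean((base / base.max() - shifted / shifted.max()) ** 2)
        )
        assert rmse_percent(a, b) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        x = np.arange(14.0)
        va = rng.uniform(0.5, 10, 14)
        vb = rng.uniform(0.5, 10, 14)
        a = SIVProfile(wire_positions=x, values=va)
        b = SIVProfile(wire_positions=x, values=vb)
        na, nb = va / np.abs(va).max(), vb / np.abs(vb).max()
        brute = 100 * np.sqrt(sum((na[i] - nb[i]) ** 2 for i in range(14)) / 14)
        assert rmse_percent(a, b) == pytest.approx(brute, rel=1e-12)

    def test_grid_mismatch_rejected(self, efi):
        small = EFIMatrix(values=efi.values[:8, :8])
        with pytest.raises(ValueError):
            rmse_percent(efi, small)


class TestCalibrate:
    def test_self_consistency_recovers_reference_resistor(self, model, layout, efi):
        result = cn.calibrate(efi, model, layout, mode="shared")
        assert result.shared_resistance == pytest.approx(47_000.0, rel=1e-3)
        assert result.rmse_percent < 1e-4
        assert result.converged

    def test_noisy_recovery_within_5_percent(self, model, layout):
        noise = cn.NoiseSpec(multiplicative_cv=0.03, replicates=3, seed=42)
        target, truth = cn.make_invivo_like_efi(model, layout, noise)
        result = cn.calibrate(target, model, layout, mode="shared")
        truth_gm = np.exp(np.mean(np.log(truth.transverse_resistances)))
        assert result.shared_resistance == pytest.approx(truth_gm, rel=0.05)

    def test_objective_history_monotone(self, model, layout, efi):
        result = cn.calibrate(efi, model, layout, mode="shared")
        hist = np.asarray(result.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_no_resistor_model_worse_than_calibrated(self, model, layout):
        # against an inverted-V target the insulating-wall model is always a
        # strictly worse fit than the calibrated one
        target, _ = cn.make_invivo_like_efi(model, layout, cn.NoiseSpec(seed=5))
        calibrated = cn.calibrate(target, model, layout, mode="shared")
        bare = cn.simulate_efi(cn.default_model(transverse_r_ohm=np.inf),
                               cn.default_layout())
        assert rmse_percent(bare, target) > calibrated.rmse_percent

    def test_pernode_fit_tracks_resistance_gradient(self, layout):
        # coarse template keeps the multivariate fit small; the target is
        # built with a basal-to-apical gradient the fit must reproduce in
        # direction, not necessarily in magnitude (smoothness-penalty bias)
        template = cn.default_model(step=2.0)
        n = template.geometry.n_nodes
        gradient = np.geomspace(20_000.0, 120_000.0, n)
        truth = template.with_transverse(gradient)
        target = cn.simulate_efi(truth, layout)
        result = cn.calibrate(
            target, template, layout, mode="per-node", smoothness=0.01
        )
        fitted = result.transverse_resistances
        slope = np.polyfit(np.arange(n), np.log(fitted), 1)[0]
        assert slope > 0
        assert result.rmse_percent < cn.calibrate(
            target, template, layout, mode="shared"
        ).rmse_percent + 1e-9

    def test_nonfinite_target_rejected(self, model, layout, efi):
        bad = EFIMatrix(values=np.where(np.eye(16, dtype=bool), np.nan, efi.values))
        with pytest.raises(ValueError, match="finite"):
            cn.calibrate(bad, model, layout)
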