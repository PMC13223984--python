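import numpy as np
import pandas as pd
import pytest

from sweepvep.design import Condition, make_sweep_design
from sweepvep.preprocess import epoch
from sweepvep.simulate import NoiseModel, default_response_model, simulate_sweep_recording
from sweepvep.spectral import build_spectral_table
from sweepvep.thresholds import (
    SelectionConfig,
    SelectionError,
    combine_directions,
    phase_check,
    reg_threshold,
    select_electrode,
    sig_threshold,
    significance_mask,
)

from conftest import SMALL_MONTAGE

CFG = SelectionConfig()


def _mask(pattern: str) -> np.ndarray:
    """'T'/'S' significant, 'N'/'F' not; padded with the last symbol to 18."""
    sym = pattern.replace(" ", "")
    sym = sym + sym[-1] * (18 - len(sym))
    return np.array([c in "TS" for c in sym])


class TestSignificanceMask:
    def test_strict_inequality_and_nan(self):
        z = np.array([2.33, 2.331, 10.0, np.nan, -5.0])
        assert significance_mask(z, 2.33).tolist() == [False, True, True, False, False]

    def test_all_significant(self):
        assert significance_mask(np.full(18, 10.0), 2.33).all()

    def test_worked_sequence(self):
        mask = significance_mask([1, 1, 3, 1, 3, 3, 3, 3], 2.33)
        assert mask.tolist() == [False, False, True, False, True, True, True, True]


class TestSigRule:
    def test_decreasing_hand_trace(self):
        """Fading sweep: sig run then silence; candidates at 3/4 and 4/4."""
        design = make_sweep_design("contrast", "decreasing")
        res = sig_threshold(_mask("TTTTTNNNN"), design, CFG)
        # 0-based: candidates at 5 (4/4 sig precede) and 6 (3/4); last wins
        assert res.valid and res.step_index == 6
        assert res.threshold_value == pytest.approx(design.step_values[6])
        assert res.diagnostics["candidates"] == [5, 6]

    def test_increasing_hand_trace(self):
        """Exact mirror: first non-sig step with >=3/4 of the following sig."""
        design = make_sweep_design("contrast", "increasing")
        res = sig_threshold(_mask("NNNNNSSSS"), design, CFG)
        # step 4 has 4/4 significant followers, step 3 has 3/4; first wins
        assert res.valid and res.step_index == 3
        assert res.threshold_value == pytest.approx(design.step_values[3])
        assert res.diagnostics["candidates"] == [3, 4]

    def test_increasing_is_exact_time_mirror_of_decreasing(self):
        """Reversing the mask and the sweep leaves the picked value unchanged."""
        rng = np.random.default_rng(8)
        inc_design = make_sweep_design("contrast", "increasing")
        dec_design = make_sweep_design("contrast", "decreasing")
        for _ in range(50):
            mask = rng.random(18) < 0.5
            inc = sig_threshold(mask, inc_design, CFG)
            dec = sig_threshold(mask[::-1], dec_design, CFG)
            assert inc.valid == dec.valid
            if inc.valid:
                assert inc.threshold_value == pytest.approx(dec.threshold_value)

    def test_sf_increasing_uses_fading_rule(self):
        """Increasing cpd is decreasing intensity, so the 'last non-sig' rule applies."""
        design = make_sweep_design("spatial_frequency", "increasing")
        res = sig_threshold(_mask("TTTTTNNNN"), design, CFG)
        assert res.valid and res.step_index == 6

    def test_all_false_mask_invalid(self):
        design = make_sweep_design("contrast", "increasing")
        res = sig_threshold(np.zeros(18, bool), design, CFG)
        assert not res.valid and res.threshold_value is None

    def test_length_mismatch_rejected(self):
        design = make_sweep_design("contrast", "increasing")
        with pytest.raises(ValueError):
            sig_threshold(np.zeros(17, bool), design, CFG)

    def test_swapped_reading_available(self):
        design = make_sweep_design("contrast", "increasing")
        cfg = SelectionConfig(increasing_rule="swapped")
        res = sig_threshold(_mask("NNNNNSSSS"), design, cfg)
        # last significant step with >=3/4 non-significant preceding
        assert res.valid and res.step_index == 6
        cfg2 = SelectionConfig(increasing_rule="first_significant")
        res2 = sig_threshold(_mask("NNNNNSSSS"), design, cfg2)
        assert res2.valid and res2.step_index == 5

    def test_raising_criterion_never_lowers_increasing_threshold(self):
        """A harder z criterion can only push the threshold to easier steps."""
        rng = np.random.default_rng(3)
        design = make_sweep_design("contrast", "increasing")
        for _ in range(50):
            z = np.sort(rng.normal(2, 3, 18))  # roughly growing z profile
            lo = sig_threshold(significance_mask(z, 2.0), design, CFG)
            hi = sig_threshold(significance_mask(z, 4.0), design, CFG)
            if lo.valid and hi.valid:
                assert hi.step_index >= lo.step_index

    def test_direction_symmetry_noiseless(self):
        """Increasing vs reversed-decreasing thresholds agree within one step."""
        picks = {}
        for direction in ("increasing", "decreasing"):
            design = make_sweep_design("contrast", direction)
            rec = simulate_sweep_recording(
                design,
                default_response_model("contrast"),
                NoiseModel(white_sd=1e-3, pink_scale=0),  # z defined, noise negligible
                montage=SMALL_MONTAGE,
                srate=250.0,
                seed=0,
                n_trials=2,
            )
            eps = epoch(rec, {("contrast", direction): design})
            table = build_spectral_table(eps)
            rows = table[table.electrode == "Oz"].sort_values("step_index")
            res = sig_threshold(significance_mask(rows.z, CFG.z_criterion), design, CFG)
            assert res.valid
            picks[direction] = res.threshold_value
        ratio = picks["increasing"] / picks["decreasing"]
        step_ratio = 300.0 ** (1 / 17)
        assert 1 / (step_ratio * 1.01) <= ratio <= step_ratio * 1.01


class TestElectrodeSelection:
    def _table(self, z_by_electrode, design):
        rows = []
        for lab, zvals in z_by_electrode.items():
            for step, z in enumerate(zvals):
                rows.append(
                    dict(
                        condition=design.condition.value,
                        direction=design.direction.value,
                        electrode=lab,
                        step_index=step,
                        z=z,
                    )
                )
        return pd.DataFrame(rows)

    def test_highest_easy_half_mean_wins(self):
        design = make_sweep_design("contrast", "increasing")
        z_hi = np.concatenate([np.zeros(9), np.full(9, 5.0)])
        z_lo = np.concatenate([np.full(9, 4.0), np.zeros(9)])  # big z only on hard half
        table = self._table({"Pz": z_lo, "Oz": z_hi}, design)
        assert select_electrode(table, design, CFG) == "Oz"

    def test_tie_breaks_to_first_label(self):
        design = make_sweep_design("contrast", "increasing")
        z = np.full(18, 3.0)
        table = self._table({"POz": z, "Oz": z}, design)
        assert select_electrode(table, design, CFG) == "POz"

    def test_single_electrode_table(self):
        design = make_sweep_design("contrast", "increasing")
        table = self._table({"Iz": np.ones(18)}, design)
        assert select_electrode(table, design, CFG) == "Iz"

    def test_all_undefined_is_selection_error(self):
        design = make_sweep_design("contrast", "increasing")
        table = self._table({"Oz": np.full(18, np.nan)}, design)
        with pytest.raises(SelectionError):
            select_electrode(table, design, CFG)

    def test_oz_selected_under_moderate_noise(self):
        """Occipital-peaked topography puts the best electrode at Oz."""
        design = make_sweep_design("contrast", "increasing")
        hits = 0
        for seed in range(10):
            rec = simulate_sweep_recording(
                design,
                default_response_model("contrast"),
                NoiseModel(),
                montage=SMALL_MONTAGE,
                srate=250.0,
                seed=100 + seed,
                n_trials=6,
            )
            eps = epoch(rec, {("contrast", "increasing"): design})
            table = build_spectral_table(eps)
            hits += select_electrode(table, design, CFG) == "Oz"
        assert hits >= 9


def _reg_rows(design, amps, noise_mean=0.05, snr=None, phases=None):
    n = design.n_steps
    return pd.DataFrame(
        dict(
            step_index=np.arange(n),
            amp=amps,
            noise_mean=np.full(n, noise_mean),
            snr=np.asarray(amps) / noise_mean if snr is None else snr,
            phase=np.zeros(n) if phases is None else phases,
        )
    )


class TestRegMethod:
    def test_closed_form_log_contrast_recovery(self):
        """Amplitude linear in log10 contrast, zero at log10(c) = -0.5."""
        design = make_sweep_design("contrast", "increasing")
        x = np.log10(design.step_values)
        amps = np.maximum(0.0, 2.0 * (x - (-0.5)))
        res = reg_threshold(_reg_rows(design, amps), design, CFG)
        assert res.valid
        assert res.threshold_value == pytest.approx(10 ** (-0.5), rel=1e-6)

    def test_linear_cpd_recovery_for_spatial_frequency(self):
        design = make_sweep_design("spatial_frequency", "increasing")
        cpd = np.asarray(design.step_values)
        amps = np.maximum(0.0, 0.2 * (32.0 - cpd))
        res = reg_threshold(_reg_rows(design, amps), design, CFG)
        assert res.valid
        assert res.threshold_value == pytest.approx(32.0, rel=1e-6)

    def test_no_onset_when_snr_low(self):
        design = make_sweep_design("contrast", "increasing")
        amps = np.linspace(0.01, 0.1, 18)
        rows = _reg_rows(design, amps, noise_mean=1.0)
        res = reg_threshold(rows, design, CFG)
        assert not res.valid and res.diagnostics["reason"] == "no-onset"

    def test_wrong_slope_sign_invalid(self):
        design = make_sweep_design("contrast", "increasing")
        # onset at the easiest step, but amplitude *grows* toward harder steps
        amps_easy_to_hard = np.concatenate([[5.0, 4.9], np.linspace(5.5, 12.0, 16)])
        amps = amps_easy_to_hard[::-1]  # step_index order (hard first)
        res = reg_threshold(_reg_rows(design, amps), design, CFG)
        assert not res.valid
        assert res.diagnostics["reason"] in ("slope-wrong-sign", "crossing-on-wrong-side")

    def test_phase_failure_invalidates(self):
        design = make_sweep_design("contrast", "increasing")
        x = np.log10(design.step_values)
        amps = np.maximum(0.0, 2.0 * (x + 0.5))
        phases = np.where(np.arange(18) % 2 == 0, 0.0, np.pi)  # alternating
        res = reg_threshold(_reg_rows(design, amps, phases=phases), design, CFG)
        assert not res.valid and res.diagnostics["reason"] == "phase-check-failed"


class TestPhaseCheck:
    def test_identical_phases_pass_everywhere(self):
        for cond in Condition:
            assert phase_check(np.full(6, 1.2), cond)

    def test_gradual_lead_passes_contrast_fails_sf(self):
        phases = np.arange(6) * (np.pi / 8)
        assert phase_check(phases, "contrast")
        assert not phase_check(phases, "spatial_frequency")
        assert not phase_check(phases, "orientation")

    def test_gradual_lag_passes_sf(self):
        phases = -np.arange(6) * (np.pi / 8)
        assert phase_check(phases, "spatial_frequency")
        assert not phase_check(phases, "contrast")

    def test_alternating_pi_fails(self):
        phases = np.where(np.arange(6) % 2 == 0, 0.0, np.pi)
        for cond in Condition:
            assert not phase_check(phases, cond)

    def test_wrapped_constant_phase_passes(self):
        """Phases hugging ±π are constant once unwrapped."""
        phases = np.array([np.pi - 0.05, -np.pi + 0.05, np.pi - 0.02])
        assert phase_check(phases, "orientation")


class TestCombineDirections:
    def _res(self, cond, direction, value, valid=True):
        from sweepvep.thresholds import ThresholdResult
        from sweepvep.design import Direction

        return ThresholdResult(
            "sig", Condition(cond), Direction(direction), "Oz", 0, value, valid
        )

    def test_contrast_geometric_mean(self):
        combo = combine_directions(
            self._res("contrast", "increasing", 1.0),
            self._res("contrast", "decreasing", 4.0),
        )
        assert combo.value == pytest.approx(2.0)
        assert combo.n_valid == 2 and not combo.flagged

    def test_sf_arithmetic_mean(self):
        combo = combine_directions(
            self._res("spatial_frequency", "increasing", 20.0),
            self._res("spatial_frequency", "decreasing", 30.0),
        )
        assert combo.value == pytest.approx(25.0)

    def test_equal_thresholds_pass_through(self):
        combo = combine_directions(
            self._res("orientation", "increasing", 0.7),
            self._res("orientation", "decreasing", 0.7),
        )
        assert combo.value == pytest.approx(0.7)

    def test_single_valid_flagged(self):
        combo = combine_directions(
            self._res("contrast", "increasing", 1.5),
            self._res("contrast", "decreasing", None, valid=False),
        )
        assert combo.value == 1.5 and combo.flagged

    def test_both_invalid_is_error(self):
        with pytest.raises(ValueError):
            combine_directions(
                self._res("contrast", "increasing", None, valid=False),
                self._res("contrast", "decreasing", None, valid=False),
            )
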