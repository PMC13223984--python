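"""Synthetic sweep-ssVEP recordings with known ground truth.

The generator is statistical, not biophysical: each presented step carries
a 20 Hz sinusoid (plus a weaker 40 Hz harmonic) whose amplitude follows a
hinge function of stimulus easiness above a known true threshold, weighted
across the scalp by a Gaussian topography peaked at Oz, and embedded in
1/f + white noise.  Optional biphasic frontal transients stand in for eye
blinks so that epoch rejection has something to reject.

Amplitude scale: ssVEP responses at occipital electrodes typically span a
few microvolts; the default response model grows to ~5 µV at the easiest
steps, and the default noise model (1.5 µV white + 3 µV pink) puts the
per-bin noise floor of a six-trial average near 0.1 µV, giving the z≫2.33
easy steps and near-threshold ambiguity the threshold rules must resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Condition, StimulusSweep, easiness
from .montage import DEFAULT_MONTAGE, MontageError, gaussian_topography, montage_labels
from .recording import Annotation, EEGRecording

__all__ = [
    "ResponseModel",
    "NoiseModel",
    "amplitude_response",
    "simulate_sweep_recording",
    "default_response_model",
]

FRONTAL_BLINK_WEIGHTS = {"Fp1": 1.0, "Fpz": 1.0, "Fp2": 1.0, "AF7": 0.6, "AF8": 0.6, "AFz": 0.5}


@dataclass(frozen=True)
class ResponseModel:
    """Hinge amplitude-vs-easiness response with saturation.

    ``true_threshold`` is in the sweep's native units; ``gain`` is µV per
    unit of easiness (log10 units for contrast/orientation, cpd for
    spatial frequency) above threshold, capped at ``amplitude_cap``.
    """

    condition: Condition
    true_threshold: float
    gain: float
    amplitude_cap: float = 5.0
    fundamental: float = 20.0
    harmonic_ratio: float = 0.3
    topography_sigma_m: float = 0.02
    phase0: float = 0.0
    phase_drift: float = 0.0  # radians per core step


@dataclass(frozen=True)
class NoiseModel:
    """Additive channel noise: white + 1/f, optional blink transients."""

    white_sd: float = 1.5  # µV
    pink_exponent: float = 1.0
    pink_scale: float = 3.0  # µV (time-domain SD of the 1/f component)
    blink_rate: float = 0.0  # events per minute
    blink_amplitude: float = 300.0  # µV at the frontal pole
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.white_sd, self.pink_scale, self.blink_rate) < 0:
            raise ValueError("noise scales must be non-negative")


def default_response_model(condition: Condition | str, **overrides) -> ResponseModel:
    """Study-plausible response models per condition.

    Thresholds sit a third of the way up the sweep, as in typical adult
    observers; gains are set so the response saturates near the cap at the
    easiest steps.
    """
    condition = Condition(condition)
    defaults = {
        Condition.CONTRAST: dict(true_threshold=0.55, gain=3.0),  # % Michelson
        Condition.SPATIAL_FREQUENCY: dict(true_threshold=30.0, gain=0.25),  # cpd
        Condition.ORIENTATION: dict(true_threshold=0.3, gain=4.0),  # degrees
    }[condition]
    defaults.update(overrides)
    return ResponseModel(condition=condition, **defaults)


def amplitude_response(intensity, model: ResponseModel):
    """Ground-truth 20 Hz amplitude (µV) at the topography peak.

    Zero at and below the true threshold on the easiness scale, then
    linear in easiness with slope ``gain`` until ``amplitude_cap``.
    """
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise ValueError("stimulus intensity must be non-negative")
    e = easiness(model.condition, np.where(arr > 0, arr, np.nan))
    e_thr = easiness(model.condition, np.asarray(model.true_threshold, dtype=float))
    amp = np.clip((e - e_thr) * model.gain, 0.0, model.amplitude_cap)
    amp = np.where(np.isnan(amp), 0.0, amp)
    return float(amp) if np.isscalar(intensity) else amp


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-SD 1/f**exponent noise via spectral shaping."""
    n_freq = n // 2 + 1
    spectrum = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    freqs = np.arange(n_freq, dtype=float)
    freqs[0] = 1.0
    spectrum *= freqs ** (-exponent / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_kernel(srate: float) -> np.ndarray:
    """Biphasic ~300 ms transient, unit peak."""
    t = np.arange(int(0.3 * srate)) / srate
    k = np.sin(2 * np.pi * t / 0.3) * np.exp(-((t - 0.1) / 0.1) ** 2)
    peak = np.abs(k).max()
    return k / peak if peak > 0 else k


def simulate_sweep_recording(
    design: StimulusSweep,
    response: ResponseModel,
    noise: NoiseModel,
    montage=None,
    srate: float = 250.0,
    seed: int | None = None,
    n_trials: int = 1,
    gap_s: float = 2.0,
    first_trial: int = 0,
) -> EEGRecording:
    """Simulate ``n_trials`` sweep trials as one continuous recording.

    Trials are separated by ``gap_s`` of stimulus-free noise.  Step onsets
    land on whole seconds so the 20 Hz carrier is phase-continuous across
    epochs.  Fully reproducible from ``seed`` (which overrides any seed on
    the noise model).
    """
    if srate < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if montage is None:
        labels = montage_labels(DEFAULT_MONTAGE)
    else:
        labels = tuple(montage)
        known = set(montage_labels(DEFAULT_MONTAGE))
        unknown = [lab for lab in labels if lab not in known]
        if unknown:
            raise MontageError(f"unknown electrode labels: {unknown}")
    if "Oz" not in labels:
        raise MontageError("montage must include Oz")

    seed = noise.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    weights = gaussian_topography(labels, sigma_m=response.topography_sigma_m)

    trial_values = design.trial_values
    n_step_samp = int(round(design.step_duration * srate))
    trial_len = len(trial_values) * n_step_samp
    gap_len = int(round(gap_s * srate))
    total = n_trials * trial_len + max(0, n_trials - 1) * gap_len
    samples = np.zeros((len(labels), total))
    annotations: list[Annotation] = []

    core = design.core_slice_in_trial()
    amps = amplitude_response(np.asarray(trial_values), response)
    t_global = np.arange(total) / srate

    for trial_i in range(n_trials):
        t0 = trial_i * (trial_len + gap_len)
        for pos, value in enumerate(trial_values):
            s0 = t0 + pos * n_step_samp
            t = t_global[s0 : s0 + n_step_samp]
            core_index = int(np.clip(pos - core.start, 0, design.n_steps - 1))
            phi = response.phase0 + response.phase_drift * core_index
            carrier = amps[pos] * (
                np.sin(2 * np.pi * response.fundamental * t + phi)
                + response.harmonic_ratio
                * np.sin(2 * np.pi * 2 * response.fundamental * t + phi)
            )
            samples[:, s0 : s0 + n_step_samp] += np.outer(weights, carrier)
            if core.start <= pos < core.stop:
                step = pos - core.start
            else:
                step = -1 if pos < core.start else design.n_steps
            annotations.append(
                Annotation(
                    onset=s0 / srate,
                    duration=design.step_duration,
                    trial=first_trial + trial_i,
                    step=step,
                    condition=design.condition,
                    direction=design.direction,
                )
            )

    if noise.white_sd > 0:
        samples += noise.white_sd * rng.standard_normal(samples.shape)
    if noise.pink_scale > 0:
        for ch in range(len(labels)):
            samples[ch] += noise.pink_scale * _pink_noise(rng, total, noise.pink_exponent)
    if noise.blink_rate > 0:
        kernel = _blink_kernel(srate)
        n_blinks = rng.poisson(noise.blink_rate * (total / srate) / 60.0)
        onsets = rng.integers(0, max(1, total - len(kernel)), size=n_blinks)
        for onset in onsets:
            for lab, w in FRONTAL_BLINK_WEIGHTS.items():
                if lab in labels:
                    ch = labels.index(lab)
                    samples[ch, onset : onset + len(kernel)] += (
                        noise.blink_amplitude * w * kernel
                    )

    return EEGRecording(labels=labels, srate=float(srate), samples=samples, annotations=annotations)
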