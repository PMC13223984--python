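"""Single-bin spectral estimation with a neighbouring-bin noise floor.

Epochs belonging to the same sweep step are averaged in the time domain
(which cancels non-phase-locked noise), then a 1-Hz-resolution DFT is
taken of each step's averaged 1-s epoch.  The 20 Hz amplitude is adjusted
for the noise floor by subtracting the mean amplitude of the 12
neighbouring 1-Hz bins — six on each side, skipping the immediately
adjacent bins (19 and 21 Hz) — and z-scored by the standard deviation of
those same 12 bins.  SNR is the raw amplitude over the noise-floor mean.

Amplitude normalization is 2|X_k|/N, so a sinusoid a·sin(2πft+φ) measured
at its own bin reads amplitude a and phase φ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition, Direction
from .preprocess import EpochSet

__all__ = [
    "SpectrumConfig",
    "trial_average",
    "dft_bin",
    "amplitude_spectrum",
    "noise_floor",
    "build_spectral_table",
    "pooled_periodogram",
    "topography_array",
]

TABLE_COLUMNS = [
    "condition",
    "direction",
    "electrode",
    "step_index",
    "amp",
    "noise_mean",
    "noise_sd",
    "adj_amp",
    "z",
    "snr",
    "phase",
    "n_epochs_averaged",
    "flag",
]


@dataclass(frozen=True)
class SpectrumConfig:
    analysis_freq: float = 20.0
    resolution: float = 1.0
    n_neighbors_per_side: int = 6
    skip_adjacent: int = 1

    def neighbor_bins(self, n_bins: int) -> np.ndarray:
        """Neighbour bin indices on the resolution grid; errors if out of range."""
        k = int(round(self.analysis_freq / self.resolution))
        lo = np.arange(k - self.skip_adjacent - self.n_neighbors_per_side, k - self.skip_adjacent)
        hi = np.arange(k + self.skip_adjacent + 1, k + self.skip_adjacent + 1 + self.n_neighbors_per_side)
        bins = np.concatenate([lo, hi])
        if bins.min() < 0 or bins.max() >= n_bins:
            raise ValueError(
                f"neighbour bins {bins.min()}..{bins.max()} fall outside the "
                f"spectrum (0..{n_bins - 1})"
            )
        return bins


def trial_average(epochs: EpochSet, condition, direction):
    """Time-domain average of retained epochs per step.

    Returns ``(averages, missing)`` where ``averages`` maps step index to
    ``(mean_waveform [n_channels, n_samples], n_epochs)`` and ``missing``
    lists steps that had annotations but no retained epoch (their spectral
    rows propagate as undefined).
    """
    condition = Condition(condition)
    direction = Direction(direction)
    groups: dict[int, list[np.ndarray]] = {}
    for (trial, step), arr in epochs.epochs.items():
        if epochs.meta[(trial, step)] == (condition, direction):
            groups.setdefault(step, []).append(arr)
    dropped = {
        step
        for (trial, step), _ in epochs.rejected.items()
        if epochs.meta.get((trial, step), (None, None)) == (condition, direction)
    }
    averages = {
        step: (np.mean(arrs, axis=0), len(arrs)) for step, arrs in groups.items()
    }
    missing = sorted(dropped - set(averages))
    return averages, missing


def dft_bin(waveform, srate: float, freq: float, resolution: float = 1.0):
    """Amplitude (µV) and phase (rad) of one DFT bin.

    The waveform must span exactly ``1/resolution`` seconds.  Phase uses
    the sine convention: a·sin(2πft+φ) → (a, φ), with φ in (−π, π].
    """
    x = np.asarray(waveform, dtype=float)
    n = x.shape[-1]
    expected = srate / resolution
    if abs(n - expected) > 1e-6:
        raise ValueError(
            f"waveform has {n} samples; {expected:g} required for "
            f"{resolution:g} Hz resolution at {srate:g} Hz"
        )
    k = freq / resolution
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"{freq} Hz is not on the {resolution} Hz bin grid")
    k = int(round(k))
    if not (0 <= k <= n // 2):
        raise ValueError(f"{freq} Hz exceeds Nyquist")
    basis = np.exp(-2j * np.pi * k * np.arange(n) / n)
    coeff = (x * basis).sum(axis=-1)
    amp = 2.0 * np.abs(coeff) / n
    phase = np.angle(coeff) + np.pi / 2.0  # sine convention
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    phase = np.where(phase == -np.pi, np.pi, phase)  # report (−π, π]
    if np.ndim(amp) == 0:
        return float(amp), float(phase)
    return amp, phase


def amplitude_spectrum(waveform, srate: float, resolution: float = 1.0) -> np.ndarray:
    """Amplitudes of all bins 0..Nyquist under the 2|X|/N normalization."""
    x = np.asarray(waveform, dtype=float)
    n = x.shape[-1]
    expected = srate / resolution
    if abs(n - expected) > 1e-6:
        raise ValueError("waveform length inconsistent with requested resolution")
    coeffs = np.fft.rfft(x, axis=-1)
    amps = 2.0 * np.abs(coeffs) / n
    amps[..., 0] /= 2.0  # DC has no conjugate twin
    return amps


def noise_floor(spectrum: np.ndarray, cfg: SpectrumConfig = SpectrumConfig()):
    """Mean and sample SD (ddof=1) of the 12 neighbouring bin amplitudes."""
    spectrum = np.asarray(spectrum, dtype=float)
    bins = cfg.neighbor_bins(spectrum.shape[-1])
    neigh = spectrum[..., bins]
    return float(np.mean(neigh)), float(np.std(neigh, ddof=1))


def build_spectral_table(
    epochs: EpochSet,
    cfg: SpectrumConfig = SpectrumConfig(),
    pairs=None,
) -> pd.DataFrame:
    """Per (condition, direction, electrode, step) spectral quantities.

    ``pairs`` restricts to specific (condition, direction) combinations;
    by default every combination present in the epochs is analysed.
    Degenerate rows (noise SD or mean of zero) keep their amplitudes but
    carry NaN z / snr and a ``flag``.
    """
    if pairs is None:
        pairs = sorted({cd for cd in epochs.meta.values()})
    rows = []
    for condition, direction in pairs:
        averages, missing = trial_average(epochs, condition, direction)
        for step in sorted(set(averages) | set(missing)):
            if step not in averages:
                for lab in epochs.labels:
                    rows.append(
                        dict(
                            condition=condition.value,
                            direction=direction.value,
                            electrode=lab,
                            step_index=step,
                            amp=np.nan,
                            noise_mean=np.nan,
                            noise_sd=np.nan,
                            adj_amp=np.nan,
                            z=np.nan,
                            snr=np.nan,
                            phase=np.nan,
                            n_epochs_averaged=0,
                            flag="no-retained-epochs",
                        )
                    )
                continue
            mean_wave, n_avg = averages[step]
            spectra = amplitude_spectrum(mean_wave, epochs.srate, cfg.resolution)
            amps, phases = dft_bin(mean_wave, epochs.srate, cfg.analysis_freq, cfg.resolution)
            amps = np.atleast_1d(amps)
            phases = np.atleast_1d(phases)
            for ch, lab in enumerate(epochs.labels):
                nmean, nsd = noise_floor(spectra[ch], cfg)
                amp = float(amps[ch])
                # numerically-zero floors (noise-free input) are degenerate
                tiny = 1e-9 * max(1.0, amp)
                flag = ""
                amp_adj = amp - nmean
                z = amp_adj / nsd if nsd > tiny else np.nan
                snr = amp / nmean if nmean > tiny else np.nan
                if nsd <= tiny:
                    flag = "degenerate-noise-sd"
                elif nmean <= tiny:
                    flag = "degenerate-noise-mean"
                rows.append(
                    dict(
                        condition=Condition(condition).value,
                        direction=Direction(direction).value,
                        electrode=lab,
                        step_index=step,
                        amp=amp,
                        noise_mean=nmean,
                        noise_sd=nsd,
                        adj_amp=amp_adj,
                        z=z,
                        snr=snr,
                        phase=float(phases[ch]),
                        n_epochs_averaged=n_avg,
                        flag=flag,
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def pooled_periodogram(
    epochs: EpochSet,
    electrode: str = "Oz",
    reference: str | None = "single:Fpz",
    resolution: float = 1.0,
) -> pd.DataFrame:
    """Mean power spectrum at one electrode, pooling all retained epochs.

    The diagnostic mirrors the exploratory pooled periodogram: every
    retained epoch (all conditions and directions) is re-referenced,
    transformed, and the per-bin power (amplitude²) averaged.  Returns a
    DataFrame with ``freq`` (Hz) and ``power`` (µV²).
    """
    from .preprocess import rereference

    if electrode not in epochs.labels:
        raise KeyError(f"no electrode {electrode!r}")
    if reference not in (None, "native"):
        epochs = rereference(epochs, reference)
    ch = epochs.labels.index(electrode)
    powers = []
    for arr in epochs.epochs.values():
        amps = amplitude_spectrum(arr[ch], epochs.srate, resolution)
        powers.append(amps**2)
    if not powers:
        return pd.DataFrame({"freq": [], "power": []})
    power = np.mean(powers, axis=0)
    freqs = np.arange(len(power)) * resolution
    return pd.DataFrame({"freq": freqs, "power": power})


def topography_array(
    table: pd.DataFrame,
    condition,
    step: int,
    direction=None,
    labels=None,
) -> np.ndarray:
    """Noise-adjusted amplitude per electrode at one step, in label order.

    With ``direction=None`` the two sweep directions are averaged.  For
    plotting/export only.
    """
    condition = Condition(condition).value
    sel = table[(table.condition == condition) & (table.step_index == step)]
    if direction is not None:
        sel = sel[sel.direction == Direction(direction).value]
    if labels is None:
        labels = list(dict.fromkeys(sel.electrode))
    out = np.empty(len(labels))
    grouped = sel.groupby("electrode")["adj_amp"].mean()
    for i, lab in enumerate(labels):
        if lab not in grouped.index:
            raise KeyError(f"no spectral row for electrode {lab!r} at step {step}")
        out[i] = grouped[lab]
    return out
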