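"""Preprocessing chain: downsample, detrend + low-pass, epoch, reject, re-reference.

The chain mirrors standard sweep-VEP practice: decimate to 250 Hz with
anti-alias filtering, remove per-channel linear trends, zero-phase
low-pass at 45 Hz (which also suppresses 50/60 Hz mains, so no notch is
needed), cut 1-s epochs aligned to step onsets, drop the preview and
postview repeats, reject epochs by a peak-to-peak amplitude criterion,
and re-reference — by default to the mean of five occipital electrodes
(O1, O2, Oz, POz, Iz), a Laplacian-style scheme that emphasises local
occipital sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .design import Condition, Direction
from .montage import OCCIPITAL_SET, electrode_positions, nearest_neighbors
from .recording import EEGRecording

__all__ = [
    "EpochSet",
    "downsample",
    "detrend_lowpass",
    "epoch",
    "reject_epochs",
    "rereference",
    "interpolate_channels",
    "AlignmentError",
]

EpochKey = tuple[int, int]  # (trial, core step index)


class AlignmentError(ValueError):
    """Annotations do not match the sweep designs."""


@dataclass
class EpochSet:
    """Retained and rejected 1-s step epochs.

    ``epochs`` maps (trial, step) to an [n_channels, n_samples] array;
    ``meta`` carries each epoch's (condition, direction); ``rejected``
    maps dropped keys to a reason string.
    """

    labels: tuple[str, ...]
    srate: float
    epochs: dict[EpochKey, np.ndarray]
    meta: dict[EpochKey, tuple[Condition, Direction]]
    rejected: dict[EpochKey, str] = field(default_factory=dict)
    reference: str = "native"

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.epochs.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent epoch shapes: {shapes}")
        overlap = self.epochs.keys() & self.rejected.keys()
        if overlap:
            raise ValueError(f"keys both retained and rejected: {sorted(overlap)}")

    @property
    def n_retained(self) -> int:
        return len(self.epochs)

    def copy_with(self, **kw) -> "EpochSet":
        return EpochSet(
            labels=kw.get("labels", self.labels),
            srate=kw.get("srate", self.srate),
            epochs=kw.get("epochs", dict(self.epochs)),
            meta=kw.get("meta", dict(self.meta)),
            rejected=kw.get("rejected", dict(self.rejected)),
            reference=kw.get("reference", self.reference),
        )


def downsample(rec: EEGRecording, target_srate: float) -> EEGRecording:
    """Polyphase anti-aliased resampling; annotation onsets stay in seconds."""
    if target_srate <= 0 or target_srate > rec.srate:
        raise ValueError(
            f"target rate must be in (0, {rec.srate}], got {target_srate}"
        )
    if target_srate == rec.srate:
        return rec.copy_with()
    ratio = Fraction(target_srate / rec.srate).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=1)
    return rec.copy_with(samples=out, srate=float(target_srate))


def _lowpass_taps(cutoff: float, srate: float) -> np.ndarray:
    # Hamming-window FIR; transition bandwidth 25% of the cutoff.
    trans = 0.25 * cutoff
    numtaps = int(math.ceil(3.3 * srate / trans))
    numtaps += 1 - numtaps % 2  # force odd
    return signal.firwin(numtaps, cutoff, window="hamming", fs=srate)


def detrend_lowpass(rec: EEGRecording, cutoff: float = 45.0) -> EEGRecording:
    """Per-channel linear detrend, then zero-phase FIR low-pass."""
    nyq = rec.srate / 2
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    x = signal.detrend(rec.samples, axis=1, type="linear")
    taps = _lowpass_taps(cutoff, rec.srate)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    x = signal.filtfilt(taps, [1.0], x, axis=1, padlen=padlen)
    return rec.copy_with(samples=x)


def epoch(rec: EEGRecording, designs) -> EpochSet:
    """Cut one epoch per (trial, core step); preview/postview are dropped.

    ``designs`` maps (condition, direction) to the :class:`StimulusSweep`
    presented; annotations referencing unknown designs, or step indices
    outside the design, raise :class:`AlignmentError`.
    """
    designs = {
        (Condition(c), Direction(d)): dsg for (c, d), dsg in dict(designs).items()
    }
    epochs: dict[EpochKey, np.ndarray] = {}
    meta: dict[EpochKey, tuple[Condition, Direction]] = {}
    for ann in rec.annotations:
        key_cd = (ann.condition, ann.direction)
        if key_cd not in designs:
            raise AlignmentError(f"no design for {key_cd}")
        design = designs[key_cd]
        if not (-1 <= ann.step <= design.n_steps):
            raise AlignmentError(f"step {ann.step} outside design ({design.n_steps} steps)")
        if ann.step in (-1, design.n_steps):
            continue  # preview / postview
        s0 = int(round(ann.onset * rec.srate))
        n = int(round(design.step_duration * rec.srate))
        if s0 + n > rec.n_samples:
            raise AlignmentError(f"epoch at {ann.onset}s exceeds the recording")
        key = (ann.trial, ann.step)
        if key in epochs:
            raise AlignmentError(f"duplicate epoch key {key}")
        epochs[key] = rec.samples[:, s0 : s0 + n].copy()
        meta[key] = key_cd
    return EpochSet(labels=rec.labels, srate=rec.srate, epochs=epochs, meta=meta)


def reject_epochs(epochs: EpochSet, ptp_limit_uv: float = 150.0) -> EpochSet:
    """Move epochs whose peak-to-peak exceeds the limit on any channel."""
    if ptp_limit_uv <= 0:
        raise ValueError("peak-to-peak limit must be positive")
    retained = dict(epochs.epochs)
    rejected = dict(epochs.rejected)
    for key, arr in list(retained.items()):
        ptp = np.ptp(arr, axis=1).max()
        if ptp > ptp_limit_uv:
            rejected[key] = f"ptp {ptp:.1f} µV > {ptp_limit_uv:g} µV"
            del retained[key]
    return epochs.copy_with(epochs=retained, rejected=rejected)


def _reference_signal(arr: np.ndarray, labels: tuple[str, ...], scheme: str) -> np.ndarray:
    if scheme == "common_average":
        return arr.mean(axis=0)
    if scheme == "occipital_mean":
        ref_labels = OCCIPITAL_SET
    elif scheme.startswith("single:"):
        ref_labels = (scheme.split(":", 1)[1],)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    missing = [lab for lab in ref_labels if lab not in labels]
    if missing:
        raise KeyError(f"reference electrodes missing from montage: {missing}")
    idx = [labels.index(lab) for lab in ref_labels]
    return arr[idx].mean(axis=0)


def rereference(epochs: EpochSet, scheme: str = "occipital_mean") -> EpochSet:
    """Subtract a reference signal from every channel.

    Schemes: ``native`` (no-op), ``occipital_mean`` (O1, O2, Oz, POz, Iz),
    ``common_average``, or ``single:<label>``.
    """
    if scheme == "native":
        return epochs.copy_with(reference="native")
    out = {
        key: arr - _reference_signal(arr, epochs.labels, scheme)
        for key, arr in epochs.epochs.items()
    }
    return epochs.copy_with(epochs=out, reference=scheme)


def interpolate_channels(epochs: EpochSet, bad_labels, k: int = 4) -> EpochSet:
    """Replace bad channels by inverse-distance weighted means of neighbours.

    Neighbours are the ``k`` nearest good electrodes on the idealized head.
    """
    bad = list(bad_labels)
    if not bad:
        return epochs.copy_with()
    missing = [lab for lab in bad if lab not in epochs.labels]
    if missing:
        raise KeyError(f"bad labels not in montage: {missing}")
    if len(bad) >= len(epochs.labels) / 2:
        raise ValueError("refusing to interpolate half or more of the montage")
    good = [lab for lab in epochs.labels if lab not in bad]
    plans = {}
    for lab in bad:
        neigh = nearest_neighbors(lab, good, k=k)
        pos = electrode_positions([lab])[0]
        npos = electrode_positions(neigh)
        w = 1.0 / np.maximum(np.linalg.norm(npos - pos, axis=1), 1e-6)
        plans[epochs.labels.index(lab)] = (
            [epochs.labels.index(nl) for nl in neigh],
            w / w.sum(),
        )
    out = {}
    for key, arr in epochs.epochs.items():
        arr = arr.copy()
        for ch, (idx, w) in plans.items():
            arr[ch] = w @ arr[idx]
        out[key] = arr
    return epochs.copy_with(epochs=out)
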