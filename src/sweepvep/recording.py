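"""Continuous recordings and on-disk formats.

The native on-disk format is a documented columnar-text triplet:

``<stem>.samples.tsv``
    one row per sample, one column per electrode, values in µV;
``<stem>.annotations.csv``
    step onsets: onset_s, duration_s, trial, step, condition, direction
    (step is -1 for the preview repeat, 0..n-1 for core steps, n for the
    postview repeat);
``<stem>.meta.json``
    sampling rate and electrode labels.

EDF and BDF files are read through mne.  Writing EDF/BDF is not offered:
the text format is lossless at the stated precision and diff-friendly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Condition, Direction

__all__ = ["Annotation", "EEGRecording", "write_recording", "load_recording", "ParseError"]

PREVIEW_STEP = -1


class ParseError(ValueError):
    """Malformed recording file."""


@dataclass(frozen=True)
class Annotation:
    """One presented sweep step."""

    onset: float  # seconds from recording start
    duration: float  # seconds
    trial: int
    step: int  # -1 preview, 0..n-1 core, n postview
    condition: Condition
    direction: Direction


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in µV."""

    labels: tuple[str, ...]
    srate: float
    samples: np.ndarray  # [n_channels, n_samples]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ParseError("duplicate electrode labels")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.labels):
            raise ParseError(
                f"samples shape {self.samples.shape} does not match "
                f"{len(self.labels)} labels"
            )
        t_end = self.samples.shape[1] / self.srate
        for ann in self.annotations:
            if ann.onset < -1e-9 or ann.onset + ann.duration > t_end + 1e-6:
                raise ParseError(
                    f"annotation at {ann.onset:.3f}s (trial {ann.trial}, "
                    f"step {ann.step}) lies outside the recording"
                )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def copy_with(self, **kw) -> "EEGRecording":
        out = EEGRecording(
            labels=kw.get("labels", self.labels),
            srate=kw.get("srate", self.srate),
            samples=kw.get("samples", self.samples.copy()),
            annotations=kw.get("annotations", list(self.annotations)),
        )
        return out


def _stem(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".samples.tsv", ".annotations.csv", ".meta.json"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def write_recording(rec: EEGRecording, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write the columnar-text triplet; returns the stem path."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(rec.labels)
    np.savetxt(
        stem.with_name(stem.name + ".samples.tsv"),
        rec.samples.T,
        fmt=fmt,
        delimiter="\t",
        header=header,
        comments="",
    )
    ann = pd.DataFrame(
        [
            {
                "onset_s": a.onset,
                "duration_s": a.duration,
                "trial": a.trial,
                "step": a.step,
                "condition": a.condition.value,
                "direction": a.direction.value,
            }
            for a in rec.annotations
        ],
        columns=["onset_s", "duration_s", "trial", "step", "condition", "direction"],
    )
    ann.to_csv(stem.with_name(stem.name + ".annotations.csv"), index=False)
    meta = {"srate": rec.srate, "labels": list(rec.labels)}
    stem.with_name(stem.name + ".meta.json").write_text(json.dumps(meta, indent=1))
    return stem


def _load_columnar(stem: Path) -> EEGRecording:
    samples_path = stem.with_name(stem.name + ".samples.tsv")
    meta_path = stem.with_name(stem.name + ".meta.json")
    ann_path = stem.with_name(stem.name + ".annotations.csv")
    if not samples_path.exists():
        raise FileNotFoundError(samples_path)
    try:
        meta = json.loads(meta_path.read_text())
        srate = float(meta["srate"])
    except (FileNotFoundError, KeyError, json.JSONDecodeError) as exc:
        raise ParseError(f"bad or missing meta sidecar {meta_path}: {exc}") from exc
    table = pd.read_csv(samples_path, sep="\t")
    labels = tuple(table.columns)
    if len(set(labels)) != len(labels):
        raise ParseError(f"{samples_path}: duplicate electrode labels in header")
    if list(meta.get("labels", labels)) != list(labels):
        raise ParseError(f"{samples_path}: labels disagree with meta sidecar")
    annotations: list[Annotation] = []
    if ann_path.exists():
        ann = pd.read_csv(ann_path)
        for row in ann.itertuples(index=False):
            annotations.append(
                Annotation(
                    onset=float(row.onset_s),
                    duration=float(row.duration_s),
                    trial=int(row.trial),
                    step=int(row.step),
                    condition=Condition(row.condition),
                    direction=Direction(row.direction),
                )
            )
    return EEGRecording(
        labels=labels,
        srate=srate,
        samples=table.to_numpy(dtype=float).T,
        annotations=annotations,
    )


def _load_edf(path: Path) -> EEGRecording:
    import mne

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate electrode labels")
    samples = raw.get_data() * 1e6  # volts -> µV
    annotations: list[Annotation] = []
    for ann in raw.annotations:
        # description convention: "trial=<i>;step=<s>;condition=<c>;direction=<d>"
        fields = dict(
            part.split("=", 1) for part in str(ann["description"]).split(";") if "=" in part
        )
        if {"trial", "step", "condition", "direction"} <= fields.keys():
            annotations.append(
                Annotation(
                    onset=float(ann["onset"]),
                    duration=float(ann["duration"]),
                    trial=int(fields["trial"]),
                    step=int(fields["step"]),
                    condition=Condition(fields["condition"]),
                    direction=Direction(fields["direction"]),
                )
            )
    return EEGRecording(
        labels=labels, srate=float(raw.info["sfreq"]), samples=samples, annotations=annotations
    )


def load_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Load a recording from columnar text or EDF/BDF.

    ``format`` may be ``"columnar-text"``, ``"EDF"`` or ``"BDF"``;
    inferred from the file extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lower().lstrip(".") if path.suffix.lower() in (".edf", ".bdf") else "columnar-text"
    format = format.lower().replace("_", "-")
    if format in ("edf", "bdf"):
        return _load_edf(path)
    if format == "columnar-text":
        return _load_columnar(_stem(path))
    raise ValueError(f"unknown format {format!r}")
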