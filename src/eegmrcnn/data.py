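"""Core data containers: recordings, band definitions, epoch sets.

Conventions used throughout the package: time in seconds, signal amplitude in
microvolts, arrays are channel-major (``channels x time`` for continuous data,
``epochs x channels x samples`` for segmented data), epochs indexed from 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "BandSpec",
    "EpochSet",
    "BANDS",
    "parse_band",
    "DEFAULT_FRONTAL_CHANNELS",
]

#: Default identities of the six frontal electrodes (10-20 system).
DEFAULT_FRONTAL_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "F7", "F8")


@dataclass(frozen=True)
class BandSpec:
    """A bandpass definition: passband edges in Hz and Butterworth design order.

    ``order`` is the order of the analog lowpass prototype; the bandpass
    transformation doubles the polynomial order, as is conventional.
    """

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got "
                f"low_hz={self.low_hz}, high_hz={self.high_hz}"
            )
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")

    def validate_rate(self, rate_hz: float) -> None:
        """Raise if the band cannot be applied to data sampled at ``rate_hz``."""
        if self.high_hz >= rate_hz / 2:
            raise ValueError(
                f"band {self.low_hz}-{self.high_hz} Hz exceeds the Nyquist "
                f"frequency {rate_hz / 2} Hz at rate {rate_hz} Hz"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low_hz:g}-{self.high_hz:g}Hz"


#: The canonical rhythm bands plus the three wide ranges used for classification.
BANDS: dict[str, BandSpec] = {
    "theta": BandSpec(4.0, 8.0),
    "alpha1": BandSpec(8.0, 10.0),
    "alpha2": BandSpec(10.0, 13.0),
    "beta": BandSpec(13.0, 30.0),
    "4-30": BandSpec(4.0, 30.0),
    "8-30": BandSpec(8.0, 30.0),
    "10-30": BandSpec(10.0, 30.0),
}


def parse_band(token: str | BandSpec) -> BandSpec:
    """Resolve a band token (``"beta"``, ``"8-30"``, or free-form ``"LOW-HIGH"``)."""
    if isinstance(token, BandSpec):
        return token
    key = token.strip().lower()
    if key in BANDS:
        return BANDS[key]
    if "-" in key:
        lo, _, hi = key.partition("-")
        try:
            return BandSpec(float(lo), float(hi))
        except ValueError as exc:
            raise ValueError(f"unparseable band token {token!r}") from exc
    raise ValueError(
        f"unknown band token {token!r}; expected one of {sorted(BANDS)} or 'LOW-HIGH'"
    )


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Attributes
    ----------
    samples : ndarray, shape (channels, time), microvolts
    rate_hz : sampling rate in samples per second
    channel_labels : ordered channel names, one per row of ``samples``
    subject_id : subject identifier
    group_label : ``"DD"``, ``"HC"`` or ``"unknown"``
    meta : free-form provenance (pipeline manifest entries accumulate here)
    """

    samples: np.ndarray
    rate_hz: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group_label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (channels x time), got shape {self.samples.shape}"
            )
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def with_samples(self, samples: np.ndarray, **changes) -> "Recording":
        """Copy of this recording with new sample data (and optional field updates)."""
        rec = replace(self, samples=samples, **changes)
        rec.meta = dict(self.meta, **changes.get("meta", {}))
        return rec

    # -- array-on-disk format: <stem>.npy + <stem>.json sidecar ---------------

    def save(self, path: str | Path) -> Path:
        """Write as ``.npy`` array plus JSON sidecar; returns the sidecar path."""
        path = Path(path)
        stem = path.with_suffix("")
        np.save(stem.with_suffix(".npy"), self.samples)
        sidecar = {
            "subject_id": self.subject_id,
            "group_label": self.group_label,
            "rate_hz": self.rate_hz,
            "channel_labels": list(self.channel_labels),
            "meta": _jsonable(self.meta),
        }
        sidecar_path = stem.with_suffix(".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1))
        return sidecar_path

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        stem = Path(path).with_suffix("")
        meta = json.loads(stem.with_suffix(".json").read_text())
        samples = np.load(stem.with_suffix(".npy"))
        return cls(
            samples=samples,
            rate_hz=meta["rate_hz"],
            channel_labels=tuple(meta["channel_labels"]),
            subject_id=meta["subject_id"],
            group_label=meta["group_label"],
            meta=meta.get("meta", {}),
        )


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping EEG segments with per-epoch labels.

    ``data`` has shape (epochs, channels, samples) with
    ``samples == epoch_len_s * rate_hz`` exactly. ``band`` is a
    :class:`BandSpec` once bandpass filtering has been applied, else the
    string ``"broadband"``.
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    epoch_len_s: float
    rate_hz: float
    band: BandSpec | str = "broadband"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (epochs x channels x samples), got {self.data.shape}"
            )
        n = self.data.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError(
                f"{n} epochs but {len(self.labels)} labels / "
                f"{len(self.subject_ids)} subject ids"
            )
        expected = int(round(self.epoch_len_s * self.rate_hz))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} samples inconsistent with "
                f"{self.epoch_len_s} s at {self.rate_hz} Hz (expected {expected})"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            epoch_len_s=self.epoch_len_s,
            rate_hz=self.rate_hz,
            band=self.band,
            meta=dict(self.meta),
        )

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of epoch sets")
        first = parts[0]
        for p in parts[1:]:
            if p.rate_hz != first.rate_hz or p.epoch_len_s != first.epoch_len_s:
                raise ValueError("epoch sets differ in rate or epoch length")
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            epoch_len_s=first.epoch_len_s,
            rate_hz=first.rate_hz,
            band=first.band,
            meta=dict(first.meta),
        )

    def save(self, path: str | Path) -> Path:
        stem = Path(path).with_suffix("")
        np.save(stem.with_suffix(".npy"), self.data)
        band = (
            {"low_hz": self.band.low_hz, "high_hz": self.band.high_hz, "order": self.band.order}
            if isinstance(self.band, BandSpec)
            else self.band
        )
        sidecar = {
            "labels": self.labels.tolist(),
            "subject_ids": self.subject_ids.tolist(),
            "epoch_len_s": self.epoch_len_s,
            "rate_hz": self.rate_hz,
            "band": band,
            "meta": _jsonable(self.meta),
        }
        sidecar_path = stem.with_suffix(".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1))
        return sidecar_path

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        stem = Path(path).with_suffix("")
        meta = json.loads(stem.with_suffix(".json").read_text())
        band = meta["band"]
        if isinstance(band, dict):
            band = BandSpec(band["low_hz"], band["high_hz"], band["order"])
        return cls(
            data=np.load(stem.with_suffix(".npy")),
            labels=np.array(meta["labels"]),
            subject_ids=np.array(meta["subject_ids"]),
            epoch_len_s=meta["epoch_len_s"],
            rate_hz=meta["rate_hz"],
            band=band,
            meta=meta.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, BandSpec):
        return {"low_hz": obj.low_hz, "high_hz": obj.high_hz, "order": obj.order}
    return obj
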