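"""EDF (European Data Format) interchange for recordings.

Reading goes through :func:`mne.io.read_raw_edf`. Writing is done by a small
EDF writer implemented here (fixed 256-byte headers plus 16-bit
little-endian data records), sufficient for uniform-rate multichannel EEG;
signals are scaled to the full 16-bit digital range per channel, so the
round-trip error is bounded by one quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import Recording

__all__ = ["read_edf", "write_edf"]

_HDR = 256


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path, record_s: float = 1.0) -> Path:
    """Write a recording as EDF; returns the path written.

    The subject id and group label are stored in the patient-identification
    field. The signal is truncated to a whole number of data records
    (``record_s`` seconds each; samples per record must come out integer).
    """
    path = Path(path)
    spr = record_s * rec.rate_hz
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(
            f"record duration {record_s}s gives non-integer samples per record "
            f"at {rec.rate_hz} Hz"
        )
    spr = int(round(spr))
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    n_ch = rec.n_channels
    data = rec.samples[:, : n_records * spr]

    phys_min, phys_max = [], []
    digitized = np.empty((n_ch, n_records * spr), dtype="<i2")
    for c in range(n_ch):
        amp = max(float(np.abs(data[c]).max()), 1e-6)
        # digitize against the limits as they round-trip through the 8-char
        # header fields, otherwise header truncation skews the scale; bump
        # until both encoded limits cover the data so clipping cannot occur
        pmin = pmax = None
        for _ in range(200):
            pmin, pmax = float(_num(-amp)), float(_num(amp))
            if pmin <= -np.abs(data[c]).max() and pmax >= np.abs(data[c]).max():
                break
            amp *= 1.005
        phys_min.append(pmin)
        phys_max.append(pmax)
        scaled = (data[c] - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        digitized[c] = np.clip(np.round(scaled), -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"{rec.subject_id} {rec.group_label}", 80))
        fh.write(_pad("eegmrcnn synthetic-or-processed EEG", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(_HDR * (1 + n_ch)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad(_num(record_s), 8))
        fh.write(_pad(str(n_ch), 4))
        # per-signal header blocks, each field contiguous across signals
        for lbl in rec.channel_labels:
            fh.write(_pad(lbl, 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(_num(v), 8))
        for v in phys_max:
            fh.write(_pad(_num(v), 8))
        for _ in range(n_ch):
            fh.write(_pad("-32768", 8))
        for _ in range(n_ch):
            fh.write(_pad("32767", 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(np.ascontiguousarray(digitized[:, sl]).tobytes())
    return path


def _num(v: float) -> str:
    """Numeric field text that fits the 8-character EDF slot."""
    s = f"{v:.8g}"
    if len(s) > 8:
        s = f"{v:.3g}"
    if len(s) > 8:
        s = s[:8]
    return s


def _parse_header(path: Path) -> dict:
    raw = path.read_bytes()
    if len(raw) < _HDR:
        raise ValueError(f"{path}: truncated EDF (no full header)")
    n_ch = int(raw[252:256].decode("ascii").strip())
    hdr_bytes = int(raw[184:192].decode("ascii").strip())
    if len(raw) < hdr_bytes:
        raise ValueError(f"{path}: truncated EDF (signal headers incomplete)")
    n_records = int(raw[236:244].decode("ascii").strip())
    record_s = float(raw[244:252].decode("ascii").strip())
    sig = raw[_HDR:hdr_bytes]

    def fields(offset: int, width: int) -> list[str]:
        base = offset * n_ch
        return [
            sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]

    labels = fields(0, 16)
    spr = [int(s) for s in fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
    record_bytes = 2 * sum(spr)
    patient = raw[8:88].decode("ascii").strip()
    expected = hdr_bytes + n_records * record_bytes
    if n_records >= 0 and len(raw) < expected:
        raise ValueError(
            f"{path}: truncated EDF ({len(raw)} bytes, expected {expected})"
        )
    return {
        "n_channels": n_ch,
        "labels": labels,
        "samples_per_record": spr,
        "record_s": record_s,
        "n_records": n_records,
        "patient": patient,
    }


def read_edf(path: str | Path, channels: list[str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    ``channels`` optionally restricts and orders the channels. Files whose
    requested channels have differing sampling rates are rejected, as are
    truncated files.
    """
    import mne

    path = Path(path)
    hdr = _parse_header(path)
    wanted_idx = range(hdr["n_channels"])
    if channels is not None:
        lookup = {l.lower(): i for i, l in enumerate(hdr["labels"])}
        missing = [c for c in channels if c.lower() not in lookup]
        if missing:
            raise KeyError(f"channels {missing} not in {hdr['labels']}")
        wanted_idx = [lookup[c.lower()] for c in channels]
    rates = {hdr["samples_per_record"][i] for i in wanted_idx}
    if len(rates) > 1:
        raise ValueError(
            f"{path}: requested channels have mixed sampling rates "
            f"({sorted(r / hdr['record_s'] for r in rates)} Hz)"
        )

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        # mne may rename duplicates; match case-insensitively on originals
        name_map = {n.lower(): n for n in raw.ch_names}
        raw.pick([name_map[c.lower()] for c in channels])
        raw.reorder_channels([name_map[c.lower()] for c in channels])
        labels = tuple(channels)
    else:
        labels = tuple(raw.ch_names)
    data_uv = raw.get_data() * 1e6  # mne loads EDF in volts

    subject_id, group = "", "unknown"
    parts = hdr["patient"].split()
    if parts:
        subject_id = parts[0]
    if len(parts) > 1 and parts[1] in ("DD", "HC"):
        group = parts[1]
    return Recording(
        samples=data_uv,
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=subject_id or path.stem,
        group_label=group,
        meta={"source": str(path), "format": "edf"},
    )
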