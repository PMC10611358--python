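"""Synthetic two-group resting-state EEG cohorts with planted band-power effects.

The generator emulates the kind of clinical cohort the classifiers are meant
for: two unequal groups of subjects (patients vs controls), ~10 min of
eyes-closed frontal EEG per subject at a nominal 250 Hz, a 1/f^alpha
background, band-limited oscillatory activity whose power can differ between
groups in chosen bands (predominantly beta for a depression-like effect), and
optional stereotyped ocular artifacts for exercising ICA removal.

Each channel is built as::

    x(t) = gain_subject * ( background_1/f(t) + sum_bands osc_band(t) ) + artifacts(t)

where each oscillatory component is white noise bandpassed with a Butterworth
filter and rescaled so that "power ratio" in :class:`CohortSpec.band_effects`
is interpretable directly as the between-group ratio of total band power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import DEFAULT_FRONTAL_CHANNELS, BandSpec, Recording

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "planted_effect_summary",
    "band_power",
    "MONTAGE_16",
]

#: A 16-channel 10-20 montage (the frontal six first).
MONTAGE_16 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8",
    "C3", "C4", "T3", "T4", "P3", "P4", "T5", "T6", "O1", "O2",
)

#: Relative ocular-artifact gain by electrode prefix: blinks project most
#: strongly onto the frontopolar pair and decay toward posterior sites.
_ARTIFACT_GAIN_BY_PREFIX = {"fp": 1.0, "f": 0.45, "c": 0.15}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``band_effects`` maps each oscillatory band to the group_b/group_a ratio of
    total band power; a ratio of 1.0 plants an oscillation with no group
    difference. ``group_a``/``group_b`` default to patient (DD) and control
    (HC) labels with the 41/34 group sizes typical of a modest clinical study.
    """

    n_group_a: int = 41
    n_group_b: int = 34
    duration_s: float = 600.0
    rate_hz: float = 250.0
    n_channels: int = 6
    band_effects: tuple[tuple[BandSpec, float], ...] = ()
    artifact_rate: float = 0.0  # ocular events per minute
    noise_exponent: float = 1.0  # alpha of the 1/f^alpha background
    background_rms: float = 10.0  # microvolts
    osc_strength: float = 1.0  # group_a oscillation variance / background band power
    subject_gain_sigma: float = 0.1  # lognormal sigma of the per-subject gain
    group_a_label: str = "DD"
    group_b_label: str = "HC"
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1:
            raise ValueError(f"n_group_a must be >= 1, got {self.n_group_a}")
        if self.n_group_b < 1:
            raise ValueError(f"n_group_b must be >= 1, got {self.n_group_b}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.artifact_rate < 0:
            raise ValueError(f"artifact_rate must be >= 0, got {self.artifact_rate}")
        effects = tuple(
            (b if isinstance(b, BandSpec) else BandSpec(*b), float(r))
            for b, r in self.band_effects
        )
        object.__setattr__(self, "band_effects", effects)
        for band, ratio in effects:
            if ratio <= 0:
                raise ValueError(
                    f"band_effects power ratio must be > 0, got {ratio} for {band}"
                )
            if self.rate_hz <= 2 * band.high_hz:
                raise ValueError(
                    f"rate_hz={self.rate_hz} must exceed twice the highest band "
                    f"edge ({band.high_hz} Hz) in band_effects"
                )
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.n_channels:
                raise ValueError(
                    f"channel_labels has {len(self.channel_labels)} entries but "
                    f"n_channels={self.n_channels}"
                )
            object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def labels(self) -> tuple[str, ...]:
        if self.channel_labels is not None:
            return self.channel_labels
        if self.n_channels <= 6:
            return DEFAULT_FRONTAL_CHANNELS[: self.n_channels]
        if self.n_channels <= len(MONTAGE_16):
            return MONTAGE_16[: self.n_channels]
        return tuple(
            list(MONTAGE_16) + [f"EEG{i}" for i in range(len(MONTAGE_16), self.n_channels)]
        )


def _one_over_f_noise(rng: np.random.Generator, n: int, rate_hz: float, alpha: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD proportional to 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    # amplitude scales as f^(-alpha/2) so that power goes as f^(-alpha)
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    shape[0] = 0.0  # zero-mean
    return np.fft.irfft(spec * shape, n=n)


def band_power(x: np.ndarray, rate_hz: float, band: BandSpec) -> float:
    """Band-integrated power of a 1-D signal via Welch's averaged periodogram.

    Serves as the package's reference band-power measure; it is independent of
    the preprocessing filters.
    """
    band.validate_rate(rate_hz)
    nperseg = min(len(x), int(4 * rate_hz))
    freqs, psd = signal.welch(x, fs=rate_hz, nperseg=nperseg)
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no frequency bins at rate {rate_hz}")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _artifact_template(rng: np.random.Generator, rate_hz: float) -> np.ndarray:
    """One ocular transient: a raised-cosine bump lasting 0.5-2 s."""
    dur = rng.uniform(0.5, 2.0)
    n = max(int(dur * rate_hz), 3)
    return np.hanning(n)


def _channel_artifact_gain(label: str) -> float:
    key = label.lower()
    for prefix in ("fp", "f", "c"):
        if key.startswith(prefix):
            return _ARTIFACT_GAIN_BY_PREFIX[prefix]
    return 0.1


def _make_subject(
    spec: CohortSpec,
    rng: np.random.Generator,
    group: str,
    subject_id: str,
    is_group_b: bool,
) -> Recording:
    n = int(round(spec.duration_s * spec.rate_hz))
    labels = spec.labels
    gain = float(np.exp(rng.normal(0.0, spec.subject_gain_sigma)))
    chans = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        bg = _one_over_f_noise(rng, n, spec.rate_hz, spec.noise_exponent)
        bg *= spec.background_rms / max(bg.std(), 1e-12)
        x = bg.copy()
        for band, ratio in spec.band_effects:
            p_bg = band_power(bg, spec.rate_hz, band)
            v_a = spec.osc_strength * p_bg
            if is_group_b:
                v = ratio * (p_bg + v_a) - p_bg
                if v <= 0:
                    raise ValueError(
                        f"band_effects ratio {ratio} for {band} is too small to "
                        f"realize against the background (needs > "
                        f"{p_bg / (p_bg + v_a):.3f})"
                    )
            else:
                v = v_a
            sos = signal.butter(
                band.order, [band.low_hz, band.high_hz], btype="bandpass",
                fs=spec.rate_hz, output="sos",
            )
            osc = signal.sosfilt(sos, rng.standard_normal(n))
            osc *= np.sqrt(v) / max(osc.std(), 1e-12)
            x += osc
        chans[c] = x
    chans *= gain

    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
        gains = np.array([_channel_artifact_gain(lbl) for lbl in labels])
        bg_sd = float(chans.std())
        for _ in range(n_events):
            tmpl = _artifact_template(rng, spec.rate_hz)
            amp = rng.uniform(5.0, 10.0) * bg_sd
            start = rng.integers(0, max(n - len(tmpl), 1))
            seg = slice(start, start + len(tmpl))
            chans[:, seg] += amp * np.outer(gains, tmpl[: chans[:, seg].shape[1]])

    return Recording(
        samples=chans,
        rate_hz=spec.rate_hz,
        channel_labels=labels,
        subject_id=subject_id,
        group_label=group,
        meta={"synthetic": True, "subject_gain": gain},
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``n_group_a + n_group_b`` labeled recordings.

    Deterministic: the same (spec, seed) yields bit-identical sample arrays.
    Group-a subjects come first in the returned list.
    """
    rng = np.random.default_rng(spec.seed)
    cohort: list[Recording] = []
    for i in range(spec.n_group_a):
        cohort.append(
            _make_subject(spec, rng, spec.group_a_label, f"{spec.group_a_label}{i:03d}", False)
        )
    for i in range(spec.n_group_b):
        cohort.append(
            _make_subject(spec, rng, spec.group_b_label, f"{spec.group_b_label}{i:03d}", True)
        )
    return cohort


def planted_effect_summary(cohort: list[Recording], band: BandSpec) -> dict:
    """Per-group mean band power (channel-averaged, per subject) and their ratio.

    The ratio is ``second group / first group`` in order of first appearance in
    the cohort, matching the group_b/group_a convention of
    :class:`CohortSpec.band_effects` for generated cohorts.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    for rec in cohort:
        band.validate_rate(rec.rate_hz)
    order: list[str] = []
    powers: dict[str, list[float]] = {}
    for rec in cohort:
        p = float(
            np.mean([band_power(rec.samples[c], rec.rate_hz, band) for c in range(rec.n_channels)])
        )
        if rec.group_label not in powers:
            order.append(rec.group_label)
            powers[rec.group_label] = []
        powers[rec.group_label].append(p)
    means = {g: float(np.mean(v)) for g, v in powers.items()}
    out = {
        "band": (band.low_hz, band.high_hz),
        "group_means": means,
        "group_order": order,
        "per_subject": {g: list(map(float, v)) for g, v in powers.items()},
    }
    if len(order) >= 2:
        out["ratio"] = means[order[1]] / means[order[0]]
    return out
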