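"""Four stochastic 1-D ECG augmentation operators and their policy.

The operators simulate interference a wearable ECG meets in daily use and
regularise training by hiding different aspects of the signal per view:

* **frequency dropout** — orthonormal DCT-II per lead, zero a random set of
  frequency bins, invert (myoelectric-band corruption surrogate);
* **crop resize** — crop a random segment (all leads at the same position)
  and resample it back to the original length (time-scale jitter);
* **cycle mask** — detect R peaks, zero a window at the same offset in every
  cardiac cycle on all leads (beat-locked occlusion);
* **channel mask** — zero a few whole leads (electrode-failure surrogate).

All operators preserve shape and sampling rate and are deterministic under
a fixed seed.  :func:`apply_policy` composes them with per-operator apply
probabilities; repeated calls with seeds ``s..s+N`` build the multi-view
set used by contrastive pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import dct, idct

from .io import EcgRecord


@dataclass
class RPeakList:
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def frequency_dropout(rec: EcgRecord, n_drop: int, seed: int) -> EcgRecord:
    """Zero ``n_drop`` randomly chosen DCT bins per lead and invert.

    Uses the orthonormal DCT-II / inverse DCT-III pair, so energy removed
    equals the summed squared coefficients of the dropped bins (Parseval).
    Bins are drawn independently per lead.
    """
    n = rec.n_samples
    if not 0 <= n_drop <= n:
        raise ValueError(f"n_drop={n_drop} outside [0, {n}]")
    if n_drop == 0:
        return rec.copy()
    rng = np.random.default_rng(seed)
    out = rec.copy()
    coeffs = dct(out.signal, type=2, norm="ortho", axis=1)
    for li in range(rec.n_leads):
        bins = rng.choice(n, size=n_drop, replace=False)
        coeffs[li, bins] = 0.0
    out.signal = idct(coeffs, type=2, norm="ortho", axis=1)
    return out


def crop_resize(rec: EcgRecord, crop_fraction: float, seed: int) -> EcgRecord:
    """Crop a random segment of ``crop_fraction`` of the record (same
    position on every lead) and linearly resample it to the original length."""
    if not 0.0 < crop_fraction <= 1.0:
        raise ValueError("crop_fraction must be in (0, 1]")
    n = rec.n_samples
    if crop_fraction == 1.0:
        return rec.copy()
    seg = max(2, int(round(crop_fraction * n)))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n - seg + 1))
    out = rec.copy()
    xp = np.arange(seg)
    xq = np.linspace(0.0, seg - 1.0, n)
    out.signal = np.stack([
        np.interp(xq, xp, rec.signal[li, start:start + seg])
        for li in range(rec.n_leads)
    ])
    return out


def detect_r_peaks(rec: EcgRecord, lead: str = "II",
                   refractory_s: float = 0.2) -> RPeakList:
    """Pan-Tompkins-style QRS detector on one lead.

    Band-pass (5-25 Hz) -> derivative -> squaring -> moving-window
    integration (150 ms) -> peak picking with an adaptive threshold and a
    200 ms refractory period, then refinement to the local extremum of the
    band-passed signal.  Returns an empty list on flat signals.  When the
    named lead is absent (reduced-lead or anonymous-channel records) the
    first channel is used.
    """
    if lead in rec.lead_names:
        x = rec.lead(lead).astype(float)
    else:
        x = rec.signal[0].astype(float)
    fs = rec.fs
    if np.allclose(x, x[0]):
        return RPeakList(np.array([], dtype=np.int64))
    hi = min(25.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, hi], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    height = 0.25 * np.quantile(integ, 0.995)
    if height <= 0:
        return RPeakList(np.array([], dtype=np.int64))
    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = sps.find_peaks(integ, height=height, distance=distance)
    # refine each detection to the dominant |bp| extremum nearby
    half = max(1, int(round(0.06 * fs)))
    refined = []
    for p in peaks:
        lo, hi_i = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi_i]))))
    refined = np.unique(refined)
    if refined.size > 1:
        keep = [int(refined[0])]
        for r in refined[1:]:
            if r - keep[-1] >= distance:
                keep.append(int(r))
        refined = np.asarray(keep)
    return RPeakList(refined)


def cycle_mask(rec: EcgRecord, peaks: RPeakList, offset_ms: float,
               width_ms: float) -> EcgRecord:
    """Zero the window [r+offset, r+offset+width) around every R peak on all
    leads, clipped to the record bounds; all other samples untouched."""
    if width_ms < 0:
        raise ValueError("width must be >= 0")
    out = rec.copy()
    if width_ms == 0 or len(peaks) == 0:
        return out
    offset = int(round(offset_ms * rec.fs / 1000.0))
    width = int(round(width_ms * rec.fs / 1000.0))
    for r in peaks.indices:
        lo = max(0, int(r) + offset)
        hi = min(rec.n_samples, int(r) + offset + width)
        if lo < hi:
            out.signal[:, lo:hi] = 0.0
    return out


def channel_mask(rec: EcgRecord, n_channels: int, seed: int) -> EcgRecord:
    """Zero ``n_channels`` leads chosen uniformly without replacement."""
    if not 0 <= n_channels <= rec.n_leads:
        raise ValueError(f"n_channels={n_channels} outside [0, {rec.n_leads}]")
    out = rec.copy()
    if n_channels == 0:
        return out
    rng = np.random.default_rng(seed)
    leads = rng.choice(rec.n_leads, size=n_channels, replace=False)
    out.signal[leads] = 0.0
    return out


@dataclass
class AugmentationPolicy:
    """Stochastic composition T of the four operators.

    Each operator fires independently with its probability; magnitudes are
    drawn uniformly from the configured ranges.  Composition order is
    frequency_dropout -> crop_resize -> cycle_mask -> channel_mask (masks
    last so they survive resampling).
    """

    p_frequency_dropout: float = 0.5
    p_crop_resize: float = 0.5
    p_cycle_mask: float = 0.5
    p_channel_mask: float = 0.5
    freq_drop_range: tuple[int, int] = (1, 50)
    crop_fraction_range: tuple[float, float] = (0.5, 1.0)
    cycle_offset_ms: float = -40.0
    cycle_width_range_ms: tuple[float, float] = (40.0, 120.0)
    channel_mask_range: tuple[int, int] = (1, 3)
    order: tuple[str, ...] = ("frequency_dropout", "crop_resize",
                              "cycle_mask", "channel_mask")

    def __post_init__(self) -> None:
        for name in ("p_frequency_dropout", "p_crop_resize", "p_cycle_mask",
                     "p_channel_mask"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        lo, hi = self.crop_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_fraction_range must sit inside (0,1]")

    @classmethod
    def off(cls) -> "AugmentationPolicy":
        return cls(p_frequency_dropout=0.0, p_crop_resize=0.0,
                   p_cycle_mask=0.0, p_channel_mask=0.0)


def apply_policy(rec: EcgRecord, policy: AugmentationPolicy,
                 seed: int) -> EcgRecord:
    """Apply the policy once; a fixed seed replays the identical view."""
    rng = np.random.default_rng(seed)
    out = rec
    for name in policy.order:
        if name == "frequency_dropout":
            fire = rng.random() < policy.p_frequency_dropout
            lo, hi = policy.freq_drop_range
            n_drop = int(rng.integers(lo, hi + 1))
            sub = int(rng.integers(0, 2 ** 31 - 1))
            if fire:
                n_drop = min(n_drop, rec.n_samples)
                out = frequency_dropout(out, n_drop, sub)
        elif name == "crop_resize":
            fire = rng.random() < policy.p_crop_resize
            frac = float(rng.uniform(*policy.crop_fraction_range))
            sub = int(rng.integers(0, 2 ** 31 - 1))
            if fire:
                out = crop_resize(out, frac, sub)
        elif name == "cycle_mask":
            fire = rng.random() < policy.p_cycle_mask
            width = float(rng.uniform(*policy.cycle_width_range_ms))
            if fire:
                peaks = detect_r_peaks(out)
                out = cycle_mask(out, peaks, policy.cycle_offset_ms, width)
        elif name == "channel_mask":
            fire = rng.random() < policy.p_channel_mask
            lo, hi = policy.channel_mask_range
            n_ch = int(rng.integers(lo, hi + 1))
            sub = int(rng.integers(0, 2 ** 31 - 1))
            if fire:
                out = channel_mask(out, min(n_ch, rec.n_leads), sub)
        else:
            raise ValueError(f"unknown operator {name!r} in policy order")
    if out is rec:
        out = rec.copy()
    return out
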