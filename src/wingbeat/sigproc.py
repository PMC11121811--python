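"""Transit-signal detection and feature extraction.

An insect crossing the sensor beam removes light by scattering, diffraction
and absorption, producing a dip in the received intensity ("transit signal")
with a roughly Gaussian envelope, amplitude-modulated by the wing stroke.
This module turns raw voltage traces into per-event features:

* wingbeat frequency -- the fundamental of the wing-flap modulation, found
  in the magnitude spectrum of the detrended in-transit signal;
* optical extinction cross-sections of wings and body,
  ``sigma_w = (V0 - Vw)/V0 * A`` and ``sigma_b = (V0 - Vb)/V0 * A``,
  where ``A`` is the beam cross-sectional area;
* the beam-area-invariant wing-to-body ratio
  ``sigma_w / (sigma_w + sigma_b)``.

Non-insect obstructions (rain droplets, falling leaves) produce smooth dips
without spectral content in the insect band (10-900 Hz by default) and are
classified out; events shorter than 10 ms are discarded and events longer
than 1 s are truncated and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TransitSignal",
    "InstrumentConfig",
    "Segment",
    "TransitEvent",
    "UnusableEventError",
    "NonInsectError",
    "detect_transits",
    "estimate_baseline",
    "estimate_levels",
    "cross_sections",
    "wing_body_ratio",
    "extract_wingbeat_frequency",
    "classify_event",
    "extract_events",
    "attach_temperature",
]

DEFAULT_SAMPLING_RATE = 30_517.0
#: Beam cross-section of a 50.8 mm diameter flat-top beam, mm^2.
DEFAULT_BEAM_AREA = math.pi * (50.8 / 2.0) ** 2


class UnusableEventError(ValueError):
    """A detected segment that cannot yield a valid event (too short,
    no usable baseline, non-physical levels)."""


class NonInsectError(ValueError):
    """A segment with no prominent spectral peak in the insect band."""


@dataclass
class TransitSignal:
    """A raw voltage trace with sampling metadata.

    ``truth`` optionally carries generator ground truth for synthetic
    traces; it is never consulted by the extraction code.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    t0: np.datetime64 | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class InstrumentConfig:
    """Detection and extraction parameters.

    Parameters
    ----------
    beam_area_A:
        Cross-sectional area of the beam in mm^2. Extinction cross-sections
        scale linearly with it; the wing-to-body ratio does not depend on it.
    min_duration, max_duration:
        Accepted transit duration window in seconds. Shorter dips are
        dropped, longer ones truncated and flagged.
    band:
        Frequency interval (Hz) searched for the wingbeat fundamental.
    detection_threshold:
        Fractional drop below baseline that triggers a detection.
    smooth_window:
        Moving-average window (s) applied before thresholding.
    noise_mult:
        A spectral peak must exceed ``noise_mult`` times the in-band median
        magnitude to count as wing modulation.
    prominence_mult:
        Required peak prominence, in units of the in-band median magnitude.
    candidate_frac:
        Peaks below this fraction of the tallest in-band peak are not
        considered as fundamental candidates.
    min_modulation_frac:
        An in-band peak must reach this fraction of the transit envelope's
        own spectral magnitude (below-band maximum) to count as wing
        modulation; smooth dips fail this absolute test even when their
        detrending residual shows relative structure.
    harmonic_tol:
        Relative tolerance when testing whether a taller peak is an integer
        multiple of a candidate fundamental.
    zero_pad_factor:
        FFT length as a multiple of the segment length.
    """

    beam_area_A: float = DEFAULT_BEAM_AREA
    min_duration: float = 0.010
    max_duration: float = 1.0
    band: tuple[float, float] = (10.0, 900.0)
    detection_threshold: float = 0.02
    smooth_window: float = 0.005
    noise_mult: float = 5.0
    prominence_mult: float = 3.0
    candidate_frac: float = 0.2
    min_modulation_frac: float = 0.02
    harmonic_tol: float = 0.1
    zero_pad_factor: int = 4
    detrend_degree: int = 8

    def __post_init__(self) -> None:
        if self.beam_area_A <= 0:
            raise ValueError("beam_area_A must be positive")
        if not 0 < self.min_duration < self.max_duration:
            raise ValueError("need 0 < min_duration < max_duration")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")


@dataclass(frozen=True)
class Segment:
    """Half-open sample range [start, stop) of one detected transit."""

    start: int
    stop: int
    truncated: bool = False

    @property
    def n(self) -> int:
        return self.stop - self.start

    def duration(self, sampling_rate: float) -> float:
        return self.n / sampling_rate


@dataclass
class TransitEvent:
    """One accepted insect passage with its extracted features."""

    t0: np.datetime64 | None
    duration: float
    v0: float
    v_body: float
    v_wing: float
    sigma_w: float
    sigma_b: float
    ratio: float
    freq: float
    temperature: float = math.nan
    truncated: bool = False

    def as_dict(self) -> dict:
        return {
            "timestamp": self.t0,
            "duration_s": self.duration,
            "v0": self.v0,
            "v_body": self.v_body,
            "v_wing": self.v_wing,
            "sigma_w_mm2": self.sigma_w,
            "sigma_b_mm2": self.sigma_b,
            "ratio": self.ratio,
            "wingbeat_hz": self.freq,
            "temperature_C": self.temperature,
            "truncated": self.truncated,
        }


# ---------------------------------------------------------------------------
# detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as [start, stop) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_transits(signal: TransitSignal, cfg: InstrumentConfig) -> list[Segment]:
    """Find candidate transit segments.

    The trace is smoothed with a short moving average and compared against
    ``baseline * (1 - detection_threshold)`` where the baseline is the trace
    median. Runs below threshold separated by less than one period of the
    slowest in-band wingbeat are merged: the wing stroke of a slow flapper
    lifts the signal back above threshold within each cycle, fragmenting a
    single transit. Merged runs shorter than ``min_duration`` are discarded;
    runs longer than ``max_duration`` are truncated and flagged.
    """
    fs = signal.sampling_rate
    x = signal.samples
    if x.size < 2:
        return []
    w = max(1, int(round(cfg.smooth_window * fs)))
    smoothed = uniform_filter1d(x, size=w, mode="nearest")
    baseline = float(np.median(smoothed))
    level = baseline * (1.0 - cfg.detection_threshold)
    runs = _runs(smoothed < level)
    if not runs:
        return []

    min_n = int(round(cfg.min_duration * fs))
    max_n = int(round(cfg.max_duration * fs))
    gap_n = max(min_n, int(round(fs / cfg.band[0])))

    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap_n:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    segments: list[Segment] = []
    pad = w // 2
    for start, stop in merged:
        if stop - start < min_n:
            continue
        start = max(0, start - pad)
        stop = min(x.size, stop + pad)
        if stop - start > max_n:
            segments.append(Segment(start, start + max_n, truncated=True))
        else:
            segments.append(Segment(start, stop))
    return segments


def estimate_baseline(
    signal: TransitSignal,
    segment: Segment,
    flank_duration: float | None = None,
) -> float:
    """Background level ``V0``: median of samples flanking the segment.

    The flank on each side spans ``flank_duration`` seconds (default: half
    the segment duration, at least 10 ms). A segment at a trace edge falls
    back to the available side only.
    """
    fs = signal.sampling_rate
    if flank_duration is None:
        flank_duration = max(0.010, 0.5 * segment.duration(fs))
    n_flank = max(1, int(round(flank_duration * fs)))
    left = signal.samples[max(0, segment.start - n_flank) : segment.start]
    right = signal.samples[segment.stop : segment.stop + n_flank]
    flanks = np.concatenate([left, right])
    if flanks.size == 0:
        raise UnusableEventError("segment has no flanking out-of-transit samples")
    return float(np.median(flanks))


# ---------------------------------------------------------------------------
# spectral extraction


def _detrended(x: np.ndarray, degree: int = 8) -> np.ndarray:
    """Remove the slow transit envelope with a polynomial fit.

    The degree is high enough to absorb a Gaussian-like dip but far too low
    to track in-band wing oscillations (an in-band component completes at
    least one full cycle over any accepted segment).
    """
    n = x.size
    t = np.linspace(-1.0, 1.0, n)
    deg = min(degree, n - 1)
    coeffs = np.polynomial.polynomial.polyfit(t, x, deg)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def _spectrum(
    x: np.ndarray, fs: float, zero_pad_factor: int, degree: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies, residual-magnitude and raw-magnitude spectra."""
    win = sps.windows.hann(x.size)
    nfft = next_fast_len(max(zero_pad_factor * x.size, x.size))
    mag = np.abs(rfft(_detrended(x, degree) * win, nfft))
    mag_raw = np.abs(rfft((x - x.mean()) * win, nfft))
    return rfftfreq(nfft, 1.0 / fs), mag, mag_raw


def _refine_peak(freqs: np.ndarray, mag: np.ndarray, idx: int) -> float:
    """Quadratic interpolation of a peak position on log magnitude."""
    if idx <= 0 or idx >= mag.size - 1:
        return float(freqs[idx])
    with np.errstate(divide="ignore"):
        a, b, c = np.log(mag[idx - 1 : idx + 2])
    denom = a - 2.0 * b + c
    if not np.isfinite(denom) or denom == 0 or not np.isfinite(a + c):
        return float(freqs[idx])
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    return float(freqs[idx] + delta * df)


def extract_wingbeat_frequency(
    signal: TransitSignal, segment: Segment, cfg: InstrumentConfig
) -> float:
    """Fundamental wingbeat frequency of a transit segment, in Hz.

    The segment is detrended (envelope removal), Hann-windowed, zero-padded
    and transformed; prominent peaks in the configured band are located, and
    the fundamental is the lowest-frequency prominent peak such that every
    taller prominent peak lies near an integer multiple of it. The tallest
    peak need not be the fundamental: a strong second harmonic is resolved
    correctly by the integer-multiple rule. The returned value is refined by
    quadratic interpolation around the peak bin.

    Raises
    ------
    NonInsectError
        If no sufficiently prominent in-band peak exists.
    UnusableEventError
        If the segment is too short to analyse.
    """
    x = signal.samples[segment.start : segment.stop]
    if x.size < 16:
        raise UnusableEventError("segment too short for spectral analysis")
    freqs, mag, mag_raw = _spectrum(
        x, signal.sampling_rate, cfg.zero_pad_factor, cfg.detrend_degree
    )
    lo, hi = cfg.band
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise NonInsectError("band empty for this sampling rate")
    bmag = mag[band]
    boff = int(np.flatnonzero(band)[0])
    floor = float(np.median(bmag))
    if floor <= 0:
        floor = float(np.finfo(float).tiny)
    below = mag_raw[freqs < lo]
    env_scale = float(below.max()) if below.size else 0.0
    peaks, _ = sps.find_peaks(
        bmag,
        height=max(cfg.noise_mult * floor, cfg.min_modulation_frac * env_scale),
        prominence=cfg.prominence_mult * floor,
    )
    if peaks.size == 0:
        raise NonInsectError("no prominent spectral peak in band")

    heights = bmag[peaks]
    keep = heights >= cfg.candidate_frac * heights.max()
    cand_idx = peaks[keep]
    cand_freq = freqs[boff + cand_idx]
    cand_h = bmag[cand_idx]

    order = np.argsort(cand_freq)
    chosen = None
    for i in order:
        f0 = cand_freq[i]
        taller = cand_freq[cand_h > cand_h[i]]
        mult = taller / f0
        if np.all(np.abs(mult - np.round(mult)) <= cfg.harmonic_tol * np.maximum(np.round(mult), 1)):
            chosen = int(cand_idx[i])
            break
    if chosen is None:
        chosen = int(cand_idx[np.argmax(cand_h)])
    return _refine_peak(freqs, mag, boff + chosen)


def classify_event(
    signal: TransitSignal, segment: Segment, cfg: InstrumentConfig
) -> str:
    """Label a detected segment ``"insect"`` or ``"non_insect"``.

    An insect event has an in-window duration and a prominent spectral peak
    in the insect band; smooth dips (droplets, leaves) and out-of-duration
    events fail one of the two tests.
    """
    dur = segment.duration(signal.sampling_rate)
    if not cfg.min_duration <= dur <= cfg.max_duration:
        return "non_insect"
    try:
        extract_wingbeat_frequency(signal, segment, cfg)
    except (NonInsectError, UnusableEventError):
        return "non_insect"
    return "insect"


# ---------------------------------------------------------------------------
# levels and cross-sections


def estimate_levels(
    signal: TransitSignal,
    segment: Segment,
    cfg: InstrumentConfig,
    freq: float | None = None,
) -> tuple[float, float]:
    """Estimate ``(v_body, v_wing)`` for a transit segment.

    Both levels apply a 10%-minimum averaging rule to the wing-cycle
    envelopes: ``v_wing`` is the mean of the lowest 10% of per-cycle minima
    (deepest occlusion, body plus wings, at the envelope peak) and
    ``v_body`` the mean of the lowest 10% of per-cycle maxima (wings
    edge-on, body only). Cycles are located as local extrema spaced by
    roughly one wingbeat period. Without wing modulation (no resolvable
    cycles) both fall back to the lowest 10% of raw samples and coincide.
    """
    x = signal.samples[segment.start : segment.stop]
    if x.size < 10:
        raise UnusableEventError("fewer than 10 samples in segment")

    def lowest_decile_mean(vals: np.ndarray) -> float:
        k = max(1, math.ceil(0.1 * vals.size))
        return float(np.mean(np.sort(vals)[:k]))

    if freq is None:
        try:
            freq = extract_wingbeat_frequency(signal, segment, cfg)
        except (NonInsectError, UnusableEventError):
            freq = None

    v_wing = v_body = lowest_decile_mean(x)
    if freq is not None and freq > 0:
        dist = max(1, int(round(0.8 * signal.sampling_rate / freq)))
        maxima, _ = sps.find_peaks(x, distance=dist)
        minima, _ = sps.find_peaks(-x, distance=dist)
        if maxima.size >= 4 and minima.size >= 4:
            v_body = lowest_decile_mean(x[maxima])
            v_wing = lowest_decile_mean(x[minima])
    return max(v_body, v_wing), min(v_wing, v_body)


def cross_sections(
    v0: float, v_wing: float, v_body: float, cfg: InstrumentConfig
) -> tuple[float, float]:
    """Optical extinction cross-sections (mm^2) of wings and body.

    ``sigma_w = (V0 - Vw)/V0 * A`` and ``sigma_b = (V0 - Vb)/V0 * A``.
    """
    if v0 <= 0:
        raise UnusableEventError("background level V0 must be positive")
    sigma_w = (v0 - v_wing) / v0 * cfg.beam_area_A
    sigma_b = (v0 - v_body) / v0 * cfg.beam_area_A
    return sigma_w, sigma_b


def wing_body_ratio(sigma_w: float, sigma_b: float) -> float:
    """Wing-to-body cross-section ratio ``sigma_w / (sigma_w + sigma_b)``."""
    total = sigma_w + sigma_b
    if total <= 0:
        raise UnusableEventError("sigma_w + sigma_b must be positive")
    return sigma_w / total


# ---------------------------------------------------------------------------
# per-trace orchestration


def extract_events(
    signal: TransitSignal, cfg: InstrumentConfig | None = None
) -> tuple[list[TransitEvent], dict[str, int]]:
    """Run detection, classification and feature extraction on one trace.

    Returns the accepted insect events and a tally reconciling every
    detected segment: ``detected == insect + non_insect + unusable``.
    """
    if cfg is None:
        cfg = InstrumentConfig()
    fs = signal.sampling_rate
    counts = {"detected": 0, "insect": 0, "non_insect": 0, "unusable": 0}
    events: list[TransitEvent] = []
    for seg in detect_transits(signal, cfg):
        counts["detected"] += 1
        try:
            v0 = estimate_baseline(signal, seg)
        except UnusableEventError:
            counts["unusable"] += 1
            continue
        try:
            freq = extract_wingbeat_frequency(signal, seg, cfg)
        except NonInsectError:
            counts["non_insect"] += 1
            continue
        except UnusableEventError:
            counts["unusable"] += 1
            continue
        try:
            v_body, v_wing = estimate_levels(signal, seg, cfg, freq=freq)
            if not v_wing <= v_body <= v0:
                raise UnusableEventError("level ordering violated")
            sigma_w, sigma_b = cross_sections(v0, v_wing, v_body, cfg)
            ratio = wing_body_ratio(sigma_w, sigma_b)
        except UnusableEventError:
            counts["unusable"] += 1
            continue
        t0 = None
        if signal.t0 is not None:
            t0 = signal.t0 + np.timedelta64(int(seg.start / fs * 1e6), "us")
        counts["insect"] += 1
        events.append(
            TransitEvent(
                t0=t0,
                duration=seg.duration(fs),
                v0=v0,
                v_body=v_body,
                v_wing=v_wing,
                sigma_w=sigma_w,
                sigma_b=sigma_b,
                ratio=ratio,
                freq=freq,
                truncated=seg.truncated,
            )
        )
    return events, counts


def attach_temperature(
    events: pd.DataFrame,
    weather: pd.DataFrame,
    staleness: float = 600.0,
    timestamp_col: str = "timestamp_iso8601",
) -> pd.DataFrame:
    """Attach the nearest-in-time weather temperature to each event.

    ``weather`` must have columns ``timestamp_iso8601`` and
    ``temperature_C`` at roughly minute cadence. Events farther than
    ``staleness`` seconds from any weather record keep the nearest value but
    are flagged in a boolean ``temp_stale`` column.
    """
    if weather.empty:
        raise ValueError("weather series is empty")
    ev = events.copy()
    ev["_ts"] = pd.to_datetime(ev[timestamp_col])
    wx = weather.copy()
    wx["_ts"] = pd.to_datetime(wx[timestamp_col])
    wx = wx.sort_values("_ts")
    order = ev["_ts"].argsort(kind="stable")
    merged = pd.merge_asof(
        ev.iloc[order],
        wx[["_ts", "temperature_C"]].rename(columns={"temperature_C": "_wx_temp"}),
        on="_ts",
        direction="nearest",
    )
    nearest = wx["_ts"].searchsorted(merged["_ts"])
    nearest = np.clip(nearest, 0, len(wx) - 1)
    prev = np.clip(nearest - 1, 0, len(wx) - 1)
    gap = np.minimum(
        np.abs((merged["_ts"].to_numpy() - wx["_ts"].to_numpy()[nearest])),
        np.abs((merged["_ts"].to_numpy() - wx["_ts"].to_numpy()[prev])),
    )
    merged["temperature_C"] = merged.pop("_wx_temp")
    merged["temp_stale"] = gap > np.timedelta64(int(staleness * 1e3), "ms")
    merged = merged.iloc[np.argsort(order.to_numpy(), kind="stable")]
    return merged.drop(columns="_ts").reset_index(drop=True)
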