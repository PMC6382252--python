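"""Auditory front-end: gammatone filterbank cochleagrams.

The cochlea is modelled as a bank of 4th-order gammatone bandpass filters with
center frequencies equally spaced on the ERB-rate (Glasberg-Moore) scale.
Band envelopes are extracted as windowed RMS energies and compressed with a
static logarithmic non-linearity, ``10*log10(1 + x**2)``, yielding a
non-negative time-frequency matrix (the cochleagram) that serves as the
observed variable of the generative models in :mod:`maxcause.mca` and
:mod:`maxcause.bsc`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

__all__ = [
    "FilterbankConfig",
    "FrameConfig",
    "Cochleagram",
    "erb_bandwidth",
    "erb_rate",
    "inverse_erb_rate",
    "erb_center_frequencies",
    "gammatone_impulse_response",
    "make_fir_kernels",
    "apply_filterbank",
    "frame_rms",
    "compress",
    "waveform_to_cochleagram",
    "cut_snippets",
    "build_dataset",
    "read_waveform",
    "save_dataset",
]

# Glasberg & Moore (1990) ERB constants, as used by Slaney's toolbox.
_EAR_Q = 9.26449
_MIN_BW = 24.7
# 4th-order correction relating the gammatone bandwidth parameter b to the ERB.
_ORDER4_BW_FACTOR = 1.019


def erb_bandwidth(f: float | np.ndarray) -> float | np.ndarray:
    """Equivalent rectangular bandwidth (Hz) of the auditory filter at ``f`` Hz."""
    return _MIN_BW + np.asarray(f, dtype=float) / _EAR_Q


def erb_rate(f):
    """Map frequency in Hz to the ERB-rate scale (ERB number)."""
    f = np.asarray(f, dtype=float)
    return _EAR_Q * np.log(1.0 + f / (_EAR_Q * _MIN_BW))


def inverse_erb_rate(e):
    """Inverse of :func:`erb_rate`: ERB number back to Hz."""
    e = np.asarray(e, dtype=float)
    return (_EAR_Q * _MIN_BW) * (np.exp(e / _EAR_Q) - 1.0)


def erb_center_frequencies(n_channels: int, f_min: float, f_max: float) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale.

    Endpoints map exactly to ``f_min`` and ``f_max``; frequencies ascend.
    A single channel with ``f_min == f_max`` returns that frequency.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if f_min > f_max or f_min <= 0:
        raise ValueError("need 0 < f_min <= f_max")
    if n_channels == 1:
        if f_min != f_max:
            raise ValueError("one channel requires f_min == f_max")
        return np.array([float(f_min)])
    e = np.linspace(erb_rate(f_min), erb_rate(f_max), n_channels)
    cf = inverse_erb_rate(e)
    cf[0], cf[-1] = f_min, f_max  # kill round-trip rounding at the endpoints
    return cf


@dataclass
class FilterbankConfig:
    """Gammatone filterbank parameters.

    ``order`` is the gammatone order n; ``bw_factor`` scales the Glasberg-Moore
    ERB into the bandwidth parameter b of the impulse response (1.019 is the
    standard 4th-order value); ``phase`` is the carrier phase in radians.
    ``filter_impl`` selects direct FIR sampling of the impulse response
    (default) or Slaney's all-pole IIR cascade ("iir").
    """

    n_channels: int = 32
    f_min: float = 1000.0
    f_max: float = 22050.0
    order: int = 4
    bw_factor: float = _ORDER4_BW_FACTOR
    phase: float = 0.0
    filter_impl: str = "fir"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (0 < self.f_min <= self.f_max):
            raise ValueError("need 0 < f_min <= f_max")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.filter_impl not in ("fir", "iir"):
            raise ValueError("filter_impl must be 'fir' or 'iir'")

    def center_frequencies(self) -> np.ndarray:
        return erb_center_frequencies(self.n_channels, self.f_min, self.f_max)


@dataclass
class FrameConfig:
    """Temporal framing: RMS window/step and waveform snippet geometry (seconds)."""

    window: float = 0.020
    step: float = 0.010
    snippet_length: float = 0.160
    snippet_overlap: float = 0.032

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("need 0 < step <= window")
        if not (0 <= self.snippet_overlap < self.snippet_length):
            raise ValueError("need 0 <= snippet_overlap < snippet_length")


@dataclass
class Cochleagram:
    """F x T matrix of compressed band energies with axis metadata."""

    values: np.ndarray
    center_freqs: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("cochleagram values must be non-negative")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")

    def flatten(self) -> np.ndarray:
        """Frequency-major flattening: channel 1 frames 1..T, then channel 2, ..."""
        return self.values.ravel(order="C")


def gammatone_impulse_response(t, cfg: FilterbankConfig, f_c: float, amplitude: float = 1.0):
    """g(t) = a * t^(n-1) * exp(-2 pi b t) * cos(2 pi f_c t + phi), for t >= 0.

    ``b`` is derived from the ERB of ``f_c`` via ``cfg.bw_factor``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("gammatone impulse response is causal: t must be >= 0")
    b = cfg.bw_factor * float(erb_bandwidth(f_c))
    n = cfg.order
    return amplitude * t ** (n - 1) * np.exp(-2.0 * np.pi * b * t) * np.cos(
        2.0 * np.pi * f_c * t + cfg.phase
    )


def _kernel_duration(b: float, order: int) -> float:
    # The envelope t^(n-1) exp(-2 pi b t) peaks at (n-1) time constants
    # tau = 1/(2 pi b); by 20 tau the tail is < ~1e-5 of the peak.
    return 20.0 / (2.0 * np.pi * b)


def make_fir_kernels(cfg: FilterbankConfig, rate: float) -> list[np.ndarray]:
    """Sampled gammatone kernels, one per channel, peak-gain normalized.

    Each kernel is scaled so the magnitude of its frequency response at the
    channel center frequency is 1.
    """
    if rate < 2.0 * cfg.f_max:
        raise ValueError("waveform rate must be >= 2 * f_max")
    kernels = []
    for fc in cfg.center_frequencies():
        b = cfg.bw_factor * float(erb_bandwidth(fc))
        dur = _kernel_duration(b, cfg.order)
        n_taps = max(int(round(dur * rate)), 8)
        t = np.arange(n_taps) / rate
        k = gammatone_impulse_response(t, cfg, fc)
        # gain at fc: |sum_k k[m] exp(-i 2 pi fc m / rate)|
        gain = abs(np.sum(k * np.exp(-2j * np.pi * fc * np.arange(n_taps) / rate)))
        if gain <= 0:
            raise ValueError(f"degenerate gammatone kernel at f_c={fc}")
        kernels.append(k / gain)
    return kernels


def _slaney_iir_coeffs(fc: float, rate: float, bw_factor: float):
    """Second-order-section coefficients of Slaney's all-pole gammatone (order 4)."""
    T = 1.0 / rate
    B = 2.0 * np.pi * bw_factor * float(erb_bandwidth(fc))
    w = 2.0 * np.pi * fc * T
    e = np.exp(B * T)
    cosw, sinw = np.cos(w), np.sin(w)
    sq_plus = math.sqrt(3.0 + 2.0 ** 1.5)
    sq_minus = math.sqrt(3.0 - 2.0 ** 1.5)
    b0, b1, b2 = 1.0, -2.0 * cosw / e, np.exp(-2.0 * B * T)
    sos = []
    for sq, sgn in ((sq_plus, +1), (sq_plus, -1), (sq_minus, +1), (sq_minus, -1)):
        a1 = -(2.0 * T * cosw / e + sgn * 2.0 * sq * T * sinw / e) / 2.0
        sos.append([T, a1, 0.0, b0, b1, b2])
    return np.asarray(sos)


def _apply_iir(x: np.ndarray, cfg: FilterbankConfig, rate: float) -> np.ndarray:
    out = np.empty((cfg.n_channels, x.shape[-1]))
    for i, fc in enumerate(cfg.center_frequencies()):
        sos = _slaney_iir_coeffs(fc, rate, cfg.bw_factor)
        # normalize numerically to unit gain at fc
        _, h = _signal.sosfreqz(sos, worN=[2.0 * np.pi * fc / rate])
        y = _signal.sosfilt(sos, x)
        out[i] = y / abs(h[0])
    return out


def apply_filterbank(samples: np.ndarray, cfg: FilterbankConfig, rate: float) -> np.ndarray:
    """Filter a waveform through the bank; returns an F x S band-signal matrix.

    Causal filtering: output sample s depends only on input samples <= s, and
    the output has the same length as the input.
    """
    x = np.asarray(samples, dtype=float)
    batched = x.ndim == 2
    if rate < 2.0 * cfg.f_max:
        raise ValueError("waveform rate must be >= 2 * f_max")
    if cfg.filter_impl == "iir":
        if batched:
            return np.stack([_apply_iir(row, cfg, rate) for row in x])
        return _apply_iir(x, cfg, rate)
    kernels = make_fir_kernels(cfg, rate)
    L = x.shape[-1]
    if batched:
        out = np.empty((x.shape[0], cfg.n_channels, L))
        for i, k in enumerate(kernels):
            full = _signal.fftconvolve(x, k[None, :], mode="full", axes=1)
            out[:, i, :] = full[:, :L]
        return out
    out = np.empty((cfg.n_channels, L))
    for i, k in enumerate(kernels):
        out[i] = _signal.fftconvolve(x, k, mode="full")[:L]
    return out


def frame_rms(band_signals: np.ndarray, frame_cfg: FrameConfig, rate: float) -> np.ndarray:
    """Windowed RMS over each band: F x T matrix of sliding-window energies.

    Frames are left-aligned at t=0; the trailing partial frame is dropped, so
    T = floor((L - window)/step) + 1 in samples.
    """
    x = np.asarray(band_signals, dtype=float)
    w = int(round(frame_cfg.window * rate))
    h = int(round(frame_cfg.step * rate))
    L = x.shape[-1]
    if L < w:
        raise ValueError("signal shorter than one analysis window")
    n_frames = (L - w) // h + 1
    csum = np.cumsum(np.square(x), axis=-1, dtype=float)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    starts = np.arange(n_frames) * h
    energy = csum[..., starts + w] - csum[..., starts]
    return np.sqrt(np.maximum(energy / w, 0.0))


def compress(x_rms: np.ndarray) -> np.ndarray:
    """Static compressive non-linearity 10*log10(1 + x^2); maps [0,inf)->[0,inf)."""
    x = np.asarray(x_rms, dtype=float)
    if np.any(x < 0):
        raise ValueError("RMS energies must be non-negative")
    return 10.0 * np.log10(1.0 + np.square(x))


def waveform_to_cochleagram(wave, fb_cfg: FilterbankConfig, frame_cfg: FrameConfig) -> Cochleagram:
    """Full front-end for one waveform: filterbank -> windowed RMS -> compression."""
    bands = apply_filterbank(wave.samples, fb_cfg, wave.rate)
    x = frame_rms(bands, frame_cfg, wave.rate)
    values = compress(x)
    w = int(round(frame_cfg.window * wave.rate))
    h = int(round(frame_cfg.step * wave.rate))
    n_frames = values.shape[-1]
    frame_times = (np.arange(n_frames) * h + w) / wave.rate
    return Cochleagram(values, fb_cfg.center_frequencies(), frame_times)


def read_waveform(path, target_rate: float = 44100.0):
    """Read a WAV file (any PCM/float), downmix to mono, resample to 44.1 kHz.

    Integer PCM is scaled to [-1, 1]; multi-channel audio is averaged across
    channels; rates other than ``target_rate`` are polyphase-resampled.
    """
    from fractions import Fraction

    from scipy.io import wavfile

    from .synth import Waveform

    rate, data = wavfile.read(path)
    x = np.asarray(data, dtype=float)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        x = x / float(np.iinfo(np.asarray(data).dtype).max)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(int(round(target_rate)), int(rate)).limit_denominator(1000)
        x = _signal.resample_poly(x, frac.numerator, frac.denominator)
    return Waveform(x, target_rate)


def save_dataset(data: np.ndarray, meta: dict, out_dir) -> None:
    """Persist an N x D cochleagram dataset as MAT and CSV with axis metadata."""
    from pathlib import Path

    from scipy.io import savemat

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "Y": data,
        "center_freqs": meta["center_freqs"],
        "frame_times": meta.get("frame_times", np.array([])),
        "flatten_order": meta.get("flatten_order", "frequency_major"),
    }
    savemat(out / "dataset.mat", payload)
    np.savetxt(out / "dataset.csv", data, delimiter=",")
    np.savetxt(out / "center_freqs.csv", meta["center_freqs"], delimiter=",")


def cut_snippets(wave, frame_cfg: FrameConfig) -> list:
    """Cut a waveform into fixed-length snippets with the configured overlap.

    Snippet starts advance by (snippet_length - snippet_overlap); a trailing
    remainder shorter than one snippet is dropped. A waveform shorter than one
    snippet yields an empty list (logged, not an error).
    """
    from .synth import Waveform  # local import to avoid a cycle

    L = len(wave.samples)
    n_snip = int(round(frame_cfg.snippet_length * wave.rate))
    hop = int(round((frame_cfg.snippet_length - frame_cfg.snippet_overlap) * wave.rate))
    if L < n_snip:
        logger.info("waveform shorter than one snippet (%d < %d samples): no snippets", L, n_snip)
        return []
    starts = np.arange(0, L - n_snip + 1, hop)
    return [Waveform(wave.samples[s : s + n_snip], wave.rate) for s in starts]


def build_dataset(waves, fb_cfg: FilterbankConfig, frame_cfg: FrameConfig):
    """Cochleagram dataset from snippet waveforms: N x D matrix of unit-norm rows.

    Each snippet is transformed to an F x T cochleagram, flattened
    frequency-major to a D = F*T vector and divided by its L2 norm.  All-zero
    cochleagrams (silence) are dropped; the count is logged and returned in the
    metadata dict alongside center frequencies and frame times.
    """
    rows = []
    meta = {"n_dropped": 0, "center_freqs": fb_cfg.center_frequencies()}
    # batch equal-length snippets through the filterbank for speed
    by_key: dict[tuple[int, float], list] = {}
    for w in waves:
        by_key.setdefault((len(w.samples), w.rate), []).append(w)
    chunk = 128  # keep the (chunk, F, L) band-signal block small
    for (L, rate), group in by_key.items():
        for i in range(0, len(group), chunk):
            X = np.stack([w.samples for w in group[i : i + chunk]])
            bands = apply_filterbank(X, fb_cfg, rate)  # (n, F, L)
            vals = compress(frame_rms(bands, frame_cfg, rate))  # (n, F, T)
            n_frames = vals.shape[-1]
            w_len = int(round(frame_cfg.window * rate))
            h_len = int(round(frame_cfg.step * rate))
            meta["frame_times"] = (np.arange(n_frames) * h_len + w_len) / rate
            for v in vals:
                flat = v.ravel(order="C")
                nrm = np.linalg.norm(flat)
                if nrm == 0.0:
                    meta["n_dropped"] += 1
                    continue
                rows.append(flat / nrm)
    if meta["n_dropped"]:
        logger.info("dropped %d all-zero cochleagrams", meta["n_dropped"])
    data = np.vstack(rows) if rows else np.empty((0, 0))
    meta["flatten_order"] = "frequency_major"
    return data, meta
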