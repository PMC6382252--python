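"""Population characterization of STRFs.

Mirrors how auditory physiologists summarize receptive fields: the 2D Fourier
amplitude spectrum of an F x T STRF is its modulation transfer function, whose
peak gives the best spectral modulation (scale, cycles/octave) and best
temporal modulation (rate, Hz); populations are compared via 2D best-scale /
best-rate histograms and a chi-squared dissimilarity; individual STRFs are
summarized by excitatory and inhibitory tuning widths along frequency
(octaves) and time (ms), measured on the rectified-squared marginal profiles
at half height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModulationTuning",
    "TuningWidths",
    "ZeroSTRFError",
    "channel_octave_positions",
    "channel_octave_widths",
    "modulation_transfer",
    "scale_rate_histogram",
    "chi2_dissimilarity",
    "tuning_width",
    "tuning_widths",
    "exclude_zero_strfs",
    "halfmax_support_fraction",
    "concentration_fraction",
]


class ZeroSTRFError(ValueError):
    """Raised when an all-zero STRF is passed where tuning is undefined."""


@dataclass
class ModulationTuning:
    """Modulation transfer function with its peak location."""

    amplitudes: np.ndarray  # (n_scales, n_rates), scale >= 0, rate signed
    scales: np.ndarray  # cycles/octave, >= 0
    rates: np.ndarray  # Hz, signed (positive = upward sweep)
    best_scale: float
    best_rate: float


@dataclass
class TuningWidths:
    """Half-height tuning widths of one STRF."""

    excit_freq: float  # octaves
    inhib_freq: float  # octaves
    excit_time: float  # ms
    inhib_time: float  # ms


def channel_octave_positions(center_freqs: np.ndarray) -> np.ndarray:
    """Channel positions in octaves above the lowest center frequency."""
    cf = np.asarray(center_freqs, dtype=float)
    return np.log2(cf / cf[0])


def channel_octave_widths(center_freqs: np.ndarray) -> np.ndarray:
    """Per-channel widths in octaves (gradient of the octave positions)."""
    return np.gradient(channel_octave_positions(center_freqs))


def modulation_transfer(
    strf: np.ndarray,
    channel_octaves: np.ndarray,
    frame_step: float = 0.010,
    remove_mean: bool = False,
) -> ModulationTuning:
    """2D Fourier modulation spectrum of an F x T STRF and its peak.

    Channels are treated as uniformly spaced in log-frequency using the mean
    octave spacing of ``channel_octaves`` (the ERB scale is near-logarithmic
    over the modelled range), so the scale axis is in cycles/octave; the rate
    axis is in Hz from the frame step.  By default the raw STRF is
    transformed (no windowing; ``remove_mean`` subtracts the mean first,
    suppressing the DC component).  The amplitude spectrum is folded to
    non-negative scales with signed rates; positive rate denotes an upward
    sweep.  Argmax ties break to the smallest |rate|, then smallest scale,
    then positive rate.
    """
    strf = np.asarray(strf, dtype=float)
    F, T = strf.shape
    if F < 2 or T < 2:
        raise ValueError("STRF must be at least 2 x 2")
    if np.linalg.norm(strf) == 0.0:
        raise ZeroSTRFError("all-zero STRF has no modulation tuning")
    if remove_mean:
        strf = strf - strf.mean()
    d_oct = float(np.mean(np.diff(channel_octaves)))
    amp_full = np.abs(np.fft.fft2(strf))
    scale_f = np.fft.fftfreq(F, d=d_oct)
    rate_f = np.fft.fftfreq(T, d=frame_step)
    keep = scale_f >= 0
    scales = scale_f[keep]
    # a component g(o - v t) with v > 0 (upward sweep) lives on r = -v*scale in
    # raw FFT coordinates; flip the sign so upward sweeps get positive rates
    rates = -rate_f
    amp = amp_full[keep, :]
    order = np.argsort(rates)
    rates = rates[order]
    amp = amp[:, order]
    peak = amp.max()
    cand = np.argwhere(amp >= peak * (1.0 - 1e-12))
    keys = [(abs(rates[j]), scales[i], -np.sign(rates[j])) for i, j in cand]
    best = cand[min(range(len(cand)), key=lambda k: keys[k])]
    return ModulationTuning(
        amplitudes=amp,
        scales=scales,
        rates=rates,
        best_scale=float(scales[best[0]]),
        best_rate=float(rates[best[1]]),
    )


def scale_rate_histogram(
    points,
    rate_bin: float = 12.0,
    scale_bin: float = 0.25,
    rate_range: tuple[float, float] = (-50.0, 50.0),
    scale_range: tuple[float, float] = (0.0, 5.0),
):
    """2D histogram of (scale, rate) peaks; returns (counts, scale_edges, rate_edges).

    Points outside the ranges are clipped into the edge bins (logged), so the
    total count is conserved.
    """
    if rate_bin <= 0 or scale_bin <= 0:
        raise ValueError("bin widths must be positive")
    pts = np.asarray(list(points), dtype=float)
    scale_edges = np.arange(scale_range[0], scale_range[1] + scale_bin / 2, scale_bin)
    rate_edges = np.arange(rate_range[0], rate_range[1] + rate_bin / 2, rate_bin)
    counts = np.zeros((len(scale_edges) - 1, len(rate_edges) - 1))
    if pts.size == 0:
        return counts, scale_edges, rate_edges
    eps = 1e-9
    n_clip = int(
        np.sum(
            (pts[:, 0] < scale_edges[0])
            | (pts[:, 0] > scale_edges[-1])
            | (pts[:, 1] < rate_edges[0])
            | (pts[:, 1] > rate_edges[-1])
        )
    )
    if n_clip:
        logger.info("clipped %d points into edge bins", n_clip)
    s = np.clip(pts[:, 0], scale_edges[0], scale_edges[-1] - eps)
    r = np.clip(pts[:, 1], rate_edges[0], rate_edges[-1] - eps)
    counts, _, _ = np.histogram2d(s, r, bins=[scale_edges, rate_edges])
    return counts, scale_edges, rate_edges


def chi2_dissimilarity(h1: np.ndarray, h2: np.ndarray) -> float:
    """chi^2 = sum over cells with h1+h2 > 0 of (h1 - h2)^2 / (h1 + h2)."""
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share a shape")
    tot = a + b
    mask = tot > 0
    return float(np.sum((a[mask] - b[mask]) ** 2 / tot[mask]))


def tuning_width(
    strf: np.ndarray,
    polarity: str,
    axis: str,
    octave_widths: np.ndarray | None = None,
    frame_step: float = 0.010,
    span_mode: str = "summed",
) -> float:
    """Half-height tuning width of one polarity of an STRF along one axis.

    The requested polarity is rectified (excitatory keeps positives,
    inhibitory keeps negatives), squared element-wise and summed over the
    other axis; the width is measured on the resulting profile as the not
    necessarily contiguous span of entries >= 50% of the profile maximum.
    Frequency widths sum the octave widths of qualifying channels; temporal
    widths count qualifying bins times the frame step, in ms.  A profile with
    no energy of the requested polarity has width 0.

    ``span_mode`` controls the frequency-span reading: ``"summed"`` (default)
    adds the octave widths of qualifying channels only (non-contiguous spans
    allowed); ``"extent"`` measures from the lowest to the highest qualifying
    channel inclusive.
    """
    strf = np.asarray(strf, dtype=float)
    if polarity == "excitatory":
        r = np.maximum(strf, 0.0)
    elif polarity == "inhibitory":
        r = np.minimum(strf, 0.0)
    else:
        raise ValueError("polarity must be 'excitatory' or 'inhibitory'")
    r = r**2
    if axis == "frequency":
        profile = r.sum(axis=1)
    elif axis == "time":
        profile = r.sum(axis=0)
    else:
        raise ValueError("axis must be 'frequency' or 'time'")
    peak = profile.max()
    if peak == 0.0:
        return 0.0
    qualifying = profile >= 0.5 * peak
    if axis == "frequency":
        if octave_widths is None:
            raise ValueError("octave_widths required for frequency tuning width")
        ow = np.asarray(octave_widths, dtype=float)
        if span_mode == "summed":
            return float(np.sum(ow[qualifying]))
        if span_mode == "extent":
            idx = np.flatnonzero(qualifying)
            return float(np.sum(ow[idx[0] : idx[-1] + 1]))
        raise ValueError("span_mode must be 'summed' or 'extent'")
    return float(np.sum(qualifying) * frame_step * 1000.0)


def tuning_widths(
    strf: np.ndarray,
    octave_widths: np.ndarray,
    frame_step: float = 0.010,
) -> TuningWidths:
    """All four half-height widths of one STRF."""
    return TuningWidths(
        excit_freq=tuning_width(strf, "excitatory", "frequency", octave_widths, frame_step),
        inhib_freq=tuning_width(strf, "inhibitory", "frequency", octave_widths, frame_step),
        excit_time=tuning_width(strf, "excitatory", "time", octave_widths, frame_step),
        inhib_time=tuning_width(strf, "inhibitory", "time", octave_widths, frame_step),
    )


def exclude_zero_strfs(strfs) -> tuple[list, int]:
    """Drop STRFs whose L2 norm is (numerically) zero; returns (kept, n_excluded)."""
    kept = []
    n_excluded = 0
    for s in strfs:
        if np.linalg.norm(np.asarray(s, dtype=float)) <= 1e-15:
            n_excluded += 1
        else:
            kept.append(s)
    return kept, n_excluded


def halfmax_support_fraction(field: np.ndarray) -> float:
    """Fraction of time-frequency cells at or above half the peak magnitude.

    The analogue, over the full field, of the half-height rule used for the
    tuning widths: a field is called localized when this fraction is small
    (its half-max support occupies few cells).  Returns 1.0 for an all-zero
    field.
    """
    g = np.abs(np.asarray(field, dtype=float))
    peak = g.max()
    if peak == 0.0:
        return 1.0
    return float(np.mean(g >= 0.5 * peak))


def concentration_fraction(field: np.ndarray, energy_fraction: float = 0.9) -> float:
    """Fraction of cells needed to hold ``energy_fraction`` of squared energy.

    A localized field concentrates its energy in few time-frequency cells, so
    this fraction is small; a diffuse field approaches 1.
    """
    x = np.abs(np.asarray(field, dtype=float)).ravel() ** 2
    total = x.sum()
    if total == 0.0:
        return 1.0
    srt = np.sort(x)[::-1]
    cum = np.cumsum(srt) / total
    needed = int(np.searchsorted(cum, energy_fraction) + 1)
    return needed / x.size
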