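"""Synthetic inputs for every pipeline stage.

Three families of test material are generated here, replacing a natural-sound
corpus and animal recordings with fully seeded constructions:

* waveform mixtures of tones, chirps and band-limited noise bursts, used to
  exercise the cochleagram front-end and the log-max superposition property;
* ground-truth non-negative generative-field dictionaries (bars, blobs, or
  overlapping localized pairs) and datasets sampled from the maximal-causes
  generative model with known Bernoulli sparsity pi and Gaussian noise sigma,
  used for parameter-recovery experiments;
* the overlapping-pairs layout doubles as the construction for demonstrating
  how explaining away produces inhibitory STRF subfields from purely
  non-negative fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .cochleagram import FilterbankConfig, FrameConfig, waveform_to_cochleagram

__all__ = [
    "Waveform",
    "GroundTruthSet",
    "make_ground_truth_fields",
    "sample_mca_dataset",
    "synth_waveform",
    "logmax_demo",
    "save_waveform_wav",
    "save_ground_truth",
]


@dataclass
class Waveform:
    """A mono waveform: amplitude samples at a fixed sampling rate (Hz)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class GroundTruthSet:
    """Known generative parameters: non-negative fields, sparsity, noise scale."""

    fields: np.ndarray  # D x H
    pi: float
    sigma: float
    grid_shape: tuple[int, int] | None = None
    latent_states: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        if np.any(self.fields < 0):
            raise ValueError("generative fields must be non-negative")
        if not np.all(self.fields.max(axis=0) > 0):
            raise ValueError("every field needs at least one positive entry")
        if not (0 < self.pi < 1):
            raise ValueError("pi must lie in (0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _bump(rows: int, cols: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Smooth non-negative blob with hard (exactly zero) support outside ``radius``."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (r - center[0]) ** 2 + (c - center[1]) ** 2
    out = np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
    out[d2 > radius**2] = 0.0
    return out


def make_ground_truth_fields(
    layout: str,
    grid_shape: tuple[int, int],
    n_fields: int,
    seed: int = 0,
    pi: float = 0.2,
    sigma: float = 0.05,
) -> GroundTruthSet:
    """Construct a D x H dictionary of non-negative fields on a rows x cols grid.

    Layouts
    -------
    ``bars``
        One field per full grid row or column (value 1 on the bar); classic
        sparse-coding benchmark where any row/column pair overlaps in one cell.
    ``blobs``
        Randomly placed localized smooth bumps.
    ``overlapping_pairs``
        Localized bumps arranged so that designated pairs share support while
        at least one field (the last) is support-disjoint from all others --
        the construction used for the explaining-away demonstration.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid dimensions must be >= 2")
    if n_fields < 2:
        raise ValueError("need at least 2 fields")
    rng = np.random.default_rng(seed)
    D = rows * cols
    fields = np.zeros((D, n_fields))

    if layout == "bars":
        if n_fields > rows + cols:
            raise ValueError(f"bars layout on {rows}x{cols} grid holds at most {rows + cols} fields")
        # interleave rows and columns so small n still mixes orientations
        order: list[tuple[str, int]] = []
        for i in range(max(rows, cols)):
            if i < rows:
                order.append(("row", i))
            if i < cols:
                order.append(("col", i))
        for h, (kind, i) in enumerate(order[:n_fields]):
            g = np.zeros((rows, cols))
            if kind == "row":
                g[i, :] = 1.0
            else:
                g[:, i] = 1.0
            fields[:, h] = g.ravel()
    elif layout == "blobs":
        radius = max(min(rows, cols) / 4.0, 1.5)
        for h in range(n_fields):
            center = (rng.uniform(1, rows - 2), rng.uniform(1, cols - 2))
            fields[:, h] = _bump(rows, cols, center, radius).ravel()
    elif layout == "overlapping_pairs":
        radius = max(min(rows, cols) / 4.0, 1.5)
        # last field is a loner in the top-left corner, disjoint from the rest
        loner = _bump(rows, cols, (radius / 1.5, radius / 1.5), radius / 1.5)
        loner_support = loner > 0
        centers = []
        n_other = n_fields - 1
        # chain of bumps in the lower-right region; consecutive bumps overlap
        for h in range(n_other):
            frac = h / max(n_other - 1, 1)
            cr = rows - 1 - radius / 1.5 - frac * (rows / 2.5)
            cc = radius + frac * (cols - 1 - 2 * radius)
            centers.append((cr, cc))
        for h, center in enumerate(centers):
            g = _bump(rows, cols, center, radius)
            g[loner_support] = 0.0  # keep the loner support-disjoint
            if g.max() == 0:
                raise ValueError("grid too small for requested overlapping_pairs layout")
            fields[:, h] = g.ravel()
        fields[:, -1] = loner.ravel()
        # verify the loner really is disjoint from every other field
        others = fields[:, :-1].sum(axis=1) > 0
        assert not np.any(others & (fields[:, -1] > 0))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return GroundTruthSet(fields=fields, pi=pi, sigma=sigma, grid_shape=(rows, cols), seed=seed)


def sample_mca_dataset(gt: GroundTruthSet, n: int, seed: int = 0):
    """Sample n observations from the maximal-causes generative model.

    Each latent vector is i.i.d. Bernoulli(pi) per unit; the noiseless
    observation is the element-wise maximum of the active fields (the all-zero
    vector when no unit is active), to which isotropic Gaussian noise of scale
    sigma is added.  The noise is not truncated at zero, so observations may
    contain small negative values.  Returns ``(Y, S)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    D, H = gt.fields.shape
    S = (rng.random((n, H)) < gt.pi).astype(float)
    Y = np.empty((n, D))
    chunk = max(1, int(2e7 // (D * H)))
    for i in range(0, n, chunk):
        s = S[i : i + chunk]
        # max_h s_h W_dh: inactive units contribute 0, matching the empty-max
        # convention since W >= 0
        Y[i : i + chunk] = np.max(gt.fields[None, :, :] * s[:, None, :], axis=2)
    if gt.sigma > 0:
        Y += rng.normal(0.0, gt.sigma, size=Y.shape)
    return Y, S


def _normalize_peak(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def synth_waveform(
    components: list[dict],
    duration: float,
    rate: float = 44100.0,
    seed: int = 0,
) -> Waveform:
    """Synthesize a waveform as a linear sum of elementary components.

    Each component is a dict with a ``kind`` key:

    * ``{"kind": "tone", "freq": Hz, "amplitude": a}``
    * ``{"kind": "chirp", "f0": Hz, "f1": Hz, "amplitude": a}`` (linear sweep)
    * ``{"kind": "noise_burst", "band": (lo, hi), "window": (t0, t1), "amplitude": a}``

    Every component accepts an optional ``"window": (t0, t1)`` restricting it
    to a time interval (an acoustic event rather than a continuous source);
    windows are applied with 5 ms raised-cosine ramps so gating adds no
    clicks.  Components are peak-normalized to 1 before amplitude scaling
    and summed in the waveform domain.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    nyq = rate / 2.0
    for comp in components:
        kind = comp["kind"]
        amp = comp.get("amplitude", 1.0)
        if kind == "tone":
            f = comp["freq"]
            if f >= nyq:
                raise ValueError(f"tone frequency {f} Hz >= Nyquist {nyq} Hz")
            x = np.sin(2.0 * np.pi * f * t)
        elif kind == "chirp":
            f0, f1 = comp["f0"], comp["f1"]
            if max(f0, f1) >= nyq:
                raise ValueError("chirp endpoint frequency >= Nyquist")
            x = _signal.chirp(t, f0=f0, t1=duration, f1=f1, method="linear")
        elif kind == "noise_burst":
            lo, hi = comp["band"]
            if hi >= nyq:
                raise ValueError("noise band upper edge >= Nyquist")
            x = rng.standard_normal(n)
            sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
            x = _signal.sosfilt(sos, x)
        else:
            raise ValueError(f"unknown component kind {kind!r}")
        if "window" in comp:
            x = x * _window_envelope(t, comp["window"], rate)
        out += amp * _normalize_peak(x)
    return Waveform(out, rate)


def _window_envelope(t: np.ndarray, window, rate: float, ramp: float = 0.005) -> np.ndarray:
    """Rectangular gate with raised-cosine on/off ramps of ``ramp`` seconds."""
    t0, t1 = window
    env = np.zeros_like(t)
    inside = (t >= t0) & (t < t1)
    env[inside] = 1.0
    ramp = min(ramp, max((t1 - t0) / 2.0, 1e-6))
    rise = inside & (t < t0 + ramp)
    fall = inside & (t >= t1 - ramp)
    env[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t0) / ramp))
    env[fall] = 0.5 * (1.0 - np.cos(np.pi * (t1 - t[fall]) / ramp))
    return env


def save_waveform_wav(wave: Waveform, path) -> None:
    """Write a waveform as 32-bit float PCM WAV."""
    from scipy.io import wavfile

    wavfile.write(path, int(round(wave.rate)), wave.samples.astype(np.float32))


def save_ground_truth(gt: GroundTruthSet, out_dir, layout: str = "unknown") -> None:
    """Persist a ground-truth set as MAT + CSV plus a plain-text manifest."""
    from pathlib import Path

    from scipy.io import savemat

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    savemat(out / "ground_truth.mat", {"W": gt.fields, "pi": gt.pi, "sigma": gt.sigma})
    np.savetxt(out / "ground_truth_fields.csv", gt.fields, delimiter=",")
    D, H = gt.fields.shape
    with open(out / "manifest.txt", "w") as fh:
        fh.write(
            f"layout: {layout}\nseed: {gt.seed}\npi: {gt.pi}\nsigma: {gt.sigma}\n"
            f"H: {H}\nD: {D}\ngrid_shape: {gt.grid_shape}\n"
        )


def logmax_demo(
    w1: Waveform,
    w2: Waveform,
    fb_cfg: FilterbankConfig | None = None,
    frame_cfg: FrameConfig | None = None,
) -> dict:
    """Compare max- and sum-composition of cochleagrams against the true mixture.

    Computes the cochleagram of the summed waveforms and the element-wise max
    and sum of the two individual cochleagrams; ``err_max``/``err_sum`` are the
    mean squared deviations of each composition from the mixture cochleagram.
    For sparse sources the max is the better approximation (the log-max rule).
    """
    fb_cfg = fb_cfg or FilterbankConfig()
    frame_cfg = frame_cfg or FrameConfig()
    if len(w1.samples) != len(w2.samples) or w1.rate != w2.rate:
        raise ValueError("waveforms must share length and rate")
    mix = Waveform(w1.samples + w2.samples, w1.rate)
    c1 = waveform_to_cochleagram(w1, fb_cfg, frame_cfg).values
    c2 = waveform_to_cochleagram(w2, fb_cfg, frame_cfg).values
    c_mix = waveform_to_cochleagram(mix, fb_cfg, frame_cfg).values
    c_max = np.maximum(c1, c2)
    c_sum = c1 + c2
    return {
        "coch_mix": c_mix,
        "coch_max": c_max,
        "coch_sum": c_sum,
        "err_max": float(np.mean((c_max - c_mix) ** 2)),
        "err_sum": float(np.mean((c_sum - c_mix) ** 2)),
    }
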