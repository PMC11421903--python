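"""Mel-spectrogram feature battery and second-harmonic contour statistics.

Two complementary acoustic descriptions of each rumble:

* a 94-dimension battery summarising the distribution of energy across
  time and frequency in a mel spectrogram (gain-invariant by
  construction, so recording-level differences cannot drive
  classification); and
* the second-harmonic (f1) frequency contour — the spectral ridge that is
  most robust to recording-equipment differences — reduced to nine summary
  statistics.

Default STFT parameters follow the display settings used for rumble
spectrograms: 2 kHz sample rate, 800-sample Hann window, 90% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "StftParams",
    "MelSpectrogram",
    "F1Contour",
    "hz_to_mel",
    "mel_to_hz",
    "mel_spectrogram",
    "extract_mel_features",
    "mel_feature_names",
    "trace_f1_contour",
    "contour_stats",
    "CONTOUR_STAT_NAMES",
    "extract_features_table",
    "SilentCallError",
    "UntraceableCallError",
]


class SilentCallError(ValueError):
    """Raised for an all-zero spectrogram ('silent call')."""


class UntraceableCallError(ValueError):
    """Raised when no voiced frames can be traced ('untraceable call')."""


@dataclass(frozen=True)
class StftParams:
    sample_rate_hz: int = 2000
    window_samples: int = 800
    overlap: float = 0.9
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.window_samples * (1.0 - self.overlap))))

    @property
    def bin_hz(self) -> float:
        return self.sample_rate_hz / self.window_samples


@dataclass
class MelSpectrogram:
    """Band x frame mel-scale energies with axis metadata."""

    energies: np.ndarray  # (n_bands, n_frames), power
    band_centers_hz: np.ndarray
    band_centers_mel: np.ndarray
    frame_times: np.ndarray  # window-centre times, s
    duration_s: float


@dataclass
class F1Contour:
    """Per-frame second-harmonic frequency estimates with voicing flags."""

    freq_hz: np.ndarray  # ridge frequency per frame
    voiced: np.ndarray  # bool per frame
    frame_times: np.ndarray
    duration_s: float


def hz_to_mel(f):
    """HTK mel scale: mel = 2595 * log10(1 + f/700). Monotone; mel(0) = 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _frames(waveform: np.ndarray, stft: StftParams) -> np.ndarray:
    x = np.asarray(waveform, dtype=float)
    win, hop = stft.window_samples, stft.hop
    if x.size < win:
        raise ValueError(
            f"signal length {x.size} shorter than one window ({win} samples)"
        )
    n_frames = (x.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _power_spectrogram(waveform: np.ndarray, stft: StftParams):
    """Frame-wise |rfft|^2 with the configured window; no padding.

    Frame count = floor((N - win)/hop) + 1.
    """
    frames = _frames(waveform, stft)
    # symmetric window (fftbins=False): time-reversing a call then exactly
    # mirrors its frame magnitudes when the frames tile the signal
    w = sps.get_window(stft.window, stft.window_samples, fftbins=False)
    spec = np.abs(np.fft.rfft(frames * w, axis=1)) ** 2  # (frames, bins)
    freqs = np.fft.rfftfreq(stft.window_samples, d=1.0 / stft.sample_rate_hz)
    times = (np.arange(frames.shape[0]) * stft.hop + stft.window_samples / 2.0) / (
        stft.sample_rate_hz
    )
    return spec, freqs, times


def _mel_filterbank(
    n_bands: int, n_fft_bins: int, stft: StftParams, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_bands + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(stft.window_samples, d=1.0 / stft.sample_rate_hz)
    fb = np.zeros((n_bands, n_fft_bins))
    for b in range(n_bands):
        lo, mid, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    centers_hz = hz_pts[1:-1]
    return fb, centers_hz


def mel_spectrogram(
    waveform: np.ndarray,
    stft: StftParams | None = None,
    n_bands: int = 22,
    fmin: float = 8.0,
    fmax: float = 500.0,
) -> MelSpectrogram:
    """Power spectrogram pooled into triangular mel-spaced bands."""
    stft = stft or StftParams()
    if not fmin < fmax <= stft.sample_rate_hz / 2.0:
        raise ValueError("need fmin < fmax <= Nyquist")
    spec, _freqs, times = _power_spectrogram(waveform, stft)
    fb, centers_hz = _mel_filterbank(n_bands, spec.shape[1], stft, fmin, fmax)
    energies = fb @ spec.T  # (bands, frames)
    return MelSpectrogram(
        energies=energies,
        band_centers_hz=centers_hz,
        band_centers_mel=np.asarray(hz_to_mel(centers_hz)),
        frame_times=times,
        duration_s=len(np.asarray(waveform)) / stft.sample_rate_hz,
    )


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sd (n-1), skew, excess kurtosis; skew/kurt -> 0 when sd == 0."""
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        return m, 0.0, 0.0, 0.0
    z = (x - m) / np.std(x)  # population sd for the shape moments
    return m, sd, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def mel_feature_names(n_bands: int = 22) -> list[str]:
    names = []
    for b in range(n_bands):
        for stat in ("mean", "sd", "skew", "kurt"):
            names.append(f"melband{b + 1:02d}_{stat}")
    names += [
        "duration_s",
        "tmarg_skew",
        "centroid_mean_mel",
        "centroid_sd_mel",
        "entropy_mean",
        "entropy_sd",
    ]
    return names


def extract_mel_features(ms: MelSpectrogram) -> pd.Series:
    """94 named, gain-invariant summaries of the mel spectrogram.

    22 bands x 4 temporal moments of normalized band energy (88), plus call
    duration, the skew of the call's energy distribution over time, and the
    mean/sd over frames of the spectral centroid (mel units) and spectral
    entropy.  Energies are normalized by total call energy first, so
    scaling the waveform leaves the vector unchanged exactly.
    """
    E = np.asarray(ms.energies, dtype=float)
    if E.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    total = E.sum()
    if total <= 0.0:
        raise SilentCallError("silent call")
    En = E / total
    values: list[float] = []
    for b in range(En.shape[0]):
        values.extend(_moments(En[b]))

    values.append(float(ms.duration_s))

    frame_energy = En.sum(axis=0)  # sums to 1
    t = np.arange(En.shape[1], dtype=float)
    mu_t = float(np.sum(frame_energy * t))
    var_t = float(np.sum(frame_energy * (t - mu_t) ** 2))
    tskew = (
        float(np.sum(frame_energy * (t - mu_t) ** 3) / var_t**1.5)
        if var_t > 0
        else 0.0
    )
    values.append(tskew)

    nz = frame_energy > 0
    P = En[:, nz] / frame_energy[nz]
    centroid = ms.band_centers_mel @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(P > 0, P * np.log(P), 0.0), axis=0)
    for series in (centroid, ent):
        m, sd, _, _ = _moments(series)
        values.extend([m, sd])

    out = pd.Series(values, index=mel_feature_names(En.shape[0]), dtype=float)
    assert len(out) == 4 * En.shape[0] + 6
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("non-finite feature value")
    return out


# ---------------------------------------------------------------------------
# second-harmonic contour


def trace_f1_contour(
    waveform: np.ndarray,
    stft: StftParams | None = None,
    f1_band: tuple[float, float] = (14.0, 80.0),
    jump_penalty: float = 0.05,
    prominence_threshold: float = 5.0,
) -> F1Contour:
    """Trace the second-harmonic ridge by dynamic programming.

    The ridge maximizes summed spectral magnitude within ``f1_band`` under a
    per-frame jump cost of ``jump_penalty`` (in units of the call's maximum
    magnitude) per frequency bin.  A frame is voiced when the ridge
    magnitude exceeds ``prominence_threshold`` times the median in-band
    magnitude of that frame; if no frame is voiced the call is untraceable.
    """
    stft = stft or StftParams()
    lo, hi = f1_band
    if not 0 < lo < hi <= stft.sample_rate_hz / 2.0:
        raise ValueError("f1_band must lie within (0, Nyquist]")
    spec, freqs, times = _power_spectrogram(waveform, stft)
    mag = np.sqrt(spec)
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 2:
        raise ValueError("f1_band narrower than one frequency bin")
    M = mag[:, band]  # (frames, bins)
    band_freqs = freqs[band]
    peak = M.max()
    if peak <= 0:
        raise UntraceableCallError("untraceable call")
    Mn = M / peak
    n_frames, n_bins = Mn.shape

    # DP over ridge paths: score(t,b) = Mn[t,b] + max_b' score(t-1,b') - lam*|b-b'|
    lam = jump_penalty
    score = Mn[0].copy()
    back = np.zeros((n_frames, n_bins), dtype=int)
    bins = np.arange(n_bins)
    cost = lam * np.abs(bins[:, None] - bins[None, :])  # (b, b')
    for ti in range(1, n_frames):
        cand = score[None, :] - cost  # (b, b')
        back[ti] = np.argmax(cand, axis=1)
        score = Mn[ti] + cand[bins, back[ti]]
    path = np.zeros(n_frames, dtype=int)
    path[-1] = int(np.argmax(score))
    for ti in range(n_frames - 1, 0, -1):
        path[ti - 1] = back[ti, path[ti]]

    ridge_mag = M[np.arange(n_frames), path]
    med = np.median(M, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        prominence = np.where(med > 0, ridge_mag / med, np.inf)
    voiced = (prominence >= prominence_threshold) & (ridge_mag > 0)
    if not voiced.any():
        raise UntraceableCallError("untraceable call")
    return F1Contour(
        freq_hz=band_freqs[path],
        voiced=voiced,
        frame_times=times,
        duration_s=len(np.asarray(waveform)) / stft.sample_rate_hz,
    )


CONTOUR_STAT_NAMES = (
    "f1_mean",
    "f1_sd",
    "f1_skew",
    "f1_kurt",
    "f1_p10",
    "f1_p90",
    "f1_q25",
    "f1_q50",
    "f1_q75",
)


def contour_stats(c: F1Contour) -> pd.Series:
    """Nine summary statistics of the traced f1 contour (all Hz).

    Mean, sd, skew, excess kurtosis, 10th/90th percentile of the voiced
    values, plus the frequency at the voiced frame nearest 25/50/75% of
    total call duration.  Degenerate convention: skew and kurtosis are 0
    when the contour is constant; percentiles use linear interpolation.
    """
    v = np.asarray(c.voiced, dtype=bool)
    if v.sum() < 4:
        raise ValueError("need at least 4 voiced frames")
    f = np.asarray(c.freq_hz, dtype=float)[v]
    t = np.asarray(c.frame_times, dtype=float)[v]
    mean, sd, skew, kurt = _moments(f)
    p10, p90 = np.percentile(f, [10, 90], method="linear")
    qs = []
    for frac in (0.25, 0.50, 0.75):
        target = frac * c.duration_s
        qs.append(f[int(np.argmin(np.abs(t - target)))])
    return pd.Series(
        [mean, sd, skew, kurt, float(p10), float(p90), *map(float, qs)],
        index=list(CONTOUR_STAT_NAMES),
        dtype=float,
    )


def extract_features_table(
    waveforms: dict[str, np.ndarray],
    stft: StftParams | None = None,
    n_bands: int = 22,
    fmin: float = 8.0,
    fmax: float = 500.0,
    f1_band: tuple[float, float] = (14.0, 80.0),
) -> pd.DataFrame:
    """Per-call feature rows: call_id + 94 mel features + 9 contour stats.

    Calls whose contour cannot be traced get NaN contour statistics (they
    are later excluded from contour-based analyses).
    """
    stft = stft or StftParams()
    rows = []
    for call_id, wav in waveforms.items():
        ms = mel_spectrogram(wav, stft, n_bands=n_bands, fmin=fmin, fmax=fmax)
        feats = extract_mel_features(ms)
        try:
            cs = contour_stats(trace_f1_contour(wav, stft, f1_band=f1_band))
        except (UntraceableCallError, ValueError):
            cs = pd.Series(np.nan, index=list(CONTOUR_STAT_NAMES))
        row = pd.concat([pd.Series({"call_id": call_id}), feats, cs])
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)
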