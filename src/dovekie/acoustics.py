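"""Per-call acoustic parameter extraction.

Implements the measurement set used for the little auk repertoire:
autocorrelation fundamental-frequency tracking with octave-jump smoothing,
f0 contour statistics (min/max/mean/start/end/range, mean absolute slope,
cumulative variation), spectral energy quartiles and centre of gravity,
and amplitude-/frequency-modulation rates.

All measures are amplitude-normalized: rescaling the waveform by a constant
gain changes no feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft
from scipy import signal as sps

__all__ = [
    "F0Contour",
    "AcousticFeatureVector",
    "FeatureUndefinedError",
    "track_f0",
    "f0_statistics",
    "spectral_quartiles",
    "am_rate",
    "fm_rate",
    "extract_features",
]

# Defaults bracket the species' observed f0 (per-type means span ~600-1210 Hz).
DEFAULT_F0_FLOOR = 300.0
DEFAULT_F0_CEILING = 1600.0
DEFAULT_FRAME_S = 0.04
DEFAULT_HOP_S = 0.01
DEFAULT_VOICING_THRESHOLD = 0.45


class FeatureUndefinedError(ValueError):
    """A feature cannot be computed (e.g. too few voiced frames)."""


@dataclass
class F0Contour:
    """Frame-wise fundamental-frequency track.

    ``f0`` is NaN on unvoiced frames; ``times`` are frame centres in
    seconds and strictly increasing.
    """

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (len(self.times) == len(self.f0) == len(self.voiced)):
            raise ValueError("times, f0, voiced must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.f0[self.voiced] <= 0):
            raise ValueError("voiced frames must carry positive f0")

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


@dataclass
class AcousticFeatureVector:
    """The per-call parameter set.

    Units: Hz for frequencies, s for duration, Hz/s for slope/variation
    measures, 1/s for modulation rates.
    """

    f0_min: float
    f0_max: float
    f0_mean: float
    f0_start: float
    f0_end: float
    f0_range: float
    f0_abs_slope: float
    f0_var: float
    q25: float
    q50: float
    q75: float
    spectral_cog: float
    duration: float
    am_rate: float
    fm_rate: float
    call_id: str = ""
    call_type: str = ""
    context: str = ""

    FEATURE_NAMES = (
        "f0_min", "f0_max", "f0_mean", "f0_start", "f0_end", "f0_range",
        "f0_abs_slope", "f0_var", "q25", "q50", "q75", "spectral_cog",
        "duration", "am_rate", "fm_rate",
    )

    def __post_init__(self) -> None:
        if not (self.f0_min <= self.f0_mean <= self.f0_max):
            raise ValueError("f0 ordering violated: min <= mean <= max")
        if not np.isclose(self.f0_range, self.f0_max - self.f0_min,
                          rtol=1e-9, atol=1e-6):
            raise ValueError("f0_range must equal f0_max - f0_min")
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError("quartile ordering violated")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.am_rate < 0 or self.fm_rate < 0:
            raise ValueError("modulation rates must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FEATURE_NAMES}


def _frame_signal(x: np.ndarray, frame_len: int, hop_len: int) -> np.ndarray:
    frames = sliding_window_view(x, frame_len)[::hop_len]
    return np.ascontiguousarray(frames)


def track_f0(waveform: np.ndarray, sample_rate: int,
             floor: float = DEFAULT_F0_FLOOR,
             ceiling: float = DEFAULT_F0_CEILING,
             frame: float = DEFAULT_FRAME_S,
             hop: float = DEFAULT_HOP_S,
             voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
             n_candidates: int = 4,
             octave_cost: float = 0.25,
             octave_bias: float = 0.05) -> F0Contour:
    """Autocorrelation pitch tracking with octave-jump smoothing.

    Per frame, the windowed normalized autocorrelation is searched for
    peaks in the lag band ``[1/ceiling, 1/floor]``; peak positions are
    refined by parabolic interpolation.  Candidate salience is the peak
    autocorrelation plus ``octave_bias`` per octave above the floor, which
    resolves the near-tie between the true period and its subharmonic
    (period-doubled) peak in favour of the higher candidate.  A frame is
    voiced iff its strongest peak reaches ``voicing_threshold``.  Within
    each run of voiced frames the final path is chosen among the top
    ``n_candidates`` per frame by minimizing
    ``(1 - salience) + octave_cost * |log2(f0_i / f0_{i-1})|``, which
    suppresses octave jumps.

    An all-unvoiced contour is returned, not raised; downstream statistics
    raise :class:`FeatureUndefinedError`.
    """
    x = np.asarray(waveform, dtype=float)
    fs = sample_rate
    frame_len = int(round(frame * fs))
    hop_len = max(int(round(hop * fs)), 1)
    if len(x) < frame_len:
        raise ValueError(
            f"waveform ({len(x)} samples) shorter than one frame ({frame_len})")

    frames = _frame_signal(x, frame_len, hop_len)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop_len + frame_len / 2) / fs

    lag_min = max(int(np.floor(fs / ceiling)), 2)
    lag_max = min(int(np.ceil(fs / floor)), frame_len - 2)
    if lag_min >= lag_max:
        raise ValueError("floor/ceiling incompatible with frame length")

    win = np.hanning(frame_len)
    nfft = sfft.next_fast_len(2 * frame_len)
    fw = frames - frames.mean(axis=1, keepdims=True)
    fw *= win
    spec = np.fft.rfft(fw, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, :frame_len]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ac / ac[:, :1]
    r = np.where(np.isfinite(r), r, 0.0)

    cand_f0 = np.zeros((n_frames, n_candidates))
    cand_salience = np.full((n_frames, n_candidates), -np.inf)
    best_raw = np.zeros(n_frames)
    band = r[:, lag_min:lag_max + 1]
    interior = band[:, 1:-1]
    is_peak = (interior >= band[:, :-2]) & (interior > band[:, 2:])
    for i in range(n_frames):
        peak_lags = np.flatnonzero(is_peak[i]) + lag_min + 1
        if len(peak_lags) == 0:
            continue
        salience = (r[i, peak_lags]
                    + octave_bias * np.log2(fs / (peak_lags * floor)))
        order = np.argsort(salience)[::-1][:n_candidates]
        for j, lag in enumerate(peak_lags[order]):
            lag_ref, strength = _parabolic(r[i], lag)
            f0_cand = fs / lag_ref
            cand_f0[i, j] = f0_cand
            cand_salience[i, j] = (min(strength, 1.0)
                                   + octave_bias * np.log2(f0_cand / floor))
        best_raw[i] = min(r[i, peak_lags].max(), 1.0)

    # voicing uses the raw peak autocorrelation, not the octave-biased salience
    voiced = best_raw >= voicing_threshold
    voiced &= np.isfinite(cand_salience[:, 0])
    f0 = np.full(n_frames, np.nan)
    for start, stop in _runs(voiced):
        idx = np.arange(start, stop)
        f0[idx] = _viterbi_path(cand_f0[idx], cand_salience[idx], octave_cost)
    return F0Contour(times=times, f0=f0, voiced=voiced)


def _parabolic(r: np.ndarray, lag: int) -> tuple[float, float]:
    """Refine an autocorrelation peak by fitting a parabola to 3 points."""
    if lag <= 0 or lag >= len(r) - 1:
        return float(lag), float(r[lag])
    a, b, c = r[lag - 1], r[lag], r[lag + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(lag), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return lag + delta, float(b - 0.25 * (a - c) * delta)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of each contiguous True run."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def _viterbi_path(f0s: np.ndarray, strengths: np.ndarray,
                  octave_cost: float) -> np.ndarray:
    """Lowest-cost candidate path through one voiced run."""
    n, k = f0s.shape
    valid = np.isfinite(strengths) & (f0s > 0)
    local = np.where(valid, 1.0 - strengths, np.inf)
    cost = local[0].copy()
    back = np.zeros((n, k), dtype=int)
    logf = np.where(valid, np.log2(np.maximum(f0s, 1e-9)), np.nan)
    for i in range(1, n):
        trans = octave_cost * np.abs(logf[i][None, :] - logf[i - 1][:, None])
        trans = np.where(np.isfinite(trans), trans, np.inf)
        total = cost[:, None] + trans
        back[i] = np.argmin(total, axis=0)
        cost = np.min(total, axis=0) + local[i]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmin(cost))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return f0s[np.arange(n), path]


def f0_statistics(contour: F0Contour) -> dict[str, float]:
    """Contour summary statistics over voiced frames.

    ``f0_abs_slope`` is the mean absolute local slope |df0/dt| across
    consecutive voiced frame pairs (Hz/s); ``f0_var`` is the cumulative
    absolute f0 change divided by the voiced-span duration (Hz/s).
    """
    if contour.n_voiced < 2:
        raise FeatureUndefinedError(
            f"need >= 2 voiced frames, got {contour.n_voiced}")
    t = contour.times[contour.voiced]
    f = contour.f0[contour.voiced]
    df = np.abs(np.diff(f))
    dt = np.diff(t)
    span = t[-1] - t[0]
    return {
        "f0_min": float(f.min()),
        "f0_max": float(f.max()),
        "f0_mean": float(f.mean()),
        "f0_start": float(f[0]),
        "f0_end": float(f[-1]),
        "f0_range": float(f.max() - f.min()),
        "f0_abs_slope": float(np.mean(df / dt)),
        "f0_var": float(df.sum() / span),
    }


def spectral_quartiles(waveform: np.ndarray, sample_rate: int,
                       nperseg: int = 1024) -> dict[str, float]:
    """Spectral energy quartiles and centre of gravity of the whole call.

    Computed on the Hann-windowed mean periodogram (Welch) of the full
    call; quartile frequencies interpolate linearly between bins on the
    cumulative power distribution.
    """
    x = np.asarray(waveform, dtype=float)
    if len(x) < 16:
        raise ValueError("waveform too short for spectral statistics")
    nper = min(nperseg, len(x))
    freqs, psd = sps.welch(x, fs=sample_rate, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend=False)
    total = psd.sum()
    if total <= 0:
        raise ValueError("zero-energy waveform")
    cum = np.cumsum(psd) / total
    q25, q50, q75 = np.interp([0.25, 0.50, 0.75], cum, freqs)
    cog = float(np.sum(freqs * psd) / total)
    return {"q25": float(q25), "q50": float(q50), "q75": float(q75),
            "spectral_cog": cog}


def am_rate(waveform: np.ndarray, sample_rate: int,
            smooth_hz: float = 100.0,
            prominence_frac: float = 0.10,
            min_duration: float | None = 0.05) -> float:
    """Amplitude-modulation rate: envelope peaks per second.

    The envelope is the magnitude of the analytic signal, low-pass
    smoothed at ``smooth_hz``; peaks must exceed ``prominence_frac`` of the
    envelope maximum.  Returns 0 for a flat envelope.  ``min_duration=None``
    disables the short-call guard (used when composing full extraction,
    where sub-50 ms calls still carry a defined peak count).
    """
    x = np.asarray(waveform, dtype=float)
    fs = sample_rate
    duration = len(x) / fs
    if min_duration is not None and duration < min_duration:
        raise ValueError(f"call too short (< {min_duration} s) for AM rate")
    env = np.abs(sps.hilbert(x))
    sos = sps.butter(4, smooth_hz, btype="low", fs=fs, output="sos")
    # even-reflection padding keeps the low-pass from smearing genuine
    # peaks near the call's onset/offset decay into shoulders
    pad = min(int(0.02 * fs), len(env) - 1)
    ext = np.concatenate([env[:pad][::-1], env, env[-pad:][::-1]])
    env = sps.sosfiltfilt(sos, ext)[pad:len(ext) - pad]
    if env.max() <= 0:
        return 0.0
    peaks, _ = sps.find_peaks(env, prominence=prominence_frac * env.max())
    return float(len(peaks) / duration)


def fm_rate(contour: F0Contour) -> float:
    """Frequency-modulation rate: f0-contour inflections per second.

    Counts sign changes of the smoothed frame-to-frame f0 derivative over
    the voiced span.
    """
    if contour.n_voiced < 3:
        raise FeatureUndefinedError(
            f"need >= 3 voiced frames, got {contour.n_voiced}")
    t = contour.times[contour.voiced]
    f = contour.f0[contour.voiced]
    if len(f) >= 5:
        f = np.convolve(f, np.ones(3) / 3, mode="valid")
        t = t[1:-1]
    d = np.diff(f)
    d = d[np.abs(d) > 1e-9]
    if len(d) < 2:
        return 0.0
    changes = int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
    span = t[-1] - t[0]
    return float(changes / span) if span > 0 else 0.0


def extract_features(waveform: np.ndarray, sample_rate: int,
                     call_id: str = "", call_type: str = "", context: str = "",
                     duration: float | None = None,
                     **track_kwargs) -> AcousticFeatureVector:
    """Full per-call feature extraction.

    Composes f0 tracking, contour statistics, spectral quartiles and
    modulation-rate estimation.  ``duration`` defaults to the waveform
    length (the annotated call span when records carry one).

    For calls shorter than four default analysis frames the tracker's
    frame/hop are shrunk proportionally (never below what the longest
    period of interest needs), so sub-100 ms calls still yield enough
    voiced frames for contour statistics.
    """
    call_dur = len(waveform) / sample_rate
    frame_s = track_kwargs.pop("frame", DEFAULT_FRAME_S)
    hop_s = track_kwargs.pop("hop", DEFAULT_HOP_S)
    if call_dur < 4 * frame_s:
        fl = track_kwargs.get("floor", DEFAULT_F0_FLOOR)
        min_frame = 2.5 / fl  # >= 2.5 periods at the pitch floor
        frame_s = max(call_dur / 4, min_frame)
        hop_s = frame_s / 2
    try:
        contour = track_f0(waveform, sample_rate, frame=frame_s, hop=hop_s,
                           **track_kwargs)
        stats = f0_statistics(contour)
        quart = spectral_quartiles(waveform, sample_rate)
        am = am_rate(waveform, sample_rate, min_duration=None)
        fm = fm_rate(contour)
    except (ValueError, FeatureUndefinedError) as exc:
        raise type(exc)(f"call {call_id or '<unnamed>'}: {exc}") from exc
    if duration is None:
        duration = len(waveform) / sample_rate
    return AcousticFeatureVector(
        **stats, **quart, duration=float(duration), am_rate=am, fm_rate=fm,
        call_id=call_id, call_type=call_type, context=context)
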