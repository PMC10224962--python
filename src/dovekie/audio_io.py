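"""Audio and annotation I/O, spectrograms, and call selection.

Annotations travel as CSV with columns ``call_id, wav_path, start_s, end_s,
call_type, context, individual, quality``; call boundaries are half-open
``[start, end)`` in seconds, sample indices 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .synth import CALL_TYPES, SyntheticCorpus

__all__ = [
    "CallRecord",
    "Spectrogram",
    "read_call",
    "write_wav",
    "spectrogram",
    "estimate_snr",
    "select_calls",
    "write_corpus",
]

ANNOTATION_COLUMNS = ("call_id", "wav_path", "start_s", "end_s", "call_type",
                      "context", "individual", "quality")


@dataclass
class CallRecord:
    """One call: waveform (optional if features were precomputed) plus its
    annotation metadata."""

    call_id: str
    call_type: str
    waveform: np.ndarray | None = None
    sample_rate: int | None = None
    context: str = ""
    quality: str = "high"
    source_individual: str | None = None
    start_s: float | None = None
    end_s: float | None = None
    snr_db: float | None = None
    features: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(
                f"unknown call_type {self.call_type!r}; expected one of {CALL_TYPES}")
        if self.quality not in ("high", "low"):
            raise ValueError(f"quality must be 'high' or 'low', got {self.quality!r}")


@dataclass
class Spectrogram:
    """dB-magnitude spectrogram (relative to the grid maximum)."""

    times: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray  # dB, shape (n_freqs, n_times)
    window: str
    fft_length: int
    power: np.ndarray = field(repr=False, default=None)  # linear |X|^2 grid
    window_norm: float = 1.0  # mean squared window value

    def __post_init__(self) -> None:
        if self.magnitude.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("magnitude grid inconsistent with axes")

    def energy(self) -> float:
        """Waveform-energy estimate from the linear power grid (Parseval)."""
        return float(self.power.sum() / self.window_norm)


def _to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype.kind == "f":
        return data.astype(float)
    info = np.iinfo(data.dtype)
    scale = max(abs(info.min), info.max)
    return data.astype(float) / scale


def read_call(wav_path: str | Path, annotation_row: Mapping) -> CallRecord:
    """Read one annotated call from a WAV file.

    Stereo files are downmixed to mono by channel mean; the native sample
    rate is preserved.  The annotated ``[start_s, end_s)`` span is cut out
    when present, otherwise the whole file is the call.
    """
    fs, data = wavfile.read(str(wav_path))
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        x = x.mean(axis=1)
    row = dict(annotation_row)
    start = row.get("start_s")
    end = row.get("end_s")
    if start is not None and end is not None and not pd.isna(start):
        i0, i1 = int(round(float(start) * fs)), int(round(float(end) * fs))
        seg = x[i0:i1]
    else:
        seg, start, end = x, 0.0, len(x) / fs
    return CallRecord(
        call_id=str(row.get("call_id", Path(wav_path).stem)),
        call_type=str(row["call_type"]),
        waveform=seg,
        sample_rate=int(fs),
        context=str(row.get("context", "") or ""),
        quality=str(row.get("quality", "high") or "high"),
        source_individual=(str(row["individual"])
                           if row.get("individual") not in (None, "") else None),
        start_s=float(start),
        end_s=float(end),
    )


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write mono 16-bit PCM."""
    x = np.asarray(waveform, dtype=float)
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    wavfile.write(str(path), sample_rate, (x * 32767).astype(np.int16))


def spectrogram(waveform: np.ndarray, sample_rate: int, window: str = "hann",
                fft_length: int = 715, hop: int | None = None) -> Spectrogram:
    """Short-time magnitude spectrogram.

    The analysis window is ``fft_length`` samples (as used for the visual
    call-type classification: Hann, 715 samples); the FFT itself is
    zero-padded to the next power of two for speed, which changes only the
    frequency-grid density, not the spectral content.  Default hop is half
    the window.
    """
    x = np.asarray(waveform, dtype=float)
    if fft_length < 16:
        raise ValueError("fft_length must be >= 16")
    if len(x) < fft_length:
        raise ValueError("waveform shorter than one analysis window")
    if hop is None:
        hop = fft_length // 2
    nfft = 1 << (fft_length - 1).bit_length()
    win = sps.get_window(window, fft_length)
    starts = np.arange(0, len(x) - fft_length + 1, hop)
    frames = np.stack([x[s:s + fft_length] * win for s in starts])
    spec = np.fft.rfft(frames, nfft, axis=1)
    power = (np.abs(spec) ** 2).T / nfft
    # one-sided: double interior bins so the grid sums to the frame energy
    power[1:-1] *= 2 if nfft % 2 == 0 else 1
    freqs = np.fft.rfftfreq(nfft, 1 / sample_rate)
    times = (starts + fft_length / 2) / sample_rate
    ref = power.max()
    floor_db = -100.0
    with np.errstate(divide="ignore"):
        mag = 10 * np.log10(np.maximum(power / ref if ref > 0 else power + 1.0,
                                       10 ** (floor_db / 10)))
    return Spectrogram(times=times, frequencies=freqs, magnitude=mag,
                       window=window, fft_length=fft_length, power=power,
                       window_norm=float(np.mean(win ** 2)))


def estimate_snr(audio: np.ndarray, sample_rate: int, start_s: float,
                 end_s: float, band: tuple[float, float] = (300.0, 8000.0),
                 flank_s: float = 0.1) -> float | None:
    """Signal-to-noise estimate in dB for an annotated call span.

    Call-band (default 300-8000 Hz) RMS over ``[start_s, end_s)`` divided
    by the same band's RMS over the flanking ``flank_s`` of audio on each
    side.  Returns None when no flanking audio exists.
    """
    fs = sample_rate
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, np.asarray(audio, dtype=float))
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    call = xb[i0:i1]
    nflank = int(round(flank_s * fs))
    flanks = np.concatenate([xb[max(i0 - nflank, 0):i0], xb[i1:i1 + nflank]])
    if len(call) == 0 or len(flanks) == 0:
        return None
    noise_rms = np.sqrt(np.mean(flanks ** 2))
    call_rms = np.sqrt(np.mean(call ** 2))
    if noise_rms == 0:
        return np.inf
    return float(20 * np.log10(call_rms / noise_rms)) if call_rms > 0 else -np.inf


def select_calls(records: Iterable[CallRecord], n_per_type: int = 30,
                 max_repeat_per_individual: int = 1) -> list[CallRecord]:
    """Apply the high-quality call-selection filter.

    Per call type, keep the ``n_per_type`` highest-SNR high-quality calls,
    preferring distinct source individuals; an individual is re-sampled
    (up to ``max_repeat_per_individual`` extra calls) only once distinct
    individuals are exhausted — mirroring the handling-call situation where
    21 recorded individuals forced nine to be sampled twice.  Records
    without an SNR estimate rank below those with one; all ties break by
    ``call_id`` so selection is deterministic.
    """
    if n_per_type < 0:
        raise ValueError("n_per_type must be >= 0")
    by_type: dict[str, list[CallRecord]] = {}
    for rec in records:
        by_type.setdefault(rec.call_type, []).append(rec)
    selected: list[CallRecord] = []
    for ct in sorted(by_type):
        cands = [r for r in by_type[ct] if r.quality == "high"]
        cands.sort(key=lambda r: (-(r.snr_db if r.snr_db is not None else -np.inf),
                                  r.call_id))
        chosen: list[CallRecord] = []
        used: dict[str, int] = {}
        # pass 1: best call of each distinct individual
        for r in cands:
            if len(chosen) >= n_per_type:
                break
            key = r.source_individual
            if key is not None and used.get(key, 0) >= 1:
                continue
            chosen.append(r)
            if key is not None:
                used[key] = used.get(key, 0) + 1
        # pass 2: allow limited reuse once individuals are exhausted
        if len(chosen) < n_per_type:
            chosen_ids = {r.call_id for r in chosen}
            for r in cands:
                if len(chosen) >= n_per_type:
                    break
                if r.call_id in chosen_ids:
                    continue
                key = r.source_individual
                if key is not None and used.get(key, 0) > max_repeat_per_individual:
                    continue
                chosen.append(r)
                if key is not None:
                    used[key] = used.get(key, 0) + 1
        if len(chosen) < n_per_type:
            warnings.warn(
                f"call type {ct!r}: only {len(chosen)} qualifying calls "
                f"(requested {n_per_type})", stacklevel=2)
        chosen.sort(key=lambda r: r.call_id)
        selected.extend(chosen)
    return selected


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> Path:
    """Write a synthetic corpus as WAV files plus a CSV manifest.

    Returns the manifest path.  Manifest columns: call_id, call_type,
    wav_path, and one column per ground-truth feature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for call in corpus.calls:
        wav_path = out / f"{call.call_id}.wav"
        write_wav(wav_path, call.waveform, call.sample_rate)
        row = {"call_id": call.call_id, "call_type": call.call_type,
               "wav_path": wav_path.name}
        row.update({f"truth_{k}": v for k, v in call.truth.items()})
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
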