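"""Audio frontend and unit conversions.

Provides the cent <-> Hz conversions used throughout the package, the
:class:`PitchTrace` container for time-stamped f0 annotations, excerpt
selection (time window + pitch band) and a YIN fundamental-frequency
tracker for monophonic WAV input.

All pitch analysis downstream is carried out in cents, where 100 cents is
one equal-tempered semitone and 1200 cents is one octave.  Cent values are
referenced to a fixed low frequency (MIDI note 0 by default); only
*relative* cent values matter downstream because every song is eventually
re-referenced to its tonic pitch-class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIDI0_HZ",
    "PitchTrace",
    "CentAnnotationSet",
    "hz_to_cents",
    "cents_to_hz",
    "yin_f0",
    "select_excerpt",
    "read_pitch_csv",
    "write_pitch_csv",
    "read_wav",
]

#: Default cent reference: MIDI note 0 (C-1), 440 * 2**(-69/12) Hz.
MIDI0_HZ = 440.0 * 2.0 ** (-69.0 / 12.0)


def hz_to_cents(f0, ref: float = MIDI0_HZ):
    """Convert frequency in Hz to cents above ``ref``.

    cents = 1200 * log2(f0 / ref).  Both arguments must be positive.
    """
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0) or ref <= 0:
        raise ValueError("frequencies must be positive for cent conversion")
    out = 1200.0 * np.log2(f0 / ref)
    return float(out) if out.ndim == 0 else out


def cents_to_hz(cents, ref: float = MIDI0_HZ):
    """Inverse of :func:`hz_to_cents`."""
    if ref <= 0:
        raise ValueError("reference frequency must be positive")
    cents = np.asarray(cents, dtype=float)
    out = ref * 2.0 ** (cents / 1200.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class PitchTrace:
    """Time-stamped f0 annotations for one recording or excerpt.

    Parameters
    ----------
    times : array of float
        Annotation times in seconds, strictly increasing.
    f0_hz : array of float
        Fundamental-frequency estimates in Hz; NaN where unvoiced.
    voiced : array of bool, optional
        Voicing flags.  Defaults to ``isfinite(f0_hz)``.
    source_id : str
        Label of the originating recording.
    frame_rate : float or None
        Annotations per second (None for irregular annotation streams).
    """

    times: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray | None = None
    source_id: str = ""
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        if self.voiced is None:
            self.voiced = np.isfinite(self.f0_hz)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if self.times.shape != self.f0_hz.shape or self.times.shape != self.voiced.shape:
            raise ValueError("times, f0_hz and voiced must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("annotation times must be strictly increasing")
        if np.any(self.f0_hz[self.voiced] <= 0) or np.any(
            ~np.isfinite(self.f0_hz[self.voiced])
        ):
            raise ValueError("voiced annotations must carry a positive finite f0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass
class CentAnnotationSet:
    """Voiced pitch annotations of one excerpt, in cents above ``ref_hz``."""

    cents: np.ndarray
    ref_hz: float = MIDI0_HZ
    window: tuple[float, float] | None = None
    times: np.ndarray | None = field(default=None, repr=False)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.cents = np.asarray(self.cents, dtype=float)
        if not np.all(np.isfinite(self.cents)):
            raise ValueError("cent annotations must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.cents.shape:
                raise ValueError("times must match cents in length")

    def __len__(self) -> int:
        return int(self.cents.size)

    def to_trace(self) -> PitchTrace:
        """Render back to a :class:`PitchTrace` (all annotations voiced)."""
        times = (
            self.times
            if self.times is not None
            else np.arange(len(self), dtype=float)
        )
        return PitchTrace(
            times=times,
            f0_hz=cents_to_hz(self.cents, self.ref_hz),
            source_id=self.source_id,
        )


def select_excerpt(
    trace: PitchTrace,
    window: tuple[float, float] | None = None,
    pitch_band: tuple[float, float] | None = None,
    ref_hz: float = MIDI0_HZ,
) -> CentAnnotationSet:
    """Select the melodic excerpt of a trace and convert it to cents.

    Keeps voiced annotations inside the time ``window`` (seconds, inclusive)
    and the ``pitch_band`` (Hz, inclusive), emulating the manual
    time/pitch selection performed on an annotations visualizer.

    Raises
    ------
    ValueError
        If the selection is empty (the offending window is named).
    """
    if len(trace) == 0:
        raise ValueError("cannot select an excerpt from an empty trace")
    keep = trace.voiced.copy()
    if window is not None:
        t0, t1 = float(window[0]), float(window[1])
        if t1 <= t0:
            raise ValueError(f"window {window} is empty or reversed")
        keep &= (trace.times >= t0) & (trace.times <= t1)
    if pitch_band is not None:
        lo, hi = float(pitch_band[0]), float(pitch_band[1])
        with np.errstate(invalid="ignore"):
            keep &= (trace.f0_hz >= lo) & (trace.f0_hz <= hi)
    if not np.any(keep):
        raise ValueError(
            f"empty selection for window={window}, pitch_band={pitch_band} "
            f"on trace {trace.source_id!r}"
        )
    w = window if window is not None else (float(trace.times[0]), float(trace.times[-1]))
    return CentAnnotationSet(
        cents=hz_to_cents(trace.f0_hz[keep], ref_hz),
        ref_hz=ref_hz,
        window=(float(w[0]), float(w[1])),
        times=trace.times[keep],
        source_id=trace.source_id,
    )


# ---------------------------------------------------------------------------
# YIN fundamental-frequency tracking
# ---------------------------------------------------------------------------

def _difference_function(frame: np.ndarray, max_tau: int) -> np.ndarray:
    # d(tau) = sum_j (x_j - x_{j+tau})^2 over a fixed integration window W,
    # computed via FFT cross-correlation for speed.
    w = max_tau
    x = frame
    # energy terms
    sq = x * x
    cum = np.concatenate(([0.0], np.cumsum(sq)))
    e0 = cum[w] - cum[0]                      # energy of x[0:w], constant
    taus = np.arange(max_tau + 1)
    e_tau = cum[taus + w] - cum[taus]         # energy of x[tau:tau+w]
    # cross terms r(tau) = sum_j x_j x_{j+tau}, j = 0..w-1
    n = len(x)
    size = 1
    while size < 2 * n:
        size *= 2
    fx = np.fft.rfft(x, size)
    fw = np.fft.rfft(x[:w], size)
    acf = np.fft.irfft(fx * np.conj(fw), size)[: max_tau + 1]
    return e0 + e_tau - 2.0 * acf


def _cmndf(d: np.ndarray) -> np.ndarray:
    # cumulative-mean-normalized difference; d'(0) = 1 by definition
    out = np.ones_like(d)
    csum = np.cumsum(d[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1:] = d[1:] * np.arange(1, len(d)) / csum
    out[~np.isfinite(out)] = 1.0
    return out


def _parabolic_min(d: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(d) - 1:
        return float(i)
    a, b, c = d[i - 1], d[i], d[i + 1]
    denom = a - 2.0 * b + c
    if denom <= 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


def yin_f0(
    audio: np.ndarray,
    sample_rate: int,
    frame_size: int = 2048,
    hop: int = 256,
    threshold: float = 0.15,
    source_id: str = "",
) -> PitchTrace:
    """Track the fundamental frequency of monophonic audio with YIN.

    Standard recipe: squared difference function per frame, cumulative-mean
    normalization, absolute threshold for lag selection, parabolic
    interpolation of the minimum for sub-sample precision.  Frames whose
    normalized minimum exceeds ``threshold`` are flagged unvoiced.
    Annotation times are frame centers.

    Parameters
    ----------
    audio : 1-D array
        Mono PCM samples (any float or int scale; only shape matters).
    sample_rate : int
        Samples per second, at least 8000.
    frame_size : int
        Analysis frame length; must contain two periods of the lowest
        expected f0 (lag search extends to ``frame_size // 2``).
    hop : int
        Hop between successive frames, in samples.
    threshold : float
        CMNDF absolute threshold (dimensionless), standard value 0.1-0.2.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("yin_f0 expects mono audio; downmix stereo first")
    if audio.size == 0:
        raise ValueError("empty audio")
    if sample_rate < 8000:
        raise ValueError("sample rate must be >= 8 kHz")
    if audio.size < frame_size:
        raise ValueError("audio shorter than one analysis frame")

    max_tau = frame_size // 2
    starts = np.arange(0, audio.size - frame_size + 1, hop)
    times = (starts + frame_size / 2.0) / sample_rate
    f0 = np.full(starts.size, np.nan)
    voiced = np.zeros(starts.size, dtype=bool)

    for k, s in enumerate(starts):
        frame = audio[s : s + frame_size]
        d = _difference_function(frame, max_tau)
        dn = _cmndf(d)
        # first lag dipping below threshold; descend to its local minimum
        below = np.flatnonzero(dn[2:] < threshold)
        if below.size:
            tau = int(below[0]) + 2
            while tau + 1 < len(dn) and dn[tau + 1] < dn[tau]:
                tau += 1
        else:
            tau = int(np.argmin(dn[2:])) + 2
        if dn[tau] >= threshold:
            continue  # unvoiced
        tau_star = _parabolic_min(d, tau)
        if tau_star <= 0:
            continue
        voiced[k] = True
        f0[k] = sample_rate / tau_star

    return PitchTrace(
        times=times,
        f0_hz=f0,
        voiced=voiced,
        source_id=source_id,
        frame_rate=sample_rate / hop,
    )


# ---------------------------------------------------------------------------
# I/O: Tarsos-style pitch-trace CSV and WAV
# ---------------------------------------------------------------------------

def read_pitch_csv(path, source_id: str | None = None) -> PitchTrace:
    """Read a ``time_s,f0_hz`` pitch-trace CSV (header required).

    Comment lines starting with ``#`` are tolerated; every row is a voiced
    annotation, matching Tarsos-style exports.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "f0_hz"):
        if col not in df.columns:
            raise ValueError(f"pitch-trace CSV {path} lacks required column {col!r}")
    if source_id is None:
        import os

        source_id = os.path.splitext(os.path.basename(str(path)))[0]
    return PitchTrace(
        times=df["time_s"].to_numpy(float),
        f0_hz=df["f0_hz"].to_numpy(float),
        source_id=source_id,
    )


def write_pitch_csv(trace: PitchTrace, path) -> None:
    """Write the voiced annotations of a trace as ``time_s,f0_hz`` CSV."""
    import pandas as pd

    m = trace.voiced
    pd.DataFrame({"time_s": trace.times[m], "f0_hz": trace.f0_hz[m]}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as float samples in [-1, 1] plus sample rate.

    Multi-channel input is downmixed to mono with a warning.
    """
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: downmixing {data.shape[1]} channels to mono")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(sr)
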