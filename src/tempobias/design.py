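"""Stimulus and trial design: tempo grid, pitch ladder, constrained
randomization, and additive synthesis of the complex-tone stimuli.

The experimental session presents, on every trial, five metronome ticks at a
fixed reference interval followed by five repetitions of a tone whose pitch,
interonset interval (IOI), and loudness vary across trials.  This module
reproduces that design: a log-spaced IOI grid binned into tempo-range
quintiles, a 12-tone-equal-temperament pitch ladder, block randomization under
adjacency and balance constraints, and rendering of trial audio to WAV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationFailureError, InvalidArgumentError

__all__ = [
    "TempoGrid",
    "PitchSet",
    "TrialPlan",
    "ToneSpec",
    "log_spaced_iois",
    "ioi_to_bpm",
    "pitch_frequency",
    "tempo_range_bins",
    "randomize_trials",
    "synthesize_tone",
    "render_trial_audio",
    "write_wav",
    "read_wav",
    "DEFAULT_PITCH_LABELS",
    "REF_IOI_MS",
]

#: Reference (metronome) interonset interval in milliseconds.
REF_IOI_MS = 550

#: The six-octave ladder used in the five-octave-range experiments.
DEFAULT_PITCH_LABELS = ("A2", "A3", "A4", "A5", "A6", "A7")

_NOTE_RE = re.compile(r"^([A-Ga-g])([#b]?)(-?\d+)$")

# Semitone offset of each letter name from A within the same octave
# (octave numbers increment at C, scientific pitch notation).
_LETTER_TO_SEMITONE = {"C": -9, "D": -7, "E": -5, "F": -4, "G": -2, "A": 0, "B": 2}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class TempoGrid:
    """A geometric ladder of interonset intervals.

    Attributes
    ----------
    iois_ms : tuple of int
        Intervals in milliseconds, strictly non-increasing, rounded to the
        nearest millisecond.
    bpm : tuple of float
        Tempos in beats per minute computed from the rounded intervals and
        reported to one decimal.
    ref_ioi_ms : int
        The metronome interval.
    unrounded_ms : tuple of float
        The pre-rounding geometric sequence (kept for invariant checks).
    """

    iois_ms: tuple
    bpm: tuple
    ref_ioi_ms: int
    unrounded_ms: tuple = field(repr=False, default=())

    def __len__(self) -> int:
        return len(self.iois_ms)


@dataclass(frozen=True)
class PitchSet:
    """An equally spaced pitch ladder with integer codes for regression."""

    labels: tuple
    codes: tuple
    f0_hz: tuple

    @classmethod
    def from_labels(cls, labels: Sequence[str], codes: Sequence[int] | None = None) -> "PitchSet":
        if codes is None:
            codes = range(2, 2 + len(labels))
        codes = tuple(int(c) for c in codes)
        if list(codes) != list(range(codes[0], codes[0] + len(codes))):
            raise InvalidArgumentError("pitch codes must be consecutive integers")
        return cls(
            labels=tuple(labels),
            codes=codes,
            f0_hz=tuple(pitch_frequency(lab) for lab in labels),
        )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TrialPlan:
    """An ordered, constraint-satisfying sequence of trials.

    ``trials`` rows are dicts with keys ``block``, ``trial``, ``pitch_label``,
    ``pitch_code``, ``f0_hz``, ``ioi_ms``, ``loudness_db``.
    """

    trials: tuple
    seed: int | None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.trials))


@dataclass(frozen=True)
class ToneSpec:
    """Recipe for a synthetic complex tone: four harmonic partials with a
    -6 dB/octave rolloff and a linear rise/sustain/decay envelope."""

    f0_hz: float
    duration_ms: float = 200.0
    n_partials: int = 4
    rolloff_db_per_octave: float = -6.0
    rise_ms: float = 5.0
    sustain_ms: float = 170.0
    decay_ms: float = 25.0
    sample_rate_hz: int = 44100
    peak: float = 0.5

    def __post_init__(self):
        total = self.rise_ms + self.sustain_ms + self.decay_ms
        if abs(total - self.duration_ms) > 1e-9:
            raise InvalidArgumentError(
                f"envelope segments sum to {total} ms, expected {self.duration_ms} ms"
            )
        if self.f0_hz <= 0:
            raise InvalidArgumentError("fundamental frequency must be positive")


def log_spaced_iois(
    max_ioi_ms: float, min_ioi_ms: float, n: int, ref_ioi_ms: int | None = None
) -> TempoGrid:
    """Build ``n`` geometrically spaced IOIs between the endpoints inclusive.

    Intervals are rounded to the nearest millisecond (half away from zero);
    BPM is computed as 60000 / rounded IOI and reported to one decimal.
    """
    if min_ioi_ms <= 0 or max_ioi_ms <= 0:
        raise InvalidArgumentError("IOI endpoints must be positive")
    if max_ioi_ms < min_ioi_ms:
        raise InvalidArgumentError("max_ioi_ms must be >= min_ioi_ms")
    if n < 2 and max_ioi_ms != min_ioi_ms:
        raise InvalidArgumentError("n must be >= 2")
    raw = np.geomspace(max_ioi_ms, min_ioi_ms, int(n))
    iois = _round_half_away(raw).astype(int)
    bpm = np.round(60000.0 / iois, 1)
    if ref_ioi_ms is None:
        ref_ioi_ms = int(iois[len(iois) // 2])
    return TempoGrid(
        iois_ms=tuple(int(v) for v in iois),
        bpm=tuple(float(v) for v in bpm),
        ref_ioi_ms=int(ref_ioi_ms),
        unrounded_ms=tuple(float(v) for v in raw),
    )


def ioi_to_bpm(ioi_ms: float) -> float:
    """Tempo in beats per minute for an interonset interval in ms."""
    if ioi_ms <= 0:
        raise InvalidArgumentError("interonset interval must be positive")
    return 60000.0 / ioi_ms


def pitch_frequency(note: "str | float") -> float:
    """Fundamental frequency (Hz) of a note label or a semitone offset.

    Uses 12-tone equal temperament anchored at A4 = 440 Hz.  Accepts either a
    scientific-pitch label (``"A4"``, ``"D#5"``, ``"Bb3"``) or a numeric
    semitone offset from A4.
    """
    if isinstance(note, str):
        m = _NOTE_RE.match(note.strip())
        if m is None:
            raise InvalidArgumentError(f"unparseable note label: {note!r}")
        letter, accidental, octave = m.groups()
        semis = _LETTER_TO_SEMITONE[letter.upper()]
        semis += {"#": 1, "b": -1, "": 0}[accidental]
        semis += (int(octave) - 4) * 12
    else:
        semis = float(note)
    return 440.0 * 2.0 ** (semis / 12.0)


def tempo_range_bins(grid: TempoGrid, n_bins: int = 5) -> Mapping[int, int]:
    """Assign each IOI of the grid to a tempo-range quintile.

    Returns a mapping from IOI (ms) to bin index, 0 = slowest (longest IOIs).
    """
    n = len(grid)
    if n_bins <= 0 or n % n_bins != 0:
        raise InvalidArgumentError(f"{n} IOIs not divisible into {n_bins} bins")
    size = n // n_bins
    iois = sorted(grid.iois_ms, reverse=True)
    return {ioi: i // size for i, ioi in enumerate(iois)}


def _order_block(
    pairs: list, rng: np.random.Generator, max_attempts: int
) -> list:
    """Order (pitch, bin) pairs so consecutive trials differ in both.

    Greedy sequential sampling with restart on dead ends.
    """
    for _ in range(max_attempts):
        remaining = list(pairs)
        rng.shuffle(remaining)
        seq = []
        dead = False
        while remaining:
            if seq:
                cands = [
                    i
                    for i, (p, b) in enumerate(remaining)
                    if p != seq[-1][0] and b != seq[-1][1]
                ]
            else:
                cands = list(range(len(remaining)))
            if not cands:
                dead = True
                break
            seq.append(remaining.pop(cands[rng.integers(len(cands))]))
        if not dead:
            return seq
    raise GenerationFailureError(
        f"could not satisfy adjacency constraints in {max_attempts} attempts"
    )


def randomize_trials(
    pitch_set: PitchSet,
    grid: TempoGrid,
    n_blocks: int = 3,
    seed: int | None = None,
    loudness_db: Sequence[float] = (-3.0, 0.0, 3.0),
    n_bins: int = 5,
    max_attempts: int = 10000,
    shuffle_order: bool = True,
) -> TrialPlan:
    """Generate a constrained random trial sequence.

    Within each block every pitch appears once per tempo-range bin;
    consecutive trials differ in both pitch and tempo range; across the
    ``n_blocks`` presentations of each pitch x bin pair, each loudness offset
    and each IOI of the bin occurs exactly once.  ``shuffle_order=False``
    skips the adjacency shuffle (useful for fast simulation where trial order
    is irrelevant) while preserving all balance properties.
    """
    bins = tempo_range_bins(grid, n_bins)
    bin_size = len(grid) // n_bins
    if n_blocks != bin_size or n_blocks != len(loudness_db):
        raise InvalidArgumentError(
            "n_blocks must equal both the bin size and the loudness-level count"
        )
    rng = np.random.default_rng(seed)
    by_bin: dict = {}
    for ioi, b in bins.items():
        by_bin.setdefault(b, []).append(ioi)
    for b in by_bin:
        by_bin[b] = sorted(by_bin[b], reverse=True)

    # For each pitch x bin cell, an independent permutation of IOIs and of
    # loudness offsets across blocks enforces the balance invariants.
    assignment = {}
    for code in pitch_set.codes:
        for b in range(n_bins):
            iois = list(rng.permutation(by_bin[b]))
            louds = list(rng.permutation(np.asarray(loudness_db, dtype=float)))
            assignment[(code, b)] = (iois, louds)

    label_of = dict(zip(pitch_set.codes, pitch_set.labels))
    f0_of = dict(zip(pitch_set.codes, pitch_set.f0_hz))
    pairs = [(code, b) for code in pitch_set.codes for b in range(n_bins)]
    rows = []
    trial_no = 0
    for block in range(n_blocks):
        if shuffle_order:
            ordered = _order_block(pairs, rng, max_attempts)
        else:
            ordered = list(pairs)
        for code, b in ordered:
            iois, louds = assignment[(code, b)]
            rows.append(
                {
                    "block": block,
                    "trial": trial_no,
                    "pitch_label": label_of[code],
                    "pitch_code": code,
                    "f0_hz": f0_of[code],
                    "ioi_ms": int(iois[block]),
                    "loudness_db": float(louds[block]),
                }
            )
            trial_no += 1
    return TrialPlan(trials=tuple(rows), seed=seed)


def synthesize_tone(spec: ToneSpec, seed: int | None = None) -> np.ndarray:
    """Render a complex tone by summing harmonic partials with random phase.

    Partial k (k = 1..n_partials) sits at k*f0 with amplitude
    10^(rolloff * log2(k) / 20); a linear rise/sustain/decay envelope is
    applied and the waveform is normalized to ``spec.peak``.
    """
    rate = spec.sample_rate_hz
    top = spec.n_partials * spec.f0_hz
    if top >= rate / 2:
        raise InvalidArgumentError(
            f"highest partial {top} Hz at or above Nyquist ({rate / 2} Hz)"
        )
    n = int(round(spec.duration_ms * rate / 1000.0))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    wave = np.zeros(n)
    for k in range(1, spec.n_partials + 1):
        amp = 10.0 ** (spec.rolloff_db_per_octave * np.log2(k) / 20.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave += amp * np.sin(2.0 * np.pi * k * spec.f0_hz * t + phase)

    env = np.ones(n)
    n_rise = int(round(spec.rise_ms * rate / 1000.0))
    n_decay = int(round(spec.decay_ms * rate / 1000.0))
    if n_rise > 0:
        env[:n_rise] = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    if n_decay > 0:
        env[-n_decay:] = np.linspace(1.0, 0.0, n_decay)
    # force exact zero endpoints
    env[0] = 0.0
    env[-1] = 0.0
    wave *= env
    m = np.max(np.abs(wave))
    if m > 0:
        wave *= spec.peak / m
    return wave


def render_trial_audio(
    ioi_ms: float,
    tone_spec: ToneSpec,
    metronome_spec: ToneSpec | None = None,
    ref_ioi_ms: float = REF_IOI_MS,
    gap_ms: float = 1800.0,
    n_events: int = 5,
    loudness_db: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render one trial: metronome ticks, a silent gap, then repeating tones.

    ``n_events`` metronome onsets at ``ref_ioi_ms``, then ``gap_ms`` of
    silence measured from the end of the final tick, then ``n_events`` tone
    onsets at ``ioi_ms``.  The trial's loudness offset is applied as an exact
    scalar gain on the tone.
    """
    if metronome_spec is None:
        # short, high, bright tick standing in for the wood-block sound
        metronome_spec = ToneSpec(
            f0_hz=1000.0, duration_ms=50.0, rise_ms=1.0, sustain_ms=39.0, decay_ms=10.0,
            sample_rate_hz=tone_spec.sample_rate_hz,
        )
    if metronome_spec.sample_rate_hz != tone_spec.sample_rate_hz:
        raise InvalidArgumentError("tick and tone sample rates must match")
    rate = tone_spec.sample_rate_hz
    rng = np.random.default_rng(seed)
    tick = synthesize_tone(metronome_spec, seed=rng.integers(2**32))
    tone = synthesize_tone(tone_spec, seed=rng.integers(2**32))
    tone = tone * 10.0 ** (loudness_db / 20.0)

    def samples(ms: float) -> int:
        return int(round(ms * rate / 1000.0))

    gap_start = samples((n_events - 1) * ref_ioi_ms + metronome_spec.duration_ms)
    first_tone = gap_start + samples(gap_ms)
    total = first_tone + samples((n_events - 1) * ioi_ms) + len(tone)
    out = np.zeros(total)
    for i in range(n_events):
        s = samples(i * ref_ioi_ms)
        out[s : s + len(tick)] += tick
    for i in range(n_events):
        s = first_tone + samples(i * ioi_ms)
        out[s : s + len(tone)] += tone
    return out


def write_wav(path, samples: np.ndarray, sample_rate_hz: int = 44100) -> None:
    """Write mono 16-bit PCM WAV, clipping to [-1, 1]."""
    from scipy.io import wavfile

    clipped = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (clipped * 32767.0).astype(np.int16))


def read_wav(path):
    """Read a WAV written by :func:`write_wav`; returns (rate, float samples)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    return rate, data.astype(np.float64) / 32767.0
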