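"""Synthetic rater simulation with a known generative truth.

Each simulated subject owns a response scale (intercept/slope drawn around
the 50/50 ground truth), rates trials as

    rating = beta0 + beta1 * (log2(t/t_ref) + curve(pitch)/100) + noise

clipped to the 0-100 slider, where ``curve`` is the injected per-pitch bias
in log2-percent units (sum-centered, so the subject-level mean shift stays
zero, matching the scoring identity).  Non-compliant responder types
(anchor-only, inverted) exercise the screening rules, and a per-trial tap
flag exercises the tap-failure exclusions.  Truth is returned in a ledger
separate from the trial table so the analysis path cannot touch it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design
from .curves import ortho_basis
from .errors import InvalidArgumentError

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_pitch_bias",
    "simulate_rater",
    "simulate_study",
]

RESPONDER_TYPES = ("compliant", "anchor_only", "inverted")


def default_pitch_bias(codes=(2, 3, 4, 5, 6, 7), linear=0.5, quadratic=-2.0) -> np.ndarray:
    """Inverted-U per-pitch bias built from orthonormal contrasts.

    Returns one log2-percent value per pitch code; sums to zero by
    construction of the basis.
    """
    basis = ortho_basis(codes, 2)
    return basis.basis @ np.array([linear, quadratic])


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 20
    pitch_labels: tuple = design.DEFAULT_PITCH_LABELS
    pitch_codes: tuple = (2, 3, 4, 5, 6, 7)
    max_ioi_ms: float = 1000.0
    min_ioi_ms: float = 302.0
    n_tempos: int = 15
    ref_ioi_ms: int = design.REF_IOI_MS
    n_blocks: int = 3
    loudness_db: tuple = (-3.0, 0.0, 3.0)
    beta0_mean: float = 50.0
    beta0_sd: float = 3.0
    beta1_mean: float = 50.0
    # spread and noise defaults keep slider censoring (ratings clipped to
    # 0-100) rare enough that calibration recovery stays unbiased to < 0.5
    # rating points; both are free parameters of the generator
    beta1_sd: float = 5.0
    noise_sd: float = 5.0
    pitch_bias: tuple = field(default_factory=lambda: tuple(default_pitch_bias()))
    tap_fraction: float = 0.0  # share of subjects instructed to tap
    tap_fail_prob: float = 0.276
    responder_mix: tuple = (("compliant", 1.0),)
    experiment: str = "sim"
    timbre: str = "n/a"
    register: str = "full"
    shuffle_order: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.pitch_bias) != len(self.pitch_codes):
            raise InvalidArgumentError("pitch_bias must give one value per pitch")
        total = sum(w for _, w in self.responder_mix)
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError("responder_mix weights must sum to 1")
        for name, w in self.responder_mix:
            if name not in RESPONDER_TYPES:
                raise InvalidArgumentError(f"unknown responder type {name!r}")
            if not 0.0 <= w <= 1.0:
                raise InvalidArgumentError("responder weights must lie in [0, 1]")
        if not 0.0 <= self.tap_fraction <= 1.0:
            raise InvalidArgumentError("tap_fraction must lie in [0, 1]")
        if not 0.0 <= self.tap_fail_prob <= 1.0:
            raise InvalidArgumentError("tap_fail_prob must lie in [0, 1]")

    def grid(self) -> design.TempoGrid:
        return design.log_spaced_iois(
            self.max_ioi_ms, self.min_ioi_ms, self.n_tempos, ref_ioi_ms=self.ref_ioi_ms
        )

    def pitch_set(self) -> design.PitchSet:
        return design.PitchSet.from_labels(self.pitch_labels, self.pitch_codes)

    def centered_bias(self) -> np.ndarray:
        b = np.asarray(self.pitch_bias, dtype=float)
        return b - b.mean()


@dataclass(frozen=True)
class SimulatedStudy:
    trials: pd.DataFrame
    truth: dict
    config: SimulationConfig


def _draw_responder_type(rng: np.random.Generator, mix) -> str:
    names = [n for n, _ in mix]
    weights = np.array([w for _, w in mix], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def simulate_rater(
    config: SimulationConfig,
    participant_id,
    seed,
    responder_type: str = "compliant",
    tap_instruction: str = "no_tap",
):
    """Simulate one subject; returns (trial DataFrame, truth dict)."""
    rng = np.random.default_rng(seed)
    plan = design.randomize_trials(
        config.pitch_set(),
        config.grid(),
        n_blocks=config.n_blocks,
        seed=int(rng.integers(2**32)),
        loudness_db=config.loudness_db,
        shuffle_order=config.shuffle_order,
    )
    df = plan.to_frame()
    beta0 = rng.normal(config.beta0_mean, config.beta0_sd)
    beta1 = rng.normal(config.beta1_mean, config.beta1_sd)
    bias = dict(zip(config.pitch_codes, config.centered_bias()))
    x = np.log2(config.ref_ioi_ms / df["ioi_ms"].to_numpy(dtype=float))
    curve = np.array([bias[c] for c in df["pitch_code"]])
    clean = beta0 + beta1 * (x + curve / 100.0)
    noise = rng.normal(0.0, config.noise_sd, len(df)) if config.noise_sd > 0 else 0.0
    rating = clean + noise
    if responder_type == "inverted":
        rating = 100.0 - rating
    elif responder_type == "anchor_only":
        anchors = np.array([0.0, 50.0, 100.0])
        rating = anchors[np.argmin(np.abs(rating[:, None] - anchors), axis=1)]
    rating = np.clip(rating, 0.0, 100.0)

    if tap_instruction == "tap":
        tapped = (rng.random(len(df)) >= config.tap_fail_prob).astype(object)
    else:
        tapped = np.full(len(df), "n/a", dtype=object)
    df.insert(0, "participant_id", participant_id)
    df.insert(1, "experiment", config.experiment)
    df["tap_instruction"] = tap_instruction
    df["timbre"] = config.timbre
    df["register"] = config.register
    df["rating"] = rating
    df["tapped"] = tapped
    df["practice"] = False
    truth = {
        "participant": participant_id,
        "beta0": float(beta0),
        "beta1": float(beta1),
        "responder_type": responder_type,
        "tap_instruction": tap_instruction,
        "curve": {int(c): float(v) for c, v in bias.items()},
    }
    return df, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a full study, deterministic from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(config.n_subjects)
    n_tap = int(round(config.tap_fraction * config.n_subjects))
    tap_flags = np.array(["tap"] * n_tap + ["no_tap"] * (config.n_subjects - n_tap))
    master.shuffle(tap_flags)
    frames, ledger = [], {}
    for i in range(config.n_subjects):
        pid = f"S{i + 1:03d}"
        rtype = _draw_responder_type(master, config.responder_mix)
        df, truth = simulate_rater(
            config, pid, subject_seeds[i], responder_type=rtype,
            tap_instruction=str(tap_flags[i]),
        )
        frames.append(df)
        ledger[pid] = truth
    trials = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": config.seed,
        "pitch_bias": {
            int(c): float(v)
            for c, v in zip(config.pitch_codes, config.centered_bias())
        },
        "subjects": ledger,
    }
    return SimulatedStudy(trials=trials, truth=truth, config=config)
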