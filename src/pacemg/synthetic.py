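"""Synthetic multichannel RMS-feature sessions for 8 motion classes.

The recordings this package's experiments emulate are 7-channel,
0-5 V normalized RMS amplitude features sampled from a forearm electrode
ring while a subject holds one of 8 hand/wrist motions; each session
contains 500 samples per motion.  No such dataset ships with the package,
so this module generates sessions with the statistical structure the
classifiers assume: each motion activates a small, distinct subset of
channels (a muscle-synergy-like template), samples scatter around the
class template with Gaussian noise truncated to the valid amplitude
range, and weak contractions below 20% of the maximum voluntary
contraction (MVC) are discarded at acquisition.

What this emulates: class-clustered, bounded, amplitude-gated feature
distributions with controllable class overlap.  What it does not:
transient-phase dynamics, inter-subject variability, within-session
autocorrelation, or electrode-specific noise spectra — conclusions drawn
from these sessions speak to classifier mechanics under drift, not to
absolute accuracy on recorded muscle signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drift import FULL_SCALE_V, Session, SessionSequence, drift_sample

#: default activation templates on the unit amplitude scale: 8 motions x
#: 7 channels.  Muscle synergies recruit anatomically adjacent muscles, so
#: motions 1-7 each activate a contiguous 2-channel block of the electrode
#: ring (alternating strong/moderate amplitudes distinguish neighbours);
#: motion 8 is a co-contraction raising all channels moderately.
DEFAULT_CLASS_PATTERNS = np.array([
    [0.85, 0.85, 0.08, 0.08, 0.08, 0.08, 0.08],  # 1
    [0.08, 0.70, 0.70, 0.08, 0.08, 0.08, 0.08],  # 2
    [0.08, 0.08, 0.85, 0.85, 0.08, 0.08, 0.08],  # 3
    [0.08, 0.08, 0.08, 0.70, 0.70, 0.08, 0.08],  # 4
    [0.08, 0.08, 0.08, 0.08, 0.85, 0.85, 0.08],  # 5
    [0.08, 0.08, 0.08, 0.08, 0.08, 0.70, 0.70],  # 6
    [0.85, 0.08, 0.08, 0.08, 0.08, 0.08, 0.85],  # 7
    [0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45],  # 8 co-contraction
])


@dataclass
class GeneratorConfig:
    """Session-generator parameters (amplitudes on the unit scale).

    class_overlap shrinks every class template toward the global mean:
    0 keeps the templates as-is, 1 collapses them entirely.
    """

    n_classes: int = 8
    n_channels: int = 7
    samples_per_class: int = 500
    class_mean_patterns: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_PATTERNS.copy()
    )
    noise_sd: float = 0.10
    class_overlap: float = 0.0
    mvc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_mean_patterns = np.asarray(self.class_mean_patterns, dtype=float)
        if self.class_mean_patterns.shape != (self.n_classes, self.n_channels):
            raise ValueError("class_mean_patterns shape mismatch")
        if self.noise_sd < 0 or self.class_overlap < 0 or self.mvc <= 0:
            raise ValueError("invalid generator parameters")

    def effective_patterns(self) -> np.ndarray:
        global_mean = self.class_mean_patterns.mean(axis=0)
        return (1 - self.class_overlap) * self.class_mean_patterns + \
            self.class_overlap * global_mean


def gen_session(config: GeneratorConfig, rng: np.random.Generator | None = None) -> Session:
    """Draw one session: truncated-normal scatter around class templates.

    Samples are ordered class-by-class (labels 1..n_classes), features
    returned in volts.  Truncation is by clipping to [0, 1] — a simple
    bounded-noise model, documented as such.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    patterns = config.effective_patterns()
    feats, labels = [], []
    for c in range(config.n_classes):
        x = patterns[c] + rng.normal(
            0.0, config.noise_sd, size=(config.samples_per_class, config.n_channels)
        )
        feats.append(np.clip(x, 0.0, 1.0))
        labels.append(np.full(config.samples_per_class, c + 1, dtype=int))
    return Session(np.vstack(feats) * FULL_SCALE_V, np.concatenate(labels))


def mvc_filter(session: Session, mvc: float, full_scale: float = FULL_SCALE_V) -> Session:
    """Amplitude gate: keep samples whose channel-mean exceeds 20% of MVC.

    ``mvc`` is on the unit amplitude scale; the comparison is strict, as
    at acquisition time (a contraction is recorded only if *larger than*
    the threshold).
    """
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    mean_amp = session.features.mean(axis=1) / full_scale
    keep = mean_amp > 0.2 * mvc
    return Session(session.features[keep], session.labels[keep])


def gen_longterm_sequence(
    config: GeneratorConfig,
    n_sessions: int,
    drift_per_session: float,
    apply_mvc: bool = True,
) -> SessionSequence:
    """Emulate a day-long recording: fresh draws with cumulative drift.

    Session k (0-based) is an independent draw from the base concept,
    drifted by fraction min(1, k * drift_per_session).  With
    drift_per_session = 0 all sessions are i.i.d. re-draws.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    rng = np.random.default_rng(config.seed)
    sessions = []
    for k in range(n_sessions):
        s = gen_session(config, rng=rng)
        if apply_mvc:
            s = mvc_filter(s, config.mvc)
        u = min(1.0, k * drift_per_session)
        if u > 0:
            s = Session(drift_sample(s.features, u), s.labels)
        sessions.append(s)
    return SessionSequence(
        sessions, order_tag="natural",
        meta={"kind": "longterm_synthetic", "n_sessions": n_sessions,
              "drift_per_session": drift_per_session, "seed": config.seed},
    )
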