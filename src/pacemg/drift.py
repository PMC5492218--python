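"""Simulated concept drift for multichannel amplitude features.

A session sequence Q_n = {E_(k/n)}, k = 0..n interpolates linearly between
a base session E_(0) and a maximally drifted session E_(1).  The per-sample
transform at drift fraction u = k/n models two physical disturbances of a
forearm electrode array:

1. *DC noise* (electrode-skin impedance change, muscular fatigue): each
   channel is compressed toward full scale,
       x~_j = (x_j + 0.25 u) / (1 + 0.25 u);
2. *electrode shift*: each channel is fused with its circular neighbour,
       x'_j = x~_j (1 - 0.5 u) + 0.5 u x~_{j+1},
   with channel 7 wrapping to channel 1 (the electrodes sit on a ring).

At u = 1 the transform reduces to x'_j = 0.4 x_j + 0.4 x_{j+1} + 0.2.
Drift *extent* grows with k; drift *rate* (extent between adjacent
sessions) scales as 1/n, so large n gives slow drift — the regime an
adaptive classifier can track.

The transform is closed over [0, 1]; features arriving on the 0-5 V scale
are normalized to unit scale internally and de-normalized on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: full-scale electrode output in volts
FULL_SCALE_V = 5.0


@dataclass
class Session:
    """One session: features (n, channels) in volts plus integer labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels).astype(int).ravel()
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass
class SessionSequence:
    """Ordered sessions sharing provenance; first session initializes."""

    sessions: list[Session]
    order_tag: str = "natural"  # natural | reversed | simulated
    n: int | None = None        # drift divisions when simulated
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sessions)


def drift_sample(x0: np.ndarray, u: float, full_scale: float = FULL_SCALE_V) -> np.ndarray:
    """Apply the drift transform at fraction u in [0, 1] to feature rows.

    Accepts a single vector or an (n, channels) array, in volts.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"drift fraction u={u} outside [0, 1]")
    x = np.asarray(x0, dtype=float) / full_scale
    noisy = (x + 0.25 * u) / (1.0 + 0.25 * u)
    fused = noisy * (1.0 - 0.5 * u) + 0.5 * u * np.roll(noisy, -1, axis=-1)
    return fused * full_scale


def drift_session(session: Session, u: float) -> Session:
    """Drift every sample of a session; labels are preserved (real drift
    moves the feature distribution, not the ground truth)."""
    return Session(drift_sample(session.features, u), session.labels.copy())


def make_sequence(base_session: Session, n: int) -> SessionSequence:
    """Build Q_n = {E_(k/n)} for k = 0..n from one base session.

    E_(0) is the base session itself (used for classifier initialization);
    sessions sharing k/n across different n are identical by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sessions = [drift_session(base_session, k / n) for k in range(n + 1)]
    return SessionSequence(sessions, order_tag="simulated", n=n,
                           meta={"kind": "simulated_drift", "n": n})


def drift_extent(seq: SessionSequence) -> np.ndarray:
    """Mean per-sample displacement of each session from the first."""
    base = seq.sessions[0].features
    return np.array([
        np.linalg.norm(s.features - base, axis=1).mean() for s in seq.sessions
    ])
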