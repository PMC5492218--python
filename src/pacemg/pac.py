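"""Particle adaptive classifier (PAC).

PAC is an adaptive multiclass classifier for drifting data streams built
on a fixed-size pool of *representative particles* (RPs) — replaceable
support samples whose density approximates the feature-space distribution
rather than the class boundary.  The pool is initialized by kernel-space
k-medoids clustering of the training session followed by proportional
random down-sampling, and one full-dense LS-SVM is trained per unordered
class pair (one-vs-one) on the particles of those two classes.

Streaming update (per sample x_N):

1. predict the label by one-vs-one majority vote;
2. increment every particle's unchanging time t_i;
3. find the nearest particle I = argmin_i exp(t_i / lambda) d(x_N, x_i),
   where d is the kernel-space metric — older particles look closer, so
   stale regions of the pool are refreshed first;
4. if d_Th - exp(t_I / lambda) d(x_N, x_I) > 0 (the attractive zone),
   replace particle I with x_N, reset t_I = 0, and patch every affected
   pairwise LS-SVM in O(l^2) via Cholesky factor surgery.

In unsupervised mode the candidate label is the classifier's own
prediction; in supervised mode the true label is used, the nearest-RP
search is restricted to particles of that class, and misclassified
samples are ignored entirely.  The pool size never changes, so model
complexity and per-cycle cost stay constant over arbitrarily long
streams — the property that distinguishes PAC from SV-accumulating
incremental SVMs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from . import lssvm
from .kernel import (
    KernelParams,
    distance_matrix,
    kernel_distance_from_similarity,
    kernel_vector,
)


@dataclass
class PACConfig:
    """Tunable parameters of the particle adaptive classifier.

    m : number of k-medoids clusters used to initialize the pool.
    p : fraction of the training session retained as particles.
    d_th : attractive-zone radius in kernel-space distance (range of the
        metric is [0, sqrt(2))); 0 disables replacement entirely.
    lam : time-influence factor; a particle unchanged for t samples has
        its distance inflated by exp(t / lam).
    C, gamma : LS-SVM regularizer and RBF width shared by all pairwise
        models (fixed after initial cross-validation, never re-tuned
        during streaming).
    mode : "supervised" or "unsupervised" adaptation.
    """

    m: int = 10
    p: float = 0.10
    d_th: float = 0.99
    lam: float = 1e5
    C: float = 10.0
    gamma: float = 1.0
    mode: str = "unsupervised"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.d_th < 0:
            raise ValueError("d_th must be >= 0")
        if self.lam <= 0 or self.C <= 0 or self.gamma <= 0:
            raise ValueError("lam, C, gamma must be positive")
        if self.mode not in ("supervised", "unsupervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.10 <= self.p <= 0.20:
            warnings.warn(f"p={self.p} outside the recommended range [0.10, 0.20]")
        if not 9 <= self.m <= 28:
            warnings.warn(f"m={self.m} outside the recommended range [9, 28]")
        if not 1e4 <= self.lam <= 1e6:
            warnings.warn(f"lambda={self.lam} outside the recommended range [1e4, 1e6]")
        if not 0.9 <= self.d_th <= 1.1:
            warnings.warn(f"d_th={self.d_th} outside the recommended range [0.9, 1.1]")

    @property
    def kernel(self) -> KernelParams:
        return KernelParams(gamma=self.gamma)


# ---------------------------------------------------------------------------
# k-medoids on the kernel-space metric


def kmedoids_cluster(
    samples: np.ndarray,
    m: int,
    kernel: KernelParams,
    seed: int,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """PAM-style k-medoids on the precomputed kernel-distance matrix.

    Returns (assignments, medoid_indices).  Alternates nearest-medoid
    assignment with exact medoid recomputation inside each cluster until
    convergence; deterministic given the seed.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if m > n:
        raise ValueError(f"m={m} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    D = distance_matrix(samples, kernel)
    medoids = rng.choice(n, size=m, replace=False)
    assign = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(m):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            sub = D[np.ix_(members, members)]
            new_medoids[c] = members[np.argmin(sub.sum(axis=1))]
        new_assign = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    return assign, medoids


def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` picks across clusters proportionally to size."""
    quota = sizes / sizes.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:short]] += 1
    return np.minimum(counts, sizes)


# ---------------------------------------------------------------------------
# state containers


@dataclass
class RPState:
    """The particle pool: samples, class labels, and unchanging times."""

    particles: np.ndarray  # (R, d)
    labels: np.ndarray     # (R,) integer class labels
    t: np.ndarray          # (R,) samples since last replacement

    @property
    def count(self) -> int:
        return self.particles.shape[0]


@dataclass
class OvOEnsemble:
    """One binary LS-SVM per unordered class pair, built from particles.

    ``index_map[(a, b)]`` holds the global particle indices backing each
    model's support set, in support order; labels are +1 for class a and
    -1 for class b (a < b).
    """

    classes: np.ndarray
    models: dict = field(default_factory=dict)
    index_map: dict = field(default_factory=dict)

    def pairs(self):
        return list(self.models.keys())


class EmptyCandidateSet(Exception):
    """Supervised nearest-RP search found no particle of the target class."""


# ---------------------------------------------------------------------------
# initialization


def init_rps(
    samples: np.ndarray,
    labels: np.ndarray,
    config: PACConfig,
) -> tuple[RPState, OvOEnsemble]:
    """Initialize the particle pool and the pairwise LS-SVM ensemble.

    Clusters the pooled training session (class-agnostic) into m groups,
    draws round(p*n) particles allocated across clusters by largest
    remainder, and batch-trains one LS-SVM per class pair.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(labels).astype(int).ravel()
    n = X.shape[0]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training session must contain at least 2 classes")

    assign, _ = kmedoids_cluster(X, config.m, config.kernel, config.seed)
    total = max(int(round(config.p * n)), 1)
    rng = np.random.default_rng(config.seed + 1)
    chosen: list[int] = []
    sizes = np.array([(assign == c).sum() for c in range(config.m)])
    counts = _largest_remainder(sizes, total)
    for c in range(config.m):
        members = np.flatnonzero(assign == c)
        if counts[c] > 0:
            chosen.extend(rng.choice(members, size=counts[c], replace=False))
    chosen = np.sort(np.array(chosen, dtype=int))

    rp_labels = y[chosen]
    missing = np.setdiff1d(classes, np.unique(rp_labels))
    if missing.size:
        raise ValueError(
            f"classes {missing.tolist()} received no representative particles; "
            "increase p or m"
        )
    state = RPState(
        particles=X[chosen].copy(),
        labels=rp_labels.copy(),
        t=np.zeros(len(chosen), dtype=np.int64),
    )
    ensemble = _build_ensemble(state, config)
    return state, ensemble


def _build_ensemble(state: RPState, config: PACConfig) -> OvOEnsemble:
    classes = np.unique(state.labels)
    ens = OvOEnsemble(classes=classes)
    for a, b in combinations(classes.tolist(), 2):
        idx = np.flatnonzero((state.labels == a) | (state.labels == b))
        bin_labels = np.where(state.labels[idx] == a, 1.0, -1.0)
        ens.models[(a, b)] = lssvm.batch_solve(
            state.particles[idx], bin_labels, config.C, config.kernel
        )
        ens.index_map[(a, b)] = idx.tolist()
    return ens


# ---------------------------------------------------------------------------
# prediction


def ovo_predict_from_kernel(
    ensemble: OvOEnsemble, k_all: np.ndarray
) -> tuple[int, np.ndarray]:
    """One-vs-one vote using precomputed kernel products k(x, particles)."""
    classes = ensemble.classes
    votes = np.zeros(classes.size, dtype=int)
    pos = {int(c): i for i, c in enumerate(classes)}
    for (a, b), model in ensemble.models.items():
        k = k_all[ensemble.index_map[(a, b)]]
        val = model.alpha.dot(k) + model.b
        votes[pos[a] if val >= 0 else pos[b]] += 1
    return int(classes[np.argmax(votes)]), votes


def ovo_predict(x: np.ndarray, state: RPState, ensemble: OvOEnsemble,
                config: PACConfig) -> tuple[int, np.ndarray]:
    """Predict a class label by majority vote; ties go to the lowest class."""
    k_all = kernel_vector(x, state.particles, config.kernel)
    return ovo_predict_from_kernel(ensemble, k_all)


# ---------------------------------------------------------------------------
# particle replacement machinery


def nearest_rp(
    x_n: np.ndarray,
    state: RPState,
    config: PACConfig,
    restrict_label: int | None = None,
    k_all: np.ndarray | None = None,
) -> tuple[int, float]:
    """Time-weighted nearest particle: argmin_i exp(t_i/lam) d(x_N, x_i).

    ``restrict_label`` limits the search to one class (supervised mode).
    Ties break to the lowest index.  Raises :class:`EmptyCandidateSet`
    when the restricted pool is empty.
    """
    if state.count == 0:
        raise EmptyCandidateSet("particle pool is empty")
    if k_all is None:
        k_all = kernel_vector(x_n, state.particles, config.kernel)
    d = kernel_distance_from_similarity(k_all)
    weighted = np.exp(state.t / config.lam) * d
    if restrict_label is not None:
        candidates = np.flatnonzero(state.labels == restrict_label)
        if candidates.size == 0:
            raise EmptyCandidateSet(f"no particles of class {restrict_label}")
        i = candidates[np.argmin(weighted[candidates])]
    else:
        i = int(np.argmin(weighted))
    return int(i), float(weighted[i])


def attractive_zone_decision(weighted_distance: float, config: PACConfig) -> bool:
    """True (replace) iff d_Th - weighted distance > 0, strictly."""
    return config.d_th - weighted_distance > 0


def _patch_models(
    state: RPState,
    ensemble: OvOEnsemble,
    config: PACConfig,
    idx: int,
    x_new: np.ndarray,
    new_label: int,
) -> None:
    """Patch every pairwise model affected by replacing particle ``idx``.

    Same-class replacement substitutes the sample in each model of that
    class.  A class change (unsupervised mode) removes the particle from
    the old class's models, inserts it (appended) into the new class's,
    and flips its label in the shared pair.
    """
    old_label = int(state.labels[idx])
    for (a, b), model in list(ensemble.models.items()):
        gidx = ensemble.index_map[(a, b)]
        in_old = old_label in (a, b)
        in_new = new_label in (a, b)
        if not in_old and not in_new:
            continue
        sign_new = 1.0 if new_label == a else -1.0
        if in_old and in_new:
            pos = gidx.index(idx)
            ensemble.models[(a, b)] = lssvm.replace(model, x_new, sign_new, pos)
        elif in_old:
            pos = gidx.index(idx)
            ensemble.models[(a, b)] = lssvm.delete(model, pos)
            gidx.pop(pos)
        else:  # in_new only: append
            ensemble.models[(a, b)] = lssvm.insert(
                model, x_new, sign_new, model.size
            )
            gidx.append(idx)
    state.particles[idx] = x_new
    state.labels[idx] = new_label
    state.t[idx] = 0


def pac_process_sample(
    x_n: np.ndarray,
    true_label: int | None,
    state: RPState,
    ensemble: OvOEnsemble,
    config: PACConfig,
) -> int:
    """One streaming cycle: predict, age the pool, maybe replace a particle.

    Returns the predicted label.  Never raises on a sample: when the
    attractive-zone test fails, when supervised mode sees a
    misclassification, or when a class change would exhaust a class, the
    pool is merely aged.
    """
    x_n = np.asarray(x_n, dtype=float).ravel()
    k_all = kernel_vector(x_n, state.particles, config.kernel)
    pred, _ = ovo_predict_from_kernel(ensemble, k_all)
    state.t += 1

    if config.mode == "supervised":
        if true_label is None:
            raise ValueError("supervised mode requires the true label")
        if pred != true_label:
            return pred
        candidate = int(true_label)
        restrict = candidate
    else:
        candidate = pred
        restrict = None

    try:
        idx, wdist = nearest_rp(x_n, state, config, restrict, k_all=k_all)
    except EmptyCandidateSet:
        return pred
    if not attractive_zone_decision(wdist, config):
        return pred

    old_label = int(state.labels[idx])
    if candidate != old_label and (state.labels == old_label).sum() <= 1:
        # a class change that would empty a class leaves pairwise models
        # untrainable; keep the pool intact instead
        return pred
    try:
        _patch_models(state, ensemble, config, idx, x_n, candidate)
    except lssvm.FactorBreakdownError:
        # numerical fallback: rebuild the affected ensemble from scratch
        state.particles[idx] = x_n
        state.labels[idx] = candidate
        state.t[idx] = 0
        new_ens = _build_ensemble(state, config)
        ensemble.models = new_ens.models
        ensemble.index_map = new_ens.index_map
    return pred


# ---------------------------------------------------------------------------
# diagnostics & serialization


def boundary_rp_proportion(state: RPState, C: float, gamma: float) -> float:
    """Fraction of particles that are boundary particles.

    Trains a sparse C-SVC on the pool; particles keeping nonzero dual
    coefficients in at least one pairwise model sit near a class boundary.
    A representative pool keeps this fraction well below 1.
    """
    from .svc import nsvc_train

    if np.unique(state.labels).size < 2:
        raise ValueError("boundary proportion undefined for a single class")
    model = nsvc_train(state.particles, state.labels, C=C, gamma=gamma)
    return model.sv_indices.size / state.count


class PAC:
    """Streaming facade bundling config, particle pool, and ensemble."""

    updates = True

    def __init__(self, config: PACConfig):
        self.config = config
        self.state: RPState | None = None
        self.ensemble: OvOEnsemble | None = None

    def initialize(self, samples: np.ndarray, labels: np.ndarray) -> "PAC":
        self.state, self.ensemble = init_rps(samples, labels, self.config)
        return self

    def predict(self, x: np.ndarray) -> int:
        return ovo_predict(x, self.state, self.ensemble, self.config)[0]

    def process_sample(self, x: np.ndarray, true_label: int | None = None) -> int:
        return pac_process_sample(x, true_label, self.state, self.ensemble, self.config)

    def model_size(self) -> int:
        return self.state.count

    def pair_sizes(self) -> dict:
        return {pair: m.size for pair, m in self.ensemble.models.items()}

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint to <path>.json (config) + <path>.npz (arrays)."""
        path = Path(path)
        cfg = {k: getattr(self.config, k) for k in
               ("m", "p", "d_th", "lam", "C", "gamma", "mode", "seed")}
        pairs = self.ensemble.pairs()
        meta = {
            "config": cfg,
            "pairs": [[int(a), int(b)] for a, b in pairs],
            "index_map": {f"{a}_{b}": list(map(int, self.ensemble.index_map[(a, b)]))
                          for a, b in pairs},
            "b": {f"{a}_{b}": self.ensemble.models[(a, b)].b for a, b in pairs},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        arrays = {
            "particles": self.state.particles,
            "labels": self.state.labels,
            "t": self.state.t,
        }
        for a, b in pairs:
            arrays[f"alpha_{a}_{b}"] = self.ensemble.models[(a, b)].alpha
            arrays[f"factor_{a}_{b}"] = self.ensemble.models[(a, b)].factor
        np.savez(path.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PAC":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        config = PACConfig(**meta["config"])
        pac = cls(config)
        pac.state = RPState(
            particles=arrays["particles"],
            labels=arrays["labels"],
            t=arrays["t"],
        )
        ens = OvOEnsemble(classes=np.unique(pac.state.labels))
        for a, b in meta["pairs"]:
            key = f"{a}_{b}"
            gidx = meta["index_map"][key]
            bin_labels = np.where(pac.state.labels[gidx] == a, 1.0, -1.0)
            ens.models[(a, b)] = lssvm.LSSVMModel(
                support_samples=pac.state.particles[gidx].copy(),
                support_labels=bin_labels,
                alpha=arrays[f"alpha_{key}"],
                b=float(meta["b"][key]),
                factor=arrays[f"factor_{key}"],
                C=config.C,
                kernel=config.kernel,
            )
            ens.index_map[(a, b)] = list(gidx)
        pac.ensemble = ens
        return pac
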