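"""C-SVC baselines: non-adapting (NSVC) and incremental (ISVC).

NSVC is a standard soft-margin C-SVC with RBF kernel and one-vs-one
multiclass voting; KKT pruning leaves a sparse support-vector (SV) model
that never changes after training, so its accuracy decays as the concept
drifts.

ISVC adapts by retraining: at each updating cycle the previous model's SV
set is pooled with the newly arrived sample and the C-SVC is refit.  In
supervised mode (sISVC) the new sample carries its true label; in
unsupervised mode (uISVC) it carries the model's own prediction, so
misclassifications feed back into the training set.  Because KKT
conditions retain boundary samples — precisely the ones outdated by real
drift — the SV set tends to grow without bound and per-cycle cost grows
with it.

The quadratic programs are delegated to libsvm via scikit-learn; the
contract here is the KKT conditions and the update schema, not the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: libsvm stopping tolerance; SV membership via KKT is tolerance-sensitive
QP_TOL = 1e-3

DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass
class SVCModel:
    """Fitted one-vs-one C-SVC plus the training set it was fit on."""

    estimator: SVC
    X_train: np.ndarray
    y_train: np.ndarray
    C: float
    gamma: float

    @property
    def sv_indices(self) -> np.ndarray:
        """Indices (into the training set) of samples that are SVs in at
        least one pairwise model — the union over the one-vs-one ensemble."""
        return self.estimator.support_

    @property
    def support_vectors(self) -> np.ndarray:
        return self.X_train[self.sv_indices]

    @property
    def support_labels(self) -> np.ndarray:
        return self.y_train[self.sv_indices]

    @property
    def sv_count(self) -> int:
        return self.sv_indices.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.atleast_2d(X))


def nsvc_train(samples: np.ndarray, labels: np.ndarray, C: float, gamma: float) -> SVCModel:
    """Train a one-vs-one C-SVC (RBF); zero-coefficient samples are pruned."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(labels).ravel()
    if np.unique(y).size < 2:
        raise ValueError("nsvc_train requires at least 2 classes")
    if not C > 0:
        raise ValueError("C must be positive")
    est = SVC(C=C, kernel="rbf", gamma=gamma, tol=QP_TOL,
              decision_function_shape="ovo", cache_size=64)
    est.fit(X, y)
    return SVCModel(est, X, y, float(C), float(gamma))


class NSVC:
    """Non-adapting streaming facade: train once, predict forever."""

    updates = False

    def __init__(self, C: float, gamma: float):
        self.C, self.gamma = C, gamma
        self.model: SVCModel | None = None

    def initialize(self, samples: np.ndarray, labels: np.ndarray) -> "NSVC":
        self.model = nsvc_train(samples, labels, self.C, self.gamma)
        return self

    def predict(self, x: np.ndarray) -> int:
        return int(self.model.predict(np.atleast_2d(x))[0])

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def process_sample(self, x: np.ndarray, true_label: int | None = None) -> int:
        return self.predict(x)

    def model_size(self) -> int:
        return self.model.sv_count


def isvc_update(model: SVCModel, x_n: np.ndarray, label: int) -> SVCModel:
    """One incremental cycle: refit on (previous SVs) + (the new sample)."""
    X = np.vstack([model.support_vectors, np.atleast_2d(x_n)])
    y = np.append(model.support_labels, label)
    return nsvc_train(X, y, model.C, model.gamma)


class ISVC:
    """Incremental SVC streaming facade (supervised or unsupervised)."""

    updates = True

    def __init__(self, C: float, gamma: float, mode: str = "unsupervised"):
        if mode not in ("supervised", "unsupervised"):
            raise ValueError(f"unknown mode {mode!r}")
        self.C, self.gamma, self.mode = C, gamma, mode
        self.model: SVCModel | None = None

    def initialize(self, samples: np.ndarray, labels: np.ndarray) -> "ISVC":
        self.model = nsvc_train(samples, labels, self.C, self.gamma)
        return self

    def predict(self, x: np.ndarray) -> int:
        return int(self.model.predict(np.atleast_2d(x))[0])

    def process_sample(self, x: np.ndarray, true_label: int | None = None) -> int:
        pred = self.predict(x)
        if self.mode == "supervised":
            if true_label is None:
                raise ValueError("supervised mode requires the true label")
            label = int(true_label)
        else:
            label = pred
        self.model = isvc_update(self.model, x, label)
        return pred

    def model_size(self) -> int:
        return self.model.sv_count


def grid_cv(
    samples: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    seed: int = 0,
    estimator: str = "svc",
) -> tuple[float, float]:
    """Stratified n-fold CV over a (C, gamma) grid; ties prefer small values.

    ``estimator`` selects the model whose CV accuracy is maximized: the
    sparse C-SVC ("svc") or the one-vs-one LS-SVM ("lssvm", used when
    fixing the particle classifier's kernel before streaming).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(labels).ravel()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be nonempty")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best = (-1.0, None, None)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            correct = 0
            for train_idx, test_idx in folds:
                if estimator == "svc":
                    m = nsvc_train(X[train_idx], y[train_idx], C, gamma)
                    pred = m.predict(X[test_idx])
                elif estimator == "lssvm":
                    pred = _lssvm_ovo_predict(
                        X[train_idx], y[train_idx], X[test_idx], C, gamma
                    )
                else:
                    raise ValueError(f"unknown estimator {estimator!r}")
                correct += int((pred == y[test_idx]).sum())
            acc = correct / X.shape[0]
            if acc > best[0]:
                best = (acc, C, gamma)
    return float(best[1]), float(best[2])


def _lssvm_ovo_predict(X_train, y_train, X_test, C, gamma) -> np.ndarray:
    """Batch one-vs-one LS-SVM train/predict helper for cross-validation."""
    from itertools import combinations

    from . import lssvm
    from .kernel import KernelParams
    from scipy.spatial.distance import cdist

    kp = KernelParams(gamma=gamma)
    classes = np.unique(y_train)
    votes = np.zeros((X_test.shape[0], classes.size), dtype=int)
    pos = {int(c): i for i, c in enumerate(classes)}
    for a, b in combinations(classes.tolist(), 2):
        idx = np.flatnonzero((y_train == a) | (y_train == b))
        bl = np.where(y_train[idx] == a, 1.0, -1.0)
        m = lssvm.batch_solve(X_train[idx], bl, C, kp)
        K = np.exp(-gamma * cdist(X_test, X_train[idx], "sqeuclidean"))
        vals = K.dot(m.alpha) + m.b
        votes[vals >= 0, pos[a]] += 1
        votes[vals < 0, pos[b]] += 1
    return classes[np.argmax(votes, axis=1)]
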