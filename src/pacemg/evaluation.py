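"""Prequential (test-then-update) evaluation and summary metrics.

Samples of the validating sessions are fed to the classifier one by one;
each sample is scored against its ground truth *before* the classifier
may use it for adaptation, so every sample is an out-of-sample test
exactly once.  Accuracy is aggregated at session granularity:

* RA_i — recognition accuracy of the session at position i of the
  validating order (the first session of the order initializes the
  classifier and is not scored);
* AER — mean of the last five sessions' RA x 100, the end-of-stream
  overall accuracy;
* WMP — mean over the last five sessions of the *worst* per-class
  accuracy x 100, the end-of-stream floor across motions;
* CM — row-normalized confusion matrices (rows sum to 100%), averaged
  over the last five sessions and then across sequences.

Reversing the validating order (the last session initializes, the rest
are scored backwards) controls for accidental features of the first
recording while preserving sequence length and maximum drift extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .drift import SessionSequence

#: number of ending sessions averaged by AER / WMP
ENDING_WINDOW = 5


@dataclass
class PrequentialResult:
    """Per-session outcomes of one prequential run."""

    ra: np.ndarray                 # (S,) session accuracy, validating order
    ra_per_class: np.ndarray       # (S, n_classes), NaN for absent classes
    confusion: np.ndarray          # (S, n_classes, n_classes) row-% matrices
    classes: np.ndarray
    sv_counts: np.ndarray          # model size once per session boundary
    predictions: list[np.ndarray]  # per-session predicted labels
    truths: list[np.ndarray]       # per-session true labels
    order_tag: str = "natural"
    cycle_times: np.ndarray | None = None

    @property
    def n_sessions(self) -> int:
        return self.ra.size


def confusion_matrix(predictions, truths, classes) -> np.ndarray:
    """Row-normalized class confusion in percent; NaN rows for absent truth.

    Entry (i, j) is the percentage of samples of true class i predicted as
    class j, so each defined row sums to 100.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    classes = np.asarray(classes)
    n = classes.size
    cm = np.full((n, n), np.nan)
    for i, c in enumerate(classes):
        mask = truths == c
        if not mask.any():
            continue
        row = np.array([(predictions[mask] == cj).sum() for cj in classes], dtype=float)
        cm[i] = row / mask.sum() * 100.0
    return cm


def run_prequential(
    sequence: SessionSequence,
    classifier,
    record_cycle_times: bool = False,
) -> PrequentialResult:
    """Initialize on the first session, then test-then-update the rest.

    A classifier advertising ``updates = False`` is scored session-wise
    through ``predict_batch`` (its model cannot change mid-session).
    """
    if len(sequence) < 2:
        raise ValueError("sequence needs an initialization session and at "
                         "least one validating session")
    init = sequence.sessions[0]
    classifier.initialize(init.features, init.labels)
    classes = np.unique(np.concatenate([s.labels for s in sequence.sessions]))

    ra, ra_pc, cms, svs, preds_all, truths_all, times = [], [], [], [], [], [], []
    import time as _time

    for session in sequence.sessions[1:]:
        X, y = session.features, session.labels
        if not getattr(classifier, "updates", True):
            preds = np.asarray(classifier.predict_batch(X))
        else:
            preds = np.empty(y.size, dtype=int)
            for i in range(y.size):
                t0 = _time.perf_counter() if record_cycle_times else 0.0
                preds[i] = classifier.process_sample(X[i], int(y[i]))
                if record_cycle_times:
                    times.append(_time.perf_counter() - t0)
        ra.append(float((preds == y).mean()))
        pc = np.full(classes.size, np.nan)
        for j, c in enumerate(classes):
            mask = y == c
            if mask.any():
                pc[j] = float((preds[mask] == c).mean())
        ra_pc.append(pc)
        cms.append(confusion_matrix(preds, y, classes))
        svs.append(classifier.model_size())
        preds_all.append(preds)
        truths_all.append(y.copy())

    return PrequentialResult(
        ra=np.array(ra),
        ra_per_class=np.array(ra_pc),
        confusion=np.array(cms),
        classes=classes,
        sv_counts=np.array(svs),
        predictions=preds_all,
        truths=truths_all,
        order_tag=sequence.order_tag,
        cycle_times=np.array(times) if record_cycle_times else None,
    )


def reverse_order(sequence: SessionSequence) -> SessionSequence:
    """Reverse the validating order; position indices are reassigned.

    The formerly last session becomes the initialization session, and a
    session's RA subscript is its position in the new validating order.
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 sessions to reverse")
    tag = {"natural": "reversed", "reversed": "natural"}.get(
        sequence.order_tag, sequence.order_tag
    )
    return SessionSequence(
        sessions=list(reversed(sequence.sessions)),
        order_tag=tag, n=sequence.n, meta=dict(sequence.meta),
    )


def _ending_slice(n_sessions: int) -> slice:
    if n_sessions < ENDING_WINDOW:
        raise ValueError(
            f"need at least {ENDING_WINDOW} validating sessions, got {n_sessions}"
        )
    if n_sessions < 23:
        warnings.warn(
            "sequence shorter than the reference 23 validating sessions; "
            "ending metrics average its last five sessions"
        )
    return slice(n_sessions - ENDING_WINDOW, n_sessions)


def aer(result: PrequentialResult) -> float:
    """Average ending recognition accuracy: mean RA of the last five
    validating sessions, in percent."""
    return float(result.ra[_ending_slice(result.n_sessions)].mean() * 100.0)


def wmp(result: PrequentialResult) -> float:
    """Worst-motion performance: mean over the last five sessions of the
    minimum per-class accuracy, in percent."""
    pc = result.ra_per_class[_ending_slice(result.n_sessions)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        minima = np.nanmin(pc, axis=1)
    return float(np.mean(minima) * 100.0)


def ending_confusion(results: list[PrequentialResult]) -> np.ndarray:
    """Average confusion of the last five sessions, then across runs.

    Rows undefined in a session (absent truth class) are excluded from
    the average of that cell.
    """
    per_run = []
    for r in results:
        sl = _ending_slice(r.n_sessions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_run.append(np.nanmean(r.confusion[sl], axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.array(per_run), axis=0)


def degradation_curve(
    sequences: dict[int, SessionSequence],
    classifier_factory,
) -> dict[int, float]:
    """Final-session error rate of a classifier across drift rates.

    ``sequences`` maps n (drift divisions) to its Q_n; all entries should
    share the base session and maximum drift so the curve isolates the
    rate.  Returns {n: error at E_(1)}; plotted against 1/n this is the
    degradation-vs-drift-rate curve, whose crossing of a tolerance gives
    the classifier's drift-rate threshold.
    """
    curve = {}
    for n, seq in sorted(sequences.items()):
        result = run_prequential(seq, classifier_factory())
        curve[n] = float(1.0 - result.ra[-1])
    return curve


def drift_rate_threshold(curve: dict[int, float], tolerance: float) -> float | None:
    """Largest drift rate 1/n whose final error stays below tolerance."""
    ok = [1.0 / n for n, err in curve.items() if err < tolerance]
    return max(ok) if ok else None
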