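"""Per-stream classifiers, cross-validation, and performance metrics.

One binary classifier per stream n decides "stream n attended" from the
deviant (D_n) responses only; standards are never classified.  Under the
default session plan each stream is attended in 2 of 6 runs, so the
positive:negative epoch ratio is about 1:2 — folds are stratified and the
logistic regression uses balanced class weights.

Within each training fold only: xDAWN filters (both classes), the
super-trial templates, the Fréchet mean, and the classifier are fitted;
the frozen transforms are then applied to the held-out fold.  The signal
covariance entering the xDAWN whitening is the label-free second-moment
statistic of the continuous recording, computed once per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocessing import EpochSet
from .riemann import MDM, riemannian_mean, tangent_vectors
from .xdawn import apply_filters, fit_xdawn_from_windows

__all__ = [
    "PreprocessedSession",
    "CVResult",
    "ITRReport",
    "run_stream_cv",
    "mcc",
    "itr",
    "average_confusion",
    "report_table",
]


@dataclass
class PreprocessedSession:
    """Classification-ready view of one session.

    ``epochs``: deviant epochs (all channels, baseline-corrected, rejection
    flags set) with global onset samples across the concatenated runs.
    ``sigma_x``: X'X/n_t over the continuous classification-band EEG.
    """

    epochs: EpochSet
    sigma_x: np.ndarray
    n_t: int

    @property
    def eeg_picks(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.epochs.channel_types) if t == "EEG"]
        )


@dataclass
class CVResult:
    """Aggregated confusion counts and per-fold metrics for one stream."""

    stream: int
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    fold_accuracies: list[float] = field(default_factory=list)
    fold_sizes: list[int] = field(default_factory=list)
    n_epochs: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.tn, self.fp, self.fn)

    @property
    def confusion(self) -> np.ndarray:
        """[[TN, FP], [FN, TP]] count matrix (rows = true class)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Any zero factor in the denominator yields 0 by the standard convention.
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den2 == 0:
        return 0.0
    return num / np.sqrt(float(den2))


def _epoch_covariances(
    bc_data: np.ndarray, p1: np.ndarray, filters: np.ndarray
) -> np.ndarray:
    """Super-trial covariances for a stack of epochs.

    ``bc_data`` (n, n_channels, n_times) baseline-corrected epochs,
    ``filters`` (n_channels, 2C) stacked attended/nonattended filters,
    ``p1`` (2C, n_times) stacked templates.  Returns (n, 4C, 4C) SCMs of
    [P1; X_i] (uncentered, /(N-1)), ridged where numerically singular.
    """
    n, _, n_times = bc_data.shape
    xi = np.einsum("cf,ect->eft", filters, bc_data)
    s = np.concatenate(
        [np.broadcast_to(p1, (n,) + p1.shape), xi], axis=1
    )
    covs = s @ s.transpose(0, 2, 1) / (n_times - 1)
    covs = 0.5 * (covs + covs.transpose(0, 2, 1))
    evs = np.linalg.eigvalsh(covs)
    traces = np.trace(covs, axis1=1, axis2=2)
    bad = evs[:, 0] < 1e-10 * traces
    if bad.any():
        d = covs.shape[1]
        covs[bad] += (1e-9 * traces[bad, None, None]) * np.eye(d)
    return covs


def run_stream_cv(
    session: PreprocessedSession,
    stream: int,
    n_folds: int = 10,
    seed: int = 0,
    classifier: str = "logreg",
    n_components: int = 3,
    logreg_c: float = 1.0,
    labels: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the "stream attended" decoder.

    ``labels`` overrides the attended/nonattended labels (for permutation
    null calibration); by default they come from the epoch metadata.
    """
    epochs = session.epochs.select(stream=stream, role="deviant")
    md = epochs.metadata
    y = (
        np.asarray(labels, dtype=bool)
        if labels is not None
        else (md["stream"] == md["attended_stream"]).to_numpy()
    )
    if len(epochs) != y.size:
        raise ValueError("labels length mismatch")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < n_folds or n_neg < n_folds:
        raise ValueError(
            f"need >= {n_folds} epochs per class, got {n_pos} positive / "
            f"{n_neg} negative"
        )

    picks = session.eeg_picks
    bc = epochs.data[:, picks, :].astype(float)
    raw = bc + (
        epochs.baseline_means[:, picks, None]
        if epochs.baseline_means is not None
        else 0.0
    )
    onsets = md["onset_sample"].to_numpy(dtype=int)
    sigma_x = session.sigma_x

    result = CVResult(stream=stream, n_epochs=len(epochs))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(bc, y):
        y_tr = y[train_idx]
        if y_tr.all() or not y_tr.any():
            raise ValueError("a class is absent from a training fold")
        model = fit_xdawn_from_windows(
            windows_by_class={
                "attended": raw[train_idx][y_tr],
                "nonattended": raw[train_idx][~y_tr],
            },
            onsets_by_class={
                "attended": onsets[train_idx][y_tr],
                "nonattended": onsets[train_idx][~y_tr],
            },
            sigma_x=sigma_x,
            n_t=session.n_t,
            n_components=n_components,
        )
        p1 = model.stacked_templates()
        filt = np.hstack([model.filters[c] for c in model.classes])
        covs = _epoch_covariances(bc, p1, filt)

        if classifier == "mdm":
            clf = MDM().fit(covs[train_idx], y_tr)
            pred = clf.predict(covs[test_idx]).astype(bool)
        elif classifier == "logreg":
            base = riemannian_mean(covs[train_idx], tol=1e-9, max_iter=100)
            feats = tangent_vectors(covs, base)
            # default penalty is L2
            clf = LogisticRegression(
                C=logreg_c, class_weight="balanced", max_iter=2000
            )
            clf.fit(feats[train_idx], y_tr)
            pred = clf.predict(feats[test_idx]).astype(bool)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")

        y_te = y[test_idx]
        result.tp += int((pred & y_te).sum())
        result.tn += int((~pred & ~y_te).sum())
        result.fp += int((pred & ~y_te).sum())
        result.fn += int((~pred & y_te).sum())
        result.fold_accuracies.append(float((pred == y_te).mean()))
        result.fold_sizes.append(int(y_te.size))
    return result


# ---------------------------------------------------------------------------
# metrics and reports
# ---------------------------------------------------------------------------


@dataclass
class ITRReport:
    """Wolpaw information transfer rate for an N-class selection."""

    n_classes: int
    accuracy: float
    interval_s: float
    bits_per_selection: float
    bits_per_min: float


def itr(n_classes: int, accuracy: float, interval_s: float) -> ITRReport:
    """Information transfer rate of an N-class selection every T seconds.

    bits/selection = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with the
    0*log(0) convention; accuracies below chance clip to 0 bits with a
    warning.  bits/min scales by 60/T.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if interval_s <= 0:
        raise ValueError("selection interval must be positive")
    p = accuracy

    def xlog2x(v: float) -> float:
        return 0.0 if v <= 0 else v * np.log2(v)

    bits = (
        np.log2(n_classes)
        + xlog2x(p)
        + xlog2x(1 - p)
        - (0.0 if p >= 1 else (1 - p) * np.log2(n_classes - 1))
    )
    if p < 1.0 / n_classes:
        warnings.warn("accuracy below chance; ITR clipped to 0 bits")
        bits = 0.0
    bits = max(bits, 0.0)
    return ITRReport(
        n_classes=n_classes,
        accuracy=accuracy,
        interval_s=interval_s,
        bits_per_selection=float(bits),
        bits_per_min=float(bits * 60.0 / interval_s),
    )


def average_confusion(confusions) -> np.ndarray:
    """Row-normalize each subject's 2x2 confusion matrix, then average.

    Inputs must be homogeneous: either all raw count matrices or all
    already row-normalized (rows summing to 1); mixing the two is rejected.
    """
    mats = [np.asarray(c, dtype=float) for c in confusions]
    if not mats:
        raise ValueError("no confusion matrices given")
    normalized_flags = [np.allclose(m.sum(axis=1), 1.0) for m in mats]
    if len(set(normalized_flags)) > 1:
        raise ValueError("mixed raw-count and normalized confusion matrices")
    out = []
    for m in mats:
        sums = m.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("confusion matrix with an empty true class")
        out.append(m / sums)
    return np.mean(out, axis=0)


def report_table(results: "dict[str, dict[int, CVResult]]") -> pd.DataFrame:
    """Accuracy and MCC per subject x stream, with subject and grand averages.

    ``results[subject][stream]`` is a :class:`CVResult`.  The last row is
    the grand average (mean of subject averages).
    """
    if not results:
        raise ValueError("empty results")
    rows = {}
    for subject, per_stream in results.items():
        row = {}
        for stream in sorted(per_stream):
            r = per_stream[stream]
            row[(f"Stream {stream}", "Accuracy")] = r.accuracy
            row[(f"Stream {stream}", "MCC")] = r.mcc
        accs = [v for (s, m), v in row.items() if m == "Accuracy"]
        mccs = [v for (s, m), v in row.items() if m == "MCC"]
        row[("Average", "Accuracy")] = float(np.mean(accs))
        row[("Average", "MCC")] = float(np.mean(mccs))
        rows[subject] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    table.loc["Grand Average"] = table.mean(axis=0)
    return table


def format_report(table: pd.DataFrame) -> str:
    return table.to_string(float_format=lambda v: f"{v:.2f}")
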