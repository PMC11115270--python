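"""Condition averaging and pointwise attended-vs-nonattended statistics.

For each stream the deviant responses recorded while that stream was
attended (Dt) are compared against the deviant responses of the
nonattended streams, concatenated over epochs (Dnt), with an independent
two-sample Student's (pooled-variance) t-test at every (channel, sample)
cell, alpha = 0.01, no multiple-comparison correction.  With ~64 x 600
cells an expected false-positive density of about alpha is inherent to
this uncorrected mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class EvokedResponse:
    """Arithmetic mean over contributing (non-rejected) epochs."""

    data: np.ndarray  # channels x time, µV
    n_trials: int
    condition: tuple  # (stream, attended)
    rate: float
    tmin: float
    channel_labels: list[str]


@dataclass
class SignificanceMask:
    """Pointwise test mask: True where p < alpha."""

    mask: np.ndarray  # channels x time, bool
    alpha: float
    test: str
    t_values: np.ndarray
    p_values: np.ndarray

    @property
    def density(self) -> float:
        return float(self.mask.mean())


def average_condition(epochs: EpochSet, stream: int, attended: bool) -> EvokedResponse:
    """Average the deviant responses of one stream for one attention status."""
    sel = epochs.select(stream=stream, role="deviant", attended=attended)
    if len(sel) == 0:
        raise ValueError(
            f"no epochs in group (stream={stream}, deviant, attended={attended})"
        )
    return EvokedResponse(
        data=sel.data.mean(axis=0),
        n_trials=len(sel),
        condition=(stream, attended),
        rate=epochs.rate,
        tmin=epochs.tmin,
        channel_labels=list(epochs.channel_labels),
    )


def pointwise_ttest(
    attended: "np.ndarray | EpochSet",
    nonattended: "np.ndarray | EpochSet",
    alpha: float = 0.01,
) -> SignificanceMask:
    """Independent two-sample Student's t-test per (channel, sample).

    Inputs are epoch stacks (n_epochs, channels, time) or EpochSets; the
    nonattended stack is expected to be the concatenation over both
    nonattended streams.  Pooled-variance (equal-variance) statistic, no
    correction for multiple comparisons.  Cells where both groups have zero
    variance get p = 1 when the means agree and p = 0 otherwise.
    """
    dt = attended.data if isinstance(attended, EpochSet) else np.asarray(attended)
    dnt = (nonattended.data if isinstance(nonattended, EpochSet)
           else np.asarray(nonattended))
    if dt.shape[0] < 2 or dnt.shape[0] < 2:
        raise ValueError("need at least 2 epochs per group")
    if dt.shape[1:] != dnt.shape[1:]:
        raise ValueError("group cell shapes differ")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(dt, dnt, axis=0, equal_var=True)

    degenerate = ~np.isfinite(t)
    if degenerate.any():
        means_equal = np.isclose(dt.mean(axis=0), dnt.mean(axis=0))
        p = np.where(degenerate, np.where(means_equal, 1.0, 0.0), p)
        t = np.where(degenerate, 0.0, t)
        logger.info("pointwise_ttest: %d zero-variance cells", int(degenerate.sum()))

    return SignificanceMask(
        mask=p < alpha, alpha=alpha, test="student_t", t_values=t, p_values=p
    )


def attended_vs_nonattended_mask(
    epochs: EpochSet, stream: int | None = None, alpha: float = 0.01
) -> SignificanceMask:
    """Convenience wrapper building Dt and Dnt from an EpochSet.

    With ``stream`` given, compares that stream's deviants across attention
    status (the per-stream ERP-figure comparison); otherwise pools attended
    deviants of all streams against nonattended deviants of all streams.
    """
    dt = epochs.select(stream=stream, role="deviant", attended=True)
    dnt = epochs.select(stream=stream, role="deviant", attended=False)
    return pointwise_ttest(dt, dnt, alpha=alpha)


def significant_clusters(
    mask: SignificanceMask,
    rate: float,
    tmin: float,
    channel_labels: list[str],
) -> pd.DataFrame:
    """Contiguous significant intervals per channel (channel, start_ms, end_ms)."""
    rows = []
    for ch, lab in enumerate(channel_labels):
        m = mask.mask[ch]
        edges = np.flatnonzero(np.diff(np.r_[0, m.astype(int), 0]))
        for s0, s1 in zip(edges[::2], edges[1::2]):
            rows.append(
                {
                    "channel": lab,
                    "start_ms": (tmin + s0 / rate) * 1000.0,
                    "end_ms": (tmin + s1 / rate) * 1000.0,
                }
            )
    return pd.DataFrame(rows, columns=["channel", "start_ms", "end_ms"])
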