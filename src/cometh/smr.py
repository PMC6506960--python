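"""Similarly methylated regions: segmentation and trimmed summaries.

An SMR is a maximal run of consecutive CpGs sharing one methylation state
(AAAA..., DDDD..., etc.).  An NA site terminates the current run.  Each
SMR is characterized by its CG count (number of member sites) and its
length in bp (last position - first position, so the shortest reportable
two-site SMR — adjacent CGCG — has length 2).  Runs with fewer than
``min_count`` sites (default 2) are not reported.  Distribution summaries
report min, Q1, median, mean, Q3 and max after removing one occurrence of
the largest value, which guards the summary against a single extreme
outlier region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UsageError
from .track import NA_STATE, STATES, MethylationTrack

SMR_COLUMNS = ("state", "first_position", "last_position", "cg_count", "length")

METRICS = ("count", "length")


@dataclass
class SMRSet:
    """Ordered, disjoint same-state runs for one track."""

    sample_id: str
    chrom: str
    df: pd.DataFrame = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.df)

    def of_state(self, state: str) -> pd.DataFrame:
        return self.df[self.df["state"] == state]

    def values(self, state: str, metric: str) -> np.ndarray:
        """The count or length multiset for one state."""
        if metric not in METRICS:
            raise UsageError(f"unknown metric {metric!r}")
        col = "cg_count" if metric == "count" else "length"
        return self.of_state(state)[col].to_numpy()


def segment_smrs(
    track: MethylationTrack,
    min_count: int = 2,
    na_breaks: bool = True,
) -> SMRSet:
    """Segment an annotated track into maximal same-state runs.

    NA sites break runs (``na_breaks=False`` makes them transparent
    instead, for sensitivity analysis: a run may then span NA sites, which
    do not count toward ``cg_count`` but do extend nothing — the run's
    endpoints remain non-NA member sites).  Runs with fewer than
    ``min_count`` sites are discarded.
    """
    track.require_annotated("segment_smrs")
    if min_count < 1:
        raise UsageError("min_count must be >= 1")
    states = track.df["state"].to_numpy(dtype=object)
    pos = track.positions
    if not na_breaks:
        keep = states != NA_STATE
        states = states[keep]
        pos = pos[keep]
    records = []
    n = len(states)
    i = 0
    while i < n:
        s = states[i]
        j = i + 1
        while j < n and states[j] == s:
            j += 1
        run_len = j - i
        if s != NA_STATE and run_len >= min_count:
            records.append(
                (s, int(pos[i]), int(pos[j - 1]), run_len, int(pos[j - 1] - pos[i]))
            )
        i = j
    df = pd.DataFrame(records, columns=list(SMR_COLUMNS))
    if not records:
        df = df.astype(
            {"first_position": np.int64, "last_position": np.int64,
             "cg_count": np.int64, "length": np.int64}
        )
    return SMRSet(track.sample_id, track.chrom, df)


@dataclass(frozen=True)
class SixNumberSummary:
    """min, Q1, median, mean, Q3, max of a distribution (all NaN if empty)."""

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float

    @property
    def is_empty(self) -> bool:
        return np.isnan(self.min)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.min, self.q1, self.median, self.mean, self.q3, self.max)


EMPTY_SUMMARY = SixNumberSummary(*([float("nan")] * 6))


def six_number(values: np.ndarray, quantile_method: str = "linear") -> SixNumberSummary:
    """Six-number summary with configurable quantile convention.

    The default ``"linear"`` interpolation between order statistics matches
    the convention of R's ``summary()``/``quantile(type = 7)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return EMPTY_SUMMARY
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=quantile_method)
    return SixNumberSummary(
        float(values.min()), float(q1), float(med),
        float(values.mean()), float(q3), float(values.max()),
    )


def summarize_smrs(
    smrset: SMRSet,
    state: str,
    metric: str,
    drop_largest: bool = True,
    quantile_method: str = "linear",
) -> SixNumberSummary:
    """Trimmed six-number summary of one state's count or length multiset.

    With ``drop_largest`` (the default) exactly one occurrence of the
    maximum value is removed before summarizing, so a single extreme
    region cannot dominate the summary.  A state with no SMRs (or none
    left after trimming) yields the empty sentinel, not an error.
    """
    if state not in STATES:
        raise UsageError(f"unknown state {state!r}")
    vals = smrset.values(state, metric).astype(float)
    if drop_largest and vals.size:
        vals = np.delete(vals, int(np.argmax(vals)))
    return six_number(vals, quantile_method)


def smr_report(
    smrsets: Mapping[str, SMRSet],
    drop_largest: bool = True,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Summary table over samples x states x metrics.

    One row per (sample, state, metric) with the six summary columns;
    empty combinations appear as all-NaN sentinel rows.
    """
    rows = []
    for sample, smrset in smrsets.items():
        for state in STATES:
            for metric in METRICS:
                s = summarize_smrs(smrset, state, metric, drop_largest,
                                   quantile_method)
                rows.append((sample, state, metric) + s.as_tuple())
    return pd.DataFrame(
        rows,
        columns=["sample", "state", "metric",
                 "min", "q1", "median", "mean", "q3", "max"],
    )
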