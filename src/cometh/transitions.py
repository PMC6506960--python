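"""Methylation state pairs, transition count tables, and distance profiles.

Consecutive CpGs (no intervening CpG on the same strand) form a
"methylation state pair": the ordered states of the two sites, e.g. AD.
Pairs with an NA member are excluded and pairs never bridge an NA site —
adjacency is positional.  The marginal 4x4 count table conditions row
percentages on the initial state; the distance-binned table stratifies
pairs into 50-bp gap bins ([0,50), [50,100), ..., [450,500), [500,inf))
and reports each pair's percent occurrence within its bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .track import NA_STATE, STATES, MethylationTrack

#: Left edges of the default distance bins; the final bin is open-ended.
DEFAULT_BIN_EDGES: tuple[int, ...] = tuple(range(0, 501, 50))

PAIR_LABELS: tuple[str, ...] = tuple(a + b for a in STATES for b in STATES)


def bin_labels(edges) -> list[str]:
    """Human-readable labels for half-open bins ending in [last, inf)."""
    edges = list(edges)
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"[{edges[-1]},Inf)")
    return labels


def build_state_pairs(track: MethylationTrack) -> pd.DataFrame:
    """Extract state pairs from an annotated track.

    Returns a DataFrame with columns ``initial``, ``terminal`` and
    ``distance`` (the forward distance of the left site), one row per
    adjacent site pair in which neither member is NA, in track order.
    """
    track.require_annotated("build_state_pairs")
    states = track.df["state"].to_numpy(dtype=object)
    dist = track.df["distance"].to_numpy(dtype=float)
    if len(states) < 2:
        return pd.DataFrame({"initial": [], "terminal": [], "distance": []})
    initial = states[:-1]
    terminal = states[1:]
    keep = (initial != NA_STATE) & (terminal != NA_STATE)
    return pd.DataFrame(
        {
            "initial": initial[keep],
            "terminal": terminal[keep],
            "distance": dist[:-1][keep].astype(np.int64),
        }
    )


@dataclass
class TransitionCountTable:
    """4x4 initial -> terminal state-pair counts with row percentages."""

    sample_id: str
    counts: pd.DataFrame = field(repr=False)  # index=initial, columns=terminal

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def percentages(self) -> pd.DataFrame:
        """100 * count / row total; rows with zero total are all-NaN."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = self.counts.div(totals.where(totals > 0), axis=0) * 100.0
        return pct

    @property
    def total_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        """Side-by-side counts and percentages (report layout)."""
        pct = self.percentages
        out = pd.concat(
            {"count": self.counts, "percentage": pct.round(2)}, axis=1
        )
        out.index.name = "initial"
        return out


def count_transitions(
    pairs: pd.DataFrame, sample_id: str = ""
) -> TransitionCountTable:
    """Tabulate state pairs into a 4x4 count table."""
    counts = pd.DataFrame(
        0, index=list(STATES), columns=list(STATES), dtype=np.int64
    )
    if len(pairs):
        tab = pd.crosstab(pairs["initial"], pairs["terminal"])
        counts = counts.add(tab.reindex(index=list(STATES),
                                        columns=list(STATES),
                                        fill_value=0), fill_value=0)
        counts = counts.astype(np.int64)
    counts.index.name = "initial"
    counts.columns.name = "terminal"
    return TransitionCountTable(sample_id, counts)


@dataclass
class DistanceBinnedTransitionTable:
    """Per-distance-bin 4x4 transition counts.

    ``counts`` has a (bin, initial) MultiIndex over rows and the terminal
    states as columns; bins partition the pairs (every pair falls in
    exactly one half-open bin, the final bin being open-ended).
    """

    sample_id: str
    bin_edges: tuple[int, ...]
    counts: pd.DataFrame = field(repr=False)

    @property
    def labels(self) -> list[str]:
        return bin_labels(self.bin_edges)

    def bin_counts(self, label: str) -> pd.DataFrame:
        return self.counts.loc[label]

    def bin_totals(self) -> pd.Series:
        return self.counts.groupby(level=0, sort=False).sum().sum(axis=1)

    def marginal(self) -> TransitionCountTable:
        """Summing over bins reproduces the unstratified table exactly."""
        tot = self.counts.groupby(level=1, sort=False).sum()
        tot = tot.reindex(list(STATES))
        tot.index.name = "initial"
        return TransitionCountTable(self.sample_id, tot.astype(np.int64))

    def percent_occurrence(self, denominator: str = "bin-total") -> pd.DataFrame:
        """Percent occurrence of the 16 pairs, one row per bin.

        ``denominator="bin-total"`` divides each pair count by the bin's
        total over all 16 pairs; ``"row-total"`` conditions on the initial
        state within the bin.  Empty denominators give NaN.
        """
        if denominator not in ("bin-total", "row-total"):
            raise UsageError(f"unknown denominator {denominator!r}")
        rows = {}
        for lab in self.labels:
            tab = self.bin_counts(lab).to_numpy(dtype=float)
            if denominator == "bin-total":
                denom = tab.sum()
                with np.errstate(invalid="ignore", divide="ignore"):
                    pct = np.where(denom > 0, tab / denom * 100.0, np.nan)
            else:
                rt = tab.sum(axis=1, keepdims=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    pct = np.where(rt > 0, tab / rt * 100.0, np.nan)
            rows[lab] = pct.ravel()
        out = pd.DataFrame.from_dict(rows, orient="index", columns=list(PAIR_LABELS))
        out.index.name = "distance_bin"
        return out


def bin_transitions_by_distance(
    pairs: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    sample_id: str = "",
) -> DistanceBinnedTransitionTable:
    """Stratify state pairs into half-open distance bins."""
    edges = tuple(int(e) for e in bin_edges)
    if list(edges) != sorted(set(edges)):
        raise UsageError("bin edges must be sorted and unique")
    labels = bin_labels(edges)
    full_edges = np.array(list(edges) + [np.inf])
    idx = pd.MultiIndex.from_product(
        [labels, list(STATES)], names=["distance_bin", "initial"]
    )
    counts = pd.DataFrame(0, index=idx, columns=list(STATES), dtype=np.int64)
    counts.columns.name = "terminal"
    if len(pairs):
        d = pairs["distance"].to_numpy(dtype=float)
        if (d < edges[0]).any():
            raise UsageError("pair distance below the first bin edge")
        which = np.searchsorted(full_edges, d, side="right") - 1
        lab = np.array(labels, dtype=object)[which]
        tab = pd.crosstab([lab, pairs["initial"]], pairs["terminal"])
        tab.index.names = ["distance_bin", "initial"]
        counts = counts.add(
            tab.reindex(index=idx, columns=list(STATES), fill_value=0),
            fill_value=0,
        ).astype(np.int64)
    return DistanceBinnedTransitionTable(sample_id, edges, counts)


def distance_profile(
    binned: DistanceBinnedTransitionTable,
    pair: str | tuple[str, str],
    denominator: str = "bin-total",
) -> pd.Series:
    """Percent occurrence of one state pair across distance bins.

    ``pair`` is a two-letter label like ``"DD"`` or an (initial, terminal)
    tuple.  Empty bins yield NaN.
    """
    if isinstance(pair, tuple):
        pair = pair[0] + pair[1]
    if pair not in PAIR_LABELS:
        raise UsageError(f"unknown state pair {pair!r}")
    return binned.percent_occurrence(denominator)[pair]
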