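"""Pearson chi-squared comparison of transition patterns across samples.

For each initial state, the per-sample terminal-state counts form an
r x 4 contingency table (rows = samples, columns = terminal states).  The
Pearson statistic X^2 = sum (O - E)^2 / E with E_ij = row_i * col_j / N is
computed without continuity correction; its per-cell terms are the
"contributions" used to attribute the difference to particular samples and
state pairs.  Because genome-scale counts make any difference significant,
a divide-by-n sensitivity scan re-tests the table with counts uniformly
divided by 10, 100, 1000; without rounding, X^2 scales exactly as 1/n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import UsageError
from .track import STATES
from .transitions import TransitionCountTable

#: Expected-count threshold below which the chi-squared approximation is
#: conventionally considered unreliable.
MIN_EXPECTED_WARN = 5.0


@dataclass
class ContingencyTable:
    """Samples x terminal-states counts for one initial state."""

    initial_state: str
    counts: pd.DataFrame = field(repr=False)  # index=samples, columns=A-D

    @property
    def row_labels(self) -> list[str]:
        return list(self.counts.index)

    def validate(self) -> None:
        arr = self.counts.to_numpy(dtype=float)
        if arr.shape[0] < 2:
            raise UsageError("a contingency table needs at least 2 samples")
        if (arr < 0).any():
            raise UsageError("negative counts in contingency table")
        row_zero = arr.sum(axis=1) == 0
        if row_zero.any():
            bad = self.counts.index[np.argmax(row_zero)]
            raise UsageError(f"all-zero row for sample {bad!r}")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: pd.DataFrame = field(repr=False)
    min_expected: float
    low_expected_warning: bool

    @property
    def p_display(self) -> str:
        """Printed p-value; underflowed values show as '~0'."""
        return "~0" if self.p_value < 5e-324 * 2 else f"{self.p_value:.3g}"


@dataclass
class ContributionTable:
    """Per-cell (O-E)^2/E terms of one chi-squared test."""

    cells: pd.DataFrame = field(repr=False)

    @property
    def by_sample(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def by_terminal_state(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.cells.to_numpy().sum())


def build_contingency(
    tables: list[TransitionCountTable], initial_state: str
) -> ContingencyTable:
    """Stack one initial-state row per sample into a contingency table."""
    if initial_state not in STATES:
        raise UsageError(f"unknown initial state {initial_state!r}")
    if len(tables) < 2:
        raise UsageError("need at least 2 samples to compare")
    rows = {}
    for t in tables:
        rows[t.sample_id] = t.counts.loc[initial_state]
    ct = ContingencyTable(initial_state, pd.DataFrame(rows).T)
    ct.validate()
    return ct


def _expected(arr: np.ndarray) -> np.ndarray:
    total = arr.sum()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


def pearson_chi_square(ct: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-squared test of homogeneity, no continuity correction.

    The statistic is computed directly from its cell decomposition so that
    :func:`cell_contributions` sums to it exactly.
    """
    ct.validate()
    arr = ct.counts.to_numpy(dtype=float)
    # a terminal state observed in no sample carries no information
    keep = arr.sum(axis=0) > 0
    used = arr[:, keep]
    if used.sum() == 0:
        raise UsageError("contingency table has zero grand total")
    exp = _expected(used)
    stat = float(((used - exp) ** 2 / exp).sum())
    dof = (used.shape[0] - 1) * (used.shape[1] - 1)
    p = float(chi2.sf(stat, dof)) if dof > 0 else 1.0
    expected = pd.DataFrame(
        np.zeros_like(arr), index=ct.counts.index, columns=ct.counts.columns
    )
    expected.loc[:, ct.counts.columns[keep]] = exp
    min_exp = float(exp.min())
    return ChiSquareResult(
        statistic=stat,
        df=dof,
        p_value=p,
        expected=expected,
        min_expected=min_exp,
        low_expected_warning=min_exp < MIN_EXPECTED_WARN,
    )


def cell_contributions(ct: ContingencyTable) -> ContributionTable:
    """Per-cell (O-E)^2/E; rows and columns sum to the Pearson statistic."""
    ct.validate()
    arr = ct.counts.to_numpy(dtype=float)
    keep = arr.sum(axis=0) > 0
    exp = np.zeros_like(arr)
    exp[:, keep] = _expected(arr[:, keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(exp > 0, (arr - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    return ContributionTable(
        pd.DataFrame(cells, index=ct.counts.index, columns=ct.counts.columns)
    )


ROUNDING_RULES = ("half-away", "floor", "none")


def scale_counts(
    ct: ContingencyTable, divisor: float, rounding: str = "half-away"
) -> ContingencyTable:
    """Divide every count by ``divisor`` and round per the chosen rule.

    ``"half-away"`` rounds halves away from zero (159513/10 -> 15951),
    ``"floor"`` truncates, ``"none"`` keeps fractional counts (under which
    the Pearson statistic scales exactly as 1/divisor).
    """
    if divisor <= 0:
        raise UsageError("divisor must be positive")
    if rounding not in ROUNDING_RULES:
        raise UsageError(f"unknown rounding rule {rounding!r}")
    arr = ct.counts.to_numpy(dtype=float) / divisor
    if rounding == "half-away":
        arr = np.floor(arr + 0.5)  # counts are non-negative
    elif rounding == "floor":
        arr = np.floor(arr)
    out = pd.DataFrame(arr, index=ct.counts.index, columns=ct.counts.columns)
    return ContingencyTable(ct.initial_state, out)


def sensitivity_scan(
    tables: list[TransitionCountTable],
    initial_state: str,
    divisors=(1, 10, 100, 1000),
    rounding: str = "half-away",
) -> dict[float, ChiSquareResult | None]:
    """Chi-squared test at each divisor of the large-count sensitivity scan.

    Results whose minimum expected count falls below 5 carry the
    ``low_expected_warning`` flag: at that point the approximation (and
    hence the scan step) should not be interpreted.  A divisor so large
    that rounding empties an entire row (the test becomes undefined)
    yields ``None`` for that step.
    """
    if any(d <= 0 for d in divisors):
        raise UsageError("divisors must be positive")
    ct = build_contingency(tables, initial_state)
    out: dict[float, ChiSquareResult | None] = {}
    for d in divisors:
        try:
            out[d] = pearson_chi_square(scale_counts(ct, d, rounding))
        except UsageError:
            out[d] = None
    return out


def pairwise_chi_square(
    tables: list[TransitionCountTable], initial_state: str
) -> dict[tuple[str, str], ChiSquareResult]:
    """One 2 x 4 chi-squared test per unordered sample pair.

    No multiplicity adjustment is applied (adjust downstream if desired).
    """
    if len(tables) < 2:
        raise UsageError("need at least 2 samples for pairwise tests")
    out: dict[tuple[str, str], ChiSquareResult] = {}
    for ta, tb in itertools.combinations(tables, 2):
        ct = build_contingency([ta, tb], initial_state)
        out[(ta.sample_id, tb.sample_id)] = pearson_chi_square(ct)
    return out
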