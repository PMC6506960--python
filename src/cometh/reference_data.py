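"""Published chromosome-1 transition tables for Roadmap Epigenomics tissues.

These are the reported methylation state-pair statistics for whole genome
bisulfite sequencing of normal human tissues from the Roadmap Epigenomics
Project (chromosome 1, forward strand): state-pair *counts* for the spleen
tissue of three individuals (STL001, STL002, STL003 — the three-sample,
one-tissue comparison) and state-pair row *percentages* for eight tissues
of individual STL001 (the one-sample, eight-tissue comparison).

They serve two roles: worked-example inputs for the chi-squared comparison
layer, and calibration for the synthetic track generator, whose default
base transition matrix is the STL001 spleen row-percentage matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .track import STATES
from .transitions import TransitionCountTable

#: State-pair counts (initial state -> terminal state) per spleen sample.
SPLEEN_3S1T_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "STL001": {
        "A": (159513, 12082, 7505, 16928),
        "B": (12129, 13298, 14876, 30868),
        "C": (7398, 15037, 41996, 119380),
        "D": (17048, 30890, 119492, 1425036),
    },
    "STL002": {
        "A": (170787, 13663, 9638, 18661),
        "B": (13745, 17814, 21403, 35313),
        "C": (9592, 21348, 63698, 151667),
        "D": (18723, 35534, 151708, 1308261),
    },
    "STL003": {
        "A": (209282, 13179, 8953, 17408),
        "B": (13282, 20626, 22691, 34669),
        "C": (9104, 22403, 71035, 154423),
        "D": (17244, 35103, 154381, 1342781),
    },
}

#: Reported row percentages for the same three spleen samples.
SPLEEN_3S1T_PERCENTAGES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "STL001": {
        "A": (81.37, 6.16, 3.83, 8.64),
        "B": (17.04, 18.69, 20.90, 43.37),
        "C": (4.03, 8.18, 22.85, 64.95),
        "D": (1.07, 1.94, 7.50, 89.49),
    },
    "STL002": {
        "A": (80.28, 6.42, 4.53, 8.77),
        "B": (15.57, 20.18, 24.25, 40.00),
        "C": (3.89, 8.67, 25.86, 61.58),
        "D": (1.24, 2.35, 10.02, 86.40),
    },
    "STL003": {
        "A": (84.11, 5.30, 3.60, 7.00),
        "B": (14.55, 22.60, 24.86, 37.99),
        "C": (3.54, 8.72, 27.64, 60.10),
        "D": (1.11, 2.27, 9.96, 86.66),
    },
}

#: Row-percentage matrices for eight tissues of sample STL001.
TISSUE_1S8T_PERCENTAGES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Bladder": {
        "A": (83.26, 6.62, 3.90, 6.23),
        "B": (14.03, 24.60, 25.51, 35.86),
        "C": (3.90, 11.65, 27.34, 57.11),
        "D": (1.05, 2.81, 9.59, 86.54),
    },
    "Gastric": {
        "A": (79.25, 7.53, 5.08, 8.14),
        "B": (13.96, 22.65, 25.90, 37.49),
        "C": (3.98, 10.64, 26.56, 58.82),
        "D": (1.19, 2.91, 10.98, 84.92),
    },
    "Lung": {
        "A": (79.58, 6.78, 4.19, 9.45),
        "B": (17.20, 20.25, 20.32, 42.23),
        "C": (4.47, 8.32, 22.13, 65.09),
        "D": (1.16, 2.04, 7.49, 89.32),
    },
    "Psoas": {
        "A": (74.16, 8.84, 6.61, 10.40),
        "B": (14.55, 21.15, 24.93, 39.38),
        "C": (4.75, 10.78, 24.99, 59.49),
        "D": (1.39, 3.15, 10.89, 84.57),
    },
    "SigmoidColon": {
        "A": (86.99, 4.38, 2.73, 5.90),
        "B": (12.46, 23.87, 25.10, 38.57),
        "C": (2.81, 9.03, 30.42, 57.75),
        "D": (0.85, 1.95, 8.02, 89.18),
    },
    "SmallBowel": {
        "A": (85.48, 5.08, 3.55, 5.89),
        "B": (11.66, 24.47, 27.92, 35.96),
        "C": (2.92, 10.32, 31.69, 55.07),
        "D": (0.94, 2.51, 10.46, 86.09),
    },
    "Spleen": {
        "A": (81.37, 6.16, 3.83, 8.64),
        "B": (17.04, 18.69, 20.90, 43.37),
        "C": (4.03, 8.18, 22.85, 64.95),
        "D": (1.07, 1.94, 7.50, 89.49),
    },
    "Thymus": {
        "A": (86.27, 4.12, 2.19, 7.42),
        "B": (18.33, 17.02, 14.77, 49.89),
        "C": (5.66, 8.92, 17.17, 68.24),
        "D": (1.01, 1.52, 3.49, 93.98),
    },
}


def _to_frame(rows: dict[str, tuple], dtype) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(STATES)).astype(dtype)
    df.index.name = "initial"
    df.columns.name = "terminal"
    return df


def spleen_transition_table(sample: str) -> TransitionCountTable:
    """The published state-pair count table of one spleen sample."""
    if sample not in SPLEEN_3S1T_COUNTS:
        raise KeyError(f"unknown spleen sample {sample!r}")
    return TransitionCountTable(sample, _to_frame(SPLEEN_3S1T_COUNTS[sample], np.int64))


def spleen_transition_tables() -> list[TransitionCountTable]:
    """All three published spleen count tables, in sample order."""
    return [spleen_transition_table(s) for s in SPLEEN_3S1T_COUNTS]


def tissue_transition_matrix(tissue: str) -> np.ndarray:
    """A tissue's row-stochastic transition matrix (percentages / 100).

    Rows are renormalized to sum to exactly 1 (the printed percentages
    carry rounding error of up to 0.005 per cell).
    """
    if tissue not in TISSUE_1S8T_PERCENTAGES:
        raise KeyError(f"unknown tissue {tissue!r}")
    mat = _to_frame(TISSUE_1S8T_PERCENTAGES[tissue], float).to_numpy() / 100.0
    return mat / mat.sum(axis=1, keepdims=True)


def default_base_transition() -> np.ndarray:
    """The STL001 spleen matrix — the generator's default base kernel."""
    return tissue_transition_matrix("Spleen")
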