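"""Core container for one chromosome of per-CpG methylation data.

A :class:`MethylationTrack` holds the ordered CpG records of a single
chromosome of a single sample or tissue: 1-based forward-strand position,
sequencing coverage, and the MC ratio (the fraction of reads covering the
site that are methylated, analogous to an array beta value).  After
annotation it additionally carries the discrete methylation state (A-D or
NA) and the forward distance in bp to the next CpG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The four methylation states, ordered from unmethylated to fully methylated.
STATES: tuple[str, ...] = ("A", "B", "C", "D")

#: Label for sites excluded by the coverage filter or with no ratio.
NA_STATE: str = "NA"

#: Columns every track must carry.
CORE_COLUMNS: tuple[str, ...] = ("position", "coverage", "mc_ratio")

#: Columns added by annotation.
ANNOT_COLUMNS: tuple[str, ...] = ("state", "distance")


@dataclass
class MethylationTrack:
    """Ordered per-CpG records for one chromosome of one sample.

    Parameters
    ----------
    sample_id
        Label for the sample or tissue (e.g. ``"STL001_spleen"``).
    chrom
        Chromosome name; every record belongs to it.
    df
        One row per CpG with columns ``position`` (1-based bp, strictly
        increasing), ``coverage`` (reads, >= 0) and ``mc_ratio`` (in [0, 1],
        NaN when missing).  Annotation adds ``state`` (A/B/C/D/NA) and
        ``distance`` (bp to the next site; NaN on the last row).
    """

    sample_id: str
    chrom: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    @property
    def is_annotated(self) -> bool:
        """True when both state and forward distance have been computed."""
        return all(c in self.df.columns for c in ANNOT_COLUMNS)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"track is missing columns {missing}")
        pos = self.df["position"].to_numpy()
        if len(pos) > 1:
            diffs = np.diff(pos)
            if (diffs <= 0).any():
                bad = int(np.argmax(diffs <= 0))
                word = "duplicate" if diffs[bad] == 0 else "decreasing"
                raise ValidationError(
                    f"{word} position {pos[bad + 1]} at record {bad + 1} "
                    f"of track {self.sample_id!r}"
                )
        cov = self.df["coverage"].to_numpy()
        if (cov < 0).any():
            raise ValidationError("negative coverage encountered")
        ratio = self.df["mc_ratio"].to_numpy(dtype=float)
        present = ~np.isnan(ratio)
        if ((ratio[present] < 0) | (ratio[present] > 1)).any():
            raise ValidationError("mc_ratio outside [0, 1]")
        if (present & (cov == 0)).any():
            raise ValidationError(
                "mc_ratio present at a site with coverage 0 "
                f"in track {self.sample_id!r}"
            )

    def require_annotated(self, op: str) -> None:
        from .errors import UsageError

        if not self.is_annotated:
            raise UsageError(
                f"{op} requires an annotated track; run state assignment "
                "and forward-distance computation first"
            )

    # ------------------------------------------------------------------
    def copy(self) -> "MethylationTrack":
        return MethylationTrack(self.sample_id, self.chrom, self.df.copy())


def make_track(
    sample_id: str,
    chrom: str,
    positions,
    coverages,
    mc_ratios,
) -> MethylationTrack:
    """Build a track from parallel sequences (convenience constructor)."""
    df = pd.DataFrame(
        {
            "position": np.asarray(positions, dtype=np.int64),
            "coverage": np.asarray(coverages, dtype=np.int64),
            "mc_ratio": np.asarray(mc_ratios, dtype=float),
        }
    )
    return MethylationTrack(sample_id, chrom, df)
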