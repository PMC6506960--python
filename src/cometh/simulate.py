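"""Synthetic per-CpG methylation tracks with known co-methylation structure.

The generator produces the statistical structure the analysis pipeline
assumes, with full ground truth, so every stage can be exercised and
validated without external data:

* CpG positions with realistic spacing — fixed, or shifted-geometric with
  a 2 bp minimum (adjacent CGCG) and configurable mean;
* a latent methylation-state chain whose kernel relaxes with genomic
  distance, ``T(d) = w T0 + (1 - w) 1 pi^T`` with ``w = exp(-d / lambda)``:
  at small gaps the chain follows the base kernel T0 (persistent A/D,
  upward-drifting B/C), at large gaps states become independent draws from
  the stationary distribution pi — the distance decay of co-methylation;
* per-state MC-ratio emissions within the state's ratio interval;
* read sampling: coverage from a zero-inflated truncated Poisson and
  methylated reads Binomial(coverage, true ratio), so the observed MC
  ratio is the methylated-read fraction exactly as in real tables.

The default base kernel is the published STL001 spleen transition matrix;
tissue-specific kernels for the eight STL001 tissues are available for
multi-tissue experiments.  All randomness flows from one seeded generator,
so a config (including its seed) fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .reference_data import default_base_transition
from .track import NA_STATE, STATES, MethylationTrack
from .transitions import DEFAULT_BIN_EDGES, bin_labels

STATE_BOUNDS = {
    "A": (0.0, 0.25),
    "B": (0.25, 0.5),
    "C": (0.5, 0.75),
    "D": (0.75, 1.0),
}

EMISSIONS = ("uniform", "interior", "beta")
SPACINGS = ("geometric", "fixed")


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic track.

    Defaults emulate a chromosome-1 forward-strand WGBS track of normal
    tissue: ~110 bp mean CpG spacing, ~30X mean coverage with 5% of sites
    uncovered, the STL001 spleen base kernel, and co-methylation decaying
    over a kilobase scale.
    """

    n_sites: int = 10_000
    spacing: str = "geometric"      # or "fixed"
    mean_spacing: float = 110.0     # bp; the fixed gap when spacing="fixed"
    coverage_mean: float = 30.0     # truncated-Poisson mean (>=1 reads)
    zero_coverage_prob: float = 0.05
    base_transition: np.ndarray = field(default_factory=default_base_transition)
    stationary: np.ndarray | None = None  # default: stationary of T0
    decay_length: float = 1000.0    # bp; lambda of the distance decay
    emission: str = "uniform"       # "uniform" | "interior" | "beta"
    interior_margin: float = 0.2    # fraction of interval trimmed per side
    start_position: int = 10_001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.spacing not in SPACINGS:
            raise ValidationError(f"unknown spacing model {self.spacing!r}")
        if self.mean_spacing < 2:
            raise ValidationError("mean_spacing must be >= 2 bp")
        if self.decay_length <= 0:
            raise ValidationError("decay_length must be positive")
        if self.emission not in EMISSIONS:
            raise ValidationError(f"unknown emission model {self.emission!r}")
        if not 0 <= self.interior_margin < 0.5:
            raise ValidationError("interior_margin must be in [0, 0.5)")
        if not 0 <= self.zero_coverage_prob <= 1:
            raise ValidationError("zero_coverage_prob must be in [0, 1]")
        T = np.asarray(self.base_transition, dtype=float)
        if T.shape != (4, 4) or (T < 0).any():
            raise ValidationError("base_transition must be a non-negative 4x4 matrix")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("base_transition rows must sum to 1")
        pi = self.pi
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise ValidationError("stationary distribution must sum to 1")

    @property
    def pi(self) -> np.ndarray:
        if self.stationary is not None:
            return np.asarray(self.stationary, dtype=float)
        return stationary_distribution(np.asarray(self.base_transition, float))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """The latent quantities behind one simulated track."""

    latent_states: np.ndarray       # state labels, same length as the track
    true_ratios: np.ndarray         # emitted MC ratios before read sampling
    gaps: np.ndarray                # realized forward distances (n-1 values)

    def realized_transition_matrices(
        self, bin_edges=DEFAULT_BIN_EDGES
    ) -> dict[str, pd.DataFrame]:
        """Empirical latent-state T(d) per distance bin (row percentages)."""
        return _empirical_matrices(self.latent_states, self.gaps, bin_edges)


def _empirical_matrices(states, gaps, bin_edges) -> dict[str, pd.DataFrame]:
    labels = bin_labels(bin_edges)
    full = np.array(list(bin_edges) + [np.inf], dtype=float)
    out: dict[str, pd.DataFrame] = {}
    initial = np.asarray(states[:-1], dtype=object)
    terminal = np.asarray(states[1:], dtype=object)
    ok = (initial != NA_STATE) & (terminal != NA_STATE)
    which = np.searchsorted(full, np.asarray(gaps, float), side="right") - 1
    for b, lab in enumerate(labels):
        sel = ok & (which == b)
        mat = pd.DataFrame(0.0, index=list(STATES), columns=list(STATES))
        for i, si in enumerate(STATES):
            row_sel = sel & (initial == si)
            tot = int(row_sel.sum())
            if tot == 0:
                mat.loc[si] = np.nan
                continue
            for j, sj in enumerate(STATES):
                mat.loc[si, sj] = 100.0 * (row_sel & (terminal == sj)).sum() / tot
        out[lab] = mat
    return out


def transition_matrix_at_distance(config: SimulationConfig, d: float) -> np.ndarray:
    """The latent kernel at gap d: exponential relaxation toward pi."""
    if d < 1:
        raise UsageError("distance must be >= 1 bp")
    w = float(np.exp(-d / config.decay_length))
    T0 = np.asarray(config.base_transition, dtype=float)
    return w * T0 + (1.0 - w) * np.tile(config.pi, (4, 1))


def _draw_gaps(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if n <= 0:
        return np.array([], dtype=np.int64)
    if config.spacing == "fixed":
        return np.full(n, int(round(config.mean_spacing)), dtype=np.int64)
    # shifted geometric: gap = 1 + G, G ~ Geometric(p) on {1, 2, ...},
    # so min gap = 2 and mean = 1 + 1/p = mean_spacing
    p = 1.0 / (config.mean_spacing - 1.0)
    return 1 + rng.geometric(p, size=n).astype(np.int64)


def _emit_ratios(config, rng, states_idx: np.ndarray) -> np.ndarray:
    lo = np.array([STATE_BOUNDS[s][0] for s in STATES])[states_idx]
    hi = np.array([STATE_BOUNDS[s][1] for s in STATES])[states_idx]
    width = hi - lo
    if config.emission == "uniform":
        return rng.uniform(lo, hi)
    if config.emission == "interior":
        m = config.interior_margin * width
        return rng.uniform(lo + m, hi - m)
    # beta: a symmetric Beta(2, 2) squeezed into the state interval gives
    # ratios that bunch mid-interval, closer to real bimodal-within-state data
    return lo + width * rng.beta(2.0, 2.0, size=len(states_idx))


def _draw_coverage(config, rng, n: int) -> np.ndarray:
    cov = rng.poisson(config.coverage_mean, size=n)
    for _ in range(100):  # truncate at >= 1 by resampling
        zero = cov == 0
        if not zero.any():
            break
        cov[zero] = rng.poisson(config.coverage_mean, size=int(zero.sum()))
    cov[cov == 0] = 1
    if config.zero_coverage_prob > 0:
        cov[rng.random(n) < config.zero_coverage_prob] = 0
    return cov.astype(np.int64)


def simulate_track(
    config: SimulationConfig,
    sample_id: str = "sim",
    chrom: str = "chrSim",
) -> tuple[MethylationTrack, GroundTruth]:
    """Generate one track and its ground truth.

    The same config (including seed) always yields the same output; all
    draws come from a single ``numpy.random.default_rng`` stream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    gaps = _draw_gaps(config, rng, n - 1)
    positions = config.start_position + np.concatenate(
        [[0], np.cumsum(gaps)]
    ).astype(np.int64)

    # latent chain: first site from pi, then kernel T(gap)
    T0 = np.asarray(config.base_transition, dtype=float)
    pi = config.pi
    w = np.exp(-gaps / config.decay_length)
    states_idx = np.empty(n, dtype=np.int64)
    states_idx[0] = rng.choice(4, p=pi)
    u = rng.random(n - 1)
    for i in range(n - 1):
        row = w[i] * T0[states_idx[i]] + (1.0 - w[i]) * pi
        states_idx[i + 1] = np.searchsorted(np.cumsum(row), u[i], side="right")
    states_idx = np.minimum(states_idx, 3)

    true_ratios = _emit_ratios(config, rng, states_idx)
    coverage = _draw_coverage(config, rng, n)
    meth_reads = rng.binomial(coverage, true_ratios)
    with np.errstate(invalid="ignore"):
        mc_ratio = np.where(coverage > 0, meth_reads / np.maximum(coverage, 1), np.nan)

    df = pd.DataFrame(
        {"position": positions, "coverage": coverage, "mc_ratio": mc_ratio}
    )
    track = MethylationTrack(sample_id, chrom, df)
    latent = np.array(STATES, dtype=object)[states_idx]
    truth = GroundTruth(latent, true_ratios, gaps)
    return track, truth


def recovery_report(
    annotated: MethylationTrack,
    truth: GroundTruth,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """How well the pipeline recovers the generator's latent structure.

    Returns one row per distance bin with the maximum absolute deviation
    (percentage points) between the pipeline-estimated transition
    percentages (observed states) and the realized latent T(d), plus a
    ``confusion`` row block: per latent state, the fraction of sites whose
    observed state differs (NA observations excluded from the denominator).
    """
    from .transitions import bin_transitions_by_distance, build_state_pairs

    if annotated.n_sites != len(truth.latent_states):
        raise UsageError("track and ground truth have different lengths")
    pairs = build_state_pairs(annotated)
    binned = bin_transitions_by_distance(pairs, bin_edges, annotated.sample_id)
    realized = truth.realized_transition_matrices(bin_edges)

    rows = []
    for lab in binned.labels:
        est_counts = binned.bin_counts(lab).to_numpy(dtype=float)
        row_tot = est_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            est_pct = np.where(row_tot > 0, est_counts / row_tot * 100.0, np.nan)
        true_pct = realized[lab].to_numpy(dtype=float)
        dev = np.abs(est_pct - true_pct)
        max_dev = np.nan if np.isnan(dev).all() else float(np.nanmax(dev))
        rows.append(("transition_max_abs_dev_pp", lab, max_dev))

    obs = annotated.df["state"].to_numpy(dtype=object)
    observed_ok = obs != NA_STATE
    for s in STATES:
        sel = (truth.latent_states == s) & observed_ok
        n_s = int(sel.sum())
        rate = np.nan if n_s == 0 else float((obs[sel] != s).mean())
        rows.append(("confusion_rate", s, rate))
    return pd.DataFrame(rows, columns=["quantity", "key", "value"])
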