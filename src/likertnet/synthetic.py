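"""Synthetic Likert rating tables with planted community structure.

The generator emulates the kind of data the pipeline targets: three
recall conditions, each with roughly 160-172 participants who rated 75
emotion items on a 1-5 scale.  Items are organized into planted blocks
(the ground-truth communities); the latent model is a multivariate
Gaussian with block-constant correlations - ``within_block_corr`` inside
a block, ``between_block_corr`` across blocks - shifted by per-condition,
per-block latent means and discretized to Likert levels by
equal-probability thresholds of the standard normal.

The block-constant correlation structure is sampled exactly through a
shared-factor construction: a global factor carries the between-block
correlation, one factor per block carries the extra within-block
correlation, and independent noise fills the remainder.  Positive
condition mean profiles reproduce the high-endorsement clusters typical
of rating data (and the low-endorsement "negative" block); because
ratings are non-negative, those shared means inflate every cosine
similarity uniformly - the block signal rides on top of that floor.

An optional per-condition block-swap rewires which block some items
belong to in one condition, creating genuine topology differences
between conditions rather than mere mean shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .community import Partition

__all__ = ["SyntheticConfig", "RatingsTable", "generate_ratings", "default_item_labels"]

_DEFAULT_CONDITIONS = ("aesthetic", "non_aesthetic", "consumer")

# Per-block latent means for the default 3-condition x 5-block design.
# Block 4 (index 3) is the low-endorsement "negative" block; the first
# condition endorses the positive blocks most strongly.
_DEFAULT_PROFILES = np.array([
    [0.6, 0.4, 0.5, -0.9, 0.5],
    [0.3, 0.5, 0.3, -0.7, 0.2],
    [0.2, 0.3, 0.4, -0.8, 0.1],
])


def default_item_labels(n_items: int) -> list[str]:
    return [f"item_{i + 1:02d}" for i in range(n_items)]


@dataclass
class RatingsTable:
    """One condition's participants x items table of integer Likert ratings."""

    condition: str
    data: pd.DataFrame  # index: participant ids; columns: item labels
    likert_levels: int = 5

    def __post_init__(self):
        values = self.data.to_numpy()
        if values.size and (np.isnan(values.astype(float)).any()):
            raise ValueError("ratings table contains missing values")
        iv = values.astype(int)
        if values.size and not np.array_equal(iv, values.astype(float)):
            raise ValueError("ratings must be integers")
        if values.size and (iv.min() < 1 or iv.max() > self.likert_levels):
            raise ValueError(
                f"ratings outside [1, {self.likert_levels}] in condition {self.condition!r}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate item labels")
        if self.data.index.duplicated().any():
            raise ValueError(f"duplicate participant ids in condition {self.condition!r}")

    @property
    def item_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_participants(self) -> int:
        return len(self.data)


@dataclass
class SyntheticConfig:
    """Parameters of the planted-block Likert generator.

    ``n_participants_per_condition`` may be a single count or one count
    per condition; ``planted_partition`` maps each item label to a block
    id (default: 5 equal blocks).  ``condition_mean_profiles`` is an
    (n_conditions, n_blocks) array of latent (z-scale) means.
    ``block_swaps`` optionally gives, per condition, the number of
    cross-block item pairs whose block memberships are exchanged in that
    condition's latent structure (a topology manipulation).
    """

    n_items: int = 75
    n_participants_per_condition: int | tuple = (167, 160, 172)
    n_conditions: int = 3
    planted_partition: Partition | None = None
    within_block_corr: float = 0.5
    between_block_corr: float = 0.15
    condition_mean_profiles: np.ndarray | None = None
    likert_levels: int = 5
    seed: int = 0
    condition_names: tuple = ()
    block_swaps: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        if not (0 <= self.within_block_corr < 1) or not (0 <= self.between_block_corr < 1):
            raise ValueError("correlations must lie in [0, 1)")
        if self.within_block_corr <= self.between_block_corr:
            raise ValueError(
                "within_block_corr must exceed between_block_corr, otherwise the "
                "planted structure is undetectable")
        if not self.condition_names:
            if self.n_conditions == len(_DEFAULT_CONDITIONS):
                self.condition_names = _DEFAULT_CONDITIONS
            else:
                self.condition_names = tuple(f"condition_{i + 1}" for i in range(self.n_conditions))
        if len(self.condition_names) != self.n_conditions:
            raise ValueError("condition_names length must equal n_conditions")
        if isinstance(self.n_participants_per_condition, int):
            self.n_participants_per_condition = (self.n_participants_per_condition,) * self.n_conditions
        if len(self.n_participants_per_condition) != self.n_conditions:
            raise ValueError("one participant count per condition required")
        if self.planted_partition is None:
            labels = default_item_labels(self.n_items)
            n_blocks = 5 if self.n_items >= 5 else 1
            sizes = np.full(n_blocks, self.n_items // n_blocks)
            sizes[: self.n_items % n_blocks] += 1
            ids = np.repeat(np.arange(1, n_blocks + 1), sizes)
            self.planted_partition = Partition.from_ids(labels, ids, algorithm="planted")
        elif len(self.planted_partition.labels) != self.n_items:
            # a provided partition defines the item set, one block per item
            raise ValueError("planted partition must cover every item exactly once")
        if any(len(m) == 0 for m in self.planted_partition.communities().values()):
            raise ValueError("planted blocks must be non-empty")
        n_blocks = self.planted_partition.n_communities
        if self.condition_mean_profiles is None:
            if self.n_conditions == _DEFAULT_PROFILES.shape[0] and n_blocks == _DEFAULT_PROFILES.shape[1]:
                self.condition_mean_profiles = _DEFAULT_PROFILES.copy()
            else:
                self.condition_mean_profiles = np.zeros((self.n_conditions, n_blocks))
        self.condition_mean_profiles = np.asarray(self.condition_mean_profiles, dtype=float)
        if self.condition_mean_profiles.shape != (self.n_conditions, n_blocks):
            raise ValueError(
                f"condition_mean_profiles must have shape ({self.n_conditions}, {n_blocks})")
        self._validate_psd()

    @property
    def item_labels(self) -> list[str]:
        if self.planted_partition is not None and self.planted_partition.labels:
            return list(self.planted_partition.labels)
        return default_item_labels(self.n_items)

    def _validate_psd(self):
        """The block-constant latent correlation matrix must be PSD."""
        blocks = self.planted_partition.member_ids(self.item_labels)
        rw, rb = self.within_block_corr, self.between_block_corr
        same = blocks[:, None] == blocks[None, :]
        C = np.where(same, rw, rb)
        np.fill_diagonal(C, 1.0)
        lam_min = float(np.linalg.eigvalsh(C)[0])
        if lam_min < -1e-10:
            raise ValueError(f"latent covariance is not positive semi-definite "
                             f"(min eigenvalue {lam_min:.3e})")


def _likert_thresholds(levels: int) -> np.ndarray:
    """Equal-probability cut points of the standard normal."""
    return norm.ppf(np.arange(1, levels) / levels)


def _sample_condition(cfg: SyntheticConfig, cond_idx: int, blocks: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Latent draws -> integer ratings for one condition.

    blocks: 0-based block index per item (already swap-adjusted).
    """
    n = cfg.n_participants_per_condition[cond_idx]
    rw, rb = cfg.within_block_corr, cfg.between_block_corr
    n_blocks = cfg.condition_mean_profiles.shape[1]
    g_global = rng.standard_normal((n, 1))
    g_block = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, cfg.n_items))
    z = (np.sqrt(rb) * g_global
         + np.sqrt(rw - rb) * g_block[:, blocks]
         + np.sqrt(1.0 - rw) * eps)
    z = z + cfg.condition_mean_profiles[cond_idx][blocks]
    cuts = _likert_thresholds(cfg.likert_levels)
    return 1 + (z[..., None] > cuts).sum(axis=-1)


def _swap_blocks(blocks: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Exchange block membership of n_swaps cross-block item pairs."""
    blocks = blocks.copy()
    for _ in range(n_swaps):
        for _ in range(100):
            i, j = rng.choice(len(blocks), size=2, replace=False)
            if blocks[i] != blocks[j]:
                blocks[i], blocks[j] = blocks[j], blocks[i]
                break
    return blocks


def generate_ratings(config: SyntheticConfig):
    """Generate one RatingsTable per condition plus the planted partition.

    Deterministic given ``config.seed``: each condition consumes its own
    substream spawned from the master seed, so adding a condition does
    not disturb the others.
    """
    labels = config.item_labels
    blocks0 = config.planted_partition.member_ids(labels) - 1
    streams = np.random.SeedSequence(config.seed).spawn(config.n_conditions)
    tables: dict[str, RatingsTable] = {}
    for ci, cond in enumerate(config.condition_names):
        rng = np.random.default_rng(streams[ci])
        blocks = blocks0
        if config.block_swaps.get(cond, 0):
            blocks = _swap_blocks(blocks0, int(config.block_swaps[cond]), rng)
        values = _sample_condition(config, ci, blocks, rng)
        pids = [f"{cond}_p{k + 1:03d}" for k in range(values.shape[0])]
        frame = pd.DataFrame(values, index=pids, columns=labels)
        tables[cond] = RatingsTable(cond, frame, config.likert_levels)
    return tables, config.planted_partition
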