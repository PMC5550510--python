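"""Fold-change DE calls per contrast and cross-contrast vote counting.

A gene is called dysregulated in a contrast when its |log2 fold change|
between the treated and control group means exceeds 1 (fold change > 2)
AND at least one of the two group means reaches a minimum normalized
expression of 5 (log2 scale).  Each contrast in which the gene passes
contributes one direction-specific vote; genes with >= min_votes votes
in one direction across the model panel form the consensus signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from votesig.expression import ExpressionMatrix

__all__ = [
    "Contrast",
    "DECall",
    "PipelineConfig",
    "VoteTable",
    "ConsensusSignature",
    "compute_contrast",
    "call_de",
    "call_de_table",
    "tally_votes",
    "consensus",
]


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-control comparison within one expression matrix."""

    name: str
    treated_group: str
    control_group: str

    def __post_init__(self) -> None:
        if self.treated_group == self.control_group:
            raise ValueError(f"contrast {self.name!r}: treated and control groups are identical")


@dataclass
class PipelineConfig:
    """All analysis thresholds in one place.

    Defaults are the published filter: fold change > 2 (|log2FC| > 1),
    expression floor 5 (log2), votes >= 4 of 5 models, promoter window
    +/-500 bp, alpha 0.05.
    """

    fc_log2: float = 1.0
    expr_floor: float = 5.0
    min_votes: int = 4
    window_half: int = 500
    alpha: float = 0.05
    p_adjust: str = "bh"  # {"bh", "none"}
    enrichment_mode: str = "ease"  # {"ease", "hypergeometric"}
    already_log2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_log2 <= 0:
            raise ValueError(f"fc_log2 must be > 0, got {self.fc_log2}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_votes < 1:
            raise ValueError(f"min_votes must be >= 1, got {self.min_votes}")
        if self.window_half < 0:
            raise ValueError(f"window_half must be >= 0, got {self.window_half}")
        if self.p_adjust not in ("bh", "none"):
            raise ValueError(f"p_adjust must be 'bh' or 'none', got {self.p_adjust!r}")
        if self.enrichment_mode not in ("ease", "hypergeometric"):
            raise ValueError(
                f"enrichment_mode must be 'ease' or 'hypergeometric', got {self.enrichment_mode!r}"
            )


@dataclass(frozen=True)
class DECall:
    gene_id: str
    contrast_name: str
    log2fc: float
    max_group_mean: float
    direction: str  # {"up", "down", "none"}


@dataclass
class VoteTable:
    """Per-gene direction-specific vote counts across contrasts."""

    counts: pd.DataFrame  # index gene_id, columns up_votes / down_votes
    n_contrasts: int

    def __post_init__(self) -> None:
        total = self.counts["up_votes"] + self.counts["down_votes"]
        if (total > self.n_contrasts).any():
            bad = self.counts.index[(total > self.n_contrasts).to_numpy()][0]
            raise ValueError(f"gene {bad!r} has more votes than contrasts")

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class ConsensusSignature:
    """Genes with >= min_votes direction-specific votes, ordered by
    votes descending then gene id."""

    direction: str
    min_votes: int
    genes: list[tuple[str, int]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tdirection\tvotes\n")
            for g, v in self.genes:
                fh.write(f"{g}\t{self.direction}\t{v}\n")


def compute_contrast(matrix: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-gene log2FC (difference of group means on the log2 scale) and
    the larger of the two group means.

    Returns a DataFrame indexed by gene id with columns ``log2fc`` and
    ``max_group_mean``.
    """
    treated = matrix.samples_in_group(contrast.treated_group)
    control = matrix.samples_in_group(contrast.control_group)
    if not treated:
        raise ValueError(f"contrast {contrast.name!r}: no samples in treated group {contrast.treated_group!r}")
    if not control:
        raise ValueError(f"contrast {contrast.name!r}: no samples in control group {contrast.control_group!r}")
    t_mean = matrix.values[treated].mean(axis=1)
    c_mean = matrix.values[control].mean(axis=1)
    return pd.DataFrame(
        {"log2fc": t_mean - c_mean, "max_group_mean": np.maximum(t_mean, c_mean)},
        index=matrix.values.index,
    )


def call_de(log2fc: float, max_group_mean: float, config: PipelineConfig) -> str:
    """Direction of a single DE call: 'up', 'down' or 'none'.

    Up requires log2FC strictly greater than the threshold (fold change
    exactly 2 does not pass "greater than 2-fold") plus the expression
    floor in at least one compared condition.
    """
    if not (np.isfinite(log2fc) and np.isfinite(max_group_mean)):
        raise ValueError("call_de requires finite inputs")
    if max_group_mean >= config.expr_floor:
        if log2fc > config.fc_log2:
            return "up"
        if log2fc < -config.fc_log2:
            return "down"
    return "none"


def call_de_table(stats: pd.DataFrame, contrast_name: str, config: PipelineConfig) -> pd.DataFrame:
    """Vectorized :func:`call_de` over a compute_contrast result."""
    lfc = stats["log2fc"].to_numpy()
    mgm = stats["max_group_mean"].to_numpy()
    floored = mgm >= config.expr_floor
    direction = np.where(
        floored & (lfc > config.fc_log2),
        "up",
        np.where(floored & (lfc < -config.fc_log2), "down", "none"),
    )
    out = stats.copy()
    out["direction"] = direction
    out["contrast_name"] = contrast_name
    return out


def tally_votes(calls: dict[str, pd.DataFrame]) -> VoteTable:
    """Count direction-specific votes per gene across contrasts.

    ``calls`` maps contrast name to a call table with a ``direction``
    column indexed by gene id.  Genes absent from a contrast (platform
    differences) contribute no vote there; the universe is the union.
    """
    universe: pd.Index = pd.Index([])
    for df in calls.values():
        universe = universe.union(df.index)
    up = pd.Series(0, index=universe, dtype=int)
    down = pd.Series(0, index=universe, dtype=int)
    for df in calls.values():
        d = df["direction"]
        up = up.add((d == "up").astype(int), fill_value=0).astype(int)
        down = down.add((d == "down").astype(int), fill_value=0).astype(int)
    counts = pd.DataFrame({"up_votes": up, "down_votes": down})
    return VoteTable(counts=counts, n_contrasts=len(calls))


def consensus(votes: VoteTable, config: PipelineConfig, direction: str) -> ConsensusSignature:
    """Genes with >= min_votes votes in the given direction, sorted by
    votes descending then gene id."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    col = "up_votes" if direction == "up" else "down_votes"
    sel = votes.counts.loc[votes.counts[col] >= config.min_votes, col]
    ordered = sorted(sel.items(), key=lambda gv: (-gv[1], gv[0]))
    return ConsensusSignature(direction=direction, min_votes=config.min_votes, genes=[(g, int(v)) for g, v in ordered])


def log2fc_matrix(stats_by_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x contrasts matrix of log2 fold changes (heat-map export)."""
    cols = {name: df["log2fc"] for name, df in stats_by_contrast.items()}
    return pd.DataFrame(cols)
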