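"""Fold-change screening of log2-scale RMA expression matrices.

The screen mirrors a standard sorted-population microarray analysis: a
"not expressed" threshold is derived from negative-control genes (internal
standards known to be silent in the tissue, e.g. eye-specific genes in
embryonic cortex), and genes are called up- or down-regulated when their
group-mean fold-change between a target and a reference population reaches a
cutoff (3-fold by default) while being expressed above the threshold in at
least one of the two populations.

RMA values are log2 scale, so a difference of group means is a log2
fold-change and ``2**diff`` the linear fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ScreenResult",
    "derive_threshold",
    "fold_change",
    "screen_genes",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample table of log2-scale RMA values with sample groups."""

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_mean(self, group: str) -> pd.Series:
        cols = self.samples_in_group(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)

    def to_tsv(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")
        if groups_path is not None:
            pd.DataFrame(
                {"sample_id": self.sample_ids,
                 "group": [self.group_of[s] for s in self.sample_ids]}
            ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        gdf = pd.read_csv(groups_path, sep="\t")
        return cls(values=values, group_of=dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1])))


@dataclass
class ScreenResult:
    """Outcome of a fold-change screen.

    ``fold_of`` maps every eligible gene to its linear fold-change (target
    over reference, always > 0); ``up_genes`` and ``down_genes`` are disjoint
    and sorted by descending absolute log2 fold-change.
    """

    threshold: float
    fold_cutoff: float
    target_group: str
    reference_group: str
    up_genes: list[str]
    down_genes: list[str]
    fold_of: dict[str, float]
    table: pd.DataFrame = field(repr=False, default=None)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "fold_cutoff": self.fold_cutoff,
            "target_group": self.target_group,
            "reference_group": self.reference_group,
            "n_eligible": int(len(self.fold_of)),
            "n_up": len(self.up_genes),
            "n_down": len(self.down_genes),
        }


def derive_threshold(
    control_rmas: Sequence[float], multiplier: float = 2.0, grain: float = 0.5
) -> float:
    """Expression threshold from negative-control RMA values.

    Returns ``mean + multiplier * SD`` (sample SD, ddof=1) rounded **up** to
    the nearest multiple of ``grain``.  With controls averaging 5.5 with SD
    0.7 and the default rule this yields 5.5 + 1.4 = 6.9, rounded to 7.0 —
    the conventional RMA >= 7 expressed/not-expressed boundary.
    """
    vals = np.asarray(control_rmas, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control values (sample SD undefined)")
    t = float(vals.mean() + multiplier * vals.std(ddof=1))
    if grain <= 0:
        return t
    return float(math.ceil(t / grain - 1e-9) * grain)


def fold_change(rma_target: float, rma_reference: float) -> float:
    """Linear fold-change from two log2-scale RMA values: ``2**(t - r)``."""
    return float(2.0 ** (rma_target - rma_reference))


def screen_genes(
    matrix: ExpressionMatrix,
    target_group: str,
    reference_group: str,
    threshold: float,
    fold_cutoff: float = 3.0,
) -> ScreenResult:
    """Call up- and down-regulated genes between two sample groups.

    A gene is *eligible* when the larger of its two group means reaches
    ``threshold`` (so down-regulated genes expressed only in the reference
    population are kept).  Eligible genes with linear fold >= ``fold_cutoff``
    are up-regulated; those with fold <= 1/``fold_cutoff`` are down-regulated
    (ties at the cutoff included).  Output order is by descending |log2 fold|,
    ties broken by gene id.
    """
    groups = set(matrix.group_of.values())
    for g in (target_group, reference_group):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}")
    if fold_cutoff <= 0:
        raise ValueError("fold_cutoff must be positive")

    tgt = matrix.group_mean(target_group)
    ref = matrix.group_mean(reference_group)
    log2fc = tgt - ref
    eligible = np.maximum(tgt, ref) >= threshold

    df = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "target_mean": tgt.to_numpy(),
            "reference_mean": ref.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "fold": np.exp2(log2fc.to_numpy()),
            "eligible": eligible.to_numpy(),
        }
    )
    log2_cut = np.log2(fold_cutoff)
    df["direction"] = "none"
    df.loc[df["eligible"] & (df["log2fc"] >= log2_cut), "direction"] = "up"
    df.loc[df["eligible"] & (df["log2fc"] <= -log2_cut), "direction"] = "down"
    df = df.sort_values(
        by=["log2fc", "gene_id"],
        key=lambda c: -c.abs() if c.name == "log2fc" else c,
        kind="mergesort",
    ).reset_index(drop=True)

    up = df.loc[df["direction"] == "up", "gene_id"].tolist()
    down = df.loc[df["direction"] == "down", "gene_id"].tolist()
    fold_of = dict(
        zip(df.loc[df["eligible"], "gene_id"], df.loc[df["eligible"], "fold"])
    )
    return ScreenResult(
        threshold=float(threshold),
        fold_cutoff=float(fold_cutoff),
        target_group=target_group,
        reference_group=reference_group,
        up_genes=up,
        down_genes=down,
        fold_of=fold_of,
        table=df,
    )
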