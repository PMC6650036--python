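"""Core containers shared by the QC, stability and workflow layers.

Everything downstream operates on a :class:`CqMatrix` — a complete
genes × samples matrix of mean quantification cycles (Cq, a.k.a. Ct) with a
group label per sample.  Stability estimators return :class:`StabilityTable`
objects so that the four methods stay comparable and exportable through one
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "StabilityTable",
    "GeNormTrace",
    "NormFinderResult",
    "EfficiencyFit",
    "AnovaResult",
    "WorkflowReport",
]


@dataclass
class CqMatrix:
    """Complete matrix of per-sample mean Cq values.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns, mean Cq in cells.  No missing
        values are allowed; all stability estimators assume a complete matrix.
    groups : pandas.Series
        Group (e.g. timepoint) label for every sample; index must equal the
        sample columns of ``values``.
    calibrator_group : str, optional
        Group to which fold changes are referenced (e.g. the earliest
        timepoint in a longitudinal design).
    """

    values: pd.DataFrame
    groups: pd.Series
    calibrator_group: str | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.columns)
        if self.values.isna().any().any():
            raise ValueError("CqMatrix must be complete: missing Cq cells found")
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("Cq values must be finite")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("Cq values must be positive cycle numbers")
        if self.calibrator_group is not None and self.calibrator_group not in set(self.groups):
            raise ValueError(f"calibrator group {self.calibrator_group!r} has no samples")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_groups(self) -> int:
        return self.groups.nunique()

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def require_groups(self, min_groups: int = 2, min_size: int = 2) -> None:
        if self.n_groups < min_groups:
            raise ValueError(f"need at least {min_groups} groups, got {self.n_groups}")
        small = self.group_sizes()[self.group_sizes() < min_size]
        if len(small):
            raise ValueError(f"groups with fewer than {min_size} samples: {dict(small)}")

    def subset(self, genes: list[str]) -> "CqMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)}")
        return CqMatrix(self.values.loc[genes], self.groups.copy(), self.calibrator_group)


# display rounding per method, applied only on export
_SCORE_DECIMALS = {"CV": 1, "GeNorm": 2, "NormFinder": 2, "PairwiseDCt": 3, "SDCq": 2}


@dataclass
class StabilityTable:
    """Per-gene stability scores and ranks for one method (lower = more stable)."""

    method: str
    scores: pd.Series  # full precision, index = gene
    ranks: pd.Series  # 1 = most stable; exact ties share a rank
    flags: pd.Series | None = None  # method-specific boolean flag (e.g. SD>1)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        scores = self.scores
        if rounded and self.method in _SCORE_DECIMALS:
            scores = scores.round(_SCORE_DECIMALS[self.method])
        out = pd.DataFrame({"gene": self.scores.index, "score": scores.to_numpy(),
                            "rank": self.ranks.reindex(self.scores.index).to_numpy()})
        if self.flags is not None:
            out["flagged"] = self.flags.reindex(self.scores.index).to_numpy()
        return out.sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)

    def ordered_genes(self) -> list[str]:
        return list(self.scores.sort_values(kind="stable").index)


def dense_ranks(scores: pd.Series) -> pd.Series:
    """Ascending dense ranks; exactly tied scores share a rank."""
    return scores.rank(method="dense").astype(int)


@dataclass
class GeNormTrace:
    """Stepwise exclusion record of the GeNorm algorithm."""

    exclusion_order: list[str]  # first element = least stable, excluded first
    m_at_step: list[float]  # M of each excluded gene at its elimination step
    final_pair: tuple[str, str]
    final_m: float  # shared M of the final pair (2-gene step)


@dataclass
class NormFinderResult:
    """Model-based stability decomposition (intergroup + intragroup)."""

    stability: pd.Series  # S per gene
    ranks: pd.Series
    intergroup_d: pd.DataFrame  # genes x groups, cycles
    intragroup_var: pd.DataFrame  # genes x groups, squared cycles
    gamma2: float  # estimated variance of the true intergroup deviations
    best_pair: tuple[str, str]
    grouped_stability: float

    def to_table(self) -> StabilityTable:
        return StabilityTable("NormFinder", self.stability, self.ranks)


@dataclass
class EfficiencyFit:
    """Amplification efficiency from a dilution-series standard curve."""

    slope: float  # cycles per log10 input amount
    intercept: float
    efficiency: float  # E = 10^(-1/slope); 2.0 = perfect doubling
    percent_efficiency: float  # (E - 1) * 100
    r_squared: float
    passes: bool  # efficiency and R^2 inside the acceptance gates
    e_low: float = 1.93
    e_high: float = 2.05
    r2_min: float = 0.98


@dataclass
class AnovaResult:
    """Per-gene one-way ANOVA across groups on fold-change values."""

    table: pd.DataFrame  # index = gene; columns F, p, stars

    def significant(self, alpha: float = 0.05) -> list[str]:
        p = self.table["p"]
        return list(self.table.index[(p < alpha).fillna(False)])


@dataclass
class WorkflowReport:
    """Everything the integrated validation workflow produced."""

    cv_table: StabilityTable
    anova: AnovaResult
    fold_changes: pd.DataFrame  # genes x samples, 2^-dCq vs calibrator group mean
    excluded_genes: list[str]
    surviving_genes: list[str]
    normfinder: NormFinderResult
    best_pair: tuple[str, str]
    grouped_stability: float
    normalization_factors: pd.Series  # per sample
    cv_threshold_pct: float
    audit: dict = field(default_factory=dict)  # optional comparison tables
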