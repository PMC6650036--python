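"""Integrated reference-gene validation workflow for longitudinal designs.

The pipeline combines the estimators that are *not* mutually confounded:

1. linearize Cq (2^-Cq) and run CV analysis (absolute overall variation);
2. plot/collect per-gene fold-change profiles against the calibrator group
   and test the group means with one-way ANOVA;
3. exclude genes with CV above a threshold (default 50 %);
4. run NormFinder on the survivors and take its best two-gene combination;
5. build the per-sample normalization factor from that pair and normalize
   target genes with the 2^-ddCt method.

Pairwise methods (GeNorm, pairwise dCt) are available in an optional audit
mode for comparison, since their rankings are inter-dependent and reward
co-regulation rather than stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnovaResult, CqMatrix, StabilityTable, WorkflowReport
from .io_qc import fold_change_vs_calibrator, linearize
from .stability import cv_analysis, genorm, normfinder, pairwise_dct

__all__ = [
    "anova_profiles",
    "exclude_high_cv",
    "integrated_workflow",
    "normalization_factor",
    "normalize_target",
    "star_category",
]

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_category(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if np.isnan(p):
        return "ns"
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def anova_profiles(
    m: CqMatrix,
    calibrator_group: str | None = None,
    on_cq_scale: bool = False,
    correction: str | None = None,
) -> AnovaResult:
    """One-way fixed-effects ANOVA across groups, per gene.

    By default the test is run on the fold-change values 2^-dCq (the scale on
    which expression profiles are drawn), not on raw Cq; exponentiation is
    nonlinear so the two are not equivalent.  ``on_cq_scale=True`` switches to
    Cq.  No multiple-testing correction is applied unless ``correction`` is
    ``"bonferroni"`` or ``"bh"``.
    """
    m.require_groups(min_groups=2, min_size=2)
    data = m.values if on_cq_scale else fold_change_vs_calibrator(m, calibrator_group)
    group_labels = list(dict.fromkeys(m.groups))
    rows = {}
    for gene in data.index:
        per_group = [
            data.loc[gene, m.groups.index[m.groups == g]].to_numpy() for g in group_labels
        ]
        if np.ptp(np.concatenate(per_group)) == 0:
            f_val, p_val = np.nan, np.nan  # all values identical: F undefined
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                f_val, p_val = stats.f_oneway(*per_group)
        rows[gene] = (float(f_val), float(p_val))
    table = pd.DataFrame(rows, index=["F", "p"]).T
    if correction == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
    elif correction == "bh":
        table["p_adj"] = _bh(table["p"].to_numpy())
    pcol = "p_adj" if correction else "p"
    table["stars"] = [star_category(p) for p in table[pcol]]
    return AnovaResult(table)


def _bh(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def exclude_high_cv(cv_table: StabilityTable, threshold_pct: float = 50.0) -> list[str]:
    """Genes surviving the CV screen (CV% <= threshold).

    Genes above the threshold are taken to be highly variable regardless of
    their between-group structure and are dropped before model-based ranking.
    """
    keep = list(cv_table.scores.index[cv_table.scores <= threshold_pct])
    if not keep:
        raise ValueError(
            f"all genes exceed CV {threshold_pct}%; review the threshold or the panel"
        )
    return keep


def normalization_factor(m: CqMatrix, pair: tuple[str, str]) -> pd.Series:
    """Per-sample normalization factor from the two best reference genes.

    NF_sample = 2^(−mean(Cq_g1, Cq_g2)); averaging Cq values (log scale) and
    linearizing equals the geometric mean of the two linearized quantities.
    """
    missing = set(pair) - set(m.values.index)
    if missing:
        raise KeyError(f"reference genes not in matrix: {sorted(missing)}")
    mean_cq = m.values.loc[list(pair)].mean(axis=0)
    nf = np.exp2(-mean_cq)
    nf.name = "normalization_factor"
    return nf


def normalize_target(
    target_cq: pd.Series,
    nf: pd.Series,
    groups: pd.Series,
    calibrator_group: str,
) -> pd.Series:
    """Relative expression of a target gene by the 2^-ddCt method.

    The target quantity 2^-Cq is divided by the per-sample normalization
    factor, then referenced to the mean normalized ratio of the calibrator
    group, whose mean fold is therefore 1 by construction.
    """
    if not set(target_cq.index) == set(nf.index):
        raise ValueError("target and normalization factor cover different samples")
    nf = nf.reindex(target_cq.index)
    groups = groups.reindex(target_cq.index)
    if groups.isna().any():
        raise ValueError("samples without group labels")
    ratio = np.exp2(-target_cq.astype(float)) / nf
    cal = ratio[groups == calibrator_group]
    if len(cal) == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    fold = ratio / cal.mean()
    fold.name = "fold_change"
    return fold


def integrated_workflow(
    m: CqMatrix,
    calibrator_group: str | None = None,
    threshold_pct: float = 50.0,
    audit: bool = False,
) -> WorkflowReport:
    """Run the full validation pipeline and collect every intermediate table.

    Raises if fewer than two groups are present (the workflow is defined for
    longitudinal designs) or if fewer than three genes survive the CV screen
    (NormFinder's decomposition needs k >= 3).
    """
    cal = calibrator_group or m.calibrator_group
    if cal is None:
        raise ValueError("integrated workflow needs a calibrator group")
    m.require_groups(min_groups=2, min_size=2)

    q = linearize(m)
    cv_table = cv_analysis(q)
    folds = fold_change_vs_calibrator(m, cal)
    anova = anova_profiles(m, cal)
    surviving = exclude_high_cv(cv_table, threshold_pct)
    excluded = [g for g in m.genes if g not in surviving]
    if len(surviving) < 3:
        raise ValueError(
            f"only {len(surviving)} genes survive the CV screen; NormFinder needs >= 3"
        )
    sub = m.subset(surviving)
    nf_result = normfinder(sub)
    nfactors = normalization_factor(m, nf_result.best_pair)

    audit_tables: dict = {}
    if audit:
        genorm_table, genorm_trace = genorm(sub)
        audit_tables = {
            "genorm": genorm_table,
            "genorm_trace": genorm_trace,
            "pairwise_dct": pairwise_dct(sub),
        }

    return WorkflowReport(
        cv_table=cv_table,
        anova=anova,
        fold_changes=folds,
        excluded_genes=excluded,
        surviving_genes=surviving,
        normfinder=nf_result,
        best_pair=nf_result.best_pair,
        grouped_stability=nf_result.grouped_stability,
        normalization_factors=nfactors,
        cv_threshold_pct=threshold_pct,
        audit=audit_tables,
    )
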