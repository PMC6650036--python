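"""The four reference-gene stability estimators and correlation analysis.

All estimators score candidate reference genes on a complete Cq matrix with
group labels; in every method a *lower* score means a *more stable* gene.

* :func:`cv_analysis` — coefficient of variation of the linearized
  quantities (2^-Cq) pooled across all samples, groups ignored.  The only
  method whose score for one gene does not depend on the other genes.
* :func:`genorm` — mean pairwise variation M (SD of log-ratios to every
  other gene), with stepwise exclusion of the least stable gene until a
  final pair remains.  Rewards co-regulated genes by construction.
* :func:`normfinder` — model-based decomposition into intergroup deviation
  and intragroup variance with empirical-Bayes shrinkage of the group
  deviations (Andersen-type model).
* :func:`pairwise_dct` — mean over partner genes of the SD of per-sample Cq
  differences; same rationale as GeNorm with a simpler statistic.
* :func:`sd_cq` — SD of raw Cq per gene with a 1-cycle flag; the
  BestKeeper-style screen kept for comparison reports (a gene can pass
  SD < 1 cycle yet vary more than 50 % on the quantity scale).

Conventions: sample SD (n−1 denominator) everywhere; genes in rows, samples
in columns.  GeNorm is computed on Cq differences, which is identical to
log2-ratios of 2^-Cq values (log2(q_j/q_k) = Cq_k − Cq_j, an SD-preserving
sign flip).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import (
    CqMatrix,
    GeNormTrace,
    NormFinderResult,
    StabilityTable,
    dense_ranks,
)

__all__ = [
    "cv_analysis",
    "sd_cq",
    "genorm",
    "normfinder",
    "pairwise_dct",
    "pearson_matrix",
]


# ---------------------------------------------------------------------------
# CV analysis
# ---------------------------------------------------------------------------

def cv_analysis(q: pd.DataFrame) -> StabilityTable:
    """Coefficient of variation (%) of linearized quantities, pooled samples.

    Parameters
    ----------
    q : pandas.DataFrame
        Linearized quantities 2^-Cq, genes × samples (see
        :func:`refstab.io_qc.linearize`).
    """
    if q.shape[1] < 2:
        raise ValueError("CV analysis needs at least 2 samples")
    mean = q.mean(axis=1)
    if (mean == 0).any():
        raise ValueError("zero mean quantity; cannot form CV")
    cv = 100.0 * q.std(axis=1, ddof=1) / mean
    return StabilityTable("CV", cv, dense_ranks(cv))


def sd_cq(m: CqMatrix, sd_flag_limit: float = 1.0) -> StabilityTable:
    """SD of raw Cq per gene across all samples, with an SD > 1 cycle flag.

    This is the screen BestKeeper applies before its index regression.  It is
    provided for comparison reports only: because Cq is a log2 quantity, an
    SD just below one cycle can hide a >50 % coefficient of variation on the
    linear scale.
    """
    if m.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = m.values.std(axis=1, ddof=1)
    return StabilityTable("SDCq", sd, dense_ranks(sd), flags=sd > sd_flag_limit)


# ---------------------------------------------------------------------------
# GeNorm
# ---------------------------------------------------------------------------

def _genorm_m(values: np.ndarray) -> np.ndarray:
    """M value per gene on the current panel: mean over partners of the SD of
    per-sample Cq differences (= SD of log2 quantity ratios)."""
    k = values.shape[0]
    # pairwise SD of differences, k x k
    sd = np.empty((k, k))
    for j in range(k):
        sd[j] = np.std(values - values[j], axis=1, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return sd.sum(axis=1) / (k - 1)


def genorm(m: CqMatrix) -> tuple[StabilityTable, GeNormTrace]:
    """GeNorm stability M with stepwise exclusion down to a final pair.

    At each step the gene with the highest M on the remaining panel is
    eliminated (ties broken by input order) and its M at that step is its
    reported score.  The final two genes share the 2-gene M — the SD of
    their mutual log-ratio — hence the ranking always has two genes at the
    top with the same value.
    """
    genes = m.genes
    if len(genes) < 3:
        raise ValueError("GeNorm needs at least 3 genes")
    remaining = list(genes)
    exclusion_order: list[str] = []
    m_at_step: list[float] = []
    scores: dict[str, float] = {}
    ranks: dict[str, int] = {}

    step_rank = len(genes) - 1
    while len(remaining) > 2:
        mvals = _genorm_m(m.values.loc[remaining].to_numpy())
        worst = int(np.argmax(mvals))  # argmax keeps first on ties = input order
        gene = remaining[worst]
        exclusion_order.append(gene)
        m_at_step.append(float(mvals[worst]))
        scores[gene] = float(mvals[worst])
        ranks[gene] = step_rank
        step_rank -= 1
        remaining.pop(worst)

    final_m = float(
        np.std(
            m.values.loc[remaining[0]].to_numpy() - m.values.loc[remaining[1]].to_numpy(),
            ddof=1,
        )
    )
    for gene in remaining:
        scores[gene] = final_m
        ranks[gene] = 1

    score_s = pd.Series({g: scores[g] for g in genes}, name="M")
    rank_s = pd.Series({g: ranks[g] for g in genes}, dtype=int)
    trace = GeNormTrace(
        exclusion_order=exclusion_order,
        m_at_step=m_at_step,
        final_pair=(remaining[0], remaining[1]),
        final_m=final_m,
    )
    return StabilityTable("GeNorm", score_s, rank_s), trace


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _normfinder_decomposition(values: np.ndarray, group_idx: list[np.ndarray]):
    """Intergroup deviations d_ig and bias-corrected intragroup variances.

    ``values`` is the genes × samples Cq matrix (Cq is already a log2-scale
    measure); ``group_idx`` holds the column indices of each group.

    The model: after removing the per-sample loading (the mean over genes of
    each sample), the centred value of gene i in group g decomposes into a
    gene-specific group deviation d_ig and noise with gene-specific variance
    sigma2_ig.  Because the subtracted sample mean contains every gene's
    noise, the naive within-group variance of the centred data is biased; the
    unbiased estimate is k/(k−2) · (s²_ig − Σ_i' s²_i'g / (k(k−1))).
    """
    k = values.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    z = values - values.mean(axis=0, keepdims=True)  # remove per-sample loading
    ngroups = len(group_idx)
    zbar = np.empty((k, ngroups))
    s2 = np.empty((k, ngroups))
    for g, idx in enumerate(group_idx):
        if len(idx) < 2:
            raise ValueError("every group needs at least 2 samples")
        zg = z[:, idx]
        zbar[:, g] = zg.mean(axis=1)
        s2[:, g] = zg.var(axis=1, ddof=1)
    d = zbar - zbar.mean(axis=1, keepdims=True)
    sigma2 = (k / (k - 2)) * (s2 - s2.sum(axis=0, keepdims=True) / (k * (k - 1)))
    sigma2 = np.clip(sigma2, 0.0, None)
    return d, sigma2


def _shrink(d: np.ndarray, c: np.ndarray, gamma2: float):
    """Empirical-Bayes posterior mean and variance of the true group deviation."""
    denom = gamma2 + c
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, gamma2 / denom, 0.0)
    return d * w, c * w  # posterior mean, posterior variance


def normfinder(m: CqMatrix) -> NormFinderResult:
    """Model-based stability (Andersen-type intergroup/intragroup model).

    Per gene i and group g the algorithm estimates the intergroup deviation
    d_ig (cycles) and the intragroup variance sigma2_ig (squared cycles),
    shrinks d toward zero in proportion to its sampling variability
    c_ig = sigma2_ig/n_g relative to the estimated spread gamma² of the true
    deviations, and scores each gene as

        S_i = mean over groups of ( |d~_ig| + sqrt(post-var_ig) ),

    the shrunken deviation plus an SE-type intragroup term.  Lower S means a
    gene that is both flat across groups and quiet within groups.

    The best two-gene normalizer treats the pair average as a composite gene
    (d averaged, variance quartered under independence) and minimises the
    same criterion; its value is the grouped stability.
    """
    m.require_groups(min_groups=2, min_size=2)
    genes = m.genes
    group_labels = list(dict.fromkeys(m.groups))
    group_idx = [np.flatnonzero((m.groups == g).to_numpy()) for g in group_labels]
    n_g = np.array([len(idx) for idx in group_idx], dtype=float)
    values = m.values.to_numpy()
    k, ngroups = len(genes), len(group_labels)

    d, sigma2 = _normfinder_decomposition(values, group_idx)
    c = sigma2 / n_g  # sampling variance of each d_ig

    gamma2 = float(
        max((d**2).sum() / ((ngroups - 1) * (k - 1)) - c.sum() / (k * ngroups), 0.0)
    )
    d_post, var_post = _shrink(d, c, gamma2)
    stability = (np.abs(d_post) + np.sqrt(var_post)).mean(axis=1)

    stab = pd.Series(stability, index=genes, name="S")
    ranks = dense_ranks(stab)

    best_pair: tuple[str, str] | None = None
    best_value = np.inf
    for i, j in combinations(range(k), 2):
        d_pair = 0.5 * (d[i] + d[j])
        c_pair = 0.25 * (c[i] + c[j])
        dp, vp = _shrink(d_pair, c_pair, gamma2)
        value = float((np.abs(dp) + np.sqrt(vp)).mean())
        if value < best_value:
            best_value = value
            best_pair = (genes[i], genes[j])
    assert best_pair is not None

    return NormFinderResult(
        stability=stab,
        ranks=ranks,
        intergroup_d=pd.DataFrame(d, index=genes, columns=group_labels),
        intragroup_var=pd.DataFrame(sigma2, index=genes, columns=group_labels),
        gamma2=gamma2,
        best_pair=best_pair,
        grouped_stability=best_value,
    )


# ---------------------------------------------------------------------------
# Pairwise delta-Ct
# ---------------------------------------------------------------------------

def pairwise_dct(m: CqMatrix) -> StabilityTable:
    """Mean SD of per-sample Cq differences against every partner gene.

    For gene i the score is the arithmetic mean over all other genes k of
    SD_samples(Cq_i − Cq_k); the zero self-difference column is excluded.
    """
    genes = m.genes
    if len(genes) < 2:
        raise ValueError("pairwise dCt needs at least 2 genes")
    values = m.values.to_numpy()
    k = len(genes)
    sd = np.empty((k, k))
    for j in range(k):
        sd[j] = np.std(values - values[j], axis=1, ddof=1)
    np.fill_diagonal(sd, 0.0)
    score = pd.Series(sd.sum(axis=1) / (k - 1), index=genes, name="mean_sd")
    return StabilityTable("PairwiseDCt", score, dense_ranks(score))


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def pearson_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Gene × gene Pearson r of linearized quantities across pooled samples.

    The self-correlation diagonal is reported as NaN (omitted from analysis),
    as is any zero-variance gene, whose correlation is undefined rather
    than 1.
    """
    if q.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    corr = q.T.corr(method="pearson")
    zero_var = q.std(axis=1, ddof=1) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, np.nan)
    return corr
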