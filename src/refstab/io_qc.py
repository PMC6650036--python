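"""Reading, validation and QC of raw Cq data.

Raw instrument exports arrive as long tables of technical-replicate Cq
readings (sample, group, gene, cq).  This module collapses replicates into a
complete :class:`~refstab.datatypes.CqMatrix` using an SD-based consistency
rule, converts Cq to relative quantities (2^-Cq), computes fold changes
against a calibrator group, and fits amplification efficiencies from
dilution-series standard curves.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CqMatrix, EfficiencyFit

__all__ = [
    "read_long",
    "read_wide",
    "validate_raw",
    "collapse_replicates",
    "linearize",
    "fold_change_vs_calibrator",
    "efficiency_from_dilution",
    "write_qc_log",
]

LONG_COLUMNS = ("sample", "group", "gene", "cq")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_long(path: str | Path, column_map: dict[str, str] | None = None,
              sheet: str | int = 0) -> pd.DataFrame:
    """Read a long-format replicate table (CSV, TSV or XLSX).

    Parameters
    ----------
    path : path
        File with one row per technical replicate.
    column_map : dict, optional
        Mapping from the canonical names ``sample``, ``group``, ``gene``,
        ``cq`` to the column names actually present, for instrument exports
        with a different layout.
    sheet : str or int
        Worksheet to read when ``path`` is an XLSX workbook.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    out = df.loc[:, list(LONG_COLUMNS)].copy()
    out["cq"] = out["cq"].astype(float)
    for col in ("sample", "group", "gene"):
        out[col] = out[col].astype(str)
    return out


def read_wide(path: str | Path, calibrator_group: str | None = None) -> CqMatrix:
    """Read a wide gene × sample Cq matrix.

    The first row below the header must be the group assignment row, labelled
    ``group`` in the gene column; remaining rows are genes.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if "group" not in [i.lower() for i in df.index]:
        raise ValueError("wide table needs a 'group' row assigning samples to groups")
    group_row = next(i for i in df.index if i.lower() == "group")
    groups = df.loc[group_row].astype(str)
    values = df.drop(index=group_row).astype(float)
    return CqMatrix(values, groups, calibrator_group)


def validate_raw(raw: pd.DataFrame, min_replicates: int = 2) -> None:
    """Check the invariants of a raw replicate table."""
    missing = set(LONG_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw table is missing columns: {sorted(missing)}")
    cq = raw["cq"].astype(float)
    if not np.isfinite(cq).all():
        raise ValueError("non-finite Cq values in raw table")
    if (cq <= 0).any():
        raise ValueError("Cq values must be positive")
    ngroups = raw.groupby("sample")["group"].nunique()
    bad = list(ngroups.index[ngroups > 1])
    if bad:
        raise ValueError(f"samples mapped to more than one group: {bad}")
    counts = raw.groupby(["sample", "gene"]).size()
    few = counts[counts < min_replicates]
    if len(few):
        raise ValueError(
            f"(sample, gene) cells with fewer than {min_replicates} replicates: "
            f"{list(few.index[:5])}"
        )


# ---------------------------------------------------------------------------
# replicate collapse
# ---------------------------------------------------------------------------

def _pick_outlier(values: np.ndarray, sd_limit: float) -> tuple[int, float] | None:
    """Index of the single replicate whose removal minimises the remaining SD.

    Ties are broken by distance from the median (farthest first), then by
    input order.  Returns ``None`` if no single removal achieves SD < limit.
    """
    n = len(values)
    med = float(np.median(values))
    best: tuple[float, float, int] | None = None  # (sd, -|v-med|, idx)
    for i in range(n):
        rest = np.delete(values, i)
        if len(rest) < 2:
            continue
        sd = float(np.std(rest, ddof=1))
        key = (round(sd, 12), -abs(values[i] - med), i)
        if best is None or key < best:
            best = key
    if best is None or best[0] >= sd_limit:
        return None
    idx = best[2]
    rest = np.delete(values, idx)
    return idx, float(np.std(rest, ddof=1))


def collapse_replicates(
    raw: pd.DataFrame,
    sd_limit: float = 0.25,
    calibrator_group: str | None = None,
) -> tuple[CqMatrix, list[dict]]:
    """Collapse technical replicates to per-sample mean Cq values.

    For each (sample, gene) cell: if the replicate SD is at most ``sd_limit``
    cycles the cell value is the arithmetic mean.  Otherwise the cell is
    inconsistent and exactly one outlier replicate is removed — the one whose
    removal minimises the remaining SD — provided at least two replicates
    survive and the remaining SD drops strictly below the limit; otherwise the
    cell is unrecoverable and an error is raised.

    Returns the collapsed matrix and a QC log (one record per removal).
    """
    validate_raw(raw)
    qc_log: list[dict] = []
    cells: dict[tuple[str, str], float] = {}
    sample_group = raw.drop_duplicates("sample").set_index("sample")["group"]

    for (sample, gene), sub in raw.groupby(["sample", "gene"], sort=False):
        values = sub["cq"].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1))
        if sd <= sd_limit:
            cells[(sample, gene)] = float(np.mean(values))
            continue
        if len(values) < 3:
            raise ValueError(
                f"({sample}, {gene}): replicate SD {sd:.3f} > {sd_limit} with only "
                f"{len(values)} replicates; cannot remove an outlier"
            )
        picked = _pick_outlier(values, sd_limit)
        if picked is None:
            raise ValueError(
                f"({sample}, {gene}): replicate SD {sd:.3f} > {sd_limit} and no "
                f"single-replicate removal reaches SD < {sd_limit}"
            )
        idx, new_sd = picked
        kept = np.delete(values, idx)
        qc_log.append(
            {
                "sample": sample,
                "gene": gene,
                "removed_cq": float(values[idx]),
                "original_sd": sd,
                "remaining_sd": new_sd,
                "kept_cq": [float(v) for v in kept],
            }
        )
        cells[(sample, gene)] = float(np.mean(kept))

    samples = list(dict.fromkeys(raw["sample"]))
    genes = list(dict.fromkeys(raw["gene"]))
    matrix = pd.DataFrame(index=genes, columns=samples, dtype=float)
    for (sample, gene), value in cells.items():
        matrix.at[gene, sample] = value
    if matrix.isna().any().any():
        holes = [(g, s) for g in genes for s in samples if pd.isna(matrix.at[g, s])]
        raise ValueError(f"missing (gene, sample) cells after collapse: {holes[:5]}")
    groups = sample_group.reindex(samples)
    return CqMatrix(matrix, groups, calibrator_group), qc_log


def write_qc_log(qc_log: list[dict], path: str | Path) -> None:
    """Write the replicate-removal log as JSON lines."""
    with open(path, "w") as fh:
        for record in qc_log:
            fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# linearization and fold changes
# ---------------------------------------------------------------------------

def linearize(m: CqMatrix | pd.DataFrame) -> pd.DataFrame:
    """Transform Cq to relative quantities, q = 2^-Cq.

    One cycle difference corresponds to a two-fold quantity difference at
    100 % amplification efficiency; the result is strictly positive and
    order-reversing in Cq.
    """
    values = m.values if isinstance(m, CqMatrix) else m
    return np.exp2(-values.astype(float))


def fold_change_vs_calibrator(m: CqMatrix, calibrator_group: str | None = None) -> pd.DataFrame:
    """Per-sample fold changes 2^-dCq referenced to the calibrator group.

    dCq of a sample is its Cq minus the mean Cq of the calibrator-group
    samples for that gene, so the calibrator group *mean Cq* maps to a fold
    change of exactly 1 (individual calibrator samples may differ from 1).
    """
    cal = calibrator_group or m.calibrator_group
    if cal is None:
        raise ValueError("no calibrator group given")
    cal_samples = m.groups.index[m.groups == cal]
    if len(cal_samples) == 0:
        raise ValueError(f"calibrator group {cal!r} has no samples")
    cal_mean = m.values[cal_samples].mean(axis=1)
    dcq = m.values.sub(cal_mean, axis=0)
    return np.exp2(-dcq)


# ---------------------------------------------------------------------------
# amplification efficiency
# ---------------------------------------------------------------------------

def efficiency_from_dilution(
    points: list[tuple[float, float]] | np.ndarray,
    e_low: float = 1.93,
    e_high: float = 2.05,
    r2_min: float = 0.98,
) -> EfficiencyFit:
    """Fit a standard curve Cq ~ log10(input amount) and derive efficiency.

    E = 10^(-1/slope); a slope of -1/log10(2) ≈ -3.32 corresponds to perfect
    doubling (E = 2, 100 %).  The fit is gated on E in [e_low, e_high] and
    R² >= r2_min.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_amount, cq) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 dilution points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("dilution amounts have zero variance")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValueError("standard curve has zero slope; efficiency undefined")
    efficiency = float(10.0 ** (-1.0 / fit.slope))
    r2 = float(fit.rvalue**2)
    return EfficiencyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=efficiency,
        percent_efficiency=(efficiency - 1.0) * 100.0,
        r_squared=r2,
        passes=(e_low <= efficiency <= e_high) and (r2 >= r2_min),
        e_low=e_low,
        e_high=e_high,
        r2_min=r2_min,
    )
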