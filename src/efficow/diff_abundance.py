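"""Differential protein abundance between efficiency groups.

The comparison convention: fold change is the ratio of *arithmetic
means on the normalized raw scale* (case over control), displayed signed
— a ratio r ≥ 1 is shown as +r, a ratio below 1 as −1/r, so down-shifts
mirror up-shifts symmetrically around ±1. Significance comes from a
two-tailed equal-variance (Student) t-test on log-transformed
abundances. A protein is a DAP (differentially abundant protein) when
p ≤ p_thresh and |signed FC| ≥ fc_thresh, both boundaries inclusive
(defaults 0.05 and 1.5).

No multiple-testing correction gates the DAP call; a Benjamini–Hochberg
column is emitted for downstream use. Proteins with fewer than two
observed values in either group are kept with status ``untested`` so the
enrichment background still covers the whole quantified universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from efficow.lfq import sample_columns

__all__ = [
    "fold_change",
    "ttest_protein",
    "pi_score",
    "differential_table",
    "call_daps",
    "DapCounts",
    "export_heatmap_matrix",
]


def fold_change(mean_case: float, mean_ctrl: float) -> float:
    """Signed fold change from two positive group means.

    ``r = mean_case/mean_ctrl``; returns ``r`` when r ≥ 1 else ``−1/r``.
    The magnitude is always ≥ 1 and swapping the groups flips the sign.
    """
    if mean_case <= 0 or mean_ctrl <= 0:
        raise ValueError("fold_change requires strictly positive group means")
    r = mean_case / mean_ctrl
    return r if r >= 1 else -1.0 / r


def ttest_protein(case_values, ctrl_values) -> tuple[float, float]:
    """Two-tailed, equal-variance two-sample t-test (on log-scale values).

    Returns ``(t, p)``; requires at least two finite values per group.
    """
    case = np.asarray(case_values, float)
    ctrl = np.asarray(ctrl_values, float)
    case = case[np.isfinite(case)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 observed values per group")
    t, p = stats.ttest_ind(case, ctrl, equal_var=True)
    return float(t), float(p)


def pi_score(p_value: float, log2fc: float) -> float:
    """Volcano ranking score: ``−log10(p) × log2FC``.

    Combines significance and effect size into one signed number; zero
    iff the effect is null (log2FC = 0) or the p-value is 1. A p of
    exactly 0 is capped at the smallest positive float before the log.
    """
    if not 0 <= p_value <= 1:
        raise ValueError("p_value must lie in [0, 1]")
    p = max(p_value, np.finfo(float).tiny)
    return float(-np.log10(p) * log2fc)


def differential_table(proteins: pd.DataFrame, groups: pd.Series,
                       case: str = "HEF", control: str = "LEF",
                       p_thresh: float = 0.05,
                       fc_thresh: float = 1.5) -> pd.DataFrame:
    """Per-protein differential-abundance table.

    ``proteins`` is the normalized raw-scale protein matrix from
    :func:`efficow.lfq.rollup_top3`; ``groups`` maps sample_id → group
    label. Means and fold changes are computed on the raw scale, the
    t-test on log2 values, per the module convention. Output columns:
    protein_id, n_case, n_ctrl, mean_case, mean_ctrl, fc_signed, log2fc,
    t, p, p_bh, pi_score, is_dap, status.
    """
    samples = sample_columns(proteins)
    unknown = [s for s in samples if s not in groups.index]
    if unknown:
        raise ValueError(f"samples without group labels: {unknown}")
    case_cols = [s for s in samples if groups[s] == case]
    ctrl_cols = [s for s in samples if groups[s] == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group for testing")

    raw_case = proteins[case_cols].to_numpy(float)
    raw_ctrl = proteins[ctrl_cols].to_numpy(float)
    n_case = np.sum(~np.isnan(raw_case), axis=1)
    n_ctrl = np.sum(~np.isnan(raw_ctrl), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        mean_case = np.nanmean(raw_case, axis=1)
        mean_ctrl = np.nanmean(raw_ctrl, axis=1)

    rows = []
    for i, protein_id in enumerate(proteins["protein_id"]):
        row = {"protein_id": protein_id,
               "n_case": int(n_case[i]), "n_ctrl": int(n_ctrl[i]),
               "mean_case": mean_case[i], "mean_ctrl": mean_ctrl[i],
               "fc_signed": np.nan, "log2fc": np.nan, "t": np.nan,
               "p": np.nan, "pi_score": np.nan, "status": "ok"}
        if n_case[i] >= 2 and n_ctrl[i] >= 2:
            row["fc_signed"] = fold_change(mean_case[i], mean_ctrl[i])
            row["log2fc"] = float(np.log2(mean_case[i] / mean_ctrl[i]))
            lc = np.log2(raw_case[i][~np.isnan(raw_case[i])])
            lv = np.log2(raw_ctrl[i][~np.isnan(raw_ctrl[i])])
            t, p = ttest_protein(lc, lv)
            row["t"], row["p"] = t, p
            row["pi_score"] = pi_score(p, row["log2fc"])
        else:
            row["status"] = "untested"
        rows.append(row)
    table = pd.DataFrame(rows)

    tested = table["status"] == "ok"
    table["p_bh"] = np.nan
    if tested.any():
        from efficow.enrichment import bh_adjust
        table.loc[tested, "p_bh"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table, _ = call_daps(table, p_thresh=p_thresh, fc_thresh=fc_thresh)
    return table


@dataclass(frozen=True)
class DapCounts:
    """DAP tally: total flagged, up/down split, and share of the universe."""

    total: int
    up: int
    down: int
    universe: int

    @property
    def percent_of_universe(self) -> float:
        return 100.0 * self.total / self.universe if self.universe else 0.0


def call_daps(table: pd.DataFrame, p_thresh: float = 0.05,
              fc_thresh: float = 1.5) -> tuple[pd.DataFrame, DapCounts]:
    """Flag DAPs: p ≤ p_thresh AND |signed FC| ≥ fc_thresh (inclusive).

    Returns the table with ``is_dap`` set plus a :class:`DapCounts`
    partitioning the flags by fold-change sign over the full input
    universe (untested rows count in the universe, never as DAPs).
    """
    if p_thresh <= 0 or fc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    with np.errstate(invalid="ignore"):
        flag = (out["p"].to_numpy(float) <= p_thresh) & \
               (np.abs(out["fc_signed"].to_numpy(float)) >= fc_thresh)
    flag &= out["p"].notna().to_numpy()
    out["is_dap"] = flag
    up = int(np.sum(flag & (out["fc_signed"].to_numpy(float) > 0)))
    down = int(np.sum(flag & (out["fc_signed"].to_numpy(float) < 0)))
    return out, DapCounts(total=int(flag.sum()), up=up, down=down,
                          universe=len(out))


def export_heatmap_matrix(table: pd.DataFrame,
                          proteins: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready matrix: DAP rows, z-scored per protein (ddof=1).

    Each retained protein row has mean 0 and SD 1 across its observed
    samples; a zero-variance row is exported as all zeros with a
    warning rather than dropped.
    """
    daps = table.loc[table["is_dap"], "protein_id"]
    if daps.empty:
        raise ValueError("no DAPs to export")
    samples = sample_columns(proteins)
    sub = proteins.set_index("protein_id").loc[daps, samples]
    mat = sub.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=1, keepdims=True)
        sd = np.nanstd(mat, axis=1, ddof=1, keepdims=True)
    flat = sd.ravel()
    zero_var = (flat == 0) | ~np.isfinite(flat)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance protein row(s) exported as zeros",
            UserWarning, stacklevel=2)
    z = np.where(zero_var[:, None], 0.0, (mat - mean) / np.where(sd == 0, 1, sd))
    return pd.DataFrame(z, index=sub.index, columns=samples)
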