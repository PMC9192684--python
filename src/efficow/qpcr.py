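"""ΔΔCt relative quantification for qPCR with reference-gene selection.

The model assumes perfect per-cycle doubling (amplification efficiency
2): one cycle earlier means twice the template. For each sample,

    ΔCt  = Ct(target) − Ct(reference)
    RQ'  = 2^(−ΔCt)
    RQ   = RQ' / mean(RQ' over the control group)

so the control group's mean RQ is exactly 1 by construction and a case
RQ of, say, 0.37 reads "37% of the control level". Subtracting the
reference gene cancels sample-wise loading/efficiency shifts.

The reference gene is chosen among candidate housekeeping genes as the
one with the smallest standard deviation of raw Ct across all samples —
the most "consistent" gene. Candidates missing in any sample are
excluded with a warning; ties break lexicographically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from efficow.diff_abundance import ttest_protein

__all__ = ["read_ct", "select_reference", "ddct_rq", "compare_rq"]

CT_COLUMNS = ["sample_id", "group", "gene", "ct"]


def read_ct(path) -> pd.DataFrame:
    """Read a Ct table CSV; technical replicates averaged on the Ct scale."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(df["ct"].to_numpy(float)).all():
        raise ValueError("non-finite Ct values")
    return (df.groupby(["sample_id", "group", "gene"], as_index=False)["ct"]
              .mean())


def select_reference(records: pd.DataFrame,
                     candidate_genes) -> tuple[str, pd.DataFrame]:
    """Pick the most stable candidate gene (smallest Ct SD across samples).

    Returns ``(gene, report)``; the report lists every candidate's SD
    and completeness. A candidate not measured in every sample is
    excluded with a warning; if none is complete, raises.
    """
    all_samples = set(records["sample_id"])
    rows = []
    for gene in candidate_genes:
        sub = records[records["gene"] == gene]
        complete = set(sub["sample_id"]) == all_samples
        sd = float(sub["ct"].std(ddof=1)) if len(sub) > 1 else np.nan
        rows.append({"gene": gene, "ct_sd": sd, "complete": complete})
        if not complete:
            warnings.warn(f"reference candidate {gene} missing in some samples; "
                          "excluded", UserWarning, stacklevel=2)
    report = pd.DataFrame(rows)
    eligible = report[report["complete"]]
    if eligible.empty:
        raise ValueError("no reference candidate measured in every sample")
    best_sd = eligible["ct_sd"].min()
    tied = sorted(eligible.loc[eligible["ct_sd"] == best_sd, "gene"])
    if len(tied) > 1:
        warnings.warn(f"reference SD tie between {tied}; choosing {tied[0]}",
                      UserWarning, stacklevel=2)
    return tied[0], report.sort_values("ct_sd").reset_index(drop=True)


def ddct_rq(records: pd.DataFrame, target_gene: str, reference_gene: str,
            control_group: str = "LEF") -> pd.DataFrame:
    """Per-sample ΔΔCt relative quantities for one target gene.

    Returns rows (sample_id, group, gene, delta_ct, rq) with the control
    group's mean rq equal to 1 exactly. Samples lacking either the
    target or the reference Ct are dropped with a warning.
    """
    wide = records.pivot_table(index=["sample_id", "group"], columns="gene",
                               values="ct", aggfunc="mean")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene} absent from Ct records")
    sub = wide[[target_gene, reference_gene]]
    dropped = sub.index[sub.isna().any(axis=1)]
    if len(dropped):
        warnings.warn(f"dropping samples with missing Ct: "
                      f"{[s for s, _ in dropped]}", UserWarning, stacklevel=2)
        sub = sub.dropna()
    delta_ct = sub[target_gene] - sub[reference_gene]
    raw_rq = np.power(2.0, -delta_ct)
    groups = sub.index.get_level_values("group")
    ctrl_mean = raw_rq[groups == control_group].mean()
    if not np.isfinite(ctrl_mean) or ctrl_mean <= 0:
        raise ValueError(f"control group '{control_group}' empty or invalid")
    out = pd.DataFrame({
        "sample_id": sub.index.get_level_values("sample_id"),
        "group": groups,
        "gene": target_gene,
        "delta_ct": delta_ct.to_numpy(float),
        "rq": (raw_rq / ctrl_mean).to_numpy(float),
    })
    return out.reset_index(drop=True)


def compare_rq(rq_rows: pd.DataFrame, case_group: str = "HEF",
               control_group: str = "LEF") -> dict:
    """Group comparison of relative quantities.

    The test is a two-tailed equal-variance t on log2(rq) (ratio data
    are compared on the log scale); group means are reported on the rq
    scale, where the control mean is 1 by construction. Returns a dict
    with gene, case_mean, control_mean, sem per group, p and status.
    """
    case = rq_rows.loc[rq_rows["group"] == case_group, "rq"].to_numpy(float)
    ctrl = rq_rows.loc[rq_rows["group"] == control_group, "rq"].to_numpy(float)
    gene = rq_rows["gene"].iloc[0] if len(rq_rows) else ""
    out = {
        "gene": gene,
        "case_mean": float(case.mean()) if case.size else np.nan,
        "control_mean": float(ctrl.mean()) if ctrl.size else np.nan,
        "case_sem": float(case.std(ddof=1) / np.sqrt(case.size)) if case.size > 1 else np.nan,
        "control_sem": float(ctrl.std(ddof=1) / np.sqrt(ctrl.size)) if ctrl.size > 1 else np.nan,
        "p": np.nan,
        "status": "ok",
    }
    if case.size < 2 or ctrl.size < 2:
        out["status"] = "untested"
        return out
    _, p = ttest_protein(np.log2(case), np.log2(ctrl))
    out["p"] = p
    return out
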