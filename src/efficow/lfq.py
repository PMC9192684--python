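"""Label-free quantification: TIC normalization, top-3 rollup, PCA QC.

The input is a peptide-level intensity table (rows = peptides, one
intensity column per sample, NaN = not detected). Missing is a distinct
state from zero: zeros in input files are converted to missing on read,
and no imputation is performed.

Normalization scales each sample so its total ion current (TIC, the sum
of its non-missing intensities) equals the median raw TIC across
samples. Protein abundance is the Top-3 (Hi-3) estimate: the arithmetic
mean of the protein's three most abundant peptides; proteins seen with
only one or two peptides use all of them. Peptide ranking is *global*
(by across-sample mean intensity) so each protein uses one fixed peptide
set in every sample, which stabilises between-group ratios; a per-sample
variant is available for sensitivity analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "tic_normalize",
    "rollup_top3",
    "log_transform",
    "pca_summary",
    "read_peptides",
    "read_samples",
    "sample_columns",
]

#: Non-intensity columns of a peptide table.
ID_COLUMNS = ["peptide_id", "protein_id"]


def sample_columns(peptides: pd.DataFrame) -> list[str]:
    """The intensity (sample) columns of a peptide or protein table."""
    reserved = set(ID_COLUMNS) | {"n_peptides_total", "n_peptides_used"}
    return [c for c in peptides.columns if c not in reserved]


def _validate_peptide_table(peptides: pd.DataFrame) -> list[str]:
    for col in ID_COLUMNS:
        if col not in peptides.columns:
            raise ValueError(f"peptide table lacks required column '{col}'")
    if peptides["protein_id"].isna().any():
        bad = peptides.loc[peptides["protein_id"].isna(), "peptide_id"].tolist()
        raise ValueError(f"peptides mapped to no protein: {bad[:10]}")
    samples = sample_columns(peptides)
    if not samples:
        raise ValueError("peptide table has no sample intensity columns")
    vals = peptides[samples].to_numpy(float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative intensities are not allowed")
    return samples


def tic_normalize(peptides: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each sample to the median total ion current.

    Returns ``(normalized table, report)``. The report has one row per
    sample with its raw TIC, scale factor (median raw TIC / raw TIC) and
    post-normalization TIC; post TICs agree to 1e-6 relative. Missing
    entries stay missing. A sample with no observed intensity at all is
    an error (its TIC, hence factor, would be undefined).
    """
    samples = _validate_peptide_table(peptides)
    raw_tic = peptides[samples].sum(skipna=True)
    empty = raw_tic.index[peptides[samples].notna().sum() == 0].tolist()
    if empty:
        raise ValueError(f"sample(s) with all intensities missing: {empty}")
    reference = float(raw_tic.median())
    factors = reference / raw_tic
    out = peptides.copy()
    out[samples] = peptides[samples] * factors
    report = pd.DataFrame({
        "sample_id": samples,
        "raw_tic": raw_tic.to_numpy(float),
        "scale_factor": factors.to_numpy(float),
        "post_tic": out[samples].sum(skipna=True).to_numpy(float),
    })
    return out, report


def rollup_top3(peptides: pd.DataFrame, per_sample: bool = False) -> pd.DataFrame:
    """Roll peptide intensities up to protein abundances (Top-3 / Hi-3).

    For each protein, peptides are ranked by mean intensity across all
    samples (missing values excluded from both numerator and
    denominator) and the top three — or all, when only one or two exist
    — form a fixed global set; the per-sample abundance is the
    arithmetic mean of those peptides' observed intensities in that
    sample. ``per_sample=True`` instead ranks within each sample
    independently (sensitivity variant).

    Returns a protein × sample frame with ``protein_id``,
    ``n_peptides_total``, ``n_peptides_used`` and one abundance column
    per sample; an abundance is missing iff all contributing peptides
    are missing in that sample.
    """
    samples = _validate_peptide_table(peptides)
    if len(peptides) == 0:
        raise ValueError("peptide table is empty")
    rows = []
    for protein_id, grp in peptides.groupby("protein_id", sort=True):
        mat = grp[samples].to_numpy(float)
        n_total = len(grp)
        n_used = min(3, n_total)
        if per_sample:
            # rank within each sample; NaNs sort last and never enter the mean
            abund = np.full(len(samples), np.nan)
            for j in range(len(samples)):
                col = mat[:, j]
                obs = col[~np.isnan(col)]
                if obs.size:
                    abund[j] = np.sort(obs)[::-1][:3].mean()
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                pep_mean = np.nanmean(mat, axis=1)
            order = np.argsort(np.nan_to_num(pep_mean, nan=-np.inf))[::-1]
            top = mat[order[:3], :]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                abund = np.nanmean(top, axis=0)
        rows.append({"protein_id": protein_id,
                     "n_peptides_total": n_total,
                     "n_peptides_used": n_used,
                     **dict(zip(samples, abund))})
    return pd.DataFrame(rows, columns=["protein_id", "n_peptides_total",
                                       "n_peptides_used", *samples])


def log_transform(proteins: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Elementwise log of a protein matrix; missing values preserved.

    Non-missing abundances must be strictly positive — zeros should have
    been treated as missing upstream.
    """
    samples = sample_columns(proteins)
    vals = proteins[samples].to_numpy(float)
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValueError(
            "non-positive abundance encountered; treat zeros as missing upstream"
        )
    out = proteins.copy()
    out[samples] = np.log(vals) / np.log(base)
    return out


def pca_summary(log_proteins: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on complete-case proteins (QC for outliers/grouping).

    Proteins with any missing value are dropped; each remaining protein
    (feature) is mean-centered but not unit-scaled, since log
    intensities are already on a common scale. Returns ``(scores,
    variance_pct)`` where ``scores`` has per-sample coordinates on the
    first two components and ``variance_pct`` gives the percentage of
    variance explained by every component (sums to 100).
    """
    samples = sample_columns(log_proteins)
    if len(samples) < 3:
        raise ValueError("PCA needs at least 3 samples")
    complete = log_proteins.dropna(subset=samples)
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete-case proteins")
    X = complete[samples].to_numpy(float).T  # samples x proteins
    pca = PCA(n_components=None)
    coords = pca.fit_transform(X)
    variance_pct = 100.0 * pca.explained_variance_ratio_
    scores = pd.DataFrame({
        "sample_id": samples,
        "pc1": coords[:, 0],
        "pc2": coords[:, 1] if coords.shape[1] > 1 else 0.0,
    })
    return scores, variance_pct


def read_peptides(path) -> pd.DataFrame:
    """Read a peptide TSV; empty cells and zeros become missing (NaN)."""
    df = pd.read_csv(path, sep="\t")
    samples = _validate_peptide_table(df)
    df[samples] = df[samples].replace(0, np.nan)
    if df["peptide_id"].duplicated().any():
        dups = df.loc[df["peptide_id"].duplicated(), "peptide_id"].tolist()
        raise ValueError(f"duplicate peptide_ids: {dups[:10]}")
    return df


def read_samples(path) -> pd.Series:
    """Read the sample→group sidecar TSV (columns sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"samples file lacks column '{col}'")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in samples file")
    return df.set_index("sample_id")["group"]
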