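"""Score transformations and assay QC statistics.

The screen's raw readout is a median fluorescence intensity (MFI) per
(sample, capture bead, detection antibody).  Before calling interactions the
pipeline puts measurements from different antibodies on a common scale:

* **SNR** — MFI divided by the median buffer-well MFI of the same capture and
  detection antibody pair; the buffer median itself maps to SNR exactly 1.
* **Quantile normalization** — forces replicate columns onto one empirical
  distribution (the row-wise mean of the column-sorted values) while
  preserving within-column rank order; ties share the mean of the reference
  values across the tied ranks.
* **Z / robust Z** — location-scale standardization.  The robust variant uses
  median and MAD with the 1.4826 normal-consistency constant:
  ``(x - median(x)) / (1.4826 * MAD(x))``, so that for Gaussian data one
  robust-Z unit is one standard deviation.

QC statistics: one-way ANOVA with Dunnett many-to-one comparisons against the
mock-transfection group (verifies that RAMP transfection actually elevated
RAMP levels), and the one-sided Wilcoxon rank-sum test for replicate
reproducibility of a coexpressed pair against its receptor-only control.

Because MFI noise is multiplicative, pipeline stages feed *log* intensities
into the robust-Z standardization; the transformation functions themselves are
scale-agnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateScaleError, ValidationError

MAD_CONSTANT = 1.4826  # E[MAD]/sigma^-1 for the normal distribution


def robust_z(values) -> np.ndarray:
    """Robust Z-scores: ``(x - median(x)) / (1.4826 * MAD(x))``.

    Invariant under positive affine transforms of the input; the median maps
    to 0 and, for Gaussian data, the scale estimate is consistent for the SD.

    Raises
    ------
    DegenerateScaleError
        If the MAD is zero (more than half the values identical).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("robust_z expects a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("robust_z expects finite values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateScaleError("MAD is zero; robust Z undefined")
    return (x - med) / (MAD_CONSTANT * mad)


def z_score(values) -> np.ndarray:
    """Classical standardization to mean 0, SD 1 (ddof=0)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("z_score expects a 1-D vector of length >= 2")
    sd = x.std()
    if sd == 0:
        raise DegenerateScaleError("SD is zero; Z-score undefined")
    return (x - x.mean()) / sd


def snr_transform(mfi: pd.DataFrame, buffer: pd.DataFrame) -> pd.DataFrame:
    """Attach per-record SNRs: MFI over the median buffer MFI of the same
    (capture antibody, detection antibody) combination.

    Raises
    ------
    ValidationError
        Listing any (capture, detection) combinations without buffer records.
    """
    key = ["capture_antibody_id", "detection_antibody_id"]
    if buffer.empty:
        raise ValidationError("no buffer records supplied for SNR transform")
    buf_med = buffer.groupby(key)["mfi"].median().rename("buffer_median")
    out = mfi.merge(buf_med, left_on=key, right_index=True, how="left")
    missing = out["buffer_median"].isna()
    if missing.any():
        combos = out.loc[missing, key].drop_duplicates().to_records(index=False).tolist()
        raise ValidationError(f"missing buffer records for combination(s): {combos[:10]}")
    out["snr"] = out["mfi"] / out["buffer_median"]
    return out


def quantile_normalize(matrix) -> np.ndarray | pd.DataFrame:
    """Quantile-normalize columns to the common reference distribution
    (row-wise mean of the column-sorted values).

    Within-column rank order is preserved; tied values receive the mean of the
    reference values across their tied ranks, so the operation is idempotent.
    Accepts a 2-D array or DataFrame of equal-length columns.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("quantile_normalize expects a 2-D matrix with >= 2 columns")
    if not np.all(np.isfinite(x)):
        raise ValidationError("quantile_normalize expects finite values")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col_ref = np.empty(n)
        col_ref[order] = reference
        # average reference values over blocks of tied input values
        sorted_vals = x[order, j]
        block_start = 0
        for i in range(1, n + 1):
            if i == n or sorted_vals[i] != sorted_vals[block_start]:
                idx = order[block_start:i]
                col_ref[idx] = reference[block_start:i].mean()
                block_start = i
        out[:, j] = col_ref
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def ramp_expression_qc(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    mock_group: str = "mock",
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Transfection QC: one-way ANOVA over transfection groups followed by
    Dunnett many-to-one comparisons of each RAMP group against mock.

    Returns one row per non-mock group with the mean difference vs mock and
    the Dunnett-adjusted p-value; the ANOVA F statistic and p are attached as
    ``DataFrame.attrs['anova_f'] / ['anova_p']``.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {g: sub[value_col].to_numpy(float) for g, sub in groups.groupby(group_col)}
    if mock_group not in groups:
        raise ValidationError(f"reference group {mock_group!r} missing")
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups including the mock reference")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    control = np.asarray(groups[mock_group], float)
    names = [g for g in groups if g != mock_group]
    treatments = [np.asarray(groups[g], float) for g in names]
    f_stat, anova_p = stats.f_oneway(control, *treatments)
    res = stats.dunnett(*treatments, control=control, alternative="two-sided")
    out = pd.DataFrame(
        {
            "group": names,
            "mean_diff_vs_mock": [t.mean() - control.mean() for t in treatments],
            "adjusted_p": res.pvalue,
        }
    )
    out.attrs["anova_f"] = float(f_stat)
    out.attrs["anova_p"] = float(anova_p)
    return out


def replicate_reproducibility(pair_scores, mock_scores) -> float:
    """One-sided (greater) Wilcoxon rank-sum p-value that the coexpressed
    GPCR-RAMP measurements exceed the receptor-plus-mock measurements.

    Exact when both samples are small and tie-free.
    """
    x = np.asarray(pair_scores, float)
    y = np.asarray(mock_scores, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("replicate_reproducibility requires non-empty samples")
    return float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)
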