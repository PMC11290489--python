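"""Threshold selection and binary interaction calling.

Three thresholding regimes, matching the three arms of the screen:

* **Literature-calibrated (epitope-based schemes).**  For each (RAMP, scheme)
  the robust-Z scores of pairs with a literature label are swept over a
  candidate grid; at each threshold ``t`` a pair is a hit iff ``score > t``,
  giving sensitivity (fraction of known interactors detected) and specificity
  (fraction of known non-interactors rejected).  The working threshold is the
  intersection of the two curves: the grid point minimizing
  ``|sensitivity - specificity|``, ties broken by larger
  ``sensitivity + specificity``, then by the smaller threshold (step curves
  can touch over an interval).
* **Density + MAD (protein-based capture).**  Each receptor-specific antibody
  gets its own threshold: the peak (mode) of a Gaussian kernel density
  estimate of its score population — which is dominated by the non-interacting
  bulk — plus 6 scaled MADs (6 x 1.4826 x MAD).
* **Fixed cutoff (endogenous screens).**  SNR -> quantile normalization
  across replicates -> robust Z of log scores per detection antibody;
  replicate-mean robust-Z above 3.5 is annotated as an interaction.

Hits are strict: a score exactly at a threshold is not a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, DegenerateScaleError, ValidationError
from .io import EPITOPE_SCHEMES, Scheme
from .normalize import MAD_CONSTANT, quantile_normalize, robust_z, snr_transform

ENDOGENOUS_THRESHOLD = 3.5
MAD_MULTIPLIER = 6.0
KDE_GRID_POINTS = 512


@dataclass
class ThresholdSet:
    """Thresholds per calling regime, all in robust-Z units."""

    epitope: dict[tuple[str, str], float] = field(default_factory=dict)  # (ramp, scheme) -> t
    protein: dict[str, float] = field(default_factory=dict)  # antibody -> t
    endogenous: float = ENDOGENOUS_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(kind="epitope", ramp_id=r, scheme_or_antibody=s, threshold=t)
            for (r, s), t in sorted(self.epitope.items())
        ]
        rows += [
            dict(kind="protein", ramp_id="", scheme_or_antibody=a, threshold=t)
            for a, t in sorted(self.protein.items())
        ]
        rows.append(
            dict(kind="endogenous", ramp_id="", scheme_or_antibody="", threshold=self.endogenous)
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Score computation
# ---------------------------------------------------------------------------


def pair_scores(score_input: pd.DataFrame, log_scale: bool = True) -> pd.DataFrame:
    """Robust-Z scores per (GPCR, RAMP, scheme, capture antibody).

    Standardization is per capture-detection antibody pair — the measurement
    population of one antibody across all membrane samples — so antibodies
    with different affinities end up on a common scale.  MFI values are
    log-transformed first (``log_scale=True``, the default) because the noise
    is multiplicative; robust Z on the log scale then has its nominal normal
    reference distribution.

    Mock co-transfection rows are standardized along with the rest (they are
    part of each antibody's population) but downstream calling only consults
    the RAMP rows.
    """
    required = {"gpcr_id", "ramp_id", "scheme_id", "capture_antibody_id", "detection_antibody_id", "mfi"}
    missing = required - set(score_input.columns)
    if missing:
        raise ValidationError(f"score input is missing columns {sorted(missing)}")
    df = score_input.copy()
    vals = df["mfi"].to_numpy(float)
    if np.any(vals <= 0) and log_scale:
        raise ValidationError("MFI values must be positive for log-scale scoring")
    df["_x"] = np.log(vals) if log_scale else vals
    df["score"] = np.nan
    for _, idx in df.groupby(["capture_antibody_id", "detection_antibody_id"]).groups.items():
        x = df.loc[idx, "_x"].to_numpy(float)
        if len(x) < 2:
            raise ValidationError("antibody population with fewer than 2 measurements")
        df.loc[idx, "score"] = robust_z(x)
    return df.drop(columns="_x")


# ---------------------------------------------------------------------------
# Literature-calibrated thresholds
# ---------------------------------------------------------------------------


def candidate_grid(scores) -> np.ndarray:
    """Candidate thresholds: sorted unique observed scores plus the midpoints
    between consecutive unique scores."""
    u = np.unique(np.asarray(scores, dtype=float))
    if u.size == 0:
        raise CalibrationError("no scores to build a candidate grid from")
    mids = (u[:-1] + u[1:]) / 2.0
    return np.sort(np.concatenate([u, mids]))


def sens_spec_curves(
    scores: pd.Series | dict,
    truth: pd.DataFrame,
    thresholds=None,
) -> pd.DataFrame:
    """Confusion counts and sensitivity/specificity per candidate threshold.

    ``scores`` maps (gpcr_id, ramp_id) to a robust-Z score; ``truth`` is a
    labeled truth table with columns gpcr_id, ramp_id, label.  Only labeled
    pairs with a score enter the curves.  A pair is called a hit iff
    ``score > t``; sensitivity is the fraction of labeled interactors called,
    specificity the fraction of labeled non-interactors not called.
    """
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    labels = {
        (row.gpcr_id, row.ramp_id): row.label == "interacting" for row in truth.itertuples()
    }
    keys = [k for k in scores.index if k in labels]
    if not keys:
        raise CalibrationError("no labeled pairs with scores")
    s = scores.loc[keys].to_numpy(float)
    y = np.array([labels[k] for k in keys], dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError(
            "truth set must contain both interacting and non-interacting labeled pairs"
        )
    grid = candidate_grid(s) if thresholds is None else np.asarray(thresholds, dtype=float)
    rows = []
    for t in grid:
        hit = s > t
        tp = int((hit & y).sum())
        fp = int((hit & ~y).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(
            dict(
                threshold=float(t),
                tp=tp,
                tn=tn,
                fp=fp,
                fn=fn,
                sensitivity=tp / n_pos,
                specificity=tn / n_neg,
            )
        )
    return pd.DataFrame(rows)


def select_intersection_threshold(curves: pd.DataFrame) -> float:
    """The sensitivity/specificity crossing point on the candidate grid.

    Minimizes ``|sensitivity - specificity|``; among ties, maximizes
    ``sensitivity + specificity``; among remaining ties, the smallest
    threshold.
    """
    if curves.empty:
        raise CalibrationError("empty curve table")
    gap = (curves["sensitivity"] - curves["specificity"]).abs().to_numpy()
    total = (curves["sensitivity"] + curves["specificity"]).to_numpy()
    t = curves["threshold"].to_numpy()
    order = np.lexsort((t, -total, gap))
    return float(t[order[0]])


def calibrate_epitope_thresholds(
    scored: pd.DataFrame,
    truth: pd.DataFrame,
    ramps=None,
    schemes: tuple[Scheme, ...] = EPITOPE_SCHEMES,
) -> dict[tuple[str, str], float]:
    """Intersection thresholds per (RAMP, epitope scheme), calibrated jointly
    over all receptors with a literature label."""
    out = {}
    ramps = ramps if ramps is not None else sorted(r for r in scored["ramp_id"].unique() if r != "mock")
    scheme_ids = [s.scheme_id for s in schemes]
    on_target = scored["on_target"] if "on_target" in scored.columns else True
    for r in ramps:
        for sch in scheme_ids:
            sub = scored[(scored["ramp_id"] == r) & (scored["scheme_id"] == sch) & on_target]
            if sub.empty:
                continue
            s = sub.set_index(["gpcr_id", "ramp_id"])["score"]
            curves = sens_spec_curves(s, truth)
            out[(r, sch)] = select_intersection_threshold(curves)
    if not out:
        raise CalibrationError("no (RAMP, scheme) stratum had scores to calibrate")
    return out


# ---------------------------------------------------------------------------
# Density + MAD thresholds (protein-based capture)
# ---------------------------------------------------------------------------


def density_mad_threshold(
    scores, mad_multiplier: float = MAD_MULTIPLIER, grid_points: int = KDE_GRID_POINTS
) -> float:
    """Per-antibody threshold: KDE mode of the score population plus
    ``mad_multiplier`` scaled MADs (default 6 x 1.4826 x MAD).

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth) evaluated
    on a ``grid_points``-point grid spanning [min, max]; because most samples
    are off-target for any given antibody, the mode tracks the non-interacting
    bulk.  If the MAD is zero the sample SD replaces the scaled MAD; if that
    is also zero the scale is degenerate.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 8:
        raise ValidationError("density_mad_threshold needs >= 8 scores per antibody")
    if not np.all(np.isfinite(x)):
        raise ValidationError("density_mad_threshold expects finite scores")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = MAD_CONSTANT * mad
    if scale == 0:
        scale = x.std()
        if scale == 0:
            raise DegenerateScaleError("both MAD and SD are zero; threshold undefined")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_points)
    mode = float(grid[np.argmax(kde(grid))])
    return mode + mad_multiplier * scale


def protein_thresholds(
    scored: pd.DataFrame, mad_multiplier: float = MAD_MULTIPLIER
) -> dict[str, float]:
    """Density-MAD threshold per receptor-specific capture antibody, computed
    from that antibody's full score population (on- and off-target samples)."""
    out = {}
    prot = scored[scored["capture_family"] == "protein_based"]
    for ab, sub in prot.groupby("capture_antibody_id"):
        out[str(ab)] = density_mad_threshold(sub["score"].to_numpy(), mad_multiplier)
    return out


# ---------------------------------------------------------------------------
# Applying thresholds
# ---------------------------------------------------------------------------


def apply_thresholds(scored: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Binary call matrix: one row per scored (pair, scheme/antibody) with its
    threshold and ``hit = score > threshold`` (strict).

    Only on-target RAMP co-transfection rows are called (mock rows have no
    pair to call; off-target rows are background population only).  A scored
    entry without a matching threshold raises.
    """
    df = scored[scored["ramp_id"] != "mock"].copy()
    if "on_target" in df.columns:
        df = df[df["on_target"].astype(bool)]
    if df.empty:
        return pd.DataFrame(
            columns=["gpcr_id", "ramp_id", "scheme_id", "capture_family", "capture_antibody_id", "score", "threshold", "hit"]
        )
    thr = np.full(len(df), np.nan)
    is_protein = df["capture_family"].eq("protein_based").to_numpy()
    for i, (_, row) in enumerate(df.iterrows()):
        if is_protein[i]:
            thr[i] = thresholds.protein.get(row["capture_antibody_id"], np.nan)
        else:
            thr[i] = thresholds.epitope.get((row["ramp_id"], row["scheme_id"]), np.nan)
    if np.isnan(thr).any():
        miss = df.loc[np.isnan(thr), ["ramp_id", "scheme_id", "capture_antibody_id"]].drop_duplicates()
        raise ValidationError(f"missing threshold(s) for {miss.head(10).to_dict('records')}")
    df["threshold"] = thr
    df["hit"] = df["score"].to_numpy(float) > thr
    cols = ["gpcr_id", "ramp_id", "scheme_id", "capture_family", "capture_antibody_id", "score", "threshold", "hit"]
    return df[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Endogenous pipeline
# ---------------------------------------------------------------------------


def endogenous_call(
    mfi: pd.DataFrame,
    panel: pd.DataFrame,
    sheet: pd.DataFrame,
    threshold: float = ENDOGENOUS_THRESHOLD,
    per_cell_line: bool = True,
    return_replicate_rz: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Call endogenous GPCR-RAMP complexes at a fixed robust-Z cutoff.

    Pipeline per (cell line, detection antibody): SNR against buffer medians,
    quantile normalization across the replicate columns, robust Z of the log
    scores across capture antibodies per replicate, technical replicates
    averaged within each biological replicate, and the replicate-mean robust-Z
    compared against ``threshold`` (strict).  Returns one row per
    (cell line, capture antibody, detection antibody) with the mean robust-Z,
    the per-replicate robust-Z spread, and the call.

    ``per_cell_line=False`` pools the replicate columns of all cell lines into
    one quantile normalization (a config switch; the default normalizes within
    cell line, treating plates of different lines as separate batches).
    ``return_replicate_rz=True`` additionally returns the long table of
    per-replicate robust-Z scores (useful for null-calibration diagnostics:
    each replicate column is standardized across the antibody population, so
    under the no-interaction null its scores follow the standard-normal
    reference).
    """
    sheet = sheet.copy()
    sheet["is_buffer"] = sheet["is_buffer"].astype(bool)
    merged = mfi.merge(sheet, on="sample_id", how="left", validate="many_to_one")
    if merged["is_buffer"].isna().any():
        raise ValidationError("mfi references samples missing from the sample sheet")
    buffer = merged[merged["is_buffer"]]
    signal = merged[~merged["is_buffer"]]
    if signal.empty:
        empty = pd.DataFrame(
            columns=["cell_line", "capture_antibody_id", "detection_antibody_id", "mean_rz", "n_replicates", "hit"]
        )
        return (empty, pd.DataFrame()) if return_replicate_rz else empty
    with_snr = snr_transform(signal, buffer)
    with_snr["log_snr"] = np.log(with_snr["snr"])

    group_cols = ["cell_line", "detection_antibody_id"] if per_cell_line else ["detection_antibody_id"]
    out_rows = []
    replicate_frames = []
    for gkey, sub in with_snr.groupby(group_cols):
        wide = sub.pivot_table(
            index=["cell_line", "capture_antibody_id"],
            columns=["bio_replicate", "tech_replicate"],
            values="log_snr",
        )
        if wide.isna().any().any():
            raise ValidationError(f"unbalanced replicate design for group {gkey}")
        mat = quantile_normalize(wide) if wide.shape[1] >= 2 else wide
        # robust Z per replicate column across the capture-antibody population
        rz = mat.copy()
        for col in rz.columns:
            rz[col] = robust_z(rz[col].to_numpy())
        # average technical duplicates within bio replicate, then bio replicates
        bio_level = rz.T.groupby(level="bio_replicate").mean().T
        mean_rz = bio_level.mean(axis=1)
        det = gkey[-1] if isinstance(gkey, tuple) else gkey
        if return_replicate_rz:
            long = rz.stack(list(range(rz.columns.nlevels)), future_stack=True).rename("rz").reset_index()
            long["detection_antibody_id"] = det
            replicate_frames.append(long)
        for (cl, ab), m in mean_rz.items():
            out_rows.append(
                dict(
                    cell_line=cl,
                    capture_antibody_id=ab,
                    detection_antibody_id=det,
                    mean_rz=float(m),
                    n_replicates=int(rz.shape[1]),
                    hit=bool(m > threshold),
                )
            )
    out = pd.DataFrame(out_rows)
    target = panel.set_index("antibody_id")["target_id"]
    out["gpcr_id"] = out["capture_antibody_id"].map(target)
    out["ramp_id"] = out["detection_antibody_id"].map(target)
    if return_replicate_rz:
        reps = pd.concat(replicate_frames, ignore_index=True) if replicate_frames else pd.DataFrame()
        return out, reps
    return out


def aggregate_replicate_rz(rz_values, threshold: float = ENDOGENOUS_THRESHOLD) -> tuple[float, bool]:
    """Mean of replicate robust-Z values and the strict fixed-cutoff call."""
    x = np.asarray(rz_values, dtype=float)
    if x.size == 0:
        raise ValidationError("no replicate scores to aggregate")
    m = float(x.mean())
    return m, m > threshold
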