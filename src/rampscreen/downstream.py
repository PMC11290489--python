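"""Post-interactome analyses: expression ratios, RAMP expression clustering,
per-cell-type interaction percentages, transducer-coupling enrichment, and
in-situ proximity-assay (RCP) statistics.

All operations consume the interactome annotation (yes/no/inconclusive per
receptor-RAMP pair) together with external tables: nTPM expression per gene
per cell type, GPCRdb-style transducer couplings, and per-image RCP counts.
Inconclusive pairs are excluded throughout.  Expression is binarized at
nTPM > 1 (strict), the convention of the consensus expression atlases.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ValidationError

logger = logging.getLogger(__name__)

NTPM_EXPRESSED = 1.0  # strict ">" cutoff


# ---------------------------------------------------------------------------
# Expression ratios
# ---------------------------------------------------------------------------


def expression_ratios(
    expression: pd.DataFrame, annotation: pd.DataFrame, ramp_id: str
) -> pd.DataFrame:
    """GPCR:RAMP nTPM ratios per (receptor, cell type) for one RAMP.

    A ratio is formed only in contexts where both genes clear nTPM > 1; each
    (receptor, context) combination contributes one observation.  Only
    receptors annotated yes or no are kept.
    """
    ann = annotation[(annotation["ramp_id"] == ramp_id) & annotation["annotation"].isin(["yes", "no"])]
    label = ann.set_index("gpcr_id")["annotation"]
    expr = expression.set_index(["gene_id", "context_id"])["ntpm"]
    ramp_expr = expr.loc[ramp_id] if ramp_id in expr.index.get_level_values(0) else pd.Series(dtype=float)
    rows = []
    for g in label.index:
        if g not in expr.index.get_level_values(0):
            continue
        for ctx, g_ntpm in expr.loc[g].items():
            r_ntpm = ramp_expr.get(ctx, 0.0)
            if g_ntpm > NTPM_EXPRESSED and r_ntpm > NTPM_EXPRESSED:
                rows.append(
                    dict(
                        gpcr_id=g,
                        ramp_id=ramp_id,
                        context_id=ctx,
                        ratio=float(g_ntpm) / float(r_ntpm),
                        annotation_label=label[g],
                    )
                )
    return pd.DataFrame(rows, columns=["gpcr_id", "ramp_id", "context_id", "ratio", "annotation_label"])


def expression_ratio_test(
    expression: pd.DataFrame, annotation: pd.DataFrame, ramps=None
) -> pd.DataFrame:
    """Per RAMP: two-sided Wilcoxon rank-sum test comparing GPCR:RAMP
    expression ratios of annotated interactors (yes) vs non-interactors (no).

    RAMPs with ratios on only one side are skipped with a warning.
    """
    if ramps is None:
        ramps = sorted(annotation["ramp_id"].unique())
    rows = []
    for r in ramps:
        ratios = expression_ratios(expression, annotation, r)
        yes = ratios.loc[ratios["annotation_label"] == "yes", "ratio"].to_numpy()
        no = ratios.loc[ratios["annotation_label"] == "no", "ratio"].to_numpy()
        if yes.size == 0 or no.size == 0:
            logger.warning("ramp %s skipped: ratios available for only one annotation group", r)
            continue
        p = float(stats.mannwhitneyu(yes, no, alternative="two-sided").pvalue)
        rows.append(
            dict(
                ramp_id=r,
                n_yes=int(yes.size),
                n_no=int(no.size),
                median_ratio_yes=float(np.median(yes)),
                median_ratio_no=float(np.median(no)),
                p_value=p,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binarization and clustering
# ---------------------------------------------------------------------------


def binarize_and_cluster(
    expression: pd.DataFrame,
    genes=None,
    metric: str = "euclidean",
    linkage_method: str = "complete",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Binarize expression at nTPM > 1, build the log2 heat matrix (0 where
    not expressed, log2(nTPM) where expressed), and hierarchically cluster
    genes over contexts.

    Returns ``(binary, log2_matrix, leaf_order)``.  Linkage defaults to
    complete with Euclidean distance (configurable).
    """
    wide = expression.pivot_table(index="gene_id", columns="context_id", values="ntpm", aggfunc="first").fillna(0.0)
    if genes is not None:
        missing = [g for g in genes if g not in wide.index]
        if missing:
            raise ValidationError(f"genes absent from expression table: {missing}")
        wide = wide.loc[list(genes)]
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValidationError("need >= 2 genes and >= 2 contexts to cluster")
    binary = wide > NTPM_EXPRESSED
    log2m = pd.DataFrame(
        np.where(binary, np.log2(wide.where(binary, 1.0)), 0.0),
        index=wide.index,
        columns=wide.columns,
    )
    if not binary.to_numpy().any():
        raise ValidationError("all-zero expression matrix; clustering undefined")
    link = hierarchy.linkage(log2m.to_numpy(), method=linkage_method, metric=metric)
    order = [log2m.index[i] for i in hierarchy.leaves_list(link)]
    return binary, log2m, order


def pct_interacting_per_context(
    expression: pd.DataFrame, annotation: pd.DataFrame, ramps=None
) -> pd.DataFrame:
    """Percentage of annotated-interacting vs non-interacting receptors among
    the receptors expressed (nTPM > 1) in each cell type, restricted to cell
    types where the RAMP itself is expressed.

    Contexts without any expressed, decidably annotated receptor are omitted;
    within a row pct_yes + pct_no = 100.
    """
    if ramps is None:
        ramps = sorted(annotation["ramp_id"].unique())
    expr = expression.set_index(["gene_id", "context_id"])["ntpm"]
    gene_level = expression.groupby("gene_id")
    contexts = sorted(expression["context_id"].unique())
    rows = []
    for r in ramps:
        ann = annotation[(annotation["ramp_id"] == r) & annotation["annotation"].isin(["yes", "no"])]
        label = ann.set_index("gpcr_id")["annotation"]
        for ctx in contexts:
            ramp_ntpm = expr.get((r, ctx), 0.0)
            if not ramp_ntpm > NTPM_EXPRESSED:
                continue
            expressed = [
                g
                for g in label.index
                if expr.get((g, ctx), 0.0) > NTPM_EXPRESSED
            ]
            if not expressed:
                continue
            n_yes = sum(label[g] == "yes" for g in expressed)
            n = len(expressed)
            rows.append(
                dict(
                    context_id=ctx,
                    ramp_id=r,
                    n_gpcrs_expressed=n,
                    pct_yes=100.0 * n_yes / n,
                    pct_no=100.0 * (n - n_yes) / n,
                )
            )
    _ = gene_level  # grouping kept for potential per-gene summaries
    return pd.DataFrame(rows, columns=["context_id", "ramp_id", "n_gpcrs_expressed", "pct_yes", "pct_no"])


# ---------------------------------------------------------------------------
# Coupling enrichment
# ---------------------------------------------------------------------------


def _rxc_log_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        log_fact[r].sum()
        + log_fact[c].sum()
        - log_fact[n]
        - log_fact[table].sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    rows, cols = len(row_margins), len(col_margins)

    def rec(i, remaining_cols, current):
        if i == rows - 1:
            last = np.array(remaining_cols)
            if (last >= 0).all() and last.sum() == row_margins[-1]:
                yield current + [list(last)]
            return
        target = row_margins[i]

        def fill(j, left, row):
            if j == cols - 1:
                if 0 <= left <= remaining_cols[-1]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, target, []):
            new_remaining = [rc - v for rc, v in zip(remaining_cols, row)]
            yield from rec(i + 1, new_remaining, current + [row])

    yield from rec(0, list(col_margins), [])


def exact_rxc_test(table, max_total: int = 200) -> float:
    """Exact conditional test of independence for an r x c contingency table
    (Freeman-Halton generalization of the Fisher test): total probability of
    all tables with the observed margins whose probability does not exceed
    the observed table's."""
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("contingency table must be a non-negative 2-D array")
    n = int(obs.sum())
    if n == 0:
        raise ValidationError("empty contingency table")
    if n > max_total:
        raise ValidationError(f"exact r x c test limited to total count <= {max_total}")
    log_fact = np.array([math.lgamma(k + 1) for k in range(n + 1)])
    lp_obs = _rxc_log_prob(obs, log_fact)
    p = 0.0
    for t in _enumerate_tables(obs.sum(axis=1).tolist(), obs.sum(axis=0).tolist()):
        lp = _rxc_log_prob(np.array(t), log_fact)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def binarize_barr(log_emax_over_ec50: float) -> bool:
    """Beta-arrestin coupling call: 0 means no coupling, > 0 means coupling."""
    return float(log_emax_over_ec50) > 0.0


@dataclass
class CouplingComparison:
    comparison: str
    table: np.ndarray
    odds_ratio: float
    p_value: float

    def as_row(self) -> dict:
        return dict(
            comparison=self.comparison,
            table=self.table.tolist(),
            odds_ratio=self.odds_ratio,
            p_value=self.p_value,
        )


def coupling_enrichment(
    coupling: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Fisher exact tests relating RAMP interaction to transducer coupling.

    A receptor counts as RAMP-interacting when annotated yes for at least one
    RAMP and non-interacting when annotated no for every RAMP (inconclusive
    pairs are ignored; receptors with only inconclusive annotations drop out).
    Compared against that split: membership of each G-protein family among
    primary couplers (2x2), among secondary couplers (2x2), the number of
    primary G-protein couplings (r x c, exact conditional test, p only), and
    each beta-arrestin subtype binarized at log(Emax/EC50) > 0 (2x2).
    2x2 odds ratios are conditional MLEs.  Comparisons with an empty margin
    are skipped with a warning.
    """
    decided = annotation[annotation["annotation"].isin(["yes", "no"])]
    by_gpcr = decided.groupby("gpcr_id")["annotation"].agg(lambda s: "yes" if (s == "yes").any() else "no")
    gpcrs = [g for g in by_gpcr.index if g in set(coupling["gpcr_id"])]
    if not gpcrs:
        raise ValidationError("no annotated receptors with coupling data")
    interacting = np.array([by_gpcr[g] == "yes" for g in gpcrs])

    gprot = coupling[~coupling["transducer"].str.contains("arrestin", case=False)]
    barr = coupling[coupling["transducer"].str.contains("arrestin", case=False)]

    rows = []

    def fisher_2x2(name: str, member: np.ndarray) -> None:
        tab = np.array(
            [
                [int((member & interacting).sum()), int((member & ~interacting).sum())],
                [int((~member & interacting).sum()), int((~member & ~interacting).sum())],
            ]
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            logger.warning("comparison %s skipped: empty margin", name)
            return
        p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
        orr = float(stats.contingency.odds_ratio(tab, kind="conditional").statistic)
        rows.append(dict(comparison=name, table=tab.tolist(), odds_ratio=orr, p_value=p))

    for tier in ("primary", "secondary"):
        sub = gprot[gprot["tier"] == tier]
        fams = sorted(sub["transducer"].unique())
        coupled = {
            g: set(sub.loc[sub["gpcr_id"] == g, "transducer"]) for g in gpcrs
        }
        for fam in fams:
            member = np.array([fam in coupled[g] for g in gpcrs])
            fisher_2x2(f"{tier}_{fam}", member)

    # number of primary G-protein couplings: r x c exact test
    n_primary = np.array(
        [int((gprot[(gprot["tier"] == "primary") & (gprot["gpcr_id"] == g)]).shape[0]) for g in gpcrs]
    )
    levels = sorted(set(n_primary))
    if len(levels) >= 2 and interacting.any() and (~interacting).any():
        tab = np.array(
            [
                [int(((n_primary == k) & interacting).sum()) for k in levels],
                [int(((n_primary == k) & ~interacting).sum()) for k in levels],
            ]
        )
        try:
            p = exact_rxc_test(tab)
            rows.append(dict(comparison="n_primary_couplings", table=tab.tolist(), odds_ratio=np.nan, p_value=p))
        except ValidationError as exc:
            logger.warning("n_primary_couplings skipped: %s", exc)
    else:
        logger.warning("n_primary_couplings skipped: empty margin")

    for sub_name, subdf in barr.groupby("transducer"):
        vals = subdf.set_index("gpcr_id")["log_emax_over_ec50"]
        with_data = [g for g in gpcrs if g in vals.index and not pd.isna(vals[g])]
        if not with_data:
            continue
        member_map = {g: binarize_barr(vals[g]) for g in with_data}
        mask = np.array([g in member_map for g in gpcrs])
        inter_sub = interacting[mask]
        member = np.array([member_map[g] for g in np.array(gpcrs)[mask]])
        tab = np.array(
            [
                [int((member & inter_sub).sum()), int((member & ~inter_sub).sum())],
                [int((~member & inter_sub).sum()), int((~member & ~inter_sub).sum())],
            ]
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            logger.warning("comparison barr_%s skipped: empty margin", sub_name)
            continue
        p = float(stats.fisher_exact(tab)[1])
        orr = float(stats.contingency.odds_ratio(tab, kind="conditional").statistic)
        rows.append(dict(comparison=f"barr_{sub_name}", table=tab.tolist(), odds_ratio=orr, p_value=p))

    return pd.DataFrame(rows, columns=["comparison", "table", "odds_ratio", "p_value"])


# ---------------------------------------------------------------------------
# Proximity-assay (RCP) statistics
# ---------------------------------------------------------------------------


def molboolean_summarize(rcp: pd.DataFrame, blank_condition: str = "blank") -> pd.DataFrame:
    """Blank-corrected RCPs per cell and percent complexed, per image.

    Per image and channel: RCPs/cell = count / nuclei; the mean blank
    RCPs/cell (images of cells never exposed to primary antibody) is
    subtracted and negatives clamp to 0.  Percent overlap normalizes the net
    complex channel to the total net RCPs per cell across the three channels.
    """
    if blank_condition not in set(rcp["stain_condition"]):
        raise ValidationError(f"blank condition {blank_condition!r} missing from RCP table")
    if (rcp["nuclei"] < 1).any():
        raise ValidationError("every image must contain at least one nucleus")
    channels = ("rcp_gpcr", "rcp_ramp", "rcp_overlap")
    per_cell = rcp.copy()
    for ch in channels:
        per_cell[ch + "_pc"] = per_cell[ch] / per_cell["nuclei"]
    blank_means = per_cell.loc[per_cell["stain_condition"] == blank_condition, [c + "_pc" for c in channels]].mean()
    signal = per_cell[per_cell["stain_condition"] != blank_condition].copy()
    n_clamped = 0
    for ch in channels:
        net = signal[ch + "_pc"] - blank_means[ch + "_pc"]
        n_clamped += int((net < 0).sum())
        signal["net_" + ch] = net.clip(lower=0.0)
    if n_clamped:
        logger.info("molboolean_summarize: clamped %d negative net value(s) to 0", n_clamped)
    total = signal[["net_" + c for c in channels]].sum(axis=1)
    signal["pct_overlap"] = np.where(total > 0, 100.0 * signal["net_rcp_overlap"] / total, 0.0)
    cols = ["image_id", "stain_condition", "nuclei"] + ["net_" + c for c in channels] + ["pct_overlap"]
    return signal[cols].reset_index(drop=True)


def molboolean_compare(
    summaries: pd.DataFrame, positive_control: str, value_col: str = "pct_overlap", alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA over stain conditions followed by Dunnett comparisons of
    each condition against the positive control; flags conditions whose
    adjusted p falls below ``alpha``."""
    groups = {c: sub[value_col].to_numpy(float) for c, sub in summaries.groupby("stain_condition")}
    if positive_control not in groups:
        raise ValidationError(f"positive control {positive_control!r} missing")
    if len(groups) < 2:
        raise ValidationError("need at least two stain conditions")
    for c, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"condition {c!r} has fewer than 2 images")
    control = groups[positive_control]
    names = [c for c in groups if c != positive_control]
    treatments = [groups[c] for c in names]
    f_stat, anova_p = stats.f_oneway(control, *treatments)
    res = stats.dunnett(*treatments, control=control, alternative="two-sided")
    out = pd.DataFrame(
        {
            "stain_condition": names,
            "mean_diff_vs_control": [t.mean() - control.mean() for t in treatments],
            "adjusted_p": res.pvalue,
        }
    )
    out["significant"] = out["adjusted_p"] < alpha
    out.attrs["anova_f"] = float(f_stat)
    out.attrs["anova_p"] = float(anova_p)
    return out
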