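"""Evidence classes, yes/no/inconclusive integration, and summary counts.

Per (receptor, RAMP, capture family) the fraction of capture-detection
schemes that called the pair is graded: **strong** above two-thirds, **weak**
below one-third, **medium** in between (a fraction exactly at a third is
medium), and **absent** when no scheme produced data — which happens only for
protein-based capture, since receptors without validated antibodies have zero
protein schemes while every library receptor has all five epitope schemes.

The two capture families then vote.  Strong+strong or strong+medium is an
interaction (*yes*); weak+weak or weak+medium a non-interaction (*no*);
strong+weak and medium+medium are contradictory or undecided
(*inconclusive*).  Without protein data the epitope class decides alone:
strong -> yes, weak -> no, medium -> inconclusive.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .errors import ValidationError

CLASSES = ("strong", "medium", "weak", "absent")
LABELS = ("yes", "no", "inconclusive")


def evidence_class(n_passing: int, n_schemes: int) -> str:
    """Grade the fraction of passing schemes: strong (> 2/3), weak (< 1/3),
    medium otherwise; absent when there are no schemes at all."""
    if n_schemes < 0 or n_passing < 0:
        raise ValidationError("scheme counts must be non-negative")
    if n_passing > n_schemes:
        raise ValidationError("n_passing cannot exceed n_schemes")
    if n_schemes == 0:
        return "absent"
    # integer arithmetic keeps the exact-thirds boundary exact
    if 3 * n_passing > 2 * n_schemes:
        return "strong"
    if 3 * n_passing < n_schemes:
        return "weak"
    return "medium"


#: Complete decision table for (epitope class, protein class) -> label.
_INTEGRATION_TABLE: dict[tuple[str, str], str] = {
    ("strong", "strong"): "yes",
    ("strong", "medium"): "yes",
    ("medium", "strong"): "yes",
    ("weak", "weak"): "no",
    ("weak", "medium"): "no",
    ("medium", "weak"): "no",
    ("strong", "weak"): "inconclusive",
    ("weak", "strong"): "inconclusive",
    ("medium", "medium"): "inconclusive",
    ("strong", "absent"): "yes",
    ("weak", "absent"): "no",
    ("medium", "absent"): "inconclusive",
}


def integrate_yes_no(epitope_class: str, protein_class: str) -> str:
    """Integrate epitope- and protein-capture evidence into yes/no/inconclusive."""
    if epitope_class == "absent":
        raise ValidationError(
            "epitope evidence cannot be absent: every library receptor has all epitope schemes"
        )
    key = (epitope_class, protein_class)
    if key not in _INTEGRATION_TABLE:
        raise ValidationError(f"unknown evidence class combination {key}")
    return _INTEGRATION_TABLE[key]


def build_evidence(calls: pd.DataFrame) -> pd.DataFrame:
    """Evidence table from a binary call matrix: per (receptor, RAMP, capture
    family) the number of schemes with data, the number passing, and the
    class.  For protein-based capture each receptor-specific antibody counts
    as one scheme."""
    required = {"gpcr_id", "ramp_id", "scheme_id", "capture_family", "capture_antibody_id", "hit"}
    missing = required - set(calls.columns)
    if missing:
        raise ValidationError(f"call matrix is missing columns {sorted(missing)}")
    if calls.empty:
        return pd.DataFrame(
            columns=["gpcr_id", "ramp_id", "capture_family", "n_schemes", "n_passing", "evidence_class"]
        )
    df = calls.copy()
    df["unit"] = np.where(
        df["capture_family"] == "protein_based", df["capture_antibody_id"], df["scheme_id"]
    )
    grouped = (
        df.groupby(["gpcr_id", "ramp_id", "capture_family"])
        .agg(n_schemes=("unit", "nunique"), n_passing=("hit", "sum"))
        .reset_index()
    )
    grouped["n_passing"] = grouped["n_passing"].astype(int)
    grouped["evidence_class"] = [
        evidence_class(p, s) for p, s in zip(grouped["n_passing"], grouped["n_schemes"])
    ]
    return grouped


def annotate_interactome(evidence: pd.DataFrame) -> pd.DataFrame:
    """Final interactome annotation per (receptor, RAMP) from the evidence
    table; pairs lacking protein-capture data are integrated with protein
    class 'absent'."""
    wide = evidence.pivot_table(
        index=["gpcr_id", "ramp_id"],
        columns="capture_family",
        values="evidence_class",
        aggfunc="first",
    )
    if "epitope_based" not in wide.columns:
        raise ValidationError("no epitope-based evidence to integrate")
    rows = []
    for (g, r), row in wide.iterrows():
        epi = row.get("epitope_based")
        prot = row.get("protein_based")
        if epi is None or (isinstance(epi, float) and np.isnan(epi)):
            raise ValidationError(f"pair ({g}, {r}) lacks epitope evidence")
        if prot is None or (isinstance(prot, float) and np.isnan(prot)):
            prot = "absent"
        rows.append(dict(gpcr_id=g, ramp_id=r, annotation=integrate_yes_no(epi, prot)))
    return pd.DataFrame(rows)


def overlap_counts(sets_by_ramp: dict[str, set], universe=None) -> pd.DataFrame:
    """UpSet-style membership-pattern counts across per-RAMP receptor sets.

    Returns one row per membership pattern (including the none-of-any
    pattern); the counts partition the universe, which defaults to the union
    of the sets.
    """
    ramps = sorted(sets_by_ramp)
    sets = {r: set(sets_by_ramp[r]) for r in ramps}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    universe = set(universe)
    rows = []
    for pattern in itertools.product([True, False], repeat=len(ramps)):
        members = set(universe)
        for r, inside in zip(ramps, pattern):
            members = members & sets[r] if inside else members - sets[r]
        rows.append(
            dict(
                pattern="&".join(r for r, inside in zip(ramps, pattern) if inside) or "none",
                **{r: inside for r, inside in zip(ramps, pattern)},
                count=len(members),
            )
        )
    return pd.DataFrame(rows)


def expression_quartile_bias(
    evidence: pd.DataFrame,
    expression: dict[str, float] | pd.Series,
    entity_col: str = "gpcr_id",
) -> pd.DataFrame:
    """Evidence-class composition per expression quartile.

    Entities are split at the three sample quartiles (linear/type-7
    quantiles; a value exactly at a boundary goes to the lower bin); within
    each quartile the strong/medium/weak(/absent) proportions sum to 1.
    Detects expression-level bias: an unbiased assay shows similar
    proportions in every quartile.
    """
    if isinstance(expression, dict):
        expression = pd.Series(expression)
    ev = evidence[evidence[entity_col].isin(expression.index)].copy()
    entities = ev[entity_col].unique()
    if len(entities) < 4:
        raise ValidationError("need at least 4 entities with expression to form quartiles")
    expr = expression.loc[entities].astype(float)
    bounds = np.quantile(expr.to_numpy(), [0.25, 0.5, 0.75])  # type-7 by default
    quart = {
        e: int(np.searchsorted(bounds, v, side="left")) + 1 for e, v in expr.items()
    }
    ev["quartile"] = ev[entity_col].map(quart)
    counts = (
        ev.groupby(["quartile", "evidence_class"]).size().rename("n").reset_index()
    )
    counts["proportion"] = counts.groupby("quartile")["n"].transform(lambda s: s / s.sum())
    return counts


def protein_capture_summary(calls: pd.DataFrame, n_panel_antibodies: int | None = None) -> pd.DataFrame:
    """Per RAMP: how many receptor-specific capture antibodies detected at
    least one complex, the percentage of the antibody panel that represents,
    and the number of unique receptors involved."""
    prot = calls[calls["capture_family"] == "protein_based"]
    if n_panel_antibodies is None:
        n_panel_antibodies = prot["capture_antibody_id"].nunique()
    if n_panel_antibodies <= 0:
        raise ValidationError("panel antibody count must be positive")
    rows = []
    for r, sub in prot.groupby("ramp_id"):
        hits = sub[sub["hit"]]
        n_abs = hits["capture_antibody_id"].nunique()
        rows.append(
            dict(
                ramp_id=r,
                n_positive_antibodies=n_abs,
                n_panel_antibodies=n_panel_antibodies,
                pct_positive_antibodies=100.0 * n_abs / n_panel_antibodies,
                n_unique_gpcrs=hits["gpcr_id"].nunique(),
            )
        )
    return pd.DataFrame(rows)


def summarize_screen(
    calls: pd.DataFrame, evidence: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Headline count tables: hits per (RAMP, scheme) — the call-matrix column
    sums — evidence-class counts per (RAMP, capture family), and
    yes/no/inconclusive counts per RAMP."""
    if calls.empty:
        hits = pd.DataFrame(columns=["ramp_id", "scheme_id", "n_hits", "n_pairs"])
    else:
        hits = (
            calls.groupby(["ramp_id", "scheme_id"])
            .agg(n_hits=("hit", "sum"), n_pairs=("hit", "size"))
            .reset_index()
        )
        hits["n_hits"] = hits["n_hits"].astype(int)
    ev_counts = (
        evidence.groupby(["ramp_id", "capture_family", "evidence_class"]).size().rename("n").reset_index()
        if not evidence.empty
        else pd.DataFrame(columns=["ramp_id", "capture_family", "evidence_class", "n"])
    )
    ann_counts = (
        annotation.groupby(["ramp_id", "annotation"]).size().rename("n").reset_index()
        if not annotation.empty
        else pd.DataFrame(columns=["ramp_id", "annotation", "n"])
    )
    return {"hits_per_scheme": hits, "evidence_counts": ev_counts, "annotation_counts": ann_counts}
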