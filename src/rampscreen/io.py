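"""Tabular data model: schemas, readers/writers, validation, and score-input assembly.

All tables are plain pandas DataFrames in long format, exchanged as CSV/TSV
(delimiter inferred from the file extension, overridable).  Each table kind has
a registered schema: required columns, key columns that must be unique, and
numeric columns that are coerced on read.  Validation is total — malformed
input raises :class:`~rampscreen.errors.ValidationError` naming the offending
rows; the only silent-ish path is missing MFI values, which are dropped with a
logged count.

The special token ``"mock"`` marks empty/mock transfection in ``gpcr_id`` /
``ramp_id``; buffer wells are flagged explicitly with ``is_buffer``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

MOCK = "mock"

# ---------------------------------------------------------------------------
# Capture-detection schemes
# ---------------------------------------------------------------------------

CAPTURE_FAMILIES = ("epitope_based", "protein_based")
CAPTURE_KINDS = (
    "gpcr_tag_1d4",
    "gpcr_tag_flag",
    "ramp_tag_ha",
    "ramp_tag_ollas",
    "ramp_specific",
    "gpcr_specific",
)
DETECTION_KINDS = ("anti_1d4_pe", "anti_ollas_pe", "anti_ramp_pe")


@dataclass(frozen=True)
class Scheme:
    """One capture-detection scheme: a capture-antibody class paired with a
    fluorophore-conjugated detection antibody.

    Epitope-based schemes capture an engineered tag (or the RAMP itself, via
    anti-RAMP antibodies, which generalize to every receptor and therefore
    count as epitope-based); protein-based schemes capture the receptor's
    native sequence with receptor-specific antibodies.
    """

    scheme_id: str
    capture_family: str
    capture_kind: str
    detection_kind: str

    def __post_init__(self) -> None:
        if self.capture_family not in CAPTURE_FAMILIES:
            raise ValidationError(f"unknown capture_family {self.capture_family!r}")
        if self.capture_kind not in CAPTURE_KINDS:
            raise ValidationError(f"unknown capture_kind {self.capture_kind!r}")
        if self.detection_kind not in DETECTION_KINDS:
            raise ValidationError(f"unknown detection_kind {self.detection_kind!r}")
        if self.capture_kind == "ramp_specific" and self.capture_family != "epitope_based":
            raise ValidationError("ramp_specific capture must be epitope_based")
        if self.capture_kind == "gpcr_specific" and self.capture_family != "protein_based":
            raise ValidationError("gpcr_specific capture must be protein_based")


#: The five epitope-based schemes of the dual-tagged screen: capture the
#: receptor by its tag and detect the RAMP tag, or capture the RAMP (by tag or
#: by anti-RAMP antibody) and detect the receptor tag.
EPITOPE_SCHEMES: tuple[Scheme, ...] = (
    Scheme("capt_1d4_det_ollas", "epitope_based", "gpcr_tag_1d4", "anti_ollas_pe"),
    Scheme("capt_flag_det_ollas", "epitope_based", "gpcr_tag_flag", "anti_ollas_pe"),
    Scheme("capt_ha_det_1d4", "epitope_based", "ramp_tag_ha", "anti_1d4_pe"),
    Scheme("capt_ollas_det_1d4", "epitope_based", "ramp_tag_ollas", "anti_1d4_pe"),
    Scheme("capt_ramp_det_1d4", "epitope_based", "ramp_specific", "anti_1d4_pe"),
)

PROTEIN_SCHEME = Scheme("capt_gpcr_det_ollas", "protein_based", "gpcr_specific", "anti_ollas_pe")

# ---------------------------------------------------------------------------
# Schema registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableSchema:
    kind: str
    columns: tuple[str, ...]
    key: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    non_negative: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    s.kind: s
    for s in (
        TableSchema(
            "mfi",
            ("sample_id", "capture_antibody_id", "detection_antibody_id", "mfi"),
            ("sample_id", "capture_antibody_id", "detection_antibody_id"),
            numeric=("mfi",),
            non_negative=("mfi",),
        ),
        TableSchema(
            "panel",
            ("antibody_id", "bead_id", "target_id", "target_class", "role", "host"),
            ("antibody_id",),
        ),
        TableSchema(
            "samples",
            (
                "sample_id",
                "cell_line",
                "gpcr_id",
                "ramp_id",
                "bio_replicate",
                "tech_replicate",
                "total_protein",
                "is_buffer",
            ),
            ("sample_id",),
            numeric=("bio_replicate", "tech_replicate", "total_protein"),
        ),
        TableSchema("truth", ("gpcr_id", "ramp_id", "label"), ("gpcr_id", "ramp_id")),
        TableSchema(
            "expression",
            ("gene_id", "context_id", "ntpm"),
            ("gene_id", "context_id"),
            numeric=("ntpm",),
            non_negative=("ntpm",),
        ),
        TableSchema(
            "coupling",
            ("gpcr_id", "transducer", "tier", "log_emax_over_ec50"),
            ("gpcr_id", "transducer", "tier"),
            numeric=("log_emax_over_ec50",),
        ),
        TableSchema(
            "rcp",
            ("image_id", "stain_condition", "nuclei", "rcp_gpcr", "rcp_ramp", "rcp_overlap"),
            ("image_id",),
            numeric=("nuclei", "rcp_gpcr", "rcp_ramp", "rcp_overlap"),
            non_negative=("nuclei", "rcp_gpcr", "rcp_ramp", "rcp_overlap"),
        ),
        TableSchema(
            "scores",
            ("gpcr_id", "ramp_id", "scheme_id", "antibody_id", "score"),
            ("gpcr_id", "ramp_id", "scheme_id", "antibody_id"),
            numeric=("score",),
        ),
        TableSchema(
            "calls",
            ("gpcr_id", "ramp_id", "scheme_id", "antibody_id", "score", "threshold", "hit"),
            ("gpcr_id", "ramp_id", "scheme_id", "antibody_id"),
            numeric=("score", "threshold"),
        ),
        TableSchema(
            "evidence",
            ("gpcr_id", "ramp_id", "capture_family", "n_schemes", "n_passing", "evidence_class"),
            ("gpcr_id", "ramp_id", "capture_family"),
            numeric=("n_schemes", "n_passing"),
            non_negative=("n_schemes", "n_passing"),
        ),
        TableSchema(
            "annotation",
            ("gpcr_id", "ramp_id", "annotation"),
            ("gpcr_id", "ramp_id"),
        ),
    )
}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_table(path: str | Path, kind: str, delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate a typed table.

    Header matching is case-insensitive and order-free; extra columns are kept.
    Numeric columns are coerced; unparsable numerics raise.  For MFI tables,
    missing MFI values are dropped with a logged count (they are excluded
    pairwise downstream rather than imputed).
    """
    path = Path(path)
    if kind not in SCHEMAS:
        raise ValidationError(f"unknown table kind {kind!r}")
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_table(df, kind)


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate (and coerce) a DataFrame against the registered schema."""
    schema = SCHEMAS[kind]
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{kind} table is missing required column(s): {missing}")
    df = df.copy()
    for col in schema.numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.upper() != "NA")
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValidationError(f"{kind} table: unparsable numeric in {col!r} at rows {rows}")
        df[col] = coerced
    if kind == "mfi":
        miss = df["mfi"].isna()
        if miss.any():
            logger.info("mfi table: dropping %d record(s) with missing MFI", int(miss.sum()))
            df = df.loc[~miss].reset_index(drop=True)
    else:
        for col in schema.numeric:
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()[:5]
                raise ValidationError(f"{kind} table: missing value in {col!r} at rows {rows}")
    for col in schema.non_negative:
        neg = df[col] < 0
        if neg.any():
            rows = df.index[neg].tolist()[:5]
            raise ValidationError(f"{kind} table: negative value in {col!r} at rows {rows}")
    dup = df.duplicated(subset=list(schema.key), keep=False)
    if dup.any():
        keys = df.loc[dup, list(schema.key)].drop_duplicates().head(5).to_dict("records")
        raise ValidationError(f"{kind} table: duplicate key(s) {keys}")
    _validate_kind_specific(df, kind)
    return df.reset_index(drop=True)


def _validate_kind_specific(df: pd.DataFrame, kind: str) -> None:
    if kind == "panel":
        capture = df[df["role"] == "capture"]
        if capture["bead_id"].duplicated().any():
            dups = capture.loc[capture["bead_id"].duplicated(), "bead_id"].tolist()[:5]
            raise ValidationError(f"panel: bead_id not unique among capture antibodies: {dups}")
        detection = df[df["role"] == "detection"]
        has_bead = detection["bead_id"].notna() & (detection["bead_id"].astype(str) != "")
        if has_bead.any():
            raise ValidationError("panel: detection antibodies must not carry a bead_id")
        bad_role = ~df["role"].isin(["capture", "detection"])
        if bad_role.any():
            raise ValidationError(f"panel: unknown role {df.loc[bad_role, 'role'].unique().tolist()}")
    elif kind == "samples":
        if "is_buffer" in df.columns:
            df["is_buffer"] = df["is_buffer"].map(_parse_bool)
            buf = df[df["is_buffer"]]
            bad = (buf["gpcr_id"] != MOCK) | (buf["ramp_id"] != MOCK)
            if bad.any():
                rows = buf.index[bad].tolist()[:5]
                raise ValidationError(f"samples: buffer wells must have gpcr_id=ramp_id='mock' (rows {rows})")
    elif kind == "truth":
        bad = ~df["label"].isin(["interacting", "non_interacting"])
        if bad.any():
            raise ValidationError(f"truth: unknown label(s) {df.loc[bad, 'label'].unique().tolist()}")
    elif kind == "rcp":
        if (df["nuclei"] < 1).any():
            raise ValidationError("rcp: nuclei must be >= 1")
    elif kind == "coupling":
        bad = ~df["tier"].isin(["primary", "secondary"])
        if bad.any():
            raise ValidationError(f"coupling: unknown tier(s) {df.loc[bad, 'tier'].unique().tolist()}")


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in {"true", "1", "yes", "t"}


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    delimiter: str | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a table as CSV/TSV; optionally drop a JSON metadata sidecar
    (``<path>.meta.json``) recording provenance (seed, config hash, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)
    if metadata is not None:
        write_sidecar(path, metadata)
    return path


def write_sidecar(path: str | Path, metadata: dict) -> Path:
    from . import __version__

    side = Path(str(path) + ".meta.json")
    payload = dict(metadata)
    payload.setdefault("rampscreen_version", __version__)
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return side


def config_hash(obj) -> str:
    """Stable short hash of a (nested) configuration mapping or dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Score-input assembly
# ---------------------------------------------------------------------------


def _capture_kind(row: pd.Series) -> str | None:
    cls, target = row["target_class"], str(row["target_id"]).upper()
    if cls == "epitope_tag":
        return {
            "1D4": "gpcr_tag_1d4",
            "FLAG": "gpcr_tag_flag",
            "HA": "ramp_tag_ha",
            "OLLAS": "ramp_tag_ollas",
        }.get(target)
    if cls == "ramp":
        return "ramp_specific"
    if cls == "gpcr":
        return "gpcr_specific"
    return None


def _detection_kind(row: pd.Series) -> str | None:
    cls, target = row["target_class"], str(row["target_id"]).upper()
    if cls == "epitope_tag" and target == "1D4":
        return "anti_1d4_pe"
    if cls == "epitope_tag" and target == "OLLAS":
        return "anti_ollas_pe"
    if cls == "ramp":
        return "anti_ramp_pe"
    return None


def build_score_input(
    mfi: pd.DataFrame,
    panel: pd.DataFrame,
    sheet: pd.DataFrame,
    schemes: tuple[Scheme, ...] = EPITOPE_SCHEMES + (PROTEIN_SCHEME,),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join MFI records with the panel and sample sheet into the long scoring
    table: one row per measured (GPCR, RAMP, scheme, antibody, replicate).

    Returns ``(long_table, buffer)``.  ``long_table`` covers membrane samples
    (including the receptor-plus-mock rows, which serve as negative
    references); buffer wells are carried separately because they define SNR
    denominators.

    Scheme-to-record resolution: an MFI record belongs to a scheme when its
    capture antibody's kind and its detection antibody's kind match the
    scheme's.  Rows where the capture bead actually addresses the sample's
    receptor/RAMP are flagged ``on_target``; these are the pair rows, exactly
    one per (receptor, co-transfection state, scheme, antibody, replicate).
    Off-target rows (a receptor-specific or RAMP-specific bead read in a
    sample not containing its target) are retained with ``on_target=False``:
    they are each antibody's background population, which per-antibody
    standardization and density thresholding require.  In mock samples all
    anti-RAMP beads see only background and are exchangeable, so the first
    RAMP's bead stands as the single on-target representative, keeping the
    pair design balanced.
    """
    for col in ("sample_id", "capture_antibody_id", "detection_antibody_id", "mfi"):
        if col not in mfi.columns:
            raise ValidationError(f"mfi table missing column {col!r}")
    panel = panel.set_index("antibody_id", drop=False)
    unknown_capture = set(mfi["capture_antibody_id"]) - set(panel.index)
    unknown_detect = set(mfi["detection_antibody_id"]) - set(panel.index)
    if unknown_capture or unknown_detect:
        raise ValidationError(
            f"mfi references unknown antibodies: capture={sorted(unknown_capture)[:5]} "
            f"detection={sorted(unknown_detect)[:5]}"
        )
    unknown_samples = set(mfi["sample_id"]) - set(sheet["sample_id"])
    if unknown_samples:
        raise ValidationError(f"mfi references unknown samples: {sorted(unknown_samples)[:5]}")

    cap_kind = panel.apply(_capture_kind, axis=1)
    det_kind = panel.apply(_detection_kind, axis=1)
    cap_target = panel["target_id"]

    df = mfi.merge(sheet, on="sample_id", how="left", validate="many_to_one")
    df["capture_kind"] = df["capture_antibody_id"].map(cap_kind)
    df["detection_kind"] = df["detection_antibody_id"].map(det_kind)
    df["capture_target"] = df["capture_antibody_id"].map(cap_target)

    buffer_mask = df["is_buffer"].map(_parse_bool) if df["is_buffer"].dtype == object else df["is_buffer"]
    buffer_df = df.loc[buffer_mask.astype(bool)].copy()
    memb = df.loc[~buffer_mask.astype(bool) & (df["gpcr_id"] != MOCK)].copy()

    ramp_universe = sorted(r for r in sheet["ramp_id"].unique() if r != MOCK)
    first_ramp = ramp_universe[0] if ramp_universe else None

    out_frames = []
    for scheme in schemes:
        sub = memb[
            (memb["capture_kind"] == scheme.capture_kind)
            & (memb["detection_kind"] == scheme.detection_kind)
        ].copy()
        if scheme.capture_kind == "ramp_specific":
            sub["on_target"] = (sub["capture_target"] == sub["ramp_id"]) | (
                (sub["ramp_id"] == MOCK) & (sub["capture_target"] == first_ramp)
            )
        elif scheme.capture_kind == "gpcr_specific":
            sub["on_target"] = sub["capture_target"] == sub["gpcr_id"]
        else:
            sub["on_target"] = True
        sub["scheme_id"] = scheme.scheme_id
        sub["capture_family"] = scheme.capture_family
        out_frames.append(sub)
    cols = [
        "gpcr_id",
        "ramp_id",
        "scheme_id",
        "capture_family",
        "capture_antibody_id",
        "detection_antibody_id",
        "sample_id",
        "cell_line",
        "bio_replicate",
        "tech_replicate",
        "on_target",
        "mfi",
    ]
    pairs = (
        pd.concat(out_frames, ignore_index=True)[cols]
        if out_frames
        else pd.DataFrame(columns=cols)
    )
    return pairs, buffer_df
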