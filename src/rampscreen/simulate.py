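"""Seed-reproducible synthetic bead-array screens with known ground truth.

The generator emulates the design of the dual-tagged GPCR-RAMP interactome
screen: every receptor is expressed alone (receptor + mock) and coexpressed
with each RAMP, the resulting membrane samples are read over five
epitope-based capture-detection schemes plus zero-to-six receptor-specific
capture antibodies per receptor, and buffer wells carry assay background.

Signal model (per MFI record)::

    log MFI = baseline(bead) + affinity(capture antibody)
              + log_effect * 1[complex read out by this scheme in this sample]
              + Normal(0, noise_sd)

MFI is the exponential of that sum, so intensities are strictly positive and
measurement noise is multiplicative (log-normal), the typical behavior of
bead-array readouts.  Per-antibody affinity offsets are drawn once per capture
antibody and reused across every sample, which is what makes per-antibody
score populations (and per-antibody thresholds) meaningful.  Buffer wells are
baseline-only records; their medians define SNR denominators.

Everything is driven by a single :class:`SimulationConfig`; identical config
and seed give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MOCK

__all__ = [
    "SimulationConfig",
    "simulate_screen",
    "simulate_truth_set",
    "simulate_endogenous",
    "simulate_rcp_counts",
    "simulate_expression",
    "simulate_coupling",
]

#: Log-scale location of bead background fluorescence (arbitrary units).
BASELINE_LOG_MFI = 5.0
#: Log-scale spread of per-bead backgrounds.
BASELINE_SD = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of a synthetic screen.

    Parameters
    ----------
    n_gpcrs:
        Number of receptors in the library.
    ramps:
        RAMP identifiers; each receptor is coexpressed with each of these.
    interact_prob:
        Probability, per (receptor, RAMP), that the pair truly interacts.
    log_effect:
        Mean log-MFI shift added when a true complex is read out
        (natural-log scale; 2.0 is roughly a 7-fold MFI increase).
    noise_sd:
        SD of the log-MFI measurement noise.
    ab_affinity_sd:
        Log-scale spread of per-capture-antibody affinity/background offsets,
        shared across all samples of one antibody.
    n_protein_abs_range:
        Closed interval of receptor-specific capture antibodies per receptor
        (0 allowed: receptors without validated antibodies).
    n_buffer_wells:
        Buffer (no-lysate) wells per capture-detection combination.
    truth_label_noise:
        Probability that a literature truth label is flipped when sampling a
        truth set.
    seed:
        Seed of the random generator; fully determines all outputs.
    """

    n_gpcrs: int
    ramps: tuple[str, ...] = ("RAMP1", "RAMP2", "RAMP3")
    interact_prob: float = 0.5
    log_effect: float = 2.0
    noise_sd: float = 0.5
    ab_affinity_sd: float = 0.5
    n_protein_abs_range: tuple[int, int] = (0, 6)
    n_buffer_wells: int = 16
    truth_label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gpcrs < 1:
            raise ConfigurationError("n_gpcrs must be a positive integer")
        if len(self.ramps) == 0:
            raise ConfigurationError("ramps list must not be empty")
        if not (0.0 <= self.interact_prob <= 1.0):
            raise ConfigurationError("interact_prob must lie in [0, 1]")
        if not (0.0 <= self.truth_label_noise < 1.0):
            raise ConfigurationError("truth_label_noise must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.ab_affinity_sd < 0:
            raise ConfigurationError("ab_affinity_sd must be >= 0")
        lo, hi = self.n_protein_abs_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("n_protein_abs_range must satisfy 0 <= lo <= hi")
        if self.n_buffer_wells < 1:
            raise ConfigurationError("n_buffer_wells must be a positive integer")

    def to_dict(self) -> dict:
        return asdict(self)


def _gpcr_ids(n: int) -> list[str]:
    return [f"GPCR{i + 1:04d}" for i in range(n)]


def _epitope_combos(ramps) -> list[tuple[str, str]]:
    combos = [
        ("ab_1d4", "det_ollas_pe"),
        ("ab_flag", "det_ollas_pe"),
        ("ab_ha", "det_1d4_pe"),
        ("ab_ollas", "det_1d4_pe"),
    ]
    combos += [(f"ab_{r.lower()}", "det_1d4_pe") for r in ramps]
    return combos


def _base_panel(ramps) -> list[dict]:
    rows = [
        dict(antibody_id="ab_1d4", bead_id="bead_1d4", target_id="1D4", target_class="epitope_tag", role="capture", host="mouse_mab"),
        dict(antibody_id="ab_flag", bead_id="bead_flag", target_id="FLAG", target_class="epitope_tag", role="capture", host="mouse_mab"),
        dict(antibody_id="ab_ha", bead_id="bead_ha", target_id="HA", target_class="epitope_tag", role="capture", host="mouse_mab"),
        dict(antibody_id="ab_ollas", bead_id="bead_ollas", target_id="OLLAS", target_class="epitope_tag", role="capture", host="mouse_mab"),
        dict(antibody_id="det_1d4_pe", bead_id="", target_id="1D4", target_class="epitope_tag", role="detection", host="mouse_mab"),
        dict(antibody_id="det_ollas_pe", bead_id="", target_id="OLLAS", target_class="epitope_tag", role="detection", host="mouse_mab"),
    ]
    for r in ramps:
        rows.append(
            dict(antibody_id=f"ab_{r.lower()}", bead_id=f"bead_{r.lower()}", target_id=r, target_class="ramp", role="capture", host="rabbit_pab")
        )
    return rows


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the heterologous dual-tagged screen.

    Returns ``(mfi, panel, sheet, truth)``:

    * ``sheet`` — one membrane sample per receptor x (mock + each RAMP), a
      mock-only control, and ``n_buffer_wells`` buffer wells;
    * ``mfi`` — one record per sample per scheme-relevant
      (capture bead, detection antibody) combination, every bead being
      measured in every well as in a multiplexed assay;
    * ``truth`` — the sampled interacting flag per (receptor, RAMP) pair.
    """
    rng = np.random.default_rng(config.seed)
    gpcrs = _gpcr_ids(config.n_gpcrs)
    ramps = list(config.ramps)

    # ground truth
    flags = rng.random((len(gpcrs), len(ramps))) < config.interact_prob
    truth = pd.DataFrame(
        [
            dict(gpcr_id=g, ramp_id=r, interacting=bool(flags[i, j]))
            for i, g in enumerate(gpcrs)
            for j, r in enumerate(ramps)
        ]
    )

    # antibody panel: shared epitope/RAMP reagents plus per-receptor pAbs
    panel_rows = _base_panel(ramps)
    lo, hi = config.n_protein_abs_range
    n_abs = rng.integers(lo, hi + 1, size=len(gpcrs))
    for g, k in zip(gpcrs, n_abs):
        for j in range(k):
            ab = f"ab_{g.lower()}_p{j + 1}"
            panel_rows.append(
                dict(antibody_id=ab, bead_id=f"bead_{g.lower()}_p{j + 1}", target_id=g, target_class="gpcr", role="capture", host="rabbit_pab")
            )
    panel = pd.DataFrame(panel_rows)

    # sample sheet
    sample_rows = []
    for g in gpcrs:
        for r in [MOCK] + ramps:
            sample_rows.append(
                dict(sample_id=f"s_{g.lower()}_{r.lower()}", cell_line="Expi293F", gpcr_id=g, ramp_id=r, bio_replicate=1, tech_replicate=1, total_protein=2.0, is_buffer=False)
            )
    sample_rows.append(
        dict(sample_id="s_mock_mock", cell_line="Expi293F", gpcr_id=MOCK, ramp_id=MOCK, bio_replicate=1, tech_replicate=1, total_protein=2.0, is_buffer=False)
    )
    for b in range(config.n_buffer_wells):
        sample_rows.append(
            dict(sample_id=f"buffer_{b + 1:03d}", cell_line="Expi293F", gpcr_id=MOCK, ramp_id=MOCK, bio_replicate=1, tech_replicate=1, total_protein=0.0, is_buffer=True)
        )
    sheet = pd.DataFrame(sample_rows)

    # per-bead baselines and per-capture-antibody affinity offsets
    capture = panel[panel["role"] == "capture"]
    baseline = {a: BASELINE_LOG_MFI + rng.normal(0, BASELINE_SD) for a in capture["antibody_id"]}
    affinity = {a: rng.normal(0, config.ab_affinity_sd) for a in capture["antibody_id"]}

    combos = _epitope_combos(ramps) + [
        (ab, "det_ollas_pe") for ab in capture.loc[capture["target_class"] == "gpcr", "antibody_id"]
    ]
    combo_df = pd.DataFrame(combos, columns=["capture_antibody_id", "detection_antibody_id"])
    combo_df["capture_target"] = combo_df["capture_antibody_id"].map(
        capture.set_index("antibody_id")["target_id"]
    )
    combo_df["capture_class"] = combo_df["capture_antibody_id"].map(
        capture.set_index("antibody_id")["target_class"]
    )

    n_s, n_c = len(sheet), len(combo_df)
    rec = pd.DataFrame(
        {
            "sample_id": np.repeat(sheet["sample_id"].to_numpy(), n_c),
            "gpcr_id": np.repeat(sheet["gpcr_id"].to_numpy(), n_c),
            "ramp_id": np.repeat(sheet["ramp_id"].to_numpy(), n_c),
            "is_buffer": np.repeat(sheet["is_buffer"].to_numpy(), n_c),
            "capture_antibody_id": np.tile(combo_df["capture_antibody_id"].to_numpy(), n_s),
            "detection_antibody_id": np.tile(combo_df["detection_antibody_id"].to_numpy(), n_s),
            "capture_target": np.tile(combo_df["capture_target"].to_numpy(), n_s),
            "capture_class": np.tile(combo_df["capture_class"].to_numpy(), n_s),
        }
    )

    truth_map = {(row.gpcr_id, row.ramp_id): row.interacting for row in truth.itertuples()}
    pair_interacts = np.array(
        [truth_map.get((g, r), False) for g, r in zip(rec["gpcr_id"], rec["ramp_id"])]
    )
    # which records read out the complex
    is_tag_scheme = rec["capture_class"].eq("epitope_tag").to_numpy()
    is_ramp_capture = rec["capture_class"].eq("ramp").to_numpy()
    is_gpcr_capture = rec["capture_class"].eq("gpcr").to_numpy()
    ramp_matches = rec["capture_target"].to_numpy() == rec["ramp_id"].to_numpy()
    gpcr_matches = rec["capture_target"].to_numpy() == rec["gpcr_id"].to_numpy()
    readout = is_tag_scheme | (is_ramp_capture & ramp_matches) | (is_gpcr_capture & gpcr_matches)
    complex_present = pair_interacts & readout & ~rec["is_buffer"].to_numpy()

    log_mfi = (
        rec["capture_antibody_id"].map(baseline).to_numpy()
        + np.where(rec["is_buffer"], 0.0, rec["capture_antibody_id"].map(affinity).to_numpy())
        + config.log_effect * complex_present
        + rng.normal(0, config.noise_sd, size=len(rec))
    )
    mfi = rec[["sample_id", "capture_antibody_id", "detection_antibody_id"]].copy()
    mfi["mfi"] = np.exp(log_mfi)
    return mfi, panel, sheet, truth


def simulate_truth_set(
    truth: pd.DataFrame,
    coverage: float = 1.0,
    label_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample a literature-style truth set from the simulated ground truth.

    ``coverage`` is the fraction of pairs labeled (sampled without
    replacement); ``label_noise`` flips each sampled label independently.
    With ``coverage=1, label_noise=0`` the truth set reproduces the ground
    truth exactly.
    """
    if not (0.0 < coverage <= 1.0):
        raise ConfigurationError("coverage must lie in (0, 1]; 0 makes calibration impossible")
    if not (0.0 <= label_noise < 1.0):
        raise ConfigurationError("label_noise must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(truth)
    k = int(round(coverage * n))
    k = max(k, 1)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    sub = truth.iloc[idx].copy()
    flip = rng.random(k) < label_noise
    lab = sub["interacting"].to_numpy(bool) ^ flip
    sub["label"] = np.where(lab, "interacting", "non_interacting")
    return sub[["gpcr_id", "ramp_id", "label"]].reset_index(drop=True)


def simulate_endogenous(
    config: SimulationConfig,
    n_cell_lines: int = 3,
    n_antibodies: int | None = None,
    n_bio: int = 3,
    n_tech: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an endogenous (wild-type cell line) interaction screen.

    Receptor-specific capture beads are read with anti-RAMP detection
    antibodies over biological triplicates measured in technical duplicate
    (counts configurable).  A minority of (receptor, RAMP) pairs — governed by
    ``config.interact_prob`` — carry the interaction effect, shared across
    cell lines; per-antibody affinity offsets are shared across replicates so
    antibody-to-antibody background variation is reproducible, as in a real
    assay.  Returns ``(mfi, panel, sheet, truth)``.
    """
    if n_cell_lines < 1:
        raise ConfigurationError("n_cell_lines must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_ab = n_antibodies if n_antibodies is not None else config.n_gpcrs
    if n_ab < 1:
        raise ConfigurationError("need at least one capture antibody")
    gpcrs = _gpcr_ids(config.n_gpcrs)
    ramps = list(config.ramps)

    flags = rng.random((len(gpcrs), len(ramps))) < config.interact_prob
    truth = pd.DataFrame(
        [
            dict(gpcr_id=g, ramp_id=r, interacting=bool(flags[i, j]))
            for i, g in enumerate(gpcrs)
            for j, r in enumerate(ramps)
        ]
    )

    panel_rows = []
    ab_target = {}
    for i in range(n_ab):
        g = gpcrs[i % len(gpcrs)]
        ab = f"ab_endo_{i + 1:04d}"
        ab_target[ab] = g
        panel_rows.append(
            dict(antibody_id=ab, bead_id=f"bead_endo_{i + 1:04d}", target_id=g, target_class="gpcr", role="capture", host="rabbit_pab")
        )
    for r in ramps:
        panel_rows.append(
            dict(antibody_id=f"det_{r.lower()}_pe", bead_id="", target_id=r, target_class="ramp", role="detection", host="rabbit_pab")
        )
    panel = pd.DataFrame(panel_rows)

    cells = [f"cellline_{c + 1}" for c in range(n_cell_lines)]
    sample_rows = []
    for cl in cells:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                sample_rows.append(
                    dict(sample_id=f"s_{cl}_b{b}_t{t}", cell_line=cl, gpcr_id=MOCK, ramp_id=MOCK, bio_replicate=b, tech_replicate=t, total_protein=2.0, is_buffer=False)
                )
    for b in range(config.n_buffer_wells):
        sample_rows.append(
            dict(sample_id=f"buffer_{b + 1:03d}", cell_line="buffer", gpcr_id=MOCK, ramp_id=MOCK, bio_replicate=1, tech_replicate=1, total_protein=0.0, is_buffer=True)
        )
    sheet = pd.DataFrame(sample_rows)

    abs_ = list(ab_target)
    baseline = {a: BASELINE_LOG_MFI + rng.normal(0, BASELINE_SD) for a in abs_}
    # affinity/background offsets per (capture antibody, detection antibody)
    affinity = {
        (a, r): rng.normal(0, config.ab_affinity_sd) for a in abs_ for r in ramps
    }
    truth_map = {(row.gpcr_id, row.ramp_id): row.interacting for row in truth.itertuples()}

    records = []
    for cl in cells:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                sid = f"s_{cl}_b{b}_t{t}"
                for a in abs_:
                    g = ab_target[a]
                    for r in ramps:
                        mu = (
                            baseline[a]
                            + affinity[(a, r)]
                            + config.log_effect * truth_map[(g, r)]
                        )
                        records.append((sid, a, f"det_{r.lower()}_pe", mu))
    for bsmp in sheet.loc[sheet["is_buffer"], "sample_id"]:
        for a in abs_:
            for r in ramps:
                records.append((bsmp, a, f"det_{r.lower()}_pe", baseline[a]))
    mfi = pd.DataFrame(
        records, columns=["sample_id", "capture_antibody_id", "detection_antibody_id", "mu"]
    )
    mfi["mfi"] = np.exp(mfi.pop("mu") + rng.normal(0, config.noise_sd, size=len(mfi)))
    return mfi, panel, sheet, truth


def simulate_rcp_counts(
    n_images: int,
    mean_rcp_per_cell: tuple[float, float, float] = (5.0, 5.0, 2.0),
    blank_rate: float = 0.5,
    cells_per_image: tuple[int, int] = (20, 60),
    seed: int | np.random.Generator = 0,
    stain_condition: str = "gpcr_ramp",
) -> pd.DataFrame:
    """Simulate per-image rolling-circle-product (RCP) counts for an in-situ
    proximity assay.

    Per image: a nuclei count uniform on ``cells_per_image`` and Poisson
    counts per channel (free receptor, free RAMP, complex) with the given
    per-cell rates, plus a matched blank series (no primary antibody) whose
    channels all run at ``blank_rate`` per cell.
    """
    if n_images < 1:
        raise ConfigurationError("n_images must be >= 1")
    rates = tuple(float(r) for r in mean_rcp_per_cell)
    if any(r < 0 for r in rates) or blank_rate < 0:
        raise ConfigurationError("RCP rates must be >= 0")
    lo, hi = cells_per_image
    if lo < 1 or hi < lo:
        raise ConfigurationError("cells_per_image must satisfy 1 <= lo <= hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for cond, (rg, rr, ro) in ((stain_condition, rates), ("blank", (blank_rate,) * 3)):
        for i in range(n_images):
            cells = int(rng.integers(lo, hi + 1))
            rows.append(
                dict(
                    image_id=f"{cond}_img{i + 1:04d}",
                    stain_condition=cond,
                    nuclei=cells,
                    rcp_gpcr=int(rng.poisson(rg * cells)),
                    rcp_ramp=int(rng.poisson(rr * cells)),
                    rcp_overlap=int(rng.poisson(ro * cells)),
                )
            )
    return pd.DataFrame(rows)


def simulate_expression(
    gpcr_ids,
    ramp_ids,
    n_contexts: int = 30,
    seed: int | np.random.Generator = 0,
    annotation: pd.DataFrame | None = None,
    interactor_ratio_boost: float = 1.0,
) -> pd.DataFrame:
    """Synthetic single-cell-type expression table (nTPM per gene per context).

    Expression is zero-inflated log-normal.  If an interactome annotation is
    supplied, receptors annotated ``yes`` get their log-nTPM raised by
    ``interactor_ratio_boost`` in contexts where they are expressed, giving
    the downstream ratio test a real signal to find.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contexts = [f"celltype_{c + 1:02d}" for c in range(n_contexts)]
    yes_pairs = set()
    if annotation is not None:
        yes_pairs = {
            (row.gpcr_id, row.ramp_id)
            for row in annotation.itertuples()
            if row.annotation == "yes"
        }
    rows = []
    for gene in list(ramp_ids) + list(gpcr_ids):
        is_ramp = gene in set(ramp_ids)
        p_on = 0.8 if is_ramp else 0.5
        for ctx in contexts:
            if rng.random() > p_on:
                ntpm = float(rng.uniform(0, 0.8))
            else:
                mu = 1.5
                if not is_ramp and any((gene, r) in yes_pairs for r in ramp_ids):
                    mu += interactor_ratio_boost
                ntpm = float(np.exp(rng.normal(mu, 0.8)))
            rows.append(dict(gene_id=gene, context_id=ctx, ntpm=round(ntpm, 4)))
    return pd.DataFrame(rows)


G_PROTEIN_FAMILIES = ("Gs", "Gi/o", "Gq/11", "G12/13")
BARR_SUBTYPES = ("beta-arrestin-1", "beta-arrestin-2")


def simulate_coupling(gpcr_ids, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Synthetic transducer-coupling table in the style of a GPCRdb export:
    one primary G-protein family per receptor, a random set of secondary
    families, and log(Emax/EC50) values for the two beta-arrestin subtypes
    (0 encodes no coupling)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for g in gpcr_ids:
        primary = G_PROTEIN_FAMILIES[rng.integers(len(G_PROTEIN_FAMILIES))]
        rows.append(dict(gpcr_id=g, transducer=primary, tier="primary", log_emax_over_ec50=np.nan))
        for fam in G_PROTEIN_FAMILIES:
            if fam != primary and rng.random() < 0.3:
                rows.append(dict(gpcr_id=g, transducer=fam, tier="secondary", log_emax_over_ec50=np.nan))
        for sub in BARR_SUBTYPES:
            val = float(np.round(rng.uniform(0, 3), 3)) if rng.random() < 0.6 else 0.0
            rows.append(dict(gpcr_id=g, transducer=sub, tier="primary", log_emax_over_ec50=val))
    return pd.DataFrame(rows)
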