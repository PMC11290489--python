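"""End-to-end orchestration: simulate -> QC -> score -> call -> integrate ->
downstream, with stage artifacts on disk so each stage is independently
inspectable, testable and resumable.

A :class:`PipelineConfig` (YAML file or keyword arguments; unknown keys are
rejected) fixes every tunable and the seed; a run writes all intermediate
tables as TSV with JSON metadata sidecars (config hash, seed, version) plus a
plain-text summary and a log of per-stage record counts.  Two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, downstream, evidence, io, normalize, simulate
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "score", "call", "integrate", "endogenous", "downstream")


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run.  Defaults give a small but complete
    demonstration screen (50 receptors) that finishes in well under a minute."""

    out_dir: str = "rampscreen_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # screen simulation
    n_gpcrs: int = 50
    ramps: tuple[str, ...] = ("RAMP1", "RAMP2", "RAMP3")
    interact_prob: float = 0.5
    log_effect: float = 2.0
    noise_sd: float = 0.5
    ab_affinity_sd: float = 0.5
    n_protein_abs_range: tuple[int, int] = (0, 6)
    n_buffer_wells: int = 16
    # truth set
    truth_coverage: float = 1.0
    truth_label_noise: float = 0.0
    # calling
    mad_multiplier: float = 6.0
    endogenous_threshold: float = 3.5
    endogenous_cell_lines: int = 3
    endogenous_interact_prob: float = 0.05
    endogenous_noise_sd: float = 0.15
    endogenous_log_effect: float = 3.0
    # downstream
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    n_expression_contexts: int = 30
    rcp_images_per_condition: int = 20

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        self.stages = tuple(self.stages)
        self.ramps = tuple(self.ramps)
        self.n_protein_abs_range = tuple(self.n_protein_abs_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self, seed: int | None = None) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            n_gpcrs=self.n_gpcrs,
            ramps=self.ramps,
            interact_prob=self.interact_prob,
            log_effect=self.log_effect,
            noise_sd=self.noise_sd,
            ab_affinity_sd=self.ab_affinity_sd,
            n_protein_abs_range=self.n_protein_abs_range,
            n_buffer_wells=self.n_buffer_wells,
            truth_label_noise=self.truth_label_noise,
            seed=self.seed if seed is None else seed,
        )


class PipelineRun:
    """Executes stages in order and tracks artifacts on disk and in memory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.artifacts: dict[str, pd.DataFrame] = {}
        self.meta = {"seed": config.seed, "config_hash": io.config_hash(config.to_dict())}

    # -- artifact bookkeeping -------------------------------------------------

    def _write(self, df: pd.DataFrame, relpath: str, name: str) -> None:
        io.write_table(df, self.out / relpath, metadata=self.meta)
        self.artifacts[name] = df
        logger.info("stage artifact %-24s %6d records -> %s", name, len(df), relpath)

    def _need(self, name: str, relpath: str, producer: str) -> pd.DataFrame:
        if name in self.artifacts:
            return self.artifacts[name]
        path = self.out / relpath
        if path.exists():
            return pd.read_csv(path, sep="\t")
        raise ValidationError(
            f"stage requires artifact {name!r} ({relpath}); enable the {producer!r} stage or provide the file"
        )

    # -- stages ---------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config.sim_config()
        mfi, panel, sheet, truth = simulate.simulate_screen(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 1]))
        truth_set = simulate.simulate_truth_set(
            truth, coverage=self.config.truth_coverage, label_noise=self.config.truth_label_noise, seed=rng
        )
        self._write(mfi, "sim/mfi.tsv", "mfi")
        self._write(panel, "sim/panel.tsv", "panel")
        self._write(sheet, "sim/samples.tsv", "samples")
        self._write(truth, "sim/ground_truth.tsv", "ground_truth")
        self._write(truth_set, "sim/truth_set.tsv", "truth_set")

    def stage_qc(self) -> None:
        mfi = self._need("mfi", "sim/mfi.tsv", "simulate")
        sheet = self._need("samples", "sim/samples.tsv", "simulate")
        merged = mfi.merge(sheet, on="sample_id")
        memb = merged[~merged["is_buffer"].astype(bool)]
        rows = []
        for r in self.config.ramps:
            bead = f"ab_{r.lower()}"
            sub = memb[(memb["capture_antibody_id"] == bead) & memb["ramp_id"].isin([io.MOCK, r])]
            if sub.empty:
                continue
            groups = {
                grp: np.log(vals["mfi"].to_numpy(float))
                for grp, vals in sub.groupby("ramp_id")
            }
            if io.MOCK not in groups or len(groups) < 2:
                continue
            qc = normalize.ramp_expression_qc(groups, mock_group=io.MOCK)
            qc.insert(0, "capture_bead", bead)
            qc["anova_p"] = qc.attrs["anova_p"]
            rows.append(qc)
        table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        self._write(table, "qc/ramp_expression_qc.tsv", "qc")

    def stage_score(self) -> None:
        mfi = self._need("mfi", "sim/mfi.tsv", "simulate")
        panel = self._need("panel", "sim/panel.tsv", "simulate")
        sheet = self._need("samples", "sim/samples.tsv", "simulate")
        pairs, _buffer = io.build_score_input(mfi, panel, sheet)
        scored = calling.pair_scores(pairs)
        self._write(scored, "scores/pair_scores.tsv", "scores")

    def stage_call(self) -> None:
        scored = self._need("scores", "scores/pair_scores.tsv", "score")
        truth_set = self._need("truth_set", "sim/truth_set.tsv", "simulate")
        thresholds = calling.ThresholdSet(
            epitope=calling.calibrate_epitope_thresholds(scored, truth_set, ramps=self.config.ramps),
            protein=calling.protein_thresholds(scored, self.config.mad_multiplier),
            endogenous=self.config.endogenous_threshold,
        )
        calls = calling.apply_thresholds(scored, thresholds)
        self._write(thresholds.to_frame(), "calls/thresholds.tsv", "thresholds")
        self._write(calls, "calls/call_matrix.tsv", "calls")

    def stage_integrate(self) -> None:
        calls = self._need("calls", "calls/call_matrix.tsv", "call")
        ev = evidence.build_evidence(calls)
        ann = evidence.annotate_interactome(ev)
        yes_sets = {
            r: set(ann[(ann["ramp_id"] == r) & (ann["annotation"] == "yes")]["gpcr_id"])
            for r in self.config.ramps
        }
        universe = set(ann["gpcr_id"])
        upset = evidence.overlap_counts(yes_sets, universe=universe)
        summary = evidence.summarize_screen(calls, ev, ann)
        self._write(ev, "evidence/evidence.tsv", "evidence")
        self._write(ann, "evidence/annotation.tsv", "annotation")
        self._write(upset, "evidence/upset_counts.tsv", "upset")
        for name, df in summary.items():
            self._write(df, f"evidence/{name}.tsv", name)
        prot_summary = evidence.protein_capture_summary(calls)
        self._write(prot_summary, "evidence/protein_capture_summary.tsv", "protein_capture_summary")

    def stage_endogenous(self) -> None:
        cfg = simulate.SimulationConfig(
            n_gpcrs=self.config.n_gpcrs,
            ramps=self.config.ramps,
            interact_prob=self.config.endogenous_interact_prob,
            log_effect=self.config.endogenous_log_effect,
            noise_sd=self.config.endogenous_noise_sd,
            ab_affinity_sd=self.config.ab_affinity_sd,
            n_buffer_wells=self.config.n_buffer_wells,
            seed=self.config.seed + 1,
        )
        mfi, panel, sheet, truth = simulate.simulate_endogenous(
            cfg, n_cell_lines=self.config.endogenous_cell_lines
        )
        endo = calling.endogenous_call(mfi, panel, sheet, threshold=self.config.endogenous_threshold)
        self._write(truth, "endogenous/ground_truth.tsv", "endo_truth")
        self._write(endo, "endogenous/endogenous_calls.tsv", "endo_calls")

    def stage_downstream(self) -> None:
        ann = self._need("annotation", "evidence/annotation.tsv", "integrate")
        gpcrs = sorted(ann["gpcr_id"].unique())
        rng_expr = np.random.default_rng(np.random.SeedSequence([self.config.seed, 2]))
        expr = simulate.simulate_expression(
            gpcrs,
            self.config.ramps,
            n_contexts=self.config.n_expression_contexts,
            seed=rng_expr,
            annotation=ann,
            interactor_ratio_boost=1.0,
        )
        self._write(expr, "downstream/expression.tsv", "expression")
        ratio = downstream.expression_ratio_test(expr, ann, ramps=self.config.ramps)
        self._write(ratio, "downstream/expression_ratio_test.tsv", "ratio_test")
        binary, log2m, order = downstream.binarize_and_cluster(
            expr,
            genes=list(self.config.ramps),
            metric=self.config.cluster_metric,
            linkage_method=self.config.cluster_linkage,
        )
        self._write(
            log2m.reset_index(), "downstream/ramp_expression_log2.tsv", "ramp_expression_log2"
        )
        (self.out / "downstream/ramp_cluster_order.txt").write_text("\n".join(order) + "\n")
        pct = downstream.pct_interacting_per_context(expr, ann, ramps=self.config.ramps)
        self._write(pct, "downstream/pct_interacting_per_context.tsv", "pct_context")
        coupling = simulate.simulate_coupling(
            gpcrs, seed=np.random.default_rng(np.random.SeedSequence([self.config.seed, 3]))
        )
        self._write(coupling, "downstream/coupling.tsv", "coupling")
        enrich = downstream.coupling_enrichment(coupling, ann)
        self._write(enrich, "downstream/coupling_enrichment.tsv", "coupling_enrichment")
        rng_rcp = np.random.default_rng(np.random.SeedSequence([self.config.seed, 4]))
        frames = []
        for cond, overlap_rate in (("pair_positive_control", 3.0), ("pair_a", 2.5), ("pair_b", 0.5)):
            tab = simulate.simulate_rcp_counts(
                self.config.rcp_images_per_condition,
                mean_rcp_per_cell=(4.0, 4.0, overlap_rate),
                blank_rate=0.3,
                seed=rng_rcp,
                stain_condition=cond,
            )
            frames.append(tab if not frames else tab[tab["stain_condition"] == cond])
        rcp = pd.concat(frames, ignore_index=True)
        self._write(rcp, "downstream/rcp_counts.tsv", "rcp")
        summaries = downstream.molboolean_summarize(rcp)
        self._write(summaries, "downstream/rcp_summary.tsv", "rcp_summary")
        compare = downstream.molboolean_compare(summaries, positive_control="pair_positive_control")
        self._write(compare, "downstream/rcp_compare.tsv", "rcp_compare")

    # -- driver ---------------------------------------------------------------

    def run(self) -> Path:
        self.out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root = logging.getLogger("rampscreen")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        try:
            io.write_sidecar(self.out / "run", {**self.meta, "config": self.config.to_dict()})
            stage_fns = {
                "simulate": self.stage_simulate,
                "qc": self.stage_qc,
                "score": self.stage_score,
                "call": self.stage_call,
                "integrate": self.stage_integrate,
                "endogenous": self.stage_endogenous,
                "downstream": self.stage_downstream,
            }
            for stage in ALL_STAGES:
                if stage not in self.config.stages:
                    continue
                logger.info("=== stage %s ===", stage)
                try:
                    stage_fns[stage]()
                except Exception:
                    logger.exception("stage %s failed", stage)
                    raise
            self._write_summary()
        finally:
            root.removeHandler(handler)
            handler.close()
        return self.out

    def _write_summary(self) -> None:
        lines = [f"rampscreen run (seed={self.config.seed}, config {self.meta['config_hash']})", ""]
        if "annotation" in self.artifacts:
            ann = self.artifacts["annotation"]
            for r in self.config.ramps:
                sub = ann[ann["ramp_id"] == r]
                counts = sub["annotation"].value_counts()
                lines.append(
                    f"{r}: yes={counts.get('yes', 0)} no={counts.get('no', 0)} "
                    f"inconclusive={counts.get('inconclusive', 0)} of {len(sub)} receptors"
                )
        if "hits_per_scheme" in self.artifacts:
            lines.append("")
            lines.append("hits per (RAMP, scheme):")
            for row in self.artifacts["hits_per_scheme"].itertuples():
                lines.append(f"  {row.ramp_id} {row.scheme_id}: {row.n_hits}/{row.n_pairs}")
        (self.out / "summary.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages end to end; returns the run directory."""
    return PipelineRun(config).run()
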