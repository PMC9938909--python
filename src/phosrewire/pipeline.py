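"""Study-level orchestration: stage sequencing, logging, and TSV outputs.

A :class:`StudyConfig` names the study kind, the input files (or a request
to simulate them), and every stage parameter with its standard default
(fold-change threshold 0.58, alpha 0.05, >= 10 quantified substrates per
kinase, 1000 KSEA permutations, 9999 gene-set samples, priming offsets
3-5). ``run_pipeline`` executes filter -> normalize -> impute ->
regulation -> rewiring / substrate discovery -> KSEA -> enrichment and
writes per-stage TSVs plus a run log and the resolved configuration, which
together suffice to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core_io, enrichment, ksea, preprocess, regulation, rewiring, substrate_discovery
from .core_io import IntensityTable, KinaseAnnotationSet
from .synthetic_data import SimBundle, default_config, generate_study

logger = logging.getLogger(__name__)

STUDY_KINDS = ("cell_ir", "proteome", "mouse", "gsk3i")


@dataclass
class StudyConfig:
    study: str = "cell_ir"
    intensity_path: str | None = None
    design_path: str | None = None
    kinase_annotation_path: str | None = None
    gmt_path: str | None = None
    simulate: bool = True
    n_features: int = 2000
    control: str | None = None          # derived from study kind when None
    fc_threshold: float = regulation.FC_THRESHOLD
    alpha: float = regulation.ALPHA
    min_total_replicates: int = 0
    min_substrates: int = 10
    n_perm: int = 1000
    gene_set_samples: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study not in STUDY_KINDS:
            raise ValueError(f"study must be one of {STUDY_KINDS}")
        if self.control is None:
            self.control = {"mouse": "CHOW", "gsk3i": "ADIPO"}.get(self.study, "CTRL")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _load_inputs(config: StudyConfig):
    if config.simulate:
        bundle = generate_study(default_config(
            config.study, seed=config.seed, n_features=config.n_features))
        return bundle.table, bundle.annotations, bundle
    table = core_io.load_intensity_table(config.intensity_path,
                                         config.design_path)
    annotations = None
    if config.kinase_annotation_path:
        annotations = core_io.load_kinase_annotations(config.kinase_annotation_path)
    return table, annotations, None


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> Path:
    """Execute every stage of one study and write results under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    results: dict[str, pd.DataFrame] = {}
    stage = "load"
    try:
        table, annotations, bundle = _load_inputs(config)
        note(stage, f"{len(table.feature_ids)} features x {len(table.sample_ids)} samples")

        stage = "preprocess"
        spec = preprocess.FilterSpec(
            min_total_replicates=config.min_total_replicates,
            require_group=config.control if config.study == "proteome" else None)
        study_key = {"proteome": "cell_ir"}.get(config.study, config.study)
        table = preprocess.preprocess_study(table, study_key, filter_spec=spec,
                                            seed=config.seed)
        note(stage, f"{len(table.feature_ids)} features after filtering; "
                    f"{int(table.imputed.to_numpy().sum()) if table.imputed is not None else 0} values imputed")

        stage = "regulation"
        treatments = ("Basal", "GSK3i") if config.study == "gsk3i" else ("BAS", "INS")
        groups = list(table.design["group"].unique())
        reg_frames = {}
        for g in groups:
            if config.study == "mouse":
                res = regulation.moderated_t_test(table, g, treatments)
            else:
                res = regulation.insulin_response_test(table, g, treatments)
            res = regulation.adjust_within_family(res, family=g)
            reg_frames[g] = regulation.call_regulated(
                res, config.fc_threshold, config.alpha)
        results["regulation"] = pd.concat(reg_frames.values(), ignore_index=True)
        ctrl_calls = reg_frames[config.control].set_index("feature_id", drop=False)
        n_reg = int(ctrl_calls["label"].isin(["up", "down"]).sum())
        note(stage, f"{n_reg} features regulated in {config.control}")

        if config.study in ("cell_ir", "proteome"):
            stage = "rewiring"
            calls = rewiring.compare_models(
                table, ctrl_calls, control=config.control,
                treatments=treatments, fc=config.fc_threshold,
                alpha=config.alpha)
            modes = rewiring.attribute_defect(
                table, calls, ctrl_calls, control=config.control,
                treatments=treatments, fc=config.fc_threshold,
                alpha=config.alpha)
            calls = calls.merge(modes, on=["feature_id", "model"], how="left")
            results["rewiring_calls"] = calls
            results["summary_counts"] = rewiring.summarize_calls(calls, ctrl_calls)
            results["defect_bias"] = rewiring.defect_bias_tests(calls, ctrl_calls)
            note(stage, f"{int(calls['defective'].sum())} defective, "
                        f"{int(calls['emergent'].sum())} emergent (feature,model) pairs")
        elif config.study == "mouse":
            stage = "rewiring"
            chow = reg_frames["CHOW"].set_index("feature_id")
            rows = []
            for m in [g for g in groups if g != "CHOW"]:
                diet = reg_frames[m].set_index("feature_id")
                for fid in table.feature_ids:
                    d, e = rewiring.classify_mouse_mode(
                        chow.loc[fid], diet.loc[fid],
                        config.fc_threshold, config.alpha)
                    rows.append((fid, m, d, e))
            calls = pd.DataFrame(rows, columns=["feature_id", "model",
                                                "defective", "emergent"])
            results["rewiring_calls"] = calls
            note(stage, f"{int(calls['defective'].sum())} defective, "
                        f"{int(calls['emergent'].sum())} emergent (feature,diet) pairs")
        elif config.study == "gsk3i":
            stage = "substrates"
            evidence = substrate_discovery.evidence_from_study(table, annotations)
            sub_calls = substrate_discovery.discover_substrates(
                ctrl_calls, table, evidence,
                fc=config.fc_threshold, alpha=config.alpha)
            results["substrate_calls"] = sub_calls
            summary = substrate_discovery.substrate_summary(sub_calls)
            note(stage, f"{summary['n_peptides']} putative substrate peptides "
                        f"({summary['n_sites']} sites, {summary['n_proteins']} proteins)")

        if annotations is not None and config.study in ("cell_ir", "mouse"):
            stage = "ksea"
            models = [g for g in groups if g != config.control]
            signatures = [ksea.build_signature(table, "ins_bas", g,
                                               treatments=treatments)
                          for g in [config.control, *models]]
            results["ksea_results"] = ksea.batch_ksea(
                signatures, table, annotations,
                min_substrates=config.min_substrates,
                n_perm=config.n_perm, seed=config.seed)
            note(stage, f"{results['ksea_results']['kinase'].nunique()} kinases scored")

        stage = "enrichment"
        if config.gmt_path:
            collection = core_io.load_gmt(config.gmt_path)
            universe = set(table.annotations["gene"])
            fore = set(table.annotations.loc[
                ctrl_calls.index[ctrl_calls["label"].isin(["up", "down"])],
                "gene"]) & universe
            results["enrichment_fisher"] = enrichment.fisher_enrichment(
                fore, universe, collection)
            note(stage, f"{len(collection)} gene sets tested")
    except Exception as exc:  # pragma: no cover - error path formatting
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    core_io.write_results(results, out)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    if bundle is not None:
        _write_truth(bundle, out)
    return out


def _write_truth(bundle: SimBundle, out: Path) -> None:
    truth = bundle.truth
    truth.features.reset_index().to_csv(out / "truth_features.tsv",
                                        sep="\t", index=False)
    truth.defective.to_csv(out / "truth_defective.tsv", sep="\t", index=False)
    truth.emergent.to_csv(out / "truth_emergent.tsv", sep="\t", index=False)
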