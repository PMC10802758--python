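"""End-to-end orchestration with provenance capture.

``run_pipeline`` executes the eight analysis stages in order --
missingness filter, GIS median-polish batch correction, cell-type
QC/outlier flagging, bootstrap covariate regression, network module
discovery, module preservation against the paired bulk fraction,
differential/trait statistics, and enrichment integration -- writing
every intermediate table plus a machine-readable run manifest
(parameters, per-stage seeds, package versions, input checksums).

A single global seed deterministically derives per-stage seeds by
hashing the stage name, so any stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from . import qc, stats, enrichment
from .tampor import tampor_correct
from .network import CoexpressionNetwork
from .preservation import module_preservation, classify_preservation

log = logging.getLogger("vasculonet")

STAGES = ("filter", "tampor", "qc_flag", "regress", "network",
          "preservation", "diffstats", "enrichment")


@dataclass
class PipelineConfig:
    vascular: str
    design: str
    traits: str
    outdir: str
    bulk: str | None = None
    markers: str | None = None
    gwas: list = field(default_factory=list)
    biofluid: dict = field(default_factory=dict)
    seed: int = 0
    max_missing_fraction: float = 0.50
    n_boot: int = 1000
    preservation_permutations: int = 500
    gwas_permutations: int = 10_000
    network: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vascular", "design", "traits"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r}: no such file {p}")
        for name in ("bulk", "markers"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r}: no such file {p}")
        for p in list(self.gwas) + list(self.biofluid.values()):
            if not Path(p).exists():
                raise FileNotFoundError(f"config input: no such file {p}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure aborts with the stage name and cause; outputs of
    completed stages are retained and the manifest marks the failure.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    import vasculonet
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "versions": {"vasculonet": getattr(vasculonet, "__version__", "0"),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "inputs": {k: {"path": str(v), "sha256": _checksum(v)}
                   for k, v in (("vascular", config.vascular),
                                ("bulk", config.bulk),
                                ("design", config.design),
                                ("traits", config.traits),
                                ("markers", config.markers)) if v},
        "parameters": {"max_missing_fraction": config.max_missing_fraction,
                       "n_boot": config.n_boot,
                       "preservation_permutations": config.preservation_permutations,
                       "gwas_permutations": config.gwas_permutations,
                       "network": config.network},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage,
                                   "seed": stage_seed(config.seed, stage), **info})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    state: dict = {}
    try:
        _run_stages(config, out, state, done)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "_stage", "unknown")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return out


def _run_stages(cfg: PipelineConfig, out: Path, state: dict, done) -> None:
    def guard(stage):
        def deco(fn):
            def run():
                try:
                    info = fn() or {}
                except Exception as exc:
                    exc._stage = stage
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                done(stage, **info)
            return run
        return deco

    design = vio.read_batch_design(cfg.design)
    traits = vio.read_traits(cfg.traits)

    @guard("filter")
    def s_filter():
        vasc = vio.read_abundance_matrix(cfg.vascular)
        state["vascular"] = vio.filter_missingness(vasc, cfg.max_missing_fraction)
        info = {"proteins_vascular": len(state["vascular"])}
        if cfg.bulk:
            bulk = vio.read_abundance_matrix(cfg.bulk)
            state["bulk"] = vio.filter_missingness(bulk, cfg.max_missing_fraction)
            info["proteins_bulk"] = len(state["bulk"])
        return info

    @guard("tampor")
    def s_tampor():
        res = tampor_correct(state["vascular"], design)
        state["vascular"] = res.corrected
        vio.write_abundance_matrix(res.corrected, out / "vascular_tampor.tsv")
        info = {"iterations_vascular": res.n_iterations,
                "converged_vascular": res.converged}
        if "bulk" in state:
            res_b = tampor_correct(state["bulk"], design)
            state["bulk"] = res_b.corrected
            vio.write_abundance_matrix(res_b.corrected, out / "bulk_tampor.tsv")
            info.update(iterations_bulk=res_b.n_iterations)
        return info

    @guard("qc_flag")
    def s_qc():
        gis = design.loc[design["is_gis"]].index
        bio = [c for c in state["vascular"].columns if c not in set(gis)]
        state["bio_samples"] = bio
        if not cfg.markers:
            state["scores"] = None
            state["flagged"] = []
            return {"flagged": []}
        markers = vio.read_marker_gmt(cfg.markers)
        state["markers"] = markers
        scores = qc.score_cell_types(state["vascular"][bio], markers)
        flagged = qc.flag_outliers(scores)
        state["scores"] = scores.drop(index=flagged)
        state["flagged"] = flagged
        keep = [c for c in bio if c not in set(flagged)]
        state["bio_samples"] = keep
        state["vascular"] = state["vascular"][keep]
        if "bulk" in state:
            state["bulk"] = state["bulk"][[c for c in keep
                                           if c in state["bulk"].columns]]
        vio.write_table(scores.reset_index(), out / "cell_type_scores.tsv")
        vio.write_table(pd.DataFrame({"flagged_sample": flagged}),
                        out / "flagged_samples.tsv")
        return {"flagged": flagged}

    @guard("regress")
    def s_regress():
        tr = traits.loc[[s for s in state["bio_samples"] if s in traits.index]].copy()
        tr["batch"] = design.loc[tr.index, "batch"]
        nuisance = ["age", "sex", "PMI", "batch"]
        if state.get("scores") is not None and "neuron" in state["scores"].columns:
            nuisance = ["neuronal_score"] + nuisance
        corrected, report = qc.bootstrap_regress(
            state["vascular"], tr, state.get("scores"), nuisance=nuisance,
            n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "regress"))
        state["vascular"] = corrected
        vio.write_abundance_matrix(corrected, out / "vascular_regressed.tsv")
        vio.write_table(report.coefficients.reset_index(),
                        out / "regression_coefficients.tsv")
        return {"n_boot": report.n_boot,
                "excluded_samples": report.excluded_samples}

    @guard("network")
    def s_network():
        net = CoexpressionNetwork(**cfg.network)
        net.fit(state["vascular"])
        state["partition"] = net.partition_
        part = net.partition_
        vio.write_table(part.labels.rename("module").reset_index(),
                        out / "module_labels.tsv")
        vio.write_table(part.kme.reset_index(), out / "kme.tsv")
        vio.write_table(part.eigenproteins.reset_index(),
                        out / "eigenproteins.tsv")
        with open(out / "network_params.yaml", "w") as fh:
            yaml.safe_dump(part.params, fh)
        return {"n_modules": len(part.eigenproteins),
                "reassign_iterations": part.n_reassign_iterations}

    @guard("preservation")
    def s_preservation():
        if "bulk" not in state:
            return {"skipped": True}
        res = module_preservation(
            state["vascular"], state["partition"].labels, state["bulk"],
            n_permutations=cfg.preservation_permutations,
            seed=stage_seed(cfg.seed, "preservation"))
        res.table["category"] = classify_preservation(res)
        vio.write_table(res.table.reset_index(), out / "preservation.tsv")
        state["preservation"] = res
        return {"n_permutations": res.n_permutations}

    @guard("diffstats")
    def s_diffstats():
        groups = traits["diagnosis"].reindex(state["vascular"].columns)
        diff = stats.anova_tukey(state["vascular"], groups)
        vio.write_table(diff.reset_index(), out / "differential_abundance.tsv")
        state["diff"] = diff
        mtc = stats.module_trait_correlation(state["partition"].eigenproteins,
                                             traits)
        vio.write_table(mtc, out / "module_trait_correlation.tsv")
        info = {}
        if "bulk" in state:
            enr = stats.log2_enrichment(state["vascular"], state["bulk"],
                                        state["partition"].labels)
            state["enrichment_ratio"] = enr
            vio.write_table(enr.per_protein.reset_index(),
                            out / "vascular_bulk_enrichment.tsv")
            selected = stats.select_classifier_proteins(diff, enr)
            vio.write_table(pd.DataFrame({"protein": selected}),
                            out / "classifier_proteins.tsv")
            info["n_classifier_proteins"] = len(selected)
        return info

    @guard("enrichment")
    def s_enrichment():
        labels = state["partition"].labels
        info = {}
        if state.get("markers"):
            msets = enrichment.modules_as_gene_sets(labels)
            bg = {vio.symbol_of(p) for p in labels.index}
            fet = enrichment.fisher_set_enrichment(msets, state["markers"], bg)
            vio.write_table(fet, out / "cell_type_enrichment.tsv")
            info["celltype_rows"] = len(fet)
        if cfg.gwas:
            tables = [vio.read_gene_pvalues(p) for p in cfg.gwas]
            g = enrichment.gwas_permutation_enrichment(
                labels, tables, n_perm=cfg.gwas_permutations,
                seed=stage_seed(cfg.seed, "enrichment"))
            vio.write_table(g.table.reset_index(), out / "gwas_enrichment.tsv")
            info["gwas_modules_flagged_5"] = int(g.table["flagged_5"].sum())
        if cfg.biofluid:
            tabs = {k: vio.read_biofluid_table(p)
                    for k, p in cfg.biofluid.items()}
            for direction in ("all", "increased", "decreased"):
                t = enrichment.biofluid_overlap(labels, tabs, direction)
                vio.write_table(t, out / f"biofluid_overlap_{direction}.tsv")
        if "bulk" in state:
            ov = enrichment.set_overlap(state["vascular"].index,
                                        state["bulk"].index)
            info["overlap_counts"] = list(ov.counts)
        return info

    for runner in (s_filter, s_tampor, s_qc, s_regress, s_network,
                   s_preservation, s_diffstats, s_enrichment):
        runner()
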