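"""End-to-end pipeline: simulate -> scan -> permute -> characterize -> analyze.

Runs the four genome-scan models (diet additive, diet interactive, HFCA
subset, HP subset), characterizes the significant QTL of each, and applies
the downstream architecture analyses.  Deterministic given the master seed;
every output file records the seed and a config hash, and a run manifest
captures per-file checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import (
    FilterConfig,
    allele_diet_ranking,
    colocalize,
    correlation_structure,
    differential_expression,
    founder_enrichment,
    ranking_to_frame,
)
from .data import AlleleProbabilityTensor, ExpressionPanel
from .io import (
    config_hash,
    sha256_file,
    write_alleleprobs,
    write_lod,
    write_markers,
    write_panel,
    write_tsv,
)
from .kinship import KinshipSet, loco_kinship
from .peaks import (
    ClassificationConfig,
    QtlPeak,
    characterize_phenotype,
    peaks_to_frame,
)
from .permute import PermutationConfig, two_stage_screen
from .scan import ScanContext
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

MODELS = ("additive", "interactive", "subset-HFCA", "subset-HP")


@dataclass
class PipelineConfig:
    output_dir: str = "outbredqtl_run"
    seed: int = 0
    models: tuple[str, ...] = MODELS
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("output_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "models" in raw:
            bad = [m for m in raw["models"] if m not in MODELS]
            if bad:
                raise ValueError(f"unknown models {bad}; choose from {MODELS}")
            kwargs["models"] = tuple(raw["models"])
        for key, klass in (
            ("simulation", SimulationConfig),
            ("permutation", PermutationConfig),
            ("classification", ClassificationConfig),
            ("filters", FilterConfig),
        ):
            if key in raw:
                section = dict(raw[key])
                if key == "simulation" and "chromosomes" in section:
                    section["chromosomes"] = tuple(
                        tuple(c) for c in section["chromosomes"]
                    )
                kwargs[key] = klass(**section)
        return cls(**kwargs)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)

    def science_snapshot(self) -> dict:
        """Config snapshot without run-location fields, so the config hash in
        output headers is byte-stable across output directories."""
        snap = dataclasses.asdict(self)
        snap.pop("output_dir", None)
        snap.pop("log_level", None)
        return snap


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    checksums: dict[str, str]
    timestamps: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _model_context(
    model: str,
    geno: AlleleProbabilityTensor,
    panel: ExpressionPanel,
    kinship: KinshipSet,
) -> tuple[ScanContext, AlleleProbabilityTensor, pd.DataFrame, np.ndarray | None]:
    """Scan context plus the (possibly subset) genotypes/phenotypes for one
    model.  Subset models drop the diet covariate automatically."""
    diet = panel.diet_indicator()
    if model == "additive":
        ctx = ScanContext(
            geno, diet, ["diet"], kinship, "additive"
        )
        return ctx, geno, panel.values, diet
    if model == "interactive":
        ctx = ScanContext(
            geno, diet, ["diet"], kinship, "interactive", interactive=diet
        )
        return ctx, geno, panel.values, diet
    level = model.split("-", 1)[1]
    mask = (panel.covariates["diet"] == level).to_numpy()
    sub_geno = geno.subset(mask)
    sub_kinship = kinship.subset(mask)
    ctx = ScanContext(sub_geno, None, None, sub_kinship, model)
    return ctx, sub_geno, panel.values.loc[:, mask], None


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all stage outputs.

    Any stage failure aborts with the stage name attached to the exception.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(handler)
    snapshot = config.snapshot()
    chash = config_hash(config.science_snapshot())
    seed = config.seed
    timestamps: dict[str, float] = {}
    outputs: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - context then re-raise
                raise RuntimeError(f"pipeline stage '{name}' failed") from exc
            timestamps[name] = time.time() - t0
            logger.info("stage %s done (%.1fs)", name, timestamps[name])
            return result

        return wrap

    # -- simulate ---------------------------------------------------------
    sim = dataclasses.replace(config.simulation, seed=seed)

    @stage("simulate")
    def _simulate():
        geno, panel, truth = simulate_dataset(sim)
        write_markers(geno.markers, outdir / "markers.tsv", seed, chash)
        write_alleleprobs(geno, outdir / "alleleprobs.h5", seed)
        write_panel(panel, outdir, seed, chash)
        truth.to_json(outdir / "ground_truth.json")
        outputs.extend(
            outdir / n
            for n in (
                "markers.tsv",
                "alleleprobs.h5",
                "expression.tsv",
                "feature_annotations.tsv",
                "covariates.tsv",
                "ground_truth.json",
            )
        )
        return geno, panel, truth

    geno, panel, truth = _simulate

    @stage("kinship")
    def _kinship():
        return loco_kinship(geno)

    kinship = _kinship

    # -- scans + permutation + characterization per model -----------------
    perm_cfg = dataclasses.replace(config.permutation, seed=seed)
    all_peaks: dict[str, list[QtlPeak]] = {}
    for model in config.models:

        @stage(f"scan-{model}")
        def _scan(model=model):
            ctx, sub_geno, values, diet = _model_context(
                model, geno, panel, kinship
            )
            lods = {}
            observed = {}
            for feat in values.index:
                y = values.loc[feat].to_numpy(float)
                lod, _ = ctx.scan_phenotype(y)
                lods[str(feat)] = lod
                observed[str(feat)] = float(lod.max())
            lod_df = pd.DataFrame(lods, index=sub_geno.markers.index)
            write_lod(lod_df, outdir / f"lod_{model}.h5", model, seed)
            outputs.append(outdir / f"lod_{model}.h5")
            screen = two_stage_screen(
                ctx, values, perm_cfg, observed_max=pd.Series(observed)
            )
            write_tsv(
                screen.to_frame(),
                outdir / f"thresholds_{model}.tsv",
                seed,
                chash,
                index=False,
            )
            outputs.append(outdir / f"thresholds_{model}.tsv")
            thresholds = {
                r.phenotype: r.threshold
                for r in screen.records
                if r.stage == "full"
            }
            sub_kin = kinship if model in ("additive", "interactive") else None
            if sub_kin is None:
                mask = (
                    panel.covariates["diet"] == model.split("-", 1)[1]
                ).to_numpy()
                sub_kin = kinship.subset(mask)
            cov = diet if model == "additive" else None
            peaks: list[QtlPeak] = []
            for pid in screen.significant:
                ann = panel.annotations.loc[pid]
                peaks.extend(
                    characterize_phenotype(
                        sub_geno,
                        values.loc[pid].to_numpy(float),
                        pid,
                        str(ann["feature_class"]),
                        str(ann["chrom"]),
                        float(ann["tss_mb"]),
                        lod_df[pid].to_numpy(),
                        thresholds[pid],
                        model,
                        covariates=cov,
                        kinship=sub_kin,
                        config=config.classification,
                    )
                )
            write_tsv(
                peaks_to_frame(peaks),
                outdir / f"qtl_{model}.tsv",
                seed,
                chash,
                index=False,
            )
            outputs.append(outdir / f"qtl_{model}.tsv")
            return peaks

        all_peaks[model] = _scan

    # -- architecture -----------------------------------------------------
    @stage("architecture")
    def _architecture():
        additive = all_peaks.get("additive", [])
        mrna_peaks = [p for p in additive if p.feature_class == "mrna"]
        mirna_peaks = [p for p in additive if p.feature_class == "mirna"]
        if len(mrna_peaks) + len(mirna_peaks) >= 2:
            effects = np.array(
                [
                    p.founder_effects.effects
                    for p in additive
                    if p.founder_effects is not None
                ]
            )
            if len(effects) >= 2 and np.ptp(effects) > 0:
                enr = founder_enrichment(effects)
                write_tsv(
                    enr.dunn, outdir / "founder_enrichment.tsv", seed, chash,
                    index=False,
                )
                outputs.append(outdir / "founder_enrichment.tsv")
        pairs = colocalize(mrna_peaks, mirna_peaks)
        pair_df = pd.DataFrame(
            [
                {
                    "mirqtl": p.mirqtl.phenotype,
                    "eqtl": p.eqtl.phenotype,
                    "chrom": p.chrom,
                    "distance_mb": p.distance_mb,
                }
                for p in pairs
            ]
        )
        write_tsv(pair_df, outdir / "colocalization.tsv", seed, chash, index=False)
        outputs.append(outdir / "colocalization.tsv")

        # eQTL categories for the correlation analysis
        by_pheno: dict[str, set[str]] = {}
        for p in mrna_peaks:
            by_pheno.setdefault(p.phenotype, set()).add(p.qtl_class)
        multi = [f for f, cls in by_pheno.items() if len(cls) > 1]
        categories = pd.Series(
            {
                f: next(iter(cls))
                for f, cls in by_pheno.items()
                if len(cls) == 1
            }
        )
        mrna_panel = panel.of_class("mrna")
        mirna_panel = panel.of_class("mirna")
        if len(mirna_panel.values) and len(mrna_panel.values):
            corr = correlation_structure(
                mirna_panel.values,
                mrna_panel.values,
                categories,
                exclude_mrna=multi,
            )
            write_tsv(
                corr.records[corr.records["significant"]],
                outdir / "correlations_significant.tsv",
                seed,
                chash,
                index=False,
            )
            outputs.append(outdir / "correlations_significant.tsv")

        de = differential_expression(
            panel.values,
            panel.annotations["feature_class"],
            panel.covariates["diet"],
            config.filters,
        )
        write_tsv(de, outdir / "differential_expression.tsv", seed, chash)
        outputs.append(outdir / "differential_expression.tsv")

        ranking = allele_diet_ranking(
            all_peaks.get("interactive", []),
            all_peaks.get("subset-HFCA", []),
            all_peaks.get("subset-HP", []),
            panel.values,
            geno,
            panel.covariates["diet"],
        )
        write_tsv(
            ranking_to_frame(ranking),
            outdir / "diet_interaction_ranking.tsv",
            seed,
            chash,
            index=False,
        )
        outputs.append(outdir / "diet_interaction_ranking.tsv")

    _architecture

    manifest = RunManifest(
        config=snapshot,
        version=__version__,
        seed=seed,
        checksums={str(p.name): sha256_file(p) for p in outputs if p.exists()},
        timestamps=timestamps,
    )
    manifest.to_json(outdir / "manifest.json")
    logging.getLogger().removeHandler(handler)
    handler.close()
    return manifest
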