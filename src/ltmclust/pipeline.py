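"""End-to-end workflow: cohort -> screened matrix -> LSM -> curves -> JCMs.

Stages
------
1. load (or simulate) the binary symptom matrix and frequency-screen it;
2. establish the latent structural model: run the EAST-style search, and/or
   re-fit by EM the parameters of a supplied base structure (a factor map is
   authored against the latent names of a specific structure, so the curve
   and joint-clustering stages run on that *base model*; when no structure is
   supplied the learned one is the base);
3. per-latent information curves and significant-manifest lists;
4. per-factor joint clustering with sub-syndrome splits;
5. a run manifest (seeds, versions, config hash) for reproducibility.

All randomness flows from the master seed through named per-stage seeds
(``SeedSequence([master, stage_index])``); no wall-clock entropy enters any
computation, so identical config + seed reproduces every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .curves import information_curve, select_significant
from .data import read_symptom_matrix, screen_by_frequency, write_symptom_matrix, prevalence_table
from .em import bic_score, fit_em
from .errors import ConfigurationError, DegenerateLatentError, LtmclustError
from .jcm import SyndromeFactorMap, build_jcm, study_factor_map
from .model import LatentTreeModel
from .search import SearchConfig, search_structure
from .synthetic import generate_cohort, study_cohort_preset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_STAGES = ["simulate", "screen", "structure", "refit", "curves", "factors"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence([master, idx]).generate_state(1, dtype=np.uint32)[0]
        & 0x7FFFFFFF
    )


@dataclass
class PipelineConfig:
    out_dir: str
    input_csv: str | None = None          # None -> simulate the preset cohort
    preset_n_records: int = 559
    min_count: int = 1                    # frequency screen cutoff (explicit)
    threshold: float = 95.0               # information-coverage rule, percent
    scope: str = "all"                    # coverage normalisation: all|children
    jcm_mode: str = "flat"
    base_model_path: str | None = None    # structure for curves/factor stages
    factor_map_path: str | None = None    # None -> shipped study factor map
    learn_structure: bool = True
    search_max_latents: int = 30
    cardinality_bounds: tuple[int, int] = (2, 5)
    seed: int = 0
    plots: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 100.0:
            raise ConfigurationError("threshold must be in (0, 100]")
        if self.scope not in ("all", "children"):
            raise ConfigurationError("scope must be 'all' or 'children'")
        if self.jcm_mode != "flat":
            raise ConfigurationError("only the flat JCM mode is implemented")

    def analysis_dict(self) -> dict:
        """Config fields that determine results (out_dir only routes them)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LtmclustError):
                exc.args = (f"[stage {name}] {exc}",)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow; returns a summary dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    with _stage("load"):
        truth_model = None
        if cfg.input_csv is None:
            spec = study_cohort_preset(
                n_records=cfg.preset_n_records,
                seed=stage_seed(cfg.seed, "simulate"),
            )
            cohort, tags, truth_model = generate_cohort(spec)
            write_symptom_matrix(cohort, out / "cohort.csv")
            if tags is not None:
                tags.to_csv(out / "cohort_tags.csv", index=False)
            truth_model.save(out / "model_planted.json")
            if cfg.base_model_path is None:
                cfg = dataclasses.replace(
                    cfg, base_model_path=str(out / "model_planted.json")
                )
        else:
            cohort = read_symptom_matrix(cfg.input_csv)
        summary["n_records"] = cohort.n_records
        summary["n_symptoms_raw"] = cohort.n_symptoms

    with _stage("screen"):
        data = screen_by_frequency(cohort, cfg.min_count)
        prevalence_table(data).to_csv(out / "prevalence.tsv", sep="\t", index=False)
        summary["n_symptoms"] = data.n_symptoms

    learned = None
    if cfg.learn_structure:
        with _stage("structure"):
            scfg = SearchConfig(
                max_latents=cfg.search_max_latents,
                cardinality_bounds=cfg.cardinality_bounds,
                seed=stage_seed(cfg.seed, "structure"),
            )
            learned, trace = search_structure(data, scfg)
            learned.save(out / "model_learned.json")
            (out / "model_learned.dot").write_text(learned.to_dot(), "utf-8")
            with open(out / "search_trace.jsonl", "w", encoding="utf-8") as fh:
                for t in trace:
                    fh.write(json.dumps(dataclasses.asdict(t)) + "\n")
            summary["learned_n_latents"] = len(learned.latent_names)
            summary["learned_bic"] = float(bic_score(learned, data))

    with _stage("refit"):
        if cfg.base_model_path is not None:
            structure = LatentTreeModel.load(cfg.base_model_path)
            res = fit_em(
                structure, data, tol=1e-6, max_iter=300, restarts=2,
                seed=stage_seed(cfg.seed, "refit"), init_model=structure,
            )
            base = res.model
        elif learned is not None:
            base = learned
        else:
            raise ConfigurationError(
                "need base_model_path or learn_structure=True"
            )
        base.save(out / "model_base.json")
        (out / "model_base.dot").write_text(base.to_dot(), "utf-8")
        summary["base_bic"] = float(bic_score(base, data))

    with _stage("curves"):
        curve_seed = stage_seed(cfg.seed, "curves")
        cdir = out / "curves"
        cdir.mkdir(exist_ok=True)
        significant: dict[str, list[str]] = {}
        for latent in base.latent_names:
            latent_scope = (
                base.manifest_names if cfg.scope == "all"
                else base.leaf_descendants(latent)
            )
            if not latent_scope:
                continue
            try:
                curve = information_curve(base, latent, latent_scope, seed=curve_seed)
            except DegenerateLatentError:
                logger.info("latent %s carries no information; no curve", latent)
                continue
            safe = latent.replace("/", "_")
            curve.to_tsv(cdir / f"{safe}.tsv")
            if cfg.plots:
                curve.plot(cdir / f"{safe}.png")
            significant[latent] = select_significant(curve, cfg.threshold)
        with open(out / "significant_manifests.tsv", "w", encoding="utf-8") as fh:
            fh.write("latent\tsignificant_manifests\n")
            for latent, sel in significant.items():
                fh.write(f"{latent}\t{','.join(sel)}\n")
        summary["significant"] = significant

    with _stage("factors"):
        fmap = (
            SyndromeFactorMap.load(cfg.factor_map_path)
            if cfg.factor_map_path
            else study_factor_map()
        )
        fmap.save(out / "factor_map.json")
        fdir = out / "factors"
        fdir.mkdir(exist_ok=True)
        jcm_summary = {}
        for i, factor in enumerate(fmap.factors, start=1):
            jcm = build_jcm(
                base, data, factor, fmap,
                z_name=f"Z{i}",
                threshold=cfg.threshold,
                scope=cfg.scope,
                cardinality_bounds=cfg.cardinality_bounds,
                seed=stage_seed(cfg.seed, "factors") + i,
                curve_seed=curve_seed,
            )
            safe = factor.replace("/", "_")
            (fdir / f"{safe}.tsv").write_text(
                "\n".join(jcm.report_lines()) + "\n", "utf-8"
            )
            jcm.curve.to_tsv(fdir / f"{safe}_curve.tsv")
            if cfg.plots:
                jcm.curve.plot(fdir / f"{safe}_curve.png")
            for s in jcm.subsyndromes:
                if s.curve is not None:
                    s.curve.to_tsv(fdir / f"{safe}_{s.name}_curve.tsv")
                    if cfg.plots:
                        s.curve.plot(fdir / f"{safe}_{s.name}_curve.png")
            jcm_summary[factor] = {
                "z": jcm.z_name,
                "cardinality": jcm.cardinality,
                "selected_raw": jcm.selected_raw,
                "selected": jcm.selected,
                "subsyndromes": {
                    s.name: s.selected for s in jcm.subsyndromes
                },
            }
        summary["factors"] = jcm_summary

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.analysis_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), "utf-8"
    )
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), "utf-8"
    )
    return summary
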