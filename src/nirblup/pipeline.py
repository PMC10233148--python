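"""Configured end-to-end runs: simulate/load -> adjust -> GRM -> GREML -> CV.

A run is described by one declarative mapping (usually a YAML file) and
produces a manifest recording the configuration hash, seed, package
version and every stage output, so the run can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .greml import FitOptions, fit_bivariate, fit_single_trait
from .grm import build_grm, grm_condition, pca_grm
from .io import (
    blues_to_series,
    read_genotypes,
    read_phenotypes,
    write_blues,
    write_genotypes,
    write_grm,
    write_phenotypes,
)
from .phenotypes import edit_outliers, estimate_line_variance, fit_blues
from .simulate import TRAIT_EP, TRAIT_NIR, SimulationConfig, simulate_dataset
from .validation import make_folds, run_cv, run_forward

log = logging.getLogger("nirblup")

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulation: dict | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    trait_ep: str = TRAIT_EP
    trait_nir: str = TRAIT_NIR
    min_maf: float = 0.0
    ridge: float = 1e-6
    outlier_edit: bool = True
    greml: dict = field(default_factory=dict)  # max_iter / tol overrides
    cv: dict | None = None  # {k, repeats, scenarios}
    forward: dict | None = None  # {test_years, mode}
    pca_components: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigurationError("config must set out_dir")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_real = self.genotypes is not None or self.phenotypes is not None
        if has_sim == has_real:
            raise ConfigurationError(
                "config must set exactly one of a simulation block or "
                "genotype/phenotype paths"
            )
        if has_real:
            for p in (self.genotypes, self.phenotypes):
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"input file missing: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(genotypes, phenotypes: pd.DataFrame, traits=(TRAIT_EP, TRAIT_NIR)):
    """Structural diagnostics; never mutates data.

    Returns a list of ``{"level": "warning"|"error", "message": ...}``.
    """
    diags = []
    geno_lines = set(genotypes.line_ids)
    if len(genotypes.line_ids) != len(geno_lines):
        diags.append({"level": "error", "message": "duplicate line ids in genotypes"})
    pheno_lines = set(phenotypes["line_id"])
    orphans = sorted(pheno_lines - geno_lines)
    if orphans:
        diags.append(
            {
                "level": "warning",
                "message": f"{len(orphans)} phenotyped lines absent from genotypes "
                f"(e.g. {orphans[:3]})",
            }
        )
    for tr in traits:
        if tr not in set(phenotypes["trait"]):
            diags.append(
                {"level": "error", "message": f"trait {tr!r} absent from phenotypes"}
            )
    bad_years = [y for y in phenotypes["year"].unique() if not str(y).strip()]
    if bad_years:
        diags.append({"level": "error", "message": "empty year labels present"})
    return diags


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages and write a manifest; returns it."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "status": "running",
    }

    def record(stage: str, **paths):
        manifest["stages"][stage] = {k: str(v) for k, v in paths.items()}
        log.info("stage %s done: %s", stage, paths)

    try:
        # -- inputs -------------------------------------------------------
        if config.simulation is not None:
            sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
            log.info("simulating: %s", sim)
            geno, pheno, truth = simulate_dataset(sim)
            write_genotypes(geno, out / "genotypes.raw")
            write_phenotypes(pheno, out / "phenotypes.csv")
            truth.to_frame().to_csv(out / "truth.csv", index=False)
            record(
                "simulate",
                genotypes=out / "genotypes.raw",
                phenotypes=out / "phenotypes.csv",
                truth=out / "truth.csv",
            )
        else:
            geno = read_genotypes(config.genotypes)
            pheno = read_phenotypes(config.phenotypes)
            record("load", genotypes=config.genotypes, phenotypes=config.phenotypes)

        diags = validate_inputs(geno, pheno, (config.trait_ep, config.trait_nir))
        manifest["diagnostics"] = diags
        if any(d["level"] == "error" for d in diags):
            raise DataError(f"input validation failed: {diags}")

        # -- phenotype adjustment ------------------------------------------
        if config.outlier_edit:
            pheno, removed = edit_outliers(pheno)
            (out / "outliers_removed.csv").write_text(removed.to_csv(index=False))
        blues_frames, h2_line = [], {}
        for trait in (config.trait_ep, config.trait_nir):
            blues_frames.append(fit_blues(pheno, trait))
            lv = estimate_line_variance(pheno, trait)
            h2_line[trait] = {
                "sigma2_g": lv.sigma2_g,
                "sigma2_e": lv.sigma2_e,
                "T": lv.T,
                "R": lv.R,
                "H2": lv.H2,
            }
        blues = pd.concat(blues_frames, ignore_index=True)
        write_blues(blues, out / "blues.csv")
        record("adjust", blues=out / "blues.csv")

        # -- GRM ------------------------------------------------------------
        grm = grm_condition(build_grm(geno, min_maf=config.min_maf), config.ridge)
        write_grm(grm, out / "grm.tsv")
        record("grm", grm=out / "grm.tsv")
        if config.pca_components:
            scores, explained = pca_grm(grm, config.pca_components)
            scores.to_csv(out / "grm_pca.csv", index_label="line_id")
            record("pca", scores=out / "grm_pca.csv")

        # -- GREML fits ------------------------------------------------------
        opts = FitOptions(**config.greml) if config.greml else FitOptions()
        ep = blues_to_series(blues, config.trait_ep)
        nir = blues_to_series(blues, config.trait_nir)
        st = fit_single_trait(ep, grm, opts)
        bv = fit_bivariate(ep, nir, grm, opts)
        comps = {
            "line_model": h2_line,
            "single_trait": {
                "sigma2_g": st.sigma2_g,
                "sigma2_e": st.sigma2_e,
                "h2": st.h2,
                "loglik": st.loglik,
                "n_iter": st.n_iter,
            },
            "bivariate": {
                "G0": bv.G0.tolist(),
                "R0": bv.R0.tolist(),
                "r_g": bv.r_g,
                "r_p": bv.r_p,
                "h2": list(bv.h2),
                "loglik": bv.loglik,
                "n_iter": bv.n_iter,
            },
        }
        (out / "variance_components.json").write_text(json.dumps(comps, indent=2))
        gebv = pd.DataFrame(
            {
                "line_id": grm.line_ids,
                "gebv_single_ep": st.gebv.to_numpy(),
                "gebv_ep": bv.gebv_ep.to_numpy(),
                "gebv_nir": bv.gebv_nir.to_numpy(),
            }
        )
        gebv.to_csv(out / "gebv.csv", index=False)
        record("fit", components=out / "variance_components.json", gebv=out / "gebv.csv")

        # -- cross-validation -----------------------------------------------
        if config.cv:
            k = int(config.cv.get("k", 5))
            repeats = int(config.cv.get("repeats", 10))
            scenarios = config.cv.get("scenarios", ["S0", "S1", "S2", "S3"])
            plan = make_folds(sorted(ep.index), k=k, repeats=repeats, seed=config.seed)
            report = run_cv(ep, nir, grm, plan, scenarios, opts)
            report.folds.to_csv(out / "cv_folds.csv", index=False)
            (out / "cv_summary.json").write_text(
                json.dumps(report.to_json_dict(), indent=2)
            )
            record("cv", folds=out / "cv_folds.csv", summary=out / "cv_summary.json")

        # -- forward prediction ----------------------------------------------
        if config.forward:
            first_year = (
                pheno.sort_values("year").groupby("line_id")["year"].first()
            )
            fwd = run_forward(
                ep,
                nir,
                grm,
                first_year,
                config.forward["test_years"],
                mode=config.forward.get("mode", "multi"),
                options=opts,
            )
            fwd.by_year.to_csv(out / "forward.csv", index=False)
            record("forward", by_year=out / "forward.csv")

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
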