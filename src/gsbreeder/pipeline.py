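"""End-to-end orchestration: simulate -> QC -> LMM -> G-BLUP -> CV -> report.

A single YAML config drives the run; one master seed deterministically
spawns a sub-seed per stage, so reruns of the same config are reproducible
(bit-identical for the deterministic solver path).  Every run directory
gets a ``manifest.json`` recording the config, stage seeds, wall times,
record counts and the SHA-256 of each output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breedstats, crossval, gblup, pheno_lmm, simdata, snp_qc
from .containers import ConfigurationError, MarkerPanel, read_phenotypes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "lmm", "gblup", "cv", "density", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    simulate: dict | None = None
    genotypes: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    traits: list[str] | None = None
    qc: dict = field(default_factory=dict)
    lmm: dict = field(default_factory=dict)
    gblup: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    density: dict | None = None
    report: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigurationError("config must set a master seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if not (self.genotypes and self.marker_map and self.phenotypes):
                raise ConfigurationError(
                    "config needs either a 'simulate' block or paths to "
                    "genotypes, marker_map and phenotypes"
                )
            for p in (self.genotypes, self.marker_map, self.phenotypes):
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        if self.density is not None and "panel_sizes" not in self.density:
            raise ConfigurationError("density block needs 'panel_sizes'")


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_stage(cfg: RunConfig, seed_sim: int, out: Path):
    sim = dict(cfg.simulate or {})
    n_markers = int(sim.get("n_markers", 5000))
    pedigree = simdata.simulate_pedigree(simdata.PedigreeSpec(), seed=seed_sim)
    panel = simdata.simulate_genotypes(
        pedigree,
        n_markers=n_markers,
        missing_rate=float(sim.get("missing_rate", 0.01)),
        invariant_fraction=float(sim.get("invariant_fraction", 0.015)),
        seed=seed_sim,
    )
    traits_cfg = sim.get("traits", "default")
    if traits_cfg == "default":
        traits = simdata.default_traits(max_qtl=max(1, n_markers // 2))
    else:
        traits = [
            simdata.make_trait(
                t["name"],
                float(t["h2"]),
                int(t.get("n_qtl", 100)),
                t.get("kind", "continuous"),
                int(t.get("score_levels", 0)),
            )
            for t in traits_cfg
        ]
    table, truth = simdata.simulate_phenotypes(
        panel, pedigree, traits, seed=seed_sim + 1
    )
    panel.to_files(out / "genotypes.tsv", out / "marker_map.tsv")
    table.to_csv(out / "phenotypes.csv", index=False)
    truth.to_frame().to_csv(out / "true_breeding_values.csv", index=False)
    return panel, table


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Raises with a stage-tagged message on failure; outputs of completed
    stages are left in place.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }
    t_start = time.time()
    stage = "simulate"
    try:
        if config.simulate is not None:
            panel, table = _simulate_stage(config, seeds["simulate"], out)
        else:
            panel = MarkerPanel.from_files(config.genotypes, config.marker_map)
            table = read_phenotypes(config.phenotypes)
        manifest["stages"]["simulate"] = {
            "n_individuals": panel.n_individuals,
            "n_markers": panel.n_markers,
            "n_records": len(table),
            "seconds": round(time.time() - t_start, 3),
        }

        stage = "qc"
        t0 = time.time()
        qc_panel, qc_report = snp_qc.run_qc(
            panel,
            cr_threshold=float(config.qc.get("cr_threshold", 0.90)),
            maf_threshold=float(config.qc.get("maf_threshold", 0.05)),
        )
        qc_report.to_json(out / "qc_report.json")
        (out / "qc_report.txt").write_text(qc_report.to_text())
        manifest["stages"]["qc"] = {
            "n_retained": qc_report.n_retained,
            "reduction_percent": round(qc_report.reduction_percent, 2),
            "seconds": round(time.time() - t0, 3),
        }

        trait_names = config.traits or sorted(table["trait"].unique())
        W = gblup.impute_missing(qc_panel.genotypes)
        K = gblup.genomic_relationship(W)
        families = (
            table.drop_duplicates("individual").set_index("individual")["family"]
        )

        stage = "lmm"
        t0 = time.time()
        pheno_fits: dict[str, pheno_lmm.PhenoFit] = {}
        corrected_rows = []
        vc_out = {}
        for trait in trait_names:
            fit = pheno_lmm.fit_trait(
                table,
                trait,
                genetic_level=config.lmm.get("genetic_level", "individual"),
                max_iter=int(config.lmm.get("max_iter", 2000)),
                tol=float(config.lmm.get("tol", 1e-6)),
            )
            pheno_fits[trait] = fit
            vc_out[trait] = {
                "sigma2": fit.components.sigma2,
                "converged": fit.components.converged,
                "n_iterations": fit.components.n_iterations,
                "h2_phen": fit.h2_phen,
                "r_yy": fit.r_yy,
                "aliased": fit.components.aliased,
            }
            for ind, val in fit.corrected_phenotypes.items():
                corrected_rows.append({"trait": trait, "individual": ind, "corrected": val})
        with open(out / "variance_components.json", "w") as fh:
            json.dump(vc_out, fh, indent=2)
        pd.DataFrame(corrected_rows).to_csv(out / "corrected_phenotypes.csv", index=False)
        manifest["stages"]["lmm"] = {
            "n_traits": len(trait_names),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "gblup"
        t0 = time.time()
        genomic_h2: dict[str, float] = {}
        gebv_rows = []
        for trait in trait_names:
            y = pheno_fits[trait].corrected_phenotypes.reindex(qc_panel.individual_ids)
            gvar = gblup.estimate_genomic_variance(y.to_numpy(), K)
            genomic_h2[trait] = gvar["h2"]
            vy = float(np.var(y.to_numpy(), ddof=1))
            h2 = min(max(gvar["h2"], 1e-3), 1 - 1e-3)
            model = gblup.GenomicModel(
                y=y.to_numpy(),
                W=W,
                sigma_g2=h2 * vy,
                sigma_e2=(1 - h2) * vy,
                nQ=config.gblup.get("nQ"),
            )
            fit = gblup.solve_direct(model)
            for ind, val in zip(qc_panel.individual_ids, fit.gebv):
                gebv_rows.append({"trait": trait, "individual": ind, "gebv": val})
        pd.DataFrame(gebv_rows).to_csv(out / "gebv.csv", index=False)
        manifest["stages"]["gblup"] = {
            "genomic_h2": {t: round(v, 4) for t, v in genomic_h2.items()},
            "seconds": round(time.time() - t0, 3),
        }

        stage = "cv"
        t0 = time.time()
        scheme = crossval.CVScheme(
            n_folds=int(config.cv.get("n_folds", 13)),
            strategy=config.cv.get("strategy", "random"),
        )
        folds = crossval.make_folds(
            qc_panel.individual_ids, scheme, seed=seeds["cv"], families=families
        )
        cv_out = {}
        cv_results: dict[str, crossval.CVResult] = {}
        for trait in trait_names:
            y = pheno_fits[trait].corrected_phenotypes.reindex(qc_panel.individual_ids)
            vy = float(np.var(y.to_numpy(), ddof=1))
            h2 = min(max(genomic_h2[trait], 1e-3), 1 - 1e-3)
            res = crossval.cv_run(
                W, y, folds, sigma_g2=h2 * vy, sigma_e2=(1 - h2) * vy,
                nQ=config.gblup.get("nQ"),
            )
            cv_results[trait] = res
            cv_out[trait] = {
                "r_gy": res.r_gy,
                "sd_r": res.sd_r,
                "b": res.b,
                "sd_b": res.sd_b,
                "r_gy_pooled": res.r_gy_pooled,
            }
            res.per_fold.to_csv(out / f"cv_folds_{trait}.csv", index=False)
        with open(out / "cv_results.json", "w") as fh:
            json.dump(cv_out, fh, indent=2)
        manifest["stages"]["cv"] = {"seconds": round(time.time() - t0, 3)}

        stage = "density"
        if config.density is not None:
            t0 = time.time()
            dtraits = config.density.get("traits", trait_names[:1])
            sizes = [int(s) for s in config.density["panel_sizes"]]
            for trait in dtraits:
                y = pheno_fits[trait].corrected_phenotypes.reindex(qc_panel.individual_ids)
                h2 = min(max(genomic_h2[trait], 1e-3), 1 - 1e-3)
                dens = breedstats.density_experiment(
                    qc_panel, y, sizes, h2=h2, scheme=scheme,
                    seed=seeds["density"], families=families,
                )
                dens.to_csv(out / f"density_{trait}.csv", index=False)
            manifest["stages"]["density"] = {"seconds": round(time.time() - t0, 3)}

        stage = "report"
        t0 = time.time()
        rep = config.report
        stats = []
        for trait in trait_names:
            res = cv_results[trait]
            stats.append(
                breedstats.DerivedStats(
                    trait=trait,
                    h2_phen=pheno_fits[trait].h2_phen,
                    r_yy=pheno_fits[trait].r_yy,
                    h2_genomic=genomic_h2[trait],
                    r_gy=res.r_gy,
                    sd_r=res.sd_r,
                    b=res.b,
                    sd_b=res.sd_b,
                    n_population=qc_panel.n_individuals,
                    l_f=float(rep.get("l_f", 24)),
                    l_gs_short=float(rep.get("l_gs_short", 12)),
                    l_gs_long=float(rep.get("l_gs_long", 24)),
                    target_accuracies=tuple(
                        rep.get("targets", breedstats.DEFAULT_TARGET_ACCURACIES)
                    ),
                )
            )
        t3, t4 = breedstats.build_tables(stats)
        t3.to_csv(out / "genetic_parameters.csv", index=False)
        t4.to_csv(out / "efficiency.csv", index=False)
        (out / "genetic_parameters.md").write_text(t3.to_markdown(index=False))
        (out / "efficiency.md").write_text(t4.to_markdown(index=False))
        manifest["stages"]["report"] = {"seconds": round(time.time() - t0, 3)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
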