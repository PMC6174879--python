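"""End-to-end orchestration: simulate/load -> stats -> four-gametes ->
SFS -> demographic fits -> unit conversion, with every intermediate
artifact written to disk and seeds recorded for reproducibility.

A run is described by a structured config (YAML on disk)::

    seed: 1
    outdir: run1
    stages: [stats, fourgametes, sfs, demography, convert]
    simulate:              # either this block or `inputs:`
      model: split_mig
      params: {nu1: 3.5, nu2: 6.0, T: 1.4, m12: 1.65, m21: 1.65}
      n_variable_loci_target: 400
      ...
    inputs:                # real data: paths to the three text files
      vcf: data.vcf
      popmap: popmap.tsv
      annotation: annotation.tsv
    models: [neutral, split_mig, split_nomig]
    fit: {n_starts: 3, n_genealogies: 20000, jackknife: 10}
    calibration:
      rates: [6.83e-10, 6.67e-10]   # per-site per-year, averaged
      generation_alpha: 1.0
      generation_survival: 0.62963  # G = alpha + s/(1-s)
      L_bp: null                    # default: adjusted surveyed length
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import convert as conv
from . import demography, fourgametes, sfs, stats
from .loci import read_dataset
from .simulate import DemographicParams, SimulationConfig, generate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

_ALL_STAGES = ("stats", "fourgametes", "sfs", "demography", "convert")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "ucepop_run"
    stages: tuple[str, ...] = _ALL_STAGES
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None  # vcf / popmap / annotation paths
    models: tuple[str, ...] = ("neutral", "split_mig", "split_nomig")
    n_starts: int = 3
    n_genealogies: int = 20000
    jackknife_blocks: int = 10
    run_jackknife: bool = False
    thinning: str = "random"
    rates_per_year: tuple[float, ...] = (6.83e-10, 6.67e-10)
    generation_alpha: float = 1.0
    generation_survival: float = 0.62963
    L_bp: float | None = None  # default: adjusted surveyed length (see below)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of `simulate` or `inputs` must be given")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    config: dict
    seeds: dict[str, int]
    sections: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seeds": self.seeds, "sections": self.sections},
            indent=2,
            default=_jsonable,
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw["simulate"])
        if "params" in sim:
            sim["params"] = DemographicParams(**sim["params"])
        raw["simulate"] = SimulationConfig(**sim)
    for key in ("stages", "models", "rates_per_year"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if raw.get("L_bp") is not None:
        raw["L_bp"] = float(raw["L_bp"])
    return RunConfig(**raw)


def _config_digest(cfg_dict: dict) -> str:
    return hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the enabled stages in order, writing artifacts under
    ``cfg.outdir``; reruns with the same config reproduce identical
    outputs (all randomness is derived from ``cfg.seed``)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    from . import __version__

    cfg_dict = asdict(cfg)
    seeds = {
        "root": cfg.seed,
        "thinning": cfg.seed + 1,
        "jackknife": cfg.seed + 2,
        "permutation": cfg.seed + 3,
        "fit": cfg.seed + 4,
    }
    report = RunReport(
        config={**cfg_dict, "digest": _config_digest(cfg_dict), "version": __version__},
        seeds=seeds,
    )

    # --- input or simulation ------------------------------------------------
    if cfg.simulate is not None:
        ds = generate_dataset(cfg.simulate)
        paths = ds.write(cfg.outdir)
        ls = ds.locus_set
        report.sections["data"] = {
            "source": "simulated",
            "paths": paths,
            "truth": asdict(cfg.simulate),
        }
    else:
        ls = read_dataset(cfg.inputs["vcf"], cfg.inputs["popmap"], cfg.inputs["annotation"])
        report.sections["data"] = {"source": "loaded", "paths": dict(cfg.inputs)}
    n_var = sum(1 for l in ls.loci if l.is_variable)
    report.sections["data"].update(
        n_loci=len(ls.loci),
        n_variable_loci=n_var,
        n_invariant_loci=len(ls.loci) - n_var,
        n_snps=int(sum(l.n_snps for l in ls.loci)),
        n_samples=ls.n_samples,
        total_length_bp=int(ls.total_length_bp()),
    )

    def _stage_error(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stats --------------------------------------------------------------
    if "stats" in cfg.stages:
        try:
            div = stats.divergence_stats(ls)
            fst = stats.weir_cockerham_fst(ls, level="overall")
            fst_locus = stats.weir_cockerham_fst(ls, level="locus")
            g_obs, g_p = stats.permutation_differentiation_test(
                ls, n_perm=1000, rng=np.random.default_rng(seeds["permutation"])
            )
            het = stats.heterozygosity_summary(ls)
            assign = stats.assign_individuals(ls, n_pcs=min(4, ls.n_samples - 1))
            fst_locus.table.to_csv(os.path.join(cfg.outdir, "fst_by_locus.tsv"), sep="\t", index=False)
            het.hwe_p_by_snp.to_csv(os.path.join(cfg.outdir, "hwe_by_snp.tsv"), sep="\t", index=False)
            assign.posteriors.to_csv(os.path.join(cfg.outdir, "assignment.tsv"), sep="\t")
            report.sections["stats"] = {
                "pi_overall": div.pi_overall,
                "pi_by_pop": div.pi_by_pop,
                "dxy": div.dxy,
                "dA": div.dA,
                "fst_overall": fst.overall,
                "g_statistic": g_obs,
                "g_test_p": g_p,
                "ho_by_pop": het.ho_by_pop,
                "he_by_pop": het.he_by_pop,
                "n_loci_out_of_hwe": het.n_loci_out_of_hwe,
                "unique_alleles": het.unique_alleles,
                "diagnosability": assign.diagnosability,
            }
        except Exception as exc:  # noqa: BLE001 - stage-labelled rethrow
            _stage_error("stats", exc)

    # --- four-gametes -------------------------------------------------------
    if "fourgametes" in cfg.stages:
        try:
            _, fg_report = fourgametes.filter_locus_set(ls)
            fg_report.to_csv(os.path.join(cfg.outdir, "fourgametes.tsv"), sep="\t", index=False)
            summary = fourgametes.recombination_summary(
                fg_report[fg_report["n_snps"] > 0]
            )
            report.sections["fourgametes"] = summary
        except Exception as exc:
            _stage_error("fourgametes", exc)

    # --- SFS ----------------------------------------------------------------
    snp_matrix = None
    data_sfs = None
    if "sfs" in cfg.stages or "demography" in cfg.stages:
        try:
            snp_matrix = sfs.prepare_snp_matrix(
                ls, thinning=cfg.thinning, rng=np.random.default_rng(seeds["thinning"])
            )
            data_sfs = sfs.build_folded_joint_sfs(snp_matrix)
            sfs.write_sfs(data_sfs, os.path.join(cfg.outdir, "joint_sfs.txt"))
            report.sections["sfs"] = {
                "n_snps": snp_matrix.n_snps,
                "dropped": snp_matrix.dropped,
                "mass": data_sfs.mass,
                "shape": list(data_sfs.data.shape),
            }
        except Exception as exc:
            _stage_error("sfs", exc)

    # --- demography ---------------------------------------------------------
    best_fit = None
    ci_table = None
    if "demography" in cfg.stages:
        try:
            table, fits = demography.compare_models(
                data_sfs,
                models=list(cfg.models),
                n_starts=cfg.n_starts,
                n_genealogies=cfg.n_genealogies,
                seed=seeds["fit"],
            )
            table.to_csv(os.path.join(cfg.outdir, "model_comparison.tsv"), sep="\t", index=False)
            best_model = table.loc[0, "model"]
            best_fit = fits[best_model]
            section = {
                "model_comparison": table.to_dict(orient="records"),
                "best_model": best_model,
                "best_params": best_fit.param_dict(),
                "loglik": best_fit.loglik,
                "converged": bool(best_fit.converged),
            }
            if cfg.run_jackknife:
                jk = sfs.jackknife_datasets(
                    snp_matrix, cfg.jackknife_blocks, np.random.default_rng(seeds["jackknife"])
                )
                ci_table = demography.jackknife_ci(jk.replicates, best_model, best_fit)
                ci_table.to_csv(os.path.join(cfg.outdir, "jackknife_ci.tsv"), sep="\t", index=False)
                section["jackknife_ci"] = ci_table.to_dict(orient="records")
            report.sections["demography"] = section
        except Exception as exc:
            _stage_error("demography", exc)

    # --- conversion ---------------------------------------------------------
    if "convert" in cfg.stages and best_fit is not None:
        try:
            g = conv.generation_time(cfg.generation_alpha, cfg.generation_survival)
            cal = conv.RateCalibration(conv.average_rate(list(cfg.rates_per_year)), g)
            if cfg.L_bp is not None:
                L = cfg.L_bp
            else:
                # adjusted surveyed length: total surveyed bp scaled by the
                # proportion of SNPs retained after thinning to 1 SNP/locus
                total_snps = sum(l.n_snps for l in ls.loci)
                L = ls.total_length_bp() * (snp_matrix.n_snps / max(total_snps, 1))
            p = best_fit.params
            ci = None
            if ci_table is not None:
                ci = {
                    row["parameter"]: (row["ci_lower"], row["ci_upper"])
                    for _, row in ci_table.iterrows()
                }
            bio = conv.convert_parameters(
                best_fit.theta, p.nu1, p.nu2, p.T, p.m12, p.m21, cal, L, ci=ci
            )
            bio.as_table().to_csv(os.path.join(cfg.outdir, "bio_units.tsv"), sep="\t", index=False)
            report.sections["convert"] = {
                "rate_per_year": cal.rate_per_year,
                "generation_time_years": g,
                "mu_per_generation": cal.mu_per_generation,
                "L_bp": L,
                "bio_units": {
                    k: getattr(bio, k)
                    for k in ("Nref", "N1", "N2", "T_years", "migrants_1", "migrants_2")
                },
            }
        except Exception as exc:
            _stage_error("convert", exc)

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    return report
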