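"""End-to-end orchestration: simulate/load -> QC -> PRS -> MR -> epi report.

A run is fully determined by a :class:`PipelineConfig` (serializable to
YAML) and its seed; identical config + seed gives byte-identical estimate
tables.  Stages run in study order: genotype/sample QC, base-target
harmonization, LD clumping, threshold optimization with permutation p,
scoring, observational models, causal estimation with stratified and
sensitivity analyses.
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

import prsmr
from prsmr import epi, mr, plinkio, prs, qc
from prsmr.simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("prsmr")

CONTINUOUS = epi.CONTINUOUS_OUTCOMES
BINARY = epi.BINARY_OUTCOMES
OUTCOMES = CONTINUOUS + BINARY


class DataError(RuntimeError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    # either simulate…
    simulation: SimulationConfig | None = None
    # …or load from disk
    genotypes_prefix: str | None = None          # PLINK1 triplet prefix
    phenotypes_path: str | None = None
    base_gwas_path: str | None = None

    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    clump_params: prs.ClumpParams = field(default_factory=prs.ClumpParams)
    threshold_grid: tuple[float, ...] = prs.DEFAULT_GRID
    n_perm: int = 1000
    n_pcs: int = 3
    methods: tuple[str, ...] = ("tsls", "gmm")
    strata: tuple[str, ...] = mr.STRATA
    adjustments: tuple[str, ...] = ("partial", "full")
    bootstrap: int = 0
    seed: int = 0
    output_dir: str = "prsmr_output"

    def __post_init__(self) -> None:
        if self.simulation is None and self.genotypes_prefix is None:
            self.simulation = SimulationConfig(seed=self.seed)
        unknown = set(self.methods) - {"tsls", "gmm"}
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            raw["simulation"] = SimulationConfig(**sim)
        if "qc_thresholds" in raw:
            raw["qc_thresholds"] = qc.QCThresholds(**raw["qc_thresholds"])
        if "clump_params" in raw:
            raw["clump_params"] = prs.ClumpParams(**raw["clump_params"])
        for key in ("threshold_grid", "methods", "strata", "adjustments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        if d.get("simulation"):
            d["simulation"]["maf_range"] = list(d["simulation"]["maf_range"])
            d["simulation"]["causal_beta"] = dict(d["simulation"]["causal_beta"])
        for key in ("threshold_grid", "methods", "strata", "adjustments"):
            d[key] = list(d[key])
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path


def _load_inputs(config: PipelineConfig) -> dict:
    if config.genotypes_prefix is not None:
        prefix = Path(config.genotypes_prefix)
        if not prefix.with_suffix(".bed").exists():
            raise DataError(f"missing genotype file: {prefix.with_suffix('.bed')}")
        for attr, what in (("phenotypes_path", "phenotype table"),
                           ("base_gwas_path", "base summary statistics")):
            p = getattr(config, attr)
            if p is None or not Path(p).exists():
                raise DataError(f"missing {what}: {p}")
        dosages, variants, samples = plinkio.read_bed(prefix)
        variants = variants.rename(columns={"chrom": "chrom"})
        cohort = plinkio.read_phenotypes(config.phenotypes_path)
        if len(cohort) != dosages.shape[0]:
            raise DataError("phenotype table and fam file disagree on sample count")
        base = plinkio.read_gwas(config.base_gwas_path)
        return {"dosages": dosages, "variants": variants, "cohort": cohort,
                "base_gwas": base, "truth": None}
    log.info("simulating dataset: %s", config.simulation)
    return simulate_dataset(config.simulation)


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run every stage; returns (and optionally writes) the analysis report."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    out = Path(config.output_dir)
    if write:
        plinkio.ensure_writable(out)
        _setup_log(out)

    data = _load_inputs(config)
    dosages, variants = data["dosages"], data["variants"]
    cohort, base = data["cohort"].copy(), data["base_gwas"]
    n0, m0 = dosages.shape
    log.info("input: %d samples x %d variants", n0, m0)

    # ---- QC: marker filters -> sample filters -> relatedness -> PCs ----
    report = qc.QCReport(n_variants_in=m0, n_samples_in=n0)
    info = (base.set_index("SNP")["INFO"].reindex(variants["snp_id"]).values
            if "INFO" in base.columns else None)
    keep_v, _ = qc.filter_variants(dosages, variants, config.qc_thresholds,
                                   info=info, report=report)
    dosages = dosages[:, keep_v]
    variants = variants.iloc[keep_v].reset_index(drop=True)
    log.info("marker QC: %s -> %d variants", report.variants_removed,
             report.n_variants_out)

    _, keep_s, _ = qc.sample_qc(dosages, config.qc_thresholds, report=report)
    dosages, cohort = dosages[keep_s], cohort.iloc[keep_s].reset_index(drop=True)

    kin_pairs, keep_r, _ = qc.remove_related(
        dosages, config.qc_thresholds, sample_ids=list(cohort["sample_id"]),
        report=report)
    dosages, cohort = dosages[keep_r], cohort.iloc[keep_r].reset_index(drop=True)
    report.n_samples_out = len(cohort)
    log.info("sample QC: %s -> %d samples", report.samples_removed,
             report.n_samples_out)

    pcs, evr = qc.compute_pcs(dosages, config.n_pcs)
    pc_cols = [f"pc{i + 1}" for i in range(config.n_pcs)]
    cohort[pc_cols] = pcs

    # ---- harmonization + clumping + threshold optimization ----
    harmonized, harm_report = qc.harmonize_variants(base, variants)
    log.info("harmonization: %s", harm_report.to_dict())
    vindex = {sid: j for j, sid in enumerate(variants["snp_id"])}
    clumped = prs.clump(harmonized, dosages, config.clump_params,
                        variant_index=vindex)
    log.info("clumping: %d -> %d index SNPs", len(harmonized), len(clumped))

    # exclusions before instrument fitting: lipid-lowering med users out
    analysis = cohort[cohort.get("lipid_med", 0) != 1].reset_index(drop=True)
    arows = np.flatnonzero((cohort.get("lipid_med", 0) != 1).to_numpy()
                           if "lipid_med" in cohort.columns
                           else np.ones(len(cohort), bool))
    adose = dosages[arows]
    exposure = epi.zstandardize(analysis["adiponectin"].to_numpy(), log_first=True)
    covariates = analysis[["age", "sex"] + pc_cols].to_numpy(dtype=float)

    perm_seed = int(rng.integers(0, 2 ** 31 - 1))
    emp_p, model = prs.empirical_pvalue(
        clumped, adose, exposure, covariates, grid=config.threshold_grid,
        n_perm=config.n_perm, seed=perm_seed, variant_index=vindex)
    log.info("PRS: threshold %.3g, %d SNPs, incremental R2 %.4f, empirical "
             "p %.4g (%d permutations)", model.threshold, model.n_snps,
             model.fit_r2, emp_p, config.n_perm)

    score = prs.score(adose, model.weights, vindex)
    analysis = analysis.assign(prs=score)

    fs_crude = mr.first_stage_f(exposure, score, None)
    fs_adj = mr.first_stage_f(exposure, score, covariates)
    log.info("first-stage F: crude %.1f, adjusted %.1f",
             fs_crude.f_stat, fs_adj.f_stat)

    # ---- observational + descriptive ----
    obs_rows = []
    for outcome in OUTCOMES:
        for adj in config.adjustments:
            try:
                obs_rows.append(epi.observational_assoc(
                    analysis, outcome, adj, pc_cols).to_row())
            except (ValueError, KeyError) as exc:
                obs_rows.append({"outcome": outcome, "adjustment": adj,
                                 "note": f"unavailable: {exc}"})
    observational = pd.DataFrame(obs_rows)
    analysis["normal_weight"] = (analysis["bmi"] < 25).astype(int)
    descriptive = epi.descriptive_table(
        analysis,
        ["age", "sex", "alcohol", "smoking_current", "smoking_former",
         "adiponectin", "bmi"] + OUTCOMES,
        group_col="normal_weight")

    # ---- causal estimates: outcomes x strata x methods x adjustments ----
    estimates = mr_analysis(analysis, pc_cols, config)
    balance = mr.confounder_balance(
        analysis["prs"].to_numpy(),
        analysis[["age", "sex", "bmi", "alcohol", "smoking_current",
                  "smoking_former"]])

    scatter = {}
    avindex = {sid: j for j, sid in enumerate(variants["snp_id"])}
    for outcome in OUTCOMES:
        y = analysis[outcome].to_numpy(dtype=float)
        if outcome in epi.LOG_OUTCOMES:
            y = np.log(y)
        scatter[outcome] = mr.pleiotropy_scatter(
            model, adose, exposure, y, pcs[arows], avindex)

    report_dict = {
        "provenance": {"package": "prsmr", "version": prsmr.__version__,
                       "seed": config.seed, "perm_seed": perm_seed,
                       "runtime_s": round(time.time() - t0, 2)},
        "qc": report.to_dict(),
        "harmonization": harm_report.to_dict(),
        "kinship_flagged_pairs": len(kin_pairs),
        "pca_variance_explained": [float(v) for v in evr],
        "prs": {"threshold": model.threshold, "n_snps": model.n_snps,
                "fit_r2": model.fit_r2, "empirical_p": emp_p,
                "grid": {f"{t:.3g}": r for t, r in model.grid.items()}},
        "first_stage": {"crude_f": fs_crude.f_stat, "adjusted_f": fs_adj.f_stat,
                        "r2_partial": fs_adj.r2_partial},
        "n_analysis": len(analysis),
    }
    result = {"report": report_dict, "estimates": estimates,
              "observational": observational, "descriptive": descriptive,
              "balance": balance, "scatter": scatter, "model": model,
              "kinship_pairs": kin_pairs, "analysis": analysis,
              "variants": variants, "dosages": adose}
    if write:
        _write_outputs(out, result, config)
    return result


def mr_analysis(analysis: pd.DataFrame, pc_cols: list[str],
                config: PipelineConfig) -> pd.DataFrame:
    """Estimate tables for every outcome x stratum x method x adjustment.

    Standardization of exposure and continuous outcomes happens on each
    outcome's full analysis sample (after its exclusions), before
    stratification, so stratum effects share the per-SD scale.
    """
    rows = []
    for outcome in OUTCOMES:
        binary = outcome in BINARY
        for adj in config.adjustments:
            try:
                sub, cols, excl = epi.analysis_frame(
                    analysis, outcome, adj, pc_cols)
            except (ValueError, KeyError) as exc:
                rows.append({"outcome": outcome, "adjustment": adj,
                             "note": f"unavailable: {exc}"})
                continue
            expo = epi.zstandardize(sub["adiponectin"].to_numpy(), log_first=True)
            y = sub[outcome].to_numpy(dtype=float)
            if not binary:
                y = epi.zstandardize(y, log_first=outcome in epi.LOG_OUTCOMES)
            z = sub["prs"].to_numpy(dtype=float)
            for method in config.methods:
                if method == "tsls":
                    fn = mr.two_stage_binary if binary else mr.tsls
                    kwargs = ({"bootstrap": config.bootstrap,
                               "seed": config.seed} if binary else {})
                else:
                    fn = mr.gmm_binary if binary else mr.gmm_continuous
                    kwargs = {}
                ests = mr.run_stratified(sub, y, expo, z, cols, fn,
                                         strata=tuple(config.strata),
                                         outcome=outcome, adjustment=adj,
                                         estimator_kwargs=kwargs)
                rows.extend(e.to_row() for e in ests)
    return pd.DataFrame(rows)


def _setup_log(out: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(out / "pipeline.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def _write_outputs(out: Path, result: dict, config: PipelineConfig) -> None:
    float_fmt = "%.10g"
    result["estimates"].to_csv(out / "estimates.tsv", sep="\t", index=False,
                               float_format=float_fmt)
    result["observational"].to_csv(out / "observational.tsv", sep="\t",
                                   index=False, float_format=float_fmt)
    result["descriptive"].to_csv(out / "descriptive.tsv", sep="\t",
                                 index=False, float_format=float_fmt)
    result["balance"].to_csv(out / "balance.tsv", sep="\t", index=False,
                             float_format=float_fmt)
    result["kinship_pairs"].to_csv(out / "kinship_flagged.tsv", sep="\t",
                                   index=False, float_format=float_fmt)
    for outcome, tab in result["scatter"].items():
        tab.to_csv(out / f"scatter_{outcome}.tsv", sep="\t", index=False,
                   float_format=float_fmt)
    result["model"].to_files(out / "prs")
    scores = result["analysis"][["sample_id", "prs"]].rename(
        columns={"sample_id": "IID", "prs": "score"})
    scores.insert(0, "FID", scores["IID"])
    scores.to_csv(out / "scores.tsv", sep="\t", index=False,
                  float_format=float_fmt)
    (out / "report.json").write_text(json.dumps(result["report"], indent=2))
    config.to_yaml(out / "config.yaml")
    log.info("outputs written to %s", out)
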