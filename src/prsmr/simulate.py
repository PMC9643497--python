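"""Synthetic genotype/phenotype generator with known causal architecture.

The generator emulates the study design of a one-sample MR analysis of
circulating adiponectin in a sub-Saharan African T2D case-control cohort:

* LD-structured diploid genotypes in blocks, with optional subpopulation
  allele-frequency divergence so genetic principal components capture
  population structure;
* an external base GWAS of log-adiponectin (sex-combined meta-analysis
  scale, default N = 29,347) whose true per-allele effects are known;
* a target cohort with a log-normal exposure partly determined by a sparse
  set of instrument SNPs, seven continuous cardiometabolic outcomes, two
  binary outcomes, shared unobserved confounding, covariates, and
  case-control ascertainment on T2D (default case share 0.48).

Everything the analysis modules later have to estimate (per-variant effects,
the causal effect of the exposure on each outcome, confounder loadings,
pleiotropic variants) is recorded in :class:`TrueParams` and never consumed
by the analysis code itself.

LD model
--------
Within a block all variants share one minor-allele frequency and each
haplotype copies its previous allele with probability ``s`` (else a fresh
Bernoulli draw), giving adjacent-genotype correlation exactly ``s`` and
hence adjacent r^2 = s^2 = ``target_adjacent_r2``.  Blocks are independent
and separated by > 1 Mb so LD never crosses a clumping window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from prsmr import plinkio

CONTINUOUS_OUTCOMES = ["homa_ir", "hdl", "ldl", "total_cholesterol",
                       "triglycerides", "sbp", "dbp"]
BINARY_OUTCOMES = ["t2d", "hypertension"]
OUTCOMES = CONTINUOUS_OUTCOMES + BINARY_OUTCOMES

#: sign of the latent confounder's loading per outcome; mirrors the
#: direction of the observational associations the design emulates
#: (inverse for insulin resistance, triglycerides and T2D).
_CONFOUNDER_SIGN = {
    "homa_ir": -1.0, "hdl": 1.0, "ldl": 1.0, "total_cholesterol": 1.0,
    "triglycerides": -1.0, "sbp": 1.0, "dbp": 1.0, "t2d": -1.0,
    "hypertension": 1.0,
}

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _default_causal_beta() -> dict[str, float]:
    # headline architecture: a positive causal effect on LDL, null elsewhere
    d = {o: 0.0 for o in OUTCOMES}
    d["ldl"] = 0.55
    return d


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_samples: int = 2000
    n_variants: int = 5000
    n_blocks: int = 250
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_adjacent_r2: float = 0.5
    n_instrument_snps: int = 50
    instrument_variance_fraction: float = 0.03
    causal_beta: dict[str, float] = field(default_factory=_default_causal_beta)
    confounder_effect_exposure: float = 0.3
    confounder_effect_outcome: float = 0.3
    pleiotropy_fraction: float = 0.0
    pleiotropy_effect: float = 0.0
    base_gwas_n: int = 29347
    case_fraction: float = 0.48
    n_subpops: int = 3
    subpop_fst: float = 0.02
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0 or self.n_blocks <= 0:
            raise ValueError("n_samples, n_variants and n_blocks must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.target_adjacent_r2 < 1.0):
            raise ValueError("target_adjacent_r2 must be in [0, 1)")
        if not (0 <= self.n_instrument_snps <= self.n_variants):
            raise ValueError("n_instrument_snps must be in [0, n_variants]")
        if not (0.0 <= self.instrument_variance_fraction < 1.0):
            raise ValueError("instrument_variance_fraction must be in [0, 1)")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if isinstance(self.causal_beta, (int, float)):
            self.causal_beta = {o: float(self.causal_beta) for o in OUTCOMES}
        else:
            unknown = set(self.causal_beta) - set(OUTCOMES)
            if unknown:
                raise ValueError(f"causal_beta for unknown outcomes: {sorted(unknown)}")
            self.causal_beta = {o: float(self.causal_beta.get(o, 0.0)) for o in OUTCOMES}
        if self.base_gwas_n <= 0:
            raise ValueError("base_gwas_n must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        var_left = (1.0 - self.instrument_variance_fraction
                    - self.confounder_effect_exposure ** 2)
        if var_left <= 0:
            raise ValueError("instrument variance fraction plus squared confounder "
                             "loading must leave positive residual exposure variance")


@dataclass
class TrueParams:
    """Ground truth of one simulated dataset; for tests only, never for analysis."""

    beta_exposure: np.ndarray          # per-allele effect on the standardized log-exposure
    instrument_snps: list[str]
    causal_beta: dict[str, float]
    confounder_effect_exposure: float
    confounder_effect_outcome: float
    pleiotropic_snps: list[str]
    pleiotropy_effect: float

    def to_json(self, path: str | Path, variants: pd.DataFrame | None = None) -> Path:
        payload = {
            "causal_beta": self.causal_beta,
            "confounder_effect_exposure": self.confounder_effect_exposure,
            "confounder_effect_outcome": self.confounder_effect_outcome,
            "instrument_snps": self.instrument_snps,
            "pleiotropic_snps": self.pleiotropic_snps,
            "pleiotropy_effect": self.pleiotropy_effect,
            "beta_exposure": {},
        }
        if variants is not None:
            nz = np.flatnonzero(self.beta_exposure)
            payload["beta_exposure"] = {
                str(variants["snp_id"].iloc[j]): float(self.beta_exposure[j]) for j in nz
            }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def simulate_genotypes(config: SimulationConfig,
                       n_samples: int | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw LD-structured diploid dosages plus a variant table.

    Returns ``(dosages, variants)``: dosages are A1-allele counts in
    {0, 1, 2} (NaN where masked missing), samples x variants; the variant
    table carries snp_id, chrom, pos, a1, a2, maf (generating frequency)
    and block index.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_samples if n_samples is not None else config.n_samples
    m, n_blocks = config.n_variants, min(config.n_blocks, config.n_variants)
    s = math.sqrt(config.target_adjacent_r2)

    block_sizes = np.full(n_blocks, m // n_blocks)
    block_sizes[: m % n_blocks] += 1
    lo, hi = config.maf_range
    block_maf = rng.uniform(lo, hi, size=n_blocks)

    # subpopulation allele frequencies: Balding-Nichols beta draws around
    # the block MAF, one frequency per (block, subpop)
    subpop = np.arange(n) % max(config.n_subpops, 1)
    k_sub = max(config.n_subpops, 1)
    if k_sub > 1 and config.subpop_fst > 0:
        fst = config.subpop_fst
        a = block_maf * (1 - fst) / fst
        b = (1 - block_maf) * (1 - fst) / fst
        freqs = np.clip(rng.beta(a[:, None], b[:, None], size=(n_blocks, k_sub)),
                        1e-4, 1 - 1e-4)
    else:
        freqs = np.repeat(block_maf[:, None], k_sub, axis=1)

    dosages = np.empty((n, m), dtype=np.float64)
    chrom = np.empty(m, dtype=np.int64)
    pos = np.empty(m, dtype=np.int64)
    block_of = np.empty(m, dtype=np.int64)
    chrom_cursor = {c: 1_000_000 for c in range(1, 23)}
    col = 0
    p_sample = freqs[:, subpop]  # (n_blocks, n) per-sample generating frequency
    for blk, size in enumerate(block_sizes):
        p = p_sample[blk]  # (n,)
        hap = np.empty((2, n, size))
        hap[:, :, 0] = rng.random((2, n)) < p
        if size > 1:
            copy = rng.random((2, n, size - 1)) < s
            fresh = (rng.random((2, n, size - 1)) < p[None, :, None]).astype(float)
            for j in range(1, size):
                hap[:, :, j] = np.where(copy[:, :, j - 1], hap[:, :, j - 1],
                                        fresh[:, :, j - 1])
        dosages[:, col:col + size] = hap.sum(axis=0)
        c = 1 + blk % 22
        start = chrom_cursor[c]
        pos[col:col + size] = start + 5_000 * np.arange(size)
        chrom_cursor[c] = start + 5_000 * size + 2_000_000  # > clump window apart
        chrom[col:col + size] = c
        block_of[col:col + size] = blk
        col += size

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    a1_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    a1 = _BASES[a1_idx]
    a2 = _BASES[(a1_idx + shift) % 4]
    variants = pd.DataFrame({
        "snp_id": [f"rs{j + 1:07d}" for j in range(m)],
        "chrom": chrom, "pos": pos, "a1": a1, "a2": a2,
        "maf": np.minimum(block_maf, 1 - block_maf)[block_of],
        "block": block_of,
    })
    return dosages, variants


def draw_true_effects(config: SimulationConfig, dosages: np.ndarray,
                      variants: pd.DataFrame, rng: np.random.Generator,
                      ) -> np.ndarray:
    """Per-allele effects on the standardized log-exposure.

    One instrument SNP per block (so clumping keeps them distinct), scaled
    so that jointly they explain ``instrument_variance_fraction`` of the
    exposure variance in this cohort.
    """
    m = dosages.shape[1]
    beta = np.zeros(m)
    if config.n_instrument_snps == 0:
        return beta
    blocks = variants["block"].values
    uniq = np.unique(blocks)
    if config.n_instrument_snps > uniq.size:
        raise ValueError("need at least as many LD blocks as instrument SNPs")
    chosen_blocks = rng.choice(uniq, size=config.n_instrument_snps, replace=False)
    idx = np.array([rng.choice(np.flatnonzero(blocks == b)) for b in chosen_blocks])
    raw = rng.normal(0.0, 1.0, size=idx.size)
    raw[np.abs(raw) < 0.2] = 0.2 * np.sign(raw[np.abs(raw) < 0.2] + 1e-12)
    g = _genetic_value(dosages[:, idx], raw)
    v = g.var()
    if v <= 0:
        raise ValueError("instrument SNPs carry no dosage variance")
    beta[idx] = raw * math.sqrt(config.instrument_variance_fraction / v)
    return beta


def _genetic_value(dosages: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Sum of beta * dosage with missing entries replaced by the variant mean."""
    d = dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan = np.isnan(d)
    d[nan] = np.broadcast_to(col_mean, d.shape)[nan]
    return d @ beta


def simulate_base_gwas(config: SimulationConfig, variants: pd.DataFrame,
                       true_beta: np.ndarray, rng: np.random.Generator,
                       ) -> pd.DataFrame:
    """Base summary statistics for a standardized trait at sample size N.

    ``SE = 1/sqrt(2 N p (1-p))``; the observed beta is the true per-allele
    effect plus normal noise with that SE; P is the two-sided normal test;
    INFO is uniform on [0.3, 1] so the INFO < 0.8 filter removes variants.
    """
    from scipy.stats import norm

    if config.base_gwas_n <= 0:
        raise ValueError("base_gwas_n must be positive")
    m = len(variants)
    eaf = np.clip(variants["maf"].values + rng.normal(0, 0.005, size=m), 0.01, 0.99)
    se = 1.0 / np.sqrt(2.0 * config.base_gwas_n * eaf * (1.0 - eaf))
    beta = true_beta + rng.normal(0.0, se)
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame({
        "SNP": variants["snp_id"].values,
        "CHR": variants["chrom"].values,
        "BP": variants["pos"].values,
        "A1": variants["a1"].values,
        "A2": variants["a2"].values,
        "EAF": eaf,
        "BETA": beta,
        "SE": se,
        "P": np.clip(p, 1e-320, 1.0),
        "N": config.base_gwas_n,
        "INFO": rng.uniform(0.3, 1.0, size=m),
    })


def simulate_cohort(config: SimulationConfig, dosages: np.ndarray,
                    variants: pd.DataFrame, true_beta: np.ndarray,
                    rng: np.random.Generator,
                    ) -> tuple[pd.DataFrame, TrueParams]:
    """Phenotypes, covariates and outcomes for a case-control target cohort.

    ``dosages`` is the simulated *pool* (may be larger than
    ``config.n_samples``); T2D cases are oversampled from it until the case
    share matches ``case_fraction``.  The returned table carries a
    ``pool_row`` column indexing the pool rows that were kept.
    """
    n_pool = dosages.shape[0]
    n = config.n_samples
    if n_pool < n:
        raise ValueError(f"pool of {n_pool} smaller than requested cohort of {n}")

    U = rng.normal(0.0, 1.0, size=n_pool)
    ivf = config.instrument_variance_fraction
    g = _genetic_value(dosages, true_beta)
    g = g - g.mean()
    gx, gy = config.confounder_effect_exposure, config.confounder_effect_outcome
    eps_sd = math.sqrt(max(1.0 - ivf - gx ** 2, 1e-12))
    x_std = g + gx * U + rng.normal(0.0, eps_sd, size=n_pool)
    adiponectin = np.exp(8.93 + 1.0 * x_std)  # ng/ml, median ~ 7.5e3

    # covariates (age/sex/BMI/alcohol/smoking/medication); BMI loads on the
    # confounder, not on the genotypes, so the score stays balance-testable
    age = np.clip(rng.normal(54.2, 10.0, size=n_pool), 25, 90)
    sex = (rng.random(n_pool) < 0.624).astype(int)  # 1 = female
    bmi = np.clip(27.4 + 4.7 * (0.3 * U + math.sqrt(1 - 0.09)
                                * rng.normal(size=n_pool)), 15, 55)
    smoke_draw = rng.random(n_pool)
    smoking_current = (smoke_draw < 0.037).astype(int)
    smoking_former = ((smoke_draw >= 0.037) & (smoke_draw < 0.037 + 0.116)).astype(int)
    alcohol = (rng.random(n_pool) < 0.272).astype(int)
    lipid_med = (rng.random(n_pool) < 0.012).astype(int)

    cov_shift = 0.01 * (age - 54.2) + 0.1 * sex + 0.02 * (bmi - 27.4)

    # pleiotropy: a fraction of instrument SNPs act on outcomes directly
    inst_idx = np.flatnonzero(true_beta)
    n_pleio = int(round(config.pleiotropy_fraction * inst_idx.size))
    pleio_idx = (rng.choice(inst_idx, size=n_pleio, replace=False)
                 if n_pleio else np.array([], dtype=int))
    pleio_shift = (_genetic_value(dosages[:, pleio_idx],
                                  np.full(n_pleio, config.pleiotropy_effect))
                   if n_pleio else 0.0)

    def latent(outcome: str, extra_sd: float = 1.0) -> np.ndarray:
        return (config.causal_beta[outcome] * x_std
                + _CONFOUNDER_SIGN[outcome] * gy * U
                + cov_shift + pleio_shift
                + rng.normal(0.0, extra_sd, size=n_pool))

    hdl = 42.9 + 11.0 * latent("hdl")
    ldl = 132.1 + 35.0 * latent("ldl")
    tc = 203.3 + 40.0 * latent("total_cholesterol")
    tg = np.exp(math.log(98.0) + 0.45 * latent("triglycerides"))
    z_sbp = latent("sbp") + 0.5 * config.causal_beta["hypertension"] * x_std
    z_dbp = latent("dbp") + 0.5 * config.causal_beta["hypertension"] * x_std
    sbp = np.clip(138.2 + 20.0 * z_sbp, 80, 260)
    dbp = np.clip(82.8 + 11.0 * z_dbp, 40, 160)
    bp_med = (rng.random(n_pool) < np.where(z_sbp > 0, 0.35, 0.15)).astype(int)
    hypertension = ((sbp >= 130) | (dbp >= 80) | (bp_med == 1)).astype(int)

    # T2D: logistic latent on the standardized exposure and confounder, made
    # consistent with the fasting-glucose rule (>= 7.0 mmol/L or medication)
    lin = (config.causal_beta["t2d"] * x_std + _CONFOUNDER_SIGN["t2d"] * gy * U
           + 0.03 * (bmi - 27.4) + 0.02 * (age - 54.2))
    prev_target = min(0.30, config.case_fraction)
    alpha = _match_prevalence(lin, prev_target)
    t2d = (rng.random(n_pool) < expit(alpha + lin)).astype(int)
    glucose_med = np.where(t2d == 1, (rng.random(n_pool) < 0.4), False).astype(int)
    glucose = np.where(
        t2d == 1,
        7.0 + rng.exponential(2.0, size=n_pool),
        np.clip(rng.normal(5.2, 0.7, size=n_pool), 3.2, 6.9),
    )
    # medicated cases may be controlled below the diagnostic cut
    controlled = (glucose_med == 1) & (rng.random(n_pool) < 0.5)
    glucose = np.where(controlled, np.clip(rng.normal(6.0, 0.5, size=n_pool), 4.0, 6.9),
                       glucose)
    t2d = ((glucose >= 7.0) | (glucose_med == 1)).astype(int)

    insulin = np.exp(math.log(6.0) + 0.6 * latent("homa_ir", extra_sd=0.8))
    homa_ir = insulin * glucose / 22.5

    # case-control ascertainment: oversample cases to the target share
    n_cases = int(round(config.case_fraction * n))
    case_rows = np.flatnonzero(t2d == 1)
    ctrl_rows = np.flatnonzero(t2d == 0)
    if case_rows.size < n_cases or ctrl_rows.size < n - n_cases:
        raise ValueError(
            f"case_fraction {config.case_fraction} unreachable: pool has "
            f"{case_rows.size} cases / {ctrl_rows.size} controls for a cohort "
            f"of {n}; enlarge the pool or shrink the effects")
    keep = np.concatenate([rng.choice(case_rows, size=n_cases, replace=False),
                           rng.choice(ctrl_rows, size=n - n_cases, replace=False)])
    keep.sort()

    cohort = pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "pool_row": keep,
        "adiponectin": adiponectin[keep],
        "homa_ir": homa_ir[keep],
        "hdl": hdl[keep], "ldl": ldl[keep], "total_cholesterol": tc[keep],
        "triglycerides": tg[keep], "sbp": sbp[keep], "dbp": dbp[keep],
        "t2d": t2d[keep], "hypertension": hypertension[keep],
        "glucose": glucose[keep], "insulin": insulin[keep],
        "age": age[keep], "sex": sex[keep], "bmi": bmi[keep],
        "alcohol": alcohol[keep],
        "smoking_current": smoking_current[keep],
        "smoking_former": smoking_former[keep],
        "bp_med": bp_med[keep], "glucose_med": glucose_med[keep],
        "lipid_med": lipid_med[keep],
        "subpop": (keep % max(config.n_subpops, 1)),
    })
    truth = TrueParams(
        beta_exposure=true_beta,
        instrument_snps=[variants["snp_id"].iloc[j] for j in inst_idx],
        causal_beta=dict(config.causal_beta),
        confounder_effect_exposure=gx,
        confounder_effect_outcome=gy,
        pleiotropic_snps=[variants["snp_id"].iloc[j] for j in pleio_idx],
        pleiotropy_effect=config.pleiotropy_effect if n_pleio else 0.0,
    )
    return cohort, truth


def _match_prevalence(lin: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + lin)) == target (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + lin).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(config: SimulationConfig, pool_factor: float = 3.0,
                     ) -> dict:
    """One call that yields an aligned, analysis-ready synthetic study.

    Returns a dict with keys ``dosages`` (cohort rows only), ``variants``,
    ``base_gwas``, ``cohort``, ``truth``.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pool = max(config.n_samples, int(math.ceil(config.n_samples * pool_factor)))
    pool_dosages, variants = simulate_genotypes(config, n_samples=n_pool, rng=rng)
    true_beta = draw_true_effects(config, pool_dosages, variants, rng)
    base_gwas = simulate_base_gwas(config, variants, true_beta, rng)
    cohort, truth = simulate_cohort(config, pool_dosages, variants, true_beta, rng)
    dosages = pool_dosages[cohort["pool_row"].values]
    cohort = cohort.drop(columns=["pool_row"]).reset_index(drop=True)
    return {"dosages": dosages, "variants": variants, "base_gwas": base_gwas,
            "cohort": cohort, "truth": truth, "config": config}


def write_dataset(cohort: pd.DataFrame, dosages: np.ndarray,
                  variants: pd.DataFrame, base_gwas: pd.DataFrame,
                  directory: str | Path, truth: TrueParams | None = None,
                  ) -> dict[str, Path]:
    """Persist a simulated study: PLINK triplet, TSV tables, truth JSON."""
    directory = plinkio.ensure_writable(directory)
    paths = plinkio.write_bed(directory / "genotypes", dosages, variants,
                              list(cohort["sample_id"]))
    paths["base_gwas"] = plinkio.write_gwas(directory / "base_gwas.tsv", base_gwas)
    paths["phenotypes"] = plinkio.write_phenotypes(directory / "phenotypes.tsv", cohort)
    if truth is not None:
        paths["truth"] = truth.to_json(directory / "truth.json", variants)
    return paths


# ---------------------------------------------------------------------------
# lightweight IV benchmark generator (estimator calibration studies)
# ---------------------------------------------------------------------------

def simulate_iv_dataset(n: int, beta: float, rng: np.random.Generator, *,
                        instrument_r2: float = 0.05,
                        confounding: float = 0.4,
                        binary: bool = False,
                        heteroskedastic: bool = False,
                        n_covariates: int = 2,
                        ) -> dict[str, np.ndarray]:
    """Small direct structural-equation draw for estimator calibration.

    z is a genotype-score-like instrument explaining ``instrument_r2`` of
    var(x); U is a shared confounder loading ``confounding`` on both x and
    the outcome, so the OLS slope of y on x is biased upward by about
    ``confounding**2`` while a valid IV is not.  With ``binary=True`` the
    outcome is Bernoulli with logit = beta * x + confounding * U.
    """
    z = rng.normal(size=n)
    U = rng.normal(size=n)
    C = rng.normal(size=(n, n_covariates))
    a = math.sqrt(instrument_r2)
    ex_sd = math.sqrt(max(1.0 - instrument_r2 - confounding ** 2, 1e-9))
    x = a * z + confounding * U + ex_sd * rng.normal(size=n)
    lin = beta * x + confounding * U + C @ np.full(n_covariates, 0.1)
    if binary:
        y = (rng.random(n) < expit(lin)).astype(float)
    else:
        err_sd = 0.3 + 0.7 * np.abs(x) if heteroskedastic else 1.0
        y = lin + err_sd * rng.normal(size=n)
    return {"y": y, "x": x, "z": z, "covariates": C, "confounder": U}
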