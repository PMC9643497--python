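"""Clumping-and-thresholding polygenic score construction.

The instrument is built the C+T way: greedy LD clumping keeps the most
significant SNP per LD region (the target cohort is its own LD reference
panel), then a grid of p-value cutoffs is scanned and the cutoff whose
score best improves model fit for the exposure — incremental R^2 over a
covariate-only regression — wins.  Statistical significance of the selected
score is assessed with a permutation-based empirical p-value (the exposure
is permuted, the entire grid optimization is re-run each time).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_GRID = (5e-8, 1e-6, 1e-5, 1e-4, 5e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def fine_grid(p_min: float = 5e-8, p_max: float = 1.0, n: int = 100) -> np.ndarray:
    """Log-spaced dense threshold grid (PRSice-style fine scan)."""
    return np.logspace(math.log10(p_min), math.log10(p_max), n)


@dataclass
class ClumpParams:
    p_index_max: float = 1.0
    r2_max: float = 0.1
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_max < 1.0):
            raise ValueError("r2_max must be in [0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class PRSModel:
    """The fitted instrument: cutoff, per-variant weights, fit statistics."""

    threshold: float
    weights: pd.DataFrame       # snp_id, effect_allele, beta, p
    n_snps: int
    fit_r2: float               # incremental R^2 over the covariate-only model
    empirical_p: float | None = None
    grid: dict[float, float] = field(default_factory=dict)  # threshold -> inc R^2

    def to_files(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        wpath = prefix.with_suffix(".weights.tsv")
        self.weights.to_csv(wpath, sep="\t", index=False)
        meta = {"threshold": self.threshold, "n_snps": self.n_snps,
                "fit_r2": self.fit_r2, "empirical_p": self.empirical_p,
                "grid": {f"{t:.6g}": r for t, r in self.grid.items()}}
        jpath = prefix.with_suffix(".model.json")
        jpath.write_text(json.dumps(meta, indent=2))
        return {"weights": wpath, "meta": jpath}


@dataclass
class GeneRegion:
    chrom: str | int
    start: int
    end: int
    flank: int = 250_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")


def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete entries."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("fewer than two pairwise-complete entries")
    x, y = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    vx, vy = x @ x, y @ y
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in a dosage vector")
    r = (x @ y) / math.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def _r2_vector(panel: np.ndarray, idx: int, others: np.ndarray) -> np.ndarray:
    """r^2 between panel column idx and each column in others (pairwise complete)."""
    x = panel[:, idx]
    out = np.empty(others.size)
    Y = panel[:, others]
    okx = ~np.isnan(x)
    for k in range(others.size):
        y = Y[:, k]
        ok = okx & ~np.isnan(y)
        xs, ys = x[ok], y[ok]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        vx, vy = xs @ xs, ys @ ys
        out[k] = 0.0 if vx == 0 or vy == 0 else (xs @ ys) ** 2 / (vx * vy)
    return out


def clump(stats: pd.DataFrame, panel: np.ndarray, params: ClumpParams,
          variant_index: dict[str, int] | None = None) -> pd.DataFrame:
    """Greedy LD clumping of harmonized summary statistics.

    ``stats`` needs snp_id, chrom, pos, P (plus anything else, carried).
    ``panel`` is the LD reference dosage matrix; ``variant_index`` maps
    snp_id to panel column (defaults to row order of ``stats``).

    Repeatedly takes the remaining SNP with the smallest p (ties: position,
    then id), keeps it, and removes every unprocessed SNP on the same
    chromosome within ``window_kb`` whose r^2 with it exceeds ``r2_max``.
    Output is sorted by chromosome and position.
    """
    if len(stats) == 0:
        raise ValueError("no variants to clump")
    df = stats.reset_index(drop=True)
    if variant_index is None:
        variant_index = {sid: i for i, sid in enumerate(df["snp_id"])}
    cols = np.array([variant_index[sid] for sid in df["snp_id"]])

    elig = df["P"].values <= params.p_index_max
    order = df.loc[elig].sort_values(
        ["P", "pos", "snp_id"], kind="mergesort").index.to_numpy()
    alive = np.zeros(len(df), dtype=bool)
    alive[order] = True
    kept: list[int] = []
    window = params.window_kb * 1000.0
    chrom = df["chrom"].values
    pos = df["pos"].values.astype(float)
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        near = np.flatnonzero(alive & (chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= window))
        if near.size:
            r2 = _r2_vector(panel, cols[i], cols[near])
            alive[near[r2 > params.r2_max]] = False
    out = df.loc[kept].sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def score(dosages: np.ndarray, weights: pd.DataFrame,
          variant_index: dict[str, int]) -> np.ndarray:
    """Per-sample weighted allele score.

    score_i = sum_j beta_j * dose_ij; a missing dose is replaced by twice
    the effect-allele frequency among non-missing samples at that variant.
    """
    missing_ids = [s for s in weights["snp_id"] if s not in variant_index]
    if missing_ids:
        raise KeyError(f"weights reference variants absent from dosages: "
                       f"{missing_ids[:5]}{'...' if len(missing_ids) > 5 else ''}")
    cols = np.array([variant_index[s] for s in weights["snp_id"]])
    beta = weights["beta"].to_numpy(dtype=float)
    G = dosages[:, cols].copy()
    col_mean = np.nanmean(G, axis=0)  # = 2 * effect-allele freq among non-missing
    nan = np.isnan(G)
    G[nan] = np.broadcast_to(col_mean, G.shape)[nan]
    return G @ beta


def _covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the span of [1, covariates]."""
    if covariates is None or covariates.size == 0:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), covariates])
    q, r = np.linalg.qr(C)
    return q[:, np.abs(np.diag(r)) > 1e-10]


def incremental_r2(y: np.ndarray, s: np.ndarray,
                   covariates: np.ndarray | None) -> float:
    """R^2 gain of adding score ``s`` to a covariate-only regression of y."""
    q = _covariate_basis(covariates, y.size)
    y_res = y - q @ (q.T @ y)
    s_res = s - q @ (q.T @ s)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    denom = float(s_res @ s_res)
    if ss_tot == 0 or denom == 0:
        return 0.0
    return float((s_res @ y_res) ** 2 / denom / ss_tot)


def _threshold_scores(stats: pd.DataFrame, dosages: np.ndarray,
                      variant_index: dict[str, int], grid: np.ndarray,
                      ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Scores for every usable grid threshold.

    Returns (usable thresholds, per-threshold weight row indices,
    score matrix n x T).
    """
    p = stats["P"].values
    thresholds, idx_sets, scores = [], [], []
    for t in np.sort(np.asarray(grid, dtype=float)):
        rows = np.flatnonzero(p <= t)
        if rows.size == 0:
            continue
        thresholds.append(t)
        idx_sets.append(rows)
        w = stats.iloc[rows][["snp_id", "beta_aligned"]].rename(
            columns={"beta_aligned": "beta"})
        scores.append(score(dosages, w, variant_index))
    if not thresholds:
        raise ValueError("no SNP survives any threshold in the grid")
    return np.array(thresholds), idx_sets, np.column_stack(scores)


def optimize_threshold(stats: pd.DataFrame, dosages: np.ndarray,
                       exposure: np.ndarray,
                       covariates: np.ndarray | None,
                       grid: np.ndarray | tuple = DEFAULT_GRID,
                       variant_index: dict[str, int] | None = None,
                       ) -> PRSModel:
    """Pick the p-value cutoff whose score maximizes incremental R^2.

    ``stats`` are harmonized, clumped summary statistics (snp_id,
    effect_allele, beta_aligned, P).  Ties favour the smaller threshold.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if variant_index is None:
        variant_index = {sid: i for i, sid in enumerate(stats["snp_id"])}
    thresholds, idx_sets, S = _threshold_scores(stats, dosages, variant_index, grid)
    r2 = np.array([incremental_r2(exposure, S[:, k], covariates)
                   for k in range(thresholds.size)])
    best = int(np.argmax(r2))  # argmax takes the first max; grid sorted ascending
    rows = idx_sets[best]
    weights = stats.iloc[rows][["snp_id", "effect_allele", "beta_aligned", "P"]]
    weights = weights.rename(columns={"beta_aligned": "beta", "P": "p"})
    return PRSModel(threshold=float(thresholds[best]),
                    weights=weights.reset_index(drop=True),
                    n_snps=len(rows), fit_r2=float(r2[best]),
                    grid=dict(zip(thresholds.tolist(), r2.tolist())))


def empirical_pvalue(stats: pd.DataFrame, dosages: np.ndarray,
                     exposure: np.ndarray, covariates: np.ndarray | None,
                     grid: np.ndarray | tuple = DEFAULT_GRID,
                     n_perm: int = 10_000, seed: int = 0,
                     variant_index: dict[str, int] | None = None,
                     ) -> tuple[float, PRSModel]:
    """Permutation-based empirical p for the optimized score.

    The exposure is permuted ``n_perm`` times (covariates and genotypes
    fixed); the full grid optimization is re-run on each permutation and
    empirical p = (1 + #{permuted best R^2 >= observed}) / (n_perm + 1).

    The per-permutation grid scan uses the projected-residual identity: with
    Q an orthonormal covariate basis and s~_t each threshold score
    residualized on Q, the incremental R^2 of threshold t for permuted y is
    (s~_t' y~)^2 / (s~_t' s~_t) / SS_tot — dot products only, numerically
    identical to refitting both regressions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if variant_index is None:
        variant_index = {sid: i for i, sid in enumerate(stats["snp_id"])}
    model = optimize_threshold(stats, dosages, exposure, covariates, grid,
                               variant_index)
    thresholds, _, S = _threshold_scores(stats, dosages, variant_index,
                                         np.asarray(grid, dtype=float))
    n = exposure.size
    q = _covariate_basis(covariates, n)
    S_res = S - q @ (q.T @ S)
    s_norm = (S_res ** 2).sum(axis=0)
    usable = s_norm > 0
    ss_tot = float(((exposure - exposure.mean()) ** 2).sum())

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        y = rng.permutation(exposure)
        y_res = y - q @ (q.T @ y)
        num = (S_res[:, usable].T @ y_res) ** 2
        best = (num / s_norm[usable]).max() / ss_tot
        count += best >= model.fit_r2
    p = (1.0 + count) / (n_perm + 1.0)
    model.empirical_p = float(p)
    return float(p), model


def count_snps_near_gene(model: PRSModel, variants: pd.DataFrame,
                         region: GeneRegion) -> int:
    """Model SNPs on region.chrom with pos in [start-flank, end+flank]."""
    pos_map = variants.set_index("snp_id")
    missing = [s for s in model.weights["snp_id"] if s not in pos_map.index]
    if missing:
        raise KeyError(f"unknown variant positions for {missing[:5]}")
    sub = pos_map.loc[model.weights["snp_id"], ["chrom", "pos"]]
    on_chrom = sub["chrom"].astype(str) == str(region.chrom)
    lo, hi = region.start - region.flank, region.end + region.flank
    return int((on_chrom & (sub["pos"] >= lo) & (sub["pos"] <= hi)).sum())
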