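"""Variant/sample quality control, allele harmonization, kinship and PCs.

Implements the standard pre-PRS QC stack for a base-GWAS-plus-target-cohort
design: marker filters (missingness, MAF, Hardy-Weinberg exact test, INFO),
sample filters (missingness, heterozygosity F coefficient), base/target
allele harmonization with strand flipping, relatedness pruning with a
KING-robust kinship estimator, and genetic principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: second-/first-degree kinship cutoffs on the KING scale
KINSHIP_SECOND_DEGREE = 0.0884


@dataclass
class QCThresholds:
    """Filter thresholds; defaults follow common PRS-protocol practice."""

    maf_min: float = 0.01
    marker_missing_max: float = 0.01
    sample_missing_max: float = 0.01
    hwe_p_min: float = 1e-6
    info_min: float = 0.8
    het_sd: float = 3.0
    kinship_second_degree: float = KINSHIP_SECOND_DEGREE

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_missing_max", "sample_missing_max",
                     "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.het_sd <= 0 or self.kinship_second_degree <= 0:
            raise ValueError("het_sd and kinship_second_degree must be positive")


@dataclass
class HarmonizationReport:
    n_matched: int = 0
    n_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_duplicate: int = 0
    n_dropped_mismatch: int = 0

    @property
    def n_shared(self) -> int:
        return (self.n_matched + self.n_dropped_ambiguous
                + self.n_dropped_duplicate + self.n_dropped_mismatch)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_shared"] = self.n_shared
        return d


@dataclass
class QCReport:
    """Per-filter removal counts; filters apply sequentially, no double count."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    variants_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    n_variants_out: int = 0
    n_samples_out: int = 0

    def check_conservation(self) -> bool:
        ok_v = (self.n_variants_out + sum(self.variants_removed.values())
                == self.n_variants_in)
        ok_s = (self.n_samples_out + sum(self.samples_removed.values())
                == self.n_samples_in)
        # a side never filtered carries no removal entries and keeps out == 0
        if not self.variants_removed and self.n_variants_out == 0:
            ok_v = True
        if not self.samples_removed and self.n_samples_out == 0:
            ok_s = True
        return ok_v and ok_s

    def to_dict(self) -> dict:
        return asdict(self)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_variants(base: pd.DataFrame, target: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align base effect alleles to the target's A1 allele.

    base: columns SNP, A1 (effect), A2, BETA (plus any others, carried along).
    target: columns snp_id, a1, a2.

    Rules, per shared id: duplicated ids (in either set) dropped entirely;
    palindromic (A/T, C/G) variants dropped; exact allele match kept;
    match after complementing both target alleles kept and counted as a
    strand flip; the aligned beta's sign flips when the base effect allele
    corresponds to the target's a2.  Anything else is an allele mismatch.
    """
    base_ids = base["SNP"].astype(str)
    targ_ids = target["snp_id"].astype(str)
    shared = set(base_ids) & set(targ_ids)
    if not shared:
        raise ValueError("no shared variant ids between base and target")

    dup = (set(base_ids[base_ids.duplicated(keep=False)])
           | set(targ_ids[targ_ids.duplicated(keep=False)])) & shared
    rep = HarmonizationReport(n_dropped_duplicate=len(dup))

    b = base.set_index(base_ids)[["A1", "A2", "BETA"]]
    t = target.set_index(targ_ids)[["a1", "a2"]]
    rows = []
    for sid in shared - dup:
        ea, oa = str(b.at[sid, "A1"]).upper(), str(b.at[sid, "A2"]).upper()
        ta1, ta2 = str(t.at[sid, "a1"]).upper(), str(t.at[sid, "a2"]).upper()
        if _is_palindromic(ea, oa) or _is_palindromic(ta1, ta2):
            rep.n_dropped_ambiguous += 1
            continue
        beta = float(b.at[sid, "BETA"])
        flipped = False
        if (ea, oa) == (ta1, ta2):
            aligned = beta
        elif (ea, oa) == (ta2, ta1):
            aligned = -beta
        else:
            cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
            if (cea, coa) == (ta1, ta2):
                aligned, flipped = beta, True
            elif (cea, coa) == (ta2, ta1):
                aligned, flipped = -beta, True
            else:
                rep.n_dropped_mismatch += 1
                continue
        rep.n_matched += 1
        rep.n_flipped += int(flipped)
        rows.append((sid, aligned, flipped))

    aligned = pd.DataFrame(rows, columns=["snp_id", "beta_aligned", "strand_flipped"])
    extra = base.set_index(base_ids).loc[aligned["snp_id"]]
    for col in ("EAF", "SE", "P", "N", "INFO"):
        if col in extra.columns:
            aligned[col] = extra[col].values
    # effect allele is now the target a1 by construction
    aligned = aligned.merge(
        target[["snp_id", "a1", "a2"] +
               [c for c in ("chrom", "pos") if c in target.columns]],
        on="snp_id", how="left").rename(columns={"a1": "effect_allele",
                                                 "a2": "other_allele"})
    return aligned.reset_index(drop=True), rep


def variant_metrics(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant call rate, MAF and Hardy-Weinberg exact-test p."""
    n = dosages.shape[0]
    miss = np.isnan(dosages)
    call_rate = 1.0 - miss.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    n_het = np.nansum(dosages == 1, axis=0).astype(int)
    n_hom1 = np.nansum(dosages == 2, axis=0).astype(int)
    n_hom2 = np.nansum(dosages == 0, axis=0).astype(int)
    hwe_p = np.array([hwe_exact_test(h1, het, h2) if (h1 + het + h2) else np.nan
                      for h1, het, h2 in zip(n_hom1, n_het, n_hom2)])
    return pd.DataFrame({"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
                         "n_hom1": n_hom1, "n_het": n_het, "n_hom2": n_hom2})


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts no more probable than
    the observed one, conditional on the allele counts (the standard exact
    HWE test).  Uses the ratio recurrence across heterozygote counts, so the
    whole distribution is evaluated in O(n) without factorials.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible heterozygote counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    probs = np.empty(hets.size)

    def up_ratio(h: int) -> float:
        # P(h+2)/P(h), conditional on allele counts
        return ((n_rare - h) * (2 * n - n_rare - h)) / ((h + 2.0) * (h + 1.0))

    # anchor at the mode and recurse outward so nothing overflows
    mode_i = 0
    while mode_i + 1 < hets.size and up_ratio(int(hets[mode_i])) > 1.0:
        mode_i += 1
    probs[mode_i] = 1.0
    for i in range(mode_i + 1, hets.size):
        probs[i] = probs[i - 1] * up_ratio(int(hets[i - 1]))
    for i in range(mode_i - 1, -1, -1):
        probs[i] = probs[i + 1] / up_ratio(int(hets[i]))
    probs /= probs.sum()
    obs_i = (n_het - het_min) // 2
    p = probs[probs <= probs[obs_i] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_variants(dosages: np.ndarray, variants: pd.DataFrame,
                    th: QCThresholds, info: np.ndarray | None = None,
                    report: QCReport | None = None,
                    ) -> tuple[np.ndarray, QCReport]:
    """Sequential marker filters; returns kept column indices and the report.

    Order: missingness -> MAF -> HWE -> INFO.  Metrics are computed from the
    dosages; INFO comes from the base summary statistics when available.
    """
    m = dosages.shape[1]
    met = variant_metrics(dosages)
    rep = report if report is not None else QCReport(
        n_variants_in=m, n_samples_in=dosages.shape[0])

    keep = np.ones(m, dtype=bool)
    fail = keep & ((1.0 - met["call_rate"].values) > th.marker_missing_max)
    rep.variants_removed["marker_missingness"] = int(fail.sum())
    keep &= ~fail

    fail = keep & (met["maf"].values < th.maf_min)
    rep.variants_removed["maf"] = int(fail.sum())
    keep &= ~fail

    fail = keep & (met["hwe_p"].values < th.hwe_p_min)
    rep.variants_removed["hwe"] = int(fail.sum())
    keep &= ~fail

    if info is not None:
        info = np.asarray(info, dtype=float)
        fail = keep & (info < th.info_min)
        rep.variants_removed["info"] = int(fail.sum())
        keep &= ~fail

    rep.n_variants_out = int(keep.sum())
    return np.flatnonzero(keep), rep


def sample_qc(dosages: np.ndarray, th: QCThresholds,
              report: QCReport | None = None,
              ) -> tuple[pd.DataFrame, np.ndarray, QCReport]:
    """Sample missingness and heterozygosity-F filters.

    het_f = (O_hom - E_hom) / (m - E_hom) per sample, with
    E_hom = sum_j (1 - 2 p_j (1 - p_j)) over that sample's non-missing
    variants; samples with missingness above threshold or |F - mean| beyond
    ``het_sd`` standard deviations are removed.
    """
    n, m = dosages.shape
    if n < 2:
        raise ValueError("sample QC needs at least two samples")
    miss = np.isnan(dosages)
    usable = (~miss).sum(axis=1)
    if (usable == 0).any():
        raise ValueError("sample with zero usable variants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    exp_hom_j = 1.0 - 2.0 * p * (1.0 - p)
    obs_hom = ((dosages == 0) | (dosages == 2)).sum(axis=1)
    e_hom = np.where(~miss, exp_hom_j[None, :], 0.0).sum(axis=1)
    het_f = (obs_hom - e_hom) / (usable - e_hom)

    missingness = miss.mean(axis=1)
    metrics = pd.DataFrame({"call_rate": 1.0 - missingness, "het_f": het_f})

    rep = report if report is not None else QCReport(
        n_variants_in=m, n_samples_in=n)
    keep = np.ones(n, dtype=bool)
    fail = keep & (missingness > th.sample_missing_max)
    rep.samples_removed["sample_missingness"] = int(fail.sum())
    keep &= ~fail

    mu, sd = het_f[keep].mean(), het_f[keep].std(ddof=1)
    fail = keep & (np.abs(het_f - mu) > th.het_sd * sd) if sd > 0 else np.zeros(n, bool)
    rep.samples_removed["heterozygosity"] = int(fail.sum())
    keep &= ~fail

    rep.n_samples_out = int(keep.sum())
    return metrics, np.flatnonzero(keep), rep


def king_kinship(dosages: np.ndarray) -> np.ndarray:
    """Pairwise KING-robust kinship matrix.

    phi_ij = (N_het,het - 2 * N_opposite_hom) / (N_het_i + N_het_j), counted
    over variants non-missing in both samples.  Duplicates/MZ twins give
    ~0.5, parent-offspring ~0.25, unrelated ~0.
    """
    n, m = dosages.shape
    het = (dosages == 1)
    hom0 = (dosages == 0)
    hom2 = (dosages == 2)
    ok = ~np.isnan(dosages)
    hetf = het.astype(np.float32)
    okf = ok.astype(np.float32)
    n_hh = hetf @ hetf.T
    n_opp = hom0.astype(np.float32) @ hom2.astype(np.float32).T
    n_opp = n_opp + n_opp.T
    # het counts restricted to the pairwise-complete variants
    het_i = hetf @ okf.T          # het in i and non-missing in j
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)
    return phi.astype(np.float64)


def remove_related(dosages: np.ndarray, th: QCThresholds,
                   sample_ids: list[str] | None = None,
                   report: QCReport | None = None,
                   ) -> tuple[pd.DataFrame, np.ndarray, QCReport]:
    """Prune to an unrelated set at the second-degree kinship cutoff.

    Flagged pairs are resolved greedily: drop the member with more flagged
    partners; ties broken by lower call rate, then lexicographic id.
    Returns (kinship table of flagged pairs, kept row indices, report).
    """
    n, m = dosages.shape
    if n < 2:
        raise ValueError("relatedness pruning needs at least two samples")
    if m < 200:
        raise ValueError(f"kinship needs >= 200 variants for stability, got {m}")
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    phi = king_kinship(dosages)
    iu, ju = np.triu_indices(n, k=1)
    flagged = phi[iu, ju] > th.kinship_second_degree
    pairs = pd.DataFrame({"id1": np.asarray(ids)[iu[flagged]],
                          "id2": np.asarray(ids)[ju[flagged]],
                          "kinship": phi[iu[flagged], ju[flagged]]})

    call_rate = 1.0 - np.isnan(dosages).mean(axis=1)
    adj: dict[int, set[int]] = {}
    for i, j in zip(iu[flagged], ju[flagged]):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    removed: set[int] = set()
    while True:
        active = {i: {j for j in nb if j not in removed}
                  for i, nb in adj.items() if i not in removed}
        active = {i: nb for i, nb in active.items() if nb}
        if not active:
            break
        worst = max(active, key=lambda i: (len(active[i]), -call_rate[i], ids[i]))
        removed.add(worst)

    keep = np.array([i for i in range(n) if i not in removed], dtype=int)
    rep = report if report is not None else QCReport(
        n_variants_in=m, n_samples_in=n)
    rep.samples_removed["relatedness"] = len(removed)
    rep.n_samples_out = keep.size
    return pairs, keep, rep


def compute_pcs(dosages: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """First k genetic principal components of the standardized dosages.

    Missing entries are mean-imputed (for the PCA only); columns are
    centred and scaled to unit variance; returns (scores n x k, fraction of
    variance explained per component), components ordered by decreasing
    variance.
    """
    n, m = dosages.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    X = dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.broadcast_to(mu, X.shape)[nan]
    X -= mu
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    if k > min(n - 1, int(keep.sum())):
        raise ValueError(f"k={k} exceeds the rank of the dosage matrix")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
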