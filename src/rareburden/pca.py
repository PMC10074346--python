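"""Common-variant QC, LD pruning, and principal components for stratification.

Genotypes are diploid dosage matrices (samples x variants, 0/1/2, negative =
missing).  Defaults mirror standard practice: MAF > 1%, call rate > 99%,
Hardy-Weinberg p > 1e-5, greedy sliding-window pruning at r^2 <= 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QcThresholds", "hwe_test", "qc_filter", "ld_prune", "compute_pcs"]


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    callrate_min: float = 0.99
    hwe_p_min: float = 1e-5
    r2_max: float = 0.4
    window: int = 50
    step: int = 5

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5 and 0 <= self.callrate_min <= 1
                and 0 <= self.hwe_p_min <= 1 and 0 <= self.r2_max <= 1):
            raise ValueError("QC thresholds out of range")
        if self.step < 1 or self.window < self.step:
            raise ValueError("require window >= step >= 1")


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p for Hardy-Weinberg proportions."""
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("no genotypes")
    q = (2 * n_bb + n_ab) / (2 * n)
    if q <= 0 or q >= 1:
        return 1.0  # monomorphic by convention
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, 1))


def _maf(col: np.ndarray) -> float:
    obs = col[col >= 0]
    if obs.size == 0:
        return 0.0
    af = obs.mean() / 2.0
    return min(af, 1.0 - af)


def qc_filter(genotypes: np.ndarray, thresholds: QcThresholds | None = None) -> np.ndarray:
    """Indices of variants passing MAF, call-rate and HWE simultaneously."""
    thr = thresholds or QcThresholds()
    G = np.asarray(genotypes)
    keep = []
    for j in range(G.shape[1]):
        col = G[:, j]
        obs = col[col >= 0]
        if col.size and obs.size / col.size <= thr.callrate_min:
            continue
        if _maf(col) <= thr.maf_min:
            continue
        n_aa = int(np.sum(obs == 0))
        n_ab = int(np.sum(obs == 1))
        n_bb = int(np.sum(obs == 2))
        if hwe_test(n_aa, n_ab, n_bb) <= thr.hwe_p_min:
            continue
        keep.append(j)
    return np.asarray(keep, dtype=int)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = (a >= 0) & (b >= 0)
    if mask.sum() < 3:
        return 0.0
    x, y = a[mask].astype(float), b[mask].astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(genotypes: np.ndarray, thresholds: QcThresholds | None = None,
             variant_ids=None) -> np.ndarray:
    """Greedy sliding-window LD pruning.

    Within each window, while any retained pair has r^2 > r2_max, the member
    with the lower MAF is dropped (ties: the later variant); the window then
    advances by ``step``.  Variants are assumed position-ordered within
    chromosome.  Returns retained variant indices (or ids if given).
    """
    thr = thresholds or QcThresholds()
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    alive = np.ones(m, dtype=bool)
    mafs = np.array([_maf(G[:, j].astype(np.int64)) for j in range(m)])
    # mean-impute missing entries once so window correlations vectorize
    Z = G.copy()
    Z[Z < 0] = np.nan
    mu = np.nanmean(np.where(np.isnan(Z), np.nan, Z), axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    inds = np.where(np.isnan(Z))
    Z[inds] = np.take(mu, inds[1])
    start = 0
    while start < m:
        window = [j for j in range(start, min(start + thr.window, m)) if alive[j]]
        if len(window) >= 2:
            sub = Z[:, window]
            sd = sub.std(axis=0)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub, rowvar=False)
            corr[np.isnan(corr)] = 0.0
            corr[:, sd == 0] = 0.0
            corr[sd == 0, :] = 0.0
            r2 = corr ** 2
            local_alive = np.ones(len(window), dtype=bool)
            changed = True
            while changed:
                changed = False
                for a in range(len(window)):
                    if not local_alive[a]:
                        continue
                    for b in range(a + 1, len(window)):
                        if not local_alive[b]:
                            continue
                        if r2[a, b] > thr.r2_max:
                            i, j = window[a], window[b]
                            if mafs[i] < mafs[j]:
                                local_alive[a] = False
                            else:  # lower MAF, or tie -> later position
                                local_alive[b] = False
                            changed = True
                            break
                    if changed:
                        break
            for pos, j in enumerate(window):
                alive[j] = local_alive[pos]
        start += thr.step
    kept = np.flatnonzero(alive)
    if variant_ids is not None:
        ids = np.asarray(variant_ids)
        return ids[kept]
    return kept


def compute_pcs(genotypes: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal components of a standardized genotype matrix.

    Columns are mean-centered and scaled by sqrt(2 p (1-p)) with p the
    observed allele frequency; missing entries are mean-imputed.  Returns the
    samples x k matrix of left singular vectors scaled by their singular
    values, each component's sign fixed so its largest-magnitude loading is
    positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if n < k + 1 or m < k:
        raise ValueError(f"need at least {k + 1} samples and {k} variants for k={k}")
    Z = G.copy()
    Z[Z < 0] = np.nan
    mu = np.nanmean(Z, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    p = mu / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[sd == 0] = 1.0
    inds = np.where(np.isnan(Z))
    Z[inds] = np.take(mu, inds[1])
    Z = (Z - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if k > np.sum(S > 1e-10):
        raise ValueError(f"rank of the standardized matrix is below k={k}")
    pcs = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
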