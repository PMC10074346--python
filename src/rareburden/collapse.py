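"""Collapse qualifying genotypes into per-gene genetic scores.

Genetic models:

* ``codominant`` -- 2 if the sample carries at least one biallelic qualifying
  variant, 1 if at least one monoallelic variant, 0 otherwise;
* ``heterozygous`` -- 1 iff at least one monoallelic variant (samples whose
  only qualifying genotypes are biallelic score 0);
* ``recessive``   -- 1 iff at least one biallelic variant;
* ``dominant``    -- 1 iff any qualifying variant at all.

On chromosome X males are hemizygous (ploidy 1) and a single alternate
allele counts as biallelic, i.e. hemizygous males are equivalent to
homozygous females.  Compound heterozygotes (two distinct monoallelic
variants in one gene) are *not* promoted to biallelic by default because the
data are unphased; ``compound_het=True`` enables that promotion.
"""

from __future__ import annotations

import numpy as np

MODELS = ("codominant", "heterozygous", "recessive", "dominant")

__all__ = ["MODELS", "zygosity", "gene_score", "carrier_counts", "testable"]


def zygosity(dosage: int, ploidy: int) -> str:
    """Classify one genotype as none / monoallelic / biallelic."""
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    if dosage < 0 or dosage > ploidy:
        raise ValueError(f"dosage {dosage} exceeds ploidy {ploidy}")
    if dosage == 0:
        return "none"
    if ploidy == 1:
        return "biallelic"  # hemizygous == homozygous
    return "monoallelic" if dosage == 1 else "biallelic"


def _mono_bi(dosages: np.ndarray, ploidy: np.ndarray, compound_het: bool):
    """Per-sample flags (any monoallelic variant, any biallelic variant)."""
    d = np.asarray(dosages)
    if d.ndim == 1:
        d = d[:, None]
    d = np.where(d < 0, 0, d)  # missing genotypes score 0
    pl = np.asarray(ploidy)
    if pl.ndim == 1:
        pl = pl[:, None]
    pl = np.broadcast_to(pl, d.shape)
    mono = np.any((d == 1) & (pl == 2), axis=1)
    bi = np.any((d > 0) & (d == pl), axis=1)
    if compound_het:
        n_mono = np.sum((d == 1) & (pl == 2), axis=1)
        bi = bi | (n_mono >= 2)
    return mono, bi


def gene_score(dosages, ploidy, model: str, compound_het: bool = False) -> np.ndarray:
    """Per-sample collapsed score for one gene's qualifying variants.

    ``dosages`` is samples x variants (ints; negatives denote missing and are
    treated as 0); ``ploidy`` is per sample x variant (or per sample).
    An empty variant set yields all-zero scores.
    """
    d = np.atleast_2d(np.asarray(dosages))
    n = d.shape[0]
    if d.shape[1] == 0:
        return np.zeros(n, dtype=np.int64)
    mono, bi = _mono_bi(d, ploidy, compound_het)
    if model == "codominant":
        return np.where(bi, 2, np.where(mono, 1, 0)).astype(np.int64)
    if model == "heterozygous":
        return mono.astype(np.int64)
    if model == "recessive":
        return bi.astype(np.int64)
    if model == "dominant":
        return (mono | bi).astype(np.int64)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def carrier_counts(score, status):
    """Integer carrier counts split by zygosity class and case status.

    Returns a dict with monoallelic (score == 1) and biallelic (score >= 2)
    counts for cases and controls plus any-carrier totals.  For 0/1-coded
    models every carrier lands in the ``mono`` bucket of this bookkeeping
    unless the model put a 2 there; the any-carrier totals are model-safe.
    """
    score = np.asarray(score)
    status = np.asarray(status).astype(bool)
    if score.shape != status.shape:
        raise ValueError("score and status are misaligned")
    case_mono = int(np.sum((score == 1) & status))
    case_bi = int(np.sum((score >= 2) & status))
    ctrl_mono = int(np.sum((score == 1) & ~status))
    ctrl_bi = int(np.sum((score >= 2) & ~status))
    return {
        "case_mono": case_mono,
        "case_bi": case_bi,
        "ctrl_mono": ctrl_mono,
        "ctrl_bi": ctrl_bi,
        "case_total": case_mono + case_bi,
        "ctrl_total": ctrl_mono + ctrl_bi,
        "total": case_mono + case_bi + ctrl_mono + ctrl_bi,
    }


def testable(score, min_carriers: int = 3) -> bool:
    """True iff the number of carriers across all samples reaches the floor."""
    return int(np.sum(np.asarray(score) > 0)) >= min_carriers
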