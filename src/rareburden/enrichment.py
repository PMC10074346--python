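"""Candidate gene-set burden analyses with a matched-gene empirical null.

A gene set pools qualifying variants across its member genes into one
super-gene score (default rule: pLOF variants at gnomAD AF < 1e-3, with
optional per-gene overrides such as bLOF-only restriction or branchpoint
inclusion).  The empirical null replaces each member gene with a random gene
of similar pLI and CoNeS and re-runs the identical burden test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .collapse import carrier_counts, gene_score
from .firth import AssocResult, burden_test, firth_lrt
from .variant_sets import NONE, PLOF_ONLY, VariantSetSpec, qualifies, restrict_blof

__all__ = ["GeneRule", "GeneSetSpec", "EnrichmentResult", "set_burden_test",
           "sample_matched_sets", "empirical_p", "zygosity_equality_test",
           "carrier_proportion", "ratio", "compare_group_means",
           "gene_set_scan", "load_gene_set_config"]

@dataclass(frozen=True)
class GeneRule:
    """Variant qualification rule for one member gene."""
    class_rule: str = PLOF_ONLY
    af_max: float = 1e-3
    cadd_rule: str = NONE
    include_bp: bool = False
    blof_only: bool = False

    def spec(self) -> VariantSetSpec:
        return VariantSetSpec("set", self.class_rule, self.af_max,
                              self.cadd_rule, self.include_bp)


@dataclass
class GeneSetSpec:
    name: str
    genes: list
    model: str = "codominant"
    default_rule: GeneRule = field(default_factory=GeneRule)
    overrides: dict = field(default_factory=dict)  # gene -> GeneRule

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene set must have at least one member")
        stray = set(self.overrides) - set(self.genes)
        if stray:
            raise ValueError(f"overrides reference non-member genes: {sorted(stray)}")

    def rule_for(self, gene: str) -> GeneRule:
        return self.overrides.get(gene, self.default_rule)


@dataclass
class EnrichmentResult:
    observed: AssocResult
    replicates: int
    empirical_p: float
    null_ps: np.ndarray


def _qualifying_ids(cohort: Cohort, gene: str, rule: GeneRule) -> list:
    ann = cohort.variants
    sub = ann[ann["gene"] == gene]
    spec = rule.spec()
    ids = [vid for vid, row in sub.iterrows()
           if qualifies(row, spec, cohort.msc)]
    if rule.blof_only:
        ids = restrict_blof(ids, ann)
    return ids


def pooled_score(cohort: Cohort, set_spec: GeneSetSpec,
                 compound_het: bool = False) -> np.ndarray:
    """Per-sample super-gene score over the pooled qualifying variants."""
    ids: list = []
    for gene in set_spec.genes:
        ids.extend(_qualifying_ids(cohort, gene, set_spec.rule_for(gene)))
    if not ids:
        return np.zeros(len(cohort.samples), dtype=np.int64)
    d, pl = cohort.dosages_for(ids)
    model = set_spec.model
    if model == "heterozygous":
        # heterozygous-only: count monoallelic carriers; samples whose only
        # qualifying genotypes are biallelic are coded 0
        return gene_score(d, pl, "heterozygous", compound_het)
    return gene_score(d, pl, model, compound_het)


def set_burden_test(cohort: Cohort, set_spec: GeneSetSpec, covariates=None,
                    min_carriers: int = 3) -> AssocResult:
    """Burden test of a pooled gene-set score under the set's genetic model."""
    score = pooled_score(cohort, set_spec)
    if not np.any(score):
        return AssocResult(gene=set_spec.name, model=set_spec.model,
                           spec_id="set", skipped=True,
                           reason="empty pooled qualifying variant set")
    cov = cohort.covariates() if covariates is None else covariates
    res = burden_test(score, cohort.status, cov, min_carriers=min_carriers,
                      gene=set_spec.name, model=set_spec.model, spec_id="set")
    counts = carrier_counts(score, cohort.status)
    res.n_case_mono, res.n_case_bi = counts["case_mono"], counts["case_bi"]
    res.n_ctrl_mono, res.n_ctrl_bi = counts["ctrl_mono"], counts["ctrl_bi"]
    return res


def sample_matched_sets(targets, gene_features: pd.DataFrame, R: int,
                        tol_pli: float = 0.1, tol_cones: float = 0.5,
                        seed: int = 0, exclude=None) -> list[list]:
    """R random gene sets matched on pLI and CoNeS.

    Each replicate replaces every target gene with a distinct uniformly drawn
    gene satisfying |delta pLI| <= tol_pli and |delta CoNeS| <= tol_cones,
    without replacement within the replicate.  ``exclude`` genes (default:
    the targets themselves) are never drawn.
    """
    rng = np.random.default_rng(seed)
    targets = list(targets)
    excluded = set(exclude) if exclude is not None else set(targets)
    pli = gene_features["pli"]
    cones = gene_features["cones"]
    pools = {}
    for g in targets:
        if g not in gene_features.index:
            raise KeyError(f"target gene {g!r} absent from the feature table")
        ok = ((pli - pli[g]).abs() <= tol_pli) & ((cones - cones[g]).abs() <= tol_cones)
        pool = [x for x in gene_features.index[ok] if x not in excluded]
        if not pool:
            raise ValueError(
                f"target gene {g!r} has an empty match pool (size 0) at "
                f"tol_pli={tol_pli}, tol_cones={tol_cones}")
        pools[g] = pool
    out = []
    for _ in range(R):
        chosen: list = []
        taken: set = set()
        for g in targets:
            avail = [x for x in pools[g] if x not in taken]
            if not avail:
                raise ValueError(
                    f"match pool exhausted for {g!r} within a replicate "
                    f"(pool size {len(pools[g])})")
            pick = avail[rng.integers(len(avail))]
            chosen.append(pick)
            taken.add(pick)
        out.append(chosen)
    return out


def empirical_p(observed_p: float, null_ps) -> float:
    """Add-one empirical p: (1 + #{null <= observed}) / (R + 1)."""
    null_ps = np.asarray(null_ps, dtype=float)
    R = null_ps.size
    if R < 1:
        raise ValueError("need at least one null replicate")
    return float((1 + np.sum(null_ps <= observed_p)) / (R + 1))


def gene_set_scan(cohort: Cohort, set_spec: GeneSetSpec, R: int = 1000,
                  tol_pli: float = 0.1, tol_cones: float = 0.5, seed: int = 0,
                  covariates=None) -> EnrichmentResult:
    """Observed set burden test plus matched-resampling empirical p-value."""
    observed = set_burden_test(cohort, set_spec, covariates=covariates)
    if observed.skipped:
        raise ValueError(f"observed set not testable: {observed.reason}")
    null_sets = sample_matched_sets(set_spec.genes, cohort.gene_features, R,
                                    tol_pli, tol_cones, seed)
    null_ps = []
    for members in null_sets:
        null_spec = GeneSetSpec(name="null", genes=members, model=set_spec.model,
                                default_rule=set_spec.default_rule)
        r = set_burden_test(cohort, null_spec, covariates=covariates)
        null_ps.append(1.0 if r.skipped else r.p)
    null_ps = np.asarray(null_ps)
    return EnrichmentResult(observed, R, empirical_p(observed.p, null_ps), null_ps)


def load_gene_set_config(path):
    """Parse a YAML/JSON gene-set config into (GeneSetSpec, run options).

    Expected keys: name, genes, model (optional), default_rule (optional
    mapping of GeneRule fields), overrides (gene -> rule mapping), and the
    resampling options R, tol_pli, tol_cones, seed.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    default_rule = GeneRule(**raw.get("default_rule", {}))
    overrides = {g: GeneRule(**r) for g, r in raw.get("overrides", {}).items()}
    spec = GeneSetSpec(name=raw["name"], genes=list(raw["genes"]),
                       model=raw.get("model", "codominant"),
                       default_rule=default_rule, overrides=overrides)
    opts = {k: raw[k] for k in ("R", "tol_pli", "tol_cones", "seed") if k in raw}
    return spec, opts


def zygosity_equality_test(het_ind, bi_ind, status, covariates=None) -> float:
    """LRT (df=1) of zygosity-specific vs single-carrier Firth models.

    The full model carries separate log-odds for monoallelic and biallelic
    carriers; the null collapses them into one any-carrier parameter.
    Implemented in the equivalent parametrization (any-carrier indicator plus
    a biallelic-difference term) so the null is the point constraint
    'difference = 0', tested with the full design's Jeffreys penalty.
    """
    het = np.asarray(het_ind, dtype=float)
    bi = np.asarray(bi_ind, dtype=float)
    y = np.asarray(status, dtype=float)
    if not np.any(bi):
        raise ValueError("no biallelic carriers: zygosity test undefined")
    if not np.any(het):
        raise ValueError("no monoallelic carriers: zygosity test undefined")
    if np.any((het > 0) & (bi > 0)):
        raise ValueError("zygosity indicators must be disjoint")
    n = y.shape[0]
    cov = (np.empty((n, 0)) if covariates is None
           else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if cov.ndim == 2 and cov.shape[0] != n:
        cov = cov.T
    X = np.column_stack([np.ones(n), het + bi, bi, cov])
    p, _ = firth_lrt(y, X, j=2)
    return p


def carrier_proportion(n_carriers: int, denominator: int) -> float:
    """Carrier percentage, rounded half-up to one decimal."""
    if denominator < 1 or not (0 <= n_carriers <= denominator):
        raise ValueError("require 0 <= n_carriers <= denominator, denominator >= 1")
    pct = Decimal(100 * n_carriers) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def ratio(a: int, b: int, decimals: int = 1) -> float:
    """a/b rounded half-up (e.g. a male:female ratio)."""
    if b == 0:
        raise ValueError("zero denominator")
    q = Decimal(a) / Decimal(b)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def compare_group_means(values_a, values_b):
    """Welch two-sample t-test; returns (mean_a, sd_a, mean_b, sd_b, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return (a.mean(), 0.0, b.mean(), 0.0, 1.0)
        raise ValueError("both groups are degenerate with different means")
    t = stats.ttest_ind(a, b, equal_var=False)
    return (float(a.mean()), float(a.std(ddof=1)),
            float(b.mean()), float(b.std(ddof=1)), float(t.pvalue))
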