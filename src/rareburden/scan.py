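"""Genome-wide burden scan: joint, trans-ethnic and trans-pipeline analyses.

For every gene x variant set x genetic model with at least three carriers,
the joint analysis tests all samples with global principal components as
covariates; the trans-ethnic (ancestry strata) and trans-pipeline
(processing strata) analyses refit within each stratum using
stratum-specific PCs and combine the stratum p-values by sample-size
weighted Z-scores with effect direction.  Results failing the consistency
rule (joint p < 1e-3 but either meta p > 0.05) are flagged as discarded.
The effective number of tests per model is estimated from the variance of
the eigenvalues of the cross-gene correlation matrix of the signed joint Z
statistics across variant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .collapse import carrier_counts, gene_score, testable
from .firth import burden_test, genomic_lambda
from .pca import QcThresholds, compute_pcs, qc_filter
from .variant_sets import build_gene_sets, enumerate_specs

log = logging.getLogger(__name__)

__all__ = ["MetaResult", "ScanSummary", "run_scan", "stouffer_meta",
           "consistency_filter", "eigen_meff", "bonferroni_threshold"]


@dataclass
class MetaResult:
    z: float
    p: float
    k_strata: int
    direction: str  # one char per stratum: + - ? 0


@dataclass
class ScanSummary:
    results: pd.DataFrame
    model_stats: dict = field(default_factory=dict)  # model -> summary dict


def stouffer_meta(pvalues, directions, sample_sizes) -> MetaResult:
    """Sample-size weighted Z meta-analysis with effect direction.

    Z_i = Phi^-1(1 - p_i/2) * sign_i, weights sqrt(n_i),
    Z = sum(w_i Z_i) / sqrt(sum w_i^2), p = 2 Phi(-|Z|).
    A stratum with direction 0 contributes Z_i = 0.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no strata to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("stratum p-values must lie in (0, 1]")
    d = np.sign(np.asarray(directions, dtype=float))
    n = np.asarray(sample_sizes, dtype=float)
    z_i = stats.norm.isf(p / 2.0) * d
    w = np.sqrt(n)
    z = float(np.sum(w * z_i) / np.sqrt(np.sum(w ** 2)))
    p_meta = float(min(max(2.0 * stats.norm.sf(abs(z)), 1e-300), 1.0))
    dir_str = "".join("+" if x > 0 else "-" if x < 0 else "0" for x in d)
    return MetaResult(z, p_meta, int(p.size), dir_str)


def consistency_filter(p_joint, p_eth, p_pipe) -> bool:
    """False (discard) iff joint p < 0.001 and either meta p > 0.05.

    A missing meta p (None/NaN) is treated as consistent.
    """
    if p_joint is None or np.isnan(p_joint) or p_joint >= 0.001:
        return True
    for p in (p_eth, p_pipe):
        if p is not None and not np.isnan(p) and p > 0.05:
            return False
    return True


def eigen_meff(stat_matrix, pairwise: bool = False) -> float:
    """Effective number of tests from eigenvalue variance.

    ``stat_matrix`` is genes x variant sets of (signed) test statistics.
    The correlation matrix across the M sets is computed on complete rows
    (or pairwise-complete when ``pairwise``); with eigenvalues l_1..l_M,
    Meff = 1 + (M - 1) * (1 - Var(l) / M) using the sample variance
    (denominator M - 1), clipped to [1, M].
    """
    S = pd.DataFrame(np.asarray(stat_matrix, dtype=float))
    M = S.shape[1]
    if M < 2:
        raise ValueError("need at least 2 variant-set columns")
    if pairwise:
        corr = S.corr(min_periods=2).to_numpy()
        if np.isnan(corr).any():
            raise ValueError("pairwise correlation incomplete")
    else:
        complete = S.dropna()
        if len(complete) < 2:
            raise ValueError("fewer than 2 complete rows; try pairwise=True")
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(complete.to_numpy(), rowvar=False)
        # constant columns yield NaN correlations: treat as independent
        corr = np.where(np.isnan(corr), 0.0, corr)
        np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    var = float(np.var(eig, ddof=1))
    meff = 1.0 + (M - 1.0) * (1.0 - var / M)
    return float(np.clip(meff, 1.0, M))


def bonferroni_threshold(n_genes: int, meff_sets: float, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_genes * Meff_sets)."""
    if n_genes < 1 or meff_sets < 1:
        raise ValueError("n_genes and Meff_sets must be >= 1")
    return alpha / (n_genes * meff_sets)


def _signed_z(p: float, beta: float) -> float:
    z = float(np.sqrt(stats.chi2.isf(min(max(p, 1e-300), 1.0), 1)))
    return z * (1.0 if beta > 0 else -1.0 if beta < 0 else 0.0)


def _pcs_for(genotypes: np.ndarray, n_pcs: int, qc: QcThresholds) -> np.ndarray | None:
    keep = qc_filter(genotypes, qc)
    if keep.size == 0:
        return None
    G = genotypes[:, keep]
    k = min(n_pcs, G.shape[0] - 1, G.shape[1])
    if k < 1:
        return None
    try:
        return compute_pcs(G, k)
    except ValueError:
        return None


def _stratum_test(cohort, members, score, model, spec_id, gene, pcs,
                  min_carriers, n_pcs, qc):
    """Burden test restricted to one stratum; None when not testable."""
    y = cohort.status[members]
    if len(np.unique(y)) < 2:
        log.info("stratum skipped for %s/%s: single outcome class", gene, spec_id)
        return None
    s = score[members]
    if not testable(s, min_carriers):
        return None
    cov = cohort.covariates()[members]
    if pcs is not None:
        cov = np.column_stack([cov, pcs])  # stratum-specific PCs
    res = burden_test(s, y, cov, min_carriers=min_carriers,
                      gene=gene, model=model, spec_id=spec_id)
    return None if res.skipped else res


def score_table(cohort: Cohort, specs=None, models=("codominant",)) -> pd.DataFrame:
    """Long-format per-sample gene scores (sample_id, gene, model, spec_id, score)."""
    if specs is None:
        specs = enumerate_specs()
    gene_sets = build_gene_sets(cohort.variants, specs, cohort.msc)
    col_of = {vid: j for j, vid in enumerate(cohort.variants.index)}
    ploidy = cohort.ploidy()
    frames = []
    for gene, per_spec in gene_sets.items():
        for spec in specs:
            vids = per_spec[spec.spec_id]
            if not vids:
                continue
            cols = [col_of[v] for v in vids]
            for model in models:
                s = gene_score(cohort.genotypes[:, cols], ploidy[:, cols], model)
                frames.append(pd.DataFrame({
                    "sample_id": cohort.samples.index, "gene": gene,
                    "model": model, "spec_id": spec.spec_id, "score": s}))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "gene", "model", "spec_id",
                                     "score"])
    return pd.concat(frames, ignore_index=True)


def run_scan(cohort: Cohort, specs=None, models=("codominant", "recessive"),
             n_pcs: int = 5, min_carriers: int = 3, qc: QcThresholds | None = None,
             compound_het: bool = False) -> ScanSummary:
    """Scan genes x variant sets x models with joint + stratified analyses."""
    cohort.validate()
    if specs is None:
        specs = enumerate_specs()
    qc = qc or QcThresholds()

    global_pcs = _pcs_for(cohort.genotypes, n_pcs, qc)
    global_cov = cohort.covariates(global_pcs)
    status = cohort.status
    ploidy = cohort.ploidy()

    # stratum-specific PCs (ancestry for trans-ethnic, pipeline for trans-pipeline)
    strata = {}
    for axis in ("ancestry", "pipeline"):
        labels = cohort.samples[axis].to_numpy()
        groups = {}
        for lab in pd.unique(labels):
            members = np.flatnonzero(labels == lab)
            pcs = _pcs_for(cohort.genotypes[members], n_pcs, qc)
            groups[lab] = (members, pcs)
        strata[axis] = groups

    gene_sets = build_gene_sets(cohort.variants, specs, cohort.msc)
    col_of = {vid: j for j, vid in enumerate(cohort.variants.index)}

    rows = []
    per_model_pjoint: dict[str, list] = {m: [] for m in models}
    per_model_z: dict[str, dict] = {m: {} for m in models}

    for gene, per_spec in gene_sets.items():
        for spec in specs:
            vids = per_spec[spec.spec_id]
            if not vids:
                continue
            cols = [col_of[v] for v in vids]
            d = cohort.genotypes[:, cols]
            pl = ploidy[:, cols]
            for model in models:
                score = gene_score(d, pl, model, compound_het=compound_het)
                counts = carrier_counts(score if model == "codominant"
                                        else gene_score(d, pl, "codominant",
                                                        compound_het=compound_het),
                                        status)
                if not testable(score, min_carriers):
                    rows.append(dict(gene=gene, model=model, spec_id=spec.spec_id,
                                     **counts, skipped=True,
                                     reason=f"carriers<{min_carriers}"))
                    continue
                joint = burden_test(score, status, global_cov,
                                    min_carriers=min_carriers, gene=gene,
                                    model=model, spec_id=spec.spec_id)
                if joint.skipped:
                    rows.append(dict(gene=gene, model=model, spec_id=spec.spec_id,
                                     **counts, skipped=True, reason=joint.reason))
                    continue

                metas = {}
                for axis in ("ancestry", "pipeline"):
                    groups = strata[axis]
                    if len(groups) == 1:
                        metas[axis] = MetaResult(
                            _signed_z(joint.p, joint.beta), joint.p, 1,
                            "+" if joint.beta > 0 else "-" if joint.beta < 0 else "0")
                        continue
                    ps, ds, ns = [], [], []
                    for lab, (members, pcs) in groups.items():
                        r = _stratum_test(cohort, members, score, model,
                                          spec.spec_id, gene, pcs,
                                          min_carriers, n_pcs, qc)
                        if r is None:
                            continue
                        ps.append(r.p)
                        ds.append(np.sign(r.beta))
                        ns.append(members.size)
                    metas[axis] = stouffer_meta(ps, ds, ns) if ps else None

                p_eth = metas["ancestry"].p if metas["ancestry"] else np.nan
                p_pipe = metas["pipeline"].p if metas["pipeline"] else np.nan
                kept = consistency_filter(joint.p, p_eth, p_pipe)
                rows.append(dict(
                    gene=gene, model=model, spec_id=spec.spec_id, **counts,
                    odds_ratio=joint.odds_ratio, ci_low=joint.ci_low,
                    ci_high=joint.ci_high, p_joint=joint.p, method=joint.method,
                    p_eth=p_eth, p_pipe=p_pipe, kept=kept,
                    skipped=False, reason=""))
                per_model_pjoint[model].append(joint.p)
                per_model_z[model].setdefault(gene, {})[spec.spec_id] = \
                    _signed_z(joint.p, joint.beta)

    results = pd.DataFrame(rows)
    if len(results):
        order_cols = [c for c in ("p_joint", "gene") if c in results.columns]
        results = results.sort_values(order_cols, na_position="last",
                                      kind="mergesort").reset_index(drop=True)

    model_stats = {}
    spec_ids = [s.spec_id for s in specs]
    for model in models:
        pvals = per_model_pjoint[model]
        zmap = per_model_z[model]
        n_genes = len(zmap)
        lam = genomic_lambda(pvals) if pvals else np.nan
        if n_genes and len(spec_ids) >= 2:
            Z = pd.DataFrame.from_dict(zmap, orient="index")
            Z = Z.reindex(columns=spec_ids)
            try:
                meff_sets = eigen_meff(Z.to_numpy())
            except ValueError:
                try:
                    meff_sets = eigen_meff(Z.to_numpy(), pairwise=True)
                except ValueError:
                    meff_sets = float(len(spec_ids))
        else:
            meff_sets = 1.0
        threshold = (bonferroni_threshold(n_genes, meff_sets)
                     if n_genes else np.nan)
        model_stats[model] = dict(
            n_genes=n_genes, lambda_gc=lam, meff_sets=meff_sets,
            meff_total=meff_sets * n_genes, threshold=threshold)
    return ScanSummary(results, model_stats)
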