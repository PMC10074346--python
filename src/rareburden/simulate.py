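"""Synthetic stratified case-control cohorts with known ground truth.

The generator simulates a large virtual population (default 20x the
requested case+control totals), draws rare genotypes per variant within each
gene, assigns disease status through a configurable logistic model
(baseline + age + sex + planted per-gene genetic effects), and then samples
cases and controls without replacement to the requested quotas -- mirroring
case-control ascertainment.

Randomness is fully reproducible: a single root seed is combined with fixed
string labels (one stream per gene, one for the sample sheet, one for the
common background) so that adding or removing a gene never perturbs the
draws of any other gene.

X-linked genes: males carry a single allele (ploidy 1) and the configured
class frequency is interpreted as the allele frequency, so the male carrier
(hemizygote) frequency equals it directly.  On autosomes the configured
value is the carrier frequency f and the allele frequency is derived under
Hardy-Weinberg as q = 1 - sqrt(1 - f).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .collapse import gene_score

PLANT_MODELS = ("codominant", "recessive", "x_recessive")

__all__ = ["SimConfig", "simulate_cohort", "simulate_common_background",
           "default_config"]


@dataclass
class SimConfig:
    n_cases: int = 100
    n_controls: int = 100
    # (ancestry label, pipeline label, weight); weights sum to 1
    strata: list = field(default_factory=lambda: [("EUR", "central", 1.0)])
    # gene -> variant class -> population carrier frequency (allele frequency
    # for X-linked genes); classes: pLOF, missense, inframe, branchpoint,
    # synonymous
    carrier_freq: dict = field(default_factory=dict)
    # gene -> (model in PLANT_MODELS, log-odds per score unit)
    planted_effects: dict = field(default_factory=dict)
    baseline_logodds: float = -6.0
    beta_age: float = 0.05
    beta_male: float = 0.8
    age_case: tuple = (55.7, 17.4)   # Table-1-style defaults, descriptive
    age_ctrl: tuple = (43.8, 20.1)   # population (infected controls) draw
    male_frac_case: float = 0.708
    male_frac_ctrl: float = 0.395
    n_common_background: int = 200
    fst: float = 0.05
    variants_per_class: int = 2
    pop_factor: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least 1 case and 1 control")
        w = sum(s[2] for s in self.strata)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"stratum weights sum to {w}, expected 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        for gene, classes in self.carrier_freq.items():
            for vc, f in classes.items():
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"carrier frequency {f} for {gene}/{vc} out of [0,1]")
        for gene, (model, _) in self.planted_effects.items():
            if model not in PLANT_MODELS:
                raise ValueError(f"unknown planted model {model!r} for {gene}")
            total = sum(self.carrier_freq.get(gene, {}).values())
            if total <= 0:
                raise ValueError(
                    f"gene {gene!r} has a planted effect but zero carrier frequency")


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(label.encode()),)))


def _gene_chrom(config: SimConfig, gene: str, rank: int) -> str:
    if config.planted_effects.get(gene, (None,))[0] == "x_recessive":
        return "X"
    return str(rank % 22 + 1)


def _gene_variants(config: SimConfig, gene: str, rank: int) -> pd.DataFrame:
    """Deterministic per-gene variant annotation rows."""
    rng = _rng(config.seed, f"gene-annot:{gene}")
    chrom = _gene_chrom(config, gene, rank)
    base_pos = 100_000 + rank * 10_000
    rows = []
    k = 0
    for vclass in ("pLOF", "missense", "inframe", "branchpoint", "synonymous"):
        f = config.carrier_freq.get(gene, {}).get(vclass, 0.0)
        if f <= 0:
            continue
        for _ in range(config.variants_per_class):
            fv = f / config.variants_per_class
            if chrom == "X":
                q = fv
            else:
                q = 1.0 - np.sqrt(1.0 - fv)
            cadd = float(np.round(rng.uniform(0, 40), 3))
            if vclass == "pLOF":
                blof = rng.choice(["deleterious", "neutral", "untested"],
                                  p=[0.6, 0.2, 0.2])
            else:
                blof = "untested"
            ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            rows.append({
                "chrom": chrom, "pos": base_pos + k, "ref": ref, "alt": alt,
                "gene": gene, "vclass": vclass, "gnomad_af": float(q),
                "cadd": cadd, "blof": str(blof),
                "bp_flag": int(vclass == "branchpoint"), "_q": float(q),
            })
            k += 1
    return pd.DataFrame(rows)


def _draw_gene_dosages(config: SimConfig, gene: str, var_rows: pd.DataFrame,
                       male: np.ndarray) -> np.ndarray:
    rng = _rng(config.seed, f"gene-geno:{gene}")
    n = male.shape[0]
    d = np.zeros((n, len(var_rows)), dtype=np.int8)
    for j, (_, row) in enumerate(var_rows.iterrows()):
        q = row["_q"]
        if row["chrom"] == "X":
            copies = np.where(male, 1, 2)
            d[:, j] = rng.binomial(copies, q)
        else:
            d[:, j] = rng.binomial(2, q, size=n)
    return d


def _balding_nichols(rng: np.random.Generator, n_variants: int, n_strata: int,
                     fst: float):
    """Ancestral frequencies and per-stratum drifted frequencies."""
    p_anc = rng.uniform(0.1, 0.9, size=n_variants)
    if fst <= 0:
        p_strat = np.tile(p_anc, (n_strata, 1))
    else:
        a = p_anc * (1.0 - fst) / fst
        b = (1.0 - p_anc) * (1.0 - fst) / fst
        p_strat = rng.beta(a, b, size=(n_strata, n_variants))
    return p_anc, p_strat


def simulate_common_background(config: SimConfig, stratum_idx=None):
    """Common diploid genotypes under a two-level divergence model.

    Ancestral frequencies are Uniform(0.1, 0.9); each stratum's frequency is
    Beta-distributed around the ancestral value with variance controlled by
    ``fst`` (Balding-Nichols), and genotypes are Hardy-Weinberg within
    stratum.  ``stratum_idx`` assigns samples to strata; when omitted,
    n_cases + n_controls samples are assigned by the configured weights.
    Returns ``(genotypes, ancestral_freqs, stratum_idx)``.
    """
    if config.n_common_background < 1:
        raise ValueError("n_common_background must be >= 1")
    rng = _rng(config.seed, "background")
    n_strata = len(config.strata)
    if stratum_idx is None:
        n = config.n_cases + config.n_controls
        weights = np.array([s[2] for s in config.strata])
        stratum_idx = rng.choice(n_strata, size=n, p=weights)
    stratum_idx = np.asarray(stratum_idx)
    p_anc, p_strat = _balding_nichols(rng, config.n_common_background,
                                      n_strata, config.fst)
    G = rng.binomial(2, p_strat[stratum_idx, :]).astype(np.int8)
    return G, p_anc, stratum_idx


def _planted_logodds(config: SimConfig, gene_dosages: dict, var_tables: dict,
                     male: np.ndarray) -> np.ndarray:
    n = male.shape[0]
    total = np.zeros(n)
    for gene, (model, beta) in config.planted_effects.items():
        d = gene_dosages[gene]
        chrom = var_tables[gene]["chrom"].iloc[0]
        pl = np.full(d.shape, 2, dtype=np.int8)
        if chrom == "X":
            pl[male.astype(bool), :] = 1
        score_model = "recessive" if model == "x_recessive" else model
        total += beta * gene_score(d, pl, score_model)
    return total


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a stratified case-control cohort with planted effects.

    Identical configs (including seed) give byte-identical cohorts.  Raises
    if the virtual population cannot fill the case or control quota.
    """
    rng = _rng(config.seed, "samples")
    n_pop = config.pop_factor * (config.n_cases + config.n_controls)
    weights = np.array([s[2] for s in config.strata])
    stratum_idx = rng.choice(len(config.strata), size=n_pop, p=weights)
    male = rng.random(n_pop) < config.male_frac_ctrl
    age = np.clip(rng.normal(config.age_ctrl[0], config.age_ctrl[1], n_pop), 0, 105)
    age = np.round(age, 1)

    genes = sorted(config.carrier_freq)
    var_tables, gene_dosages = {}, {}
    for rank, gene in enumerate(genes):
        vt = _gene_variants(config, gene, rank)
        if len(vt) == 0:
            continue
        var_tables[gene] = vt
        gene_dosages[gene] = _draw_gene_dosages(config, gene, vt, male)

    logit = (config.baseline_logodds + config.beta_age * age
             + config.beta_male * male.astype(float)
             + _planted_logodds(config, gene_dosages, var_tables, male))
    diseased = rng.random(n_pop) < 1.0 / (1.0 + np.exp(-logit))

    case_pool = np.flatnonzero(diseased)
    ctrl_pool = np.flatnonzero(~diseased)
    if case_pool.size < config.n_cases:
        raise ValueError(
            f"virtual population produced {case_pool.size} cases "
            f"< quota {config.n_cases}; raise pop_factor or baseline_logodds")
    if ctrl_pool.size < config.n_controls:
        raise ValueError(
            f"virtual population produced {ctrl_pool.size} controls "
            f"< quota {config.n_controls}")
    cases = rng.choice(case_pool, size=config.n_cases, replace=False)
    ctrls = rng.choice(ctrl_pool, size=config.n_controls, replace=False)
    sel = np.concatenate([cases, ctrls])
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)

    samples = pd.DataFrame({
        "status": status,
        "sex": np.where(male[sel], "M", "F"),
        "age": age[sel],
        "ancestry": [config.strata[i][0] for i in stratum_idx[sel]],
        "pipeline": [config.strata[i][1] for i in stratum_idx[sel]],
        "auto_ab": "unknown",
    }, index=pd.Index([f"S{i:06d}" for i in range(sel.size)], name="sample_id"))

    variant_frames, dosage_blocks = [], []
    for gene in genes:
        if gene not in var_tables:
            continue
        variant_frames.append(var_tables[gene])
        dosage_blocks.append(gene_dosages[gene][sel, :])

    # common background variants, annotated as class 'other'
    bg_G, bg_af, _ = simulate_common_background(config, stratum_idx[sel])
    bg_rng = _rng(config.seed, "background-annot")
    n_bg = config.n_common_background
    bg_rows = pd.DataFrame({
        "chrom": [str(i % 22 + 1) for i in range(n_bg)],
        "pos": [50_000_000 + i * 1_000 for i in range(n_bg)],
        "ref": bg_rng.choice(["A", "C", "G", "T"], size=n_bg),
        "alt": "",
        "gene": [f"BG{i:05d}" for i in range(n_bg)],
        "vclass": "other",
        "gnomad_af": np.round(bg_af, 6),
        "cadd": np.nan,
        "blof": "untested",
        "bp_flag": 0,
    })
    bg_rows["alt"] = [
        {"A": "G", "G": "A", "C": "T", "T": "C"}[r] for r in bg_rows["ref"]]
    variant_frames.append(bg_rows)
    dosage_blocks.append(bg_G)

    variants = pd.concat(variant_frames, ignore_index=True)
    variants = variants.drop(columns=["_q"], errors="ignore")
    variants.index = pd.Index(
        [f"v{i:06d}" for i in range(len(variants))], name="variant_id")
    genotypes = np.hstack(dosage_blocks).astype(np.int8)

    all_genes = sorted(set(variants["gene"]))
    feat_rng = _rng(config.seed, "gene-features")
    gene_features = pd.DataFrame({
        "pli": np.round(feat_rng.uniform(0, 1, len(all_genes)), 4),
        "cones": np.round(feat_rng.normal(0, 1, len(all_genes)), 4),
    }, index=pd.Index(all_genes, name="gene"))
    msc = pd.Series(np.round(feat_rng.uniform(10, 30, len(all_genes)), 3),
                    index=gene_features.index, name="msc")

    return Cohort(samples, variants, genotypes, gene_features, msc).validate()


def default_config(n_cases=100, n_controls=100, n_null_genes=20, seed=0,
                   **overrides) -> SimConfig:
    """A convenience config: null genes with gnomAD-style frequencies."""
    carrier_freq = {}
    rng = np.random.default_rng(12345)  # fixed: gene universe, not a draw
    for i in range(n_null_genes):
        carrier_freq[f"G{i:04d}"] = {
            "pLOF": float(np.round(rng.uniform(1e-3, 8e-3), 5)),
            "missense": float(np.round(rng.uniform(2e-3, 2e-2), 5)),
            "synonymous": float(np.round(rng.uniform(2e-3, 1e-2), 5)),
        }
    carrier_freq.update(overrides.pop("carrier_freq", {}))
    return SimConfig(n_cases=n_cases, n_controls=n_controls,
                     carrier_freq=carrier_freq, seed=seed, **overrides)
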