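import numpy as np
import pandas as pd
import pytest

from rareburden.cohort import Cohort
from rareburden.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small two-stratum cohort with no planted effects."""
    cfg = default_config(
        n_cases=150, n_controls=150, n_null_genes=12, seed=11,
        strata=[("EUR", "central", 0.6), ("ME", "other", 0.4)],
        n_common_background=300)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_x_cohort():
    """Cohort with one planted X-linked recessive risk gene."""
    cfg = default_config(
        n_cases=400, n_controls=250, n_null_genes=10, seed=7,
        strata=[("EUR", "central", 0.7), ("ME", "other", 0.3)],
        carrier_freq={"XGENE": {"pLOF": 8e-3, "missense": 8e-3}},
        planted_effects={"XGENE": ("x_recessive", 3.0)},
        n_common_background=200)
    return simulate_cohort(cfg)


def toy_cohort(genotypes, chroms, sexes, status, genes=None):
    """Hand-built minimal cohort for format/collapse tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    genes = genes or ["GENE1"] * m
    variants = pd.DataFrame({
        "chrom": [str(c) for c in chroms],
        "pos": np.arange(1000, 1000 + m),
        "ref": ["A"] * m, "alt": ["T"] * m,
        "gene": genes, "vclass": ["pLOF"] * m,
        "gnomad_af": [1e-4] * m, "cadd": [30.0] * m,
        "blof": ["untested"] * m, "bp_flag": [0] * m,
    }, index=pd.Index([f"v{i}" for i in range(m)], name="variant_id"))
    samples = pd.DataFrame({
        "status": status, "sex": sexes,
        "age": np.linspace(30, 70, n), "ancestry": ["EUR"] * n,
        "pipeline": ["central"] * n, "auto_ab": ["unknown"] * n,
    }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
    ug = sorted(set(genes))
    feats = pd.DataFrame({"pli": [0.5] * len(ug), "cones": [0.0] * len(ug)},
                         index=pd.Index(ug, name="gene"))
    msc = pd.Series([15.0] * len(ug), index=feats.index, name="msc")
    return Cohort(samples, variants, genotypes, feats, msc).validate()
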