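"""Qualifying-variant set definitions and per-gene variant indexing.

Nine numbered variant sets are screened per gene: sets 1-3 take predicted
loss-of-function (pLOF) variants below gnomAD allele frequencies 1%, 0.1%,
and 0.01%; sets 4-6 take pLOF plus missense/in-frame variants whose CADD
score reaches the per-gene mutation significance cut-off (MSC) at the same
three frequency ceilings; sets 7-9 take pLOF plus missense/in-frame variants
with no CADD filter.  The CADD >= MSC rule applies to missense/in-frame
variants only; pLOF variants are exempt.  Branchpoint variants count as
pLOF-class only in sets with ``include_bp=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VCLASSES = ("pLOF", "missense", "inframe", "branchpoint", "synonymous", "other")
BLOF_LEVELS = ("deleterious", "neutral", "untested")

PLOF_ONLY = "PLOF_ONLY"
MISSLOF = "MISSLOF"
GE_MSC = "GE_MSC"
NONE = "NONE"

__all__ = [
    "VCLASSES", "BLOF_LEVELS", "PLOF_ONLY", "MISSLOF", "GE_MSC", "NONE",
    "VariantSetSpec", "enumerate_specs", "qualifies", "build_gene_sets",
    "restrict_blof",
]


@dataclass(frozen=True)
class VariantSetSpec:
    spec_id: str
    class_rule: str  # PLOF_ONLY or MISSLOF
    af_max: float    # 1e-2, 1e-3 or 1e-4
    cadd_rule: str   # GE_MSC or NONE
    include_bp: bool = False

    def __post_init__(self):
        if self.class_rule == PLOF_ONLY and self.cadd_rule == GE_MSC:
            raise ValueError("CADD rule is meaningless for a pLOF-only set")


def enumerate_specs() -> list[VariantSetSpec]:
    """The nine standard variant sets, in their canonical numbering."""
    afs = (1e-2, 1e-3, 1e-4)
    specs = [VariantSetSpec(str(i + 1), PLOF_ONLY, af, NONE)
             for i, af in enumerate(afs)]
    specs += [VariantSetSpec(str(i + 4), MISSLOF, af, GE_MSC)
              for i, af in enumerate(afs)]
    specs += [VariantSetSpec(str(i + 7), MISSLOF, af, NONE)
              for i, af in enumerate(afs)]
    return specs


def _effective_class(vclass: str, bp_flag, include_bp: bool) -> str:
    if include_bp and (vclass == "branchpoint" or bp_flag):
        return "pLOF"
    return vclass


def qualifies(variant, spec: VariantSetSpec, msc=None) -> bool:
    """Whether one annotated variant belongs to a qualifying set.

    ``variant`` is a mapping/row with fields gene, vclass, gnomad_af, cadd,
    bp_flag.  Missing gnomAD AF is treated as 0 (absent from gnomAD means
    ultra-rare).  ``msc`` maps gene -> CADD threshold and is required when
    the spec carries the GE_MSC rule.
    """
    vclass = _effective_class(variant["vclass"], variant.get("bp_flag", False),
                              spec.include_bp)
    if vclass in ("synonymous", "other", "branchpoint"):
        return False
    if spec.class_rule == PLOF_ONLY and vclass != "pLOF":
        return False
    if vclass not in ("pLOF", "missense", "inframe"):
        return False
    af = variant.get("gnomad_af")
    af = 0.0 if af is None or pd.isna(af) else float(af)
    if not af < spec.af_max:
        return False
    if spec.cadd_rule == GE_MSC and vclass in ("missense", "inframe"):
        gene = variant["gene"]
        if msc is None or gene not in msc or pd.isna(msc[gene]):
            raise KeyError(f"no MSC threshold available for gene {gene!r}")
        cadd = variant.get("cadd")
        if cadd is None or pd.isna(cadd):
            return False
        if not float(cadd) >= float(msc[gene]):
            return False
    return True


def _variant_key(row) -> tuple:
    return (row["chrom"], row["pos"], row["ref"], row["alt"])


def build_gene_sets(variants: pd.DataFrame, specs=None, msc=None):
    """Index qualifying variants as gene -> spec_id -> list of variant ids.

    ``variants`` must carry columns chrom, pos, ref, alt, gene, vclass,
    gnomad_af, cadd, bp_flag and a unique index (variant ids).  Every gene
    present in the table appears in the output for every spec, with an empty
    list when nothing qualifies.  Duplicate (chrom, pos, ref, alt) rows are
    rejected: multi-allelic records must be split upstream.
    """
    if specs is None:
        specs = enumerate_specs()
    keys = variants.apply(_variant_key, axis=1) if len(variants) else pd.Series(dtype=object)
    if len(variants) and keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate variant row {dup}; split multi-allelics upstream")
    index: dict[str, dict[str, list]] = {}
    for gene in variants["gene"].unique():
        index[gene] = {spec.spec_id: [] for spec in specs}
    for vid, row in variants.iterrows():
        for spec in specs:
            if qualifies(row, spec, msc):
                index[row["gene"]][spec.spec_id].append(vid)
    return index


def gene_sets_to_frame(index) -> pd.DataFrame:
    """Flatten a build_gene_sets index into a gene/spec/variant table."""
    rows = [{"gene": gene, "spec_id": sid, "n_variants": len(vids),
             "variant_ids": ";".join(map(str, vids))}
            for gene, per in index.items() for sid, vids in per.items()]
    return pd.DataFrame(rows, columns=["gene", "spec_id", "n_variants",
                                       "variant_ids"])


def restrict_blof(variant_ids, annotation: pd.DataFrame):
    """Keep only biochemically proven LOF variants (blof == deleterious)."""
    if "blof" not in annotation.columns:
        raise KeyError("annotation table has no 'blof' column")
    keep = annotation.loc[annotation["blof"] == "deleterious"].index
    return [v for v in variant_ids if v in set(keep)]
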