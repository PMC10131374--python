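"""Per-variant clonal fractions and sample-level PIK3CA clonality categories.

The clonal fraction of a variant is its allele fraction divided by the
sample's estimated tumor fraction — a proxy for the fraction of tumor
cells carrying the variant. Variants are called clonal at a clonal
fraction of >= 0.25 in ctDNA and >= 0.50 in tissue (inclusive thresholds;
the ctDNA cutoff is where a heterozygous single-copy alteration would be
present in a majority of diploid tumor cells). These estimates ignore
zygosity and local copy number, so variants on amplified alleles can have
overestimated clonal fractions; fractions are therefore capped at 1.0,
which never changes a label since both thresholds are below 1.

Sample categories for a target gene (PIK3CA by default) count pathogenic
SNVs only — alterations of known or likely oncogenic significance; indels,
copy-number changes and rearrangements in the target gene do not count
toward multiplicity:

* no target SNV                  -> ``no_pik3ca``
* one, clonal / subclonal        -> ``clonal_single`` / ``subclonal_single``
* two or more, >= 2 clonal       -> ``clonal_multiple``
* two or more, <= 1 clonal       -> ``subclonal_multiple``
* tumor fraction underivable (or any target SNV unlabelable) -> ``unestimable``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .tumor_fraction import (
    DegenerateInputError,
    TumorFractionResult,
    ctdna_fraction,
    tissue_tumor_fraction,
)
from .variant_io import (
    AlterationType,
    AssayMode,
    ClinicalRecord,
    ClonalityCategory,
    Oncogenicity,
    SampleProfile,
)

logger = logging.getLogger(__name__)

TARGET_GENE = "PIK3CA"

#: Inclusive clonal-fraction thresholds per assay mode.
CLONAL_THRESHOLDS: Mapping[AssayMode, float] = {
    AssayMode.CTDNA: 0.25,
    AssayMode.TISSUE: 0.50,
}

PATHOGENIC = (Oncogenicity.KNOWN, Oncogenicity.LIKELY)

CATEGORY_ORDER = [
    ClonalityCategory.CLONAL_MULTIPLE,
    ClonalityCategory.SUBCLONAL_MULTIPLE,
    ClonalityCategory.CLONAL_SINGLE,
    ClonalityCategory.SUBCLONAL_SINGLE,
    ClonalityCategory.NO_PIK3CA,
    ClonalityCategory.UNESTIMABLE,
]

__all__ = [
    "TARGET_GENE",
    "CLONAL_THRESHOLDS",
    "CATEGORY_ORDER",
    "ClonalCall",
    "clonal_fraction",
    "label_variant",
    "annotate_sample",
    "categorize_sample",
    "cohort_flow",
]


@dataclass(frozen=True)
class ClonalCall:
    """Clonal-fraction estimate and label for one variant.

    ``label`` is ``clonal``, ``subclonal``, or ``unestimable`` (allele
    fraction or tumor fraction unavailable, e.g. copy-number alterations).
    ``raw_fraction`` preserves the pre-cap ratio.
    """

    variant_index: int
    clonal_fraction: float | None
    label: str
    raw_fraction: float | None = None


def clonal_fraction(af: float, tumor_fraction: float, *, cap: float = 1.0) -> float:
    """AF / tumor fraction, capped at ``cap`` (raw value logged when capped)."""
    if not (tumor_fraction > 0):
        raise DegenerateInputError(
            f"tumor fraction must be positive, got {tumor_fraction}"
        )
    if not (0.0 <= af <= 1.0):
        raise DegenerateInputError(f"allele fraction {af} outside [0, 1]")
    raw = af / tumor_fraction
    if raw > cap:
        logger.debug("clonal fraction %.4f capped to %.2f", raw, cap)
    return min(raw, cap)


def label_variant(
    cf: float,
    assay_mode: AssayMode | str,
    thresholds: Mapping[AssayMode, float] = CLONAL_THRESHOLDS,
) -> str:
    """Label a clonal fraction: clonal at or above the assay-mode threshold."""
    if cf < 0:
        raise DegenerateInputError(f"clonal fraction must be nonnegative, got {cf}")
    return "clonal" if cf >= thresholds[AssayMode(assay_mode)] else "subclonal"


def annotate_sample(
    sample: SampleProfile,
    *,
    target_gene: str = TARGET_GENE,
    thresholds: Mapping[AssayMode, float] = CLONAL_THRESHOLDS,
    **tf_kwargs,
) -> SampleProfile:
    """Derive tumor fraction, per-variant clonal calls, and the category.

    Mutates and returns ``sample``. Keyword arguments are forwarded to the
    mode-appropriate tumor-fraction estimator.
    """
    tf: TumorFractionResult
    if sample.assay_mode == AssayMode.CTDNA:
        tf = ctdna_fraction(sample, **tf_kwargs)
    else:
        tf = tissue_tumor_fraction(sample, **tf_kwargs)
    sample.derived_tumor_fraction = tf.value
    sample.tumor_fraction_method = tf.method
    calls: list[ClonalCall] = []
    for i, v in enumerate(sample.variants):
        if tf.value is None or v.allele_fraction is None:
            calls.append(ClonalCall(i, None, "unestimable"))
            continue
        raw = v.allele_fraction / tf.value
        cf = clonal_fraction(v.allele_fraction, tf.value)
        calls.append(
            ClonalCall(i, cf, label_variant(cf, sample.assay_mode, thresholds), raw)
        )
    sample.clonal_calls = calls
    sample.clonality_category = categorize_sample(sample, target_gene=target_gene)
    return sample


def categorize_sample(
    sample: SampleProfile, *, target_gene: str = TARGET_GENE
) -> ClonalityCategory:
    """Assign the clonality category from already-computed variant labels."""
    if sample.clonal_calls is None:
        raise ValueError(
            f"sample {sample.sample_id}: clonal calls not computed; run annotate_sample"
        )
    labels = []
    for v, call in zip(sample.variants, sample.clonal_calls):
        if (
            v.gene == target_gene
            and v.alteration_type == AlterationType.SNV
            and v.oncogenicity in PATHOGENIC
        ):
            labels.append(call.label)
    n = len(labels)
    if n == 0:
        return ClonalityCategory.NO_PIK3CA
    if "unestimable" in labels:
        return ClonalityCategory.UNESTIMABLE
    n_clonal = labels.count("clonal")
    if n == 1:
        return (
            ClonalityCategory.CLONAL_SINGLE
            if n_clonal == 1
            else ClonalityCategory.SUBCLONAL_SINGLE
        )
    return (
        ClonalityCategory.CLONAL_MULTIPLE
        if n_clonal >= 2
        else ClonalityCategory.SUBCLONAL_MULTIPLE
    )


def cohort_flow(
    profiles: Iterable[SampleProfile],
    clinical: Iterable[ClinicalRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate category counts (flow-diagram analogue), optionally per arm.

    Returns one row per category in a fixed order with a ``total`` column
    and, when clinical records are supplied, one column per arm. The
    ``unestimable`` row doubles as the exclusion count.
    """
    arm_by_id = {c.sample_id: c.arm for c in clinical} if clinical is not None else {}
    arms = ["control", "experimental"] if clinical is not None else []
    counts = {cat: {"total": 0, **{a: 0 for a in arms}} for cat in CATEGORY_ORDER}
    for p in profiles:
        cat = p.clonality_category
        if cat is None:
            raise ValueError(f"sample {p.sample_id}: category not assigned")
        counts[cat]["total"] += 1
        arm = arm_by_id.get(p.sample_id)
        if arm in counts[cat]:
            counts[cat][arm] += 1
    df = pd.DataFrame(
        [{"category": cat.value, **counts[cat]} for cat in CATEGORY_ORDER],
        columns=["category", "total", *arms],
    )
    df["excluded"] = (df["category"] == ClonalityCategory.UNESTIMABLE.value) * df["total"]
    return df
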