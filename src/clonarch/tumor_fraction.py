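"""Sample-level tumor (ctDNA) fraction estimation.

Liquid (ctDNA) mode: if an externally supplied aneuploidy-based tumor
fraction is present it takes precedence; otherwise the maximum somatic
allele fraction (MSAF) is used — the highest allele fraction among
non-germline variants after excluding clonal-hematopoiesis-associated
alterations. Variants whose somatic status is ambiguous are excluded by
default (conservative; configurable).

Tissue mode: each somatic variant with SGZ copy-number estimates yields a
per-variant tumor fraction

    TF = 2*AF / (mc - AF*(wc + mc - 2))

where mc and wc are the mutated and wild-type copy numbers; the sample
tumor fraction is the maximum over usable somatic variants, capped at 1.0
(amplified alleles can push the raw value above 1; the raw value is kept
on the result for inspection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import SampleProfile, SomaticStatus, VariantCall

logger = logging.getLogger(__name__)

#: Genes whose variants are treated as clonal-hematopoiesis-associated even
#: when the per-variant CH flag was not set by the upstream pipeline.
DEFAULT_CH_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})

#: Hard ceiling on any tumor-fraction estimate.
TUMOR_FRACTION_CAP = 1.0

__all__ = [
    "DEFAULT_CH_GENES",
    "TUMOR_FRACTION_CAP",
    "TumorFractionResult",
    "DegenerateInputError",
    "msaf",
    "ctdna_fraction",
    "sgz_variant_tumor_fraction",
    "tissue_tumor_fraction",
]


class DegenerateInputError(ValueError):
    """Inputs outside the domain of a tumor-fraction formula."""


@dataclass(frozen=True)
class TumorFractionResult:
    """A sample tumor-fraction estimate and how it was obtained.

    ``method`` is one of ``aneuploidy``, ``msaf``, ``sgz_max`` or ``none``
    (no usable variant). ``contributing_variant`` is the index into the
    sample's variant list of the variant that set the value, when one did.
    ``raw_value`` preserves the pre-cap estimate.
    """

    value: float | None
    method: str
    contributing_variant: int | None = None
    raw_value: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) != (self.method == "none"):
            raise ValueError("value is absent iff method is 'none'")


def _msaf_eligible(
    v: VariantCall, include_ambiguous: bool, ch_genes: frozenset[str]
) -> bool:
    if v.allele_fraction is None:
        return False
    if v.somatic_status == SomaticStatus.GERMLINE:
        return False
    if v.somatic_status == SomaticStatus.AMBIGUOUS and not include_ambiguous:
        return False
    if v.ch_flag or v.gene in ch_genes:
        return False
    return True


def msaf(
    variants: list[VariantCall],
    *,
    include_ambiguous: bool = False,
    ch_genes: frozenset[str] = DEFAULT_CH_GENES,
) -> TumorFractionResult:
    """Maximum somatic allele fraction over CH-filtered non-germline variants.

    Returns method ``none`` when no variant is eligible; that is a valid
    result (the sample sheds no detectable tumor DNA), not an error.
    """
    best_i, best_af = None, None
    for i, v in enumerate(variants):
        if not _msaf_eligible(v, include_ambiguous, ch_genes):
            continue
        if best_af is None or v.allele_fraction > best_af:
            best_i, best_af = i, v.allele_fraction
    if best_i is None or best_af == 0.0:
        return TumorFractionResult(value=None, method="none")
    return TumorFractionResult(value=best_af, method="msaf", contributing_variant=best_i)


def ctdna_fraction(
    sample: SampleProfile,
    *,
    include_ambiguous: bool = False,
    ch_genes: frozenset[str] = DEFAULT_CH_GENES,
) -> TumorFractionResult:
    """ctDNA tumor fraction: aneuploidy estimate if supplied, else MSAF."""
    atf = sample.aneuploidy_tumor_fraction
    if atf is not None:
        if not (0.0 < atf <= 1.0):
            raise DegenerateInputError(
                f"aneuploidy tumor fraction {atf} outside (0, 1]"
            )
        return TumorFractionResult(value=atf, method="aneuploidy")
    return msaf(sample.variants, include_ambiguous=include_ambiguous, ch_genes=ch_genes)


def sgz_variant_tumor_fraction(af: float, mc: float, wc: float) -> float:
    """Per-variant tumor fraction from allele fraction and SGZ copy numbers.

    For a heterozygous diploid variant (mc = wc = 1) this reduces to 2*AF.
    Raises :class:`DegenerateInputError` when the denominator is
    nonpositive (copy-number state inconsistent with the observed AF).
    """
    if not (0.0 < af <= 1.0):
        raise DegenerateInputError(f"allele fraction {af} outside (0, 1]")
    if mc <= 0:
        raise DegenerateInputError(f"mutated copies must be positive, got {mc}")
    denom = mc - af * (wc + mc - 2.0)
    if denom <= 0:
        raise DegenerateInputError(
            f"nonpositive denominator for af={af}, mc={mc}, wc={wc}"
        )
    return 2.0 * af / denom


def tissue_tumor_fraction(
    sample: SampleProfile, *, cap: float = TUMOR_FRACTION_CAP
) -> TumorFractionResult:
    """Sample tumor fraction as the max per-variant SGZ estimate (capped).

    Somatic variants lacking mc/wc or with degenerate denominators are
    skipped (the skipped count is logged); if none is usable the result has
    method ``none``.
    """
    best_i, best_tf = None, None
    skipped = 0
    for i, v in enumerate(sample.variants):
        if v.somatic_status != SomaticStatus.SOMATIC:
            continue
        if v.allele_fraction is None or v.mutated_copies is None:
            skipped += 1
            continue
        try:
            tf = sgz_variant_tumor_fraction(
                v.allele_fraction, v.mutated_copies, v.wildtype_copies
            )
        except DegenerateInputError:
            skipped += 1
            continue
        if best_tf is None or tf > best_tf:
            best_i, best_tf = i, tf
    if skipped:
        logger.debug(
            "sample %s: skipped %d somatic variant(s) without a usable SGZ estimate",
            sample.sample_id,
            skipped,
        )
    if best_i is None:
        return TumorFractionResult(value=None, method="none")
    if best_tf > cap:
        logger.warning(
            "sample %s: tumor fraction %.4f exceeds %.2f (amplified allele?); capping",
            sample.sample_id,
            best_tf,
            cap,
        )
    return TumorFractionResult(
        value=min(best_tf, cap),
        method="sgz_max",
        contributing_variant=best_i,
        raw_value=best_tf,
    )
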