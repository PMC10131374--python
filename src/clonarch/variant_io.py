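"""Domain types and tab-delimited I/O for variant and clinical tables.

The interchange format is UTF-8 tab-delimited text with ``.`` marking absent
values. One row per called alteration per sample for the variant table; one
row per patient for the clinical table. Column names are documented on the
reader functions. A minimal VCF ingestion path is provided as a convenience
mapping from INFO keys; the flat table is the canonical format because VCF
has no natural slots for mutated/wild-type copy numbers or the
clonal-hematopoiesis flag.

Gene symbols are matched case-sensitively after whitespace trimming, and
protein-change strings are opaque labels (no HGVS parsing): classification
downstream depends only on counts and flags.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MISSING = "."

__all__ = [
    "MISSING",
    "AlterationType",
    "AssayMode",
    "SomaticStatus",
    "Oncogenicity",
    "ClonalityCategory",
    "VariantCall",
    "SampleProfile",
    "ClinicalRecord",
    "PathwayConfig",
    "TableFormatError",
    "TableValidationError",
    "read_variant_table",
    "read_clinical_table",
    "read_variant_vcf",
    "write_variant_table",
    "write_category_table",
    "read_category_table",
]


class TableFormatError(ValueError):
    """A table is structurally unusable (missing column, duplicate key)."""


class TableValidationError(ValueError):
    """A row holds a value outside its documented domain."""


class AssayMode(str, enum.Enum):
    CTDNA = "ctdna"
    TISSUE = "tissue"


class AlterationType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "indel"
    AMPLIFICATION = "CNA-amplification"
    LOSS = "CNA-loss"
    REARRANGEMENT = "rearrangement"


class SomaticStatus(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    AMBIGUOUS = "ambiguous"


class Oncogenicity(str, enum.Enum):
    KNOWN = "known"
    LIKELY = "likely"
    VUS = "VUS"


class ClonalityCategory(str, enum.Enum):
    CLONAL_SINGLE = "clonal_single"
    SUBCLONAL_SINGLE = "subclonal_single"
    CLONAL_MULTIPLE = "clonal_multiple"
    SUBCLONAL_MULTIPLE = "subclonal_multiple"
    NO_PIK3CA = "no_pik3ca"
    UNESTIMABLE = "unestimable"


@dataclass(frozen=True)
class VariantCall:
    """One called alteration in one sample.

    ``allele_fraction`` is undefined (None) for copy-number alterations and
    rearrangements. ``mutated_copies``/``wildtype_copies`` (mc/wc) are the
    per-variant copy-number estimates used in tissue mode; both present or
    both absent.
    """

    gene: str
    alteration_type: AlterationType
    protein_change: str = MISSING
    allele_fraction: float | None = None
    somatic_status: SomaticStatus = SomaticStatus.SOMATIC
    ch_flag: bool = False
    oncogenicity: Oncogenicity = Oncogenicity.VUS
    mutated_copies: float | None = None
    wildtype_copies: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip())
        af = self.allele_fraction
        if af is not None and not (0.0 <= af <= 1.0):
            raise TableValidationError(
                f"allele_fraction {af!r} outside [0, 1] for {self.gene}"
            )
        mc, wc = self.mutated_copies, self.wildtype_copies
        if (mc is None) != (wc is None):
            raise TableValidationError(
                "mutated_copies and wildtype_copies must both be present or both absent"
            )
        if mc is not None:
            if mc < 0 or wc < 0 or mc + wc <= 0:
                raise TableValidationError(
                    f"invalid copy numbers mc={mc}, wc={wc} for {self.gene}"
                )


@dataclass
class SampleProfile:
    """A sample's assay mode, variants and derived clonality state."""

    sample_id: str
    assay_mode: AssayMode
    variants: list[VariantCall] = field(default_factory=list)
    aneuploidy_tumor_fraction: float | None = None
    derived_tumor_fraction: float | None = None
    tumor_fraction_method: str | None = None
    clonality_category: ClonalityCategory | None = None
    # parallel to `variants` once clonality has been annotated
    clonal_calls: list["object"] | None = None

    def __post_init__(self) -> None:
        atf = self.aneuploidy_tumor_fraction
        if atf is not None and not (0.0 < atf <= 1.0):
            raise TableValidationError(
                f"aneuploidy_tumor_fraction {atf!r} outside (0, 1] for {self.sample_id}"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient arm, response, PFS and stratification factors."""

    sample_id: str
    arm: str  # "control" | "experimental"
    responder: bool | None
    pfs_time: float  # months
    pfs_event: bool
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("control", "experimental"):
            raise TableValidationError(f"unknown arm {self.arm!r}")
        if not (self.pfs_time > 0):
            raise TableValidationError(
                f"pfs_time must be positive, got {self.pfs_time!r} for {self.sample_id}"
            )


@dataclass(frozen=True)
class PathwayConfig:
    """Named gene sets with per-pathway exclusions applied before analysis."""

    pathways: Mapping[str, frozenset[str]]
    excluded_genes: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def genes(self, pathway: str) -> frozenset[str]:
        """Retained gene set for a pathway (exclusions removed)."""
        if pathway not in self.pathways:
            raise KeyError(f"unknown pathway {pathway!r}")
        return frozenset(self.pathways[pathway]) - frozenset(
            self.excluded_genes.get(pathway, frozenset())
        )


# ---------------------------------------------------------------------------
# parsing helpers

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "alteration_type",
    "protein_change",
    "allele_fraction",
    "somatic_status",
    "ch_flag",
    "oncogenicity",
    "mutated_copies",
    "wildtype_copies",
]
# optional sample-level column: aneuploidy_tumor_fraction

CLINICAL_COLUMNS = ["sample_id", "arm", "responder", "pfs_months", "pfs_event"]


def _opt_float(value: object, *, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in (MISSING, ""):
        return None
    try:
        return float(s)
    except ValueError:
        raise TableValidationError(f"row {row}: non-numeric {column} {s!r}") from None


def _parse_bool(value: object, *, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise TableValidationError(f"row {row}: non-boolean {column} {value!r}")


def _parse_enum(cls, value: object, *, row: int, column: str):
    try:
        return cls(str(value).strip())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise TableValidationError(
            f"row {row}: {column} {value!r} not one of {{{allowed}}}"
        ) from None


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return df


def read_variant_table(
    path: str | Path, assay_mode: AssayMode | str
) -> list[SampleProfile]:
    """Read a tab-delimited variant table into one profile per sample.

    Required columns: sample_id, gene, alteration_type, protein_change,
    allele_fraction, somatic_status, ch_flag, oncogenicity, mutated_copies,
    wildtype_copies. Optional: aneuploidy_tumor_fraction (sample-level,
    repeated on each row of the sample or given on any one of them).
    Samples are returned in first-appearance order; rows with invalid values
    raise with the offending 1-based data row number.
    """
    assay_mode = AssayMode(assay_mode)
    df = _read_tsv(path, VARIANT_COLUMNS)
    profiles: dict[str, SampleProfile] = {}
    for i, rec in enumerate(df.to_dict("records"), start=1):
        sid = str(rec["sample_id"]).strip()
        if not sid or sid == MISSING:
            raise TableValidationError(f"row {i}: missing sample_id")
        af = _opt_float(rec["allele_fraction"], row=i, column="allele_fraction")
        if af is not None and not (0.0 <= af <= 1.0):
            raise TableValidationError(
                f"row {i}: allele_fraction {af} outside [0, 1]"
            )
        variant = VariantCall(
            gene=str(rec["gene"]),
            alteration_type=_parse_enum(
                AlterationType, rec["alteration_type"], row=i, column="alteration_type"
            ),
            protein_change=str(rec["protein_change"]).strip() or MISSING,
            allele_fraction=af,
            somatic_status=_parse_enum(
                SomaticStatus, rec["somatic_status"], row=i, column="somatic_status"
            ),
            ch_flag=_parse_bool(rec["ch_flag"], row=i, column="ch_flag"),
            oncogenicity=_parse_enum(
                Oncogenicity, rec["oncogenicity"], row=i, column="oncogenicity"
            ),
            mutated_copies=_opt_float(rec["mutated_copies"], row=i, column="mutated_copies"),
            wildtype_copies=_opt_float(
                rec["wildtype_copies"], row=i, column="wildtype_copies"
            ),
        )
        atf = _opt_float(
            rec.get("aneuploidy_tumor_fraction", MISSING),
            row=i,
            column="aneuploidy_tumor_fraction",
        )
        if sid not in profiles:
            profiles[sid] = SampleProfile(
                sample_id=sid, assay_mode=assay_mode, aneuploidy_tumor_fraction=atf
            )
        elif atf is not None:
            if profiles[sid].aneuploidy_tumor_fraction is None:
                profiles[sid].aneuploidy_tumor_fraction = atf
            elif profiles[sid].aneuploidy_tumor_fraction != atf:
                raise TableValidationError(
                    f"row {i}: conflicting aneuploidy_tumor_fraction for {sid}"
                )
        profiles[sid].variants.append(variant)
    return list(profiles.values())


def read_clinical_table(
    path: str | Path,
    allowed_strata: Mapping[str, Iterable[str]] | None = None,
) -> list[ClinicalRecord]:
    """Read the per-patient clinical table.

    Required columns: sample_id, arm (control|experimental), responder
    (1/0/.), pfs_months (> 0), pfs_event (1/0). Any additional column is
    treated as a stratification factor; if ``allowed_strata`` declares its
    levels, unknown levels are rejected.
    """
    df = _read_tsv(path, CLINICAL_COLUMNS)
    strata_cols = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        sid = str(rec["sample_id"]).strip()
        if sid in seen:
            raise TableFormatError(f"row {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        responder_raw = str(rec["responder"]).strip()
        responder = (
            None
            if responder_raw in (MISSING, "")
            else _parse_bool(responder_raw, row=i, column="responder")
        )
        pfs_time = _opt_float(rec["pfs_months"], row=i, column="pfs_months")
        if pfs_time is None or pfs_time <= 0:
            raise TableValidationError(f"row {i}: pfs_months must be positive")
        strata = {c: str(rec[c]).strip() for c in strata_cols}
        if allowed_strata is not None:
            for factor, level in strata.items():
                if factor in allowed_strata and level not in set(allowed_strata[factor]):
                    raise TableValidationError(
                        f"row {i}: unknown level {level!r} for stratification factor {factor!r}"
                    )
        records.append(
            ClinicalRecord(
                sample_id=sid,
                arm=str(rec["arm"]).strip(),
                responder=responder,
                pfs_time=pfs_time,
                pfs_event=_parse_bool(rec["pfs_event"], row=i, column="pfs_event"),
                strata=strata,
            )
        )
    return records


def _fmt(value: object) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_variant_table(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    """Write profiles back to the canonical tab-delimited variant table."""
    rows = []
    for p in profiles:
        for v in p.variants:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "gene": v.gene,
                    "alteration_type": _fmt(v.alteration_type),
                    "protein_change": v.protein_change,
                    "allele_fraction": _fmt(v.allele_fraction),
                    "somatic_status": _fmt(v.somatic_status),
                    "ch_flag": _fmt(v.ch_flag),
                    "oncogenicity": _fmt(v.oncogenicity),
                    "mutated_copies": _fmt(v.mutated_copies),
                    "wildtype_copies": _fmt(v.wildtype_copies),
                    "aneuploidy_tumor_fraction": _fmt(p.aneuploidy_tumor_fraction),
                }
            )
    cols = VARIANT_COLUMNS + ["aneuploidy_tumor_fraction"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


CATEGORY_COLUMNS = [
    "sample_id",
    "clonality_category",
    "tumor_fraction",
    "tumor_fraction_method",
    "clonal_fractions",
]


def write_category_table(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    """Write per-sample category assignments with per-variant clonal fractions.

    The ``clonal_fractions`` column packs one ``gene|protein_change|fraction|label``
    entry per variant, ``;``-separated, so the table round-trips losslessly
    through :func:`read_category_table` (reals to 6 significant digits).
    """
    rows = []
    for p in profiles:
        if p.clonality_category is None:
            raise ValueError(f"sample {p.sample_id}: category not assigned")
        entries = []
        for v, call in zip(p.variants, p.clonal_calls or []):
            entries.append(
                f"{v.gene}|{v.protein_change}|{_fmt(call.clonal_fraction)}|{call.label}"
            )
        rows.append(
            {
                "sample_id": p.sample_id,
                "clonality_category": _fmt(p.clonality_category),
                "tumor_fraction": _fmt(p.derived_tumor_fraction),
                "tumor_fraction_method": _fmt(p.tumor_fraction_method),
                "clonal_fractions": ";".join(entries) or MISSING,
            }
        )
    pd.DataFrame(rows, columns=CATEGORY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_category_table(path: str | Path) -> pd.DataFrame:
    """Read a category table written by :func:`write_category_table`.

    Returns a DataFrame with parsed ``tumor_fraction`` (float, NaN when
    absent) and the packed ``clonal_fractions`` expanded into a list of
    (gene, protein_change, fraction, label) tuples per row.
    """
    df = _read_tsv(path, CATEGORY_COLUMNS)
    df["tumor_fraction"] = [
        _opt_float(v, row=i, column="tumor_fraction")
        for i, v in enumerate(df["tumor_fraction"], start=1)
    ]
    parsed = []
    for i, packed in enumerate(df["clonal_fractions"], start=1):
        entries = []
        if packed not in (MISSING, ""):
            for item in packed.split(";"):
                gene, pchange, frac, label = item.split("|")
                entries.append(
                    (gene, pchange, _opt_float(frac, row=i, column="clonal_fractions"), label)
                )
        parsed.append(entries)
    df["clonal_fractions"] = parsed
    return df


def read_variant_vcf(
    path: str | Path,
    assay_mode: AssayMode | str,
    sample_id: str | None = None,
) -> SampleProfile:
    """Convenience VCF reader: one VCF per sample.

    INFO keys mapped: GENE, TYPE (alteration type), PCHANGE, AF, SOMATIC
    (flag; absent means germline unless STATUS is given), CH (flag), ONC,
    MC, WC. Unrecognized records fall back to conservative defaults
    (ambiguous somatic status, VUS oncogenicity).
    """
    from cyvcf2 import VCF

    assay_mode = AssayMode(assay_mode)
    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else Path(path).stem)
    profile = SampleProfile(sample_id=sid, assay_mode=assay_mode)
    for rec in vcf:
        info = dict(rec.INFO)
        status_str = info.get("STATUS")
        if status_str is not None:
            status = SomaticStatus(str(status_str))
        else:
            status = (
                SomaticStatus.SOMATIC if info.get("SOMATIC") else SomaticStatus.AMBIGUOUS
            )
        onc_str = info.get("ONC")
        profile.variants.append(
            VariantCall(
                gene=str(info.get("GENE", MISSING)),
                alteration_type=AlterationType(str(info.get("TYPE", "SNV"))),
                protein_change=str(info.get("PCHANGE", MISSING)),
                allele_fraction=float(info["AF"]) if "AF" in info else None,
                somatic_status=status,
                ch_flag=bool(info.get("CH", False)),
                oncogenicity=Oncogenicity(str(onc_str)) if onc_str else Oncogenicity.VUS,
                mutated_copies=float(info["MC"]) if "MC" in info else None,
                wildtype_copies=float(info["WC"]) if "WC" in info else None,
            )
        )
    return profile
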