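"""Truth-labelled synthetic cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the clonality analysis
assumes, at the level of variant-call tables (no read-level simulation):

* each sample carries one or several pathogenic PIK3CA SNVs at assigned
  cancer-cell fractions (CCFs), plus a truncal somatic passenger that
  anchors the maximum somatic allele fraction;
* plasma shed (ctDNA fraction) is lognormal, truncated to (0, 1];
* the expected allele fraction of a heterozygous variant is
  CCF x shed / 2, and the observed AF is binomial read sampling at the
  configured depth (variants drawing zero reads go undetected);
* clonal-hematopoiesis and germline contaminants are added at configured
  rates with their flags set, as the MSAF exclusion rules expect;
* pathway co-alterations occur at per-category rates, responses are
  Bernoulli and PFS is Weibull with per-category proportional hazards and
  independent uniform censoring.

A single NumPy generator seeded from ``SimulationConfig.seed`` drives all
draws in a fixed per-sample order (category, shed, PIK3CA CCFs,
passengers, contaminants, co-alterations, clinical), so output is
bit-reproducible for a given config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonality import CLONAL_THRESHOLDS
from .pathway_coalteration import DEFAULT_PATHWAY_CONFIG
from .variant_io import (
    AlterationType,
    AssayMode,
    ClinicalRecord,
    ClonalityCategory,
    MISSING,
    Oncogenicity,
    SampleProfile,
    SomaticStatus,
    VariantCall,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_survival_groups",
    "truth_scorecard",
    "profiles_to_variant_frame",
    "clinical_to_frame",
]

PIK3CA_HOTSPOTS = [
    "H1047R", "E545K", "E542K", "E726K", "N345K", "C420R", "H1047L", "P539R",
    "Q546K", "E453K", "G118D", "M1043I",
]

#: Genes used for MSAF-anchoring passengers and germline contaminants; kept
#: outside the default pathway lists so co-alteration rates stay calibrated.
PASSENGER_GENES = ["ESR1", "GATA3", "CDH1", "ARID1A", "MAP3K1", "SPEN"]
CH_GENE_POOL = ["DNMT3A", "TET2", "ASXL1"]

_CM = ClonalityCategory.CLONAL_MULTIPLE.value
_SM = ClonalityCategory.SUBCLONAL_MULTIPLE.value
_CS = ClonalityCategory.CLONAL_SINGLE.value
_SS = ClonalityCategory.SUBCLONAL_SINGLE.value


def _default_pathway_rates() -> dict[str, dict[str, float]]:
    # Clonal-multiple vs subclonal-multiple RTK rates follow the observed
    # 19.1% vs 47.4% contrast; other pathways differ modestly or not at all.
    return {
        "RTK": {_CM: 0.191, _SM: 0.474, _CS: 0.20, _SS: 0.25},
        "PI3K": {_CM: 0.10, _SM: 0.21, _CS: 0.12, _SS: 0.15},
        "MAPK": {_CM: 0.12, _SM: 0.21, _CS: 0.12, _SS: 0.12},
        "p53": {_CM: 0.45, _SM: 0.50, _CS: 0.45, _SS: 0.45},
    }


def _default_orr() -> dict[str, dict[str, float]]:
    # (control, experimental) response probabilities per category.
    return {
        _CM: {"control": 2 / 18, "experimental": 12 / 29},
        _SM: {"control": 0.0, "experimental": 1 / 14},
        _CS: {"control": 0.095, "experimental": 0.17},
        _SS: {"control": 0.17, "experimental": 0.28},
    }


def _default_hr() -> dict[str, float]:
    # Hazard multipliers relative to the clonal-multiple baseline; with the
    # per-arm Weibull scales below these imply medians near 7.6/5.1 months
    # (experimental) and 3.9/2.0 (control) for the multiple-mutation groups.
    return {_CM: 1.0, _SM: 1.8, _CS: 1.05, _SS: 0.95}


@dataclass
class SimulationConfig:
    """Cohort-generator parameters (defaults are the study conditions).

    ``p_multiple`` and the conditional clonal shares reflect the observed
    cohort composition (66/337 multiple; 71.2% of multiples and 91.1% of
    singles clonal; 15/19 subclonal multiples with exactly one clonal
    mutation). Depth defaults to 5000x, typical of hybrid-capture liquid
    panels; shed is lognormal with median 10%.
    """

    n_samples: int = 400
    seed: int = 0
    assay_mode: AssayMode = AssayMode.CTDNA
    depth: int = 5000
    ctdna_lognormal_mu: float = math.log(0.10)
    ctdna_lognormal_sigma: float = 1.0
    ctdna_fraction_min: float = 0.0
    p_multiple: float = 66 / 337
    p_clonal_given_multiple: float = 0.712
    p_clonal_given_single: float = 0.911
    p_one_clonal_given_subclonal_multiple: float = 15 / 19
    p_third_mutation: float = 0.15
    ccf_clonal_range: tuple[float, float] = (0.40, 1.0)
    ccf_subclonal_range: tuple[float, float] = (0.02, 0.18)
    n_extra_passengers_mean: float = 1.0
    ch_rate: float = 0.25
    ch_af_range: tuple[float, float] = (0.002, 0.03)
    germline_rate: float = 0.5
    pathway_alteration_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_pathway_rates
    )
    p_experimental: float = 2 / 3
    orr_by_category_arm: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_orr
    )
    pfs_weibull_shape: float = 1.0
    pfs_weibull_scale_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 3.9 / math.log(2),
            "experimental": 7.6 / math.log(2),
        }
    )
    hr_by_category: Mapping[str, float] = field(default_factory=_default_hr)
    censor_range: tuple[float, float] = (1.0, 30.0)

    def validate(self) -> None:
        for name in (
            "p_multiple",
            "p_clonal_given_multiple",
            "p_clonal_given_single",
            "p_one_clonal_given_subclonal_multiple",
            "p_third_mutation",
            "ch_rate",
            "germline_rate",
            "p_experimental",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")
        for rng_name in ("ccf_clonal_range", "ccf_subclonal_range"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{rng_name} must be a nonempty interval in [0, 1]")
        threshold = CLONAL_THRESHOLDS[AssayMode(self.assay_mode)]
        if self.ccf_clonal_range[0] < threshold:
            raise ValueError(
                f"ccf_clonal_range must lie at or above the clonal threshold {threshold}"
            )
        if self.ccf_subclonal_range[1] >= threshold:
            raise ValueError(
                f"ccf_subclonal_range must lie below the clonal threshold {threshold}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth retained by the simulator (never in the observable tables).

    ``samples``: one row per sample (true category, shed, arm, outcome
    parameters). ``variants``: one row per simulated PIK3CA mutation with
    its true CCF, true label and detection flag. ``pathways``: one row per
    sample x pathway with the true alteration status.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    pathways: pd.DataFrame
    config: dict


def _draw_shed(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    lo = cfg.ctdna_fraction_min
    for _ in range(10000):
        shed = float(rng.lognormal(cfg.ctdna_lognormal_mu, cfg.ctdna_lognormal_sigma))
        if lo < shed <= 1.0:
            return shed
    raise ValueError("ctDNA-fraction distribution incompatible with truncation bounds")


def _observed_af(p_true: float, depth: int, rng: np.random.Generator) -> float:
    reads = int(rng.binomial(depth, min(p_true, 1.0)))
    return reads / depth


def _make_snv(
    gene: str,
    pchange: str,
    ccf: float,
    shed: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    oncogenicity: Oncogenicity = Oncogenicity.KNOWN,
) -> VariantCall | None:
    af = _observed_af(ccf * shed / 2.0, cfg.depth, rng)
    if af == 0.0:
        return None
    tissue = AssayMode(cfg.assay_mode) == AssayMode.TISSUE
    return VariantCall(
        gene=gene,
        alteration_type=AlterationType.SNV,
        protein_change=pchange,
        allele_fraction=af,
        somatic_status=SomaticStatus.SOMATIC,
        ch_flag=False,
        oncogenicity=oncogenicity,
        mutated_copies=1.0 if tissue else None,
        wildtype_copies=1.0 if tissue else None,
    )


def _true_category(labels: Sequence[str]) -> str:
    n = len(labels)
    n_clonal = sum(1 for x in labels if x == "clonal")
    if n == 1:
        return _CS if n_clonal else _SS
    return _CM if n_clonal >= 2 else _SM


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (variant table, clinical table, truth) for one cohort.

    The returned tables use the canonical tab-delimited column schema and
    round-trip through :mod:`clonarch.variant_io` unchanged.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    threshold = CLONAL_THRESHOLDS[AssayMode(cfg.assay_mode)]

    profiles: list[SampleProfile] = []
    clinical: list[ClinicalRecord] = []
    truth_samples, truth_variants, truth_pathways = [], [], []

    for i in range(cfg.n_samples):
        sid = f"S{i:04d}"
        arm = "experimental" if rng.random() < cfg.p_experimental else "control"
        multiple = rng.random() < cfg.p_multiple
        if multiple:
            clonal_cat = rng.random() < cfg.p_clonal_given_multiple
        else:
            clonal_cat = rng.random() < cfg.p_clonal_given_single
        shed = _draw_shed(cfg, rng)

        # --- PIK3CA mutation CCFs --------------------------------------
        def draw_ccf(clonal: bool) -> float:
            lo, hi = cfg.ccf_clonal_range if clonal else cfg.ccf_subclonal_range
            return float(rng.uniform(lo, hi))

        if not multiple:
            mut_clonal = [clonal_cat]
        else:
            n_mut = 2 + (1 if rng.random() < cfg.p_third_mutation else 0)
            if clonal_cat:
                mut_clonal = [True, True] + [
                    bool(rng.random() < 0.5) for _ in range(n_mut - 2)
                ]
            elif rng.random() < cfg.p_one_clonal_given_subclonal_multiple:
                mut_clonal = [True] + [False] * (n_mut - 1)
            else:
                mut_clonal = [False] * n_mut
        ccfs = [draw_ccf(c) for c in mut_clonal]
        pchanges = list(rng.choice(PIK3CA_HOTSPOTS, size=len(ccfs), replace=False))
        true_labels = ["clonal" if c >= threshold else "subclonal" for c in ccfs]
        category = _true_category(true_labels)

        profile = SampleProfile(sample_id=sid, assay_mode=AssayMode(cfg.assay_mode))

        for pchange, ccf, label in zip(pchanges, ccfs, true_labels):
            v = _make_snv("PIK3CA", pchange, ccf, shed, cfg, rng)
            detected = v is not None
            if detected:
                profile.variants.append(v)
            truth_variants.append(
                {
                    "sample_id": sid,
                    "gene": "PIK3CA",
                    "protein_change": pchange,
                    "true_ccf": ccf,
                    "true_label": label,
                    "detected": detected,
                }
            )

        # --- somatic passengers (truncal anchor + extras) ---------------
        n_extra = min(
            int(rng.poisson(cfg.n_extra_passengers_mean)), len(PASSENGER_GENES) - 1
        )
        passenger_ccfs = [1.0] + [float(rng.uniform(0.1, 1.0)) for _ in range(n_extra)]
        genes = rng.choice(PASSENGER_GENES, size=len(passenger_ccfs), replace=False)
        for gene, ccf in zip(genes, passenger_ccfs):
            v = _make_snv(
                str(gene), f"P{int(rng.integers(100, 999))}fs", ccf, shed, cfg, rng,
                oncogenicity=Oncogenicity.VUS,
            )
            if v is not None:
                profile.variants.append(v)

        # --- contaminants ----------------------------------------------
        if rng.random() < cfg.ch_rate:
            ch_af = float(rng.uniform(*cfg.ch_af_range))
            af = _observed_af(ch_af, cfg.depth, rng)
            if af > 0:
                profile.variants.append(
                    VariantCall(
                        gene=str(rng.choice(CH_GENE_POOL)),
                        alteration_type=AlterationType.SNV,
                        protein_change=f"R{int(rng.integers(100, 999))}*",
                        allele_fraction=af,
                        somatic_status=SomaticStatus.SOMATIC,
                        ch_flag=True,
                        oncogenicity=Oncogenicity.VUS,
                    )
                )
        if rng.random() < cfg.germline_rate:
            af = _observed_af(0.5, cfg.depth, rng)
            profile.variants.append(
                VariantCall(
                    gene=str(rng.choice(PASSENGER_GENES)),
                    alteration_type=AlterationType.SNV,
                    protein_change=f"V{int(rng.integers(100, 999))}I",
                    allele_fraction=af,
                    somatic_status=SomaticStatus.GERMLINE,
                    ch_flag=False,
                    oncogenicity=Oncogenicity.VUS,
                )
            )

        # --- pathway co-alterations -------------------------------------
        for pathway, rates in cfg.pathway_alteration_rates.items():
            altered = rng.random() < rates[category]
            truth_pathways.append(
                {"sample_id": sid, "pathway": pathway, "altered": altered}
            )
            if not altered:
                continue
            gene = str(rng.choice(sorted(DEFAULT_PATHWAY_CONFIG.genes(pathway))))
            if rng.random() < 0.7:
                v = _make_snv(
                    gene, f"A{int(rng.integers(100, 999))}T",
                    float(rng.uniform(0.3, 1.0)), shed, cfg, rng,
                )
                if v is not None:
                    profile.variants.append(v)
            else:
                profile.variants.append(
                    VariantCall(
                        gene=gene,
                        alteration_type=AlterationType.AMPLIFICATION,
                        protein_change=MISSING,
                        allele_fraction=None,
                        somatic_status=SomaticStatus.SOMATIC,
                        ch_flag=False,
                        oncogenicity=Oncogenicity.KNOWN,
                    )
                )

        # --- clinical outcome -------------------------------------------
        responder = bool(rng.random() < cfg.orr_by_category_arm[category][arm])
        shape = cfg.pfs_weibull_shape
        scale = cfg.pfs_weibull_scale_by_arm[arm]
        hazard = cfg.hr_by_category[category]
        u = float(rng.random())
        event_time = scale * (-math.log(u) / hazard) ** (1.0 / shape)
        censor_time = float(rng.uniform(*cfg.censor_range))
        pfs_time = max(min(event_time, censor_time), 1e-3)
        pfs_event = event_time <= censor_time
        clinical.append(
            ClinicalRecord(
                sample_id=sid,
                arm=arm,
                responder=responder,
                pfs_time=pfs_time,
                pfs_event=pfs_event,
                strata={
                    "visceral_disease": "yes" if rng.random() < 0.55 else "no",
                    "endocrine_sensitivity": "sensitive"
                    if rng.random() < 0.6
                    else "resistant",
                    "region": str(rng.choice(["NA", "EU", "ASIA"])),
                },
            )
        )
        profiles.append(profile)
        truth_samples.append(
            {
                "sample_id": sid,
                "true_category": category,
                "true_ctdna_fraction": shed,
                "arm": arm,
                "n_pik3ca_mut": len(ccfs),
                "responder": responder,
                "pfs_time": pfs_time,
                "pfs_event": pfs_event,
            }
        )

    variant_df = profiles_to_variant_frame(profiles)
    clinical_df = clinical_to_frame(clinical)
    cfg_dict = asdict(cfg)
    cfg_dict["assay_mode"] = AssayMode(cfg.assay_mode).value
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            truth_samples,
            columns=[
                "sample_id", "true_category", "true_ctdna_fraction", "arm",
                "n_pik3ca_mut", "responder", "pfs_time", "pfs_event",
            ],
        ),
        variants=pd.DataFrame(
            truth_variants,
            columns=[
                "sample_id", "gene", "protein_change", "true_ccf",
                "true_label", "detected",
            ],
        ),
        pathways=pd.DataFrame(
            truth_pathways, columns=["sample_id", "pathway", "altered"]
        ),
        config=cfg_dict,
    )
    return variant_df, clinical_df, truth


def profiles_to_variant_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Render profiles as the canonical variant table (strings, '.' absent)."""
    from .variant_io import VARIANT_COLUMNS, _fmt

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
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["aneuploidy_tumor_fraction"])


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Render clinical records as the canonical clinical table."""
    from .variant_io import _fmt

    strata_cols: list[str] = []
    for r in records:
        for k in r.strata:
            if k not in strata_cols:
                strata_cols.append(k)
    rows = [
        {
            "sample_id": r.sample_id,
            "arm": r.arm,
            "responder": _fmt(r.responder),
            "pfs_months": _fmt(r.pfs_time),
            "pfs_event": _fmt(r.pfs_event),
            **{k: r.strata.get(k, MISSING) for k in strata_cols},
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "arm", "responder", "pfs_months", "pfs_event"]
        + strata_cols,
    )


def simulate_survival_groups(
    n_per_group: int,
    hazard_ratio: float,
    *,
    shape: float = 1.0,
    scale: float = 10.0,
    censor_range: tuple[float, float] = (1.0, 30.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two Weibull groups under exact proportional hazards (A has the HR).

    Returns (times_a, events_a, times_b, events_b); useful for checking
    hazard-ratio recovery of the survival machinery.
    """
    rng = np.random.default_rng(seed)

    def draw(h: float) -> tuple[np.ndarray, np.ndarray]:
        u = rng.random(n_per_group)
        t = scale * (-np.log(u) / h) ** (1.0 / shape)
        c = rng.uniform(*censor_range, size=n_per_group)
        return np.minimum(t, c), t <= c

    ta, ea = draw(hazard_ratio)
    tb, eb = draw(1.0)
    return ta, ea, tb, eb


@dataclass(frozen=True)
class Scorecard:
    """Recovery metrics of inferred categories/clonal fractions vs truth."""

    accuracy: float
    confusion: pd.DataFrame  # rows: truth, columns: inferred
    mae_clonal_fraction: float | None
    n_samples: int
    n_matched_variants: int


def truth_scorecard(truth: SyntheticTruth, inferred: pd.DataFrame) -> Scorecard:
    """Score an inferred category table against the simulator's truth.

    ``inferred`` needs columns ``sample_id`` and ``clonality_category``; a
    ``clonal_fractions`` column (as parsed by ``read_category_table``)
    additionally enables the CCF calibration metric over detected PIK3CA
    mutations.
    """
    t = truth.samples.set_index("sample_id")
    inf = inferred.set_index("sample_id")
    if set(t.index) != set(inf.index):
        raise ValueError("sample ids of truth and inferred tables differ")
    merged = t.join(inf, how="inner")
    correct = merged["true_category"] == merged["clonality_category"]
    confusion = pd.crosstab(
        merged["true_category"], merged["clonality_category"], dropna=False
    )
    mae = None
    n_matched = 0
    if "clonal_fractions" in inf.columns:
        true_ccf = truth.variants.set_index(
            ["sample_id", "gene", "protein_change"]
        )["true_ccf"]
        errs = []
        for sid, entries in inf["clonal_fractions"].items():
            for gene, pchange, cf, _label in entries:
                key = (sid, gene, pchange)
                if cf is not None and key in true_ccf.index:
                    errs.append(abs(cf - float(true_ccf.loc[key])))
        if errs:
            mae = float(np.mean(errs))
            n_matched = len(errs)
    return Scorecard(
        accuracy=float(correct.mean()) if len(merged) else float("nan"),
        confusion=confusion,
        mae_clonal_fraction=mae,
        n_samples=len(merged),
        n_matched_variants=n_matched,
    )
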