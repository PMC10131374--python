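"""End-to-end orchestration: simulate -> categorize -> coalter -> outcomes.

Each stage reads and writes flat tab-delimited/JSON files so any stage can
be rerun in isolation; a run manifest records the config snapshot, seed,
package version and SHA-256 digests of every output, making runs with the
same seed and config verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clonality import annotate_sample, cohort_flow
from .outcomes import compare_orr, compare_survival, km_curve, orr_with_exact_ci
from .pathway_coalteration import (
    DEFAULT_PATHWAY_CONFIG,
    compare_groups,
    gene_alteration_matrix,
    pairwise_pathway_association,
    pathway_alteration_matrix,
)
from .synthetic_data import SimulationConfig, simulate_cohort
from .variant_io import (
    AssayMode,
    ClonalityCategory,
    read_category_table,
    read_clinical_table,
    read_variant_table,
    write_category_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "StageError", "load_simulation_config", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    version: str
    config: dict
    digests: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a JSON or YAML mapping of field names."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("ccf_clonal_range", "ccf_subclonal_range", "ch_af_range", "censor_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "assay_mode" in raw:
        raw["assay_mode"] = AssayMode(raw["assay_mode"])
    return SimulationConfig(**raw)


def run_all(
    config: SimulationConfig | str | Path | None = None,
    out_dir: str | Path = "clonarch_run",
    *,
    seed: int | None = None,
    with_clinical: bool = True,
) -> RunManifest:
    """Run every stage on a simulated cohort and write all outputs.

    ``config`` may be a SimulationConfig, a JSON/YAML config path, or None
    for defaults; ``seed`` overrides the config seed. Outputs: the two
    input tables plus truth files, the per-sample category table, flow
    counts, gene/pathway comparison tables, ORR and PFS summaries, and
    ``manifest.json``. A stage failure raises :class:`StageError` naming
    the stage; outputs written so far are kept.
    """
    if config is None:
        config = SimulationConfig()
    elif not isinstance(config, SimulationConfig):
        config = load_simulation_config(config)
    if seed is not None:
        config.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        version=__version__,
        config=dataclasses.asdict(config),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.config["assay_mode"] = AssayMode(config.assay_mode).value

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: done in %.2fs", name, manifest.timings[name])
            return result

        return wrap

    # ------------------------------------------------------------ simulate
    def _simulate():
        variant_df, clinical_df, truth = simulate_cohort(config)
        variant_df.to_csv(out / "variants.tsv", sep="\t", index=False)
        clinical_df.to_csv(out / "clinical.tsv", sep="\t", index=False)
        truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
        truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
        truth.pathways.to_csv(out / "truth_pathways.tsv", sep="\t", index=False)

    stage("simulate")(_simulate)

    # ---------------------------------------------------------- categorize
    def _categorize():
        profiles = read_variant_table(out / "variants.tsv", config.assay_mode)
        for p in profiles:
            annotate_sample(p)
        write_category_table(profiles, out / "categories.tsv")
        clinical = (
            read_clinical_table(out / "clinical.tsv") if with_clinical else None
        )
        flow = cohort_flow(profiles, clinical)
        flow.to_csv(out / "flow_counts.tsv", sep="\t", index=False)
        (out / "flow_counts.json").write_text(
            json.dumps(flow.set_index("category")["total"].to_dict(), indent=2)
        )
        return profiles

    profiles = stage("categorize")(_categorize)

    # ------------------------------------------------------------- coalter
    def _coalter():
        by_cat = {
            cat: [
                p.sample_id
                for p in profiles
                if p.clonality_category == cat
            ]
            for cat in ClonalityCategory
        }
        group_a = by_cat[ClonalityCategory.CLONAL_MULTIPLE]
        group_b = by_cat[ClonalityCategory.SUBCLONAL_MULTIPLE]
        gm = gene_alteration_matrix(profiles)
        pm = pathway_alteration_matrix(profiles, DEFAULT_PATHWAY_CONFIG)
        gm.to_long().to_csv(out / "gene_tiles.tsv", sep="\t", index=False)
        pm.to_long().to_csv(out / "pathway_tiles.tsv", sep="\t", index=False)
        if group_a and group_b:
            compare_groups(gm, group_a, group_b).to_csv(
                out / "gene_comparisons.tsv", sep="\t", index=False
            )
            compare_groups(pm, group_a, group_b).to_csv(
                out / "pathway_comparisons.tsv", sep="\t", index=False
            )
            pairwise_pathway_association(pm).to_csv(
                out / "pathway_pairwise.tsv", sep="\t", index=False
            )
        else:
            logger.warning("a clonality group is empty; co-alteration tables skipped")

    stage("coalter")(_coalter)

    # ------------------------------------------------------------ outcomes
    if not with_clinical or not (out / "clinical.tsv").exists():
        logger.info("no clinical table; outcomes stage skipped")
    else:

        def _outcomes():
            categories = read_category_table(out / "categories.tsv")
            clinical = read_clinical_table(out / "clinical.tsv")
            clin = {c.sample_id: c for c in clinical}
            cat_of = dict(
                zip(categories["sample_id"], categories["clonality_category"])
            )
            summary: dict = {"orr": [], "orr_comparisons": [], "pfs": []}

            def members(cat: str, arm: str | None):
                return [
                    clin[sid]
                    for sid, c in cat_of.items()
                    if c == cat
                    and sid in clin
                    and (arm is None or clin[sid].arm == arm)
                    and clin[sid].responder is not None
                ]

            cats = [c.value for c in ClonalityCategory]
            for cat in cats:
                for arm in (None, "control", "experimental"):
                    group = members(cat, arm)
                    if not group:
                        continue
                    res = orr_with_exact_ci(
                        sum(bool(r.responder) for r in group), len(group)
                    )
                    summary["orr"].append(
                        {
                            "category": cat,
                            "arm": arm or "both",
                            "responders": res.responders,
                            "total": res.total,
                            "orr": res.orr,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "display": res.display(),
                        }
                    )
            cm, sm = (
                ClonalityCategory.CLONAL_MULTIPLE.value,
                ClonalityCategory.SUBCLONAL_MULTIPLE.value,
            )
            for arm in (None, "control", "experimental"):
                ga, gb = members(cm, arm), members(sm, arm)
                if ga and gb:
                    p = compare_orr(
                        [bool(r.responder) for r in ga],
                        [bool(r.responder) for r in gb],
                    )
                    summary["orr_comparisons"].append(
                        {"groups": f"{cm} vs {sm}", "arm": arm or "both", "p_value": p}
                    )
                if (
                    ga
                    and gb
                    and any(r.pfs_event for r in ga)
                    and any(r.pfs_event for r in gb)
                ):
                    sc = compare_survival(
                        [r.pfs_time for r in ga],
                        [r.pfs_event for r in ga],
                        [r.pfs_time for r in gb],
                        [r.pfs_event for r in gb],
                        label_a=cm,
                        label_b=sm,
                    )
                    summary["pfs"].append(
                        {
                            "arm": arm or "both",
                            "median_a": sc.median_a,
                            "median_b": sc.median_b,
                            "hazard_ratio": sc.hazard_ratio,
                            "hr_ci": [sc.hr_ci_low, sc.hr_ci_high],
                            "logrank_p": sc.logrank_p,
                        }
                    )
            km_rows = []
            for cat in (cm, sm):
                for arm in ("control", "experimental"):
                    group = members(cat, arm)
                    if not group:
                        continue
                    curve = km_curve(
                        [r.pfs_time for r in group], [r.pfs_event for r in group]
                    )
                    for t, s in zip(curve.timeline, curve.survival):
                        km_rows.append(
                            {"category": cat, "arm": arm, "time": t, "survival": s}
                        )
            pd.DataFrame(km_rows).to_csv(
                out / "km_coordinates.tsv", sep="\t", index=False
            )
            pd.DataFrame(summary["orr"]).to_csv(
                out / "orr_table.tsv", sep="\t", index=False
            )
            (out / "outcomes_summary.json").write_text(
                json.dumps(summary, indent=2, default=float)
            )

        stage("outcomes")(_outcomes)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.digests[f.name] = _digest(f)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
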