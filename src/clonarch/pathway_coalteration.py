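"""Gene- and pathway-level alteration status and exact 2x2 comparisons.

A gene (or pathway) is "altered" in a sample when at least one pathogenic
alteration — base substitution, indel, copy-number alteration or
rearrangement of known or likely oncogenic significance — is detected in
that gene (or in any retained gene of the pathway's list). PIK3CA itself is
removed from the PI3K pathway list in the default configuration so that
pathway comparisons between PIK3CA-clonality groups are not tautological.

Group comparisons use the two-sided Fisher exact test (sum of hypergeometric
point probabilities no larger than the observed table's), with no multiple
testing adjustment by default; an optional Benjamini-Hochberg column is
available for reuse beyond the original analysis design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Oncogenicity, PathwayConfig, SampleProfile

PATHOGENIC = (Oncogenicity.KNOWN, Oncogenicity.LIKELY)

# Approximate pathway gene lists over a liquid-panel-like gene universe;
# user-overridable (PathwayConfig or load_pathway_config).
DEFAULT_PATHWAYS: dict[str, frozenset[str]] = {
    "RTK": frozenset(
        {
            "EGFR", "ERBB2", "ERBB3", "FGFR1", "FGFR2", "FGFR3", "MET",
            "ALK", "RET", "KIT", "PDGFRA", "NTRK1", "FLT3",
        }
    ),
    "PI3K": frozenset(
        {
            "PIK3CA", "PTEN", "AKT1", "AKT2", "AKT3", "PIK3R1", "MTOR",
            "TSC1", "TSC2", "STK11", "RICTOR",
        }
    ),
    "MAPK": frozenset(
        {"KRAS", "NRAS", "HRAS", "BRAF", "RAF1", "MAP2K1", "MAP2K2", "NF1"}
    ),
    "p53": frozenset({"TP53", "MDM2", "MDM4", "CDKN2A", "ATM", "CHEK2"}),
}

DEFAULT_PATHWAY_CONFIG = PathwayConfig(
    pathways=DEFAULT_PATHWAYS,
    excluded_genes={"PI3K": frozenset({"PIK3CA"})},
)

__all__ = [
    "DEFAULT_PATHWAYS",
    "DEFAULT_PATHWAY_CONFIG",
    "AlterationMatrix",
    "GroupComparison",
    "load_pathway_config",
    "pathway_altered",
    "gene_alteration_matrix",
    "pathway_alteration_matrix",
    "fisher_exact_2x2",
    "compare_groups",
    "pairwise_pathway_association",
]


def load_pathway_config(path: str | Path) -> PathwayConfig:
    """Load pathway gene lists from JSON: {"pathways": {...}, "excluded_genes": {...}}."""
    raw = json.loads(Path(path).read_text())
    return PathwayConfig(
        pathways={k: frozenset(v) for k, v in raw["pathways"].items()},
        excluded_genes={
            k: frozenset(v) for k, v in raw.get("excluded_genes", {}).items()
        },
    )


@dataclass
class AlterationMatrix:
    """Samples x columns alteration-status matrix.

    ``types`` holds, per cell, the set of distinct alteration types observed
    (empty set = unaltered). ``status`` summarizes each cell as
    none / one_type / multiple_types.
    """

    types: pd.DataFrame  # object cells: frozenset of alteration-type strings

    @property
    def sample_ids(self) -> list[str]:
        return list(self.types.index)

    @property
    def columns(self) -> list[str]:
        return list(self.types.columns)

    @property
    def altered(self) -> pd.DataFrame:
        return self.types.map(lambda s: len(s) > 0)

    @property
    def status(self) -> pd.DataFrame:
        def cell(s: frozenset) -> str:
            if not s:
                return "none"
            return "one_type" if len(s) == 1 else "multiple_types"

        return self.types.map(cell)

    def to_long(self) -> pd.DataFrame:
        """Tile-plot-ready long format (sample_id, label, status, types)."""
        rows = []
        for sid in self.types.index:
            for col in self.types.columns:
                s = self.types.at[sid, col]
                if s:
                    rows.append(
                        {
                            "sample_id": sid,
                            "label": col,
                            "status": "one_type" if len(s) == 1 else "multiple_types",
                            "types": ";".join(sorted(s)),
                        }
                    )
        return pd.DataFrame(rows, columns=["sample_id", "label", "status", "types"])


def pathway_altered(
    sample: SampleProfile, pathway: str, config: PathwayConfig = DEFAULT_PATHWAY_CONFIG
) -> bool:
    """True iff the sample has >= 1 pathogenic alteration in a retained pathway gene."""
    try:
        genes = config.genes(pathway)
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    return any(
        v.gene in genes and v.oncogenicity in PATHOGENIC for v in sample.variants
    )


def gene_alteration_matrix(
    profiles: Sequence[SampleProfile], genes: Iterable[str] | None = None
) -> AlterationMatrix:
    """Per-gene pathogenic alteration-type sets across samples.

    When ``genes`` is omitted, columns are all genes with at least one
    pathogenic alteration anywhere in the cohort, sorted.
    """
    sets: dict[str, dict[str, set[str]]] = {p.sample_id: {} for p in profiles}
    observed: set[str] = set()
    for p in profiles:
        for v in p.variants:
            if v.oncogenicity in PATHOGENIC:
                observed.add(v.gene)
                sets[p.sample_id].setdefault(v.gene, set()).add(
                    v.alteration_type.value
                )
    cols = sorted(observed) if genes is None else list(genes)
    data = {
        col: [frozenset(sets[p.sample_id].get(col, set())) for p in profiles]
        for col in cols
    }
    return AlterationMatrix(
        pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=cols)
    )


def pathway_alteration_matrix(
    profiles: Sequence[SampleProfile],
    config: PathwayConfig = DEFAULT_PATHWAY_CONFIG,
) -> AlterationMatrix:
    """Per-pathway alteration-type sets (union over retained pathway genes)."""
    names = list(config.pathways)
    rows = []
    for p in profiles:
        row = {}
        for name in names:
            genes = config.genes(name)
            row[name] = frozenset(
                v.alteration_type.value
                for v in p.variants
                if v.gene in genes and v.oncogenicity in PATHOGENIC
            )
        rows.append(row)
    return AlterationMatrix(
        pd.DataFrame(rows, index=[p.sample_id for p in profiles], columns=names)
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums the hypergeometric point probabilities of every table with the
    same margins whose probability does not exceed the observed table's.
    Degenerate tables (an all-zero margin) return p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class GroupComparison:
    """Alteration prevalence of one gene/pathway in two sample groups."""

    label: str
    altered_a: int
    size_a: int
    altered_b: int
    size_b: int
    p_value: float

    @property
    def proportion_a(self) -> float:
        return self.altered_a / self.size_a

    @property
    def proportion_b(self) -> float:
        return self.altered_b / self.size_b

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.altered_a, self.size_a - self.altered_a],
            [self.altered_b, self.size_b - self.altered_b],
        ]


def compare_groups(
    matrix: AlterationMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    adjust: bool = False,
) -> pd.DataFrame:
    """Fisher-exact comparison of alteration prevalence per column.

    Columns altered in neither group are omitted (tile-plot semantics).
    No multiplicity adjustment by default; ``adjust=True`` appends a
    Benjamini-Hochberg ``q_value`` column.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    missing = (a | b) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"sample ids not in matrix: {sorted(missing)}")
    altered = matrix.altered
    rows = []
    for col in matrix.columns:
        ka = int(altered.loc[list(group_a), col].sum())
        kb = int(altered.loc[list(group_b), col].sum())
        if ka == 0 and kb == 0:
            continue
        comp = GroupComparison(
            label=col,
            altered_a=ka,
            size_a=len(a),
            altered_b=kb,
            size_b=len(b),
            p_value=fisher_exact_2x2(
                [[ka, len(a) - ka], [kb, len(b) - kb]]
            ),
        )
        rows.append(
            {
                "label": comp.label,
                "altered_a": comp.altered_a,
                "size_a": comp.size_a,
                "proportion_a": comp.proportion_a,
                "altered_b": comp.altered_b,
                "size_b": comp.size_b,
                "proportion_b": comp.proportion_b,
                "p_value": comp.p_value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label", "altered_a", "size_a", "proportion_a",
            "altered_b", "size_b", "proportion_b", "p_value",
        ],
    )
    if adjust and len(df):
        df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def pairwise_pathway_association(
    matrix: AlterationMatrix, pathways: Sequence[str] | None = None
) -> pd.DataFrame:
    """Co-occurrence / mutual-exclusivity screen over pathway pairs.

    For each pair, the 2x2 of joint alteration status across samples gives
    a Fisher p-value and an odds ratio; zero cells get the Haldane-Anscombe
    0.5 correction (flagged in the ``corrected`` column).
    """
    names = list(pathways) if pathways is not None else matrix.columns
    if len(names) < 2:
        raise ValueError("need at least two pathways")
    altered = matrix.altered
    rows = []
    for pa, pb in combinations(names, 2):
        a = altered[pa].to_numpy(dtype=bool)
        b = altered[pb].to_numpy(dtype=bool)
        t = np.array(
            [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
        )
        p = fisher_exact_2x2(t)
        corrected = bool((t == 0).any())
        tt = t + 0.5 if corrected else t
        odds = float(tt[0, 0] * tt[1, 1] / (tt[0, 1] * tt[1, 0]))
        rows.append(
            {
                "pathway_a": pa,
                "pathway_b": pb,
                "both": int(t[0, 0]),
                "a_only": int(t[0, 1]),
                "b_only": int(t[1, 0]),
                "neither": int(t[1, 1]),
                "odds_ratio": odds,
                "corrected": corrected,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
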