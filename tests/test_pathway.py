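"""Pathway status, Fisher exact p-values (vs enumeration oracle), comparisons."""

import numpy as np
import pytest
from scipy import stats

from clonarch import (
    AlterationType,
    Oncogenicity,
    compare_groups,
    fisher_exact_2x2,
    gene_alteration_matrix,
    pairwise_pathway_association,
    pathway_alteration_matrix,
    pathway_altered,
)
from clonarch.pathway_coalteration import DEFAULT_PATHWAY_CONFIG

from conftest import profile, snv


def fisher_oracle(table):
    """Brute-force two-sided Fisher p: enumerate all tables with the
    observed margins and sum hypergeometric point probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    probs = {
        x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


class TestPathwayAltered:
    def test_membership_with_pathogenic_alteration(self):
        p = profile([snv(gene="ERBB2", af=0.1, onc=Oncogenicity.KNOWN)])
        assert pathway_altered(p, "RTK")

    def test_pik3ca_excluded_from_pi3k_by_default(self):
        p = profile([snv(gene="PIK3CA", af=0.1, onc=Oncogenicity.KNOWN)])
        assert not pathway_altered(p, "PI3K")
        # but a PTEN alteration still counts
        q = profile([snv(gene="PTEN", af=0.1, onc=Oncogenicity.LIKELY)])
        assert pathway_altered(q, "PI3K")

    def test_vus_only_sample_is_unaltered(self):
        p = profile([snv(gene="ERBB2", af=0.1, onc=Oncogenicity.VUS)])
        assert not pathway_altered(p, "RTK")

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError, match="WNT"):
            pathway_altered(profile([]), "WNT")


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,printed,sig",
        [
            ([[9, 38], [9, 10]], 0.032, 2),
            ([[82, 323], [35, 80]], 0.0233, 3),
            ([[22, 383], [15, 100]], 0.0119, 3),
            ([[156, 582], [98, 193]], 4.01e-5, 3),
            ([[45, 693], [38, 253]], 5.09e-4, 3),
            ([[177, 561], [48, 243]], 9.34e-3, 3),
            ([[3, 244], [3, 21]], 0.0103, 3),
            ([[6, 241], [3, 21]], 0.0361, 3),
        ],
    )
    def test_reproduces_reported_contingency_p_values(self, table, printed, sig):
        p = fisher_exact_2x2(table)
        assert p == pytest.approx(printed, rel=10 ** (1 - sig) / 2 + 5e-3)
        assert round(p, -int(np.floor(np.log10(printed))) + sig - 1) == printed

    def test_zero_signal_table(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 5], [0, 5]]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            t = rng.integers(0, 50, size=(2, 2))
            if t.sum() > 200:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(t), rel=1e-7
            )

    def test_invariant_to_simultaneous_row_and_column_swaps(self):
        t = [[7, 12], [3, 25]]
        swapped = [[25, 3], [12, 7]]
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_exact_2x2(swapped), rel=1e-12
        )


def _toy_cohort():
    """6 samples, 2 genes: TP53 altered in A only (3 vs 0), ERBB2 1 vs 1."""
    profiles = []
    for i in range(3):
        variants = [snv(gene="TP53", af=0.1, pchange="R175H")]
        if i == 0:
            variants.append(snv(gene="ERBB2", af=0.1, pchange="V842I"))
        p = profile(variants, sample_id=f"A{i}")
        profiles.append(p)
    for i in range(3):
        variants = []
        if i == 0:
            variants.append(snv(gene="ERBB2", af=0.1, pchange="V842I"))
        profiles.append(profile(variants, sample_id=f"B{i}"))
    return profiles


class TestCompareGroups:
    def test_toy_counts_match_enumeration_oracle(self):
        matrix = gene_alteration_matrix(_toy_cohort())
        df = compare_groups(matrix, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        df = df.set_index("label")
        assert df.loc["TP53", ["altered_a", "altered_b"]].tolist() == [3, 0]
        assert df.loc["TP53", "p_value"] == pytest.approx(
            fisher_oracle([[3, 0], [0, 3]])
        )
        assert df.loc["ERBB2", "p_value"] == pytest.approx(
            fisher_oracle([[1, 2], [1, 2]])
        )

    def test_identical_groups_give_p_one(self):
        profiles = _toy_cohort()
        # duplicate group A's variant content under new ids
        dup = []
        for p in profiles[:3]:
            q = profile(list(p.variants), sample_id="D" + p.sample_id)
            dup.append(q)
        matrix = gene_alteration_matrix(profiles[:3] + dup)
        df = compare_groups(matrix, ["A0", "A1", "A2"], ["DA0", "DA1", "DA2"])
        assert (df["p_value"] == 1.0).all()

    def test_column_altered_in_neither_group_omitted(self):
        profiles = _toy_cohort()
        matrix = gene_alteration_matrix(profiles, genes=["TP53", "ERBB2", "KRAS"])
        df = compare_groups(matrix, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert "KRAS" not in set(df["label"])

    def test_empty_or_overlapping_groups_rejected(self):
        matrix = gene_alteration_matrix(_toy_cohort())
        with pytest.raises(ValueError, match="nonempty"):
            compare_groups(matrix, [], ["B0"])
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(matrix, ["A0"], ["A0", "B0"])

    def test_optional_bh_adjustment_is_monotone(self):
        matrix = gene_alteration_matrix(_toy_cohort())
        df = compare_groups(
            matrix, ["A0", "A1", "A2"], ["B0", "B1", "B2"], adjust=True
        )
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()
        assert (df["q_value"] <= 1.0).all()


class TestPairwisePathwayAssociation:
    def test_perfect_cooccurrence_corrected_odds(self):
        profiles = []
        for i in range(5):
            profiles.append(
                profile(
                    [
                        snv(gene="ERBB2", af=0.1),
                        snv(gene="KRAS", af=0.1, pchange="G12D"),
                    ],
                    sample_id=f"S{i}",
                )
            )
        for i in range(5, 10):
            profiles.append(profile([], sample_id=f"S{i}"))
        matrix = pathway_alteration_matrix(profiles, DEFAULT_PATHWAY_CONFIG)
        df = pairwise_pathway_association(matrix, ["RTK", "MAPK"])
        row = df.iloc[0]
        assert row["corrected"]
        assert np.isfinite(row["odds_ratio"]) and row["odds_ratio"] > 1
        assert row["p_value"] == pytest.approx(fisher_oracle([[5, 0], [0, 5]]))

    def test_independent_pathways_type_i_error_near_nominal(self):
        rng = np.random.default_rng(42)
        n, reps = 500, 200
        rejections = 0
        for _ in range(reps):
            a = rng.random(n) < 0.3
            b = rng.random(n) < 0.3
            t = [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
            if fisher_exact_2x2(t) < 0.05:
                rejections += 1
        rate = rejections / reps
        # exact test is conservative: reject at most ~5% plus binomial noise
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_sample_cohort_p_one(self):
        profiles = [profile([snv(gene="ERBB2", af=0.1)], sample_id="S0")]
        matrix = pathway_alteration_matrix(profiles, DEFAULT_PATHWAY_CONFIG)
        with pytest.warns(UserWarning):
            df = pairwise_pathway_association(matrix)
        assert (df["p_value"] == 1.0).all()

    def test_requires_two_pathways(self):
        matrix = pathway_alteration_matrix(
            [profile([], sample_id="S0")], DEFAULT_PATHWAY_CONFIG
        )
        with pytest.raises(ValueError, match="two pathways"):
            pairwise_pathway_association(matrix, ["RTK"])
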