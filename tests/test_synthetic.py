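"""The synthetic generators: determinism, validation, and recovery of
every planted effect by the consuming analysis stage."""

import numpy as np
import pandas as pd
import pytest

from lncmeth import (
    CohortSpec,
    PlantedSite,
    SequenceSpec,
    classify_seed,
    mann_whitney,
    qmsp_level,
    revcomp,
    simulate_cohort,
    simulate_expression_matrix,
    simulate_sequences,
    simulate_survival,
    smith_waterman,
    spearman,
)
from lncmeth.align import ScoringScheme
from lncmeth.stats import expr_col, meth_col


class TestDeterminism:
    def test_cohort_byte_identical_under_same_seed(self):
        f1, c1 = simulate_cohort(CohortSpec(seed=42), make_ct=True)
        f2, c2 = simulate_cohort(CohortSpec(seed=42), make_ct=True)
        assert f1.to_csv() == f2.to_csv()
        assert c1.to_csv() == c2.to_csv()

    def test_matrix_and_sequences_deterministic(self):
        net = [("L1", "M1", 0.5)]
        m1 = simulate_expression_matrix(50, net, seed=3)
        m2 = simulate_expression_matrix(50, net, seed=3)
        assert m1.equals(m2)
        spec = SequenceSpec(n_background=2, length_range=(100, 200), seed=9)
        s1 = {r.id: str(r.seq) for r in simulate_sequences(spec)}
        s2 = {r.id: str(r.seq) for r in simulate_sequences(spec)}
        assert s1 == s2

    def test_different_seed_differs(self):
        f1, _ = simulate_cohort(CohortSpec(seed=1))
        f2, _ = simulate_cohort(CohortSpec(seed=2))
        assert not f1.equals(f2)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, msg",
        [
            ({"n_patients": 1}, "n_patients"),
            ({"censoring_rate": 1.5}, "censoring_rate"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"coupling_slope": 2.0}, "coupling_slope"),
            ({"fraction_with_metastasis": {"peritoneal": 1.2}}, "peritoneal"),
            ({"fraction_with_metastasis": {"cranial": 0.1}}, "cranial"),
        ],
    )
    def test_bad_values_name_the_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            CohortSpec(**kwargs)


class TestCohortStructure:
    def test_composition(self, default_cohort):
        frame, _ = default_cohort
        counts = frame["tissue"].value_counts()
        assert counts["T"] == 140 and counts["N"] == 123
        assert counts["PM"] == 59 and counts["D"] == 18
        pm_pat = set(frame.loc[frame["tissue"] == "PM", "patient"])
        t_pat = set(frame.loc[frame["tissue"] == "T", "patient"])
        assert pm_pat <= t_pat  # every PM shares its patient with a tumor

    def test_null_spec_means_indistinguishable(self):
        spec = CohortSpec(methylation_shift_normal_to_tumor=0.0,
                          metastasis_shift={}, pm_reversal={}, seed=5)
        frame, _ = simulate_cohort(spec)
        t = frame.loc[frame["tissue"] == "T", meth_col("GAS5")]
        n = frame.loc[frame["tissue"] == "N", meth_col("GAS5")]
        _, p = mann_whitney(t, n)
        assert p > 0.001  # no planted effect to detect

    def test_tumor_shift_power(self):
        """With the default +0.3 shift at n=140 the Mann-Whitney rejects
        at alpha=0.001 for at least 9/10 genes in >= 95% of replicates."""
        ok = 0
        reps = 200
        for s in range(reps):
            frame, _ = simulate_cohort(CohortSpec(seed=10_000 + s))
            t = frame[frame["tissue"] == "T"]
            n = frame[frame["tissue"] == "N"]
            hits = sum(
                mann_whitney(t[meth_col(g)], n[meth_col(g)])[1] < 1e-3
                for g in CohortSpec().gene_panel
            )
            ok += hits >= 9
        assert ok / reps >= 0.95

    def test_inverse_coupling_produces_negative_correlation(self, default_cohort):
        frame, _ = default_cohort
        sub = frame[frame["tissue"].isin(["T", "N"])]
        for g in CohortSpec().gene_panel:
            rs = spearman(sub[meth_col(g)], sub[expr_col(g)]).rs
            assert rs < -0.3

    def test_ct_table_round_trips_methylation(self, default_cohort):
        frame, ct = default_cohort
        lv = qmsp_level(ct, "meth_MEG3", "FULLY_METH")
        got = pd.DataFrame([vars(x) for x in lv]).set_index("sample")["pmr"]
        want = frame.set_index("sample")[meth_col("MEG3")]
        rel = ((got.reindex(want.index) - want).abs() / want).max()
        assert rel < 1e-9

    def test_ct_table_round_trips_expression(self, default_cohort):
        frame, ct = default_cohort
        from lncmeth.qpcr import aggregate_replicates

        agg = aggregate_replicates(ct)
        sub = agg[agg["assay"].isin(["expr_GAS5", "B2M"])]
        piv = sub.pivot(index="sample", columns="assay", values="ct")
        dct = piv["expr_GAS5"] - piv["B2M"]
        want = frame.set_index("sample")[expr_col("GAS5")]
        assert ((-dct.reindex(want.index)) - want).abs().max() < 1e-9


class TestExpressionMatrix:
    def test_planted_edges_realized_within_tolerance(self):
        net = [("L1", "M1", 0.7), ("L1", "R1", -0.6), ("L2", "M2", 0.4)]
        m = simulate_expression_matrix(400, net, seed=6)
        for src, tgt, target_rs in net:
            rs = spearman(m.loc[src], m.loc[tgt]).rs
            assert rs == pytest.approx(target_rs, abs=0.1)

    def test_empty_network_null_distribution(self):
        m = simulate_expression_matrix(100, [], seed=1, n_background=30)
        rs = []
        genes = list(m.index)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                rs.append(abs(spearman(m.loc[a], m.loc[b]).rs))
        assert np.percentile(rs, 95) < 0.3

    def test_mirna_screen_recovers_planted_edge(self):
        """A planted rs = -0.7 edge passes the miRNA screen thresholds
        (rs < -0.6, p < 0.0025) in >= 80% of replicates at n = 60."""
        from lncmeth.screen import ScreenConfig, screen_partners

        cfg = ScreenConfig.mirna_default()
        hits = 0
        for s in range(100):
            m = simulate_expression_matrix(60, [("L1", "R1", -0.7)], seed=s)
            got = screen_partners(m, ["L1"], cfg, partners=["R1"])
            hits += len(got) == 1
        assert hits >= 80

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_expression_matrix(
                20, [("L1", "M1", 0.5), ("L2", "M1", 0.5)], seed=0
            )

    def test_chain_must_be_source_first(self):
        with pytest.raises(ValueError, match="source-first"):
            simulate_expression_matrix(
                20, [("M1", "M2", 0.5), ("L1", "M1", 0.5)], seed=0
            )

    def test_out_of_range_rs_rejected(self):
        with pytest.raises(ValueError, match="target rs"):
            simulate_expression_matrix(20, [("L1", "M1", 1.0)], seed=0)


def longest_complementary_run(a: str, b: str) -> int:
    """Longest exact complementary run between two sequences (longest
    common substring of a and revcomp(b)), by diagonal scanning."""
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(revcomp(b).encode(), dtype=np.uint8)
    eq = x[:, None] == y[None, :]
    best = 0
    for off in range(-len(x) + 1, len(y)):
        d = np.diagonal(eq, offset=off).astype(int)
        if d.size <= best:
            continue
        run = 0
        m = 0
        for v in d:
            run = run + 1 if v else 0
            m = max(m, run)
        best = max(best, m)
    return best


class TestSequences:
    def test_planted_revcomp_segment_aligns_full_length(self):
        spec = SequenceSpec(
            length_range=(300, 600),
            planted_sites=(PlantedSite("HOST", "GUEST", "revcomp", 32, 120),),
            seed=4,
        )
        seqs = {r.id: str(r.seq) for r in simulate_sequences(spec)}
        aln = smith_waterman(
            seqs["GUEST"][:32], seqs["HOST"], ScoringScheme(), mode="complementarity"
        )
        assert aln.matches >= 32
        assert aln.b_start <= 120 and aln.b_end >= 152

    @pytest.mark.parametrize(
        "site_type", ["6mer", "7mer-A1", "7mer-m8", "8mer", "7mer-m8 g-bulged"]
    )
    def test_planted_seed_site_classifies_to_declared_type(self, site_type):
        spec = SequenceSpec(
            length_range=(200, 300),
            planted_sites=(
                PlantedSite("HOST", "MIR", f"seed:{site_type}", 8, 90),
            ),
            guest_lengths={"MIR": 22},
            seed=11,
        )
        seqs = {r.id: str(r.seq) for r in simulate_sequences(spec)}
        hits = classify_seed(seqs["MIR"], seqs["HOST"])
        assert any(
            s.site_type == site_type and abs(s.position - 90) <= 1 for s in hits
        )

    def test_overlapping_plants_rejected(self):
        spec_kwargs = dict(
            length_range=(300, 400),
            planted_sites=(
                PlantedSite("HOST", "G1", "revcomp", 30, 100),
                PlantedSite("HOST", "G2", "revcomp", 30, 110),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_sequences(SequenceSpec(**spec_kwargs))

    def test_no_planted_sites_no_long_spurious_runs(self):
        """Random backgrounds of 500-1000 nt keep the longest spurious
        exact complementary run well below 15 nt."""
        for s in range(20):
            spec = SequenceSpec(n_background=2, length_range=(500, 1000),
                                seed=300 + s)
            seqs = [str(r.seq) for r in simulate_sequences(spec)]
            assert longest_complementary_run(seqs[0], seqs[1]) < 15


class TestSurvivalHelper:
    def test_reproducible_and_rate_sensible(self):
        d1 = simulate_survival(500, hazard_ratio=2.0, seed=3)
        d2 = simulate_survival(500, hazard_ratio=2.0, seed=3)
        assert d1.equals(d2)
        assert 0.1 < d1["event"].mean() <= 1.0
        # exposed arm dies faster on average
        assert (
            d1.loc[d1["exposed"] == 1, "time"].mean()
            < d1.loc[d1["exposed"] == 0, "time"].mean()
        )
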