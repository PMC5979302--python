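"""Read-count frequencies, run CI99% statistics, and the global gene ratio."""

import numpy as np
import pandas as pd
import pytest
from ampcnv.rc_cnv import (
    ReadCountMatrix,
    flag_rc_outliers,
    global_gene_ratio,
    rc_frequency,
    run_ci99,
)
from ampcnv.states import RcFlag
from ampcnv.synthetic import CnvSpec, NoiseModel, gen_cohort_with_case, gen_counts


def matrix_from_counts(panel, rows):
    ids = [a.id for a in panel.amplicons]
    return ReadCountMatrix(
        counts=pd.DataFrame(rows, columns=ids).set_axis(
            [f"S{i+1}" for i in range(len(rows))]
        ),
        panel=panel,
    )


class TestFrequency:
    def test_two_amplicon_plex_arithmetic(self, panel):
        """Counts (300, 100) within a plex yield frequencies (0.75, 0.25)."""
        ids = [a.id for a in panel.amplicons]
        row = {aid: 100 for aid in ids}
        a_ids = [a.id for a in panel.amplicons_in_plex("A")]
        # plex A: one amplicon at 300, the rest at 0 except one at 100
        for aid in a_ids:
            row[aid] = 0
        row[a_ids[0]], row[a_ids[1]] = 300, 100
        m = matrix_from_counts(panel, [row])
        freq = rc_frequency(m)
        assert freq.loc["S1", a_ids[0]] == pytest.approx(0.75)
        assert freq.loc["S1", a_ids[1]] == pytest.approx(0.25)

    def test_uniform_plex_gives_equal_shares(self, panel):
        m = matrix_from_counts(panel, [{a.id: 500 for a in panel.amplicons}])
        freq = rc_frequency(m)
        for a in panel.amplicons_in_plex("A"):
            assert freq.loc["S1", a.id] == pytest.approx(1 / 17)

    def test_random_matrix_frequencies_sum_to_one_per_plex(self, panel):
        rng = np.random.default_rng(11)
        rows = [{a.id: int(rng.integers(1, 10000)) for a in panel.amplicons}
                for _ in range(6)]
        freq = rc_frequency(matrix_from_counts(panel, rows))
        for plex in panel.plexes:
            cols = [a.id for a in panel.amplicons_in_plex(plex)]
            np.testing.assert_allclose(freq[cols].sum(axis=1), 1.0,
                                       atol=1e-12)

    def test_library_size_invariance(self, panel):
        rng = np.random.default_rng(2)
        row = {a.id: int(rng.integers(100, 5000)) for a in panel.amplicons}
        scaled = {k: v * 7 for k, v in row.items()}
        f1 = rc_frequency(matrix_from_counts(panel, [row]))
        f2 = rc_frequency(matrix_from_counts(panel, [scaled]))
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_zero_plex_total_names_sample_and_plex(self, panel):
        row = {a.id: 100 for a in panel.amplicons}
        for a in panel.amplicons_in_plex("C"):
            row[a.id] = 0
        with pytest.raises(ValueError, match=r"'C'.*'S1'"):
            rc_frequency(matrix_from_counts(panel, [row]))

    def test_column_mismatch_rejected(self, panel):
        with pytest.raises(ValueError, match="panel amplicons"):
            ReadCountMatrix(
                counts=pd.DataFrame({"bogus": [1]}), panel=panel
            )


class TestRunCi99:
    def test_identical_samples_collapse_interval_to_mean(self, panel):
        rows = [{a.id: 1000 for a in panel.amplicons}] * 4
        stats = run_ci99(matrix_from_counts(panel, rows))
        assert (stats.stats["sd"] == 0).all()
        np.testing.assert_allclose(stats.stats["ci99_low"],
                                   stats.stats["mean"])
        np.testing.assert_allclose(stats.stats["ci99_high"],
                                   stats.stats["mean"])

    def test_bounds_match_hand_computation(self, panel):
        """Five constructed samples: bounds equal mean +/- 2.576 sd."""
        rng = np.random.default_rng(5)
        rows = [{a.id: int(rng.integers(500, 2000))
                 for a in panel.amplicons} for _ in range(5)]
        m = matrix_from_counts(panel, rows)
        stats = run_ci99(m)
        freq = rc_frequency(m)
        aid = panel.amplicons[0].id
        mean, sd = freq[aid].mean(), freq[aid].std(ddof=1)
        assert stats.stats.loc[aid, "ci99_low"] == pytest.approx(
            mean - 2.576 * sd)
        assert stats.stats.loc[aid, "ci99_high"] == pytest.approx(
            mean + 2.576 * sd)

    def test_exclusion_leaves_out_the_sample(self, panel):
        rows = [{a.id: 1000 for a in panel.amplicons}] * 4
        rows.append({a.id: 5000 for a in panel.amplicons})
        m = matrix_from_counts(panel, rows)
        stats = run_ci99(m, exclude_sample="S5")
        assert stats.n_baseline == 4
        assert (stats.stats["sd"] == 0).all()

    def test_too_few_baseline_samples_is_error(self, panel):
        rows = [{a.id: 1000 for a in panel.amplicons}] * 3
        with pytest.raises(ValueError, match=">= 3"):
            run_ci99(matrix_from_counts(panel, rows), exclude_sample="S1")

    def test_coverage_near_99_percent_on_normal_cohort(self, panel):
        """~99% of a seeded normal cohort's frequencies fall inside their
        own run CI99 (Monte-Carlo, +/-2% band)."""
        m = gen_counts(panel, CnvSpec.diploid(), depth=2000,
                       noise=NoiseModel(0.25, 0.05), n_samples=50, seed=123)
        stats = run_ci99(m)
        freq = rc_frequency(m)
        inside = ((freq >= stats.stats["ci99_low"])
                  & (freq <= stats.stats["ci99_high"]))
        coverage = float(inside.to_numpy().mean())
        assert 0.97 <= coverage <= 1.0


class TestFlagging:
    def _stats(self, panel):
        rows = [{a.id: 1000 + 10 * i for a in panel.amplicons}
                for i in range(5)]
        m = matrix_from_counts(panel, rows)
        return m, run_ci99(m)

    def test_mean_frequency_is_in_ci(self, panel):
        m, stats = self._stats(panel)
        flags = flag_rc_outliers(stats.stats["mean"], stats)
        assert set(flags.values()) == {RcFlag.IN_CI}

    def test_boundary_value_is_in_ci(self, panel):
        m, stats = self._stats(panel)
        flags = flag_rc_outliers(stats.stats["ci99_high"], stats)
        assert set(flags.values()) == {RcFlag.IN_CI}
        flags = flag_rc_outliers(stats.stats["ci99_high"] + 1e-9, stats)
        assert set(flags.values()) == {RcFlag.HIGH}

    def test_unknown_amplicon_is_error(self, panel):
        _, stats = self._stats(panel)
        with pytest.raises(KeyError):
            flag_rc_outliers(pd.Series({"nope": 0.1}), stats)

    def test_gene2_halved_sample_flags_split_by_gene(self, panel):
        """Raw comparison: deleted gene LOW and partner gene HIGH."""
        g1, g2 = panel.gene_labels
        m = gen_cohort_with_case(
            panel, CnvSpec.whole_gene(panel, g2, 1), n_normal=12,
            noise=NoiseModel(0.25, 0.05), seed=31,
        )
        stats = run_ci99(m, exclude_sample="CASE")
        flags = flag_rc_outliers(rc_frequency(m).loc["CASE"], stats)
        for a in panel.amplicons:
            expected = RcFlag.LOW if a.gene == g2 else RcFlag.HIGH
            assert flags[a.id] is expected, a.id

    def test_gene2_halved_recentered_flags_follow_plex_majority(self, panel):
        """With median recentering the anchor lands on the majority gene
        (gene 2 in every bundled plex), so the partner gene flags HIGH."""
        g1, g2 = panel.gene_labels
        m = gen_cohort_with_case(
            panel, CnvSpec.whole_gene(panel, g2, 1), n_normal=12,
            noise=NoiseModel(0.25, 0.05), seed=31,
        )
        stats = run_ci99(m, exclude_sample="CASE")
        flags = flag_rc_outliers(rc_frequency(m).loc["CASE"], stats,
                                 panel=panel)
        for a in panel.amplicons_for_gene(g1):
            assert flags[a.id] is RcFlag.HIGH, a.id
        # the majority gene carries the anchor: never flagged HIGH
        for a in panel.amplicons_for_gene(g2):
            assert flags[a.id] is not RcFlag.HIGH, a.id

    def test_recentering_absorbs_compositional_shift_of_partial_event(
        self, panel
    ):
        """A partial deletion drags its plex-mates' raw frequencies up;
        recentering keeps the unaffected amplicons IN_CI."""
        g1, _ = panel.gene_labels
        affected = ["D_1", "D_3", "D_5"]
        m = gen_cohort_with_case(
            panel, CnvSpec.exons(affected, 1), n_normal=12,
            noise=NoiseModel(0.25, 0.05), seed=13,
        )
        stats = run_ci99(m, exclude_sample="CASE")
        flags = flag_rc_outliers(rc_frequency(m).loc["CASE"], stats,
                                 panel=panel)
        for aid in affected:
            assert flags[aid] is RcFlag.LOW
        others = [a.id for a in panel.amplicons_in_plex("D")
                  if a.id not in affected]
        n_in = sum(flags[aid] is RcFlag.IN_CI for aid in others)
        assert n_in >= len(others) - 1

    def test_self_inclusive_cohort_flags_about_one_percent(self, panel):
        m = gen_counts(panel, CnvSpec.diploid(), depth=2000,
                       noise=NoiseModel(0.25, 0.05), n_samples=50, seed=321)
        stats = run_ci99(m)
        freq = rc_frequency(m)
        n_out = sum(
            f is not RcFlag.IN_CI
            for s in m.samples
            for f in flag_rc_outliers(freq.loc[s], stats).values()
        )
        rate = n_out / (len(m.samples) * 93)
        assert 0.0 <= rate <= 0.03


class TestGlobalGeneRatio:
    def test_calibrated_diploid_cohort_centers_on_0_7(self, panel):
        m = gen_counts(panel, CnvSpec.diploid(), n_samples=4, seed=1,
                       calibrate_gene_ratio=0.7)
        res = global_gene_ratio(m)
        np.testing.assert_allclose(res.global_ratio, 0.7, rtol=0.01)

    def test_halving_gene2_doubles_every_plex_ratio(self, panel):
        g2 = panel.gene_labels[1]
        base = gen_counts(panel, CnvSpec.diploid(), n_samples=1, seed=6,
                          calibrate_gene_ratio=0.7)
        halved = gen_counts(panel, CnvSpec.whole_gene(panel, g2, 1),
                            n_samples=1, seed=6, calibrate_gene_ratio=0.7)
        r0 = global_gene_ratio(base)
        r1 = global_gene_ratio(halved)
        for plex in panel.plexes:
            assert r1.per_plex.iloc[0][plex] == pytest.approx(
                2 * r0.per_plex.iloc[0][plex], rel=1e-3)
        assert r1.global_ratio.iloc[0] == pytest.approx(1.4, rel=0.01)

    def test_equal_gene_sums_give_unit_ratio(self, panel):
        g1, g2 = panel.gene_labels
        row = {}
        for plex in panel.plexes:
            ids1 = [a.id for a in panel.amplicons_for_gene(g1, plex)]
            ids2 = [a.id for a in panel.amplicons_for_gene(g2, plex)]
            total = len(ids1) * len(ids2) * 10
            for aid in ids1:
                row[aid] = total // len(ids1)
            for aid in ids2:
                row[aid] = total // len(ids2)
        res = global_gene_ratio(matrix_from_counts(panel, [row]))
        assert res.global_ratio.iloc[0] == pytest.approx(1.0)

    def test_zero_gene_sum_is_error(self, panel):
        g2 = panel.gene_labels[1]
        row = {a.id: 0 if a.gene == g2 else 100 for a in panel.amplicons}
        with pytest.raises(ValueError, match="zero gene-2"):
            global_gene_ratio(matrix_from_counts(panel, [row]))

    def test_aberrant_sample_flagged_against_cohort(self, panel):
        g2 = panel.gene_labels[1]
        m = gen_cohort_with_case(
            panel, CnvSpec.whole_gene(panel, g2, 1), n_normal=8,
            noise=NoiseModel(0.25, 0.05), seed=44, calibrate_gene_ratio=0.7,
        )
        res = global_gene_ratio(m)
        assert bool(res.flagged["CASE"])
        assert not res.flagged.drop("CASE").any()

    def test_wide_vs_long_tsv_round_trip(self, panel, tmp_path):
        m = gen_counts(panel, n_samples=3, seed=9)
        wide = tmp_path / "wide.tsv"
        m.to_tsv(wide)
        back = ReadCountMatrix.from_tsv(wide, panel)
        pd.testing.assert_frame_equal(back.counts, m.counts)
        long = tmp_path / "long.tsv"
        m.counts.rename_axis("sample").reset_index().melt(
            id_vars="sample", var_name="amplicon_id", value_name="count"
        ).to_csv(long, sep="\t", index=False)
        back2 = ReadCountMatrix.from_tsv(long, panel)
        pd.testing.assert_frame_equal(
            back2.counts.sort_index(), m.counts.sort_index(),
            check_names=False,
        )
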