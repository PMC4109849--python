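"""Telomere-rank assignment and positional variability scans."""

import numpy as np
import pandas as pd
import pytest

from tagen import (DataError, DegenerateTestError, assign_telomere_ranks,
                   distance_trend, positional_group_scan)


def _genes(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene_id"])


class TestAssignTelomereRanks:
    def test_three_genes_on_one_chromosome(self):
        """Genes at 100, 5000 and 9900 on a 10 kb chromosome: the outer two
        are rank 1 on their arms (distances 100 and 0 via the gene end), the
        middle gene is rank 2 on its nearer arm."""
        genes = _genes([("chr1", 100, 600, "gA"),
                        ("chr1", 5000, 5500, "gB"),
                        ("chr1", 9900, 10_000, "gC")])
        pos = assign_telomere_ranks(genes, {"chr1": 10_000}).set_index("gene_id")
        assert pos.loc["gA", "arm"] == "left"
        assert pos.loc["gA", "telomere_rank"] == 1
        assert pos.loc["gA", "distance_to_telomere"] == 100
        assert pos.loc["gC", "arm"] == "right"
        assert pos.loc["gC", "telomere_rank"] == 1
        assert pos.loc["gC", "distance_to_telomere"] == 0
        assert pos.loc["gB", "arm"] == "right"      # midpoint 5250 > 5000
        assert pos.loc["gB", "telomere_rank"] == 2
        assert pos.loc["gB", "distance_to_telomere"] == 4500

    def test_single_gene_per_arm_rank_one(self):
        genes = _genes([("chr1", 10, 20, "gL"), ("chr1", 980, 990, "gR")])
        pos = assign_telomere_ranks(genes, {"chr1": 1_000})
        assert (pos["telomere_rank"] == 1).all()

    def test_translation_invariance(self):
        genes = _genes([("chr1", 100, 300, "a"), ("chr1", 400, 600, "b"),
                        ("chr1", 800, 950, "c")])
        base = assign_telomere_ranks(genes, {"chr1": 1_000})
        shifted = genes.assign(start=genes["start"] + 10, end=genes["end"] + 10)
        moved = assign_telomere_ranks(shifted, {"chr1": 1_010})
        pd.testing.assert_series_equal(
            base.set_index("gene_id")["telomere_rank"],
            moved.set_index("gene_id")["telomere_rank"])

    def test_rank_bijection_within_arm(self):
        rng = np.random.default_rng(0)
        starts = rng.choice(np.arange(0, 9_000, 10), 40, replace=False)
        genes = _genes([("chr1", int(s), int(s) + 5, f"g{i}")
                        for i, s in enumerate(starts)])
        pos = assign_telomere_ranks(genes, {"chr1": 10_000})
        for _, arm in pos.groupby("arm"):
            assert sorted(arm["telomere_rank"]) == list(range(1, len(arm) + 1))

    def test_centromere_split_overrides_midpoint(self):
        genes = _genes([("chr1", 400, 450, "g")])
        mid = assign_telomere_ranks(genes, {"chr1": 1_000})
        cen = assign_telomere_ranks(genes, {"chr1": 1_000}, centromeres={"chr1": 300})
        assert mid.loc[0, "arm"] == "left"
        assert cen.loc[0, "arm"] == "right"
        assert cen.loc[0, "distance_to_telomere"] == 550

    def test_out_of_bounds_coordinates(self):
        with pytest.raises(DataError):
            assign_telomere_ranks(_genes([("chr1", 900, 1_100, "g")]),
                                  {"chr1": 1_000})


def _synthetic_universe(seed, elevated_ranks=(), n_arms=8, n_ranks=10,
                        high=0.6, low=0.15, sd=0.03):
    """Gene positions on a toy genome plus CVs elevated at chosen ranks."""
    rng = np.random.default_rng(seed)
    rows, cvs = [], {}
    for arm in range(n_arms):
        chrom, side = f"chr{arm // 2 + 1}", ("left", "right")[arm % 2]
        for rank in range(1, n_ranks + 1):
            gid = f"a{arm}_r{rank}"
            rows.append({"gene_id": gid, "chromosome": chrom, "arm": side,
                         "start": 0, "end": 100, "telomere_rank": rank,
                         "distance_to_telomere": 2_000 * rank})
            mu = high if rank in elevated_ranks else low
            cvs[gid] = max(rng.normal(mu, sd), 0.01)
    return pd.DataFrame(rows), pd.Series(cvs)


class TestPositionalGroupScan:
    def test_elevated_telomeric_ranks_detected(self):
        positions, cvs = _synthetic_universe(1, elevated_ranks=(1, 2))
        scan = positional_group_scan(cvs, positions, group_size=16,
                                     n_boot=2_000, seed=2, max_rank=6)
        sig = scan.set_index("rank")["significant"]
        assert sig.loc[1] and sig.loc[2]
        assert not sig.loc[4] and not sig.loc[5] and not sig.loc[6]

    def test_uniform_universe_no_systematic_significance(self):
        hits = total = 0
        for seed in range(10):
            positions, cvs = _synthetic_universe(100 + seed)
            scan = positional_group_scan(cvs, positions, group_size=16,
                                         n_boot=1_000, seed=seed, max_rank=5)
            hits += int(scan["significant"].sum())
            total += len(scan)
        assert hits / total < 0.12      # ~2.5% expected, wide binomial margin

    def test_group_of_whole_universe_p_one(self):
        positions, cvs = _synthetic_universe(3, n_arms=2, n_ranks=3)
        scan = positional_group_scan(cvs, positions, group_size=len(cvs),
                                     n_boot=500, seed=4, max_rank=1)
        assert scan.loc[0, "empirical_p"] == 1.0

    def test_shuffled_labels_lose_signal(self):
        positions, cvs = _synthetic_universe(5, elevated_ranks=(1,))
        shuffled = pd.Series(np.random.default_rng(6).permutation(cvs.to_numpy()),
                             index=cvs.index)
        scan = positional_group_scan(shuffled, positions, group_size=16,
                                     n_boot=1_000, seed=7, max_rank=3)
        assert scan["significant"].sum() <= 1


class TestDistanceTrend:
    def test_exact_linear_construction(self):
        positions, _ = _synthetic_universe(8, n_arms=2, n_ranks=10)
        cvs = pd.Series(0.9 - 1e-5 * positions["distance_to_telomere"].to_numpy(),
                        index=positions["gene_id"].to_numpy())
        res = distance_trend(cvs, positions)
        assert res["slope_per_bp"] == pytest.approx(-1e-5)
        assert res["pearson_r"] == pytest.approx(-1.0)

    def test_constant_cv_degenerate(self):
        positions, _ = _synthetic_universe(9, n_arms=2, n_ranks=5)
        cvs = pd.Series(0.3, index=positions["gene_id"].to_numpy())
        with pytest.raises(DegenerateTestError):
            distance_trend(cvs, positions)

    def test_telomere_graded_noise_yields_negative_slope(self):
        detected = 0
        for seed in range(20):
            positions, cvs = _synthetic_universe(200 + seed,
                                                 elevated_ranks=(1, 2, 3))
            res = distance_trend(cvs, positions)
            detected += (res["slope_per_bp"] < 0) and (res["p"] < 0.05)
        assert detected >= 18

    def test_centromere_orientation_flips_sign(self):
        positions, _ = _synthetic_universe(10, n_arms=2, n_ranks=10)
        cvs = pd.Series(0.9 - 1e-5 * positions["distance_to_telomere"].to_numpy(),
                        index=positions["gene_id"].to_numpy())
        tel = distance_trend(cvs, positions, coordinate="telomere")
        cen = distance_trend(cvs, positions, coordinate="centromere")
        assert tel["slope_per_bp"] < 0 < cen["slope_per_bp"]
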