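import itertools
import math

import numpy as np
import pandas as pd
import pytest

from woundarray.core import ValidationError
from woundarray.io import read_bed, write_bed
from woundarray.positional import (
    assign_coordinates,
    characterize_clusters,
    chromosome_enrichment,
    expected_clusters,
    find_positional_clusters,
    rank_loci,
)
from woundarray.synthetic import SyntheticConfig, generate_annotation, generate_expression


def make_loci(n: int, arm: str = "2L", start_step: int = 1000, length: int = 500):
    rows = []
    for i in range(n):
        start = i * start_step
        rows.append((f"g{i}", arm, start, start + length, "+" if i % 2 else "-"))
    return rank_loci(pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"]))


def directed(genes, direction="up"):
    return pd.DataFrame(
        {"direction": [direction] * len(genes)}, index=pd.Index(genes, name="gene")
    )


class TestAssignCoordinates:
    def test_first_transcript_kept(self):
        ann = pd.DataFrame(
            [
                ("gA", "2L", 100, 600, "+"),
                ("gA", "2L", 5000, 9000, "+"),
                ("gB", "2L", 2000, 2500, "-"),
            ],
            columns=["gene", "arm", "start", "end", "strand"],
        )
        loci, unmapped = assign_coordinates(["gA", "gB"], ann)
        row = loci[loci["gene"] == "gA"].iloc[0]
        assert row["start"] == 100
        assert not unmapped

    def test_unmapped_reported(self):
        ann = pd.DataFrame(
            [("gA", "2L", 100, 600, "+")],
            columns=["gene", "arm", "start", "end", "strand"],
        )
        loci, unmapped = assign_coordinates(["gA", "gZ"], ann)
        assert unmapped == ["gZ"]

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValidationError):
            assign_coordinates(["gA"], pd.DataFrame(columns=["gene", "arm", "start", "end", "strand"]))

    def test_bed_round_trip(self, tmp_path):
        loci = make_loci(20)
        path = tmp_path / "loci.bed"
        write_bed(loci, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(
            rank_loci(back), loci, check_dtype=False
        )


class TestChromosomeEnrichment:
    def build(self, arm_sizes: dict[str, int]):
        rows = []
        for arm, n in arm_sizes.items():
            for i in range(n):
                rows.append((f"{arm}_{i}", arm, i * 1000, i * 1000 + 500, "+"))
        return rank_loci(pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"]))

    def test_full_set_gives_p_one(self):
        loci = self.build({"X": 4, "2L": 6})
        res = chromosome_enrichment(set(loci["gene"]), loci, n_rand=50, seed=0)
        np.testing.assert_allclose(res["p_hyper"], 1.0)
        assert list(res["observed"]) == [6, 4]  # arms sorted: 2L, X

    def test_exhaustive_enumeration_oracle(self):
        # N=10, arm K=5, draw 4 all on that arm
        loci = self.build({"A": 5, "B": 5})
        chosen = [f"A_{i}" for i in range(4)]
        res = chromosome_enrichment(chosen, loci, n_rand=10, seed=1)
        genes = list(loci["gene"])
        count = sum(
            1
            for combo in itertools.combinations(genes, 4)
            if sum(g.startswith("A") for g in combo) >= 4
        )
        expected = count / math.comb(10, 4)
        assert res.loc["A", "p_hyper"] == pytest.approx(expected)

    def test_all_small_configs_match_enumeration(self):
        for n_total in (4, 6, 8, 10, 12):
            for k_arm in (1, n_total // 2, n_total - 1):
                loci = self.build({"A": k_arm, "B": n_total - k_arm})
                genes = list(loci["gene"])
                for n_draw in (1, min(3, n_total), n_total // 2):
                    chosen = genes[:n_draw]
                    res = chromosome_enrichment(chosen, loci, n_rand=5, seed=0)
                    k_obs = sum(g.startswith("A") for g in chosen)
                    count = sum(
                        1
                        for combo in itertools.combinations(genes, n_draw)
                        if sum(g.startswith("A") for g in combo) >= k_obs
                    )
                    expected = count / math.comb(n_total, n_draw)
                    assert res.loc["A", "p_hyper"] == pytest.approx(expected), (
                        n_total, k_arm, n_draw,
                    )

    def test_empirical_converges_to_hypergeometric(self):
        loci = self.build({"A": 30, "B": 70})
        chosen = [f"A_{i}" for i in range(8)] + [f"B_{i}" for i in range(4)]
        res = chromosome_enrichment(chosen, loci, n_rand=1000, seed=2)
        p = res.loc["A", "p_hyper"]
        mc_se = math.sqrt(p * (1 - p) / 1000)
        assert abs(res.loc["A", "p_empirical"] - p) < 3 * mc_se + 2 / 1001

    def test_empty_set_rejected(self):
        loci = self.build({"A": 5})
        with pytest.raises(ValidationError):
            chromosome_enrichment(set(), loci)


def brute_force_clusters(member_flags: list[bool], window: int, min_de: int):
    """Independent oracle: score every window, exhaustively merge seeds."""
    n = len(member_flags)
    w = min(window, n)
    covered = []
    for lo in range(0, n - w + 1):
        if sum(member_flags[lo : lo + w]) >= min_de:
            covered.append((lo, lo + w - 1))
    merged = []
    for lo, hi in covered:
        placed = False
        for m in merged:
            if lo <= m[1] + 1 and hi >= m[0] - 1:
                m[0], m[1] = min(m[0], lo), max(m[1], hi)
                placed = True
                break
        if not placed:
            merged.append([lo, hi])
    # repeat merging until stable (exhaustive)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(merged)), 2):
            if merged[a] and merged[b]:
                (alo, ahi), (blo, bhi) = merged[a], merged[b]
                if alo <= bhi + 1 and blo <= ahi + 1:
                    merged[a] = [min(alo, blo), max(ahi, bhi)]
                    merged[b] = None
                    changed = True
        merged = [m for m in merged if m]
    out = []
    for lo, hi in sorted(merged):
        out.append([i for i in range(lo, hi + 1) if member_flags[i]])
    return out


class TestFindPositionalClusters:
    def test_three_consecutive_up_genes(self):
        loci = make_loci(50)
        members = directed(["g10", "g11", "g12"])
        clusters = find_positional_clusters(members, loci)
        assert len(clusters) == 1
        assert clusters[0].genes == ["g10", "g11", "g12"]
        assert clusters[0].direction == "up"
        assert clusters[0].arm == "2L"

    def test_below_min_de_no_cluster(self):
        loci = make_loci(50)
        assert find_positional_clusters(directed(["g5", "g6"]), loci) == []

    def test_directions_never_mix(self):
        loci = make_loci(30)
        members = pd.concat(
            [directed(["g1", "g2"], "up"), directed(["g3", "g4"], "down")]
        )
        assert find_positional_clusters(members, loci) == []

    def test_window_smaller_than_min_de_rejected(self):
        loci = make_loci(30)
        with pytest.raises(ValidationError):
            find_positional_clusters(directed(["g1"]), loci, min_de=5, window_genes=3)

    def test_members_within_one_arm(self):
        rows = []
        for arm in ("2L", "2R"):
            for i in range(20):
                rows.append((f"{arm}_g{i}", arm, i * 1000, i * 1000 + 500, "+"))
        loci = rank_loci(pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"]))
        members = directed(["2L_g18", "2L_g19", "2R_g0", "2R_g1", "2R_g2"])
        clusters = find_positional_clusters(members, loci)
        for c in clusters:
            arms = {g.split("_")[0] for g in c.genes}
            assert len(arms) == 1

    def test_brute_force_oracle_random_arms(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = 200
            loci = make_loci(n)
            n_members = int(rng.integers(3, 40))
            picks = rng.choice(n, size=n_members, replace=False)
            members = directed([f"g{i}" for i in picks])
            window = int(rng.integers(3, 15))
            min_de = int(rng.integers(3, window + 1))
            got = find_positional_clusters(members, loci, min_de, window)
            flags = [f"g{i}" in set(members.index) for i in range(n)]
            expect = brute_force_clusters(flags, window, min_de)
            got_ranks = [c.member_ranks for c in got]
            assert got_ranks == expect, (trial, window, min_de)

    def test_merging_idempotent(self):
        loci = make_loci(60)
        members = directed([f"g{i}" for i in [5, 6, 7, 12, 13, 14, 15]])
        first = find_positional_clusters(members, loci)
        again = find_positional_clusters(members, loci)
        assert [c.genes for c in first] == [c.genes for c in again]


class TestExpectedClusters:
    def small_genome(self, seed=0, n=300, n_members=20):
        rng = np.random.default_rng(seed)
        rows = []
        for arm in ("2L", "2R", "3L"):
            for i in range(n // 3):
                rows.append((f"{arm}_g{i}", arm, i * 1000, i * 1000 + 500, "+"))
        loci = rank_loci(pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"]))
        picks = rng.choice(len(loci), size=n_members, replace=False)
        genes = loci["gene"].to_numpy()[picks]
        dirs = np.where(rng.random(n_members) < 0.5, "up", "down")
        members = pd.DataFrame({"direction": dirs}, index=pd.Index(genes, name="gene"))
        return loci, members

    def test_deterministic(self):
        loci, members = self.small_genome(1)
        a = expected_clusters(members, loci, n_rand=50, seed=9)
        b = expected_clusters(members, loci, n_rand=50, seed=9)
        assert (a["null"] == b["null"]).all()
        assert a["p_empirical"] == b["p_empirical"]

    def test_null_calibration(self):
        # uniformly random directed sets should rarely look significant
        calm = 0
        for seed in range(50):
            loci, members = self.small_genome(seed + 100)
            res = expected_clusters(members, loci, n_rand=100, seed=seed)
            if res["p_empirical"] > 0.05:
                calm += 1
        assert calm >= 45

    def test_planted_cluster_detected(self):
        cfg = SyntheticConfig(n_genes=2000, de_fraction=0.012, noise_sd=0.25,
                              n_planted_clusters=2, cluster_size=5,
                              template_fraction=0.0, seed=21)
        _, _, truth = generate_expression(cfg)
        annotation, truth = generate_annotation(cfg, truth)
        loci = rank_loci(annotation)
        mask = truth["direction"] != "none"
        members = pd.DataFrame(
            {"direction": truth.loc[mask, "direction"]},
        )
        res = expected_clusters(members, loci, n_rand=100, seed=22)
        assert res["observed"] >= 1
        assert res["p_empirical"] <= 0.05

    def test_invalid_nrand(self):
        loci, members = self.small_genome(2)
        with pytest.raises(ValidationError):
            expected_clusters(members, loci, n_rand=0)

    def test_null_mean_matches_shuffled_ids(self):
        # relabelling genes while keeping loci fixed is another draw from
        # the stratified null; means should agree within Monte-Carlo error
        loci, members = self.small_genome(7, n_members=30)
        res = expected_clusters(members, loci, n_rand=200, seed=3)
        rng = np.random.default_rng(4)
        counts = []
        arm_of = loci.set_index("gene")["arm"]
        for _ in range(200):
            rows = []
            for (arm, direction), cnt in members.groupby(
                [arm_of.reindex(members.index), "direction"]
            ).size().items():
                pool = loci.loc[loci["arm"] == arm, "gene"].to_numpy()
                rows.extend(
                    (g, direction) for g in rng.choice(pool, int(cnt), replace=False)
                )
            rand = pd.DataFrame(rows, columns=["gene", "direction"]).set_index("gene")
            counts.append(len(find_positional_clusters(rand, loci)))
        se = np.std(counts, ddof=1) / math.sqrt(len(counts)) + res["null_sd"] / math.sqrt(200)
        assert abs(np.mean(counts) - res["null_mean"]) < 4 * max(se, 0.05)


class TestCharacterizeClusters:
    def test_opposed_pair_and_gap(self):
        loci = rank_loci(pd.DataFrame(
            [("gA", "2L", 0, 100, "+"), ("gB", "2L", 200, 300, "-")],
            columns=["gene", "arm", "start", "end", "strand"],
        ))
        clusters = find_positional_clusters(
            directed(["gA", "gB"]), loci, min_de=2, window_genes=2
        )
        stats = characterize_clusters(clusters, loci)
        row = stats.loc[0]
        assert row["opposed_pairs"] == 1
        assert row["mean_intergenic"] == 100
        assert row["mean_gene_length"] == 100

    def test_singleton_missing_intergenic(self):
        loci = make_loci(10)
        from woundarray.positional import PositionalCluster

        cl = PositionalCluster("2L", "up", ["g3"], (3000, 3500), 1, [3])
        stats = characterize_clusters([cl], loci)
        assert math.isnan(stats.loc[0, "mean_intergenic"])
        assert stats.loc[0, "mean_gene_length"] == 500

    def test_no_clusters_rejected(self):
        with pytest.raises(ValidationError):
            characterize_clusters([], make_loci(5))
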