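"""Chromosomal mapping and positional clustering of regulated genes.

Loci live in a DataFrame with columns ``gene, arm, start, end, strand``
(0-based half-open coordinates) plus a per-arm ``rank`` in start order.
Clusters are runs of co-directional regulated genes found by sliding a
window of consecutive genome ranks; significance comes from stratified
random gene sets preserving the per-arm (and per-direction) composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

LOCUS_COLUMNS = ["gene", "arm", "start", "end", "strand"]


def rank_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Sort by (arm, start) and attach consecutive within-arm ranks."""
    for col in LOCUS_COLUMNS:
        if col not in loci.columns:
            raise ValidationError(f"locus table lacks column {col!r}")
    if (loci["start"] >= loci["end"]).any():
        bad = loci.loc[loci["start"] >= loci["end"], "gene"].iloc[0]
        raise ValidationError(f"locus {bad!r} has start >= end")
    out = loci.sort_values(["arm", "start"], kind="stable").reset_index(drop=True)
    out["rank"] = out.groupby("arm").cumcount()
    return out


def assign_coordinates(
    genes: pd.Index | list[str], annotation: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Attach one locus per gene; duplicate records resolve to the first.

    Returns (ranked loci for mapped genes with all annotation genes still
    ranked genome-wide, list of unmapped gene ids).
    """
    if len(annotation) == 0:
        raise ValidationError("empty annotation")
    first = annotation.drop_duplicates(subset="gene", keep="first")
    ranked = rank_loci(first)
    known = set(ranked["gene"])
    unmapped = [g for g in genes if g not in known]
    return ranked, unmapped


@dataclass
class PositionalCluster:
    arm: str
    direction: str
    genes: list[str]
    span: tuple[int, int]  # bp, first member start to last member end
    window_gene_count: int  # total annotated genes in the spanning fragment
    member_ranks: list[int] = field(default_factory=list)


def chromosome_enrichment(
    gene_set: set[str] | list[str],
    loci: pd.DataFrame,
    n_rand: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-arm over-representation of a gene set.

    For each arm: observed member count k, expected count K·n/N, upper
    hypergeometric tail P[X ≥ k] with population all annotated genes, and
    an add-one empirical p from ``n_rand`` uniform random sets of size n.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    known = set(loci["gene"])
    stray = gene_set - known
    if stray:
        raise ValidationError(f"genes not in annotation: {sorted(stray)[:5]}")
    n_total = len(loci)
    n_draw = len(gene_set)
    member = loci["gene"].isin(gene_set).to_numpy()
    arms = sorted(loci["arm"].unique())
    rng = np.random.default_rng(seed)
    arm_codes = loci["arm"].to_numpy()
    rand_counts = {arm: np.zeros(n_rand, dtype=int) for arm in arms}
    for i in range(n_rand):
        pick = rng.choice(n_total, size=n_draw, replace=False)
        picked_arms, counts = np.unique(arm_codes[pick], return_counts=True)
        for a, c in zip(picked_arms, counts):
            rand_counts[a][i] = c
    rows = []
    for arm in arms:
        on_arm = arm_codes == arm
        big_k = int(on_arm.sum())
        k = int((member & on_arm).sum())
        p_hyper = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_draw))
        p_emp = (1 + int((rand_counts[arm] >= k).sum())) / (n_rand + 1)
        rows.append(
            {
                "arm": arm,
                "observed": k,
                "expected": big_k * n_draw / n_total,
                "p_hyper": p_hyper,
                "p_empirical": p_emp,
            }
        )
    return pd.DataFrame(rows).set_index("arm")


def find_positional_clusters(
    directed_set: pd.DataFrame,
    loci: pd.DataFrame,
    min_de: int = 3,
    window_genes: int = 10,
) -> list[PositionalCluster]:
    """Detect clusters of co-directional genes within rank windows.

    ``directed_set`` is indexed by gene with a ``direction`` column.  For
    each arm and direction every window of ``window_genes`` consecutive
    ranks is scored; windows holding ≥ ``min_de`` members seed clusters and
    overlapping/adjacent seed windows merge.  Output is sorted by
    (arm, span start) and cluster members never span two arms.
    """
    if window_genes < min_de:
        raise ValidationError("window_genes must be ≥ min_de")
    if "rank" not in loci.columns:
        loci = rank_loci(loci)
    direction_of = directed_set["direction"]
    clusters: list[PositionalCluster] = []
    for arm, arm_loci in loci.groupby("arm", sort=True):
        arm_loci = arm_loci.sort_values("rank")
        arm_genes = arm_loci["gene"].to_numpy()
        n_arm = len(arm_genes)
        for direction in ("up", "down"):
            members = direction_of.index[direction_of == direction]
            is_member = np.isin(arm_genes, members)
            if is_member.sum() < min_de:
                continue
            width = min(window_genes, n_arm)
            counts = np.convolve(is_member.astype(int), np.ones(width, dtype=int), "valid")
            seeds = np.flatnonzero(counts >= min_de)
            if len(seeds) == 0:
                continue
            # merge windows that overlap or touch into rank intervals
            intervals: list[list[int]] = []
            for s in seeds:
                lo, hi = int(s), int(s) + width - 1
                if intervals and lo <= intervals[-1][1] + 1:
                    intervals[-1][1] = max(intervals[-1][1], hi)
                else:
                    intervals.append([lo, hi])
            for lo, hi in intervals:
                inside = np.flatnonzero(is_member[lo : hi + 1]) + lo
                member_genes = [arm_genes[i] for i in inside]
                first, last = inside[0], inside[-1]
                span = (
                    int(arm_loci.iloc[first]["start"]),
                    int(arm_loci.iloc[last]["end"]),
                )
                clusters.append(
                    PositionalCluster(
                        arm=str(arm),
                        direction=direction,
                        genes=member_genes,
                        span=span,
                        window_gene_count=int(last - first + 1),
                        member_ranks=[int(i) for i in inside],
                    )
                )
    clusters.sort(key=lambda c: (c.arm, c.span[0], c.direction))
    return clusters


def _random_directed_set(
    directed_set: pd.DataFrame, loci: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Random set preserving per-arm, per-direction counts (stratified)."""
    arm_of = loci.set_index("gene")["arm"]
    strata = directed_set.groupby(
        [arm_of.reindex(directed_set.index), "direction"]
    ).size()
    rows = []
    for (arm, direction), count in strata.items():
        pool = loci.loc[loci["arm"] == arm, "gene"].to_numpy()
        pick = rng.choice(pool, size=int(count), replace=False)
        rows.extend((g, direction) for g in pick)
    return pd.DataFrame(rows, columns=["gene", "direction"]).set_index("gene")


def expected_clusters(
    directed_set: pd.DataFrame,
    loci: pd.DataFrame,
    min_de: int = 3,
    window_genes: int = 10,
    n_rand: int = 100,
    seed: int | None = None,
) -> dict:
    """Observed cluster count vs a stratified-random null.

    Returns observed count, null mean ± sd, the full null distribution and
    the add-one empirical p of seeing ≥ observed clusters by chance.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be ≥ 1")
    if "rank" not in loci.columns:
        loci = rank_loci(loci)
    observed = len(
        find_positional_clusters(directed_set, loci, min_de, window_genes)
    )
    rng = np.random.default_rng(seed)
    null = np.zeros(n_rand, dtype=int)
    for i in range(n_rand):
        rand = _random_directed_set(directed_set, loci, rng)
        null[i] = len(find_positional_clusters(rand, loci, min_de, window_genes))
    p_emp = (1 + int((null >= observed).sum())) / (n_rand + 1)
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_rand > 1 else 0.0,
        "null": null,
        "p_empirical": p_emp,
    }


def characterize_clusters(
    clusters: list[PositionalCluster], loci: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster geometry stats plus a genome-wide baseline row.

    Mean gene length, count of adjacent member pairs on opposite strands,
    and mean intergenic distance over adjacent member pairs (missing for
    singletons).  The baseline row aggregates all annotated genes.
    """
    if not clusters:
        raise ValidationError("no clusters to characterize")
    by_gene = loci.set_index("gene")
    rows = []
    for i, cl in enumerate(clusters):
        sub = by_gene.loc[cl.genes].sort_values("start")
        lengths = (sub["end"] - sub["start"]).to_numpy()
        strands = sub["strand"].to_numpy()
        opposed = int(sum(strands[j] != strands[j + 1] for j in range(len(sub) - 1)))
        if len(sub) > 1:
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            mean_gap = float(gaps.mean())
        else:
            mean_gap = float("nan")
        rows.append(
            {
                "cluster": i,
                "arm": cl.arm,
                "direction": cl.direction,
                "n_genes": len(cl.genes),
                "mean_gene_length": float(lengths.mean()),
                "gene_lengths": ",".join(str(int(v)) for v in lengths),
                "opposed_pairs": opposed,
                "mean_intergenic": mean_gap,
            }
        )
    # genome-wide baseline across all annotated genes
    all_sorted = loci.sort_values(["arm", "start"])
    base_lengths = (all_sorted["end"] - all_sorted["start"]).to_numpy()
    gaps = []
    for _, arm_loci in all_sorted.groupby("arm"):
        s = arm_loci["start"].to_numpy()
        e = arm_loci["end"].to_numpy()
        if len(s) > 1:
            gaps.extend(s[1:] - e[:-1])
    rows.append(
        {
            "cluster": -1,
            "arm": "genome",
            "direction": "all",
            "n_genes": len(loci),
            "mean_gene_length": float(base_lengths.mean()),
            "gene_lengths": "",
            "opposed_pairs": -1,
            "mean_intergenic": float(np.mean(gaps)) if gaps else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("cluster")
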