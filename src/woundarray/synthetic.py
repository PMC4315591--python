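"""Synthetic four-condition microarray data with planted, known structure.

Every downstream stage gets a truth standard: planted per-condition log2
effects (realizing the wounded-only and shared-response sign patterns),
planted chromosomal runs of co-directional genes, planted discrete level
profiles, and a small DAG ontology with a designated enriched term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONDITIONS, DesignTable, ExpressionMatrix, ValidationError
from .ontology import OntologyGraph, Term

DEFAULT_ARMS = ("X", "2L", "2R", "3L", "3R")


@dataclass
class SyntheticConfig:
    n_genes: int = 5000
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    noise_sd: float = 0.25
    de_fraction: float = 0.1
    fc_range: tuple[float, float] = (1.3, 8.0)
    n_planted_clusters: int = 2
    cluster_size: int = 5
    arms: dict[str, int] | None = None  # arm → gene count; None = even split
    ontology_terms: int = 40
    seed: int = 0
    # extras beyond the minimum emulation
    template_fraction: float = 0.05
    template_amplitude: float = 2.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    array_effect_sd: float = 0.0  # per-array log2 shift, exercises normalization
    truth_fc: float = 1.3  # threshold defining planted region labels

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 replicates per condition")
        if len(set(self.conditions)) != 4:
            raise ValidationError("need exactly 4 distinct condition labels")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.fc_range[0] <= 1.0 or self.fc_range[1] < self.fc_range[0]:
            raise ValidationError("fc_range lower bound must exceed 1")
        for name in ("n_planted_clusters", "cluster_size", "ontology_terms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    def arm_counts(self) -> dict[str, int]:
        if self.arms is not None:
            if sum(self.arms.values()) != self.n_genes:
                raise ValidationError("arm gene counts must sum to n_genes")
            return dict(self.arms)
        base = self.n_genes // len(DEFAULT_ARMS)
        counts = {arm: base for arm in DEFAULT_ARMS}
        for i in range(self.n_genes - base * len(DEFAULT_ARMS)):
            counts[DEFAULT_ARMS[i]] += 1
        return counts


# Planted effect patterns: condition-shift vectors (units of delta = log2 fc)
# over (JNK+W, JNK-W, JNK+, JNK-).  The wounded-only (WO) patterns move one
# population in wounded discs only; the shared (WNWD) patterns move a
# population in both disc states by distinct amounts.
PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "WO:JNK+_up": (1, 0, 0, 0),
    "WO:JNK-_down": (0, -1, 0, 0),
    "WO:JNK+_down": (-1, 0, 0, 0),
    "WO:JNK-_up": (0, 1, 0, 0),
    "WNWD:auto_up_more_W": (2, 0, 1, 0),
    "WNWD:auto_up_more_NW": (1, 0, 2, 0),
    "WNWD:auto_down_more_W": (-2, 0, -1, 0),
    "WNWD:auto_down_more_NW": (-1, 0, -2, 0),
    "WNWD:auto_up_W_down_NW": (1, 0, -1, 0),
    "WNWD:auto_down_W_up_NW": (-1, 0, 1, 0),
    "WNWD:nonauto_up_more_W": (0, -2, 0, -1),
    "WNWD:nonauto_up_more_NW": (0, -1, 0, -2),
    "WNWD:nonauto_down_more_W": (0, 2, 0, 1),
    "WNWD:nonauto_down_more_NW": (0, 1, 0, 2),
    "W∩NW": (1, 0, 1, 0),
    "NW∩D": (0, 0, 1, 0),
}

DEFAULT_PATTERN_WEIGHTS = {name: 1.0 for name in PATTERNS}

TRUTH_COLUMNS = [
    "effect_" + c for c in CONDITIONS
] + ["pattern", "venn_region", "direction", "template", "cluster"]


def _venn_label(effects: np.ndarray, truth_fc: float) -> str:
    cut = math.log2(truth_fc)
    w = effects[0] - effects[1]
    nw = effects[2] - effects[3]
    d = w - nw
    parts = []
    if abs(w) >= cut:
        parts.append("W")
    if abs(nw) >= cut:
        parts.append("NW")
    if abs(d) >= cut:
        parts.append("D")
    return "∩".join(parts) if parts else "none"


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, DesignTable, pd.DataFrame]:
    """Planted expression matrix (linear scale), design and truth table."""
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    effects = np.zeros((config.n_genes, 4))
    truth = pd.DataFrame(
        {
            "pattern": "none",
            "venn_region": "none",
            "direction": "none",
            "template": "",
            "cluster": -1,
        },
        index=pd.Index(genes, name="gene"),
    )

    n_de = int(round(config.de_fraction * config.n_genes))
    perm = rng.permutation(config.n_genes)
    de_idx = perm[:n_de]
    pattern_names = list(PATTERNS)
    for j, gi in enumerate(de_idx):
        name = pattern_names[j % len(pattern_names)]
        fc = rng.uniform(*config.fc_range)
        delta = math.log2(fc)
        vec = np.asarray(PATTERNS[name], dtype=float) * delta
        effects[gi] = vec
        truth.iloc[gi, truth.columns.get_loc("pattern")] = name

    # planted level profiles on a disjoint slice of non-DE genes
    n_templates = int(round(config.template_fraction * config.n_genes))
    template_idx = perm[n_de : n_de + n_templates]
    level_choices = [
        t for t in _nondegenerate_level_vectors() if len(set(t)) > 1
    ]
    for gi in template_idx:
        levels = level_choices[rng.integers(len(level_choices))]
        effects[gi] = (np.asarray(levels, dtype=float) - 2.0) * config.template_amplitude
        truth.iloc[gi, truth.columns.get_loc("template")] = ".".join(
            map(str, levels)
        )
        truth.iloc[gi, truth.columns.get_loc("pattern")] = "template"

    w_effect = effects[:, 0] - effects[:, 1]
    truth["venn_region"] = [
        _venn_label(effects[i], config.truth_fc) for i in range(config.n_genes)
    ]
    truth["direction"] = np.where(
        w_effect > 1e-12, "up", np.where(w_effect < -1e-12, "down", "none")
    )
    for i, cond in enumerate(CONDITIONS):
        truth["effect_" + cond] = effects[:, i]
    truth = truth[TRUTH_COLUMNS]

    n_samples = 4 * config.n_replicates
    sample_ids = [
        f"{cond}_{r + 1}"
        for cond in config.conditions
        for r in range(config.n_replicates)
    ]
    means = baseline[:, None] + np.repeat(effects, config.n_replicates, axis=1)
    log2_values = means + rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    if config.array_effect_sd > 0:
        log2_values += rng.normal(0.0, config.array_effect_sd, n_samples)[None, :]
    linear = np.exp2(log2_values)

    matrix = ExpressionMatrix(
        pd.DataFrame(linear, index=pd.Index(genes, name="gene"), columns=sample_ids),
        scale="linear",
    )
    design = DesignTable(
        pd.DataFrame(
            {
                "sample": sample_ids,
                "condition": [
                    cond for cond in config.conditions for _ in range(config.n_replicates)
                ],
                "replicate": [
                    r + 1 for _ in config.conditions for r in range(config.n_replicates)
                ],
            }
        ),
        conditions=tuple(config.conditions),
    )
    return matrix, design, truth


def _nondegenerate_level_vectors() -> list[tuple[int, int, int, int]]:
    import itertools

    return [
        combo
        for combo in itertools.product((1, 2, 3), repeat=4)
        if len(set(combo)) > 1
    ]


def generate_annotation(
    config: SyntheticConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping loci per gene with planted co-directional runs.

    Cluster members are consecutive in genome order, share an arm and a
    planted regulation direction.  Returns (annotation, updated truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    counts = config.arm_counts()
    if config.n_planted_clusters > 0 and config.cluster_size > min(counts.values()):
        raise ValidationError("cluster_size exceeds genes on the smallest arm")
    truth = truth.copy()
    genes = list(truth.index)

    # reserve cluster members: same direction within a cluster
    cluster_members: list[list[str]] = []
    used: set[str] = set()
    for ci in range(config.n_planted_clusters):
        direction = "up" if ci % 2 == 0 else "down"
        pool = [
            g
            for g in genes
            if truth.at[g, "direction"] == direction
            and truth.at[g, "pattern"] != "template"
            and g not in used
        ]
        if len(pool) < config.cluster_size:
            raise ValidationError(
                f"not enough {direction}-regulated genes to plant cluster {ci}"
            )
        members = [pool[int(i)] for i in rng.choice(len(pool), config.cluster_size, replace=False)]
        cluster_members.append(members)
        used.update(members)
        for g in members:
            truth.at[g, "cluster"] = ci

    rest = [g for g in genes if g not in used]
    rest = [rest[int(i)] for i in rng.permutation(len(rest))]

    arm_names = sorted(counts)
    arm_lists: dict[str, list[str]] = {}
    cursor = 0
    reserved = {arm: 0 for arm in arm_names}
    for ci, members in enumerate(cluster_members):
        reserved[arm_names[ci % len(arm_names)]] += len(members)
    for arm in arm_names:
        take = counts[arm] - reserved[arm]
        if take < 0:
            raise ValidationError(f"arm {arm!r} too small for its planted clusters")
        arm_lists[arm] = rest[cursor : cursor + take]
        cursor += take
    for ci, members in enumerate(cluster_members):
        arm = arm_names[ci % len(arm_names)]
        pos = int(rng.integers(0, len(arm_lists[arm]) + 1))
        arm_lists[arm] = arm_lists[arm][:pos] + members + arm_lists[arm][pos:]

    rows = []
    for arm in arm_names:
        pos = 0
        for g in arm_lists[arm]:
            gap = int(rng.integers(100, 10001))
            length = int(rng.integers(500, 20001))
            start = pos + gap
            end = start + length
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((g, arm, start, end, strand))
    annotation = pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"])
    return annotation, truth


@dataclass
class AnnotationMap:
    """Gene→term annotation table plus the planted enrichment target."""

    table: pd.DataFrame  # columns: gene, term, aspect
    enriched_term: str = ""
    enriched_level3: tuple[str, ...] = field(default_factory=tuple)


def generate_ontology(
    config: SyntheticConfig, truth: pd.DataFrame | None = None
) -> tuple[OntologyGraph, AnnotationMap]:
    """Small molecular-function DAG (depth ≥ 5) with gene annotations.

    One designated deep term annotates an excess of planted-DE genes so a
    level-3 enrichment signal exists by construction.
    """
    if config.ontology_terms < 4:
        raise ValidationError("need at least 4 ontology terms")
    rng = np.random.default_rng(config.seed + 2)
    ns = "molecular_function"

    def tid(i: int) -> str:
        return f"GO:{i:07d}"

    terms: list[Term] = [Term(tid(1), name="root", namespace=ns)]
    levels = {tid(1): 1}
    # two level-2 branches, then level-3 terms under them
    n = config.ontology_terms
    idx = 2
    level2 = []
    for _ in range(min(2, n - 1)):
        t = Term(tid(idx), name=f"term{idx}", namespace=ns, parents=[tid(1)])
        terms.append(t)
        levels[t.id] = 2
        level2.append(t.id)
        idx += 1
    level3 = []
    while idx <= min(n, 7):
        parent = level2[(idx - 4) % len(level2)]
        t = Term(tid(idx), name=f"term{idx}", namespace=ns, parents=[parent])
        terms.append(t)
        levels[t.id] = 3
        level3.append(t.id)
        idx += 1
    # guarantee a chain reaching depth 5
    deep_parent = level3[0] if level3 else level2[0]
    chain_end = deep_parent
    while idx <= n and levels[chain_end] < 5:
        t = Term(tid(idx), name=f"term{idx}", namespace=ns, parents=[chain_end])
        terms.append(t)
        levels[t.id] = levels[chain_end] + 1
        chain_end = t.id
        idx += 1
    # remaining terms: random attachment below level 3; some get 2 parents
    attachable = [t.id for t in terms if levels[t.id] >= 3]
    while idx <= n:
        parent = attachable[int(rng.integers(len(attachable)))]
        parents = [parent]
        if rng.random() < 0.3 and len(attachable) > 1:
            other = attachable[int(rng.integers(len(attachable)))]
            if other != parent and levels[other] <= levels[parent]:
                parents.append(other)
        t = Term(tid(idx), name=f"term{idx}", namespace=ns, parents=parents)
        terms.append(t)
        levels[t.id] = min(levels[p] for p in parents) + 1
        attachable.append(t.id)
        idx += 1
    graph = OntologyGraph(terms)

    rows: list[tuple[str, str, str]] = []
    enriched_term = chain_end
    if truth is not None:
        annotatable = [t.id for t in terms if levels[t.id] >= 3]
        for gene in truth.index:
            k = int(rng.integers(0, 3))
            for _ in range(k):
                term = annotatable[int(rng.integers(len(annotatable)))]
                rows.append((gene, term, "F"))
        de_genes = truth.index[truth["pattern"].str.startswith(("WO", "WNWD"))]
        for gene in de_genes:
            if rng.random() < 0.6:
                rows.append((gene, enriched_term, "F"))
    table = pd.DataFrame(rows, columns=["gene", "term", "aspect"]).drop_duplicates()
    from .ontology import level3_projection

    enriched_l3 = tuple(sorted(level3_projection(enriched_term, graph)))
    return graph, AnnotationMap(
        table=table, enriched_term=enriched_term, enriched_level3=enriched_l3
    )
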