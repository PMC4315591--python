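"""OBO 1.2 ontology handling, level-3 projection, hypergeometric enrichment.

Term level is 1 + the minimum number of ``is_a`` edges to the namespace
root (root = level 1); ``part_of`` and other relationship types are
ignored.  Annotations deeper than level 3 are projected up to every
level-3 ancestor on an ``is_a`` path to the root, then tested for
over-representation with an upper hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .core import ValidationError


@dataclass
class Term:
    id: str
    name: str = ""
    namespace: str = ""
    parents: list[str] = field(default_factory=list)  # is_a parents


class OntologyGraph:
    """A DAG of terms connected by child→parent ``is_a`` edges."""

    def __init__(self, terms: list[Term]):
        self.terms: dict[str, Term] = {t.id: t for t in terms}
        self._check_acyclic()
        self._levels: dict[str, int] = {}
        self._compute_levels()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(tid: str, stack: list[str]) -> None:
            if state.get(tid) == 1:
                return
            if state.get(tid) == 0:
                raise ValidationError(f"ontology cycle through {tid!r}")
            state[tid] = 0
            for p in self.terms[tid].parents:
                if p in self.terms:
                    visit(p, stack + [tid])
            state[tid] = 1

        for tid in self.terms:
            visit(tid, [])

    def _compute_levels(self) -> None:
        roots = [t.id for t in self.terms.values() if not t.parents]
        children: dict[str, list[str]] = {tid: [] for tid in self.terms}
        for t in self.terms.values():
            for p in t.parents:
                if p in children:
                    children[p].append(t.id)
        # BFS down from the roots: level = 1 + shortest is_a path from root
        frontier = list(roots)
        for r in roots:
            self._levels[r] = 1
        while frontier:
            nxt = []
            for tid in frontier:
                for c in children[tid]:
                    if c not in self._levels:
                        self._levels[c] = self._levels[tid] + 1
                        nxt.append(c)
            frontier = nxt

    def level(self, term_id: str) -> int:
        if term_id not in self.terms:
            raise ValidationError(f"unknown term {term_id!r}")
        return self._levels[term_id]

    def roots(self) -> list[str]:
        return [tid for tid, t in self.terms.items() if not t.parents]

    def namespace_terms(self, namespace: str) -> list[str]:
        return [
            tid for tid, t in self.terms.items() if t.namespace == namespace
        ]

    def ancestors(self, term_id: str) -> set[str]:
        """All is_a ancestors (excluding the term itself)."""
        if term_id not in self.terms:
            raise ValidationError(f"unknown term {term_id!r}")
        out: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            tid = stack.pop()
            if tid in out or tid not in self.terms:
                continue
            out.add(tid)
            stack.extend(self.terms[tid].parents)
        return out


def level3_projection(term_id: str, graph: OntologyGraph, level: int = 3) -> set[str]:
    """Level-``level`` ancestor set of a term (itself when already there).

    Terms above the target level project to the empty set.
    """
    lv = graph.level(term_id)
    if lv == level:
        return {term_id}
    if lv < level:
        return set()
    return {a for a in graph.ancestors(term_id) if graph.level(a) == level}


def project_annotations(
    annotations: pd.DataFrame,
    graph: OntologyGraph,
    namespace: str | None = None,
    level: int = 3,
) -> dict[str, set[str]]:
    """Map each level-3 term to the genes annotated at or below it.

    ``annotations`` has columns ``gene`` and ``term`` (GAF-style, already
    restricted or filtered by aspect upstream).  Unknown terms are skipped.
    """
    term_genes: dict[str, set[str]] = {}
    for gene, term in zip(annotations["gene"], annotations["term"]):
        if term not in graph.terms:
            continue
        if namespace and graph.terms[term].namespace != namespace:
            continue
        for anc in level3_projection(term, graph, level=level):
            term_genes.setdefault(anc, set()).add(gene)
    return term_genes


def hypergeometric_enrichment(
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
    term_genes: dict[str, set[str]],
    graph: OntologyGraph | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` within ``universe``.

    p = P[X ≥ k] under Hypergeometric(N = |universe|, K = node size,
    n = |gene_set|); rows with p < alpha, sorted ascending by p.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    stray = gene_set - universe
    if stray:
        raise ValidationError(
            f"gene_set members outside universe: {sorted(stray)[:5]}"
        )
    n_universe = len(universe)
    n_draw = len(gene_set)
    rows = []
    for term, genes in sorted(term_genes.items()):
        node = genes & universe
        node_size = len(node)
        if node_size == 0:
            continue
        members = sorted(node & gene_set)
        k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, node_size, n_draw))
        rows.append(
            {
                "term": term,
                "name": graph.terms[term].name if graph else "",
                "node_size": node_size,
                "expected": node_size * n_draw / n_universe,
                "observed": k,
                "p": p,
                "genes": ",".join(members),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "name", "node_size", "expected", "observed", "p", "genes"],
    )
    out = out[out["p"] < alpha].sort_values(["p", "term"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# OBO 1.2 and GAF-style I/O


def read_obo(path) -> OntologyGraph:
    """Parse a minimal OBO 1.2 file (id, name, namespace, is_a stanza tags)."""
    terms: list[Term] = []
    current: Term | None = None
    in_term = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                if current is not None:
                    terms.append(current)
                current = Term(id="")
                in_term = True
            elif line.startswith("["):
                if current is not None:
                    terms.append(current)
                current = None
                in_term = False
            elif in_term and current is not None and ":" in line:
                key, _, value = line.partition(":")
                value = value.strip()
                if key == "id":
                    current.id = value
                elif key == "name":
                    current.name = value
                elif key == "namespace":
                    current.namespace = value
                elif key == "is_a":
                    current.parents.append(value.split("!")[0].strip())
                elif key == "is_obsolete" and value == "true":
                    current = None
                    in_term = False
    if current is not None:
        terms.append(current)
    return OntologyGraph([t for t in terms if t.id])


def write_obo(graph: OntologyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for tid in sorted(graph.terms):
            t = graph.terms[tid]
            fh.write("[Term]\n")
            fh.write(f"id: {t.id}\n")
            fh.write(f"name: {t.name}\n")
            fh.write(f"namespace: {t.namespace}\n")
            for p in t.parents:
                fh.write(f"is_a: {p} ! {graph.terms[p].name if p in graph.terms else ''}\n")
            fh.write("\n")


def read_gaf(path) -> pd.DataFrame:
    """Read a GAF-style TSV with columns gene, term, aspect."""
    df = pd.read_csv(path, sep="\t", comment="!", header=None,
                     names=["gene", "term", "aspect"], dtype=str)
    return df


def write_gaf(annotations: pd.DataFrame, path) -> None:
    annotations[["gene", "term", "aspect"]].to_csv(
        path, sep="\t", header=False, index=False
    )
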