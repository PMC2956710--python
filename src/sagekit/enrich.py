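"""Category enrichment of tag clusters against gene annotation tables.

For each (cluster, term) a 2x2 contingency table is built at the gene
level: genes in the cluster versus genes in all other clusters of the same
biological replicate (multi-tag genes count once).  Two one-tailed scores
are available:

* ``fisher`` -- the hypergeometric upper tail P(X >= a);
* ``ease`` -- the EASE score, the same computation after removing one
  in-cluster, in-category gene (a replaced by max(a-1, 0)), a conservative
  penalization of small categories; EASE p >= Fisher p on every table.

Annotation semantics live entirely in the input gene->term table; no
ontology-graph traversal is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """a: in-cluster in-category; b: in-cluster not; c: rest in-category;
    d: rest not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def cluster_size(self) -> int:
        return self.a + self.b

    @property
    def category_size(self) -> int:
        return self.a + self.c


def _upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with the table's margins."""
    population = a + b + c + d
    if population == 0:
        return 1.0
    successes = a + c
    draws = a + b
    return float(stats.hypergeom.sf(a - 1, population, successes, draws))


def ease_score(table: ContingencyTable, mode: str = "ease") -> float:
    """One-tailed enrichment p-value in ``fisher`` or ``ease`` mode."""
    if mode == "fisher":
        return _upper_tail(table.a, table.b, table.c, table.d)
    if mode == "ease":
        a = max(table.a - 1, 0)
        return _upper_tail(a, table.b, table.c, table.d)
    raise ValueError(f"unknown mode {mode!r}")


def cluster_enrichment(
    assignments: Mapping[str, int],
    tag_to_gene: Mapping[str, str | None],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    replicate: str = "",
) -> pd.DataFrame:
    """Score every (cluster, term) pair within one replicate.

    ``assignments`` maps tags to cluster ids; tags resolve to genes through
    ``tag_to_gene`` (tags without a gene are dropped with a count, genes
    without annotation stay in the table background).  Returns one row per
    (cluster, term) with both p-values and an ``enriched`` flag at
    EASE p <= alpha.
    """
    if not annotations:
        raise ValueError("annotation table is empty")
    cluster_genes: dict[int, set] = {}
    n_geneless = 0
    for tag, cl in assignments.items():
        gene = tag_to_gene.get(tag)
        if gene is None:
            n_geneless += 1
            continue
        cluster_genes.setdefault(cl, set()).add(gene)
    all_genes = set().union(*cluster_genes.values()) if cluster_genes else set()
    terms = sorted({t for g in all_genes for t in annotations.get(g, ())})
    rows = []
    for cl in sorted(cluster_genes):
        in_cluster = cluster_genes[cl]
        rest = all_genes - in_cluster
        for term in terms:
            a = sum(1 for g in in_cluster if term in annotations.get(g, ()))
            b = len(in_cluster) - a
            c = sum(1 for g in rest if term in annotations.get(g, ()))
            d = len(rest) - c
            table = ContingencyTable(a, b, c, d)
            fisher_p = ease_score(table, "fisher")
            ease_p = ease_score(table, "ease")
            rows.append(
                (replicate, cl, term, a, b, c, d, fisher_p, ease_p, ease_p <= alpha)
            )
    out = pd.DataFrame(
        rows,
        columns=["replicate", "cluster", "term", "a", "b", "c", "d",
                 "fisher_p", "ease_p", "enriched"],
    )
    out.attrs["n_geneless_tags"] = n_geneless
    return out


def replicate_consensus(
    results: Sequence[pd.DataFrame],
    amalgamations: Sequence[Mapping[int, int]],
    term_categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count, per (major trend group, term), the number of replicates in
    which the term is enriched in any cluster of that group.

    ``amalgamations`` maps each replicate's cluster ids to major groups.
    Redundant terms may be pooled via ``term_categories`` (term ->
    representative category).  Pairs enriched in zero replicates are
    suppressed.
    """
    if len(results) != len(amalgamations):
        raise ValueError("one amalgamation map required per replicate")
    term_sets = [frozenset(res["term"].unique()) for res in results]
    if len(set(term_sets)) > 1:
        raise ValueError("replicates analyzed with different annotation tables")
    hits: dict[tuple[int, str], set] = {}
    for rep_idx, (res, amalg) in enumerate(zip(results, amalgamations)):
        enr = res[res["enriched"]]
        for _, row in enr.iterrows():
            group = amalg[row["cluster"]]
            term = row["term"]
            if term_categories is not None:
                term = term_categories.get(term, term)
            hits.setdefault((group, term), set()).add(rep_idx)
    rows = [
        (group, term, len(reps)) for (group, term), reps in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["group", "term", "n_replicates"])
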