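"""Exact count-based differential expression between SAGE libraries.

The test is the Audic-Claverie exact test: given a tag observed ``x`` times
in a library of ``N1`` tags, the count ``y`` in a second library of ``N2``
tags has, under the null of equal relative abundance, the conditional
distribution

.. math::

    P(y \\mid x) = \\left(\\frac{N_2}{N_1}\\right)^{y}
        \\frac{(x+y)!}{x!\\,y!\\,(1 + N_2/N_1)^{x+y+1}},

which is the negative-binomial law ``y ~ NB(x+1, N1/(N1+N2))``.  Tail
probabilities are therefore computed through the regularized incomplete
beta function rather than naive summation.  The two-sided p-value doubles
the smaller of the two *away-from-null* conditional tails — ``P(Y >= y | x)``
and, conditioning the other way, ``P(X >= x | y)`` — capped at 1.  This
combination is exchange-symmetric (p(x, y, N1, N2) = p(y, x, N2, N1)) and
coincides with the exact conditional binomial test of ``y`` out of
``x + y`` trials with success probability ``N2/(N1+N2)``.  Library-level
comparisons apply a
cross-replicate consistency rule: a tag counts as differentially expressed
only when significant with the same direction in every biological
replicate.  No multiple-testing correction is applied by default, matching
the raw-threshold design at p <= 0.05 / 0.01 / 0.001; an FDR option is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sagekit.tagproc import TagCountTable, TagMap

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ACComparison:
    """One tag's counts in two libraries of given sizes."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be nonnegative")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be positive")

    def pvalue(self) -> float:
        return float(ac_pvalue(self.x, self.y, self.n1, self.n2))


def _check_ac_args(x, y, n1, n2):
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be positive")
    return x, y, n1, n2


def ac_tails(x, y, n1, n2):
    """One-sided conditional tails ``(P(Y <= y | x), P(Y >= y | x))``.

    Both condition on the first library's count; note the boundary outcome
    belongs to both tails, so they sum to 1 + P(y|x).
    """
    x, y, n1, n2 = _check_ac_args(x, y, n1, n2)
    p1 = n1 / (n1 + n2)
    return stats.nbinom.cdf(y, x + 1, p1), stats.nbinom.sf(y - 1, x + 1, p1)


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value; vectorized over counts.

    Doubles the smaller of the two away-from-null conditional tails
    ``P(Y >= y | x)`` and ``P(X >= x | y)``, capped at 1.  Via the
    negative-binomial/binomial tail identity both tails are tails of
    ``Binom(x + y, N2/(N1+N2))`` at ``y``, so the value is
    exchange-symmetric: p(x, y, N1, N2) = p(y, x, N2, N1).
    """
    x, y, n1, n2 = _check_ac_args(x, y, n1, n2)
    q = n2 / (n1 + n2)
    n = x + y
    upper = stats.binom.sf(y - 1, n, q)   # = P(Y >= y | x)
    lower = stats.binom.cdf(y, n, q)      # = P(X >= x | y)
    p = 2.0 * np.minimum(upper, lower)
    return np.minimum(p, 1.0)


def pairwise_de(
    lib_a: TagCountTable,
    lib_b: TagCountTable,
    comparison: str,
    replicate: str = "",
) -> pd.DataFrame:
    """Test every tag present in either library.

    Tags absent from one library enter with count 0; library sizes are the
    final (post-filter) totals.  Direction is the sign of the cpm
    difference (B relative to A); equal cpm gives direction "none".
    """
    if lib_a.library_id == lib_b.library_id:
        raise ValueError("cannot compare a library with itself")
    n1, n2 = lib_a.total_tags, lib_b.total_tags
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both libraries must be non-empty")
    tags = sorted(set(lib_a.counts) | set(lib_b.counts))
    x = np.array([lib_a.counts.get(t, 0) for t in tags], dtype=np.int64)
    y = np.array([lib_b.counts.get(t, 0) for t in tags], dtype=np.int64)
    p = ac_pvalue(x, y, n1, n2)
    cpm_a = 1e6 * x / n1
    cpm_b = 1e6 * y / n2
    direction = np.where(cpm_b > cpm_a, "up", np.where(cpm_b < cpm_a, "down", "none"))
    return pd.DataFrame(
        {
            "tag": tags,
            "comparison": comparison,
            "replicate": replicate,
            "x": x,
            "y": y,
            "n1": n1,
            "n2": n2,
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "direction": direction,
            "p": p,
        }
    )


def fdr_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini-Hochberg adjustment appended as column ``q``."""
    out = results.copy()
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


@dataclass
class ConsistencySummary:
    """Counts of tags consistently significant across all replicates."""

    counts: pd.DataFrame          # index (comparison, direction, alpha) -> n
    detail: pd.DataFrame          # per (tag, comparison, alpha, direction)

    def n_consistent(self, comparison: str, direction: str, alpha: float) -> int:
        try:
            return int(self.counts.loc[(comparison, direction, alpha), "n"])
        except KeyError:
            return 0


def consistent_de(
    results: pd.DataFrame,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> ConsistencySummary:
    """Apply the cross-replicate consistency rule.

    ``results`` concatenates :func:`pairwise_de` outputs over replicates.
    A tag is consistently up (down) in a comparison at level alpha iff it is
    significant at alpha with that same direction in *every* replicate.
    """
    replicates = sorted(results["replicate"].unique())
    if not replicates:
        raise ValueError("no replicates in results")
    n_rep = len(replicates)
    for comparison, sub in results.groupby("comparison"):
        missing = set(replicates) - set(sub["replicate"].unique())
        if missing:
            raise ValueError(f"comparison {comparison} missing replicate(s) {sorted(missing)}")
    rows = []
    detail_rows = []
    for comparison, sub in results.groupby("comparison"):
        for alpha in alphas:
            sig = sub[sub["p"] <= alpha]
            for direction in ("up", "down"):
                dsig = sig[sig["direction"] == direction]
                per_tag = dsig.groupby("tag")["replicate"].nunique()
                consistent = per_tag[per_tag == n_rep].index
                rows.append((comparison, direction, alpha, len(consistent)))
                detail_rows.extend(
                    (t, comparison, alpha, direction) for t in consistent
                )
    counts = pd.DataFrame(rows, columns=["comparison", "direction", "alpha", "n"])
    counts = counts.set_index(["comparison", "direction", "alpha"])
    detail = pd.DataFrame(
        detail_rows, columns=["tag", "comparison", "alpha", "direction"]
    )
    return ConsistencySummary(counts, detail)


# ---------------------------------------------------------------------------
# Trend labeling
# ---------------------------------------------------------------------------

#: Default trend-label rule table over the signed significance pattern of
#: the (stage1->stage2, stage2->stage3) steps, refined by the net cpm
#: change for the two non-monotone patterns.  Keys: (step1, step2) with
#: steps in {"up", "flat", "down"}; values either a letter or a dict over
#: net direction {"up", "down", "flat"}.
DEFAULT_TREND_RULES: dict = {
    ("up", "up"): "A",
    ("up", "flat"): "B",
    ("flat", "up"): "C",
    ("up", "down"): {"up": "D", "down": "E", "flat": "F"},
    ("down", "down"): "G",
    ("down", "flat"): "H",
    ("flat", "down"): "I",
    ("down", "up"): {"up": "J", "down": "K", "flat": "L"},
    ("flat", "flat"): "M",
}

#: Major-trend groups: 1 up during progression, 2 down, 3 peak at the
#: middle stage, 4 constant, 5 valley at the middle stage.
_STEP_GROUPS = {
    ("up", "up"): 1,
    ("up", "flat"): 1,
    ("flat", "up"): 1,
    ("down", "down"): 2,
    ("down", "flat"): 2,
    ("flat", "down"): 2,
    ("up", "down"): 3,
    ("down", "up"): 5,
    ("flat", "flat"): 4,
}


@dataclass
class TrendLabel:
    tag: str
    step1: str
    step2: str
    net: str
    label: str
    group: int


def _consensus_step(directions: Sequence[str], significant: Sequence[bool]) -> str:
    """A step is up/down only when significant with that direction in every
    replicate; anything else is flat."""
    if all(significant) and len(set(directions)) == 1 and directions[0] in ("up", "down"):
        return directions[0]
    return "flat"


def classify_trend(
    tag: str,
    profiles: Sequence[Sequence[float]],
    step1_calls: Sequence[tuple[str, bool]],
    step2_calls: Sequence[tuple[str, bool]],
    rules: Mapping = DEFAULT_TREND_RULES,
) -> TrendLabel:
    """Label a tag's expression trend across three ordered stages.

    ``profiles`` holds one cpm triple per replicate; ``step*_calls`` hold
    per-replicate (direction, significant) for the two stage transitions.
    The label comes from the rule table; the major group from the
    canonical five-group rule.
    """
    for prof in profiles:
        if len(prof) != 3:
            raise ValueError("trend classification requires exactly 3 stages")
    s1 = _consensus_step([d for d, _ in step1_calls], [s for _, s in step1_calls])
    s2 = _consensus_step([d for d, _ in step2_calls], [s for _, s in step2_calls])
    arr = np.asarray(profiles, dtype=float)
    net_diff = float(np.mean(arr[:, 2] - arr[:, 0]))
    net = "up" if net_diff > 0 else ("down" if net_diff < 0 else "flat")
    rule = rules[(s1, s2)]
    label = rule[net] if isinstance(rule, Mapping) else rule
    return TrendLabel(tag, s1, s2, net, label, _STEP_GROUPS[(s1, s2)])


# ---------------------------------------------------------------------------
# Candidate-gene funnel
# ---------------------------------------------------------------------------

def candidate_gene_summary(
    tags: Iterable[str],
    tag_map: TagMap,
    known_genes: Iterable[str] = (),
) -> dict:
    """Collapse a consistent tag set to candidate genes and novel genes.

    Relevant tags exclude ambiguous and host-mapped tags; candidate genes
    collapse multi-tag genes and drop tags without an annotated gene
    (no-map / genomic-only); novel genes are candidates absent from the
    supplied known-gene list.
    """
    tags = list(tags)
    known = set(known_genes)
    classes = {t: tag_map.class_of(t) for t in tags}
    relevant = [t for t, c in classes.items() if c not in ("ambiguous", "host")]
    genes = {tag_map.gene_of(t) for t in relevant}
    genes.discard(None)
    novel = genes - known
    report = {
        "n_input_tags": len(tags),
        "n_ambiguous": sum(1 for c in classes.values() if c == "ambiguous"),
        "n_host": sum(1 for c in classes.values() if c == "host"),
        "n_relevant": len(relevant),
        "n_no_map": sum(1 for t in relevant if classes[t] == "no_map"),
        "n_genomic_only": sum(1 for t in relevant if classes[t] == "genomic_only"),
        "n_candidate_genes": len(genes),
        "n_novel": len(novel),
        "candidate_genes": sorted(genes),
        "novel_genes": sorted(novel),
    }
    if not (report["n_novel"] <= report["n_candidate_genes"] <= report["n_relevant"]
            <= report["n_input_tags"]):
        raise AssertionError("funnel counts are not monotone")
    return report
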