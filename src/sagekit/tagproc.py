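"""Tag extraction, filtering and accounting for LongSAGE libraries.

A LongSAGE library is sequenced as *ditags*: two 17-base tags ligated
tail-to-tail between anchoring-enzyme (NlaIII, ``CATG``) sites.  This module
parses ditag reads into tag observations, applies the standard three-stage
filter cascade (bad tags containing N calls, low sequence-quality tags,
linker-derived artifact tags), counts duplicate ditags, and produces a
per-library composition report whose arithmetic is integer-exact:

    unfiltered_total = final_total + n_bad + n_below_qf + n_ldt1 + n_ldt2

Duplicate ditags are counted and reported but *not* removed from totals;
a removal mode is available for protocols that discard them.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

TAG_LENGTH = 17
ANCHOR = "CATG"
DITAG_LENGTH = 2 * TAG_LENGTH

#: Default linker-derived 17-mers (one per linker type).  Real linker
#: sequences are protocol-specific; these are configuration, used
#: consistently by the synthetic generator and the filter.
DEFAULT_LINKER_TAGS_TYPE1 = frozenset({"TCCCTATTAAGGGTTCT"})
DEFAULT_LINKER_TAGS_TYPE2 = frozenset({"TCCCCGTACATCGTTAG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DitagRead:
    """One sequenced ditag with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]
    library_id: str

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass
class TagObservation:
    """A single 17-base tag parsed from a ditag.

    ``qf`` is the sequence quality factor: the probability that all 17 base
    calls are correct, :math:`\\prod_j (1 - 10^{-Q_j/10})`.
    """

    tag: str
    qf: float
    ditag_id: str

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH:
            raise ValueError(f"tag {self.tag!r} is not {TAG_LENGTH} bases")


@dataclass
class TagCountTable:
    """Per-library map from tag sequence to observed count."""

    library_id: str
    counts: dict[str, int]

    @property
    def total_tags(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def tag_types(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.counts, dtype="int64", name=self.library_id)
        s.index.name = "tag"
        return s

    def to_tsv(self, path) -> None:
        self.to_series().sort_index().to_csv(path, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path, library_id: str) -> "TagCountTable":
        s = pd.read_csv(path, sep="\t", header=None, index_col=0).iloc[:, 0]
        return cls(library_id, {str(t): int(c) for t, c in s.items()})


@dataclass
class LibraryComposition:
    """Filter-cascade accounting record for one library.

    Mirrors the per-library composition report of a LongSAGE study: raw tag
    totals, tags removed at each filter stage, duplicate-ditag statistics,
    and the final useful-tag totals.
    """

    library_id: str
    unfiltered_total: int
    n_bad: int
    total_minus_bad: int
    tag_types_minus_bad: int
    n_duplicate_ditags: int
    pct_duplicate_ditags: float
    mean_qf: float
    n_below_qf: int
    total_q95: int
    tag_types_q95: int
    n_ldt_type1: int
    n_ldt_type2: int
    final_total: int
    final_tag_types: int

    def validate(self) -> None:
        if self.total_minus_bad != self.unfiltered_total - self.n_bad:
            raise ValueError(f"{self.library_id}: bad-tag accounting does not balance")
        if self.total_q95 != self.total_minus_bad - self.n_below_qf:
            raise ValueError(f"{self.library_id}: QF accounting does not balance")
        if self.final_total != self.total_q95 - self.n_ldt_type1 - self.n_ldt_type2:
            raise ValueError(f"{self.library_id}: LDT accounting does not balance")
        expected_pct = duplicate_pct(self.n_duplicate_ditags, self.total_minus_bad)
        if abs(self.pct_duplicate_ditags - expected_pct) > 0.005 + 1e-9:
            raise ValueError(f"{self.library_id}: duplicate-ditag percentage inconsistent")
        for name in ("unfiltered_total", "n_bad", "n_duplicate_ditags",
                     "n_below_qf", "n_ldt_type1", "n_ldt_type2", "final_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.library_id}: {name} negative")

    @classmethod
    def from_stage_counts(
        cls,
        library_id: str,
        *,
        unfiltered_total: int,
        n_bad: int,
        n_duplicate_ditags: int,
        n_below_qf: int,
        n_ldt_type1: int,
        n_ldt_type2: int,
        mean_qf: float = float("nan"),
        tag_types_minus_bad: int = 0,
        tag_types_q95: int = 0,
        final_tag_types: int = 0,
    ) -> "LibraryComposition":
        """Build the composition record from raw per-stage counts.

        Derived totals are computed here so the accounting identities hold by
        construction; ``validate`` re-checks them.
        """
        total_minus_bad = unfiltered_total - n_bad
        total_q95 = total_minus_bad - n_below_qf
        final_total = total_q95 - n_ldt_type1 - n_ldt_type2
        comp = cls(
            library_id=library_id,
            unfiltered_total=unfiltered_total,
            n_bad=n_bad,
            total_minus_bad=total_minus_bad,
            tag_types_minus_bad=tag_types_minus_bad,
            n_duplicate_ditags=n_duplicate_ditags,
            pct_duplicate_ditags=duplicate_pct(n_duplicate_ditags, total_minus_bad),
            mean_qf=mean_qf,
            n_below_qf=n_below_qf,
            total_q95=total_q95,
            tag_types_q95=tag_types_q95,
            n_ldt_type1=n_ldt_type1,
            n_ldt_type2=n_ldt_type2,
            final_total=final_total,
            final_tag_types=final_tag_types,
        )
        comp.validate()
        return comp

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


#: Mapping ambiguity classes, in funnel-report order.
MAPPING_CLASSES = (
    "unique_sense",
    "antisense",
    "ambiguous",
    "genomic_only",
    "no_map",
    "host",
)


@dataclass
class TagMap:
    """Tag -> gene hits with an ambiguity class per tag.

    ``hits`` maps a tag to a list of ``(gene_id, strand)`` tuples where
    strand is ``"+"`` (sense) or ``"-"`` (antisense).  A tag is
    ``unique_sense`` iff it has exactly one sense-strand gene hit and no
    cross-species hit.
    """

    hits: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    mapping_class: dict[str, str] = field(default_factory=dict)

    def gene_of(self, tag: str) -> str | None:
        """Best gene for a tag: the single sense hit, else the single
        antisense hit, else None."""
        hits = self.hits.get(tag, [])
        sense = [g for g, s in hits if s == "+"]
        if len(sense) == 1:
            return sense[0]
        anti = [g for g, s in hits if s == "-"]
        if len(sense) == 0 and len(anti) == 1:
            return anti[0]
        return None

    def class_of(self, tag: str) -> str:
        return self.mapping_class.get(tag, "no_map")

    def to_tsv(self, path) -> None:
        rows = []
        for tag, cls in sorted(self.mapping_class.items()):
            hits = self.hits.get(tag, [])
            gene = self.gene_of(tag) or ""
            strand = hits[0][1] if hits else ""
            rows.append((tag, gene, cls, strand))
        pd.DataFrame(rows, columns=["tag", "gene", "class", "strand"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def phred_qf(qualities: Sequence[int]) -> float:
    """Probability that every base call in the tag is correct."""
    q = np.asarray(qualities, dtype=float)
    return float(np.prod(1.0 - 10.0 ** (-q / 10.0)))


def extract_tags(
    reads: Iterable[DitagRead],
) -> tuple[list[TagObservation], Counter]:
    """Parse ditag reads into per-tag observations plus a duplicate ledger.

    Each ditag yields two 17-base observations: the first tag read 5'->3',
    the second reverse-complemented (standard SAGE orientation).  The ledger
    counts occurrences of each distinct ditag sequence for duplicate-ditag
    accounting.  Reads without 34 usable bases between anchors are skipped
    and logged, not fatal.
    """
    observations: list[TagObservation] = []
    ledger: Counter = Counter()
    n_skipped = 0
    n_reads = 0
    for read in reads:
        n_reads += 1
        seq = read.sequence
        start = seq.find(ANCHOR)
        if start < 0:
            # tolerate reads delivered without the leading anchor
            ditag_start = 0
        else:
            ditag_start = start + len(ANCHOR)
        ditag = seq[ditag_start : ditag_start + DITAG_LENGTH]
        if len(ditag) < DITAG_LENGTH:
            n_skipped += 1
            logger.debug("read %s: <%d usable bases, skipped", read.read_id, DITAG_LENGTH)
            continue
        quals = list(read.qualities[ditag_start : ditag_start + DITAG_LENGTH])
        ledger[ditag] += 1
        tag1 = ditag[:TAG_LENGTH]
        tag2 = revcomp(ditag[TAG_LENGTH:DITAG_LENGTH])
        q1 = quals[:TAG_LENGTH]
        q2 = quals[TAG_LENGTH:DITAG_LENGTH][::-1]
        observations.append(TagObservation(tag1, phred_qf(q1), read.read_id))
        observations.append(TagObservation(tag2, phred_qf(q2), read.read_id))
    if n_reads == 0:
        raise ValueError("no ditag reads supplied")
    if n_skipped:
        logger.info("skipped %d short reads", n_skipped)
    return observations, ledger


def filter_bad_tags(
    obs: Sequence[TagObservation],
) -> tuple[list[TagObservation], int]:
    """Remove bad tags: any tag containing at least one N base call."""
    kept = [o for o in obs if "N" not in o.tag]
    return kept, len(obs) - len(kept)


def quality_filter(
    obs: Sequence[TagObservation], threshold: float = 0.95
) -> tuple[list[TagObservation], int, float]:
    """Remove observations whose quality factor falls below ``threshold``.

    Returns (kept, n_removed, mean_qf) where mean_qf is the mean quality
    factor over all *input* observations.
    """
    if not obs:
        return [], 0, float("nan")
    mean_qf = float(np.mean([o.qf for o in obs]))
    kept = [o for o in obs if o.qf >= threshold]
    return kept, len(obs) - len(kept), mean_qf


def count_tags(obs: Sequence[TagObservation], library_id: str) -> TagCountTable:
    counts: Counter = Counter(o.tag for o in obs)
    return TagCountTable(library_id, dict(counts))


def remove_ldts(
    counts: TagCountTable,
    linker_type1: Iterable[str] = DEFAULT_LINKER_TAGS_TYPE1,
    linker_type2: Iterable[str] = DEFAULT_LINKER_TAGS_TYPE2,
) -> tuple[TagCountTable, int, int]:
    """Remove linker-derived tags (exact sequence match to a linker set)."""
    set1, set2 = set(linker_type1), set(linker_type2)
    if not set1 or not set2:
        raise ValueError("linker sequence sets must be non-empty")
    n1 = sum(c for t, c in counts.counts.items() if t in set1)
    n2 = sum(c for t, c in counts.counts.items() if t in set2)
    cleaned = {
        t: c for t, c in counts.counts.items() if t not in set1 and t not in set2
    }
    return TagCountTable(counts.library_id, cleaned), int(n1), int(n2)


def duplicate_pct(n_duplicates: int, post_bad_total: int) -> float:
    """Duplicate-ditag percentage: ditag duplicates over the post-bad-tag
    *tag* total, reported to 2 decimals (the convention under which the
    published composition tables balance)."""
    if post_bad_total <= 0:
        return 0.0
    return round(100.0 * n_duplicates / post_bad_total, 2)


def count_duplicate_ditags(
    ledger: Mapping[str, int], post_bad_total: int | None = None
) -> tuple[int, float]:
    """Count ditag occurrences beyond the first of each distinct sequence.

    Duplicates are counted, not removed.  ``post_bad_total`` is the tag
    total after bad-tag removal used as the percentage denominator; when
    omitted the ledger's own tag total (2 tags per ditag) is used.
    """
    n_total = sum(ledger.values())
    n_duplicates = int(n_total - len(ledger)) if ledger else 0
    if post_bad_total is None:
        post_bad_total = 2 * n_total
    return n_duplicates, duplicate_pct(n_duplicates, post_bad_total)


def build_library_composition(
    library_id: str,
    *,
    unfiltered_total: int,
    n_bad: int,
    post_bad: TagCountTable,
    n_duplicate_ditags: int,
    n_below_qf: int,
    mean_qf: float,
    post_qf: TagCountTable,
    n_ldt_type1: int,
    n_ldt_type2: int,
    final: TagCountTable,
) -> LibraryComposition:
    """Assemble the composition report from the actual filter-stage outputs,
    cross-checking that the stage tables are mutually consistent."""
    if post_bad.total_tags != unfiltered_total - n_bad:
        raise ValueError(f"{library_id}: post-bad table inconsistent with counts")
    if post_qf.total_tags != post_bad.total_tags - n_below_qf:
        raise ValueError(f"{library_id}: post-QF table inconsistent with counts")
    if final.total_tags != post_qf.total_tags - n_ldt_type1 - n_ldt_type2:
        raise ValueError(f"{library_id}: final table inconsistent with counts")
    return LibraryComposition.from_stage_counts(
        library_id,
        unfiltered_total=unfiltered_total,
        n_bad=n_bad,
        n_duplicate_ditags=n_duplicate_ditags,
        n_below_qf=n_below_qf,
        n_ldt_type1=n_ldt_type1,
        n_ldt_type2=n_ldt_type2,
        mean_qf=mean_qf,
        tag_types_minus_bad=post_bad.tag_types,
        tag_types_q95=post_qf.tag_types,
        final_tag_types=final.tag_types,
    )


def normalize_cpm(counts: TagCountTable) -> dict[str, float]:
    """Counts per million over the library's final total."""
    total = counts.total_tags
    if total <= 0:
        raise ValueError(f"library {counts.library_id} is empty")
    return {t: 1e6 * c / total for t, c in counts.counts.items()}


def process_library(
    reads: Iterable[DitagRead],
    library_id: str,
    qf_threshold: float = 0.95,
    linker_type1: Iterable[str] = DEFAULT_LINKER_TAGS_TYPE1,
    linker_type2: Iterable[str] = DEFAULT_LINKER_TAGS_TYPE2,
) -> tuple[TagCountTable, LibraryComposition]:
    """Run the full filter cascade on one library's ditag reads."""
    obs, ledger = extract_tags(reads)
    unfiltered_total = len(obs)
    post_bad_obs, n_bad = filter_bad_tags(obs)
    post_bad = count_tags(post_bad_obs, library_id)
    n_dup, _ = count_duplicate_ditags(ledger, post_bad.total_tags)
    post_qf_obs, n_below_qf, mean_qf = quality_filter(post_bad_obs, qf_threshold)
    post_qf = count_tags(post_qf_obs, library_id)
    final, n1, n2 = remove_ldts(post_qf, linker_type1, linker_type2)
    comp = build_library_composition(
        library_id,
        unfiltered_total=unfiltered_total,
        n_bad=n_bad,
        post_bad=post_bad,
        n_duplicate_ditags=n_dup,
        n_below_qf=n_below_qf,
        mean_qf=mean_qf,
        post_qf=post_qf,
        n_ldt_type1=n1,
        n_ldt_type2=n2,
        final=final,
    )
    return final, comp


# ---------------------------------------------------------------------------
# Tag-to-gene mapping
# ---------------------------------------------------------------------------

def canonical_tag(sequence: str) -> str | None:
    """The canonical LongSAGE tag of a transcript: the 17 bases immediately
    3' of the 3'-most anchoring-enzyme site (CATG) on the sense strand.
    Returns None when no site leaves 17 downstream bases."""
    pos = sequence.rfind(ANCHOR)
    while pos >= 0:
        tag = sequence[pos + len(ANCHOR) : pos + len(ANCHOR) + TAG_LENGTH]
        if len(tag) == TAG_LENGTH:
            return tag
        pos = sequence.rfind(ANCHOR, 0, pos)
    return None


def build_tag_map(
    transcripts: Iterable[tuple[str, str]],
    host_transcripts: Iterable[tuple[str, str]] = (),
    genome_sequences: Iterable[str] = (),
) -> TagMap:
    """Derive a tag->gene map from transcript sequences.

    ``transcripts`` and ``host_transcripts`` are (gene_id, sequence) pairs.
    Sense tags are the canonical tags of each transcript; antisense tags the
    canonical tags of the reverse complement.  Classification:

    * >=2 human sense genes, or hits in both species -> ``ambiguous``
    * exactly 1 human sense gene -> ``unique_sense``
    * no sense hit but an antisense hit -> ``antisense``
    * host-only hit -> ``host``
    * found only in a supplied genome sequence -> ``genomic_only``

    Tags observed in libraries but absent from every source are classed
    ``no_map`` by :func:`classify_tag_mapping`.
    """
    tmap = TagMap()
    for gene, seq in transcripts:
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            tag = canonical_tag(s)
            if tag is None:
                if strand == "+":
                    logger.debug("transcript %s: no usable anchoring site", gene)
                continue
            tmap.hits.setdefault(tag, [])
            if (gene, strand) not in tmap.hits[tag]:
                tmap.hits[tag].append((gene, strand))
    host_tags: set[str] = set()
    for gene, seq in host_transcripts:
        for s in (seq, revcomp(seq)):
            tag = canonical_tag(s)
            if tag is not None:
                host_tags.add(tag)
    genomic_tags: set[str] = set()
    for gseq in genome_sequences:
        for s in (gseq, revcomp(gseq)):
            for i in range(len(s) - len(ANCHOR) - TAG_LENGTH + 1):
                if s[i : i + len(ANCHOR)] == ANCHOR:
                    genomic_tags.add(s[i + len(ANCHOR) : i + len(ANCHOR) + TAG_LENGTH])

    for tag in set(tmap.hits) | host_tags | genomic_tags:
        hits = tmap.hits.get(tag, [])
        sense_genes = {g for g, s in hits if s == "+"}
        anti_genes = {g for g, s in hits if s == "-"}
        in_host = tag in host_tags
        if (sense_genes or anti_genes) and in_host:
            cls = "ambiguous"
        elif len(sense_genes) > 1:
            cls = "ambiguous"
        elif len(sense_genes) == 1:
            cls = "unique_sense"
        elif anti_genes:
            cls = "ambiguous" if len(anti_genes) > 1 else "antisense"
        elif in_host:
            cls = "host"
        else:
            cls = "genomic_only"
        tmap.mapping_class[tag] = cls
    return tmap


def classify_tag_mapping(
    tags: Iterable[str], tag_map: TagMap
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify observed tags against a map and summarize the funnel.

    "Relevant" tags are those that are neither ambiguous nor host-derived.
    The gene-level collapse merges relevant tags sharing a gene; tags with
    no gene (no_map / genomic_only) contribute no candidate gene.
    """
    classes = {t: tag_map.class_of(t) for t in tags}
    funnel: dict[str, int] = {"n_input": len(classes)}
    for cls in MAPPING_CLASSES:
        funnel[f"n_{cls}"] = sum(1 for c in classes.values() if c == cls)
    relevant = [t for t, c in classes.items() if c not in ("ambiguous", "host")]
    funnel["n_relevant"] = len(relevant)
    genes = [tag_map.gene_of(t) for t in relevant]
    funnel["n_candidate_genes"] = len({g for g in genes if g is not None})
    return classes, funnel


def read_fastq(path, library_id: str) -> list[DitagRead]:
    """Read ditag reads from a Sanger-encoded FASTQ file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            DitagRead(
                rec.id,
                str(rec.seq),
                rec.letter_annotations["phred_quality"],
                library_id,
            )
        )
    return reads
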