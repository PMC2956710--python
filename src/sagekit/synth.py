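"""Ground-truthed synthetic LongSAGE atlas generation.

The generator emulates the statistical structure of a replicated LongSAGE
progression experiment: three biological replicates sampled at three
ordered disease stages (androgen-sensitive AS, responsive to
androgen-deprivation RAD, castration-recurrent CR), each library a fixed
number of 17-base tags drawn multinomially from per-tag relative
abundances.  Each tag type carries a planted expression trend from the
five canonical major groups:

1. up during progression, 2. down during progression, 3. peak at the RAD
stage, 4. constant, 5. valley at the RAD stage,

realized as stage multipliers of magnitude ``effect_size`` with
within-group lognormal jitter (which also generates the finer sub-pattern
diversity seen in real data).  Raw ditag reads with per-base Phred
qualities can be synthesized on top, injecting N-base errors, low-quality
tags, linker-derived ditags and duplicate ditags at configured rates, with
the ground truth of every injection retained.  A tag-to-gene map with
ambiguity classes, gene annotations with planted category enrichment, and
group-structured expression matrices for signature projection round out
the test harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sagekit.tagproc import (
    ANCHOR,
    DEFAULT_LINKER_TAGS_TYPE1,
    DEFAULT_LINKER_TAGS_TYPE2,
    TAG_LENGTH,
    DitagRead,
    TagCountTable,
    TagMap,
    revcomp,
)

STAGES = ("AS", "RAD", "CR")
N_GROUPS = 5
BASES = np.array(list("ACGT"))


@dataclass
class AtlasConfig:
    """Study design and contamination rates for one synthetic atlas.

    Defaults reflect a full-scale replicated LongSAGE experiment: nine
    libraries of 3x10^5 tags, ~5x10^4 tag types, mostly constant
    transcripts with a minority of four-fold progression trends, ~0.3% bad
    tags, ~20% of tags below the 0.95 quality threshold, rare
    linker-derived ditags and a few percent duplicate ditags.
    """

    seed: int = 0
    n_replicates: int = 3
    stages: tuple[str, ...] = STAGES
    n_tag_types: int = 50_000
    library_size: int = 300_000
    trend_mix: tuple[float, ...] = (0.05, 0.05, 0.05, 0.80, 0.05)
    effect_size: float = 4.0
    jitter_sigma: float = 0.1
    count_mode: str = "multinomial"   # or "poisson"
    # raw-read contamination rates (per tag or per ditag)
    frac_bad: float = 0.003
    frac_low_qf: float = 0.20
    frac_ldt: float = 0.0006
    frac_duplicate_ditags: float = 0.05
    # tag-to-gene mapping class proportions (remainder is unique_sense)
    frac_ambiguous_map: float = 0.10
    frac_antisense: float = 0.05
    frac_nomap: float = 0.04
    frac_genomic_only: float = 0.03
    frac_host: float = 0.03
    frac_two_tag_genes: float = 0.02
    # planted annotation enrichment
    annotation_true_rate: float = 0.6
    annotation_bg_rate: float = 0.05

    def validate(self) -> None:
        fracs = dict(
            frac_bad=self.frac_bad, frac_low_qf=self.frac_low_qf,
            frac_ldt=self.frac_ldt,
            frac_duplicate_ditags=self.frac_duplicate_ditags,
            frac_ambiguous_map=self.frac_ambiguous_map,
            frac_antisense=self.frac_antisense, frac_nomap=self.frac_nomap,
            frac_genomic_only=self.frac_genomic_only, frac_host=self.frac_host,
            frac_two_tag_genes=self.frac_two_tag_genes,
            annotation_true_rate=self.annotation_true_rate,
            annotation_bg_rate=self.annotation_bg_rate,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        map_total = (self.frac_ambiguous_map + self.frac_antisense
                     + self.frac_nomap + self.frac_genomic_only + self.frac_host)
        if map_total > 1.0:
            raise ValueError("mapping-class fractions exceed 1")
        if len(self.trend_mix) != N_GROUPS:
            raise ValueError(f"trend_mix must have {N_GROUPS} entries")
        if abs(sum(self.trend_mix) - 1.0) > 1e-9 or min(self.trend_mix) < 0:
            raise ValueError("trend_mix must be nonnegative and sum to 1")
        if len(self.stages) < 2:
            raise ValueError("at least 2 stages required")
        if self.library_size <= 0 or self.n_tag_types <= 0:
            raise ValueError("library_size and n_tag_types must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.effect_size < 1:
            raise ValueError("effect_size is a fold change, must be >= 1")
        if self.count_mode not in ("multinomial", "poisson"):
            raise ValueError("count_mode must be 'multinomial' or 'poisson'")


@dataclass
class SyntheticAtlas:
    """Simulated libraries plus every piece of planted ground truth."""

    config: AtlasConfig
    libraries: dict[tuple[str, str], TagCountTable]   # (replicate, stage)
    truth_trends: dict[str, int]                      # tag -> major group 1..5
    tag_map: TagMap
    annotations: dict[str, set[str]]                  # gene -> terms
    base_abundance: pd.Series = field(repr=False, default=None)

    @property
    def replicates(self) -> list[str]:
        return sorted({r for r, _ in self.libraries})

    def stage_counts(self, replicate: str) -> pd.DataFrame:
        """Tags x stages count frame for one replicate (union tag set)."""
        cols = {
            stage: self.libraries[(replicate, stage)].to_series()
            for stage in self.config.stages
        }
        return pd.DataFrame(cols).fillna(0).astype(int)


def _stage_multipliers(config: AtlasConfig) -> np.ndarray:
    """(group, stage) mean multipliers realizing the five trend shapes."""
    f = config.effect_size
    n_stages = len(config.stages)
    mid = np.sqrt(f)
    mult = np.ones((N_GROUPS, n_stages))
    ramp_up = np.concatenate([[1.0], np.full(max(n_stages - 2, 0), mid), [f]])
    mult[0] = ramp_up                      # group 1: up during progression
    mult[1] = ramp_up[::-1]                # group 2: down
    mult[2, 1:-1] = f                      # group 3: peak at middle stage(s)
    mult[4, 0] = mult[4, -1] = f           # group 5: valley at middle stage(s)
    return mult


def _random_tags(rng: np.random.Generator, n: int, forbidden: set[str]) -> list[str]:
    tags: list[str] = []
    seen = set(forbidden)
    while len(tags) < n:
        block = rng.integers(0, 4, size=(max(n - len(tags), 16), TAG_LENGTH))
        for row in block:
            tag = "".join(BASES[row])
            if tag not in seen:
                seen.add(tag)
                tags.append(tag)
                if len(tags) == n:
                    break
    return tags


def _build_tag_assignments(
    rng: np.random.Generator, config: AtlasConfig, tags: list[str]
) -> tuple[TagMap, dict[str, str | None]]:
    """Assign a mapping class and gene to every tag."""
    n = len(tags)
    classes = np.full(n, "unique_sense", dtype=object)
    order = rng.permutation(n)
    bounds = np.cumsum([
        int(round(config.frac_ambiguous_map * n)),
        int(round(config.frac_antisense * n)),
        int(round(config.frac_nomap * n)),
        int(round(config.frac_genomic_only * n)),
        int(round(config.frac_host * n)),
    ])
    classes[order[: bounds[0]]] = "ambiguous"
    classes[order[bounds[0]:bounds[1]]] = "antisense"
    classes[order[bounds[1]:bounds[2]]] = "no_map"
    classes[order[bounds[2]:bounds[3]]] = "genomic_only"
    classes[order[bounds[3]:bounds[4]]] = "host"

    tmap = TagMap()
    gene_counter = 0
    pending_pair: str | None = None
    for i, tag in enumerate(tags):
        cls = str(classes[i])
        tmap.mapping_class[tag] = cls
        if cls == "unique_sense":
            if pending_pair is not None:
                gene = pending_pair
                pending_pair = None
            else:
                gene = f"GENE{gene_counter:06d}"
                gene_counter += 1
                if rng.random() < config.frac_two_tag_genes:
                    pending_pair = gene
            tmap.hits[tag] = [(gene, "+")]
        elif cls == "antisense":
            gene = f"GENE{gene_counter:06d}"
            gene_counter += 1
            tmap.hits[tag] = [(gene, "-")]
        elif cls == "ambiguous":
            g1 = f"GENE{gene_counter:06d}"
            g2 = f"GENE{gene_counter + 1:06d}"
            gene_counter += 2
            tmap.hits[tag] = [(g1, "+"), (g2, "+")]
        else:
            tmap.hits[tag] = []
    gene_of = {t: tmap.gene_of(t) for t in tags}
    return tmap, gene_of


def _build_annotations(
    rng: np.random.Generator,
    config: AtlasConfig,
    gene_of: Mapping[str, str | None],
    truth: Mapping[str, int],
) -> dict[str, set[str]]:
    """Plant one category per trend group on that group's genes."""
    annotations: dict[str, set[str]] = {}
    for tag, gene in gene_of.items():
        if gene is None:
            continue
        terms = annotations.setdefault(gene, set())
        for g in range(1, N_GROUPS + 1):
            rate = (config.annotation_true_rate if truth[tag] == g
                    else config.annotation_bg_rate)
            if rng.random() < rate:
                terms.add(f"term_group{g}")
    return annotations


def generate_atlas(config: AtlasConfig) -> SyntheticAtlas:
    """Draw one full atlas deterministically from ``config.seed``.

    Per (replicate, stage) library, counts are multinomial on exactly
    ``library_size`` tags (or independent Poisson in ``poisson`` mode) with
    per-tag weights = Gamma(2) base abundance x planted-trend stage
    multiplier x lognormal(0, jitter_sigma) noise drawn independently per
    (tag, stage, replicate).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    forbidden = set(DEFAULT_LINKER_TAGS_TYPE1) | set(DEFAULT_LINKER_TAGS_TYPE2)
    tags = _random_tags(rng, config.n_tag_types, forbidden)
    groups = rng.choice(
        np.arange(1, N_GROUPS + 1), size=config.n_tag_types, p=list(config.trend_mix)
    )
    truth = dict(zip(tags, (int(g) for g in groups)))
    base = rng.gamma(shape=2.0, scale=1.0, size=config.n_tag_types)
    mult = _stage_multipliers(config)

    libraries: dict[tuple[str, str], TagCountTable] = {}
    for r in range(config.n_replicates):
        rep = f"rep{r + 1}"
        for s, stage in enumerate(config.stages):
            jitter = (
                rng.lognormal(0.0, config.jitter_sigma, size=config.n_tag_types)
                if config.jitter_sigma > 0 else 1.0
            )
            weights = base * mult[groups - 1, s] * jitter
            p = weights / weights.sum()
            if config.count_mode == "multinomial":
                counts = rng.multinomial(config.library_size, p)
            else:
                counts = rng.poisson(config.library_size * p)
            lib_id = f"{rep}-{stage}"
            libraries[(rep, stage)] = TagCountTable(
                lib_id, {t: int(c) for t, c in zip(tags, counts) if c > 0}
            )

    tmap, gene_of = _build_tag_assignments(rng, config, tags)
    annotations = _build_annotations(rng, config, gene_of, truth)
    return SyntheticAtlas(
        config=config,
        libraries=libraries,
        truth_trends=truth,
        tag_map=tmap,
        annotations=annotations,
        base_abundance=pd.Series(base, index=tags, name="base_abundance"),
    )


# ---------------------------------------------------------------------------
# Raw ditag reads
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    """Ground truth of every contamination injected into one library."""

    bad_tags: list[tuple[str, int]] = field(default_factory=list)     # (read id, tag slot)
    low_qf_tags: list[tuple[str, int]] = field(default_factory=list)
    ldt_reads: dict[str, int] = field(default_factory=dict)           # read id -> linker type
    duplicate_reads: list[str] = field(default_factory=list)


def generate_raw_ditags(
    atlas: SyntheticAtlas,
    frac_bad: float | None = None,
    frac_low_qf: float | None = None,
    frac_ldt: float | None = None,
    frac_duplicate_ditags: float | None = None,
) -> tuple[dict[str, list[DitagRead]], dict[str, ReadTruth]]:
    """Synthesize ditag reads (with Phred qualities) for every library.

    Each ditag is ``CATG + tag1 + revcomp(tag2) + CATG``.  Clean tag bases
    carry qualities in [30, 40] (quality factor always >= 0.983); low-quality
    tags carry qualities in [15, 22] (factor always < 0.90, i.e. below the
    0.95 threshold); bad tags have one base replaced by N.  Linker-derived
    ditags (both tags a linker 17-mer) and duplicate ditags are appended at
    their configured per-ditag rates.  Contamination rates default to the
    atlas config; overrides must be nonnegative.
    """
    cfg = atlas.config
    rates = {
        "frac_bad": cfg.frac_bad if frac_bad is None else frac_bad,
        "frac_low_qf": cfg.frac_low_qf if frac_low_qf is None else frac_low_qf,
        "frac_ldt": cfg.frac_ldt if frac_ldt is None else frac_ldt,
        "frac_duplicate_ditags": (
            cfg.frac_duplicate_ditags if frac_duplicate_ditags is None
            else frac_duplicate_ditags
        ),
    }
    for name, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if cfg.library_size % 2:
        raise ValueError("ditag synthesis requires an even library_size")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD17A9]))
    linker1 = sorted(DEFAULT_LINKER_TAGS_TYPE1)
    linker2 = sorted(DEFAULT_LINKER_TAGS_TYPE2)

    all_reads: dict[str, list[DitagRead]] = {}
    all_truth: dict[str, ReadTruth] = {}
    for (rep, stage), table in sorted(atlas.libraries.items()):
        lib = table.library_id
        truth = ReadTruth()
        tags = np.repeat(
            np.array(sorted(table.counts), dtype=object),
            [table.counts[t] for t in sorted(table.counts)],
        )
        rng.shuffle(tags)
        n_ditags = len(tags) // 2
        reads: list[DitagRead] = []

        def make_read(read_id, t1, t2, q1, q2):
            seq = ANCHOR + t1 + revcomp(t2) + ANCHOR
            quals = [40] * len(ANCHOR) + list(q1) + list(q2[::-1]) + [40] * len(ANCHOR)
            return DitagRead(read_id, seq, quals, lib)

        for i in range(n_ditags):
            t1, t2 = str(tags[2 * i]), str(tags[2 * i + 1])
            read_id = f"{lib}:d{i}"
            pair = [t1, t2]
            quals = []
            for slot in range(2):
                if rng.random() < rates["frac_low_qf"]:
                    q = rng.integers(15, 23, size=TAG_LENGTH)
                    truth.low_qf_tags.append((read_id, slot))
                else:
                    q = rng.integers(30, 41, size=TAG_LENGTH)
                quals.append(q)
                if rng.random() < rates["frac_bad"]:
                    pos = int(rng.integers(0, TAG_LENGTH))
                    pair[slot] = pair[slot][:pos] + "N" + pair[slot][pos + 1:]
                    truth.bad_tags.append((read_id, slot))
            reads.append(make_read(read_id, pair[0], pair[1], quals[0], quals[1]))

        n_ldt = rng.binomial(n_ditags, rates["frac_ldt"])
        for j in range(n_ldt):
            ltype = 1 if rng.random() < 0.75 else 2
            ltag = str(rng.choice(linker1 if ltype == 1 else linker2))
            read_id = f"{lib}:ldt{j}"
            q = rng.integers(30, 41, size=TAG_LENGTH)
            reads.append(make_read(read_id, ltag, ltag, q, q))
            truth.ldt_reads[read_id] = ltype

        n_dup = rng.binomial(n_ditags, rates["frac_duplicate_ditags"])
        for j, src in enumerate(rng.integers(0, n_ditags, size=n_dup)):
            original = reads[int(src)]
            read_id = f"{lib}:dup{j}"
            reads.append(
                DitagRead(read_id, original.sequence, list(original.qualities), lib)
            )
            truth.duplicate_reads.append(read_id)

        all_reads[lib] = reads
        all_truth[lib] = truth
    return all_reads, all_truth


# ---------------------------------------------------------------------------
# Transcript sequences consistent with the tag map
# ---------------------------------------------------------------------------

def generate_transcripts(
    atlas: SyntheticAtlas, flank: int = 40
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Emit (gene, sequence) transcript records realizing the atlas tag map.

    Sense transcripts end ``...CATG + tag``; host transcripts are emitted
    for host-class tags under a second species' gene ids.  Random flanks
    avoid anchoring sites so the canonical-tag rule recovers each planted
    tag.  Antisense-class tags are realized as the reverse complement
    transcript of a sense construct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([atlas.config.seed, 0x7AC5]))
    non_anchor = np.array(list("ACT"))  # flanks free of CATG by construction

    def flank_seq() -> str:
        return "".join(rng.choice(non_anchor, size=flank))

    human: list[tuple[str, str]] = []
    host: list[tuple[str, str]] = []
    host_counter = 0
    for tag, cls in atlas.tag_map.mapping_class.items():
        construct = flank_seq() + ANCHOR + tag
        if cls == "unique_sense":
            human.append((atlas.tag_map.hits[tag][0][0], construct))
        elif cls == "ambiguous":
            for gene, _ in atlas.tag_map.hits[tag]:
                human.append((gene, flank_seq() + ANCHOR + tag))
        elif cls == "antisense":
            human.append((atlas.tag_map.hits[tag][0][0], revcomp(construct)))
        elif cls == "host":
            host.append((f"HOST{host_counter:05d}", construct))
            host_counter += 1
    return human, host


# ---------------------------------------------------------------------------
# Signature expression matrices
# ---------------------------------------------------------------------------

def generate_signature_matrix(
    n_genes: int,
    groups: Mapping[str, int] | Sequence[int],
    separation: float,
    seed: int,
    signature_fraction: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Group-structured expression matrix for signature-projection tests.

    Returns (genes x samples matrix, sample->group labels, signature gene
    ids).  Baseline expression is N(0, 1); a random ``signature_fraction``
    subset of genes receives a mean shift of ``separation`` standard
    deviations per group step, with a random sign per gene — real
    signatures mix up- and down-regulated genes, and a signed signature is
    what correlation-based component scores respond to.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not isinstance(groups, Mapping):
        groups = {f"group{i + 1}": n for i, n in enumerate(groups)}
    if len(groups) < 2:
        raise ValueError("at least 2 sample groups required"
                         + (" for separation > 0" if separation > 0 else ""))
    if any(n < 1 for n in groups.values()):
        raise ValueError("each group needs at least one sample")
    rng = np.random.default_rng(seed)
    sample_ids, labels = [], []
    for gname, n in groups.items():
        for i in range(n):
            sample_ids.append(f"{gname}_s{i + 1}")
            labels.append(gname)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    X = rng.normal(0.0, 1.0, size=(n_genes, len(sample_ids)))
    n_sig = max(2, int(round(signature_fraction * n_genes)))
    sig_idx = rng.choice(n_genes, size=n_sig, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_sig)
    offsets = {g: k * separation for k, g in enumerate(groups)}
    for j, lab in enumerate(labels):
        X[sig_idx, j] += signs * offsets[lab]
    matrix = pd.DataFrame(X, index=genes, columns=sample_ids)
    return matrix, pd.Series(labels, index=sample_ids, name="group"), [genes[i] for i in sorted(sig_idx)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[DitagRead], path) -> None:
    """Write ditag reads as Sanger-encoded FASTQ."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_atlas(atlas: SyntheticAtlas, outdir) -> None:
    """Persist an atlas: per-library 2-column tag-count TSVs (the flat-file
    dialect of GEO SAGE samples), tag map and annotation TSVs, truth table
    and a JSON manifest of the generating configuration."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (_, _), table in sorted(atlas.libraries.items()):
        table.to_tsv(outdir / f"{table.library_id}.counts.tsv")
    atlas.tag_map.to_tsv(outdir / "tag_map.tsv")
    pd.DataFrame(
        [(g, t) for g, terms in sorted(atlas.annotations.items()) for t in sorted(terms)],
        columns=["gene", "term"],
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pd.Series(atlas.truth_trends, name="group").rename_axis("tag").to_csv(
        outdir / "truth_trends.tsv", sep="\t"
    )
    manifest = {"config": asdict(atlas.config)}
    manifest["config"]["stages"] = list(atlas.config.stages)
    manifest["config"]["trend_mix"] = list(atlas.config.trend_mix)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
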