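"""End-to-end orchestration: simulate/ingest -> filter -> DE -> cluster ->
enrich -> tree -> project, with provenance and report writing.

Every stage writes its tables under the output directory and registers
itself in a JSON run manifest carrying the configuration and seed, so a
rerun with the same configuration reproduces outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from sagekit import cluster as clu
from sagekit import de, enrich, pca, synth, tagproc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one atlas run."""

    seed: int = 0
    outdir: str = "results"
    input_mode: str = "synthetic"          # synthetic | fastq | tag-counts
    input_paths: dict = field(default_factory=dict)   # library id -> path
    use_reads: bool = True                 # synthesize + filter raw ditags
    qf_threshold: float = 0.95
    alphas: tuple[float, ...] = de.DEFAULT_ALPHAS
    min_combined: int = 10
    k: int = 10
    n_runs: int = 100
    known_genes: tuple[str, ...] = ()
    # synthetic-mode atlas overrides (None -> AtlasConfig default)
    n_tag_types: int | None = None
    library_size: int | None = None
    trend_mix: tuple[float, ...] | None = None
    effect_size: float | None = None

    def validate(self) -> None:
        if not 0 < self.qf_threshold <= 1:
            raise ValueError("qf_threshold must be in (0, 1]")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        if self.min_combined < 0 or self.k < 1 or self.n_runs < 1:
            raise ValueError("min_combined, k and n_runs must be positive")
        if self.input_mode not in ("synthetic", "fastq", "tag-counts"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    def atlas_config(self) -> synth.AtlasConfig:
        kwargs = {"seed": self.seed}
        for name in ("n_tag_types", "library_size", "trend_mix", "effect_size"):
            value = getattr(self, name)
            if value is not None:
                kwargs[name] = value
        return synth.AtlasConfig(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_atlas_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all outputs.

    Returns a dict of in-memory stage results; the JSON manifest under
    ``outdir`` records configuration, seed and the files each stage wrote.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    results: dict = {}

    def run_stage(name, fn):
        try:
            files = fn()
        except Exception as exc:   # abort with the offending stage named
            raise StageError(name, exc) from exc
        manifest["stages"][name] = sorted(files)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    # -- simulate ----------------------------------------------------------
    def stage_simulate():
        if config.input_mode == "synthetic":
            atlas = synth.generate_atlas(config.atlas_config())
            results["atlas"] = atlas
            synth.write_atlas(atlas, out / "atlas")
            return [str(out / "atlas")]
        results["atlas"] = None
        return []

    run_stage("simulate", stage_simulate)
    atlas = results["atlas"]

    # -- filter ------------------------------------------------------------
    def stage_filter():
        files = []
        finals: dict[str, tagproc.TagCountTable] = {}
        compositions: dict[str, tagproc.LibraryComposition] = {}
        if config.input_mode == "tag-counts":
            for lib, path in sorted(config.input_paths.items()):
                finals[lib] = tagproc.TagCountTable.from_tsv(path, lib)
        elif config.input_mode == "fastq" or (atlas is not None and config.use_reads):
            if config.input_mode == "fastq":
                read_sets = {
                    lib: tagproc.read_fastq(path, lib)
                    for lib, path in sorted(config.input_paths.items())
                }
            else:
                raw, _ = synth.generate_raw_ditags(atlas)
                read_sets = raw
            for lib, reads in sorted(read_sets.items()):
                final, comp = tagproc.process_library(
                    reads, lib, qf_threshold=config.qf_threshold
                )
                finals[lib] = final
                compositions[lib] = comp
        else:   # synthetic counts used directly, trivial composition
            for (_, _), table in sorted(atlas.libraries.items()):
                finals[table.library_id] = table
                compositions[table.library_id] = (
                    tagproc.LibraryComposition.from_stage_counts(
                        table.library_id,
                        unfiltered_total=table.total_tags,
                        n_bad=0, n_duplicate_ditags=0, n_below_qf=0,
                        n_ldt_type1=0, n_ldt_type2=0,
                        final_tag_types=table.tag_types,
                    )
                )
        results["final_counts"] = finals
        results["compositions"] = compositions
        rows = [c.to_dict() for c in compositions.values()]
        if rows:
            path = out / "library_composition.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            files.append(str(path))
        for lib, table in finals.items():
            path = out / f"{lib}.final_counts.tsv"
            table.to_tsv(path)
            files.append(str(path))
        return files

    run_stage("filter", stage_filter)
    finals = results["final_counts"]

    # group libraries into replicate x stage from atlas layout or id pattern
    def library_layout() -> dict[str, dict[str, str]]:
        layout: dict[str, dict[str, str]] = {}
        if atlas is not None:
            for (rep, stage), table in atlas.libraries.items():
                layout.setdefault(rep, {})[stage] = table.library_id
        else:
            for lib in finals:
                rep, _, stage = lib.partition("-")
                layout.setdefault(rep, {})[stage] = lib
        return layout

    layout = library_layout()
    stages = list(atlas.config.stages) if atlas is not None else sorted(
        {s for d in layout.values() for s in d}
    )

    # -- differential expression ------------------------------------------
    def stage_de():
        frames = []
        for rep, stage_libs in sorted(layout.items()):
            for i in range(len(stages)):
                for j in range(i + 1, len(stages)):
                    a, b = stages[i], stages[j]
                    frames.append(
                        de.pairwise_de(
                            finals[stage_libs[a]], finals[stage_libs[b]],
                            comparison=f"{a} vs {b}", replicate=rep,
                        )
                    )
        all_de = pd.concat(frames, ignore_index=True)
        summary = de.consistent_de(all_de, config.alphas)
        results["de"] = all_de
        results["consistency"] = summary
        de_path = out / "de_results.tsv"
        all_de.to_csv(de_path, sep="\t", index=False)
        sum_path = out / "consistency_summary.tsv"
        summary.counts.reset_index().to_csv(sum_path, sep="\t", index=False)

        # trend labels + candidate funnel for the middle->last comparison
        files = [str(de_path), str(sum_path)]
        if len(stages) >= 3 and atlas is not None:
            alpha = max(config.alphas)
            key_cmp = f"{stages[-2]} vs {stages[-1]}"
            detail = summary.detail
            key_tags = sorted(
                detail[(detail["comparison"] == key_cmp) & (detail["alpha"] == alpha)]["tag"]
            )
            labels = _trend_labels(all_de, key_tags, layout, stages, alpha)
            results["trends"] = labels
            trend_path = out / "trend_labels.tsv"
            pd.DataFrame(
                [(t.tag, t.step1, t.step2, t.net, t.label, t.group) for t in labels],
                columns=["tag", "step1", "step2", "net", "label", "group"],
            ).to_csv(trend_path, sep="\t", index=False)
            funnel = de.candidate_gene_summary(
                key_tags, atlas.tag_map, config.known_genes
            )
            results["funnel"] = funnel
            funnel_path = out / "candidate_funnel.json"
            funnel_path.write_text(json.dumps(funnel, indent=2))
            files += [str(trend_path), str(funnel_path)]
        return files

    run_stage("de", stage_de)

    # -- clustering --------------------------------------------------------
    def stage_cluster():
        files = []
        consensus: dict[str, clu.ConsensusResult] = {}
        amalgams: dict[str, dict[int, int]] = {}
        profiles: dict[str, pd.DataFrame] = {}
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1]))
        for rep in sorted(layout):
            counts = _stage_count_frame(finals, layout[rep], stages)
            sel = clu.select_clustering_tags(
                counts, atlas.tag_map, config.min_combined
            ) if atlas is not None else counts
            raw = sel[stages].to_numpy(dtype=float)
            if raw.shape[0] < config.k:
                raise ValueError(
                    f"replicate {rep}: {raw.shape[0]} clustering tags < K={config.k}"
                )
            res = clu.consensus_cluster(
                raw, config.k, n_runs=config.n_runs,
                seed=int(rng.integers(2**31 - 1)),
            )
            consensus[rep] = res
            amalgams[rep] = clu.amalgamate_groups(res.centers)
            profiles[rep] = sel
            assign = pd.DataFrame(
                {
                    "tag": sel.index,
                    "cluster": res.labels,
                    "stability": res.stability,
                    "group": [amalgams[rep][c] for c in res.labels],
                }
            )
            path = out / f"clusters_{rep}.tsv"
            assign.to_csv(path, sep="\t", index=False)
            files.append(str(path))
        results["consensus"] = consensus
        results["amalgamation"] = amalgams
        results["cluster_profiles"] = profiles
        return files

    run_stage("cluster", stage_cluster)

    # -- enrichment --------------------------------------------------------
    def stage_enrich():
        if atlas is None:
            return []
        gene_of = {t: atlas.tag_map.gene_of(t) for t in atlas.tag_map.mapping_class}
        per_rep = []
        amalgams = []
        for rep in sorted(layout):
            res = results["consensus"][rep]
            sel = results["cluster_profiles"][rep]
            assignments = dict(zip(sel.index, (int(c) for c in res.labels)))
            per_rep.append(
                enrich.cluster_enrichment(
                    assignments, gene_of, atlas.annotations, replicate=rep
                )
            )
            amalgams.append(results["amalgamation"][rep])
        consensus = enrich.replicate_consensus(per_rep, amalgams)
        results["enrichment"] = per_rep
        results["enrichment_consensus"] = consensus
        enr_path = out / "enrichment.tsv"
        pd.concat(per_rep, ignore_index=True).to_csv(enr_path, sep="\t", index=False)
        cons_path = out / "enrichment_consensus.tsv"
        consensus.to_csv(cons_path, sep="\t", index=False)
        return [str(enr_path), str(cons_path)]

    run_stage("enrich", stage_enrich)

    # -- library tree ------------------------------------------------------
    def stage_tree():
        tree = clu.build_library_tree(list(finals.values()))
        results["tree"] = tree
        path = out / "library_tree.nwk"
        path.write_text(tree.newick + "\n")
        dpath = out / "library_distances.tsv"
        tree.distances.to_csv(dpath, sep="\t")
        return [str(path), str(dpath)]

    run_stage("tree", stage_tree)

    # -- signature projection ---------------------------------------------
    def stage_pca():
        matrix, groups, signature = synth.generate_signature_matrix(
            n_genes=500, groups={"AS": 10, "CR": 10}, separation=3.0,
            seed=int(np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x9CA])
            ).integers(2**31 - 1)),
        )
        scores, report = pca.project_signature(matrix, signature, groups)
        results["pc_scores"] = scores
        results["pca_report"] = report
        spath = out / "pc_scores.tsv"
        scores.scores.to_csv(spath, sep="\t")
        rpath = out / "pca_report.json"
        rpath.write_text(json.dumps(report, indent=2))
        return [str(spath), str(rpath)]

    run_stage("pca", stage_pca)

    # funnel integrity
    funnel = results.get("funnel")
    if funnel is not None:
        assert funnel["n_relevant"] <= funnel["n_input_tags"]
        assert funnel["n_novel"] <= funnel["n_candidate_genes"]
    return results


def _stage_count_frame(finals, stage_libs, stages) -> pd.DataFrame:
    cols = {s: finals[stage_libs[s]].to_series() for s in stages}
    return pd.DataFrame(cols).fillna(0).astype(int)


def _trend_labels(all_de, tags, layout, stages, alpha):
    """Per-tag trend labels from the per-replicate step calls."""
    step_cmps = [f"{stages[i]} vs {stages[i + 1]}" for i in range(len(stages) - 1)]
    labels = []
    indexed = all_de.set_index(["tag", "comparison", "replicate"]).sort_index()
    for tag in tags:
        profiles, s1_calls, s2_calls = [], [], []
        for rep in sorted(layout):
            try:
                r1 = indexed.loc[(tag, step_cmps[0], rep)]
                r2 = indexed.loc[(tag, step_cmps[1], rep)]
            except KeyError:
                continue
            profiles.append((r1["cpm_a"], r1["cpm_b"], r2["cpm_b"]))
            s1_calls.append((r1["direction"], r1["p"] <= alpha))
            s2_calls.append((r2["direction"], r2["p"] <= alpha))
        if profiles:
            labels.append(de.classify_trend(tag, profiles, s1_calls, s2_calls))
    return labels


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _common_options(fn):
    fn = click.option("--seed", type=int, default=0, show_default=True)(fn)
    fn = click.option("--out", "outdir", type=click.Path(), default="results",
                      show_default=True)(fn)
    return fn


@click.group()
def main():
    """LongSAGE atlas analysis pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@main.command()
@_common_options
@click.option("--n-tag-types", type=int, default=None)
@click.option("--library-size", type=int, default=None)
@click.option("--effect-size", type=float, default=None)
@click.option("--reads/--no-reads", default=False, show_default=True,
              help="also write raw ditag FASTQ files")
def simulate(seed, outdir, n_tag_types, library_size, effect_size, reads):
    """Generate a synthetic atlas and write it to disk."""
    cfg = PipelineConfig(seed=seed, outdir=outdir, n_tag_types=n_tag_types,
                         library_size=library_size, effect_size=effect_size)
    atlas = synth.generate_atlas(cfg.atlas_config())
    synth.write_atlas(atlas, Path(outdir) / "atlas")
    if reads:
        raw, _ = synth.generate_raw_ditags(atlas)
        for lib, rds in raw.items():
            synth.write_fastq(rds, Path(outdir) / "atlas" / f"{lib}.fastq")
    click.echo(f"atlas written to {outdir}/atlas")


@main.command("filter")
@_common_options
@click.option("--fastq", "fastqs", type=(str, click.Path(exists=True)),
              multiple=True, help="library id and FASTQ path")
@click.option("--qf-threshold", type=float, default=0.95, show_default=True)
def filter_cmd(seed, outdir, fastqs, qf_threshold):
    """Extract, filter and count tags from ditag FASTQ files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for lib, path in fastqs:
        reads = tagproc.read_fastq(path, lib)
        final, comp = tagproc.process_library(reads, lib, qf_threshold=qf_threshold)
        final.to_tsv(out / f"{lib}.final_counts.tsv")
        rows.append(comp.to_dict())
    pd.DataFrame(rows).to_csv(out / "library_composition.tsv", sep="\t", index=False)
    click.echo(f"filtered {len(fastqs)} libraries")


@main.command("all")
@_common_options
@click.option("--n-tag-types", type=int, default=None)
@click.option("--library-size", type=int, default=None)
@click.option("--effect-size", type=float, default=None)
@click.option("-k", type=int, default=10, show_default=True)
@click.option("--n-runs", type=int, default=100, show_default=True)
@click.option("--reads/--no-reads", "use_reads", default=True, show_default=True)
def run_all(seed, outdir, n_tag_types, library_size, effect_size, k, n_runs, use_reads):
    """Run the full synthetic-atlas pipeline."""
    cfg = PipelineConfig(
        seed=seed, outdir=outdir, n_tag_types=n_tag_types,
        library_size=library_size, effect_size=effect_size,
        k=k, n_runs=n_runs, use_reads=use_reads,
    )
    run_atlas_pipeline(cfg)
    click.echo(f"pipeline complete; outputs in {outdir}")


@main.command("de")
@_common_options
@click.option("--counts", "count_files", type=(str, str, click.Path(exists=True)),
              multiple=True, required=True,
              help="replicate id, stage label, tag-count TSV path")
def de_cmd(seed, outdir, count_files):
    """Pairwise exact tests + cross-replicate consistency from count TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    layout: dict[str, dict[str, tagproc.TagCountTable]] = {}
    stage_order: list[str] = []
    for rep, stage, path in count_files:
        layout.setdefault(rep, {})[stage] = tagproc.TagCountTable.from_tsv(
            path, f"{rep}-{stage}"
        )
        if stage not in stage_order:
            stage_order.append(stage)
    frames = []
    for rep, stage_libs in sorted(layout.items()):
        for i in range(len(stage_order)):
            for j in range(i + 1, len(stage_order)):
                a, b = stage_order[i], stage_order[j]
                frames.append(de.pairwise_de(
                    stage_libs[a], stage_libs[b], f"{a} vs {b}", rep
                ))
    all_de = pd.concat(frames, ignore_index=True)
    all_de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    summary = de.consistent_de(all_de)
    summary.counts.reset_index().to_csv(
        out / "consistency_summary.tsv", sep="\t", index=False
    )
    click.echo(f"tested {all_de['tag'].nunique()} tag types")


@main.command("cluster")
@_common_options
@click.option("--counts", "count_files", type=(str, click.Path(exists=True)),
              multiple=True, required=True, help="stage label and count TSV (one replicate)")
@click.option("-k", type=int, default=10, show_default=True)
@click.option("--n-runs", type=int, default=100, show_default=True)
@click.option("--min-combined", type=int, default=10, show_default=True)
def cluster_cmd(seed, outdir, count_files, k, n_runs, min_combined):
    """Consensus Poisson K-means over one replicate's stage libraries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {
        stage: tagproc.TagCountTable.from_tsv(path, stage).to_series()
        for stage, path in count_files
    }
    counts = pd.DataFrame(cols).fillna(0).astype(int)
    counts = counts[counts.sum(axis=1) > min_combined]
    res = clu.consensus_cluster(counts.to_numpy(dtype=float), k, n_runs, seed)
    groups = clu.amalgamate_groups(res.centers)
    pd.DataFrame({
        "tag": counts.index, "cluster": res.labels, "stability": res.stability,
        "group": [groups[c] for c in res.labels],
    }).to_csv(out / "clusters.tsv", sep="\t", index=False)
    click.echo(f"clustered {len(counts)} tags into K={k}")


@main.command("enrich")
@_common_options
@click.option("--assignments", type=click.Path(exists=True), required=True,
              help="TSV with tag/gene and cluster columns")
@click.option("--annotations", "annotations_path", type=click.Path(exists=True),
              required=True, help="2-column gene, term TSV")
@click.option("--alpha", type=float, default=0.05, show_default=True)
def enrich_cmd(seed, outdir, assignments, annotations_path, alpha):
    """EASE-score category enrichment of clusters against an annotation table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    assign = pd.read_csv(assignments, sep="\t")
    ann = pd.read_csv(annotations_path, sep="\t")
    annotations = {
        g: set(sub[ann.columns[1]]) for g, sub in ann.groupby(ann.columns[0])
    }
    key = assign.columns[0]
    res = enrich.cluster_enrichment(
        dict(zip(assign[key], assign["cluster"])),
        {g: g for g in assign[key]}, annotations, alpha=alpha,
    )
    res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    click.echo(f"{int(res['enriched'].sum())} enriched (cluster, term) pairs")


@main.command("pca")
@_common_options
@click.option("--matrix", type=click.Path(exists=True), required=True,
              help="genes x samples TSV with a sample-id header")
@click.option("--groups", "groups_path", type=click.Path(exists=True), required=True,
              help="2-column sample, group TSV")
@click.option("--signature", type=click.Path(exists=True), default=None,
              help="one gene id per line; default all genes")
def pca_cmd(seed, outdir, matrix, groups_path, signature):
    """Signature projection onto the largest principal components."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mat = pd.read_csv(matrix, sep="\t", index_col=0)
    grp = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    genes = (
        [ln.strip() for ln in Path(signature).read_text().splitlines() if ln.strip()]
        if signature else list(mat.index)
    )
    scores, report = pca.project_signature(mat, genes, grp)
    scores.scores.to_csv(out / "pc_scores.tsv", sep="\t")
    (out / "pca_report.json").write_text(json.dumps(report, indent=2))
    click.echo(json.dumps(report))


if __name__ == "__main__":
    main()
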