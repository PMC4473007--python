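"""End-to-end orchestration: reads -> islands -> annotation -> expression ->
profiles -> clustering, from a single YAML config, with a checksummed output
manifest and stage-level caching (a stage is skipped when its outputs already
exist and nothing upstream was recomputed)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import clustering as clu
from . import expression as expr_mod
from . import io as io_mod
from . import islands as isl
from . import profiles as prof
from . import reads as rd
from . import synthetic_data as syn
from .genome import Genome

logger = logging.getLogger(__name__)

STAGES = ["reads", "islands", "annotation", "expression", "profiles", "clustering"]


@dataclass
class PipelineConfig:
    genome: Genome
    condition_reads: dict[str, Path]
    refseq_path: Path
    ensembl_path: Path
    probes_path: Path
    outdir: Path
    seed: int = 0
    island_params: isl.IslandCallerParams = field(default_factory=isl.IslandCallerParams)
    window_size: int = 200
    region_kind: str = "promoter_2kb"
    silent_floor: float | None = None
    cluster_k: int = 3
    cluster_restarts: int = 10
    cluster_bin_size: int = 50
    profile_spec: prof.ProfileSpec = field(default_factory=prof.ProfileSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _p(rel: str) -> Path:
            p = Path(rel)
            return p if p.is_absolute() else base / p

        cfg = cls(
            genome=Genome({str(k): int(v) for k, v in raw["genome"].items()}),
            condition_reads={c: _p(p) for c, p in raw["conditions"].items()},
            refseq_path=_p(raw["refseq"]),
            ensembl_path=_p(raw["ensembl"]),
            probes_path=_p(raw["probes"]),
            outdir=_p(raw.get("outdir", "results")),
            seed=int(raw.get("seed", 0)),
            island_params=isl.IslandCallerParams(**raw.get("island_params", {})),
            window_size=int(raw.get("window_size", 200)),
            region_kind=str(raw.get("region_kind", "promoter_2kb")),
            silent_floor=raw.get("silent_floor"),
            cluster_k=int(raw.get("cluster", {}).get("k", 3)),
            cluster_restarts=int(raw.get("cluster", {}).get("n_restarts", 10)),
            cluster_bin_size=int(raw.get("cluster", {}).get("bin_size", 50)),
        )
        # fail fast: every referenced input must exist before any stage runs
        missing = [
            str(p)
            for p in [cfg.refseq_path, cfg.ensembl_path, cfg.probes_path,
                      *cfg.condition_reads.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"pipeline inputs missing: {missing}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


class _StageRunner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.records: list[dict] = []
        self._upstream_ran = False

    def run(self, name: str, outputs: list[Path], inputs: list[Path], params: dict, fn):
        cached = all(p.exists() for p in outputs) and not self._upstream_ran
        t0 = time.time()
        if not cached:
            try:
                fn()
            except Exception as exc:  # halt with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            self._upstream_ran = True
        self.records.append(
            {
                "stage": name,
                "status": "cached" if cached else "computed",
                "wall_seconds": round(time.time() - t0, 3),
                "parameters": params,
                "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )
        logger.info("stage %-10s %s (%.1fs)", name, self.records[-1]["status"],
                    self.records[-1]["wall_seconds"])


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(out)
    conds = list(config.condition_reads)
    p = config.island_params

    # ---- stage 1: read filtering + window tracks ------------------------
    frag_paths = {c: out / f"{c}.fragments.tsv" for c in conds}
    raw_bg = {c: out / f"{c}.raw.bedgraph" for c in conds}
    norm_bg = {c: out / f"{c}.norm.bedgraph" for c in conds}

    def _stage_reads():
        for cond in conds:
            reads = io_mod.read_reads_bed6(config.condition_reads[cond])
            reads = rd.deduplicate(rd.drop_multimappers(reads))
            frags = rd.extend_reads(reads, p.fragment_length, config.genome)
            frags.to_csv(frag_paths[cond], sep="\t", index=False)
            track = rd.summarize_windows(frags, config.genome, config.window_size)
            io_mod.write_bedgraph(track, raw_bg[cond])
            io_mod.write_bedgraph(rd.normalize_per_million(track), norm_bg[cond])

    runner.run(
        "reads",
        outputs=[*frag_paths.values(), *raw_bg.values(), *norm_bg.values()],
        inputs=list(config.condition_reads.values()),
        params={"window_size": config.window_size, "fragment_length": p.fragment_length},
        fn=_stage_reads,
    )

    # ---- stage 2: island calling + two-condition comparison -------------
    island_paths = {c: out / f"{c}.islands.tsv" for c in conds}
    comparison_path = out / "peak_comparison.tsv"

    def _load_track(cond):
        frags = pd.read_csv(frag_paths[cond], sep="\t")
        return rd.summarize_windows(frags, config.genome, config.window_size)

    def _stage_islands():
        called = {}
        for cond in conds:
            called[cond] = isl.call_islands(_load_track(cond), p)
            io_mod.write_islands(called[cond], island_paths[cond])
        cmp_ = isl.compare_conditions(called[conds[0]], called[conds[1]])
        _write_tsv(
            pd.DataFrame(
                [
                    {"group": conds[0], "total_peaks": cmp_.total_a,
                     "shared_peaks": cmp_.shared_a, "unique_peaks": cmp_.unique_a},
                    {"group": conds[1], "total_peaks": cmp_.total_b,
                     "shared_peaks": cmp_.shared_b, "unique_peaks": cmp_.unique_b},
                ]
            ),
            comparison_path,
        )

    runner.run(
        "islands",
        outputs=[*island_paths.values(), comparison_path],
        inputs=list(frag_paths.values()),
        params={"window_size": p.window_size, "gap_size": p.gap_size,
                "e_value": p.e_value,
                "effective_genome_fraction": p.effective_genome_fraction},
        fn=_stage_islands,
    )

    # ---- stage 3: annotation ---------------------------------------------
    merged_path = out / "merged_genes.tsv"
    enriched_paths = {c: out / f"{c}.enriched_genes.tsv" for c in conds}
    gene_cmp_path = out / "gene_comparison.tsv"
    feature_paths = {c: out / f"{c}.features.tsv" for c in conds}
    dist_paths = {c: out / f"{c}.tss_distance.tsv" for c in conds}
    chromdist_path = out / "chromosome_distribution.tsv"

    def _stage_annotation():
        refseq = io_mod.read_genes_tsv(config.refseq_path)
        ensembl = io_mod.read_genes_tsv(config.ensembl_path)
        merged = ann.merge_annotations(refseq, ensembl)
        io_mod.write_genes_tsv(merged, merged_path)
        enriched = {}
        all_islands = []
        for cond in conds:
            islands = io_mod.read_islands(island_paths[cond])
            all_islands.extend(islands)
            enriched[cond] = ann.enriched_genes(
                islands, merged, config.region_kind, config.genome
            )
            _write_tsv(pd.DataFrame({"gene_id": enriched[cond]}), enriched_paths[cond])
            classified = ann.classify_peaks(islands, merged)
            fr = ann.feature_fractions(classified).rename("fraction").reset_index()
            fr.columns = ["feature", "fraction"]
            _write_tsv(fr, feature_paths[cond])
            _write_tsv(ann.distances_to_tss(islands, merged), dist_paths[cond])
        cmp_rows = ann.gene_set_comparison(enriched[conds[0]], enriched[conds[1]])
        _write_tsv(pd.DataFrame([cmp_rows]), gene_cmp_path)
        _write_tsv(ann.chromosome_distribution(all_islands, config.genome), chromdist_path)

    runner.run(
        "annotation",
        outputs=[merged_path, gene_cmp_path, chromdist_path,
                 *enriched_paths.values(), *feature_paths.values(), *dist_paths.values()],
        inputs=[config.refseq_path, config.ensembl_path, *island_paths.values()],
        params={"region_kind": config.region_kind},
        fn=_stage_annotation,
    )

    # ---- stage 4: expression ---------------------------------------------
    genes_expr_path = out / "gene_expression.tsv"

    def _stage_expression():
        probes = io_mod.read_expression_tsv(config.probes_path)
        merged = io_mod.read_genes_tsv(merged_path)
        gene_table = expr_mod.probes_to_genes(probes, known_genes=[g.gene_id for g in merged])
        with_dec = expr_mod.assign_categories(gene_table, "deciles")
        with_four = expr_mod.assign_categories(
            gene_table, "four", silent_floor=config.silent_floor
        )
        merged_tbl = with_dec.merge(with_four[["gene_id", "category4"]], on="gene_id")
        _write_tsv(merged_tbl, genes_expr_path)

    runner.run(
        "expression",
        outputs=[genes_expr_path],
        inputs=[config.probes_path, merged_path],
        params={"silent_floor": config.silent_floor},
        fn=_stage_expression,
    )

    # ---- stage 5: profiles (conditions pooled) ---------------------------
    tss_curves_path = out / "tss_decile_curves.tsv"
    metagene_path = out / "metagene_decile_curves.tsv"
    matrix_path = out / "promoter_matrix.tsv"

    def _pooled_fragments():
        return pd.concat(
            [pd.read_csv(frag_paths[c], sep="\t") for c in conds], ignore_index=True
        )

    def _stage_profiles():
        frags = _pooled_fragments()
        merged = io_mod.read_genes_tsv(merged_path)
        gene_tbl = pd.read_csv(genes_expr_path, sep="\t")
        deciles = gene_tbl.set_index("gene_id")["decile"]
        fine = prof.profile_matrix(frags, merged, prof.ProfileSpec(mode="tss_fine"))
        _write_tsv(prof.category_profile(fine, deciles), tss_curves_path)
        meta = prof.profile_matrix(frags, merged, prof.ProfileSpec(mode="metagene"))
        _write_tsv(prof.category_profile(meta, deciles), metagene_path)
        pm = prof.promoter_matrix(frags, merged, bin_size=config.cluster_bin_size)
        _write_tsv(pm.values, matrix_path, index=True)

    runner.run(
        "profiles",
        outputs=[tss_curves_path, metagene_path, matrix_path],
        inputs=[*frag_paths.values(), merged_path, genes_expr_path],
        params={"cluster_bin_size": config.cluster_bin_size},
        fn=_stage_profiles,
    )

    # ---- stage 6: clustering ---------------------------------------------
    assign_path = out / "cluster_assignments.tsv"
    centroid_path = out / "cluster_centroids.tsv"
    boxplot_path = out / "cluster_expression.tsv"
    heatmap_path = out / "promoter_heatmap.png"

    def _stage_clustering():
        values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        frags_total = sum(
            len(pd.read_csv(frag_paths[c], sep="\t", usecols=["chrom"])) for c in conds
        )
        pm = prof.ProfileMatrix(
            values=values,
            spec=prof.ProfileSpec(
                mode="tss_fine", tss_halfwidth=2000, tss_bin=config.cluster_bin_size
            ),
            total_reads=frags_total,
        )
        result = clu.cluster_promoters(
            pm, config.cluster_k, seed=config.seed, n_restarts=config.cluster_restarts
        )
        expr_series = (
            pd.read_csv(genes_expr_path, sep="\t").set_index("gene_id")["value"]
        )
        sorted_matrix, boundaries, summary = clu.sort_and_render(pm, result, expr_series)
        _write_tsv(result.assignments.rename("cluster").reset_index(), assign_path)
        _write_tsv(result.centroids, centroid_path, index=True)
        _write_tsv(summary, boxplot_path)
        clu.plot_heatmap(sorted_matrix, boundaries, str(heatmap_path))

    runner.run(
        "clustering",
        outputs=[assign_path, centroid_path, boxplot_path, heatmap_path],
        inputs=[matrix_path, genes_expr_path],
        params={"k": config.cluster_k, "n_restarts": config.cluster_restarts,
                "seed": config.seed},
        fn=_stage_clustering,
    )

    manifest = {"seed": config.seed, "stages": runner.records}
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest


def make_demo(outdir: str | Path, seed: int = 0) -> Path:
    """Write a small, fully ground-truthed demo dataset plus a pipeline config.

    Uses the generator defaults (5 Mb genome, 300 genes, ~200k reads per
    condition) and returns the path of the pipeline YAML it wrote.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = syn.SimulationConfig(seed=seed)
    sim = syn.simulate_all(config)
    io_mod.write_genes_tsv(sim.refseq, outdir / "refseq_genes.tsv")
    io_mod.write_genes_tsv(sim.ensembl, outdir / "ensembl_genes.tsv")
    io_mod.write_genes_bed12(sim.refseq, outdir / "refseq_genes.bed12")
    io_mod.write_genes_bed12(sim.ensembl, outdir / "ensembl_genes.bed12")
    io_mod.write_expression_tsv(sim.probe_table, outdir / "probes.tsv")
    for cond, reads in sim.reads.items():
        io_mod.write_reads_bed6(reads, outdir / f"{cond}.reads.bed")
    io_mod.write_json(sim.ground_truth.to_dict(), outdir / "ground_truth.json")
    yaml_cfg = {
        "seed": seed,
        "outdir": "results",
        "genome": {c: int(n) for c, n in sim.genome.chrom_lengths.items()},
        "conditions": {c: f"{c}.reads.bed" for c in config.conditions},
        "refseq": "refseq_genes.tsv",
        "ensembl": "ensembl_genes.tsv",
        "probes": "probes.tsv",
        "silent_floor": config.expression_floor,
        "island_params": {},
        "cluster": {"k": 3, "n_restarts": 10, "bin_size": 50},
    }
    cfg_path = outdir / "pipeline.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(yaml_cfg, fh, sort_keys=True)
    return cfg_path
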