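"""End-to-end orchestration: align -> collapse -> cluster -> annotate -> benchmark.

A run is described by a :class:`RunConfig` (serializable to YAML).  Each
stage records a content hash of its inputs and parameters in a manifest
(``manifest.json`` in the output directory); re-running with unchanged
inputs skips completed stages, so interrupted runs resume where they
stopped.  The delineation itself is fully deterministic — the only
randomness in the package lives in the simulator and flows through its
single seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotate as _annotate
from . import benchmark as _benchmark
from . import cluster as _cluster
from . import io as _io
from .align import AlignmentParams, CollapseParams, all_vs_all, collapse_all_genomes
from .model import GeneRecord

log = logging.getLogger("triortho.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    genomes_dir: str
    taxonomy: str
    out_dir: str
    levels: list[str] = field(default_factory=list)  # empty = root level only
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    collapse: CollapseParams = field(default_factory=CollapseParams)
    collapse_enabled: bool = True
    closure: str = "triangulate"
    metadata: str | None = None
    reference: str | None = None   # refog TSV benchmarked at reference_level
    reference_level: str | None = None
    log_base: float = 2.0
    robust_deviants: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "alignment" in d and isinstance(d["alignment"], dict):
            d["alignment"] = AlignmentParams(**d["alignment"])
        if "collapse" in d and isinstance(d["collapse"], dict):
            d["collapse"] = CollapseParams(**d["collapse"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Manifest

def _hash_inputs(paths: Sequence[Path], params: object) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    h.update(repr(params).encode())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                log.warning("unreadable manifest %s; rebuilding", path)

    def fresh(self, stage: str, input_hash: str, outputs: Sequence[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        return (entry is not None and entry.get("inputs") == input_hash
                and all(Path(o).exists() for o in entry.get("outputs", []))
                and [str(o) for o in outputs] == entry.get("outputs"))

    def record(self, stage: str, input_hash: str, outputs: Sequence[Path]) -> None:
        self.data["stages"][stage] = {
            "inputs": input_hash,
            "outputs": [str(o) for o in outputs],
            "mtimes": {str(o): Path(o).stat().st_mtime for o in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stages

def _load_genomes(genomes_dir: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    fastas = sorted(genomes_dir.glob("*.fasta")) + sorted(genomes_dir.glob("*.fa"))
    if not fastas:
        raise FileNotFoundError(f"no FASTA files in {genomes_dir}")
    for p in fastas:
        _, recs = _io.read_genome_fasta(p, p.stem)
        records.extend(recs)
    return records


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline; returns a summary dict of headline stats."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest = _Manifest(out / "manifest.json")
    genomes_dir = Path(config.genomes_dir)
    fastas = sorted(genomes_dir.glob("*.fasta")) + sorted(genomes_dir.glob("*.fa"))
    summary: dict[str, object] = {}

    hits_path = out / "hits.tsv"
    collapse_path = out / "collapse_map.tsv"
    clusters_path = out / "clusters.tsv"

    # --- align ------------------------------------------------------------
    stage = "align"
    try:
        ih = _hash_inputs(fastas, config.alignment)
        if manifest.fresh(stage, ih, [hits_path]):
            log.info("align: outputs up to date, skipping")
        else:
            records = _load_genomes(genomes_dir)
            hits = all_vs_all(records, config.alignment)
            _io.write_hits_tsv(hits, hits_path)
            manifest.record(stage, ih, [hits_path])
            log.info("align: %d genes read, %d hits emitted",
                     len(records), len(hits))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(exc)) from exc

    # --- collapse ---------------------------------------------------------
    stage = "collapse"
    try:
        ih = _hash_inputs(list(fastas) + [hits_path], config.collapse)
        if not config.collapse_enabled:
            expansion: dict[str, list[str]] = {}
            _io.write_collapse_map_tsv(expansion, collapse_path)
            manifest.record(stage, ih, [collapse_path])
        elif manifest.fresh(stage, ih, [collapse_path]):
            log.info("collapse: outputs up to date, skipping")
        else:
            records = _load_genomes(genomes_dir)
            hits = _io.read_hits_tsv(hits_path)
            expansion = collapse_all_genomes(records, hits, config.collapse)
            _io.write_collapse_map_tsv(expansion, collapse_path)
            manifest.record(stage, ih, [collapse_path])
            n_abs = sum(len(v) for v in expansion.values())
            log.info("collapse: %d genes absorbed into representatives", n_abs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- cluster ----------------------------------------------------------
    stage = "cluster"
    try:
        taxonomy = _io.read_taxonomy(config.taxonomy)
        levels = config.levels or [taxonomy.root_level.level_id]
        ih = _hash_inputs([hits_path, collapse_path, Path(config.taxonomy)],
                          (config.closure, tuple(levels)))
        if manifest.fresh(stage, ih, [clusters_path]):
            log.info("cluster: outputs up to date, skipping")
            groups_by_level, gene_genome = _io.read_clusters_tsv(clusters_path)
        else:
            records = _load_genomes(genomes_dir)
            genome_of = {r.gene_id: r.genome_id for r in records}
            hits = _io.read_hits_tsv(hits_path)
            for h in hits:
                if h.query_id not in genome_of or h.subject_id not in genome_of:
                    raise ValueError(f"hit references unknown gene "
                                     f"{h.query_id}/{h.subject_id}")
            expansion = _io.read_collapse_map_tsv(collapse_path)
            groups_by_level = _cluster.cluster_all_levels(
                hits, taxonomy, levels, genome_of, expansion, config.closure)
            gene_genome = genome_of
            _io.write_clusters_tsv(groups_by_level, clusters_path, gene_genome)
            manifest.record(stage, ih, [clusters_path])
            for level_id, groups in groups_by_level.items():
                level_genes = [g for g, gm in genome_of.items()
                               if gm in taxonomy.level(level_id).member_genomes]
                frac = _cluster.fraction_clustered(groups, level_genes)
                summary[f"pct_clustered_{level_id}"] = 100.0 * frac
                log.info("cluster: level %s: %d groups, %.1f%% of genes clustered",
                         level_id, len(groups), 100.0 * frac)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- annotate ---------------------------------------------------------
    stage = "annotate"
    try:
        metadata = (_io.read_metadata_tsv(config.metadata)
                    if config.metadata else None)
        records = _load_genomes(genomes_dir)
        genome_of = {r.gene_id: r.genome_id for r in records}
        hits = _io.read_hits_tsv(hits_path)
        annot_paths = []
        for level_id, groups in groups_by_level.items():
            level = taxonomy.level(level_id)
            level_hits = [h for h in hits
                          if genome_of[h.query_id] in level.member_genomes
                          and genome_of[h.subject_id] in level.member_genomes]
            edges = _cluster.best_reciprocal_hits(level_hits, genome_of)
            annotations = _annotate.annotate_level(
                groups, level, level_hits, edges, genome_of, metadata,
                config.robust_deviants)
            p = out / f"annotations.{level_id}.tsv"
            write_annotations_tsv(annotations, p)
            annot_paths.append(p)
        ih = _hash_inputs([hits_path, clusters_path], config.robust_deviants)
        manifest.record(stage, ih, annot_paths)
        log.info("annotate: wrote %d level annotation tables", len(annot_paths))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- benchmark --------------------------------------------------------
    if config.reference:
        stage = "benchmark"
        try:
            ref_level = config.reference_level or levels[0]
            refogs = _io.read_refogs_tsv(config.reference)
            ref = _benchmark.Partition.from_blocks(refogs)
            pred = _benchmark.Partition.from_blocks(
                {g.og_id: g.members for g in groups_by_level[ref_level]},
                universe=ref.universe | frozenset(
                    g for grp in groups_by_level[ref_level] for g in grp.members))
            result = _benchmark.compare(ref, pred, log_base=config.log_base)
            report = {
                "level": ref_level,
                "vi": result.vi,
                "event_counts": result.event_counts,
                "split_events": result.total_split_events,
                "fuse_events": result.total_fuse_events,
                "summary": result.summary_row(),
                "records": [dataclasses.asdict(r) for r in result.records],
            }
            (out / "benchmark.json").write_text(
                json.dumps(report, indent=2, sort_keys=True))
            summary["benchmark_vi"] = result.vi
            summary["benchmark_events"] = result.event_counts
            log.info("benchmark: VI=%.3f bits, events=%s",
                     result.vi, result.event_counts)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    return summary


def write_annotations_tsv(annotations, path: str | Path) -> None:
    def fmt(x, nd=4):
        if x is None:
            return "NA"
        return f"{x:.{nd}f}" if isinstance(x, float) else str(x)

    with open(path, "w") as fh:
        fh.write("#og_id\tuniversality\tduplicability\tclass\tevol_rate\t"
                 "length_median\tlength_sd\texon_median\texon_sd\t"
                 "deviants\tsiblings\n")
        for a in sorted(annotations, key=lambda a: a.og_id):
            fh.write("\t".join([
                a.og_id, fmt(a.universality), fmt(a.duplicability),
                a.copy_number_class, fmt(a.evol_rate),
                fmt(a.length_median, 1), fmt(a.length_sd, 2),
                fmt(a.exon_median, 1), fmt(a.exon_sd, 2),
                ";".join(a.deviants), ";".join(sorted(a.sibling_group_ids)),
            ]) + "\n")
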