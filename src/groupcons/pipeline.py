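"""End-to-end orchestration: read -> conserve -> score -> gent -> trace ->
tree -> motif -> cross-method report.

``run_pipeline`` executes every configured stage on one alignment and
writes a deterministic report bundle: one TSV per stage, a JSON sidecar
with full-precision values for every TSV, a cross-method summary marking
which methods flagged each column, and a provenance manifest.  All
floating-point TSV values are printed at 3 decimals; the sidecars keep full
precision.  Numbers in the report are produced by the stage modules only —
the pipeline formats, it never recomputes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .alignment import (Alignment, GroupPartition, read_fasta_alignment,
                        read_groups, read_msf)
from .conservation import conservation_census, similarity_census
from .estimators import METHOD_NAMES, consensus_identified
from .gent import GEntParams, gent_scan
from .motifs import motif_presence, read_motif_file
from .phylo import (bootstrap_trees, jtt_distance_matrix, majority_consensus,
                    trim_alignment, upgma, write_newick)
from .trace import partition_tree, trace_residues

log = logging.getLogger("groupcons")


@dataclass
class PipelineConfig:
    """Inputs, per-stage parameters and output location for one run."""

    alignment_path: str
    groups_path: str | None = None
    motifs_path: str | None = None
    output_dir: str = "groupcons_out"
    seed: int = 0
    # stage switches / parameters
    gent: GEntParams = field(default_factory=GEntParams)
    estimator_methods: tuple[str, ...] = METHOD_NAMES
    top_fraction: float = 0.05
    trace_partitions: tuple[int, ...] = (2, 4, 8)
    run_tree: bool = True
    bootstrap_replicates: int = 0
    trim_gap_fraction: float = 0.8
    common_min_methods: int = 4

    def validate(self) -> None:
        if not Path(self.alignment_path).exists():
            raise FileNotFoundError(self.alignment_path)
        for p in (self.groups_path, self.motifs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.groups_path is None:
            raise ValueError("a group table is required (groups_path)")


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = asdict(config)
    d.pop("output_dir")  # where results land does not affect what they are
    return d


def version_manifest(config: PipelineConfig,
                     input_paths: list[str]) -> dict[str, Any]:
    """Provenance record: version, config hash, seed, input checksums."""
    cfg = _config_dict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    checksums = {}
    for p in input_paths:
        if p and Path(p).exists():
            checksums[p] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return {"tool": "groupcons", "version": __version__,
            "config": cfg, "config_sha256": cfg_hash,
            "seed": config.seed, "input_sha256": checksums,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def load_alignment(path: str | Path) -> Alignment:
    """Dispatch on content: MSF if the header announces it, else FASTA."""
    head = Path(path).read_text()[:4096]
    if "MSF:" in head or head.lstrip().startswith(("PileUp", "!!AA")):
        return read_msf(path)
    return read_fasta_alignment(path)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    records = json.loads(df.to_json(orient="records"))
    path.with_suffix(".json").write_text(
        json.dumps(records, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; returns the in-memory report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = version_manifest(
        config, [config.alignment_path, config.groups_path or "",
                 config.motifs_path or ""])
    bundle: dict[str, Any] = {"manifest": manifest}
    flags: dict[int, set[str]] = {}

    def flag(index: int, source: str) -> None:
        flags.setdefault(int(index), set()).add(source)

    def stage(name: str):
        log.info("stage %s", name)
        return time.monotonic()

    try:
        t0 = stage("load")
        alignment = load_alignment(config.alignment_path)
        partition = read_groups(config.groups_path)
        partition.validate(alignment)

        t0 = stage("conserve")
        census = conservation_census(alignment)
        sim = similarity_census(alignment)
        _write(census["table"], out / "conservation.tsv")
        _write(sim, out / "similarity.tsv")
        bundle["census"] = {k: v for k, v in census.items() if k != "table"}
        bundle["similarity"] = sim
        for i in census["table"].loc[
                census["table"]["percent"] >= 60, "index"]:
            flag(i, "identity_census")

        t0 = stage("score")
        consensus_sets = {}
        for method in config.estimator_methods:
            cols = consensus_identified(alignment, method,
                                        top_fraction=config.top_fraction)
            consensus_sets[method] = sorted(cols)
            for i in cols:
                flag(i, method)
        bundle["estimator_consensus"] = consensus_sets
        (out / "estimator_consensus.json").write_text(
            json.dumps(consensus_sets, indent=1, sort_keys=True))

        t0 = stage("gent")
        tables = gent_scan(alignment, partition, config.gent)
        for g, df in tables.items():
            _write(df, out / f"gent_{g}.tsv")
            for i in df.loc[df["selected"], "index"]:
                flag(i, f"gent:{g}")
        bundle["gent"] = tables

        t0 = stage("distances")
        trimmed, _ = trim_alignment(alignment, config.trim_gap_fraction)
        dm = jtt_distance_matrix(trimmed)
        pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(
            out / "distances.tsv", sep="\t", float_format="%.6f")

        t0 = stage("trace")
        dendro = upgma(dm)
        trace_frames = []
        for p in config.trace_partitions:
            tp = partition_tree(dendro, min(p, alignment.n_sequences))
            df = trace_residues(alignment, tp)
            df.insert(1, "P", tp.P)
            trace_frames.append(df)
            for i in df.loc[df["group_specific"], "index"]:
                flag(i, f"trace:P{tp.P}")
        trace_all = pd.concat(trace_frames, ignore_index=True)
        _write(trace_all, out / "trace.tsv")
        bundle["trace"] = trace_all

        if config.run_tree:
            t0 = stage("tree")
            from .phylo import neighbor_joining
            tree = neighbor_joining(dm)
            write_newick(tree, str(out / "nj_tree.nwk"))
            bundle["nj_tree"] = tree
            if config.bootstrap_replicates > 0:
                reps = bootstrap_trees(trimmed, config.bootstrap_replicates,
                                       config.seed)
                cons = majority_consensus(reps)
                write_newick(cons, str(out / "consensus_tree.nwk"))
                bundle["consensus_tree"] = cons

        if config.motifs_path:
            t0 = stage("motif")
            patterns = read_motif_file(config.motifs_path)
            presence = motif_presence(alignment, partition, patterns)
            _write(presence, out / "motifs.tsv")
            bundle["motifs"] = presence
    except Exception as exc:
        (out / "MANIFEST.json").write_text(
            json.dumps({**manifest, "failed": True, "error": str(exc)},
                       indent=1, default=str))
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    summary = pd.DataFrame(
        [(i, len(srcs), ";".join(sorted(srcs)))
         for i, srcs in sorted(flags.items())],
        columns=["index", "n_methods", "methods"])
    common = summary[summary["n_methods"] >= config.common_min_methods]
    _write(summary, out / "cross_method.tsv")
    _write(common, out / "common_positions.tsv")
    bundle["cross_method"] = summary
    bundle["common_positions"] = common
    manifest_out = {**manifest, "outputs": sorted(
        p.name for p in out.iterdir() if p.name != "MANIFEST.json")}
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest_out, indent=1, default=str))
    return bundle
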