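"""End-to-end orchestration: states -> segment scan -> pair association
-> (optional) motif scan, with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .errors import ConfigError
from .expression import build_state_sequences, read_de_table, state_map
from .genome import GenomeAnnotation, adjacent_pairs, read_gff3
from .motifs import (
    REGISTRY,
    assign_context,
    scan_genome,
    write_hits_bed,
    write_hits_tsv,
)
from .pairs import classify_pairs, write_pairs_report
from .segments import (
    WindowSpec,
    call_clusters,
    permutation_test,
    write_cluster_reports,
    write_scan_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunParams:
    window: int = 6
    min_concordant: int = 4
    iterations: int = 100_000
    seed: int = 0
    tie_rule: str = "greater_or_equal"
    missing_policy: str = "treat-missing-as-O"
    upstream_window: int = 1000
    patterns: tuple[str, ...] = ()


@dataclass
class RunManifest:
    inputs: dict[str, dict]  # name -> {path, sha256}
    params: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_all(
    gff: str,
    de_table: str,
    out_dir: str,
    fasta: str | None = None,
    params: RunParams | None = None,
) -> RunManifest:
    """Execute every analysis stage and write all reports into ``out_dir``."""
    params = params or RunParams()
    if params.patterns and fasta is None:
        raise ConfigError("motif patterns requested but no FASTA given")
    unknown = [p for p in params.patterns if p not in REGISTRY]
    if unknown:
        raise ConfigError(
            f"unknown motif patterns {unknown}; available: {sorted(REGISTRY)}"
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {"gff": {"path": str(gff), "sha256": _checksum(gff)},
              "de_table": {"path": str(de_table), "sha256": _checksum(de_table)}}
    if fasta is not None:
        inputs["fasta"] = {"path": str(fasta), "sha256": _checksum(fasta)}
    manifest = RunManifest(
        inputs=inputs,
        params=dataclasses.asdict(params),
        version=__version__,
    )

    annotation = read_gff3(gff)
    records = read_de_table(de_table)
    sequences = build_state_sequences(annotation, records, params.missing_policy)
    states = state_map(sequences)
    fold_changes = {r.gene_id: r.log2_fold_change for r in records}
    spec = WindowSpec(k=params.window, m=params.min_concordant)

    # segment scan
    result = permutation_test(
        sequences, spec,
        n_iterations=params.iterations,
        seed=params.seed,
        tie_rule=params.tie_rule,
    )
    scan_path = out / "scan_report.tsv"
    write_scan_report(result, spec, str(scan_path))
    manifest.outputs["scan_report"] = str(scan_path)

    clusters = call_clusters(sequences, spec, annotation)
    bed = out / "clusters.bed"
    tsv = out / "clusters.tsv"
    write_cluster_reports(clusters, states, fold_changes, str(bed), str(tsv))
    manifest.outputs["clusters_bed"] = str(bed)
    manifest.outputs["clusters_tsv"] = str(tsv)

    # pair association
    pairs = adjacent_pairs(annotation)
    usable = [
        p for p in pairs
        if p.left.id in states and p.right.id in states
    ]
    table, n_excluded = classify_pairs(usable, states)
    pairs_path = out / "pairs_report.tsv"
    write_pairs_report(table, n_excluded, str(pairs_path))
    manifest.outputs["pairs_report"] = str(pairs_path)

    # track export
    tracks = export_tracks(annotation, states, fold_changes, clusters)
    tracks_path = out / "tracks.tsv"
    tracks.to_csv(tracks_path, sep="\t", index=False)
    manifest.outputs["tracks"] = str(tracks_path)

    # motif scan
    if params.patterns:
        fa = Fasta(fasta)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        hits = scan_genome(
            seqs, [REGISTRY[p] for p in params.patterns], strands="both"
        )
        hits = assign_context(hits, annotation, params.upstream_window)
        hits_tsv = out / "motif_hits.tsv"
        hits_bed = out / "motif_hits.bed"
        write_hits_tsv(hits, str(hits_tsv))
        write_hits_bed(hits, str(hits_bed))
        manifest.outputs["motif_hits_tsv"] = str(hits_tsv)
        manifest.outputs["motif_hits_bed"] = str(hits_bed)

    manifest_path = out / "manifest.json"
    manifest.write(str(manifest_path))
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def export_tracks(
    annotation: GenomeAnnotation,
    states: dict[str, str],
    fold_changes: dict[str, float],
    clusters=(),
) -> pd.DataFrame:
    """Per-gene track table: coordinates, state, log2FC, cluster membership
    and nearest-tRNA distance, suitable for genome-browser plotting."""
    cluster_of: dict[str, str] = {}
    for idx, c in enumerate(clusters, 1):
        for gid in c.gene_ids:
            cluster_of[gid] = f"cluster{idx}"
    rows = []
    for chrom, genes in annotation.chromosomes.items():
        trnas = [g for g in genes if g.is_trna]
        for g in genes:
            dist = None
            for t in trnas:
                if t.id == g.id:
                    d = 0
                elif t.end <= g.start:
                    d = g.start - t.end
                elif t.start >= g.end:
                    d = t.start - g.end
                else:
                    d = 0
                dist = d if dist is None else min(dist, d)
            rows.append(
                (
                    chrom, g.id, g.start, g.end, g.strand,
                    states.get(g.id, "O"),
                    fold_changes.get(g.id, 0.0),
                    cluster_of.get(g.id, ""),
                    "" if dist is None else dist,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "gene_id", "start", "end", "strand",
            "state", "log2fc", "cluster", "nearest_trna_distance",
        ],
    )
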