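"""End-to-end orchestration: similarity -> graph -> sweep -> families ->
motifs -> annotation -> optional element detection -> host network.

Every stage writes its outputs to the run directory and records them in
a manifest with SHA-256 checksums, so identical config + inputs yield
identical files and a run is reconstructible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from tbssr import io as tio
from tbssr.annotate import AnnotationRules, build_profiles, family_report, per_protein_table
from tbssr.elements import ElementRules, find_bim, find_rit, find_tn554_like
from tbssr.hostnet import group_hosts, shared_family_graph
from tbssr.mcl import MclOptions, SweepGrid, inflation_sweep
from tbssr.msa import MotifOptions, find_catalytic_motif, guide_tree, progressive_msa, Msa
from tbssr.similarity import ScoringScheme, all_vs_all, build_graph

logger = logging.getLogger("tbssr")


@dataclass
class PipelineConfig:
    """All paths and stage parameters of one reproducible run."""

    fasta: str = ""
    metadata: str = ""
    hits: str | None = None
    gff: str | None = None
    out_dir: str = "tbssr_run"
    e_cutoff: float = 0.01
    weight_cap: float = 200.0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    mcl_options: MclOptions = field(default_factory=MclOptions)
    sweep_grid: SweepGrid = field(default_factory=SweepGrid)
    motif_options: MotifOptions = field(default_factory=MotifOptions)
    annotation_rules: AnnotationRules = field(default_factory=AnnotationRules)
    element_rules: ElementRules = field(default_factory=ElementRules)
    bim_partner_famint: int | None = 45
    network_min_family_size: int = 2
    min_msa_size: int = 2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        converters = {
            "scoring": ScoringScheme,
            "mcl_options": MclOptions,
            "sweep_grid": SweepGrid,
            "motif_options": MotifOptions,
            "annotation_rules": AnnotationRules,
            "element_rules": ElementRules,
        }
        for key, klass in converters.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                for fname, ftype in (
                    (f.name, f.type) for f in dataclasses.fields(klass)
                ):
                    if fname in d and isinstance(d[fname], list):
                        d[fname] = tuple(d[fname])
                kwargs[key] = klass(**d)
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order and return the manifest.

    When ``config.hits`` points to a precomputed BLAST-tabular table the
    alignment stage is skipped and the graph is built from the file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), started=time.time())

    def record(stage: str, *paths: Path) -> None:
        manifest.stages.append(stage)
        for p in paths:
            manifest.outputs[str(p)] = _sha256(p)

    logger.info("config: %s", dataclasses.asdict(config))

    proteins = tio.load_proteins(config.fasta, config.metadata)
    logger.info("loaded %d proteins", len(proteins))

    # 1-2) similarity search + graph
    if config.hits:
        hits = tio.read_hits_blasttab(config.hits)
        hits = [h for h in hits if h.e_value <= config.e_cutoff]
        logger.info("similarity: %d precomputed hits from %s", len(hits), config.hits)
    else:
        hits = all_vs_all(proteins, config.scoring, config.e_cutoff)
        logger.info(
            "similarity: %d hits (E <= %g, scoring %s)",
            len(hits), config.e_cutoff, dataclasses.asdict(config.scoring),
        )
        hits_path = out / "hits.blasttab.tsv"
        tio.write_hits_blasttab(hits, hits_path)
        record("similarity", hits_path)
    graph = build_graph(
        hits,
        weight_cap=config.weight_cap,
        node_ids=[p.id for p in proteins],
        e_cutoff=config.e_cutoff,
        database_size=sum(p.length for p in proteins),
    )
    abc_path = out / "graph.abc"
    tio.write_abc(graph, abc_path)
    record("graph", abc_path)

    # 3) inflation sweep + selection
    sweep = inflation_sweep(graph, config.sweep_grid, config.mcl_options)
    for row in sweep.rows:
        if not row["converged"]:
            manifest.warnings.append(
                f"MCL not converged at inflation {row['inflation']}"
            )
    partition = sweep.selected
    logger.info(
        "sweep: selected inflation %.1f (ICCC %.4f, %d families)",
        sweep.selected_inflation, partition.iccc, partition.n_families,
    )
    sweep_path = out / "sweep.tsv"
    clusters_path = out / "clusters.mcl"
    partition_path = out / "partition.tsv"
    tio.write_sweep_tsv(sweep, sweep_path)
    tio.write_clusters_mcl(partition, clusters_path)
    tio.write_partition_tsv(partition, partition_path)
    record("sweep", sweep_path, clusters_path, partition_path)

    # 4) per-family MSA + motif
    by_id = {p.id: p for p in proteins}
    msa_dir = out / "msa"
    msa_dir.mkdir(exist_ok=True)
    motifs = {}
    msa_paths = []
    for fam in range(partition.n_families):
        members = [by_id[pid] for pid in partition.members(fam)]
        if len(members) < config.min_msa_size:
            continue
        tree = guide_tree(members, graph)
        msa = progressive_msa(members, tree, config.scoring, family_index=fam)
        motifs[fam] = find_catalytic_motif(msa, config.motif_options)
        p = msa_dir / f"famint{fam:03d}.afa"
        tio.write_msa_fasta(msa, p)
        msa_paths.append(p)
    motif_path = out / "motifs.tsv"
    import pandas as pd

    pd.DataFrame(
        [
            {
                "famint": fam,
                "found": m.found,
                "label": m.label,
                "y_column": m.y_column if m.y_column is not None else "",
                "median_spacing": m.median_spacing if m.median_spacing is not None else "",
                "y_conservation": round(m.y_conservation, 4),
                "r_conservation": round(m.r_conservation, 4),
            }
            for fam, m in sorted(motifs.items())
        ]
    ).to_csv(motif_path, sep="\t", index=False)
    record("msa_motif", motif_path, *msa_paths)
    logger.info("motifs: %d/%d families with a catalytic motif",
                sum(m.found for m in motifs.values()), len(motifs))

    # 5) annotation
    profiles = build_profiles(partition, proteins, motifs, config.annotation_rules)
    table, summary = family_report(profiles, partition, config.annotation_rules)
    report_path = out / "family_report.tsv"
    summary_path = out / "summary.json"
    per_protein_path = out / "per_protein.tsv"
    table.to_csv(report_path, sep="\t", index=False)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    per_protein_table(profiles, partition).to_csv(
        per_protein_path, sep="\t", index=False
    )
    record("annotation", report_path, summary_path, per_protein_path)
    logger.info("annotation summary: %s", summary)

    # 6) element detection (optional)
    if config.gff:
        features = tio.read_gff3(config.gff)
        calls = find_rit(features, config.element_rules)
        calls += find_tn554_like(features, config.element_rules)
        if config.bim_partner_famint is not None:
            calls += find_bim(
                features, config.bim_partner_famint, config.element_rules
            )
        egff = out / "elements.gff3"
        etsv = out / "elements.tsv"
        tio.write_element_calls(calls, egff, etsv)
        record("elements", egff, etsv)
        logger.info("elements: %d calls", len(calls))

    # 7) host network
    nodes = group_hosts(proteins)
    host_graph = shared_family_graph(
        partition, proteins, nodes, config.network_min_family_size
    )
    edges_path = out / "host_edges.tsv"
    comps_path = out / "host_components.tsv"
    tio.write_host_edges(host_graph, edges_path)
    tio.write_host_components(host_graph.components, comps_path)
    record("host_network", edges_path, comps_path)
    logger.info(
        "host network: %d nodes, %d edges, %d components",
        len(host_graph.nodes), len(host_graph.edges), len(host_graph.components),
    )

    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest
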