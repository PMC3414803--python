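"""File-format plumbing: FASTA, metadata TSV, BLAST tabular, GFF3, ABC.

Coordinates are 0-based half-open everywhere inside the package;
1-based inclusive conventions apply only at file boundaries (BLAST
tabular and GFF3), converted on read and write.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tbssr.elements import ElementCall, GeneFeature
from tbssr.mcl import FamintPartition, SweepResult
from tbssr.records import ProteinRecord
from tbssr.similarity import SimilarityGraph, SimilarityHit, bit_score
from tbssr.synthetic import SynthReplicon, TruthTable

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; the id is the first header token."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list, path: str | Path) -> None:
    """Accepts ProteinRecord objects or (id, seq) pairs."""
    out = []
    for r in records:
        if isinstance(r, ProteinRecord):
            out.append(SeqRecord(Seq(r.sequence), id=r.id, description=""))
        else:
            pid, seq = r
            out.append(SeqRecord(Seq(seq), id=pid, description=""))
    SeqIO.write(out, str(path), "fasta")


def write_msa_fasta(msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(msa.rows):
            fh.write(f">{pid}\n{msa.rows[pid]}\n")


# -- metadata ---------------------------------------------------------------

def write_metadata_tsv(proteins: list[ProteinRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": p.id,
                "mge_type": p.mge_type,
                "host": p.host,
                "replicon": p.replicon,
            }
            for p in proteins
        ]
    ).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "mge_type", "host", "replicon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    return df


def load_proteins(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[ProteinRecord]:
    """Join a protein FASTA with its sidecar metadata TSV."""
    seqs = dict(read_fasta(fasta_path))
    meta = read_metadata_tsv(metadata_path).set_index("protein_id")
    records = []
    for pid, seq in seqs.items():
        if pid in meta.index:
            row = meta.loc[pid]
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=seq,
                    mge_type=row["mge_type"] or "unknown",
                    host=row["host"],
                    replicon=row["replicon"],
                )
            )
        else:
            records.append(ProteinRecord(id=pid, sequence=seq))
    return records


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    rows = []
    for pid in sorted(truth.entries):
        e = truth.entries[pid]
        rows.append(
            {
                "protein_id": pid,
                "true_family": e.true_family,
                "mge_type": e.mge_type,
                "host": e.host,
                "r_index": e.motif_positions[0] if e.motif_positions else "",
                "y_index": e.motif_positions[1] if e.motif_positions else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- BLAST tabular ----------------------------------------------------------

def write_hits_blasttab(hits: list[SimilarityHit], path: str | Path) -> None:
    """12-column BLAST tabular; coordinates 1-based inclusive on disk."""
    with open(path, "w") as fh:
        for h in hits:
            (qs, qe), (ss, se) = h.aligned_ranges
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{100 * h.identity:.2f}",
                        str(max(qe - qs, se - ss)),
                        "0",
                        "0",
                        str(qs + 1),
                        str(qe),
                        str(ss + 1),
                        str(se),
                        f"{h.e_value:.17g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_hits_blasttab(path: str | Path) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular into directed hits.

    Raw scores are not stored in the format; they are back-computed
    from the bit score so downstream weights depend only on the
    E-value column, as in the similarity graph itself.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns"
                )
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                qs, qe = int(parts[6]), int(parts[7])
                ss, se = int(parts[8]), int(parts[9])
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    raw_score=max(int(round(bits)), 0),
                    bit_score=bits,
                    e_value=ev,
                    identity=pident / 100.0,
                    aligned_ranges=((qs - 1, qe), (ss - 1, se)),
                )
            )
    return hits


# -- ABC edge list / clusters ----------------------------------------------

def write_abc(graph: SimilarityGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (i, j), w in sorted(graph.edges.items()):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t{w:.6g}\n")


def read_abc(
    path: str | Path,
    node_ids: list[str] | None = None,
    weight_cap: float = 200.0,
) -> SimilarityGraph:
    edges = []
    seen: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            u, v, w = parts[0], parts[1], float(parts[2])
            edges.append((u, v, w))
            for x in (u, v):
                if x not in seen_set:
                    seen.append(x)
                    seen_set.add(x)
    g = SimilarityGraph(node_ids if node_ids is not None else seen, weight_cap)
    for u, v, w in edges:
        g.add_edge(u, v, w)
    return g


def write_clusters_mcl(partition: FamintPartition, path: str | Path) -> None:
    """MCL native dialect: one cluster per line, members tab-separated."""
    with open(path, "w") as fh:
        for members in partition.clusters():
            fh.write("\t".join(members) + "\n")


def write_partition_tsv(partition: FamintPartition, path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "famint": fam}
        for pid, fam in sorted(partition.assignment.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | Path) -> FamintPartition:
    from tbssr.mcl import rank_families

    df = pd.read_csv(path, sep="\t")
    clusters: dict[int, list[str]] = {}
    for _, row in df.iterrows():
        clusters.setdefault(int(row["famint"]), []).append(str(row["protein_id"]))
    return rank_families(list(clusters.values()))


def write_sweep_tsv(result: SweepResult, path: str | Path) -> None:
    pd.DataFrame(result.rows).to_csv(path, sep="\t", index=False)


# -- GFF3 -------------------------------------------------------------------

def write_gff3(replicon: SynthReplicon | list[GeneFeature], path: str | Path,
               replicon_length: int | None = None) -> None:
    """CDS features; 1-based inclusive coordinates on disk."""
    if isinstance(replicon, SynthReplicon):
        features = replicon.features
        lengths = {replicon.replicon_id: replicon.length}
    else:
        features = replicon
        lengths = {}
        for f in features:
            lengths[f.replicon] = max(lengths.get(f.replicon, 0), f.end)
        if replicon_length is not None:
            lengths = {rep: replicon_length for rep in lengths}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in sorted(lengths):
            fh.write(f"##sequence-region {rep} 1 {lengths[rep]}\n")
        for f in features:
            attrs = [f"ID={f.id}", f"product_len={f.product_len}",
                     f"is_tbssr={'true' if f.is_tbssr else 'false'}"]
            if f.famint is not None:
                attrs.append(f"famint={f.famint}")
            fh.write(
                "\t".join(
                    [
                        f.replicon, "tbssr", "CDS",
                        str(f.start + 1), str(f.end), ".",
                        f.strand, "0", ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(
    path: str | Path, tbssr_ids: set[str] | None = None
) -> list[GeneFeature]:
    """Read CDS features from GFF3 (1-based inclusive -> half-open).

    A feature is marked as a recombinase when its attributes carry
    ``is_tbssr=true``, when its id is in ``tbssr_ids``, or when the
    ``product`` attribute mentions integrase/recombinase.
    """
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            amap = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    amap[k.strip()] = v.strip()
            fid = amap.get("ID", f"{seqid}:{lineno}")
            is_tbssr = amap.get("is_tbssr", "").lower() == "true"
            if tbssr_ids is not None and fid in tbssr_ids:
                is_tbssr = True
            product = amap.get("product", "").lower()
            if "integrase" in product or "recombinase" in product:
                is_tbssr = True
            famint = int(amap["famint"]) if "famint" in amap else None
            product_len = (
                int(amap["product_len"]) if "product_len" in amap else -1
            )
            features.append(
                GeneFeature(
                    replicon=seqid,
                    start=s - 1,
                    end=e,
                    strand=strand,
                    id=fid,
                    product_len=product_len,
                    is_tbssr=is_tbssr,
                    famint=famint,
                )
            )
    return sorted(features, key=lambda f: (f.replicon, f.start))


def write_element_calls(
    calls: list[ElementCall], gff_path: str | Path, tsv_path: str | Path
) -> None:
    """Element calls as a diagnostics TSV plus a simple GFF3 of spans."""
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "element_id": f"elem{i:03d}",
                "type": c.type,
                "replicon": c.replicon,
                "members": ",".join(c.members),
                "span": c.span,
                "strand": c.strand,
                "has_tnpC": c.has_tnpC,
                "conflict": c.conflict,
                **{f"diag_{k}": v for k, v in c.diagnostics.items()},
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls):
            fh.write(
                "\t".join(
                    [
                        c.replicon, "tbssr", "mobile_genetic_element",
                        "1", str(max(c.span, 1)), ".", c.strand, ".",
                        f"ID=elem{i:03d};element_type={c.type};"
                        f"members={','.join(c.members)}",
                    ]
                )
                + "\n"
            )


# -- host network -----------------------------------------------------------

def write_host_edges(graph, path: str | Path) -> None:
    rows = [
        {"node1": a, "node2": b, "weight": w}
        for (a, b), w in sorted(graph.edges.items())
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_host_components(components: list[list[str]], path: str | Path) -> None:
    rows = [
        {"component": i, "node": n}
        for i, comp in enumerate(components)
        for n in comp
    ]
    pd.DataFrame(rows, columns=["component", "node"]).to_csv(
        path, sep="\t", index=False
    )
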