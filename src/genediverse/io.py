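"""File dialect readers and writers.

All coordinates are 1-based inclusive (GTF convention).  Readers accept
the same dialects the writers emit: GTF or BioMart-style TSV for
annotations, TSV matrices with a transcript -> gene map, TSV group
labels, Newick trees.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from genediverse.structure import AnnotationTable
from genediverse.tensor import IsoformExpressionTensor
from genediverse.tree import SampleTree

__all__ = [
    "write_annotation_gtf",
    "read_annotation_gtf",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "read_labels",
    "write_labels",
    "write_tensor",
    "read_tensor",
    "read_tree",
    "write_tree",
]


def write_annotation_gtf(table: AnnotationTable, path: str | Path) -> None:
    """Emit gene/transcript/exon features with gene_id, transcript_id and
    the Ensembl_canonical tag on canonical transcripts."""
    lines = []
    for gid, g in table.genes.iterrows():
        attrs = f'gene_id "{gid}"; gene_biotype "{g["biotype"]}";'
        lines.append(
            "\t".join(
                [
                    g["chromosome"], "sim", "gene",
                    str(g["start"]), str(g["end"]), ".", g["strand"], ".", attrs,
                ]
            )
        )
        txs = table.transcripts[table.transcripts["gene_id"] == gid]
        for tid, t in txs.iterrows():
            tag = ' tag "Ensembl_canonical";' if t["canonical"] else ""
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";{tag}'
            exons = table.transcript_exons(tid)
            t_start = int(exons["start"].min())
            t_end = int(exons["end"].max())
            lines.append(
                "\t".join(
                    [
                        g["chromosome"], "sim", "transcript",
                        str(t_start), str(t_end), ".", g["strand"], ".", attrs,
                    ]
                )
            )
            for _, e in exons.iterrows():
                eattrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'exon_number "{int(e["rank"])}";'
                )
                lines.append(
                    "\t".join(
                        [
                            g["chromosome"], "sim", "exon",
                            str(int(e["start"])), str(int(e["end"])),
                            ".", g["strand"], ".", eattrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gtf(path: str | Path, labels: pd.Series | None = None) -> AnnotationTable:
    """Read gene/transcript/exon features from a GTF file (via gffutils).

    Canonical transcripts are recognized by the 'Ensembl_canonical' tag.
    Group labels default to 'non_epigene' unless supplied.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gene_rows, tx_rows, exon_rows = [], [], []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        gene_rows.append(
            {
                "gene_id": gid,
                "label": labels.get(gid, "non_epigene") if labels is not None else "non_epigene",
                "chromosome": g.seqid,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "biotype": g.attributes.get("gene_biotype", ["protein_coding"])[0],
            }
        )
    for t in db.features_of_type("transcript"):
        tags = t.attributes.get("tag", [])
        tx_rows.append(
            {
                "transcript_id": t.attributes["transcript_id"][0],
                "gene_id": t.attributes["gene_id"][0],
                "canonical": "Ensembl_canonical" in tags,
            }
        )
    for e in db.features_of_type("exon"):
        exon_rows.append(
            {
                "transcript_id": e.attributes["transcript_id"][0],
                "start": e.start,
                "end": e.end,
                "rank": int(e.attributes["exon_number"][0]),
            }
        )
    return AnnotationTable(
        genes=pd.DataFrame(gene_rows).set_index("gene_id"),
        transcripts=pd.DataFrame(tx_rows).set_index("transcript_id"),
        exons=pd.DataFrame(exon_rows),
    )


def write_annotation_tsv(table: AnnotationTable, prefix: str | Path) -> None:
    """BioMart-style TSV triplet: <prefix>.genes.tsv / .transcripts.tsv /
    .exons.tsv."""
    prefix = str(prefix)
    table.genes.to_csv(f"{prefix}.genes.tsv", sep="\t")
    table.transcripts.to_csv(f"{prefix}.transcripts.tsv", sep="\t")
    table.exons.to_csv(f"{prefix}.exons.tsv", sep="\t", index=False)


def read_annotation_tsv(prefix: str | Path) -> AnnotationTable:
    prefix = str(prefix)
    return AnnotationTable(
        genes=pd.read_csv(f"{prefix}.genes.tsv", sep="\t", index_col="gene_id"),
        transcripts=pd.read_csv(
            f"{prefix}.transcripts.tsv", sep="\t", index_col="transcript_id"
        ),
        exons=pd.read_csv(f"{prefix}.exons.tsv", sep="\t"),
    )


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("gene_id").to_csv(path, sep="\t")


def write_tensor(tensor: IsoformExpressionTensor, prefix: str | Path) -> None:
    """<prefix>.matrix.tsv (transcripts x samples) and <prefix>.map.tsv
    (transcript_id, gene_id)."""
    prefix = str(prefix)
    tensor.matrix.rename_axis("transcript_id").to_csv(f"{prefix}.matrix.tsv", sep="\t")
    pd.Series(tensor.gene_of, name="gene_id").rename_axis("transcript_id").to_csv(
        f"{prefix}.map.tsv", sep="\t"
    )


def read_tensor(matrix_path: str | Path, map_path: str | Path) -> IsoformExpressionTensor:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gene_of = pd.read_csv(map_path, sep="\t", index_col=0)["gene_id"].to_dict()
    return IsoformExpressionTensor(matrix, gene_of)


def read_tree(path: str | Path) -> SampleTree:
    return SampleTree.from_newick(Path(path).read_text())


def write_tree(tree: SampleTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
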