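"""Readers and writers for the flat-text formats the pipeline uses.

FASTA goes through Bio.SeqIO.  GFF3 here is the gene-feature subset the
positional statistics need (seqid, start, end, strand, ID attribute);
rows with other feature types are ignored on read.  Homology tables use
the 12-column BLAST ``-outfmt 6`` layout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneRecord, HomologyHit, TruthEvent

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

TRUTH_COLUMNS = ["genome", "donor", "acceptor", "kind", "start", "end", "epoch"]


def write_fasta(records: list[GeneRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.cds), id=rec.gene_id, description="")
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(records: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.gene_id)):
            fh.write(
                f"{rec.chrom}\tquartetconv\tgene\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.gene_id}\n"
            )


def read_gff3_genes(path, genome: str, cds: dict[str, str] | None = None) -> list[GeneRecord]:
    """Read gene features from a GFF3 file into ranked GeneRecords.

    Ranks are assigned per chromosome by start coordinate (ties by id);
    CDS sequences are attached from ``cds`` when given.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
            dtype={"seqid": str},
        )
    except pd.errors.EmptyDataError:
        return []
    df = df[df["type"] == "gene"]
    records = []
    for row in df.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"{path}: gene feature without ID attribute")
        records.append(
            GeneRecord(
                gene_id=gene_id, genome=genome, chrom=row.seqid,
                start=int(row.start), end=int(row.end),
                strand=row.strand if row.strand in "+-" else "+",
                cds=(cds or {}).get(gene_id, ""),
            )
        )
    from .simgenome import _assign_ranks

    return _assign_ranks(records)


def write_homology_tsv(hits, path) -> None:
    pd.DataFrame(hits, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def read_homology_tsv(path, permissive: bool = False) -> list[HomologyHit]:
    """Read a BLAST outfmt-6 table.

    Malformed rows raise with their line number, or are skipped (with the
    same message available via logging) when ``permissive`` is set.
    """
    import logging

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 12:
                    raise ValueError(f"expected 12 columns, got {len(parts)}")
                hits.append(
                    HomologyHit(
                        query=parts[0], subject=parts[1],
                        pident=float(parts[2]), length=int(parts[3]),
                        evalue=float(parts[10]), bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                msg = f"{path}:{lineno}: malformed homology row ({exc})"
                if permissive:
                    logging.getLogger(__name__).warning(msg)
                    continue
                raise ValueError(msg) from None
    return hits


def write_truth_tsv(truth: list[TruthEvent], path) -> None:
    pd.DataFrame(
        [(t.genome, t.donor, t.acceptor, t.kind, t.start, t.end, t.epoch) for t in truth],
        columns=TRUTH_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthEvent(genome=r.genome, donor=r.donor, acceptor=r.acceptor,
                   kind=r.kind, start=int(r.start), end=int(r.end), epoch=r.epoch)
        for r in df.itertuples(index=False)
    ]


def read_expression_matrix(path) -> pd.DataFrame:
    """Gene × sample expression table (TSV, first column gene id)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_calls_tsv(calls, path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "genome": c.genome, "gene1": c.gene1, "gene2": c.gene2,
                "methods": ",".join(sorted(c.methods)),
                "donor": c.donor,
                "support": "" if c.support is None else f"{c.support:.3f}",
                "tracts": ";".join(f"{s}-{e}" for s, e in c.tracts),
                "period": c.period,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tracts_bed(calls, path) -> None:
    """PCV tracts in BED-like form: acceptor gene, 0-based half-open CDS
    coordinates, donor, support."""
    rows = []
    for c in calls:
        acceptor = c.gene2 if c.donor == c.gene1 else c.gene1
        for (s, e), sup in zip(c.tracts, c.tract_support or [float("nan")] * len(c.tracts)):
            rows.append((acceptor, s - 1, e, c.donor, f"{sup:.3f}"))
    pd.DataFrame(rows, columns=["acceptor", "start", "end", "donor", "support"]).to_csv(
        path, sep="\t", index=False
    )


def write_blocks_tsv(blocks, path) -> None:
    rows = [
        {
            "block_id": b.block_id, "genome_a": b.genome_a, "genome_b": b.genome_b,
            "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
            "n_anchors": b.n_anchors, "orientation": b.orientation,
            "relation": b.relation,
            "median_ks": "" if b.median_ks is None else f"{b.median_ks:.4f}",
            "anchors": ";".join(f"{a}|{bb}" for a, bb in b.anchors),
        }
        for b in blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_quartets_tsv(quartets, path) -> None:
    rows = [
        (q.genome_a, q.genome_b, q.o1, q.o2, q.s1, q.s2)
        for q in quartets
    ]
    pd.DataFrame(
        rows, columns=["genome_a", "genome_b", "o1", "o2", "s1", "s2"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
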