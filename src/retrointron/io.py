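"""Readers/writers for the standard formats the pipeline touches.

GFF3/GTF parsing goes through :mod:`gffutils`; coordinates are converted
to the internal 0-based half-open convention at this boundary.  The
alignment table is a documented TSV dialect so the scan stage can ingest
external (tBLASTn-like) hits without re-running an aligner:

    query  target_chrom  target_start  target_end  strand  identity
    coverage  evalue  blocks

where ``blocks`` is a comma-separated list of ``qs-qe:ts-te`` ranges
(0-based half-open, query-forward order) and ``evalue`` may be ``.``.
"""

from __future__ import annotations

import logging
import os

import gffutils

from retrointron.core import AlignmentBlockSet, GapRecord, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation (GFF3 / GTF)
# ---------------------------------------------------------------------------

def read_annotation(path: str) -> dict[str, GeneModel]:
    """Load gene models from GFF3 or GTF.

    Exon features must carry transcript parentage (``Parent=`` in GFF3,
    ``transcript_id`` in GTF); orphan exons are skipped with a warning.
    Returns a mapping gene id -> :class:`GeneModel`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    is_gtf = str(path).lower().endswith((".gtf", ".gtf.gz"))
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=not is_gtf,
        disable_infer_transcripts=not is_gtf,
    )

    # transcript -> gene resolution
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            parents = list(db.parents(tx, featuretype="gene"))
            gid = parents[0].id if parents else tx.attributes.get("gene_id", [tx.id])[0]
            tx_gene[tx.id] = gid
            tx_meta[tx.id] = (tx.seqid, tx.strand)

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tids = [p.id for p in db.parents(feat, featuretype=("mRNA", "transcript"))]
            if not tids and "transcript_id" in feat.attributes:
                tids = feat.attributes["transcript_id"]
            if not tids:
                logger.warning("orphan %s at %s:%s-%s skipped",
                               ftype, feat.seqid, feat.start, feat.end)
                continue
            for tid in tids:
                iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                store.setdefault(tid, []).append(iv)
                tx_meta.setdefault(tid, (feat.seqid, feat.strand))

    genes: dict[str, GeneModel] = {}
    for tid, exs in exons.items():
        gid = tx_gene.get(tid, tid)
        chrom, strand = tx_meta[tid]
        gene = genes.get(gid)
        if gene is None:
            gene = genes[gid] = GeneModel(gid, chrom, strand)
        gene.exons[tid] = sorted(exs, key=lambda iv: iv.start)
        if tid in cds:
            gene.cds[tid] = sorted(cds[tid], key=lambda iv: iv.start)
    return genes


def write_annotation(genes: dict[str, GeneModel], path: str,
                     source: str = "retrointron") -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, gene in genes.items():
            loc = gene.locus()
            fh.write("\t".join([
                gene.chrom, source, "gene", str(loc.start + 1), str(loc.end),
                ".", gene.strand, ".", f"ID={gid}",
            ]) + "\n")
            for tid, exs in gene.exons.items():
                span = gene.span(tid)
                fh.write("\t".join([
                    gene.chrom, source, "mRNA", str(span.start + 1), str(span.end),
                    ".", gene.strand, ".", f"ID={tid};Parent={gid}",
                ]) + "\n")
                for i, iv in enumerate(exs, 1):
                    fh.write("\t".join([
                        gene.chrom, source, "exon", str(iv.start + 1), str(iv.end),
                        ".", gene.strand, ".",
                        f"ID={tid}.exon{i};Parent={tid}",
                    ]) + "\n")
                for i, iv in enumerate(gene.cds.get(tid, []), 1):
                    fh.write("\t".join([
                        gene.chrom, source, "CDS", str(iv.start + 1), str(iv.end),
                        ".", gene.strand, "0" if i == 1 else ".",
                        f"ID={tid}.cds{i};Parent={tid}",
                    ]) + "\n")


# ---------------------------------------------------------------------------
# alignment table
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "query", "target_chrom", "target_start", "target_end", "strand",
    "identity", "coverage", "evalue", "blocks",
]


def _format_blocks(blocks) -> str:
    return ",".join(f"{qs}-{qe}:{ts}-{te}" for (qs, qe), (ts, te) in blocks)


def _parse_blocks(text: str):
    blocks = []
    for part in text.split(","):
        qr, tr = part.split(":")
        qs, qe = (int(x) for x in qr.split("-"))
        ts, te = (int(x) for x in tr.split("-"))
        blocks.append(((qs, qe), (ts, te)))
    return blocks


def write_alignment_table(alignments: list[AlignmentBlockSet], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ALIGNMENT_COLUMNS) + "\n")
        for aln in alignments:
            fh.write("\t".join([
                aln.query_id, aln.target.chrom, str(aln.target.start),
                str(aln.target.end), aln.target.strand,
                f"{aln.identity:.2f}", f"{aln.coverage:.4f}",
                "." if aln.evalue is None else f"{aln.evalue:.3g}",
                _format_blocks(aln.blocks),
            ]) + "\n")


def read_alignment_table(path: str) -> list[AlignmentBlockSet]:
    """Parse the TSV alignment dialect; invalid rows are rejected with a
    logged reason rather than aborting the load."""
    out: list[AlignmentBlockSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(ALIGNMENT_COLUMNS):
                logger.warning("line %d: expected %d columns, got %d — rejected",
                               lineno, len(ALIGNMENT_COLUMNS), len(fields))
                continue
            (query, chrom, tstart, tend, strand,
             identity, coverage, evalue, blocks) = fields
            try:
                aln = AlignmentBlockSet(
                    query_id=query,
                    target=GenomicInterval(chrom, int(tstart), int(tend), strand),
                    blocks=_parse_blocks(blocks),
                    identity=float(identity),
                    coverage=float(coverage),
                    evalue=None if evalue == "." else float(evalue),
                )
            except (ValueError, KeyError) as exc:
                logger.warning("line %d rejected: %s", lineno, exc)
                continue
            aln.gaps = infer_gaps(aln.blocks)
            out.append(aln)
    return out


def infer_gaps(blocks) -> list[GapRecord]:
    """Derive explicit gap records from consecutive block boundaries."""
    gaps: list[GapRecord] = []
    for ((qs1, qe1), (ts1, te1)), ((qs2, qe2), (ts2, te2)) in zip(blocks, blocks[1:]):
        dq = qs2 - qe1
        dt = abs(ts2 - te1)
        if dq > 0 and dq >= dt:
            gaps.append(GapRecord("target", qe1, te1, dq))
        if dt > 0 and dt > dq:
            gaps.append(GapRecord("query", qe1, te1, dt))
    return gaps


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """BED3/BED6 intervals (e.g. a repeat annotation)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


class Bed12Record:
    """One BED12 line: a (spliced) transcript alignment with block structure."""

    __slots__ = ("chrom", "start", "end", "name", "score", "strand",
                 "block_starts", "block_sizes")

    def __init__(self, chrom, start, end, name, score, strand,
                 block_starts, block_sizes):
        self.chrom = chrom
        self.start = start
        self.end = end
        self.name = name
        self.score = score
        self.strand = strand
        self.block_starts = block_starts  # chrom-absolute
        self.block_sizes = block_sizes

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(intron_start, intron_end) pairs implied by the block gaps."""
        out = []
        for i in range(len(self.block_starts) - 1):
            donor = self.block_starts[i] + self.block_sizes[i]
            acceptor = self.block_starts[i + 1]
            if acceptor > donor:
                out.append((donor, acceptor))
        return out

    def to_line(self) -> str:
        rel = [s - self.start for s in self.block_starts]
        return "\t".join([
            self.chrom, str(self.start), str(self.end), self.name,
            str(self.score), self.strand, str(self.start), str(self.end),
            "0,0,0", str(len(rel)),
            ",".join(str(s) for s in self.block_sizes) + ",",
            ",".join(str(s) for s in rel) + ",",
        ])


def read_bed12(path: str) -> list[Bed12Record]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            rel = [int(x) for x in f[11].rstrip(",").split(",")]
            out.append(Bed12Record(
                f[0], start, int(f[2]), f[3], int(f[4]), f[5],
                [start + r for r in rel], sizes,
            ))
    return out


def write_bed12(records: list[Bed12Record], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
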