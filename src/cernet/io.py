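"""Readers and writers for the plain-text formats the pipeline touches.

All readers validate strictly and raise :class:`~cernet.errors.ParseError`
with the offending file/line rather than coercing silently; every
writer/reader pair is a lossless round trip on valid data.  Paths ending in
``.gz`` are transparently decompressed/compressed.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .containers import CountMatrix, FeatureAnnotation, SampleTable, SequenceSet
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path, rna_class: str, groups: dict[str, str]) -> CountMatrix:
    """Read a feature x sample TSV of integer counts.

    The first column holds feature ids; the header row holds sample ids.
    Every sample must appear in ``groups`` (sample -> "high"/"low").
    """
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty counts file", str(path), 1)
        cols = header.split("\t")[1:]
        if len(set(cols)) != len(cols):
            raise ParseError("duplicate sample ids in header", str(path), 1)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols) + 1:
                raise ParseError(
                    f"ragged row: expected {len(cols) + 1} fields, got {len(parts)}",
                    str(path), lineno,
                )
            fid = parts[0]
            vals = []
            for col, cell in zip(cols, parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ParseError(
                        f"non-integer count {cell!r} (feature {fid!r}, sample {col!r})",
                        str(path), lineno,
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"negative count {v} (feature {fid!r}, sample {col!r})",
                        str(path), lineno,
                    )
                vals.append(v)
            if fid in set(ids):
                raise ParseError(f"duplicate feature id {fid!r}", str(path), lineno)
            ids.append(fid)
            rows.append(vals)
    unknown = [s for s in cols if s not in groups]
    if unknown:
        raise ParseError(f"samples missing from group map: {unknown}", str(path))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=cols, dtype="int64")
    return CountMatrix(df, rna_class, {s: groups[s] for s in cols})


def write_counts(cm: CountMatrix, path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        cm.values.to_csv(fh, sep="\t", index_label="id")
    return path


# ---------------------------------------------------------------------------
# GTF (1-based inclusive at the boundary; 0-based half-open internally)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> FeatureAnnotation:
    """Parse transcript/exon GTF records into a :class:`FeatureAnnotation`.

    ``exon_count`` is the number of exon records per transcript and ``length``
    the sum of exon lengths.  The genomic interval is the transcript span
    (union of the transcript record and its exons), converted to 0-based
    half-open coordinates.
    """
    path = Path(path)
    spans: dict[str, list] = {}  # tid -> [chrom, start0, end, strand, biotype]
    exons: dict[str, list[tuple[int, int]]] = {}
    n_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"expected 9 tab fields, got {len(parts)}",
                                 str(path), lineno)
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), lineno) from None
            if end1 < start1:
                raise ParseError(f"end {end1} < start {start1}", str(path), lineno)
            if strand not in "+-.":
                raise ParseError(f"unknown strand {strand!r}", str(path), lineno)
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                if ftype in ("transcript", "exon"):
                    raise ParseError("missing transcript_id", str(path), lineno)
                continue
            biotype = (attr.get("transcript_biotype")
                       or attr.get("gene_biotype") or "")
            start0 = start1 - 1
            if ftype == "transcript":
                spans[tid] = [chrom, start0, end1, strand, biotype]
            elif ftype == "exon":
                exons.setdefault(tid, []).append((start0, end1))
                if tid not in spans:
                    spans[tid] = [chrom, start0, end1, strand, biotype]
                else:
                    spans[tid][1] = min(spans[tid][1], start0)
                    spans[tid][2] = max(spans[tid][2], end1)
    if n_lines == 0:
        logger.warning("empty GTF %s: returning empty annotation", path)
    records = {}
    for tid, (chrom, start0, end1, strand, biotype) in spans.items():
        ex = exons.get(tid, [(start0, end1)])
        records[tid] = (chrom, start0, end1, strand, len(ex),
                        sum(e - s for s, e in ex), biotype)
    table = pd.DataFrame.from_dict(
        records, orient="index", columns=list(FeatureAnnotation.COLUMNS)
    )
    table.index.name = "id"
    if not len(table):
        table = table.astype({"start": "int64", "end": "int64",
                              "exon_count": "int64", "length": "int64"})
    return FeatureAnnotation(table)


def write_gtf(ann: FeatureAnnotation, path, exon_blocks: dict[str, list[tuple[int, int]]] | None = None) -> Path:
    """Write annotation as GTF (1-based inclusive).

    ``exon_blocks`` maps feature id to 0-based half-open exon intervals; when
    absent, each feature's exons are laid out as ``exon_count`` contiguous
    blocks of its spliced length separated by fixed introns inside its span.
    """
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for fid, row in ann.table.iterrows():
            chrom, strand, biotype = row["chrom"], row["strand"], row["biotype"]
            start0, end = int(row["start"]), int(row["end"])
            attrs = (f'gene_id "{fid}"; transcript_id "{fid}"; '
                     f'transcript_biotype "{biotype}";')
            fh.write("\t".join([chrom, "cernet", "transcript", str(start0 + 1),
                                str(end), ".", strand, ".", attrs]) + "\n")
            if exon_blocks and fid in exon_blocks:
                blocks = exon_blocks[fid]
            else:
                blocks = _default_exon_blocks(start0, int(row["length"]),
                                              int(row["exon_count"]))
            for es, ee in blocks:
                fh.write("\t".join([chrom, "cernet", "exon", str(es + 1),
                                    str(ee), ".", strand, ".", attrs]) + "\n")
    return path


def _default_exon_blocks(start0: int, length: int, n_exons: int,
                         intron: int = 100) -> list[tuple[int, int]]:
    sizes = [length // n_exons] * n_exons
    sizes[-1] += length - sum(sizes)
    blocks, pos = [], start0
    for sz in sizes:
        blocks.append((pos, pos + sz))
        pos += sz + intron
    return blocks


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, role: str) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`, uppercasing and mapping T->U."""
    path = Path(path)
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ParseError(f"duplicate FASTA header {rec.id!r}", str(path))
            seq = str(rec.seq).upper().replace("T", "U")
            if not seq:
                raise ParseError(f"zero-length record {rec.id!r}", str(path))
            bad = set(seq) - set("ACGUN")
            if bad:
                raise ParseError(
                    f"illegal characters {sorted(bad)} in record {rec.id!r}",
                    str(path),
                )
            seqs[rec.id] = seq
    try:
        return SequenceSet(seqs, role)
    except ValidationError as exc:  # e.g. miRNA length bounds
        raise ParseError(str(exc), str(path)) from exc


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for fid in seqs:
            fh.write(f">{fid}\n")
            s = seqs[fid]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# sample tables and edge lists
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        st.table.to_csv(fh, sep="\t", index_label="sample")
    return path


EDGE_COLUMNS = ("source", "target", "edge_type", "triplet_id")


def write_edge_list(network, path, collapse_duplicates: bool = True) -> Path:
    """Export a ceRNA network as a TSV edge list.

    Each triplet contributes a lncRNA--miRNA and a miRNA--mRNA edge.  With
    ``collapse_duplicates`` an edge shared by several triplets is written once,
    carrying a comma-joined triplet-id list.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, str]] = []
    for t in network.triplets:
        rows.append((t.lncrna_id, t.mirna_id, "lnc-mir", t.triplet_id))
        rows.append((t.mirna_id, t.mrna_id, "mir-mrna", t.triplet_id))
    if collapse_duplicates:
        merged: dict[tuple[str, str, str], list[str]] = {}
        for s, tg, et, tid in rows:
            merged.setdefault((s, tg, et), []).append(tid)
        rows = [(s, tg, et, ",".join(tids)) for (s, tg, et), tids in merged.items()]
    rows.sort()
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path
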