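"""Readers and writers for the genomic file formats the pipeline touches.

Coordinate conventions
----------------------
All *internal* interval arithmetic uses 0-based half-open coordinates
(BED convention).  GFF3 gene/exon coordinates (1-based inclusive) and
Bismark cytosine-report positions (1-based) are converted on ingestion
and converted back on output.  A :class:`CpGRecord` keeps the 1-based
position of the cytosine, mirroring Bismark's reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CpGRecord",
    "Gene",
    "GenomeAnnotation",
    "Interval",
    "SignalTrack",
    "read_annotation",
    "read_bed",
    "read_bedgraph",
    "read_cytosine_report",
    "write_bed",
    "write_bedgraph",
    "write_cytosine_report",
]


@dataclass(frozen=True)
class CpGRecord:
    """One CpG cytosine with methylated/unmethylated read counts.

    ``pos`` is the 1-based position of the cytosine, as in Bismark
    cytosine reports.  ``coverage`` is the total number of reads
    informative for this site.
    """

    chrom: str
    pos: int
    strand: str
    count_meth: int
    count_unmeth: int
    context: str = "CpG"

    def __post_init__(self) -> None:
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos}"
            )

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class Interval:
    """A BED-style scored interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Step-function coverage signal on one or more chromosomes.

    ``intervals`` maps chromosome name to a list of ``(start, end,
    value)`` tuples in 0-based half-open coordinates, sorted and
    non-overlapping within each chromosome.  Bases not covered by any
    interval have value 0.
    """

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value at a single base (linear scan; test use only)."""
        for start, end, value in self.intervals.get(chrom, []):
            if start <= pos < end:
                return value
        return 0.0


@dataclass(frozen=True)
class Gene:
    """A gene with ordered exons of its longest transcript.

    ``start``/``end`` are the 0-based half-open gene span.  ``exons``
    are 0-based half-open, sorted in genomic order; transcription order
    (E1..En) is genomic order on ``+`` and reversed on ``-``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 < s1:
                out.append((e0, s1))
        return tuple(out)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in transcription order (E1 first)."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def introns_tx_order(self) -> list[tuple[int, int]]:
        return list(self.introns) if self.strand == "+" else list(self.introns[::-1])


class GenomeAnnotation:
    """Chromosome sizes plus gene models derived from a GFF3 file.

    For multi-transcript genes the longest transcript defines the
    ordered exon chain (E1..En); the gene span is the annotated gene
    feature span.
    """

    def __init__(self, chrom_sizes: dict[str, int], genes: Sequence[Gene]):
        self.chrom_sizes = dict(chrom_sizes)
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self._validate(g)
            self.genes[g.gene_id] = g

    def _validate(self, g: Gene) -> None:
        if g.start >= g.end:
            raise ValueError(f"zero-length gene {g.gene_id}")
        prev_end = None
        for s, e in g.exons:
            if s >= e:
                raise ValueError(f"zero-length exon in gene {g.gene_id}")
            if s < g.start or e > g.end:
                raise ValueError(f"exon outside gene span in {g.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in gene {g.gene_id}")
            prev_end = e
        size = self.chrom_sizes.get(g.chrom)
        if size is not None and g.end > size:
            raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def gene_lengths(self) -> dict[str, int]:
        return {gid: g.length for gid, g in self.genes.items()}


# ---------------------------------------------------------------------------
# Bismark cytosine reports
# ---------------------------------------------------------------------------

_CPG_CONTEXTS = {"CG", "CPG"}


def read_cytosine_report(path: str | Path, sample_id: str | None = None) -> list[CpGRecord]:
    """Read a Bismark cytosine report or coverage file.

    The dialect is auto-detected from the column count: 7 columns is the
    per-cytosine report (chrom, 1-based pos, strand, count_meth,
    count_unmeth, context, tricontext), 6 columns is the coverage format
    (chrom, 0-based start, 1-based end, percent, count_meth,
    count_unmeth).  Only CpG-context records are returned; the coverage
    format carries no context column and is taken to be CpG-only, as
    produced by Bismark's default extractor.
    """
    records: list[CpGRecord] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            try:
                if len(fields) == 7:
                    chrom, pos, strand, n_meth, n_unmeth, context, _tri = fields
                    if context.upper().replace("CPG", "CG") not in _CPG_CONTEXTS:
                        continue
                    rec = CpGRecord(chrom, int(pos), strand, int(n_meth), int(n_unmeth))
                elif len(fields) == 6:
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields
                    # coverage format: 0-based start column; cytosine is start+1
                    rec = CpGRecord(chrom, int(start) + 1, ".", int(n_meth), int(n_unmeth))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: unsupported dialect "
                        f"({len(fields)} columns; expected 6 or 7)"
                    )
            except ValueError as exc:
                if "unsupported dialect" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            records.append(rec)
    return records


def write_cytosine_report(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write records in the 7-column Bismark cytosine-report dialect."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_meth}\t"
                f"{r.count_unmeth}\tCG\tCGN\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff_attributes(field_: str) -> dict[str, str]:
    out = {}
    for item in field_.rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    Recognises ``gene``, ``mRNA``/``transcript`` and ``exon`` features.
    Exons attach to their parent transcript; for multi-transcript genes
    the longest transcript (by summed exon length) supplies the ordered
    exon chain.  Chromosome sizes come from ``##sequence-region``
    pragmas when present, else from the right-most feature end.
    """
    chrom_sizes: dict[str, int] = {}
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    tx_parent: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    seen_max: dict[str, int] = {}

    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            if end_i == start_i - 1:
                raise ValueError(f"{path}:{lineno}: zero-length feature")
            seen_max[chrom] = max(seen_max.get(chrom, 0), end_i)
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                gene_rows[gid] = (chrom, start_i - 1, end_i, strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: transcript missing ID/Parent")
                tx_parent[tid] = parent
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: exon without Parent")
                # exons may attach directly to a gene in minimal GFF3s
                tx_exons.setdefault(parent, []).append((start_i - 1, end_i))

    genes: list[Gene] = []
    for gid, (chrom, start, end, strand) in gene_rows.items():
        # collect transcripts of this gene; exons parented to the gene
        # itself form an implicit single transcript
        candidates: list[list[tuple[int, int]]] = []
        if gid in tx_exons:
            candidates.append(sorted(tx_exons[gid]))
        for tid, parent in tx_parent.items():
            if parent == gid and tid in tx_exons:
                candidates.append(sorted(tx_exons[tid]))
        if not candidates:
            candidates.append([(start, end)])  # exonless gene: whole span
        longest = max(candidates, key=lambda exs: sum(e - s for s, e in exs))
        genes.append(Gene(gid, chrom, start, end, strand, tuple(longest)))

    orphans = set(tx_exons) - set(gene_rows) - set(tx_parent)
    if orphans:
        raise ValueError(f"exon Parent(s) {sorted(orphans)} not found in {path}")

    for chrom, m in seen_max.items():
        chrom_sizes.setdefault(chrom, m)
    return GenomeAnnotation(chrom_sizes, genes)


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write a GenomeAnnotation as minimal GFF3 (gene/mRNA/exon)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in ann.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in ann:
            fh.write(
                f"{g.chrom}\tgbmkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tgbmkit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tgbmkit\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={tid}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping intervals on one chromosome are rejected: a step
    function has exactly one value per base.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    track = SignalTrack()
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        prev_end = -1
        ivs = []
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if start < prev_end:
                raise ValueError(
                    f"overlapping bedGraph intervals on {chrom} near {start}"
                )
            if end <= start:
                raise ValueError(f"empty bedGraph interval on {chrom} at {start}")
            ivs.append((int(start), int(end), float(value)))
            prev_end = end
        track.intervals[str(chrom)] = ivs
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.intervals:
            for start, end, value in track.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3/BED6 file into Interval records."""
    out: list[Interval] = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


def write_bed(records: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )
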