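"""Circular-chromosome data model and the oriC-anchored coordinate system.

A bacterial chromosome is modelled as a circle of ``length`` base pairs with
two replication anchors: the origin of replication (*oriC*) and the terminus
(*ter*).  Every position on the circle is described by

* ``d_norm`` — the shorter of the two circular arc distances from *oriC*,
  divided by half the genome size, so that 0 lies at *oriC* and 1 at the point
  diametrically opposite;
* ``replichore`` — ``R`` if the shorter arc runs in the increasing-coordinate
  direction (the "right" arm along the text of the genome sequence), ``L``
  otherwise;
* ``bin`` — one of four equal quarters of the circle: ``O`` is the 25% of the
  chromosome centred on *oriC*; ``R``, ``T`` and ``L`` follow in
  increasing-coordinate order, so the ``T`` quarter contains the point
  antipodal to *oriC* (and *ter* itself whenever the two replichores are of
  equal length).

Bins are anchored on *oriC* only.  When the annotated *ter* is not exactly
antipodal to *oriC*, *ter* may sit slightly off-centre inside the ``T`` bin;
this is reported in output metadata rather than corrected for.

Annotation input is accepted in the NCBI PTT dialect (tab- or
whitespace-separated, ``Location`` as ``a..b``, 1-based inclusive) and as GFF3
CDS features.  Coordinates are 1-based inclusive at the interface; a gene may
wrap the origin of the sequence text (``end < start``) when flagged
``wrapped``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

BINS = ("O", "R", "T", "L")

_LOCATION = re.compile(r"^(\d+)\.\.(\d+)$")


class AnnotationParseError(ValueError):
    """A malformed annotation row; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a circular chromosome (1-based inclusive)."""

    gene_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    cog_class: str | None = None
    product: str | None = None
    wrapped: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1 ({self.gene_id})")
        if self.end < self.start and not self.wrapped:
            raise ValueError(
                f"end < start only allowed for origin-wrapping genes ({self.gene_id})"
            )

    def span(self, genome_length: int) -> int:
        """Gene length in bp on a circle of ``genome_length``."""
        return (self.end - self.start) % genome_length + 1

    def midpoint(self, genome_length: int) -> float:
        """1-based midpoint coordinate on the circle (may be half-integral).

        Wrapping genes are handled by taking the midpoint modulo the genome
        length, so the result always lies in ``(0, genome_length]``.
        """
        half_span = ((self.end - self.start) % genome_length) / 2.0
        mid = (self.start - 1 + half_span) % genome_length + 1
        return mid - genome_length if mid > genome_length else mid


@dataclass(frozen=True)
class ReplichorePosition:
    """Position of a locus in oriC-anchored coordinates."""

    d_norm: float
    replichore: str
    bin: str


def locate(coord: float, oric: float, length: int) -> ReplichorePosition:
    """Map a genomic coordinate to oriC-anchored coordinates.

    ``d_norm`` is the shorter circular arc distance to *oriC* divided by half
    the genome size.  The replichore is ``R`` when the shorter arc runs in the
    increasing-coordinate direction (the exactly antipodal point, a
    probability-zero tie, is assigned to ``R``).  The bin is determined solely
    by the coordinate and *oriC*: ``O`` spans the circular interval
    ``[oriC - length/8, oriC + length/8)`` and ``R``, ``T``, ``L`` follow, each
    a quarter of the circle, in increasing-coordinate order.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 < coord <= length:
        raise ValueError(f"coordinate {coord} outside (0, {length}]")
    if not 0 < oric <= length:
        raise ValueError(f"oriC {oric} outside (0, {length}]")
    cw = (coord - oric) % length
    ccw = (oric - coord) % length
    half = length / 2.0
    if cw <= ccw:
        d_norm, replichore = cw / half, "R"
    else:
        d_norm, replichore = ccw / half, "L"
    shifted = (coord - oric + length / 8.0) % length
    idx = int(shifted // (length / 4.0)) % 4
    return ReplichorePosition(d_norm=min(d_norm, 1.0), replichore=replichore, bin=BINS[idx])


@dataclass
class Genome:
    """A single circular bacterial chromosome with its gene annotation."""

    accession: str
    length: int
    oric: float
    ter: float
    genes: list[GeneRecord] = field(default_factory=list)
    rrna_16s_count: int = 1
    seq_16s: str | None = None
    doubling_time_h: float | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        for anchor, name in ((self.oric, "oriC"), (self.ter, "ter")):
            if not 0 < anchor <= self.length:
                raise ValueError(f"{name} {anchor} outside (0, {self.length}]")
        if self.oric == self.ter:
            raise ValueError("oriC and ter must differ")
        if self.rrna_16s_count < 0:
            raise ValueError("rrna_16s_count must be non-negative")
        if self.doubling_time_h is not None and self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be positive")
        for g in self.genes:
            if g.start > self.length or (not g.wrapped and g.end > self.length):
                raise ValueError(
                    f"gene {g.gene_id} coordinates exceed genome length {self.length}"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.gene_id))

    # -- derived views ---------------------------------------------------

    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def position_of(self, gene: GeneRecord) -> ReplichorePosition:
        """oriC-anchored position of a gene, anchored at its midpoint."""
        return locate(gene.midpoint(self.length), self.oric, self.length)

    def positions_frame(self) -> pd.DataFrame:
        """Per-gene table: midpoint, d_norm, replichore, bin, strand, COG."""
        rows = []
        for g in self.genes:
            pos = self.position_of(g)
            rows.append(
                (g.gene_id, g.midpoint(self.length), pos.d_norm, pos.replichore,
                 pos.bin, g.strand, g.cog_class)
            )
        return pd.DataFrame(
            rows, columns=["gene_id", "mid", "d_norm", "replichore", "bin",
                           "strand", "cog_class"],
        ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _as_text(stream) -> str:
    if hasattr(stream, "read"):
        return stream.read()
    return str(stream)


def _parse_ptt_row(fields: list[str], lineno: int, length: int) -> GeneRecord:
    m = _LOCATION.match(fields[0])
    if m is None:
        raise AnnotationParseError(lineno, f"bad Location field {fields[0]!r}")
    start, end = int(m.group(1)), int(m.group(2))
    strand = fields[1]
    if strand not in ("+", "-"):
        raise AnnotationParseError(lineno, f"bad strand {strand!r}")
    if start > length or end > length:
        raise ValueError(f"line {lineno}: coordinate exceeds genome length {length}")
    pid = fields[3] if fields[3] != "-" else None
    gene_name = fields[4] if len(fields) > 4 and fields[4] != "-" else None
    if len(fields) >= 9:
        # standard 9-column PTT: Location Strand Length PID Gene Synonym Code COG Product
        synonym = fields[5] if fields[5] != "-" else None
        cog_f, product = fields[7], fields[8]
    elif len(fields) == 8:
        # compact 8-column dialect: Location Strand Length PID Gene Code COG Product
        synonym = None
        cog_f, product = fields[6], fields[7]
    else:
        raise AnnotationParseError(lineno, f"expected >= 8 columns, got {len(fields)}")
    # keep the full COG token: NCBI ptt appends the class letter(s) to the
    # numeric id (e.g. "COG0593L"), which downstream enrichment needs
    cog = cog_f if cog_f != "-" else None
    gene_id = synonym or gene_name or pid or f"gene_{lineno}"
    try:
        return GeneRecord(
            gene_id=gene_id, start=start, end=end, strand=strand,
            protein_id=pid, cog_class=cog,
            product=product if product != "-" else None,
            wrapped=end < start,
        )
    except ValueError as exc:
        raise AnnotationParseError(lineno, str(exc)) from exc


def _read_ptt(text: str, length: int) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    seen_rows = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if not _LOCATION.match(fields[0]):
            preamble = not seen_rows and (
                lineno <= 2 or fields[0].lower().startswith("location")
            )
            if preamble:
                continue
            raise AnnotationParseError(lineno, f"unparseable row {line!r}")
        if "\t" not in line and len(fields) > 9:
            # whitespace-separated with spaces inside the product description
            fields = fields[:8] + [" ".join(fields[8:])]
        genes.append(_parse_ptt_row(fields, lineno, length))
        seen_rows = True
    return genes


_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _read_gff3(text: str, length: int) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationParseError(lineno, f"expected 9 columns, got {len(fields)}")
        if fields[2] != "CDS":
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationParseError(lineno, f"bad coordinates {fields[3]}..{fields[4]}") from exc
        strand = fields[6]
        if strand not in ("+", "-"):
            raise AnnotationParseError(lineno, f"bad strand {strand!r}")
        if start > length or end > length:
            raise ValueError(f"line {lineno}: coordinate exceeds genome length {length}")
        attrs = dict(_GFF_ATTR.findall(fields[8]))
        gene_id = (attrs.get("locus_tag") or attrs.get("ID")
                   or attrs.get("protein_id") or f"gene_{lineno}")
        gene_id = gene_id.removeprefix("cds-")
        genes.append(GeneRecord(
            gene_id=gene_id, start=start, end=end, strand=strand,
            protein_id=attrs.get("protein_id"),
            cog_class=attrs.get("cog_class"),
            product=attrs.get("product"),
            wrapped=end < start,
        ))
    return genes


def read_annotation(stream, dialect: str, length: int) -> list[GeneRecord]:
    """Parse a gene annotation stream into :class:`GeneRecord` objects.

    Parameters
    ----------
    stream : str or file-like
        Annotation text in the named dialect.
    dialect : {"ptt", "gff3"}
    length : int
        Genome length in bp; rows with coordinates beyond it are rejected.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    text = _as_text(stream)
    if dialect == "ptt":
        return _read_ptt(text, length)
    if dialect == "gff3":
        return _read_gff3(text, length)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_ptt(genome: Genome, handle=None) -> str:
    """Serialize a genome's genes as a standard 9-column PTT table."""
    buf = io.StringIO()
    buf.write(f"{genome.accession} - 1..{genome.length}\n")
    buf.write(f"{len(genome.genes)} proteins\n")
    buf.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
    for g in genome.genes:
        aa_len = max(g.span(genome.length) // 3 - 1, 1)
        buf.write("\t".join([
            f"{g.start}..{g.end}", g.strand, str(aa_len),
            g.protein_id or "-", "-", g.gene_id, "-",
            g.cog_class or "-", g.product or "-",
        ]) + "\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def write_gff3(genome: Genome, handle=None) -> str:
    """Serialize a genome's genes as GFF3 CDS features (1-based inclusive)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    buf.write(f"##sequence-region {genome.accession} 1 {genome.length}\n")
    for g in genome.genes:
        attrs = [f"ID=cds-{g.gene_id}", f"locus_tag={g.gene_id}"]
        if g.protein_id:
            attrs.append(f"protein_id={g.protein_id}")
        if g.cog_class:
            attrs.append(f"cog_class={g.cog_class}")
        if g.product:
            attrs.append(f"product={g.product}")
        buf.write("\t".join([
            genome.accession, "replichore", "CDS", str(g.start), str(g.end),
            ".", g.strand, "0", ";".join(attrs),
        ]) + "\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# DoriC-style oriC/ter tables
# ---------------------------------------------------------------------------

def interval_midpoint(start: float, end: float, length: int) -> float:
    """Midpoint of a (possibly origin-wrapping) circular interval, 1-based."""
    half_span = ((end - start) % length) / 2.0
    return (start - 1 + half_span) % length + 1


def read_doric(path_or_buf) -> pd.DataFrame:
    """Read a DoriC-style CSV of replication anchors.

    Expected columns: ``accession, oriC_start, oriC_end, ter_start, ter_end``.
    """
    df = pd.read_csv(path_or_buf)
    required = {"accession", "oriC_start", "oriC_end", "ter_start", "ter_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DoriC table missing columns: {sorted(missing)}")
    return df


def anchors_for(doric: pd.DataFrame, accession: str, length: int) -> tuple[float, float]:
    """(oriC, ter) point coordinates for an accession: interval midpoints."""
    rows = doric[doric["accession"] == accession]
    if rows.empty:
        raise KeyError(f"accession {accession!r} not in DoriC table")
    row = rows.iloc[0]
    oric = interval_midpoint(float(row["oriC_start"]), float(row["oriC_end"]), length)
    ter = interval_midpoint(float(row["ter_start"]), float(row["ter_end"]), length)
    return oric, ter
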