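"""Positional function analysis: COG enrichment and HGT depletion per bin.

Gene dosage falls from oriC to ter, so selection sorts functions along the
replication axis: translation/ribosome-biogenesis genes (COG class J)
concentrate near oriC in fast growers, while horizontally acquired genes are
pushed away from it.  Both effects are tested per chromosome quarter
(O, R, T, L) with one-sided Fisher's exact tests — enrichment for COG
classes, depletion for horizontally acquired genes — Bonferroni-corrected
within the genome and reported as -log10(corrected p); values >= 1.3
(p <= 0.05) are significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .genome_model import BINS, Genome

logger = logging.getLogger(__name__)

# The 23 single-letter COG functional categories spanning information
# storage/processing, cellular processes & signaling, and metabolism
# (the poorly characterized R and S classes are not tested).
COG_CLASSES = tuple("JAKLBDYVTMNZWUOCGEFHIPQ")

SIGNIFICANCE_NEGLOG10 = 1.3  # -log10(0.05)

_TINY = 5e-324  # smallest subnormal double; avoids -log10(0)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (bin, category) Fisher test after Bonferroni correction."""

    bin: str
    category: str
    direction: str               # "enriched" or "depleted"
    odds_table: tuple[int, int, int, int]
    p_raw: float
    p_bonferroni: float
    neglog10_p: float

    @property
    def significant(self) -> bool:
        return self.neglog10_p >= SIGNIFICANCE_NEGLOG10


def fisher_one_sided(table: tuple[int, int, int, int], direction: str) -> float:
    """One-sided Fisher's exact p for a 2x2 table (a, b, c, d) given row-wise.

    ``direction`` "enriched" tests for an excess of the top-left cell
    (odds ratio > 1), "depleted" for a deficit.
    """
    a, b, c, d = table
    alternative = "greater" if direction == "enriched" else "less"
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def _result(bin_: str, category: str, direction: str,
            table: tuple[int, int, int, int], n_tests: int) -> EnrichmentResult:
    p_raw = fisher_one_sided(table, direction)
    p_bonf = min(1.0, p_raw * n_tests)
    return EnrichmentResult(
        bin=bin_, category=category, direction=direction, odds_table=table,
        p_raw=p_raw, p_bonferroni=p_bonf,
        neglog10_p=-math.log10(max(p_bonf, _TINY)),
    )


def cog_enrichment(genome: Genome, classes: tuple[str, ...] = COG_CLASSES
                   ) -> list[EnrichmentResult]:
    """Per-bin enrichment of each COG class among COG-annotated genes.

    For each (bin, class) the 2x2 table is [in-bin & in-class, in-bin &
    other-class; out-of-bin & in-class, out-of-bin & other-class] over all
    genes carrying any COG annotation (unannotated genes are excluded).
    One-sided Fisher tests for enrichment, Bonferroni family = 4 bins x the
    full class panel per genome, regardless of which classes are observed.
    """
    letters = []
    bins = []
    for g in genome.genes:
        if g.cog_class is None:
            continue
        # .ptt COG fields may read e.g. "COG0001" or a bare letter; functional
        # class letters follow the numeric id when present ("COG0001J").
        letter = g.cog_class[-1] if g.cog_class[-1].isalpha() else None
        if letter is None:
            continue
        letters.append(letter)
        bins.append(genome.position_of(g).bin)
    if not letters:
        raise ValueError("no COG-annotated genes in genome")
    df = pd.DataFrame({"letter": letters, "bin": bins})
    n_total = len(df)
    n_tests = len(BINS) * len(classes)
    results = []
    for bin_ in BINS:
        in_bin = int((df["bin"] == bin_).sum())
        for cls in classes:
            in_class = int((df["letter"] == cls).sum())
            k = int(((df["bin"] == bin_) & (df["letter"] == cls)).sum())
            table = (k, in_bin - k, in_class - k,
                     n_total - in_bin - (in_class - k))
            results.append(_result(bin_, cls, "enriched", table, n_tests))
    return results


@dataclass
class HgtDepletionOutcome:
    """Depletion results, or an explicit skipped status for ineligible GC."""

    status: str                         # "ok" or "skipped"
    reason: str = ""
    results: list[EnrichmentResult] = field(default_factory=list)


def _in_region(coord: float, start: int, end: int) -> bool:
    if end >= start:
        return start <= coord <= end
    return coord >= start or coord <= end  # origin-wrapping region


def hgt_depletion(genome: Genome, hgt_regions: list[tuple[int, int]],
                  gc_percent: float | None = None,
                  gc_range: tuple[float, float] = (40.0, 60.0)
                  ) -> HgtDepletionOutcome:
    """Per-bin depletion of horizontally acquired genes.

    ``hgt_regions`` are 1-based inclusive intervals of predicted horizontally
    acquired sequence (e.g. from a compositional scanner, supplied as input);
    a gene counts as horizontally acquired when its midpoint lies in any
    region.  Compositional HGT prediction is only reliable for genomes with
    GC content in [40, 60]%, so a genome outside that window (when
    ``gc_percent`` is supplied) is skipped with an explicit status.  One
    one-sided depletion Fisher test per bin, Bonferroni family of 4.
    """
    if gc_percent is not None and not gc_range[0] <= gc_percent <= gc_range[1]:
        reason = (f"GC content {gc_percent:.1f}% outside "
                  f"[{gc_range[0]:g}, {gc_range[1]:g}]%")
        logger.info("HGT depletion skipped for %s: %s", genome.accession, reason)
        return HgtDepletionOutcome(status="skipped", reason=reason)
    if not hgt_regions:
        raise ValueError("hgt_regions must be nonempty")
    for start, end in hgt_regions:
        if start < 1 or end < 1 or start > genome.length or end > genome.length:
            raise ValueError(f"malformed HGT interval ({start}, {end})")
    rows = []
    for g in genome.genes:
        mid = g.midpoint(genome.length)
        is_hgt = any(_in_region(mid, s, e) for s, e in hgt_regions)
        rows.append((genome.position_of(g).bin, is_hgt))
    df = pd.DataFrame(rows, columns=["bin", "hgt"])
    n_total = len(df)
    n_hgt = int(df["hgt"].sum())
    results = []
    for bin_ in BINS:
        in_bin = int((df["bin"] == bin_).sum())
        k = int(((df["bin"] == bin_) & df["hgt"]).sum())
        table = (k, in_bin - k, n_hgt - k, n_total - in_bin - (n_hgt - k))
        results.append(_result(bin_, "HGT", "depleted", table, len(BINS)))
    return HgtDepletionOutcome(status="ok", results=results)


def read_bed_regions(path_or_buf) -> list[tuple[int, int]]:
    """Read BED-like 3-column TSV (0-based half-open) as 1-based inclusive."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    regions = []
    for _, row in df.iterrows():
        start0, end0 = int(row["start"]), int(row["end"])
        if end0 <= start0 or start0 < 0:
            raise ValueError(f"malformed BED interval [{start0}, {end0})")
        regions.append((start0 + 1, end0))
    return regions


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        a, b, c, d = r.odds_table
        rows.append((r.bin, r.category, r.direction, a, b, c, d,
                     r.p_raw, r.p_bonferroni, r.neglog10_p, r.significant))
    return pd.DataFrame(rows, columns=[
        "bin", "category", "direction", "n11", "n12", "n21", "n22",
        "p_raw", "p_bonferroni", "neglog10_p", "significant",
    ])
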