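"""Pairwise genome comparison: 16S identity, BBH orthology, pair selection.

Orthologs between two genomes are defined operationally as bidirectional best
hits (BBH): protein ``a`` and ``b`` are paired iff ``b`` is the best-scoring
hit of ``a`` against the partner proteome, ``a`` is the best hit of ``b`` in
the reverse search, and both directions pass the E-value cutoff (default
1e-10).  The similarity backend is pluggable: the default is a deterministic
global protein alignment scorer (BLOSUM62) with a monotone score-to-pseudo-
E-value map; an adapter for a phmmer-compatible HMMER search (via pyhmmer) is
provided for real proteomes.

Genome pairs enter the comparative analysis only when they show >= 97% global
16S rRNA identity, carry the same number of 16S rRNA genes (a growth-rate
proxy), are not strains of one species, and both exceed 1.3 Mb (excluding
obligate parasites with unusually stable reduced genomes).  Redundant pairs
are pruned to one per unordered species pair, deterministically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import Genome

logger = logging.getLogger(__name__)

_NT = "ACGTN"
_NEG = -1.0e30


def _validate_nt(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    s = seq.upper()
    bad = set(s) - set(_NT)
    if bad:
        raise ValueError(f"{label}: non-nucleotide symbols {sorted(bad)}")
    return s


def _half_units(value: float, name: str) -> int:
    doubled = value * 2.0
    if doubled != round(doubled):
        raise ValueError(f"{name} must be a multiple of 0.5, got {value}")
    return int(round(doubled))


def nw_stats(seq_a: str, seq_b: str, gap_open: float = 10.0,
             gap_extend: float = 0.5, match: float = 5.0,
             mismatch: float = -4.0, n_score: float = -2.0
             ) -> tuple[float, int, int]:
    """(score, matches, columns) of the optimal NW global alignment.

    Full global alignment with affine gaps — a gap of length g costs
    ``gap_open + gap_extend * g`` — and penalized end gaps.  Among co-optimal
    alignments the one with the most matched columns is reported, and among
    those the shortest, so the result is a canonical function of the inputs
    rather than of any traceback order.  This is achieved by running the DP
    on the packed integer objective ``2*score*A + matches*B - columns`` with
    ``B > columns_max`` and ``A > matches_max*B + columns_max``: distinct
    scores differ by at least 0.5 (all scoring parameters are required to be
    multiples of 0.5), so the packing is a strict lexicographic order and
    every quantity stays an exact integer in float64.

    ``N`` pairs with everything at ``n_score`` and never counts as a match.
    """
    a = _validate_nt(seq_a, "seq_a")
    b = _validate_nt(seq_b, "seq_b")
    n, m = len(a), len(b)
    B = n + m + 1
    A = (min(n, m) + 1) * B
    if 20 * A * B > 2 ** 52:
        raise ValueError("sequences too long for exact packed alignment DP")
    match2 = _half_units(match, "match")
    mismatch2 = _half_units(mismatch, "mismatch")
    nscore2 = _half_units(n_score, "n_score")
    open2 = _half_units(gap_open, "gap_open")
    ext2 = _half_units(gap_extend, "gap_extend")

    code = {c: i for i, c in enumerate(_NT)}
    # packed per-column contributions
    csub = np.full((5, 5), mismatch2 * A - 1.0)
    np.fill_diagonal(csub, match2 * A + B - 1.0)
    csub[4, :] = nscore2 * A - 1.0
    csub[:, 4] = nscore2 * A - 1.0
    gap_first = -(open2 + ext2) * A - 1.0   # first column of a gap
    gap_next = -ext2 * A - 1.0              # each further column
    ai = np.fromiter((code[c] for c in a), dtype=np.intp, count=n)
    bi = np.fromiter((code[c] for c in b), dtype=np.intp, count=m)

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a; vertical)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b; horizontal)
    M[0, 0] = 0.0
    X[1:, 0] = gap_first + gap_next * np.arange(n)
    Y[0, 1:] = gap_first + gap_next * np.arange(m)
    cols = np.arange(m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + csub[ai[i - 1], bi]
        X[i, 1:] = np.maximum(best_prev[1:] + gap_first, X[i - 1, 1:] + gap_next)
        # horizontal gaps within the row: running-max reformulation of
        # Y[i,j] = max_{k<j} (max(M[i,k], X[i,k]) + gap_first + (j-1-k)*gap_next)
        c = np.maximum(M[i], X[i])
        running = np.maximum.accumulate(c - gap_next * cols)
        Y[i, 1:] = running[:-1] + gap_first + gap_next * (cols[1:] - 1)

    packed = int(max(M[n, m], X[n, m], Y[n, m]))
    q, r = divmod(packed, A)
    if r > min(n, m) * B:  # true matches*B - columns term is negative
        r -= A
        q += 1
    matches = r // B + 1
    columns = matches * B - r
    return q / 2.0, int(matches), int(columns)


def nw_identity(seq_a: str, seq_b: str, gap_open: float = 10.0,
                gap_extend: float = 0.5, match: float = 5.0,
                mismatch: float = -4.0, n_score: float = -2.0) -> float:
    """Percent identity, 100 * matches / alignment length, of the optimal
    Needleman-Wunsch global alignment (see :func:`nw_stats`)."""
    _, matches, columns = nw_stats(seq_a, seq_b, gap_open=gap_open,
                                   gap_extend=gap_extend, match=match,
                                   mismatch=mismatch, n_score=n_score)
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# Similarity backends for BBH
# ---------------------------------------------------------------------------

class ProteinAlignmentScorer:
    """Deterministic global protein aligner used as the default BBH backend.

    Scores are BLOSUM62 global alignment scores (affine gaps -11/-1 via
    Bio.Align.PairwiseAligner).  The pseudo E-value ``m * n * 2**(-score)``
    is a strictly decreasing function of the score at fixed lengths, which is
    all the BBH contract requires of it; it is not a statistical E-value.
    """

    def __init__(self, open_gap_score: float = -11.0, extend_gap_score: float = -1.0):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = open_gap_score
        aligner.extend_gap_score = extend_gap_score
        self._aligner = aligner

    @staticmethod
    def _pseudo_evalue(score: float, m: int, n: int) -> float:
        log10_e = math.log10(m) + math.log10(n) - score * math.log10(2.0)
        if log10_e > 300.0:
            return math.inf
        return 10.0 ** log10_e

    def search(self, queries: dict[str, str], targets: dict[str, str]
               ) -> dict[tuple[str, str], tuple[float, float]]:
        out = {}
        for qid, q in queries.items():
            for tid, t in targets.items():
                s = float(self._aligner.score(q, t))
                out[(qid, tid)] = (s, self._pseudo_evalue(s, len(q), len(t)))
        return out


class PhmmerScorer:
    """Adapter running a phmmer-compatible all-vs-all search via pyhmmer."""

    def __init__(self, cpus: int = 1):
        self.cpus = cpus

    def search(self, queries: dict[str, str], targets: dict[str, str]
               ) -> dict[tuple[str, str], tuple[float, float]]:
        import pyhmmer

        alphabet = pyhmmer.easel.Alphabet.amino()
        qseqs = [pyhmmer.easel.TextSequence(name=qid.encode(), sequence=seq).digitize(alphabet)
                 for qid, seq in queries.items()]
        tseqs = [pyhmmer.easel.TextSequence(name=tid.encode(), sequence=seq).digitize(alphabet)
                 for tid, seq in targets.items()]
        def _name(x) -> str:
            return x.decode() if isinstance(x, bytes) else str(x)

        out: dict[tuple[str, str], tuple[float, float]] = {}
        for top_hits in pyhmmer.hmmer.phmmer(qseqs, tseqs, cpus=self.cpus):
            qname = _name(top_hits.query.name)
            for hit in top_hits:
                out[(qname, _name(hit.name))] = (float(hit.score), float(hit.evalue))
        return out


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float = 0.0
    evalue: float | None = None


@dataclass
class OrthologMap:
    """One-to-one ortholog pairing between two genomes.

    ``to_frame`` annotates every pair with oriC-anchored positions in both
    genomes, plus the leading/lagging status of each gene.  A gene is on the
    leading strand when its transcription is co-directional with replication
    fork movement on its replichore: ``+`` on replichore R or ``-`` on L.
    """

    pairs: list[OrthologPair]
    genome_a: Genome | None = None
    genome_b: Genome | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        if self.genome_a is None or self.genome_b is None:
            raise ValueError("positional annotation requires both genome references")
        idx_a = self.genome_a.gene_index()
        idx_b = self.genome_b.gene_index()
        rows = []
        for p in self.pairs:
            ga, gb = idx_a[p.gene_a], idx_b[p.gene_b]
            pa = self.genome_a.position_of(ga)
            pb = self.genome_b.position_of(gb)
            lead_a = (ga.strand == "+") == (pa.replichore == "R")
            lead_b = (gb.strand == "+") == (pb.replichore == "R")
            rows.append((
                p.gene_a, p.gene_b,
                ga.midpoint(self.genome_a.length), gb.midpoint(self.genome_b.length),
                pa.d_norm, pb.d_norm, pa.replichore, pb.replichore,
                pa.bin, pb.bin, ga.strand, gb.strand, lead_a, lead_b,
            ))
        return pd.DataFrame(rows, columns=[
            "gene_a", "gene_b", "mid_a", "mid_b", "d_a", "d_b",
            "repl_a", "repl_b", "bin_a", "bin_b", "strand_a", "strand_b",
            "lead_a", "lead_b",
        ])

    def to_tsv(self, handle) -> None:
        pd.DataFrame(
            [(p.gene_a, p.gene_b, p.score, p.evalue) for p in self.pairs],
            columns=["gene_a", "gene_b", "score", "evalue"],
        ).to_csv(handle, sep="\t", index=False)


def _best_per_query(hits: dict[tuple[str, str], tuple[float, float]]
                    ) -> dict[str, tuple[str, float, float]]:
    best: dict[str, tuple[str, float, float]] = {}
    for (qid, tid), (score, evalue) in hits.items():
        cur = best.get(qid)
        # ties on best score broken by lexicographically smallest target id
        if cur is None or score > cur[1] or (score == cur[1] and tid < cur[0]):
            best[qid] = (tid, score, evalue)
    return best


def best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
              scorer=None, evalue_cutoff: float = 1e-10,
              genome_a: Genome | None = None, genome_b: Genome | None = None,
              ) -> OrthologMap:
    """Bidirectional-best-hit ortholog mapping between two proteomes.

    A pair ``(a, b)`` is retained iff ``b`` is ``a``'s best hit, ``a`` is
    ``b``'s best hit, and both directions pass ``evalue_cutoff``.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be nonempty")
    scorer = scorer if scorer is not None else ProteinAlignmentScorer()
    fwd = _best_per_query(scorer.search(proteome_a, proteome_b))
    rev = _best_per_query(scorer.search(proteome_b, proteome_a))
    pairs = []
    for aid in sorted(fwd):
        bid, score, evalue = fwd[aid]
        back = rev.get(bid)
        if back is None or back[0] != aid:
            continue
        if evalue > evalue_cutoff or back[2] > evalue_cutoff:
            continue
        pairs.append(OrthologPair(gene_a=aid, gene_b=bid, score=score, evalue=evalue))
    return OrthologMap(pairs=pairs, genome_a=genome_a, genome_b=genome_b)


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSummary:
    """Per-genome metadata needed for pair selection."""

    accession: str
    organism: str
    length: int
    rrna_16s_count: int
    seq_16s: str | None = None


@dataclass
class PairSelection:
    """Audit record for one candidate genome pair."""

    accession_a: str
    accession_b: str
    identity_16s: float | None = None
    same_copy_number: bool = False
    min_genome_size_ok: bool = False
    same_species_strains: bool = False
    accepted: bool = False
    reason: str = ""


def _species_token(organism: str) -> str:
    parts = organism.split()
    return " ".join(parts[:2]).lower()


def select_pairs(summaries: list[GenomeSummary],
                 identity_threshold: float = 97.0,
                 min_genome_size: int = 1_300_000) -> list[PairSelection]:
    """Score all unordered genome pairs against the study's selection filters.

    Acceptance requires 16S identity >= ``identity_threshold``, equal 16S
    copy number, both genomes >= ``min_genome_size`` bp, and distinct
    species.  Among accepted pairs, one pair is kept per unordered species
    pair: the lexicographically smallest accession pair (a deterministic
    stand-in for random pruning of redundant pairs).
    """
    ordered = sorted(summaries, key=lambda s: s.accession)
    audits: list[PairSelection] = []
    for i, sa in enumerate(ordered):
        for sb in ordered[i + 1:]:
            audit = PairSelection(accession_a=sa.accession, accession_b=sb.accession)
            if sa.seq_16s is None or sb.seq_16s is None:
                logger.warning("pair (%s, %s) skipped: missing 16S sequence",
                               sa.accession, sb.accession)
                audit.reason = "missing 16S sequence"
                audits.append(audit)
                continue
            audit.identity_16s = nw_identity(sa.seq_16s, sb.seq_16s)
            audit.same_copy_number = sa.rrna_16s_count == sb.rrna_16s_count
            audit.min_genome_size_ok = (sa.length >= min_genome_size
                                        and sb.length >= min_genome_size)
            audit.same_species_strains = (_species_token(sa.organism)
                                          == _species_token(sb.organism))
            if audit.identity_16s < identity_threshold:
                audit.reason = "16S identity below threshold"
            elif not audit.same_copy_number:
                audit.reason = "different 16S copy number"
            elif not audit.min_genome_size_ok:
                audit.reason = "genome below minimum size"
            elif audit.same_species_strains:
                audit.reason = "strains of the same species"
            else:
                audit.accepted = True
            audits.append(audit)

    # redundancy pruning: one accepted pair per unordered species pair
    by_org = {s.accession: s.organism for s in summaries}
    kept: dict[tuple[str, str], PairSelection] = {}
    for audit in audits:
        if not audit.accepted:
            continue
        key = tuple(sorted((_species_token(by_org[audit.accession_a]),
                            _species_token(by_org[audit.accession_b]))))
        cur = kept.get(key)
        if cur is None or ((audit.accession_a, audit.accession_b)
                           < (cur.accession_a, cur.accession_b)):
            if cur is not None:
                cur.accepted = False
                cur.reason = "redundant species pair"
            kept[key] = audit
        else:
            audit.accepted = False
            audit.reason = "redundant species pair"
    return audits


def selection_frame(audits: list[PairSelection]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in audits])
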