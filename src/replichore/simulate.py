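"""Synthetic genome pairs with known rearrangement ground truth.

The generator builds a circular ancestor genome and derives a partner from it
by the event classes the topology analysis is designed to detect:

* *symmetric interreplichore translocations*: a fraction ``f`` of the genes in
  the L and R bins relocate to the mirrored position on the opposite
  replichore, plus Gaussian noise ``sigma`` (in normalized-distance units)
  controlling the departure from perfect symmetry;
* *oriC/ter-local inversions*: genes in the O and T bins flip across the
  oriC-ter axis at a separate rate, reproducing the known inversion hotspots
  adjacent to the replication anchors;
* *strand handling*: a translocated gene keeps its leading-strand status with
  probability ``p_s`` (locally inverted genes keep it automatically, since an
  inversion flips strand and replichore together);
* *ortholog loss*: a fraction ``q`` of genes has no ortholog in the partner.

Every run emits the true per-gene event labels, the true ortholog map and
the realized positions, so each downstream statistic can be checked against
ground truth.  Sequence divergence is mild per-site substitution, keeping
BBH ortholog recovery essentially perfect at the default E-value cutoff so
that orthology errors are not confounded with topology statistics.

Contact matrices are simulated as a power-law distance decay plus, for a
longitudinal topology, an anti-diagonal band linking loci equidistant from
oriC, with multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import Genome, GeneRecord, locate
from .orthology import OrthologMap, OrthologPair

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

# default COG-class weights: roughly realistic relative frequencies with the
# translation class J boosted near oriC at draw time; ~15% of genes carry no
# COG annotation
_COG_WEIGHTS = {
    "J": 4, "A": 1, "K": 5, "L": 4, "B": 1, "D": 1, "Y": 1, "V": 1, "T": 3,
    "M": 4, "N": 1, "Z": 1, "W": 1, "U": 1, "O": 3, "C": 4, "G": 4, "E": 6,
    "F": 2, "H": 3, "I": 2, "P": 3, "Q": 2, None: 9,
}


@dataclass(frozen=True)
class EvolutionParams:
    """Event rates relating a genome pair.

    Defaults describe a longitudinal-topology pair: crossing fraction at the
    0.45 median observed for high-translocation pairs, near-symmetric
    relocation (sigma = 0.02), strong leading-strand preservation, and ~28%
    ortholog loss (the median conservation between closely related pairs is
    about 72%).
    """

    n_genes: int = 2000
    genome_length: int = 2_000_000
    crossing_fraction: float = 0.45
    symmetry_sd: float = 0.02
    strand_preservation: float = 0.9
    ortholog_loss: float = 0.28
    ot_inversion_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("crossing_fraction", "strand_preservation",
                     "ortholog_loss", "ot_inversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.symmetry_sd < 0:
            raise ValueError("symmetry_sd must be >= 0")
        if self.n_genes < 8:
            raise ValueError("n_genes must be >= 8")
        if self.genome_length < self.n_genes * 300:
            raise ValueError("genome_length must be >= n_genes * 300")


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _mutate(rng: np.random.Generator, seq: str, alphabet: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = np.array(list(alphabet))[rng.integers(0, len(alphabet), int(hit.sum()))]
    return "".join(arr)


def generate_genome(n_genes: int = 2000, genome_length: int = 2_000_000,
                    seed: int = 0, leading_strand_bias: float = 0.75,
                    cog_weights: dict | None = None,
                    with_sequences: bool = True, accession: str = "SYN001",
                    rrna_16s_count: int = 7,
                    doubling_time_h: float | None = None,
                    ) -> tuple[Genome, dict[str, str] | None]:
    """Build a random circular genome with oriC/ter antipodal by default.

    Genes are laid out without overlap, one per equal-width slot around the
    circle.  Strand is drawn with ``leading_strand_bias`` (the probability of
    a gene sitting on the leading strand of its replichore, defaulting to the
    realistic ~75% majority).  COG classes follow ``cog_weights`` with the
    translation class J four-fold concentrated in the oriC quarter.  Returns
    the genome and, when ``with_sequences``, a random seeded proteome.
    """
    if n_genes < 8:
        raise ValueError("n_genes must be >= 8")
    if genome_length < n_genes * 300:
        raise ValueError(f"cannot pack {n_genes} genes into {genome_length} bp")
    if not 0.0 <= leading_strand_bias <= 1.0:
        raise ValueError("leading_strand_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    oric = float(genome_length)
    ter = genome_length / 2.0
    slot = genome_length / n_genes
    starts = (np.floor(np.arange(n_genes) * slot) + 1).astype(int)
    max_len = max(int(slot * 0.8), 93)
    lengths = rng.integers(max(90, int(slot * 0.3)), max_len + 1, n_genes)
    lengths = lengths - lengths % 3  # whole codons

    weights = dict(_COG_WEIGHTS if cog_weights is None else cog_weights)
    classes = list(weights)
    base_w = np.array([weights[c] for c in classes], dtype=float)
    near_w = base_w.copy()
    if "J" in classes:
        near_w[classes.index("J")] *= 4.0

    genes = []
    proteome: dict[str, str] | None = {} if with_sequences else None
    for i in range(n_genes):
        start = int(starts[i])
        end = int(start + lengths[i] - 1)
        pos = locate((start + end) / 2.0, oric, genome_length)
        lead = rng.random() < leading_strand_bias
        strand = "+" if lead == (pos.replichore == "R") else "-"
        w = near_w if pos.d_norm < 0.25 else base_w
        cog = rng.choice(classes, p=w / w.sum())
        gene_id = f"{accession}_{i:05d}"
        protein_id = f"P{i:05d}"
        genes.append(GeneRecord(
            gene_id=gene_id, start=start, end=end, strand=strand,
            protein_id=protein_id,
            cog_class=f"COG{i % 4000:04d}{cog}" if cog is not None else None,
        ))
        if proteome is not None:
            proteome[gene_id] = _random_seq(rng, AA20, max(int(lengths[i]) // 3 - 1, 20))
    genome = Genome(
        accession=accession, length=genome_length, oric=oric, ter=ter,
        genes=genes, rrna_16s_count=rrna_16s_count,
        seq_16s=_random_seq(rng, NT4, 1542),
        doubling_time_h=doubling_time_h,
    )
    return genome, proteome


@dataclass
class EvolvedPair:
    """A derived partner genome plus full ground truth."""

    genome_b: Genome
    ortholog_map: OrthologMap
    truth: pd.DataFrame
    proteome_b: dict[str, str] | None = None
    params: EvolutionParams | None = None


def evolve_pair(genome: Genome, params: EvolutionParams,
                proteome: dict[str, str] | None = None,
                protein_divergence: float = 0.02,
                rrna_divergence: float = 0.01) -> EvolvedPair:
    """Derive a partner genome by translocation/inversion/loss events.

    See the module docstring for the event model.  The returned truth table
    records, per ancestor gene, the event label (conserved, translocated,
    inverted_local, lost) and the realized positions and leading-strand flip
    status in both genomes; the ortholog map is the true gene correspondence.
    """
    rng = np.random.default_rng(params.seed)
    n = len(genome.genes)
    length = genome.length
    half = length / 2.0

    mids = np.array([g.midpoint(length) for g in genome.genes])
    pos = [locate(m, genome.oric, length) for m in mids]
    d_a = np.array([p.d_norm for p in pos])
    repl_a = np.array([p.replichore for p in pos])
    bins_a = np.array([p.bin for p in pos])
    strands = np.array([g.strand for g in genome.genes])
    lead_a = (strands == "+") == (repl_a == "R")

    lost = rng.random(n) < params.ortholog_loss
    in_lr = np.isin(bins_a, ("L", "R"))
    trans = ~lost & in_lr & (rng.random(n) < params.crossing_fraction)
    inv = ~lost & ~in_lr & (rng.random(n) < params.ot_inversion_rate)
    conserved = ~lost & ~trans & ~inv

    labels = np.where(lost, "lost",
                      np.where(trans, "translocated",
                               np.where(inv, "inverted_local", "conserved")))

    surviving = ~lost
    for b in ("O", "R", "T", "L"):
        b_mask = bins_a == b
        if b_mask.any() and not (b_mask & surviving).any():
            raise ValueError(
                f"loss and crossing rates jointly exhausted bin {b}; "
                "no orthologs left to compare"
            )

    noise = rng.normal(0.0, params.symmetry_sd, n) if params.symmetry_sd > 0 else np.zeros(n)
    d_t = d_a.copy()
    repl_t = repl_a.copy()
    moved = trans | inv
    d_t[moved] = np.clip(d_a[moved] + noise[moved], 0.0, 1.0)
    # a translocated L/R gene stays an L/R-bin gene: fold the symmetry noise
    # back at the quarter boundaries (preserves |noise| while keeping the
    # crossing fraction identical to the bin-to-bin rate it parameterizes)
    folded = (d_a[trans] + noise[trans] - 0.25) % 1.0
    d_t[trans] = 0.25 + np.where(folded <= 0.5, folded, 1.0 - folded)
    repl_t[moved] = np.where(repl_a[moved] == "R", "L", "R")

    lead_t = lead_a.copy()
    keep = rng.random(n) < params.strand_preservation
    lead_t[trans & ~keep] = ~lead_a[trans & ~keep]
    # local inversions flip strand and replichore together: leading preserved

    # target coordinate on the circle, then a non-overlapping layout anchored
    # at each gene's own target: genes are swept in circular order starting
    # after the widest target gap, and only nudged forward on collision, so
    # positional error stays local (a gene length or so) instead of drifting
    sign = np.where(repl_t == "R", 1.0, -1.0)
    coord_t = (genome.oric + sign * d_t * half) % length
    idx_surv = np.flatnonzero(surviving)
    order = idx_surv[np.argsort(coord_t[idx_surv], kind="stable")]
    m = len(order)
    max_len = max(int(0.8 * length / m), 93)
    targets = coord_t[order]
    lens = np.array([min(genome.genes[gi].span(length), max_len)
                     for gi in order])
    gaps = np.diff(np.concatenate([targets, [targets[0] + length]]))
    sweep = np.roll(np.arange(m), -(int(np.argmax(gaps)) + 1))
    starts_real = np.empty(m)
    cursor = -np.inf
    for k in sweep:
        want = targets[k] - lens[k] / 2.0
        if targets[k] < targets[sweep[0]]:
            want += length  # past the seam: unwrap to keep the sweep monotone
        s = max(want, cursor)
        starts_real[k] = s
        cursor = s + lens[k] + 1
    if cursor - starts_real[sweep[0]] > length:
        raise ValueError("cannot lay out partner genome without overlap")

    genes_b = []
    proteome_b: dict[str, str] | None = {} if proteome is not None else None
    d_b = np.full(n, np.nan)
    repl_b_arr = np.array([""] * n, dtype=object)
    lead_b_arr = np.zeros(n, dtype=bool)
    for rank, gi in enumerate(order):
        src = genome.genes[gi]
        glen = int(lens[rank])
        start = int(starts_real[rank] % length) + 1
        end_raw = start + glen - 1
        wrapped = end_raw > length
        end = end_raw - length if wrapped else end_raw
        mid = (start - 1 + (glen - 1) / 2.0) % length + 1
        p_real = locate(mid - length if mid > length else mid,
                        genome.oric, length)
        # strand chosen so the realized leading status equals the target
        strand = "+" if lead_t[gi] == (p_real.replichore == "R") else "-"
        genes_b.append(GeneRecord(
            gene_id=src.gene_id, start=start, end=end, strand=strand,
            protein_id=src.protein_id, cog_class=src.cog_class,
            product=src.product, wrapped=wrapped,
        ))
        d_b[gi] = p_real.d_norm
        repl_b_arr[gi] = p_real.replichore
        lead_b_arr[gi] = lead_t[gi]
        if proteome_b is not None:
            proteome_b[src.gene_id] = _mutate(rng, proteome[src.gene_id],
                                              AA20, protein_divergence)

    genome_b = Genome(
        accession=f"{genome.accession}_p", length=length,
        oric=genome.oric, ter=genome.ter, genes=genes_b,
        rrna_16s_count=genome.rrna_16s_count,
        seq_16s=(_mutate(rng, genome.seq_16s, NT4, rrna_divergence)
                 if genome.seq_16s else None),
        doubling_time_h=genome.doubling_time_h,
    )
    omap = OrthologMap(
        pairs=[OrthologPair(gene_a=genome.genes[gi].gene_id,
                            gene_b=genome.genes[gi].gene_id)
               for gi in sorted(order)],
        genome_a=genome, genome_b=genome_b,
    )
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genome.genes],
        "label": labels,
        "d_a": d_a,
        "d_b": d_b,
        "repl_a": repl_a,
        "repl_b": [r if r else None for r in repl_b_arr],
        "flip": np.where(surviving, lead_a != lead_b_arr, False),
    })
    return EvolvedPair(genome_b=genome_b, ortholog_map=omap, truth=truth,
                       proteome_b=proteome_b, params=params)


def synth_contact_map(genome: Genome, topology: str, bin_size: float,
                      decay_exponent: float = 1.0, band_strength: float = 3.0,
                      noise_sd: float = 0.15, seed: int = 0) -> np.ndarray:
    """Simulate a normalized chromosome contact matrix.

    Contacts decay as ``(1 + s)**-decay_exponent`` with circular bin
    separation ``s``.  In ``longitudinal`` mode, cells linking loci
    equidistant from oriC on opposite replichores (the anti-diagonal through
    oriC) are amplified by ``1 + band_strength`` with a one-bin Gaussian
    profile, emulating the symmetric interreplichore contacts of a
    longitudinally arranged chromosome.  Multiplicative log-normal noise is
    applied symmetrically; the output is exactly symmetric.
    """
    if topology not in ("transverse", "longitudinal"):
        raise ValueError(f"unknown topology {topology!r}")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    n = round(genome.length / bin_size)
    if n < 4 or abs(n * bin_size - genome.length) > bin_size:
        raise ValueError("bin size does not tile the genome within one bin")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    sep = np.abs(i[:, None] - i[None, :])
    sep = np.minimum(sep, n - sep)
    mat = (1.0 + sep) ** (-decay_exponent)
    if topology == "longitudinal" and band_strength > 0:
        mids = (i + 0.5) * bin_size
        t = (mids[:, None] + mids[None, :] - 2.0 * genome.oric) % genome.length
        delta = np.minimum(t, genome.length - t) / bin_size
        mat = mat * (1.0 + band_strength * np.exp(-0.5 * delta ** 2))
    if noise_sd > 0:
        z = rng.normal(0.0, 1.0, (n, n))
        mat = mat * np.exp(noise_sd * (z + z.T) / np.sqrt(2.0))
    return mat
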