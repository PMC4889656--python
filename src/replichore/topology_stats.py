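"""Topology inference statistics from an ortholog map.

Given a one-to-one ortholog map between two closely related genomes, this
module computes the statistics that summarise how gene positions moved
between the two chromosomes, and calls a gross chromosome topology from
them:

* gene-order conservation (rho_GOC): rank correlation between the two
  oriC-anchored position vectors of the orthologs;
* bin-wise conservation/translocation rates over the four chromosome
  quarters O, R, T, L (P_i on the diagonal, T_i-j off it);
* the interreplichore translocation rate T_L-R/R-L, restricted to the L and
  R bins so that the inversion-prone neighbourhoods of oriC and ter do not
  inflate it;
* the per-pair interreplichore symmetry statistic D_inter = |d_A - d_B| and
  leading/lagging strand flips, with seeded randomized nulls;
* the topology call itself: a pair with T_L-R/R-L above 0.1 is labelled
  longitudinal (replichores spatially close, Caulobacter-like), otherwise
  transverse (E. coli-like);
* enrichment of chromosome contact frequencies at translocated
  interreplichore locus pairs, and the expression-symmetry comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import BINS, Genome, locate

_BIN_IDX = {b: i for i, b in enumerate(BINS)}


class InsufficientData(ValueError):
    """Raised when a statistic is undefined for the given input size."""


def _frame(omap) -> pd.DataFrame:
    """Accept an OrthologMap or a pre-annotated pair DataFrame."""
    if isinstance(omap, pd.DataFrame):
        return omap
    return omap.to_frame()


# ---------------------------------------------------------------------------
# Gene-order conservation and its phylogenetic-distance correction
# ---------------------------------------------------------------------------

def gene_order_conservation(omap, method: str = "spearman") -> float:
    """Correlation between the two oriC-distance vectors of the orthologs.

    Spearman by default (configurable to Pearson).  Positions equidistant
    from oriC on either replichore are equivalent here: the statistic sees
    only d_norm, not the replichore.
    """
    df = _frame(omap)
    if len(df) < 3:
        raise InsufficientData("gene order conservation needs >= 3 ortholog pairs")
    if method == "spearman":
        return float(stats.spearmanr(df["d_a"], df["d_b"]).statistic)
    if method == "pearson":
        return float(stats.pearsonr(df["d_a"], df["d_b"]).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def loess_residual(y, identity_16s, span: float = 0.75) -> np.ndarray:
    """Residuals of a LOESS fit of ``y`` against 16S identity.

    Removes the component of a gene-organization statistic explained by
    phylogenetic distance.  Residuals are observed minus predicted, so a
    positive residual means more conservation than expected at that
    phylogenetic distance.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    y = np.asarray(y, dtype=float)
    x = np.asarray(identity_16s, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and identity_16s must be equal-length 1-D vectors")
    if len(y) < 10:
        raise InsufficientData("LOESS correction needs >= 10 points")
    if np.ptp(x) == 0:
        raise ValueError(
            "degenerate predictor: all 16S identities equal; use raw y instead"
        )
    fitted = lowess(y, x, frac=span, return_sorted=False)
    return y - fitted


# ---------------------------------------------------------------------------
# Bin-wise conservation / translocation
# ---------------------------------------------------------------------------

@dataclass
class BinMatrix:
    """4x4 ortholog counts: source bin in genome A x destination bin in B.

    Rates are row-normalized; ``P_i`` (gene position conservation of bin i)
    is the diagonal, ``T_i-j`` the off-diagonal translocation rates.  Rows
    with no orthologs have no defined rates (NaN).
    """

    counts: np.ndarray
    n_orthologs: int

    @property
    def rates(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.counts / row_sums
        r[row_sums[:, 0] == 0] = np.nan
        return r

    def p(self, bin_: str) -> float:
        i = _BIN_IDX[bin_]
        return float(self.rates[i, i])

    def t(self, src: str, dst: str) -> float:
        return float(self.rates[_BIN_IDX[src], _BIN_IDX[dst]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(BINS), columns=list(BINS))


def bin_conservation(omap) -> BinMatrix:
    """Count ortholog pairs by (bin in A, bin in B)."""
    df = _frame(omap)
    counts = np.zeros((4, 4), dtype=int)
    for ba, bb in zip(df["bin_a"], df["bin_b"]):
        counts[_BIN_IDX[ba], _BIN_IDX[bb]] += 1
    return BinMatrix(counts=counts, n_orthologs=len(df))


@dataclass(frozen=True)
class InterreplichoreRate:
    """Directional and pooled L<->R translocation rates (None when a
    denominator is empty)."""

    t_l_to_r: float | None
    t_r_to_l: float | None
    combined: float | None


def interreplichore_rate(omap) -> InterreplichoreRate:
    """T_L-R, T_R-L and their pooled combination from the bin matrix.

    T_L-R is the share of L-bin genes of genome A (with any ortholog) whose
    partner lies in the R bin of genome B; symmetric for T_R-L.  The pooled
    rate divides the summed numerators by the summed denominators.  Only the
    L and R bins enter, deliberately excluding the inversion-prone O and T
    neighbourhoods.
    """
    bm = bin_conservation(omap)
    c = bm.counts
    li, ri = _BIN_IDX["L"], _BIN_IDX["R"]
    n_l, n_r = int(c[li].sum()), int(c[ri].sum())
    t_lr = c[li, ri] / n_l if n_l else None
    t_rl = c[ri, li] / n_r if n_r else None
    combined = (c[li, ri] + c[ri, li]) / (n_l + n_r) if (n_l + n_r) else None
    return InterreplichoreRate(t_l_to_r=t_lr, t_r_to_l=t_rl, combined=combined)


# ---------------------------------------------------------------------------
# Interreplichore translocation profile, symmetry and strand flips
# ---------------------------------------------------------------------------

@dataclass
class TranslocationProfile:
    """Per-pair statistics for orthologs whose replichore differs between
    the two genomes (all bins, so oriC/ter-local interreplichore moves are
    captured too, unlike the L/R-restricted rate)."""

    pairs: pd.DataFrame
    t_l_to_r: float | None
    t_r_to_l: float | None
    t_lr_combined: float | None
    frac_symmetric: float
    flip_rate: float
    symmetric_cut: float = 0.1

    def __len__(self) -> int:
        return len(self.pairs)


def translocation_profile(omap, symmetric_cut: float = 0.1) -> TranslocationProfile:
    """Interreplichore pairs with D_inter = |d_A - d_B| and strand flips.

    A translocation is symmetric when the gene lands at (nearly) the same
    normalized distance from oriC on the opposite replichore, i.e. D_inter is
    near zero.  A strand flip is a change of leading/lagging status; a gene
    is leading when transcribed co-directionally with its replication fork
    (``+`` on replichore R, ``-`` on L).
    """
    df = _frame(omap)
    sub = df[df["repl_a"] != df["repl_b"]].copy()
    sub["d_inter"] = (sub["d_a"] - sub["d_b"]).abs()
    sub["strand_flip"] = sub["lead_a"] != sub["lead_b"]
    rate = interreplichore_rate(df)
    n = len(sub)
    return TranslocationProfile(
        pairs=sub.reset_index(drop=True),
        t_l_to_r=rate.t_l_to_r,
        t_r_to_l=rate.t_r_to_l,
        t_lr_combined=rate.combined,
        frac_symmetric=float((sub["d_inter"] < symmetric_cut).mean()) if n else float("nan"),
        flip_rate=float(sub["strand_flip"].mean()) if n else float("nan"),
        symmetric_cut=symmetric_cut,
    )


@dataclass
class NullDistribution:
    """Randomized-null samples of D_inter and strand-flip rates.

    Obtained by re-pairing genes uniformly at random within the
    interreplichore-translocated set (partner positions and strands are
    permuted together), with a seeded generator for reproducibility.
    """

    d_inter: np.ndarray        # flattened, n_reps * n_pairs samples
    flip_rates: np.ndarray     # one rate per replicate
    frac_symmetric: float      # share of null D_inter below the cut
    n_reps: int
    seed: int

    def summary(self) -> dict[str, float]:
        q = np.quantile(self.d_inter, [0.25, 0.5, 0.75])
        return {
            "mean_d_inter": float(self.d_inter.mean()),
            "median_d_inter": float(q[1]),
            "q25_d_inter": float(q[0]),
            "q75_d_inter": float(q[2]),
            "mean_flip_rate": float(self.flip_rates.mean()),
        }


def randomized_null(omap, n_reps: int, seed: int,
                    symmetric_cut: float = 0.1) -> NullDistribution:
    """Null distributions of D_inter and flip rate under random re-pairing.

    Accepts an OrthologMap, a pair DataFrame, or a TranslocationProfile.
    Each replicate permutes the partner-genome entries (position and strand
    move together) among the translocated set and recomputes the statistics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    prof = omap if isinstance(omap, TranslocationProfile) else translocation_profile(omap)
    n = len(prof)
    if n == 0:
        raise InsufficientData("empty translocation profile: nothing to randomize")
    d_a = prof.pairs["d_a"].to_numpy()
    d_b = prof.pairs["d_b"].to_numpy()
    lead_a = prof.pairs["lead_a"].to_numpy(dtype=bool)
    lead_b = prof.pairs["lead_b"].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(n), (n_reps, 1)), axis=1)
    d_mat = np.abs(d_a[None, :] - d_b[idx])
    flips = lead_a[None, :] != lead_b[idx]
    return NullDistribution(
        d_inter=d_mat.ravel(),
        flip_rates=flips.mean(axis=1),
        frac_symmetric=float((d_mat < symmetric_cut).mean()),
        n_reps=n_reps,
        seed=seed,
    )


def topology_call(t_lr_combined: float, threshold: float = 0.1) -> str:
    """Call the gross chromosome topology from the pooled L<->R rate.

    ``longitudinal`` iff the rate strictly exceeds the threshold (default
    0.1), else ``transverse``.  High interreplichore translocation rates mark
    chromosomes whose two arms are spatially close along their length.
    """
    if not 0.0 <= t_lr_combined <= 1.0:
        raise ValueError(f"T_L-R/R-L must lie in [0, 1], got {t_lr_combined}")
    return "longitudinal" if t_lr_combined > threshold else "transverse"


# ---------------------------------------------------------------------------
# Contact-map enrichment at translocated loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactEnrichment:
    median_test: float
    median_control: float
    p_value: float
    n_test: int
    n_control: int


def translocated_locus_pairs(profile: TranslocationProfile, genome: Genome
                             ) -> list[tuple[float, float]]:
    """Coordinate pairs, in ``genome``'s frame, of translocated orthologs.

    The first coordinate is the gene's own midpoint; the second is the point
    of ``genome`` at the partner gene's normalized oriC distance on the
    partner's replichore, i.e. where the translocated copy sits relative to
    this chromosome's coordinate system.
    """
    half = genome.length / 2.0
    out = []
    for _, row in profile.pairs.iterrows():
        if row["repl_b"] == "R":
            partner = (genome.oric + row["d_b"] * half) % genome.length
        else:
            partner = (genome.oric - row["d_b"] * half) % genome.length
        if partner == 0:
            partner = genome.length
        out.append((float(row["mid_a"]), float(partner)))
    return out


def _matrix_bin(coord: float, bin_size: float, n_bins: int) -> int:
    return min(int((coord - 1) // bin_size), n_bins - 1)


def contact_enrichment(contacts: np.ndarray, bin_size: float, genome: Genome,
                       locus_pairs: list[tuple[float, float]]
                       ) -> ContactEnrichment:
    """Test whether translocated interreplichore loci show elevated contacts.

    ``contacts`` is a symmetric normalized contact matrix over fixed-size
    genomic bins.  The test set holds the contact frequencies of matrix cells
    containing at least one translocated interreplichore locus pair; the
    control set holds all other interreplichore cells (a cell in both is
    assigned to the test set only).  The two sets are compared with a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test with continuity
    correction and mid-ranked ties.
    """
    contacts = np.asarray(contacts, dtype=float)
    if contacts.ndim != 2 or contacts.shape[0] != contacts.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(contacts, contacts.T, equal_nan=True):
        raise ValueError("contact matrix must be symmetric")
    n_bins = contacts.shape[0]
    if abs(n_bins * bin_size - genome.length) > bin_size:
        raise ValueError("bin size does not tile the genome within one bin")

    mids = (np.arange(n_bins) + 0.5) * bin_size
    mids = np.clip(mids, 1, genome.length)
    repl = np.array([locate(m, genome.oric, genome.length).replichore for m in mids])
    universe = {
        (i, j)
        for i in range(n_bins) for j in range(i + 1, n_bins)
        if repl[i] != repl[j]
    }
    test_cells = set()
    for ca, cb in locus_pairs:
        i = _matrix_bin(ca, bin_size, n_bins)
        j = _matrix_bin(cb, bin_size, n_bins)
        cell = (min(i, j), max(i, j))
        if cell in universe:
            test_cells.add(cell)
    control_cells = universe - test_cells
    if not test_cells or not control_cells:
        raise InsufficientData("empty test or control contact-cell set")
    test_vals = np.array([contacts[c] for c in sorted(test_cells)])
    ctrl_vals = np.array([contacts[c] for c in sorted(control_cells)])
    res = stats.mannwhitneyu(test_vals, ctrl_vals, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return ContactEnrichment(
        median_test=float(np.median(test_vals)),
        median_control=float(np.median(ctrl_vals)),
        p_value=float(res.pvalue),
        n_test=len(test_vals),
        n_control=len(ctrl_vals),
    )


def read_contact_matrix(path_or_buf) -> tuple[np.ndarray, float]:
    """Read a dense contact matrix TSV whose header row holds bin starts.

    Returns the matrix and the inferred bin size.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", index_col=0)
    starts = df.columns.astype(float).to_numpy()
    if len(starts) < 2:
        raise ValueError("contact matrix needs >= 2 bins")
    bin_size = float(np.median(np.diff(starts)))
    return df.to_numpy(dtype=float), bin_size


def write_contact_matrix(contacts: np.ndarray, bin_size: float, handle) -> None:
    n = contacts.shape[0]
    starts = (np.arange(n) * bin_size).astype(int)
    pd.DataFrame(contacts, index=starts, columns=starts).to_csv(handle, sep="\t")


# ---------------------------------------------------------------------------
# Expression symmetry across replichores
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSymmetry:
    delta_d_high: np.ndarray   # |d_i - d_j| for strongly co-expressed pairs
    delta_d_low: np.ndarray    # |d_i - d_j| for uncorrelated/anti-correlated pairs
    p_value: float

    @property
    def median_high(self) -> float:
        return float(np.median(self.delta_d_high))

    @property
    def median_low(self) -> float:
        return float(np.median(self.delta_d_low))


def expression_symmetry(expr: pd.DataFrame, genome: Genome,
                        rho_cut: float = 0.5) -> ExpressionSymmetry:
    """Do co-expressed interreplichore gene pairs sit equidistant from oriC?

    For every pair of genes on opposite replichores, the Spearman correlation
    of their expression profiles across conditions is computed.  The
    distribution of |d_i - d_j| for strongly co-expressed pairs
    (rho > ``rho_cut``) is compared against pairs with rho <= 0 using a
    two-sided Wilcoxon rank-sum test.  A smaller median |delta d| in the
    co-expressed set indicates that symmetric positioning tracks shared
    expression state.

    ``expr`` is a genes x conditions table indexed by gene id; genes absent
    from the genome annotation or with constant profiles are dropped.
    """
    if expr.shape[1] < 2:
        raise InsufficientData("expression symmetry needs >= 2 conditions")
    idx = genome.gene_index()
    keep = [g for g in expr.index if g in idx]
    if len(keep) < 4:
        raise InsufficientData("too few genes mappable to the genome")
    mat = expr.loc[keep].to_numpy(dtype=float)
    variable = mat.std(axis=1) > 0
    keep = [g for g, v in zip(keep, variable) if v]
    mat = mat[variable]
    pos = [genome.position_of(idx[g]) for g in keep]
    d = np.array([p.d_norm for p in pos])
    repl = np.array([p.replichore for p in pos])

    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    rho = np.corrcoef(ranks)
    inter = repl[:, None] != repl[None, :]
    upper = np.triu(np.ones_like(inter, dtype=bool), k=1)
    mask = inter & upper
    dd = np.abs(d[:, None] - d[None, :])
    high = dd[mask & (rho > rho_cut)]
    low = dd[mask & (rho <= 0)]
    if len(high) == 0 or len(low) == 0:
        raise InsufficientData("no gene pairs in one of the correlation classes")
    res = stats.mannwhitneyu(high, low, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return ExpressionSymmetry(delta_d_high=high, delta_d_low=low,
                              p_value=float(res.pvalue))
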