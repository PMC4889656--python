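"""Tests for the core topology statistics: conservation, translocation
rates, interreplichore symmetry, nulls, topology call, contact and
expression analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_pair_frame

from replichore.simulate import (EvolutionParams, evolve_pair,
                                 generate_genome, synth_contact_map)
from replichore.topology_stats import (InsufficientData, bin_conservation,
                                       contact_enrichment, expression_symmetry,
                                       gene_order_conservation,
                                       interreplichore_rate, loess_residual,
                                       randomized_null, topology_call,
                                       translocated_locus_pairs,
                                       translocation_profile)


class TestGeneOrderConservation:
    def test_identical_positions_give_one(self):
        d = np.linspace(0.01, 0.99, 50)
        df = make_pair_frame(d, d, ["R"] * 50, ["R"] * 50)
        assert gene_order_conservation(df) == pytest.approx(1.0)

    def test_reversed_positions_give_minus_one(self):
        d = np.linspace(0.01, 0.99, 50)
        df = make_pair_frame(d, d[::-1], ["R"] * 50, ["R"] * 50)
        assert gene_order_conservation(df) == pytest.approx(-1.0)

    def test_random_pairing_is_near_zero(self):
        rng = np.random.default_rng(17)
        n = 10_000
        df = make_pair_frame(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                             ["R"] * n, ["R"] * n)
        assert abs(gene_order_conservation(df)) < 0.05

    def test_too_few_pairs(self):
        df = make_pair_frame([0.1, 0.2], [0.1, 0.2], ["R", "R"], ["R", "R"])
        with pytest.raises(InsufficientData):
            gene_order_conservation(df)

    def test_perfect_on_eventless_synthetic_pair(self, ancestor):
        params = EvolutionParams(crossing_fraction=0.0, symmetry_sd=0.0,
                                 ortholog_loss=0.0, ot_inversion_rate=0.0,
                                 seed=5)
        pair = evolve_pair(ancestor, params)
        assert gene_order_conservation(pair.ortholog_map) == pytest.approx(1.0)


class TestLoessResidual:
    def test_linear_signal_fully_explained(self):
        x = np.linspace(97, 100, 60)
        y = 3.0 - 0.4 * x
        assert np.abs(loess_residual(y, x)).max() < 1e-6

    def test_constant_signal(self):
        x = np.linspace(97, 100, 60)
        assert np.abs(loess_residual(np.full(60, 0.9), x)).max() < 1e-6

    def test_planted_offsets_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(97, 100, 200)
        y = 0.5 + 0.1 * (x - 97) + rng.normal(0, 0.005, 200)
        idx = rng.choice(200, 12, replace=False)
        y[idx] += 0.5
        resid = loess_residual(y, x)
        assert resid[idx].mean() == pytest.approx(0.5, rel=0.10)

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="raw y"):
            loess_residual(np.arange(20.0), np.full(20, 98.0))


class TestBinConservation:
    def test_identity_map_gives_identity_rates(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 1, 200)
        repl = np.where(rng.random(200) < 0.5, "R", "L")
        bm = bin_conservation(make_pair_frame(d, d, repl, repl))
        assert np.allclose(bm.rates, np.eye(4))
        assert bm.counts.sum() == 200

    def test_partial_translocation_counts(self):
        # 4 O-bin genes in A; one partner moved to T
        df = make_pair_frame([0.1, 0.12, 0.15, 0.2], [0.1, 0.12, 0.15, 0.9],
                             ["R"] * 4, ["R"] * 4)
        bm = bin_conservation(df)
        assert bm.p("O") == pytest.approx(0.75)
        assert bm.t("O", "T") == pytest.approx(0.25)

    def test_rows_normalize_to_one(self, longitudinal_pair):
        bm = bin_conservation(longitudinal_pair.ortholog_map)
        sums = np.nansum(bm.rates, axis=1)
        occupied = bm.counts.sum(axis=1) > 0
        assert np.allclose(sums[occupied], 1.0)
        assert bm.counts.sum() == len(longitudinal_pair.ortholog_map)

    def test_empty_row_reported_absent(self):
        df = make_pair_frame([0.1], [0.1], ["R"], ["R"])
        bm = bin_conservation(df)
        assert np.isnan(bm.p("T"))


class TestInterreplichoreRate:
    def test_half_crossing(self):
        d = [0.5] * 20
        repl_a = ["L"] * 10 + ["R"] * 10
        repl_b = ["R"] * 5 + ["L"] * 5 + ["L"] * 5 + ["R"] * 5
        rate = interreplichore_rate(make_pair_frame(d, d, repl_a, repl_b))
        assert rate.t_l_to_r == pytest.approx(0.5)
        assert rate.t_r_to_l == pytest.approx(0.5)
        assert rate.combined == pytest.approx(0.5)

    def test_no_crossings(self):
        d = [0.5] * 10
        rate = interreplichore_rate(make_pair_frame(d, d, ["L"] * 10, ["L"] * 10))
        assert rate.combined == 0.0
        assert rate.t_r_to_l is None  # no R-bin genes at all

    def test_recovers_generator_crossing_fraction(self, ancestor):
        params = EvolutionParams(crossing_fraction=0.4, symmetry_sd=0.02,
                                 ortholog_loss=0.1, seed=31)
        pair = evolve_pair(ancestor, params)
        rate = interreplichore_rate(pair.ortholog_map)
        assert rate.combined == pytest.approx(0.4, abs=0.05)


class TestTranslocationProfile:
    def test_symmetric_translocation_no_flip(self):
        df = make_pair_frame([0.4], [0.4], ["R"], ["L"],
                             lead_a=[True], lead_b=[True])
        prof = translocation_profile(df)
        assert len(prof) == 1
        assert prof.pairs["d_inter"].iloc[0] == pytest.approx(0.0)
        assert not prof.pairs["strand_flip"].iloc[0]

    def test_d_inter_magnitude(self):
        df = make_pair_frame([0.2], [0.7], ["R"], ["L"])
        prof = translocation_profile(df)
        assert prof.pairs["d_inter"].iloc[0] == pytest.approx(0.5)

    def test_same_strand_symbol_across_replichores_is_flip(self):
        # '+' on R is leading; '+' on L is lagging -> flip
        df = make_pair_frame([0.4], [0.4], ["R"], ["L"],
                             lead_a=[True], lead_b=[False])
        assert df["strand_a"].iloc[0] == df["strand_b"].iloc[0] == "+"
        prof = translocation_profile(df)
        assert bool(prof.pairs["strand_flip"].iloc[0])

    def test_profile_restricted_to_interreplichore_pairs(self, longitudinal_pair):
        prof = translocation_profile(longitudinal_pair.ortholog_map)
        assert (prof.pairs["repl_a"] != prof.pairs["repl_b"]).all()


class TestRandomizedNull:
    def _uniform_profile(self, n, seed=0, lead_p=0.5):
        rng = np.random.default_rng(seed)
        repl_a = ["R"] * n
        repl_b = ["L"] * n
        return make_pair_frame(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               repl_a, repl_b,
                               lead_a=rng.random(n) < lead_p,
                               lead_b=rng.random(n) < lead_p)

    def test_deterministic_given_seed(self, longitudinal_pair):
        a = randomized_null(longitudinal_pair.ortholog_map, n_reps=5, seed=99)
        b = randomized_null(longitudinal_pair.ortholog_map, n_reps=5, seed=99)
        assert np.array_equal(a.d_inter, b.d_inter)
        assert np.array_equal(a.flip_rates, b.flip_rates)

    def test_uniform_positions_mean_is_one_third(self):
        # E|U - U'| = 1/3 for independent uniforms
        df = self._uniform_profile(1000, seed=1)
        null = randomized_null(df, n_reps=100, seed=2)
        assert null.d_inter.size == 100_000
        assert null.d_inter.mean() == pytest.approx(1 / 3, abs=0.01)

    def test_random_strands_flip_rate_is_half(self):
        df = self._uniform_profile(1000, seed=3)
        null = randomized_null(df, n_reps=100, seed=4)
        assert null.flip_rates.mean() == pytest.approx(0.5, abs=0.02)

    def test_validation(self, longitudinal_pair):
        with pytest.raises(ValueError):
            randomized_null(longitudinal_pair.ortholog_map, n_reps=0, seed=1)
        empty = make_pair_frame([0.5], [0.5], ["R"], ["R"])
        with pytest.raises(InsufficientData):
            randomized_null(empty, n_reps=10, seed=1)

    def test_observed_symmetry_exceeds_null(self, longitudinal_pair):
        """Near-mirrored generator output is far more symmetric than random
        re-pairing."""
        prof = translocation_profile(longitudinal_pair.ortholog_map)
        null = randomized_null(prof, n_reps=50, seed=7)
        assert prof.frac_symmetric > null.frac_symmetric + 0.2


class TestTopologyCall:
    @pytest.mark.parametrize("rate,expected", [
        (0.03, "transverse"),     # E. coli / Salmonella regime
        (0.50, "longitudinal"),   # C. crescentus regime
        (0.10, "transverse"),     # boundary: strict inequality
    ])
    def test_calls(self, rate, expected):
        assert topology_call(rate) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            topology_call(1.2)


@pytest.fixture(scope="module")
def contact_setting():
    genome, _ = generate_genome(n_genes=1000, genome_length=1_000_000,
                                seed=1, with_sequences=False)
    params = EvolutionParams(n_genes=1000, genome_length=1_000_000,
                             crossing_fraction=0.45, seed=2)
    pair = evolve_pair(genome, params)
    profile = translocation_profile(pair.ortholog_map)
    return genome, profile


class TestContactEnrichment:
    BIN = 25_000

    def test_planted_longitudinal_band_detected(self, contact_setting):
        genome, profile = contact_setting
        mat = synth_contact_map(genome, "longitudinal", self.BIN,
                                band_strength=3.0, seed=3)
        enr = contact_enrichment(mat, self.BIN, genome,
                                 translocated_locus_pairs(profile, genome))
        assert enr.p_value < 0.01
        assert enr.median_test > enr.median_control

    def test_cells_are_disjoint_and_test_takes_precedence(self, contact_setting):
        genome, _ = contact_setting
        mat = synth_contact_map(genome, "transverse", self.BIN, seed=4)
        # one translocated locus pair -> exactly one test cell, removed from
        # the control universe (oriC at the sequence origin: bins 0-19 are
        # replichore R, 20-39 are L, so there are 20*20 interreplichore cells)
        pairs = [(100.0, 990_000.0)]
        enr = contact_enrichment(mat, self.BIN, genome, pairs)
        assert enr.n_test == 1
        assert enr.n_test + enr.n_control == 400
        assert enr.n_control == 399

    def test_asymmetric_matrix_rejected(self, contact_setting):
        genome, _ = contact_setting
        mat = synth_contact_map(genome, "transverse", self.BIN, seed=5)
        mat[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            contact_enrichment(mat, self.BIN, genome, [(1.0, 600_000.0)])

    def test_empty_test_set_rejected(self, contact_setting):
        genome, _ = contact_setting
        mat = synth_contact_map(genome, "transverse", self.BIN, seed=6)
        # both loci on the same replichore -> no interreplichore test cell
        with pytest.raises(InsufficientData):
            contact_enrichment(mat, self.BIN, genome, [(100.0, 200.0)])

    def test_null_pvalues_are_uniform(self, contact_setting):
        """With test cells unrelated to the matrix signal, the Wilcoxon p is
        calibrated (KS against U[0,1])."""
        genome, _ = contact_setting
        rng = np.random.default_rng(9)
        pvals = []
        for rep in range(100):
            mat = synth_contact_map(genome, "transverse", self.BIN,
                                    seed=1000 + rep)
            pairs = [(rng.uniform(1, 500_000), rng.uniform(500_001, 1_000_000))
                     for _ in range(40)]
            pvals.append(contact_enrichment(mat, self.BIN, genome, pairs).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestExpressionSymmetry:
    def _genome(self):
        genome, _ = generate_genome(n_genes=120, genome_length=120_000,
                                    seed=5, with_sequences=False)
        return genome

    def test_planted_symmetric_modules_detected(self):
        genome = self._genome()
        rng = np.random.default_rng(7)
        pos = {g.gene_id: genome.position_of(g) for g in genome.genes}
        ids = [g.gene_id for g in genome.genes]
        right = sorted((i for i in ids if pos[i].replichore == "R"),
                       key=lambda i: pos[i].d_norm)
        left = sorted((i for i in ids if pos[i].replichore == "L"),
                      key=lambda i: pos[i].d_norm)
        expr = pd.DataFrame(rng.normal(0, 1, (len(ids), 30)), index=ids)
        for k in range(15):  # mirrored gene pairs share a module profile
            base = rng.normal(0, 1, 30)
            expr.loc[right[k]] = base + rng.normal(0, 0.2, 30)
            expr.loc[left[k]] = base + rng.normal(0, 0.2, 30)
        res = expression_symmetry(expr, genome)
        assert res.p_value < 0.05
        assert res.median_high < res.median_low

    def test_position_independent_expression_is_null(self):
        genome = self._genome()
        ids = [g.gene_id for g in genome.genes]
        rng = np.random.default_rng(13)
        pvals = []
        for rep in range(40):
            expr = pd.DataFrame(rng.normal(0, 1, (len(ids), 25)), index=ids)
            try:
                pvals.append(expression_symmetry(expr, genome).p_value)
            except InsufficientData:
                continue
        # no systematic signal: p-values should not pile up near zero
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_identical_profiles_at_equal_distance_contribute_zero(self):
        genome = self._genome()
        pos = {g.gene_id: genome.position_of(g) for g in genome.genes}
        right = min((i for i in pos if pos[i].replichore == "R"),
                    key=lambda i: pos[i].d_norm)
        left = min((i for i in pos if pos[i].replichore == "L"),
                   key=lambda i: abs(pos[i].d_norm - pos[right].d_norm))
        ids = [g.gene_id for g in genome.genes]
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.normal(0, 1, (len(ids), 20)), index=ids)
        expr.loc[left] = expr.loc[right]  # identical profiles, rho = 1
        res = expression_symmetry(expr, genome)
        expected = abs(pos[right].d_norm - pos[left].d_norm)
        assert np.isclose(res.delta_d_high, expected, atol=1e-12).any()

    def test_too_few_conditions(self):
        genome = self._genome()
        expr = pd.DataFrame(np.zeros((5, 1)),
                            index=[g.gene_id for g in genome.genes[:5]])
        with pytest.raises(InsufficientData):
            expression_symmetry(expr, genome)
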