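import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumdriver import (
    SimulationParams,
    bh_fdr,
    gene_significance,
    per_patient_hit_prob,
    poisson_binomial_tail,
    simulate_cohort,
    simulate_gene_lengths,
)


def enumeration_tail(probs, k):
    """Brute-force P(X >= k) over all 2^n Bernoulli outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= k:
            weight = 1.0
            for p, x in zip(probs, outcome):
                weight *= p if x else (1.0 - p)
            total += weight
    return total


def stepup_qvalues(p_values):
    """Direct transcription of the BH step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, m * p[i] / (rank_idx + 1))
        q[i] = running
    return q


class TestHitProbability:
    def test_zero_mutations_means_zero_probability(self):
        assert per_patient_hit_prob(0, 3100, 62_000_000) == 0.0

    def test_whole_territory_gene_is_certain(self):
        assert per_patient_hit_prob(1, 500, 500) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # 1 - (1 - 5e-5)^62
        expected = 1.0 - (1.0 - 3100 / 62_000_000) ** 62
        assert per_patient_hit_prob(62, 3100, 62_000_000) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(3.0953e-3, rel=1e-4)

    def test_gene_longer_than_territory_rejected(self):
        with pytest.raises(ValueError):
            per_patient_hit_prob(10, 200, 100)


class TestPoissonBinomialTail:
    @pytest.mark.parametrize(
        "probs,k,expected",
        [
            ([0.5, 0.5], 1, 0.75),
            ([0.3, 0.9, 0.2], 0, 1.0),
            ([0.1, 0.1, 0.1], 2, 0.028),
            ([0.2], 2, 0.0),  # k beyond the trial count
        ],
    )
    def test_examples_against_enumeration(self, probs, k, expected):
        assert poisson_binomial_tail(probs, k) == pytest.approx(expected, abs=1e-12)
        if k <= len(probs):
            assert poisson_binomial_tail(probs, k) == pytest.approx(
                enumeration_tail(probs, k), abs=1e-12
            )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.data(),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_exhaustive_enumeration(self, probs, data):
        k = data.draw(st.integers(min_value=0, max_value=len(probs)))
        assert poisson_binomial_tail(probs, k) == pytest.approx(
            enumeration_tail(probs, k), abs=1e-12
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=40)
    def test_tail_nonincreasing_in_k(self, probs):
        tails = [poisson_binomial_tail(probs, k) for k in range(len(probs) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_tail_monotone_in_probabilities(self):
        lo = poisson_binomial_tail([0.1, 0.2, 0.3], 2)
        hi = poisson_binomial_tail([0.1, 0.5, 0.3], 2)
        assert hi >= lo

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.5, 1.2], 1)


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_stepup_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_matches_stepup_definition_and_permutation_invariance(self, p_values):
        q = bh_fdr(p_values)
        assert q == pytest.approx(stepup_qvalues(p_values), abs=1e-12)
        # permutation equivariance
        perm = np.argsort(np.asarray(p_values))[::-1]
        q_perm = bh_fdr(np.asarray(p_values)[perm])
        assert q_perm == pytest.approx(q[perm], abs=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, -0.1])


class TestGeneSignificance:
    def test_spiked_gene_attains_minimum_p(self):
        """A gene hit in 6 of 8 patients against ~40-SNV backgrounds must
        dominate the significance ranking."""
        params = SimulationParams(seed=7, spike_genes={"SPIKED": 6})
        cohort = simulate_cohort(params)
        lengths = simulate_gene_lengths({r.gene for r in cohort.records}, seed=8)
        results = gene_significance(cohort, lengths)
        assert results[0].gene == "SPIKED"
        assert results[0].p_value == min(r.p_value for r in results)
        assert results[0].flagged

    def test_missing_gene_length_raises_with_gene_names(self, default_cohort):
        with pytest.raises(KeyError, match="G0"):
            gene_significance(default_cohort, {"TP53": 1000})

    def test_small_cohort_matches_enumeration(self):
        params = SimulationParams(
            seed=13, n_samples=5, n_private=60, n_shared_pairs=0,
            n_shared_triples=0, load_range=(0, 1000), n_genes=40,
        )
        cohort = simulate_cohort(params)
        lengths = simulate_gene_lengths({r.gene for r in cohort.records}, seed=14)
        for result in gene_significance(cohort, lengths)[:10]:
            oracle = enumeration_tail(result.per_patient_probs, result.observed_patients)
            assert result.p_value == pytest.approx(oracle, abs=1e-12)

    def test_null_simulations_control_discovery_fraction(self):
        """With no spiked signal the q<0.10 discovery fraction stays within
        the FDR bound (0.10 plus 3 binomial standard errors)."""
        rng = np.random.default_rng(101)
        n_genes, n_patients, territory = 150, 8, 62_000_000
        lengths = np.maximum(300, rng.lognormal(np.log(1500), 0.5, n_genes).astype(int))
        n_reps = 500
        discoveries = 0
        total = n_reps * n_genes
        gene_probs = lengths / territory
        for _ in range(n_reps):
            loads = rng.integers(19, 75, size=n_patients)
            # per-patient uniform placement: gene g hit iff >=1 of n_i mutations lands in it
            hits = np.zeros(n_genes, dtype=int)
            for n_i in loads:
                hits += rng.binomial(n_i, gene_probs) > 0
            p_values = np.ones(n_genes)
            for g in np.nonzero(hits)[0]:
                probs = [
                    per_patient_hit_prob(int(n_i), int(lengths[g]), territory)
                    for n_i in loads
                ]
                p_values[g] = poisson_binomial_tail(probs, int(hits[g]))
            discoveries += int((bh_fdr(p_values) < 0.10).sum())
        fraction = discoveries / total
        se = np.sqrt(0.10 * 0.90 / total)
        assert fraction <= 0.10 + 3 * se

    def test_unmutated_gene_has_p_one(self):
        # k = 0 tail is 1 by definition
        assert poisson_binomial_tail([0.1] * 8, 0) == 1.0

    def test_mutation_count_statistic_agrees_on_sparse_data(self):
        """Where every gene is hit at most once per patient the two
        statistics give near-identical p-values."""
        params = SimulationParams(seed=23, n_genes=5000,
                                  n_shared_pairs=0, n_shared_triples=0)
        cohort = simulate_cohort(params)
        lengths = simulate_gene_lengths({r.gene for r in cohort.records}, seed=24)
        by_patients = {r.gene: r.p_value for r in gene_significance(cohort, lengths)}
        by_mutations = {
            r.gene: r.p_value
            for r in gene_significance(cohort, lengths, statistic="mutations")
        }
        for gene, p in by_patients.items():
            assert by_mutations[gene] == pytest.approx(p, rel=1e-2, abs=1e-6)
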