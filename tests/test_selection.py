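"""Gated dN/dS estimation, regions, clonal partitions, AF windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumordnds.cohort_io import MutationRecord, VariantClass
from tumordnds.selection import (
    SelectionParameterError,
    af_window_dnds,
    compare_dnds_distributions,
    estimate_dnds,
    min_mutation_threshold,
    mutation_key,
    partition_clonal,
    region_dnds,
    replicate_error,
    sample_dnds,
    trunk_branch_dnds,
)
from tumordnds.site_model import GeneSites, SiteTable


def record(gene="G", klass=VariantClass.NONSILENT, sample="S1", patient="P1",
           af=None, key=None):
    return MutationRecord(patient, sample, gene, klass, af, klass.value, key)


def toy_table(**genes) -> SiteTable:
    table = SiteTable()
    for gene, (n_n, n_s) in genes.items():
        table.per_gene[gene] = GeneSites(n_n, n_s, int(n_n + n_s))
    return table


class TestEstimate:
    @pytest.mark.parametrize(
        "N, S, nN, nS, expected",
        [(30, 10, 3000, 1000, 1.0), (40, 5, 2000, 1000, 4.0), (12, 8, 3e7, 1e7, 0.5)],
    )
    def test_values(self, N, S, nN, nS, expected):
        est = estimate_dnds(N, S, nN, nS)
        assert est.valid and est.value == pytest.approx(expected)

    def test_below_threshold(self):
        est = estimate_dnds(5, 4, 3000, 1000)
        assert not est.valid and est.reason == "below_threshold"

    def test_no_silent(self):
        est = estimate_dnds(20, 0, 3000, 1000)
        assert not est.valid and est.reason == "no_silent"

    @pytest.mark.parametrize("nN, nS", [(0, 1000), (1000, 0), (-1, 1000)])
    def test_bad_site_masses(self, nN, nS):
        with pytest.raises(SelectionParameterError):
            estimate_dnds(10, 10, nN, nS)

    @settings(derandomize=True, max_examples=50)
    @given(
        factor=st.floats(0.1, 100),
        N=st.integers(1, 500),
        S=st.integers(1, 500),
    )
    def test_scale_invariance(self, factor, N, S):
        base = estimate_dnds(N, S, 3000.0, 1000.0, min_mutations=1)
        scaled = estimate_dnds(N, S, 3000.0 * factor, 1000.0 * factor, min_mutations=1)
        assert scaled.value == pytest.approx(base.value, rel=1e-9)


class TestSampleDnds:
    def test_matches_brute_force_recount(self, site_table, rng):
        genes = site_table.genes
        for _ in range(100):
            m = int(rng.integers(0, 40))
            options = [VariantClass.NONSILENT, VariantClass.SILENT, VariantClass.OTHER]
            records = [
                record(gene=str(rng.choice(genes)), klass=options[int(rng.integers(3))])
                for _ in range(m)
            ]
            profile = sample_dnds(records, site_table, min_mutations=1)
            # independent oracle: direct tallies over the record list
            n_oracle = sum(1 for r in records if r.variant_class is VariantClass.NONSILENT)
            s_oracle = sum(1 for r in records if r.variant_class is VariantClass.SILENT)
            assert (profile.N, profile.S) == (n_oracle, s_oracle)
            if s_oracle > 0 and n_oracle + s_oracle >= 1:
                expected = (n_oracle / site_table.nN_total) / (s_oracle / site_table.nS_total)
                assert profile.dnds == pytest.approx(expected)

    def test_empty_sample_invalid(self, site_table):
        profile = sample_dnds([], site_table)
        assert profile.N == profile.S == 0 and not profile.valid

    def test_below_threshold_flagged(self, site_table):
        records = [record(gene=site_table.genes[0])] * 4 + [
            record(gene=site_table.genes[0], klass=VariantClass.SILENT)
        ] * 3
        assert not sample_dnds(records, site_table).valid

    def test_unknown_genes_dropped(self, site_table):
        records = [record(gene="NOT_A_GENE")] * 5
        profile = sample_dnds(records, site_table, min_mutations=1)
        assert profile.N == 0 and profile.n_dropped_genes == 5


class TestRegionDnds:
    def test_background_attribution_hand_example(self):
        table = toy_table(A=(600, 200), B=(400, 200))
        muts = (
            [record("A")] * 3
            + [record("A", VariantClass.SILENT)]
            + [record("B", VariantClass.SILENT)] * 2
        )
        est = region_dnds(muts, ["A"], table, min_genes=1, min_mutations=1)
        # S_eff = 1 + 2 * (200 / 400) = 2 -> (3/600)/(2/200) = 0.5
        assert est.valid and est.value == pytest.approx(0.5)

    def test_no_background_reduces_to_plain_formula(self):
        table = toy_table(A=(600, 200), B=(400, 200))
        muts = [record("A")] * 3 + [record("A", VariantClass.SILENT)] * 2
        est = region_dnds(muts, ["A"], table, min_genes=1, min_mutations=1)
        assert est.value == pytest.approx((3 / 600) / (2 / 200))

    def test_whole_genome_region_equals_sample_estimate(self, site_table, rng):
        genes = site_table.genes
        records = [
            record(gene=str(rng.choice(genes)),
                   klass=VariantClass.NONSILENT if rng.random() < 0.7 else VariantClass.SILENT)
            for _ in range(300)
        ]
        region = region_dnds(records, genes, site_table, min_genes=1)
        sample = sample_dnds(records, site_table)
        assert region.value == pytest.approx(sample.dnds)

    def test_min_genes_gate(self, site_table):
        est = region_dnds([record(gene=site_table.genes[0])], site_table.genes[:5],
                          site_table, min_genes=100)
        assert not est.valid and est.reason == "too_few_genes"

    def test_empty_subset_is_error(self, site_table):
        with pytest.raises(SelectionParameterError):
            region_dnds([], [], site_table)


class TestClonalPartition:
    @staticmethod
    def sample_of(keys, sample_id):
        return [record(gene=k, sample=sample_id, key=k) for k in keys]

    def test_trunk_and_branches(self):
        samples = {
            "s1": self.sample_of(["a", "b", "c"], "s1"),
            "s2": self.sample_of(["a", "b", "d"], "s2"),
        }
        part = partition_clonal(samples)
        assert sorted(m.gene for m in part.trunk) == ["a", "b"]
        assert [m.gene for m in part.branch_per_sample["s1"]] == ["c"]
        assert [m.gene for m in part.branch_per_sample["s2"]] == ["d"]

    def test_identical_samples_all_trunk(self):
        samples = {s: self.sample_of(["a", "b"], s) for s in ("s1", "s2", "s3")}
        part = partition_clonal(samples)
        assert len(part.trunk) == 2
        assert all(not v for v in part.branch_per_sample.values())

    def test_disjoint_samples_empty_trunk(self):
        samples = {"s1": self.sample_of(["a"], "s1"), "s2": self.sample_of(["b"], "s2")}
        assert partition_clonal(samples).trunk == []

    def test_single_sample_is_error(self):
        with pytest.raises(SelectionParameterError):
            partition_clonal({"s1": self.sample_of(["a"], "s1")})

    def test_partition_disjoint_and_exhaustive(self, rng):
        universe = [f"m{i}" for i in range(30)]
        samples = {
            f"s{j}": self.sample_of(
                [k for k in universe if rng.random() < 0.6], f"s{j}"
            )
            for j in range(3)
        }
        part = partition_clonal(samples)
        trunk_keys = {mutation_key(m) for m in part.trunk}
        for sid, records in samples.items():
            branch_keys = {mutation_key(m) for m in part.branch_per_sample[sid]}
            assert not trunk_keys & branch_keys
            assert trunk_keys | branch_keys == {mutation_key(m) for m in records}

    def test_all_trunk_branch_estimate_invalid(self, site_table):
        gene = site_table.genes[0]
        keys = [f"k{i}" for i in range(30)]
        samples = {
            s: [record(gene=gene, sample=s, key=k) for k in keys] for s in ("s1", "s2")
        }
        estimates = trunk_branch_dnds(partition_clonal(samples), site_table)
        assert not estimates.branch_pooled.valid  # zero branch mutations


class TestAfWindows:
    AFS = (0.1, 0.2, 0.3, 0.6)

    def records(self):
        return [
            record(af=af, klass=VariantClass.NONSILENT if i % 2 else VariantClass.SILENT)
            for i, af in enumerate(self.AFS)
        ] + [record(af=None)]

    def test_early_window_af_above_threshold(self, site_table):
        result = af_window_dnds(self.records(), site_table, 0.25, 1.0, min_mutations=1)
        assert result.n_in_window == 2 and result.n_missing_af == 1

    def test_late_window_af_below_threshold(self, site_table):
        result = af_window_dnds(
            self.records(), site_table, 0.0, 0.33, min_mutations=1,
            lower_inclusive=True, upper_inclusive=False,
        )
        assert result.n_in_window == 3

    def test_windows_partition_the_af_axis(self, site_table, rng):
        records = [record(af=float(a)) for a in rng.random(100)]
        edges = [0.0, 0.25, 0.5, 0.75, 1.0]
        totals = sum(
            af_window_dnds(records, site_table, lo, hi, min_mutations=1).n_in_window
            for lo, hi in zip(edges, edges[1:])
        )
        # (0, .25] + (.25, .5] + (.5, .75] + (.75, 1] covers every AF > 0
        assert totals == sum(1 for r in records if r.allele_frequency > 0)

    def test_inverted_bounds_rejected(self, site_table):
        with pytest.raises(SelectionParameterError):
            af_window_dnds([], site_table, 0.5, 0.2)


class TestReplicateError:
    def test_two_point_group(self):
        assert replicate_error([[0.9, 1.1]]) == pytest.approx(math.sqrt(0.02))

    def test_identical_replicates_zero(self):
        assert replicate_error([[1.0, 1.0, 1.0]]) == 0.0

    def test_pooling_across_groups(self):
        pooled = replicate_error([[0.9, 1.1], [2.0, 2.0]])
        # half the degrees of freedom carry variance 0.02, half carry 0
        assert pooled == pytest.approx(math.sqrt(0.01))

    def test_no_eligible_group_is_error(self):
        with pytest.raises(SelectionParameterError):
            replicate_error([[1.0]])


class TestMinMutationThreshold:
    def test_vacuous_criterion_gives_one(self, site_table):
        assert min_mutation_threshold(site_table, tolerance=math.inf) == 1

    def test_monotone_in_tolerance(self, site_table):
        loose = min_mutation_threshold(site_table, tolerance=0.5, reps=500, seed=7)
        tight = min_mutation_threshold(site_table, tolerance=0.1, reps=500, seed=7)
        assert loose <= tight

    def test_deterministic_given_seed(self, site_table):
        a = min_mutation_threshold(site_table, reps=500, seed=11)
        b = min_mutation_threshold(site_table, reps=500, seed=11)
        assert a == b


class TestCompareDistributions:
    def test_identical_groups_not_distinguished(self):
        group = [0.5, 0.8, 1.0, 1.2, 1.5]
        assert compare_dnds_distributions(group, group) > 0.9

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(1.0, 0.1, 100)
        b = rng.normal(1.5, 0.1, 100)
        assert compare_dnds_distributions(a, b) < 0.01

    def test_insufficient_n_is_error(self):
        with pytest.raises(SelectionParameterError):
            compare_dnds_distributions([1.0, 1.1], [1.0, 1.1, 1.2])
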