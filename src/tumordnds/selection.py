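"""Genome-level dN/dS estimation with validity gating and partitions.

The selection strength of a tumor sample is estimated by treating its exome
as one concatenated sequence:

    dN/dS = (N / nN) / (S / nS)

where ``N`` and ``S`` are the counts of nonsilent and silent point mutations
and ``nN``/``nS`` the corresponding site masses from the reference
(:mod:`tumordnds.site_model`).  Samples with too few mutations give unstable
ratios, so estimates are gated: a sample is valid only when ``N + S`` reaches
a minimum burden (default 10) and at least one silent mutation was observed.
No pseudocounts are applied — under-powered samples are excluded, not
smoothed.

Beyond the per-sample estimate, this module provides region-level estimates
with background-silent attribution, the trunk/branch (clonal/subclonal)
partition of a multi-sample patient, allele-frequency-windowed estimates,
replicate-error pooling, and the simulation-based derivation of the minimum
mutation threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort_io import MutationRecord, SampleMeta, VariantClass
from .site_model import SiteTable

logger = logging.getLogger(__name__)

#: Default minimum total mutation burden (N + S) for a valid estimate.
MIN_MUTATIONS = 10


class SelectionParameterError(ValueError):
    """Invalid estimator parameters (non-positive site masses, bad bounds, ...)."""


@dataclass(frozen=True)
class DnDsEstimate:
    """A gated dN/dS estimate: either a value or a reason it is invalid."""

    value: float | None
    valid: bool
    reason: str | None = None  # "below_threshold" | "no_silent" | None

    def __float__(self) -> float:
        if not self.valid or self.value is None:
            return math.nan
        return self.value


@dataclass
class SampleProfile:
    """Per-sample mutation counts and gated dN/dS estimate."""

    patient_id: str
    sample_id: str
    N: int
    S: int
    estimate: DnDsEstimate
    meta: SampleMeta | None = None
    n_dropped_genes: int = 0

    @property
    def dnds(self) -> float | None:
        return self.estimate.value if self.estimate.valid else None

    @property
    def valid(self) -> bool:
        return self.estimate.valid

    @property
    def total(self) -> int:
        return self.N + self.S


def estimate_dnds(
    N: int,
    S: int,
    nN: float,
    nS: float,
    min_mutations: int = MIN_MUTATIONS,
) -> DnDsEstimate:
    """Gated genome-level estimator ``(N/nN)/(S/nS)``.

    Returns an invalid estimate with reason ``below_threshold`` when
    ``N + S < min_mutations`` and ``no_silent`` when ``S == 0`` (the ratio is
    undefined without silent mutations).
    """
    if nN <= 0 or nS <= 0:
        raise SelectionParameterError(f"site masses must be positive: nN={nN}, nS={nS}")
    if N < 0 or S < 0:
        raise SelectionParameterError(f"mutation counts must be non-negative: N={N}, S={S}")
    if N + S < min_mutations:
        return DnDsEstimate(None, False, "below_threshold")
    if S == 0:
        return DnDsEstimate(None, False, "no_silent")
    return DnDsEstimate((N / nN) / (S / nS), True)


def count_mutations(
    mutations: Iterable[MutationRecord],
    site_table: SiteTable | None = None,
) -> tuple[int, int, int]:
    """Tally ``(N, S, n_dropped)`` over records.

    Records in genes absent from ``site_table`` (when given) are dropped and
    counted; ``other``-class records never enter either tally.
    """
    n = s = dropped = 0
    known = site_table.per_gene if site_table is not None else None
    for record in mutations:
        if known is not None and record.gene not in known:
            dropped += 1
            continue
        if record.variant_class is VariantClass.NONSILENT:
            n += 1
        elif record.variant_class is VariantClass.SILENT:
            s += 1
    return n, s, dropped


def sample_dnds(
    mutations: Sequence[MutationRecord],
    site_table: SiteTable,
    min_mutations: int = MIN_MUTATIONS,
    meta: SampleMeta | None = None,
) -> SampleProfile:
    """Genome-level profile for the mutations of one sample."""
    patient_id = mutations[0].patient_id if mutations else (meta.patient_id if meta else "")
    sample_id = mutations[0].sample_id if mutations else (meta.sample_id if meta else "")
    if any(m.sample_id != sample_id for m in mutations):
        raise SelectionParameterError("sample_dnds expects mutations of a single sample")
    n, s, dropped = count_mutations(mutations, site_table)
    if dropped:
        logger.info("sample %s: dropped %d mutations in genes absent from the site table",
                    sample_id, dropped)
    estimate = estimate_dnds(n, s, site_table.nN_total, site_table.nS_total, min_mutations)
    return SampleProfile(patient_id, sample_id, n, s, estimate, meta, dropped)


def region_dnds(
    mutations: Sequence[MutationRecord],
    gene_subset: Iterable[str],
    site_table: SiteTable,
    min_genes: int = 100,
    min_mutations: int = MIN_MUTATIONS,
) -> DnDsEstimate:
    """dN/dS of a gene region with background-silent attribution.

    Somatic mutations are extremely sparse, so a region's own silent count is
    boosted by the sample's *background* silent mutations — those in genes
    harbouring only silent mutations — attributed proportionally to the
    region's share of the genome's synonymous-site mass:

        S_eff = S_region(non-background) + B * nS_region / nS_total

    Background genes are excluded from the region's own silent count before
    attribution so their mutations are not counted twice; with the region
    equal to the whole genome the formula collapses to the plain sample
    estimate.  Regions smaller than ``min_genes`` genes are invalid
    (pass a smaller ``min_genes`` deliberately for toy inputs).
    """
    region = set(gene_subset)
    if not region:
        raise SelectionParameterError("empty gene subset")
    unknown = region - set(site_table.per_gene)
    if unknown:
        raise SelectionParameterError(f"genes absent from site table: {sorted(unknown)[:5]}")
    if len(region) < min_genes:
        return DnDsEstimate(None, False, "too_few_genes")

    in_table = [m for m in mutations if m.gene in site_table.per_gene]
    per_gene_n: dict[str, int] = {}
    per_gene_s: dict[str, int] = {}
    for record in in_table:
        if record.variant_class is VariantClass.NONSILENT:
            per_gene_n[record.gene] = per_gene_n.get(record.gene, 0) + 1
        elif record.variant_class is VariantClass.SILENT:
            per_gene_s[record.gene] = per_gene_s.get(record.gene, 0) + 1
    background_genes = {g for g in per_gene_s if per_gene_n.get(g, 0) == 0}
    background_silent = sum(per_gene_s[g] for g in background_genes)

    n_region = sum(c for g, c in per_gene_n.items() if g in region)
    s_region = sum(c for g, c in per_gene_s.items() if g in region and g not in background_genes)

    nn_region, ns_region, _ = site_table.subset_mass(region)
    if nn_region <= 0 or ns_region <= 0:
        return DnDsEstimate(None, False, "no_sites")
    s_eff = s_region + background_silent * ns_region / site_table.nS_total
    if n_region + s_region + background_silent < min_mutations:
        return DnDsEstimate(None, False, "below_threshold")
    if s_eff == 0:
        return DnDsEstimate(None, False, "no_silent")
    return DnDsEstimate((n_region / nn_region) / (s_eff / ns_region), True)


def mutation_key(record: MutationRecord) -> tuple:
    """Cross-sample identity of a mutation.

    Uses the most specific key the input provides: genomic position / protein
    change when available, otherwise gene + raw class + AF rounded to 0.01.
    """
    if record.position_key:
        return (record.gene, record.position_key)
    af_bin = None if record.allele_frequency is None else round(record.allele_frequency, 2)
    return (record.gene, record.raw_class or record.variant_class.value, af_bin)


@dataclass
class ClonalPartition:
    """Trunk (shared by all samples) vs branch (private) mutations of a patient."""

    trunk: list[MutationRecord]
    branch_per_sample: dict[str, list[MutationRecord]]
    leaf_per_sample: dict[str, list[MutationRecord]]

    @property
    def branch_pooled(self) -> list[MutationRecord]:
        return [m for records in self.branch_per_sample.values() for m in records]


def partition_clonal(
    samples: Mapping[str, Sequence[MutationRecord]],
    key: Callable[[MutationRecord], tuple] = mutation_key,
) -> ClonalPartition:
    """Partition a multi-sample patient into trunk and branch mutations.

    Trunk mutations are those whose identity key appears in every sample;
    everything else is private to the sample carrying it.  Requires at least
    two samples — the partition is undefined for one.
    """
    if len(samples) < 2:
        raise SelectionParameterError("clonal partition requires at least 2 samples")
    key_sets = {sid: {key(m) for m in records} for sid, records in samples.items()}
    trunk_keys = set.intersection(*key_sets.values())
    first_sid = next(iter(samples))
    seen: set[tuple] = set()
    trunk: list[MutationRecord] = []
    for record in samples[first_sid]:
        k = key(record)
        if k in trunk_keys and k not in seen:
            trunk.append(record)
            seen.add(k)
    branch = {
        sid: [m for m in records if key(m) not in trunk_keys]
        for sid, records in samples.items()
    }
    leaf = {sid: list(records) for sid, records in samples.items()}
    logger.debug("clonal partition over %d samples using key builder %s",
                 len(samples), key.__name__)
    return ClonalPartition(trunk, branch, leaf)


@dataclass
class TrunkBranchEstimates:
    trunk: DnDsEstimate
    branch_pooled: DnDsEstimate
    leaf_per_sample: dict[str, DnDsEstimate]


def trunk_branch_dnds(
    partition: ClonalPartition,
    site_table: SiteTable,
    min_mutations: int = MIN_MUTATIONS,
) -> TrunkBranchEstimates:
    """dN/dS of the trunk, the pooled branches, and each leaf of a patient."""

    def est(records: Sequence[MutationRecord]) -> DnDsEstimate:
        n, s, _ = count_mutations(records, site_table)
        return estimate_dnds(n, s, site_table.nN_total, site_table.nS_total, min_mutations)

    return TrunkBranchEstimates(
        trunk=est(partition.trunk),
        branch_pooled=est(partition.branch_pooled),
        leaf_per_sample={sid: est(records) for sid, records in partition.leaf_per_sample.items()},
    )


@dataclass(frozen=True)
class AfWindowResult:
    estimate: DnDsEstimate
    N: int
    S: int
    n_in_window: int
    n_missing_af: int


def af_window_dnds(
    mutations: Sequence[MutationRecord],
    site_table: SiteTable,
    af_low: float,
    af_high: float,
    min_mutations: int = MIN_MUTATIONS,
    lower_inclusive: bool = False,
    upper_inclusive: bool = True,
) -> AfWindowResult:
    """dN/dS restricted to mutations in an allele-frequency window.

    The default window is half-open, ``af_low < AF <= af_high``, so that
    windows partitioning [0, 1] are exact: an "early" window AF > t maps to
    ``(t, 1]`` and a "late" window AF < t to ``[0, t)`` (set
    ``lower_inclusive=True, upper_inclusive=False``).  Records with missing
    AF are skipped and counted.
    """
    if not (0.0 <= af_low < af_high <= 1.0):
        raise SelectionParameterError(f"invalid AF window ({af_low}, {af_high}]")
    missing = 0
    selected = []
    for record in mutations:
        af = record.allele_frequency
        if af is None:
            missing += 1
            continue
        above = af >= af_low if lower_inclusive else af > af_low
        below = af <= af_high if upper_inclusive else af < af_high
        if above and below:
            selected.append(record)
    if missing:
        logger.debug("AF window (%s, %s]: skipped %d records with missing AF",
                     af_low, af_high, missing)
    n, s, _ = count_mutations(selected, site_table)
    estimate = estimate_dnds(n, s, site_table.nN_total, site_table.nS_total, min_mutations)
    return AfWindowResult(estimate, n, s, len(selected), missing)


def replicate_error(groups: Sequence[Sequence[float | SampleProfile]]) -> float:
    """Pooled within-group standard deviation of replicate dN/dS estimates.

    Each group holds estimates from same-patient, same-status samples
    sequenced separately; the pooled SD is
    ``sqrt(sum((n_g - 1) * var_g) / sum(n_g - 1))`` over groups with at least
    two valid estimates.
    """
    ss = 0.0
    dof = 0
    for group in groups:
        values = []
        for item in group:
            if isinstance(item, SampleProfile):
                if item.valid:
                    values.append(item.dnds)
            else:
                values.append(float(item))
        if len(values) >= 2:
            arr = np.asarray(values, dtype=float)
            ss += arr.var(ddof=1) * (len(arr) - 1)
            dof += len(arr) - 1
    if dof == 0:
        raise SelectionParameterError("no replicate group with >= 2 valid estimates")
    return math.sqrt(ss / dof)


def min_mutation_threshold(
    site_table: SiteTable,
    tolerance: float = 0.25,
    confidence: float = 0.95,
    reps: int = 2000,
    seed: int = 0,
    max_m: int = 1000,
) -> int:
    """Smallest mutation burden at which a neutral genome is well estimated.

    For each candidate burden ``m`` the estimator is applied to ``reps``
    neutral samples in which each mutation is nonsilent with probability
    ``nN / (nN + nS)``.  The burden passes when the fraction of finite
    estimates (S > 0) reaches ``confidence`` and the median finite estimate
    lies within ``tolerance`` of 1.  An infinite tolerance disables the
    criterion entirely, so the threshold degenerates to 1.  Deterministic
    given ``seed``.
    """
    if math.isinf(tolerance):
        return 1
    p_nonsilent = site_table.nN_total / (site_table.nN_total + site_table.nS_total)
    ratio = site_table.nN_total / site_table.nS_total
    rng = np.random.default_rng(seed)
    for m in range(1, max_m + 1):
        n = rng.binomial(m, p_nonsilent, size=reps)
        s = m - n
        finite = s > 0
        if finite.mean() < confidence:
            continue
        estimates = (n[finite] / s[finite]) / ratio
        if abs(np.median(estimates) - 1.0) <= tolerance:
            return m
    raise SelectionParameterError(f"criterion unreachable for m <= {max_m}")


def compare_dnds_distributions(
    group_a: Sequence[float],
    group_b: Sequence[float],
) -> float:
    """Two-sided rank-based (Mann-Whitney U) p-value for two dN/dS sets."""
    if len(group_a) < 3 or len(group_b) < 3:
        raise SelectionParameterError("each group needs at least 3 valid estimates")
    return float(stats.mannwhitneyu(group_a, group_b, alternative="two-sided").pvalue)
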