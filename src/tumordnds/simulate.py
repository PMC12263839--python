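"""Synthetic multi-sample tumor cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes of a
real whole-exome cohort: a coding reference, per-sample mutation sets drawn
under a chosen selection strength omega, paired samples whose later dN/dS
contracts toward neutrality by a factor kappa, multi-sample patients with a
positively selected trunk and purifying-selected branches, censored survival
whose hazard rises as the tumor approaches neutrality, and drug exposures
that rescale the distance from neutrality.

Every generated mutation carries a unique identity key, so trunk mutations
shared across samples are recoverable by the clonal partition.  Ground-truth
parameters (true omega values, hazard parameters) are returned alongside the
data and are never consumed by the analysis under test.  All randomness
flows through one ``numpy`` generator derived from the config seed, so a
config reproduces its cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import site_model
from .cohort_io import (
    ClinicalRecord,
    MutationRecord,
    SampleMeta,
    SampleStatus,
    VariantClass,
)
from .regression import PairedObservation
from .selection import MIN_MUTATIONS, estimate_dnds, SampleProfile
from .site_model import SENSE_CODONS, SiteTable


# ---------------------------------------------------------------------------
# distribution specs

@dataclass(frozen=True)
class LogUniform:
    """Log-uniform law on [lo, hi]."""

    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, size=None):
        return np.exp(rng.uniform(math.log(self.lo), math.log(self.hi), size))


@dataclass(frozen=True)
class LogUniformInt:
    """Integer-rounded log-uniform law, for mutation burdens."""

    lo: int
    hi: int

    def sample(self, rng: np.random.Generator, size=None):
        return np.rint(np.exp(rng.uniform(math.log(self.lo), math.log(self.hi), size))).astype(int)


@dataclass(frozen=True)
class Fixed:
    value: float

    def sample(self, rng: np.random.Generator, size=None):
        return np.full(size, self.value) if size is not None else self.value


@dataclass(frozen=True)
class TruncNormal:
    """Normal law truncated to positive values by redrawing."""

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size=None):
        n = size if size is not None else 1
        out = rng.normal(self.mean, self.sd, n)
        while (bad := out <= 0).any():
            out[bad] = rng.normal(self.mean, self.sd, bad.sum())
        return out if size is not None else float(out[0])


@dataclass(frozen=True)
class BetaScaled:
    """Beta(a, b) rescaled to the interval (lo, hi) — an allele-frequency law."""

    a: float
    b: float
    lo: float = 0.0
    hi: float = 1.0

    def sample(self, rng: np.random.Generator, size=None):
        return self.lo + (self.hi - self.lo) * rng.beta(self.a, self.b, size)


#: Clonal (trunk) mutations sit at high AF, subclonal (branch) at low AF; the
#: default laws straddle the conventional early/late window anchors
#: (AF > 0.25 early, AF < 0.33 late).
TRUNK_AF = BetaScaled(8, 8, 0.3, 0.6)
BRANCH_AF = BetaScaled(2, 8, 0.0, 0.35)


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential event times with hazard h0 * exp(beta * (center - DIS)).

    With ``beta > 0`` patients near neutrality (small DIS) have the highest
    hazard.  ``censoring_rate`` is the probability a patient is censored
    before the event; censored patients report a uniform fraction of their
    event time.
    """

    h0: float = 0.05  # baseline hazard per month
    beta: float = 2.0
    center: float = 0.5
    censoring_rate: float = 0.2


@dataclass(frozen=True)
class DrugSpec:
    """A drug and its multiplicative effect on the DIS scale (< 1 pushes
    exposed patients closer to neutrality)."""

    label: str
    effect: float = 1.0
    exposure_prob: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # reference
    n_genes: int = 120
    codons_per_gene: int = 300
    # paired cohort
    n_patients: int = 100
    omega1_law: LogUniform = LogUniform(0.3, 3.0)
    kappa: float = 0.5
    pair_noise_sd: float = 0.1
    mutations_per_sample_law: LogUniformInt = LogUniformInt(100, 5000)
    #: fraction of patients deliberately given a sub-threshold sample so the
    #: validity gate is exercised downstream
    invalid_sample_rate: float = 0.05
    # patient history
    trunk_omega: float = 1.5
    branch_omega: float = 0.7
    trunk_mutations: int = 500
    branch_mutations: int = 500
    trunk_af: BetaScaled = TRUNK_AF
    branch_af: BetaScaled = BRANCH_AF
    # outcome
    survival: SurvivalSpec = SurvivalSpec()
    drugs: tuple[DrugSpec, ...] = (
        DrugSpec("drug_A", 0.5),
        DrugSpec("drug_B", 1.0),
        DrugSpec("drug_C", 0.8),
    )


# ---------------------------------------------------------------------------
# reference

def generate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], SiteTable]:
    """Random stop-free coding sequences and their site table.

    Returns ``(records, site_table)`` where records are (gene, sequence)
    pairs; codons are drawn uniformly from the 61 sense codons.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    codon_array = np.array(SENSE_CODONS)
    records = []
    table = SiteTable()
    for i in range(config.n_genes):
        gene = f"GENE{i + 1:04d}"
        codons = codon_array[rng.integers(0, len(codon_array), config.codons_per_gene)]
        seq = "".join(codons)
        records.append((gene, seq))
        table.per_gene[gene] = site_model.gene_site_counts(seq)
    return records, table


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for gene, seq in records:
            handle.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# samples

def nonsilent_probability(omega: float, site_table: SiteTable) -> float:
    """P(mutation is nonsilent) under selection strength omega."""
    n_n, n_s = site_table.nN_total, site_table.nS_total
    return omega * n_n / (omega * n_n + n_s)


def simulate_counts(
    omega: float,
    m_total: int,
    site_table: SiteTable,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Fast path: draw only the (N, S) split of a sample's mutation burden."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    n = int(rng.binomial(m_total, nonsilent_probability(omega, site_table)))
    return n, m_total - n


def simulate_sample(
    omega: float,
    m_total: int,
    site_table: SiteTable,
    af_law: BetaScaled,
    rng: np.random.Generator,
    patient_id: str = "SIM",
    sample_id: str = "SIM_S1",
    key_prefix: str = "",
) -> list[MutationRecord]:
    """Draw ``m_total`` mutation records under selection strength ``omega``.

    Each mutation is nonsilent with probability omega*nN/(omega*nN + nS)
    (genome totals); its gene is drawn proportionally to the class-matching
    site mass, its AF from ``af_law``.  Each record gets a unique position
    key (stable given the rng state) so cross-sample identity is exact.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    genes = np.array(site_table.genes)
    n_mass = np.array([site_table.per_gene[g].nN for g in genes])
    s_mass = np.array([site_table.per_gene[g].nS for g in genes])
    is_nonsilent = rng.random(m_total) < nonsilent_probability(omega, site_table)
    gene_idx = np.empty(m_total, dtype=int)
    n_count = int(is_nonsilent.sum())
    if n_count:
        gene_idx[is_nonsilent] = rng.choice(len(genes), n_count, p=n_mass / n_mass.sum())
    if m_total - n_count:
        gene_idx[~is_nonsilent] = rng.choice(
            len(genes), m_total - n_count, p=s_mass / s_mass.sum()
        )
    afs = af_law.sample(rng, m_total)
    records = []
    for i in range(m_total):
        nonsilent = bool(is_nonsilent[i])
        records.append(
            MutationRecord(
                patient_id=patient_id,
                sample_id=sample_id,
                gene=str(genes[gene_idx[i]]),
                variant_class=VariantClass.NONSILENT if nonsilent else VariantClass.SILENT,
                allele_frequency=float(np.clip(afs[i], 0.0, 1.0)),
                raw_class="Missense_Mutation" if nonsilent else "Silent",
                position_key=f"{key_prefix}mut{i:06d}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# paired cohort

@dataclass
class PairedCohort:
    profiles: list[SampleProfile]
    pairs: list[PairedObservation]
    truth: pd.DataFrame  # patient_id, omega_1, omega_2_true
    n_redrawn: int = 0


def simulate_paired_cohort(
    config: SimulationConfig,
    site_table: SiteTable | None = None,
    rng: np.random.Generator | None = None,
) -> PairedCohort:
    """Two-sample patients whose later selection strength contracts to 1.

    Per patient: omega_1 ~ omega1_law; omega_2 = 1 + kappa*(omega_1 - 1) +
    Normal(0, pair_noise_sd), redrawn while non-positive; both samples'
    mutation burdens come from ``mutations_per_sample_law`` (a configurable
    fraction of patients get a deliberately sub-threshold first sample);
    dN/dS is then *estimated* from the simulated counts, so the returned
    pairs carry realistic estimation noise on top of the generative law.
    """
    rng = rng or np.random.default_rng(config.seed)
    if site_table is None:
        _, site_table = generate_reference(config, rng)
    profiles: list[SampleProfile] = []
    truth_rows = []
    n_redrawn = 0
    for i in range(config.n_patients):
        patient = f"P{i + 1:04d}"
        omega_1 = float(config.omega1_law.sample(rng))
        omega_2 = 1.0 + config.kappa * (omega_1 - 1.0) + rng.normal(0.0, config.pair_noise_sd)
        while omega_2 <= 0:
            n_redrawn += 1
            omega_2 = 1.0 + config.kappa * (omega_1 - 1.0) + rng.normal(0.0, config.pair_noise_sd)
        m_1 = int(config.mutations_per_sample_law.sample(rng))
        m_2 = int(config.mutations_per_sample_law.sample(rng))
        if rng.random() < config.invalid_sample_rate:
            m_1 = int(rng.integers(0, MIN_MUTATIONS))
        for suffix, omega, m, status, timepoint in (
            ("pre", omega_1, m_1, SampleStatus.PRE_TREATMENT, 1.0),
            ("post", omega_2, m_2, SampleStatus.POST_TREATMENT, 2.0),
        ):
            n, s = simulate_counts(omega, m, site_table, rng)
            meta = SampleMeta(
                patient_id=patient,
                sample_id=f"{patient}_{suffix}",
                status=status,
                timepoint=timepoint,
            )
            profiles.append(
                SampleProfile(
                    patient_id=patient,
                    sample_id=meta.sample_id,
                    N=n,
                    S=s,
                    estimate=estimate_dnds(n, s, site_table.nN_total, site_table.nS_total),
                    meta=meta,
                )
            )
        truth_rows.append(dict(patient_id=patient, omega_1=omega_1, omega_2_true=omega_2))

    pairs = []
    by_patient: dict[str, list[SampleProfile]] = {}
    for profile in profiles:
        by_patient.setdefault(profile.patient_id, []).append(profile)
    for patient, (pre, post) in ((k, tuple(v)) for k, v in by_patient.items()):
        if pre.valid and post.valid:
            pairs.append(
                PairedObservation(
                    patient_id=patient,
                    dnds_1=pre.dnds,
                    dnds_2=post.dnds,
                    n_1=pre.N,
                    n_2=post.N,
                    context="pre_post_treatment",
                )
            )
    return PairedCohort(profiles, pairs, pd.DataFrame(truth_rows), n_redrawn)


# ---------------------------------------------------------------------------
# multi-sample patient history

def simulate_patient_history(
    config: SimulationConfig,
    n_samples: int,
    site_table: SiteTable | None = None,
    rng: np.random.Generator | None = None,
    patient_id: str = "P0001",
) -> dict[str, list[MutationRecord]]:
    """Multi-sample patient: shared trunk plus per-sample private branches.

    Trunk mutations (selection ``trunk_omega``, high-AF law) are generated
    once and replicated into every sample with identical identity keys;
    branch mutations (``branch_omega``, low-AF law) are private per sample.
    """
    if n_samples < 2:
        raise ValueError("a patient history needs at least 2 samples")
    rng = rng or np.random.default_rng(config.seed)
    if site_table is None:
        _, site_table = generate_reference(config, rng)
    trunk = simulate_sample(
        config.trunk_omega, config.trunk_mutations, site_table, config.trunk_af,
        rng, patient_id, "TRUNK", key_prefix="trunk:",
    )
    samples: dict[str, list[MutationRecord]] = {}
    for j in range(n_samples):
        sample_id = f"{patient_id}_S{j + 1}"
        shared = [replace(m, sample_id=sample_id) for m in trunk]
        private = simulate_sample(
            config.branch_omega, config.branch_mutations, site_table, config.branch_af,
            rng, patient_id, sample_id, key_prefix=f"branch{j}:",
        )
        samples[sample_id] = shared + private
    return samples


# ---------------------------------------------------------------------------
# outcomes

def simulate_survival(
    pairs: Sequence[PairedObservation],
    spec: SurvivalSpec,
    rng: np.random.Generator,
    drug_exposures: pd.DataFrame | None = None,
) -> list[ClinicalRecord]:
    """Censored event times whose hazard depends on the distance from neutrality.

    T ~ Exponential(rate = h0 * exp(beta * (center - DIS))); with beta > 0,
    near-neutral patients (small DIS) fail sooner.  Each patient is censored
    with probability ``censoring_rate`` at a uniform fraction of its event
    time.
    """
    exposures = {}
    if drug_exposures is not None:
        exposures = drug_exposures.set_index("patient_id").to_dict("index")
    records = []
    for pair in pairs:
        rate = spec.h0 * math.exp(spec.beta * (spec.center - pair.dis))
        time = float(rng.exponential(1.0 / rate))
        event = True
        if rng.random() < spec.censoring_rate:
            time *= float(rng.uniform(0.05, 1.0))
            event = False
        drug_row = exposures.get(pair.patient_id, {})
        drugs = frozenset(d for d, v in drug_row.items() if d.startswith("drug") and v == 1)
        records.append(
            ClinicalRecord(
                patient_id=pair.patient_id,
                survival_time=max(time, 1e-6),
                event=event,
                drugs=drugs,
            )
        )
    return records


def simulate_drug_exposures(
    config: SimulationConfig,
    patient_ids: Sequence[str],
    rng: np.random.Generator,
    base_dis_scale: float = 0.5,
) -> pd.DataFrame:
    """Random drug exposures and the DIS values they shape.

    Each exposed drug multiplies the scale of the patient's exponential DIS
    law by its effect; halving the scale doubles the hazard of reaching
    neutrality, so a drug with effect 0.5 carries a true Cox HR of 2.
    Returns a frame with patient_id, dis and one 0/1 column per drug.
    """
    rows = []
    for patient in patient_ids:
        scale = base_dis_scale
        exposure = {}
        for drug in config.drugs:
            exposed = int(rng.random() < drug.exposure_prob)
            exposure[drug.label] = exposed
            if exposed:
                scale *= drug.effect
        dis = float(rng.exponential(scale))
        rows.append(dict(patient_id=patient, dis=dis, **exposure))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk cohort

def write_cohort(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic cohort in the formats the readers consume.

    Produces reference.fasta, site_table.tsv, mutations.maf.tsv, samples.tsv,
    clinical.tsv and truth.tsv under ``out_dir``; fully determined by
    ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records, site_table = generate_reference(config, rng)
    write_fasta(records, out / "reference.fasta")
    site_table.to_tsv(out / "site_table.tsv")

    cohort = simulate_paired_cohort(config, site_table, rng)

    maf_rows = []
    meta_rows = []
    for profile in cohort.profiles:
        meta = profile.meta
        meta_rows.append(
            dict(
                Patient_ID=meta.patient_id,
                Tumor_Sample_Barcode=meta.sample_id,
                status=meta.status.value,
                timepoint=meta.timepoint,
            )
        )
        # regenerate per-mutation rows consistent with the profile counts
        for klass, count in (("Missense_Mutation", profile.N), ("Silent", profile.S)):
            if count == 0:
                continue
            genes = np.array(site_table.genes)
            mass = np.array(
                [
                    site_model_mass.nN if klass == "Missense_Mutation" else site_model_mass.nS
                    for site_model_mass in site_table.per_gene.values()
                ]
            )
            idx = rng.choice(len(genes), count, p=mass / mass.sum())
            afs = np.clip(rng.beta(2, 4, count), 0.0, 1.0)
            for k in range(count):
                maf_rows.append(
                    dict(
                        Hugo_Symbol=str(genes[idx[k]]),
                        Variant_Classification=klass,
                        Tumor_Sample_Barcode=meta.sample_id,
                        Patient_ID=meta.patient_id,
                        AF=round(float(afs[k]), 4),
                    )
                )
    pd.DataFrame(maf_rows).to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    exposures = simulate_drug_exposures(
        config, [p.patient_id for p in cohort.profiles[::2]], rng
    )
    clinical = simulate_survival(cohort.pairs, config.survival, rng, exposures)
    clin_frame = pd.DataFrame(
        dict(
            Patient_ID=[r.patient_id for r in clinical],
            survival_time=[round(r.survival_time, 6) for r in clinical],
            event=[int(r.event) for r in clinical],
        )
    )
    for drug in config.drugs:
        exposed = exposures.set_index("patient_id")[drug.label]
        clin_frame[drug.label] = [
            int(exposed.get(p, 0)) for p in clin_frame["Patient_ID"]
        ]
    clin_frame.to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return {
        "fasta": out / "reference.fasta",
        "site_table": out / "site_table.tsv",
        "maf": out / "mutations.maf.tsv",
        "samples": out / "samples.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.tsv",
    }
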