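"""Nonsynonymous / synonymous site counting over coding sequences.

The genome-level selection estimator normalises observed mutation counts by
the number of sites at which each kind of mutation could occur.  For every
sense codon, each of the three positions contributes a synonymous-site
fraction equal to the share of its three possible single-nucleotide
substitutions that preserve the encoded amino acid; the remainder is
nonsynonymous.  Substitutions that create a stop codon are protein-changing
and therefore count as nonsynonymous.  All nine neighbours of a codon are
weighted equally (no transition/transversion bias).

The whole exome is treated as one concatenated coding sequence: per-gene
site counts are summed into genome totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_CODE.stop_codons)
SENSE_CODONS = tuple(sorted(_CODE.forward_table))


class SiteModelError(ValueError):
    """Invalid codon or coding sequence."""


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Return ``(nN, nS)`` site counts for one sense codon.

    For each of the three positions the synonymous fraction is the number of
    the three possible substitutions that leave the amino acid unchanged,
    divided by 3.  ``nS`` sums those fractions; ``nN = 3 - nS``, so the two
    always add up to exactly 3.

    Raises
    ------
    SiteModelError
        If the codon contains a base outside {A, C, G, T} or is a stop codon
        (stop codons carry no protein-level selection information and are
        excluded from site counting).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise SiteModelError(f"not an unambiguous DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        raise SiteModelError(f"stop codon {codon!r} is excluded from site counting")
    return _SITE_COUNTS[codon]


def _enumerate_codon(codon: str) -> tuple[float, float]:
    aa = _CODE.forward_table[codon]
    n_syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            # mutation to a stop is protein-changing, hence nonsynonymous
            if neighbour not in STOP_CODONS and _CODE.forward_table[neighbour] == aa:
                n_syn += 1
    n_s = n_syn / 3.0
    return 3.0 - n_s, n_s


_SITE_COUNTS: Mapping[str, tuple[float, float]] = {
    c: _enumerate_codon(c) for c in SENSE_CODONS
}


@dataclass(frozen=True)
class GeneSites:
    """Site counts for one gene."""

    nN: float
    nS: float
    length_nt: int


@dataclass
class SiteTable:
    """Per-gene and genome-total nonsynonymous/synonymous site counts."""

    per_gene: dict[str, GeneSites] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.per_gene)

    @property
    def nN_total(self) -> float:
        return sum(g.nN for g in self.per_gene.values())

    @property
    def nS_total(self) -> float:
        return sum(g.nS for g in self.per_gene.values())

    @property
    def length_total(self) -> int:
        return sum(g.length_nt for g in self.per_gene.values())

    def subset_mass(self, genes: Iterable[str]) -> tuple[float, float, int]:
        """``(nN, nS, length_nt)`` summed over ``genes``."""
        n_n = n_s = 0.0
        length = 0
        for gene in genes:
            sites = self.per_gene[gene]
            n_n += sites.nN
            n_s += sites.nS
            length += sites.length_nt
        return n_n, n_s, length

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("gene\tnN\tnS\tlength_nt\n")
            for gene, sites in self.per_gene.items():
                handle.write(
                    f"{gene}\t{sites.nN:.6f}\t{sites.nS:.6f}\t{sites.length_nt}\n"
                )
            handle.write(
                f"TOTAL\t{self.nN_total:.6f}\t{self.nS_total:.6f}\t{self.length_total}\n"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteTable":
        table = cls()
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[:4] != ["gene", "nN", "nS", "length_nt"]:
                raise SiteModelError(f"unexpected site-table header in {path}")
            for line in handle:
                gene, n_n, n_s, length = line.rstrip("\n").split("\t")[:4]
                if gene == "TOTAL":
                    continue
                table.per_gene[gene] = GeneSites(float(n_n), float(n_s), int(length))
        return table


def gene_site_counts(cds: str) -> GeneSites:
    """Site counts for one coding sequence.

    The terminal stop codon, if present, is trimmed before counting.

    Raises
    ------
    SiteModelError
        If, after trimming, the sequence is empty, has a length not divisible
        by 3, contains an ambiguous base, or contains an internal stop codon.
    """
    seq = cds.upper()
    if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    if not seq:
        raise SiteModelError("empty coding sequence")
    if len(seq) % 3 != 0:
        raise SiteModelError(f"length {len(seq)} is not a multiple of 3")
    n_n = n_s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise SiteModelError(f"internal stop codon at position {i}")
        c_n, c_s = codon_site_counts(codon)
        n_n += c_n
        n_s += c_s
    return GeneSites(n_n, n_s, len(seq))


def build_site_table(cds_fasta: str | Path) -> SiteTable:
    """Build a :class:`SiteTable` from a FASTA of coding sequences.

    One record per gene; the record identifier is taken as the gene symbol.
    Genes that fail validation (ambiguous bases, internal stops, length not a
    multiple of 3) are skipped with a warning rather than repaired.

    Raises
    ------
    SiteModelError
        If no gene passes validation.
    """
    table = SiteTable()
    skipped = 0
    for record in SeqIO.parse(str(cds_fasta), "fasta"):
        gene = record.id
        if gene in table.per_gene:
            logger.warning("duplicate gene %s: keeping the first record", gene)
            skipped += 1
            continue
        try:
            table.per_gene[gene] = gene_site_counts(str(record.seq))
        except SiteModelError as exc:
            logger.warning("skipping gene %s: %s", gene, exc)
            skipped += 1
    if not table.per_gene:
        raise SiteModelError(f"no valid coding sequences in {cds_fasta}")
    if skipped:
        logger.info("site table built with %d genes (%d skipped)", len(table.per_gene), skipped)
    # guard against accumulated floating error in the per-codon identity
    assert math.isclose(table.nN_total + table.nS_total, table.length_total)
    return table
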