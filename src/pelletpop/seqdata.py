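"""Phased-allele sequence data: FASTA I/O, alignment cleaning, allele encoding.

A diploid individual contributes two phased allele sequences per intron
locus.  The on-disk convention is one FASTA per locus with record ids
``<sampleID>_a1`` / ``<sampleID>_a2``.  Alignments are cleaned by removing
every column that contains a gap or a non-ACGT symbol in any sequence, after
which distinct allele sequences are numbered to give a multi-allelic
genotype table suitable for F-statistics.

Columns and positions are 0-based internally and 1-based in reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pelletpop")

VALID_BASES = frozenset("ACGT")

#: default header dialect: ``<sample>_a1`` / ``<sample>_a2``
ALLELE_HEADER_RE = re.compile(r"^(?P<sample>.+)_a(?P<allele>[12])$")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent phased alignments."""


@dataclass
class AlignedLocus:
    """A per-locus alignment of phased allele pairs keyed by individual.

    Parameters
    ----------
    locus_name : str
        Identifier of the locus (e.g. intron name).
    alleles : dict
        Maps individual id to its ``(allele1, allele2)`` sequence pair.
        The two alleles may be identical (homozygote).
    """

    locus_name: str
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for pair in self.alleles.values() for s in pair}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus_name!r}: sequences of unequal length {sorted(lengths)}"
            )
        if self.alleles and next(iter(lengths)) == 0:
            raise AlignmentError(f"locus {self.locus_name!r}: zero-length alignment")

    @property
    def length(self) -> int:
        """Alignment length in bp (0 for an empty locus)."""
        if not self.alleles:
            return 0
        return len(next(iter(self.alleles.values()))[0])

    @property
    def individuals(self) -> list[str]:
        return sorted(self.alleles)

    def allele_sequences(self, subset=None) -> list[str]:
        """All allele sequences (two per individual), in sorted individual order."""
        inds = self.individuals if subset is None else sorted(set(subset) & set(self.alleles))
        return [s for ind in inds for s in self.alleles[ind]]

    def is_clean(self) -> bool:
        return all(
            set(s) <= VALID_BASES for pair in self.alleles.values() for s in pair
        )


def read_phased_fasta(path, locus_name: str | None = None,
                      header_re: re.Pattern | str = ALLELE_HEADER_RE) -> AlignedLocus:
    """Read one locus of phased alleles from FASTA.

    Headers must match ``header_re`` with named groups ``sample`` and
    ``allele`` (values "1"/"2").  Lowercase input is normalized to uppercase.
    Unpaired allele records raise :class:`AlignmentError` naming the sample.
    """
    if isinstance(header_re, str):
        header_re = re.compile(header_re)
    path = str(path)
    if locus_name is None:
        locus_name = re.sub(r"\.(fa|fasta|fna)$", "", path.rsplit("/", 1)[-1])
    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        m = header_re.match(rec.id)
        if m is None:
            raise AlignmentError(
                f"locus {locus_name!r}: header {rec.id!r} does not match allele dialect"
            )
        sample, allele = m.group("sample"), m.group("allele")
        slot = pairs.setdefault(sample, {})
        if allele in slot:
            raise AlignmentError(f"locus {locus_name!r}: duplicate allele _{allele} for {sample!r}")
        slot[allele] = str(rec.seq).upper()
    alleles = {}
    for sample, slot in pairs.items():
        if set(slot) != {"1", "2"}:
            raise AlignmentError(
                f"locus {locus_name!r}: sample {sample!r} has unpaired allele records"
            )
        alleles[sample] = (slot["1"], slot["2"])
    return AlignedLocus(locus_name=locus_name, alleles=alleles)


def write_phased_fasta(locus: AlignedLocus, path) -> None:
    """Write a locus back to FASTA in the ``_a1``/``_a2`` dialect (sorted ids)."""
    records = []
    for ind in locus.individuals:
        a1, a2 = locus.alleles[ind]
        records.append(SeqRecord(Seq(a1), id=f"{ind}_a1", description=""))
        records.append(SeqRecord(Seq(a2), id=f"{ind}_a2", description=""))
    SeqIO.write(records, str(path), "fasta")


def clean_alignment(locus: AlignedLocus) -> AlignedLocus:
    """Remove every column containing a gap or non-ACGT symbol in any sequence.

    Column removal is the only edit; the operation is idempotent.  Raises
    :class:`AlignmentError` if every column is removed.
    """
    if not locus.alleles:
        return replace(locus)
    seqs = locus.allele_sequences()
    arr = np.array([list(s) for s in seqs])
    keep = np.ones(arr.shape[1], dtype=bool)
    for j in range(arr.shape[1]):
        keep[j] = set(arr[:, j]) <= VALID_BASES
    if not keep.any():
        raise AlignmentError(f"locus {locus.locus_name!r}: all columns removed by cleaning")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("locus %s: removed %d of %d columns", locus.locus_name, n_removed,
                    arr.shape[1])
    cleaned = {}
    for ind in locus.individuals:
        a1, a2 = locus.alleles[ind]
        cleaned[ind] = (
            "".join(np.array(list(a1))[keep]),
            "".join(np.array(list(a2))[keep]),
        )
    return AlignedLocus(locus_name=locus.locus_name, alleles=cleaned)


def encode_alleles(locus: AlignedLocus, subset=None) -> tuple[dict[str, tuple[int, int]], int]:
    """Number the distinct allele sequences at a locus.

    Identical sequences share one code; codes 1..k are assigned by first
    occurrence scanning individuals in sorted-id order (allele 1 before
    allele 2), so the output is stable under input-order permutation.

    Returns ``(codes, k)`` where ``codes`` maps individual to its unordered
    genotype ``(c1, c2)`` and ``k`` is the number of distinct alleles among
    the subset.
    """
    inds = locus.individuals if subset is None else sorted(set(subset) & set(locus.alleles))
    if not inds:
        raise ValueError(f"locus {locus.locus_name!r}: empty individual subset")
    code_of: dict[str, int] = {}
    codes: dict[str, tuple[int, int]] = {}
    for ind in inds:
        pair = []
        for seq in locus.alleles[ind]:
            if seq not in code_of:
                code_of[seq] = len(code_of) + 1
            pair.append(code_of[seq])
        codes[ind] = (pair[0], pair[1])
    return codes, len(code_of)


@dataclass
class GenotypeTable:
    """Multi-allelic integer-coded diploid genotypes (individuals x loci).

    ``codes[(individual, locus)]`` is an unordered pair of 1-based allele
    codes; absent keys are missing genotypes.  ``populations`` labels each
    individual.
    """

    individuals: list[str]
    loci: list[str]
    codes: dict[tuple[str, str], tuple[int, int]]
    populations: dict[str, str]
    allele_counts: dict[str, int] = field(default_factory=dict)

    def n_typed_loci(self, individual: str) -> int:
        return sum(1 for loc in self.loci if (individual, loc) in self.codes)

    def filter_min_loci(self, min_loci: int) -> "GenotypeTable":
        """Keep individuals typed at ``min_loci`` or more loci."""
        keep = [i for i in self.individuals if self.n_typed_loci(i) >= min_loci]
        return GenotypeTable(
            individuals=keep,
            loci=list(self.loci),
            codes={k: v for k, v in self.codes.items() if k[0] in set(keep)},
            populations={i: self.populations[i] for i in keep},
            allele_counts=dict(self.allele_counts),
        )

    def total_alleles(self) -> int:
        """Total distinct alleles summed over loci (single source of truth)."""
        return sum(self.allele_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for loc in self.loci:
                pair = self.codes.get((ind, loc))
                rows.append({
                    "sample": ind,
                    "pop": self.populations.get(ind),
                    "locus": loc,
                    "allele1_code": pair[0] if pair else None,
                    "allele2_code": pair[1] if pair else None,
                })
        return pd.DataFrame(rows)


def build_genotype_table(loci: list[AlignedLocus], populations: dict[str, str],
                         subset=None) -> GenotypeTable:
    """Encode a set of cleaned loci into one multi-allelic genotype table.

    ``subset`` restricts the encoded individuals (e.g. to the analysis
    grouping); allele counts per locus are computed over that same subset so
    the table's allele total is consistent with downstream statistics.
    """
    all_inds: set[str] = set()
    codes: dict[tuple[str, str], tuple[int, int]] = {}
    allele_counts: dict[str, int] = {}
    for locus in loci:
        loc_codes, k = encode_alleles(locus, subset=subset)
        allele_counts[locus.locus_name] = k
        for ind, pair in loc_codes.items():
            codes[(ind, locus.locus_name)] = pair
            all_inds.add(ind)
    individuals = sorted(all_inds)
    pops = {i: populations[i] for i in individuals if i in populations}
    missing = [i for i in individuals if i not in pops]
    if missing:
        raise ValueError(f"individuals without population label: {missing[:5]}")
    return GenotypeTable(individuals=individuals, loci=[l.locus_name for l in loci],
                         codes=codes, populations=pops, allele_counts=allele_counts)


def individual_heterozygosity(individual: str, loci: list[AlignedLocus],
                              per_locus_mean: bool = False) -> float:
    """Heterozygous positions per bp for one individual, pooled over loci.

    The default pools counts: (sum of positions where allele1 != allele2 over
    the individual's available loci) divided by (sum of those loci's cleaned
    lengths).  ``per_locus_mean=True`` instead averages per-locus rates
    (non-default alternative).
    """
    het_sites = []
    lengths = []
    for locus in loci:
        pair = locus.alleles.get(individual)
        if pair is None:
            continue
        a1, a2 = pair
        het_sites.append(sum(1 for x, y in zip(a1, a2) if x != y))
        lengths.append(len(a1))
    if not lengths:
        raise ValueError(f"individual {individual!r} absent from every locus")
    if per_locus_mean:
        return float(np.mean([h / ln for h, ln in zip(het_sites, lengths)]))
    return float(sum(het_sites) / sum(lengths))
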