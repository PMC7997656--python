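"""Informative-SNP classification for paired genomes.

Two genomes sharing one circulation (mother/fetus, donor/recipient) can be
told apart at loci where their genotypes differ. Conventionally genome A
is the host whose plasma is sampled (mother, recipient) and genome B the
second genome (fetus, donor). Categories:

* ``A_SPECIFIC`` — A heterozygous x/y, B homozygous x/x: allele y marks
  molecules that can only come from genome A.
* ``B_SPECIFIC`` — A homozygous x/x, B heterozygous x/y: allele y marks
  genome B (e.g. a fetal-specific allele).
* ``DUAL`` — both homozygous for different alleles: every molecule at the
  locus is assignable to one genome.
* ``UNINFORMATIVE`` — anything else.

The fetal (or graft) DNA fraction follows from fragment counts at
B_SPECIFIC loci: with fetal fraction F and a heterozygous fetus, a
proportion F/2 of molecules carry the fetal-specific allele and 1 - F/2
the shared allele, hence F = 2s / (s + h).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

_VALID_ALLELES = frozenset("ACGT")
# allele pairs collapsed by bisulfite conversion (C->T on the + strand,
# G->A on the - strand)
_BISULFITE_PAIRS = (frozenset("CT"), frozenset("GA"))


class SnpCategory(str, enum.Enum):
    A_SPECIFIC = "A_SPECIFIC"
    B_SPECIFIC = "B_SPECIFIC"
    DUAL = "DUAL"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class Genotype:
    """A biallelic genotype at one locus; the allele pair is unordered."""

    chrom: str
    pos: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        for a in (self.allele1, self.allele2):
            if a not in _VALID_ALLELES:
                raise ValueError(f"invalid allele {a!r} at {self.chrom}:{self.pos}")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele1, self.allele2))

    @property
    def is_hom(self) -> bool:
        return self.allele1 == self.allele2


@dataclass(frozen=True)
class InformativeSnp:
    chrom: str
    pos: int
    category: SnpCategory
    specific_allele: str | None = None
    shared_allele: str | None = None
    # for DUAL loci: allele carried by genome A / genome B
    allele_a: str | None = None
    allele_b: str | None = None
    bisulfite_ambiguous: bool = False
    reason: str | None = None

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _ambiguous(pair: frozenset[str]) -> bool:
    return pair in _BISULFITE_PAIRS


def classify_snp_pair(gt_a: Genotype | None, gt_b: Genotype | None,
                      chrom: str | None = None, pos: int | None = None) -> InformativeSnp:
    """Classify one locus by the genotype relationship of genomes A and B.

    A missing genotype on either side yields UNINFORMATIVE with a reason
    flag rather than an error. C/T and G/A allele pairs are retained but
    flagged ``bisulfite_ambiguous``: after bisulfite conversion the
    unmethylated-C strand cannot distinguish them, and the fragment
    partition decides usability per strand.
    """
    if gt_a is None or gt_b is None:
        present = gt_a or gt_b
        if present is None and (chrom is None or pos is None):
            raise ValueError("locus unknown: both genotypes missing")
        return InformativeSnp(
            chrom=chrom if present is None else present.chrom,
            pos=pos if present is None else present.pos,
            category=SnpCategory.UNINFORMATIVE,
            reason="missing_genotype",
        )
    if (gt_a.chrom, gt_a.pos) != (gt_b.chrom, gt_b.pos):
        raise ValueError(
            f"mismatched loci: {gt_a.chrom}:{gt_a.pos} vs {gt_b.chrom}:{gt_b.pos}"
        )
    chrom, pos = gt_a.chrom, gt_a.pos

    if gt_a.is_hom and gt_b.is_hom:
        if gt_a.alleles != gt_b.alleles:
            pair = gt_a.alleles | gt_b.alleles
            return InformativeSnp(
                chrom, pos, SnpCategory.DUAL,
                allele_a=gt_a.allele1, allele_b=gt_b.allele1,
                bisulfite_ambiguous=_ambiguous(frozenset(pair)),
            )
        return InformativeSnp(chrom, pos, SnpCategory.UNINFORMATIVE)

    for het, hom, category in (
        (gt_a, gt_b, SnpCategory.A_SPECIFIC),
        (gt_b, gt_a, SnpCategory.B_SPECIFIC),
    ):
        if not het.is_hom and hom.is_hom and hom.allele1 in het.alleles:
            shared = hom.allele1
            (specific,) = het.alleles - {shared}
            return InformativeSnp(
                chrom, pos, category,
                specific_allele=specific, shared_allele=shared,
                bisulfite_ambiguous=_ambiguous(frozenset((specific, shared))),
            )
    return InformativeSnp(chrom, pos, SnpCategory.UNINFORMATIVE)


@dataclass
class InformativeSnpSet:
    """Classified loci indexed by (chrom, pos), with category counts."""

    snps: dict[tuple[str, int], InformativeSnp] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[InformativeSnp]:
        return iter(self.snps.values())

    def get(self, chrom: str, pos: int) -> InformativeSnp | None:
        return self.snps.get((chrom, pos))

    def counts(self) -> dict[SnpCategory, int]:
        out = {c: 0 for c in SnpCategory}
        for snp in self.snps.values():
            out[snp.category] += 1
        return out

    def informative(self) -> "InformativeSnpSet":
        return InformativeSnpSet(
            {
                loc: s
                for loc, s in self.snps.items()
                if s.category is not SnpCategory.UNINFORMATIVE
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "category": s.category.value,
                "specific_allele": s.specific_allele or ".",
                "shared_allele": s.shared_allele or ".",
                "allele_a": s.allele_a or ".",
                "allele_b": s.allele_b or ".",
                "bisulfite_ambiguous": int(s.bisulfite_ambiguous),
            }
            for s in sorted(self, key=lambda s: (s.chrom, s.pos))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "category", "specific_allele", "shared_allele",
                "allele_a", "allele_b", "bisulfite_ambiguous",
            ],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "InformativeSnpSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        snps = {}
        for row in df.itertuples(index=False):
            snp = InformativeSnp(
                chrom=str(row.chrom),
                pos=int(row.pos),
                category=SnpCategory(row.category),
                specific_allele=None if row.specific_allele == "." else row.specific_allele,
                shared_allele=None if row.shared_allele == "." else row.shared_allele,
                allele_a=None if row.allele_a == "." else row.allele_a,
                allele_b=None if row.allele_b == "." else row.allele_b,
                bisulfite_ambiguous=bool(row.bisulfite_ambiguous),
            )
            snps[snp.locus] = snp
        return cls(snps)


def enumerate_informative_snps(
    genotypes_a: Mapping[tuple[str, int], Genotype],
    genotypes_b: Mapping[tuple[str, int], Genotype],
) -> InformativeSnpSet:
    """Classify every locus genotyped in both genomes."""
    shared_loci = set(genotypes_a) & set(genotypes_b)
    if not shared_loci:
        raise ValueError("no loci genotyped in both genomes")
    snps = {
        locus: classify_snp_pair(genotypes_a[locus], genotypes_b[locus])
        for locus in shared_loci
    }
    return InformativeSnpSet(snps)


def estimate_fetal_fraction(n_specific: int, n_shared: int) -> float:
    """Fetal (or donor) DNA fraction from allele-tagged fragment counts.

    ``n_specific`` fragments carry the B-specific (e.g. fetal-specific)
    allele and ``n_shared`` the shared allele at the same B_SPECIFIC loci.
    With genome B heterozygous at these loci only half of its molecules
    carry the specific allele, so F = 2s / (s + h), clipped to [0, 1].
    """
    if n_specific < 0 or n_shared < 0:
        raise ValueError("fragment counts must be non-negative")
    total = n_specific + n_shared
    if total == 0:
        raise ValueError("no fragments at B-specific loci")
    return min(1.0, 2.0 * n_specific / total)


def read_genotypes(path: str | Path) -> dict[tuple[str, int], Genotype]:
    """Read genotypes from a 4-column TSV (chrom, pos, allele1, allele2)
    or a VCF (first sample's GT, biallelic SNPs only)."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf_genotypes(path)
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "allele1", "allele2"],
        dtype={"chrom": str},
        comment="#",
    )
    return {
        (str(c), int(p)): Genotype(str(c), int(p), a1, a2)
        for c, p, a1, a2 in zip(df["chrom"], df["pos"], df["allele1"], df["allele2"])
    }


def _read_vcf_genotypes(path: Path) -> dict[tuple[str, int], Genotype]:
    """Biallelic SNP records, GT of the first sample."""
    from cyvcf2 import VCF

    out: dict[tuple[str, int], Genotype] = {}
    for record in VCF(str(path)):
        if len(record.REF) != 1 or len(record.ALT) != 1 or len(record.ALT[0]) != 1:
            continue
        a, b = record.genotypes[0][:2]
        if a < 0 or b < 0:  # missing call
            continue
        alleles = [record.REF if g == 0 else record.ALT[0] for g in (a, b)]
        out[(record.CHROM, record.POS)] = Genotype(
            record.CHROM, record.POS, alleles[0], alleles[1]
        )
    return out
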