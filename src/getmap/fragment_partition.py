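"""Allele-based fragment classification and per-class methylation vectors.

Each bisulfite plasma fragment may overlap informative SNP loci and/or
candidate mutation loci, plus one or more CpG sites with an observed
methylation state. A fragment is analyzable only if it carries at least
one genotype-discriminating allele *and* at least one CpG observation.

Class votes per usable SNP/mutation observation:

* A_SPECIFIC locus, specific allele observed -> CLASS_A
* B_SPECIFIC locus, specific allele -> CLASS_B; shared allele -> SHARED
* DUAL locus, genome-A allele -> CLASS_A; genome-B allele -> CLASS_B
* mutation locus, alternate allele -> MUTANT; reference allele -> WILDTYPE

Fragments whose observations vote for different classes are CONFLICT and
excluded from every class; fragments with no informative overlap are
UNCLASSIFIED. Observations flagged bisulfite-ambiguous for the fragment's
strand (C/T or G/A alleles made unreadable by conversion) are ignored.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from getmap.reference_panel import CpGSite
from getmap.genotyping import InformativeSnpSet, SnpCategory
from getmap.variant_calling import VariantCall


class FragmentClass(str, enum.Enum):
    CLASS_A = "CLASS_A"
    CLASS_B = "CLASS_B"
    SHARED = "SHARED"
    MUTANT = "MUTANT"
    WILDTYPE = "WILDTYPE"
    UNCLASSIFIED = "UNCLASSIFIED"
    CONFLICT = "CONFLICT"


class MethState(str, enum.Enum):
    METHYLATED = "M"
    UNMETHYLATED = "U"


class SnpObservation(NamedTuple):
    chrom: str
    pos: int
    base: str
    bisulfite_ambiguous: bool = False


class CpgObservation(NamedTuple):
    site: CpGSite
    methylated: bool


@dataclass
class Fragment:
    """One sequenced cfDNA molecule with its SNP and CpG observations.

    Paired-end read overlap is collapsed upstream, so a fragment carries
    at most one observation per CpG site.
    """

    id: str
    snp_observations: list[SnpObservation] = field(default_factory=list)
    cpg_observations: list[CpgObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_observations and not self.cpg_observations:
            raise ValueError(f"fragment {self.id}: no observations")
        cpg_sites = [o.site for o in self.cpg_observations]
        if len(set(cpg_sites)) != len(cpg_sites):
            raise ValueError(f"fragment {self.id}: duplicate CpG site observation")
        snp_loci = [(o.chrom, o.pos) for o in self.snp_observations]
        if len(set(snp_loci)) != len(snp_loci):
            raise ValueError(f"fragment {self.id}: duplicate SNP locus observation")


def assign_fragment_class(
    fragment: Fragment,
    snps: InformativeSnpSet | None = None,
    mutations: Mapping[tuple[str, int], VariantCall] | Iterable[VariantCall] | None = None,
) -> FragmentClass:
    """Vote-based class assignment for one fragment."""
    mut_by_locus: dict[tuple[str, int], VariantCall] = {}
    if mutations is not None:
        if isinstance(mutations, Mapping):
            mut_by_locus = dict(mutations)
        else:
            mut_by_locus = {m.locus: m for m in mutations}

    votes: set[FragmentClass] = set()
    for obs in fragment.snp_observations:
        if obs.bisulfite_ambiguous:
            continue
        locus = (obs.chrom, obs.pos)
        snp = snps.get(obs.chrom, obs.pos) if snps is not None else None
        if snp is not None and snp.category is not SnpCategory.UNINFORMATIVE:
            if snp.category is SnpCategory.A_SPECIFIC:
                if obs.base == snp.specific_allele:
                    votes.add(FragmentClass.CLASS_A)
            elif snp.category is SnpCategory.B_SPECIFIC:
                if obs.base == snp.specific_allele:
                    votes.add(FragmentClass.CLASS_B)
                elif obs.base == snp.shared_allele:
                    votes.add(FragmentClass.SHARED)
            elif snp.category is SnpCategory.DUAL:
                if obs.base == snp.allele_a:
                    votes.add(FragmentClass.CLASS_A)
                elif obs.base == snp.allele_b:
                    votes.add(FragmentClass.CLASS_B)
            continue
        mut = mut_by_locus.get(locus)
        if mut is not None:
            if obs.base == mut.alt:
                votes.add(FragmentClass.MUTANT)
            elif obs.base == mut.ref:
                votes.add(FragmentClass.WILDTYPE)

    if not votes:
        return FragmentClass.UNCLASSIFIED
    if len(votes) > 1:
        return FragmentClass.CONFLICT
    return votes.pop()


def partition_fragments(
    fragments: Sequence[Fragment],
    snps: InformativeSnpSet | None = None,
    mutations: Mapping[tuple[str, int], VariantCall] | Iterable[VariantCall] | None = None,
) -> dict[FragmentClass, list[Fragment]]:
    """Group fragments by assigned class; every fragment lands in exactly
    one bucket (classified, UNCLASSIFIED or CONFLICT)."""
    out: dict[FragmentClass, list[Fragment]] = defaultdict(list)
    for f in fragments:
        out[assign_fragment_class(f, snps, mutations)].append(f)
    return dict(out)


@dataclass
class MethylationVector:
    """Aggregate methylation of one allele-defined fragment class.

    For each selected CpG site covered by at least one fragment,
    ``density[i] = methylated_count[i] / covering_count[i]`` — the
    fraction of class fragments methylated at that site (the x vector
    matched against the reference matrix in deconvolution).
    """

    class_label: str
    sites: list[CpGSite]
    methylated_count: np.ndarray
    covering_count: np.ndarray

    def __post_init__(self) -> None:
        self.methylated_count = np.asarray(self.methylated_count, dtype=int)
        self.covering_count = np.asarray(self.covering_count, dtype=int)
        if (self.covering_count < 1).any():
            raise ValueError("every retained site needs >= 1 covering fragment")
        if (self.methylated_count > self.covering_count).any():
            raise ValueError("methylated count exceeds coverage")

    @property
    def density(self) -> np.ndarray:
        return self.methylated_count / self.covering_count

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "methylated": self.methylated_count,
                "covering": self.covering_count,
                "density": self.density,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, class_label: str = "class") -> "MethylationVector":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            class_label=class_label,
            sites=[CpGSite(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])],
            methylated_count=df["methylated"].to_numpy(),
            covering_count=df["covering"].to_numpy(),
        )


def aggregate_methylation(
    fragments: Sequence[Fragment],
    mask: Iterable[CpGSite],
    class_label: str = "class",
) -> MethylationVector:
    """Tally per-site methylation over one class of fragments.

    Only CpG sites inside ``mask`` (the informative-site selection) are
    tallied; sites covered by no fragment are absent from the output.
    """
    if not fragments:
        raise ValueError("empty fragment list")
    mask_set = set(mask)
    meth: dict[CpGSite, int] = defaultdict(int)
    cover: dict[CpGSite, int] = defaultdict(int)
    for frag in fragments:
        if not frag.cpg_observations:
            raise ValueError(f"fragment {frag.id}: no CpG observations")
        for obs in frag.cpg_observations:
            if obs.site not in mask_set:
                continue
            cover[obs.site] += 1
            if obs.methylated:
                meth[obs.site] += 1
    sites = sorted(cover)
    return MethylationVector(
        class_label=class_label,
        sites=sites,
        methylated_count=np.array([meth[s] for s in sites], dtype=int),
        covering_count=np.array([cover[s] for s in sites], dtype=int),
    )


def read_fragments(path: str | Path) -> list[Fragment]:
    """Read fragments from TSV: id, comma-joined SNP observations
    ``chrom:pos:base[:*]`` ('*' = bisulfite-ambiguous), comma-joined CpG
    observations ``chrom:pos:M|U``. '.' marks an empty field."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["id", "snps", "cpgs"], dtype=str
    )
    fragments = []
    for row in df.itertuples(index=False):
        snp_obs = []
        if isinstance(row.snps, str) and row.snps != ".":
            for token in row.snps.split(","):
                parts = token.split(":")
                if len(parts) not in (3, 4):
                    raise ValueError(f"bad SNP observation {token!r} in {row.id}")
                snp_obs.append(
                    SnpObservation(
                        parts[0], int(parts[1]), parts[2],
                        bisulfite_ambiguous=len(parts) == 4 and parts[3] == "*",
                    )
                )
        cpg_obs = []
        if isinstance(row.cpgs, str) and row.cpgs != ".":
            for token in row.cpgs.split(","):
                chrom, pos, state = token.split(":")
                cpg_obs.append(
                    CpgObservation(CpGSite(chrom, int(pos)), state.upper() == "M")
                )
        fragments.append(
            Fragment(id=str(row.id), snp_observations=snp_obs, cpg_observations=cpg_obs)
        )
    return fragments


def write_fragments(fragments: Sequence[Fragment], path: str | Path) -> None:
    rows = []
    for f in fragments:
        snps = ",".join(
            f"{o.chrom}:{o.pos}:{o.base}" + (":*" if o.bisulfite_ambiguous else "")
            for o in f.snp_observations
        ) or "."
        cpgs = ",".join(
            f"{o.site.chrom}:{o.site.pos}:{'M' if o.methylated else 'U'}"
            for o in f.cpg_observations
        ) or "."
        rows.append((f.id, snps, cpgs))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
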