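"""Plasma-vs-buffy-coat somatic variant calling and variant triage.

Tumor-associated single-nucleotide variants can be read directly from
plasma: a variant is a candidate somatic mutation when its alternate
allele is seen in plasma on at least a depth-dependent number of reads
but never in the buffy coat (the white-cell constitutional genome). The
depth-dependent threshold treats alternate reads at a clean position as
sequencing errors arriving Binomial(depth, error_rate) and requires the
observed count to be inconsistent with error alone at level ``alpha``.

For a pregnant cancer patient the plasma-specific variants are a mix of
fetal alleles and tumor mutations; they are triaged by membership in a
common-SNP catalog (population variants are fetal candidates) and by
their read support in the tumor tissue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binom

_BASES = ("A", "C", "G", "T")

DEFAULT_ERROR_RATE = 0.003
DEFAULT_ALPHA = 1e-6


class VariantClass(str, enum.Enum):
    CANDIDATE_SOMATIC = "CANDIDATE_SOMATIC"
    FETAL_SPECIFIC = "FETAL_SPECIFIC"
    TUMOR_SPECIFIC = "TUMOR_SPECIFIC"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class PileupSite:
    """Per-base plasma and buffy-coat read counts at one position."""

    chrom: str
    pos: int
    ref_base: str
    plasma_counts: dict[str, int]
    buffy_counts: dict[str, int]
    passed_realignment: bool = True

    @property
    def plasma_depth(self) -> int:
        return sum(self.plasma_counts.get(b, 0) for b in _BASES)

    @property
    def buffy_depth(self) -> int:
        return sum(self.buffy_counts.get(b, 0) for b in _BASES)


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    plasma_alt_count: int
    plasma_depth: int
    buffy_alt_count: int
    passed_realignment: bool = True
    classification: VariantClass = VariantClass.DISCARDED
    reason: str | None = None

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def dynamic_alt_threshold(
    depth: int,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """Minimum alternate-read count that rejects the sequencing-error model.

    Returns the smallest integer c >= 1 such that
    P(X >= c | X ~ Binomial(depth, error_rate)) < alpha.
    The threshold is non-decreasing in depth: deeper positions accumulate
    more error reads, so more are needed before a variant is credible.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 < error_rate < 1):
        raise ValueError("error_rate must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    # sf(c - 1) = P(X >= c); scan upward from 1 — thresholds are small
    # (tens of reads) even at high depth, so the scan is cheap
    c = 1
    while binom.sf(c - 1, depth, error_rate) >= alpha:
        c += 1
        if c > depth + 1:
            break
    return c


def call_plasma_variants(
    sites: Sequence[PileupSite],
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
    require_realignment: bool = True,
) -> list[VariantCall]:
    """Call candidate somatic variants from paired plasma/buffy pileups.

    Per site the alternate allele is the most frequent non-reference base
    in plasma. The call is CANDIDATE_SOMATIC iff the plasma alternate
    count reaches :func:`dynamic_alt_threshold` at the site's plasma
    depth, the buffy coat shows zero alternate reads, and — when
    ``require_realignment`` — the site survived confirmatory realignment
    with a second aligner (an upstream boolean). Failing sites are
    returned as DISCARDED with a reason code, never dropped.
    """
    calls: list[VariantCall] = []
    for site in sites:
        non_ref = {b: site.plasma_counts.get(b, 0) for b in _BASES if b != site.ref_base}
        # deterministic tie-break on base order
        alt = max(_BASES, key=lambda b: (non_ref.get(b, -1), -_BASES.index(b)))
        call = VariantCall(
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref_base,
            alt=alt,
            plasma_alt_count=non_ref.get(alt, 0),
            plasma_depth=site.plasma_depth,
            buffy_alt_count=site.buffy_counts.get(alt, 0),
            passed_realignment=site.passed_realignment,
        )
        if call.plasma_depth == 0 or call.plasma_alt_count == 0:
            call.reason = "no_alt_reads"
        elif call.plasma_alt_count < dynamic_alt_threshold(
            call.plasma_depth, error_rate, alpha
        ):
            call.reason = "below_dynamic_threshold"
        elif call.buffy_alt_count > 0:
            call.reason = "present_in_buffy_coat"
        elif require_realignment and not call.passed_realignment:
            call.reason = "failed_realignment"
        else:
            call.classification = VariantClass.CANDIDATE_SOMATIC
        calls.append(call)
    return calls


def triage_pregnancy_lymphoma_variant(
    variant: VariantCall,
    in_dbsnp: bool,
    tumor_alt_count: int,
    min_tumor_reads: int = 3,
) -> VariantClass:
    """Triage a plasma-specific variant into fetal vs tumor origin.

    A variant matching a common-SNP catalog entry and completely absent
    from the tumor tissue is a fetal-specific allele; a variant absent
    from the catalog but supported by at least ``min_tumor_reads`` tumor
    reads is a tumor-specific mutation; every other combination is
    discarded. The three outcomes partition the input space.
    """
    if tumor_alt_count < 0:
        raise ValueError("tumor_alt_count must be >= 0")
    if in_dbsnp and tumor_alt_count == 0:
        return VariantClass.FETAL_SPECIFIC
    if not in_dbsnp and tumor_alt_count >= min_tumor_reads:
        return VariantClass.TUMOR_SPECIFIC
    return VariantClass.DISCARDED


def read_pileups(path: str | Path) -> list[PileupSite]:
    """Read pileups from TSV: chrom, pos, ref, plasma A/C/G/T, buffy
    A/C/G/T, and an optional trailing realignment flag (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref"] + [f"plasma_{b}" for b in _BASES] + [
        f"buffy_{b}" for b in _BASES
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    has_flag = "passed_realignment" in df.columns
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            PileupSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_base=str(row.ref),
                plasma_counts={b: int(getattr(row, f"plasma_{b}")) for b in _BASES},
                buffy_counts={b: int(getattr(row, f"buffy_{b}")) for b in _BASES},
                passed_realignment=bool(row.passed_realignment) if has_flag else True,
            )
        )
    return sites


def read_snp_catalog(path: str | Path) -> set[tuple[str, int]]:
    """Read a common-SNP position set from 2-column TSV (chrom, pos) or
    VCF; used for dbSNP-style membership tests, no network lookup."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF

        return {(record.CHROM, record.POS) for record in VCF(str(path))}
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1],
        names=["chrom", "pos"], dtype={"chrom": str}, comment="#",
    )
    return {(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])}


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "plasma_alt_count": c.plasma_alt_count,
                "plasma_depth": c.plasma_depth,
                "buffy_alt_count": c.buffy_alt_count,
                "passed_realignment": int(c.passed_realignment),
                "classification": c.classification.value,
                "reason": c.reason or ".",
            }
            for c in calls
        ]
    )
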