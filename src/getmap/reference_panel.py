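"""Reference tissue methylomes and tissue-informative marker CpG selection.

A reference panel holds, for K candidate tissues (the study design uses
neutrophils, lymphocytes, liver, lung and placenta), the methylation
density of every assayed CpG site. Deconvolution only uses *marker* sites
at which one tissue stands apart from the rest. A site is a marker when

1. the spread between the highest and lowest per-tissue density exceeds
   ``diff_min`` (default 0.25), and
2. after removing the tissue with the highest density, or the tissue with
   the lowest density, the coefficient of variation (sd/mean) of the
   remaining K-1 densities is below ``cv_max`` (default 0.3) — i.e. the
   remaining tissues are mutually consistent and the removed tissue is a
   lone outlier.

Both removals are tried and the site passes if either does: a site may be
marked by one hypermethylated outlier or one hypomethylated outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd


class CpGSite(NamedTuple):
    """A CpG cytosine located by chromosome and 1-based position."""

    chrom: str
    pos: int
    strand: str | None = None


@dataclass
class TissueMethylome:
    """Per-CpG methylated/total read counts for one reference tissue.

    ``sites`` maps each :class:`CpGSite` to ``(methylated_count,
    total_count)``. Density is defined only where ``total_count > 0``.
    """

    tissue: str
    sites: dict[CpGSite, tuple[int, int]] = field(default_factory=dict)

    def density(self, site: CpGSite) -> float | None:
        counts = self.sites.get(site)
        if counts is None:
            return None
        meth, total = counts
        if total == 0:
            return None
        return meth / total

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ReferencePanel:
    """Marker-site methylation densities for K tissues.

    ``matrix`` has one row per site in ``sites`` (sorted by chromosome then
    position) and one column per tissue in ``tissues``; every entry lies in
    [0, 1]. ``mask`` is the full informative-site set the rows were drawn
    from — rows are its intersection with the sites actually covered by
    the fragment class under analysis.
    """

    tissues: list[str]
    sites: list[CpGSite]
    matrix: np.ndarray
    mask: set[CpGSite]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sites), len(self.tissues)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sites)} sites x {len(self.tissues)} tissues"
            )
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() > 1
        ):
            raise ValueError("methylation densities must lie in [0, 1]")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.tissues)
        df.insert(0, "chrom", [s.chrom for s in self.sites])
        df.insert(1, "pos", [s.pos for s in self.sites])
        return df

    def write(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        """Write the panel as TSV; optionally the mask as BED alongside."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if mask_path is not None:
            ordered = sorted(self.mask)
            bed = pd.DataFrame(
                {
                    "chrom": [s.chrom for s in ordered],
                    "start": [s.pos - 1 for s in ordered],
                    "end": [s.pos for s in ordered],
                }
            )
            bed.to_csv(mask_path, sep="\t", index=False, header=False)

    @classmethod
    def read(cls, path: str | Path, mask_path: str | Path | None = None) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        tissues = [c for c in df.columns if c not in ("chrom", "pos")]
        sites = [CpGSite(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])]
        if mask_path is not None:
            bed = pd.read_csv(
                mask_path, sep="\t", header=None, names=["chrom", "start", "end"]
            )
            mask = {
                CpGSite(str(c), int(s) + 1) for c, s in zip(bed["chrom"], bed["start"])
            }
        else:
            mask = set(sites)
        return cls(tissues=tissues, sites=sites, matrix=df[tissues].to_numpy(), mask=mask)


def load_tissue_methylome(path: str | Path, tissue: str) -> TissueMethylome:
    """Load a bedGraph-like methylome table for one tissue.

    Expected columns (TSV, no header, gzip accepted by extension):
    chrom, start, end, methylated_count, total_count with 0-based
    half-open coordinates; the CpG cytosine position is ``start + 1``
    (1-based). Zero-coverage sites are retained with undefined density.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "methylated", "total"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed methylome table {path}: {exc}") from exc

    for col in ("start", "end", "methylated", "total"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 1 if len(bad) else "?"
            raise ValueError(
                f"malformed methylome table {path}: non-integer '{col}' at line {line}"
            )
    if (df["methylated"] < 0).any() or (df["total"] < 0).any():
        line = int(df.index[(df["methylated"] < 0) | (df["total"] < 0)][0]) + 1
        raise ValueError(f"negative count at line {line} of {path}")
    over = df["methylated"] > df["total"]
    if over.any():
        line = int(df.index[over][0]) + 1
        raise ValueError(
            f"methylated count exceeds total at line {line} of {path}"
        )

    sites = {
        CpGSite(chrom, start + 1): (int(m), int(t))
        for chrom, start, m, t in zip(
            df["chrom"], df["start"], df["methylated"], df["total"]
        )
    }
    return TissueMethylome(tissue=tissue, sites=sites)


def _cv(values: np.ndarray) -> np.ndarray:
    """Coefficient of variation (sample sd / mean) per row; 0 where
    sd == 0 (uniform rows are maximally consistent, and the 0/0 case
    must not reject them)."""
    sd = values.std(axis=1, ddof=1)
    mean = values.mean(axis=1)
    out = np.zeros(len(values))
    nonconst = sd > 0
    # sd>0 with mean==0 is impossible for densities >= 0
    out[nonconst] = sd[nonconst] / mean[nonconst]
    return out


def common_density_matrix(
    methylomes: Sequence[TissueMethylome], min_depth: int = 1
) -> tuple[list[CpGSite], np.ndarray]:
    """Sites covered at >= ``min_depth`` in every methylome, with their
    density matrix (sites x tissues), sorted by (chrom, pos)."""
    eligible: set[CpGSite] | None = None
    for m in methylomes:
        ok = {s for s, (_, t) in m.sites.items() if t >= min_depth}
        eligible = ok if eligible is None else eligible & ok
    sites = sorted(eligible or set())
    dens = np.empty((len(sites), len(methylomes)))
    for k, m in enumerate(methylomes):
        dens[:, k] = [m.sites[s][0] / m.sites[s][1] for s in sites]
    return sites, dens


def select_informative_cpgs(
    methylomes: Sequence[TissueMethylome],
    diff_min: float = 0.25,
    cv_max: float = 0.3,
    min_depth: int = 10,
) -> set[CpGSite]:
    """Select tissue-informative marker CpG sites.

    A site passes when (i) max density - min density > ``diff_min`` and
    (ii) dropping the highest-density tissue OR the lowest-density tissue
    leaves the remaining K-1 densities with CV < ``cv_max``. Sites missing
    (or under ``min_depth``) in any tissue are skipped silently.
    """
    if len(methylomes) < 3:
        raise ValueError(
            "informative-site selection needs at least 3 tissues "
            "(CV after one removal requires >= 2 remaining values)"
        )
    sites, dens = common_density_matrix(methylomes, min_depth=min_depth)
    if not sites:
        return set()

    spread_ok = dens.max(axis=1) - dens.min(axis=1) > diff_min
    # remove exactly one tissue per trial; ties broken by first tissue order
    hi = dens.argmax(axis=1)
    lo = dens.argmin(axis=1)
    n, k = dens.shape
    rows = np.arange(n)
    keep = np.ones((n, k), dtype=bool)
    keep[rows, hi] = False
    without_hi = dens[keep].reshape(n, k - 1)
    keep = np.ones((n, k), dtype=bool)
    keep[rows, lo] = False
    without_lo = dens[keep].reshape(n, k - 1)
    cv_ok = (_cv(without_hi) < cv_max) | (_cv(without_lo) < cv_max)

    selected = spread_ok & cv_ok
    return {s for s, take in zip(sites, selected) if take}


def build_reference_matrix(
    methylomes: Sequence[TissueMethylome],
    mask: Iterable[CpGSite],
    observed_sites: Iterable[CpGSite],
) -> ReferencePanel:
    """Assemble the reference matrix M over mask ∩ observed sites.

    ``observed_sites`` are the CpG sites actually covered by the fragment
    class being deconvolved; rows are ordered by (chrom, pos).
    """
    usable = set(mask) & set(observed_sites)
    sites = sorted(
        s
        for s in usable
        if all(m.density(s) is not None for m in methylomes)
    )
    if not sites:
        raise ValueError("no usable marker sites (empty mask/observed intersection)")
    matrix = np.empty((len(sites), len(methylomes)))
    for k, m in enumerate(methylomes):
        matrix[:, k] = [m.density(s) for s in sites]
    return ReferencePanel(
        tissues=[m.tissue for m in methylomes],
        sites=sites,
        matrix=matrix,
        mask=set(mask),
    )


def panel_from_methylomes(
    methylomes: Sequence[TissueMethylome],
    diff_min: float = 0.25,
    cv_max: float = 0.3,
    min_depth: int = 10,
) -> ReferencePanel:
    """Convenience: select markers and build the full-mask panel."""
    mask = select_informative_cpgs(
        methylomes, diff_min=diff_min, cv_max=cv_max, min_depth=min_depth
    )
    return build_reference_matrix(methylomes, mask, mask)
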