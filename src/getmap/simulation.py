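"""Synthetic reference panels, fragment sampling, and accuracy harness.

Real reference methylomes (whole-genome bisulfite sequencing of sorted
tissues) are large controlled-access datasets; this module emulates their
essential structure so the full pipeline can be exercised end to end:

* :func:`synthesize_reference_panel` builds K tissue methylomes over a
  shared CpG catalog in which a chosen fraction of sites are markers —
  one tissue is a lone methylation outlier (hypomethylated against a
  high common baseline, or hypermethylated against a moderate one) so
  that the marker-selection criteria are satisfiable — and the rest are
  background sites on which all tissues agree.
* :func:`sample_fragments` Bernoulli-samples bisulfite fragments: each
  fragment draws a source tissue from the mixture proportions, a small
  number of CpG sites, and per-site methylation states with probability
  equal to the source tissue's density there.
* :func:`run_accuracy_experiment` reproduces the self-deconvolution
  design: per scenario and per tissue, fragments are repeatedly sampled
  from that single tissue at scenario-matched fragment/CpG counts,
  aggregated and deconvolved; accuracy is the contribution assigned back
  to the source tissue.

All sampling is deterministic given a seed; replicate ``r`` of any
experiment uses ``seed + r`` within its tissue's seed stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from getmap.deconvolution import TissueContribution, deconvolve
from getmap.fragment_partition import (
    CpgObservation,
    Fragment,
    aggregate_methylation,
)
from getmap.reference_panel import (
    CpGSite,
    TissueMethylome,
    build_reference_matrix,
    select_informative_cpgs,
)

DEFAULT_TISSUES = ("neutrophils", "lymphocytes", "liver", "lung", "placenta")

# Scenario scales follow the study medians of informative-fragment and
# covered-CpG counts: the cancer scenario pairs 29,868 mutant-allele
# molecules with 18,193 CpG sites (~1.64 fragments per distinct site);
# the pregnancy (53,039 sites) and transplant (141,794 sites) scenarios
# reuse that per-site fragment density, since their fragment totals are
# not printed. See docs/methods.md.
_SCENARIO_SCALES = {
    "pregnancy": {"n_fragments": 87_000, "n_cpg_sites": 53_039},
    "transplant": {"n_fragments": 232_700, "n_cpg_sites": 141_794},
    "cancer": {"n_fragments": 29_868, "n_cpg_sites": 18_193},
}

# offset between per-tissue seed streams; replicate r adds r within a stream
_TISSUE_SEED_STRIDE = 100_003


@dataclass(frozen=True)
class ScenarioConfig:
    """Fragment/CpG counts and replication for one simulated scenario."""

    name: str
    n_fragments: int
    n_cpg_sites: int
    mean_cpgs_per_fragment: float = 2.0
    max_cpgs_per_fragment: int = 10
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1 or self.n_cpg_sites < 1:
            raise ValueError("fragment and CpG-site counts must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def preset(
        cls, name: str, scale_down: int = 1, seed: int = 0, n_replicates: int = 30
    ) -> "ScenarioConfig":
        """A named scenario, with counts divided by ``scale_down``."""
        if name not in _SCENARIO_SCALES:
            raise ValueError(
                f"unknown scenario {name!r}; choose from {sorted(_SCENARIO_SCALES)}"
            )
        base = _SCENARIO_SCALES[name]
        return cls(
            name=name,
            n_fragments=max(1, base["n_fragments"] // scale_down),
            n_cpg_sites=max(1, base["n_cpg_sites"] // scale_down),
            n_replicates=n_replicates,
            seed=seed,
        )


def synthesize_reference_panel(
    n_tissues: int = 5,
    n_sites: int = 20_000,
    marker_fraction: float = 0.2,
    seed: int = 0,
    tissues: Sequence[str] | None = None,
    depth: int = 300,
) -> list[TissueMethylome]:
    """Generate K synthetic tissue methylomes with designated marker sites.

    Markers are split evenly across tissues, alternating hypomethylated
    outliers (marked tissue near density 0.05, others near 0.85) and
    hypermethylated outliers (marked tissue near 0.95, others near 0.35);
    background sites put all tissues near one shared Beta-drawn baseline.
    Read counts per site are Poisson(``depth``) with binomial methylated
    counts, so densities carry realistic sampling noise.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if not (0 < marker_fraction <= 1):
        raise ValueError("marker_fraction must be in (0, 1]")
    if tissues is None:
        tissues = (
            list(DEFAULT_TISSUES[:n_tissues])
            if n_tissues <= len(DEFAULT_TISSUES)
            else [f"tissue{k}" for k in range(n_tissues)]
        )
    if len(tissues) != n_tissues:
        raise ValueError("tissue-name count mismatch")

    rng = np.random.default_rng(seed)
    n_markers = round(marker_fraction * n_sites)
    conc = 200.0  # Beta concentration: tight within-tissue reproducibility

    dens = np.empty((n_sites, n_tissues))
    # background: one shared baseline per site, small per-tissue scatter
    baseline = rng.uniform(0.3, 0.7, size=n_sites)
    dens[:] = rng.beta(baseline[:, None] * 1000.0, (1 - baseline[:, None]) * 1000.0,
                       size=(n_sites, n_tissues))
    # markers: site j marked for tissue j % K, alternating outlier polarity
    marked_tissue = np.arange(n_markers) % n_tissues
    hypo = (np.arange(n_markers) // n_tissues) % 2 == 0
    lo, hi, mid, top = 0.05, 0.85, 0.35, 0.95
    for j in range(n_markers):
        base_conc = 2 * conc  # non-outlier tissues agree tightly at markers
        if hypo[j]:
            row = rng.beta(hi * base_conc, (1 - hi) * base_conc, size=n_tissues)
            row[marked_tissue[j]] = rng.beta(lo * conc, (1 - lo) * conc)
        else:
            row = rng.beta(mid * base_conc, (1 - mid) * base_conc, size=n_tissues)
            row[marked_tissue[j]] = rng.beta(top * conc, (1 - top) * conc)
        dens[j] = row

    totals = rng.poisson(depth, size=(n_sites, n_tissues)).clip(min=1)
    meths = rng.binomial(totals, dens)

    sites = [CpGSite("chr1", 100 + 2 * i) for i in range(n_sites)]
    return [
        TissueMethylome(
            tissue=tissues[k],
            sites={
                s: (int(meths[i, k]), int(totals[i, k]))
                for i, s in enumerate(sites)
            },
        )
        for k in range(n_tissues)
    ]


def _density_matrix(
    methylomes: Sequence[TissueMethylome], sites: Sequence[CpGSite]
) -> np.ndarray:
    dens = np.empty((len(sites), len(methylomes)))
    for k, m in enumerate(methylomes):
        col = [m.density(s) for s in sites]
        if any(d is None for d in col):
            raise ValueError(f"undefined density in {m.tissue} at a requested site")
        dens[:, k] = col
    return dens


def sample_fragments(
    source: TissueMethylome | Mapping[CpGSite, float]
    | tuple[Sequence[float], Sequence[TissueMethylome]],
    n_fragments: int,
    sites: Sequence[CpGSite] | None = None,
    mean_cpgs: float = 2.0,
    max_cpgs: int = 10,
    seed: int = 0,
    id_prefix: str = "frag",
) -> list[Fragment]:
    """Bernoulli-sample allele-tagged bisulfite fragments.

    ``source`` is a single tissue methylome, a site->density map, or a
    ``(proportions, methylomes)`` mixture. Each fragment draws its source
    tissue from the proportions, a CpG count from a Poisson(``mean_cpgs``)
    clamped to [1, ``max_cpgs``], its sites uniformly from ``sites``
    (duplicates within a fragment collapsed), and each methylation state
    as Bernoulli(source density at the site).
    """
    if isinstance(source, tuple):
        proportions, methylomes = source
        proportions = np.asarray(proportions, dtype=float)
        if proportions.min() < 0 or abs(proportions.sum() - 1.0) > 1e-9:
            raise ValueError("mixture proportions must be on the simplex")
        if len(proportions) != len(methylomes):
            raise ValueError("one proportion per methylome required")
        if sites is None:
            sites = sorted(
                set.intersection(*(set(m.sites) for m in methylomes))
            )
        dens = _density_matrix(methylomes, sites)
    else:
        if isinstance(source, TissueMethylome):
            if sites is None:
                sites = sorted(s for s in source.sites if source.density(s) is not None)
            dens = _density_matrix([source], sites)
        else:
            if sites is None:
                sites = sorted(source)
            dens = np.asarray([[source[s]] for s in sites], dtype=float)
        proportions = np.ones(1)
    if len(sites) == 0:
        raise ValueError("empty CpG site set")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")

    rng = np.random.default_rng(seed)
    src = rng.choice(len(proportions), size=n_fragments, p=proportions)
    n_cpgs = rng.poisson(mean_cpgs, size=n_fragments).clip(1, max_cpgs)

    frag_idx = np.repeat(np.arange(n_fragments), n_cpgs)
    site_idx = rng.integers(0, len(sites), size=len(frag_idx))
    # collapse duplicate sites within a fragment (one observation per site)
    pairs = np.unique(np.stack([frag_idx, site_idx], axis=1), axis=0)
    frag_idx, site_idx = pairs[:, 0], pairs[:, 1]
    p_meth = dens[site_idx, src[frag_idx]]
    methylated = rng.random(len(p_meth)) < p_meth

    counts = np.bincount(frag_idx, minlength=n_fragments)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    site_list = list(sites)
    fragments = []
    for i in range(n_fragments):
        lo, hi = offsets[i], offsets[i + 1]
        fragments.append(
            Fragment(
                id=f"{id_prefix}{i}",
                cpg_observations=[
                    CpgObservation(site_list[site_idx[j]], bool(methylated[j]))
                    for j in range(lo, hi)
                ],
            )
        )
    return fragments


@dataclass
class AccuracyTable:
    """Self-deconvolution accuracy summary (percent contributions).

    ``mean_percent[k]`` is the mean deduced contribution vector across
    replicates when tissue k's fragments were deconvolved; the diagonal
    is the accuracy. ``replicates`` holds the long-format per-replicate
    contributions.
    """

    tissues: list[str]
    mean_percent: np.ndarray
    median_percent: np.ndarray
    replicates: pd.DataFrame

    def diagonal(self, stat: str = "mean") -> np.ndarray:
        matrix = self.mean_percent if stat == "mean" else self.median_percent
        return np.diag(matrix)

    def to_frame(self, stat: str = "mean") -> pd.DataFrame:
        matrix = self.mean_percent if stat == "mean" else self.median_percent
        df = pd.DataFrame(matrix, columns=self.tissues)
        df.insert(0, "simulated_tissue", self.tissues)
        return df

    def write(self, path: str | Path, stat: str = "mean") -> None:
        self.to_frame(stat).to_csv(path, sep="\t", index=False, float_format="%.2f")


def _replicate_contribution(
    methylomes: Sequence[TissueMethylome],
    mask_sites: list[CpGSite],
    source: TissueMethylome | tuple[Sequence[float], Sequence[TissueMethylome]],
    config: ScenarioConfig,
    rep_seed: int,
) -> TissueContribution:
    rng = np.random.default_rng(rep_seed)
    if config.n_cpg_sites < len(mask_sites):
        take = rng.choice(len(mask_sites), size=config.n_cpg_sites, replace=False)
        usable = [mask_sites[i] for i in np.sort(take)]
    else:
        usable = mask_sites
    fragments = sample_fragments(
        source,
        n_fragments=config.n_fragments,
        sites=usable,
        mean_cpgs=config.mean_cpgs_per_fragment,
        max_cpgs=config.max_cpgs_per_fragment,
        seed=rep_seed,
    )
    vector = aggregate_methylation(fragments, usable, class_label=config.name)
    panel = build_reference_matrix(methylomes, mask_sites, vector.sites)
    return deconvolve(vector, panel)


def run_accuracy_experiment(
    methylomes: Sequence[TissueMethylome],
    mask: set[CpGSite],
    config: ScenarioConfig,
) -> AccuracyTable:
    """Self-deconvolution accuracy over all tissues of a panel.

    For each tissue, ``config.n_replicates`` replicates sample pure
    fragments from that tissue at the scenario's fragment/CpG counts,
    aggregate them and deconvolve against the panel; the table reports
    mean and median contribution vectors per simulated tissue.
    """
    mask_sites = sorted(mask)
    if not mask_sites:
        raise ValueError("empty marker mask")
    tissues = [m.tissue for m in methylomes]
    k = len(tissues)
    records = []
    for ti, tissue_methylome in enumerate(methylomes):
        stream = config.seed + _TISSUE_SEED_STRIDE * ti
        for r in range(config.n_replicates):
            try:
                contrib = _replicate_contribution(
                    methylomes, mask_sites, tissue_methylome, config, stream + r
                )
            except ValueError as exc:
                raise ValueError(
                    f"replicate {r} for tissue {tissues[ti]} failed: {exc}"
                ) from exc
            for tj, pct in enumerate(contrib.percent):
                records.append(
                    {
                        "scenario": config.name,
                        "simulated_tissue": tissues[ti],
                        "replicate": r,
                        "tissue": tissues[tj],
                        "percent": pct,
                    }
                )
    reps = pd.DataFrame(records)
    wide = reps.pivot_table(
        index=["simulated_tissue", "replicate"], columns="tissue", values="percent"
    )[tissues]
    mean = np.vstack([wide.loc[t].mean().to_numpy() for t in tissues])
    median = np.vstack([wide.loc[t].median().to_numpy() for t in tissues])
    return AccuracyTable(
        tissues=tissues, mean_percent=mean, median_percent=median, replicates=reps
    )


def mix_and_recover(
    true_proportions: Sequence[float],
    methylomes: Sequence[TissueMethylome],
    mask: set[CpGSite],
    config: ScenarioConfig,
) -> tuple[TissueContribution, np.ndarray]:
    """Sample one mixture at known proportions and deconvolve it.

    Returns the estimated contribution and the per-tissue absolute error
    ``|p_hat_k - p_k|`` (as fractions).
    """
    p = np.asarray(true_proportions, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true_proportions must be on the simplex")
    if len(p) != len(methylomes):
        raise ValueError("one proportion per tissue required")
    contrib = _replicate_contribution(
        methylomes, sorted(mask), (p, list(methylomes)), config, config.seed
    )
    return contrib, np.abs(contrib.proportions - p)


def build_panel_and_mask(
    n_tissues: int = 5,
    n_sites: int = 20_000,
    marker_fraction: float = 0.2,
    seed: int = 0,
    diff_min: float = 0.25,
    cv_max: float = 0.3,
    min_depth: int = 10,
) -> tuple[list[TissueMethylome], set[CpGSite]]:
    """Convenience: synthesize methylomes and run marker selection."""
    methylomes = synthesize_reference_panel(
        n_tissues=n_tissues,
        n_sites=n_sites,
        marker_fraction=marker_fraction,
        seed=seed,
    )
    mask = select_informative_cpgs(
        methylomes, diff_min=diff_min, cv_max=cv_max, min_depth=min_depth
    )
    return methylomes, mask
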