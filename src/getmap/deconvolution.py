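"""Simplex-constrained quadratic-programming deconvolution.

The class methylation vector x (one density per usable CpG site) is
modeled as a convex combination of the reference tissue profiles,
``x_i ≈ sum_k p_k M[i, k]``, and the proportions p are the minimizer of

    sum_i w_i (x_i - (M p)_i)^2    s.t.   sum_k p_k = 1,  p_k >= 0.

Weights are uniform by default; ``weighting="coverage"`` weights each
site by its covering-fragment count, since densities estimated from few
molecules are noisier.

For the panel sizes this problem meets (a handful of candidate tissues)
the QP is solved exactly by support enumeration: for every candidate
active set the equality-constrained least-squares KKT system is solved
directly, infeasible candidates are discarded, and the best feasible
stationary point is the global minimizer of this convex program. Panels
with more than 12 tissues fall back to non-negative least squares with a
sum-to-one penalty row polished by SLSQP. :func:`grid_search_oracle`
enumerates the simplex at a fixed resolution and serves as an
independent check of the QP solution.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from getmap.fragment_partition import MethylationVector
from getmap.reference_panel import ReferencePanel

_SIMPLEX_TOL = 1e-6


@dataclass
class TissueContribution:
    """Estimated tissue proportions for one fragment class."""

    tissues: list[str]
    proportions: np.ndarray  # fractions, sum to 1
    residual: float  # weighted sum of squared per-site deviations
    n_sites_used: int
    exactly_determined: bool = False

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.min() < 0:
            raise ValueError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("proportions must sum to 1 within 1e-6")

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.proportions

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.tissues, self.proportions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": self.tissues,
                "proportion_percent": np.round(self.percent, 2),
            }
        )

    def write_json(self, path: str | Path) -> None:
        payload = {
            "contributions_percent": {
                t: round(float(v), 2) for t, v in zip(self.tissues, self.percent)
            },
            "residual": float(self.residual),
            "n_sites_used": int(self.n_sites_used),
            "exactly_determined": bool(self.exactly_determined),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _objective(p: np.ndarray, m: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    r = x - m @ p
    return float(np.sum(w * r * r))


_ENUMERATION_MAX_K = 12


def _solve_support_enumeration(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray | None:
    """Exact simplex-constrained least squares by active-set enumeration.

    Solves min ||a p - b||^2 s.t. sum p = 1, p >= 0 by solving the
    equality-constrained KKT system on every support set and keeping the
    best feasible solution; for a convex QP the optimum's support is
    among them, so the result is the global minimizer.
    """
    gram = 2.0 * a.T @ a
    rhs_full = 2.0 * a.T @ b
    best_p, best_obj = None, np.inf
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            s = list(support)
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = gram[np.ix_(s, s)]
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.concatenate([rhs_full[s], [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            if (sol[:r] < -1e-12).any():
                continue
            p = np.zeros(k)
            p[s] = np.clip(sol[:r], 0.0, None)
            resid = a @ p - b
            obj = float(resid @ resid)
            if obj < best_obj:
                best_p, best_obj = p, obj
    return best_p


def _solve_simplex_lsq(m: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimize sum w_i (x_i - (M p)_i)^2 over the probability simplex."""
    sw = np.sqrt(w)
    a = m * sw[:, None]
    b = x * sw
    k = m.shape[1]

    if k <= _ENUMERATION_MAX_K:
        p = _solve_support_enumeration(a, b, k)
        if p is not None:
            return p / p.sum()
    return _solve_simplex_iterative(m, x, w)


def _solve_simplex_iterative(m: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fallback solver: penalized NNLS warm start polished by SLSQP."""
    sw = np.sqrt(w)
    a = m * sw[:, None]
    b = x * sw
    k = m.shape[1]
    # warm start: NNLS with a penalty row enforcing sum(p) = 1
    lam = 100.0 * max(1.0, np.abs(a).max())
    a_aug = np.vstack([a, lam * np.ones((1, k))])
    b_aug = np.concatenate([b, [lam]])
    p0, _ = optimize.nnls(a_aug, b_aug)
    s = p0.sum()
    p0 = p0 / s if s > 0 else np.full(k, 1.0 / k)

    res = optimize.minimize(
        _objective,
        p0,
        args=(m, x, w),
        jac=lambda p, m_, x_, w_: -2.0 * m_.T @ (w_ * (x_ - m_ @ p)),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones_like(p)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    p = res.x if res.success and _objective(res.x, m, x, w) <= _objective(p0, m, x, w) + 1e-15 else p0
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    # polish: re-solve the equality-constrained KKT system on the
    # detected support so the minimizer is exact, not ftol-limited
    support = np.flatnonzero(p > 1e-9)
    polished = _solve_support_kkt(a, b, k, support)
    if polished is not None and _objective(polished, m, x, w) <= _objective(p, m, x, w) + 1e-15:
        return polished
    return p


def _solve_support_kkt(a: np.ndarray, b: np.ndarray, k: int, support: np.ndarray) -> np.ndarray | None:
    """Solve the sum-to-one least squares restricted to one support set;
    returns None when singular or infeasible (negative entries)."""
    r = len(support)
    if r == 0:
        return None
    gram = 2.0 * a.T @ a
    rhs_full = 2.0 * a.T @ b
    kkt = np.zeros((r + 1, r + 1))
    kkt[:r, :r] = gram[np.ix_(support, support)]
    kkt[:r, r] = 1.0
    kkt[r, :r] = 1.0
    rhs = np.concatenate([rhs_full[support], [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        return None
    if (sol[:r] < -1e-12).any():
        return None
    p = np.zeros(k)
    p[support] = np.clip(sol[:r], 0.0, None)
    return p / p.sum()


def _align(x: MethylationVector, panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match vector sites to panel rows; returns (M, x, coverage)."""
    panel_index = {site: i for i, site in enumerate(panel.sites)}
    rows, dens, cov = [], [], []
    for site, meth, n in zip(x.sites, x.methylated_count, x.covering_count):
        i = panel_index.get(site)
        if i is None:
            continue
        rows.append(i)
        dens.append(meth / n)
        cov.append(n)
    if not rows:
        raise ValueError("methylation vector shares no sites with the panel")
    return panel.matrix[rows], np.asarray(dens), np.asarray(cov, dtype=float)


def deconvolve(
    x: MethylationVector,
    panel: ReferencePanel,
    weighting: str = "uniform",
) -> TissueContribution:
    """Estimate tissue proportions for one fragment class.

    Requires at least as many usable sites as tissues; with exactly K
    sites the solution is flagged ``exactly_determined``. Sites absent
    from the panel (e.g. where any reference density is undefined) are
    dropped before solving.
    """
    if weighting not in ("uniform", "coverage"):
        raise ValueError(f"unknown weighting {weighting!r}")
    m, dens, cov = _align(x, panel)
    k = panel.n_tissues
    n = len(dens)
    if n < k:
        raise ValueError(
            f"underdetermined system: {n} usable sites < {k} tissues"
        )
    w = cov if weighting == "coverage" else np.ones(n)
    p = _solve_simplex_lsq(m, dens, w)
    return TissueContribution(
        tissues=list(panel.tissues),
        proportions=p,
        residual=_objective(p, m, dens, w),
        n_sites_used=n,
        exactly_determined=(n == k),
    )


def _simplex_grid(k: int, step: float):
    """All K-part compositions of 1 at resolution step."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    for cuts in itertools.combinations(range(n + k - 1), k - 1):
        parts = []
        prev = -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + k - 2 - prev)
        yield np.array(parts, dtype=float) / n


def grid_search_oracle(
    x: MethylationVector,
    panel: ReferencePanel,
    step: float = 0.01,
    weighting: str = "uniform",
) -> TissueContribution:
    """Exhaustive simplex-grid minimizer of the deconvolution objective.

    Test oracle only: enumerates every grid point at resolution ``step``
    (limited to K <= 4 tissues) and returns the best. The QP solution
    must never have a larger objective than this.
    """
    if panel.n_tissues > 4:
        raise ValueError("grid search is limited to K <= 4 tissues")
    m, dens, cov = _align(x, panel)
    w = cov if weighting == "coverage" else np.ones(len(dens))
    best_p, best_obj = None, np.inf
    for p in _simplex_grid(panel.n_tissues, step):
        obj = _objective(p, m, dens, w)
        if obj < best_obj:
            best_p, best_obj = p, obj
    return TissueContribution(
        tissues=list(panel.tissues),
        proportions=best_p,
        residual=best_obj,
        n_sites_used=len(dens),
    )
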