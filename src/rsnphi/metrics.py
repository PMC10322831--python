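"""Reference metrics: Phi*, causal density, and mean correlation.

Three comparison measures computed on the same binary series as the
IIT 3.0 analysis:

* **Phi\\*** — the integrated-information measure of the IIT 2.0 lineage,
  computed here as the plug-in mutual information between the lagged
  whole-system states minus the sum of part-wise lagged mutual
  informations, minimized over all bipartitions of the regions into
  near-equal halves (sizes {2, 3} for 5 regions, 10 bipartitions).
* **Causal density (CD)** — the mean conditional Granger causality over
  all N(N-1) directed region pairs, from least-squares VAR fits whose
  order is selected in 1..p_max by an information criterion (BIC by
  default).  Concatenated multi-subject series are fitted as separate
  trials sharing coefficients, so no regression row spans a subject
  boundary.
* **mu[rho]** — the mean Pearson correlation over all N(N-1)/2 unordered
  region pairs.

All three are deterministic functions of their input.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BinaryTimeSeries


# ---------------------------------------------------------------------------
# Phi*

@dataclass
class PhiStarResult:
    tau: int
    whole_mi: float
    part_mis: tuple[float, ...]
    mip_partition: tuple[tuple[int, ...], tuple[int, ...]]
    phi_star: float


def _lagged_state_pairs(series: BinaryTimeSeries, tau: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(past, present) row pairs at lag tau, never spanning a segment."""
    past, present = [], []
    bounds = [s.start for s in series.provenance] + [series.n_timepoints]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = series.values[a:b]
        if seg.shape[0] > tau:
            past.append(seg[:-tau])
            present.append(seg[tau:])
    if not past:
        raise ValueError(f"series too short for lag {tau}")
    return np.concatenate(past), np.concatenate(present)


def _plugin_mi(x_idx: np.ndarray, y_idx: np.ndarray, nx: int, ny: int,
               miller_madow: bool = False) -> float:
    """Plug-in mutual information (nats) between two discrete sequences."""
    joint = np.zeros((nx, ny))
    np.add.at(joint, (x_idx, y_idx), 1.0)
    n = joint.sum()
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * (np.log(joint[nz])
                                   - np.log(np.outer(px, py)[nz]))))
    if miller_madow:
        kxy = int(nz.sum())
        kx = int((px > 0).sum())
        ky = int((py > 0).sum())
        mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2 * n)
    return max(mi, 0.0)


def _balanced_bipartitions(n: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Bipartitions into parts of sizes floor(n/2) and ceil(n/2)."""
    r = n // 2
    out = []
    seen = set()
    for first in itertools.combinations(range(n), r):
        second = tuple(x for x in range(n) if x not in first)
        key = frozenset((first, second))
        if key in seen:
            continue
        seen.add(key)
        out.append((first, second))
    return out


def _part_index(values: np.ndarray, part: tuple[int, ...]) -> np.ndarray:
    weights = 1 << np.arange(len(part))
    return values[:, list(part)].astype(np.int64) @ weights


def phi_star(series: BinaryTimeSeries, tau: int = 1,
             miller_madow: bool = False) -> PhiStarResult:
    """Phi* at lag ``tau``: whole-system MI minus part MIs at the MIP.

    Evaluates every bipartition of the regions into near-equal halves
    (all 10 splits of sizes 2|3 for five regions) and records the minimum
    of whole - sum(parts) together with the minimizing partition.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    past, present = _lagged_state_pairs(series, tau)
    n = series.n_regions
    full = tuple(range(n))
    whole = _plugin_mi(_part_index(past, full), _part_index(present, full),
                       2**n, 2**n, miller_madow)
    best = None
    for p1, p2 in _balanced_bipartitions(n):
        parts = tuple(
            _plugin_mi(_part_index(past, p), _part_index(present, p),
                       2 ** len(p), 2 ** len(p), miller_madow)
            for p in (p1, p2))
        val = whole - sum(parts)
        if best is None or val < best[0]:
            best = (val, (p1, p2), parts)
    val, mip, parts = best
    return PhiStarResult(tau=tau, whole_mi=whole, part_mis=parts,
                         mip_partition=mip, phi_star=float(val))


# ---------------------------------------------------------------------------
# VAR fitting and Granger causality

@dataclass
class VARFit:
    order_p: int
    coefs: np.ndarray            # (p, N, N); coefs[l, i, j]: x_j(t-l-1) -> x_i(t)
    intercept: np.ndarray
    resid_cov: np.ndarray
    n_obs: int
    ic_values: dict[int, float]


def _lag_design(x: np.ndarray, boundaries: list[int], p: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (regressors, targets) over segments; rows never cross segments."""
    t, n = x.shape
    bounds = list(boundaries) + [t]
    xs, ys = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        if seg.shape[0] <= p:
            continue
        rows = seg.shape[0] - p
        lagged = np.concatenate([seg[p - l - 1:p - l - 1 + rows]
                                 for l in range(p)], axis=1)
        xs.append(lagged)
        ys.append(seg[p:])
    if not xs:
        raise ValueError(f"no segment longer than the VAR order {p}")
    return np.concatenate(xs), np.concatenate(ys)


def _ols_resid_cov(design: np.ndarray, target: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    design1 = np.column_stack([np.ones(design.shape[0]), design])
    coef, _, rank, _ = np.linalg.lstsq(design1, target, rcond=None)
    if rank < design1.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressors ({rank} < {design1.shape[1]}); "
            "lag structure is collinear")
    resid = target - design1 @ coef
    cov = resid.T @ resid / resid.shape[0]
    return coef, cov


def fit_var(series, p_max: int = 20, criterion: str = "bic",
            boundaries: list[int] | None = None) -> VARFit:
    """Least-squares VAR fit with order selected in 1..p_max.

    ``series`` may be a BinaryTimeSeries (provenance segments become
    trials) or a plain time x region float array.  The order minimizes
    BIC (default) or AIC computed from the residual covariance on each
    order's own effective sample.
    """
    if isinstance(series, BinaryTimeSeries):
        x = series.values.astype(float)
        boundaries = series.segment_boundaries
    else:
        x = np.asarray(series, dtype=float)
        boundaries = boundaries or [0]
    t, n = x.shape
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    ic: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    for p in range(1, p_max + 1):
        design, target = _lag_design(x, boundaries, p)
        coef, cov = _ols_resid_cov(design, target)
        nobs = target.shape[0]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            logdet = -np.inf  # perfect fit; will win any criterion
        k = p * n * n + n
        penalty = k * (np.log(nobs) if criterion == "bic" else 2.0)
        ic[p] = float(logdet + penalty / nobs)
        fits[p] = (coef, cov, nobs)
    order = min(ic, key=ic.get)
    coef, cov, nobs = fits[order]
    intercept = coef[0]
    lag_coefs = coef[1:].reshape(order, n, n).transpose(0, 2, 1)
    return VARFit(order_p=order, coefs=lag_coefs, intercept=intercept,
                  resid_cov=cov, n_obs=nobs, ic_values=ic)


@dataclass
class GrangerResult:
    order_p: int
    pairwise_F: np.ndarray       # [i, j] = F(i -> j); diagonal NaN
    causal_density: float


def causal_density(series, p_max: int = 20, criterion: str = "bic",
                   order: int | None = None) -> GrangerResult:
    """Mean conditional Granger causality over all directed region pairs.

    For each ordered pair (i -> j), F = ln(restricted / full residual
    variance of region j), where the restricted model drops region i's
    lags while conditioning on every other region.  Numerically negative
    ratios are clamped at zero with a warning.  CD is the mean over all
    N(N-1) directed values.
    """
    if isinstance(series, BinaryTimeSeries):
        x = series.values.astype(float)
        boundaries = series.segment_boundaries
    else:
        x = np.asarray(series, dtype=float)
        boundaries = [0]
    n = x.shape[1]
    if order is None:
        order = fit_var(x, p_max=p_max, criterion=criterion,
                        boundaries=boundaries).order_p
    design, target = _lag_design(x, boundaries, order)
    _, full_cov = _ols_resid_cov(design, target)
    full_var = np.diag(full_cov)

    fmat = np.full((n, n), np.nan)
    for i in range(n):
        keep = [l * n + c for l in range(order) for c in range(n) if c != i]
        _, red_cov = _ols_resid_cov(design[:, keep], target)
        for j in range(n):
            if j == i:
                continue
            ratio = red_cov[j, j] / full_var[j]
            if ratio < 1.0:
                if ratio < 1.0 - 1e-10:
                    warnings.warn(
                        f"negative Granger statistic for {i}->{j} clamped "
                        "to 0", stacklevel=2)
                fmat[i, j] = 0.0
            else:
                fmat[i, j] = np.log(ratio)
    cd = float(np.nanmean(fmat))
    return GrangerResult(order_p=order, pairwise_F=fmat, causal_density=cd)


# ---------------------------------------------------------------------------
# mean correlation

@dataclass
class CorrelationResult:
    pairwise_rho: dict[tuple[int, int], float]
    mu_rho: float


def mean_correlation(series) -> CorrelationResult:
    """Mean Pearson correlation over all unordered region pairs."""
    x = series.values.astype(float) if isinstance(series, BinaryTimeSeries) \
        else np.asarray(series, dtype=float)
    n = x.shape[1]
    if (x.std(axis=0) == 0).any():
        bad = np.flatnonzero(x.std(axis=0) == 0).tolist()
        raise ValueError(f"constant region(s) {bad}: correlation undefined")
    rho = {}
    for i, j in itertools.combinations(range(n), 2):
        rho[(i, j)] = float(stats.pearsonr(x[:, i], x[:, j])[0])
    return CorrelationResult(pairwise_rho=rho,
                             mu_rho=float(np.mean(list(rho.values()))))
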