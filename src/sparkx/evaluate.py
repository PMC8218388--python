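"""Calibration and power assessment for the spatial covariance test.

Provides the permutation-null construction used on real data (coordinates
shuffled across locations, test re-run, p-values pooled over replicates),
type-I-error / genomic-inflation summaries on null p-values, truth-based and
adjustment-based power at an FDR level, and the empirical-FDR significance
threshold derived from permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covtest import adjust_pvalues, sparkx_test

__all__ = [
    "CalibrationReport",
    "PowerReport",
    "permute_null",
    "type1_error",
    "power_at_fdr",
    "empirical_fdr_threshold",
]

# median of chi-square(1) — the null expectation of the median test statistic
_CHI1_MEDIAN = 0.45493642311957174


@dataclass
class CalibrationReport:
    empirical_type1: dict[float, float]
    lambda_gc: float
    ks_pvalue: float
    n_tests: int


@dataclass
class PowerReport:
    power_at_fdr: float
    fdr_level: float
    n_true: int
    n_declared: int
    method: str


def permute_null(
    counts,
    coords,
    X: np.ndarray | None = None,
    n_perms: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Pooled combined p-values under coordinate permutation.

    Each replicate randomly permutes the coordinate rows (and covariate rows,
    jointly) across locations, severing any gene-location dependence while
    preserving both marginals, then reruns the full test. Returns an
    (n_perms, n_ok_genes) matrix of combined p-values.
    """
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    pos = coords.positions if hasattr(coords, "positions") else np.asarray(coords)
    n = pos.shape[0]
    rows = []
    for _ in range(n_perms):
        perm = rng.permutation(n)
        xp = X[perm] if X is not None else None
        res = sparkx_test(counts, pos[perm], X=xp)
        rows.append([r.combined_p for r in res if r.status == "ok"])
    return np.asarray(rows, dtype=float)


def type1_error(pvals, alphas=(0.05, 0.01)) -> CalibrationReport:
    """Observed rejection fractions, genomic inflation factor and KS uniformity.

    lambda_gc = median(qchisq(1 - p, df=1)) / 0.4549..., which is 1 for
    exactly uniform p-values.
    """
    p = np.asarray(pvals, float).ravel()
    p = p[np.isfinite(p)]
    rej = {float(a): float(np.mean(p <= a)) for a in alphas}
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / _CHI1_MEDIAN)
    ks = float(stats.kstest(p, "uniform").pvalue)
    return CalibrationReport(rej, lam, ks, p.size)


def power_at_fdr(
    pvals, truth, fdr_level: float = 0.05, method: str = "truth_fdr"
) -> PowerReport:
    """Proportion of true SE genes recovered at a false-discovery-rate level.

    ``truth_fdr`` sweeps p-value thresholds and declares at the largest one
    whose realized false-discovery proportion (computed against the known
    labels) stays within ``fdr_level`` — the natural definition when ground
    truth is available. ``BY``/``BH`` instead declare where the step-up
    adjusted p-value is below the level.
    """
    p = np.asarray(pvals, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    if p.size != truth.size:
        raise ValueError("pvals and truth must align")
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("power is undefined without any true SE gene")
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must lie in (0, 1)")
    if method == "truth_fdr":
        order = np.argsort(p, kind="stable")
        false_cum = np.cumsum(~truth[order])
        declared = np.arange(1, p.size + 1)
        fdp = false_cum / declared
        # a threshold declares every tied p-value, so only tie boundaries
        # are admissible cut points
        boundary = np.append(p[order][:-1] < p[order][1:], True)
        ok = np.flatnonzero((fdp <= fdr_level) & boundary)
        if ok.size == 0:
            return PowerReport(0.0, fdr_level, n_true, 0, method)
        k = ok[-1] + 1
        tp = int(truth[order[:k]].sum())
        return PowerReport(tp / n_true, fdr_level, n_true, int(k), method)
    if method in ("BY", "BH"):
        adj = adjust_pvalues(p, method=method)
        declared = adj <= fdr_level
        tp = int((declared & truth).sum())
        return PowerReport(tp / n_true, fdr_level, n_true, int(declared.sum()), method)
    raise ValueError(f"unknown method {method!r}")


def empirical_fdr_threshold(real_p, perm_p, level: float = 0.01) -> float:
    """Largest p-value cutoff with permutation-estimated FDR below ``level``.

    The estimated FDR at cutoff t is mean(perm_p <= t) * n_real divided by
    the number of real p-values at or below t. Returns 0.0 when no cutoff is
    admissible (then nothing is declared).
    """
    real = np.sort(np.asarray(real_p, float).ravel())
    perm = np.sort(np.asarray(perm_p, float).ravel())
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    n_real = real.size
    n_perm = perm.size
    # candidate cutoffs are the observed real p-values
    n_perm_le = np.searchsorted(perm, real, side="right")
    n_real_le = np.arange(1, n_real + 1)
    est_fdr = (n_perm_le / n_perm) * n_real / n_real_le
    ok = np.flatnonzero(est_fdr <= level)
    if ok.size == 0:
        return 0.0
    return float(real[ok[-1]])
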