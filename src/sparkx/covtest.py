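"""The non-parametric projection-covariance test for spatial expression.

For a standardized expression vector y and an n x d (transformed) coordinate
matrix S the statistic is

    T = trace(E_C Sigma_C) / n
      = (y' y)^{-1} (Hy)' S (S'S)^{-1} S' (Hy) / n,

where E = y (y'y)^{-1} y', Sigma = S (S'S)^{-1} S' are projection covariance
matrices, H = I - X (X'X)^{-1} X' is the centering/covariate-residual
projection (X = 1_n without covariates), and E_C = HEH, Sigma_C = H Sigma H.
Under independence of y and S, T is asymptotically distributed as
(1/n^2) sum_j lambda_E lambda_Sigma,j z_j^2 with z_j iid N(0,1), where
lambda_E = (y'y)^{-1} y'Hy and lambda_Sigma,j are the eigenvalues of
(S'S)^{-1} S'HS. Nothing n x n is ever materialized: every quantity reduces
to d x d / q x q algebra plus sparse dot products over the non-zero counts,
giving O(n d^2 + p n' d) time and O(n d^2) memory for p genes with n'
non-zero locations on average.

Evidence from the eleven kernels (identity + 5 Gaussian + 5 cosine) is
aggregated per gene with the Cauchy combination rule, which is valid under
arbitrary dependence between the per-kernel p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from ._davies import mixture_chi2_sf, saddlepoint_sf
from .io_formats import CountMatrix, Coordinates
from .kernels import TransformedCoordinates, default_kernel_set

__all__ = [
    "ProjectionContext",
    "SingleKernelResult",
    "GeneTestResult",
    "build_context",
    "gene_statistic",
    "mixture_coefficients",
    "davies_pvalue",
    "cauchy_combine",
    "sparkx_test",
    "adjust_pvalues",
]

_EIG_CLIP = 1e-8  # numerical tolerance for eigenvalues of projection products


@dataclass
class ProjectionContext:
    """Per-kernel cached quantities shared by all genes.

    Built once per kernel: d x d and q x d cross-products of the transformed
    coordinates S and covariate design X, plus the eigenvalues of
    (S'S)^{-1} S'HS (real, in [0, 1], obtained from the symmetric congruent
    form (S'S)^{-1/2} S'HS (S'S)^{-1/2}).
    """

    S: np.ndarray  # n x d
    X: np.ndarray  # n x q
    label: str = "identity"
    StS: np.ndarray = field(init=False)
    XtX_inv: np.ndarray = field(init=False)
    XtS: np.ndarray = field(init=False)
    StS_inv: np.ndarray = field(init=False)
    StHS: np.ndarray = field(init=False)
    lambda_Sigma: np.ndarray = field(init=False)
    col_sum_S: np.ndarray = field(init=False)
    col_sum_X: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S, X = np.asarray(self.S, float), np.asarray(self.X, float)
        n, d = S.shape
        q = X.shape[1]
        if n <= d + q:
            raise ValueError(f"need n > d + q, got n={n}, d={d}, q={q}")
        self.StS = S.T @ S
        xtx = X.T @ X
        try:
            self.XtX_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariate design X is rank-deficient") from exc
        self.XtS = X.T @ S
        # S'HS = S'S - (X'S)'(X'X)^{-1}(X'S)
        self.StHS = self.StS - self.XtS.T @ self.XtX_inv @ self.XtS
        # eigenvalues via the symmetric congruent form; guarantees real values
        try:
            L = np.linalg.cholesky(self.StS)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "S'S is singular: transformed coordinate columns are dependent"
            ) from exc
        Li = scipy.linalg.solve_triangular(L, np.eye(d), lower=True)
        M = Li @ self.StHS @ Li.T
        lam = np.linalg.eigvalsh((M + M.T) / 2.0)
        if lam.min() < -_EIG_CLIP or lam.max() > 1.0 + _EIG_CLIP:
            raise ValueError("projection eigenvalues outside [0, 1]")
        self.lambda_Sigma = np.clip(lam, 0.0, 1.0)[::-1].copy()
        self.StS_inv = Li.T @ Li
        self.col_sum_S = S.sum(axis=0)
        self.col_sum_X = X.sum(axis=0)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def d(self) -> int:
        return self.S.shape[1]


@dataclass
class SingleKernelResult:
    label: str
    T: float
    lambda_E: float
    lambda_Sigma: np.ndarray
    p: float


@dataclass
class GeneTestResult:
    gene_id: str
    per_kernel: list[SingleKernelResult]
    combined_p: float
    adjusted_p: float
    status: str = "ok"  # ok | degenerate_skipped


def build_context(
    S: TransformedCoordinates | np.ndarray, X: np.ndarray
) -> ProjectionContext:
    """Cache the one-time quantities for one kernel's transformed coordinates."""
    if isinstance(S, TransformedCoordinates):
        return ProjectionContext(S.positions, X, label=S.spec.label)
    return ProjectionContext(np.asarray(S, float), X)


def gene_statistic(y: np.ndarray, ctx: ProjectionContext) -> tuple[float, float]:
    """Test statistic T and expression eigenvalue lambda_E for one gene.

    ``y`` is the standardized expression vector (mean 0, sample sd 1). Only
    O(nd + qd + d^2) work; equals trace(E_C Sigma_C)/n from the dense
    definition.
    """
    y = np.asarray(y, float).ravel()
    n = ctx.n
    if y.size != n:
        raise ValueError("expression vector length does not match context")
    yty = float(y @ y)
    ytX = y @ ctx.X
    ytS = y @ ctx.S
    # a = S'Hy ; y'Hy via the same covariate sweep
    a = ytS - ctx.XtS.T @ (ctx.XtX_inv @ ytX)
    ytHy = yty - float(ytX @ ctx.XtX_inv @ ytX)
    t_stat = float(a @ ctx.StS_inv @ a) / (yty * n)
    lam_e = ytHy / yty
    return t_stat, lam_e


def mixture_coefficients(
    lambda_E: float, lambda_Sigma: np.ndarray, n: int
) -> np.ndarray:
    """Null-mixture weights {lambda_E * lambda_Sigma,j / n^2}, zeros removed."""
    lam_e = float(lambda_E)
    lam_s = np.asarray(lambda_Sigma, float)
    if lam_e < -1e-10 or np.any(lam_s < -1e-10):
        raise ValueError("eigenvalues must be non-negative")
    lam_e = max(lam_e, 0.0)
    lam_s = np.clip(lam_s, 0.0, None)
    coeffs = lam_e * lam_s / float(n) ** 2
    return coeffs[coeffs > 0]


def davies_pvalue(coeffs, t: float) -> float:
    """P(sum_k coeffs_k chi2_1 >= t), clamped to [1e-300, 1]."""
    coeffs = np.asarray(coeffs, float)
    if np.any(coeffs < 0):
        raise ValueError("mixture coefficients must be non-negative")
    coeffs = coeffs[coeffs > 0]
    if coeffs.size == 0:
        return 1.0
    return mixture_chi2_sf(coeffs, t)


_CAUCHY_GUARD_HI = 1.0 - 1e-15
_CAUCHY_GUARD_LO = 1e-300


def cauchy_combine(pvals) -> float:
    """Cauchy combination of K p-values; valid under arbitrary dependence.

    C = mean(tan((0.5 - p_k) pi)); combined p = 0.5 - arctan(C)/pi. For p
    below ~1e-16 the tangent is numerically 1/(pi p), which is used directly
    to avoid overflow.
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, _CAUCHY_GUARD_LO, _CAUCHY_GUARD_HI)
    small = p < 1e-16
    stat = np.empty_like(p)
    stat[~small] = np.tan((0.5 - p[~small]) * np.pi)
    stat[small] = 1.0 / (p[small] * np.pi)
    c = stat.mean()
    if c > 1e15:
        combined = 1.0 / (c * np.pi)
    else:
        combined = 0.5 - np.arctan(c) / np.pi
    return float(min(max(combined, _CAUCHY_GUARD_LO), _CAUCHY_GUARD_HI))


def adjust_pvalues(pvals, method: str = "BY") -> np.ndarray:
    """Benjamini-Hochberg / Benjamini-Yekutieli step-up adjusted p-values."""
    p = np.asarray(pvals, float).ravel()
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    if method == "BY":
        cm = np.sum(1.0 / np.arange(1, m + 1))
    elif method == "BH":
        cm = 1.0
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    adj = ranked * cm * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _batch_statistics(
    counts: sp.csr_matrix, ctx: ProjectionContext
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (T, lambda_E, degenerate-mask) for all genes against one kernel.

    Standardization constants are folded in analytically so only the sparse
    raw counts are touched: for raw counts c with mean m and sample sd s,
    y = (c - m)/s and every needed dot product reduces to raw sparse products
    plus cached column sums.
    """
    n = ctx.n
    row_sum = np.asarray(counts.sum(axis=1)).ravel()
    row_sq = np.asarray(counts.multiply(counts).sum(axis=1)).ravel()
    m = row_sum / n
    var = (row_sq - n * m**2) / (n - 1)
    degenerate = var <= 0
    s = np.sqrt(np.where(degenerate, 1.0, var))

    CS = counts @ ctx.S  # p x d
    CX = counts @ ctx.X  # p x q
    ytS = (CS - np.outer(m, ctx.col_sum_S)) / s[:, None]
    ytX = (CX - np.outer(m, ctx.col_sum_X)) / s[:, None]
    yty = float(n - 1)

    a = ytS - ytX @ (ctx.XtX_inv @ ctx.XtS)  # p x d rows of S'Hy
    t_stat = np.einsum("ij,jk,ik->i", a, ctx.StS_inv, a) / (yty * n)
    ytHy = yty - np.einsum("ij,jk,ik->i", ytX, ctx.XtX_inv, ytX)
    lam_e = ytHy / yty
    return t_stat, lam_e, degenerate


def _kernel_pvalues(
    t_stat: np.ndarray, lam_e: np.ndarray, ctx: ProjectionContext
) -> np.ndarray:
    """Per-gene mixture p-values for one kernel.

    The mixture weights are lambda_E * lambda_Sigma,j / n^2; lambda_E only
    rescales them, so P(Q >= T) is evaluated as the shared lambda_Sigma
    mixture at threshold T n^2 / lambda_E.
    """
    base = ctx.lambda_Sigma[ctx.lambda_Sigma > 0]
    n2 = float(ctx.n) ** 2
    pvals = np.ones(t_stat.size)
    for i in range(t_stat.size):
        if lam_e[i] <= 0 or base.size == 0:
            continue
        pvals[i] = mixture_chi2_sf(base, t_stat[i] * n2 / lam_e[i])
    return pvals


def sparkx_test(
    counts: CountMatrix | sp.spmatrix,
    coords: Coordinates | np.ndarray,
    X: np.ndarray | None = None,
    option: str = "mixture",
    fdr_method: str = "BY",
) -> list[GeneTestResult]:
    """Run the covariance test for every gene across the kernel set.

    ``option='mixture'`` tests all eleven kernels and combines their p-values
    with the Cauchy rule; ``option='single:<label>'`` restricts to one kernel.
    Genes with zero variance are reported with status ``degenerate_skipped``
    and NaN p-values rather than silently dropped.
    """
    if isinstance(counts, CountMatrix):
        gene_ids = counts.gene_ids
        mat = counts.values
    else:
        mat = sp.csr_matrix(counts)
        gene_ids = [f"gene_{i}" for i in range(mat.shape[0])]
    pos = coords.positions if isinstance(coords, Coordinates) else np.asarray(coords)
    n = mat.shape[1]
    if pos.shape[0] != n:
        raise ValueError("coordinates do not match count matrix columns")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)

    kernel_set = default_kernel_set(pos)
    if option.startswith("single:"):
        label = option.split(":", 1)[1]
        kernel_set = [k for k in kernel_set if k.spec.label == label]
        if not kernel_set:
            raise ValueError(f"unknown kernel label {label!r}")
    elif option != "mixture":
        raise ValueError(f"unknown option {option!r}")

    contexts = [build_context(k, X) for k in kernel_set]
    per_kernel_T: list[np.ndarray] = []
    per_kernel_p: list[np.ndarray] = []
    lam_e = None
    degenerate = None
    for ctx in contexts:
        t_stat, le, degen = _batch_statistics(mat, ctx)
        pv = _kernel_pvalues(t_stat, le, ctx)
        per_kernel_T.append(t_stat)
        per_kernel_p.append(pv)
        lam_e, degenerate = le, degen

    p_genes = mat.shape[0]
    combined = np.full(p_genes, np.nan)
    ok = ~degenerate
    for i in np.flatnonzero(ok):
        combined[i] = cauchy_combine([pk[i] for pk in per_kernel_p])
    adjusted = np.full(p_genes, np.nan)
    if ok.any():
        adjusted[ok] = adjust_pvalues(combined[ok], method=fdr_method)

    results = []
    for i in range(p_genes):
        status = "degenerate_skipped" if degenerate[i] else "ok"
        per = [
            SingleKernelResult(
                label=ctx.label,
                T=float(per_kernel_T[k][i]),
                lambda_E=float(lam_e[i]),
                lambda_Sigma=ctx.lambda_Sigma,
                p=float("nan") if degenerate[i] else float(per_kernel_p[k][i]),
            )
            for k, ctx in enumerate(contexts)
        ]
        results.append(
            GeneTestResult(
                gene_id=gene_ids[i],
                per_kernel=per,
                combined_p=float(combined[i]),
                adjusted_p=float(adjusted[i]),
                status=status,
            )
        )
    return results


def combined_pvalues(results: list[GeneTestResult]) -> np.ndarray:
    """Convenience: array of combined p-values for non-degenerate genes."""
    return np.array(
        [r.combined_p for r in results if r.status == "ok"], dtype=float
    )
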