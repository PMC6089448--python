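"""Pedigree relationship matrix and single-locus mixed-model association.

The numerator relationship matrix A is built by the recursive tabular
method. The mixed model

    y = 1*mu + X*beta + u + e,   u ~ N(0, A*sigma_a2),  e ~ N(0, I*sigma_e2)

is fitted by REML: the variance ratio lambda = sigma_e2 / sigma_a2 is
profiled out by bounded one-dimensional search on log(lambda), with
generalized least squares for the fixed effects at each candidate. The
search works in the eigenbasis of A, so each candidate costs O(n p^2)
after a single symmetric eigendecomposition (which may be precomputed
and shared across fits on the same pedigree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DimensionError, ModelError
from .pedigree import Pedigree

GENOTYPE_LEVELS = ("GG", "AG", "AA")
CONTRAST_NAMES = ("AG-GG", "AA-GG")

LOG_LAMBDA_BOUNDS = (np.log(1e-4), np.log(1e4))
LOG_LAMBDA_TOL = 1e-6


def build_numerator_relationship(pedigree: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular method.

    Returns (A, ids) with ids in topological order (parents before
    offspring). Unknown parents contribute zero relationship; founder
    diagonals are exactly 1.
    """
    order = pedigree.topological_order()
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, animal in enumerate(order):
        sire, dam = pedigree.parents(animal)
        si = index[sire] if sire is not None else None
        di = index[dam] if dam is not None else None
        if i > 0:
            row = np.zeros(i)
            if si is not None:
                row += 0.5 * a[si, :i]
            if di is not None:
                row += 0.5 * a[di, :i]
            a[i, :i] = row
            a[:i, i] = row
        f = 0.5 * a[si, di] if (si is not None and di is not None) else 0.0
        a[i, i] = 1.0 + f
    return a, order


def inbreeding_coefficients(pedigree: Pedigree) -> dict[str, float]:
    a, order = build_numerator_relationship(pedigree)
    return {animal: float(a[i, i] - 1.0) for i, animal in enumerate(order)}


def a_inverse_henderson(pedigree: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Direct A-inverse by Henderson's rules, inbreeding-adjusted.

    The Mendelian-sampling variances are taken from the tabular A so the
    inverse is exact for inbred pedigrees as well.
    """
    a, order = build_numerator_relationship(pedigree)
    index = {an: i for i, an in enumerate(order)}
    n = len(order)
    ainv = np.zeros((n, n))
    for i, animal in enumerate(order):
        sire, dam = pedigree.parents(animal)
        si = index[sire] if sire is not None else None
        di = index[dam] if dam is not None else None
        # Mendelian sampling variance: 1 - (A_ss + A_dd)/4 over known parents
        m = 1.0
        for pi in (si, di):
            if pi is not None:
                m -= 0.25 * a[pi, pi]
        alpha = 1.0 / m
        ainv[i, i] += alpha
        for pi in (si, di):
            if pi is not None:
                ainv[i, pi] -= alpha / 2.0
                ainv[pi, i] -= alpha / 2.0
        for pi in (si, di):
            for qi in (si, di):
                if pi is not None and qi is not None:
                    ainv[pi, qi] += alpha / 4.0
    return ainv, order


@dataclass
class AEigen:
    """Cached symmetric eigendecomposition of a relationship matrix."""

    vectors: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    @classmethod
    def from_matrix(cls, a: np.ndarray) -> "AEigen":
        a = np.asarray(a, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError("relationship matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ModelError("relationship matrix is not symmetric")
        values, vectors = np.linalg.eigh(a)
        if values.min() < -1e-8 * max(1.0, values.max()):
            raise ModelError(
                f"relationship matrix is not positive semi-definite "
                f"(min eigenvalue {values.min():.3g})"
            )
        return cls(vectors=vectors, values=np.clip(values, 0.0, None))

    @property
    def n(self) -> int:
        return self.values.size

    def sqrt_transform(self, z: np.ndarray) -> np.ndarray:
        """Map iid standard normals z to a draw with covariance A."""
        return self.vectors @ (np.sqrt(self.values) * z)


@dataclass
class ContrastEstimate:
    name: str
    estimate: float | None
    se: float | None
    p_value: float | None
    estimable: bool = True
    reason: str = ""


@dataclass
class MixedModelFit:
    mu: float
    contrasts: dict[str, ContrastEstimate]
    sigma_a2: float
    sigma_e2: float
    lam: float
    log_restricted_likelihood: float
    u: np.ndarray = field(repr=False)
    n: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    note: str = ""


def _design(genotype_classes: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Intercept + indicator columns for non-reference genotype classes present."""
    cols = [np.ones(genotype_classes.size)]
    names = []
    for level in GENOTYPE_LEVELS[1:]:
        ind = (genotype_classes == level).astype(float)
        if ind.any():
            cols.append(ind)
            names.append(f"{level}-GG")
    return np.column_stack(cols), names


def _reml_profile(
    log_lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled restricted log-likelihood at a candidate ratio.

    Returns (restricted loglik, beta_hat, (X'W^-1X)^-1, sigma_a2_hat)
    where W = diag(d + lambda) in the eigenbasis of A.
    """
    lam = np.exp(log_lam)
    w = d + lam
    n, p = xt.shape
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    xty = xw.T @ yt
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    sigma_a2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise ModelError("singular fixed-effect coefficient matrix")
    ll = -0.5 * (
        (n - p) * (np.log(sigma_a2) + 1.0 + np.log(2 * np.pi))
        + np.log(w).sum()
        + logdet_xtx
    )
    return ll, beta, xtx_inv, sigma_a2


def reml_fit(
    y: np.ndarray,
    genotype_classes: list[str] | np.ndarray,
    a: np.ndarray | None = None,
    *,
    a_eig: AEigen | None = None,
    fixed_lambda: float | None = None,
    polygenic: bool = True,
) -> MixedModelFit:
    """Fit the single-locus animal model by REML.

    ``genotype_classes`` holds "GG"/"AG"/"AA" (anything else, e.g. "" or
    None, drops the animal). ``a``/``a_eig`` must cover exactly the rows
    of ``y``; with missing genotype classes the corresponding rows of
    both are dropped. ``polygenic=False`` forces sigma_a2 = 0, reducing
    to ordinary least squares on genotype-class means.
    """
    y = np.asarray(y, dtype=float)
    classes = np.asarray(
        ["" if g is None else str(g) for g in genotype_classes], dtype=object
    )
    if y.ndim != 1 or classes.shape != y.shape:
        raise DimensionError("y and genotype_classes must be equal-length vectors")
    if not np.isfinite(y).all():
        raise ModelError("phenotypes must be finite")
    if a_eig is None:
        if a is None:
            raise ConfigurationError("provide a relationship matrix or its eigendecomposition")
        if a.shape != (y.size, y.size):
            raise DimensionError(
                f"relationship matrix shape {a.shape} does not match {y.size} phenotypes"
            )
        a_eig = AEigen.from_matrix(a)
    if a_eig.n != y.size:
        raise DimensionError("eigendecomposition order does not match phenotype vector")

    keep = np.isin(classes, GENOTYPE_LEVELS)
    if not keep.all():
        # re-decompose on the subset; rare path, callers normally pre-filter
        sub = a if a is not None else a_eig.vectors @ (a_eig.values[:, None] * a_eig.vectors.T)
        sub = np.asarray(sub)[np.ix_(keep, keep)]
        return reml_fit(y[keep], classes[keep], sub, fixed_lambda=fixed_lambda, polygenic=polygenic)

    x, contrast_names = _design(classes)
    n, p = x.shape

    if not polygenic:
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sigma_e2 = float(resid @ resid) / (n - p)
        xtx_inv = np.linalg.inv(x.T @ x)
        cov = sigma_e2 * xtx_inv
        fit = _assemble_fit(
            beta, cov, contrast_names, classes,
            sigma_a2=0.0, sigma_e2=sigma_e2, lam=np.inf,
            ll=np.nan, u=np.zeros(n), n=n,
        )
        fit.note = "polygenic component fixed to zero (OLS on class means)"
        return fit

    yt = a_eig.vectors.T @ y
    xt = a_eig.vectors.T @ x
    d = a_eig.values

    if fixed_lambda is not None:
        log_lam_hat = float(np.log(fixed_lambda))
        ll = _reml_profile(log_lam_hat, d, yt, xt)[0]
    else:
        res = optimize.minimize_scalar(
            lambda ll_: -_reml_profile(ll_, d, yt, xt)[0],
            bounds=LOG_LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": LOG_LAMBDA_TOL},
        )
        log_lam_hat = float(res.x)
        ll = -float(res.fun)

    ll, beta, xtx_inv, sigma_a2 = _reml_profile(log_lam_hat, d, yt, xt)
    lam = float(np.exp(log_lam_hat))
    sigma_e2 = lam * sigma_a2
    cov = sigma_a2 * xtx_inv

    w = d + lam
    resid_t = yt - xt @ beta
    u = a_eig.vectors @ ((d / w) * resid_t)

    return _assemble_fit(
        beta, cov, contrast_names, classes,
        sigma_a2=float(sigma_a2), sigma_e2=float(sigma_e2), lam=lam,
        ll=float(ll), u=u, n=n,
    )


def _assemble_fit(beta, cov, contrast_names, classes, *, sigma_a2, sigma_e2, lam, ll, u, n):
    contrasts: dict[str, ContrastEstimate] = {}
    class_counts = {lvl: int((classes == lvl).sum()) for lvl in GENOTYPE_LEVELS}
    for name in CONTRAST_NAMES:
        if name in contrast_names:
            j = contrast_names.index(name) + 1  # +1 for intercept column
            est = float(beta[j])
            se = float(np.sqrt(cov[j, j]))
            z = est / se if se > 0 else np.nan
            p = float(2.0 * stats.norm.sf(abs(z)))
            contrasts[name] = ContrastEstimate(name, est, se, p)
        else:
            level = name.split("-")[0]
            contrasts[name] = ContrastEstimate(
                name, None, None, None, estimable=False,
                reason=f"no phenotyped animals in genotype class {level}",
            )
    return MixedModelFit(
        mu=float(beta[0]),
        contrasts=contrasts,
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        lam=lam,
        log_restricted_likelihood=ll,
        u=np.asarray(u),
        n=n,
        class_counts=class_counts,
    )


def solve_mme(
    y: np.ndarray, genotype_classes: np.ndarray, ainv: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's mixed-model equations at a fixed variance ratio.

    Returns (beta, u). Used as an independent route to the GLS fixed
    effects computed in the eigenbasis (they agree to numerical
    precision for PSD A with known lambda).
    """
    classes = np.asarray(genotype_classes, dtype=object)
    x, _ = _design(classes)
    n = y.size
    z = np.eye(n)
    top = np.hstack([x.T @ x, x.T @ z])
    bottom = np.hstack([z.T @ x, z.T @ z + lam * ainv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    p = x.shape[1]
    return sol[:p], sol[p:]


def significance_stars(p_value: float | None) -> str:
    if p_value is None:
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def genotype_contrasts(fit: MixedModelFit, n_traits_tested: int = 1):
    """Contrast table with significance markers at p<0.05 (*) and p<0.01 (**).

    A Bonferroni-adjusted p is emitted alongside for transparency; stars
    are assigned on the nominal p, matching the source presentation.
    With small cohorts the Wald p-values are approximate (noted in the
    output).
    """
    import pandas as pd

    rows = []
    for name in CONTRAST_NAMES:
        c = fit.contrasts[name]
        if not c.estimable:
            rows.append(
                {"contrast": name, "estimate": None, "se": None, "p_value": None,
                 "p_bonferroni": None, "stars": "", "estimable": False, "reason": c.reason}
            )
            continue
        rows.append(
            {
                "contrast": name,
                "estimate": c.estimate,
                "se": c.se,
                "p_value": c.p_value,
                "p_bonferroni": min(1.0, c.p_value * n_traits_tested),
                "stars": significance_stars(c.p_value),
                "estimable": True,
                "reason": "",
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["note"] = (
        "Wald z inference; p-values are large-sample approximations and are "
        "approximate for small cohorts"
    )
    return table
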