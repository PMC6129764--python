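"""Group statistics: voxel-wise t-tests, image-based meta-analysis (IBMA),
and multiple-comparison correction.

The voxel-wise GLM regresses each voxel's per-subject value on an
intercept, a group indicator (or nothing for the one-sample case), and any
covariates, and tests the coefficient of interest with a t statistic on
n - p degrees of freedom.  IBMA combiners merge per-study statistic or
effect maps: Stouffer's z, Fisher's chi-square, inverse-variance fixed and
DerSimonian-Laird mixed effects, Worsley-Friston's (max p)^k conjunction,
and Nichols' max-p minimum conjunction.  FDR control uses the
Benjamini-Hochberg (independent/PRDS) and Benjamini-Yekutieli (arbitrary
dependence) step-up procedures; FWER control uses Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "IBMAStudy",
    "glm_ttest",
    "ibma_combine",
    "correct_multiple",
]


@dataclass
class StatMap:
    """Per-voxel statistic with df and two-sided p companions."""

    stat: np.ndarray
    df: float
    p: np.ndarray
    kind: str = "t"   # "t" | "z" | "chi2" | "p"

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != self.stat.shape:
            raise ValueError("p and stat shapes differ")


@dataclass
class IBMAStudy:
    """One study's map for meta-analysis.

    Depending on the combiner, ``map`` holds z-values, p-values, or effect
    estimates (with ``variance`` then required); ``n`` is the study sample
    size (used only for bookkeeping/weighting extensions).
    """

    map: np.ndarray
    n: int | None = None
    variance: np.ndarray | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=np.float64)
            if self.variance.shape != self.map.shape:
                raise ValueError("variance map shape differs from effect map")


def _as_2d(maps) -> tuple[np.ndarray, tuple]:
    """Stack per-subject maps to (n_subjects, n_voxels); remember the shape."""
    arr = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    shape = arr.shape[1:]
    return arr.reshape(arr.shape[0], -1), shape


def glm_ttest(
    maps,
    groups: np.ndarray | list | None = None,
    covariates: np.ndarray | None = None,
    contrast: str = "two",
    two_sided: bool = True,
) -> StatMap:
    """Voxel-wise t-test via a per-voxel linear model.

    * ``two``: design = [intercept, group indicator, covariates]; t on the
      group coefficient, df = n - p.
    * ``one``: design = [intercept, covariates]; t on the intercept
      (mean against zero).
    * ``paired``: ``groups`` must mark two conditions with matched ordering;
      the condition difference is tested as a one-sample t (covariates
      allowed).
    """
    Y, shape = _as_2d(maps)
    n = Y.shape[0]

    if contrast == "paired":
        if groups is None:
            raise ValueError("paired contrast needs group labels")
        g = np.asarray(groups)
        lab = np.unique(g)
        if len(lab) != 2:
            raise ValueError("paired contrast needs exactly 2 conditions")
        a, b = Y[g == lab[0]], Y[g == lab[1]]
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired groups must have equal size and matched order")
        Y = a - b
        n = Y.shape[0]
        groups = None
        contrast = "one"

    cols = [np.ones(n)]
    test_col = 0
    if contrast == "two":
        if groups is None:
            raise ValueError("two-sample contrast needs group labels")
        g = np.asarray(groups)
        lab = np.unique(g)
        if len(lab) != 2:
            raise ValueError(f"need exactly 2 groups, got {lab.tolist()}")
        indicator = (g == lab[1]).astype(float)
        cols.append(indicator)
        test_col = 1
    elif contrast != "one":
        raise ValueError("contrast must be 'one', 'two' or 'paired'")
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match the number of subjects")
        cols.extend(cov.T)
    X = np.column_stack(cols)
    p_cols = X.shape[1]
    if n <= p_cols:
        raise ValueError(f"need more subjects ({n}) than design columns ({p_cols})")
    rank = np.linalg.matrix_rank(X)
    if rank < p_cols:
        raise ValueError(
            "rank-deficient design; check for collinear columns "
            f"(rank {rank} < {p_cols})"
        )
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p_cols
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[test_col, test_col], 1e-300))
    t = beta[test_col] / se
    if two_sided:
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        p = sps.t.sf(t, df)
    return StatMap(t.reshape(shape), df=float(df), p=p.reshape(shape), kind="t")


_P_FLOOR = np.finfo(np.float64).tiny


def _clip_p(p: np.ndarray) -> np.ndarray:
    if np.any(p <= 0):
        warnings.warn("p = 0 inputs clipped to the smallest positive float")
    return np.clip(p, _P_FLOOR, 1.0)


def ibma_combine(studies: list[IBMAStudy], method: str = "stouffer") -> StatMap:
    """Combine per-study maps voxel-wise.

    p-value methods (``fisher``, ``worsley_friston``, ``nichols``) read
    ``map`` as p-values; ``stouffer`` reads z-values; the effect-size
    methods (``fixed``, ``mixed``) need effect maps with variances.
    """
    if len(studies) < 2:
        raise ValueError("need at least 2 studies")
    shapes = {s.map.shape for s in studies}
    if len(shapes) != 1:
        raise ValueError("study maps are not on a common grid")
    k = len(studies)
    stack = np.stack([s.map for s in studies])

    if method == "stouffer":
        z = stack.sum(axis=0) / np.sqrt(k)
        p = 2.0 * sps.norm.sf(np.abs(z))
        return StatMap(z, df=np.inf, p=p, kind="z")
    if method == "fisher":
        p_in = _clip_p(stack)
        x = -2.0 * np.log(p_in).sum(axis=0)
        p = sps.chi2.sf(x, df=2 * k)
        return StatMap(x, df=float(2 * k), p=p, kind="chi2")
    if method == "worsley_friston":
        p_in = _clip_p(stack)
        p = np.max(p_in, axis=0) ** k
        return StatMap(p, df=float(k), p=p, kind="p")
    if method == "nichols":
        p_in = _clip_p(stack)
        p = np.max(p_in, axis=0)
        return StatMap(p, df=float(k), p=p, kind="p")
    if method in ("fixed", "mixed"):
        for s in studies:
            if s.variance is None:
                raise ValueError(f"{method}-effects combiner needs variance maps")
        v = np.stack([s.variance for s in studies])
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
        if method == "mixed":
            # DerSimonian-Laird between-study variance, floored at 0
            w = 1.0 / v
            theta_fixed = (w * stack).sum(axis=0) / w.sum(axis=0)
            q = (w * (stack - theta_fixed) ** 2).sum(axis=0)
            c = w.sum(axis=0) - (w**2).sum(axis=0) / w.sum(axis=0)
            tau2 = np.maximum((q - (k - 1)) / np.maximum(c, 1e-300), 0.0)
            v = v + tau2
        w = 1.0 / v
        theta = (w * stack).sum(axis=0) / w.sum(axis=0)
        z = (w * stack).sum(axis=0) / np.sqrt(w.sum(axis=0))
        p = 2.0 * sps.norm.sf(np.abs(z))
        out = StatMap(z, df=np.inf, p=p, kind="z")
        out.effect = theta  # combined effect estimate alongside the z map
        out.effect_variance = 1.0 / w.sum(axis=0)
        return out
    raise ValueError(f"unknown IBMA method {method!r}")


def correct_multiple(
    p, method: str = "bh", q_or_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-comparison correction.

    ``bh``/``by`` are the step-up FDR procedures (BY divides the level by
    the harmonic constant c(m) = sum 1/j); ``bonferroni`` controls FWER.
    Returns (reject flags, adjusted p), shaped like the input.
    """
    p = np.asarray(p, dtype=np.float64)
    shape = p.shape
    flat = p.ravel()
    if flat.size == 0:
        return np.zeros(shape, dtype=bool), np.zeros(shape)
    if np.any((flat < 0) | (flat > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'bh', 'by' or 'bonferroni'")
    reject, p_adj, _, _ = multipletests(flat, alpha=q_or_alpha, method=sm_method)
    return reject.reshape(shape), p_adj.reshape(shape)
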