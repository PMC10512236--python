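"""Negative-binomial Wald differential expression.

Implements the classic RNA-seq testing stack: median-of-ratios size
factors, per-feature NB2 generalized linear models with a log link and
sample-specific offsets, Wald tests on a contrast coefficient, and
Benjamini-Hochberg adjustment. The model for feature i in sample j is

    K_ij ~ NB(mu_ij, alpha_i),   mu_ij = s_j * exp(x_j' beta_i),

with Var(K) = mu + alpha * mu^2. Dispersions are estimated per feature by
a simple method of moments on normalized counts (no empirical-Bayes
shrinkage across features, no independent filtering, no fold-change
shrinkage); coefficients are fitted by Fisher scoring (IRLS).
Hybrid-vs-parent contrasts use treatment coding with the parental species
as the reference level and subset both samples and features to the focal
parent's subgenome plus its Ty families.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8
FALLBACK_DISPERSION = 0.1
IRLS_TOL = 1e-8
IRLS_MAXIT = 100


# ---------------------------------------------------------------------------
# Size factors


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization.

    s_j = median over reference features i of k_ij / g_i, where g_i is the
    geometric mean of feature i across samples and the reference set is
    the features with no zero count (features containing any zero are
    excluded, the standard convention). Corrects for both sequencing depth
    and RNA composition.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with all-positive counts; supply a pseudo-reference "
            "or filter samples"
        )
    ref = arr[positive]
    geo = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geo[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Design matrices


@dataclasses.dataclass
class DesignSpec:
    """Treatment-coded design: main factors plus optional interactions.

    ``terms`` lists column names of the sample sheet, or tuples of names
    for interaction terms (e.g. ``["temperature", "species",
    ("species", "temperature")]``). ``reference`` maps factor -> reference
    level; unlisted factors use their lexicographically first level.
    ``contrast`` names the coefficient tested by the Wald test.
    """

    terms: Sequence
    contrast: str
    reference: Mapping[str, str] = dataclasses.field(default_factory=dict)


def design_matrix(samples: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(samples))}
    dummies: dict = {}

    def factor_dummies(factor: str) -> dict:
        if factor not in dummies:
            levels = sorted(samples[factor].astype(str).unique())
            ref = str(spec.reference.get(factor, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {factor!r}")
            dummies[factor] = {
                lvl: (
                    f"{factor}_{lvl}_vs_{ref}",
                    (samples[factor].astype(str) == lvl).to_numpy(float),
                )
                for lvl in levels
                if lvl != ref
            }
        return dummies[factor]

    for term in spec.terms:
        if isinstance(term, str):
            for name, vec in factor_dummies(term).values():
                cols[name] = vec
        else:
            parts = [factor_dummies(f) for f in term]
            for combo in itertools.product(*(p.values() for p in parts)):
                name = ":".join(c[0] for c in combo)
                vec = np.ones(len(samples))
                for c in combo:
                    vec = vec * c[1]
                cols[name] = vec

    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is not full rank on these samples")
    if spec.contrast not in X.columns:
        raise ValueError(
            f"contrast {spec.contrast!r} not among design columns "
            f"{list(X.columns)}"
        )
    return X


# ---------------------------------------------------------------------------
# Dispersion


def dispersion_moments(counts: pd.DataFrame, sf: pd.Series,
                       design=None) -> pd.Series:
    """Per-feature method-of-moments dispersion on normalized counts.

    Moments are taken within design cells (samples sharing a design-matrix
    row) so genuine group differences are not mistaken for overdispersion:
    pooling E[s^2_g] = m_g + alpha m_g^2 over cells g gives

        alpha = max(1e-8, sum_g (n_g-1)(s^2_g - m_g) / sum_g (n_g-1) m_g^2).

    ``design`` is the design matrix (array-like) or None for a single cell.
    A trend-free fallback of 0.1 applies when fewer than 3 residual degrees
    of freedom remain.
    """
    q = counts.div(sf, axis=1).to_numpy(dtype=float)
    n = q.shape[1]
    if design is None:
        groups = [np.arange(n)]
    else:
        X = np.asarray(design, dtype=float)
        _, inverse = np.unique(X, axis=0, return_inverse=True)
        groups = [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]
    dof = n - len(groups)
    if dof < 3:
        logger.info("dispersion fallback %.2f: only %d residual dof",
                    FALLBACK_DISPERSION, dof)
        return pd.Series(FALLBACK_DISPERSION, index=counts.index)
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in groups:
        if len(idx) < 2:
            continue
        m = q[:, idx].mean(axis=1)
        v = q[:, idx].var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v - m)
        den += w * np.square(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha = np.where(np.isfinite(alpha), alpha, FALLBACK_DISPERSION)
    return pd.Series(np.maximum(alpha, MIN_DISPERSION), index=counts.index)


#: Pseudo-observations the cross-feature median contributes when
#: moderating per-feature dispersion estimates.
MODERATION_PRIOR_DOF = 10.0


def moderate_dispersions(alpha: pd.Series, residual_dof: int,
                         prior_dof: float = MODERATION_PRIOR_DOF) -> pd.Series:
    """Shrink per-feature dispersions toward the cross-feature median.

    Raw method-of-moments estimates are noisy at typical replicate
    numbers, which degrades Wald calibration feature by feature. A
    precision-weighted pull toward the (trend-free) median,

        alpha* = (dof * alpha_i + prior_dof * median(alpha)) / (dof + prior_dof),

    stabilizes them without modelling any mean-dispersion trend.
    """
    if len(alpha) < 3:
        return alpha
    center = float(alpha.median())
    w = residual_dof / (residual_dof + prior_dof)
    return (w * alpha + (1 - w) * center).clip(lower=MIN_DISPERSION)


# ---------------------------------------------------------------------------
# NB GLM via IRLS


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    """Fisher scoring for the NB2 log-link GLM with fixed dispersion.

    Returns (beta, cov, converged). Weights are mu / (1 + alpha * mu).
    """
    n, p = X.shape
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = None
    for _ in range(IRLS_MAXIT):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        xtwx = X.T @ WX
        try:
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError:
            return None, None, False
        if beta is not None:
            denom = np.maximum(np.abs(beta), 1.0)
            if np.max(np.abs(beta_new - beta) / denom) < IRLS_TOL:
                beta = beta_new
                break
        beta = beta_new
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
    else:
        return beta, None, False
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, True


def nb_wald_fit(
    counts: pd.DataFrame,
    sf: pd.Series,
    design: pd.DataFrame | DesignSpec,
    samples: pd.DataFrame | None = None,
    dispersion=None,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test for one contrast coefficient.

    ``design`` is a prebuilt design matrix or a :class:`DesignSpec` (then
    ``samples`` must be given). ``dispersion`` may be None (method of
    moments), a scalar, or a per-feature Series. Returns a DataFrame with
    baseMean, log2FoldChange, lfcSE, stat, pvalue; features that cannot be
    fitted (all-zero, non-convergent) carry missing p.
    """
    if isinstance(design, DesignSpec):
        if samples is None:
            raise ValueError("samples required when design is a DesignSpec")
        contrast = contrast or design.contrast
        design = design_matrix(samples.loc[counts.columns], design)
    X = design.loc[counts.columns].to_numpy(dtype=float)
    if contrast is None:
        raise ValueError("a contrast coefficient name is required")
    ci = list(design.columns).index(contrast)

    if dispersion is None:
        raw = dispersion_moments(counts, sf, X)
        n_cells = np.unique(X, axis=0).shape[0]
        alphas = moderate_dispersions(raw, max(counts.shape[1] - n_cells, 1))
    elif np.isscalar(dispersion):
        alphas = pd.Series(float(dispersion), index=counts.index)
    else:
        alphas = dispersion.reindex(counts.index)

    offset = np.log(sf.loc[counts.columns].to_numpy(dtype=float))
    norm = counts.div(sf, axis=1)

    rows = []
    for fid in counts.index:
        y = counts.loc[fid].to_numpy(dtype=float)
        base_mean = float(norm.loc[fid].mean())
        if not np.any(y > 0):
            rows.append((fid, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        alpha = max(float(alphas.loc[fid]), MIN_DISPERSION)
        beta, cov, ok = _irls_nb(y, X, offset, alpha)
        if not ok or cov is None:
            logger.info("fit failed for %s", fid)
            est = np.nan if beta is None else beta[ci] / LOG2
            rows.append((fid, base_mean, est, np.nan, np.nan, np.nan))
            continue
        lfc = beta[ci] / LOG2
        se = np.sqrt(cov[ci, ci]) / LOG2
        z = lfc / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((fid, base_mean, lfc, se, z, p))

    out = pd.DataFrame(
        rows,
        columns=["feature", "baseMean", "log2FoldChange", "lfcSE", "stat",
                 "pvalue"],
    ).set_index("feature")
    out["padj"] = bh_adjust(out["pvalue"])
    return out


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing p are excluded from m."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        pv = p[ok]
        m = pv.size
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        cummin = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.minimum(cummin, 1.0)
        out = np.empty(m)
        out[order] = vals
        adj[ok] = out
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="padj")
    return adj


# ---------------------------------------------------------------------------
# Contrast orchestration


@dataclasses.dataclass
class Contrast:
    """One hybrid-vs-parent comparison.

    Samples are subset to {hybrid, focal parent}; features to the focal
    parent's subgenome (genes plus its Ty families). ``extra_terms`` adds
    factors (and interaction tuples) to the design beyond species.
    """

    name: str
    focal_parent: str
    hybrid_level: str = "hybrid"
    species_column: str = "species"
    extra_terms: Sequence = ()
    contrast: str | None = None  # default: the species main effect
    alpha: float = 0.05


def run_contrasts(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    feature_subgenome: pd.Series,
    contrasts: Sequence[Contrast],
    dispersion=None,
) -> dict:
    """Run each contrast on its sample/feature subset; size factors are
    recomputed within each subset."""
    results = {}
    for c in contrasts:
        keep_samples = sample_sheet[
            sample_sheet[c.species_column].isin([c.focal_parent, c.hybrid_level])
        ]
        for level in (c.focal_parent, c.hybrid_level):
            n = int((keep_samples[c.species_column] == level).sum())
            if n < 2:
                raise ValueError(
                    f"contrast {c.name!r}: level {level!r} has {n} replicate(s); "
                    "at least 2 required"
                )
        keep_features = feature_subgenome[
            feature_subgenome == c.focal_parent
        ].index.intersection(counts.index)
        sub = counts.loc[keep_features, keep_samples.index]

        terms = list(c.extra_terms) + [c.species_column]
        contrast_name = (
            c.contrast
            or f"{c.species_column}_{c.hybrid_level}_vs_{c.focal_parent}"
        )
        spec = DesignSpec(
            terms=terms,
            contrast=contrast_name,
            reference={c.species_column: c.focal_parent},
        )
        sf = size_factors(sub)
        res = nb_wald_fit(sub, sf, spec, samples=keep_samples,
                          dispersion=dispersion)
        res["significant"] = res["padj"] < c.alpha
        results[c.name] = res
    return results


def summarize_contrasts(results: Mapping[str, pd.DataFrame],
                        ty_features: Sequence[str] = (),
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-contrast tallies of tested / up / down features (and Ty subsets)."""
    ty = set(ty_features)
    rows = []
    for name, res in results.items():
        sig = res["padj"] < alpha
        up = sig & (res["log2FoldChange"] > 0)
        down = sig & (res["log2FoldChange"] < 0)
        is_ty = res.index.isin(ty)
        rows.append(
            {
                "contrast": name,
                "n_tested": int(res["pvalue"].notna().sum()),
                "n_up": int(up.sum()),
                "n_down": int(down.sum()),
                "ty_tested": int((res["pvalue"].notna() & is_ty).sum()),
                "ty_up": int((up & is_ty).sum()),
                "ty_down": int((down & is_ty).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
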