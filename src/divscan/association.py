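"""Single-SNP additive and dominance association tests under Y = SNP + f + e.

``f`` is a half-sib family effect, treated as random (the default, a two-step
GLS-LS scheme) or fixed (family indicator columns, for cross-checking).  The
GLS-LS route first estimates the family variance component with a one-way
ANOVA moment estimator (truncated at zero), removes GLS estimates of the
fixed non-genetic covariates (e.g. hatch) from the phenotype under the
implied compound-symmetry covariance, and then tests each SNP on the adjusted
phenotype with the same covariance.  Per SNP two 1-df tests are run: a linear
trend over dosage {0,1,2} (additive) and a heterozygote deviation
(dominance), each with a two-sided p-value from the t reference distribution.

The genome-wide significance threshold is Bonferroni over traits x effects x
SNPs: alpha / (n_traits * n_effects * n_snps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DomainError
from .genotype_io import MISSING

log = logging.getLogger(__name__)

MIN_CLASS_N = 3


def bonferroni_threshold(
    alpha: float, n_snps: int, n_traits: int = 2, n_effects: int = 2
) -> float:
    """alpha / (n_traits * n_effects * n_snps)."""
    if alpha <= 0 or n_snps <= 0 or n_traits <= 0 or n_effects <= 0:
        raise DomainError("all Bonferroni arguments must be positive")
    return alpha / (n_traits * n_effects * n_snps)


def family_variance_components(y: np.ndarray, families: np.ndarray):
    """One-way ANOVA moment estimators of (family variance, residual variance).

    sigma_f^2 = (MSB - MSW) / n0 truncated at 0, with
    n0 = (N - sum n_i^2 / N) / (k - 1).
    """
    y = np.asarray(y, dtype=float)
    fam_codes, fam_idx = np.unique(families, return_inverse=True)
    k = len(fam_codes)
    if k < 2:
        raise DataError("need at least two families")
    n = len(y)
    n_i = np.bincount(fam_idx)
    sums = np.bincount(fam_idx, weights=y)
    means = sums / n_i
    ssb = float((n_i * (means - y.mean()) ** 2).sum())
    ssw = float(((y - means[fam_idx]) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (n_i**2).sum() / n) / (k - 1)
    sigma2_f = max(0.0, (msb - msw) / n0)
    return sigma2_f, msw


def _whiten(y, X, fam_idx, sigma2_f, sigma2_e):
    """Transform (y, X) so the compound-symmetry covariance becomes spherical.

    For a family of size m, V = s_e^2 I + s_f^2 J and
    V^{-1/2} = (1/s_e) (I - (c/m) J) with c = 1 - sqrt(s_e^2/(s_e^2 + m s_f^2)).
    """
    if sigma2_f <= 0:
        return y.copy(), X.copy()
    se = np.sqrt(sigma2_e)
    yw = y.astype(float).copy()
    Xw = X.astype(float).copy()
    for fam in np.unique(fam_idx):
        sel = fam_idx == fam
        m = sel.sum()
        c = 1.0 - np.sqrt(sigma2_e / (sigma2_e + m * sigma2_f))
        yw[sel] -= c * yw[sel].mean()
        Xw[sel] -= c * Xw[sel].mean(axis=0)
    return yw / se, Xw / se


def _design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(n)], ["intercept"]
    if covariates is not None:
        for name in covariates.columns:
            series = covariates[name]
            if series.dtype.kind in "OUb" or series.nunique() < 10:
                levels = sorted(series.astype(str).unique())
                for lev in levels[1:]:  # first level absorbed by intercept
                    cols.append((series.astype(str) == lev).to_numpy(float))
                    names.append(f"{name}[{lev}]")
            else:
                cols.append(series.to_numpy(float))
                names.append(name)
    return np.column_stack(cols), names


def adjust_phenotypes(
    y: np.ndarray,
    families: np.ndarray,
    covariates: pd.DataFrame | None = None,
):
    """GLS removal of fixed non-genetic covariate effects.

    Returns (adjusted y, sigma2_f, sigma2_e, coefficient Series).  The family
    effect itself is *not* subtracted -- it stays in the model for the SNP
    tests.  With a zero family-variance estimate the GLS step reduces to
    ordinary least squares (logged).
    """
    y = np.asarray(y, dtype=float)
    sigma2_f, sigma2_e = family_variance_components(y, families)
    if sigma2_f == 0.0:
        log.info("family variance estimate is zero; GLS reduces to OLS")
    X, names = _design(covariates, len(y))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(f"collinear covariate design; columns: {names}")
    _, fam_idx = np.unique(families, return_inverse=True)
    yw, Xw = _whiten(y, X, fam_idx, sigma2_f, sigma2_e)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    adjusted = y - X @ beta
    return adjusted, sigma2_f, sigma2_e, pd.Series(beta, index=names)


def _t_pvalues(yw, Xw, test_cols):
    """OLS on whitened data; two-sided t p-values for the requested columns."""
    n, p = Xw.shape
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = n - rank
    if df <= 0:
        return beta, {c: (np.nan, np.nan) for c in test_cols}
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    out = {}
    for c in test_cols:
        se = np.sqrt(s2 * XtX_inv[c, c])
        if se == 0:
            out[c] = (beta[c], np.nan)
            continue
        t = beta[c] / se
        pval = 2.0 * sps.t.sf(abs(t), df)
        out[c] = (beta[c], max(pval, np.finfo(float).tiny))
    return beta, out


def snp_tests(
    y_adj: np.ndarray,
    genotypes: np.ndarray,
    families: np.ndarray,
    sigma2_f: float,
    sigma2_e: float,
    trait: str = "trait",
    family_mode: str = "random",
    min_class_n: int = MIN_CLASS_N,
    marker_ids=None,
) -> pd.DataFrame:
    """Additive and dominance 1-df tests for every SNP column.

    family_mode "random": GLS with the compound-symmetry covariance implied by
    (sigma2_f, sigma2_e).  family_mode "fixed": family indicator columns in
    an OLS fit.  SNPs that are monomorphic or lack two genotype classes with
    ``min_class_n`` observations are skipped with a reason; the dominance test
    alone is skipped when there are no heterozygotes.
    """
    if family_mode not in ("random", "fixed"):
        raise DomainError(f"unknown family_mode {family_mode!r}")
    y_adj = np.asarray(y_adj, dtype=float)
    genotypes = np.atleast_2d(np.asarray(genotypes))
    if genotypes.shape[0] != len(y_adj):
        genotypes = genotypes.T
    n_snp = genotypes.shape[1]
    _, fam_idx = np.unique(families, return_inverse=True)
    if marker_ids is None:
        marker_ids = [f"snp{j}" for j in range(n_snp)]

    fam_dummies = None
    if family_mode == "fixed":
        k = fam_idx.max() + 1
        fam_dummies = np.zeros((len(y_adj), k - 1))
        for f in range(1, k):
            fam_dummies[fam_idx == f, f - 1] = 1.0

    rows = []
    for j in range(n_snp):
        g = genotypes[:, j]
        ok = (g != MISSING) & np.isfinite(y_adj)
        gj, yj, fj = g[ok].astype(float), y_adj[ok], fam_idx[ok]
        counts = {int(k): int((gj == k).sum()) for k in (0, 1, 2)}
        classes_ok = sum(1 for v in counts.values() if v >= min_class_n)
        base = {
            "marker": marker_ids[j],
            "trait": trait,
            "n": int(ok.sum()),
            "n_aa": counts[2],
            "n_ab": counts[1],
            "n_bb": counts[0],
            "method": "gls-ls" if family_mode == "random" else "fixed-family",
        }
        if len(set(gj)) < 2 or classes_ok < 2:
            rows.append(
                {**base, "add_beta": np.nan, "add_p": np.nan, "dom_beta": np.nan,
                 "dom_p": np.nan, "skipped": "monomorphic-or-thin-classes"}
            )
            continue
        x_add = gj
        x_dom = (gj == 1).astype(float)
        test_dom = counts[1] > 0 and len(set(gj)) == 3
        cols = [np.ones(len(yj)), x_add] + ([x_dom] if test_dom else [])
        X = np.column_stack(cols)
        if fam_dummies is not None:
            # rebuild dummies on the complete-case subset
            sub = fam_dummies[ok]
            keep = sub.sum(axis=0) > 0
            X = np.column_stack([X, sub[:, keep]])
            yw, Xw = yj, X
        else:
            yw, Xw = _whiten(yj, X, fj, sigma2_f, sigma2_e)
        _, res = _t_pvalues(yw, Xw, [1, 2] if test_dom else [1])
        add_beta, add_p = res[1]
        dom_beta, dom_p = res.get(2, (np.nan, np.nan))
        rows.append(
            {**base, "add_beta": add_beta, "add_p": add_p, "dom_beta": dom_beta,
             "dom_p": dom_p, "skipped": "" if test_dom else "no-dominance-test"}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssocModelSpec:
    trait: str
    covariates: tuple[str, ...] = ("hatch",)
    family_mode: str = "random"
    alpha: float = 0.05
    n_traits: int = 2
    n_effects: int = 2

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise DomainError("alpha must be in (0, 1)")


def run_association(
    pheno: pd.DataFrame,
    genotypes: np.ndarray,
    spec: AssocModelSpec,
    marker_ids=None,
) -> pd.DataFrame:
    """Two-step association analysis of one trait: covariate adjustment, then
    per-SNP tests.  ``pheno`` rows must align with genotype rows and carry a
    ``family`` column plus the covariate columns."""
    cov = pheno[list(spec.covariates)] if spec.covariates else None
    usable = (cov.nunique() > 1).to_numpy() if cov is not None else np.array([], bool)
    cov = cov.loc[:, usable] if cov is not None and usable.any() else None
    y_adj, s2f, s2e, _ = adjust_phenotypes(
        pheno[spec.trait].to_numpy(), pheno["family"].to_numpy(), cov
    )
    return snp_tests(
        y_adj,
        genotypes,
        pheno["family"].to_numpy(),
        s2f,
        s2e,
        trait=spec.trait,
        family_mode=spec.family_mode,
        marker_ids=marker_ids,
    )


def significance_overlap(
    results: pd.DataFrame, threshold: float, traits: tuple[str, str] = ("AFW", "AFP")
) -> dict:
    """Count SNPs genome-wide significant (either effect) for any trait and
    for both traits; returns counts plus the both-traits percentage."""
    sig: dict[str, set] = {}
    for trait in traits:
        sub = results[results["trait"] == trait]
        hit = (sub["add_p"] < threshold) | (sub["dom_p"] < threshold)
        sig[trait] = set(sub.loc[hit.fillna(False), "marker"])
    any_sig = set().union(*sig.values())
    both = set.intersection(*sig.values()) if sig else set()
    return {
        "n_significant_any": len(any_sig),
        "n_significant_both": len(both),
        "pct_both": 100.0 * len(both) / len(any_sig) if any_sig else np.nan,
    }
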