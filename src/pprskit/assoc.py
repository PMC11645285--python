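"""Trait transforms, per-variant association scans and meta-analysis utilities.

The linear scan uses exact partialling-out (Frisch-Waugh) so the whole
variant panel is fit in a handful of matrix products while remaining
numerically identical to per-variant OLS. Logistic fits go through
statsmodels one variant at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from pprskit.io import GenotypeMatrix

BLOM_OFFSET = 3.0 / 8.0

ADJUSTMENT_LABELS = ("none", "BMI", "WFM", "VAT", "WHR")


@dataclass(frozen=True)
class AssocRecord:
    """One per-variant effect estimate under a named trait/adjustment."""

    variant_id: str
    trait: str
    adjustment: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    note: str = ""

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect inverse-variance pooled estimate."""

    pooled_beta: float
    pooled_se: float
    p: float
    k_studies: int
    per_study: tuple
    q_het: float


@dataclass(frozen=True)
class TransformSpec:
    kind: str = "rank-inverse-normal"
    tie_policy: str = "average-rank"
    offset: float = BLOM_OFFSET

    def __post_init__(self):
        if self.kind not in {"rank-inverse-normal", "log", "standardize", "none"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not 0 <= self.offset < 0.5:
            raise ValueError("offset must be in [0, 0.5)")


def records_to_frame(records) -> pd.DataFrame:
    """Summary-statistics table (one row per AssocRecord)."""
    return pd.DataFrame([{
        "variant_id": r.variant_id, "trait": r.trait, "adjustment": r.adjustment,
        "effect_allele": r.effect_allele, "other_allele": r.other_allele,
        "eaf": r.eaf, "beta": r.beta, "se": r.se, "p": r.p, "n": r.n, "note": r.note,
    } for r in records])


# ---------------------------------------------------------------------------
# transforms


def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset, average-rank ties.

    Maps value with rank r (of n finite values) to
    ``Phi^-1((r - offset) / (n + 1 - 2*offset))``. NaN propagates.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 3:
        raise ValueError("need at least 3 finite values")
    xf = x[finite]
    if np.all(xf == xf[0]):
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(xf, method="average")
    out = np.full_like(x, np.nan)
    out[finite] = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    return out


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if spec.kind == "none":
        return x
    if spec.kind == "log":
        if np.nanmin(x) <= 0:
            raise ValueError("log transform requires strictly positive values")
        return np.log(x)
    if spec.kind == "standardize":
        return (x - np.nanmean(x)) / np.nanstd(x)
    return rank_inverse_normal(x, offset=spec.offset)


# ---------------------------------------------------------------------------
# association scans


def _design(covariates) -> np.ndarray:
    if covariates is None:
        return None
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return c


def _complete_rows(y, c):
    mask = np.isfinite(y)
    if c is not None:
        mask &= np.all(np.isfinite(c), axis=1)
    return mask


def assoc_scan(genotypes: GenotypeMatrix, phenotype, covariates=None,
               family: str = "linear", trait: str = "trait",
               adjustment: str = "none") -> list[AssocRecord]:
    """Additive per-variant association scan with a fixed covariate set.

    Listwise deletion on phenotype/covariates, then per-variant deletion of
    missing dosages; the per-record ``n`` is the count actually used.
    Constant dosages and logistic separation are flagged in ``note`` with
    NaN estimates rather than dropped.
    """
    if family not in {"linear", "logistic"}:
        raise ValueError(f"unknown family {family!r}")
    y_all = np.asarray(phenotype, dtype=float)
    c_all = _design(covariates)
    base = _complete_rows(y_all, c_all)
    y = y_all[base]
    C = np.column_stack([np.ones(base.sum()), c_all[base]]) if c_all is not None \
        else np.ones((base.sum(), 1))
    D = genotypes.dosages[base]

    if family == "logistic":
        return _logistic_scan(genotypes, y, C, D, trait, adjustment)
    return _linear_scan(genotypes, y, C, D, trait, adjustment)


def _record(genotypes, j, d_used, trait, adjustment, beta, se, p, n, note=""):
    v = genotypes.variants.iloc[j]
    eaf = float(np.nanmean(d_used) / 2) if n else np.nan
    return AssocRecord(
        variant_id=v["variant_id"], trait=trait, adjustment=adjustment,
        effect_allele=v["effect_allele"], other_allele=v["other_allele"],
        eaf=eaf, beta=beta, se=se, p=p, n=n, note=note,
    )


def _linear_scan(genotypes, y, C, D, trait, adjustment) -> list[AssocRecord]:
    n, m = D.shape
    k = C.shape[1]
    # partial out covariates once; exact OLS via Frisch-Waugh
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    records = []
    clean = ~np.isnan(D).any(axis=0)
    if clean.any():
        G = D[:, clean]
        G_r = G - Q @ (Q.T @ G)
        gg = np.einsum("ij,ij->j", G_r, G_r)
        gy = G_r.T @ y_r
        yy = float(y_r @ y_r)
        df = n - k - 1
        const = gg <= 1e-12 * n
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(const, np.nan, gy / gg)
            rss = np.maximum(yy - beta * gy, 0.0)
            se = np.sqrt(rss / df / gg)
            tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), df)
        idx = np.flatnonzero(clean)
        for jj, j in enumerate(idx):
            if const[jj]:
                records.append((j, _record(genotypes, j, G[:, jj], trait, adjustment,
                                           np.nan, np.nan, np.nan, n, "constant dosage")))
            else:
                records.append((j, _record(genotypes, j, G[:, jj], trait, adjustment,
                                           float(beta[jj]), float(se[jj]),
                                           float(p[jj]), n)))
    for j in np.flatnonzero(~clean):
        d = D[:, j]
        use = np.isfinite(d)
        records.append((j, _linear_single(genotypes, j, y[use], C[use], d[use],
                                          trait, adjustment)))
    records.sort(key=lambda t: t[0])
    return [r for _, r in records]


def _linear_single(genotypes, j, y, C, d, trait, adjustment) -> AssocRecord:
    n, k = C.shape
    if n - k - 1 <= 0 or np.ptp(d) == 0:
        return _record(genotypes, j, d, trait, adjustment, np.nan, np.nan, np.nan,
                       n, "constant dosage")
    X = np.column_stack([C, d])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    tstat = coef[-1] / se
    p = float(2 * stats.t.sf(abs(tstat), df))
    return _record(genotypes, j, d, trait, adjustment, float(coef[-1]), se, p, n)


def _logistic_scan(genotypes, y, C, D, trait, adjustment) -> list[AssocRecord]:
    records = []
    for j in range(D.shape[1]):
        d = D[:, j]
        use = np.isfinite(d)
        yi, Ci, di = y[use], C[use], d[use]
        n = int(use.sum())
        if np.ptp(di) == 0:
            records.append(_record(genotypes, j, di, trait, adjustment,
                                   np.nan, np.nan, np.nan, n, "constant dosage"))
            continue
        X = np.column_stack([Ci, di])
        note, beta, se, p = "", np.nan, np.nan, np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yi, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                note = "nonconvergence"
            elif fit.bse[-1] > 1e3:
                note = "separation"
            else:
                beta, se = float(fit.params[-1]), float(fit.bse[-1])
                p = float(2 * stats.norm.sf(abs(beta / se)))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            note = "separation"
        records.append(_record(genotypes, j, di, trait, adjustment, beta, se, p, n, note))
    return records


def interaction_scan(genotypes: GenotypeMatrix, phenotype, modifier, covariates=None,
                     log_transform: bool = False, trait: str = "trait",
                     adjustment: str = "none") -> list[AssocRecord]:
    """Gene-environment interaction scan with HC3 robust standard errors.

    Fits ``phenotype ~ G + E + G*E + covariates`` per variant and reports
    the interaction coefficient. The phenotype is log-transformed first
    when requested (strictly positive values required).
    """
    y_all = np.asarray(phenotype, dtype=float)
    if log_transform:
        if np.nanmin(y_all) <= 0:
            raise ValueError("log transform requires strictly positive phenotype")
        y_all = np.log(y_all)
    e_all = np.asarray(modifier, dtype=float)
    c_all = _design(covariates)
    base = _complete_rows(y_all, c_all) & np.isfinite(e_all)
    y, e = y_all[base], e_all[base]
    C = c_all[base] if c_all is not None else np.empty((base.sum(), 0))
    records = []
    for j in range(genotypes.n_variants):
        d = genotypes.dosages[base, j]
        use = np.isfinite(d)
        yi, ei, di, Ci = y[use], e[use], d[use], C[use]
        n = int(use.sum())
        if np.ptp(di) == 0:
            records.append(_record(genotypes, j, di, trait, adjustment,
                                   np.nan, np.nan, np.nan, n, "constant dosage"))
            continue
        X = np.column_stack([np.ones(n), di, ei, di * ei, Ci])
        fit = sm.OLS(yi, X).fit(cov_type="HC3")
        beta, se = float(fit.params[3]), float(fit.bse[3])
        p = float(fit.pvalues[3])
        records.append(_record(genotypes, j, di, trait, adjustment, beta, se, p, n,
                               "interaction"))
    return records


# ---------------------------------------------------------------------------
# meta-analysis and proxies


def ivw_meta(estimates) -> MetaResult:
    """Fixed-effect inverse-variance-weighted pooling of (beta, se) pairs.

    Accepts ``(beta, se)`` tuples or AssocRecords. Reports Cochran's Q.
    """
    per_study = tuple(estimates)
    if not per_study:
        raise ValueError("no studies to pool")
    betas, ses = [], []
    for e in per_study:
        b, s = (e.beta, e.se) if isinstance(e, AssocRecord) else (e[0], e[1])
        if not s > 0:
            raise ValueError(f"non-positive SE {s}")
        betas.append(float(b))
        ses.append(float(s))
    b = np.array(betas)
    w = 1.0 / np.array(ses) ** 2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    q = float(np.sum(w * (b - pooled) ** 2))
    return MetaResult(pooled, pooled_se, p, len(per_study), per_study, q)


def select_proxy(target: str, genotypes: GenotypeMatrix, r2_min: float = 0.4,
                 window_bp: int = 1_500_000):
    """Best LD proxy for ``target``: highest r^2 above ``r2_min`` within the window.

    Ties broken by smaller distance, then lexicographic id. Returns None if
    no candidate exceeds the threshold.
    """
    from pprskit.loci import ld_r2  # local import avoids a module cycle

    jt = genotypes.column(target)
    vt = genotypes.variants.iloc[jt]
    cands = []
    for j, v in genotypes.variants.iterrows():
        if j == jt or v["chrom"] != vt["chrom"]:
            continue
        dist = abs(int(v["pos"]) - int(vt["pos"]))
        if dist > window_bp:
            continue
        try:
            r2 = ld_r2(genotypes, target, v["variant_id"])
        except ValueError:
            continue
        if r2 > r2_min:
            cands.append((-r2, dist, v["variant_id"]))
    if not cands:
        return None
    return min(cands)[2]


# ---------------------------------------------------------------------------
# multiple testing and enrichment


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr(p, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at FDR level ``q``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must be in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def fisher_one_sided(table) -> float:
    """Upper-tail (enrichment) Fisher's exact probability for a 2x2 table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    return float(stats.fisher_exact(t, alternative="greater")[1])
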