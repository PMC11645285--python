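"""Sign-concordance score partitioning, weighted-sum scoring and outcome models.

Loci whose liver-fat-increasing allele lowers circulating triglycerides
form the "discordant" (liver-retention) score; loci raising both form the
"concordant" (systemic) score. Scores are weighted allele sums, compared
across outcomes by a two-sample Wald statistic and AIC differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from pprskit.io import GenotypeMatrix

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PartitionResult:
    """Discordant/concordant variant weights plus exclusions and orientation.

    Weights are oriented liver-fat betas (all positive); ``orientation``
    maps each variant to its liver-fat-increasing allele.
    """

    discordant: dict
    concordant: dict
    excluded: dict  # variant_id -> reason
    orientation: dict  # variant_id -> effect allele after orientation

    def __post_init__(self):
        overlap = set(self.discordant) & set(self.concordant)
        if overlap:
            raise ValueError(f"variants in both groups: {sorted(overlap)}")

    def group_of(self, variant_id: str) -> str:
        if variant_id in self.discordant:
            return "discordant"
        if variant_id in self.concordant:
            return "concordant"
        if variant_id in self.excluded:
            return "excluded"
        raise KeyError(variant_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, weights in (("discordant", self.discordant),
                               ("concordant", self.concordant)):
            for vid, w in weights.items():
                rows.append((vid, group, w, self.orientation.get(vid, ""), ""))
        for vid, reason in self.excluded.items():
            rows.append((vid, "excluded", np.nan, self.orientation.get(vid, ""), reason))
        return pd.DataFrame(rows, columns=["variant_id", "group", "weight",
                                           "oriented_allele", "reason"])


@dataclass(frozen=True)
class EffectEstimate:
    """Per-SD score effect on one outcome (log-OR for logistic, log-HR for cox)."""

    score_name: str
    outcome: str
    model: str
    beta: float
    se: float
    ci95: tuple  # on the OR/HR scale
    p: float
    n_cases: int
    n_total: int
    loglik: float = np.nan
    n_params: int = 0
    r2_nagelkerke: float = np.nan
    ph_p: float = np.nan  # Schoenfeld-residual proportional-hazards test (cox)
    note: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass(frozen=True)
class WaldResult:
    w: float
    w2: float
    p: float
    df: int = 1


# ---------------------------------------------------------------------------
# partitioning


def _resolve_alleles(pdff_rec, tg_rec):
    """Return TG beta expressed per copy of the liver-trait record's effect allele."""
    pe, po = pdff_rec.effect_allele, pdff_rec.other_allele
    te, to = tg_rec.effect_allele, tg_rec.other_allele
    for flip_sign, (e, o) in ((1.0, (te, to)), (-1.0, (to, te))):
        if (e, o) == (pe, po):
            return flip_sign * tg_rec.beta
        comp = (_COMPLEMENT.get(e), _COMPLEMENT.get(o))
        if comp == (pe, po):
            return flip_sign * tg_rec.beta
    return None


def partition_by_concordance(pdff_assoc: dict, tg_assoc: dict,
                             alpha_tg: float = 0.05) -> PartitionResult:
    """Split loci by the sign of their triglyceride effect.

    Parameters
    ----------
    pdff_assoc, tg_assoc : dict of variant_id -> AssocRecord
        Per-locus strongest liver-fat association and the matching
        triglyceride association.
    alpha_tg : float
        Loci whose TG association P is not below this are excluded
        ("no TG association").

    Each variant is oriented to its liver-fat-increasing allele; with the
    oriented TG effect negative the locus is discordant, positive
    concordant. Weights are the oriented liver-fat betas.
    """
    mismatched = [v for v in pdff_assoc if v in tg_assoc
                  and _resolve_alleles(pdff_assoc[v], tg_assoc[v]) is None]
    if mismatched:
        raise ValueError(f"unresolvable allele mismatch for {sorted(mismatched)}")
    disc, conc, excl, orient = {}, {}, {}, {}
    for vid, prec in pdff_assoc.items():
        if prec.beta >= 0:
            orient[vid] = prec.effect_allele
            w = prec.beta
            sign = 1.0
        else:
            orient[vid] = prec.other_allele
            w = -prec.beta
            sign = -1.0
        trec = tg_assoc.get(vid)
        if trec is None:
            excl[vid] = "no TG record"
            continue
        tg_beta = sign * _resolve_alleles(prec, trec)
        if not (trec.p < alpha_tg) or tg_beta == 0:
            excl[vid] = "no TG association"
        elif tg_beta < 0:
            disc[vid] = w
        else:
            conc[vid] = w
    return PartitionResult(disc, conc, excl, orient)


# ---------------------------------------------------------------------------
# scoring


def compute_score(genotypes: GenotypeMatrix, weights: dict, orientation: dict,
                  max_missing: float = 0.10) -> np.ndarray:
    """Weighted allele sum over the oriented effect alleles.

    Missing dosages are imputed to twice the oriented allele frequency;
    any variant missing in more than ``max_missing`` of samples is an error.
    """
    score = np.zeros(genotypes.n_samples)
    for vid, w in weights.items():
        j = genotypes.column(vid)
        v = genotypes.variants.iloc[j]
        d = genotypes.dosages[:, j].copy()
        allele = orientation.get(vid, v["effect_allele"])
        if allele == v["effect_allele"]:
            eaf = v["eaf"]
        elif allele == v["other_allele"]:
            d = 2.0 - d
            eaf = 1.0 - v["eaf"]
        else:
            raise ValueError(f"{vid}: oriented allele {allele!r} matches neither allele")
        miss = np.isnan(d)
        if miss.mean() > max_missing:
            raise ValueError(f"{vid}: {miss.mean():.1%} missing dosages exceeds "
                             f"{max_missing:.0%} ceiling")
        if miss.any():
            log.info("imputed %d missing dosages for %s to 2*EAF", miss.sum(), vid)
            d[miss] = 2.0 * eaf
        score += w * d
    return score


# ---------------------------------------------------------------------------
# outcome association


def _nagelkerke(ll_full, ll_null, n):
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    return float(cox_snell / (1.0 - np.exp(2.0 * ll_null / n)))


def outcome_assoc(score, outcome, covariates=None, model: str = "logistic",
                  score_name: str = "score", outcome_name: str = "outcome",
                  event=None) -> EffectEstimate:
    """Associate a (per-SD standardized) score with a binary or survival outcome.

    For ``model='logistic'`` ``outcome`` is the 0/1 case flag; for
    ``model='cox'`` ``outcome`` is the follow-up time and ``event`` the
    event indicator. Rows with missing data are dropped listwise.
    """
    s = np.asarray(score, dtype=float)
    sd = np.nanstd(s)
    if sd == 0:
        raise ValueError("constant score")
    s = (s - np.nanmean(s)) / sd
    c = np.asarray(covariates, dtype=float) if covariates is not None else None
    if c is not None and c.ndim == 1:
        c = c[:, None]

    if model == "logistic":
        y = np.asarray(outcome, dtype=float)
        mask = np.isfinite(s) & np.isfinite(y)
        if c is not None:
            mask &= np.all(np.isfinite(c), axis=1)
        yi, si = y[mask], s[mask]
        X = np.column_stack([np.ones(mask.sum()), si]) if c is None else \
            np.column_stack([np.ones(mask.sum()), si, c[mask]])
        note = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yi, X).fit(disp=0, maxiter=200)
            null = sm.Logit(yi, X[:, [0] + list(range(2, X.shape[1]))]).fit(
                disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            note = "nonconvergence"
        elif fit.bse[1] > 1e3:
            note = "separation"
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(2 * stats.norm.sf(abs(beta / se)))
        return EffectEstimate(
            score_name, outcome_name, "logistic", beta, se,
            (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
            p, int(yi.sum()), int(mask.sum()),
            loglik=float(fit.llf), n_params=X.shape[1],
            r2_nagelkerke=_nagelkerke(fit.llf, null.llf, mask.sum()), note=note,
        )

    if model == "cox":
        t = np.asarray(outcome, dtype=float)
        e = np.asarray(event, dtype=float)
        mask = np.isfinite(s) & np.isfinite(t) & np.isfinite(e)
        if c is not None:
            mask &= np.all(np.isfinite(c), axis=1)
        if np.any(t[mask] <= 0):
            raise ValueError("cox model requires positive follow-up times")
        df = pd.DataFrame({"time": t[mask], "event": e[mask], "score": s[mask]})
        if c is not None:
            for i in range(c.shape[1]):
                df[f"c{i}"] = c[mask, i]
        cph = CoxPHFitter()
        note = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(df, duration_col="time", event_col="event")
            except Exception:
                return EffectEstimate(score_name, outcome_name, "cox", np.nan, np.nan,
                                      (np.nan, np.nan), np.nan, int(e[mask].sum()),
                                      int(mask.sum()), note="nonconvergence")
            ph = proportional_hazard_test(cph, df, time_transform="rank")
        beta = float(cph.params_["score"])
        se = float(cph.standard_errors_["score"])
        p = float(2 * stats.norm.sf(abs(beta / se)))
        return EffectEstimate(
            score_name, outcome_name, "cox", beta, se,
            (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
            p, int(e[mask].sum()), int(mask.sum()),
            loglik=float(cph.log_likelihood_), n_params=df.shape[1] - 2,
            ph_p=float(ph.summary.loc["score", "p"]), note=note,
        )

    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# score comparison


def wald_compare(e1: EffectEstimate, e2: EffectEstimate) -> WaldResult:
    """Two-sample Wald test of equal score effects on the same outcome."""
    if (e1.outcome, e1.model) != (e2.outcome, e2.model):
        raise ValueError("estimates must share outcome and model")
    if e1.se == 0 or e2.se == 0:
        raise ValueError("zero standard error")
    w = (e1.beta - e2.beta) / np.sqrt(e1.se ** 2 + e2.se ** 2)
    return WaldResult(w=float(w), w2=float(w * w), p=float(stats.chi2.sf(w * w, 1)))


def aic_compare(model_fits) -> pd.DataFrame:
    """Pairwise AIC differences (row minus column) for fits on identical samples."""
    fits = list(model_fits)
    if not fits:
        raise ValueError("no fits")
    base = (fits[0].outcome, fits[0].n_total)
    for f in fits[1:]:
        if (f.outcome, f.n_total) != base:
            raise ValueError("fits must share outcome and sample set")
    names = [f.score_name for f in fits]
    aics = np.array([f.aic for f in fits])
    return pd.DataFrame(aics[:, None] - aics[None, :], index=names, columns=names)


def quartile_contrast(score, biomarkers: pd.DataFrame) -> pd.DataFrame:
    """Top-vs-bottom score-quartile contrast per biomarker (rank-sum test).

    Quartile boundaries are type-7 empirical quantiles; returns mean
    difference (top minus bottom) and two-sided Mann-Whitney P per column.
    """
    s = np.asarray(score, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(s) == 0:
        raise ValueError("constant score")
    q1, q3 = np.quantile(s, [0.25, 0.75])  # numpy default is type 7 ("linear")
    bottom, top = s <= q1, s >= q3
    rows = []
    for col in biomarkers.columns:
        x = np.asarray(biomarkers[col], dtype=float)
        lo, hi = x[bottom & np.isfinite(x)], x[top & np.isfinite(x)]
        stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        rows.append((col, float(hi.mean() - lo.mean()), float(p), len(hi), len(lo)))
    return pd.DataFrame(rows, columns=["biomarker", "difference", "p", "n_top",
                                       "n_bottom"])
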