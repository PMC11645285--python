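"""Causal mediation analysis for variant -> adiposity -> liver-trait paths.

Linear structural models fit by OLS; average causal mediation effect
(ACME) and average direct effect (ADE) via the potential-outcomes plug-in
estimator, contrasting 0 vs 2 copies of the effect allele and averaging
over the two treatment levels when an exposure-mediator interaction is
included. Inference is by nonparametric percentile bootstrap. Sensitivity
to unobserved mediator-outcome confounding follows the error-correlation
(rho) parameterization for linear models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

#: treatment/control exposure levels: a one-allele contrast, so that without
#: interaction ACME reduces to the product of coefficients a*b
EXPOSURE_LEVELS = (0.0, 1.0)


@dataclass(frozen=True)
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    prop_mediated_ci: tuple
    n_boot: int
    interaction: bool
    classification: str
    n: int
    # internals reused by the sensitivity analysis
    _fit: dict = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class SensitivityCurve:
    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rho_zero: float


def _ols(X, y):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, resid


def _point_estimates(x, m, y, C, interaction):
    """ACME/ADE/total from the two fitted linear models."""
    n = len(x)
    Xm = np.column_stack([np.ones(n), x, C])
    am, em = _ols(Xm, m)
    a = am[1]
    if interaction:
        Xy = np.column_stack([np.ones(n), x, m, x * m, C])
        ay, ey = _ols(Xy, y)
        cprime, bcoef, theta = ay[1], ay[2], ay[3]
    else:
        Xy = np.column_stack([np.ones(n), x, m, C])
        ay, ey = _ols(Xy, y)
        cprime, bcoef, theta = ay[1], ay[2], 0.0
    t0, t1 = EXPOSURE_LEVELS
    dt = t1 - t0
    # mediation effect at exposure level t: a*(b + theta*t)*dt
    delta = 0.5 * sum(a * (bcoef + theta * t) * dt for t in (t0, t1))
    # direct effect at mediator distribution of level t
    m_hat = {t: Xm @ am + am[1] * (t - x) for t in (t0, t1)}
    zeta = 0.5 * sum(np.mean(cprime * dt + theta * m_hat[t] * dt) for t in (t0, t1))
    return float(delta), float(zeta), float(delta + zeta), {
        "a": float(a), "b": float(bcoef), "theta": float(theta),
        "c_prime": float(cprime), "resid_m": em, "resid_y": ey,
    }


def _ci(samples, level=0.95):
    lo = np.percentile(samples, 100 * (1 - level) / 2)
    hi = np.percentile(samples, 100 * (1 + level) / 2)
    return (float(lo), float(hi))


def classify_mediation(acme, ade, total, acme_ci, ade_ci) -> str:
    """Label the mediation pattern from point estimates and 95% CIs.

    ``none`` when the ACME CI covers 0; ``complete`` when only the ADE CI
    covers 0; ``inconsistent`` when the mediated and total effects have
    opposite signs with both intervals excluding 0; else
    ``consistent-partial``.
    """
    covers = lambda ci: ci[0] <= 0 <= ci[1]
    if covers(acme_ci):
        return "none"
    if covers(ade_ci):
        return "complete"
    if np.sign(acme) != np.sign(total):
        return "inconsistent"
    return "consistent-partial"


def mediate(exposure, mediator, outcome, covariates=None, n_boot: int = 1000,
            interaction: bool = False, seed: int = 0) -> MediationResult:
    """Estimate how much of the exposure's effect flows through the mediator.

    Fits ``mediator ~ exposure + covariates`` and ``outcome ~ exposure +
    mediator (+ exposure*mediator) + covariates`` on complete cases and
    bootstraps percentile CIs. Deterministic given ``seed``.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    C = np.asarray(covariates, dtype=float) if covariates is not None else \
        np.empty((len(x), 0))
    if C.ndim == 1:
        C = C[:, None]
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & \
        np.all(np.isfinite(C), axis=1)
    x, m, y, C = x[mask], m[mask], y[mask], C[mask]
    n = len(x)
    if n < 50:
        raise ValueError("need at least 50 complete cases")
    if np.ptp(m) == 0 or np.ptp(y) == 0:
        raise ValueError("mediator or outcome is constant")

    acme, ade, total, fit = _point_estimates(x, m, y, C, interaction)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3ED]))
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = _point_estimates(x[idx], m[idx], y[idx], C[idx], interaction)[:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_boot = boots[:, 0] / boots[:, 2]
    prop = acme / total if total != 0 else np.nan
    acme_ci, ade_ci, total_ci = _ci(boots[:, 0]), _ci(boots[:, 1]), _ci(boots[:, 2])
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=float(prop),
        acme_ci=acme_ci, ade_ci=ade_ci, total_ci=total_ci,
        prop_mediated_ci=_ci(prop_boot[np.isfinite(prop_boot)]),
        n_boot=n_boot, interaction=interaction,
        classification=classify_mediation(acme, ade, total, acme_ci, ade_ci),
        n=n,
        _fit={**fit, "x": x, "m": m, "y": y, "C": C, "seed": seed},
    )


def _acme_curve(a, sigma_m, sigma_y, rho_tilde, rho_grid):
    """ACME(rho) for the linear-linear case.

    With residual SDs sigma_y (outcome ~ exposure + covariates, mediator
    omitted) and sigma_m (mediator model), and rho_tilde the correlation of
    those residuals, ACME(rho) = a * sigma_y/sigma_m *
    (rho_tilde - rho * sqrt((1 - rho_tilde^2)/(1 - rho^2))) * dt.
    The curve crosses zero exactly once, at rho = rho_tilde.
    """
    dt = EXPOSURE_LEVELS[1] - EXPOSURE_LEVELS[0]
    r = np.asarray(rho_grid, dtype=float)
    return (a * (sigma_y / sigma_m)
            * (rho_tilde - r * np.sqrt((1 - rho_tilde ** 2) / (1 - r ** 2))) * dt)


def _sensitivity_inputs(x, m, y, C):
    n = len(x)
    Xt = np.column_stack([np.ones(n), x, C])
    am, em = _ols(Xt, m)
    _, ey = _ols(Xt, y)  # outcome model WITHOUT the mediator
    sigma_m = em.std(ddof=Xt.shape[1])
    sigma_y = ey.std(ddof=Xt.shape[1])
    rho_tilde = float(np.corrcoef(em, ey)[0, 1])
    return float(am[1]), sigma_m, sigma_y, rho_tilde


def sensitivity_rho(result: MediationResult, rho_grid=None,
                    n_boot: int = 200) -> SensitivityCurve:
    """ACME under assumed mediator/outcome error correlation rho.

    Only defined for the linear no-interaction case. ``rho_zero`` is the
    smallest \\|rho\\| on the grid at which the 95% CI of ACME(rho) covers 0.
    """
    if result.interaction:
        raise ValueError("sensitivity analysis requires the no-interaction model")
    if rho_grid is None:
        rho_grid = np.arange(-0.9, 0.9001, 0.05)
    rho_grid = np.asarray(rho_grid, dtype=float)
    fit = result._fit
    x, m, y, C = fit["x"], fit["m"], fit["y"], fit["C"]
    a, sm, sy, rt = _sensitivity_inputs(x, m, y, C)
    curve = _acme_curve(a, sm, sy, rt, rho_grid)

    rng = np.random.default_rng(np.random.SeedSequence([fit["seed"], 0x5E45]))
    n = len(x)
    boot = np.empty((n_boot, len(rho_grid)))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, smb, syb, rtb = _sensitivity_inputs(x[idx], m[idx], y[idx], C[idx])
        boot[i] = _acme_curve(ab, smb, syb, rtb, rho_grid)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    covers = (lo <= 0) & (0 <= hi)
    # the point-estimate curve crosses zero exactly at rho = rho_tilde, where
    # the interval necessarily straddles 0; include it in case the grid
    # resolution skips the (possibly narrow) covering band
    candidates = np.append(np.abs(rho_grid[covers]), abs(rt))
    rho_zero = float(candidates.min())
    return SensitivityCurve(rho_grid=rho_grid, acme_at_rho=curve,
                            ci_low=lo, ci_high=hi, rho_zero=rho_zero)


def mediation_to_frame(results: dict) -> pd.DataFrame:
    """Tabulate named MediationResults (variant, mediator, trait) -> row."""
    rows = []
    for (variant, mediator, trait), res in results.items():
        rows.append({
            "variant": variant, "mediator": mediator, "trait": trait,
            "acme": res.acme, "acme_lo": res.acme_ci[0], "acme_hi": res.acme_ci[1],
            "ade": res.ade, "ade_lo": res.ade_ci[0], "ade_hi": res.ade_ci[1],
            "total": res.total, "total_lo": res.total_ci[0],
            "total_hi": res.total_ci[1], "prop_mediated": res.prop_mediated,
            "classification": res.classification, "n": res.n,
        })
    return pd.DataFrame(rows)
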