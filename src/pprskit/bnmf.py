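"""Bayesian non-negative matrix factorization with automatic relevance
determination, for hypothesis-free soft clustering of variant-trait z-scores.

Model: V ~ WH with Gaussian likelihood (fixed noise scale sigma^2) and
half-normal priors on each component's columns/rows, w_k ~ HN(lambda_k),
h_k ~ HN(lambda_k), with inverse-gamma(a, b) hyperpriors on the relevance
scales lambda_k. MAP estimation alternates multiplicative updates of W and
H with the closed-form lambda update; irrelevant components shrink to the
empty-component floor and are pruned. The MAP objective

    F = ||V - WH||^2 / (2 sigma^2)
        + sum_k [ (||w_k||^2/2 + ||h_k||^2/2 + b) / lambda_k ]
        + ((m + n)/2 + a + 1) * sum_k log lambda_k

is non-increasing over iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class ZMatrix:
    """Nonnegative variant x trait-direction z-score matrix.

    Each trait is split into a ``_pos`` and a ``_neg`` column holding the
    positive/negative part of its (aligned, sample-size-scaled) z-score.
    """

    variant_ids: list
    columns: list
    values: np.ndarray
    n_per_trait: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("z matrix entries must be nonnegative")

    def signed(self) -> pd.DataFrame:
        """Reconstruct signed aligned z-scores (pos minus neg per trait)."""
        traits = sorted({c.rsplit("_", 1)[0] for c in self.columns})
        out = {}
        for t in traits:
            pos = self.values[:, self.columns.index(f"{t}_pos")]
            neg = self.values[:, self.columns.index(f"{t}_neg")]
            out[t] = pos - neg
        return pd.DataFrame(out, index=self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variant_ids, columns=self.columns)


@dataclass
class BNMFResult:
    w: np.ndarray  # variants x K (selected solution, all components)
    h: np.ndarray  # K x columns
    k_selected: int
    restart_log: pd.DataFrame  # columns: restart, seed, k, objective
    variant_ids: list
    columns: list
    objective_trace: np.ndarray  # best restart's per-iteration objective
    memberships: dict | None = None
    cluster_names: dict | None = None


def build_z_matrix(assoc_by_trait: dict, align_trait: str = "PDFF",
                   corr_prune: float = 0.85, trait_corr=None) -> ZMatrix:
    """Build the aligned, scaled, direction-split z-score matrix.

    Parameters
    ----------
    assoc_by_trait : dict of trait -> {variant_id: AssocRecord}
        (lists of records are accepted and keyed by variant id)
    align_trait : str
        Trait whose z-score is made positive per variant by sign-flipping
        all of that variant's entries.
    trait_corr : optional square DataFrame of phenotypic trait correlations
        For each pair with \\|corr\\| > ``corr_prune``, the later trait (input
        order) is dropped.
    """
    by_trait = {}
    for trait, recs in assoc_by_trait.items():
        by_trait[trait] = (recs if isinstance(recs, dict)
                           else {r.variant_id: r for r in recs})
    if align_trait not in by_trait:
        raise ValueError(f"missing align trait {align_trait!r}")

    traits = list(by_trait)
    if trait_corr is not None:
        tc = pd.DataFrame(trait_corr)
        kept = []
        for t in traits:
            clash = [k for k in kept
                     if t in tc.columns and k in tc.index
                     and abs(tc.loc[k, t]) > corr_prune]
            if clash and t != align_trait:
                log.info("dropping trait %s (corr > %.2f with %s)", t, corr_prune,
                         clash[0])
                continue
            kept.append(t)
        traits = kept

    vids = sorted(by_trait[align_trait])
    n_per_trait = {t: float(np.median([r.n for r in by_trait[t].values()]))
                   for t in traits}
    med_n = float(np.median(list(n_per_trait.values())))
    z = np.zeros((len(vids), len(traits)))
    for jt, t in enumerate(traits):
        scale = np.sqrt(med_n / n_per_trait[t])
        for iv, v in enumerate(vids):
            rec = by_trait[t].get(v)
            if rec is None:
                continue
            if not rec.se > 0:
                raise ValueError(f"{v}/{t}: se must be positive")
            z[iv, jt] = scale * rec.beta / rec.se
    ja = traits.index(align_trait)
    flip = np.where(z[:, ja] < 0, -1.0, 1.0)
    z = z * flip[:, None]
    cols, vals = [], []
    for jt, t in enumerate(traits):
        cols += [f"{t}_pos", f"{t}_neg"]
        vals += [np.maximum(z[:, jt], 0.0), np.maximum(-z[:, jt], 0.0)]
    return ZMatrix(vids, cols, np.column_stack(vals), n_per_trait)


# ---------------------------------------------------------------------------
# ARD-NMF fitting


def _ard_objective(V, W, H, lam, sigma2, a, b):
    m, n = V.shape
    resid = V - W @ H
    pen = np.sum((0.5 * np.sum(W ** 2, axis=0) + 0.5 * np.sum(H ** 2, axis=1) + b)
                 / lam)
    return (np.sum(resid ** 2) / (2 * sigma2) + pen
            + ((m + n) / 2 + a + 1) * np.sum(np.log(lam)))


def _ard_restart(V, k_max, rng, sigma2, a, b, tol, max_iter):
    m, n = V.shape
    scale = np.sqrt(V.mean() / k_max + _EPS)
    W = rng.uniform(0, 1, (m, k_max)) * scale
    H = rng.uniform(0, 1, (k_max, n)) * scale
    const = (m + n) / 2 + a + 1
    lam = (0.5 * np.sum(W ** 2, axis=0) + 0.5 * np.sum(H ** 2, axis=1) + b) / const
    trace = [_ard_objective(V, W, H, lam, sigma2, a, b)]
    for _ in range(max_iter):
        W *= (V @ H.T) / (W @ (H @ H.T) + sigma2 * W / lam[None, :] + _EPS)
        H *= (W.T @ V) / ((W.T @ W) @ H + sigma2 * H / lam[:, None] + _EPS)
        lam = (0.5 * np.sum(W ** 2, axis=0) + 0.5 * np.sum(H ** 2, axis=1) + b) / const
        obj = _ard_objective(V, W, H, lam, sigma2, a, b)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * abs(trace[-2]):
            break
    # effective components: relevance scale above the empty-component floor
    # (a dead component's lambda collapses to exactly b/const)
    active = lam > (b / const) * 1.05
    return W, H, lam, np.array(trace), active


def bnmf_fit(z, k_max: int = 7, n_restarts: int = 1000, tol: float = 1e-10,
             max_iter: int = 3000, seed: int = 0, a: float = 10.0,
             sigma2=None) -> BNMFResult:
    """Fit ARD-NMF over many restarts; select the modal component count.

    Per restart, multiplicative updates prune irrelevant components; the
    effective K is the number of surviving components. ``k_selected`` is
    the modal K across restarts and the returned factorization is the best
    (lowest) objective among restarts converging to that K. Fully
    reproducible given ``seed``.
    """
    V = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if V.size == 0 or not np.any(V > 0):
        raise ValueError("z matrix is all zero or empty")
    if (V < 0).any():
        raise ValueError("z matrix must be nonnegative")
    m, n = V.shape
    if sigma2 is None:
        sigma2 = float(np.mean(V ** 2))
    b = a * np.sqrt(sigma2)  # keeps memberships invariant to rescaling V

    rows, results = [], []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        W, H, lam, trace, active = _ard_restart(V, k_max, rng, sigma2, a, b,
                                                tol, max_iter)
        k_eff = int(active.sum())
        rows.append((r, seed, k_eff, float(trace[-1])))
        results.append((k_eff, float(trace[-1]), W, H, trace, active))
    log_df = pd.DataFrame(rows, columns=["restart", "seed", "k", "objective"])

    ks = log_df["k"].to_numpy()
    counts = np.bincount(ks)
    k_selected = int(np.argmax(counts))
    at_modal = [res for res in results if res[0] == k_selected]
    best = min(at_modal, key=lambda res: res[1])
    _, _, W, H, trace, active = best
    order = np.argsort(-(np.max(W, axis=0) * np.max(H, axis=1)))
    keep = [k for k in order if active[k]]
    vids = z.variant_ids if isinstance(z, ZMatrix) else list(range(m))
    cols = z.columns if isinstance(z, ZMatrix) else list(range(n))
    return BNMFResult(w=W[:, keep], h=H[keep, :], k_selected=k_selected,
                      restart_log=log_df, variant_ids=vids, columns=cols,
                      objective_trace=trace)


def extract_clusters(result: BNMFResult) -> BNMFResult:
    """Assign variants to clusters by a signal-to-noise-maximizing weight cutoff.

    A single cutoff is searched on the pooled distribution of all
    variant-cluster weights (grid = midpoints between sorted unique
    weights); the cutoff maximizing the signal-to-noise ratio — the
    between-group separation over the pooled within-group variance of
    root-scale weights, n_above*n_below*(mean_above - mean_below)^2 /
    (n*within_var) on sqrt(w) (root scale keeps the criterion equivariant
    under rescaling of z while taming the heavy signal tail) — is kept
    and a variant joins every cluster where its weight exceeds it; the
    same variant may appear in several clusters. Cluster names are the two
    top-weighted trait-direction labels.
    """
    if result.k_selected < 1 or result.w.shape[1] < 1:
        raise ValueError("no clusters in result")
    W = result.w
    pooled = np.sort(W.ravel())
    if np.allclose(pooled, pooled[0]):
        warnings.warn("degenerate all-equal weights; single cluster keeps all variants")
        result.memberships = {0: {v: float(W[i, 0]) for i, v in
                                  enumerate(result.variant_ids)}}
        result.cluster_names = {0: _name_cluster(result, 0)}
        return result
    root = np.sqrt(pooled)
    uniq = np.unique(root)
    mids = (uniq[:-1] + uniq[1:]) / 2
    best_cut, best_snr = mids[0] ** 2, -np.inf
    n_all = len(root)
    for cut_root in mids:
        cut = cut_root ** 2
        above, below = root[root > cut_root], root[root <= cut_root]
        if len(above) == 0 or len(below) == 0:
            continue
        between = len(above) * len(below) * (above.mean() - below.mean()) ** 2
        within = len(above) * above.var() + len(below) * below.var()
        snr = between / (n_all * within) if within > 0 else np.inf
        if snr > best_snr:
            best_snr, best_cut = snr, cut
    memberships, names = {}, {}
    for k in range(W.shape[1]):
        members = {result.variant_ids[i]: float(W[i, k])
                   for i in np.flatnonzero(W[:, k] > best_cut)}
        if not members:
            warnings.warn(f"cluster {k} is empty at the SNR cutoff")
        memberships[k] = members
        names[k] = _name_cluster(result, k)
    result.memberships = memberships
    result.cluster_names = names
    return result


def _name_cluster(result: BNMFResult, k: int) -> str:
    top = np.argsort(-result.h[k])[:2]
    return "/".join(str(result.columns[j]) for j in top)


def cluster_pprs(memberships: dict, pdff_weights: dict) -> dict:
    """Per-cluster score weight maps (liver-fat betas) for ``compute_score``.

    Overlapping variants contribute to every cluster they belong to; a
    member without a liver-fat weight is an error, an empty cluster a
    warning.
    """
    out = {}
    for k, members in memberships.items():
        if not members:
            warnings.warn(f"cluster {k} has no members; empty weight map")
            out[k] = {}
            continue
        missing = [v for v in members if v not in pdff_weights]
        if missing:
            raise ValueError(f"cluster {k}: members without weights: {missing}")
        out[k] = {v: pdff_weights[v] for v in members}
    return out


def memberships_to_frame(result: BNMFResult) -> pd.DataFrame:
    rows = []
    for k, members in (result.memberships or {}).items():
        name = (result.cluster_names or {}).get(k, str(k))
        for v, w in members.items():
            rows.append((k, name, v, w))
    return pd.DataFrame(rows, columns=["cluster", "cluster_name", "variant", "weight"])
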