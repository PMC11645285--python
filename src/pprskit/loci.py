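"""Independent-locus identification: LD, greedy clumping, stepwise conditional
selection and pleiotropic locus merging.

All LD is computed from the in-run genotype matrix (dosage Pearson r^2);
there is no external reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pprskit.io import GenotypeMatrix


@dataclass(frozen=True)
class LDPair:
    variant_a: str
    variant_b: str
    r2: float
    d_prime: float | None = None


@dataclass(frozen=True)
class ClumpParams:
    """PLINK-style clumping parameters (p1 threshold, r2 floor, kb window)."""

    p1: float = 5e-8
    r2: float = 0.01
    kb: int = 1000

    def __post_init__(self):
        if not 0 < self.p1 < 1:
            raise ValueError("p1 must be in (0,1)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must be in (0,1)")
        if self.kb <= 0:
            raise ValueError("kb must be positive")


@dataclass
class Locus:
    locus_id: int
    chrom: object
    span: tuple  # (min pos, max pos), closed
    members: set
    lead_by_trait: dict  # trait -> variant_id

    def __post_init__(self):
        missing = set(self.lead_by_trait.values()) - self.members
        if missing:
            raise ValueError(f"leads {sorted(missing)} not among members")


def ld_r2(genotypes: GenotypeMatrix, a: str, b: str) -> float:
    """Squared Pearson correlation of dosages on pairwise-complete samples."""
    da = genotypes.dosage(a)
    db = genotypes.dosage(b)
    use = np.isfinite(da) & np.isfinite(db)
    da, db = da[use], db[use]
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


def clump(assoc, genotypes: GenotypeMatrix, params: ClumpParams = ClumpParams()
          ) -> list[str]:
    """Greedy LD clumping of significant variants; returns lead variant ids.

    Variants with P < p1 are sorted by ascending P (ties by position then
    id); the best remaining becomes a lead and absorbs all unassigned
    significant variants within ``kb`` kilobases at r^2 >= ``params.r2``.
    """
    pos = {v: (c, p) for v, c, p in zip(genotypes.variants["variant_id"],
                                        genotypes.variants["chrom"],
                                        genotypes.variants["pos"])}
    sig = [r for r in assoc if np.isfinite(r.p) and r.p < params.p1]
    sig.sort(key=lambda r: (r.p, pos[r.variant_id], r.variant_id))
    leads, assigned = [], set()
    for rec in sig:
        vid = rec.variant_id
        if vid in assigned:
            continue
        leads.append(vid)
        assigned.add(vid)
        chrom, p0 = pos[vid]
        for other in sig:
            ov = other.variant_id
            if ov in assigned:
                continue
            oc, op = pos[ov]
            if oc != chrom or abs(op - p0) > params.kb * 1000:
                continue
            if ld_r2(genotypes, vid, ov) >= params.r2:
                assigned.add(ov)
    return leads


def _conditional_fit(y, C, G_sel, g):
    """P value of g in OLS y ~ C + G_sel + g; None if g is collinear."""
    from scipy import stats

    X = np.column_stack([C] + ([G_sel] if G_sel is not None else []) + [g[:, None]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return None, None
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return float(p[-1]), p


def stepwise_conditional(genotypes: GenotypeMatrix, phenotype, covariates=None,
                         candidates=None, p_thresh: float = 5e-8,
                         window_bp: int = 10_000_000) -> list[str]:
    """Forward-then-backward conditional selection on individual-level data.

    Forward: repeatedly add the candidate with the smallest conditional P
    (conditioning on already-selected variants within ``window_bp``) while
    it is below ``p_thresh``. Backward: drop any selected variant whose
    joint-model P exceeds the threshold, worst first. Collinear candidates
    are skipped with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    c = np.asarray(covariates, dtype=float) if covariates is not None else None
    if c is not None and c.ndim == 1:
        c = c[:, None]
    mask = np.isfinite(y)
    if c is not None:
        mask &= np.all(np.isfinite(c), axis=1)
    y = y[mask]
    C = np.column_stack([np.ones(mask.sum()), c[mask]]) if c is not None \
        else np.ones((mask.sum(), 1))
    candidates = list(candidates or [])
    pos = {v: (genotypes.variants.iloc[genotypes.column(v)]["chrom"],
               int(genotypes.variants.iloc[genotypes.column(v)]["pos"]))
           for v in candidates}

    def dosage(v):
        d = genotypes.dosage(v)[mask]
        return np.where(np.isfinite(d), d, np.nanmean(d))

    selected: list[str] = []
    skipped: set[str] = set()
    while True:
        best = None
        for v in candidates:
            if v in selected or v in skipped:
                continue
            chrom, p0 = pos[v]
            nearby = [s for s in selected
                      if pos[s][0] == chrom and abs(pos[s][1] - p0) <= window_bp]
            G_sel = np.column_stack([dosage(s) for s in nearby]) if nearby else None
            pv, _ = _conditional_fit(y, C, G_sel, dosage(v))
            if pv is None:
                warnings.warn(f"{v} collinear with selected set; skipped")
                skipped.add(v)
                continue
            if best is None or pv < best[0]:
                best = (pv, v)
        if best is None or best[0] >= p_thresh:
            break
        selected.append(best[1])

    # backward pass on the joint model
    from scipy import stats as _st

    changed = True
    while changed and selected:
        changed = False
        G = np.column_stack([dosage(s) for s in selected])
        _, pvals = _conditional_fit(y, C, G[:, :-1] if G.shape[1] > 1 else None,
                                    G[:, -1])
        X = np.column_stack([C, G])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = len(y) - X.shape[1]
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * np.diag(np.linalg.pinv(X.T @ X)))
        pj = 2 * _st.t.sf(np.abs(coef / se), df)[C.shape[1]:]
        worst = int(np.argmax(pj))
        if pj[worst] >= p_thresh:
            del selected[worst]
            changed = True
    return selected


def merge_pleiotropic(lead_sets: dict, genotypes: GenotypeMatrix,
                      dist_bp: int = 1_000_000, r2_min: float = 0.2) -> list[Locus]:
    """Merge lead variants across trait/adjustment scans into pleiotropic loci.

    Parameters
    ----------
    lead_sets : dict of (trait, adjustment) -> list of AssocRecord
        Lead variants per scan, carrying their P values.

    Two leads join the same locus when they sit on one chromosome within
    ``dist_bp`` AND their r^2 strictly exceeds ``r2_min`` (transitively).
    Loci get consecutive ids ordered by (chromosome, min position); per
    trait the member with the lowest P becomes that trait's lead, P ties
    broken by trait-name order of the contributing scans, then position,
    then id.
    """
    # deterministic variant ordering regardless of input dict order
    best: dict[str, dict] = {}
    for (trait, adjustment) in sorted(lead_sets):
        for rec in lead_sets[(trait, adjustment)]:
            entry = best.setdefault(rec.variant_id, {})
            if trait not in entry or rec.p < entry[trait].p:
                entry[trait] = rec
    vids = sorted(best)
    missing = [v for v in vids if v not in set(genotypes.variants["variant_id"])]
    if missing:
        raise ValueError(f"leads absent from genotype matrix: {missing}")
    meta = genotypes.variants.set_index("variant_id")
    parent = {v: v for v in vids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(vids):
        ca, pa = meta.loc[a, "chrom"], int(meta.loc[a, "pos"])
        for b in vids[i + 1:]:
            if meta.loc[b, "chrom"] != ca or abs(int(meta.loc[b, "pos"]) - pa) > dist_bp:
                continue
            if ld_r2(genotypes, a, b) > r2_min:
                parent[find(a)] = find(b)

    groups: dict[str, list] = {}
    for v in vids:
        groups.setdefault(find(v), []).append(v)
    comps = sorted(groups.values(),
                   key=lambda g: min((meta.loc[v, "chrom"], int(meta.loc[v, "pos"]))
                                     for v in g))
    loci = []
    for i, members in enumerate(comps, start=1):
        chrom = meta.loc[members[0], "chrom"]
        positions = [int(meta.loc[v, "pos"]) for v in members]
        lead_by_trait = {}
        traits = sorted({t for v in members for t in best[v]})
        for trait in traits:
            cands = [(best[v][trait].p, int(meta.loc[v, "pos"]), v)
                     for v in members if trait in best[v]]
            lead_by_trait[trait] = min(cands)[2]
        loci.append(Locus(locus_id=i, chrom=chrom,
                          span=(min(positions), max(positions)),
                          members=set(members), lead_by_trait=lead_by_trait))
    return loci


def loci_to_frame(loci) -> pd.DataFrame:
    rows = []
    for lc in loci:
        rows.append((lc.locus_id, lc.chrom, lc.span[0], lc.span[1],
                     ";".join(sorted(lc.members)),
                     ";".join(f"{t}={v}" for t, v in sorted(lc.lead_by_trait.items()))))
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "span_start", "span_end",
                                       "members", "lead_by_trait"])
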