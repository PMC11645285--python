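"""Synthetic cohorts with a planted two-pathway genetic architecture.

Cohorts carry two groups of causal variants for liver fat: a
"discordant" group whose effect alleles raise liver fat while lowering
circulating triglycerides (retention mechanism) and a "concordant" group
raising both (systemic mechanism). Binary outcomes load on the two
pathway scores with opposite cardiovascular signs, so downstream
partitioning and outcome association can be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pprskit.io import GenotypeMatrix, add_derived_covariates
from pprskit.pprs import PartitionResult

ADIPOSITY_INDICES = ["BMI", "WFM", "VAT", "WHR"]

#: span of plausible per-allele liver-fat effects (SD units)
BETA_RANGE = (0.03, 0.29)

#: default planted-architecture sizes
N_DISCORDANT = 10
N_CONCORDANT = 13


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant with its true per-allele effects (SD units)."""

    variant_id: str
    maf: float
    beta_pdff: float
    beta_tg: float
    n_tags: int = 0
    tag_r2: float = 0.8

    @property
    def group(self) -> str:
        if self.beta_pdff == 0 or self.beta_tg == 0:
            return "null"
        return "discordant" if math.copysign(1, self.beta_pdff) != math.copysign(1, self.beta_tg) else "concordant"

    def validate(self):
        if not 0 < self.maf < 1:
            raise ValueError(f"{self.variant_id}: MAF {self.maf} outside (0,1)")
        if self.n_tags and not 0 < self.tag_r2 <= 1:
            raise ValueError(f"{self.variant_id}: tag r2 {self.tag_r2} outside (0,1]")


@dataclass(frozen=True)
class AdiposinessSpec:
    """Means/SDs and correlation matrix of the four adiposity indices."""

    means: tuple = (27.0, 25.0, 4.0, 0.9)
    sds: tuple = (4.5, 8.0, 2.0, 0.09)
    corr: tuple = (
        (1.0, 0.85, 0.75, 0.50),
        (0.85, 1.0, 0.70, 0.45),
        (0.75, 0.70, 1.0, 0.55),
        (0.50, 0.45, 0.55, 1.0),
    )

    def corr_matrix(self) -> np.ndarray:
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (4, 4) or not np.allclose(c, c.T):
            raise ValueError("adiposity correlation matrix must be symmetric 4x4")
        if np.linalg.eigvalsh(c).min() <= 1e-10:
            raise ValueError("adiposity correlation matrix not positive-definite")
        return c


@dataclass(frozen=True)
class OutcomeSpec:
    """Baseline prevalence/hazard and per-SD pathway log-effects of one outcome."""

    prevalence: float
    beta_discordant: float
    beta_concordant: float
    baseline_hazard: float = 0.004  # events per year under exponential PH
    followup_years: float = 15.0

    def validate(self, name: str):
        if not 0 < self.prevalence < 1:
            raise ValueError(f"outcome {name}: prevalence {self.prevalence} outside (0,1)")
        if self.baseline_hazard <= 0 or self.followup_years <= 0:
            raise ValueError(f"outcome {name}: hazard/follow-up must be positive")


DEFAULT_OUTCOMES = {
    "liver_disease": OutcomeSpec(0.05, 0.40, 0.20),
    "cardiovascular": OutcomeSpec(0.12, -0.30, 0.35),
    "hypertension": OutcomeSpec(0.25, 0.00, 0.30),
    "diabetes": OutcomeSpec(0.08, 0.15, 0.35),
}


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 5000
    n_null_variants: int = 500
    discordant_loci: tuple = ()
    concordant_loci: tuple = ()
    adiposity_spec: AdiposinessSpec = field(default_factory=AdiposinessSpec)
    mediation_fraction: float = 0.25
    mediation_index: str = "VAT"
    mediator_effect: float = 0.30  # liver-fat SD per mediator SD
    interaction_coefs: tuple = ()  # ((variant_id, coef), ...) optional GxE terms
    interaction_index: str = "BMI"
    outcome_spec: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    noise_sd: float = 1.0
    seed: int = 0

    def all_causal(self) -> list[PlantedVariant]:
        return list(self.discordant_loci) + list(self.concordant_loci)

    def validate(self):
        for v in self.all_causal():
            v.validate()
            if v.beta_pdff == 0 or v.beta_tg == 0:
                raise ValueError(f"{v.variant_id}: causal variant betas must be nonzero")
        for v in self.discordant_loci:
            if v.group != "discordant":
                raise ValueError(f"{v.variant_id}: betas not discordant")
        for v in self.concordant_loci:
            if v.group != "concordant":
                raise ValueError(f"{v.variant_id}: betas not concordant")
        self.adiposity_spec.corr_matrix()
        for name, spec in self.outcome_spec.items():
            spec.validate(name)
        if self.mediation_index not in ADIPOSITY_INDICES:
            raise ValueError(f"unknown mediation index {self.mediation_index!r}")
        if not 0 <= abs(self.mediation_fraction) < 1:
            raise ValueError("mediation_fraction magnitude must be < 1")


def default_config(seed: int = 0, n_samples: int = 5000, n_null_variants: int = 500,
                   **overrides) -> SimConfig:
    """Default planted architecture: 10 discordant + 13 concordant loci.

    Per-allele liver-fat effect magnitudes are drawn uniformly from the
    plausible span ``BETA_RANGE``; triglyceride effects get the group's
    sign with magnitudes in the same span. The draw is keyed by ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11E1E]))
    disc, conc = [], []
    for i in range(N_DISCORDANT):
        disc.append(PlantedVariant(
            variant_id=f"disc{i + 1}",
            maf=float(rng.uniform(0.05, 0.5)),
            beta_pdff=float(rng.uniform(*BETA_RANGE)),
            beta_tg=-float(rng.uniform(*BETA_RANGE)),
        ))
    for i in range(N_CONCORDANT):
        conc.append(PlantedVariant(
            variant_id=f"conc{i + 1}",
            maf=float(rng.uniform(0.05, 0.5)),
            beta_pdff=float(rng.uniform(*BETA_RANGE)),
            beta_tg=float(rng.uniform(*BETA_RANGE)),
        ))
    cfg = SimConfig(
        n_samples=n_samples,
        n_null_variants=n_null_variants,
        discordant_loci=tuple(disc),
        concordant_loci=tuple(conc),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation


def _variant_layout(config: SimConfig) -> pd.DataFrame:
    """Assign chromosomes/positions: causal loci far apart, tags close by."""
    rows = []
    causal = config.all_causal()
    for i, v in enumerate(causal):
        chrom = (i % 22) + 1
        pos = 5_000_000 + (i // 22) * 50_000_000
        rows.append((v.variant_id, chrom, pos, "causal", v.variant_id))
        for t in range(v.n_tags):
            rows.append((f"{v.variant_id}_tag{t + 1}", chrom, pos + 2_000 * (t + 1),
                         "tag", v.variant_id))
    for j in range(config.n_null_variants):
        chrom = (j % 22) + 1
        pos = 120_000_000 + (j // 22) * 3_000_000
        rows.append((f"null{j + 1}", chrom, pos, "null", ""))
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "kind", "source"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _draw_dosages(config: SimConfig, layout: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Binomial(2, MAF) dosages; tags are copy-with-error of their source.

    Copying each of the two allele copies with probability sqrt(r2) and
    redrawing it from Bernoulli(MAF) otherwise gives allele correlation
    sqrt(r2), hence dosage r^2 equal to the target in expectation.
    """
    n = config.n_samples
    causal = {v.variant_id: v for v in config.all_causal()}
    master = np.random.SeedSequence([config.seed, 0xD05A6E])
    children = master.spawn(len(layout))
    mafs = np.empty(len(layout))
    alleles: dict[str, np.ndarray] = {}
    dosages = np.empty((n, len(layout)))
    null_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x4AF5]))
    for j, row in layout.iterrows():
        rng = np.random.default_rng(children[j])
        if row["kind"] == "null":
            maf = float(null_rng.uniform(0.05, 0.5))
            a = rng.random((n, 2)) < maf
        elif row["kind"] == "causal":
            maf = causal[row["variant_id"]].maf
            a = rng.random((n, 2)) < maf
            alleles[row["variant_id"]] = a
        else:  # tag
            src = causal[row["source"]]
            maf = src.maf
            keep = rng.random((n, 2)) < math.sqrt(src.tag_r2)
            fresh = rng.random((n, 2)) < maf
            a = np.where(keep, alleles[src.variant_id], fresh)
        mafs[j] = maf
        dosages[:, j] = a.sum(axis=1)
    return dosages, mafs


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a cohort; identical config and seed give identical output.

    Returns the dosage matrix and a phenotype table with age/sex (and
    derived covariates), adiposity indices, quantitative traits (PDFF,
    cT1, TG) and, per configured outcome, a baseline case flag plus
    incident event indicator/time among baseline-free individuals.
    """
    config.validate()
    layout = _variant_layout(config)
    dosages, mafs = _draw_dosages(config, layout)
    n = config.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E07]))

    variants = pd.DataFrame({
        "variant_id": layout["variant_id"],
        "chrom": layout["chrom"],
        "pos": layout["pos"],
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": mafs,
    })
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids, variants, dosages)

    # covariates
    age = rng.uniform(45, 75, n).round(1)
    sex = rng.integers(0, 2, n)
    pheno = pd.DataFrame({"sample_id": sample_ids, "age": age, "sex": sex})
    pheno = add_derived_covariates(pheno)

    # adiposity latents (z-scale), with the mediated genetic component
    spec = config.adiposity_spec
    corr = spec.corr_matrix()
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")
    causal = config.all_causal()
    centered = {v.variant_id: gm.dosage(v.variant_id) - 2 * v.maf for v in causal}
    f, b_med = config.mediation_fraction, config.mediator_effect
    med_col = ADIPOSITY_INDICES.index(config.mediation_index)
    if f != 0.0:
        for v in causal:
            z[:, med_col] += (f * v.beta_pdff / b_med) * centered[v.variant_id]
    for k, name in enumerate(ADIPOSITY_INDICES):
        pheno[name] = spec.means[k] + spec.sds[k] * z[:, k]

    # quantitative traits (SD units before noise); total per-allele liver-fat
    # effect stays beta_pdff: direct (1-f)*beta plus b_med * (f*beta/b_med)
    pdff = b_med * z[:, med_col] + config.noise_sd * rng.standard_normal(n)
    tg = 0.15 * z[:, 0] + config.noise_sd * rng.standard_normal(n)
    genetic_pdff = np.zeros(n)
    for v in causal:
        g = centered[v.variant_id]
        pdff += (1 - f) * v.beta_pdff * g
        genetic_pdff += v.beta_pdff * g
        tg += v.beta_tg * g
    for vid, coef in config.interaction_coefs:
        gcol = ADIPOSITY_INDICES.index(config.interaction_index)
        pdff += coef * centered[vid] * z[:, gcol]
    ct1 = 0.4 * genetic_pdff + config.noise_sd * rng.standard_normal(n)
    pheno["PDFF"], pheno["cT1"], pheno["TG"] = pdff, ct1, tg

    # pathway scores (standardized) drive the binary outcomes
    def pathway(vs):
        s = np.zeros(n)
        for v in vs:
            s += abs(v.beta_pdff) * centered[v.variant_id]
        sd = s.std()
        return s / sd if sd > 0 else s

    s_disc = pathway(config.discordant_loci)
    s_conc = pathway(config.concordant_loci)
    for name, ospec in config.outcome_spec.items():
        lin = ospec.beta_discordant * s_disc + ospec.beta_concordant * s_conc
        logit0 = math.log(ospec.prevalence / (1 - ospec.prevalence))
        p_case = 1 / (1 + np.exp(-(logit0 + lin)))
        case = rng.random(n) < p_case
        pheno[name] = case.astype(int)
        # incident events among baseline-free individuals: exponential PH
        hazard = ospec.baseline_hazard * np.exp(lin)
        t_event = rng.exponential(1 / hazard)
        t_cens = rng.uniform(0.5 * ospec.followup_years, ospec.followup_years, n)
        event = (t_event <= t_cens) & ~case
        time = np.where(case, np.nan, np.minimum(t_event, t_cens))
        pheno[f"{name}_event"] = np.where(case, np.nan, event.astype(float))
        pheno[f"{name}_time"] = np.round(time, 4)
    return gm, pheno


def planted_truth(config: SimConfig) -> PartitionResult:
    """Ground-truth discordant/concordant assignment with true PDFF betas as weights.

    Weights are oriented to the liver-fat-increasing allele, mirroring the
    orientation the estimated partition uses.
    """
    config.validate()
    disc, conc, orientation = {}, {}, {}
    for v in config.discordant_loci:
        disc[v.variant_id] = abs(v.beta_pdff)
        orientation[v.variant_id] = "A" if v.beta_pdff > 0 else "G"
    for v in config.concordant_loci:
        conc[v.variant_id] = abs(v.beta_pdff)
        orientation[v.variant_id] = "A" if v.beta_pdff > 0 else "G"
    return PartitionResult(discordant=disc, concordant=conc, excluded={},
                           orientation=orientation)
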