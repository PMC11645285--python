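"""Data containers and file I/O.

Coordinates are 1-based (VCF convention) and intervals closed. The effect
allele is written as the VCF ALT allele, so the DS field counts effect
alleles directly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]

#: covariate columns derived from age and sex that every phenotype table carries
DERIVED_COVARIATES = ["age2", "age_sex", "age2_sex"]


class GenotypeIOError(ValueError):
    """Malformed genotype input (carries the offending line/record where known)."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Attributes
    ----------
    sample_ids : list of str
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos,
        effect_allele, other_allele, eaf``; ``pos`` is 1-based.
    dosages : numpy.ndarray of float, shape (n_samples, n_variants)
        Expected effect-allele counts in [0, 2]; NaN marks missing.
    """

    sample_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise GenotypeIOError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise GenotypeIOError(f"duplicated variant ids: {dups}")
        self._index = {vid: j for j, vid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.column(variant_id)]

    def subset(self, variant_ids) -> "GenotypeMatrix":
        cols = [self.column(v) for v in variant_ids]
        return GenotypeMatrix(
            self.sample_ids, self.variants.iloc[cols], self.dosages[:, cols]
        )

    def empirical_eaf(self) -> np.ndarray:
        """Effect-allele frequency recomputed from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def validate(self, eaf_tol: float = 0.05) -> None:
        """Check metadata invariants; raise ``GenotypeIOError`` on violation."""
        v = self.variants
        missing = [c for c in VARIANT_COLUMNS if c not in v.columns]
        if missing:
            raise GenotypeIOError(f"variant table missing columns {missing}")
        for chrom, grp in v.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeIOError(f"positions not strictly increasing on {chrom}")
        emp = self.empirical_eaf()
        stated = v["eaf"].to_numpy(dtype=float)
        ok = np.isnan(emp) | (np.abs(emp - stated) <= eaf_tol)
        if not ok.all():
            bad = v.loc[~ok, "variant_id"].tolist()
            raise GenotypeIOError(f"eaf inconsistent with dosages for {bad}")


# ---------------------------------------------------------------------------
# schema-commented TSV helpers


def write_table(df: pd.DataFrame, path, schema_name: str = "table") -> None:
    """Write a TSV whose first line declares the column schema as a comment."""
    with open(path, "w") as fh:
        fh.write(f"#schema:{schema_name}:" + ",".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, schema_name: str | None = None) -> pd.DataFrame:
    """Read a schema-commented TSV, validating the declared columns."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#schema:"):
            raise GenotypeIOError(f"{path}: missing #schema header comment")
        _, name, cols = header.rstrip("\n").split(":", 2)
        if schema_name is not None and name != schema_name:
            raise GenotypeIOError(f"{path}: schema {name!r}, expected {schema_name!r}")
        df = pd.read_csv(fh, sep="\t")
    declared = cols.split(",")
    if list(df.columns) != declared:
        raise GenotypeIOError(
            f"{path}: columns {list(df.columns)} do not match declared {declared}"
        )
    return df


# ---------------------------------------------------------------------------
# genotype TSV


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    body = gm.variants.copy()
    dm = pd.DataFrame(gm.dosages.T.round(4), columns=gm.sample_ids)
    write_table(pd.concat([body, dm], axis=1), path, schema_name="genotypes")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = read_table(path, schema_name="genotypes")
    sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    gm = GenotypeMatrix(
        sample_ids, df[VARIANT_COLUMNS], df[sample_ids].to_numpy(dtype=float).T
    )
    return gm


# ---------------------------------------------------------------------------
# VCF with DS (dosage) FORMAT field

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
##INFO=<ID=EAF,Number=1,Type=Float,Description="Effect (ALT) allele frequency">
"""


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF; ALT is the effect allele."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in gm.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.sample_ids))
            + "\n"
        )
        for j, row in gm.variants.iterrows():
            ds = gm.dosages[:, j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["variant_id"]),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                f"EAF={row['eaf']:.6g}",
                "DS",
            ]
            fields += ["." if np.isnan(d) else f"{d:.4f}" for d in ds]
            fh.write("\t".join(fields) + "\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a VCF with a DS FORMAT field; missing DS becomes NaN, never 0."""
    vcf = pysam.VariantFile(str(path))
    sample_ids = list(vcf.header.samples)
    rows, dosage_cols = [], []
    seen = set()
    for rec in vcf:
        if "DS" not in rec.format:
            raise GenotypeIOError(
                f"{path}: record {rec.id} at {rec.chrom}:{rec.pos} lacks DS field"
            )
        if rec.id in seen:
            raise GenotypeIOError(f"{path}: duplicated variant id {rec.id}")
        seen.add(rec.id)
        if rec.alts is None or len(rec.alts) != 1:
            raise GenotypeIOError(f"{path}: {rec.id} is not biallelic")
        try:
            eaf = rec.info.get("EAF", None)
        except ValueError:  # EAF not declared in this file's header
            eaf = None
        col = np.full(len(sample_ids), np.nan)
        for i, s in enumerate(sample_ids):
            ds = rec.samples[s].get("DS", None)
            if ds is not None:
                col[i] = float(ds)
        rows.append(
            {
                "variant_id": rec.id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "effect_allele": rec.alts[0],
                "other_allele": rec.ref,
                "eaf": float(eaf) if eaf is not None else np.nan,
            }
        )
        dosage_cols.append(col)
    vcf.close()
    if not rows:
        raise GenotypeIOError(f"{path}: no variant records")
    variants = pd.DataFrame(rows)
    if variants["eaf"].isna().any():
        gm = GenotypeMatrix(sample_ids, variants, np.column_stack(dosage_cols))
        variants = variants.assign(eaf=np.where(
            variants["eaf"].isna(), gm.empirical_eaf(), variants["eaf"]
        ))
    return GenotypeMatrix(sample_ids, variants, np.column_stack(dosage_cols))


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path, format: str = "tsv") -> None:
    if format == "vcf":
        write_genotypes_vcf(gm, path)
    elif format == "tsv":
        write_genotypes_tsv(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype table


def add_derived_covariates(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add age^2, age x sex and age^2 x sex columns derived from age/sex."""
    out = pheno.copy()
    out["age2"] = out["age"] ** 2
    out["age_sex"] = out["age"] * out["sex"]
    out["age2_sex"] = out["age"] ** 2 * out["sex"]
    return out


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    for col in ["sample_id", "age", "sex"]:
        if col not in pheno.columns:
            raise GenotypeIOError(f"phenotype table missing column {col!r}")
    for col in DERIVED_COVARIATES:
        if col not in pheno.columns:
            continue
        expected = {
            "age2": pheno["age"] ** 2,
            "age_sex": pheno["age"] * pheno["sex"],
            "age2_sex": pheno["age"] ** 2 * pheno["sex"],
        }[col]
        if not np.allclose(pheno[col], expected, equal_nan=True):
            raise GenotypeIOError(f"derived covariate {col!r} inconsistent with age/sex")
    time_cols = [c for c in pheno.columns if c.endswith("_time")]
    for col in time_cols:
        if (pheno[col].dropna() < 0).any():
            raise GenotypeIOError(f"negative event time in {col!r}")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    write_table(pheno, path, schema_name="phenotypes")


def read_phenotypes(path) -> pd.DataFrame:
    pheno = read_table(path, schema_name="phenotypes")
    validate_phenotypes(pheno)
    return pheno
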