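"""Readers, writers and basic QC for cohort phenotype/genotype data.

All downstream modules consume the containers defined here:

* :class:`Cohort` — participant table (age, sex, carrier status, family
  links), visit-wise quantitative traits and visit-wise symptom/sign flags.
* :class:`GenotypeMatrix` — imputed allele dosages (``DS`` in ``[0, 2]``)
  plus per-variant imputation quality (INFO/R2).
* :class:`WeightTable` — per-allele effect weights used for polygenic
  scoring.

Conventions: genomic coordinates are 1-based and closed as in VCF; the
missing-value sentinel in delimited text files is an empty field or ``NA``
(written back as ``NA``); FAM files use the PLINK 6-column dialect with sex
coded 1 = male, 2 = female, 0 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Cohort",
    "GenotypeMatrix",
    "WeightTable",
    "QCRules",
    "QCReport",
    "read_cohort",
    "apply_trait_qc",
    "dosage_to_genotype",
    "allele_frequency",
    "load_yaml_config",
]

NA = "NA"

#: Hard upper bounds for cardiac traits; values strictly above the bound are
#: implausible recordings and set to missing.
DEFAULT_TRAIT_BOUNDS = {"HR": 200.0, "QRS": 200.0, "QTC": 600.0, "PQ": 320.0}


# ---------------------------------------------------------------------------
# containers


@dataclass
class Cohort:
    """Participant-level cohort data.

    ``participants`` is indexed by participant_id with columns
    ``age`` (years), ``sex`` ('male'/'female'), ``family_id``, ``carrier``
    (0/1) and ``cause_of_death`` (string or NA). ``traits`` and ``flags``
    share the same index; their columns are named ``<name>_v<visit>`` with
    visit in {1, 2}. Flags are boolean, traits are floats with NaN missing.
    ``pedigree`` carries the PLINK FAM columns for kinship computation.
    """

    participants: pd.DataFrame
    traits: pd.DataFrame
    flags: pd.DataFrame
    pedigree: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        idx = self.participants.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicated participant_id: {dups}")
        ages = self.participants["age"]
        if (ages.dropna() < 0).any():
            raise ValueError("negative ages present")
        carrier = self.participants["carrier"]
        if not carrier.isin([0, 1]).all():
            raise ValueError("carrier must be coded 0/1")
        for col in self.traits.columns:
            visit = col.rsplit("_v", 1)[-1]
            if visit not in ("1", "2"):
                raise ValueError(f"trait column {col!r}: visit index must be 1 or 2")

    # -- convenience -------------------------------------------------------
    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants.index)

    def trait_names(self) -> list[str]:
        return sorted({c.rsplit("_v", 1)[0] for c in self.traits.columns})

    def trait(self, name: str, visit: int = 1) -> pd.Series:
        return self.traits[f"{name}_v{visit}"]

    def n(self) -> int:
        return len(self.participants)

    # -- serialization -----------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / "phenotypes.tsv",
            "flags": outdir / "flags.tsv",
            "fam": outdir / "cohort.fam",
        }
        pheno = pd.concat([self.participants, self.traits], axis=1)
        pheno.to_csv(paths["phenotypes"], sep="\t", na_rep=NA,
                     index_label="participant_id", float_format="%.10g")
        self.flags.astype(int).to_csv(paths["flags"], sep="\t",
                                      index_label="participant_id")
        self.pedigree.to_csv(paths["fam"], sep=" ", header=False, index=False)
        return paths


_DEMOG_COLS = ["age", "sex", "family_id", "carrier", "cause_of_death"]


def _read_fam(fam_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{fam_path}: malformed FAM line {lineno}: expected 6 "
                    f"whitespace-delimited columns, got {len(parts)}"
                )
            rows.append(parts)
    fam = pd.DataFrame(
        rows, columns=["family_id", "participant_id", "father", "mother",
                       "sex_code", "phenotype"],
    )
    fam["sex_code"] = fam["sex_code"].astype(int)
    return fam


def read_cohort(phenotype_path: str | Path, flags_path: str | Path,
                fam_path: str | Path) -> Cohort:
    """Read a cohort from a phenotype table, a flag table and a FAM file.

    The phenotype table must contain one row per participant with the
    demographic columns plus ``<trait>_v<visit>`` columns; the flag table
    holds 0/1 symptom and sign indicators. Flag rows whose participant_id
    is absent from the phenotype table raise an error naming the IDs.
    """
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col="participant_id",
                        na_values=[NA], keep_default_na=True,
                        dtype={"participant_id": str})
    pheno.index = pheno.index.astype(str)
    flags = pd.read_csv(flags_path, sep="\t", index_col="participant_id")
    flags.index = flags.index.astype(str)
    fam = _read_fam(fam_path)

    unmatched = flags.index.difference(pheno.index)
    if len(unmatched):
        raise ValueError(
            "flag table contains participant_id absent from phenotypes: "
            + ", ".join(map(str, unmatched.tolist()))
        )
    demog = pheno[[c for c in _DEMOG_COLS if c in pheno.columns]].copy()
    if "cause_of_death" not in demog.columns:
        demog["cause_of_death"] = np.nan
    if "family_id" not in demog.columns:
        fam_map = fam.set_index("participant_id")["family_id"]
        demog["family_id"] = demog.index.map(fam_map)
    demog["carrier"] = demog["carrier"].astype(int)
    traits = pheno[[c for c in pheno.columns if c not in _DEMOG_COLS]].astype(float)
    flags = flags.reindex(pheno.index).fillna(0).astype(bool)
    return Cohort(participants=demog, traits=traits, flags=flags, pedigree=fam)


# ---------------------------------------------------------------------------
# trait QC


@dataclass
class QCRules:
    """Per-trait upper bounds and the minimum asymptomatic-carrier count."""

    upper_bounds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BOUNDS))
    min_asymptomatic_carriers: int = 25


@dataclass
class QCReport:
    values_masked: dict[str, int]
    traits_dropped: dict[str, int]  # trait -> non-missing asympt-carrier count


def apply_trait_qc(cohort: Cohort, rules: QCRules,
                   asymptomatic_carrier_ids: list[str] | None = None,
                   ) -> tuple[Cohort, QCReport]:
    """Mask implausible trait values and drop under-observed traits.

    Values strictly above a trait's upper bound are set to missing (rows are
    never dropped). A trait is removed entirely when fewer than
    ``rules.min_asymptomatic_carriers`` asymptomatic carriers have a
    non-missing baseline (visit 1) value — under-observed traits cannot
    support the screen's primary contrast. The count rule is skipped when no
    asymptomatic-carrier ID list is supplied.
    """
    known = set(cohort.trait_names())
    unknown = set(rules.upper_bounds) - known
    if unknown:
        raise KeyError(f"QC rules reference unknown traits: {sorted(unknown)}")

    traits = cohort.traits.copy()
    masked: dict[str, int] = {}
    for name, bound in rules.upper_bounds.items():
        for col in traits.columns:
            if col.rsplit("_v", 1)[0] == name:
                bad = traits[col] > bound
                if bad.any():
                    masked[col] = int(bad.sum())
                    traits.loc[bad, col] = np.nan

    dropped: dict[str, int] = {}
    if asymptomatic_carrier_ids is not None:
        ac = traits.index.intersection(pd.Index(asymptomatic_carrier_ids))
        for name in cohort.trait_names():
            col = f"{name}_v1"
            n_obs = int(traits.loc[ac, col].notna().sum()) if col in traits else 0
            if n_obs < rules.min_asymptomatic_carriers:
                dropped[name] = n_obs
        drop_cols = [c for c in traits.columns
                     if c.rsplit("_v", 1)[0] in dropped]
        traits = traits.drop(columns=drop_cols)

    out = Cohort(participants=cohort.participants, traits=traits,
                 flags=cohort.flags, pedigree=cohort.pedigree)
    return out, QCReport(values_masked=masked, traits_dropped=dropped)


# ---------------------------------------------------------------------------
# genotype utilities


def dosage_to_genotype(dosage):
    """Hard-call allele dosages.

    Rounds to the nearest integer genotype in {0, 1, 2} when the dosage is
    within 0.3 of it, otherwise returns missing (NaN). Accepts scalars or
    arrays; raises on dosages outside [0, 2].
    """
    arr = np.asarray(dosage, dtype=float)
    finite = np.isfinite(arr)
    if ((arr[finite] < 0) | (arr[finite] > 2)).any():
        raise ValueError("dosage outside [0, 2]")
    rounded = np.round(arr)
    # tolerance keeps the band edges (0.7, 1.3, ...) inside despite binary
    # floating-point representation
    out = np.where(np.abs(arr - rounded) <= 0.3 + 1e-9, rounded, np.nan)
    out = np.where(finite, out, np.nan)
    if np.isscalar(dosage) or np.ndim(dosage) == 0:
        val = float(out)
        return int(val) if np.isfinite(val) else None
    return out


def allele_frequency(dosages: np.ndarray, subset=None) -> np.ndarray:
    """Minor allele frequency from a participants × variants dosage matrix.

    The alternate-allele frequency is the dosage sum over twice the number
    of non-missing participants, folded to the minor allele. ``subset`` is
    an optional boolean mask or integer index over rows. All-missing columns
    give NaN.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
        squeeze = True
    else:
        squeeze = False
    if subset is not None:
        d = d[np.asarray(subset)]
    if d.shape[0] == 0:
        raise ValueError("empty subset")
    n_obs = np.isfinite(d).sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.nansum(d, axis=0) / (2.0 * n_obs)
    alt = np.where(n_obs == 0, np.nan, alt)
    maf = np.minimum(alt, 1.0 - alt)
    return float(maf[0]) if squeeze else maf


# ---------------------------------------------------------------------------
# genotypes (VCF with DS dosage field)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``variants`` has columns chrom, pos (1-based), ref, alt, info
    (imputation R2 in [0, 1]); ``dosage`` is participants × variants with
    values in [0, 2] (NaN missing); ``samples`` gives the row order.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples × variants")
        d = self.dosage
        finite = np.isfinite(d)
        if ((d[finite] < 0) | (d[finite] > 2)).any():
            raise ValueError("dosages outside [0, 2]")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, cols = [], []
        for var in vcf:
            info = var.INFO.get("R2")
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                         float(info) if info is not None else 1.0))
            ds = var.format("DS")
            if ds is not None:
                col = np.asarray(ds, dtype=float).reshape(-1)
                col[col < -0.5] = np.nan  # cyvcf2 missing sentinel
            else:
                gt = np.asarray(var.genotype.array())[:, :2]
                col = np.where((gt < 0).any(axis=1), np.nan,
                               (gt > 0).sum(axis=1)).astype(float)
            cols.append(col)
        vcf.close()
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "info"])
        dosage = (np.column_stack(cols) if cols
                  else np.empty((len(samples), 0)))
        return cls(samples=samples, variants=variants, dosage=dosage)

    def to_vcf(self, path: str | Path, hard_calls: np.ndarray | None = None,
               phased: np.ndarray | None = None) -> Path:
        """Write an uncompressed VCF with a DS FORMAT field.

        ``hard_calls`` (participants × variants, values 0/1/2/NaN) fills the
        GT field; ``phased`` optionally gives the maternal/paternal split as
        an (participants, variants, 2) array of 0/1 alleles written with the
        ``|`` separator.
        """
        path = Path(path)
        contigs = list(dict.fromkeys(self.variants["chrom"]))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,'
                     'Description="Imputation quality">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Alternate allele dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for j, var in self.variants.reset_index(drop=True).iterrows():
                fields = [str(var.chrom), str(int(var.pos)), ".", var.ref,
                          var.alt, ".", "PASS", f"R2={var['info']:.4f}", "GT:DS"]
                ds = self.dosage[:, j]
                for i in range(len(self.samples)):
                    if phased is not None:
                        a, b = phased[i, j]
                        gt = f"{a}|{b}"
                    elif hard_calls is not None and np.isfinite(hard_calls[i, j]):
                        g = int(hard_calls[i, j])
                        gt = ["0/0", "0/1", "1/1"][g]
                    else:
                        gt = "./."
                    d = ds[i]
                    fields.append(f"{gt}:{d:.4g}" if np.isfinite(d) else f"{gt}:.")
                fh.write("\t".join(fields) + "\n")
        return path


# ---------------------------------------------------------------------------
# PGS weight tables


@dataclass
class WeightTable:
    """Per-allele PGS weights keyed by (chrom, pos, effect_allele, other_allele)."""

    table: pd.DataFrame  # columns chrom, pos, effect_allele, other_allele, weight

    def __post_init__(self) -> None:
        t = self.table
        key = t[["chrom", "pos", "effect_allele", "other_allele"]]
        if key.duplicated().any():
            raise ValueError("duplicate variant keys in weight table")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect allele equals other allele")

    @classmethod
    def read(cls, path: str | Path) -> "WeightTable":
        t = pd.read_csv(path, sep="\t",
                        dtype={"chrom": str, "pos": int, "effect_allele": str,
                               "other_allele": str, "weight": float})
        return cls(table=t)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
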