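"""Synthetic family cohorts with a founder variant and known ground truth.

The generator emulates the study design the screen targets: a population
biobank of ~36,000 volunteers containing ~74 heterozygous carriers of a
founder deletion (carrier fraction 0.2%, allele frequency 0.1%), clustered
as singleton carriers plus small multi-carrier families; a shared founder
haplotype around the deletion, truncated by recombination in a configurable
subset of carriers; quantitative ECG traits with configurable carrier and
asymptomatic-carrier ("protective") effects; and age-dependent symptom
penetrance calibrated to a background symptomatic prevalence of 5.7% with a
carrier odds ratio of ~9.

Everything is driven by a single integer seed; a fixed seed reproduces the
output byte-for-byte. Ground truth (true effects, penetrance parameters,
haplotype boundaries, carrier list) is emitted alongside the data so
recovery tests can score the screen.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .cohort_io import Cohort, GenotypeMatrix, WeightTable
from .groups import DEFAULT_SYMPTOMS, DEFAULT_SIGNS

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "FounderRegion",
    "simulate_cohort",
    "simulate_founder_region",
    "power_carrier_design",
    "power_gwas",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TraitSpec:
    """Generating model for one quantitative trait.

    ``carrier_effect`` shifts all carriers (a direct variant effect);
    ``protective_effect`` shifts only carriers who end up asymptomatic (the
    signature of a factor associated with absence of symptoms). ``h2_family``
    is the fraction of residual variance shared within a family.
    """

    name: str
    mean: float
    sd: float
    age_slope: float = 0.0
    sex_effect: float = 0.0  # added for females
    carrier_effect: float = 0.0
    protective_effect: float = 0.0
    h2_family: float = 0.3
    visit2_noise_corr: float = 0.6


def default_trait_panel() -> list[TraitSpec]:
    """Trait panel mirroring the screened ECG/anthropometric variables.

    The three non-null protective effects are the reported ones: heart rate
    +6.41 beats/min, QRS duration −5.7 ms and lnSDNN −0.216; baseline means,
    SDs and covariate slopes are population-typical values for adults.
    """
    return [
        TraitSpec("HR", 70.0, 11.0, age_slope=-0.05, sex_effect=3.0,
                  protective_effect=6.41),
        TraitSpec("QRS", 95.0, 10.0, age_slope=0.08, sex_effect=-6.0,
                  protective_effect=-5.7),
        TraitSpec("lnSDNN", 3.70, 0.40, age_slope=-0.012,
                  protective_effect=-0.216),
        TraitSpec("lnRMSSD", 3.40, 0.45, age_slope=-0.015),
        TraitSpec("lnRMSSDc", 3.40, 0.42, age_slope=-0.010),
        TraitSpec("QTC", 420.0, 20.0, age_slope=0.10, sex_effect=8.0),
        TraitSpec("PQ", 160.0, 22.0, age_slope=0.30, sex_effect=-4.0),
        TraitSpec("BMI", 26.0, 4.0, age_slope=0.05),
        TraitSpec("height", 175.0, 7.5, sex_effect=-13.0),
        TraitSpec("weight", 80.0, 13.0, sex_effect=-10.0),
        TraitSpec("SBP", 125.0, 15.0, age_slope=0.45, sex_effect=-5.0),
        TraitSpec("cholesterol", 5.1, 1.0, age_slope=0.02),
    ]


@dataclass
class PGSTraitLink:
    """Optional coupling of a trait to the true polygenic score.

    ``base_slope`` is in trait-SD units per score-SD; ``group_multipliers``
    scales the slope per group (keys from groups.GROUPS), the device used to
    inject a group-specific PGS response.
    """

    trait: str
    base_slope: float = 0.3
    group_multipliers: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    n_individuals: int = 36_339
    seed: int = 0
    # pedigree structure
    singleton_fraction: float = 0.5      # of generated *units*
    children_range: tuple[int, int] = (2, 3)
    spouse_prob: float = 0.4             # child founds its own nuclear family
    grandchildren_range: tuple[int, int] = (1, 2)
    # founder variant
    founder_allele_freq: float = 0.001
    # symptom / penetrance model (logistic in age with carrier main effect;
    # the intercept is calibrated numerically to the background prevalence)
    background_symptomatic_prevalence: float = 0.057
    carrier_log_or: float = math.log(9.0)
    penetrance_age_slope: float = 0.05   # per year, centred at age 40
    cardiac_death_prob: float = 0.05     # among symptomatic carriers
    # traits
    traits: list[TraitSpec] = field(default_factory=default_trait_panel)
    trait_missing_rate: float = 0.0
    pgs_link: PGSTraitLink | None = None
    # founder region
    region_chrom: str = "6"
    index_pos: int = 118_880_000
    n_region_variants: int = 160
    region_halfspan_bp: int = 1_500_000
    founder_halfspan_bp: int = 690_000
    region_rare_fraction: float = 0.3
    recombinant_fraction: float = 0.055
    # genome background
    n_genome_variants: int = 400
    n_pgs_variants: int = 150
    pgs_weight_sd: float = 0.1
    dosage_noise_sd: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.founder_allele_freq <= 0.5):
            raise ValueError("founder_allele_freq must be in (0, 0.5]")
        for p in (self.singleton_fraction, self.spouse_prob,
                  self.background_symptomatic_prevalence,
                  self.recombinant_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        expected_carriers = 2 * self.founder_allele_freq * self.n_individuals
        if expected_carriers < 1:
            raise ValueError(
                f"infeasible config: expected carriers "
                f"{expected_carriers:.2f} < 1")


@dataclass
class SimTruth:
    trait_effects: dict
    penetrance: dict
    founder_span_bp: tuple[int, int]
    shared_span_bp: tuple[int, int]
    recombinants: dict
    carrier_ids: list[str]
    family_of: dict
    pgs_link: dict | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# founder region


@dataclass
class FounderRegion:
    """Phased founder-region data for deletion-bearing carrier chromosomes."""

    variants: pd.DataFrame        # chrom, pos, ref, alt, maf (deletion excluded)
    founder_hap: np.ndarray       # the ancestral haplotype (0/1 per variant)
    del_haps: np.ndarray          # carriers × variants, the deletion phase
    carrier_ids: list[str]
    index_pos: int
    founder_span_bp: tuple[int, int]
    shared_span_bp: tuple[int, int]
    recombinant_rows: dict        # carrier row -> (left_bp, right_bp)


def simulate_founder_region(
    n_carriers: int,
    rng: np.random.Generator,
    *,
    carrier_ids: list[str] | None = None,
    chrom: str = "6",
    index_pos: int = 118_880_000,
    n_variants: int = 160,
    region_halfspan_bp: int = 1_500_000,
    founder_halfspan_bp: int = 690_000,
    rare_fraction: float = 0.3,
    recombinants: int | list[tuple[int, int, int]] | None = None,
) -> FounderRegion:
    """Simulate the phased deletion-bearing haplotypes around the founder locus.

    All carriers copy one ancestral haplotype over the founder span;
    ``recombinants`` (a count, or explicit ``(row, left_bp, right_bp)``
    triples) retain it only over a sub-span and carry independent alleles
    outside, with the first flanking variant forced discordant so the
    recorded breakpoint is exactly where sharing stops.
    """
    lo, hi = index_pos - region_halfspan_bp, index_pos + region_halfspan_bp
    pos = np.sort(rng.choice(np.arange(lo, hi, 997), size=n_variants,
                             replace=False))
    pos = pos[pos != index_pos]
    n_variants = len(pos)
    rare = rng.random(n_variants) < rare_fraction
    maf = np.where(rare, rng.uniform(0.002, 0.01, n_variants),
                   rng.uniform(0.02, 0.5, n_variants))
    founder = (rng.random(n_variants) < maf).astype(np.int8)

    f_left, f_right = index_pos - founder_halfspan_bp, index_pos + founder_halfspan_bp
    in_founder = (pos >= f_left) & (pos <= f_right)

    haps = (rng.random((n_carriers, n_variants)) < maf[None, :]).astype(np.int8)
    haps[:, in_founder] = founder[in_founder]
    # force discordance at the first variant flanking the founder span
    for edge in (_first_outside(pos, in_founder, "left"),
                 _first_outside(pos, in_founder, "right")):
        if edge is not None:
            haps[:, edge] = rng.integers(0, 2, n_carriers, dtype=np.int8)
            if (haps[:, edge] == founder[edge]).all():
                haps[0, edge] = 1 - founder[edge]

    if recombinants is None:
        recombinants = 0
    if isinstance(recombinants, int):
        rows = rng.choice(n_carriers, size=recombinants, replace=False)
        spans = []
        for r in rows:
            left = index_pos - int(rng.uniform(0.25, 0.8) * founder_halfspan_bp)
            right = index_pos + int(rng.uniform(0.25, 0.8) * founder_halfspan_bp)
            spans.append((int(r), left, right))
    else:
        spans = [(int(r), int(l), int(h)) for r, l, h in recombinants]

    recomb_rows: dict[int, tuple[int, int]] = {}
    for r, left, right in spans:
        keep = (pos >= left) & (pos <= right) & in_founder
        outside = in_founder & ~keep
        haps[r, outside] = (rng.random(int(outside.sum())) < maf[outside]
                            ).astype(np.int8)
        for edge in (_first_outside(pos, keep, "left"),
                     _first_outside(pos, keep, "right")):
            if edge is not None and in_founder[edge]:
                haps[r, edge] = 1 - founder[edge]
        recomb_rows[r] = (left, right)

    if recomb_rows:
        shared = (max(l for l, _ in recomb_rows.values()),
                  min(h for _, h in recomb_rows.values()))
    else:
        shared = (f_left, f_right)
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": np.where(founder, "G", "A"), "alt": np.where(founder, "A", "G"),
        "maf": maf,
    })
    # ref/alt labels are arbitrary bases; keep alleles distinct and biallelic
    variants["ref"] = "A"
    variants["alt"] = "G"
    ids = carrier_ids or [f"C{i:04d}" for i in range(n_carriers)]
    return FounderRegion(variants=variants, founder_hap=founder, del_haps=haps,
                         carrier_ids=list(ids), index_pos=index_pos,
                         founder_span_bp=(f_left, f_right),
                         shared_span_bp=shared, recombinant_rows=recomb_rows)


def _first_outside(pos: np.ndarray, inside: np.ndarray, side: str) -> int | None:
    idx = np.nonzero(inside)[0]
    if len(idx) == 0:
        return None
    if side == "left":
        return int(idx[0] - 1) if idx[0] > 0 else None
    return int(idx[-1] + 1) if idx[-1] + 1 < len(pos) else None


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimResult:
    cohort: Cohort
    genotypes: GenotypeMatrix
    deletion_index: int           # column of the deletion in ``genotypes``
    region: FounderRegion
    weights: WeightTable
    pgs_true: np.ndarray          # standardized true polygenic score
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = self.cohort.write(outdir)
        paths["genotypes"] = outdir / "genotypes.vcf"
        hard = np.round(self.genotypes.dosage)
        self.genotypes.to_vcf(paths["genotypes"], hard_calls=hard)
        paths["region"] = outdir / "region_phased.vcf"
        _write_region_vcf(paths["region"], self.region)
        paths["weights"] = outdir / "weights.tsv"
        self.weights.write(paths["weights"])
        paths["truth"] = outdir / "truth.json"
        self.truth.to_json(paths["truth"])
        return paths


def _write_region_vcf(path: Path, region: FounderRegion) -> None:
    """Phased carrier-only VCF of the founder region, deletion included."""
    n = len(region.carrier_ids)
    pos = region.variants["pos"].to_numpy()
    ins = int(np.searchsorted(pos, region.index_pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={region.variants['chrom'].iloc[0]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(region.carrier_ids) + "\n")
        chrom = region.variants["chrom"].iloc[0]
        other = np.zeros((n, len(pos)), dtype=np.int8)  # non-deletion phase
        # the non-deletion chromosome is an independent population haplotype
        rng = np.random.default_rng(abs(hash("region-other-phase")) % 2**31)
        other[:] = (rng.random(other.shape)
                    < region.variants["maf"].to_numpy()[None, :])

        def row(j_pos, ref, alt, a_del, a_other, vid="."):
            fields = [str(chrom), str(j_pos), vid, ref, alt, ".", "PASS", ".",
                      "GT"]
            fields += [f"{a_del[i]}|{a_other[i]}" for i in range(n)]
            fh.write("\t".join(fields) + "\n")

        for j in range(len(pos)):
            if j == ins:
                row(region.index_pos, "CAGA", "C", np.ones(n, dtype=int),
                    np.zeros(n, dtype=int), vid="founder_del")
            row(int(pos[j]), region.variants["ref"].iloc[j],
                region.variants["alt"].iloc[j], region.del_haps[:, j],
                other[:, j])
        if ins == len(pos):
            row(region.index_pos, "CAGA", "C", np.ones(n, dtype=int),
                np.zeros(n, dtype=int), vid="founder_del")


def _build_pedigree(config: SimConfig, rng: np.random.Generator):
    """Units of singletons and 2–3-generation families until the target size."""
    records = []  # (family_id, participant_id, father, mother, sex, age)
    counter = 0
    fam_counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    while len(records) < config.n_individuals:
        fam_counter += 1
        fid = f"F{fam_counter:05d}"
        if rng.random() < config.singleton_fraction:
            sex = int(rng.integers(1, 3))
            age = float(np.clip(rng.normal(40, 13), 4, 90))
            records.append((fid, new_id(), "0", "0", sex, age))
            continue
        f_age = float(np.clip(rng.normal(62, 7), 35, 90))
        father, mother = new_id(), new_id()
        records.append((fid, father, "0", "0", 1, f_age))
        records.append((fid, mother, "0", "0", 2,
                        float(np.clip(f_age + rng.normal(0, 3), 30, 90))))
        n_children = int(rng.integers(config.children_range[0],
                                      config.children_range[1] + 1))
        for _ in range(n_children):
            child = new_id()
            c_sex = int(rng.integers(1, 3))
            c_age = float(np.clip(f_age - rng.normal(29, 4), 4, 80))
            records.append((fid, child, father, mother, c_sex, c_age))
            if rng.random() < config.spouse_prob:
                spouse = new_id()
                s_sex = 1 if c_sex == 2 else 2
                records.append((fid, spouse, "0", "0", s_sex,
                                float(np.clip(c_age + rng.normal(0, 4), 18, 80))))
                for _ in range(int(rng.integers(config.grandchildren_range[0],
                                                config.grandchildren_range[1] + 1))):
                    g_sex = int(rng.integers(1, 3))
                    g_age = float(np.clip(c_age - rng.normal(28, 4), 4, 60))
                    gfather = child if c_sex == 1 else spouse
                    gmother = spouse if c_sex == 1 else child
                    records.append((fid, new_id(), gfather, gmother, g_sex, g_age))
    records = records[: config.n_individuals]
    fam = pd.DataFrame(records, columns=["family_id", "participant_id",
                                         "father", "mother", "sex_code", "age"])
    # drop dangling parent links truncated away with the tail
    present = set(fam["participant_id"])
    for col in ("father", "mother"):
        fam[col] = fam[col].where(fam[col].isin(present), "0")
    return fam


def _assign_deletion(fam: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Seed founder chromosomes with the deletion and transmit Mendelianly.

    The per-founder seeding probability is calibrated so the expected number
    of carriers matches 2 × allele frequency × cohort size, accounting for
    expected transmissions down the pedigree.
    """
    ids = fam["participant_id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    children: dict[str, list[str]] = {s: [] for s in ids}
    for r in fam.itertuples(index=False):
        for par in (r.father, r.mother):
            if par in children:
                children[par].append(r.participant_id)

    exp_desc: dict[str, float] = {}

    def expected_transmitted(ind: str) -> float:
        if ind not in exp_desc:
            exp_desc[ind] = sum(0.5 * (1 + expected_transmitted(c))
                                for c in children[ind])
        return exp_desc[ind]

    founders = [r.participant_id for r in fam.itertuples(index=False)
                if r.father == "0" and r.mother == "0"]
    weights = np.array([1.0 + expected_transmitted(s) for s in founders])
    target = 2 * config.founder_allele_freq * len(ids)
    q0 = min(target / weights.sum(), 0.5)

    alleles = np.zeros(len(ids), dtype=np.int8)
    seeded = rng.random(len(founders)) < q0
    for s, hit in zip(founders, seeded):
        if hit:
            alleles[pos[s]] = 1
    # transmit in pedigree order (parents always precede children here)
    for r in fam.itertuples(index=False):
        inherited = 0
        for par in (r.father, r.mother):
            if par in pos and alleles[pos[par]] >= 1:
                inherited += int(rng.random() < 0.5)
        if inherited:
            alleles[pos[r.participant_id]] = min(
                alleles[pos[r.participant_id]] + inherited, 2)
    return alleles


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None
                    ) -> SimResult:
    """Generate a full synthetic cohort with files parseable by cohort_io."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    fam = _build_pedigree(config, rng)
    n = len(fam)
    ids = fam["participant_id"].tolist()
    age = fam["age"].to_numpy()
    female = fam["sex_code"].to_numpy() == 2
    alleles = _assign_deletion(fam, config, rng)
    carrier = (alleles >= 1).astype(int)

    # ---- symptoms: logistic penetrance, intercept calibrated to background
    prev = config.background_symptomatic_prevalence
    slope = config.penetrance_age_slope

    def mean_prev(a: float) -> float:
        return float(np.mean(expit(a + slope * (age[carrier == 0] - 40.0)))) - prev

    intercept = optimize.brentq(mean_prev, -20, 5)
    logit_p = intercept + slope * (age - 40.0) + config.carrier_log_or * carrier
    symptomatic = rng.random(n) < expit(logit_p)

    # ---- flags: symptomatic participants get 1–2 random flags
    flag_names = DEFAULT_SYMPTOMS + DEFAULT_SIGNS
    flags = pd.DataFrame(False, index=pd.Index(ids, name="participant_id"),
                         columns=[f"{f}_v{v}" for f in flag_names for v in (1, 2)])
    sym_idx = np.nonzero(symptomatic)[0]
    for i in sym_idx:
        k = 1 + int(rng.random() < 0.3)
        chosen = rng.choice(len(flag_names), size=k, replace=False)
        for c in chosen:
            visit = int(rng.integers(1, 3))
            flags.iloc[i, flags.columns.get_loc(f"{flag_names[c]}_v{visit}")] = True
    cod = np.full(n, np.nan, dtype=object)
    for i in sym_idx:
        if carrier[i] and rng.random() < config.cardiac_death_prob:
            cod[i] = "cardiac arrest"

    asympt_carrier = (carrier == 1) & ~symptomatic
    group = np.where(carrier == 1,
                     np.where(symptomatic, "symptomatic_carrier",
                              "asymptomatic_carrier"),
                     np.where(symptomatic, "symptomatic_noncarrier",
                              "asymptomatic_noncarrier"))

    # ---- genome background + PGS weights
    n_gen = config.n_genome_variants
    gen_maf = rng.uniform(0.05, 0.5, n_gen)
    gen_geno = rng.binomial(2, gen_maf[None, :], size=(n, n_gen)).astype(float)
    chroms = np.array([str(1 + (j % 22)) for j in range(n_gen)])
    order = np.argsort(chroms.astype(int), kind="stable")
    chroms = chroms[order]
    gen_maf = gen_maf[order]
    gen_geno = gen_geno[:, order]
    positions = np.zeros(n_gen, dtype=int)
    for c in np.unique(chroms):
        m = chroms == c
        positions[m] = 1_000_000 + 50_000 * np.arange(m.sum())

    w = np.zeros(n_gen)
    pgs_idx = rng.choice(n_gen, size=min(config.n_pgs_variants, n_gen),
                         replace=False)
    w[pgs_idx] = rng.normal(0, config.pgs_weight_sd, len(pgs_idx))
    raw = gen_geno @ w
    pgs_true = (raw - raw.mean()) / raw.std() if raw.std() > 0 else raw * 0.0

    # ---- traits
    fam_codes, fam_uniques = pd.factorize(fam["family_id"])
    trait_cols = {}
    truth_effects = {}
    for spec in config.traits:
        b_fam = rng.normal(0, 1, len(fam_uniques))[fam_codes]
        sd_f = spec.sd * math.sqrt(spec.h2_family)
        sd_e = spec.sd * math.sqrt(1 - spec.h2_family)
        systematic = (spec.mean + spec.age_slope * (age - 40.0)
                      + spec.sex_effect * female
                      + spec.carrier_effect * carrier
                      + spec.protective_effect * asympt_carrier)
        if config.pgs_link is not None and config.pgs_link.trait == spec.name:
            mult = np.ones(n)
            for g, m in config.pgs_link.group_multipliers.items():
                mult[group == g] = m
            systematic = systematic + (config.pgs_link.base_slope * spec.sd
                                       * mult * pgs_true)
        e1 = rng.normal(0, 1, n)
        e2 = (spec.visit2_noise_corr * e1
              + math.sqrt(1 - spec.visit2_noise_corr**2) * rng.normal(0, 1, n))
        v1 = systematic + sd_f * b_fam + sd_e * e1
        v2 = systematic + sd_f * b_fam + sd_e * e2
        if config.trait_missing_rate > 0:
            v1[rng.random(n) < config.trait_missing_rate] = np.nan
            v2[rng.random(n) < config.trait_missing_rate] = np.nan
        trait_cols[f"{spec.name}_v1"] = v1
        trait_cols[f"{spec.name}_v2"] = v2
        truth_effects[spec.name] = {"carrier": spec.carrier_effect,
                                    "protective": spec.protective_effect,
                                    "sd": spec.sd}

    # ---- founder region haplotypes for carriers
    carrier_rows = np.nonzero(carrier == 1)[0]
    carrier_ids = [ids[i] for i in carrier_rows]
    n_car = len(carrier_ids)
    n_recomb = int(round(config.recombinant_fraction * n_car))
    region = simulate_founder_region(
        n_car, rng, carrier_ids=carrier_ids, chrom=config.region_chrom,
        index_pos=config.index_pos, n_variants=config.n_region_variants,
        region_halfspan_bp=config.region_halfspan_bp,
        founder_halfspan_bp=config.founder_halfspan_bp,
        rare_fraction=config.region_rare_fraction,
        recombinants=n_recomb)

    # region genotypes for everyone (two phases; carriers' first phase is the
    # deletion-bearing haplotype)
    r_maf = region.variants["maf"].to_numpy()
    n_reg = len(r_maf)
    hap_a = (rng.random((n, n_reg)) < r_maf[None, :]).astype(np.int8)
    hap_b = (rng.random((n, n_reg)) < r_maf[None, :]).astype(np.int8)
    hap_a[carrier_rows] = region.del_haps
    reg_geno = (hap_a + hap_b).astype(float)

    # ---- assemble the genotype matrix: genome + region + the deletion
    del_dos = alleles.astype(float)
    variants = pd.concat([
        pd.DataFrame({"chrom": chroms, "pos": positions,
                      "ref": "A", "alt": "C", "info": 1.0}),
        region.variants.assign(info=1.0)[["chrom", "pos", "ref", "alt", "info"]],
        pd.DataFrame({"chrom": [config.region_chrom], "pos": [config.index_pos],
                      "ref": ["CAGA"], "alt": ["C"], "info": [1.0]}),
    ], ignore_index=True)
    dosage = np.column_stack([gen_geno, reg_geno, del_dos[:, None]])
    if config.dosage_noise_sd > 0:
        noise = rng.normal(0, config.dosage_noise_sd, dosage.shape)
        dosage = np.clip(dosage + noise, 0, 2)
    # sort region+deletion columns by position on chromosome 6
    chr6 = variants["chrom"] == config.region_chrom
    chr6_order = variants.loc[chr6, "pos"].argsort(kind="stable")
    new_cols = np.concatenate([np.nonzero(~chr6.to_numpy())[0],
                               np.nonzero(chr6.to_numpy())[0][chr6_order]])
    variants = variants.iloc[new_cols].reset_index(drop=True)
    dosage = dosage[:, new_cols]
    deletion_index = int(np.nonzero(
        (variants["chrom"] == config.region_chrom).to_numpy()
        & (variants["pos"] == config.index_pos).to_numpy())[0][0])
    genotypes = GenotypeMatrix(samples=ids, variants=variants, dosage=dosage)

    weights = WeightTable(pd.DataFrame({
        "chrom": chroms[pgs_idx], "pos": positions[pgs_idx],
        "effect_allele": "C", "other_allele": "A",
        "weight": w[pgs_idx],
    }).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True))

    participants = pd.DataFrame({
        "age": age, "sex": np.where(female, "female", "male"),
        "family_id": fam["family_id"].to_numpy(), "carrier": carrier,
        "cause_of_death": cod,
    }, index=pd.Index(ids, name="participant_id"))
    traits = pd.DataFrame(trait_cols, index=participants.index)
    pedigree = fam[["family_id", "participant_id", "father", "mother",
                    "sex_code"]].copy()
    pedigree["phenotype"] = -9
    cohort = Cohort(participants=participants, traits=traits, flags=flags,
                    pedigree=pedigree)

    truth = SimTruth(
        trait_effects=truth_effects,
        penetrance={"intercept": float(intercept), "age_slope": slope,
                    "carrier_log_or": config.carrier_log_or,
                    "background_prevalence": prev},
        founder_span_bp=region.founder_span_bp,
        shared_span_bp=region.shared_span_bp,
        recombinants={str(region.carrier_ids[r]): list(span)
                      for r, span in region.recombinant_rows.items()},
        carrier_ids=carrier_ids,
        family_of=dict(zip(ids, fam["family_id"].tolist())),
        pgs_link=(asdict(config.pgs_link) if config.pgs_link else None),
    )
    return SimResult(cohort=cohort, genotypes=genotypes,
                     deletion_index=deletion_index, region=region,
                     weights=weights, pgs_true=pgs_true, truth=truth)


def simulate_correlated_null_traits(cohort: Cohort, n_traits: int,
                                    rng: np.random.Generator,
                                    h2_family: float = 0.4,
                                    n_factors: int = 5,
                                    kinship=None) -> pd.DataFrame:
    """Correlated null traits with family structure, independent of outcome.

    The panel mimics a battery of inter-correlated clinical variables that
    carry familial resemblance but no carrier/symptom signal — the null
    scenario for false-discovery and genomic-control calibration. By
    default the familial component is a household effect (one draw shared
    by the whole family); when a pedigree ``kinship`` matrix is supplied
    the component is instead additive-genetic, u ~ N(0, h2 · 2Φ), the
    covariance the mixed model assumes. Returns visit-1 trait columns
    indexed like the cohort.
    """
    n = cohort.n()
    if kinship is not None:
        if list(kinship.ids) != list(cohort.participants.index):
            raise ValueError("kinship order must match cohort order")
        b_fam = rng.normal(size=(n, n_traits))
        for idx, block in kinship.blocks:
            if len(idx) > 1:
                w, u = np.linalg.eigh(2.0 * block)
                L = u * np.sqrt(np.maximum(w, 0.0))
                b_fam[idx] = L @ rng.normal(size=(len(idx), n_traits))
            else:
                b_fam[idx] *= math.sqrt(2.0 * block[0, 0])
    else:
        fam_codes, fam_uniq = pd.factorize(cohort.participants["family_id"])
        b_fam = rng.normal(size=(len(fam_uniq), n_traits))[fam_codes]
    factors = rng.normal(size=(n, n_factors))
    load = rng.normal(scale=0.5, size=(n_factors, n_traits))
    noise = rng.normal(size=(n, n_traits))
    vals = (factors @ load + math.sqrt(h2_family) * b_fam
            + math.sqrt(1 - h2_family) * noise)
    return pd.DataFrame({f"null{j:03d}_v1": vals[:, j] for j in range(n_traits)},
                        index=cohort.participants.index)


# ---------------------------------------------------------------------------
# analytic power calculators (Wald test on the log odds ratio)


def _wald_power(cells: np.ndarray, log_or: float, alpha: float) -> float:
    if cells.min() < 1:
        warnings.warn("degenerate design: expected cell below 1")
        return float("nan")
    se = math.sqrt(float((1.0 / cells).sum()))
    za = stats.norm.isf(alpha / 2)
    ncp = log_or / se
    return float(stats.norm.sf(za - ncp) + stats.norm.cdf(-za - ncp))


def power_carrier_design(n_total: float, carrier_freq: float,
                         asymptomatic_fraction: float, odds_ratio: float,
                         alpha: float = 0.05) -> float:
    """Power of the carrier-vs-noncarrier symptomatic comparison.

    Two-sided Wald test of the log odds ratio with variance from expected
    2×2 cell counts: carriers are a fraction ``carrier_freq`` of ``n_total``
    and the background symptomatic probability is
    ``1 − asymptomatic_fraction``.
    """
    if min(n_total, carrier_freq, odds_ratio) <= 0 or not 0 < alpha < 1:
        raise ValueError("arguments must be positive with alpha in (0, 1)")
    p0 = 1.0 - asymptomatic_fraction
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    n_car = n_total * carrier_freq
    n_non = n_total - n_car
    cells = np.array([n_car * p1, n_car * (1 - p1),
                      n_non * p0, n_non * (1 - p0)])
    return _wald_power(cells, math.log(odds_ratio), alpha)


def power_gwas(n_case: float, n_control: float, maf: float,
               odds_ratio: float, alpha: float = 5e-8) -> float:
    """Power of a per-allele case/control test at a biallelic variant."""
    if min(n_case, n_control, maf, odds_ratio) <= 0 or not 0 < alpha < 1:
        raise ValueError("arguments must be positive with alpha in (0, 1)")
    p0 = maf
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    cells = np.array([2 * n_case * p1, 2 * n_case * (1 - p1),
                      2 * n_control * p0, 2 * n_control * (1 - p0)])
    return _wald_power(cells, math.log(odds_ratio), alpha)
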