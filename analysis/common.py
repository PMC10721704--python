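"""Shared setup for the numbered analysis drivers.

One study-scale synthetic cohort (seed 2024) is generated by
01_simulate_cohort.py into scratch/data/ and re-read by the later stages,
so the whole pipeline runs off files exactly as it would on real exports.
"""

from pathlib import Path

import pandas as pd

from penescreen.cohort_io import GenotypeMatrix, WeightTable, read_cohort
from penescreen.synthetic import PGSTraitLink

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = ROOT / "scratch" / "data"   # bulky generated inputs, not tracked
SEED = 2024

# study-scale design point: ~74 carriers against a thinned non-carrier pool;
# the QRS polygenic score responds 3x more strongly in symptomatic carriers
SIM_KW = dict(n_individuals=3100, founder_allele_freq=0.0119, seed=SEED,
              n_region_variants=160, n_genome_variants=400,
              n_pgs_variants=150,
              pgs_link=PGSTraitLink(trait="QRS", base_slope=0.4,
                                    group_multipliers={
                                        "symptomatic_carrier": 3.0}))


def load_dataset():
    if not (DATA / "phenotypes.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(DATA / "phenotypes.tsv", DATA / "flags.tsv",
                         DATA / "cohort.fam")
    genotypes = GenotypeMatrix.from_vcf(DATA / "genotypes.vcf")
    weights = WeightTable.read(DATA / "weights.tsv")
    return cohort, genotypes, weights


def covariates(cohort, ids=None, pcs=None):
    part = cohort.participants if ids is None else cohort.participants.loc[ids]
    cov = pd.DataFrame({
        "age": part["age"].astype(float),
        "age2": part["age"].astype(float) ** 2,
        "sex": (part["sex"] == "female").astype(float),
    }, index=part.index)
    if pcs is not None:
        cov = cov.join(pcs.reindex(cov.index))
    return cov
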