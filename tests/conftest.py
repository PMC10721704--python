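import numpy as np
import pandas as pd
import pytest

from penescreen.groups import assign_groups
from penescreen.kinship import pedigree_kinship
from penescreen.synthetic import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """A fast cohort configuration for tests: ~3,100 participants with an
    enriched founder-allele frequency so the carrier groups reach the sizes
    the screen needs (~74 carriers, ~48 of them asymptomatic)."""
    base = dict(n_individuals=3100, founder_allele_freq=0.0119, seed=11,
                n_region_variants=60, n_genome_variants=120,
                n_pgs_variants=40)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def paper_like():
    """One shared simulated cohort + groups + pedigree kinship."""
    res = simulate_cohort(small_config())
    groups = assign_groups(res.cohort)
    kin = pedigree_kinship(res.cohort.pedigree)
    return res, groups, kin


@pytest.fixture()
def tiny_cohort_files(tmp_path):
    """Three-participant fixture files written by hand."""
    (tmp_path / "phenotypes.tsv").write_text(
        "participant_id\tage\tsex\tcarrier\tcause_of_death\tHR_v1\tHR_v2\tQRS_v1\tQRS_v2\n"
        "P1\t50\tmale\t1\tNA\t72\t75\t90\tNA\n"
        "P2\t40\tfemale\t0\tNA\t65\t64\t88\t91\n"
        "P3\t30\tfemale\t0\tNA\tNA\t70\t110\t108\n"
    )
    (tmp_path / "flags.tsv").write_text(
        "participant_id\tHF_v1\tHF_v2\tatrial_fibrillation_v1\tatrial_fibrillation_v2\n"
        "P1\t0\t0\t0\t0\n"
        "P2\t0\t1\t0\t0\n"
        "P3\t0\t0\t1\t0\n"
    )
    (tmp_path / "cohort.fam").write_text(
        "FAM1 P1 0 0 1 -9\nFAM1 P2 0 0 2 -9\nFAM2 P3 0 0 2 -9\n"
    )
    return tmp_path


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


from penescreen.synthetic import simulate_correlated_null_traits


def make_null_traits(cohort, n_traits: int, rng, h2_family: float = 0.4,
                     n_factors: int = 5) -> pd.DataFrame:
    return simulate_correlated_null_traits(cohort, n_traits, rng,
                                           h2_family=h2_family,
                                           n_factors=n_factors)
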