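#!/usr/bin/env python
"""Polygenic scores: group associations and the PGS×group interaction.

Scores participants with the simulated weight table (with and without
chromosome 6, the founder-locus chromosome), tests the score against the
asymptomatic-carrier outcome under the PGS ~ age + sex + outcome model,
and fits the interaction model trait ~ age + sex + group + PGS +
PGS:group for the QRS score.
"""

import pandas as pd
from common import RESULTS, SEED, load_dataset

from penescreen.groups import assign_groups
from penescreen.pgs import pgs_group_assoc, pgs_trait_interaction, score_pgs


def main() -> None:
    cohort, genotypes, weights = load_dataset()
    groups = assign_groups(cohort)
    part = cohort.participants
    covars = pd.DataFrame({"age": part["age"].astype(float),
                           "sex": (part["sex"] == "female").astype(float)},
                          index=part.index)

    full = score_pgs(genotypes, weights)
    no6 = score_pgs(genotypes, weights, exclude_chroms=["6"])
    print(f"scored {full.n_matched} weight variants "
          f"({no6.n_excluded_chrom} on chr6 excluded in the no-chr6 score)")

    sel = groups["group"].isin(["asymptomatic_carrier",
                                "asymptomatic_noncarrier"])
    ids = groups.index[sel]
    outcome = (groups.loc[ids, "group"] == "asymptomatic_carrier").astype(float)
    scores = pd.DataFrame({"PGS_QRS": full.scores["standardized"],
                           "PGS_QRS_no_chr6": no6.scores["standardized"]})
    assoc = pgs_group_assoc(scores, covars.loc[ids], outcome, B=1000,
                            seed=SEED)
    assoc.to_csv(RESULTS / "pgs_group_assoc.tsv", sep="\t")
    print("\ngroup association (percentile coding):")
    print(assoc.round(4).to_string())

    inter = pgs_trait_interaction(cohort.trait("QRS"),
                                  full.scores["standardized"], groups, covars)
    inter.interactions.to_csv(RESULTS / "pgs_interaction.tsv", sep="\t")
    print("\nPGS_QRS x group interaction terms:")
    print(inter.interactions.round(5).to_string())
    print("\nper-group partial correlation of PGS_QRS and QRS:")
    for g, r in sorted(inter.partial_corr.items()):
        print(f"  {g}: {r:.3f}")


if __name__ == "__main__":
    main()
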