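"""Polygenic scores: computation, group association and trait interaction.

A polygenic score (PGS) is the weighted sum of effect-allele dosages over a
weight table produced upstream (e.g. shrinkage-adjusted GWAS summary
statistics). Scores are standardized within the cohort and expressed as
percentiles; extreme-tail codings (above the 80th / below the 20th
percentile) probe non-linear effects. Group associations use the linear
model  PGS ~ age + sex + outcome; multiplicity across the score panel is
handled with the same pooled-permutation q-values as the trait screen.
Chromosome exclusion (e.g. dropping chromosome 6) separates genuine
polygenic signal from variants tagging the founder haplotype.

The interaction analysis asks whether a score predicts its own trait
differently per carrier/symptom group:
trait ~ age + sex + group + PGS + PGS:group, with per-group partial
correlations (trait and PGS residualized on age and sex) describing the
fitted surface, and a rank-normalized refit as sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GenotypeMatrix, WeightTable
from .kinship import ols_outcome_stats
from .screen import empirical_q, rank_normalize

__all__ = [
    "PGSProfile",
    "score_pgs",
    "pgs_group_assoc",
    "pgs_trait_interaction",
    "pgs_severity_trend",
    "InteractionResult",
]

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class PGSProfile:
    """Per-participant score panel plus the variant-matching audit trail."""

    scores: pd.DataFrame      # raw, standardized, percentile, high20, low20
    n_matched: int
    n_dropped_palindromic: int
    n_excluded_chrom: int
    excluded_chroms: list[str] = field(default_factory=list)


def score_pgs(genotypes: GenotypeMatrix, weights: WeightTable,
              exclude_chroms: list[str] | None = None) -> PGSProfile:
    """Weighted allele-dosage score for every participant.

    Weight variants are matched to genotype variants on (chrom, pos) with
    allele orientation resolved: when the effect allele is the genotype's
    ALT the dosage enters directly, when it is the REF the complementary
    dosage (2 − DS) is used. Strand-ambiguous palindromic variants (A/T,
    C/G) are dropped. Raises when no variant matches (including when every
    chromosome is excluded), listing the failures.
    """
    exclude = set(map(str, exclude_chroms or []))
    gv = genotypes.variants
    lookup = {(str(c), int(p)): j for j, (c, p)
              in enumerate(zip(gv["chrom"], gv["pos"]))}
    raw = np.zeros(len(genotypes.samples))
    n_matched = n_pal = n_excl = 0
    failures = []
    for row in weights.table.itertuples(index=False):
        if str(row.chrom) in exclude:
            n_excl += 1
            continue
        if {row.effect_allele, row.other_allele} in _PALINDROMIC:
            n_pal += 1
            continue
        j = lookup.get((str(row.chrom), int(row.pos)))
        if j is None:
            failures.append(f"{row.chrom}:{row.pos} not genotyped")
            continue
        ref, alt = gv["ref"].iloc[j], gv["alt"].iloc[j]
        dos = genotypes.dosage[:, j]
        if np.isnan(dos).any():  # mean-impute sporadic missing dosages
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        if (row.effect_allele, row.other_allele) == (alt, ref):
            raw += row.weight * dos
        elif (row.effect_allele, row.other_allele) == (ref, alt):
            raw += row.weight * (2.0 - dos)
        else:
            failures.append(f"{row.chrom}:{row.pos} allele mismatch "
                            f"({row.effect_allele}/{row.other_allele} vs "
                            f"{ref}/{alt})")
            continue
        n_matched += 1
    if n_matched == 0:
        raise ValueError(
            "no weight variants matched the genotypes: "
            + ("; ".join(failures[:10]) if failures else
               "all excluded or palindromic"))
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    ranks = stats.rankdata(std, method="average")
    pct = 100.0 * (ranks - 0.5) / len(ranks)
    scores = pd.DataFrame({
        "raw": raw, "standardized": std, "percentile": pct,
        "high20": (pct > 80).astype(int), "low20": (pct < 20).astype(int),
    }, index=pd.Index(genotypes.samples, name="participant_id"))
    return PGSProfile(scores=scores, n_matched=n_matched,
                      n_dropped_palindromic=n_pal, n_excluded_chrom=n_excl,
                      excluded_chroms=sorted(exclude))


# ---------------------------------------------------------------------------
# group association (PGS ~ age + sex + outcome)




def pgs_group_assoc(scores: pd.DataFrame, covars: pd.DataFrame,
                    outcome: pd.Series, mode: str = "percentile",
                    B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Association of each score with group membership (outcome last).

    ``scores`` holds one standardized score per column (participants ×
    scores); ``mode`` codes the response as the continuous percentile or as
    the extreme-tail indicator (``high20`` / ``low20``). Empirical q-values
    come from pooling B per-score permutations of the response. Constant
    scores are skipped.
    """
    if mode not in ("percentile", "high20", "low20"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = covars.index
    out = outcome.reindex(ids).to_numpy(dtype=float)
    if not ((out == 0) | (out == 1)).all() or len(np.unique(out)) < 2:
        raise ValueError("outcome must be 0/1 with both groups non-empty")
    X = np.column_stack([np.ones(len(ids)),
                         covars.to_numpy(dtype=float), out])
    rng = np.random.default_rng(seed)
    kept, resp = [], []
    for name in scores.columns:
        s = scores[name].reindex(ids).to_numpy(dtype=float)
        if np.std(s) == 0:
            continue
        ranks = stats.rankdata(s, method="average")
        pct = 100.0 * (ranks - 0.5) / len(ranks)
        if mode == "percentile":
            resp.append(pct)
        elif mode == "high20":
            resp.append((pct > 80).astype(float))
        else:
            resp.append((pct < 20).astype(float))
        kept.append(name)
    if not kept:
        raise ValueError("no non-constant scores")
    Y = np.column_stack(resp)
    beta, se, p = ols_outcome_stats(Y, X)
    pooled = np.empty((Y.shape[1], B))
    for j in range(Y.shape[1]):
        perms = np.empty((len(ids), B))
        col = Y[:, j]
        for b in range(B):
            perms[:, b] = rng.permutation(col)
        _b, _s, pp = ols_outcome_stats(perms, X)
        pooled[j] = pp
    q = empirical_q(p, pooled.ravel(), B)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "q": q},
                        index=pd.Index(kept, name="score"))


# ---------------------------------------------------------------------------
# PGS × group interaction


@dataclass
class InteractionResult:
    interactions: pd.DataFrame     # per non-reference group
    partial_corr: dict[str, float]
    model_spec: dict
    nobs: int


def pgs_trait_interaction(trait: pd.Series, pgs: pd.Series,
                          groups: pd.DataFrame, covars: pd.DataFrame,
                          ref_group: str = "asymptomatic_noncarrier",
                          include_age_sex_interactions: bool = False,
                          min_group: int = 3) -> InteractionResult:
    """Does the score predict its trait differently per group?

    Fits trait ~ age + sex + group + PGS + PGS:group (reference group =
    asymptomatic non-carrier) by OLS and Wald-tests each PGS:group term;
    optional PGS:age and PGS:sex terms are available behind a flag. Groups
    below ``min_group`` members are reported untestable. Also returns the
    per-group partial correlation between PGS and trait (both residualized
    on age + sex) and the rank-normal sensitivity p-values.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "trait": trait, "pgs": pgs,
        "age": covars["age"], "sex": covars["sex"],
        "group": groups["group"],
    }).dropna()
    sizes = df["group"].value_counts()
    if sizes.get(ref_group, 0) < min_group:
        raise ValueError(f"reference group {ref_group} below {min_group}")
    testable = [g for g in sizes.index
                if g != ref_group and sizes[g] >= min_group]
    small = [g for g in sizes.index
             if g != ref_group and sizes[g] < min_group]
    dfit = df[df["group"].isin(testable + [ref_group])].copy()

    terms = "age + sex + C(group, Treatment('%s'))" % ref_group
    formula = (f"trait ~ {terms} + pgs + pgs:C(group, Treatment('{ref_group}'))")
    if include_age_sex_interactions:
        formula += " + pgs:age + pgs:sex"
    fit = smf.ols(formula, data=dfit).fit()
    dfit_rn = dfit.assign(trait=rank_normalize(dfit["trait"]))
    fit_rn = smf.ols(formula, data=dfit_rn).fit()

    rows = []
    for g in testable:
        term = f"pgs:C(group, Treatment('{ref_group}'))[T.{g}]"
        rows.append((g, fit.params[term], fit.bse[term], fit.pvalues[term],
                     fit_rn.pvalues[term], False))
    for g in small:
        rows.append((g, np.nan, np.nan, np.nan, np.nan, True))
    inter = pd.DataFrame(rows, columns=["group", "beta", "se", "p",
                                        "p_rank_normal", "untestable"]
                         ).set_index("group")

    pcorr = {}
    for g, sub in df.groupby("group"):
        if len(sub) < min_group + 2:
            pcorr[g] = np.nan
            continue
        sex_num = (sub["sex"].astype(str) == "female").astype(float) \
            if sub["sex"].dtype == object else sub["sex"].astype(float)
        Z = np.column_stack([np.ones(len(sub)), sub["age"], sex_num])
        rt = sub["trait"] - Z @ np.linalg.lstsq(Z, sub["trait"], rcond=None)[0]
        rp = sub["pgs"] - Z @ np.linalg.lstsq(Z, sub["pgs"], rcond=None)[0]
        pcorr[g] = float(np.corrcoef(rt, rp)[0, 1])

    return InteractionResult(
        interactions=inter, partial_corr=pcorr,
        model_spec={"formula": formula, "reference": ref_group,
                    "age_sex_interactions": include_age_sex_interactions},
        nobs=int(fit.nobs))


def pgs_severity_trend(pgs: pd.Series, n_signs: pd.Series):
    """Spearman trend of the score against the count of signs/symptoms
    among symptomatic carriers. Returns (rho, p)."""
    df = pd.DataFrame({"pgs": pgs, "n": n_signs}).dropna()
    if len(df) < 3:
        return float("nan"), float("nan")
    res = stats.spearmanr(df["pgs"], df["n"])
    return float(res.statistic), float(res.pvalue)
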