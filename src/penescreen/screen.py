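"""Two-step screen for factors associated with absence of symptoms.

Step 1 compares each quantitative trait between asymptomatic carriers
(outcome = 1) and asymptomatic non-carriers (outcome = 0) with the kinship
mixed model, adjusting for age, age², sex and genetic PCs. Multiplicity
across the correlated trait panel is handled with empirical q-values from a
pooled permutation null: each trait's values are shuffled across
participants while kinship, PCs, covariates and carrier status stay
attached to the participant, the model is refitted, and all permuted
p-values are pooled into one null distribution.

Step 2 re-tests the step-1 hits in the two confirmatory contrasts. A hit is
"confirmed" as a candidate protective factor when the asymptomatic-vs-
symptomatic-carrier contrast shows the same direction of effect as step 1
while the symptomatic-carrier-vs-asymptomatic-noncarrier contrast shows no
difference or the opposite direction — the pattern that rules out a direct
effect of the variant itself on the trait.

Sensitivity analyses: rank-based inverse-normal transformation of the
trait (Blom offset) and a 1:4 age- and sex-matched control subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .kinship import KinshipMatrix, KinshipEigen, fit_lmm_batch

__all__ = [
    "ScreenDesign",
    "ScreenResult",
    "build_design",
    "run_step1",
    "permutation_q",
    "empirical_q",
    "confirm_directions",
    "rank_normalize",
    "match_controls",
    "run_screen",
]


# ---------------------------------------------------------------------------
# design


@dataclass
class ScreenDesign:
    """Fixed block of the screen: participants, covariates and outcome.

    Everything that stays linked to the participant during permutations
    (kinship, PCs, age, sex, carrier/outcome coding) lives here; only the
    trait vector is ever shuffled.
    """

    ids: list[str]
    X: np.ndarray           # intercept + covariates + outcome (last column)
    names: list[str]
    kinship: KinshipMatrix
    _eigen_cache: dict = field(default_factory=dict, repr=False)

    def eigen_for(self, mask: np.ndarray) -> tuple[KinshipEigen, np.ndarray]:
        key = mask.tobytes()
        if key not in self._eigen_cache:
            sub_ids = [self.ids[i] for i in np.nonzero(mask)[0]]
            self._eigen_cache[key] = KinshipEigen(self.kinship, subset_ids=sub_ids)
        return self._eigen_cache[key], self.X[mask]


def build_design(covars: pd.DataFrame, outcome: pd.Series,
                 kinship: KinshipMatrix) -> ScreenDesign:
    """Assemble the fixed design block aligned to ``covars``' index."""
    ids = list(covars.index.astype(str))
    X = np.column_stack([np.ones(len(ids)), covars.to_numpy(dtype=float),
                         outcome.reindex(covars.index).to_numpy(dtype=float)])
    names = ["intercept"] + list(covars.columns) + ["outcome"]
    return ScreenDesign(ids=ids, X=X, names=names,
                        kinship=kinship.subset(ids))


def _screen_covars(cohort: Cohort, covars: pd.DataFrame | None,
                   ids: pd.Index) -> pd.DataFrame:
    """Default covariate block: age, age², sex plus any supplied PC columns."""
    part = cohort.participants.loc[ids]
    base = pd.DataFrame({
        "age": part["age"].astype(float),
        "age2": part["age"].astype(float) ** 2,
        "sex": (part["sex"] == "female").astype(float),
    }, index=ids)
    if covars is not None:
        base = base.join(covars.reindex(ids).astype(float))
    return base


def _design_for_contrast(cohort: Cohort, groups: pd.DataFrame,
                         kinship: KinshipMatrix, one: str, zero: str,
                         covars: pd.DataFrame | None) -> ScreenDesign:
    sel = groups["group"].isin([one, zero])
    ids = groups.index[sel]
    outcome = (groups.loc[ids, "group"] == one).astype(float)
    return build_design(_screen_covars(cohort, covars, ids), outcome, kinship)


# ---------------------------------------------------------------------------
# step 1


def _fit_columns(design: ScreenDesign, Y: np.ndarray, mask: np.ndarray):
    eig, Xm = design.eigen_for(mask)
    return fit_lmm_batch(Y[mask], Xm, eig)


def run_step1(cohort: Cohort, groups: pd.DataFrame, kinship: KinshipMatrix,
              traits: list[str] | None = None,
              covars: pd.DataFrame | None = None, visit: int = 1,
              design: ScreenDesign | None = None) -> pd.DataFrame:
    """Per-trait mixed-model comparison of the step-1 groups.

    Returns a DataFrame indexed by trait with beta (effect of being an
    asymptomatic carrier), SE, p and the complete-case n. Traits without
    variance in the analysis subset are skipped with a warning.
    """
    if design is None:
        design = _design_for_contrast(cohort, groups, kinship,
                                      "asymptomatic_carrier",
                                      "asymptomatic_noncarrier", covars)
    traits = traits or cohort.trait_names()
    rows = []
    for trait in traits:
        y = cohort.trait(trait, visit).reindex(design.ids).to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(design.X).all(axis=1)
        if np.nanstd(y[mask]) == 0:
            warnings.warn(f"trait {trait} has no variance; skipped")
            continue
        beta, se, p, gamma = _fit_columns(design, y[:, None], mask)
        rows.append((trait, float(beta[0]), float(se[0]), float(p[0]),
                     float(gamma[0]), int(mask.sum())))
    return pd.DataFrame(rows, columns=["trait", "beta", "se", "p", "gamma",
                                       "n"]).set_index("trait")


# ---------------------------------------------------------------------------
# permutation q-values


def empirical_q(p_obs: np.ndarray, p_perm_pool: np.ndarray, B: int
                ) -> np.ndarray:
    """Pooled-null empirical q-values.

    For each observed p: q = (mean permutation count of p-values at or below
    it) / (observed count at or below it), with a zero pooled count replaced
    by one to avoid q = 0, then monotonized by a running maximum from the
    smallest observed p and capped at 1.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    pool = np.sort(np.asarray(p_perm_pool, dtype=float))
    order = np.argsort(p_obs, kind="stable")
    q = np.empty_like(p_obs)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        exceed = np.searchsorted(pool, p_obs[i], side="right")
        mean_null = max(exceed, 1) / B
        running = max(running, mean_null / rank)
        q[i] = min(running, 1.0)
    return q


def permutation_q(cohort: Cohort, design: ScreenDesign,
                  traits: list[str], B: int = 1000, seed: int = 0,
                  visit: int = 1, step1: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Attach pooled-permutation empirical q-values to the step-1 p-values.

    Only the trait vector is permuted (within its non-missing subset); the
    fixed block — kinship, covariates, outcome — stays linked to the
    participants. The same grid-REML fitter produces observed and permuted
    statistics, so the two are exchangeable under the null.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    if step1 is None:
        step1 = run_step1(cohort, None, None, traits=traits, design=design)
    pooled = []
    for trait in sorted(traits):  # trait-order invariance: canonical order
        y = cohort.trait(trait, visit).reindex(design.ids).to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(design.X).all(axis=1)
        vals = y[mask]
        perms = np.empty((mask.sum(), B))
        for b in range(B):
            perms[:, b] = rng.permutation(vals)
        ym = np.full((len(y), B), np.nan)
        ym[mask] = perms
        _beta, _se, p, _g = _fit_columns(design, ym, mask)
        pooled.append(p)
    pooled = np.concatenate(pooled)
    if pooled.size == 0:
        raise ValueError("empty pooled permutation null")
    out = step1.copy()
    out["q"] = empirical_q(out["p"].to_numpy(), pooled, B)
    return out


# ---------------------------------------------------------------------------
# step 2: directional confirmation


def confirm_directions(hits: pd.DataFrame, cohort: Cohort,
                       groups: pd.DataFrame, kinship: KinshipMatrix,
                       covars: pd.DataFrame | None = None, visit: int = 1,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Re-test step-1 hits in the two confirmatory contrasts.

    ``hits`` is the (subset of the) step-1 table for significant traits.
    Verdict "confirmed" requires a same-sign effect when comparing
    asymptomatic to symptomatic carriers AND an opposite-sign or
    non-significant (p > alpha) effect when comparing symptomatic carriers
    to asymptomatic non-carriers. Contrasts with a group below 2 members are
    "untestable".
    """
    if len(hits) == 0:
        raise ValueError("no step-1 hits to confirm")
    counts = groups["group"].value_counts()
    testable = (counts.get("symptomatic_carrier", 0) >= 2
                and counts.get("asymptomatic_carrier", 0) >= 2)
    rows = []
    if testable:
        d_carrier = _design_for_contrast(cohort, groups, kinship,
                                         "asymptomatic_carrier",
                                         "symptomatic_carrier", covars)
        d_cross = _design_for_contrast(cohort, groups, kinship,
                                       "symptomatic_carrier",
                                       "asymptomatic_noncarrier", covars)
    for trait, row in hits.iterrows():
        if not testable:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan, "untestable"))
            continue
        res = []
        for d in (d_carrier, d_cross):
            y = cohort.trait(trait, visit).reindex(d.ids).to_numpy(dtype=float)
            mask = np.isfinite(y) & np.isfinite(d.X).all(axis=1)
            beta, se, p, _g = _fit_columns(d, y[:, None], mask)
            res.append((float(beta[0]), float(p[0])))
        (b_car, p_car), (b_cross, p_cross) = res
        same_dir = np.sign(b_car) == np.sign(row["beta"])
        cross_ok = (np.sign(b_cross) != np.sign(row["beta"])) or (p_cross > alpha)
        verdict = "confirmed" if (same_dir and cross_ok) else "not_confirmed"
        rows.append((trait, b_car, p_car, b_cross, p_cross, verdict))
    return pd.DataFrame(rows, columns=[
        "trait", "beta_asympt_vs_sympt_carrier", "p_asympt_vs_sympt_carrier",
        "beta_sympt_carrier_vs_asympt_noncarrier",
        "p_sympt_carrier_vs_asympt_noncarrier", "verdict",
    ]).set_index("trait")


# ---------------------------------------------------------------------------
# sensitivity tools


def rank_normalize(values) -> np.ndarray | pd.Series:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks r (average rank for ties) to Φ⁻¹((r − 3/8)/(n + 1/4)) over
    the n non-missing values; missing values stay missing. Raises on
    degenerate input (all values equal).
    """
    is_series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    vals = arr[mask]
    if len(vals) < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.ptp(vals) == 0:
        raise ValueError("all values equal; ranks are degenerate")
    ranks = stats.rankdata(vals, method="average")
    out = np.full_like(arr, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.375) / (len(vals) + 0.25))
    if is_series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 4
                   ) -> list[str]:
    """Age- and sex-matched controls, ``ratio`` per case, without replacement.

    ``cases`` and ``pool`` are indexed by participant_id with ``age`` and
    ``sex`` columns. Cases are processed in order of fewest eligible
    (same-sex) pool members first; each takes its ``ratio`` nearest-age
    matches (ties broken by smaller ID). Raises when any sex stratum of the
    pool is too small, listing the shortfall.
    """
    short = []
    for sex, grp in cases.groupby("sex"):
        need = ratio * len(grp)
        have = int((pool["sex"] == sex).sum())
        if have < need:
            short.append(f"{sex}: need {need}, have {have}")
    if short:
        raise ValueError("insufficient matching pool — " + "; ".join(short))

    eligible = {sex: int((pool["sex"] == sex).sum())
                for sex in cases["sex"].unique()}
    order = sorted(cases.index, key=lambda i: (eligible[cases.at[i, "sex"]],
                                               str(i)))
    available = pool.copy()
    chosen: list[str] = []
    for cid in order:
        sex = cases.at[cid, "sex"]
        age = cases.at[cid, "age"]
        cand = available[available["sex"] == sex]
        dist = (cand["age"] - age).abs()
        pick = dist.to_frame("d").assign(id=dist.index.astype(str)) \
                   .sort_values(["d", "id"], kind="stable").index[:ratio]
        chosen.extend(map(str, pick))
        available = available.drop(index=pick)
    return chosen


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ScreenResult:
    step1: pd.DataFrame          # beta, se, p, q per trait
    hits: list[str]
    step2: pd.DataFrame | None
    sensitivity_rank: pd.DataFrame | None = None
    sensitivity_matched: pd.DataFrame | None = None


def run_screen(cohort: Cohort, groups: pd.DataFrame, kinship: KinshipMatrix,
               covars: pd.DataFrame | None = None,
               traits: list[str] | None = None, B: int = 1000, seed: int = 0,
               q_threshold: float = 0.05, visit: int = 1,
               sensitivity: bool = False) -> ScreenResult:
    """Run the full two-step screen and, optionally, the sensitivity re-runs."""
    traits = traits or cohort.trait_names()
    design = _design_for_contrast(cohort, groups, kinship,
                                  "asymptomatic_carrier",
                                  "asymptomatic_noncarrier", covars)
    step1 = run_step1(cohort, groups, kinship, traits=traits, design=design,
                      visit=visit)
    step1 = permutation_q(cohort, design, list(step1.index), B=B, seed=seed,
                          visit=visit, step1=step1)
    hits = list(step1.index[step1["q"] <= q_threshold])
    step2 = None
    if hits:
        step2 = confirm_directions(step1.loc[hits], cohort, groups, kinship,
                                   covars, visit=visit)
    sens_rank = None
    if sensitivity and hits:
        normed = cohort.traits.copy()
        for t in hits:
            normed[f"{t}_v{visit}"] = rank_normalize(cohort.trait(t, visit))
        norm_cohort = Cohort(participants=cohort.participants, traits=normed,
                             flags=cohort.flags, pedigree=cohort.pedigree)
        sens_rank = run_step1(norm_cohort, groups, kinship, traits=hits,
                              design=design, visit=visit)
    sens_matched = None
    if sensitivity and hits:
        gi = groups["group"]
        case_ids = gi.index[gi == "asymptomatic_carrier"]
        pool_ids = gi.index[gi == "asymptomatic_noncarrier"]
        part = cohort.participants
        controls = match_controls(part.loc[case_ids, ["age", "sex"]],
                                  part.loc[pool_ids, ["age", "sex"]])
        keep = list(map(str, case_ids)) + controls
        sub = groups.loc[keep]
        d = _design_for_contrast(cohort, sub, kinship,
                                 "asymptomatic_carrier",
                                 "asymptomatic_noncarrier",
                                 covars.reindex(keep) if covars is not None
                                 else None)
        sens_matched = run_step1(cohort, sub, kinship, traits=hits, design=d,
                                 visit=visit)
    return ScreenResult(step1=step1, hits=hits, step2=step2,
                        sensitivity_rank=sens_rank,
                        sensitivity_matched=sens_matched)
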