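"""Genome-wide logistic scan, founder-LD confound screen and burden tests.

The scan compares asymptomatic carriers (cases) with asymptomatic
non-carriers (controls) on an unrelated subset, one variant at a time, with
logit(outcome) ~ age + sex + PC1 + dosage. Group-specific MAF filters
(cases > 0.1, controls > 0.05) and an imputation-quality filter
(INFO > 0.4) are applied first; filtered variants carry a reason code.

Because the founder variant rides on a long shared haplotype, strong
associations can merely tag that haplotype. The LD-confound screen
regresses −log10(p) of the sub-threshold variants on their r² with the
founder variant and flags outliers (externally studentized residual > 3
with r² < 0.1) as independent suggestive signals.

Region-based rare-variant burden tests collapse qualifying minor alleles
into a per-participant count and fit the same logistic model; severe
case/control imbalance makes the asymptotic p anticonservative, so the
reported p is calibrated by label permutations of a covariate-adjusted
score statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GenotypeMatrix, allele_frequency
from .kinship import fit_logistic

__all__ = [
    "ScanResult",
    "RegionResult",
    "gwas_scan",
    "ld_confound_screen",
    "burden_test",
    "gene_regions",
]


# ---------------------------------------------------------------------------
# batched per-variant logistic fits


def _logistic_scan_batch(Xc: np.ndarray, G: np.ndarray, y: np.ndarray,
                         max_iter: int = 25, tol: float = 1e-8):
    """Newton fits of y ~ Xc + g for every column g of G simultaneously."""
    n, pc = Xc.shape
    M = G.shape[1]
    p = pc + 1
    null = fit_logistic(y, Xc)
    beta = np.zeros((p, M))
    beta[:pc] = null.beta[:, None]
    active = np.ones(M, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        Ga = G[:, idx]
        Ba = beta[:, idx]
        eta = np.clip(Xc @ Ba[:pc] + Ga * Ba[pc], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        resid = y[:, None] - mu
        grad_top = Xc.T @ resid                     # (pc, m)
        grad_bot = np.einsum("nm,nm->m", Ga, resid)
        A = np.einsum("np,nm,nq->mpq", Xc, w, Xc)
        b_vec = np.einsum("np,nm,nm->mp", Xc, w, Ga)
        c = np.einsum("nm,nm,nm->m", Ga, w, Ga)
        H = np.empty((len(idx), p, p))
        H[:, :pc, :pc] = A
        H[:, :pc, pc] = b_vec
        H[:, pc, :pc] = b_vec
        H[:, pc, pc] = c
        g_full = np.concatenate([grad_top, grad_bot[None, :]], axis=0).T
        try:
            step = np.linalg.solve(H, g_full[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(H[i], g_full[i], rcond=None)[0]
                             for i in range(len(idx))])
        beta[:, idx] += step.T
        done = np.max(np.abs(step), axis=1) < tol
        active[idx[done]] = False
    converged = ~active
    # standard errors from the final Hessian
    eta = np.clip(Xc @ beta[:pc] + G * beta[pc], -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    A = np.einsum("np,nm,nq->mpq", Xc, w, Xc)
    b_vec = np.einsum("np,nm,nm->mp", Xc, w, G)
    c = np.einsum("nm,nm,nm->m", G, w, G)
    H = np.empty((M, p, p))
    H[:, :pc, :pc] = A
    H[:, :pc, pc] = b_vec
    H[:, pc, :pc] = b_vec
    H[:, pc, pc] = c
    se = np.full(M, np.nan)
    for i in range(M):
        try:
            se[i] = np.sqrt(np.linalg.inv(H[i])[p - 1, p - 1])
        except np.linalg.LinAlgError:
            pass
    return beta[pc], se, converged


@dataclass
class ScanResult:
    """Per-variant association records of the genome-wide scan."""

    table: pd.DataFrame

    def tested(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "tested"]

    def skip_counts(self) -> dict[str, int]:
        skipped = self.table[self.table["status"] != "tested"]
        return skipped["status"].value_counts().to_dict()


def gwas_scan(genotypes: GenotypeMatrix, outcome: pd.Series,
              covars: pd.DataFrame, founder_dosage: np.ndarray | None = None,
              maf_case_min: float = 0.1, maf_control_min: float = 0.05,
              info_min: float = 0.4, chunk: int = 512) -> ScanResult:
    """Per-variant logistic scan on the (already unrelated) analysis subset.

    ``outcome`` (0/1) and ``covars`` are indexed by participant_id matching
    ``genotypes.samples`` order after reindexing; ``founder_dosage``
    supplies the founder-variant dosages for the r² column.
    """
    ids = pd.Index(genotypes.samples)
    y = outcome.reindex(ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome missing for some genotyped samples")
    if int(y.sum()) < 2:
        raise ValueError("fewer than 2 cases; aborting scan")
    Xc = np.column_stack([np.ones(len(ids)),
                          covars.reindex(ids).to_numpy(dtype=float)])
    D = genotypes.dosage
    case = y == 1
    maf_case = allele_frequency(D, subset=case)
    maf_ctrl = allele_frequency(D, subset=~case)
    info = genotypes.variants["info"].to_numpy(dtype=float)

    status = np.full(len(info), "tested", dtype=object)
    status[~(maf_case > maf_case_min)] = "carrier-MAF"
    status[(status == "tested") & ~(maf_ctrl > maf_control_min)] = "control-MAF"
    status[(status == "tested") & ~(info > info_min)] = "INFO"

    out = genotypes.variants.copy()
    out["maf_case"] = maf_case
    out["maf_control"] = maf_ctrl
    out["status"] = status
    out["beta"] = np.nan
    out["se"] = np.nan
    out["p"] = np.nan
    out["OR"] = np.nan
    out["r2_founder"] = np.nan
    if founder_dosage is not None:
        fd = np.asarray(founder_dosage, dtype=float)
        with np.errstate(invalid="ignore"):
            sd = D.std(axis=0)
            ok = (sd > 0) & (fd.std() > 0)
            r = np.zeros(D.shape[1])
            if ok.any():
                Dc = D[:, ok] - D[:, ok].mean(axis=0)
                fc = fd - fd.mean()
                r[ok] = (Dc.T @ fc) / (len(fd) * sd[ok] * fd.std())
            out["r2_founder"] = r ** 2

    test_idx = np.nonzero(status == "tested")[0]
    for start in range(0, len(test_idx), chunk):
        cols = test_idx[start:start + chunk]
        G = np.nan_to_num(D[:, cols], nan=0.0)
        beta, se, conv = _logistic_scan_batch(Xc, G, y)
        out.iloc[cols, out.columns.get_loc("beta")] = beta
        out.iloc[cols, out.columns.get_loc("se")] = se
        p = 2 * stats.norm.sf(np.abs(beta / se))
        sep = (~conv) | (np.abs(beta) > 15) | ~np.isfinite(se)
        p[sep] = np.nan
        out.iloc[cols, out.columns.get_loc("p")] = p
        out.iloc[cols, out.columns.get_loc("OR")] = np.exp(beta)
        bad = np.nonzero(sep)[0]
        if len(bad):
            col = out.columns.get_loc("status")
            out.iloc[cols[bad], col] = "separation"
    return ScanResult(table=out)


# ---------------------------------------------------------------------------
# founder-LD confound screen


def ld_confound_screen(scan: ScanResult | pd.DataFrame, p_max: float = 5e-4,
                       resid_threshold: float = 3.0, r2_max: float = 0.1
                       ) -> pd.DataFrame:
    """Separate founder-haplotype tagging from independent suggestive hits.

    Among variants with p ≤ ``p_max``, −log10(p) is regressed on r² with
    the founder variant; variants lying above the line (externally
    studentized residual > ``resid_threshold``) with low LD
    (r² < ``r2_max``) are flagged "independent_suggestive", all others
    "founder_LD". This operationalizes the visual line-fit inspection as a
    deterministic rule.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    table = scan.table if isinstance(scan, ScanResult) else scan
    sel = table[(table["status"] == "tested") & (table["p"] <= p_max)].copy()
    if len(sel) == 0:
        return sel.assign(flag=pd.Series(dtype=object))
    if len(sel) < 10:
        raise ValueError(f"only {len(sel)} variants below p_max; need >= 10")
    r2 = sel["r2_founder"].to_numpy(dtype=float)
    neglog = -np.log10(sel["p"].to_numpy(dtype=float))
    if np.allclose(r2, 0):
        warnings.warn("all r2 with founder variant are 0; flagging all "
                      "variants independent")
        sel["flag"] = "independent_suggestive"
        return sel
    fit = sm.OLS(neglog, sm.add_constant(r2)).fit()
    resid = OLSInfluence(fit).resid_studentized_external
    sel["ld_resid"] = resid
    sel["flag"] = np.where((resid > resid_threshold) & (r2 < r2_max),
                           "independent_suggestive", "founder_LD")
    return sel


# ---------------------------------------------------------------------------
# region burden tests


def _irls_null(y: np.ndarray, X: np.ndarray, max_iter: int = 20,
               tol: float = 1e-8):
    """Covariate-only logistic fit; returns (mu, w, X'WX⁻¹ pieces)."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        step = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return mu, mu * (1 - mu)


def _score_stat(y: np.ndarray, X: np.ndarray, b: np.ndarray) -> float:
    """Covariate-adjusted score statistic for the burden term."""
    mu, w = _irls_null(y, X)
    U = float(b @ (y - mu))
    wx = X * w[:, None]
    xwx_inv = np.linalg.inv(wx.T @ X)
    bwx = b @ wx
    V = float(b @ (w * b) - bwx @ xwx_inv @ bwx)
    if V <= 0:
        return 0.0
    return U * U / V


@dataclass
class RegionResult:
    region_id: str
    chrom: str
    start: int
    end: int
    maf_tier: float
    n_variants: int
    beta: float
    se: float
    wald_p: float
    perm_p: float
    subregions: pd.DataFrame | None = None


def burden_test(genotypes: GenotypeMatrix, outcome: pd.Series,
                covars: pd.DataFrame, region: tuple[str, int, int],
                maf_tier: float = 0.01, info_min: float = 0.8,
                n_perm: int = 199, seed: int = 0,
                region_id: str | None = None,
                subregion_threshold: float | None = None,
                n_subregions: int = 10) -> RegionResult:
    """Collapsing burden test of a genomic region with permutation p.

    Qualifying variants: inside ``region`` (chrom, start, end; 1-based
    closed), overall MAF ≤ ``maf_tier`` (and > 0), INFO > ``info_min``. The
    burden is each participant's summed minor-allele dosage. The asymptotic
    Wald p from the logistic fit is reported alongside a permutation p from
    ``n_perm`` outcome-label permutations of the covariate-adjusted score
    statistic. When ``subregion_threshold`` is given and the region is
    significant, the region is split into ``n_subregions`` equal-bp
    segments (remainder assigned to the last) and each segment is retested.
    """
    chrom, start, end = region
    ids = pd.Index(genotypes.samples)
    y = outcome.reindex(ids).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(ids)),
                         covars.reindex(ids).to_numpy(dtype=float)])
    v = genotypes.variants
    inside = ((v["chrom"].astype(str) == str(chrom))
              & (v["pos"] >= start) & (v["pos"] <= end)).to_numpy()
    maf = allele_frequency(genotypes.dosage)
    info = v["info"].to_numpy(dtype=float)
    qual = inside & (maf <= maf_tier) & (maf > 0) & (info > info_min)
    rid = region_id or f"{chrom}:{start}-{end}"
    if not qual.any():
        return RegionResult(rid, str(chrom), start, end, maf_tier, 0,
                            np.nan, np.nan, np.nan, np.nan)
    D = np.nan_to_num(genotypes.dosage[:, qual], nan=0.0)
    af = np.nan_to_num(D.mean(axis=0) / 2.0, nan=0.0)
    minor = np.where(af <= 0.5, D, 2.0 - D)
    b = minor.sum(axis=1)

    fit = fit_logistic(y, np.column_stack([X, b]))
    beta, se, wald_p = fit.outcome

    rng = np.random.default_rng(seed)
    t_obs = _score_stat(y, X, b)
    count = 0
    for _ in range(n_perm):
        t = _score_stat(rng.permutation(y), X, b)
        if t >= t_obs - 1e-12:
            count += 1
    perm_p = (1 + count) / (1 + n_perm)

    subs = None
    if subregion_threshold is not None:
        resolution = 1.0 / (n_perm + 1)
        sig_p = perm_p if resolution <= subregion_threshold else wald_p
        if np.isfinite(sig_p) and sig_p < subregion_threshold:
            subs = pd.DataFrame([
                _subregion_row(genotypes, outcome, covars, (chrom, s, e),
                               maf_tier, info_min, n_perm, seed + 1 + k)
                for k, (s, e) in enumerate(
                    tile_region(start, end, n_subregions))
            ])
    return RegionResult(rid, str(chrom), start, end, maf_tier,
                        int(qual.sum()), beta, se, wald_p, perm_p,
                        subregions=subs)


def _subregion_row(genotypes, outcome, covars, region, maf_tier, info_min,
                   n_perm, seed):
    r = burden_test(genotypes, outcome, covars, region, maf_tier=maf_tier,
                    info_min=info_min, n_perm=n_perm, seed=seed)
    return {"chrom": r.chrom, "start": r.start, "end": r.end,
            "n_variants": r.n_variants, "beta": r.beta, "wald_p": r.wald_p,
            "perm_p": r.perm_p}


def tile_region(start: int, end: int, n: int = 10) -> list[tuple[int, int]]:
    """Split [start, end] into n equal-bp segments; remainder goes last."""
    width = (end - start + 1) // n
    if width < 1:
        raise ValueError("region too small to tile")
    edges = [(start + i * width, start + (i + 1) * width - 1) for i in range(n)]
    edges[-1] = (edges[-1][0], end)
    return edges


def gene_regions(genes: pd.DataFrame, flank: int = 50_000) -> pd.DataFrame:
    """Gene ± flank regions from a table with gene, chrom, start, end."""
    out = genes.copy()
    out["region_start"] = np.maximum(out["start"] - flank, 1)
    out["region_end"] = out["end"] + flank
    return out
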