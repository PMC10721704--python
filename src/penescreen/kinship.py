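"""Kinship matrices, genotype PCs, unrelated-subset selection and model fits.

The trait screen adjusts for family structure with a linear mixed model

    y = X beta + u + e,   Var(u) = 2 Phi sigma2_g,   Var(e) = I sigma2_e,

where Phi is the pairwise kinship matrix (phi = 0.5 for self). Pedigree
kinship is block-diagonal by family, so the model is fitted by a one-time
block-wise eigendecomposition of 2 Phi followed by a 1-D profile-REML
optimization of the variance ratio gamma = sigma2_g / sigma2_e; fixed
effects are then tested with Wald statistics. A vectorized batch fitter
evaluates many trait (or permuted-trait) columns against the same design on
a shared gamma grid, which is what makes permutation-based q-values
affordable.

Genome-wide case/control scans instead use a plain logistic model on an
unrelated subset, selected by the same kinship threshold rules the screen
uses (drop the younger of each related pair within group, then drop
controls related to cases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "KinshipEigen",
    "TraitModelFit",
    "LogisticFit",
    "pedigree_kinship",
    "genotype_kinship",
    "genotype_pcs",
    "select_unrelated",
    "fit_lmm",
    "fit_lmm_batch",
    "fit_logistic",
    "inflation_lambda",
]


# ---------------------------------------------------------------------------
# kinship containers


@dataclass
class KinshipMatrix:
    """Block-diagonal pairwise kinship phi (self = 0.5).

    ``blocks`` is a list of ``(row_indices, phi_block)`` pairs covering all
    participants; indices refer to positions in ``ids``. Participants not in
    any multi-member block are unrelated singletons.
    """

    ids: list[str]
    blocks: list[tuple[np.ndarray, np.ndarray]]
    provenance: str = "pedigree"

    def __post_init__(self) -> None:
        for idx, block in self.blocks:
            if not np.allclose(block, block.T):
                raise ValueError("kinship block not symmetric")

    @classmethod
    def from_dense(cls, ids: list[str], phi: np.ndarray,
                   provenance: str = "genotype") -> "KinshipMatrix":
        return cls(ids=list(ids), blocks=[(np.arange(len(ids)), np.asarray(phi))],
                   provenance=provenance)

    def to_dense(self) -> np.ndarray:
        n = len(self.ids)
        out = np.zeros((n, n))
        for idx, block in self.blocks:
            out[np.ix_(idx, idx)] = block
        return out

    def related_pairs(self, threshold: float):
        """Yield (id_i, id_j, phi) for all pairs with phi > threshold."""
        for idx, block in self.blocks:
            m = len(idx)
            for a in range(m):
                for b in range(a + 1, m):
                    if block[a, b] > threshold:
                        yield self.ids[idx[a]], self.ids[idx[b]], block[a, b]

    def subset(self, keep_ids: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        order = [pos[s] for s in keep_ids]
        new_pos = {old: new for new, old in enumerate(order)}
        blocks = []
        for idx, block in self.blocks:
            mask = np.array([i in new_pos for i in idx])
            if not mask.any():
                continue
            sub = np.nonzero(mask)[0]
            blocks.append((np.array([new_pos[idx[i]] for i in sub]),
                           block[np.ix_(sub, sub)]))
        return KinshipMatrix(ids=list(keep_ids), blocks=blocks,
                             provenance=self.provenance)

    def serialize(self, path) -> None:
        """Long-format TSV: id_i, id_j, phi for all within-block pairs."""
        rows = []
        for idx, block in self.blocks:
            for a in range(len(idx)):
                for b in range(a, len(idx)):
                    rows.append((self.ids[idx[a]], self.ids[idx[b]],
                                 block[a, b]))
        pd.DataFrame(rows, columns=["id_i", "id_j", "phi"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def pedigree_kinship(fam: pd.DataFrame) -> KinshipMatrix:
    """Recursive kinship coefficients from a PLINK-style pedigree table.

    ``fam`` needs columns family_id, participant_id, father, mother ("0" =
    unknown/founder parent). Founders are unrelated, phi(self) =
    0.5 (1 + F) with F the parental kinship. Raises if any individual is its
    own ancestor.
    """
    ids = list(fam["participant_id"].astype(str))
    pos = {s: i for i, s in enumerate(ids)}
    blocks = []
    for _fid, grp in fam.groupby("family_id", sort=False):
        members = list(grp["participant_id"].astype(str))
        parents = {r.participant_id: (str(r.father), str(r.mother))
                   for r in grp.itertuples(index=False)}
        order = _topological(members, parents)
        loc = {s: i for i, s in enumerate(order)}
        m = len(order)
        phi = np.zeros((m, m))
        for i, ind in enumerate(order):
            f, mo = parents[ind]
            fi = loc.get(f)
            mi = loc.get(mo)
            phi[i, i] = 0.5 + (0.5 * phi[fi, mi]
                               if fi is not None and mi is not None else 0.0)
            for j in range(i):
                val = 0.0
                if fi is not None:
                    val += 0.5 * phi[fi, j]
                if mi is not None:
                    val += 0.5 * phi[mi, j]
                phi[i, j] = phi[j, i] = val
        blocks.append((np.array([pos[s] for s in order]), phi))
    return KinshipMatrix(ids=ids, blocks=blocks, provenance="pedigree")


def _topological(members: list[str], parents: dict) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}  # 1 = visiting, 2 = done

    def visit(ind: str, stack: tuple) -> None:
        if state.get(ind) == 2:
            return
        if state.get(ind) == 1:
            raise ValueError(f"pedigree cycle: {ind} is its own ancestor")
        state[ind] = 1
        for par in parents.get(ind, ("0", "0")):
            if par in parents:  # parent inside the family table
                visit(par, stack + (ind,))
        state[ind] = 2
        order.append(ind)

    for ind in members:
        visit(ind, ())
    return order


def genotype_kinship(gm: GenotypeMatrix, maf_min: float = 0.01) -> KinshipMatrix:
    """Standardized-GRM kinship estimate (GRM / 2) from dosages."""
    d = np.asarray(gm.dosage, dtype=float)
    p = np.nanmean(d, axis=0) / 2.0
    keep = (np.minimum(p, 1 - p) > maf_min) & np.isfinite(p)
    d = d[:, keep]
    p = p[keep]
    z = (np.nan_to_num(d, nan=0.0) - 2 * p) / np.sqrt(2 * p * (1 - p))
    grm = z @ z.T / z.shape[1]
    return KinshipMatrix.from_dense(gm.samples, grm / 2.0, provenance="genotype")


# ---------------------------------------------------------------------------
# genotype principal components


def genotype_pcs(gm: GenotypeMatrix | np.ndarray, k: int,
                 maf_min: float = 0.01,
                 exclude_chroms: list[str] | None = None) -> pd.DataFrame:
    """First ``k`` PCs of the centered, variance-standardized dosage matrix.

    Constant columns (and columns failing the MAF filter) are dropped with a
    warning. Component signs are fixed by making each component's
    largest-magnitude variant loading positive. ``exclude_chroms`` drops
    whole chromosomes first — standard practice for long-range-LD blocks
    such as a founder-haplotype region, whose internal correlation would
    otherwise hijack the leading components.
    """
    if isinstance(gm, GenotypeMatrix):
        d = np.asarray(gm.dosage, dtype=float)
        if exclude_chroms:
            keep_v = ~gm.variants["chrom"].astype(str).isin(
                set(map(str, exclude_chroms))).to_numpy()
            d = d[:, keep_v]
        index = pd.Index(gm.samples, name="participant_id")
    else:
        d = np.asarray(gm, dtype=float)
        index = pd.RangeIndex(d.shape[0])
    if k == 0:
        return pd.DataFrame(index=index)
    p = np.nanmean(d, axis=0) / 2.0
    sd = np.nanstd(d, axis=0)
    keep = (np.minimum(p, 1 - p) > maf_min) & (sd > 0)
    if keep.sum() < d.shape[1]:
        warnings.warn(f"dropping {int((~keep).sum())} constant/low-MAF variants")
    if keep.sum() < k:
        raise ValueError(f"fewer than k={k} variants after MAF filter")
    z = (d[:, keep] - 2 * p[keep]) / sd[keep]
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=index,
                        columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# unrelated-subset selection


def select_unrelated(kinship: KinshipMatrix, ages: pd.Series,
                     roles: pd.Series, threshold: float = 0.125) -> list[str]:
    """IDs retained after kinship pruning for the unrelated-subset analyses.

    Two rules, applied in order: (1) within each role group, while any kept
    pair has phi > threshold, drop the younger member (age ties drop the
    lexicographically later ID); (2) drop kept controls related to any kept
    case. ``roles`` maps participant_id to 'case' / 'control' (participants
    with other labels are pruned within their own label only). The result is
    invariant to input row order.
    """
    kept = set(kinship.ids)
    pairs = sorted((min(i, j), max(i, j), phi)
                   for i, j, phi in kinship.related_pairs(threshold))
    # (1) within-group pruning
    changed = True
    while changed:
        changed = False
        for i, j, _phi in pairs:
            if i in kept and j in kept and roles.get(i) == roles.get(j):
                ai, aj = ages.get(i), ages.get(j)
                if ai < aj:
                    drop = i
                elif aj < ai:
                    drop = j
                else:
                    drop = max(i, j)
                kept.discard(drop)
                changed = True
    # (2) controls related to cases
    for i, j, _phi in pairs:
        if i in kept and j in kept:
            ri, rj = roles.get(i), roles.get(j)
            if {ri, rj} == {"case", "control"}:
                kept.discard(i if ri == "control" else j)
    return sorted(kept)


# ---------------------------------------------------------------------------
# mixed-model machinery


class KinshipEigen:
    """Block-wise eigendecomposition of 2 Phi on an (optional) row subset."""

    def __init__(self, kinship: KinshipMatrix, subset_ids: list[str] | None = None):
        ids = list(kinship.ids) if subset_ids is None else list(subset_ids)
        if subset_ids is not None:
            kinship = kinship.subset(ids)
        self.ids = ids
        n = len(ids)
        lam = np.zeros(n)
        rotations: list[tuple[np.ndarray, np.ndarray]] = []
        covered = np.zeros(n, dtype=bool)
        for idx, block in kinship.blocks:
            two_phi = 2.0 * block
            if len(idx) == 1:
                lam[idx] = two_phi[0, 0]
            else:
                w, u = np.linalg.eigh(two_phi)
                if w.min() < -1e-8:
                    raise ValueError(
                        "2*kinship not positive semi-definite; consider adding "
                        "a small diagonal jitter")
                lam[idx] = np.maximum(w, 0.0)
                rotations.append((idx, u))
            covered[idx] = True
        lam[~covered] = 1.0  # participants absent from all blocks: unrelated
        self.lam = lam
        self._rotations = rotations

    def rotate(self, a: np.ndarray) -> np.ndarray:
        """Apply U' block-wise to an (n,) or (n, m) array."""
        out = np.array(a, dtype=float, copy=True)
        for idx, u in self._rotations:
            out[idx] = u.T @ out[idx]
        return out


@dataclass
class TraitModelFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma2_g: float
    sigma2_e: float
    gamma: float
    n: int
    reml: float

    def coef(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.p[i])

    @property
    def outcome(self) -> tuple[float, float, float]:
        return float(self.beta[-1]), float(self.se[-1]), float(self.p[-1])


def _reml_pieces(y_rot: np.ndarray, x_rot: np.ndarray, lam: np.ndarray,
                 gamma: float):
    v = gamma * lam + 1.0
    w = 1.0 / np.sqrt(v)
    xw = x_rot * w[:, None]
    yw = y_rot * w
    q, r = np.linalg.qr(xw)
    coef_proj = q.T @ yw
    # floor guards the degenerate perfect-fit case (y in the column span)
    rss = max(float(yw @ yw - coef_proj @ coef_proj), 1e-300)
    n, p = x_rot.shape
    logdet_v = float(np.log(v).sum())
    logdet_xvx = float(2.0 * np.log(np.abs(np.diag(r))).sum())
    sigma2_e = rss / (n - p)
    reml = -0.5 * ((n - p) * np.log(sigma2_e) + logdet_v + logdet_xvx)
    return reml, sigma2_e, r, coef_proj


DEFAULT_GAMMA_GRID = np.concatenate([[0.0], np.logspace(-3, 3, 31)])


def fit_lmm(y: np.ndarray, X: np.ndarray, kinship: KinshipMatrix | KinshipEigen,
            names: list[str] | None = None, fixed_gamma: float | None = None,
            tol: float = 1e-8) -> TraitModelFit:
    """REML fit of the kinship mixed model; Wald tests per coefficient.

    ``y`` and the design matrix ``X`` (intercept included, outcome
    conventionally last) must be aligned to the kinship ID order. Rows with
    any missing value are dropped (complete-case) and the kinship
    eigendecomposition is recomputed on the retained subset. The variance
    ratio gamma = sigma2_g/sigma2_e is profiled on a log grid and refined by
    bounded Brent minimization; ``fixed_gamma`` skips the optimization.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n, p = int(mask.sum()), X.shape[1]
    if n < p + 2:
        raise ValueError(f"too few complete cases ({n}) for {p} coefficients")
    if isinstance(kinship, KinshipEigen):
        if mask.all():
            eig = kinship
        else:
            raise ValueError("pass a KinshipMatrix when y/X contain missing rows")
    else:
        ids = [kinship.ids[i] for i in np.nonzero(mask)[0]]
        eig = KinshipEigen(kinship, subset_ids=ids)
    y_rot = eig.rotate(y[mask])
    x_rot = eig.rotate(X[mask])
    lam = eig.lam

    def neg_reml(log_gamma: float) -> float:
        return -_reml_pieces(y_rot, x_rot, lam, np.exp(log_gamma))[0]

    if fixed_gamma is not None:
        gamma = float(fixed_gamma)
    else:
        grid = DEFAULT_GAMMA_GRID
        crits = np.array([_reml_pieces(y_rot, x_rot, lam, g)[0] for g in grid])
        best = int(np.argmax(crits))
        if best == 0:
            gamma = 0.0
        else:
            lo = np.log(grid[max(best - 1, 1)])
            hi = np.log(grid[min(best + 1, len(grid) - 1)])
            if lo == hi:
                gamma = grid[best]
            else:
                res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi),
                                               method="bounded",
                                               options={"xatol": tol})
                if not res.success:
                    raise RuntimeError(
                        f"REML profile optimization failed in bracket "
                        f"[{lo:.3f}, {hi:.3f}]: {res.message}")
                gamma = float(np.exp(res.x))
                if -res.fun < crits[best]:  # keep grid point if refinement lost
                    gamma = float(grid[best])

    reml, sigma2_e, r, coef_proj = _reml_pieces(y_rot, x_rot, lam, gamma)
    beta = np.linalg.solve(r, coef_proj)
    rinv = np.linalg.inv(r)
    cov = sigma2_e * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return TraitModelFit(
        names=names or [f"b{i}" for i in range(p)],
        beta=beta, se=se, p=pvals, sigma2_g=gamma * sigma2_e,
        sigma2_e=sigma2_e, gamma=gamma, n=n, reml=reml)


def fit_lmm_batch(Y: np.ndarray, X: np.ndarray, eig: KinshipEigen,
                  gammas: np.ndarray | None = None):
    """Profile-REML fits of many trait columns against one design.

    ``Y`` is (n, B) with no missing values, aligned to ``eig``. The variance
    ratio is optimized per column on a shared grid (no scalar refinement:
    Wald statistics are flat in gamma near the REML optimum, and using the
    identical procedure for observed and permuted columns keeps the
    permutation comparison exchangeable). Returns (beta, se, p) arrays of
    length B for the last design column plus the selected gamma per column.
    """
    if gammas is None:
        gammas = DEFAULT_GAMMA_GRID
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    B = Y.shape[1]
    y_rot = eig.rotate(Y)
    x_rot = eig.rotate(X)
    lam = eig.lam

    crit = np.empty((len(gammas), B))
    cache = []
    for gi, g in enumerate(gammas):
        v = g * lam + 1.0
        w = 1.0 / np.sqrt(v)
        xw = x_rot * w[:, None]
        q, r = np.linalg.qr(xw)
        yw = y_rot * w[:, None]
        cproj = q.T @ yw  # (p, B)
        rss = np.maximum(np.einsum("ij,ij->j", yw, yw)
                         - np.einsum("ij,ij->j", cproj, cproj), 1e-300)
        logdet = float(np.log(v).sum()) + 2.0 * float(
            np.log(np.abs(np.diag(r))).sum())
        crit[gi] = (n - p) * np.log(rss / (n - p)) + logdet
        cache.append((r, cproj, rss))

    best = np.argmin(crit, axis=0)
    beta_out = np.empty(B)
    se_out = np.empty(B)
    gamma_out = np.empty(B)
    for gi in np.unique(best):
        cols = np.nonzero(best == gi)[0]
        r, cproj, rss = cache[gi]
        beta_all = np.linalg.solve(r, cproj[:, cols])
        rinv = np.linalg.inv(r)
        var_last = float((rinv @ rinv.T)[-1, -1])
        sigma2 = rss[cols] / (n - p)
        beta_out[cols] = beta_all[-1]
        se_out[cols] = np.sqrt(sigma2 * var_last)
        gamma_out[cols] = gammas[gi]
    p_out = 2 * stats.norm.sf(np.abs(beta_out / se_out))
    return beta_out, se_out, p_out, gamma_out


# ---------------------------------------------------------------------------
# logistic regression (IRLS, with separation detection)


@dataclass
class LogisticFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    separation: bool
    n: int

    @property
    def outcome(self) -> tuple[float, float, float]:
        return float(self.beta[-1]), float(self.se[-1]), float(self.p[-1])

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta[-1]))


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None,
                 max_iter: int = 40, tol: float = 1e-9) -> LogisticFit:
    """Maximum-likelihood logistic fit via Newton iterations.

    The exposure of interest goes last in ``X``. Quasi-separation (diverging
    coefficients) is flagged and the Wald p for all coefficients is set
    missing rather than reported from a degenerate Hessian.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("outcome must be binary with both classes present")
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    separation = (not converged) or bool(np.max(np.abs(beta)) > 15)
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separation = True
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    if separation:
        pvals = np.full(p, np.nan)
    return LogisticFit(names=names or [f"b{i}" for i in range(p)], beta=beta,
                       se=se, p=pvals, converged=converged,
                       separation=separation, n=n)


def ols_outcome_stats(Y: np.ndarray, X: np.ndarray):
    """OLS beta/SE/p of the last design column for every response column."""
    n, p = X.shape
    q, r = np.linalg.qr(X)
    coefs = np.linalg.solve(r, q.T @ Y)
    proj = q.T @ Y
    rss = np.maximum(np.einsum("ij,ij->j", Y, Y)
                     - np.einsum("ij,ij->j", proj, proj), 1e-300)
    sigma2 = rss / (n - p)
    rinv = np.linalg.inv(r)
    var_last = float((rinv @ rinv.T)[-1, -1])
    beta = coefs[-1]
    se = np.sqrt(sigma2 * var_last)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    return beta, se, pvals


def inflation_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over its
    null expectation (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
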