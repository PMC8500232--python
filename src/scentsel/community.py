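"""Distance-based geographic statistics.

Bray–Curtis and Euclidean distance construction, permutational multivariate
ANOVA (PERMANOVA) with a region + population-nested-in-region design,
Mantel tests (Spearman), constrained ordination of principal coordinates
(CAP / db-RDA) with compound-vector fitting, random-forest group
distinctness via the out-of-bag error, and the univariate group tests
(Mann–Whitney U, nested ANOVA).

PERMANOVA uses the trace formulation on the Gower-centred matrix
G = (I - 11'/n)(-D^2/2)(I - 11'/n): for a term with projection difference
H, SS = tr(H G), and the permutation distribution is obtained by permuting
rows and columns of G.  Sequential (Type I) sums of squares are used for
the nested design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata, mannwhitneyu, f as f_dist
from skbio import DistanceMatrix
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from statsmodels.stats.multitest import multipletests

from .data import ScentMatrix


# ---------------------------------------------------------------------------
# distances

def bray_curtis(matrix: ScentMatrix) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities d(x,y) = sum|x-y| / sum(x+y)."""
    X = matrix.values.to_numpy(dtype=float)
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        pair = [matrix.sample_ids[i] for i in zero_rows[:2]]
        raise ValueError(f"samples {pair} are both all-zero; distance undefined")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=matrix.sample_ids)


def euclidean_1d(values: pd.Series) -> DistanceMatrix:
    """Pairwise |x - y| distances of a univariate per-sample quantity."""
    v = values.to_numpy(dtype=float)[:, None]
    d = squareform(pdist(v, metric="euclidean"))
    return DistanceMatrix(d, ids=list(values.index))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    """Per-term partition of a distance matrix with permutation p-values."""

    table: pd.DataFrame  # index: term; columns: df, SS, MS, pseudo_F, p
    n_permutations: int
    permuted_f: dict[str, np.ndarray] | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_permutations={self.n_permutations})\n{self.table}"


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _hat(dummies: np.ndarray) -> np.ndarray:
    """Projection onto the column space of the design (pseudoinverse-based)."""
    return dummies @ np.linalg.pinv(dummies)


def _dummy(labels: np.ndarray) -> np.ndarray:
    cats = pd.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)


def permanova_nested(
    d: DistanceMatrix,
    region,
    population=None,
    n_perm: int = 9999,
    seed: int | None = 0,
    permutation: str = "free",
    method: str = "sampled",
    keep_permuted: bool = False,
) -> PermanovaResult:
    """PERMANOVA with `region` and, optionally, `population` nested in region.

    Sequential (Type I) sums of squares; pseudo-F per term uses the residual
    mean square of the full model.  ``p = (1 + #{F* >= F}) / (1 + n_perm)``
    under row permutation (``permutation="free"`` permutes all rows;
    ``"within-region"`` restricts permutations to region strata).

    ``method="exact"`` (single factor only) enumerates every distinct label
    assignment and returns the exact tail fraction, the observed assignment
    included.
    """
    ids = list(d.ids)
    n = len(ids)
    region = pd.Series(region).loc[ids] if hasattr(region, "loc") else pd.Series(
        list(region), index=ids
    )
    r = region.to_numpy()
    if population is not None:
        population = (
            population.loc[ids] if hasattr(population, "loc") else pd.Series(
                list(population), index=ids)
        )
        p_lab = population.to_numpy()
        combo = pd.crosstab(pd.Series(p_lab), pd.Series(r))
        if ((combo > 0).sum(axis=1) > 1).any():
            raise ValueError("a population spans more than one region")
        counts = pd.Series(p_lab).value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"singleton population(s): {list(counts.index[counts < 2])}"
            )

    g = _gower_center(np.asarray(d.data, dtype=float))
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: no variation to partition")

    def partition(order: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
        """Sequential SS per term and residual SS for row order `order`."""
        rr = r[order]
        hats = [np.full((n, n), 1.0 / n)]
        names = []
        hats.append(_hat(_dummy(rr)))
        names.append("region")
        if population is not None:
            pp = p_lab[order]
            hats.append(_hat(np.hstack([_dummy(rr), _dummy(pp)])))
            names.append("population(region)")
        ss = np.array(
            [np.trace(hats[i + 1] @ g) - np.trace(hats[i] @ g)
             for i in range(len(names))]
        )
        ss_res = ss_total - ss.sum()
        if ss_res < 1e-10 * ss_total:  # exact fit up to round-off
            ss_res = 0.0
        return ss, np.array(names, dtype=object), ss_res, len(names)

    # dfs from the observed design
    a = len(pd.unique(r))
    dfs = [a - 1]
    names = ["region"]
    if population is not None:
        b = len(pd.unique(p_lab))
        dfs.append(b - a)
        names.append("population(region)")
        if dfs[-1] <= 0:
            raise ValueError("nested population term has zero degrees of freedom")
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    identity = np.arange(n)
    ss_obs, _, ss_res_obs, _ = partition(identity)

    def fstat(ss, ss_res):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.array(dfs)) / (ss_res / df_res)
        return np.where(np.isnan(f), np.inf, f) if ss_res == 0 else f

    ms_res = ss_res_obs / df_res if ss_res_obs > 0 else 0.0
    f_obs = fstat(ss_obs, ss_res_obs)

    if method == "exact":
        if population is not None:
            raise ValueError("exact enumeration supports a single factor only")
        # distinct label assignments = distinct permutations of the label tuple
        seen = set()
        fs = []
        for perm in itertools.permutations(range(n)):
            key = tuple(r[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            ss_p, _, ss_res_p, _ = partition(np.array(perm))
            fs.append(float(fstat(ss_p, ss_res_p)[0]))
        fs = np.array(fs)
        pvals = np.array([np.mean(fs >= f_obs[0] - 1e-12)])
        table = pd.DataFrame(
            {
                "df": dfs + [df_res],
                "SS": list(ss_obs) + [ss_res_obs],
                "MS": list(ss_obs / np.array(dfs)) + [ms_res],
                "pseudo_F": list(f_obs) + [np.nan],
                "p": list(pvals) + [np.nan],
            },
            index=names + ["residual"],
        )
        return PermanovaResult(table, n_permutations=len(fs),
                               permuted_f={"region": fs} if keep_permuted else None)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    archive: dict[str, list[float]] = {t: [] for t in names}
    for _ in range(n_perm):
        if permutation == "free":
            order = rng.permutation(n)
        elif permutation == "within-region":
            order = identity.copy()
            for lev in pd.unique(r):
                idx = np.flatnonzero(r == lev)
                order[idx] = idx[rng.permutation(len(idx))]
        else:
            raise ValueError(f"unknown permutation scheme {permutation!r}")
        ss_p, _, ss_res_p, _ = partition(order)
        f_p = fstat(ss_p, ss_res_p)
        exceed += f_p >= f_obs - 1e-12
        if keep_permuted:
            for t, v in zip(names, f_p):
                archive[t].append(v)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "df": dfs + [df_res],
            "SS": list(ss_obs) + [ss_res_obs],
            "MS": list(ss_obs / np.array(dfs)) + [ms_res],
            "pseudo_F": list(f_obs) + [np.nan],
            "p": list(pvals) + [np.nan],
        },
        index=names + ["residual"],
    )
    return PermanovaResult(
        table,
        n_permutations=n_perm,
        permuted_f={t: np.asarray(v) for t, v in archive.items()}
        if keep_permuted
        else None,
    )


# ---------------------------------------------------------------------------
# Mantel

def mantel_spearman(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Mantel test on two distance matrices with Spearman rank correlation.

    The permutation p-value (one-sided, positive association) is obtained by
    jointly permuting rows and columns of the second matrix.
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices have different sample sets")
        d2 = d2.filter(d1.ids)
    a = np.asarray(d1.data, dtype=float)
    b = np.asarray(d2.data, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    ra = rankdata(a[iu])

    def rho_for(mat: np.ndarray) -> float:
        rb = rankdata(mat[iu])
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean()
        denom = np.sqrt((ra_c ** 2).sum() * (rb_c ** 2).sum())
        if denom == 0:
            return 0.0
        return float((ra_c * rb_c).sum() / denom)

    rho_obs = rho_for(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += rho_for(b[np.ix_(perm, perm)]) >= rho_obs - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    return rho_obs, p


# ---------------------------------------------------------------------------
# CAP (constrained analysis of principal coordinates)

@dataclass
class OrdinationResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame        # samples x constrained axes (CAP1, CAP2, ...)
    vectors: pd.DataFrame            # compound, r_axis1, r_axis2, max_abs_r, p, p_adj, selected


def cap_ordination(
    d: DistanceMatrix,
    grouping,
    compounds: ScentMatrix | None = None,
    r_threshold: float = 0.5,
    n_axes: int = 2,
) -> OrdinationResult:
    """Constrained ordination of principal coordinates (CAP / db-RDA).

    Principal coordinates of `d` (axes with negative eigenvalues dropped)
    are regressed on the group indicators; the constrained axes are the
    eigenvectors of the fitted coordinates.  Compound vectors are Pearson
    correlations of each compound's amounts with the first `n_axes`
    constrained axes; compounds whose strongest correlation exceeds
    `r_threshold` in absolute value are flagged, with Benjamini–Hochberg
    adjusted p-values across all compounds tested.
    """
    ids = list(d.ids)
    grouping = (
        grouping.loc[ids] if hasattr(grouping, "loc") else pd.Series(list(grouping), index=ids)
    )
    labels = grouping.to_numpy()
    if len(pd.unique(labels)) < 2:
        raise ValueError("cap_ordination requires at least two groups")

    g = _gower_center(np.asarray(d.data, dtype=float))
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals.max(), 1.0) * 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(evals)  # principal coordinates

    x = _dummy(labels)
    x = x - x.mean(axis=0)
    if np.linalg.matrix_rank(x) == 0:
        raise ValueError("rank-deficient group indicators")
    h = _hat(x)
    fitted = h @ coords
    resid = coords - fitted

    # constrained axes: eigenvectors of the fitted coordinate cross-product
    cval, cvec = np.linalg.eigh(fitted.T @ fitted)
    corder = np.argsort(cval)[::-1]
    cval, cvec = cval[corder], cvec[:, corder]
    n_constrained = min(len(pd.unique(labels)) - 1, coords.shape[1])
    cval = np.clip(cval[:n_constrained], 0.0, None)
    site = coords @ cvec[:, :n_constrained]

    uval = np.linalg.eigvalsh(resid.T @ resid)[::-1]
    uval = np.clip(uval[uval > 1e-10 * max(uval.max(), 1.0)], 0.0, None)

    axes = [f"CAP{i + 1}" for i in range(site.shape[1])]
    site_scores = pd.DataFrame(site, index=pd.Index(ids, name="sample_id"), columns=axes)

    vectors = pd.DataFrame()
    if compounds is not None:
        comp = compounds.values.loc[ids]
        k = min(n_axes, site.shape[1])
        rows = []
        for c in comp.columns:
            v = comp[c].to_numpy(dtype=float)
            rs, ps = [], []
            for j in range(k):
                if np.std(v) == 0:
                    rs.append(0.0)
                    ps.append(1.0)
                else:
                    r_, p_ = pearsonr(v, site[:, j])
                    rs.append(r_)
                    ps.append(p_)
            best = int(np.argmax(np.abs(rs)))
            rows.append(
                {"compound_id": c,
                 **{f"r_axis{j + 1}": rs[j] for j in range(k)},
                 "max_abs_r": abs(rs[best]),
                 "p": ps[best]}
            )
        vectors = pd.DataFrame(rows).set_index("compound_id")
        vectors["p_adj"] = multipletests(vectors["p"], method="fdr_bh")[1]
        vectors["selected"] = (vectors["max_abs_r"] > r_threshold) & (
            vectors["p_adj"] < 0.05
        )

    return OrdinationResult(
        constrained_eigenvalues=cval,
        unconstrained_eigenvalues=uval,
        site_scores=site_scores,
        vectors=vectors,
    )


# ---------------------------------------------------------------------------
# random-forest distinctness

@dataclass
class RFResult:
    oob_error: float                 # percent
    importance: pd.Series            # per compound
    top: pd.DataFrame                # ranked top-k


def rf_distinctness(
    matrix: ScentMatrix,
    labels,
    ntree: int = 9999,
    mtry: int = 17,
    seed: int | None = 0,
    top_k: int = 25,
    importance: str = "impurity",
) -> RFResult:
    """Group distinctness as the random-forest out-of-bag (OOB) error.

    Lower OOB error means more distinct groups.  Importance is the mean
    decrease in impurity by default; ``importance="permutation"`` uses
    permutation importance on the training data.
    """
    ids = matrix.sample_ids
    y = (labels.loc[ids] if hasattr(labels, "loc") else pd.Series(list(labels), index=ids)).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")
    x = matrix.values.to_numpy(dtype=float)
    eff_mtry = min(mtry, matrix.n_compounds)
    if eff_mtry < mtry:
        import warnings

        warnings.warn(
            f"mtry={mtry} exceeds the number of compounds; clamped to {eff_mtry}"
        )
    rf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=eff_mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(x, y)
    oob_error = 100.0 * (1.0 - rf.oob_score_)
    if importance == "permutation":
        imp = permutation_importance(
            rf, x, y, n_repeats=5, random_state=seed, n_jobs=1
        ).importances_mean
    else:
        imp = rf.feature_importances_
    imp = pd.Series(imp, index=matrix.compound_ids, name="importance")
    top = (
        imp.sort_values(ascending=False)
        .head(top_k)
        .rename_axis("compound_id")
        .reset_index()
    )
    return RFResult(oob_error=oob_error, importance=imp, top=top)


# ---------------------------------------------------------------------------
# univariate group tests

def group_tests(values, region, population=None) -> dict:
    """Mann–Whitney U across the two regions and, when populations are
    given, a nested fixed-effects ANOVA (region + population within region).
    """
    values = pd.Series(values)
    region = pd.Series(region).loc[values.index] if hasattr(region, "loc") else pd.Series(
        list(region), index=values.index
    )
    out: dict = {}
    levels = pd.unique(region)
    if len(levels) != 2:
        raise ValueError("Mann–Whitney comparison needs exactly two regions")
    g1 = values[region == levels[0]]
    g2 = values[region == levels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")
    u, p = mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    out["mannwhitney"] = {"U": float(u), "p": float(p),
                          "groups": (str(levels[0]), str(levels[1]))}

    if population is not None:
        population = (
            population.loc[values.index]
            if hasattr(population, "loc")
            else pd.Series(list(population), index=values.index)
        )
        pops_per_region = population.groupby(region).nunique()
        if (pops_per_region < 2).any():
            raise ValueError(
                "nested population term has zero degrees of freedom "
                "(a region contains a single population)"
            )
        # sequential (Type I) nested fixed-effects ANOVA via projections;
        # the nested term's df is the number of populations minus regions
        y = values.to_numpy(dtype=float)
        r_lab = region.to_numpy()
        p_lab = population.to_numpy()
        n = len(y)
        a = len(pd.unique(r_lab))
        b = len(pd.unique(p_lab))
        h0 = np.full((n, n), 1.0 / n)
        hr = _hat(_dummy(r_lab))
        hrp = _hat(np.hstack([_dummy(r_lab), _dummy(p_lab)]))
        ss_region = float(y @ (hr - h0) @ y)
        ss_pop = float(y @ (hrp - hr) @ y)
        ss_res = float(y @ (np.eye(n) - hrp) @ y)
        dfs = [a - 1, b - a, n - b]
        ms = [ss_region / dfs[0], ss_pop / dfs[1], ss_res / dfs[2]]
        fvals = [ms[0] / ms[2], ms[1] / ms[2], np.nan]
        pvals = [
            float(f_dist.sf(fvals[0], dfs[0], dfs[2])),
            float(f_dist.sf(fvals[1], dfs[1], dfs[2])),
            np.nan,
        ]
        out["anova"] = pd.DataFrame(
            {"df": dfs, "sum_sq": [ss_region, ss_pop, ss_res],
             "mean_sq": ms, "F": fvals, "p": pvals},
            index=["region", "population(region)", "residual"],
        )
    return out
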