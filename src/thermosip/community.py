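"""SIP-fraction community analysis.

Operates on OTU count tables (rows = OTUs, columns = samples) whose samples
carry fraction labels (12C-light, 13C-light, 13C-heavy) and treatment
metadata. Provides rarefaction to equal depth, Bray-Curtis dissimilarity on
relative abundance, principal coordinate analysis, a permutational
multivariate ANOVA with sequential (Type I) decomposition over one or two
categorical terms, a permutation-based differential-abundance screen, and
Spearman correlation matrices of enriched OTUs against soil attributes.

The differential-abundance screen is a transparent stand-in for
negative-binomial Wald testing (DESeq2-style tools): it ranks OTUs by a
variance-moderated difference of mean log2 relative abundance and draws
p-values from a permutation null pooled across OTUs, then applies
Benjamini-Hochberg FDR. Its OTU lists are not numerically comparable to
DESeq2's.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

#: rarefaction depth used when the data allow it
DEFAULT_RAREFACTION_DEPTH = 23_932


def _numeric_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Drop non-numeric columns (e.g. taxonomy) from a counts table."""
    return table.select_dtypes(include=[np.number])


def rarefy(table: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Columns whose total is below ``depth`` are dropped with a warning.
    Reproducible from ``seed``; uses multivariate hypergeometric draws (exact
    subsampling without replacement).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = _numeric_counts(table)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    kept = {}
    for col in counts.columns:
        col_counts = counts[col].to_numpy(dtype=np.int64)
        total = int(col_counts.sum())
        if total < depth:
            warnings.warn(f"sample {col!r} has only {total} reads (< {depth}); dropped")
            continue
        if total == depth:
            kept[col] = col_counts
        else:
            kept[col] = rng.multivariate_hypergeometric(col_counts, depth)
    out = pd.DataFrame(kept, index=counts.index)
    if "taxonomy" in table.columns:
        out.insert(0, "taxonomy", table["taxonomy"])
    return out


def relative_abundance(table: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    counts = _numeric_counts(table).astype(float) + pseudocount
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("all-zero sample in counts table")
    return counts / sums


def bray_curtis(abundances: pd.DataFrame, samples_as: str = "columns") -> pd.DataFrame:
    """Bray-Curtis dissimilarity on relative abundance.

    ``d(a, b) = 1 - 2 * sum_i min(a_i, b_i) / sum_i (a_i + b_i)``; inputs that
    are raw counts are normalised per sample first. Returns a square symmetric
    DataFrame with zero diagonal.
    """
    mat = _numeric_counts(abundances)
    if samples_as == "columns":
        mat = mat.T
    elif samples_as != "rows":
        raise ValueError("samples_as must be 'columns' or 'rows'")
    x = mat.to_numpy(dtype=float)
    sums = x.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("all-zero sample")
    x = x / sums
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        # with rows normalised to 1, 2*sum(min)/sum(a+b) reduces to sum(min)
        shared = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = 1.0 - shared
    return pd.DataFrame(d, index=mat.index, columns=mat.index)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(distance: pd.DataFrame, k: int | None = None) -> PcoaResult:
    """Principal coordinate analysis (classical MDS, Gower double-centering).

    Coordinates are eigenvectors scaled by the square root of positive
    eigenvalues, ordered by decreasing eigenvalue. Negative eigenvalues are
    reported but no correction is applied. Axis signs are fixed so each axis's
    largest-magnitude coordinate is positive.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    b = _gower_center(d)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * abs(evals[0]), 1e-12) if evals[0] > 0 else evals > 0
    n_pos = int(pos.sum())
    if k is None:
        k = n_pos
    if k > n_pos:
        raise ValueError(f"requested {k} axes but only {n_pos} positive eigenvalues")
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] *= -1
    total = evals[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=distance.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=evals[:n_pos],
        proportion_explained=evals[:n_pos] / total,
        negative_eigenvalues=evals[evals < 0],
    )


# -- PERMANOVA --------------------------------------------------------------


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T


def _dummy(labels: pd.Series) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lev).to_numpy(float) for lev in levels])


@dataclass
class PermanovaResult:
    """Sequential (Type I) PERMANOVA decomposition."""

    table: pd.DataFrame  # per-term df, SS, R2, pseudo-F, p
    n_permutations: int
    seed: int | None
    exact: bool


def permanova(
    distance: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str] | str,
    n_permutations: int = 999,
    seed: int = 0,
    blocks: str | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Sequential decomposition over one or two categorical terms following the
    distance-based linear-model trace construction: with the Gower-centred
    matrix G and hat matrix H of the (incrementally grown) dummy design,
    SS(term) is the increase of tr(HG). The pseudo-F for each term uses the
    residual of the full model. p-values come from unrestricted permutation of
    sample identities (within ``blocks`` when given); if every distinct
    permutation can be enumerated within ``n_permutations``, the exact
    permutation distribution is used and p = #{F* >= F_obs} / #permutations
    (the identity included), otherwise p = (#{F* >= F_obs} + 1) /
    (n_permutations + 1) over sampled permutations.
    """
    if isinstance(terms, str):
        terms = [terms]
    if not 1 <= len(terms) <= 2:
        raise ValueError("one or two terms are supported")
    ids = list(distance.index)
    meta = metadata.loc[ids]
    n = len(ids)
    for term in terms:
        counts = meta[term].value_counts()
        if (counts < 2).any():
            raise ValueError(f"term {term!r} has a level with fewer than 2 samples")
    g = _gower_center(distance.to_numpy(dtype=float))
    ss_total = float(np.trace(g))

    designs = []
    x = np.ones((n, 1))
    prev_rank = 1
    for term in terms:
        x = np.column_stack([x, _dummy(meta[term])])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        designs.append((term, h, rank - prev_rank))
        prev_rank = rank
    h_full = designs[-1][1]
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    tol = 1e-10 * max(ss_total, 1.0)

    def stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_res = float(np.trace(gmat) - np.trace(h_full @ gmat))
        if abs(ss_res) < tol:
            ss_res = 0.0  # perfect separation; F becomes +inf
        ss_terms = []
        prev = 0.0
        for _, h, _df in designs:
            explained = float(np.trace(h @ gmat))
            ss_terms.append(explained - prev)
            prev = explained
        ms_res = ss_res / df_res
        f = np.array([
            (ss_t / max(df_t, 1) / ms_res) if ms_res > 0
            else (np.inf if ss_t > tol else 0.0)
            for (_, _, df_t), ss_t in zip(designs, ss_terms)
        ])
        return f, ss_res

    f_obs, ss_res = stats(g)
    ss_terms_obs = []
    prev = 0.0
    for _, h, _ in designs:
        explained = float(np.trace(h @ g))
        ss_terms_obs.append(explained - prev)
        prev = explained

    # permutation null
    if blocks is not None:
        block_labels = meta[blocks].to_numpy()
        groups = [np.flatnonzero(block_labels == b) for b in pd.unique(block_labels)]
        n_distinct = int(np.prod([math.factorial(len(gr)) for gr in groups]))
    else:
        groups = [np.arange(n)]
        n_distinct = math.factorial(n)

    exact = n_distinct <= n_permutations + 1
    exceed = np.zeros(len(designs))
    if exact:
        perms = []
        for combo in itertools.product(*[itertools.permutations(gr) for gr in groups]):
            perm = np.empty(n, dtype=int)
            for gr, arrangement in zip(groups, combo):
                perm[gr] = np.asarray(arrangement)
            perms.append(perm)
        for perm in perms:
            f_perm, _ = stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - 1e-12
        pvals = exceed / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        for _ in range(n_permutations):
            perm = np.empty(n, dtype=int)
            for gr in groups:
                perm[gr] = rng.permutation(gr)
            f_perm, _ = stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - 1e-12
        pvals = (exceed + 1.0) / (n_permutations + 1.0)
        n_used = n_permutations

    rows = []
    for (term, _h, df_t), ss_t, f_t, p_t in zip(designs, ss_terms_obs, f_obs, pvals):
        rows.append({"term": term, "df": df_t, "SS": ss_t, "R2": ss_t / ss_total,
                     "pseudo_F": f_t, "p_value": p_t})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "pseudo_F": np.nan, "p_value": np.nan})
    table = pd.DataFrame(rows)
    return PermanovaResult(table=table, n_permutations=n_used, seed=seed, exact=exact)


# -- differential abundance screen ------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-OTU differential-abundance screen output.

    ``table`` columns: log2_fold_change, statistic, p_value, q_value
    (Benjamini-Hochberg), direction (+1/-1), significant (q < threshold).
    """

    table: pd.DataFrame
    contrast: str
    fdr_threshold: float
    n_permutations: int
    seed: int


def _moderated_stats(log_rel: np.ndarray, is_g1: np.ndarray) -> np.ndarray:
    """Variance-moderated difference of group means per OTU (rows)."""
    g1 = log_rel[:, is_g1]
    g2 = log_rel[:, ~is_g1]
    n1, n2 = g1.shape[1], g2.shape[1]
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    var = (g1.var(axis=1, ddof=1) / n1) + (g2.var(axis=1, ddof=1) / n2)
    se = np.sqrt(var)
    s0 = np.median(se)
    return diff / (se + s0)


def enrichment_screen(
    table: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    pseudocount: float = 1.0,
    n_permutations: int = 300,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    contrast: str = "group1-vs-group2",
) -> EnrichmentResult:
    """Permutation screen for differentially abundant OTUs (group1 vs group2).

    Per OTU the reported effect is the log2 fold-change of mean relative
    abundance (with ``pseudocount`` added to counts before normalising). The
    test statistic is a variance-moderated difference of mean log2 relative
    abundances; its null distribution pools the statistics of all OTUs over
    group relabelings, giving p-value resolution 1/(n_relabelings x n_OTUs + 1)
    — fine enough for stringent FDR levels even with few samples. When every
    distinct relabeling can be enumerated within ``n_permutations`` the exact
    set is used; the observed labeling (and, for equal group sizes, its
    mirror) is excluded from the null so the tested signal cannot leak into
    its own reference distribution. Benjamini-Hochberg adjustment yields
    q-values.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = _numeric_counts(table)
    cols = list(group1) + list(group2)
    missing = set(cols) - set(counts.columns)
    if missing:
        raise ValueError(f"samples not in table: {sorted(missing)}")
    rel = relative_abundance(counts[cols], pseudocount=pseudocount)
    log_rel = np.log2(rel.to_numpy())
    is_g1 = np.array([c in set(group1) for c in cols])

    mean1 = rel.loc[:, group1].mean(axis=1)
    mean2 = rel.loc[:, group2].mean(axis=1)
    log2fc = np.log2(mean1 / mean2)

    stat_obs = _moderated_stats(log_rel, is_g1)

    n_samples, n1 = len(cols), int(is_g1.sum())
    observed = frozenset(np.flatnonzero(is_g1))
    forbidden = {observed}
    if n1 == n_samples - n1:
        forbidden.add(frozenset(np.flatnonzero(~is_g1)))
    n_distinct = math.comb(n_samples, n1) - len(forbidden)
    null_rows = []
    if n_distinct <= n_permutations:
        for combo in itertools.combinations(range(n_samples), n1):
            if frozenset(combo) in forbidden:
                continue
            lab = np.zeros(n_samples, dtype=bool)
            lab[list(combo)] = True
            null_rows.append(_moderated_stats(log_rel, lab))
    else:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        while len(null_rows) < n_permutations:
            lab = rng.permutation(is_g1)
            if frozenset(np.flatnonzero(lab)) in forbidden:
                continue
            null_rows.append(_moderated_stats(log_rel, lab))
    null_abs = np.sort(np.abs(np.stack(null_rows).ravel()))
    # p = (1 + #null >= |obs|) / (1 + total null)
    n_null = null_abs.size
    ge = n_null - np.searchsorted(null_abs, np.abs(stat_obs) - 1e-12, side="left")
    pvals = (1.0 + ge) / (1.0 + n_null)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    out = pd.DataFrame(
        {
            "log2_fold_change": log2fc.to_numpy(),
            "statistic": stat_obs,
            "p_value": pvals,
            "q_value": qvals,
            "direction": np.where(stat_obs >= 0, 1, -1),
            "significant": qvals < fdr_threshold,
        },
        index=counts.index,
    )
    return EnrichmentResult(out, contrast, fdr_threshold, len(null_rows), seed)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, exposed for oracle tests)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# -- correlations ------------------------------------------------------------


def correlation_heatmap(
    enrichment: EnrichmentResult,
    table: pd.DataFrame,
    soil_vars: pd.DataFrame,
    significant_only: bool = True,
    cluster_columns: bool = True,
) -> pd.DataFrame:
    """Spearman correlations of enriched-OTU abundances with soil attributes.

    Rows are OTUs ordered by decreasing log2 fold-change (as in a clustered
    image map of differential abundance); columns are soil variables, ordered
    by average-linkage hierarchical clustering on 1 - |rho| when requested.
    ``soil_vars`` must be indexed by the same sample ids as the abundance
    columns. A constant variable yields NaN (correlation undefined), not 0.
    """
    counts = _numeric_counts(table)
    ids = [s for s in counts.columns if s in soil_vars.index]
    if not ids:
        raise ValueError("no overlapping sample ids between table and soil_vars")
    rel = relative_abundance(counts[ids])
    sel = enrichment.table
    if significant_only:
        sel = sel[sel["significant"]]
    sel = sel.sort_values("log2_fold_change", ascending=False)
    otus = [o for o in sel.index if o in rel.index]
    sv = soil_vars.loc[ids]
    numeric_vars = sv.select_dtypes(include=[np.number]).columns
    rho = np.full((len(otus), len(numeric_vars)), np.nan)
    for j, var in enumerate(numeric_vars):
        y = sv[var].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.isnan(y).any():
            continue  # undefined, stays NaN
        for i, otu in enumerate(otus):
            x = rel.loc[otu, ids].to_numpy()
            if np.ptp(x) == 0:
                continue  # constant abundance: correlation undefined
            rho[i, j] = spearmanr(x, y).statistic
    out = pd.DataFrame(rho, index=otus, columns=list(numeric_vars))
    if cluster_columns and out.shape[1] > 2:
        filled = out.fillna(0.0)
        dist = 1.0 - np.abs(np.corrcoef(filled.to_numpy().T))
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        order = hierarchy.leaves_list(
            hierarchy.average(squareform(dist, checks=False))
        )
        out = out.iloc[:, order]
    return out
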