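"""Self-contained statistical kernel used by every pipeline stage.

All statistics are implemented here from their defining formulas — two-sample
t-test, Benjamini–Hochberg step-up adjustment, log-space hypergeometric upper
tail, hypergeometric over-representation analysis (ORA), weighted running-sum
preranked gene set enrichment analysis (GSEA), and PCA scores via SVD. scipy
is used only for special functions (the t-distribution tail probability and
``gammaln``), never for the statistics themselves, so that library
implementations remain available as independent cross-checks in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "TestResult",
    "ORAResult",
    "GSEAResult",
    "ZeroVarianceError",
    "two_sample_ttest",
    "bh_adjust",
    "hypergeometric_tail",
    "ora",
    "preranked_gsea",
    "pca_scores",
]


class ZeroVarianceError(ValueError):
    """Both groups are constant and equal; the t statistic is undefined."""


@dataclass
class TestResult:
    """Two-sample comparison on the log2 scale.

    ``estimate`` is mean(a) - mean(b), i.e. the log2 fold change when the
    groups are log2 intensities.
    """

    estimate: float
    t_stat: float
    p: float
    df: float
    n_a: int
    n_b: int


def two_sample_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TestResult:
    """Two-sided two-sample t-test (Student by default, Welch by flag).

    Parameters
    ----------
    group_a, group_b
        Observed values; each group needs at least two observations.
    equal_var
        If True, pool the variances (Student's test, df = n_a + n_b - 2);
        otherwise use the Welch statistic with Satterthwaite df.

    Raises
    ------
    ZeroVarianceError
        If both groups have zero variance (the statistic is 0/0). Callers in
        the pipelines catch this and record the protein as untestable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 values (got {n_a}, {n_b})")
    mean_a, mean_b = a.mean(), b.mean()
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    estimate = mean_a - mean_b

    if equal_var:
        df = n_a + n_b - 2
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        denom = math.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    else:
        se2_a = var_a / n_a
        se2_b = var_b / n_b
        denom = math.sqrt(se2_a + se2_b)
        if se2_a + se2_b > 0:
            df = (se2_a + se2_b) ** 2 / (
                se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1)
            )
        else:
            df = n_a + n_b - 2

    if denom == 0.0:
        if estimate == 0.0:
            raise ZeroVarianceError(
                "both groups constant and equal; t statistic undefined"
            )
        t_stat = math.inf if estimate > 0 else -math.inf
        p = 0.0
    else:
        t_stat = estimate / denom
        # two-sided p from the t distribution survival function
        p = 2.0 * float(special.stdtr(df, -abs(t_stat)))
    return TestResult(
        estimate=float(estimate),
        t_stat=float(t_stat),
        p=float(min(p, 1.0)),
        df=float(df),
        n_a=int(n_a),
        n_b=int(n_b),
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    NaN entries are propagated as NaN and do not count toward the number of
    tests. Output is aligned with the input order. q_(i) =
    min_{j>=i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    q = np.full(p.shape, np.nan)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[valid] = qv
    return q


def _log_comb(n: float, k: float) -> float:
    return float(
        special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    )


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated ("success") items in the universe,
    n: selection size, k: observed overlap. Computed by summing exact
    log-space terms, so it is stable for large counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    upper = min(K, n)
    lower = max(k, n - (N - K))  # support lower bound
    terms = [
        _log_comb(K, j) + _log_comb(N - K, n - j) - log_denom
        for j in range(lower, upper + 1)
    ]
    if not terms:
        return 0.0
    return float(min(1.0, math.exp(special.logsumexp(np.array(terms)))))


@dataclass
class ORAResult:
    """Over-representation of one gene set in a selection from a universe."""

    set_name: str
    k: int  # overlap of selection with the set (within the universe)
    K: int  # set size after intersecting with the universe
    n: int  # selection size
    N: int  # universe size
    p_hyper: float
    q_bh: float = math.nan

    @property
    def enrichment_ratio(self) -> float:
        if self.K == 0 or self.n == 0:
            return math.nan
        return (self.k / self.n) / (self.K / self.N)


def ora(
    selection: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Sequence[str]] | "object",
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis.

    Each gene set is intersected with the universe before testing; sets with
    no members in the universe are skipped (reported via the ``skipped``
    attribute on the returned frame). BH adjustment is applied across the
    tested sets. ``sets`` may be a mapping or a GeneSetCollection.

    Returns a DataFrame with one row per tested set, sorted by p-value.
    """
    if hasattr(sets, "sets"):
        sets = sets.sets  # GeneSetCollection duck-typing
    universe = set(universe)
    selection = set(selection)
    if not universe:
        raise ValueError("empty universe")
    if not selection:
        raise ValueError("empty selection")
    stray = selection - universe
    if stray:
        raise ValueError(
            f"selection contains ids outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(selection)
    rows: list[ORAResult] = []
    skipped: list[str] = []
    for name, members in sets.items():
        in_universe = universe.intersection(members)
        K = len(in_universe)
        if K == 0:
            skipped.append(name)
            continue
        k = len(selection & in_universe)
        if k < min_overlap:
            skipped.append(name)
            continue
        p = hypergeometric_tail(k, K, n, N)
        rows.append(ORAResult(set_name=name, k=k, K=K, n=n, N=N, p_hyper=p))
    table = pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_hyper": r.p_hyper,
                "enrichment_ratio": r.enrichment_ratio,
            }
            for r in rows
        ]
    )
    if len(table):
        table["q_bh"] = bh_adjust(table["p_hyper"].to_numpy())
        table = table.sort_values("p_hyper", kind="stable").reset_index(drop=True)
    else:
        table = pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_hyper", "enrichment_ratio", "q_bh"]
        )
    table.attrs["skipped_sets"] = skipped
    return table


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    n_members: int = 0
    n_perm: int = 0
    p_weight: float = 1.0


def _enrichment_score(
    metric_sorted: np.ndarray,
    hit_positions: np.ndarray,
    p_weight: float,
) -> tuple[float, int]:
    """Signed-maximum running-sum enrichment score.

    Hits increment by |metric|^p_weight normalised over hits; misses decrement
    by 1/(N - N_hits). Returns (ES, index of the extreme deviation in the
    sorted list).
    """
    N = metric_sorted.size
    n_hits = hit_positions.size
    if n_hits == 0 or n_hits >= N:
        raise ValueError("set must be a nonempty strict subset of the ranked list")
    weights = np.abs(metric_sorted[hit_positions]) ** p_weight
    total = weights.sum()
    if total == 0:
        # all hit metrics are exactly 0 — fall back to unweighted steps
        weights = np.ones(n_hits)
        total = float(n_hits)
    step = np.full(N, -1.0 / (N - n_hits))
    step[hit_positions] = weights / total
    running = np.cumsum(step)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def preranked_gsea(
    ranked: Sequence[tuple[str, float]] | pd.DataFrame,
    sets: Mapping[str, Sequence[str]] | "object",
    p_weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    Parameters
    ----------
    ranked
        (id, metric) pairs, or a two-column DataFrame. Sorted internally by
        metric descending; ties keep the input order (stable sort).
    sets
        Mapping of set name to members, or a GeneSetCollection.
    p_weight
        Exponent on |metric| for hit increments; 0 gives the classical
        unweighted Kolmogorov–Smirnov-style statistic.
    n_perm
        Random same-size member sets per gene set (>= 10).
    seed
        Seed for the permutation RNG.

    Notes
    -----
    NES = ES / mean(|null ES| of matching sign); p_perm is the fraction of
    same-sign null ES at least as extreme; FDR q compares the observed NES
    against the pooled null NES distribution of matching sign, in the style
    of the original GSEA procedure.
    """
    if hasattr(sets, "sets"):
        sets = sets.sets
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if isinstance(ranked, pd.DataFrame):
        ids = ranked.iloc[:, 0].astype(str).to_numpy()
        metric = ranked.iloc[:, 1].to_numpy(dtype=float)
    else:
        ids = np.array([str(i) for i, _ in ranked])
        metric = np.array([float(m) for _, m in ranked])
    if len(ids) != len(set(ids)):
        raise ValueError("ranked ids must be unique")
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite")
    order = np.argsort(-metric, kind="stable")
    ids_sorted = ids[order]
    metric_sorted = metric[order]
    pos_of = {g: i for i, g in enumerate(ids_sorted)}
    N = len(ids_sorted)
    rng = np.random.default_rng(seed)

    records = []
    null_by_set: list[np.ndarray] = []
    for name, members in sets.items():
        hit_positions = np.array(
            sorted(pos_of[g] for g in set(members) if g in pos_of), dtype=int
        )
        size = hit_positions.size
        if size < min_size:
            continue
        if size >= N:
            raise ValueError(f"set {name!r} covers the whole ranked list")
        es, i_ext = _enrichment_score(metric_sorted, hit_positions, p_weight)
        # leading edge: hit members at/before the peak for positive ES,
        # at/after the trough for negative ES
        if es >= 0:
            le_positions = hit_positions[hit_positions <= i_ext]
        else:
            le_positions = hit_positions[hit_positions >= i_ext]
        leading_edge = [ids_sorted[i] for i in le_positions]
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hits = np.sort(rng.choice(N, size=size, replace=False))
            null_es[b], _ = _enrichment_score(metric_sorted, perm_hits, p_weight)
        null_by_set.append(null_es)
        records.append(
            {
                "set_name": name,
                "es": es,
                "size": size,
                "leading_edge": leading_edge,
                "null_es": null_es,
            }
        )

    if not records:
        return pd.DataFrame(
            columns=[
                "set_name", "es", "nes", "p_perm", "fdr_q",
                "size", "leading_edge", "n_perm", "p_weight",
            ]
        )

    # normalize observed and null ES by the mean |null ES| of matching sign
    all_null_nes: list[float] = []
    for rec in records:
        null_es = rec["null_es"]
        pos_mean = null_es[null_es >= 0].mean() if (null_es >= 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        es = rec["es"]
        if es >= 0:
            rec["nes"] = es / pos_mean if pos_mean and pos_mean > 0 else np.nan
            same = null_es[null_es >= 0]
            rec["p_perm"] = (
                float((same >= es).sum() + 1) / (same.size + 1) if same.size else 1.0
            )
        else:
            rec["nes"] = -(abs(es) / neg_mean) if neg_mean and neg_mean > 0 else np.nan
            same = null_es[null_es < 0]
            rec["p_perm"] = (
                float((same <= es).sum() + 1) / (same.size + 1) if same.size else 1.0
            )
        null_nes = np.where(
            null_es >= 0,
            null_es / pos_mean if pos_mean and pos_mean > 0 else np.nan,
            -(np.abs(null_es) / neg_mean) if neg_mean and neg_mean > 0 else np.nan,
        )
        all_null_nes.append(null_nes[np.isfinite(null_nes)])

    pooled_null = np.concatenate(all_null_nes)
    obs_nes = np.array([rec["nes"] for rec in records])
    for rec in records:
        nes = rec["nes"]
        if not np.isfinite(nes):
            rec["fdr_q"] = np.nan
            continue
        if nes >= 0:
            null_frac_denom = max((pooled_null >= 0).sum(), 1)
            null_frac = (pooled_null >= nes).sum() / null_frac_denom
            obs_denom = max((obs_nes >= 0).sum(), 1)
            obs_frac = (obs_nes >= nes).sum() / obs_denom
        else:
            null_frac_denom = max((pooled_null < 0).sum(), 1)
            null_frac = (pooled_null <= nes).sum() / null_frac_denom
            obs_denom = max((obs_nes < 0).sum(), 1)
            obs_frac = (obs_nes <= nes).sum() / obs_denom
        rec["fdr_q"] = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else np.nan

    table = pd.DataFrame(
        [
            {
                "set_name": rec["set_name"],
                "es": rec["es"],
                "nes": rec["nes"],
                "p_perm": rec["p_perm"],
                "fdr_q": rec["fdr_q"],
                "size": rec["size"],
                "leading_edge": rec["leading_edge"],
                "n_perm": n_perm,
                "p_weight": p_weight,
            }
            for rec in records
        ]
    )
    return table.sort_values("nes", ascending=False, kind="stable").reset_index(
        drop=True
    )


def pca_scores(
    matrix: pd.DataFrame | np.ndarray, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions by SVD.

    ``matrix`` is features x samples (proteins in rows); samples are the
    observations that get scores, matching the QC use where each pull-down
    sample is one point. Missing values must be resolved (imputed) first.

    Returns (scores, explained_variance_fractions); scores has one row per
    sample and columns PC1..PCk.
    """
    if isinstance(matrix, pd.DataFrame):
        sample_names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float).T  # samples x features
    else:
        X = np.asarray(matrix, dtype=float).T
        sample_names = [f"s{i}" for i in range(X.shape[0])]
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before PCA")
    k = int(n_components)
    if k < 1 or k > min(X.shape):
        raise ValueError(f"n_components={k} outside [1, {min(X.shape)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    # deterministic sign: largest-magnitude loading of each PC is positive
    for j in range(k):
        i_big = np.argmax(np.abs(scores[:, j]))
        if scores[i_big, j] < 0:
            scores[:, j] = -scores[:, j]
    out = pd.DataFrame(
        scores, index=sample_names, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return out, evr
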