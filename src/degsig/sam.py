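"""Per-anchor DEG-set construction: correlation prefilter + two-class SAM.

The pipeline stratifies samples on an anchor gene's expression (mean±SEM),
prefilters genes by |Pearson r| against the anchor over all samples, and
runs a two-class unpaired significance analysis of microarrays (SAM) with
a permutation-based FDR, keeping genes significantly up in the
anchor-high group.  The resulting set is named ``<anchor>-DEG``.

The SAM statistic is the moderated t ``d = (mean_hi - mean_lo)/(s + s0)``
with the pooled standard error ``s`` and a variance-stabilizing fudge
factor ``s0``.  FDR estimation follows the classic recipe: compare each
ordered observed statistic with the mean permuted order statistic, call
genes beyond a margin Δ, and estimate false calls as the median permuted
count past the smallest called statistic (π0 fixed at 1, conservative).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import DegsigError, logger, pearson_r, pearson_r_matrix  # noqa: F401 (pearson_r re-exported)
from .io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection, align_samples
from .stratify import StratifyResult, mean_sem_split


@dataclass(frozen=True)
class SamParams:
    n_permutations: int = 1000
    s0_method: str = "median"  # median | tusher | fixed
    s0_value: float = 0.0
    q_threshold: float = 0.05
    seed: int = 0
    r_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise DegsigError("n_permutations must be >= 100")
        if self.s0_method not in ("median", "tusher", "fixed"):
            raise DegsigError(f"unknown s0_method {self.s0_method!r}")
        if self.s0_method == "fixed" and self.s0_value < 0:
            raise DegsigError("s0_value must be >= 0")
        if not (0 < self.q_threshold <= 1):
            raise DegsigError("q_threshold must be in (0, 1]")


@dataclass
class DegResult:
    anchor: str
    table: pd.DataFrame  # index gene_id; columns r, d, dbar, q, selected
    n_high: int
    n_low: int
    s0: float
    n_permutations: int
    exhaustive: bool

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_gene_set(self) -> GeneSet:
        members = self.selected
        if not members:
            raise DegsigError(f"no genes selected for anchor {self.anchor!r}")
        return GeneSet(
            name=f"{self.anchor}-DEG",
            description=f"genes up in {self.anchor}-high samples (SAM q<= threshold)",
            members=frozenset(members),
        )


# ---------------------------------------------------------------------------
# primitives


def correlation_prefilter(expr: ExpressionMatrix, anchor: str, threshold: float = 0.2) -> list[tuple[str, float]]:
    """Genes whose |Pearson r| with the anchor strictly exceeds `threshold`.

    Correlation is computed over all samples; the anchor itself is excluded;
    genes with undefined r (constant rows) are skipped with a logged count.
    """
    y = expr.row(anchor).to_numpy()
    others = [g for g in expr.gene_ids if g != anchor]
    X = expr.data.loc[others].to_numpy()
    r = pearson_r_matrix(X, y)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.info("prefilter: skipped %d genes with undefined correlation", n_undef)
    keep = np.abs(r) > threshold
    keep &= ~np.isnan(r)
    out = [(g, float(rv)) for g, rv, k in zip(others, r, keep) if k]
    if not out:
        raise DegsigError(
            f"no genes pass |r| > {threshold} against {anchor!r}; review the threshold"
        )
    return out


def sam_statistic(high_values, low_values, s0: float = 0.0) -> float:
    """SAM d statistic for one gene; with s0=0 this is the pooled t statistic."""
    hi = np.asarray(high_values, dtype=float)
    lo = np.asarray(low_values, dtype=float)
    n1, n2 = hi.size, lo.size
    if n1 < 2 or n2 < 2:
        raise DegsigError(f"both groups need >= 2 samples, got {n1} and {n2}")
    ss = float(((hi - hi.mean()) ** 2).sum() + ((lo - lo.mean()) ** 2).sum())
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    return float((hi.mean() - lo.mean()) / (s + s0))


def _group_stats(X: np.ndarray, H: np.ndarray, n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (d numerators, pooled s) for many label assignments.

    X is genes x samples; H is samples x B with 1 marking the high group.
    Returns (diff, s), each genes x B.
    """
    X2 = X**2
    n = n1 + n2
    sum_all = X.sum(axis=1, keepdims=True)
    sumsq_all = X2.sum(axis=1, keepdims=True)
    sum_hi = X @ H
    sumsq_hi = X2 @ H
    sum_lo = sum_all - sum_hi
    sumsq_lo = sumsq_all - sumsq_hi
    mean_hi = sum_hi / n1
    mean_lo = sum_lo / n2
    ss = (sumsq_hi - sum_hi**2 / n1) + (sumsq_lo - sum_lo**2 / n2)
    ss = np.maximum(ss, 0.0)  # guard tiny negatives from cancellation
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n - 2) * ss)
    return mean_hi - mean_lo, s


def _choose_s0(diff: np.ndarray, s: np.ndarray, params: SamParams) -> float:
    if params.s0_method == "fixed":
        return float(params.s0_value)
    if params.s0_method == "median" or s.size < 20:
        return float(np.median(s))
    # Tusher-style: minimize the coefficient of variation of the MAD of d
    # within s-percentile windows, over candidate s0 = percentiles of s.
    candidates = np.percentile(s, np.arange(0, 101, 5))
    qbins = np.percentile(s, np.arange(0, 101, 10))
    bin_idx = np.clip(np.searchsorted(qbins, s, side="right") - 1, 0, 9)
    best_s0, best_cv = float(np.median(s)), np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = []
        for b in range(10):
            db = d[bin_idx == b]
            if db.size >= 2:
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_highs(n: int, n1: int, B: int, seed: int) -> tuple[np.ndarray, bool]:
    """Index array (n_perm x n1) of high-group members per permutation.

    Enumerates all C(n, n1) arrangements when that count is <= B, else
    draws B seeded random assignments.
    """
    from math import comb

    total = comb(n, n1)
    if total <= 1:
        raise DegsigError("degenerate labels: only one label arrangement exists")
    if total <= B:
        idx = np.array(list(itertools.combinations(range(n), n1)), dtype=np.intp)
        return idx, True
    rng = np.random.default_rng(seed)
    idx = np.empty((B, n1), dtype=np.intp)
    for b in range(B):
        idx[b] = rng.choice(n, size=n1, replace=False)
    return idx, False


def sam_select_up(
    expr_candidates: ExpressionMatrix,
    strat: StratifyResult,
    params: SamParams,
    r_values: dict[str, float] | None = None,
) -> DegResult:
    """Two-class unpaired SAM calling genes up in the high group.

    Permutes the high/low labels (exhaustively when feasible under the
    permutation budget), estimates per-gene FDR q against the permutation
    null, and selects genes with d > 0 and q <= ``params.q_threshold``.
    """
    high = [s for s in strat.high_ids if s in set(expr_candidates.sample_ids)]
    low = [s for s in strat.low_ids if s in set(expr_candidates.sample_ids)]
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise DegsigError(f"both stratified groups need >= 2 samples, got {n1} and {n2}")
    genes = expr_candidates.gene_ids
    if not genes:
        raise DegsigError("no candidate genes supplied")
    X = expr_candidates.data[high + low].to_numpy()
    n = n1 + n2

    # observed statistics and s0 (s0 is held fixed across permutations)
    obs_hi = np.zeros((n, 1))
    obs_hi[:n1, 0] = 1.0
    diff_obs, s_obs = _group_stats(X, obs_hi, n1, n2)
    s0 = _choose_s0(diff_obs[:, 0], s_obs[:, 0], params)
    d_obs = (diff_obs[:, 0] / (s_obs[:, 0] + s0))

    # permuted statistics
    high_idx, exhaustive = _permutation_highs(n, n1, params.n_permutations, params.seed)
    B = high_idx.shape[0]
    H = np.zeros((n, B))
    H[high_idx.T, np.arange(B)] = 1.0
    diff_p, s_p = _group_stats(X, H, n1, n2)
    d_perm = diff_p / (s_p + s0)  # genes x B
    d_perm_sorted = np.sort(d_perm, axis=0)  # order statistics per permutation

    order = np.argsort(d_obs, kind="stable")  # ascending
    d_sorted = d_obs[order]
    dbar_sorted = d_perm_sorted.mean(axis=1)

    q_sorted = _fdr_up(d_sorted, dbar_sorted, d_perm_sorted)

    # map back to gene order
    G = len(genes)
    dbar = np.empty(G)
    dbar[order] = dbar_sorted
    q = np.empty(G)
    q[order] = q_sorted

    selected = (d_obs > 0) & (q <= params.q_threshold)
    r_col = [r_values.get(g, np.nan) if r_values else np.nan for g in genes]
    table = pd.DataFrame(
        {"r": r_col, "d": d_obs, "dbar": dbar, "q": q, "selected": selected},
        index=pd.Index(genes, name="gene_id"),
    )
    logger.info("SAM (%d hi/%d lo, %d perms%s, s0=%.4g): %d/%d genes selected up",
                n1, n2, B, " exhaustive" if exhaustive else "", s0, int(selected.sum()), G)
    return DegResult(anchor="", table=table, n_high=n1, n_low=n2, s0=float(s0),
                     n_permutations=B, exhaustive=exhaustive)


def _fdr_up(d_sorted: np.ndarray, dbar_sorted: np.ndarray, d_perm_sorted: np.ndarray) -> np.ndarray:
    """Per-gene q for the positive side, aligned with ascending d order.

    For each margin Δ (taken from the observed positive-side exceedances
    d - dbar), genes with d - dbar >= Δ and d > 0 are called; expected
    false calls are the median over permutations of the number of permuted
    statistics at or above the smallest called d.  Each gene's q is the
    minimum FDR over margins that admit it, made monotone along the d
    ranking by a cumulative minimum.
    """
    G = d_sorted.size
    B = d_perm_sorted.shape[1]
    diff = d_sorted - dbar_sorted
    pos = d_sorted > 0
    q = np.ones(G)
    if not pos.any():
        return q
    deltas = np.unique(diff[pos])  # ascending
    n_called = np.zeros(deltas.size, dtype=int)
    cutoffs = np.empty(deltas.size)
    for k, delta in enumerate(deltas):
        called = (diff >= delta) & pos
        n_called[k] = int(called.sum())
        cutoffs[k] = d_sorted[called].min() if n_called[k] else np.inf
    # per permutation, number of permuted statistics at or above each cutoff
    counts = np.empty((B, deltas.size))
    for b in range(B):
        counts[b] = G - np.searchsorted(d_perm_sorted[:, b], cutoffs, side="left")
    false = np.median(counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.minimum(1.0, false / n_called)
    fdr[n_called == 0] = 1.0
    # a gene is admitted by every margin no larger than its own exceedance;
    # its q is the best FDR among those margins
    prefix_min = np.minimum.accumulate(fdr)
    admit = np.searchsorted(deltas, diff[pos], side="right") - 1
    q[pos] = prefix_min[admit]
    # monotone along the significance ranking: a gene's q never exceeds the
    # q of any gene with smaller d (cumulative minimum over ascending d)
    q = np.minimum.accumulate(q)
    q[~pos] = 1.0
    return q


def sam_select_down(
    expr_candidates: ExpressionMatrix,
    strat: StratifyResult,
    params: SamParams,
    r_values: dict[str, float] | None = None,
) -> DegResult:
    """Symmetric down-regulated side (off by default in the pipeline).

    Runs the up-side engine on the negated matrix and flips signs back.
    """
    neg = ExpressionMatrix(-expr_candidates.data)
    res = sam_select_up(neg, strat, params, r_values=r_values)
    res.table["d"] = -res.table["d"]
    res.table["dbar"] = -res.table["dbar"]
    return res


def build_deg_sets(
    expr: ExpressionMatrix,
    clin: ClinicalTable | None,
    anchors: list[str],
    params: SamParams,
) -> tuple[GeneSetCollection, dict[str, DegResult]]:
    """Run the full per-anchor DEG pipeline and collect "<anchor>-DEG" sets.

    Anchors whose pipeline fails (degenerate stratification, no prefilter
    survivors, empty selection) are skipped with a logged reason; an error
    is raised only if every anchor fails.
    """
    if clin is not None:
        expr, clin = align_samples(expr, clin)
    sets: list[GeneSet] = []
    results: dict[str, DegResult] = {}
    for anchor in anchors:
        try:
            strat = mean_sem_split(expr.row(anchor))
            candidates = correlation_prefilter(expr, anchor, params.r_threshold)
            cand_genes = [g for g, _ in candidates]
            r_map = dict(candidates)
            sub = expr.subset_genes(cand_genes)
            res = sam_select_up(sub, strat, params, r_values=r_map)
            res.anchor = anchor
            results[anchor] = res
            sets.append(res.to_gene_set())
        except DegsigError as exc:
            logger.warning("anchor %s skipped: %s", anchor, exc)
    if not sets:
        raise DegsigError(f"DEG construction failed for every anchor in {anchors}")
    return GeneSetCollection(sets), results
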