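"""Single-sample (ssGSEA) and two-class GSEA enrichment scoring.

ssGSEA scores one sample at a time: genes are ranked by expression, and
the enrichment score of a set is the integrated difference between the
rank-weighted ECDF of member genes and the plain ECDF of non-members.
Per-set scores are z-normalized across samples, since downstream
stratification and association operate on z-scores.

Two-class GSEA ranks genes by signal-to-noise between the classes, takes
the maximum deviation of the weighted Kolmogorov-Smirnov running sum as
the enrichment score, and calibrates NES / nominal p / FDR q against a
seeded permutation null (phenotype or gene-set permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import DegsigError, logger
from .io import ExpressionMatrix, GeneSetCollection

DEFAULT_ALPHA = 0.75
NES_THRESHOLD = 1.25
FDR_THRESHOLD = 0.25


@dataclass
class EnrichmentMatrix:
    """Raw ssGSEA scores and their per-set z-scores (sets x samples)."""

    es: pd.DataFrame
    z: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        if self.es.shape != self.z.shape:
            raise DegsigError("es and z matrices must share shape")

    @property
    def set_names(self) -> list[str]:
        return list(self.es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.es.columns)


def znormalize(row) -> np.ndarray:
    """(v - mean)/sd with the n-1 sd; a constant row maps to all zeros."""
    v = np.asarray(row, dtype=float)
    if v.size < 2:
        raise DegsigError("znormalize needs length >= 2")
    sd = v.std(ddof=1)
    if sd == 0.0:
        logger.info("znormalize: constant row mapped to zeros")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _rank_descending(expr_column: pd.Series) -> list[str]:
    """Gene ids ordered by expression descending, ties by gene id."""
    df = pd.DataFrame({"v": expr_column.to_numpy(dtype=float)}, index=expr_column.index.astype(str))
    df = df.sort_index().sort_values("v", ascending=False, kind="stable")
    return list(df.index)


def ssgsea_sample(expr_column: pd.Series, sets: GeneSetCollection, alpha: float = DEFAULT_ALPHA) -> dict[str, float]:
    """Per-set ssGSEA enrichment scores for one sample.

    With G genes ranked descending, the i-th ranked gene carries rank
    value G-i (top gene G).  ES(set) = sum over positions of
    P_in^w(i) - P_out(i), where P_in^w weights member genes by rank^alpha
    and P_out is the ECDF of non-members.
    """
    if alpha < 0:
        raise DegsigError("alpha must be >= 0")
    genes = list(expr_column.index.astype(str))
    G = len(genes)
    if G < 2:
        raise DegsigError("ssGSEA needs >= 2 genes")
    ranked = _rank_descending(expr_column)
    pos_of = {g: i for i, g in enumerate(ranked)}
    rank_value = G - np.arange(G, dtype=float)  # top gene gets G
    weights = rank_value**alpha
    scores: dict[str, float] = {}
    for gs in sets:
        members = gs.members & pos_of.keys()
        m = len(members)
        if m == 0:
            raise DegsigError(f"set {gs.name!r} has no overlap with the gene universe")
        if m == G:
            raise DegsigError(f"set {gs.name!r} covers the whole gene universe")
        in_mask = np.zeros(G, dtype=bool)
        in_mask[[pos_of[g] for g in members]] = True
        w_in = np.where(in_mask, weights, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~in_mask) / (G - m)
        scores[gs.name] = float(np.sum(p_in - p_out))
    return scores


def ssgsea_matrix(expr: ExpressionMatrix, sets: GeneSetCollection, alpha: float = DEFAULT_ALPHA) -> EnrichmentMatrix:
    """Column-wise ssGSEA followed by per-set z-normalization.

    Sets without overlap with the gene universe are dropped with a logged
    warning; a set equal to the whole universe is an error.
    """
    universe = set(expr.gene_ids)
    usable = []
    for gs in sets:
        m = len(gs.members & universe)
        if m == 0:
            logger.warning("set %r has no overlap with the expression matrix; dropped", gs.name)
        elif m == len(universe):
            raise DegsigError(f"set {gs.name!r} covers the whole gene universe")
        else:
            usable.append(gs)
    if not usable:
        raise DegsigError("no gene set overlaps the expression matrix")
    coll = GeneSetCollection(usable)
    cols = {}
    for sample in expr.sample_ids:
        cols[sample] = ssgsea_sample(expr.data[sample], coll, alpha=alpha)
    es = pd.DataFrame(cols, columns=expr.sample_ids)
    es = es.loc[[gs.name for gs in coll]]
    z = pd.DataFrame(
        {name: znormalize(es.loc[name]) for name in es.index},
        index=es.columns,
    ).T
    z.columns = es.columns
    return EnrichmentMatrix(es=es, z=z, alpha=alpha)


# ---------------------------------------------------------------------------
# two-class GSEA


@dataclass
class GseaResult:
    table: pd.DataFrame  # index set name; columns ES, NES, nominal_p, fdr_q, significant
    n_permutations: int
    perm_mode: str

    def significant_sets(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def signal_to_noise(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio (class 1 minus class 0).

    Class standard deviations are floored at 0.2x|class mean| (0.2 when
    the mean is zero), the convention of the reference GSEA tool.
    """
    X1, X0 = X[:, labels == 1], X[:, labels == 0]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    s1, s0 = X1.std(axis=1, ddof=1), X0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.where(m1 != 0, 0.2 * np.abs(m1), 0.2))
    s0 = np.maximum(s0, np.where(m0 != 0, 0.2 * np.abs(m0), 0.2))
    return (m1 - m0) / (s1 + s0)


def _running_es(metric: np.ndarray, order: np.ndarray, member_mask: np.ndarray) -> float:
    """Maximum-deviation ES for one set given a gene ranking.

    Member genes advance the running sum by |metric| (normalized), others
    decrement it uniformly.
    """
    in_ranked = member_mask[order]
    w = np.abs(metric[order]) * in_ranked
    total = w.sum()
    m = int(in_ranked.sum())
    G = order.size
    if total == 0:  # all member metrics zero: fall back to uniform hits
        w = in_ranked.astype(float)
        total = float(m)
    running = np.cumsum(w / total - (~in_ranked) / (G - m))
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_two_class(
    expr: ExpressionMatrix,
    labels,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    perm_mode: str | None = None,
    seed: int = 0,
) -> GseaResult:
    """Two-class GSEA with permutation-based NES, nominal p and FDR q.

    `labels` is a per-sample binary vector (aligned with expr columns or a
    pd.Series indexed by sample id); class 1 is the "high" phenotype.
    `perm_mode` defaults to gene_set when either class has < 7 samples,
    else phenotype.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(expr.sample_ids).to_numpy()
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != len(expr.sample_ids):
        raise DegsigError("labels must align with expression samples")
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if perm_mode is None:
        perm_mode = "gene_set" if min(n0, n1) < 7 else "phenotype"
    if perm_mode == "phenotype" and min(n0, n1) < 3:
        raise DegsigError(f"phenotype permutation needs >= 3 samples per class, got {n0}/{n1}")
    if perm_mode not in ("phenotype", "gene_set"):
        raise DegsigError(f"unknown perm_mode {perm_mode!r}")

    genes = np.array(expr.gene_ids)
    universe = set(genes)
    usable = [gs for gs in sets if 0 < len(gs.members & universe) < len(universe)]
    dropped = [gs.name for gs in sets if gs.name not in {u.name for u in usable}]
    if dropped:
        logger.warning("GSEA: dropped %d sets without usable overlap: %s", len(dropped), dropped[:5])
    if not usable:
        raise DegsigError("no usable gene sets for GSEA")
    member_masks = {gs.name: np.isin(genes, list(gs.members)) for gs in usable}

    X = expr.values
    metric = signal_to_noise(X, labels)
    order = np.argsort(-metric, kind="stable")
    es_obs = {name: _running_es(metric, order, mask) for name, mask in member_masks.items()}

    rng = np.random.default_rng(seed)
    es_perm = np.empty((len(usable), n_perm))
    if perm_mode == "phenotype":
        for b in range(n_perm):
            perm_labels = rng.permutation(labels)
            pm = signal_to_noise(X, perm_labels)
            po = np.argsort(-pm, kind="stable")
            for k, gs in enumerate(usable):
                es_perm[k, b] = _running_es(pm, po, member_masks[gs.name])
    else:  # gene_set: random sets of matched size against the observed ranking
        for k, gs in enumerate(usable):
            m = int(member_masks[gs.name].sum())
            for b in range(n_perm):
                idx = rng.choice(genes.size, size=m, replace=False)
                mask = np.zeros(genes.size, dtype=bool)
                mask[idx] = True
                es_perm[k, b] = _running_es(metric, order, mask)

    rows = []
    nes_perm_all = []
    nes_obs = {}
    for k, gs in enumerate(usable):
        es = es_obs[gs.name]
        same_sign = es_perm[k][np.sign(es_perm[k]) == np.sign(es)] if es != 0 else es_perm[k]
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        nes_obs[gs.name] = nes
        if es >= 0:
            nominal_p = float((es_perm[k][es_perm[k] >= 0] >= es).mean()) if (es_perm[k] >= 0).any() else 1.0
        else:
            nominal_p = float((es_perm[k][es_perm[k] < 0] <= es).mean()) if (es_perm[k] < 0).any() else 1.0
        # normalized permuted scores for the pooled FDR
        pos_mean = np.abs(es_perm[k][es_perm[k] > 0]).mean() if (es_perm[k] > 0).any() else np.nan
        neg_mean = np.abs(es_perm[k][es_perm[k] < 0]).mean() if (es_perm[k] < 0).any() else np.nan
        nes_p = np.where(es_perm[k] > 0, es_perm[k] / pos_mean, es_perm[k] / neg_mean)
        nes_perm_all.append(nes_p[np.isfinite(nes_p)])
        rows.append((gs.name, es, nes, nominal_p))

    pooled = np.concatenate(nes_perm_all) if nes_perm_all else np.array([])
    obs_vals = np.array([nes_obs[name] for name, *_ in rows])
    table_rows = []
    for name, es, nes, nominal_p in rows:
        q = _gsea_fdr(nes, obs_vals, pooled)
        significant = bool(q < FDR_THRESHOLD and nes > NES_THRESHOLD)
        table_rows.append((name, es, nes, nominal_p, q, significant))
    table = pd.DataFrame(
        table_rows, columns=["set", "ES", "NES", "nominal_p", "fdr_q", "significant"]
    ).set_index("set")
    return GseaResult(table=table, n_permutations=n_perm, perm_mode=perm_mode)


def _gsea_fdr(nes: float, obs_nes: np.ndarray, pooled_perm_nes: np.ndarray) -> float:
    """Standard pooled positive/negative NES FDR estimate."""
    if pooled_perm_nes.size == 0 or nes == 0:
        return 1.0
    if nes > 0:
        perm_tail = (pooled_perm_nes >= nes).sum()
        perm_side = (pooled_perm_nes > 0).sum()
        obs_tail = (obs_nes >= nes).sum()
        obs_side = (obs_nes > 0).sum()
    else:
        perm_tail = (pooled_perm_nes <= nes).sum()
        perm_side = (pooled_perm_nes < 0).sum()
        obs_tail = (obs_nes <= nes).sum()
        obs_side = (obs_nes < 0).sum()
    if perm_side == 0 or obs_side == 0 or obs_tail == 0:
        return 1.0
    return float(min(1.0, (perm_tail / perm_side) / (obs_tail / obs_side)))
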