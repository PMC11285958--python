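"""Predictor-signature correlation profiles, signature classification,
and the group-comparison statistics used for clinical contrasts.

A predictor is any per-sample score (anchor gene expression or a DEG-set
enrichment z-score).  Correlating predictors against signature z-scores
across datasets yields correlation profiles; signatures are classified as
positive or negative by the sign of their summed correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from ._utils import DegsigError, logger, pearson_r
from .enrichment import EnrichmentMatrix
from .io import ClinicalTable


@dataclass
class CorrelationProfile:
    """Signatures x predictors Pearson-r matrix for one dataset."""

    matrix: pd.DataFrame
    dataset_tag: str = ""


@dataclass
class SignatureClassification:
    positive: list[str]
    negative: list[str]
    sum_r: pd.Series
    leaf_order: list[str] = field(default_factory=list)


def correlate_predictor_signatures(predictor: pd.Series, enr: EnrichmentMatrix) -> pd.Series:
    """Pearson r of one predictor against every signature z-score row.

    Computed over the samples shared between predictor and enrichment
    matrix; signatures with undefined correlation (constant z row) are
    flagged NaN.
    """
    shared = [s for s in enr.sample_ids if s in set(predictor.index.astype(str))]
    if len(shared) < 3:
        raise DegsigError(f"need >= 3 shared samples, got {len(shared)}")
    p = predictor.loc[shared].to_numpy(dtype=float)
    out = {}
    for name in enr.set_names:
        zrow = enr.z.loc[name, shared].to_numpy(dtype=float)
        try:
            out[name] = pearson_r(p, zrow)
        except DegsigError:
            out[name] = np.nan
    result = pd.Series(out, name=getattr(predictor, "name", None))
    n_undef = int(result.isna().sum())
    if n_undef:
        logger.info("correlation: %d signatures with undefined r flagged NaN", n_undef)
    return result


def correlation_profile(predictors: pd.DataFrame, enr: EnrichmentMatrix, dataset_tag: str = "") -> CorrelationProfile:
    """Profile of every predictor row (predictors x samples) vs signatures."""
    cols = {}
    for name in predictors.index:
        cols[name] = correlate_predictor_signatures(predictors.loc[name], enr)
    return CorrelationProfile(matrix=pd.DataFrame(cols), dataset_tag=dataset_tag)


def classify_signatures(profiles: list[CorrelationProfile]) -> SignatureClassification:
    """Positive/negative signature classes by the sign of summed r.

    sum_r(signature) = sum of its correlations over all profiles and
    predictors (NaN entries skipped).  Average-linkage hierarchical
    clustering on 1 - corr between signature rows supplies a display
    (heatmap leaf) order; the operative classification is the sign alone.
    """
    if not profiles:
        raise DegsigError("no correlation profiles supplied")
    names = list(profiles[0].matrix.index)
    for p in profiles[1:]:
        if list(p.matrix.index) != names:
            raise DegsigError("profiles must share signature names (same order)")
    stacked = pd.concat([p.matrix for p in profiles], axis=1)
    sum_r = stacked.sum(axis=1, skipna=True)
    positive = list(sum_r.index[sum_r > 0])
    negative = list(sum_r.index[sum_r < 0])
    unassigned = list(sum_r.index[sum_r == 0])
    if unassigned:
        logger.warning("signatures with sum_r == 0 left unassigned: %s", unassigned)
    leaf_order = _cluster_order(stacked)
    return SignatureClassification(positive=positive, negative=negative, sum_r=sum_r, leaf_order=leaf_order)


def _cluster_order(stacked: pd.DataFrame) -> list[str]:
    if stacked.shape[0] < 3 or stacked.shape[1] < 2:
        return list(stacked.index)
    filled = stacked.fillna(0.0).to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(filled)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    try:
        link = average(squareform(dist, checks=False))
        return [stacked.index[i] for i in leaves_list(link)]
    except Exception:  # degenerate distances: keep input order
        return list(stacked.index)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class ContrastResult:
    contrast: str
    paired: bool
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_a - self.mean_b))


def student_t_test(a, b, paired: bool = False) -> tuple[float, int, float]:
    """Two-tailed Student's t-test (pooled variance when unpaired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise DegsigError("paired test needs equal lengths >= 2")
        d = a - b
        if d.std(ddof=1) == 0:
            raise DegsigError("zero variance of paired differences")
        t, p = stats.ttest_rel(a, b)
        return float(t), a.size - 1, float(p)
    if a.size < 2 or b.size < 2:
        raise DegsigError("each group needs >= 2 samples")
    sp = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if sp == 0:
        raise DegsigError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), a.size + b.size - 2, float(p)


def stage_trend(values: pd.Series, stages: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of a score against ordinal tumor stage."""
    df = pd.DataFrame({"v": values, "s": stages}).dropna()
    if len(df) < 5:
        raise DegsigError("stage trend needs >= 5 samples")
    if df["s"].nunique() < 2:
        raise DegsigError("stage trend needs >= 2 distinct stages")
    rho, p = stats.spearmanr(df["v"], df["s"])
    return float(rho), float(p)


_CONTRAST_LEVELS = {
    "tumor_vs_normal": ("tissue_class", "tumor", "normal"),
    "primary_vs_metastatic": ("timepoint", "primary", "metastatic"),
    "pre_vs_post": ("timepoint", "pre", "post"),
    "primary_vs_recurrent": ("timepoint", "primary", "recurrent"),
}
_PAIRABLE = {"pre_vs_post", "primary_vs_recurrent"}


def contrast_groups(values: pd.Series, clin: ClinicalTable, contrast: str) -> ContrastResult:
    """Compare a per-sample score between two clinical groups.

    Longitudinal contrasts (pre/post, primary/recurrent) pair samples by
    patient_id when pairing is available; otherwise the unpaired pooled-
    variance Student's t-test is used.
    """
    if contrast not in _CONTRAST_LEVELS:
        raise DegsigError(f"unknown contrast {contrast!r}")
    column, level_a, level_b = _CONTRAST_LEVELS[contrast]
    df = clin.data
    if column not in df.columns:
        raise DegsigError(f"clinical table lacks column {column!r} needed for {contrast}")
    vals = values.reindex(df.index.astype(str))
    a_ids = df.index[df[column] == level_a]
    b_ids = df.index[df[column] == level_b]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise DegsigError(f"contrast {contrast}: missing level ({level_a}: {len(a_ids)}, {level_b}: {len(b_ids)})")
    a = vals.loc[a_ids].dropna()
    b = vals.loc[b_ids].dropna()
    paired = False
    if contrast in _PAIRABLE and "patient_id" in df.columns:
        pa = df.loc[a.index, "patient_id"]
        pb = df.loc[b.index, "patient_id"]
        shared = sorted(set(pa.dropna()) & set(pb.dropna()))
        if len(shared) >= 2:
            a = pd.Series({p: a.loc[pa.index[pa == p][0]] for p in shared})
            b = pd.Series({p: b.loc[pb.index[pb == p][0]] for p in shared})
            paired = True
    t, dfree, p = student_t_test(a.to_numpy(), b.to_numpy(), paired=paired)
    return ContrastResult(
        contrast=contrast, paired=paired, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()), t=t, df=dfree, p=p,
    )
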