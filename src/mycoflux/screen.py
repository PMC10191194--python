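"""Expression filtering, normalization, and the carbon-correlation screen.

Starting from a raw transcript × sample count matrix, the screen

1. keeps transcripts "expressed under at least one condition" — within-
   condition mean count at or above an organism-specific threshold
   (plant 10, fungus 5) in at least one condition;
2. normalizes library depth with median-of-ratios size factors (the
   estimator that DESeq2-style normalization is built on);
3. correlates each transcript's normalized expression with the per-isolate
   host-derived carbon acquisition (Pearson), and selects the top and
   bottom percentile of the correlation distribution (q0.99 / q0.01);
4. flags selected correlations as significant against the critical |r| of
   the two-tailed t-test at the effective sample size, and tallies the
   functional categories of the selected transcripts via a keyword lexicon.

Fold-change matrices for heatmaps (per-isolate condition mean divided by
the across-isolate baseline, log₂) and Euclidean hierarchical clustering
orders are produced for visualisation downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CountMatrix",
    "filter_expressed",
    "size_factors",
    "MedianOfRatiosNormalizer",
    "foldchange_matrix",
    "cluster_order",
    "flag_extreme_condition",
    "select_percentiles",
    "PercentileSelection",
    "pearson_critical_value",
    "correlation_screen",
    "CorrelationScreen",
    "category_tally",
    "DEFAULT_CATEGORY_LEXICON",
]


@dataclass
class CountMatrix:
    """Raw counts (transcripts × samples) with a per-transcript organism tag."""

    counts: pd.DataFrame
    organism: pd.Series  # transcript ID -> "plant" | "fungus"

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate transcript IDs in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count matrix")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.organism.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} transcripts lack an organism tag "
                f"(e.g. {list(missing[:3])})"
            )
        self.organism = self.organism.loc[self.counts.index]

    def subset(self, transcript_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[transcript_ids], self.organism.loc[transcript_ids]
        )


def filter_expressed(
    cm: CountMatrix,
    meta: pd.DataFrame,
    plant_min: float = 10,
    fungal_min: float = 5,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep transcripts expressed under at least one condition.

    A transcript passes if its mean raw count within some condition
    reaches the threshold for its organism (``>=``; the removal rule is a
    mean *below* threshold in every condition).  Returns the filtered
    matrix and a removal report (transcript, organism, max condition mean).
    """
    if plant_min <= 0 or fungal_min <= 0:
        raise ValueError("thresholds must be positive")
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    cond = meta.loc[cm.counts.columns, "condition"]
    cond_means = cm.counts.T.groupby(cond.to_numpy()).mean().T
    max_mean = cond_means.max(axis=1)
    thr = cm.organism.map({"plant": plant_min, "fungus": fungal_min})
    if thr.isna().any():
        bad = sorted(set(cm.organism[thr.isna()]))
        raise ValueError(f"unknown organism tags: {bad}")
    keep = max_mean >= thr
    removed = pd.DataFrame(
        {
            "organism": cm.organism[~keep],
            "max_condition_mean": max_mean[~keep],
        }
    )
    return cm.subset(cm.counts.index[keep]), removed


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Reference transcripts are those with strictly positive counts in every
    sample; each sample's factor is the median over reference transcripts
    of count / (geometric mean across samples).  Dividing counts by the
    factors equalises library depth.
    """
    vals = counts.to_numpy(dtype=float)
    ref = np.all(vals > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no transcript has positive counts in every sample; the "
            "median-of-ratios reference set is empty (filter more strictly "
            "or check the matrix)"
        )
    logs = np.log(vals[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Depth normalization by median-of-ratios size factors.

    ``fit`` estimates one positive factor per sample (column); ``transform``
    divides each column by its factor.  Fitted factors are exposed as
    ``size_factors_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.size_factors_ = size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X / self.size_factors_.loc[X.columns]


def foldchange_matrix(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    genes,
    control_condition: str | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Log₂ fold change of condition means over the across-isolate baseline.

    For each gene, the mean normalized expression per isolate condition is
    divided by the mean of those condition means (the baseline expression
    level over all isolates) and log₂-transformed.  The uninoculated
    control condition, when given, is excluded from the baseline but
    reported as an extra column against the same baseline.  The
    ``pseudocount`` is added to a gene's condition means and baseline only
    if one of its condition means is zero, leaving typical genes untouched.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in norm_counts.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    cond = meta.loc[norm_counts.columns, "condition"]
    isolate_conditions = [
        c for c in pd.unique(cond) if c != control_condition
    ]
    if len(isolate_conditions) < 2:
        raise ValueError("need at least 2 isolate conditions for fold changes")
    cond_means = norm_counts.loc[genes].T.groupby(cond.to_numpy()).mean().T
    out_cols = isolate_conditions + (
        [control_condition] if control_condition is not None else []
    )
    cm = cond_means[out_cols].to_numpy(dtype=float)
    baseline = cond_means[isolate_conditions].mean(axis=1).to_numpy()

    needs_eps = (cm == 0).any(axis=1) | (baseline == 0)
    if np.any(needs_eps & (pseudocount <= 0)):
        raise ValueError(
            "gene with a zero condition mean and no positive pseudocount"
        )
    eps = np.where(needs_eps, pseudocount, 0.0)
    fc = np.log2((cm + eps[:, None]) / (baseline + eps)[:, None])
    return pd.DataFrame(fc, index=genes, columns=out_cols)


def cluster_order(matrix: pd.DataFrame, axis: int = 0, method: str = "average"):
    """Dendrogram leaf order from Euclidean agglomerative clustering.

    ``axis=0`` orders rows, ``axis=1`` columns.  Ties in the distance
    matrix are broken deterministically by input order (scipy's behaviour
    with a fixed observation order).  Returns an integer permutation.
    """
    X = matrix.to_numpy(dtype=float)
    if axis == 1:
        X = X.T
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite values in matrix to cluster")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    return np.asarray(leaves_list(Z), dtype=int)


def flag_extreme_condition(fc: pd.DataFrame, condition: str) -> pd.Series:
    """Genes whose given condition attains the row max or min.

    Generalises the "genes of interest" rule used for heatmap annotation:
    a gene is of interest when the focal isolate shows the highest or
    lowest expression among the isolate conditions in the matrix.
    """
    if condition not in fc.columns:
        raise KeyError(f"condition {condition!r} not in matrix columns")
    vals = fc.to_numpy(dtype=float)
    focal = fc[condition].to_numpy(dtype=float)
    return pd.Series(
        (focal >= vals.max(axis=1)) | (focal <= vals.min(axis=1)),
        index=fc.index,
        name="extreme_in_" + str(condition),
    )


@dataclass
class PercentileSelection:
    top_ids: list
    bottom_ids: list
    q99: float  # smallest selected top correlation
    q01: float  # largest selected bottom correlation
    m: int  # transcripts per tail


def select_percentiles(r_values: pd.Series) -> PercentileSelection:
    """Top and bottom percentile of a correlation distribution.

    Selects the ``m = ceil(0.01 n)`` largest and ``m`` smallest values
    (equivalently, values above q0.99 / below q0.01 of the empirical
    distribution).  Ties are broken by transcript ID order.  Requires
    n >= 100 so that one percentile contains at least one whole transcript.
    """
    r = pd.Series(r_values)
    n = len(r)
    if n < 100:
        raise ValueError(f"need at least 100 correlations, got {n}")
    if r.isna().any():
        raise ValueError("NaN correlation values")
    m = math.ceil(0.01 * n)
    vals = r.to_numpy(dtype=float)
    # stable order: sort by value, ties by position (ID order)
    asc = np.lexsort((np.arange(n), vals))
    bottom = asc[:m]
    desc = np.lexsort((np.arange(n), -vals))
    top = desc[:m]
    return PercentileSelection(
        top_ids=list(r.index[top]),
        bottom_ids=list(r.index[bottom]),
        q99=float(vals[top].min()),
        q01=float(vals[bottom].max()),
        m=m,
    )


def pearson_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |r| for a Pearson correlation on n pairs.

    Inverts the t statistic: ``r_crit = t / sqrt(t² + n − 2)`` with ``t``
    the (1 − α/2) quantile of Student's t on n − 2 degrees of freedom —
    the values tabulated in critical-value tables.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = st.t.ppf(1 - alpha / 2, n - 2)
    return float(t / math.sqrt(t**2 + n - 2))


class CorrelationScreen(BaseEstimator):
    """Percentile screen of transcript expression against carbon acquisition.

    Parameters
    ----------
    pairing : {"replicate", "averaged"}, default "replicate"
        "replicate" correlates each transcript's per-sample normalized
        counts with the isolate-mean carbon value assigned to every sample
        of that isolate (n = isolates × replicates).  "averaged" correlates
        condition-mean counts with the isolate means (n = isolates).
    alpha : float, default 0.05
        Level for the critical-|r| significance flag, at the effective n
        of the chosen pairing.
    percentile : float, default 0.01
        Tail mass selected at each end of the correlation distribution.

    Attributes
    ----------
    results_ : DataFrame indexed by transcript with columns
        ``pearson_r, selected ("top"/"bottom"/"none"), significant,
        r_undefined`` (+ ``category`` when annotations are given).
    q99_, q01_ : float
        Smallest selected top / largest selected bottom correlation.
    effective_n_ : int
        Sample count the critical value is computed at.
    """

    def __init__(
        self, pairing: str = "replicate", alpha: float = 0.05, percentile: float = 0.01
    ):
        self.pairing = pairing
        self.alpha = alpha
        self.percentile = percentile

    def fit(
        self,
        norm_counts: pd.DataFrame,
        meta: pd.DataFrame,
        c_values: pd.Series,
        annotations: pd.Series | None = None,
        lexicon: dict | None = None,
    ):
        if self.pairing not in ("replicate", "averaged"):
            raise ValueError(f"unknown pairing mode: {self.pairing!r}")
        meta = meta.set_index("sample") if "sample" in meta.columns else meta
        cond = meta.loc[norm_counts.columns, "condition"]
        c_values = pd.Series(c_values)
        screened = cond.isin(c_values.index)  # control condition has no C value
        if self.pairing == "replicate":
            X = norm_counts.loc[:, screened.to_numpy()].to_numpy(dtype=float)
            y = c_values.loc[cond[screened.to_numpy()]].to_numpy(dtype=float)
        else:
            cond_means = (
                norm_counts.loc[:, screened.to_numpy()]
                .T.groupby(cond[screened.to_numpy()].to_numpy())
                .mean()
                .T
            )
            cond_means = cond_means[list(c_values.index)]
            X = cond_means.to_numpy(dtype=float)
            y = c_values.to_numpy(dtype=float)
        n_eff = X.shape[1]
        if np.std(y) == 0:
            raise ValueError("carbon values have zero variance across isolates")

        r = _rowwise_pearson(X, y)
        undefined = np.isnan(r)
        r = np.where(undefined, 0.0, r)
        res = pd.DataFrame(
            {"pearson_r": r, "r_undefined": undefined}, index=norm_counts.index
        )

        valid = res.index[~undefined]
        sel = _select_tail_sets(res.loc[valid, "pearson_r"], self.percentile)
        res["selected"] = "none"
        res.loc[sel.top_ids, "selected"] = "top"
        res.loc[sel.bottom_ids, "selected"] = "bottom"

        r_crit = pearson_critical_value(n_eff, self.alpha)
        res["significant"] = (np.abs(res["pearson_r"]) >= r_crit) & ~res["r_undefined"]

        if annotations is not None:
            res["annotation"] = annotations.reindex(res.index)
        self.results_ = res
        self.q99_, self.q01_ = sel.q99, sel.q01
        self.m_per_tail_ = sel.m
        self.effective_n_ = n_eff
        self.r_critical_ = r_crit
        self._lexicon = lexicon
        return self

    def category_tally_(self, annotations: pd.Series, lexicon: dict | None = None):
        return category_tally(
            self.results_, annotations, lexicon or self._lexicon or None
        )


def _select_tail_sets(r: pd.Series, percentile: float) -> PercentileSelection:
    if percentile == 0.01:
        return select_percentiles(r)
    n = len(r)
    m = math.ceil(percentile * n)
    vals = r.to_numpy(dtype=float)
    asc = np.lexsort((np.arange(n), vals))
    desc = np.lexsort((np.arange(n), -vals))
    return PercentileSelection(
        top_ids=list(r.index[desc[:m]]),
        bottom_ids=list(r.index[asc[:m]]),
        q99=float(vals[desc[:m]].min()),
        q01=float(vals[asc[:m]].max()),
        m=m,
    )


def _rowwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of X against y; NaN for zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_screen(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    c_values: pd.Series,
    pairing: str = "replicate",
    alpha: float = 0.05,
    annotations: pd.Series | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CorrelationScreen`; returns results_."""
    return (
        CorrelationScreen(pairing=pairing, alpha=alpha)
        .fit(norm_counts, meta, c_values, annotations=annotations)
        .results_
    )


#: Keyword lexicon assigning free-text annotations to functional categories.
#: The category set mirrors the standard survey of carbon-acquisition-related
#: functions; the keywords themselves are configurable artifact choices.
DEFAULT_CATEGORY_LEXICON: dict[str, list[str]] = {
    "C metabolism": [
        "glycolysis", "sugar", "carbohydrate", "glucose", "sucrose",
        "trehalose", "mannitol", "glycogen", "invertase", "glycoside",
        "glucan", "cellulose", "starch", "inositol", "pectin", "xylan",
    ],
    "defence/disease resistance": [
        "defence", "defense", "disease resistance", "pathogenesis",
        "resistance protein", "nbs-lrr", "immune",
    ],
    "growth/cell cycle regulation": [
        "cell cycle", "cyclin", "cell division", "growth factor",
        "mitosis", "cytokinesis", "expansin",
    ],
    "host-fungus interaction": [
        "effector", "symbiosis", "mycorrhiza", "host interaction",
        "small secreted protein",
    ],
    "signal transduction": [
        "kinase", "phosphatase", "signal transduction", "signalling",
        "signaling", "gtpase", "receptor", "calmodulin",
    ],
    "stress response": [
        "stress", "heat shock", "chaperone", "oxidative", "peroxidase",
        "catalase", "dehydrin",
    ],
    "transcription regulation": [
        "transcription factor", "transcriptional regulator", "zinc finger",
        "helix-loop-helix", "homeobox", "myb", "wrky", "bzip",
    ],
    "transport": [
        "transporter", "transport protein", "permease", "channel",
        "carrier", "aquaporin", "abc transporter", "mfs",
    ],
}


def category_tally(
    results: pd.DataFrame,
    annotations: pd.Series,
    lexicon: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Percentage of selected transcripts matching each functional category.

    Matching is case-insensitive substring search of lexicon keywords in
    the free-text annotation; a transcript may count toward several
    categories.  Percentages (of the tail size) are reported both exact
    and rounded to integers for report parity.  Transcripts without an
    annotation are counted as uncategorized with a warning.
    """
    lexicon = lexicon or DEFAULT_CATEGORY_LEXICON
    rows = []
    for tail in ("top", "bottom"):
        ids = results.index[results["selected"] == tail]
        if len(ids) == 0:
            warnings.warn(f"empty {tail} selection; all categories 0%", stacklevel=2)
        ann = annotations.reindex(ids)
        n_missing = int(ann.isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} selected {tail} transcripts lack annotations; "
                "counted as uncategorized",
                stacklevel=2,
            )
        texts = ann.fillna("").str.lower()
        for cat, keywords in lexicon.items():
            hit = texts.apply(lambda t: any(k in t for k in keywords))
            pct = 100.0 * hit.sum() / len(ids) if len(ids) else 0.0
            rows.append(
                {
                    "tail": tail,
                    "category": cat,
                    "n_matching": int(hit.sum()),
                    "n_selected": len(ids),
                    "percent": pct,
                    "percent_rounded": int(round(pct)),
                }
            )
    return pd.DataFrame(rows)
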