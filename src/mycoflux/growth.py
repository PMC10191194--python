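"""Fungal growth traits and the statistics run on them.

Raw plate measurements (colony areas, dry biomass, root-tip counts,
Hartig net depth, mantle thickness, mycelium %C) are converted into the
derived traits used to characterise isolates:

* colonization percentage — colonized lateral root tips / tips in contact
  with mycelium × 100;
* hyphal density (mg/cm²) — colony dry biomass per unit colony area at
  harvest;
* radial mycelial growth rate (% area/day) — percent increase of colony
  area from plant contact (week 2) to harvest (week 4), per day.

Trait differences between isolates are assessed with one-way ANOVA plus
Tukey's HSD (Tukey–Kramer for unbalanced designs) summarised as a compact
letter display; trait structure with PCA on log-transformed data; and
trait–carbon relationships with Pearson correlation on paired
(replicate-level) or averaged (isolate-mean) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "colonization_pct",
    "hyphal_density",
    "radial_growth_rate",
    "derive_growth_traits",
    "anova_tukey",
    "AnovaTukeyResult",
    "TraitPCA",
    "pca_traits",
    "trait_c_correlation",
]


def colonization_pct(colonized, total):
    """Percentage of root tips in contact with mycelium that are colonized."""
    colonized = np.asarray(colonized, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total < 1):
        raise ValueError("total root tips in contact must be >= 1")
    if np.any(colonized > total):
        raise ValueError("colonized tips cannot exceed total tips in contact")
    out = 100.0 * colonized / total
    return float(out) if out.ndim == 0 else out


def hyphal_density(biomass_mg, area_cm2):
    """Colony dry biomass per unit colony area at harvest (mg/cm²)."""
    biomass_mg = np.asarray(biomass_mg, dtype=float)
    area_cm2 = np.asarray(area_cm2, dtype=float)
    if np.any(area_cm2 <= 0):
        raise ValueError("colony area must be positive")
    out = biomass_mg / area_cm2
    return float(out) if out.ndim == 0 else out


def radial_growth_rate(area_wk2, area_wk4, days: float = 14, ref_area=None):
    """Radial mycelial growth rate in % area/day.

    Percent increase in colony area between week 2 ("plant contact") and
    week 4 ("harvest"), divided by the number of days between them.  The
    denominator area is the week-2 colony area — the colony state when the
    host was introduced — unless ``ref_area`` (e.g. the original agar-block
    area) is supplied.
    """
    area_wk2 = np.asarray(area_wk2, dtype=float)
    area_wk4 = np.asarray(area_wk4, dtype=float)
    if days < 1:
        raise ValueError("days must be >= 1")
    denom = area_wk2 if ref_area is None else np.asarray(ref_area, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("reference area must be positive")
    out = 100.0 * (area_wk4 - area_wk2) / denom / days
    return float(out) if out.ndim == 0 else out


def derive_growth_traits(
    raw: pd.DataFrame, days: float = 14, rate_reference: str = "wk2"
) -> pd.DataFrame:
    """Derive per-record growth traits from raw plate measurements.

    ``raw`` has one row per isolate × replicate (symbiosis or fungus-only
    plate) with whichever measurement columns that plate type provides;
    traits whose inputs are absent come out as NaN.  ``rate_reference``
    selects the growth-rate denominator: ``"wk2"`` (week-2 colony area) or
    ``"agar_block"``.
    """
    out = raw.copy()
    n = len(raw)
    nan = np.full(n, np.nan)

    def have(*cols):
        return all(c in raw.columns for c in cols)

    if have("colonized_tips", "total_tips_in_contact"):
        mask = raw["total_tips_in_contact"].notna() & raw["colonized_tips"].notna()
        vals = nan.copy()
        vals[mask.to_numpy()] = colonization_pct(
            raw.loc[mask, "colonized_tips"], raw.loc[mask, "total_tips_in_contact"]
        )
        out["colonization_pct"] = vals
    if have("biomass_mg", "colony_area_wk4"):
        mask = raw["biomass_mg"].notna() & raw["colony_area_wk4"].notna()
        vals = nan.copy()
        vals[mask.to_numpy()] = hyphal_density(
            raw.loc[mask, "biomass_mg"], raw.loc[mask, "colony_area_wk4"]
        )
        out["hyphal_density"] = vals
    if have("colony_area_wk2", "colony_area_wk4"):
        mask = raw["colony_area_wk2"].notna() & raw["colony_area_wk4"].notna()
        if rate_reference == "agar_block":
            ref = raw.loc[mask, "agar_block_area"]
        elif rate_reference == "wk2":
            ref = None
        else:
            raise ValueError(f"unknown rate_reference: {rate_reference!r}")
        vals = nan.copy()
        vals[mask.to_numpy()] = radial_growth_rate(
            raw.loc[mask, "colony_area_wk2"],
            raw.loc[mask, "colony_area_wk4"],
            days=days,
            ref_area=ref,
        )
        out["radial_growth_rate"] = vals
    return out


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post-hoc letters.

    ``letters`` maps each group to its compact-letter-display string:
    groups sharing any letter are not significantly different at the
    family-wise ``alpha``.
    """

    f_statistic: float
    p_value: float
    letters: dict
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    alpha: float = 0.05


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA plus Tukey HSD compact letter display.

    Unbalanced designs use the Tukey–Kramer correction (the studentized
    range statistic with per-pair harmonic sample sizes).  Letters follow
    the insert-and-absorb algorithm and are assigned in order of
    descending group mean, so "a" always contains the largest mean.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")

    means = {g: v.mean() for g, v in by_group.items()}
    order = sorted(labels, key=lambda g: -means[g])
    mse = np.sum([np.sum((v - v.mean()) ** 2) for v in by_group.values()]) / (
        len(values) - len(labels)
    )

    if mse == 0:
        # degenerate: no within-group variance; pairs differ iff means differ
        if len(set(means.values())) == 1:
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = np.inf, 0.0
        pairs = []
        rows = []
        for i, g1 in enumerate(order):
            for g2 in order[i + 1 :]:
                rej = means[g1] != means[g2]
                rows.append(
                    {
                        "group1": g1,
                        "group2": g2,
                        "meandiff": means[g2] - means[g1],
                        "p_adj": 0.0 if rej else 1.0,
                        "reject": rej,
                    }
                )
                if rej:
                    pairs.append((g1, g2))
        pairwise = pd.DataFrame(rows)
    else:
        f_stat, p_val = st.f_oneway(*by_group.values())
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:],
            columns=[c.replace("-", "_") for c in tk.summary().data[0]],
        )[["group1", "group2", "meandiff", "p_adj", "reject"]]
        pairwise["p_adj"] = pairwise["p_adj"].astype(float)
        pairwise["reject"] = pairwise["reject"].astype(bool)
        pairs = [
            (r.group1, r.group2) for r in pairwise.itertuples() if r.reject
        ]

    letters = _compact_letter_display(order, pairs)
    return AnovaTukeyResult(float(f_stat), float(p_val), letters, pairwise, alpha)


def _compact_letter_display(order, sig_pairs):
    """Insert-and-absorb compact letter display.

    ``order`` lists the groups (descending mean); ``sig_pairs`` the pairs
    with a significant difference.  Maintains letter columns (sets of
    groups); every significant pair is split out of any shared column, and
    columns that become subsets of another are absorbed.
    """
    cols = [set(order)]
    for a, b in sorted(sig_pairs, key=lambda p: (order.index(p[0]), order.index(p[1]))):
        nxt = []
        for col in cols:
            if a in col and b in col:
                nxt.append(col - {b})
                nxt.append(col - {a})
            else:
                nxt.append(col)
        cols = _absorb(nxt)
    # letter columns sorted by their best-ranked member for a stable display
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(cols):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def _absorb(cols):
    out = []
    for c in cols:
        if any(c <= o for o in out):
            continue
        out = [o for o in out if not (o <= c)]
        out.append(c)
    return out


class TraitPCA(BaseEstimator, TransformerMixin):
    """PCA of (log-transformed) growth traits and carbon acquisition.

    Parameters
    ----------
    log_transform : bool, default True
        Apply ``ln(x + eps)`` first, with ``eps`` = smallest positive value
        in the matrix × 1e-3, so occasional zero measurements (e.g. zero
        biomass replicates) stay finite without disturbing typical values.
    scale : bool, default True
        Divide centered columns by their standard deviation (correlation
        PCA).  The traits mix mg, µm and %/day, so scaling is the default;
        disable for a covariance PCA.

    Attributes
    ----------
    scores_ : ndarray (n_samples, n_components)
    loadings_ : ndarray (n_features, n_components)
        Unit-norm eigenvectors; the largest-magnitude loading of each
        component is made positive, fixing the sign indeterminacy.
    explained_variance_ratio_ : ndarray
        Variance fractions; sums to 1.
    """

    def __init__(self, log_transform: bool = True, scale: bool = True):
        self.log_transform = log_transform
        self.scale = scale

    def fit(self, X, y=None):
        X = self._prepare(X, fitting=True)
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 observations for PCA")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [self.feature_names_[i] for i in np.flatnonzero(sd == 0)]
                raise ValueError(f"zero-variance variables cannot be scaled: {bad}")
            self.scale_ = sd
        else:
            self.scale_ = np.ones(X.shape[1])
        Xs = Xc / self.scale_
        u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        # deterministic sign: largest-|loading| entry of each PC positive
        flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, None]
        u = u * flip[None, :]
        var = s**2 / (n - 1)
        self.loadings_ = vt.T
        self.scores_ = u * s
        self.explained_variance_ = var
        total = var.sum()
        self.explained_variance_ratio_ = (
            var / total if total > 0 else np.zeros_like(var)
        )
        return self

    def transform(self, X):
        X = self._prepare(X, fitting=False)
        return (X - self.mean_) / self.scale_ @ self.loadings_

    def _prepare(self, X, fitting):
        if isinstance(X, pd.DataFrame):
            X = X.dropna(axis=1)  # drop variables with missing values
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(X.shape[1])]
        if np.any(~np.isfinite(X)):
            raise ValueError("non-finite values in PCA input")
        if self.log_transform:
            if fitting:
                pos = X[X > 0]
                if pos.size == 0:
                    raise ValueError("log transform needs at least one positive value")
                self.eps_ = pos.min() * 1e-3
            X = np.log(X + self.eps_)
        if fitting:
            self.feature_names_ = names
        return X


def pca_traits(matrix, log_transform: bool = True, scale: bool = True):
    """Thin wrapper over :class:`TraitPCA`.

    Returns ``(scores, loadings, variance_fractions)``.
    """
    p = TraitPCA(log_transform=log_transform, scale=scale).fit(matrix)
    return p.scores_, p.loadings_, p.explained_variance_ratio_


def trait_c_correlation(c_values, trait_values, paired: bool = True, groups=None):
    """Pearson correlation between carbon acquisition and a growth trait.

    ``paired=True`` correlates replicate-level values (the two vectors come
    from the same plates).  ``paired=False`` averages both vectors within
    ``groups`` (isolates) first, for traits measured on different plates
    than the carbon data.

    Returns ``(r, p)`` with a two-tailed t-test p-value.
    """
    c = np.asarray(c_values, dtype=float)
    t = np.asarray(trait_values, dtype=float)
    if len(c) != len(t):
        raise ValueError("c_values and trait_values must have equal length")
    if not paired:
        if groups is None:
            raise ValueError("averaged mode needs group labels to average within")
        g = pd.Series(np.asarray(groups))
        c = pd.Series(c).groupby(g, sort=False).mean().to_numpy()
        t = pd.Series(t).groupby(g, sort=False).mean().to_numpy()
    if len(c) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(c) == 0 or np.std(t) == 0:
        raise ValueError("zero variance in one of the vectors; r undefined")
    r, p = st.pearsonr(c, t)
    return float(r), float(p)
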