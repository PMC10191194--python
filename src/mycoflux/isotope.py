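"""Two-pool ¹³C mixing model for host-derived carbon in fungal mycelium.

An ectomycorrhizal fungus growing in symbiosis acquires carbon from its
host plant.  After pulse-labelling the plant with ¹³CO₂, the fraction of
fungal carbon that came from the host is the position of the extra-radical
mycelium (ERM) ¹³C atom% between two end members: free-living mycelium
(FLM, unlabelled baseline) and host leaves (fully labelled source)::

    %C_symbiosis = (atom%_ERM - atom%_FLM) / (atom%_leaf - atom%_FLM) * 100

Multiplying this fraction by the colony's carbon content and dry biomass
gives the absolute amount of host-derived carbon retained in the colony::

    C_symbiosis [mg] = %C_symbiosis/100 * %C_fungal/100 * biomass [mg]

Respired or exuded carbon is not captured by either quantity.  Gross
measurement outliers are removed with a per-tissue interquartile-range
fence before the mixing model is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "TISSUE_ROLES",
    "iqr_outlier_filter",
    "percent_c_symbiosis",
    "c_symbiosis_amount",
    "run_isotope_pipeline",
    "IsotopeMixingModel",
    "IsotopeResult",
]

TISSUE_ROLES = ("ERM", "FLM", "leaf")

#: absolute atom% difference below which leaf vs baseline is degenerate
DENOM_TOL = 1e-9


def iqr_outlier_filter(
    values: np.ndarray, k: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside the Tukey fences ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles use linear interpolation (numpy's default, R type 7).  The
    interval is closed, so values exactly on a fence are kept; in
    particular a constant vector (IQR = 0) is returned unchanged.  The
    filter is applied once, not re-iterated.

    Parameters
    ----------
    values : array-like of float
        Measurements to screen.  Must be finite and non-empty.
    k : float
        Fence multiplier; 1.5 is the conventional interquartile-range test.

    Returns
    -------
    kept : ndarray
        Values inside the fences, original order preserved.
    removed_idx : ndarray of int
        Positions (into ``values``) of the removed points.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("iqr_outlier_filter: empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("iqr_outlier_filter: non-finite values in input")
    if values.size < 4:
        warnings.warn(
            f"iqr_outlier_filter: only {values.size} values; quartiles are "
            "unreliable below 4 — keeping all",
            stacklevel=2,
        )
        return values, np.array([], dtype=int)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], np.flatnonzero(~keep)


def percent_c_symbiosis(erm, flm_mean, leaf):
    """Mixing fraction of host-derived fungal carbon, as a percentage.

    ``(erm - flm_mean) / (leaf - flm_mean) * 100`` with all three inputs in
    ¹³C atom%.  Values slightly below 0 or above 100 can occur under
    measurement noise and are passed through unclamped; callers flag them.
    Accepts scalars or broadcastable arrays.
    """
    erm = np.asarray(erm, dtype=float)
    flm_mean = np.asarray(flm_mean, dtype=float)
    leaf = np.asarray(leaf, dtype=float)
    denom = leaf - flm_mean
    if np.any(np.abs(denom) <= DENOM_TOL):
        raise ValueError(
            "denominator degenerate: leaf not enriched above baseline "
            f"(|leaf - flm_mean| <= {DENOM_TOL})"
        )
    out = (erm - flm_mean) / denom * 100.0
    return float(out) if out.ndim == 0 else out


def c_symbiosis_amount(pct_sym, mean_pct_c, mean_biomass_mg):
    """Absolute host-derived carbon retained in the colony, in mg.

    Both percentages enter as fractions so the product carries the biomass
    unit: ``pct_sym/100 * mean_pct_c/100 * mean_biomass_mg``.  Respired and
    exuded carbon are outside this quantity by construction.
    """
    out = (
        np.asarray(pct_sym, dtype=float)
        / 100.0
        * np.asarray(mean_pct_c, dtype=float)
        / 100.0
        * np.asarray(mean_biomass_mg, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class IsotopeResult:
    """Output of the isotope pipeline.

    Attributes
    ----------
    acquisition : DataFrame
        One row per surviving ERM replicate: isolate, replicate,
        pct_c_symbiosis, c_symbiosis_mg and an ``out_of_range`` flag for
        mixing fractions outside [0, 100].
    summary : DataFrame
        Per-isolate mean, standard error and replicate count of both
        quantities.
    removed : DataFrame
        Outlier report: isolate, tissue, replicate, atom% of every sample
        dropped by the IQR fence.
    """

    acquisition: pd.DataFrame
    summary: pd.DataFrame
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)


class IsotopeMixingModel(BaseEstimator):
    """Estimator wrapping the full atom% -> carbon-acquisition pipeline.

    Parameters
    ----------
    k : float, default 1.5
        IQR fence multiplier for the per-tissue outlier filter.
    leaf_pairing : {"plate", "isolate_mean"}, default "plate"
        "plate" pairs each ERM replicate with the leaf sample from the same
        plate (isolate + replicate); "isolate_mean" uses the mean of the
        isolate's surviving leaf samples instead.  Plates are the
        experimental unit, hence the default.

    Attributes
    ----------
    acquisition_ : DataFrame
        Per-replicate %C_symbiosis and C_symbiosis (see `IsotopeResult`).
    summary_ : DataFrame
        Per-isolate means and standard errors.
    removed_ : DataFrame
        IQR outlier report.
    """

    def __init__(self, k: float = 1.5, leaf_pairing: str = "plate"):
        self.k = k
        self.leaf_pairing = leaf_pairing

    def fit(self, samples: pd.DataFrame, colonies: pd.DataFrame):
        """Run the pipeline.

        Parameters
        ----------
        samples : DataFrame
            Columns ``isolate, tissue, replicate, atom_pct_13c`` with
            tissue in {"ERM", "FLM", "leaf"}.
        colonies : DataFrame
            Columns ``isolate, mean_biomass_mg, mean_pct_c`` — fungus-only
            plate averages per isolate.
        """
        if self.leaf_pairing not in ("plate", "isolate_mean"):
            raise ValueError(f"unknown leaf_pairing: {self.leaf_pairing!r}")
        _validate_samples(samples)
        colonies = colonies.set_index("isolate") if "isolate" in colonies else colonies

        rows, removed_rows = [], []
        for isolate, grp in samples.groupby("isolate", sort=False):
            tissues = {}
            for role in TISSUE_ROLES:
                sub = grp[grp["tissue"] == role]
                if sub.empty:
                    raise ValueError(
                        f"isolate {isolate!r}: no {role} samples; the mixing "
                        "model needs ERM, FLM and leaf measurements"
                    )
                vals = sub["atom_pct_13c"].to_numpy(dtype=float)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # <4 reps is routine for FLM
                    _, rm_idx = iqr_outlier_filter(vals, k=self.k)
                keep_mask = np.ones(len(sub), dtype=bool)
                keep_mask[rm_idx] = False
                for i in rm_idx:
                    removed_rows.append(
                        {
                            "isolate": isolate,
                            "tissue": role,
                            "replicate": sub["replicate"].iloc[i],
                            "atom_pct_13c": vals[i],
                        }
                    )
                tissues[role] = sub[keep_mask]

            flm_mean = tissues["FLM"]["atom_pct_13c"].mean()
            leaf_by_rep = tissues["leaf"].set_index("replicate")["atom_pct_13c"]
            leaf_mean = leaf_by_rep.mean()
            leaf_reps_in_input = set(
                grp.loc[grp["tissue"] == "leaf", "replicate"]
            )

            if isolate not in colonies.index:
                raise KeyError(
                    f"no colony stats (biomass, %C) for isolate {isolate!r}"
                )
            col = colonies.loc[isolate]

            if self.leaf_pairing == "plate":
                orphans = [
                    rep
                    for rep in tissues["ERM"]["replicate"]
                    if rep not in leaf_reps_in_input
                ]
                if orphans:
                    raise ValueError(
                        f"isolate {isolate!r}: ERM replicates without a paired "
                        f"leaf sample: {orphans}"
                    )

            for _, erm_row in tissues["ERM"].iterrows():
                if (
                    self.leaf_pairing == "plate"
                    and erm_row["replicate"] not in leaf_by_rep.index
                ):
                    # paired leaf was removed as an outlier; the plate has no
                    # usable end member, so drop this replicate with a report
                    removed_rows.append(
                        {
                            "isolate": isolate,
                            "tissue": "ERM (leaf outlier on plate)",
                            "replicate": erm_row["replicate"],
                            "atom_pct_13c": erm_row["atom_pct_13c"],
                        }
                    )
                    continue
                leaf_val = (
                    leaf_by_rep.loc[erm_row["replicate"]]
                    if self.leaf_pairing == "plate"
                    else leaf_mean
                )
                pct = percent_c_symbiosis(
                    erm_row["atom_pct_13c"], flm_mean, leaf_val
                )
                rows.append(
                    {
                        "isolate": isolate,
                        "replicate": erm_row["replicate"],
                        "pct_c_symbiosis": pct,
                        "c_symbiosis_mg": c_symbiosis_amount(
                            pct, col["mean_pct_c"], col["mean_biomass_mg"]
                        ),
                        "out_of_range": bool(pct < 0 or pct > 100),
                    }
                )

        acq = pd.DataFrame(rows)
        self.acquisition_ = acq
        self.summary_ = (
            acq.groupby("isolate", sort=False)
            .agg(
                pct_c_symbiosis_mean=("pct_c_symbiosis", "mean"),
                pct_c_symbiosis_se=("pct_c_symbiosis", "sem"),
                c_symbiosis_mg_mean=("c_symbiosis_mg", "mean"),
                c_symbiosis_mg_se=("c_symbiosis_mg", "sem"),
                n=("pct_c_symbiosis", "size"),
            )
            .reset_index()
        )
        self.removed_ = pd.DataFrame(
            removed_rows, columns=["isolate", "tissue", "replicate", "atom_pct_13c"]
        )
        return self

    def result_(self) -> IsotopeResult:
        return IsotopeResult(self.acquisition_, self.summary_, self.removed_)


def run_isotope_pipeline(
    samples: pd.DataFrame,
    colonies: pd.DataFrame,
    k: float = 1.5,
    leaf_pairing: str = "plate",
) -> IsotopeResult:
    """Functional wrapper around :class:`IsotopeMixingModel`."""
    model = IsotopeMixingModel(k=k, leaf_pairing=leaf_pairing).fit(samples, colonies)
    return model.result_()


def _validate_samples(samples: pd.DataFrame) -> None:
    required = {"isolate", "tissue", "replicate", "atom_pct_13c"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"isotope sample table missing columns: {sorted(missing)}")
    bad_tissue = set(samples["tissue"]) - set(TISSUE_ROLES)
    if bad_tissue:
        raise ValueError(
            f"unknown tissue roles {sorted(bad_tissue)}; expected {TISSUE_ROLES}"
        )
    atom = samples["atom_pct_13c"].to_numpy(dtype=float)
    if not np.all(np.isfinite(atom)) or np.any(atom <= 0) or np.any(atom >= 100):
        raise ValueError("atom_pct_13c values must be finite and in (0, 100)")
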