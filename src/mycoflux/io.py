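"""Delimited-table readers/writers, run configuration, and orchestration.

All interchange is plain delimited text (TSV written, comma or tab
auto-detected on read).  ``run_all`` ties the stages together — isotope
mixing model → growth-trait statistics → expression screen — and writes a
machine-readable manifest (versions, seed, config hash, per-stage record
counts, output checksums) so a rerun on the same inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import anova_tukey, derive_growth_traits, pca_traits, trait_c_correlation
from .isotope import run_isotope_pipeline
from .screen import (
    CorrelationScreen,
    CountMatrix,
    MedianOfRatiosNormalizer,
    category_tally,
    cluster_order,
    filter_expressed,
    foldchange_matrix,
)
from .synthetic import SyntheticConfig, simulate_all

log = logging.getLogger("mycoflux")

__all__ = [
    "read_table",
    "write_table",
    "read_count_matrix",
    "write_count_matrix",
    "RunConfig",
    "run_all",
    "ISOTOPE_SCHEMA",
    "COLONY_SCHEMA",
    "GROWTH_SCHEMA",
    "META_SCHEMA",
    "C_TABLE_SCHEMA",
    "ANNOTATION_SCHEMA",
]

# schema: column -> (dtype, required)
ISOTOPE_SCHEMA = {
    "isolate": (str, True),
    "tissue": (str, True),
    "replicate": (str, True),
    "atom_pct_13c": (float, True),
}
COLONY_SCHEMA = {
    "isolate": (str, True),
    "mean_biomass_mg": (float, True),
    "mean_pct_c": (float, True),
}
GROWTH_SCHEMA = {
    "isolate": (str, True),
    "replicate": (str, True),
    "plate_type": (str, True),
    "biomass_mg": (float, False),
    "colony_area_wk2": (float, False),
    "colony_area_wk4": (float, False),
    "agar_block_area": (float, False),
    "colonized_tips": (float, False),
    "total_tips_in_contact": (float, False),
    "hartig_depth_um": (float, False),
    "mantle_thickness_um": (float, False),
    "pct_c": (float, False),
}
META_SCHEMA = {
    "sample": (str, True),
    "condition": (str, True),
    "replicate": (str, True),
}
C_TABLE_SCHEMA = {"isolate": (str, True), "c_symbiosis_mg": (float, True)}
ANNOTATION_SCHEMA = {"transcript": (str, True), "annotation": (str, True)}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a delimited table and validate it against a column schema.

    The separator (tab or comma) and the line-ending convention are
    auto-detected.  Missing required columns are reported by name;
    non-numeric cells in numeric columns by row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c, (_, req) in schema.items() if req and c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col, (dtype, _) in schema.items():
        if col not in df.columns:
            continue
        if dtype is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path.name}: non-numeric value {df[col].iloc[row]!r} "
                    f"in column {col!r}, row {row + 2}"
                )
            df[col] = coerced
        elif dtype is str:
            df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_count_matrix(path, organism_path=None) -> CountMatrix:
    """Count matrix TSV: transcript rows, sample columns.

    The organism tag per transcript comes either from an ``organism``
    column inside the matrix file or from a separate two-column table
    (transcript, organism).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if "organism" in df.columns:
        organism = df.pop("organism").astype(str)
    elif organism_path is not None:
        org = pd.read_csv(organism_path, sep=None, engine="python")
        organism = org.set_index(org.columns[0])[org.columns[1]].astype(str)
    else:
        raise ValueError(
            "no organism tags: add an 'organism' column to the count matrix "
            "or pass a transcript->organism table"
        )
    counts = df.astype(np.int64)
    return CountMatrix(counts, organism)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "organism", cm.organism)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index_label="transcript", lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    With ``simulate=True`` all inputs are generated from
    ``synthetic`` + ``seed`` and written under the output directory;
    otherwise the input paths must exist.
    """

    out_dir: str = "mycoflux_out"
    simulate: bool = True
    seed: int = 0
    # input paths (used when simulate=False)
    isotope_samples: str | None = None
    colonies: str | None = None
    growth_raw: str | None = None
    counts: str | None = None
    meta: str | None = None
    annotations: str | None = None
    # isotope options
    iqr_k: float = 1.5
    leaf_pairing: str = "plate"
    # growth options
    days: float = 14.0
    pca_scale: bool = True
    pca_log: bool = True
    # screen options
    plant_min: float = 10.0
    fungal_min: float = 5.0
    pairing: str = "replicate"
    alpha: float = 0.05
    linkage_method: str = "average"
    pseudocount: float = 1.0
    # synthetic config overrides (field name -> value)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            needed = {
                "isotope_samples": self.isotope_samples,
                "colonies": self.colonies,
                "growth_raw": self.growth_raw,
                "counts": self.counts,
                "meta": self.meta,
            }
            for name, p in needed.items():
                if p is None:
                    raise ValueError(f"simulate=False but no path for {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def run_all(config: RunConfig) -> Path:
    """Run isotope → growth → screen end to end; returns the output dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_stats: dict = {}

    inputs = _load_inputs(config, out, counts_stats)
    c_summary = _isotope_stage(config, inputs, out, counts_stats)
    _growth_stage(config, inputs, c_summary, out, counts_stats)
    _screen_stage(config, inputs, c_summary, out, counts_stats)
    _write_manifest(config, out, counts_stats)
    return out


@_stage("load_inputs")
def _load_inputs(config: RunConfig, out: Path, stats: dict) -> dict:
    if config.simulate:
        cfg = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        study = simulate_all(cfg)
        inp = out / "inputs"
        write_table(study.isotope_samples, inp / "isotope_samples.tsv")
        write_table(study.colonies, inp / "colonies.tsv")
        write_table(study.growth_raw, inp / "growth_raw.tsv")
        write_table(study.meta, inp / "sample_metadata.tsv")
        write_count_matrix(study.counts, inp / "counts.tsv")
        write_table(
            study.annotations.rename_axis("transcript").reset_index(),
            inp / "annotations.tsv",
        )
        (inp / "truth.json").write_text(study.truth.to_json() + "\n")
        ann = study.annotations
        data = {
            "isotope_samples": study.isotope_samples,
            "colonies": study.colonies,
            "growth_raw": study.growth_raw,
            "counts": study.counts,
            "meta": study.meta,
            "annotations": ann,
        }
    else:
        ann = None
        if config.annotations:
            a = read_table(config.annotations, ANNOTATION_SCHEMA)
            ann = a.set_index("transcript")["annotation"]
        data = {
            "isotope_samples": read_table(config.isotope_samples, ISOTOPE_SCHEMA),
            "colonies": read_table(config.colonies, COLONY_SCHEMA),
            "growth_raw": read_table(config.growth_raw, GROWTH_SCHEMA),
            "counts": read_count_matrix(config.counts),
            "meta": read_table(config.meta, META_SCHEMA),
            "annotations": ann,
        }
    stats["n_isotope_samples"] = len(data["isotope_samples"])
    stats["n_transcripts_raw"] = len(data["counts"].counts)
    log.info(
        "loaded %d isotope samples, %d transcripts × %d samples",
        len(data["isotope_samples"]),
        *data["counts"].counts.shape,
    )
    return data


@_stage("isotope_flux")
def _isotope_stage(config, inputs, out: Path, stats: dict) -> pd.Series:
    res = run_isotope_pipeline(
        inputs["isotope_samples"].drop(
            columns=["is_injected_outlier"], errors="ignore"
        ),
        inputs["colonies"],
        k=config.iqr_k,
        leaf_pairing=config.leaf_pairing,
    )
    write_table(res.acquisition, out / "carbon_acquisition.tsv")
    write_table(res.summary, out / "carbon_summary.tsv")
    write_table(res.removed, out / "isotope_outliers_removed.tsv")
    stats["n_isotope_outliers_removed"] = len(res.removed)
    stats["n_acquisition_replicates"] = len(res.acquisition)
    log.info(
        "isotope stage: %d replicate acquisitions, %d outliers removed",
        len(res.acquisition),
        len(res.removed),
    )
    tk = anova_tukey(
        res.acquisition["c_symbiosis_mg"], res.acquisition["isolate"], config.alpha
    )
    report = pd.DataFrame(
        {"isolate": list(tk.letters), "tukey_letters": list(tk.letters.values())}
    )
    report["anova_F"] = tk.f_statistic
    report["anova_p"] = tk.p_value
    write_table(report, out / "carbon_anova_tukey.tsv")
    return res.summary.set_index("isolate")["c_symbiosis_mg_mean"]


@_stage("growth_traits")
def _growth_stage(config, inputs, c_means: pd.Series, out: Path, stats: dict):
    traits = derive_growth_traits(inputs["growth_raw"], days=config.days)
    write_table(traits, out / "growth_traits.tsv")

    trait_cols = [
        "biomass_mg",
        "pct_c",
        "hyphal_density",
        "radial_growth_rate",
        "colonization_pct",
        "hartig_depth_um",
        "mantle_thickness_um",
    ]
    rows = []
    for col in trait_cols:
        if col not in traits.columns:
            continue
        sub = traits.dropna(subset=[col])
        tk = anova_tukey(sub[col], sub["isolate"], config.alpha)
        for iso, letters in tk.letters.items():
            rows.append(
                {
                    "trait": col,
                    "isolate": iso,
                    "mean": sub.loc[sub["isolate"] == iso, col].mean(),
                    "letters": letters,
                    "anova_F": tk.f_statistic,
                    "anova_p": tk.p_value,
                }
            )
    write_table(pd.DataFrame(rows), out / "growth_anova_tukey.tsv")

    iso_means = traits.groupby("isolate")[trait_cols].mean()
    corr_rows = []
    for col in trait_cols:
        if iso_means[col].isna().all():
            continue
        paired = col == "colonization_pct"  # measured on the same plates as C
        try:
            if paired:
                per_rep = traits.dropna(subset=[col])
                c_rep = per_rep["isolate"].map(c_means)
                r, p = trait_c_correlation(c_rep, per_rep[col], paired=True)
            else:
                aligned = iso_means[col].dropna()
                r, p = trait_c_correlation(
                    c_means.loc[aligned.index], aligned, paired=True
                )
        except ValueError as e:
            log.warning("trait %s correlation skipped: %s", col, e)
            continue
        corr_rows.append({"trait": col, "pearson_r": r, "p_value": p, "paired": paired})
    write_table(pd.DataFrame(corr_rows), out / "trait_c_correlations.tsv")

    pca_input = iso_means.join(c_means.rename("c_symbiosis_mg")).dropna(axis=1)
    scores, loadings, fractions = pca_traits(
        pca_input, log_transform=config.pca_log, scale=config.pca_scale
    )
    write_table(
        pd.DataFrame(
            scores,
            index=pca_input.index,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        out / "pca_scores.tsv",
        index=True,
    )
    write_table(
        pd.DataFrame(
            loadings,
            index=pca_input.columns,
            columns=[f"PC{i+1}" for i in range(loadings.shape[1])],
        ),
        out / "pca_loadings.tsv",
        index=True,
    )
    write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(fractions))],
                "variance_fraction": fractions,
            }
        ),
        out / "pca_variance.tsv",
    )
    stats["pca_pc1_pc2_variance"] = float(fractions[:2].sum())
    log.info("growth stage: PC1+PC2 variance fraction %.3f", fractions[:2].sum())


@_stage("expression_screen")
def _screen_stage(config, inputs, c_means: pd.Series, out: Path, stats: dict):
    cm: CountMatrix = inputs["counts"]
    meta = inputs["meta"]
    filtered, removed = filter_expressed(
        cm, meta, plant_min=config.plant_min, fungal_min=config.fungal_min
    )
    stats["n_transcripts_removed_by_filter"] = len(removed)
    stats["n_transcripts_expressed"] = len(filtered.counts)
    log.info(
        "expression filter: kept %d of %d transcripts",
        len(filtered.counts),
        len(cm.counts),
    )
    norm = MedianOfRatiosNormalizer().fit(filtered.counts)
    write_table(
        norm.size_factors_.rename_axis("sample").reset_index(), out / "size_factors.tsv"
    )
    norm_counts = norm.transform(filtered.counts)

    for org in ("plant", "fungus"):
        ids = filtered.organism.index[filtered.organism == org]
        if len(ids) < 100:
            log.warning("skipping %s screen: only %d transcripts", org, len(ids))
            continue
        sub = norm_counts.loc[ids]
        scr = CorrelationScreen(pairing=config.pairing, alpha=config.alpha).fit(
            sub, meta, c_means, annotations=inputs["annotations"]
        )
        res = scr.results_.rename_axis("transcript").reset_index()
        write_table(res, out / f"screen_{org}.tsv")
        stats[f"n_{org}_screened"] = len(ids)
        stats[f"n_{org}_per_tail"] = scr.m_per_tail_
        stats[f"{org}_q99"] = scr.q99_
        stats[f"{org}_q01"] = scr.q01_
        log.info(
            "%s screen: %d transcripts, %d per tail, q99=%.3f q01=%.3f",
            org,
            len(ids),
            scr.m_per_tail_,
            scr.q99_,
            scr.q01_,
        )
        if inputs["annotations"] is not None:
            tally = category_tally(scr.results_, inputs["annotations"])
            write_table(tally, out / f"category_tally_{org}.tsv")

        selected = scr.results_.index[scr.results_["selected"] != "none"]
        if len(selected) >= 2:
            fc = foldchange_matrix(
                sub,
                meta,
                selected,
                control_condition="control" if org == "plant" else None,
                pseudocount=config.pseudocount,
            )
            order = cluster_order(
                fc[[c for c in fc.columns if c != "control"]],
                method=config.linkage_method,
            )
            fc_ordered = fc.iloc[order]
            write_table(
                fc_ordered.rename_axis("transcript").reset_index(),
                out / f"foldchange_selected_{org}.tsv",
            )


@_stage("manifest")
def _write_manifest(config: RunConfig, out: Path, stats: dict) -> None:
    cfg_json = json.dumps(asdict(config), sort_keys=True)
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.json"))
        if p.name != "manifest.json"
    }
    manifest = {
        "package": "mycoflux",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "stage_stats": stats,
        "output_sha256": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
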