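"""Synthetic study generator with recoverable ground truth.

Emulates the structure of a ¹³C pulse-label microcosm study: nine fungal
isolates plus an uninoculated plant control, isotope measurements (ERM,
FLM and leaf ¹³C atom%) invertible to a known per-isolate carbon transfer,
raw growth-plate measurements with known isolate means, and a negative-
binomial transcript count matrix in which a planted subset of transcripts
responds log-linearly to the per-isolate carbon vector.

Every downstream stage therefore has a recoverable target: with zero
noise the isotope pipeline returns the generating carbon amounts exactly,
derived growth traits equal the configured means, and the correlation
screen should recover the planted transcripts.

Three independent RNG streams (isotope / growth / counts) are spawned from
the master seed so each data family is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .screen import CountMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedStudy",
    "default_truth_c",
    "generate_isotope_data",
    "generate_growth_data",
    "generate_count_matrix",
    "generate_annotations",
    "simulate_all",
]


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the emulated design: 9 isolates, 3 transcriptome
    replicates per condition, 5 isotope/growth replicates per isolate,
    3 fungus-only (FLM) plates, 24 615 plant and 12 959 fungal transcripts.
    """

    n_isolates: int = 9
    n_transcriptome_reps: int = 3
    n_control_reps: int = 3
    n_isotope_reps: int = 5
    n_flm_reps: int = 3
    n_plant_transcripts: int = 24615
    n_fungal_transcripts: int = 12959
    n_planted_pos: int = 100
    n_planted_neg: int = 100
    #: slope of natural-log mean expression per SD of the carbon vector
    planted_effect: float = 2.0
    nb_dispersion: float = 0.1
    size_factor_range: tuple = (0.7, 1.4)
    #: natural-abundance ¹³C, atom%
    baseline_atom_pct: float = 1.08
    #: leaf atom% after ¹³CO₂ labelling, drawn per plate
    leaf_enrichment_range: tuple = (2.0, 4.0)
    #: Gaussian measurement noise on atom%, SD
    isotope_noise_sd: float = 0.02
    inject_outliers: bool = False
    #: relative Gaussian noise on growth measurements
    growth_noise: float = 0.1
    days: float = 14.0
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_isolates,
            self.n_transcriptome_reps,
            self.n_isotope_reps,
            self.n_flm_reps,
            self.n_plant_transcripts,
            self.n_fungal_transcripts,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        n_planted = self.n_planted_pos + self.n_planted_neg
        if n_planted > min(self.n_plant_transcripts, self.n_fungal_transcripts):
            raise ValueError(
                "n_planted_pos + n_planted_neg exceeds transcripts per organism"
            )
        if self.leaf_enrichment_range[0] <= self.baseline_atom_pct:
            raise ValueError(
                "leaf enrichment must exceed the natural-abundance baseline"
            )
        if not 0 < self.baseline_atom_pct < 100:
            raise ValueError("baseline atom% must be in (0, 100)")
        if self.nb_dispersion < 0 or self.isotope_noise_sd < 0 or self.growth_noise < 0:
            raise ValueError("noise parameters must be non-negative")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ValueError("size_factor_range must be positive and ordered")

    @property
    def isolates(self) -> list:
        return [f"Iso{i+1:02d}" for i in range(self.n_isolates)]

    def streams(self) -> dict:
        """One independent RNG per data family, derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("truth", "isotope", "growth", "counts")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class GroundTruth:
    true_c_per_isolate: pd.Series  # mg C, indexed by isolate
    planted_pos_ids: list = field(default_factory=list)
    planted_neg_ids: list = field(default_factory=list)
    true_size_factors: pd.Series | None = None

    def to_json(self) -> str:
        d = {
            "true_c_per_isolate": self.true_c_per_isolate.to_dict(),
            "planted_pos_ids": list(self.planted_pos_ids),
            "planted_neg_ids": list(self.planted_neg_ids),
            "true_size_factors": (
                None
                if self.true_size_factors is None
                else self.true_size_factors.to_dict()
            ),
        }
        return json.dumps(d, indent=1, sort_keys=True)


def default_truth_c(cfg: SyntheticConfig, rng=None) -> pd.Series:
    """Per-isolate host-derived carbon, mg — the quantity to recover.

    Uniform on 0.01–0.15 mg C, the scale implied by ~1 mg colonies at
    ~38 %C with mixing fractions below ~80%.
    """
    rng = rng or cfg.streams()["truth"]
    return pd.Series(
        rng.uniform(0.01, 0.15, cfg.n_isolates), index=cfg.isolates, name="c_mg"
    )


def _colony_stats(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "isolate": cfg.isolates,
            "mean_biomass_mg": rng.uniform(0.4, 1.4, cfg.n_isolates),
            "mean_pct_c": rng.uniform(37.0, 42.0, cfg.n_isolates),
        }
    )


def generate_isotope_data(
    cfg: SyntheticConfig,
    truth_c: pd.Series,
    colonies: pd.DataFrame | None = None,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isotope samples whose mixing-model inversion recovers ``truth_c``.

    For each isolate: ``n_flm_reps`` FLM baseline samples, and per ERM
    replicate a leaf sample from the same plate drawn inside the
    enrichment range, with the ERM atom% placed at the mixing fraction
    that corresponds to the isolate's true carbon transfer given its
    colony stats.  Gaussian measurement noise (``isotope_noise_sd``) is
    added to every reported value; with zero noise the pipeline inverts
    exactly.  ``inject_outliers`` appends one gross ERM outlier per
    isolate (above the upper IQR fence by construction), flagged in the
    ``is_injected_outlier`` column, with its own paired leaf sample.

    Returns ``(samples, colonies)``; colony stats are generated when not
    supplied.
    """
    rng = rng or cfg.streams()["isotope"]
    if len(truth_c) != cfg.n_isolates:
        raise ValueError("truth_c length must equal n_isolates")
    if np.any(np.asarray(truth_c, dtype=float) < 0):
        raise ValueError("truth_c must be non-negative")
    if colonies is None:
        colonies = _colony_stats(cfg, rng)
    col = colonies.set_index("isolate")
    sd = cfg.isotope_noise_sd
    base = cfg.baseline_atom_pct
    rows = []

    def draw(value):
        # measurement noise; atom% must stay inside (0, 100)
        for _ in range(100):
            v = value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            if 0 < v < 100:
                return v
        raise RuntimeError("could not draw atom% in (0, 100)")

    for iso in truth_c.index:
        frac = float(truth_c[iso]) / (
            col.loc[iso, "mean_pct_c"] / 100.0 * col.loc[iso, "mean_biomass_mg"]
        )
        if frac > 1:
            raise ValueError(
                f"isolate {iso}: true carbon exceeds total colony carbon "
                "(mixing fraction > 1); lower truth_c or raise biomass"
            )
        for r in range(cfg.n_flm_reps):
            rows.append((iso, "FLM", f"F{r+1}", draw(base), False))
        erm_clean = []
        for r in range(cfg.n_isotope_reps):
            leaf = rng.uniform(*cfg.leaf_enrichment_range)
            erm = base + frac * (leaf - base)
            erm_clean.append(erm)
            rep = f"R{r+1}"
            rows.append((iso, "ERM", rep, draw(erm), False))
            rows.append((iso, "leaf", rep, draw(leaf), False))
        if cfg.inject_outliers:
            q1, q3 = np.quantile(erm_clean, [0.25, 0.75])
            gross = q3 + 10.0 * (q3 - q1) + 1.0
            rep = f"R{cfg.n_isotope_reps+1}"
            rows.append((iso, "ERM", rep, min(gross, 99.0), True))
            rows.append(
                (iso, "leaf", rep, draw(rng.uniform(*cfg.leaf_enrichment_range)), False)
            )
    samples = pd.DataFrame(
        rows,
        columns=["isolate", "tissue", "replicate", "atom_pct_13c", "is_injected_outlier"],
    )
    return samples, colonies


def generate_growth_data(
    cfg: SyntheticConfig, rng=None, true_means: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw growth measurements plus the per-isolate true trait means.

    Fungus-only plates carry biomass, colony areas and %C; symbiosis
    plates carry root-tip counts and section depths.  Week-2 area is
    back-computed from the configured radial growth rate so that with zero
    noise every derived trait equals its configured mean.  Root-tip totals
    are fixed at 20 and true colonization means sit on a 5% grid, keeping
    the zero-noise colonized count integral.
    """
    rng = rng or cfg.streams()["growth"]
    n = cfg.n_isolates
    if true_means is None:
        area_wk4 = rng.uniform(15.0, 30.0, n)
        rate = rng.uniform(4.0, 21.0, n)
        biomass = rng.uniform(0.1, 1.4, n)
        true_means = pd.DataFrame(
            {
                "isolate": cfg.isolates,
                "biomass_mg": biomass,
                "pct_c": rng.uniform(37.0, 42.0, n),
                "colony_area_wk4": area_wk4,
                "colony_area_wk2": area_wk4 / (1 + rate * cfg.days / 100.0),
                "radial_growth_rate": rate,
                "hyphal_density": biomass / area_wk4,
                "colonization_pct": rng.choice(np.arange(50, 100, 5), n).astype(float),
                "hartig_depth_um": rng.uniform(4.0, 17.0, n),
                "mantle_thickness_um": rng.uniform(20.0, 63.0, n),
            }
        )
    tm = true_means.set_index("isolate")
    noise = cfg.growth_noise
    total_tips = 20

    def jitter(mean):
        if noise == 0:
            return float(mean)
        for _ in range(100):
            v = mean * (1.0 + rng.normal(0.0, noise))
            if v > 0:
                return float(v)
        return float(mean)

    rows = []
    for iso in tm.index:
        m = tm.loc[iso]
        for r in range(cfg.n_isotope_reps):
            rep = f"R{r+1}"
            a2 = jitter(m["colony_area_wk2"])
            a4 = max(jitter(m["colony_area_wk4"]), a2)
            rows.append(
                {
                    "isolate": iso,
                    "replicate": rep,
                    "plate_type": "fungus_only",
                    "biomass_mg": jitter(m["biomass_mg"]),
                    "colony_area_wk2": a2,
                    "colony_area_wk4": a4,
                    "agar_block_area": 1.0,
                    "pct_c": jitter(m["pct_c"]),
                }
            )
            p = m["colonization_pct"] / 100.0
            colonized = (
                int(round(p * total_tips))
                if noise == 0
                else int(rng.binomial(total_tips, p))
            )
            rows.append(
                {
                    "isolate": iso,
                    "replicate": rep,
                    "plate_type": "symbiosis",
                    "colonized_tips": colonized,
                    "total_tips_in_contact": total_tips,
                    "hartig_depth_um": jitter(m["hartig_depth_um"]),
                    "mantle_thickness_um": jitter(m["mantle_thickness_um"]),
                }
            )
    raw = pd.DataFrame(rows)
    return raw, true_means


def generate_count_matrix(
    cfg: SyntheticConfig, truth_c: pd.Series, rng=None
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with planted carbon-responsive transcripts.

    Gene base means are log-normal (median ≈ 30, wide), so a realistic
    fraction of transcripts sits below the expression filter thresholds.
    In each organism, ``n_planted_pos`` transcripts get natural-log mean
    expression ``base + planted_effect × z(C)`` per isolate condition and
    ``n_planted_neg`` the negated effect, where ``z(C)`` standardizes the
    true carbon vector; planted transcripts are drawn from genes with base
    mean ≥ 30 so the signal is not destroyed by the expression filter.
    Counts are gamma–Poisson with dispersion ``nb_dispersion`` (Poisson if
    0) times per-sample size factors drawn from ``size_factor_range`` and
    normalized to geometric mean 1.  The uninoculated control condition
    has plant expression at base level and zero fungal counts.
    """
    rng = rng or cfg.streams()["counts"]
    if len(truth_c) != cfg.n_isolates:
        raise ValueError("truth_c length must equal n_isolates")
    isolates = list(truth_c.index)
    samples, conditions = [], []
    for iso in isolates:
        for r in range(cfg.n_transcriptome_reps):
            samples.append(f"{iso}_R{r+1}")
            conditions.append(iso)
    for r in range(cfg.n_control_reps):
        samples.append(f"Ctrl_R{r+1}")
        conditions.append("control")
    meta = pd.DataFrame(
        {
            "sample": samples,
            "condition": conditions,
            "replicate": [s.rsplit("_", 1)[1] for s in samples],
            "organism": ["plant" if c == "control" else "plant+fungus" for c in conditions],
        }
    )

    c = truth_c.to_numpy(dtype=float)
    z = (c - c.mean()) / c.std() if c.std() > 0 else np.zeros_like(c)

    sf = rng.uniform(*cfg.size_factor_range, size=len(samples))
    sf = sf / np.exp(np.mean(np.log(sf)))
    sf_series = pd.Series(sf, index=samples, name="size_factor")

    gene_ids, organisms, blocks = [], [], []
    planted_pos, planted_neg = [], []
    for org, prefix, n_genes in (
        ("plant", "EG", cfg.n_plant_transcripts),
        ("fungus", "PM", cfg.n_fungal_transcripts),
    ):
        ids = [f"{prefix}{i+1:06d}" for i in range(n_genes)]
        base = rng.lognormal(mean=np.log(30.0), sigma=1.8, size=n_genes)
        eligible = np.flatnonzero(base >= 30.0)
        n_needed = cfg.n_planted_pos + cfg.n_planted_neg
        if len(eligible) < n_needed:
            eligible = np.argsort(base)[-n_needed:]
        chosen = rng.choice(
            eligible, size=cfg.n_planted_pos + cfg.n_planted_neg, replace=False
        )
        pos_idx = chosen[: cfg.n_planted_pos]
        neg_idx = chosen[cfg.n_planted_pos :]
        sign = np.zeros(n_genes)
        sign[pos_idx] = 1.0
        sign[neg_idx] = -1.0
        planted_pos += [ids[i] for i in pos_idx]
        planted_neg += [ids[i] for i in neg_idx]

        # per-gene × per-condition mean, then expand to samples with size factors
        cond_mult = np.exp(np.outer(sign * cfg.planted_effect, z))  # genes × isolates
        mean_cond = base[:, None] * cond_mult
        mu = np.empty((n_genes, len(samples)))
        for j, (s, cond) in enumerate(zip(samples, conditions)):
            if cond == "control":
                mu[:, j] = (base if org == "plant" else 0.0) * sf[j]
            else:
                mu[:, j] = mean_cond[:, isolates.index(cond)] * sf[j]
        if cfg.nb_dispersion > 0:
            lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        gene_ids += ids
        organisms += [org] * n_genes
        blocks.append(counts)

    cm = CountMatrix(
        pd.DataFrame(
            np.vstack(blocks), index=gene_ids, columns=samples, dtype=np.int64
        ),
        pd.Series(organisms, index=gene_ids, name="organism"),
    )
    truth = GroundTruth(
        true_c_per_isolate=pd.Series(c, index=isolates, name="c_mg"),
        planted_pos_ids=planted_pos,
        planted_neg_ids=planted_neg,
        true_size_factors=sf_series,
    )
    return cm, meta, truth


#: annotation phrases sampled for synthetic transcripts; most contain a
#: lexicon keyword so category tallies are non-trivial
_ANNOTATION_POOL = [
    "hypothetical protein",
    "predicted protein of unknown function",
    "sugar transporter, MFS superfamily",
    "ABC transporter family protein",
    "hexose carrier protein",
    "serine/threonine protein kinase",
    "receptor-like kinase",
    "protein phosphatase 2C",
    "zinc finger transcription factor",
    "bZIP transcription factor",
    "MYB family transcriptional regulator",
    "heat shock protein 70 chaperone",
    "glutathione peroxidase, oxidative stress response",
    "cyclin-dependent cell cycle regulator",
    "expansin precursor",
    "glycoside hydrolase, carbohydrate catabolism",
    "trehalose-6-phosphate synthase",
    "invertase, sucrose catabolism",
    "inositol monophosphatase",
    "pathogenesis-related protein, disease resistance",
    "NBS-LRR resistance protein",
    "small secreted protein, putative effector",
    "aquaporin water channel",
    "calmodulin-binding signal transduction protein",
]


def generate_annotations(transcript_ids, rng) -> pd.Series:
    """Free-text functional annotations drawn from a fixed phrase pool."""
    ann = rng.choice(_ANNOTATION_POOL, size=len(transcript_ids))
    return pd.Series(ann, index=transcript_ids, name="annotation")


@dataclass
class SimulatedStudy:
    config: SyntheticConfig
    truth: GroundTruth
    isotope_samples: pd.DataFrame
    colonies: pd.DataFrame
    growth_raw: pd.DataFrame
    growth_true_means: pd.DataFrame
    counts: CountMatrix
    meta: pd.DataFrame
    annotations: pd.Series


def simulate_all(cfg: SyntheticConfig) -> SimulatedStudy:
    """Generate every input table of one synthetic study."""
    streams = cfg.streams()
    truth_c = default_truth_c(cfg, streams["truth"])
    samples, colonies = generate_isotope_data(cfg, truth_c, rng=streams["isotope"])
    growth_raw, growth_means = generate_growth_data(cfg, rng=streams["growth"])
    counts, meta, truth = generate_count_matrix(cfg, truth_c, rng=streams["counts"])
    annotations = generate_annotations(list(counts.counts.index), streams["counts"])
    return SimulatedStudy(
        config=cfg,
        truth=truth,
        isotope_samples=samples,
        colonies=colonies,
        growth_raw=growth_raw,
        growth_true_means=growth_means,
        counts=counts,
        meta=meta,
        annotations=annotations,
    )
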