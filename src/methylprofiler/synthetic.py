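"""Synthetic cohorts with known ground truth for every platform input.

Beta values are drawn per CpG from Beta-distribution mixtures with
hyper-, hemi- and hypo-methylated modes (mimicking real array bimodality);
phenotypes are linear in the causal betas plus Gaussian noise; a reference
cohort drawn from the same generator supplies panel means and Panel-4 style
paired score/phenotype data.

All draws derive from seeded child generators keyed on the simulation seed,
so :func:`simulate_methylation` and :func:`simulate_predictor_and_phenotypes`
are mutually consistent and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import (
    AGE_TRAIT_DEFAULT,
    BETA,
    MethylationMatrix,
    PhenotypeTable,
    SampleAnnotations,
)
from .preprocessing import ReferencePanel, beta_to_m
from .scoring import PredictorModel, compute_score, write_weight_file

# child-rng stream labels
_BETAS, _MISSING, _NOISE, _ANNOT, _REFERENCE, _MEANS = range(6)


@dataclass
class CohortSimulation:
    """Full generating configuration for one synthetic cohort."""

    seed: int = 0
    n_samples: int = 50
    n_cpgs: int = 100
    causal: dict[str, dict[str, float]] = field(default_factory=dict)  # trait -> {cpg: w}
    noise_sd: dict[str, float] = field(default_factory=dict)  # trait -> sd
    missing_cell_rate: float = 0.0
    missing_cpg_ids: tuple[str, ...] = ()  # held out of the "uploaded" matrix
    age_mean: float = 50.0
    age_sd: float = 10.0
    age_missing_rate: float = 0.0
    male_fraction: float = 0.5
    age_effect: dict[str, float] = field(default_factory=dict)  # trait -> per-year slope
    sex_effect: dict[str, float] = field(default_factory=dict)  # trait -> male offset
    case_trait: str | None = None
    case_threshold_quantile: float = 0.5
    case_random: bool = False  # null model: status independent of scores
    age_trait: str | None = None  # trait reported in years (scaled to age)
    concentration: float = 30.0  # Beta draw concentration around each CpG mean
    n_reference: int = 400

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.missing_cell_rate <= 1.0:
            raise ValidationError("missing_cell_rate must lie in [0, 1]")
        all_cpgs = set(self.cpg_ids)
        for trait, wmap in self.causal.items():
            if not wmap:
                raise ValidationError(f"trait {trait!r} requested with empty causal set")
            unknown = sorted(set(wmap) - all_cpgs)
            if unknown:
                raise ValidationError(
                    f"causal CpGs for {trait!r} not among simulated CpGs: {unknown}"
                )
        unknown = sorted(set(self.missing_cpg_ids) - all_cpgs)
        if unknown:
            raise ValidationError(f"missing_cpg_ids not among simulated CpGs: {unknown}")

    @property
    def cpg_ids(self) -> list[str]:
        return [f"cg{j:08d}" for j in range(1, self.n_cpgs + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i}" for i in range(1, self.n_samples + 1)]

    @property
    def traits(self) -> list[str]:
        return list(self.causal)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


def _cpg_means(sim: CohortSimulation) -> np.ndarray:
    """Per-CpG population means from a hypo/hemi/hyper mixture."""
    rng = sim._rng(_MEANS)
    mode = rng.integers(0, 3, size=sim.n_cpgs)
    means = np.where(
        mode == 0,
        rng.beta(2.0, 10.0, size=sim.n_cpgs),       # hypomethylated
        np.where(
            mode == 1,
            rng.beta(8.0, 8.0, size=sim.n_cpgs),    # hemimethylated
            rng.beta(10.0, 2.0, size=sim.n_cpgs),   # hypermethylated
        ),
    )
    return np.clip(means, 0.02, 0.98)


def _draw_betas(sim: CohortSimulation, rng: np.random.Generator, n: int) -> np.ndarray:
    means = _cpg_means(sim)
    a = means * sim.concentration
    b = (1.0 - means) * sim.concentration
    betas = rng.beta(a, b, size=(n, sim.n_cpgs))
    return np.clip(betas, 1e-6, 1.0 - 1e-6)


def simulate_full_betas(sim: CohortSimulation) -> MethylationMatrix:
    """Complete (no missingness, all CpGs) ground-truth beta matrix."""
    betas = _draw_betas(sim, sim._rng(_BETAS), sim.n_samples)
    df = pd.DataFrame(betas, index=sim.sample_ids, columns=sim.cpg_ids)
    return MethylationMatrix(df, BETA)


def simulate_methylation(sim: CohortSimulation, as_m_values: bool = False) -> MethylationMatrix:
    """The "uploaded" matrix: cells masked at ``missing_cell_rate`` and
    ``missing_cpg_ids`` columns withheld; optionally on the M-value scale."""
    full = simulate_full_betas(sim)
    df = full.values.copy()
    if sim.missing_cpg_ids:
        df = df.drop(columns=list(sim.missing_cpg_ids))
    if sim.missing_cell_rate > 0:
        rng = sim._rng(_MISSING)
        mask = rng.random(df.shape) < sim.missing_cell_rate
        df = df.mask(mask)
    m = MethylationMatrix(df, BETA)
    if as_m_values:
        return beta_to_m(m)
    return m


def _generating_models(sim: CohortSimulation) -> list[PredictorModel]:
    models = []
    for trait, wmap in sim.causal.items():
        units = "years" if trait == sim.age_trait else "arbitrary"
        models.append(PredictorModel(trait, dict(wmap), 0.0, units=units))
    return models


def simulate_annotations(sim: CohortSimulation) -> SampleAnnotations:
    rng = sim._rng(_ANNOT)
    age = np.maximum(rng.normal(sim.age_mean, sim.age_sd, size=sim.n_samples), 0.0)
    sex = np.where(rng.random(sim.n_samples) < sim.male_fraction, "Male", "Female")
    age = pd.Series(np.round(age, 1), index=sim.sample_ids, name="Age")
    if sim.age_missing_rate > 0:
        miss = rng.random(sim.n_samples) < sim.age_missing_rate
        age[miss] = np.nan
    df = pd.DataFrame({"Sex": sex, "Age": age}, index=pd.Index(sim.sample_ids, name="ID"))
    return SampleAnnotations(df)


def simulate_predictor_and_phenotypes(sim: CohortSimulation):
    """Generating models plus phenotypes, annotations, statuses and the panel.

    Returns ``(models, phenotypes, annotations, phenotype_table, panel)``
    where ``phenotypes`` is a DataFrame of continuous trait values
    (signal + covariate effects + noise) for the simulated samples.
    """
    if not sim.causal:
        raise ValidationError("no causal trait configured")
    full = simulate_full_betas(sim)
    models = _generating_models(sim)
    ann = simulate_annotations(sim)
    rng = sim._rng(_NOISE)

    sex_code = (ann.data["Sex"] == "Male").astype(float)
    age_for_effects = ann.data["Age"].fillna(sim.age_mean)
    phen = {}
    for mod in models:
        trait = mod.trait_name
        signal = compute_score(full, mod)
        sd = sim.noise_sd.get(trait, 0.0)
        noise = rng.normal(0.0, sd, size=sim.n_samples) if sd > 0 else np.zeros(sim.n_samples)
        values = (
            signal
            + sim.age_effect.get(trait, 0.0) * age_for_effects.to_numpy()
            + sim.sex_effect.get(trait, 0.0) * sex_code.to_numpy()
            + noise
        )
        phen[trait] = values
    phen = pd.DataFrame(phen, index=pd.Index(sim.sample_ids, name="ID"))

    status_df = None
    if sim.case_trait is not None:
        if sim.case_trait not in phen.columns:
            raise ValidationError(f"case trait {sim.case_trait!r} is not simulated")
        if sim.case_random:
            status = (rng.random(sim.n_samples) < (1 - sim.case_threshold_quantile)).astype(float)
        else:
            latent = phen[sim.case_trait].to_numpy()
            thr = np.quantile(latent, sim.case_threshold_quantile)
            status = (latent > thr).astype(float)
        status_df = PhenotypeTable(
            pd.DataFrame({sim.case_trait: status}, index=phen.index)
        )

    panel = _simulate_reference_panel(sim, models)
    return models, phen, ann, status_df, panel


def _simulate_reference_panel(sim: CohortSimulation, models) -> ReferencePanel:
    rng = sim._rng(_REFERENCE)
    betas = _draw_betas(sim, rng, sim.n_reference)
    ref_ids = [f"R{i}" for i in range(1, sim.n_reference + 1)]
    ref = MethylationMatrix(pd.DataFrame(betas, index=ref_ids, columns=sim.cpg_ids), BETA)
    cpg_means = ref.values.mean(axis=0)
    age = np.maximum(rng.normal(sim.age_mean, sim.age_sd, size=sim.n_reference), 0.0)
    sex = np.where(rng.random(sim.n_reference) < sim.male_fraction, "Male", "Female")
    scores = pd.DataFrame(
        {"Sex": sex, "Age": np.round(age, 1)}, index=pd.Index(ref_ids, name="ID")
    )
    phen = pd.DataFrame(index=scores.index)
    for mod in models:
        s = compute_score(ref, mod)
        scores[mod.trait_name] = s
        sd = sim.noise_sd.get(mod.trait_name, 0.0)
        noise = rng.normal(0.0, sd, size=sim.n_reference) if sd > 0 else 0.0
        phen[mod.trait_name] = s + noise
    return ReferencePanel(cpg_means, scores, phen, provenance=f"synthetic seed={sim.seed}")


# ---------------------------------------------------------------------------
# Fixture bundle


def default_simulation(seed: int = 0, n_samples: int = 40, n_cpgs: int = 60) -> CohortSimulation:
    """A small but fully featured cohort exercising every QC path."""
    cpgs = [f"cg{j:08d}" for j in range(1, n_cpgs + 1)]
    return CohortSimulation(
        seed=seed,
        n_samples=n_samples,
        n_cpgs=n_cpgs,
        causal={
            AGE_TRAIT_DEFAULT: {cpgs[0]: 60.0, cpgs[1]: -25.0, cpgs[2]: 40.0},
            "BMI": {cpgs[3]: 8.0, cpgs[4]: -5.0, cpgs[10]: 3.0},
            "Smoking": {cpgs[5]: 4.0, cpgs[6]: 6.0},
        },
        noise_sd={AGE_TRAIT_DEFAULT: 2.0, "BMI": 0.5, "Smoking": 0.4},
        missing_cell_rate=0.02,
        missing_cpg_ids=(cpgs[10],),
        age_trait=AGE_TRAIT_DEFAULT,
        case_trait="BMI",
        case_threshold_quantile=0.7,
        age_missing_rate=0.1,
    )


def write_fixture_bundle(sim: CohortSimulation, directory, m_values: bool = False) -> dict[str, Path]:
    """Write a complete, internally consistent CSV bundle for the CLI.

    The methylation matrix is written CpGs-as-rows (the recommended upload
    orientation), so reading it exercises the transposition path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    models, phen, ann, status, panel = simulate_predictor_and_phenotypes(sim)
    uploaded = simulate_methylation(sim, as_m_values=m_values)

    paths = {}

    mat = uploaded.values.T.copy()  # CpGs as rows
    mat.index.name = "CpG"
    paths["methylation"] = directory / "methylation.csv"
    mat.to_csv(paths["methylation"], na_rep="NA")

    paths["sexageinfo"] = directory / "sexageinfo.csv"
    ann.data.reset_index().rename(columns={"index": "ID"}).to_csv(
        paths["sexageinfo"], index=False, na_rep="NA"
    )

    if status is not None:
        paths["phenotypes"] = directory / "case_control.csv"
        out = status.data.copy()
        out.index.name = "ID"
        out.astype("Int64").to_csv(paths["phenotypes"], na_rep="NA")

    model_cpgs = sorted({c for mod in models for c in mod.weights})
    paths["truncate"] = directory / "truncate_cpgs.csv"
    pd.DataFrame({"CpG": model_cpgs}).to_csv(paths["truncate"], index=False)

    paths["weights"] = directory / "weights.csv"
    write_weight_file(models, paths["weights"])

    paths["manifest"] = directory / "manifest.yml"
    manifest = {"traits": {}}
    for mod in models:
        manifest["traits"][mod.trait_name] = {
            "units": mod.units, "transform": mod.output_transform,
        }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    paths["panel"] = directory / "panel.csv"
    pd.DataFrame(
        {"CpG": panel.cpg_means.index, "MeanBeta": panel.cpg_means.to_numpy()}
    ).to_csv(paths["panel"], index=False)

    paths["reference_scores"] = directory / "reference_scores.csv"
    panel.reference_scores.to_csv(paths["reference_scores"], na_rep="NA")
    paths["reference_phenotypes"] = directory / "reference_phenotypes.csv"
    panel.reference_phenotypes.to_csv(paths["reference_phenotypes"], na_rep="NA")

    return paths
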