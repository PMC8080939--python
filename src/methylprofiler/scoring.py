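"""Linear scoring of methylation matrices against CpG weight sets.

A predictor is a sparse linear model: score_i = b0 + sum_j w_j * beta_ij,
optionally followed by a declared output transform.  Weight files are
external inputs; the engine is weight-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MissingCpGError, ValidationError
from .io import (
    AGE_TRAIT_DEFAULT,
    BETA,
    TRAIT_ORDER,
    MethylationMatrix,
    SampleAnnotations,
    ScoreTable,
    _read_csv,
)
from .qc import QCReport

UNITS_YEARS = "years"
UNITS_ARBITRARY = "arbitrary"

#: output transforms a weight-file manifest may declare.  ``expm1`` is the
#: inverse of the log1p phenotype transform used in training (back to
#: natural units); default is identity (scores stay on the training scale).
TRANSFORMS = {
    "identity": lambda s: s,
    "expm1": np.expm1,
    "exp": np.exp,
}

INTERCEPT_TOKENS = {"Intercept", "(Intercept)"}


@dataclass
class PredictorModel:
    """Named trait with CpG weights, intercept, units and output transform."""

    trait_name: str
    weights: dict[str, float]
    intercept: float = 0.0
    units: str = UNITS_ARBITRARY
    output_transform: str = "identity"

    def __post_init__(self):
        if not self.weights:
            raise ValidationError(f"predictor {self.trait_name!r} has no weights")
        if self.output_transform not in TRANSFORMS:
            raise ValidationError(
                f"unknown output transform {self.output_transform!r}; "
                f"expected one of {sorted(TRANSFORMS)}"
            )
        if self.units not in (UNITS_YEARS, UNITS_ARBITRARY):
            raise ValidationError(f"unknown units {self.units!r}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.weights)


def compute_score(m: MethylationMatrix, model: PredictorModel) -> np.ndarray:
    """Per-sample weighted sum of methylation levels, in ``m.sample_ids`` order."""
    if m.scale != BETA:
        raise ValidationError("compute_score expects a beta-scale matrix")
    cols = model.cpg_ids
    missing = [c for c in cols if c not in m.values.columns]
    if missing:
        raise MissingCpGError(missing)
    X = m.values[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = m.values[cols].columns[m.values[cols].isna().any()].tolist()
        raise ValidationError(
            f"missing beta values remain at model CpGs after preprocessing: {bad}"
        )
    w = np.array([model.weights[c] for c in cols], dtype=float)
    scores = model.intercept + X @ w
    return TRANSFORMS[model.output_transform](scores)


def order_models(models: list[PredictorModel]) -> list[PredictorModel]:
    """Age trait first, then the canonical trait listing, then extras A-Z."""

    def key(item):
        i, mod = item
        if mod.units == UNITS_YEARS:
            return (0, 0, i)
        if mod.trait_name in TRAIT_ORDER:
            return (1, TRAIT_ORDER.index(mod.trait_name), i)
        return (2, 0, mod.trait_name)

    return [mod for _, mod in sorted(enumerate(models), key=lambda it: key(it))]


def compute_score_table(
    m: MethylationMatrix,
    models: list[PredictorModel],
    annotations: SampleAnnotations | None = None,
    qc: QCReport | None = None,
) -> ScoreTable:
    if not models:
        raise ConfigurationError("no predictor models configured")
    names = [mod.trait_name for mod in models]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate trait names across models: {dups}")
    clashes = [n for n in names if n in ("ID", "Sex", "Age")]
    if clashes:
        raise ConfigurationError(
            f"trait names clash with annotation columns: {clashes}"
        )
    models = order_models(models)

    data = pd.DataFrame(index=pd.Index(m.sample_ids, name="ID"))
    if annotations is not None:
        ann = annotations.data
        unmatched = [i for i in ann.index if i not in data.index]
        if unmatched and qc is not None:
            qc.add("annotations", "annotation rows with no matching sample dropped",
                   len(unmatched))
        data["Sex"] = ann["Sex"].reindex(data.index)
        data["Age"] = ann["Age"].reindex(data.index)
    for mod in models:
        data[mod.trait_name] = compute_score(m, mod)
    age_trait = next((mod.trait_name for mod in models if mod.units == UNITS_YEARS), None)
    if qc is not None:
        qc.add("score", "traits scored", len(models))
    return ScoreTable(data, [mod.trait_name for mod in models], age_trait)


# ---------------------------------------------------------------------------
# Weight-file and manifest IO


def read_weight_file(path, default_trait: str | None = None) -> list[PredictorModel]:
    """Load ``CpG,Weight[,Trait]`` rows; ``(Intercept)`` rows set intercepts."""
    df = _read_csv(path, dtype=str)
    for col in ("CpG", "Weight"):
        if col not in df.columns:
            raise ValidationError(f"weight file {path} lacks column {col!r}")
    if "Trait" not in df.columns:
        if default_trait is None:
            raise ValidationError(
                f"weight file {path} has no Trait column and no default trait given"
            )
        df = df.assign(Trait=default_trait)
    df["Weight"] = pd.to_numeric(df["Weight"])
    models = []
    for trait, grp in df.groupby("Trait", sort=False):
        is_int = grp["CpG"].isin(INTERCEPT_TOKENS)
        intercept = float(grp.loc[is_int, "Weight"].sum())
        weights = dict(zip(grp.loc[~is_int, "CpG"].astype(str), grp.loc[~is_int, "Weight"]))
        if len(weights) != (~is_int).sum():
            raise ValidationError(f"duplicate CpG ids in weights for trait {trait!r}")
        models.append(PredictorModel(str(trait), weights, intercept))
    return models


def write_weight_file(models: list[PredictorModel], path) -> None:
    rows = []
    for mod in models:
        rows.append({"CpG": "(Intercept)", "Weight": mod.intercept, "Trait": mod.trait_name})
        for cpg, w in mod.weights.items():
            rows.append({"CpG": cpg, "Weight": w, "Trait": mod.trait_name})
    pd.DataFrame(rows, columns=["CpG", "Weight", "Trait"]).to_csv(path, index=False)


def apply_manifest(models: list[PredictorModel], manifest_path) -> list[PredictorModel]:
    """Apply per-trait units/transform declarations from a YAML manifest."""
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh) or {}
    traits = spec.get("traits", spec)
    by_name = {mod.trait_name: mod for mod in models}
    for trait, opts in (traits or {}).items():
        if trait not in by_name:
            continue
        mod = by_name[trait]
        mod.units = (opts or {}).get("units", mod.units)
        mod.output_transform = (opts or {}).get("transform", mod.output_transform)
        mod.__post_init__()  # re-validate
    return models


def load_models(weights_path, manifest_path=None, default_trait=None) -> list[PredictorModel]:
    models = read_weight_file(weights_path, default_trait=default_trait)
    if manifest_path is not None:
        models = apply_manifest(models, manifest_path)
    else:
        # sensible default: a trait named like the default age column is in years
        for mod in models:
            if mod.trait_name == AGE_TRAIT_DEFAULT:
                mod.units = UNITS_YEARS
    return models
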