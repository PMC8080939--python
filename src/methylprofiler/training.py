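"""Penalized-regression training of new methylation trait predictors.

The recipe: apply phenotype exclusions and skew transforms, residualize on
age, sex and ten ancestry components, optionally restrict probes to the
450k/EPIC intersection, then fit a LASSO (mixing parameter 1) over a
100-value lambda path with 10-fold cross-validation, refitting on all
training data at the lambda of minimum mean CV error.

Predictors are standardized internally for the penalty; returned weights
are back-transformed to the beta scale so the scoring module's plain dot
product applies them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import ValidationError
from .io import BETA, MethylationMatrix
from .qc import QCReport
from .scoring import PredictorModel

SEX_CODING = {"Female": 0.0, "Male": 1.0}


@dataclass
class PhenotypeSpec:
    """Per-trait preparation: exclusion bounds then a skew transform."""

    name: str
    transform: str = "none"  # none | log | log1p
    exclusion_bounds: tuple[float, float] | None = None  # keep values in [lo, hi]
    unit_label: str = ""

    def __post_init__(self):
        if self.transform not in ("none", "log", "log1p"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.exclusion_bounds is not None:
            lo, hi = self.exclusion_bounds
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValidationError("exclusion bounds must be finite")


def transform_phenotype(values: pd.Series, spec: PhenotypeSpec):
    """Apply exclusion rules, then the transform.

    Returns ``(transformed, retained_mask, exclusion_log)``; the mask is
    False for missing values and excluded samples.  A transform undefined
    for a retained value (log of a non-positive) is a hard error naming the
    samples.
    """
    values = pd.Series(values, dtype=float)
    mask = values.notna()
    log = []
    n_missing = int((~mask).sum())
    if n_missing:
        log.append(f"{n_missing} samples missing {spec.name}")
    if spec.exclusion_bounds is not None:
        lo, hi = spec.exclusion_bounds
        out_of_bounds = mask & ~values.between(lo, hi)
        if out_of_bounds.any():
            log.append(
                f"{int(out_of_bounds.sum())} samples outside [{lo}, {hi}] removed"
            )
        mask &= ~out_of_bounds
    retained = values[mask]
    if spec.transform == "log":
        bad = retained.index[retained <= 0].tolist()
        if bad:
            raise ValidationError(
                f"log transform undefined for non-positive {spec.name} in samples {bad}"
            )
        transformed = np.log(retained)
    elif spec.transform == "log1p":
        bad = retained.index[retained <= -1].tolist()
        if bad:
            raise ValidationError(
                f"log1p transform undefined for {spec.name} <= -1 in samples {bad}"
            )
        transformed = np.log1p(retained)
    else:
        transformed = retained.copy()
    return transformed, mask, log


@dataclass
class CovariateMatrix:
    """Age, coded sex and ancestry components, row-aligned with the phenotype."""

    data: pd.DataFrame  # columns: age, sex (0/1) and ancestry components

    @classmethod
    def from_annotations(cls, age: pd.Series, sex: pd.Series, components: pd.DataFrame):
        sex_coded = sex.map(SEX_CODING)
        if sex_coded.isna().any():
            bad = sex[sex_coded.isna()].unique().tolist()
            raise ValidationError(f"cannot code sex tokens {bad} for covariates")
        df = pd.concat(
            [age.rename("age"), sex_coded.rename("sex"), components], axis=1
        )
        return cls(df)


def precorrect_phenotype(values: pd.Series, cov: CovariateMatrix) -> pd.Series:
    """Residuals of the phenotype after least-squares projection on the covariates.

    The design includes an intercept, so residuals have mean ~0 and are
    numerically orthogonal to every covariate column.
    """
    y = pd.Series(values, dtype=float)
    X = cov.data.loc[y.index]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns {bad}")
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError(
            f"underdetermined pre-correction: {n} samples for {k} covariates + intercept"
        )
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank beyond the preceding ones
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                collinear.append(X.columns[j - 1])
        raise ValidationError(f"rank-deficient covariates; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - design @ coef
    return pd.Series(resid, index=y.index, name=y.name)


def filter_probes_to_array_intersection(
    m: MethylationMatrix, intersection_list, qc: QCReport | None = None
) -> MethylationMatrix:
    """Restrict columns to probes present on both array generations."""
    wanted = set(intersection_list)
    if not wanted:
        raise ValidationError("array intersection list is empty")
    keep = [c for c in m.cpg_ids if c in wanted]
    if not keep:
        raise ValidationError("no matrix CpGs remain after array-intersection filtering")
    if qc is not None:
        qc.add("probe_filter", "CpG sites retained on the array intersection", len(keep))
    return MethylationMatrix(m.values[keep].copy(), m.scale, m.orientation_log)


@dataclass
class TrainingConfig:
    alpha: float = 1.0  # elastic-net mixing parameter; 1 = LASSO
    n_folds: int = 10
    lambda_rule: str = "min_cv_error"
    seed: int = 0
    probe_filter: str = "none"  # none | array_intersection
    n_lambdas: int = 100

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.lambda_rule != "min_cv_error":
            raise ValidationError(f"unknown lambda rule {self.lambda_rule!r}")
        if self.probe_filter not in ("none", "array_intersection"):
            raise ValidationError(f"unknown probe filter {self.probe_filter!r}")


@dataclass
class TrainingDetails:
    lambda_path: np.ndarray
    lambda_min: float
    cv_errors: np.ndarray  # mean CV MSE per lambda
    n_selected: int


def train_predictor(
    m: MethylationMatrix,
    phenotype: pd.Series,
    cfg: TrainingConfig,
    trait_name: str = "trait",
    return_details: bool = False,
):
    """Cross-validated penalized fit; refit at lambda_min on all training data.

    Returns a sparse :class:`PredictorModel` (weights on the beta scale);
    with ``return_details=True`` also the lambda path and CV error curve.
    Fold assignment is a deterministic shuffle from ``cfg.seed``.
    """
    if m.scale != BETA:
        raise ValidationError("train_predictor expects a beta-scale matrix")
    y = pd.Series(phenotype, dtype=float).loc[m.sample_ids]
    if y.isna().any():
        raise ValidationError("phenotype contains missing values after preparation")
    n = len(y)
    if cfg.n_folds > n:
        raise ValidationError(f"n_folds={cfg.n_folds} exceeds sample size {n}")
    if float(np.var(y)) == 0.0:
        raise ValidationError("zero-variance phenotype")
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("methylation matrix contains missing values; impute first")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    Xs = (X - mu) / sd_safe

    cv = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    fit = ElasticNetCV(
        l1_ratio=cfg.alpha if cfg.alpha > 0 else 1e-3,
        alphas=cfg.n_lambdas,  # int: length of the auto-scaled lambda path
        cv=cv,
        max_iter=5_000,
        tol=1e-4,
    )
    fit.fit(Xs, y.to_numpy(dtype=float))

    coef_std = fit.coef_
    coef = coef_std / sd_safe
    intercept = float(fit.intercept_ - np.sum(coef_std * mu / sd_safe))
    nz = np.flatnonzero(coef_std)
    weights = {m.cpg_ids[j]: float(coef[j]) for j in nz}
    if not weights:
        # null fit: keep the model usable with an explicit zero weight on
        # the first probe so the intercept-only prediction still applies
        weights = {m.cpg_ids[0]: 0.0}
    model = PredictorModel(trait_name, weights, intercept)
    if not return_details:
        return model
    details = TrainingDetails(
        lambda_path=fit.alphas_,
        lambda_min=float(fit.alpha_),
        cv_errors=fit.mse_path_.mean(axis=-1),
        n_selected=len(nz),
    )
    return model, details


def evaluate_predictor(model: PredictorModel, test_m: MethylationMatrix, test_phenotype) -> dict:
    """Held-out metrics: Pearson r, squared correlation R2, RMSE.

    Constant predictions have undefined r; reported as NaN with the R2=0
    convention and a note.
    """
    from .scoring import compute_score

    y = pd.Series(test_phenotype, dtype=float).loc[test_m.sample_ids].to_numpy()
    pred = compute_score(test_m, model)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.std(pred) == 0.0 or np.std(y) == 0.0:
        return {"r": np.nan, "R2": 0.0, "RMSE": rmse,
                "note": "constant predictions or outcomes; r undefined, R2=0 by convention"}
    r = float(np.corrcoef(pred, y)[0, 1])
    return {"r": r, "R2": r * r, "RMSE": rmse}
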