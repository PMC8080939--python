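"""Automated QC transformations applied before scoring.

Pipeline order is fixed: orient -> detect scale -> convert -> impute -> fill.
Conversion happens first so that imputation means and reference fills are
always computed on the beta scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import MissingCpGError, SchemaError, ValidationError
from .io import BETA, M_VALUE, MethylationMatrix, _read_csv
from .qc import QCReport

_LN2 = np.log(2.0)


def m_to_beta(m: MethylationMatrix, qc: QCReport | None = None) -> MethylationMatrix:
    """Convert M values to beta values via beta = 2^M / (2^M + 1).

    Computed as a logistic of M*ln2 for numerical stability at large |M|.
    Calling on a beta-scale matrix is a tolerated no-op (logged).
    """
    if m.scale == BETA:
        if qc is not None:
            qc.add("convert", "values already on the beta scale; no conversion", 0)
        return m
    vals = m.values.to_numpy(dtype=float)
    beta = expit(vals * _LN2)
    out = MethylationMatrix(
        pd.DataFrame(beta, index=m.values.index, columns=m.values.columns),
        BETA,
        m.orientation_log,
    )
    if qc is not None:
        n = int(np.count_nonzero(~np.isnan(vals)))
        qc.add("convert", "M values converted to beta values", n)
    return out


def beta_to_m(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse map M = log2(beta / (1 - beta)); used by simulators and tests."""
    if m.scale != BETA:
        raise ValidationError("beta_to_m expects a beta-scale matrix")
    b = m.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        mv = np.log2(b / (1.0 - b))
    return MethylationMatrix(
        pd.DataFrame(mv, index=m.values.index, columns=m.values.columns),
        M_VALUE,
        m.orientation_log,
    )


def clip_beta(m: MethylationMatrix, qc: QCReport | None = None) -> MethylationMatrix:
    """Clip declared-beta values marginally outside [0, 1] (normalization spill)."""
    if m.scale != BETA:
        raise ValidationError("clip_beta expects a beta-scale matrix")
    vals = m.values.to_numpy(dtype=float)
    outside = (~np.isnan(vals)) & ((vals < 0.0) | (vals > 1.0))
    n = int(outside.sum())
    if n == 0:
        return m
    clipped = np.clip(vals, 0.0, 1.0)
    if qc is not None:
        qc.add("clip", "warning: beta values outside [0,1] clipped", n)
    return MethylationMatrix(
        pd.DataFrame(clipped, index=m.values.index, columns=m.values.columns),
        BETA,
        m.orientation_log,
    )


def impute_missing_values(m: MethylationMatrix, qc: QCReport | None = None) -> MethylationMatrix:
    """Mean-impute missing cells per CpG across the uploaded samples.

    Columns with no observed value at all are left missing here (they are
    handled by :func:`fill_missing_cpgs`) and flagged in the QC report.
    """
    if m.scale != BETA:
        raise ValidationError("impute_missing_values expects a beta-scale matrix")
    vals = m.values
    n_missing = int(vals.isna().to_numpy().sum())
    if n_missing == 0:
        if qc is not None:
            qc.add("impute", "no missing methylation values", 0)
        return m
    col_means = vals.mean(axis=0, skipna=True)
    fully_missing = col_means.index[col_means.isna()]
    filled = vals.fillna(col_means)
    n_imputed = n_missing - int(filled.isna().to_numpy().sum())
    if qc is not None:
        qc.add("impute", "missing values mean-imputed across input individuals", n_imputed)
        if len(fully_missing):
            qc.add(
                "impute",
                "warning: CpG sites with no observed values left for reference fill",
                len(fully_missing),
            )
    return MethylationMatrix(filled, BETA, m.orientation_log)


@dataclass
class ReferencePanel:
    """External-cohort summaries used to fill absent probes and contextualize scores.

    cpg_means
        Per-CpG mean beta values from the reference cohort.
    reference_scores
        Optional per-sample reference table: ``Sex``/``Age`` columns plus one
        predicted-score column per trait.
    reference_phenotypes
        Optional measured phenotype values for the same reference samples,
        one column per trait, row-aligned with ``reference_scores`` by ID.
    """

    cpg_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    reference_scores: pd.DataFrame | None = None
    reference_phenotypes: pd.DataFrame | None = None
    provenance: str = ""

    def __post_init__(self):
        means = self.cpg_means.dropna()
        if len(means) and (((means < 0.0) | (means > 1.0)).any()):
            raise ValidationError("reference cpg_means must lie in [0, 1]")


def read_reference_panel(
    means_path, scores_path=None, phenotypes_path=None, provenance: str = ""
) -> ReferencePanel:
    df = _read_csv(means_path)
    for col in ("CpG", "MeanBeta"):
        if col not in df.columns:
            raise SchemaError(f"reference panel {means_path} lacks column {col!r}")
    means = pd.Series(
        pd.to_numeric(df["MeanBeta"]).to_numpy(), index=df["CpG"].astype(str)
    )
    scores = None
    if scores_path is not None:
        scores = _read_csv(scores_path).set_index("ID")
        scores.index = scores.index.astype(str)
    phen = None
    if phenotypes_path is not None:
        phen = _read_csv(phenotypes_path).set_index("ID")
        phen.index = phen.index.astype(str)
    return ReferencePanel(means, scores, phen, provenance)


def fill_missing_cpgs(
    m: MethylationMatrix,
    model_cpgs,
    panel: ReferencePanel,
    qc: QCReport | None = None,
) -> MethylationMatrix:
    """Add constant reference-mean columns for model CpGs absent from the upload.

    Every sample receives the reference cohort's mean beta for each absent
    CpG, shifting all scores by the same additive constant.  CpGs absent
    from both the matrix and the panel are a hard error.
    """
    if m.scale != BETA:
        raise ValidationError("fill_missing_cpgs expects a beta-scale matrix")
    present = set(m.cpg_ids)
    needed = [c for c in dict.fromkeys(model_cpgs) if c not in present]
    # columns that survived imputation fully missing also need the reference mean
    fully_missing = [c for c in m.cpg_ids if m.values[c].isna().all()]
    unavailable = [
        c for c in needed + fully_missing if c not in panel.cpg_means.index
    ]
    if unavailable:
        raise MissingCpGError(unavailable)
    out = m.values.copy()
    for c in fully_missing:
        out[c] = panel.cpg_means[c]
    if needed:
        new_cols = pd.DataFrame(
            {c: np.full(m.n_samples, panel.cpg_means[c]) for c in needed},
            index=m.values.index,
        )
        out = pd.concat([out, new_cols], axis=1)
    if qc is not None:
        qc.add(
            "fill", "absent CpG sites filled with reference mean beta values",
            len(needed) + len(fully_missing),
        )
    return MethylationMatrix(out, BETA, m.orientation_log)
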