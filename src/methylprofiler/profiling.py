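"""Percentile-rank profiling: per-sample ranks, individual profiles,
case/control summaries and correlation panels under cohort subsetting.

Percentiles use the mid-rank rule p = 100 * (rank - 0.5) / n with averaged
ranks for ties, so a tie-free cohort averages exactly 50 and no sample hits
0 or 100.  Ranks are always recomputed on the displayed (filtered) table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import ProfilingError, ValidationError
from .io import PhenotypeTable, ScoreTable
from .preprocessing import ReferencePanel

SEX_BOTH = "both"
STATUS_CASES = "cases"
STATUS_CONTROLS = "controls"
STATUS_BOTH = "both"


@dataclass
class CohortFilter:
    """Age-range / sex / case-control restriction applied to a score table."""

    age_range: tuple[float, float] | None = None
    sex: str = SEX_BOTH
    status_filter: tuple[str, str] | None = None  # (phenotype, cases|controls|both)

    def __post_init__(self):
        if self.age_range is not None:
            lo, hi = self.age_range
            if lo > hi:
                raise ValidationError(f"age range low {lo} exceeds high {hi}")
        if self.sex not in ("Male", "Female", SEX_BOTH):
            raise ValidationError(f"sex filter must be Male, Female or both; got {self.sex!r}")
        if self.status_filter is not None:
            _, which = self.status_filter
            if which not in (STATUS_CASES, STATUS_CONTROLS, STATUS_BOTH):
                raise ValidationError(f"status filter must be cases, controls or both; got {which!r}")


def subset_cohort(
    t: ScoreTable,
    f: CohortFilter,
    phenotypes: PhenotypeTable | None = None,
) -> ScoreTable:
    """Retain samples matching the filter.

    The effective age is the uploaded chronological age where available and
    the epigenetic-age score otherwise; samples with sex NA are excluded
    when a specific sex is requested.  An empty result is valid.
    """
    keep = pd.Series(True, index=t.data.index)
    if f.age_range is not None:
        age = t.effective_age()
        if age.isna().all():
            raise ProfilingError(
                "age filtering requested but no true or epigenetic age is available"
            )
        lo, hi = f.age_range
        keep &= age.between(lo, hi)
    if f.sex != SEX_BOTH:
        if "Sex" not in t.data.columns:
            raise ProfilingError("sex filtering requested but no Sex annotations present")
        keep &= t.data["Sex"] == f.sex
    if f.status_filter is not None:
        name, which = f.status_filter
        if phenotypes is None:
            raise ProfilingError("status filtering requested but no phenotype table given")
        if name not in phenotypes.phenotypes:
            raise ProfilingError(
                f"unknown phenotype {name!r}; available: {phenotypes.phenotypes}"
            )
        status = phenotypes.data[name].reindex(t.data.index)
        if which == STATUS_CASES:
            keep &= status == 1.0
        elif which == STATUS_CONTROLS:
            keep &= status == 0.0
    return t.subset(t.data.index[keep.fillna(False)])


def _midrank_percentiles(values: np.ndarray) -> np.ndarray:
    n = len(values)
    return 100.0 * (rankdata(values, method="average") - 0.5) / n


def percentile_ranks(t: ScoreTable) -> pd.DataFrame:
    """Per-sample percentile per trait; the age trait passes through in years.

    Returns a DataFrame indexed by sample ID with the true-age column (when
    present) and one column per trait.
    """
    if len(t.data) == 0:
        raise ProfilingError("cannot compute percentile ranks for an empty table")
    cols = {}
    if "Age" in t.data.columns:
        cols["Age"] = t.data["Age"]
    for trait in t.traits:
        if trait == t.age_trait:
            cols[trait] = t.data[trait]
        else:
            cols[trait] = _midrank_percentiles(t.data[trait].to_numpy(dtype=float))
    out = pd.DataFrame(cols, index=t.data.index)
    out.index.name = "ID"
    return out


def individual_profile(t: ScoreTable, sample_id: str, traits=None) -> pd.Series:
    """Percentiles (or years for the age trait) for one sample within ``t``."""
    if sample_id not in t.data.index:
        raise KeyError(f"unknown sample id {sample_id!r}")
    traits = list(traits) if traits is not None else list(t.traits)
    unknown = [tr for tr in traits if tr not in t.traits]
    if unknown:
        raise ProfilingError(f"unknown traits {unknown}; available: {t.traits}")
    ranks = percentile_ranks(t)
    return ranks.loc[sample_id, traits]


def case_control_summary(
    t: ScoreTable,
    phenotypes: PhenotypeTable,
    phenotype: str,
    traits=None,
) -> pd.DataFrame:
    """Median and quartiles of case percentiles per trait.

    Percentiles are computed over cases plus controls together (samples with
    missing status are excluded), then summarized over the cases.  Quartiles
    interpolate linearly between order statistics.
    """
    if phenotype not in phenotypes.phenotypes:
        raise ProfilingError(
            f"unknown phenotype {phenotype!r}; available: {phenotypes.phenotypes}"
        )
    traits = list(traits) if traits is not None else [tr for tr in t.traits if tr != t.age_trait]
    unknown = [tr for tr in traits if tr not in t.traits]
    if unknown:
        raise ProfilingError(f"unknown traits {unknown}; available: {t.traits}")
    status = phenotypes.data[phenotype].reindex(t.data.index)
    known = status.notna()
    sub = t.subset(t.data.index[known])
    status = status[known]
    n_cases = int((status == 1.0).sum())
    n_controls = int((status == 0.0).sum())
    rows = []
    if n_cases == 0:
        return pd.DataFrame(
            columns=["trait", "median", "q1", "q3", "n_cases", "n_controls"]
        ).set_index("trait")
    ranks = percentile_ranks(sub)
    case_ids = status.index[status == 1.0]
    for trait in traits:
        p = ranks.loc[case_ids, trait].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(p, [25, 50, 75], method="linear")
        rows.append(
            {"trait": trait, "median": med, "q1": q1, "q3": q3,
             "n_cases": n_cases, "n_controls": n_controls}
        )
    return pd.DataFrame(rows).set_index("trait")


def _corr(df: pd.DataFrame, method: str) -> pd.DataFrame:
    if method == "pearson":
        return df.corr(method="pearson")
    if method == "spearman":
        return df.corr(method="spearman")
    raise ValidationError(f"unknown correlation method {method!r}")


def score_correlations(
    t: ScoreTable,
    traits=None,
    panel: ReferencePanel | None = None,
    phenotypes: PhenotypeTable | None = None,
    phenotype: str | None = None,
    method: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Inter-predictor correlation matrices for the input cohort.

    Returns a dict with key ``input`` and, when available, ``reference``
    (from the panel's reference scores) plus ``cases``/``controls``
    side-by-side matrices when a phenotype is named.  Zero-variance traits
    yield undefined (NaN) rows/columns, never 0.
    """
    traits = list(traits) if traits is not None else list(t.traits)
    if len(traits) < 2:
        raise ProfilingError("correlation panel needs at least two traits")
    if len(t.data) < 3:
        raise ProfilingError(
            f"correlation panel needs at least 3 samples after filtering; have {len(t.data)}"
        )
    unknown = [tr for tr in traits if tr not in t.traits]
    if unknown:
        raise ProfilingError(f"unknown traits {unknown}; available: {t.traits}")
    out = {"input": _corr(t.data[traits], method)}
    if panel is not None and panel.reference_scores is not None:
        ref_traits = [tr for tr in traits if tr in panel.reference_scores.columns]
        if len(ref_traits) >= 2:
            out["reference"] = _corr(panel.reference_scores[ref_traits], method)
    if phenotypes is not None and phenotype is not None:
        for which, code, key in ((STATUS_CASES, 1.0, "cases"), (STATUS_CONTROLS, 0.0, "controls")):
            sub = subset_cohort(t, CohortFilter(status_filter=(phenotype, which)), phenotypes)
            if len(sub.data) >= 3:
                out[key] = _corr(sub.data[traits], method)
    return out


def reference_trait_correlations(
    panel: ReferencePanel,
    traits=None,
    f: CohortFilter | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of predicted vs measured trait values in the reference cohort.

    Rows: trait, r, n, available.  Traits without paired reference data are
    reported as unavailable rather than raising.
    """
    if panel.reference_scores is None or panel.reference_phenotypes is None:
        raise ProfilingError(
            "reference panel carries no paired score/phenotype data"
        )
    scores = panel.reference_scores
    if f is not None:
        keep = pd.Series(True, index=scores.index)
        if f.age_range is not None:
            if "Age" not in scores.columns:
                raise ProfilingError("reference scores carry no Age column")
            lo, hi = f.age_range
            keep &= scores["Age"].between(lo, hi)
        if f.sex != SEX_BOTH:
            if "Sex" not in scores.columns:
                raise ProfilingError("reference scores carry no Sex column")
            keep &= scores["Sex"] == f.sex
        scores = scores[keep.fillna(False)]
    phen = panel.reference_phenotypes.reindex(scores.index)
    score_traits = [c for c in scores.columns if c not in ("Sex", "Age")]
    traits = list(traits) if traits is not None else score_traits
    rows = []
    for trait in traits:
        if trait not in scores.columns or trait not in phen.columns:
            rows.append({"trait": trait, "r": np.nan, "n": 0, "available": False})
            continue
        pair = pd.DataFrame({"s": scores[trait], "p": phen[trait]}).dropna()
        if len(pair) < 3 or pair["s"].nunique() < 2 or pair["p"].nunique() < 2:
            rows.append({"trait": trait, "r": np.nan, "n": len(pair), "available": False})
            continue
        if method == "spearman":
            r = spearmanr(pair["s"], pair["p"]).statistic
        else:
            r = float(np.corrcoef(pair["s"], pair["p"])[0, 1])
        rows.append({"trait": trait, "r": r, "n": len(pair), "available": True})
    return pd.DataFrame(rows).set_index("trait")
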