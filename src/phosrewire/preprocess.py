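"""Filtering, normalization, and condition-aware left-censored imputation.

Missing values in phosphoproteomics are predominantly missing-not-at-random:
a peptide that is absent or strongly de-phosphorylated in one condition falls
below the detection limit there while remaining well quantified elsewhere.
The imputation here exploits that structure in two steps:

1. *Condition-pair imputation* — within each biological group, when one
   treatment arm of a feature is poorly quantified while the other arm is
   well quantified, all missing values on the poor side are drawn from a
   downshifted normal ``N(val_min - downshift, sigma_wellquant^2)``, where
   ``val_min`` is the feature's minimum observed log2 intensity across all
   conditions and ``sigma_wellquant`` the standard deviation of the
   well-quantified arm. This encodes "the peptide was below the limit of
   detection on the poor side".
2. *Self imputation* (mouse / inhibitor studies) — within a single
   (group, treatment) cell with enough quantifications, remaining holes are
   drawn from that cell's own ``N(mu, sigma^2)``.

Both steps are deterministic given the master seed: each feature draws from
a substream keyed by a stable hash of its feature_id, so row order never
changes the imputed values.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import IntensityTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Replicate-count filter.

    min_total_replicates: minimum number of samples (across the whole study)
    in which a feature must be quantified. require_group: if set, the feature
    must additionally be quantified in >= 1 sample of that group.
    """

    min_total_replicates: int = 0
    require_group: str | None = None

    def __post_init__(self) -> None:
        if self.min_total_replicates < 0:
            raise ValueError("min_total_replicates must be >= 0")


@dataclass
class ImputationParams:
    """Quantification criteria and distribution parameters for imputation.

    poor_max / well_min define "poorly quantified" (count <= poor_max) and
    "well quantified" (count >= well_min) treatment arms; well_min may be a
    mapping group -> count where groups have unequal replicate numbers.
    downshift is in log2 units. step2_min gates the self-imputation step.
    skip_single_above_mean enables the inhibitor-study exception: a lone
    observed value on the poor side that exceeds the mean of the well side
    (evidence against censoring) suppresses imputation for that feature.
    """

    poor_max: int = 0
    well_min: int | dict[str, int] = 4
    downshift: float = 1.0
    step2_min: int | None = None
    skip_single_above_mean: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.downshift <= 0:
            raise ValueError("downshift must be > 0")
        wm = self.well_min if isinstance(self.well_min, int) else min(self.well_min.values())
        if self.poor_max >= wm:
            raise ValueError("poor_max must be < well_min")

    def well_min_for(self, group: str) -> int:
        if isinstance(self.well_min, int):
            return self.well_min
        return self.well_min[group]


#: Study-specific defaults quoted from the processing protocol.
STUDY_IMPUTATION_DEFAULTS: dict[str, dict] = {
    # 3T3-L1 insulin-resistance phospho: poor = 0 quantifications; well =
    # >=5/6 (CTRL) or 4/4 (each model); no self-imputation step.
    "cell_ir": dict(poor_max=0, well_min={"CTRL": 5, "CI": 4, "DEX": 4,
                                          "TNF": 4, "MPQ": 4, "AA": 4},
                    step2_min=None, skip_single_above_mean=False),
    # mouse adipose phospho: poor = 0/12, well = >=7/12, self step at >=5.
    "mouse": dict(poor_max=0, well_min=7, step2_min=5,
                  skip_single_above_mean=False),
    # GSK3 inhibitor phospho: poor <= 1/4, well >= 3/4, self step at >=3,
    # with the lone-high-value exception.
    "gsk3i": dict(poor_max=1, well_min=3, step2_min=3,
                  skip_single_above_mean=True),
}


def default_imputation_params(study: str, seed: int = 0) -> ImputationParams:
    if study not in STUDY_IMPUTATION_DEFAULTS:
        raise ValueError(f"unknown study kind {study!r}")
    return ImputationParams(rng_seed=seed, **STUDY_IMPUTATION_DEFAULTS[study])


def _feature_rng(master_seed: int, feature_id: str, stage: str) -> np.random.Generator:
    # stable across platforms and row order: hash the feature id, not its index
    digest = hashlib.sha256(f"{stage}:{feature_id}".encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, key]))


def filter_features(table: IntensityTable, spec: FilterSpec) -> IntensityTable:
    """Drop features under-quantified overall or absent from a required group."""
    counts = table.values.notna().sum(axis=1)
    keep = counts >= spec.min_total_replicates
    if spec.require_group is not None:
        cols = table.samples_of(spec.require_group)
        if not cols:
            raise ValidationError(f"required group {spec.require_group!r} has no samples")
        keep &= table.values[cols].notna().any(axis=1)
    kept = table.subset(table.feature_ids[keep])
    logger.info("filter_features: %d/%d features retained", keep.sum(), len(keep))
    return kept


def log2_median_normalize(table: IntensityTable) -> IntensityTable:
    """log2-transform and shift each sample column to the grand median.

    Each column is shifted so that its median over non-missing values equals
    the median of all column medians; this equalizes sample loading while
    keeping the intensity scale interpretable (required by the downshifted
    imputation, which reasons in absolute log2 units).
    """
    if table.scale_state != "raw":
        raise ValidationError("log2_median_normalize expects raw intensities")
    if (table.values <= 0).any().any():
        bad = table.values.columns[(table.values <= 0).any(axis=0)].tolist()
        raise ValidationError(f"non-positive raw intensities in columns {bad}")
    out = table.copy()
    logv = np.log2(out.values)
    col_medians = logv.median(axis=0, skipna=True)
    grand = float(col_medians.median())
    out.values = logv - col_medians + grand
    out.scale_state = "log2_norm"
    return out


def impute_condition_pair(
    table: IntensityTable,
    params: ImputationParams,
    group: str,
) -> IntensityTable:
    """Downshifted-normal imputation within one group's treatment pair.

    For each feature, if one treatment arm of ``group`` is poorly quantified
    (count <= poor_max) while the other is well quantified
    (count >= well_min), every missing value on the poor side is drawn from
    ``N(val_min - downshift, sigma_wellquant^2)`` with ``val_min`` the
    feature's minimum observed intensity across *all* samples of the study.
    Features whose well side has fewer than two values (sigma undefined) are
    skipped with a warning. Observed values are never overwritten.
    """
    if table.scale_state not in {"log2_norm", "imputed"}:
        raise ValidationError("imputation expects log2 median-normalized data")
    treatments = sorted(table.design["treatment"].unique())
    cols_by_treat = {t: table.samples_of(group, t) for t in treatments}
    if any(not c for c in cols_by_treat.values()):
        raise ValidationError(f"group {group!r} lacks one of the treatment arms")

    out = table.copy()
    if out.imputed is None:
        out.imputed = pd.DataFrame(False, index=out.values.index, columns=out.values.columns)
    vals = out.values
    well_min = params.well_min_for(group)

    counts = {t: vals[cols_by_treat[t]].notna().sum(axis=1) for t in treatments}
    val_min = vals.min(axis=1)  # min over all conditions (observed only)

    n_imputed = 0
    for p_t, w_t in [(treatments[0], treatments[1]), (treatments[1], treatments[0])]:
        candidates = vals.index[
            (counts[p_t] <= params.poor_max) & (counts[w_t] >= well_min)
        ]
        for fid in candidates:
            well_vals = vals.loc[fid, cols_by_treat[w_t]]
            if int(well_vals.notna().sum()) < 2:
                logger.warning("impute_condition_pair: %s %s sigma undefined, skipped",
                               fid, group)
                continue
            poor_vals = vals.loc[fid, cols_by_treat[p_t]]
            if (params.skip_single_above_mean and int(poor_vals.notna().sum()) == 1
                    and float(poor_vals.dropna().iloc[0]) > float(well_vals.mean())):
                # a lone high value argues against censoring on the poor side
                continue
            sigma = float(well_vals.std(ddof=1))
            rng = _feature_rng(params.rng_seed, str(fid), "pair")
            missing_cols = [c for c in cols_by_treat[p_t] if pd.isna(poor_vals[c])]
            draws = rng.normal(val_min[fid] - params.downshift, sigma,
                               size=len(missing_cols))
            vals.loc[fid, missing_cols] = draws
            out.imputed.loc[fid, missing_cols] = True
            n_imputed += len(missing_cols)
    logger.info("impute_condition_pair(%s): %d values imputed", group, n_imputed)
    out.scale_state = "imputed"
    return out


def impute_self(table: IntensityTable, params: ImputationParams) -> IntensityTable:
    """Within-cell normal imputation for well-populated (group, treatment) cells.

    Runs after condition-pair imputation in the mouse and inhibitor studies:
    any (group, treatment) cell with at least ``step2_min`` quantifications
    has its remaining missing values drawn from the cell's own
    ``N(mu, sigma^2)``.
    """
    if params.step2_min is None:
        raise ValidationError("step2_min not set: self-imputation not enabled for this study")
    if table.scale_state not in {"log2_norm", "imputed"}:
        raise ValidationError("imputation expects log2 median-normalized data")
    out = table.copy()
    if out.imputed is None:
        out.imputed = pd.DataFrame(False, index=out.values.index, columns=out.values.columns)
    vals = out.values
    cells = [
        (g, t, table.samples_of(g, t))
        for g in table.design["group"].unique()
        for t in table.design["treatment"].unique()
    ]
    n_imputed = 0
    rngs: dict[str, np.random.Generator] = {}
    for g, t, cols in cells:
        block = vals[cols]
        n_obs = block.notna().sum(axis=1)
        candidates = vals.index[(n_obs >= params.step2_min) & (n_obs < len(cols))]
        for fid in candidates:
            arm = vals.loc[fid, cols]
            mu = float(arm.mean())
            sigma = float(arm.std(ddof=1))
            rng = rngs.setdefault(str(fid), _feature_rng(params.rng_seed, str(fid), "self"))
            missing_cols = [c for c in cols if pd.isna(arm[c])]
            draws = rng.normal(mu, sigma, size=len(missing_cols))
            vals.loc[fid, missing_cols] = draws
            out.imputed.loc[fid, missing_cols] = True
            n_imputed += len(missing_cols)
    logger.info("impute_self: %d values imputed", n_imputed)
    out.scale_state = "imputed"
    return out


def preprocess_study(
    table: IntensityTable,
    study: str,
    filter_spec: FilterSpec | None = None,
    params: ImputationParams | None = None,
    seed: int = 0,
) -> IntensityTable:
    """Full preprocessing chain: filter, log2+normalize, impute per study kind."""
    if params is None:
        params = default_imputation_params(study, seed=seed)
    if filter_spec is not None:
        table = filter_features(table, filter_spec)
    table = log2_median_normalize(table)
    for group in table.design["group"].unique():
        table = impute_condition_pair(table, params, group)
    if params.step2_min is not None:
        table = impute_self(table, params)
    return table
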