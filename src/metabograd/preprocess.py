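"""Preprocessing chain for semi-quantitative metabolite intensities.

The canonical order is raw -> minimum-detected imputation -> nonxenobiotic
>=95% detection filter -> per-metabolite Box-Cox -> z-scoring against the
healthy-control reference (-> quantile normalisation across samples, used to
merge batches).  Each step consumes and returns a
:class:`~metabograd.io.MetaboliteMatrix` and advances its ``scale_tag``, so
an out-of-order call fails loudly.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import MetaboliteAnnotation, MetaboliteMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class BoxCoxParams:
    """Per-metabolite power parameter lambda and pre-transform shift c."""

    table: pd.DataFrame  # index metabolite_id, columns ["lam", "shift"]

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["lam"]).all():
            raise ValidationError("non-finite Box-Cox lambda")


@dataclasses.dataclass
class ReferenceStats:
    """Healthy-control mean and sd per metabolite on the Box-Cox scale."""

    table: pd.DataFrame  # index metabolite_id, columns ["mean", "sd"]

    def __post_init__(self) -> None:
        if (self.table["sd"] <= 0).any():
            bad = self.table.index[self.table["sd"] <= 0].tolist()
            raise ValidationError(f"non-positive reference sd for {bad}")


def impute_min_detected(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each missing cell with the metabolite's minimum detected level.

    Metabolites with no detected value at all cannot be imputed and are
    dropped with a warning.
    """
    if matrix.scale_tag != "raw":
        raise ValidationError(f"impute expects raw values, got {matrix.scale_tag}")
    df = matrix.data
    all_missing = df.columns[df.isna().all()]
    if len(all_missing):
        log.warning("dropping %d all-missing metabolites: %s",
                    len(all_missing), list(all_missing))
        df = df.drop(columns=all_missing)
    filled = df.fillna(df.min(axis=0))
    out = matrix.evolve(filled, "imputed")
    out.detected = matrix.detected.loc[filled.index, filled.columns]
    return out


def detection_filter(
    matrix: MetaboliteMatrix,
    annotation: MetaboliteAnnotation,
    threshold: float = 0.95,
) -> MetaboliteMatrix:
    """Keep nonxenobiotic metabolites detected in >= ``threshold`` of samples.

    The detection mask is the pre-imputation one carried on the matrix, so
    this runs identically before or after imputation.  The boundary is
    inclusive: a metabolite detected in exactly 95% of samples is retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("detection threshold must lie in (0, 1]")
    det_frac = matrix.detected.mean(axis=0)
    keep = det_frac >= threshold
    ann = annotation.data.reindex(matrix.data.columns)
    xeno = ann["xenobiotic"].fillna(False).astype(bool)
    keep &= ~xeno
    dropped = int((~keep).sum())
    if dropped:
        log.info("detection filter removed %d of %d metabolites",
                 dropped, len(keep))
    kept_cols = matrix.data.columns[keep]
    out = MetaboliteMatrix(
        data=matrix.data[kept_cols],
        scale_tag=matrix.scale_tag,
        detected=matrix.detected[kept_cols],
    )
    return out


def _boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


DEFAULT_LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def fit_boxcox(
    matrix: MetaboliteMatrix,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> BoxCoxParams:
    """Choose lambda per metabolite by maximum profile likelihood on a grid.

    A shift c makes every value strictly positive before the transform
    (c = 0 unless nonpositive values exist, then c = 1e-6 + |min|).
    """
    if matrix.scale_tag not in {"raw", "imputed"}:
        raise ValidationError(
            f"Box-Cox expects raw/imputed intensities, got {matrix.scale_tag}"
        )
    grid = np.asarray(grid, dtype=float)
    X = matrix.data.to_numpy(dtype=float)
    mins = np.nanmin(X, axis=0)
    shifts = np.where(mins > 0, 0.0, 1e-6 + np.abs(mins))
    Xs = X + shifts
    if np.nanmin(Xs) <= 0:
        bad = matrix.data.columns[np.nanmin(Xs, axis=0) <= 0]
        raise ValidationError(f"nonpositive shifted values for {list(bad)}")
    # profile log-likelihood, all metabolites at once per grid point:
    # llf(lam) = (lam - 1) * sum(log x) - n/2 * log(mean((y - ybar)^2))
    logs = np.log(Xs)
    n = np.sum(np.isfinite(Xs), axis=0)
    sum_log = np.nansum(logs, axis=0)
    best_llf = np.full(X.shape[1], -np.inf)
    best_lam = np.zeros(X.shape[1])
    with np.errstate(invalid="ignore"):
        for lam in grid:
            y = logs if lam == 0 else (np.power(Xs, lam) - 1.0) / lam
            var = np.nanvar(y, axis=0)
            llf = (lam - 1) * sum_log - n / 2 * np.log(var)
            better = llf > best_llf
            best_llf[better] = llf[better]
            best_lam[better] = lam
    table = pd.DataFrame(
        {"lam": best_lam, "shift": shifts},
        index=pd.Index(matrix.data.columns, name="metabolite_id"),
    )
    return BoxCoxParams(table=table)


def apply_boxcox(matrix: MetaboliteMatrix, params: BoxCoxParams) -> MetaboliteMatrix:
    """Apply y = ((x+c)^lam - 1)/lam (ln(x+c) at lam=0) per metabolite."""
    if matrix.scale_tag not in {"raw", "imputed"}:
        raise ValidationError(
            f"Box-Cox expects raw/imputed intensities, got {matrix.scale_tag}"
        )
    out = {}
    for met in matrix.data.columns:
        lam = float(params.table.loc[met, "lam"])
        shift = float(params.table.loc[met, "shift"])
        x = matrix.data[met].to_numpy(dtype=float) + shift
        if np.nanmin(x) <= 0:
            raise ValidationError(f"nonpositive shifted values for {met}")
        out[met] = _boxcox_transform(x, lam)
    df = pd.DataFrame(out, index=matrix.data.index)[matrix.data.columns]
    return matrix.evolve(df, "boxcox")


def zscore_to_reference(
    matrix: MetaboliteMatrix,
    reference_samples,
) -> tuple[MetaboliteMatrix, ReferenceStats]:
    """Standardise each metabolite by the reference (healthy-control) group.

    After the transform the reference subset has mean 0 and sd 1 per
    metabolite; patient values read as sd-deviations from health.
    Metabolites with zero reference sd are dropped with a warning.
    """
    if matrix.scale_tag != "boxcox":
        raise ValidationError(
            f"z-scoring expects boxcox values, got {matrix.scale_tag}"
        )
    reference_samples = list(reference_samples)
    missing = set(reference_samples) - set(matrix.data.index)
    if missing:
        raise ValidationError(f"reference samples not in matrix: {sorted(missing)}")
    ref = matrix.data.loc[reference_samples]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = sd[sd <= 0].index
    if len(degenerate):
        log.warning("dropping %d zero-variance metabolites: %s",
                    len(degenerate), list(degenerate))
    keep = sd.index[sd > 0]
    z = (matrix.data[keep] - mean[keep]) / sd[keep]
    stats_tbl = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    stats_tbl.index.name = "metabolite_id"
    out = matrix.evolve(z, "zscore")
    return out, ReferenceStats(table=stats_tbl)


def quantile_normalise(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Set every sample's value distribution to the average distribution.

    Each sample's values are replaced rank-wise by the mean order statistics
    over all samples; tied values receive the mean of the reference values
    their ranks span (the convention that preserves each sample's mean).
    Requires a complete matrix.
    """
    if matrix.scale_tag not in {"imputed", "boxcox", "zscore"}:
        raise ValidationError(
            f"quantile normalisation expects a processed complete matrix, "
            f"got {matrix.scale_tag}"
        )
    values = matrix.data.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("quantile normalisation requires a complete matrix")
    n, m = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=1)
    reference = sorted_vals.mean(axis=0)
    out = np.empty_like(values)
    for i in range(n):
        row = sorted_vals[i]
        new_sorted = np.empty(m)
        j = 0
        while j < m:
            k = j
            while k + 1 < m and row[k + 1] == row[j]:
                k += 1
            new_sorted[j:k + 1] = reference[j:k + 1].mean()
            j = k + 1
        out[i, order[i]] = new_sorted
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.evolve(df, "quantile_normalised")


def standard_chain(
    matrix: MetaboliteMatrix,
    annotation: MetaboliteAnnotation,
    reference_samples,
    detection_threshold: float = 0.95,
    quantile_normalise_last: bool = True,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
):
    """Run the full chain and return (matrix, BoxCoxParams, ReferenceStats).

    ``quantile_normalise_last`` controls whether cross-sample quantile
    normalisation is applied after z-scoring (the default) or skipped.
    """
    imputed = impute_min_detected(matrix)
    filtered = detection_filter(imputed, annotation, detection_threshold)
    params = fit_boxcox(filtered, grid=grid)
    transformed = apply_boxcox(filtered, params)
    reference_samples = [s for s in reference_samples if s in transformed.data.index]
    z, ref_stats = zscore_to_reference(transformed, reference_samples)
    if quantile_normalise_last:
        z = quantile_normalise(z)
    return z, params, ref_stats
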