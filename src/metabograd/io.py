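"""Typed tabular containers and delimited-text readers/writers.

Three table kinds flow through the pipeline: a samples x metabolites
abundance matrix, a per-sample metadata table and a per-metabolite pathway
annotation.  All are plain CSV/TSV on disk (delimiter picked by extension)
and validated pandas structures in memory.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("HC", "DC", "CTED", "IPAH_HPAH", "CTEPH")
COHORTS = ("discovery", "replication", "gradient", "none")
TIMEPOINTS = ("pre_PEA", "post_PEA", "none")
SITES = ("SVC", "PA", "ART", "none")

#: allowed provenance chain for matrix values
SCALE_CHAIN = ("raw", "imputed", "boxcox", "zscore", "quantile_normalised")


class ValidationError(ValueError):
    """Raised when a table violates its structural contract."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclasses.dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance grid with explicit missingness.

    ``data`` holds samples as rows, metabolites as columns; missing cells are
    NaN.  ``scale_tag`` records where the values sit on the preprocessing
    chain raw -> imputed -> boxcox -> zscore -> quantile_normalised.
    ``detected`` is the pre-imputation detection mask (True where the raw
    intensity was above the limit of detection); it is carried along so the
    detection filter can run after imputation.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"
    detected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_CHAIN:
            raise ValidationError(
                f"unknown scale_tag {self.scale_tag!r}; allowed: {SCALE_CHAIN}"
            )
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        if self.scale_tag == "raw":
            vals = self.data.to_numpy(dtype=float)
            bad = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    "negative raw intensity at sample "
                    f"{idx[i]!r}, metabolite {cols[j]!r}"
                )
        if self.detected is None:
            self.detected = self.data.notna()

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def evolve(self, data: pd.DataFrame, scale_tag: str) -> "MetaboliteMatrix":
        """Return a copy on the next scale, enforcing the provenance chain."""
        old = SCALE_CHAIN.index(self.scale_tag)
        new = SCALE_CHAIN.index(scale_tag)
        if new <= old:
            raise ValidationError(
                f"illegal scale transition {self.scale_tag} -> {scale_tag}"
            )
        det = self.detected
        if det is not None:
            det = det.loc[data.index, data.columns]
        return MetaboliteMatrix(data=data, scale_tag=scale_tag, detected=det)


def _check_labels(series: pd.Series, allowed: tuple, what: str) -> None:
    bad = sorted(set(series.dropna().astype(str)) - set(allowed))
    if bad:
        raise ValidationError(
            f"unknown {what} label(s) {bad}; allowed values: {list(allowed)}"
        )


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample group/cohort/batch labels, covariates and clinical variables.

    Required columns: sample_id (index), subject_id, group, cohort, batch,
    timepoint, site.  Covariate and clinical columns (age, sex, bmi,
    creatinine, bilirubin, drug_* flags, mrap, mpap, pvr, cardiac_output,
    walk_distance ...) are optional and may contain NaN.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "group", "cohort", "batch", "timepoint", "site")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        _check_labels(df["group"], GROUPS, "group")
        _check_labels(df["cohort"], COHORTS, "cohort")
        _check_labels(df["timepoint"], TIMEPOINTS, "timepoint")
        _check_labels(df["site"], SITES, "site")
        for key in ("timepoint", "site"):
            sub = df[df[key] != "none"]
            combo = sub[["subject_id", key]]
            if combo.duplicated().any():
                dup = combo[combo.duplicated()].iloc[0]
                raise ValidationError(
                    f"subject {dup['subject_id']!r} sampled twice at "
                    f"{key}={dup[key]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def samples_where(self, **conditions) -> list:
        """Sample ids matching all column==value conditions."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in conditions.items():
            mask &= self.data[col] == val
        return list(self.data.index[mask])


@dataclasses.dataclass
class MetaboliteAnnotation:
    """Metabolite -> subpathway -> superpathway map with identity flags."""

    data: pd.DataFrame

    REQUIRED = ("subpathway", "superpathway", "identity_confirmed", "xenobiotic")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing required columns: {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        for col in ("identity_confirmed", "xenobiotic"):
            self.data[col] = self.data[col].astype(bool)

    @property
    def metabolite_ids(self) -> list:
        return list(self.data.index)

    def unannotated(self, metabolite_ids) -> list:
        """Metabolite ids lacking an annotation row."""
        return [m for m in metabolite_ids if m not in self.data.index]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(
    path,
    missing_marker: str = "",
    orientation: str = "samples_rows",
) -> MetaboliteMatrix:
    """Read a raw abundance matrix from delimited text.

    Parameters
    ----------
    path : str or Path
        CSV (``.csv``) or TSV (``.tsv``/``.tab``/``.txt``) file; first row
        holds metabolite ids, first column sample ids (or transposed with
        ``orientation="metabolites_rows"``).
    missing_marker : str
        Cell content denoting a value below the limit of detection.  The
        default empty string means empty cells are missing.
    orientation : {"samples_rows", "metabolites_rows"}
    """
    path = Path(path)
    if orientation not in {"samples_rows", "metabolites_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    na_values = [missing_marker] if missing_marker else []
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        index_col=0,
        na_values=na_values,
        keep_default_na=True,
    )
    if orientation == "metabolites_rows":
        df = df.T
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MetaboliteMatrix(data=df, scale_tag="raw")


def read_processed_matrix(path, scale_tag: str = "zscore") -> MetaboliteMatrix:
    """Read an already-transformed matrix (values may be negative)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MetaboliteMatrix(data=df, scale_tag=scale_tag)


def read_metadata(path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df.index = df.index.astype(str)
    for col in ("group", "cohort", "batch", "timepoint", "site", "subject_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return SampleMetadata(data=df)


def read_annotation(path) -> MetaboliteAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df.index = df.index.astype(str)
    return MetaboliteAnnotation(data=df)


def write_table(table, path) -> None:
    """Write any of the three containers (or a bare DataFrame) to CSV/TSV."""
    path = Path(path)
    df = table.data if hasattr(table, "data") else table
    df.to_csv(path, sep=_delimiter_for(path))


def read_table(path) -> pd.DataFrame:
    """Read a generic result table written by :func:`write_table`."""
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
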