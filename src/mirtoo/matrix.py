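"""Expression-matrix container and tabular I/O.

An :class:`ExpressionMatrix` wraps a pandas DataFrame of absolute miRNA
abundances (samples as rows, miRNA assays as columns, copies per microlitre
before normalization) together with two state flags that enforce the
pipeline's ordering contracts: ``normalized`` (per-sample 50th-percentile
scaling applied) and ``log_transformed`` (log2 feature transform applied).

Sample metadata travels as a plain DataFrame with a fixed column vocabulary
(see :data:`META_COLUMNS`); :func:`validate_meta` checks it against a matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Required metadata columns. time_months/event may be all-missing.
META_COLUMNS = (
    "sample_id", "patient_id", "sex", "role", "class_label",
    "biopsy_site", "time_months", "event",
)

VALID_SEX = {"male", "female", "unknown"}
VALID_ROLE = {"reference_primary", "known_metastasis", "cup"}


class MatrixError(ValueError):
    """Raised on malformed matrices or contract violations (ordering, ids)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    data: pd.DataFrame
    normalized: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicated sample ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise MatrixError(f"duplicated miRNA ids: {dup}")
        if not self.log_transformed:
            vals = df.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise MatrixError("raw/normalized abundances must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, **flags) -> "ExpressionMatrix":
        """Return a copy carrying ``data`` and updated state flags."""
        return replace(self, data=data, **flags)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_table(cls, path: str | Path, **flags) -> "ExpressionMatrix":
        """Read a TSV/CSV table (first column sample_id, header of miRNA ids).

        Empty cells and "NA" are read as missing values.
        """
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
        df.index = df.index.astype(str)
        return cls(df.astype(float), **flags)

    def to_table(self, path: str | Path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep, na_rep="NA")


def read_meta(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={"sample_id": str})
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise MatrixError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta.to_csv(path, sep=sep, index=False, na_rep="NA")


def validate_meta(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> None:
    """Check the metadata contract; raise MatrixError on violation.

    Every matrix sample must have exactly one metadata row; class labels are
    present iff the sample is a reference primary or a known metastasis.
    """
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise MatrixError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise MatrixError("duplicated sample_id in metadata")
    bad_sex = set(meta["sex"].dropna()) - VALID_SEX
    if bad_sex:
        raise MatrixError(f"invalid sex values: {sorted(bad_sex)}")
    bad_role = set(meta["role"].dropna()) - VALID_ROLE
    if bad_role:
        raise MatrixError(f"invalid role values: {sorted(bad_role)}")
    labelled = meta["class_label"].notna()
    needs_label = meta["role"].isin({"reference_primary", "known_metastasis"})
    if (labelled != needs_label).any():
        bad = meta.loc[labelled != needs_label, "sample_id"].tolist()
        raise MatrixError(
            f"class_label must be present iff role is reference_primary/"
            f"known_metastasis; offending samples: {bad}"
        )
    if matrix is not None:
        have = set(meta["sample_id"])
        want = set(matrix.sample_ids)
        if want - have:
            raise MatrixError(f"samples without metadata: {sorted(want - have)}")


def aligned_meta(meta: pd.DataFrame, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Metadata reindexed to the matrix's sample order."""
    validate_meta(meta, matrix)
    return (
        meta.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    )
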