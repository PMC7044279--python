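"""Data containers and tab-separated readers/writers for the screening pipeline.

Three on-disk formats are supported, all plain text:

* expression matrix — TSV, probes as rows, samples as columns, log2-scale
  intensities, ``NA`` for missing values;
* clinical table — TSV with a mandatory ``sample_id`` column, survival
  endpoints (``os_time``/``os_event``, optionally ``efs_time``/``efs_event``),
  and arbitrary categorical covariate columns;
* gene sets — GMT (name, description, tab-separated members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_COLUMNS = ("os_event", "efs_event")
TIME_COLUMNS = ("os_time", "efs_time")
#: clinical columns that are not treated as categorical covariates
RESERVED_CLINICAL = {"sample_id", "os_time", "os_event", "efs_time", "efs_event", "age"}

UNKNOWN = "unknown"


class ValidationError(ValueError):
    """A file or in-memory object violates a container invariant."""


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of log2 expression intensities.

    ``values`` is a pandas DataFrame with probe ids as the index and sample
    ids as columns.  Missing intensities are NaN and are excluded probe-wise
    from scaling and testing downstream; all non-missing values must be
    finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe(self, probe_id: str) -> pd.Series:
        """Per-sample values for one probe (NaN = missing)."""
        return self.values.loc[probe_id]

    def restrict_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def restrict_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids), :])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a probe-by-sample TSV (first row sample ids, first column probe ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            probe = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric expression value at probe {probe!r}, sample {col!r}"
            )
    return ExpressionMatrix(df.astype(float))


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and categorical covariates.

    ``data`` is indexed by sample id.  ``os_time``/``os_event`` are required;
    ``efs_time``/``efs_event`` and ``age`` are optional.  Every remaining
    column is treated as a categorical covariate; missing labels are kept as
    the explicit level ``"unknown"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table is missing required column {col!r}")
        for col in TIME_COLUMNS:
            if col in self.data.columns:
                t = self.data[col].dropna()
                if (t < 0).any():
                    sid = t[t < 0].index[0]
                    raise ValidationError(f"negative {col} for sample {sid!r}")
        for col in EVENT_COLUMNS:
            if col in self.data.columns:
                e = self.data[col].dropna()
                if not e.isin([0, 1]).all():
                    sid = e[~e.isin([0, 1])].index[0]
                    raise ValidationError(
                        f"{col} for sample {sid!r} is {e[sid]!r}, expected 0 or 1"
                    )
        for col in self.covariate_columns:
            self.data[col] = (
                self.data[col].astype("object").where(self.data[col].notna(), UNKNOWN).astype(str)
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def has_efs(self) -> bool:
        return "efs_time" in self.data.columns and "efs_event" in self.data.columns

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_CLINICAL]

    def survival(self, sample_ids, endpoint: str = "os") -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for the given samples and endpoint ('os'/'efs')."""
        sub = self.data.loc[list(sample_ids)]
        return (
            sub[f"{endpoint}_time"].to_numpy(dtype=float),
            sub[f"{endpoint}_event"].to_numpy(dtype=int),
        )

    def restrict(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("clinical table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    for col in TIME_COLUMNS + ("age",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in EVENT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return ClinicalTable(df)


@dataclass
class GeneSetCollection:
    """Named, non-empty, duplicate-free gene/probe sets."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, members = parts[0], [m for m in parts[2:] if m]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def join_samples(matrix: ExpressionMatrix, clinical: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Intersect matrix and clinical table on exact sample-id match.

    Unmatched ids on either side are reported and dropped; the shared ids keep
    the matrix's column order.
    """
    m_ids, c_ids = set(matrix.sample_ids), set(clinical.sample_ids)
    shared = [s for s in matrix.sample_ids if s in c_ids]
    report = {
        "n_shared": len(shared),
        "unmatched_in_matrix": sorted(m_ids - c_ids),
        "unmatched_in_clinical": sorted(c_ids - m_ids),
    }
    if report["unmatched_in_matrix"] or report["unmatched_in_clinical"]:
        log.info(
            "sample join dropped %d matrix-only and %d clinical-only ids",
            len(report["unmatched_in_matrix"]),
            len(report["unmatched_in_clinical"]),
        )
    if not shared:
        raise ValidationError("no shared sample ids between matrix and clinical table")
    return matrix.restrict_samples(shared), clinical.restrict(shared), report
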