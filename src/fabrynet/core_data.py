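"""Tabular data model for a targeted-metabolomics study.

Three tables travel together through the pipeline:

* :class:`MetaboliteMatrix` — samples x metabolites concentrations (µM on the
  raw scale), possibly with missing cells;
* :class:`SampleMetadata` — per-sample group (control/fabry), sex, age,
  disease phenotype, treatment status, and the optional plasma biomarkers
  LysoGb3 (ng/mL) and residual enzyme activity (fraction of control);
* :class:`MetaboliteAnnotation` — metabolite -> biochemical class, using the
  Biocrates p180 reporting classes.

Everything is backed by pandas; the wrapper classes add validation, a scale
tag recording applied transforms, and alignment of the three tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-value tokens accepted in delimited inputs (case-insensitive).
DEFAULT_MISSING_TOKENS = ("", "na", "nan")

#: Closed vocabulary of metabolite classes (p180 reporting classes;
#: lysophosphatidylcholines carry their own label but are folded into
#: glycerophospholipids for composition summaries by default).
METABOLITE_CLASSES = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "glycerophospholipid",
    "lysophosphatidylcholine",
    "sphingomyelin",
    "hexoses",
)

GROUPS = ("control", "fabry")
SEXES = ("F", "M")
PHENOTYPES = ("classical", "non_classical", "not_applicable")

SCALES = ("raw", "log", "log-pareto")


class DataValidationError(ValueError):
    """A table violates an invariant of the data model."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentration table.

    ``data`` is a float DataFrame indexed by sample id with metabolite-id
    columns; NaN marks missing measurements.  ``scale`` records the
    transforms applied so far (``raw`` -> ``log`` -> ``log-pareto``).
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataValidationError(
                f"unknown scale {self.scale!r}; expected one of {SCALES}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataValidationError(f"duplicate metabolite ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if self.scale == "raw" and np.any(values[~np.isnan(values)] < 0):
            r, c = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)[0]
            raise DataValidationError(
                f"negative concentration at sample {idx[r]!r}, "
                f"metabolite {cols[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "MetaboliteMatrix":
        return MetaboliteMatrix(data=data, scale=self.scale if scale is None else scale)

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(data=self.data.copy(), scale=self.scale)


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates; one row per sample id."""

    table: pd.DataFrame  # index: sample_id

    REQUIRED = ("group", "sex", "age")
    OPTIONAL_DEFAULTS = {
        "phenotype": "not_applicable",
        "treated": "not_applicable",
        "lysoGb3": np.nan,
        "residual_enzyme_activity": np.nan,
    }

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise DataValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise DataValidationError(f"metadata missing required column {col!r}")
        for col, default in self.OPTIONAL_DEFAULTS.items():
            if col not in t.columns:
                t[col] = default
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise DataValidationError(
                f"unknown group labels {sorted(bad)}; allowed: {list(GROUPS)}"
            )
        bad = set(t["sex"]) - set(SEXES)
        if bad:
            raise DataValidationError(f"unknown sex labels {sorted(bad)}; allowed: {list(SEXES)}")
        ages = pd.to_numeric(t["age"], errors="coerce")
        if ages.isna().any():
            missing = sorted(t.index[ages.isna()])
            raise DataValidationError(f"missing or non-numeric age for samples {missing}")
        if (ages <= 0).any():
            bad_ids = sorted(t.index[ages <= 0])
            raise DataValidationError(f"non-positive age for samples {bad_ids}")
        t["age"] = ages.astype(float)
        bad = set(t["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise DataValidationError(
                f"unknown phenotype labels {sorted(bad)}; allowed: {list(PHENOTYPES)}"
            )
        # controls have no disease phenotype
        ctrl = t["group"] == "control"
        if (t.loc[ctrl, "phenotype"] != "not_applicable").any():
            raise DataValidationError("control samples must have phenotype=not_applicable")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def group_counts(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def ids_of(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.table.copy())


@dataclass
class MetaboliteAnnotation:
    """Metabolite -> biochemical class map (closed vocabulary)."""

    table: pd.DataFrame  # index: metabolite_id, column: class

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise DataValidationError(f"duplicate metabolite ids in annotation: {dups}")
        if "class" not in t.columns:
            raise DataValidationError("annotation missing required column 'class'")
        bad = set(t["class"]) - set(METABOLITE_CLASSES)
        if bad:
            raise DataValidationError(
                f"unknown metabolite classes {sorted(bad)}; allowed: {list(METABOLITE_CLASSES)}"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    def class_of(self, metabolite_id: str) -> str:
        return str(self.table.loc[metabolite_id, "class"])

    def composition(
        self, metabolites: list[str] | None = None, fold_lysopc: bool = True
    ) -> dict[str, int]:
        """Count metabolites per class.

        With ``fold_lysopc`` (default) lysophosphatidylcholines are counted
        inside glycerophospholipids, matching how panel summaries report
        class totals.
        """
        classes = self.table["class"] if metabolites is None else self.table.loc[metabolites, "class"]
        if fold_lysopc:
            classes = classes.replace("lysophosphatidylcholine", "glycerophospholipid")
        counts = classes.value_counts().to_dict()
        return {c: int(n) for c, n in counts.items()}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, sep=None) -> pd.DataFrame:
    """Read a delimited text table with the first column as index."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path) as fh:  # pandas silently renames duplicate header ids
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise DataValidationError(f"duplicate column ids: {dups}")
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def _to_float(raw: pd.DataFrame, missing_tokens) -> pd.DataFrame:
    tokens = {t.lower() for t in missing_tokens}
    out = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(arr[i, j]).strip()
            if cell.lower() in tokens:
                out[i, j] = np.nan
            else:
                try:
                    out[i, j] = float(cell)
                except ValueError:
                    raise DataValidationError(
                        f"non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                        f"column {raw.columns[j]!r}"
                    ) from None
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_matrix(
    path,
    orientation: str = "samples_in_rows",
    missing_tokens=DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
    scale: str = "raw",
) -> MetaboliteMatrix:
    """Read a concentration matrix from delimited text.

    ``orientation`` declares whether rows are samples or metabolites; the
    returned matrix is always samples x metabolites.  ``scale`` declares the
    transform state of the stored values (``raw`` enforces non-negativity;
    use ``log-pareto`` to read back a processed matrix).
    """
    if orientation not in ("samples_in_rows", "metabolites_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, sep)
    data = _to_float(raw, missing_tokens)
    if orientation == "metabolites_in_rows":
        data = data.T
    return MetaboliteMatrix(data=data, scale=scale)


def write_matrix(matrix: MetaboliteMatrix, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    matrix.data.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path, sep: str | None = None) -> SampleMetadata:
    """Read sample metadata; category strings are normalized case-insensitively."""
    raw = _read_table(path, sep)
    t = raw.copy()
    norm = {
        "group": {g.lower(): g for g in GROUPS},
        "sex": {s.lower(): s for s in SEXES},
        "phenotype": {p.lower(): p for p in PHENOTYPES},
    }
    for col, mapping in norm.items():
        if col in t.columns:
            t[col] = [
                mapping.get(str(v).strip().lower().replace("-", "_"), str(v).strip())
                for v in t[col]
            ]
    for col in ("lysoGb3", "residual_enzyme_activity"):
        if col in t.columns:
            t[col] = pd.to_numeric(t[col].replace("", np.nan), errors="coerce")
    if "treated" in t.columns:
        t["treated"] = [
            {"true": True, "false": False, "1": True, "0": False}.get(
                str(v).strip().lower(), str(v).strip().lower() or "not_applicable"
            )
            for v in t["treated"]
        ]
    return SampleMetadata(table=t)


def write_metadata(meta: SampleMetadata, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta.table.to_csv(path, sep=sep, index_label="sample_id")


def read_annotation(path, sep: str | None = None) -> MetaboliteAnnotation:
    raw = _read_table(path, sep)
    t = raw.copy()
    t["class"] = [str(v).strip().lower().replace(" ", "_") for v in t["class"]]
    return MetaboliteAnnotation(table=t)


def write_annotation(anno: MetaboliteAnnotation, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    anno.table.to_csv(path, sep=sep, index_label="metabolite_id")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    dropped_samples: list[str] = field(default_factory=list)
    dropped_metabolites: list[str] = field(default_factory=list)


def align(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    anno: MetaboliteAnnotation,
    permissive: bool = False,
) -> tuple[MetaboliteMatrix, SampleMetadata, MetaboliteAnnotation, AlignmentReport]:
    """Bring the three tables onto common, identically ordered id sets.

    Sample order follows the matrix; metabolite order follows the matrix.
    Ids present on one side only are an error in strict mode (default) and
    are dropped with a logged warning in permissive mode.
    """
    mat_samples = set(matrix.sample_ids)
    meta_samples = set(meta.sample_ids)
    common_samples = mat_samples & meta_samples
    if not common_samples:
        raise DataValidationError("no sample ids shared between matrix and metadata")
    mat_mets = set(matrix.metabolite_ids)
    anno_mets = set(anno.metabolite_ids)
    common_mets = mat_mets & anno_mets
    if not common_mets:
        raise DataValidationError("no metabolite ids shared between matrix and annotation")

    dropped_samples = sorted((mat_samples | meta_samples) - common_samples)
    dropped_mets = sorted((mat_mets | anno_mets) - common_mets)
    if (dropped_samples or dropped_mets) and not permissive:
        raise DataValidationError(
            "id mismatch between tables (strict mode): "
            f"unmatched samples {dropped_samples}, unmatched metabolites {dropped_mets}; "
            "pass permissive=True to drop them"
        )
    if dropped_samples:
        logger.warning("alignment dropping %d unmatched samples: %s", len(dropped_samples), dropped_samples)
    if dropped_mets:
        logger.warning("alignment dropping %d unmatched metabolites: %s", len(dropped_mets), dropped_mets)

    sample_order = [s for s in matrix.sample_ids if s in common_samples]
    met_order = [m for m in matrix.metabolite_ids if m in common_mets]
    out_matrix = matrix.with_data(matrix.data.loc[sample_order, met_order])
    out_meta = SampleMetadata(meta.table.loc[sample_order].copy())
    out_anno = MetaboliteAnnotation(anno.table.loc[met_order].copy())
    return out_matrix, out_meta, out_anno, AlignmentReport(dropped_samples, dropped_mets)
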