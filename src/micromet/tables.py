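"""Tabular artifacts: abundance tables, weight matrices, gene-set files.

All on-disk formats are plain tab-delimited UTF-8 text. The canonical
in-memory orientation for abundance tables is samples in rows; files may be
written or read in either orientation with an explicit flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Numeric precision used when serializing reals (full double precision).
FLOAT_FORMAT = "%.17g"

#: Reserved row labels in the weight-matrix file, in order.
_WM_RESERVED = ("__intercept__", "__alpha__", "__lambda__",
                "__cv_spearman__", "__well_predicted__")


class TableValidationError(ValueError):
    """An artifact violates one of its structural invariants."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise TableValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class AbundanceTable:
    """A samples x features matrix of non-negative abundances.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features. Values are relative
        abundances (unitless, rows summing to 1 when normalized) or raw
        counts prior to normalization.
    is_normalized : bool
        True once every row sums to 1 (total-sum scaling applied).
    is_filtered : bool
        True once features have been dropped after normalization; rows then
        sum to at most 1 (values stay on the original relative-abundance
        scale, deliberately not renormalized).
    """

    data: pd.DataFrame
    is_normalized: bool = False
    is_filtered: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise TableValidationError(
                f"non-finite value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableValidationError(
                f"negative abundance {vals[r, c]!r} at sample "
                f"{self.data.index[r]!r}, feature {self.data.columns[c]!r}")
        if self.is_normalized and not self.is_filtered:
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-8
            if bad.any():
                raise TableValidationError(
                    "normalized table has row sums != 1 for samples "
                    f"{list(self.data.index[bad][:5])}")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return (isinstance(other, AbundanceTable)
                and self.is_normalized == other.is_normalized
                and self.data.equals(other.data))


@dataclass
class WeightMatrix:
    """Per-metabolite elastic-net coefficients plus fit metadata.

    ``coefficients`` is features x metabolites; each metabolite column comes
    with an intercept, the selected mixing parameter ``alpha`` (L1 fraction),
    the sparsity parameter ``lam``, the cross-validated Spearman correlation
    and the well-predicted flag.
    """

    coefficients: pd.DataFrame
    intercepts: pd.Series
    alpha: pd.Series
    lam: pd.Series
    cv_spearman: pd.Series
    well_predicted: pd.Series
    threshold: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.coefficients.shape[1] == 0:
            raise TableValidationError("no models to serialize: "
                                       "empty metabolite list")
        _check_unique(self.coefficients.index, "feature")
        _check_unique(self.coefficients.columns, "metabolite")
        mets = self.coefficients.columns
        for name, s in [("intercepts", self.intercepts),
                        ("alpha", self.alpha), ("lambda", self.lam),
                        ("cv_spearman", self.cv_spearman),
                        ("well_predicted", self.well_predicted)]:
            if not mets.equals(pd.Index(s.index)):
                raise TableValidationError(
                    f"{name} index does not match metabolite columns")
        cv = self.cv_spearman.to_numpy(dtype=float)
        ok = np.isnan(cv) | ((cv >= -1 - 1e-12) & (cv <= 1 + 1e-12))
        if not ok.all():
            raise TableValidationError("cv_spearman outside [-1, 1]")
        wp = self.well_predicted.astype(bool)
        nonzero = (self.coefficients != 0).any(axis=0)
        bad = wp & ~nonzero
        if bad.any():
            raise TableValidationError(
                "well-predicted metabolites with all-zero coefficient "
                f"columns: {list(bad[bad].index[:5])}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.coefficients.columns)


@dataclass
class GeneSetCollection:
    """Named sets of feature identifiers, e.g. genus or protein-family sets."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise TableValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise TableValidationError(
                    f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def read_abundance_table(path, orientation: str = "samples") -> AbundanceTable:
    """Read a tab-delimited abundance table.

    Parameters
    ----------
    path : str or Path
        TSV with one header row and one leading identifier column.
    orientation : {"samples", "features"}
        Whether file rows are samples or features. The returned table is
        always samples-in-rows.
    """
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = pd.Index(df.index.astype(str), name=None)
    df.columns = pd.Index(df.columns.astype(str), name=None)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise TableValidationError(
                f"non-numeric cell {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                f"column {col!r} in {path}")
    if orientation == "features":
        df = df.T
    return AbundanceTable(df, is_normalized=False)


def write_abundance_table(table: AbundanceTable, path,
                          orientation: str = "samples") -> None:
    """Write a table as TSV; ``orientation`` controls the file layout."""
    df = table.data if orientation == "samples" else table.data.T
    label = "sample_id" if orientation == "samples" else "feature_id"
    df.to_csv(path, sep="\t", index_label=label, float_format=FLOAT_FORMAT)


def align_samples(x: AbundanceTable, y: AbundanceTable,
                  min_shared: int = 3) -> tuple[AbundanceTable, AbundanceTable]:
    """Restrict paired tables to their shared samples (order-insensitive).

    Raises if fewer than ``min_shared`` samples are common to both.
    """
    shared = [s for s in x.sample_ids if s in set(y.sample_ids)]
    if len(shared) < min_shared:
        raise TableValidationError(
            f"only {len(shared)} shared samples between the paired tables; "
            f"at least {min_shared} are required")
    return (AbundanceTable(x.data.loc[shared], x.is_normalized, x.is_filtered),
            AbundanceTable(y.data.loc[shared], y.is_normalized, y.is_filtered))


# ---------------------------------------------------------------------------
# Weight matrices
# ---------------------------------------------------------------------------

def write_weight_matrix(model: WeightMatrix, path) -> None:
    """Serialize a weight matrix with reserved metadata rows.

    Layout: header ``feature_id`` + metabolite ids; five reserved rows
    (intercept, alpha, lambda, cv_spearman, well_predicted) followed by one
    row per predictor feature. Reals keep full double precision.
    """
    model.validate()
    meta = pd.DataFrame(
        [model.intercepts.astype(float),
         model.alpha.astype(float),
         model.lam.astype(float),
         model.cv_spearman.astype(float),
         model.well_predicted.astype(bool).astype(float)],
        index=list(_WM_RESERVED))
    out = pd.concat([meta, model.coefficients])
    out.to_csv(path, sep="\t", index_label="feature_id",
               float_format=FLOAT_FORMAT)


def read_weight_matrix(path) -> WeightMatrix:
    """Read a weight matrix written by :func:`write_weight_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [r for r in _WM_RESERVED if r not in df.index]
    if missing:
        raise TableValidationError(
            f"weight-matrix file missing reserved rows: {missing}")
    coef = df.drop(index=list(_WM_RESERVED)).astype(float)
    coef.index.name = None
    coef.columns.name = None

    def row(label):
        s = df.loc[label].astype(float)
        s.name = None
        return s

    return WeightMatrix(
        coefficients=coef,
        intercepts=row("__intercept__"),
        alpha=row("__alpha__"),
        lam=row("__lambda__"),
        cv_spearman=row("__cv_spearman__"),
        well_predicted=row("__well_predicted__") > 0.5,
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read gene sets from GMT or two-column long-format TSV.

    GMT lines are ``name<TAB>description<TAB>member...``; long format is
    ``set_name<TAB>member`` per row (no header required, but a header row of
    exactly ``set_name<TAB>member`` is tolerated). Duplicate members within a
    set are dropped with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableValidationError(f"gene-set file {path} is empty")
    is_gmt = all(len(ln.split("\t")) >= 3 for ln in lines)
    if is_gmt:
        for ln in lines:
            parts = ln.split("\t")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if not members:
                raise TableValidationError(f"gene set {name!r} has no members")
            descriptions[name] = desc
            sets.setdefault(name, [])
            _extend_dedup(sets[name], members, name)
    else:
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise TableValidationError(
                    f"malformed gene-set line (expected 2 or >=3 columns): "
                    f"{ln!r}")
            name, member = parts
            if (name, member) == ("set_name", "member"):
                continue
            if not member:
                raise TableValidationError(f"gene set {name!r} has an empty "
                                           "member field")
            sets.setdefault(name, [])
            _extend_dedup(sets[name], [member], name)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _extend_dedup(target: list[str], members: list[str], name: str) -> None:
    for m in members:
        if m in target:
            msg = f"duplicate member {m!r} in gene set {name!r}; deduplicated"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)
        else:
            target.append(m)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    """Write gene sets in GMT format."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
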