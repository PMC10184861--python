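"""Feature tables, sample metadata, donor loads and ASV origin classes.

The universal exchange object is the :class:`FeatureTable`: an ASV x sample
matrix of non-negative integer read counts, ASVs as rows and samples as
columns (the classic amplicon-table orientation). Readers and writers cover
plain TSV and the BIOM-classic (v1 JSON) dialect.

Rarefaction subsamples each sample's reads *without* replacement to a common
depth (multivariate hypergeometric draw), the standard way to put
presence/absence measures on an equal sequencing-depth footing.

Origin classification labels each ASV by which donor(s) of a two-donor
mixture it was detected in: ``native_only``, ``nonnative_only``, ``shared``,
or ``unassigned`` (detected only in recipients).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "FeatureTable",
    "DonorSample",
    "OriginMap",
    "ORIGIN_CLASSES",
    "GENOTYPES",
    "ROLES",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "read_donor_loads",
    "rarefy",
    "classify_asv_origin",
]


class FormatError(ValueError):
    """Raised when an input file or table violates the expected format."""


GENOTYPES = frozenset({"WT", "Rag1KO"})
ROLES = frozenset({"donor_native", "donor_nonnative", "recipient", "singly_colonized"})
ORIGIN_CLASSES = ("native_only", "nonnative_only", "shared", "unassigned")

#: Required columns of a sample-metadata table.
METADATA_COLUMNS = ("sample_id", "mouse_id", "cage_id", "genotype", "role", "inoculum_id", "week")

#: Required columns of a donor-load table.
LOAD_COLUMNS = ("sample_id", "load_copies_per_gram", "mass_grams")


@dataclass(frozen=True)
class DonorSample:
    """A donor fecal sample with its absolute bacterial load.

    Parameters
    ----------
    sample_id : str
        Sample identifier, matching a column of the feature table.
    load : float
        16S rRNA gene copies per gram of feces (qPCR estimate), > 0.
    mass : float
        Grams of feces from this donor mixed into the inoculum, > 0.
    """

    sample_id: str
    load: float
    mass: float

    def __post_init__(self) -> None:
        if not (self.load > 0 and np.isfinite(self.load)):
            raise ValueError(f"donor load must be a positive finite number, got {self.load!r}")
        if not (self.mass > 0 and np.isfinite(self.mass)):
            raise ValueError(f"donor fecal mass must be a positive finite number, got {self.mass!r}")

    @property
    def total_copies(self) -> float:
        """Total 16S copies this donor contributes: load x mass."""
        return self.load * self.mass


class FeatureTable:
    """ASV x sample matrix of non-negative integer counts.

    Wraps a :class:`pandas.DataFrame` with ASV identifiers as the row index
    and sample identifiers as columns. Construction validates the invariants:
    unique identifiers, integral non-negative counts, at least one ASV and
    one sample.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise FormatError("feature table needs at least one ASV and one sample")
        index = data.index.astype(str)
        columns = data.columns.astype(str)
        if index.has_duplicates:
            dupes = index[index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate ASV ids: {dupes}")
        if columns.has_duplicates:
            dupes = columns[columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            float_values = np.asarray(values, dtype=float)
            if np.isnan(float_values).any():
                raise FormatError("feature table contains NaN cells")
            if not np.all(float_values == np.floor(float_values)):
                raise FormatError("feature table contains non-integer counts")
            values = float_values.astype(np.int64)
        if (values < 0).any():
            raise FormatError("feature table contains negative counts")
        self._data = pd.DataFrame(values.astype(np.int64), index=index, columns=columns)

    # -- accessors ---------------------------------------------------------

    @property
    def asv_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_asvs, n_samples) int64 array (a copy)."""
        return self._data.to_numpy(copy=True)

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def sample_totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self._data.sum(axis=0)

    def column(self, sample_id: str) -> pd.Series:
        """Counts of one sample, indexed by ASV id."""
        try:
            return self._data[sample_id].copy()
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def relative_abundance(self) -> pd.DataFrame:
        """Columns renormalised to sum to 1; all-zero samples rejected."""
        totals = self.sample_totals()
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"cannot normalise all-zero samples: {empty}")
        return self._data / totals

    def presence(self, detection_min: int = 1) -> pd.DataFrame:
        """Boolean presence matrix: count >= ``detection_min``."""
        if detection_min < 1:
            raise ValueError("detection_min must be >= 1")
        return self._data >= detection_min

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self._data[list(sample_ids)])

    def select_asvs(self, asv_ids: Sequence[str]) -> "FeatureTable":
        missing = [a for a in asv_ids if a not in self._data.index]
        if missing:
            raise KeyError(f"ASVs not in table: {missing}")
        return FeatureTable(self._data.loc[list(asv_ids)])

    def equals(self, other: "FeatureTable") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureTable({self.shape[0]} ASVs x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_table(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty feature-table file") from None
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    return frame


def _read_biom_classic(path: Path) -> pd.DataFrame:
    with open(path) as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid BIOM-classic JSON ({exc})") from None
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM-classic document missing key {key!r}")
    n_rows, n_cols = doc["shape"]
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    if len(asv_ids) != n_rows or len(sample_ids) != n_cols:
        raise FormatError(f"{path}: BIOM shape does not match row/column lists")
    matrix = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc["matrix_type"] == "dense":
        matrix = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            matrix[int(r), int(c)] = v
    else:
        raise FormatError(f"{path}: unknown BIOM matrix_type {doc['matrix_type']!r}")
    return pd.DataFrame(matrix, index=asv_ids, columns=sample_ids)


def read_feature_table(
    path: str | Path,
    dialect: str = "tsv",
    expected_sample_ids: Iterable[str] | None = None,
) -> FeatureTable:
    """Read a feature table from ``path``.

    Parameters
    ----------
    dialect : {"tsv", "biom_classic"}
        ``tsv``: header row of sample ids, first column ASV ids.
        ``biom_classic``: BIOM v1 JSON, dense or sparse matrix encoding.
    expected_sample_ids : iterable of str, optional
        If given and the table's *rows* (not its columns) match these ids,
        the table is treated as transposed and flipped; if neither or both
        orientations match, the orientation is ambiguous and an error is
        raised unless the default orientation matches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        frame = _read_tsv_table(path)
    elif dialect == "biom_classic":
        frame = _read_biom_classic(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'biom_classic'")

    if expected_sample_ids is not None:
        expected = set(map(str, expected_sample_ids))
        cols_match = expected.issubset(set(map(str, frame.columns)))
        rows_match = expected.issubset(set(map(str, frame.index)))
        if cols_match:
            pass  # default orientation confirmed (rows too -> ids ambiguous, keep default)
        elif rows_match:
            frame = frame.T
        else:
            raise FormatError(
                f"{path}: expected sample ids found in neither rows nor columns"
            )
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``table`` to ``path`` in the given dialect (TSV or BIOM-classic JSON)."""
    path = Path(path)
    if dialect == "tsv":
        frame = table.to_dataframe()
        frame.index.name = "asv_id"
        frame.to_csv(path, sep="\t")
    elif dialect == "biom_classic":
        counts = table.counts
        rows, cols = np.nonzero(counts)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "homesite",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(table.shape),
            "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [[int(r), int(c), int(counts[r, c])] for r, c in zip(rows, cols)],
        }
        with open(path, "w") as handle:
            json.dump(doc, handle)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV.

    Required columns: sample_id, mouse_id, cage_id, genotype, role,
    inoculum_id, week. Every sample with role ``recipient`` must carry an
    inoculum_id; genotypes and roles must come from the controlled
    vocabularies. Missing required fields are errors, never imputed.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in metadata")
    bad_roles = set(meta["role"]) - ROLES
    if bad_roles:
        raise FormatError(f"{path}: unknown roles {sorted(bad_roles)}; allowed {sorted(ROLES)}")
    bad_geno = set(meta["genotype"].dropna()) - GENOTYPES
    if bad_geno:
        raise FormatError(f"{path}: unknown genotypes {sorted(bad_geno)}; allowed {sorted(GENOTYPES)}")
    recipients = meta[meta["role"] == "recipient"]
    if recipients["inoculum_id"].isna().any() or (recipients["inoculum_id"] == "").any():
        bad = recipients.loc[
            recipients["inoculum_id"].isna() | (recipients["inoculum_id"] == ""), "sample_id"
        ].tolist()
        raise FormatError(f"{path}: recipient samples without inoculum_id: {bad}")
    meta = meta.copy()
    meta["week"] = meta["week"].astype(int)
    return meta


def read_donor_loads(path: str | Path) -> dict[str, DonorSample]:
    """Read a donor-load TSV into a mapping sample_id -> :class:`DonorSample`.

    Columns: sample_id, load_copies_per_gram, mass_grams.
    """
    path = Path(path)
    loads = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in LOAD_COLUMNS if c not in loads.columns]
    if missing:
        raise FormatError(f"{path}: load table missing columns {missing}")
    if loads["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in load table")
    return {
        str(row.sample_id): DonorSample(
            str(row.sample_id), float(row.load_copies_per_gram), float(row.mass_grams)
        )
        for row in loads.itertuples()
    }


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(
    table: FeatureTable,
    depth: int,
    seed: int | np.random.Generator | None = None,
    drop_small: bool = False,
) -> FeatureTable:
    """Subsample every sample without replacement to ``depth`` reads.

    Each sample's reads are drawn as a multivariate hypergeometric sample of
    size ``depth`` from its observed counts, so every output column sums to
    exactly ``depth``. Deterministic for a fixed ``seed``.

    Parameters
    ----------
    drop_small : bool
        If False (default), a sample with fewer than ``depth`` reads is an
        error naming the sample; if True, such samples are dropped.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.sample_totals()
    small = totals.index[totals < depth].tolist()
    keep = table.sample_ids
    if small:
        if not drop_small:
            raise ValueError(
                f"samples with fewer than {depth} reads: {small} (set drop_small=True to drop)"
            )
        keep = [s for s in table.sample_ids if s not in set(small)]
        if not keep:
            raise ValueError(f"all samples have fewer than {depth} reads")
    frame = table.to_dataframe()[keep]
    out = np.empty((frame.shape[0], len(keep)), dtype=np.int64)
    for j, sample in enumerate(keep):
        out[:, j] = rng.multivariate_hypergeometric(frame[sample].to_numpy(), depth)
    return FeatureTable(pd.DataFrame(out, index=frame.index, columns=keep))


# ---------------------------------------------------------------------------
# origin classification


@dataclass
class OriginMap:
    """Mapping of each ASV to its donor-origin class.

    Classes: ``native_only`` (detected in a native donor and in no
    non-native donor), ``nonnative_only`` (the symmetric case), ``shared``
    (detected in both donors), ``unassigned`` (detected in neither donor —
    e.g. only in recipients).
    """

    origins: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        bad = set(self.origins.unique()) - set(ORIGIN_CLASSES)
        if bad:
            raise ValueError(f"unknown origin classes {sorted(bad)}")

    def __getitem__(self, asv_id: str) -> str:
        return self.origins[asv_id]

    def __len__(self) -> int:
        return len(self.origins)

    def asvs(self, origin: str) -> list[str]:
        """ASV ids mapped to ``origin``."""
        if origin not in ORIGIN_CLASSES:
            raise ValueError(f"unknown origin class {origin!r}")
        return self.origins.index[self.origins == origin].tolist()

    def class_counts(self) -> dict[str, int]:
        counts = self.origins.value_counts()
        return {cls: int(counts.get(cls, 0)) for cls in ORIGIN_CLASSES}

    def to_series(self) -> pd.Series:
        return self.origins.copy()


def classify_asv_origin(
    table: FeatureTable,
    native_donor_samples: Sequence[str],
    nonnative_donor_samples: Sequence[str],
    detection_min: int = 1,
) -> OriginMap:
    """Classify every ASV in ``table`` by donor origin.

    An ASV is "detected" in a donor group when its count is >=
    ``detection_min`` in at least one of that group's samples. Detected only
    natively -> ``native_only``; only non-natively -> ``nonnative_only``; in
    both -> ``shared``; in neither -> ``unassigned``.
    """
    if len(native_donor_samples) == 0 or len(nonnative_donor_samples) == 0:
        raise ValueError("both donor sample sets must be non-empty")
    present = table.presence(detection_min)
    for sid in list(native_donor_samples) + list(nonnative_donor_samples):
        if sid not in present.columns:
            raise KeyError(f"donor sample {sid!r} not in table")
    in_native = present[list(native_donor_samples)].any(axis=1)
    in_nonnative = present[list(nonnative_donor_samples)].any(axis=1)
    origins = pd.Series("unassigned", index=present.index, dtype=object)
    origins[in_native & ~in_nonnative] = "native_only"
    origins[~in_native & in_nonnative] = "nonnative_only"
    origins[in_native & in_nonnative] = "shared"
    return OriginMap(origins)
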