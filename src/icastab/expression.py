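"""Expression-matrix container and text-format I/O (TSV/CSV, GMT, sidecars).

The central data type is :class:`ExpressionMatrix`: a genes × samples
matrix of log-scale expression values with unique gene and sample
identifiers.  Metagenes are gene-indexed, which makes genes-in-rows the
dominant access pattern, so that orientation is fixed internally even
when files store samples in rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ExpressionLoadError",
    "GMTParseError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "write_decomposition",
    "read_decomposition",
]

#: Values above this on a purportedly log-scale matrix trigger a warning.
LOG_SCALE_MAX = 30.0


class ExpressionLoadError(ValueError):
    """Raised when an expression file violates the loader's contract."""


class GMTParseError(ValueError):
    """Raised on malformed GMT gene-set files."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes × samples, with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Finite log-scale expression values.
    gene_ids, sample_ids : sequence of str
        Unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionLoadError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ExpressionLoadError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ExpressionLoadError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ExpressionLoadError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ExpressionLoadError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ExpressionLoadError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes × samples DataFrame."""
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class GeneSetCollection:
    """Named reference gene sets, as read from a GMT file.

    ``sets`` maps a unique set name to ``(description, member gene ids)``;
    member lists are non-empty.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise GMTParseError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]


def _check_log_scale(values: np.ndarray) -> None:
    if values.size and np.nanmax(values) > LOG_SCALE_MAX:
        warnings.warn(
            f"maximum value {np.nanmax(values):.3g} exceeds {LOG_SCALE_MAX}; "
            "data may not be on a logarithmic scale",
            UserWarning,
            stacklevel=3,
        )


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    genes_in_rows: bool = True,
    duplicates: str = "error",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a delimited expression matrix with a header row and id column.

    Parameters
    ----------
    path : path to a TSV/CSV file.
    delimiter : field separator, tab by default.
    genes_in_rows : if False the file stores samples in rows and is
        transposed on load; internally genes are always in rows.
    duplicates : policy for duplicated gene ids, ``"error"`` (default) or
        ``"max-variance"`` (keep the highest-variance row).
    missing : policy for missing cells, ``"error"`` (default) or
        ``"impute-row-mean"``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise ExpressionLoadError(f"cannot parse {path}: {exc}") from exc
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ExpressionLoadError(f"duplicate column ids in {path}: {dupes}")
    non_numeric = frame.columns[
        [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ExpressionLoadError(
            f"non-numeric value in column {col!r}, row {where!r} of {path}"
        )
    if not genes_in_rows:
        frame = frame.T

    if frame.index.has_duplicates:
        if duplicates == "error":
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicate gene ids in {path}: {dupes}")
        elif duplicates == "max-variance":
            order = frame.var(axis=1).to_numpy()
            keep = (
                pd.Series(order, index=range(len(frame)))
                .groupby(frame.index.to_numpy())
                .idxmax()
            )
            frame = frame.iloc[sorted(keep.to_numpy())]
        else:
            raise ValueError(f"unknown duplicates policy {duplicates!r}")

    if frame.isna().any().any():
        if missing == "error":
            gene = frame.index[frame.isna().any(axis=1)][0]
            raise ExpressionLoadError(
                f"missing value(s) in {path}, first affected gene {gene!r}"
            )
        elif missing == "impute-row-mean":
            row_means = frame.mean(axis=1)
            frame = frame.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
            if frame.isna().any().any():
                raise ExpressionLoadError(f"rows with no observed values in {path}")
        else:
            raise ValueError(f"unknown missing policy {missing!r}")

    values = frame.to_numpy(dtype=float)
    _check_log_scale(values)
    return ExpressionMatrix(values, list(frame.index.astype(str)), list(frame.columns.astype(str)))


def write_expression(
    X: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write genes × samples values with ids; inverse of :func:`read_expression`."""
    X.to_frame().to_csv(Path(path), sep=delimiter, index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in the Broad GMT dialect: name TAB description TAB genes."""
    sets: dict[str, tuple[str, list[str]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise GMTParseError(
                    f"{path}:{lineno}: expected name, description and >= 1 gene"
                )
            name, desc = fields[0], fields[1]
            members = [f for f in fields[2:] if f.strip()]
            if name in sets:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_decomposition(dec, prefix: str | Path) -> dict[str, Path]:
    """Persist a stabilized decomposition as TSV matrices plus a JSON sidecar.

    Writes ``<prefix>_S.tsv`` (components × genes), ``<prefix>_A.tsv``
    (samples × components) and ``<prefix>.json`` carrying the stability
    indices, the order M, the number of runs K, the seed and the fit
    parameters.  Returns the paths written.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    s_path = prefix.with_name(prefix.name + "_S.tsv")
    a_path = prefix.with_name(prefix.name + "_A.tsv")
    j_path = prefix.with_name(prefix.name + ".json")
    dec.metagenes.to_csv(s_path, sep="\t", index_label="component")
    dec.mixing.to_csv(a_path, sep="\t", index_label="sample")
    sidecar = {
        "M": int(dec.order),
        "K": int(dec.n_runs),
        "seed": dec.seed,
        "stabilities": [float(v) for v in dec.stabilities],
        "explained_variance_fraction": float(dec.explained_variance_fraction),
        "params": dict(dec.params),
    }
    with open(j_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return {"S": s_path, "A": a_path, "sidecar": j_path}


def read_decomposition(prefix: str | Path):
    """Read back a decomposition written by :func:`write_decomposition`."""
    from .model import StabilizedICAResults

    prefix = Path(prefix)
    metagenes = pd.read_csv(
        prefix.with_name(prefix.name + "_S.tsv"), sep="\t", index_col=0
    )
    mixing = pd.read_csv(
        prefix.with_name(prefix.name + "_A.tsv"), sep="\t", index_col=0
    )
    with open(prefix.with_name(prefix.name + ".json")) as fh:
        sidecar = json.load(fh)
    return StabilizedICAResults(
        metagenes=metagenes,
        mixing=mixing,
        stabilities=np.asarray(sidecar["stabilities"], dtype=float),
        order=int(sidecar["M"]),
        n_runs=int(sidecar["K"]),
        seed=sidecar["seed"],
        explained_variance_fraction=float(sidecar["explained_variance_fraction"]),
        params=sidecar.get("params", {}),
    )
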