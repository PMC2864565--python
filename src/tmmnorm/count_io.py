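"""Reading, validating and writing gene x library count matrices.

The :class:`CountMatrix` is the universal input of the package: a table of
non-negative integer read counts ``Y[g, k]`` with one row per gene and one
column per sequencing library, plus a library size ``N_k`` per column.
Library sizes default to the column sums but may be supplied explicitly,
because the total number of reads for a library can legitimately exceed the
counts tabulated in the matrix (reads mapped outside the annotated genes,
unmapped reads, and so on).

Counts are strictly integral: fractional cells are rejected, not rounded,
because both the sampling model and the exact tests downstream are
count-based.  Genes that are zero in every library are retained here and
excluded by downstream operations according to their own rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CountMatrixError",
    "read_counts",
    "read_gene_lengths",
    "read_gene_list",
    "write_counts",
    "write_table",
]


class CountMatrixError(ValueError):
    """Raised for malformed or inconsistent count-matrix input."""


@dataclass(frozen=True)
class CountMatrix:
    """Gene x library non-negative integer counts with library sizes.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    library_ids
        Ordered, unique library identifiers (columns).
    counts
        Integer array of shape ``(n_genes, n_libraries)``; all entries >= 0.
    library_sizes
        Positive total read count ``N_k`` per library.  Defaults to the
        column sums of ``counts``.
    """

    gene_ids: tuple
    library_ids: tuple
    counts: np.ndarray
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D array")
        if counts.size == 0:
            raise CountMatrixError("count matrix is empty")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise CountMatrixError("counts must be integral; refusing to round")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise CountMatrixError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "library_ids", tuple(str(c) for c in self.library_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixError("duplicate gene identifiers")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise CountMatrixError("duplicate library identifiers")
        if counts.shape != (len(self.gene_ids), len(self.library_ids)):
            raise CountMatrixError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.library_ids)} libraries"
            )
        if self.library_sizes is None:
            sizes = counts.sum(axis=0)
        else:
            sizes = np.asarray(self.library_sizes)
            if sizes.shape != (len(self.library_ids),):
                raise CountMatrixError("library_sizes must have one entry per library")
        if (sizes <= 0).any():
            raise CountMatrixError("library sizes must be positive")
        object.__setattr__(self, "library_sizes", sizes.astype(np.int64, copy=False))

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    def library_index(self, library_id: str) -> int:
        try:
            return self.library_ids.index(str(library_id))
        except ValueError:
            raise KeyError(f"unknown library {library_id!r}") from None

    def column(self, library_id: str) -> np.ndarray:
        """Counts for one library, in gene order."""
        return self.counts[:, self.library_index(library_id)]

    def library_size(self, library_id: str) -> int:
        return int(self.library_sizes[self.library_index(library_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.library_ids)
        )


def read_counts(
    path: str | Path,
    sep: str = "\t",
    library_sizes: Sequence[int] | Mapping[str, int] | None = None,
) -> CountMatrix:
    """Read a delimited count table (first column gene ids, header libraries).

    Lines starting with ``#`` are treated as comments.  Cells must parse as
    non-negative integers; a malformed cell raises :class:`CountMatrixError`
    naming the offending gene and library.  ``library_sizes`` overrides the
    default column-sum sizes, either positionally or as a mapping by
    library id.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise CountMatrixError(f"{path}: empty count matrix")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        if bad.size:
            g, k = bad[0]
            raise CountMatrixError(
                f"{path}: cell ({frame.index[g]!r}, {frame.columns[k]!r}) "
                f"is not a number: {frame.iat[g, k]!r}"
            )
        values = numeric.to_numpy()
    bad = np.argwhere((values < 0) | (np.mod(values, 1) != 0))
    if bad.size:
        g, k = bad[0]
        raise CountMatrixError(
            f"{path}: cell ({frame.index[g]!r}, {frame.columns[k]!r}) "
            f"is not a non-negative integer: {frame.iat[g, k]!r}"
        )
    sizes = None
    if library_sizes is not None:
        if isinstance(library_sizes, Mapping):
            try:
                sizes = np.array([library_sizes[c] for c in frame.columns])
            except KeyError as exc:
                raise CountMatrixError(f"{path}: no library size for {exc}") from None
        else:
            sizes = np.asarray(list(library_sizes))
    return CountMatrix(
        gene_ids=tuple(frame.index.astype(str)),
        library_ids=tuple(frame.columns.astype(str)),
        counts=values.astype(np.int64),
        library_sizes=sizes,
    )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one id per line, ``#`` comments, blanks ignored."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line)
    if not genes:
        raise CountMatrixError(f"{path}: gene list is empty")
    return genes


def read_gene_lengths(path: str | Path, sep: str = "\t") -> dict[str, int]:
    """Read a two-column gene-id / length table; lengths must be positive."""
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if frame.shape[1] < 1:
        raise CountMatrixError(f"{path}: expected two columns (gene id, length)")
    lengths = frame.iloc[:, 0]
    if (lengths <= 0).any() or (np.mod(lengths, 1) != 0).any():
        raise CountMatrixError(f"{path}: gene lengths must be positive integers")
    return {str(g): int(v) for g, v in lengths.items()}


def write_table(
    rows: pd.DataFrame | Iterable[Mapping[str, object]],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write labeled records as a tab-delimited table with optional ``#`` headers."""
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=isinstance(rows, pd.DataFrame))


def write_counts(
    matrix: CountMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a :class:`CountMatrix` so that :func:`read_counts` round-trips it.

    Explicit library sizes (differing from column sums) are preserved in a
    ``# library_sizes:`` comment header that :func:`read_counts` does not
    consume automatically; pass them back via its ``library_sizes`` argument.
    """
    if any("\t" in g for g in matrix.gene_ids):
        raise CountMatrixError("gene ids must not contain the tab delimiter")
    if any("\t" in c for c in matrix.library_ids):
        raise CountMatrixError("library ids must not contain the tab delimiter")
    lines = list(header_lines)
    if not np.array_equal(matrix.library_sizes, matrix.counts.sum(axis=0)):
        lines.append(
            "library_sizes: "
            + " ".join(f"{c}={n}" for c, n in zip(matrix.library_ids, matrix.library_sizes))
        )
    write_table(matrix.to_frame(), path, header_lines=lines)
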