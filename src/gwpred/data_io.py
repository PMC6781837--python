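"""Genotype/phenotype input, MAF filtering, standardization and data splits.

Genotypes are additive SNP codes (0, 1 or 2 copies of the counted allele),
one row per individual and one column per marker, stored as delimited text.
Phenotypes are one continuous value per line in the same individual order.
All downstream solvers operate on a column-standardized design matrix and a
mean-centered phenotype vector; the statistics used for standardization are
kept so the transform is invertible.

Positions exposed at the user interface (``make_split``) are 1-based, which
matches how pedigree datasets number individuals; internally everything is
0-based NumPy indexing.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("gwpred")

__all__ = [
    "GenotypeMatrix",
    "StandardizedDesign",
    "TrainTestSplit",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
    "load_qtlmas_zip",
    "maf_filter",
    "standardize",
    "make_split",
]

VALID_CODES = (0, 1, 2)


@dataclass
class GenotypeMatrix:
    """Integer SNP codes for ``n`` individuals at ``p`` markers.

    ``codes[i, j]`` counts copies of the reference allele carried by
    individual ``i`` at marker ``j``; entries must be 0, 1 or 2 (no missing
    data).
    """

    codes: np.ndarray
    individual_ids: list[str] = field(default=None)  # type: ignore[assignment]
    marker_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix (individuals x markers)")
        n, p = self.codes.shape
        if n < 2:
            raise ValueError(f"need at least 2 individuals, got {n}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if not np.isin(self.codes, VALID_CODES).all():
            bad = np.argwhere(~np.isin(self.codes, VALID_CODES))[0]
            raise ValueError(
                f"invalid genotype code {self.codes[tuple(bad)]!r} at "
                f"individual row {bad[0]}, marker column {bad[1]} "
                "(entries must be 0, 1 or 2)"
            )
        self.codes = self.codes.astype(np.int8)
        if self.individual_ids is None:
            self.individual_ids = [str(i + 1) for i in range(n)]
        if self.marker_ids is None:
            self.marker_ids = [f"M{j + 1}" for j in range(p)]
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match codes rows")
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids length does not match codes columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicated individual identifiers")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicated marker identifiers")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per marker, mean(code)/2."""
        return self.codes.mean(axis=0) / 2.0


@dataclass
class StandardizedDesign:
    """Column-standardized design matrix with centered phenotype.

    Each column of ``X`` is ``(code - col_mean) / col_sd`` with population
    (divide-by-n) standard deviations computed over the ``stats_from`` rows;
    ``y`` is the phenotype minus ``y_mean``.
    """

    X: np.ndarray
    y: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    y_mean: float

    def __post_init__(self) -> None:
        if np.any(self.col_sds <= 0):
            raise ValueError("col_sds must be strictly positive")

    def unstandardize_codes(self) -> np.ndarray:
        """Reconstruct the original genotype codes from X and the stats."""
        return self.X * self.col_sds + self.col_means


@dataclass
class TrainTestSplit:
    """Disjoint 0-based row positions for training and test individuals."""

    train_index: np.ndarray
    test_index: np.ndarray

    def __post_init__(self) -> None:
        self.train_index = np.asarray(self.train_index, dtype=np.intp)
        self.test_index = np.asarray(self.test_index, dtype=np.intp)
        if self.train_index.size == 0 or self.test_index.size == 0:
            raise ValueError("both train and test sets must be non-empty")
        if np.intersect1d(self.train_index, self.test_index).size:
            raise ValueError("train and test indices overlap")


def _tokenize(line: str, sep: str | None) -> list[str]:
    return line.split(sep) if sep else line.split()


def _is_code_token(tok: str) -> bool:
    return tok in ("0", "1", "2")


def read_genotypes(
    path: str | Path | io.TextIOBase,
    dialect: str = "delimited-codes",
    sep: str | None = None,
    header: str | bool = "auto",
    row_ids: str | bool = "auto",
) -> GenotypeMatrix:
    """Read a genotype code matrix from delimited text.

    Parameters
    ----------
    path
        File path or open text handle. One row per individual.
    dialect
        ``"delimited-codes"`` — plain 0/1/2 codes, optional marker-ID header
        row and optional leading individual-ID column;
        ``"plink-raw-like"`` — header plus six leading metadata columns
        (family id, individual id, parents, sex, phenotype) before the codes,
        as written by PLINK ``--recode A``.
    sep
        Field separator; ``None`` splits on any whitespace. A comma is
        detected automatically for paths ending in ``.csv``.
    header, row_ids
        ``True``/``False`` or ``"auto"`` (detect from the file content).
    """
    if dialect not in ("delimited-codes", "plink-raw-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(path, (str, Path)):
        if sep is None and str(path).endswith(".csv"):
            sep = ","
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    else:
        lines = [ln.rstrip("\n") for ln in path if ln.strip()]
    if not lines:
        raise ValueError("empty genotype file")

    if dialect == "plink-raw-like":
        head = _tokenize(lines[0], sep)
        n_meta = 6
        marker_ids = head[n_meta:]
        codes_rows, ind_ids = [], []
        for lineno, line in enumerate(lines[1:], start=2):
            toks = _tokenize(line, sep)
            if len(toks) != len(head):
                raise ValueError(
                    f"line {lineno}: expected {len(head)} fields, got {len(toks)}"
                )
            ind_ids.append(toks[1])
            codes_rows.append(toks[n_meta:])
        return _rows_to_matrix(codes_rows, ind_ids, marker_ids, first_lineno=2)

    first = _tokenize(lines[0], sep)
    if header == "auto":
        # a header row contains at least one token that is not a 0/1/2 code
        header = not all(_is_code_token(t) for t in first[1:] or first)
    body_start = 1 if header else 0
    if body_start >= len(lines):
        raise ValueError("no data rows in genotype file")
    probe = _tokenize(lines[body_start], sep)
    if row_ids == "auto":
        if header and first[0].upper() in ("ID", "IID", "INDIVIDUAL", "SAMPLE"):
            # an id-column label in the header is unambiguous even when the
            # individual identifiers themselves look like genotype codes
            row_ids = True
        else:
            row_ids = bool(probe) and not _is_code_token(probe[0])

    marker_ids = None
    if header:
        marker_ids = first[1:] if row_ids else first
    codes_rows, ind_ids = [], []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        toks = _tokenize(line, sep)
        if row_ids:
            ind_ids.append(toks[0])
            toks = toks[1:]
        codes_rows.append(toks)
    g = _rows_to_matrix(
        codes_rows, ind_ids or None, marker_ids, first_lineno=body_start + 1
    )
    logger.info(
        "read genotypes: %d individuals x %d markers", g.n_individuals, g.n_markers
    )
    return g


def _rows_to_matrix(rows, ind_ids, marker_ids, first_lineno: int) -> GenotypeMatrix:
    width = len(rows[0])
    codes = np.empty((len(rows), width), dtype=np.int8)
    for i, toks in enumerate(rows):
        if len(toks) != width:
            raise ValueError(
                f"line {first_lineno + i}: expected {width} genotype fields, "
                f"got {len(toks)}"
            )
        for j, tok in enumerate(toks):
            if not _is_code_token(tok):
                raise ValueError(
                    f"line {first_lineno + i}, column {j + 1}: invalid genotype "
                    f"code {tok!r} (must be 0, 1 or 2)"
                )
            codes[i, j] = int(tok)
    return GenotypeMatrix(codes, individual_ids=ind_ids, marker_ids=marker_ids)


def read_phenotypes(path: str | Path | io.TextIOBase) -> np.ndarray:
    """Read one phenotype value per line, in individual order."""
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    else:
        lines = [ln.strip() for ln in path if ln.strip()]
    try:
        return np.array([float(x) for x in lines], dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed phenotype file: {exc}") from exc


def write_genotypes(
    g: GenotypeMatrix,
    path: str | Path,
    sep: str = " ",
    header: bool = True,
    row_ids: bool = True,
) -> None:
    """Write a genotype matrix in the delimited-codes layout (round-trips)."""
    with open(path, "w") as fh:
        if header:
            cols = (["ID"] if row_ids else []) + g.marker_ids
            fh.write(sep.join(cols) + "\n")
        for i in range(g.n_individuals):
            row = [str(int(c)) for c in g.codes[i]]
            if row_ids:
                row = [g.individual_ids[i]] + row
            fh.write(sep.join(row) + "\n")


def write_phenotypes(y: Sequence[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in y:
            fh.write(f"{float(v):.10g}\n")


def load_qtlmas_zip(
    path: str | Path,
    combined: str | bool = "auto",
    sep: str | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Load a zip archive holding genotypes and phenotypes.

    Two layouts are accepted: a single member whose first column is the
    phenotype followed by the genotype codes (``combined=True``), or two
    members — one genotype matrix and one phenotype column — matched by name
    (``combined=False``). ``"auto"`` picks based on the member count.
    """
    with zipfile.ZipFile(path) as zf:
        members = [m for m in zf.namelist() if not m.endswith("/")]
        if not members:
            raise ValueError(f"{path}: empty archive")
        if combined == "auto":
            combined = len(members) == 1
        if combined:
            text = zf.read(members[0]).decode()
            lines = [ln for ln in text.splitlines() if ln.strip()]
            y, rows = [], []
            for ln in lines:
                toks = _tokenize(ln, sep)
                y.append(float(toks[0]))
                rows.append(toks[1:])
            g = _rows_to_matrix(rows, None, None, first_lineno=1)
            return g, np.asarray(y, dtype=float)
        if len(members) != 2:
            raise ValueError(
                f"{path}: expected 2 members for the split layout, got {len(members)}"
            )

        def width(m):
            first = zf.read(m).decode().lstrip().splitlines()[0]
            return len(_tokenize(first, sep))

        # the phenotype member is the single-column one
        pheno_name = min(members, key=width)
        geno_name = next(m for m in members if m != pheno_name)
        if width(pheno_name) != 1:
            raise ValueError(
                f"{path}: cannot identify a single-column phenotype member"
            )
        g = read_genotypes(io.StringIO(zf.read(geno_name).decode()), sep=sep)
        y = read_phenotypes(io.StringIO(zf.read(pheno_name).decode()))
        return g, y


def maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers whose minor allele frequency is below ``threshold``.

    The observed allele frequency is ``f_j = mean(codes_j)/2``; marker ``j``
    is kept iff ``min(f_j, 1 - f_j) >= threshold`` (inclusive boundary).
    Marker order is preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    f = g.allele_frequencies()
    keep = np.minimum(f, 1.0 - f) >= threshold
    if not keep.any():
        raise ValueError(f"MAF filter at {threshold} removed all markers")
    kept = int(keep.sum())
    if kept < g.n_markers:
        logger.info(
            "MAF filter %.4g: %d of %d markers retained", threshold, kept, g.n_markers
        )
    return GenotypeMatrix(
        g.codes[:, keep],
        individual_ids=list(g.individual_ids),
        marker_ids=[m for m, k in zip(g.marker_ids, keep) if k],
    )


def standardize(
    g: GenotypeMatrix,
    phenotypes: np.ndarray,
    stats_from: np.ndarray | None = None,
) -> StandardizedDesign:
    """Column-standardize genotypes and center the phenotype.

    Means and population (divide-by-n) standard deviations are computed over
    the ``stats_from`` rows (default: all rows, matching a single-matrix
    standardization of the full data) and applied to every row. Pass the
    training index to obtain leakage-free, training-only statistics.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if phenotypes.shape != (g.n_individuals,):
        raise ValueError(
            f"phenotype length {phenotypes.size} != {g.n_individuals} individuals"
        )
    rows = np.arange(g.n_individuals) if stats_from is None else np.asarray(stats_from)
    sub = g.codes[rows].astype(float)
    col_means = sub.mean(axis=0)
    col_sds = sub.std(axis=0)  # population convention: x_j'x_j = n exactly
    zero = col_sds == 0
    if zero.any():
        offenders = [m for m, z in zip(g.marker_ids, zero) if z]
        raise ValueError(
            "zero-variance marker(s) over standardization rows: "
            + ", ".join(offenders[:10])
            + ("..." if len(offenders) > 10 else "")
        )
    X = (g.codes.astype(float) - col_means) / col_sds
    y_mean = float(phenotypes[rows].mean())
    return StandardizedDesign(
        X=X, y=phenotypes - y_mean, col_means=col_means, col_sds=col_sds, y_mean=y_mean
    )


def kfold_splits(n: int, k: int, seed: int | None = None) -> list[TrainTestSplit]:
    """Generic K-fold partition into (train, test) index pairs.

    Folds are contiguous blocks of a (optionally shuffled) permutation of
    0..n-1, as near-equal in size as possible. The hold-out benchmark
    protocol uses a single fixed split (``make_split``); this utility exists
    for cross-validated tuning on other data.
    """
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n], got k={k}, n={n}")
    order = np.arange(n)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    folds = np.array_split(order, k)
    return [
        TrainTestSplit(
            train_index=np.concatenate([f for j, f in enumerate(folds) if j != i]),
            test_index=folds[i],
        )
        for i in range(k)
    ]


def make_split(n: int, train_last: int) -> TrainTestSplit:
    """Leading-block split: individuals 1..train_last train, the rest test.

    ``train_last`` is 1-based (individual numbering); the returned indices
    are 0-based row positions.
    """
    if not 1 <= train_last < n:
        raise ValueError(
            f"train_last must satisfy 1 <= train_last < n, got {train_last} (n={n})"
        )
    return TrainTestSplit(
        train_index=np.arange(train_last), test_index=np.arange(train_last, n)
    )
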