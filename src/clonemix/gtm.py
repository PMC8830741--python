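"""Observed genotype matrices: container, reading, writing.

The observed genotype matrix (GTM) ``D`` has one row per cell and one column
per SNV locus.  Entries are ternary: 0 (mutation absent), 1 (mutation
present) or :data:`MISSING` (locus unobserved in that cell, e.g. dropped out
or uncovered).  The fraction of missing entries, eta, is carried on the
container because the model-selection score needs it.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Code used for unobserved entries, both in memory and in the default file
#: dialect.  Configurable per file via ``missing_code`` in :func:`read_gtm`.
MISSING: int = 3

_ALLOWED = (0, 1, MISSING)


class GTMFormatError(ValueError):
    """Raised when an input matrix file cannot be parsed as a valid GTM."""


@dataclass
class GenotypeMatrix:
    """An observed N x M ternary genotype matrix with row/column labels.

    Attributes
    ----------
    values
        ``(N, M)`` int8 array with entries in ``{0, 1, MISSING}``.
    cell_ids, locus_ids
        Unique string labels for rows (cells) and columns (loci).
    eta
        Fraction of ``MISSING`` entries, in ``[0, 1]``; recomputed at
        construction.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    eta: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("genotype matrix must be 2-D and non-empty")
        bad = ~np.isin(self.values, _ALLOWED)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.values[i, j]!r} at "
                f"row {i}, column {j}; allowed codes are 0, 1, {MISSING}"
            )
        self.values = self.values.astype(np.int8)
        n, m = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.locus_ids:
            self.locus_ids = [f"locus_{j}" for j in range(m)]
        if len(self.cell_ids) != n or len(self.locus_ids) != m:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n or len(set(self.locus_ids)) != m:
            raise ValueError("cell_ids/locus_ids must be unique")
        self.eta = missing_fraction(self)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def missing_fraction(gtm: GenotypeMatrix) -> float:
    """Fraction of unobserved entries in the matrix (eta)."""
    v = gtm.values if isinstance(gtm, GenotypeMatrix) else np.asarray(gtm)
    return float(np.mean(v == MISSING))


def read_gtm(
    path,
    missing_code: int = MISSING,
    delimiter: str | None = None,
    has_header: bool = False,
    cells_as_rows: bool = True,
) -> GenotypeMatrix:
    """Read a delimited text genotype matrix.

    Parameters
    ----------
    path
        File to read.  Whitespace/tab delimiting is auto-detected; pass
        ``delimiter=","`` for CSV.
    missing_code
        Integer token that encodes an unobserved entry (default 3).
    has_header
        If true, the first row holds column labels and the first column row
        labels.
    cells_as_rows
        If false the file is transposed after reading (cells in columns).

    Returns
    -------
    GenotypeMatrix
        With orientation normalised to cells-as-rows and eta recomputed.
    """
    try:
        with open(path, "rt") as fh:
            text = fh.read()
    except OSError as exc:
        raise GTMFormatError(f"cannot read {path}: {exc}") from exc
    if not text.strip():
        raise GTMFormatError(f"{path}: file is empty")
    sep = delimiter if delimiter is not None else r"\s+"
    try:
        df = pd.read_csv(
            _stdio.StringIO(text),
            sep=sep,
            header=0 if has_header else None,
            index_col=0 if has_header else None,
            dtype=str,
            comment="#",
            engine="python",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise GTMFormatError(f"{path}: {exc}") from exc

    raw = df.to_numpy()
    parsed = np.empty(raw.shape, dtype=np.int8)
    for (i, j), tok in np.ndenumerate(raw):
        if tok is None or (isinstance(tok, float) and np.isnan(tok)):
            raise GTMFormatError(
                f"{path}: ragged or incomplete row {i} (column {j})"
            )
        try:
            val = int(str(tok).strip())
        except ValueError:
            raise GTMFormatError(
                f"{path}: unparsable token {tok!r} at row {i}, column {j}"
            ) from None
        if val == missing_code:
            parsed[i, j] = MISSING
        elif val in (0, 1):
            parsed[i, j] = val
        else:
            raise GTMFormatError(
                f"{path}: disallowed genotype code {val} at row {i}, "
                f"column {j} (expected 0, 1 or {missing_code})"
            )

    row_ids = [str(x) for x in df.index] if has_header else []
    col_ids = [str(x) for x in df.columns] if has_header else []
    if not cells_as_rows:
        parsed = parsed.T
        row_ids, col_ids = col_ids, row_ids
    return GenotypeMatrix(parsed, cell_ids=row_ids, locus_ids=col_ids)


def write_gtm(gtm: GenotypeMatrix, path, missing_code: int = MISSING) -> None:
    """Write the matrix as headered TSV (round-trips through read_gtm)."""
    v = gtm.values.astype(int).copy()
    v[gtm.values == MISSING] = missing_code
    df = pd.DataFrame(v, index=gtm.cell_ids, columns=gtm.locus_ids)
    df.to_csv(path, sep="\t")


def write_results(fit, out_prefix) -> dict[str, str]:
    """Write all clustering artifacts for a converged fit.

    Produces, under ``<out_prefix>.*``:

    - ``assignments.tsv`` — cell_id, cluster index, max posterior;
    - ``subclone_genotypes.tsv`` — the K x M inferred cluster genotypes;
    - ``predicted_gtm.tsv`` — the imputed N x M binary matrix Z;
    - ``summary.txt`` — flat ``key=value`` lines with K, alpha, beta,
      log-likelihood and the model score.

    Returns a mapping from artifact name to the path written.
    """
    prefix = str(out_prefix)
    paths = {
        "assignments": prefix + ".assignments.tsv",
        "subclone_genotypes": prefix + ".subclone_genotypes.tsv",
        "predicted_gtm": prefix + ".predicted_gtm.tsv",
        "summary": prefix + ".summary.txt",
    }
    p = fit.params
    pd.DataFrame(
        {
            "cell_id": fit.cell_ids,
            "cluster": fit.assignments,
            "max_posterior": fit.gamma[np.arange(len(fit.assignments)),
                                       fit.assignments],
        }
    ).to_csv(paths["assignments"], sep="\t", index=False)
    pd.DataFrame(
        p.C.astype(int),
        index=[f"clone_{k}" for k in range(p.K)],
        columns=fit.locus_ids,
    ).to_csv(paths["subclone_genotypes"], sep="\t")
    pd.DataFrame(
        fit.Z.astype(int), index=fit.cell_ids, columns=fit.locus_ids
    ).to_csv(paths["predicted_gtm"], sep="\t")
    score = fit.score if fit.score is not None else float("nan")
    with open(paths["summary"], "wt") as fh:
        fh.write(
            f"K={p.K}\nalpha={p.alpha:.6g}\nbeta={p.beta:.6g}\n"
            f"log_likelihood={fit.log_likelihood:.6f}\n"
            f"score={score:.6g}\nn_iter={fit.n_iter}\n"
        )
    return paths
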