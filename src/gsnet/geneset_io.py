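"""Readers, writers and the multi-gene-set batch driver.

Expression matrices travel as TSV/CSV with gene ids in the first column and
sample ids in the header; gene set collections use the GMT format (one set
per tab-separated line: name, description, gene ids).  The batch driver
runs one chosen test per gene set against the full expression matrix and
appends Benjamini-Hochberg adjusted p-values across the tested sets.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, check_labels
from .gsnca import GSNCAConfig, gsnca_test
from .msttests import ks_test, md_test, rks_test, rmd_test, ww_test
from .variance import aggr_f_test

__all__ = [
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_gmt",
    "read_labels",
    "bh_adjust",
    "test_gene_sets",
    "write_results",
    "METHODS",
]

METHODS = ("ww", "ks", "md", "rks", "rmd", "aggrf", "gsnca")

_DISPATCH = {
    "ww": ww_test,
    "ks": ks_test,
    "md": md_test,
    "rks": rks_test,
    "rmd": rmd_test,
    "aggrf": aggr_f_test,
}


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    description: str = ""
    genes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate gene ids")
        object.__setattr__(self, "genes", genes)

    def __len__(self):
        return len(self.genes)


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV or CSV matrix.

    The first column holds gene ids, the header row sample ids.  ``fmt`` is
    inferred from the filename extension when omitted.  Duplicate gene ids,
    ragged rows and non-numeric cells produce descriptive errors.
    """
    sep = _separator(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    dups = df.index[df.index.duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate gene id(s) in {path}: {', '.join(map(str, dups[:5]))}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None):
    """Write a matrix readable by :func:`read_expression` (full float precision)."""
    sep = _separator(path, fmt)
    df = expr.to_dataframe()
    df.index.name = "gene"
    df.to_csv(path, sep=sep, float_format="%.17g")


def _separator(path, fmt):
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then gene ids, tab-separated.

    Duplicate genes within a line are dropped with a warning; a non-empty
    line with fewer than three fields is an error naming the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene "
                    f"(got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate gene ids in set {name!r} removed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, desc, tuple(unique)))
    return sets


def read_labels(source, n_samples: int | None = None) -> np.ndarray:
    """Labels from a one-column text file or a '1,1,2,2' style string."""
    text = str(source)
    if "," in text and "\n" not in text and not text.endswith((".txt", ".tsv", ".csv")):
        tokens = [t for t in text.split(",") if t.strip()]
    else:
        with open(source) as fh:
            tokens = fh.read().split()
    labels = np.array([int(t) for t in tokens])
    return check_labels(labels, n_samples if n_samples is not None else labels.shape[0])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def set_seed(master_seed, set_name: str) -> int:
    """Deterministic per-set seed below 2^31, from the master seed and set name.

    Adding or removing a set never perturbs the other sets' results.
    """
    return zlib.crc32(f"{master_seed}:{set_name}".encode()) % (2**31)


def test_gene_sets(
    expr_full: ExpressionMatrix,
    labels,
    sets,
    method: str = "ks",
    min_size: int = 10,
    max_size: int = 500,
    nperm: int = 1000,
    seed=None,
    **method_kwargs,
) -> pd.DataFrame:
    """Run one test over a collection of gene sets (batch mode).

    Each set's genes are intersected with the matrix rows (case-sensitive
    exact match); sets whose matched size falls outside
    [``min_size``, ``max_size``] are recorded as skipped.  Results carry
    BH-adjusted p-values across the tested sets.  Group 1 plays the role of
    X throughout (the signed MD statistic's sign convention).

    Returns a DataFrame with one row per input set: name, n_genes,
    n_matched, method, status, p_value, p_adjusted, seed.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    labels = check_labels(labels, expr_full.n_samples)
    gene_index = set(expr_full.gene_ids)
    rows = []
    for gs in sets:
        matched = [g for g in gs.genes if g in gene_index]
        row = {
            "set": gs.name,
            "n_genes": len(gs),
            "n_matched": len(matched),
            "method": method,
            "seed": None,
        }
        if not min_size <= len(matched) <= max_size:
            row.update(status="skipped", p_value=np.nan)
            rows.append(row)
            continue
        sub = expr_full.subset_genes(matched)
        s = set_seed(seed, gs.name)
        if method == "gsnca":
            res = gsnca_test(sub, labels, config=GSNCAConfig(), nperm=nperm, seed=s, **method_kwargs)
        else:
            res = _DISPATCH[method](sub, labels, nperm=nperm, seed=s, **method_kwargs)
        row.update(status="tested", p_value=res.p_value, seed=s)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not (out["status"] == "tested").any():
        raise ValueError("no gene set passed the size filter; nothing was tested")
    out["p_adjusted"] = np.nan
    tested = out["status"] == "tested"
    out.loc[tested, "p_adjusted"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out


test_gene_sets.__test__ = False  # despite the name, not a pytest target


def write_results(df: pd.DataFrame, path, method: str, nperm: int, seed) -> None:
    """Write a batch-result TSV with a commented provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# gsnet {__version__}\tmethod={method}\tnperm={nperm}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
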