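"""Core data containers: expression matrices and two-group sample labels.

An :class:`ExpressionMatrix` holds a genes x samples block of normalized
measurements (microarray intensities or normalized RNA-seq counts) together
with unique gene and sample identifiers.  Group labels are plain integer
vectors with values 1 and 2; group 1 plays the role of "X" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "check_labels", "GroupLabelError"]


class GroupLabelError(ValueError):
    """Raised when a sample-label vector violates the two-group contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples matrix of normalized expression values.

    Parameters
    ----------
    values : ndarray, shape (p, N)
        Normalized measurements, one row per gene, one column per sample.
        Must be finite; p >= 2 genes and N >= 4 samples.
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: tuple = field(default=None)
    sample_ids: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got shape {values.shape}")
        p, n = values.shape
        if p < 2:
            raise ValueError(f"need at least 2 genes (rows), got {p}")
        if n < 4:
            raise ValueError(f"need at least 4 samples (columns), got {n}")
        gene_ids = self.gene_ids
        sample_ids = self.sample_ids
        if gene_ids is None:
            gene_ids = tuple(f"g{i + 1}" for i in range(p))
        else:
            gene_ids = tuple(str(g) for g in gene_ids)
        if sample_ids is None:
            sample_ids = tuple(f"s{j + 1}" for j in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        if len(gene_ids) != p:
            raise ValueError(f"{len(gene_ids)} gene ids for {p} rows")
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} columns")
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{gene_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with gene ids as index, sample ids as columns."""
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset by gene id (exact, case-sensitive match), preserving matrix row order."""
        wanted = set(genes)
        keep = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        if len(keep) < 2:
            raise ValueError(f"gene subset matches only {len(keep)} rows; need >= 2")
        return ExpressionMatrix(
            self.values[keep, :],
            tuple(self.gene_ids[i] for i in keep),
            self.sample_ids,
        )


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def check_labels(labels, n_samples: int) -> np.ndarray:
    """Validate a two-group label vector.

    Values must all be 1 or 2, both groups must have at least two members,
    and the length must equal the number of samples.  Returns an int array.
    """
    lab = np.asarray(labels)
    if lab.ndim != 1 or lab.shape[0] != n_samples:
        raise GroupLabelError(f"labels must be a length-{n_samples} vector, got shape {lab.shape}")
    try:
        lab = lab.astype(int)
    except (TypeError, ValueError) as exc:
        raise GroupLabelError("labels must be integers (1 or 2)") from exc
    if not np.all(np.isin(lab, (1, 2))):
        bad = sorted(set(lab.tolist()) - {1, 2})
        raise GroupLabelError(f"labels must take values 1 or 2; found {bad}")
    n1 = int(np.sum(lab == 1))
    n2 = int(np.sum(lab == 2))
    if n1 < 2 or n2 < 2:
        raise GroupLabelError(f"each group needs >= 2 samples; got n1={n1}, n2={n2}")
    return lab
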