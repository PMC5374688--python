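"""Altered-gene-set (AGS) construction from omics matrices and mutation lists.

An AGS is the sample-specific side of an enrichment run: the genes a given
sample or contrast singles out.  Builders here mirror the usual recipes -
a fixed number of top-ranking genes per sample, all genes past a
fold-change (and optionally significance) threshold, random sets of a
chosen size as a negative control, and one-set-per-sample conversion of
mutation tables.

Scores are used exactly as given (typically log2 fold changes); no
centering or normalisation is applied, so any such step is an explicit,
visible part of the caller's pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import DataError, GeneSet, GeneSetCollection

logger = logging.getLogger("netenrich")

__all__ = [
    "ScoreMatrix",
    "read_score_matrix",
    "ags_top",
    "ags_significant",
    "ags_toprandom",
    "mutations2ags",
    "read_mutation_pairs",
]


@dataclass
class ScoreMatrix:
    """Genes x samples numeric matrix, optionally with matching p-values.

    ``scores`` rows are genes (unique ids), columns samples or contrasts.
    ``pvalues``, when present, must share the exact row and column index
    (adjusted p-values companion to the scores).
    """

    scores: pd.DataFrame
    pvalues: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise DataError("duplicate gene ids in score matrix")
        if self.pvalues is not None:
            if not self.scores.index.equals(self.pvalues.index) or not self.scores.columns.equals(
                self.pvalues.columns
            ):
                raise DataError("p-value matrix must share row/column ids with scores")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


def read_score_matrix(path, pvalues_path=None) -> ScoreMatrix:
    """Read a genes x samples TSV (first column = gene id, header row)."""
    scores = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if scores.empty:
        raise DataError(f"{Path(path).name}: empty matrix")
    pvals = None
    if pvalues_path is not None:
        pvals = pd.read_csv(pvalues_path, sep="\t", index_col=0, comment="#")
    return ScoreMatrix(scores, pvals)


def _valid_scores(col: pd.Series, sample: str) -> pd.Series:
    n_nan = int(col.isna().sum())
    if n_nan:
        logger.warning("sample %r: %d NaN score(s) excluded", sample, n_nan)
    return col.dropna()


def ags_top(m: ScoreMatrix, n: int) -> GeneSetCollection:
    """Per sample: the ``n`` genes with largest absolute score.

    Ranking ties at the boundary are broken toward the lexicographically
    smaller gene id so the output is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(m.genes):
        raise ValueError(f"n={n} exceeds number of genes ({len(m.genes)})")
    sets = []
    for sample in m.samples:
        col = _valid_scores(m.scores[sample], sample)
        ranked = (
            pd.DataFrame({"absval": col.abs().to_numpy(), "gene": col.index.to_numpy()})
            .sort_values(["absval", "gene"], ascending=[False, True], kind="mergesort")
        )
        members = ranked["gene"].head(n).tolist()
        sets.append(GeneSet(str(sample), frozenset(members)))
    return GeneSetCollection(sets, role="AGS", name=f"top{n}")


def ags_significant(
    m: ScoreMatrix, cutoff: float, alpha: Optional[float] = None
) -> GeneSetCollection:
    """Per sample: genes with ``|score| > cutoff`` (strict), and adjusted
    p <= alpha when ``alpha`` is given (requires the companion matrix).

    Samples left with no gene are dropped with a warning; set sizes are
    data-driven rather than fixed.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if alpha is not None and m.pvalues is None:
        raise DataError("alpha given but score matrix has no companion p-values")
    sets = []
    for sample in m.samples:
        col = _valid_scores(m.scores[sample], sample)
        keep = col.index[col.abs() > cutoff]
        if alpha is not None:
            pcol = m.pvalues[sample].reindex(keep)
            keep = keep[(pcol <= alpha).to_numpy(dtype=bool)]
        if len(keep) == 0:
            logger.warning("sample %r: no gene passes cutoff; set dropped", sample)
            continue
        sets.append(GeneSet(str(sample), frozenset(keep.tolist())))
    return GeneSetCollection(sets, role="AGS", name=f"significant_gt{cutoff}")


def ags_toprandom(m: ScoreMatrix, n: int, seed: int = 0) -> GeneSetCollection:
    """Per sample: ``n`` genes sampled uniformly without replacement.

    A size-matched negative control for the ``top`` builder.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(m.genes):
        raise ValueError(f"n={n} exceeds number of genes ({len(m.genes)})")
    rng = np.random.default_rng(seed)
    genes = np.array(m.genes, dtype=object)
    sets = []
    for sample in m.samples:
        members = rng.choice(genes, size=n, replace=False)
        sets.append(GeneSet(str(sample), frozenset(members.tolist())))
    return GeneSetCollection(sets, role="AGS", name=f"toprandom{n}_s{seed}")


def read_mutation_pairs(path) -> pd.DataFrame:
    """Read a 2-column (sample-id, gene-id) TSV.

    A header row is auto-detected when the first field is ``sample``
    (case-insensitive).
    """
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise DataError(f"{path.name}:{lineno}: expected 2 fields (sample, gene)")
            if lineno == 1 and fields[0].lower() == "sample":
                continue
            rows.append(fields)
    return pd.DataFrame(rows, columns=["sample", "gene"])


def mutations2ags(pairs: pd.DataFrame) -> GeneSetCollection:
    """One AGS per sample from a (sample, gene) pair table; genes deduplicated."""
    if pairs is None or len(pairs) == 0:
        raise DataError("empty mutation table")
    sample_col, gene_col = pairs.columns[0], pairs.columns[1]
    sets = []
    for sample, group in pairs.groupby(sample_col, sort=False):
        sets.append(GeneSet(str(sample), frozenset(group[gene_col].astype(str))))
    return GeneSetCollection(sets, role="AGS", name="mutations")
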