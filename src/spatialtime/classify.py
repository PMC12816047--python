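"""Spot classification by prediction score and per-group expression summaries.

Spots carry per-cell-type prediction scores in [0, 1] produced upstream by
label transfer against a single-cell reference. A spot is called positive
for a cell type when its score reaches the cutoff (default 0.6, ties count
as positive); a spot may be positive for several cell types or for none.
Expression is library-size normalized (each spot scaled to the median spot
total, then log1p) before group summaries — the fraction of spots
expressing a gene and the mean normalized expression, the two numbers
behind a dot-plot panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "SpotLabels",
    "classify_spots",
    "normalize_expression",
    "group_expression_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.6


@dataclass
class SpotLabels:
    """Per-cell-type positive/negative calls for every spot."""

    labels: pd.DataFrame  # bool, one column per cell type, one row per spot
    threshold: float
    inclusive: bool = True

    @property
    def cell_types(self) -> list[str]:
        return list(self.labels.columns)

    def positive_counts(self) -> pd.Series:
        return self.labels.sum(axis=0)

    def positive_index(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.labels[cell_type].to_numpy())


def classify_spots(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    inclusive: bool = True,
) -> SpotLabels:
    """Threshold prediction scores into positive/negative calls.

    Parameters
    ----------
    scores : pandas.DataFrame
        One column per cell type, values in [0, 1].
    threshold : float
        Positivity cutoff in [0, 1].
    inclusive : bool
        If True (default), a score exactly at the threshold is positive.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    vals = scores.to_numpy(dtype=float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValidationError("prediction scores outside [0, 1]")
    flags = vals >= threshold if inclusive else vals > threshold
    labels = pd.DataFrame(flags, columns=scores.columns, index=scores.index)
    result = SpotLabels(labels=labels, threshold=threshold, inclusive=inclusive)
    for ct, n in result.positive_counts().items():
        logger.info("cell type %s: %d positive spots", ct, n)
    return result


def normalize_expression(
    counts: np.ndarray, target: float | None = None
) -> np.ndarray:
    """Library-size normalize a gene-by-spot count matrix, then log1p.

    Each spot's counts are scaled so its total equals ``target`` (default:
    the median of per-spot totals) and the result is log(1 + x). Spots with
    zero total are left at 0 for every gene, with a warning.
    """
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValidationError("counts must be non-negative")
    totals = counts.sum(axis=0).astype(float)
    if target is None:
        target = float(np.median(totals))
    out = np.zeros(counts.shape, dtype=float)
    nz = totals > 0
    if (~nz).any():
        msg = f"{int((~nz).sum())} spot(s) have zero total counts; normalized to 0"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if target > 0 and nz.any():
        out[:, nz] = np.log1p(counts[:, nz] / totals[nz] * target)
    return out


def group_expression_summary(
    normalized: np.ndarray,
    labels: SpotLabels,
    genes: list[str],
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Dot-plot style summary: per (group, gene) fraction expressing and mean.

    ``fraction_expressing`` is the share of group spots with any signal for
    the gene (normalized value > 0, equivalent to raw count > 0);
    ``mean_expression`` is the mean normalized expression across the group.
    Groups with no positive spots are skipped with a warning.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[0] != len(genes):
        raise ValidationError(
            f"{normalized.shape[0]} matrix rows but {len(genes)} gene names"
        )
    wanted = genes if gene_subset is None else list(gene_subset)
    gene_idx = {}
    for g in wanted:
        if g not in genes:
            raise ValidationError(f"gene {g!r} not in the matrix")
        gene_idx[g] = genes.index(g)
    rows = []
    any_group = False
    for ct in labels.cell_types:
        idx = labels.positive_index(ct)
        if len(idx) == 0:
            msg = f"group {ct!r} has no positive spots; skipped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        any_group = True
        sub = normalized[:, idx]
        for g, gi in gene_idx.items():
            vals = sub[gi]
            rows.append(
                {
                    "group": ct,
                    "gene": g,
                    "n_spots": len(idx),
                    "fraction_expressing": float((vals > 0).mean()),
                    "mean_expression": float(vals.mean()),
                }
            )
    if not any_group:
        raise InsufficientDataError("no group has any positive spot")
    return pd.DataFrame(rows)
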