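"""Cross-genome panel statistics.

Given per-genome counts of the four scored gene categories over a panel of
genomes, this module standardizes counts to z-scores, averages them into a
per-genome combined score (optionally on counts per Mbp), regresses counts
on genome size, flags genomes in the upper tail, and clusters genomes by
the Pearson correlation of their COG abundance profiles.

The combined score of genome g is

    S_g = (1/4) * sum_c (x_{g,c} - mu_c) / sigma_c

over the categories c in {TCS, TF, transport, defense}, with mu_c/sigma_c
the panel mean and population standard deviation.  The size-normalized
variant standardizes densities d_{g,c} = x_{g,c} / size_Mbp instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .inventory import DEFAULT_CATEGORIES

logger = logging.getLogger(__name__)

BP_PER_MBP = 1e6


class DegenerateFitError(ValueError):
    """Regression impossible: all genome sizes identical."""


@dataclass
class PanelMatrix:
    """Genome panel: sizes (bp) and per-category counts.

    ``counts`` is a genomes x categories DataFrame of nonnegative integers
    (missing = 0); ``sizes_bp`` is indexed identically.
    """

    counts: pd.DataFrame
    sizes_bp: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.fillna(0)
        self.sizes_bp = self.sizes_bp.reindex(self.counts.index)
        if self.sizes_bp.isna().any():
            raise ValueError("every genome needs a size")
        if (self.sizes_bp <= 0).any():
            raise ValueError("genome sizes must be positive")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def densities(self) -> pd.DataFrame:
        """Counts per Mbp of genome."""
        return self.counts.div(self.sizes_bp / BP_PER_MBP, axis=0)

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "size_bp", self.sizes_bp)
        df.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path) -> "PanelMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        return cls(counts=df.drop(columns=["size_bp"]), sizes_bp=df["size_bp"])


def zscore(x: float, mu: float, sigma: float) -> float:
    """Standardized value (x - mu) / sigma for externally given moments."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (x - mu) / sigma


def zscore_table(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, population sd 1 (divisor n).

    A zero-variance column yields all-zero z-scores with a warning.
    Needs at least two rows.
    """
    if len(values) < 2:
        raise ValueError("z-scores need a panel of >= 2 genomes")
    mu = values.mean(axis=0)
    sigma = values.std(axis=0, ddof=0)
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            f"zero variance in categories {list(values.columns[zero])}; "
            "their z-scores are defined as 0",
            stacklevel=2,
        )
    z = (values - mu).div(sigma.where(~zero, 1.0), axis=1)
    z.loc[:, zero] = 0.0
    return z


def combined_scores(
    panel: PanelMatrix,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    normalized: bool = False,
) -> pd.Series:
    """Per-genome combined score: mean of the designated categories' z-scores.

    ``normalized=True`` standardizes counts per Mbp instead of raw counts.
    """
    missing = [c for c in categories if c not in panel.counts.columns]
    if missing:
        raise KeyError(f"panel lacks categories {missing}")
    values = panel.densities() if normalized else panel.counts
    z = zscore_table(values[list(categories)])
    return z.mean(axis=1).rename("combined_score")


def fit_count_size_regression(
    panel: PanelMatrix, category: str
) -> tuple[float, float, float]:
    """OLS of a category's counts on genome size in Mbp.

    Returns (slope per Mbp, intercept, Pearson r with sign).
    """
    if category not in panel.counts.columns:
        raise KeyError(f"unknown category {category!r}")
    if len(panel.counts) < 3:
        raise ValueError("regression needs >= 3 genomes")
    sizes_mbp = panel.sizes_bp.to_numpy(dtype=float) / BP_PER_MBP
    if np.allclose(sizes_mbp, sizes_mbp[0]):
        raise DegenerateFitError("all genome sizes identical")
    y = panel.counts[category].to_numpy(dtype=float)
    fit = stats.linregress(sizes_mbp, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def rank_and_flag(values: pd.Series, top_fraction: float) -> pd.DataFrame:
    """Percentile ranks and upper-tail flags.

    Rank of genome g is (# genomes with strictly smaller value) / n, so ties
    share the lower rank; g is flagged when rank >= 1 - top_fraction.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if len(values) == 0:
        raise ValueError("empty panel")
    v = values.to_numpy(dtype=float)
    rank = np.array([(v < x).sum() for x in v]) / len(v)
    return pd.DataFrame(
        {"rank": rank, "flagged": rank >= 1 - top_fraction}, index=values.index
    )


def cog_profile_cluster(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson-correlation matrix of COG abundance profiles plus leaf order.

    ``profiles`` is genomes x COG ids (absent = 0).  The correlation matrix
    is symmetric with unit diagonal; a zero-variance profile gets
    correlation 0 to everything (with a warning).  Genomes are then
    hierarchically clustered with average linkage on distance 1 - r and the
    dendrogram leaf order is returned.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 genomes")
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance COG profiles: {list(profiles.index[zero])}; "
            "their correlations are defined as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=profiles.index, columns=profiles.index)

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    order = [profiles.index[i] for i in leaves]
    return corr_df, order
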