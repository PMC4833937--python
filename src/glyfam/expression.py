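"""Expression profiling: transforms, stress fold changes, MeV-style
hierarchical clustering (1 - Pearson r distance, average linkage) and
tissue-specificity classification.

Matrices are pandas DataFrames (genes x conditions, nonnegative
normalized values) with a sidecar condition -> class mapping (tissue
classes underground / aerial / seed, or mock / stress).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "log_transform",
    "fold_change",
    "regulation_call",
    "pearson_distance_matrix",
    "hierarchical_cluster",
    "specificity_class",
    "plot_heatmap",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 1.0  # expressed-threshold on the normalized scale
CONSTITUTIVE_FRACTION = 0.90


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    condition_class: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate row or column labels")
        missing = set(self.values.columns) - set(self.condition_class)
        if missing:
            raise ValueError(f"conditions without class: {sorted(missing)}")


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (matrix.values < 0).any():
        raise ValueError("negative input")
    return np.log2(matrix + pseudocount)


def fold_change(stress_value: float, mock_value: float,
                floor: float = 0.1) -> float:
    """FC = max(stress, floor) / max(mock, floor)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return max(stress_value, floor) / max(mock_value, floor)


def regulation_call(fc: float, up_threshold: float = 2.0,
                    down_threshold: float = 0.5) -> str:
    if not up_threshold > 1 > down_threshold:
        raise ValueError("need up_threshold > 1 > down_threshold")
    if fc >= up_threshold:
        return "up"
    if fc <= down_threshold:
        return "down"
    return "unchanged"


def pearson_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows sit at distance 1
    to everything (flagged with a warning)."""
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s): distance set to 1",
            stacklevel=2,
        )
    n = x.shape[0]
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    ok = ~flat
    if ok.sum() >= 2:
        r = np.corrcoef(x[ok])
        d[np.ix_(ok, ok)] = 1.0 - r
        np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return 0.5 * (d + d.T)


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "average", metric: str = "pearson"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Agglomerative clustering of rows.

    Returns (scipy linkage matrix, matrix reordered by dendrogram leaf
    order).  Default distance is 1 - Pearson r with average linkage;
    ``metric='euclidean'`` and other scipy linkage methods are available.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if metric == "pearson":
        d = squareform(pearson_distance_matrix(matrix), checks=False)
    else:
        from scipy.spatial.distance import pdist

        d = pdist(matrix.to_numpy(dtype=float), metric=metric)
    link = hierarchy.linkage(d, method=method)
    order = hierarchy.leaves_list(link)
    return link, matrix.iloc[order]


def plot_heatmap(matrix: pd.DataFrame, path, method: str = "average",
                 metric: str = "pearson", cmap: str = "RdYlGn_r") -> None:
    """Clustered-row heatmap written to PNG/SVG (format from suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, ordered = hierarchical_cluster(matrix, method=method, metric=metric)
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * matrix.shape[1], 1 + 0.3 * matrix.shape[0])
    )
    im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def specificity_class(
    gene_row: pd.Series,
    tissue_classes: dict[str, str],
    tau: float = DEFAULT_TAU,
) -> str:
    """Classify a gene's tissue profile.

    constitutive: expressed (>= tau) in >= 90% of conditions;
    seed_specific: expressed only in seed conditions;
    non_seed: expressed in every non-seed condition and no seed one;
    silent: expressed nowhere; restricted: anything else.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    conditions = list(gene_row.index)
    expressed = {c for c in conditions if gene_row[c] >= tau}
    seed = {c for c in conditions if tissue_classes[c] == "seed"}
    non_seed = set(conditions) - seed
    if not expressed:
        return "silent"
    if len(expressed) >= CONSTITUTIVE_FRACTION * len(conditions):
        return "constitutive"
    if expressed <= seed:
        return "seed_specific"
    if non_seed <= expressed and not (expressed & seed):
        return "non_seed"
    return "restricted"
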