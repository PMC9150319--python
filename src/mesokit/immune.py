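"""Expression-based tumour-microenvironment profiling.

Cytolytic activity (geometric mean of GZMA and PRF1 TPM with a 0.01
offset), reference-based immune-cell deconvolution by non-negative least
squares with a gene-permutation significance test, CD8-high flagging,
checkpoint-expression hot/cold grouping, and marker-gene / cell-fraction
correlations.

The deconvolution here is a transparent NNLS mixture fit against a
pluggable cell-type reference expression matrix, with the permutation
p-value defined as the fraction of gene-label-permuted inputs whose
reconstruction correlates with the input at least as well as the observed
fit (add-one corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

__all__ = [
    "DEFAULT_CHECKPOINT_GENES",
    "ImmuneFractions",
    "CheckpointGrouping",
    "cytolytic_score",
    "deconvolve_fractions",
    "cd8_high_flag",
    "classify_checkpoint_groups",
    "marker_fraction_correlation",
]

# VSIR and CD276 are named cohort observations; the remainder are the
# canonical checkpoint receptor/ligand panel.  Configurable everywhere.
DEFAULT_CHECKPOINT_GENES = (
    "VSIR", "CD276", "PDCD1", "CTLA4", "CD274", "LAG3", "HAVCR2", "TIGIT",
)

DEFAULT_MARKER_GENES = ("CCL2", "TGFB1", "MMP14", "MMP2")


@dataclass(frozen=True)
class ImmuneFractions:
    """Per-sample deconvolved cell-type proportions with significance."""

    sample: str
    fractions: pd.Series  # index: cell types; sums to 1
    pvalue: float

    def __post_init__(self) -> None:
        f = self.fractions
        if (f < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if abs(float(f.sum()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def cytolytic_score(expr: pd.DataFrame, sample: str, offset: float = 0.01) -> float:
    """Geometric mean of GZMA and PRF1 TPM, each offset by ``offset``."""
    for gene in ("GZMA", "PRF1"):
        if gene not in expr.index:
            raise KeyError(f"gene {gene!r} missing from expression matrix")
    g = float(expr.at["GZMA", sample])
    p = float(expr.at["PRF1", sample])
    return float(np.sqrt((g + offset) * (p + offset)))


def _nnls_fit(ref: np.ndarray, col: np.ndarray) -> np.ndarray:
    x, _ = nnls(ref, col)
    return x


def deconvolve_fractions(
    expr_column: pd.Series,
    cell_ref: pd.DataFrame,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> ImmuneFractions:
    """NNLS mixture deconvolution of one expression column.

    Fractions are the sum-to-one-normalised non-negative mixture weights.
    Significance: the observed statistic is the Pearson correlation
    between the NNLS reconstruction and the input over the shared gene
    set; the null redraws it ``n_perm`` times on gene-label-permuted
    inputs, and p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if cell_ref.shape[1] < 2:
        raise ValueError("cell reference needs at least two cell types")
    genes = cell_ref.index.intersection(expr_column.index)
    if len(genes) == 0:
        raise ValueError("no overlapping genes between column and reference")
    ref = cell_ref.loc[genes].to_numpy(dtype=float)
    col = expr_column.loc[genes].to_numpy(dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    x = _nnls_fit(ref, col)
    total = x.sum()
    if total > 0:
        fractions = x / total
    else:  # degenerate all-zero input: no evidence for any cell type
        fractions = np.full(ref.shape[1], 1.0 / ref.shape[1])

    def _corr(v: np.ndarray, w: np.ndarray) -> float:
        # ptp, not std: np.std of identical values is not exactly zero
        if np.ptp(v) == 0 or np.ptp(w) == 0:
            return 0.0
        return float(np.corrcoef(v, w)[0, 1])

    observed = _corr(ref @ x, col)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(col)
        xp = _nnls_fit(ref, perm)
        if _corr(ref @ xp, perm) >= observed:
            exceed += 1
    pvalue = (1 + exceed) / (n_perm + 1)
    return ImmuneFractions(
        sample=str(expr_column.name),
        fractions=pd.Series(fractions, index=cell_ref.columns),
        pvalue=pvalue,
    )


def cd8_high_flag(
    fractions: ImmuneFractions,
    cell_type: str = "CD8_T",
    threshold: float = 0.2,
) -> bool:
    """True iff the CD8 T-cell proportion strictly exceeds ``threshold``."""
    if cell_type not in fractions.fractions.index:
        raise KeyError(f"cell type {cell_type!r} not in fractions")
    return float(fractions.fractions[cell_type]) > threshold


@dataclass(frozen=True)
class CheckpointGrouping:
    """Hot/cold immune grouping from checkpoint-gene expression."""

    labels: pd.Series       # per sample: "hot" / "cold"
    cluster_ids: pd.Series  # raw cluster assignment (1..k_effective)
    degenerate: bool        # fewer effective clusters than requested


def classify_checkpoint_groups(
    expr: pd.DataFrame,
    checkpoint_genes=DEFAULT_CHECKPOINT_GENES,
    cytolytic: pd.Series | None = None,
    k: int = 2,
) -> CheckpointGrouping:
    """Cluster samples on checkpoint-receptor expression; label the group
    with the higher mean cytolytic score "hot".

    Average-linkage hierarchical clustering on Euclidean distance of
    log2(TPM + 1) over the checkpoint panel, cut into ``k`` groups.
    Deterministic for a fixed input and invariant to sample order.
    """
    missing = [g for g in checkpoint_genes if g not in expr.index]
    if missing:
        raise KeyError(f"checkpoint genes missing from expression matrix: {missing}")
    samples = list(expr.columns)
    if k > len(samples):
        raise ValueError(f"cannot cut {len(samples)} samples into {k} groups")
    if cytolytic is None:
        cytolytic = pd.Series(
            [cytolytic_score(expr, s) for s in samples], index=samples
        )

    x = np.log2(expr.loc[list(checkpoint_genes), samples].to_numpy(dtype=float).T + 1.0)
    d = pdist(x, metric="euclidean")
    if len(samples) == 1 or np.all(d == 0):
        ids = pd.Series(1, index=samples)
        return CheckpointGrouping(
            labels=pd.Series("cold", index=samples), cluster_ids=ids, degenerate=True
        )
    z = linkage(d, method="average")
    ids = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=samples)
    n_eff = ids.nunique()
    if n_eff < k:
        return CheckpointGrouping(
            labels=pd.Series("cold", index=samples), cluster_ids=ids, degenerate=True
        )
    means = cytolytic.groupby(ids).mean()
    hot_id = means.idxmax()
    labels = ids.map(lambda i: "hot" if i == hot_id else "cold")
    return CheckpointGrouping(labels=labels, cluster_ids=ids, degenerate=False)


def marker_fraction_correlation(
    expr: pd.DataFrame,
    fractions: pd.DataFrame,
    pvalues: pd.Series,
    marker_genes=DEFAULT_MARKER_GENES,
    p_keep: float = 0.05,
    p_sig: float = 0.001,
) -> pd.DataFrame:
    """Pearson correlation of marker-gene log2(TPM+1) with deconvolved
    cell-type fractions, over samples with deconvolution p < ``p_keep``.

    Returns a tidy table (marker, cell_type, r, p, significant); a
    constant marker or fraction yields missing r/p and is never flagged.
    """
    keep = [s for s in fractions.index if pvalues[s] < p_keep]
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} samples pass the deconvolution significance "
            f"filter (p < {p_keep}); need >= 3"
        )
    rows = []
    for marker in marker_genes:
        if marker not in expr.index:
            raise KeyError(f"marker gene {marker!r} missing from expression matrix")
        mvals = np.log2(expr.loc[marker, keep].to_numpy(dtype=float) + 1.0)
        for cell_type in fractions.columns:
            fvals = fractions.loc[keep, cell_type].to_numpy(dtype=float)
            if np.ptp(mvals) == 0 or np.ptp(fvals) == 0:
                rows.append((marker, cell_type, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(mvals, fvals)
            rows.append((marker, cell_type, float(r), float(p), bool(p < p_sig)))
    return pd.DataFrame(
        rows, columns=["marker", "cell_type", "r", "p", "significant"]
    )
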