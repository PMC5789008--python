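"""Dopaminergic gene-system index: correlation, PCA, congruence, scoring.

The composite index summarises nine dopamine-pathway polymorphisms by their
first principal component.  Because population frequencies are assembled from
heterogeneous literature samples, the correlation matrix is computed over
pairwise-complete observations and may be indefinite; it is repaired to the
nearest positive-semidefinite correlation matrix (eigenvalue clipping with a
unit-diagonal rescale) before the eigendecomposition.  The component is given
a deterministic orientation (the DAT1 9R-carrier loading is positive, i.e.
higher index = higher dopaminergic function), population scores are
loading-weighted sums of z-scored frequencies with weights renormalised over
the loci available for each population, and the published presentation scale
maps the observed score range onto 0–100.

Composite reliability is summarised by the standardised Cronbach alpha
``k·r̄ / (1 + (k−1)·r̄)`` from the mean inter-item correlation after
reflecting negatively loading items, and the stability of the component
across analysis levels (individual literature samples vs aggregated
populations) by Tucker's congruence coefficient φ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polymorphisms import ORIENTATION_ANCHOR, resolve_id

logger = logging.getLogger(__name__)

#: eigenvalue floor used when repairing an indefinite correlation matrix
PSD_FLOOR = 1e-6

#: minimum number of loci a population must have to receive a score
MIN_ITEMS_FOR_SCORE = 5


@dataclass
class CorrelationEstimate:
    """Pairwise-complete correlation matrix with per-pair observation counts."""

    matrix: pd.DataFrame
    pair_counts: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(m)) > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class PCAResult:
    """Eigendecomposition of a correlation matrix.

    ``loadings[:, c]`` is eigenvector_c · sqrt(eigenvalue_c); variance
    fractions are eigenvalues divided by the number of variables.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


@dataclass
class GeneIndexResult:
    """Full output of the index construction."""

    oriented_loadings: pd.Series
    raw_scores: pd.Series
    scaled_scores: pd.Series
    alpha: float
    mean_interitem_r: float
    #: Tucker congruence of the first components (sample vs population level),
    #: one value per compared component; empty when no sample table was given
    phi: tuple[float, ...]
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    excluded_populations: tuple[str, ...] = ()
    sample_level_loadings: pd.Series | None = field(default=None)

    def report(self) -> dict:
        """JSON-serialisable summary."""
        return {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "variance_fractions": [float(v) for v in self.variance_fractions],
            "oriented_loadings": {k: float(v) for k, v in self.oriented_loadings.items()},
            "alpha": float(self.alpha),
            "mean_interitem_r": float(self.mean_interitem_r),
            "tucker_phi": [float(v) for v in self.phi],
            "n_populations_scored": int(len(self.raw_scores)),
            "excluded_populations": list(self.excluded_populations),
        }


def pairwise_correlation(data: pd.DataFrame, min_pairs: int = 3) -> CorrelationEstimate:
    """Pearson correlations over pairwise-complete rows of ``data``.

    ``data`` is an observations × variables frame (populations × loci, or
    samples × loci).  Every variable pair must share at least ``min_pairs``
    complete observations.
    """
    notna = data.notna().to_numpy()
    counts = notna.T.astype(int) @ notna.astype(int)
    counts_df = pd.DataFrame(counts, index=data.columns, columns=data.columns)

    offdiag = ~np.eye(len(data.columns), dtype=bool)
    short = np.argwhere((counts < min_pairs) & offdiag)
    if len(short):
        pairs = sorted(
            {tuple(sorted((data.columns[i], data.columns[j]))) for i, j in short}
        )
        raise ValueError(
            f"fewer than {min_pairs} complete observations for pairs: {pairs}"
        )

    corr = data.corr(method="pearson")
    if corr.isna().any().any():
        bad = [c for c in corr.columns if corr[c].isna().any()]
        raise ValueError(f"undefined correlation (constant column?) involving {bad}")
    m = corr.to_numpy()
    np.fill_diagonal(m, 1.0)
    corr = pd.DataFrame(np.clip((m + m.T) / 2.0, -1.0, 1.0), index=corr.index, columns=corr.columns)
    return CorrelationEstimate(matrix=corr, pair_counts=counts_df)


def smooth_to_psd(corr: CorrelationEstimate, floor: float = PSD_FLOOR) -> CorrelationEstimate:
    """Repair an indefinite correlation matrix to the nearest-in-spirit PSD one.

    Eigenvalues below ``floor`` are clipped up to it, the matrix is
    reconstructed, and rows/columns are rescaled to restore the unit
    diagonal.  An already-PSD matrix passes through unchanged, so the
    operation is idempotent.
    """
    m = corr.matrix.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    rebuilt = m.copy()
    # the unit-diagonal rescale can push an eigenvalue back under the floor,
    # so clip-and-rescale is iterated to a fixed point (idempotence)
    for _ in range(200):
        vals, vecs = np.linalg.eigh(rebuilt)
        if vals.min() >= floor - 1e-12:
            break
        rebuilt = (vecs * np.maximum(vals, floor)) @ vecs.T
        d = np.sqrt(np.diag(rebuilt))
        rebuilt = rebuilt / np.outer(d, d)
        rebuilt = (rebuilt + rebuilt.T) / 2.0
        np.fill_diagonal(rebuilt, 1.0)
    out = pd.DataFrame(rebuilt, index=corr.matrix.index, columns=corr.matrix.columns)
    return CorrelationEstimate(matrix=out, pair_counts=corr.pair_counts.copy())


def pca_correlation(corr: CorrelationEstimate) -> PCAResult:
    """Principal components of a PSD correlation matrix.

    Raises ``ValueError`` on an indefinite input — smooth it first with
    :func:`smooth_to_psd`.
    """
    m = corr.matrix.to_numpy(dtype=float)
    vals, vecs = np.linalg.eigh(m)
    if vals.min() < -1e-8:
        raise ValueError(
            "correlation matrix is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3g}); apply smooth_to_psd first"
        )
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    loadings = vecs * np.sqrt(vals)
    k = m.shape[0]
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        eigenvalues=vals,
        loadings=pd.DataFrame(loadings, index=corr.matrix.index, columns=cols),
        variance_fractions=vals / k,
    )


def orient_component(
    loadings: pd.Series, anchor: str = ORIENTATION_ANCHOR, anchor_sign: int = 1
) -> pd.Series:
    """Fix the sign indeterminacy of a component via an anchor variable.

    The whole loading vector is negated iff the anchor's loading sign
    disagrees with ``anchor_sign``.
    """
    anchor = resolve_id(anchor) if anchor not in loadings.index else anchor
    val = loadings.loc[anchor]
    if val == 0:
        raise ValueError(f"anchor {anchor!r} loading is exactly zero; orientation undefined")
    if np.sign(val) != np.sign(anchor_sign):
        return -loadings
    return loadings.copy()


def tucker_phi(x, y) -> float:
    """Tucker's congruence coefficient Σxy / sqrt(Σx²·Σy²) between loading vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("loading vectors must be 1-d, equal length >= 2")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("congruence undefined for a zero loading vector")
    return float(np.clip((x * y).sum() / (nx * ny), -1.0, 1.0))


def standardized_alpha(k: int, mean_r: float) -> float:
    """Standardised Cronbach alpha of ``k`` items with mean inter-item r ``mean_r``."""
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if not (-1.0 / (k - 1) < mean_r <= 1.0):
        raise ValueError(f"mean_r={mean_r} outside (-1/(k-1), 1] for k={k}")
    return float(k * mean_r / (1.0 + (k - 1) * mean_r))


def mean_interitem_r(corr: CorrelationEstimate, orientation) -> float:
    """Mean off-diagonal correlation after reflecting items by their signs.

    ``orientation`` gives one sign per item (e.g. the signs of the oriented
    first-component loadings); items with a negative sign are reversed so
    that all items point in the direction of the composite.
    """
    s = np.sign(np.asarray(orientation, dtype=float))
    if np.any(s == 0):
        raise ValueError("orientation signs must be nonzero")
    m = corr.matrix.to_numpy(dtype=float)
    reflected = m * np.outer(s, s)
    k = m.shape[0]
    off = reflected[~np.eye(k, dtype=bool)]
    return float(off.mean())


def score_populations(
    matrix, oriented_loadings: pd.Series, min_items: int = MIN_ITEMS_FOR_SCORE
) -> pd.Series:
    """Loading-weighted composite score per population.

    Each locus column is z-scored over the populations where it is observed;
    a population's raw score is ``Σ_j λ_j z_pj / Σ_j |λ_j|`` over its present
    loci, i.e. the loading weights are renormalised over available items so
    that scores from incomplete profiles stay on the same scale.  Populations
    with fewer than ``min_items`` loci are excluded with a logged warning.
    """
    freq = matrix.frequencies if hasattr(matrix, "frequencies") else matrix
    freq = freq[oriented_loadings.index]
    z = (freq - freq.mean()) / freq.std(ddof=1)

    lam = oriented_loadings.to_numpy(dtype=float)
    zv = z.to_numpy(dtype=float)
    present = ~np.isnan(zv)

    n_items = present.sum(axis=1)
    keep = n_items >= min_items
    if not keep.all():
        dropped = list(freq.index[~keep])
        logger.warning(
            "excluding %d population(s) with fewer than %d of %d loci: %s",
            len(dropped), min_items, len(lam), dropped,
        )

    num = np.nansum(np.where(present, zv * lam, 0.0), axis=1)
    denom = (present * np.abs(lam)).sum(axis=1)
    scores = pd.Series(num[keep] / denom[keep], index=freq.index[keep], name="raw_score")
    scores.attrs["excluded"] = tuple(freq.index[~keep])
    return scores


def scale_0_100(raw_scores: pd.Series) -> pd.Series:
    """Map scores affinely so the observed minimum is 0 and maximum is 100."""
    x = np.asarray(raw_scores, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ValueError("scores are constant; 0-100 scale undefined")
    scaled = 100.0 * (x - lo) / (hi - lo)
    if isinstance(raw_scores, pd.Series):
        return pd.Series(scaled, index=raw_scores.index, name="scaled_score")
    return pd.Series(scaled, name="scaled_score")


def _component_phis(
    pop_loadings: pd.DataFrame, sample_loadings: pd.DataFrame, n_components: int = 3
) -> tuple[float, ...]:
    """Congruence per component, matching each pair up to its sign indeterminacy."""
    phis = []
    for c in range(min(n_components, pop_loadings.shape[1], sample_loadings.shape[1])):
        phi = tucker_phi(pop_loadings.iloc[:, c], sample_loadings.iloc[:, c])
        phis.append(abs(phi))
    return tuple(phis)


def build_gene_index(
    matrix,
    sample_matrix: pd.DataFrame | None = None,
    anchor: str = ORIENTATION_ANCHOR,
    anchor_sign: int = 1,
    min_items: int = MIN_ITEMS_FOR_SCORE,
) -> GeneIndexResult:
    """Run the full index construction on a population frequency matrix.

    Pipeline: pairwise correlation → PSD smoothing → PCA → orientation of the
    first component → reliability (r̄, standardised alpha) → population
    scoring → 0–100 scaling.  When ``sample_matrix`` (samples × loci) is
    supplied, the same decomposition is run at the sample level and the
    per-component Tucker φ between the two solutions is reported.
    """
    corr = smooth_to_psd(pairwise_correlation(matrix.frequencies if hasattr(matrix, "frequencies") else matrix))
    pca = pca_correlation(corr)
    oriented = orient_component(pca.loadings["PC1"], anchor=anchor, anchor_sign=anchor_sign)

    r_bar = mean_interitem_r(corr, np.sign(oriented))
    alpha = standardized_alpha(len(oriented), r_bar)

    raw = score_populations(matrix, oriented, min_items=min_items)
    scaled = scale_0_100(raw)

    phi: tuple[float, ...] = ()
    sample_pc1 = None
    if sample_matrix is not None:
        s_corr = smooth_to_psd(pairwise_correlation(sample_matrix))
        s_pca = pca_correlation(s_corr)
        phi = _component_phis(pca.loadings, s_pca.loadings)
        sample_pc1 = orient_component(s_pca.loadings["PC1"], anchor=anchor, anchor_sign=anchor_sign)

    return GeneIndexResult(
        oriented_loadings=oriented,
        raw_scores=raw,
        scaled_scores=scaled,
        alpha=alpha,
        mean_interitem_r=r_bar,
        phi=phi,
        eigenvalues=pca.eigenvalues,
        variance_fractions=pca.variance_fractions,
        excluded_populations=raw.attrs.get("excluded", ()),
        sample_level_loadings=sample_pc1,
    )
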