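"""Count-based expression comparison ("Method 1").

Pipeline: TMM library-composition normalisation, a blind (all-samples)
negative-binomial dispersion estimate, an Anscombe-type variance-
stabilising transformation to a log2-like scale, per-control 95th-
percentile gene filtering, Bonferroni-corrected pairwise regressions, and
SVD ordination / cosine-distance clustering for overviews.

The transformers follow the scikit-learn estimator protocol so they
compose with sklearn pipelines; module functions wrap them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin


# ---------------------------------------------------------------------------
# TMM normalisation (trimmed mean of M-values).

def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.30, sum_trim: float = 0.05,
) -> float:
    """Two-sample TMM factor on log2 scale conventions.

    M (log ratio) and A (abundance) are computed on genes nonzero in both
    columns; 30% of M and 5% of A are rank-trimmed from each tail and the
    factor is 2**(weighted mean of M) with inverse-asymptotic-variance
    weights.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    if n == 0:
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to multiply to 1.

    The reference column defaults to the sample whose upper quartile of
    scaled counts is closest to the mean upper quartile.  Pure depth
    differences are handled by library size; these factors correct
    composition only.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    if ref_column is None:
        uq = counts.div(lib, axis=1).quantile(0.75)
        ref_column = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_column].to_numpy()
    n_ref = float(lib[ref_column])
    factors = pd.Series(
        {
            s: _tmm_pair(counts[s].to_numpy(), ref, float(lib[s]), n_ref)
            for s in counts.columns
        }
    )
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: counts -> effective-library-size-scaled
    counts (samples as columns).

    Fitted attributes: ``factors_`` (TMM factors), ``library_sizes_``,
    ``effective_sizes_`` (library size x factor), ``ref_column_``.
    """

    def __init__(self, ref_column: str | None = None):
        self.ref_column = ref_column

    def fit(self, X: pd.DataFrame, y=None):
        self.library_sizes_ = X.sum(axis=0)
        self.factors_ = tmm_factors(X, ref_column=self.ref_column)
        self.effective_sizes_ = self.library_sizes_ * self.factors_
        self.ref_column_ = (
            self.ref_column
            if self.ref_column is not None
            else "auto"
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scale = self.effective_sizes_ / np.exp(
            np.log(self.effective_sizes_).mean()
        )
        return X.div(scale, axis=1)


# ---------------------------------------------------------------------------
# Blind dispersion and variance-stabilising transformation.

@dataclasses.dataclass(frozen=True)
class DispersionEstimate:
    """Common negative-binomial dispersion phi (var = mu + phi * mu²),
    estimated across the whole dataset without using a design."""

    phi: float
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


def blind_dispersion(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> DispersionEstimate:
    """Method-of-moments common dispersion.

    Counts are scaled to a common library size, then phi is the median
    over expressed genes of max(0, (s² - mean) / mean²) — the NB relation
    var = mu + phi mu² solved per gene and robustly pooled.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    scale = lib / lib.mean()
    x = counts.div(scale, axis=1).to_numpy(dtype=float)
    mu = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    expressed = mu > 0
    phi_g = np.maximum(0.0, (s2[expressed] - mu[expressed]) / mu[expressed] ** 2)
    phi = float(np.median(phi_g)) if phi_g.size else 0.0
    return DispersionEstimate(phi=phi, n_genes_used=int(expressed.sum()))


_POISSON_PHI_EPS = 1e-4


def _vst_values(x: np.ndarray, phi: float) -> np.ndarray:
    """Anscombe-type NB variance stabiliser on a log2-like scale.

    For phi > 0 with k = 1/phi:  y = (2/ln 2) * asinh(sqrt((x + 3/8) / (k - 3/4)))
    + log2(k), which approaches log2(x) + c for large x (y(2x) - y(x) -> 1).
    As phi -> 0 the Poisson stabiliser 2*sqrt(x + 3/8), rescaled by
    1/ln 2, is used instead; it is monotone and defined at x = 0 but is a
    square-root, not logarithmic, scale.
    """
    x = np.asarray(x, dtype=float)
    if phi < _POISSON_PHI_EPS:
        return 2.0 * np.sqrt(x + 0.375) / np.log(2.0)
    k = 1.0 / phi
    denom = k - 0.75
    if denom <= 0:  # extreme overdispersion: fall back to log2 shift form
        return np.log2(x + 0.5 / phi)
    return 2.0 / np.log(2.0) * np.arcsinh(np.sqrt((x + 0.375) / denom)) + np.log2(k)


def anscombe_vst(
    counts: pd.DataFrame,
    dispersion: DispersionEstimate | float,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Variance-stabilised expression matrix (log2-like scale).

    Counts are first divided by relative effective library size
    (library size x TMM factor, normalised to geometric mean 1) so the
    stabiliser sees size-adjusted counts on the original count scale.
    """
    phi = dispersion.phi if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        if (factors <= 0).any():
            raise ValueError("factors must be positive")
        lib = lib * factors
    scale = lib / np.exp(np.log(lib).mean())
    x = counts.div(scale, axis=1).to_numpy(dtype=float)
    return pd.DataFrame(
        _vst_values(x, phi), index=counts.index, columns=counts.columns
    )


class VarianceStabilizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer bundling TMM factors, blind dispersion and
    the Anscombe NB variance-stabilising transform.

    Fitted attributes: ``factors_``, ``dispersion_``.
    """

    def __init__(self, ref_column: str | None = None):
        self.ref_column = ref_column

    def fit(self, X: pd.DataFrame, y=None):
        self.factors_ = tmm_factors(X, ref_column=self.ref_column)
        self.dispersion_ = blind_dispersion(X, self.factors_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return anscombe_vst(X, self.dispersion_, self.factors_)


# ---------------------------------------------------------------------------
# Pairwise regressions with Bonferroni family correction.

@dataclasses.dataclass
class RegressionResult:
    control: str
    target: str
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n_genes: int
    family_size: int
    alpha_adjusted: float
    significant: bool
    usable: bool = True


def bonferroni_alpha(m: int, family_alpha: float = 0.05) -> float:
    """Per-test alpha 0.05/m (0.01 for five comparisons, 0.0166... for three)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return family_alpha / m


def pairwise_regressions(
    vst: pd.DataFrame,
    control: str,
    targets: Sequence[str],
    family_size: int | None = None,
    q: float = 0.95,
    filter_counts: pd.DataFrame | None = None,
) -> list[RegressionResult]:
    """Regress each target on the control over the control's top-expression
    genes.

    The gene subset is the control column's values at or above its 95th
    percentile, taken on the transformed scale by default; pass the raw
    matrix as ``filter_counts`` to apply the percentile before
    transformation instead.  The same genes index every target.
    Significance requires p < 0.05/m AND a positive slope.
    """
    m = family_size if family_size is not None else len(targets)
    alpha = bonferroni_alpha(m)
    x_all = (filter_counts if filter_counts is not None else vst)[control]
    threshold = float(np.quantile(x_all.to_numpy(), q))
    genes = x_all.index[x_all >= threshold]
    results = []
    for target in targets:
        x = vst.loc[genes, control].to_numpy(dtype=float)
        y = vst.loc[genes, target].to_numpy(dtype=float)
        n = len(x)
        if n < 3 or np.ptp(x) == 0:
            results.append(RegressionResult(
                control, target, float("nan"), float("nan"), float("nan"),
                float("nan"), n, m, alpha, False, usable=False,
            ))
            continue
        res = stats.linregress(x, y)
        r2 = float(res.rvalue**2)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        p = float(res.pvalue)
        results.append(RegressionResult(
            control, target, float(res.slope), float(res.intercept),
            adj_r2, p, n, m, alpha,
            significant=bool(p < alpha and res.slope > 0),
        ))
    return results


def regressions_table(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# ---------------------------------------------------------------------------
# Ordination and clustering.

@dataclasses.dataclass
class OrdinationResult:
    """Rank-2 SVD biplot of the row-centred expression matrix."""

    sample_coords: pd.DataFrame   # samples x 2
    gene_coords: pd.DataFrame     # genes x 2
    singular_values: np.ndarray
    reconstruction_error: float   # squared error of the rank-2 approximation
    degenerate: bool = False


def ordination_biplot(
    vst: pd.DataFrame, top_n: int | None = None
) -> OrdinationResult:
    """Centre rows (genes) by their global means, take the SVD, and keep
    the first two components.  The dot product of gene and sample
    coordinates approximates the centred expression (best rank-2 fit)."""
    if vst.shape[1] < 3:
        raise ValueError("ordination needs at least 3 samples")
    m = vst.copy()
    if top_n is not None:
        spread = m.max(axis=1) - m.min(axis=1)
        m = m.loc[spread.sort_values(ascending=False).index[:top_n]]
    centred = m.sub(m.mean(axis=1), axis=0)
    u, s, vt = np.linalg.svd(centred.to_numpy(dtype=float), full_matrices=False)
    degenerate = bool(s[0] == 0)
    rank2_err = float(np.sum(s[2:] ** 2))
    gene_coords = pd.DataFrame(
        u[:, :2] * np.sqrt(s[:2]), index=m.index, columns=["PC1", "PC2"]
    )
    sample_coords = pd.DataFrame(
        vt[:2].T * np.sqrt(s[:2]), index=m.columns, columns=["PC1", "PC2"]
    )
    return OrdinationResult(
        sample_coords=sample_coords,
        gene_coords=gene_coords,
        singular_values=s,
        reconstruction_error=rank2_err,
        degenerate=degenerate,
    )


@dataclasses.dataclass
class ClusteringResult:
    distance_matrix: pd.DataFrame  # symmetric cosine distances, zero diagonal
    linkage: np.ndarray            # scipy average-linkage tree


def cluster_heatmap(vst: pd.DataFrame) -> ClusteringResult:
    """Cosine distance between sample columns + average-linkage tree."""
    d = pdist(vst.to_numpy(dtype=float).T, metric="cosine")
    d = np.clip(d, 0.0, None)  # numerical negatives from identical columns
    dm = pd.DataFrame(
        squareform(d), index=vst.columns, columns=vst.columns
    )
    link = hierarchy.linkage(d, method="average")
    return ClusteringResult(distance_matrix=dm, linkage=link)
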