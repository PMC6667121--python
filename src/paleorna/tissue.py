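"""Tissue-of-origin scoring from per-transcript coverage depth ("Method 2").

The procedure: (1) derive a one-tissue-per-gene pairing from a multi-tissue
expression array by argmax; (2) keep transcripts whose mean coverage is at
or above the 95th percentile of all transcripts; (3) sum the coverage of
the retained genes into their paired tissues, giving a 10-component
cumulative tissue-score vector per sample; (4) compare a query sample's
vector against each control's by ordinary least squares and call the
control tissue with the highest r².

Coverage-depth scoring is deliberately length-normalised: two 25-nt reads
and one 50-nt read contribute the same evidence at a locus, which matters
when fragment lengths differ drastically between degraded and modern
libraries.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AssociationPairing:
    """gene -> most-associated tissue, with the array rows that produced it."""

    pairing: pd.Series            # index: gene, values: tissue label
    provenance: pd.DataFrame      # the array values used for the argmax
    unpaired: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.pairing)

    @property
    def tissues(self) -> list[str]:
        return list(self.provenance.columns)


def build_pairing(array_matrix: pd.DataFrame) -> AssociationPairing:
    """Argmax tissue per gene; ties broken lexicographically by tissue
    label (logged); all-zero rows are excluded as unpaired."""
    if array_matrix.shape[1] < 2:
        raise ValueError("array matrix needs at least 2 tissues")
    if (array_matrix.to_numpy() < 0).any():
        raise ValueError("array values must be nonnegative")
    cols_sorted = sorted(array_matrix.columns)
    m = array_matrix[cols_sorted]
    zero_rows = m.sum(axis=1) == 0
    unpaired = tuple(m.index[zero_rows])
    if unpaired:
        logger.info("%d all-zero genes left unpaired", len(unpaired))
    m = m.loc[~zero_rows]
    # idxmax on lexicographically sorted columns implements the tie rule
    n_ties = int((m.eq(m.max(axis=1), axis=0).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("%d genes had tied maxima; lexicographic tie-break", n_ties)
    pairing = m.idxmax(axis=1)
    return AssociationPairing(
        pairing=pairing,
        provenance=array_matrix.loc[~zero_rows],
        unpaired=unpaired,
    )


def p95_filter(
    coverage: pd.DataFrame,
    q: float = 0.95,
    include_zeros: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Retain transcripts at or above the ``q`` quantile of mean coverage.

    The quantile uses linear interpolation over all transcripts (zeros
    included by default — the coverage table spans the whole transcript
    set); retention is inclusive (>=).  Returns (subset, threshold).
    """
    if len(coverage) == 0:
        raise ValueError("empty coverage table")
    values = coverage["mean_coverage"]
    if not include_zeros:
        values = values[values > 0]
        if len(values) == 0:
            raise ValueError("no transcripts with nonzero coverage")
    n_nonzero = int((coverage["mean_coverage"] > 0).sum())
    if n_nonzero < 20:
        logger.warning(
            "only %d transcripts with nonzero coverage; the 95th-percentile "
            "filter may be unstable", n_nonzero,
        )
    threshold = float(np.quantile(values.to_numpy(), q))
    subset = coverage[coverage["mean_coverage"] >= threshold]
    return subset, threshold


@dataclasses.dataclass
class TissueScoreVector:
    """Cumulative per-tissue coverage scores for one sample."""

    sample_id: str
    scores: pd.Series             # index: tissue labels
    n_genes: pd.Series            # contributing genes per tissue
    p95_threshold: float

    def top_tissue(self) -> str:
        return str(self.scores.idxmax())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "n_genes": self.n_genes}
        ).rename_axis("tissue")


def tissue_scores(
    coverage: pd.DataFrame,
    pairing: AssociationPairing,
    sample_id: str = "sample",
    q: float = 0.95,
    include_zeros: bool = True,
) -> TissueScoreVector:
    """Score the tissues: S_t = sum of mean coverage over 95th-percentile
    transcripts paired to tissue t.  Unpaired genes are excluded (logged)."""
    subset, threshold = p95_filter(coverage, q=q, include_zeros=include_zeros)
    tissues = pairing.tissues
    scores = pd.Series(0.0, index=tissues)
    n_genes = pd.Series(0, index=tissues)
    n_unmatched = 0
    pair = {g.lower(): t for g, t in pairing.pairing.items()}
    for row in subset.itertuples(index=False):
        t = pair.get(str(row.transcript_id).lower())
        if t is None:
            n_unmatched += 1
            continue
        scores[t] += row.mean_coverage
        n_genes[t] += 1
    if n_unmatched:
        logger.info(
            "%d high-coverage transcripts had no tissue pairing and were "
            "excluded", n_unmatched,
        )
    if n_genes.sum() == 0:
        logger.warning("no paired transcripts passed the percentile filter; "
                       "score vector is all zero")
    return TissueScoreVector(sample_id, scores, n_genes, threshold)


def score_regression(
    a: TissueScoreVector | pd.Series, b: TissueScoreVector | pd.Series
) -> tuple[float, float, float]:
    """OLS of b on a over the per-tissue scores: (slope, intercept, r²).

    Returns NaNs when the explanatory vector has zero variance.
    """
    xa = a.scores if isinstance(a, TissueScoreVector) else a
    xb = b.scores if isinstance(b, TissueScoreVector) else b
    if not xa.index.equals(xb.index):
        xb = xb.reindex(xa.index)
        if xb.isna().any():
            raise ValueError("score vectors cover different tissues")
    x = xa.to_numpy(dtype=float)
    y = xb.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclasses.dataclass
class TissueCall:
    """Ranked control comparison for one query sample."""

    sample_id: str
    table: pd.DataFrame           # control, slope, intercept, r2 (ranked)
    top_call: str
    confident: bool
    r2_floor: float


class TissueAssigner(BaseEstimator):
    """Assign a query sample to the control tissue with the best score-vector
    regression.

    Parameters
    ----------
    r2_floor:
        Minimum r² for the top call to be flagged confident (default 0.5).

    Attributes (after :meth:`fit`)
    ------------------------------
    controls_:
        dict of control label -> TissueScoreVector.
    """

    def __init__(self, r2_floor: float = 0.5):
        self.r2_floor = r2_floor

    def fit(self, controls: Mapping[str, TissueScoreVector] | Sequence[TissueScoreVector]):
        if not isinstance(controls, Mapping):
            controls = {c.sample_id: c for c in controls}
        if len(controls) < 2:
            raise ValueError("need at least 2 control score vectors")
        self.controls_ = dict(controls)
        return self

    def predict(self, query: TissueScoreVector) -> TissueCall:
        """Regress the query against each control and rank by r²; ties are
        broken by higher slope, then control label order."""
        if not hasattr(self, "controls_"):
            raise RuntimeError("TissueAssigner is not fitted")
        rows = []
        for label, ctrl in self.controls_.items():
            slope, intercept, r2 = score_regression(ctrl, query)
            rows.append((label, slope, intercept, r2))
        table = pd.DataFrame(
            rows, columns=["control", "slope", "intercept", "r2"]
        )
        table = table.sort_values(
            by=["r2", "slope", "control"],
            ascending=[False, False, True],
            na_position="last",
        ).reset_index(drop=True)
        top = str(table.loc[0, "control"])
        top_r2 = float(table.loc[0, "r2"])
        return TissueCall(
            sample_id=query.sample_id,
            table=table,
            top_call=top,
            confident=bool(np.isfinite(top_r2) and top_r2 >= self.r2_floor),
            r2_floor=self.r2_floor,
        )


def assign_tissue(
    query: TissueScoreVector,
    controls: Mapping[str, TissueScoreVector] | Sequence[TissueScoreVector],
    r2_floor: float = 0.5,
) -> TissueCall:
    """Functional wrapper over :class:`TissueAssigner`."""
    return TissueAssigner(r2_floor=r2_floor).fit(controls).predict(query)
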