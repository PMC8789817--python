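"""Representational dissimilarity matrices and their comparison.

An RDM is a condition x condition matrix of correlation distances
(1 - Pearson) between response patterns; two RDMs are compared by the
Pearson correlation of their strictly-lower-triangular entries. Correlations
are averaged on the Fisher-z scale (atanh, mean, tanh), with |r| clipped at
1 - 1e-7 so that noise-free fixtures which legitimately reach r = 1 stay
finite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import LayerActivations
from .errors import AlignmentError, InputError, NumericError
from .splits import SplitScheme
from .stats import adjusted_ci, fisher_z


@dataclass
class RDM:
    matrix: np.ndarray  # (n_conditions, n_conditions)
    condition_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise InputError("RDM matrix must be square")
        if len(self.condition_ids) != n:
            raise InputError("condition_ids length must match matrix size")

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CorrelationResult:
    """Fisher-z averaged correlation over splits with an adjusted 95% CI."""

    mean_r: float
    per_split_r: np.ndarray
    ci_low: float
    ci_high: float
    n_splits: int


def compute_rdm(responses, condition_ids: list[str] | None = None) -> RDM:
    """Correlation-distance RDM from a conditions x features matrix."""
    if isinstance(responses, LayerActivations):
        responses = responses.matrix
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2:
        raise InputError("responses must be 2-D (conditions x features)")
    n, d = x.shape
    if n < 3:
        raise InputError("need at least 3 conditions for an RDM")
    if d < 2:
        raise InputError("need at least 2 features for an RDM")
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        ids = condition_ids or [str(i) for i in range(n)]
        raise NumericError(
            f"constant response row(s) make correlation undefined: "
            f"{[ids[i] for i in bad]}"
        )
    dist = 1.0 - np.corrcoef(x)
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    if condition_ids is None:
        condition_ids = [str(i) for i in range(n)]
    return RDM(matrix=dist, condition_ids=list(condition_ids))


def lower_tri(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strictly-below-diagonal entries in row-major (i > j) order."""
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def rdm_correlation(a: RDM, b: RDM) -> float:
    """Pearson r between the lower triangles of two RDMs."""
    if a.condition_ids != b.condition_ids:
        raise AlignmentError("RDM condition_ids differ (order matters)")
    va, vb = lower_tri(a), lower_tri(b)
    if va.std() == 0 or vb.std() == 0:
        raise NumericError("RDM lower triangle is constant; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def fisher_mean(rs) -> float:
    """tanh(mean(atanh(r))) with |r| clipped at 1 - 1e-7."""
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise InputError("fisher_mean of an empty list")
    if np.any(np.abs(rs) > 1 + 1e-12):
        raise InputError("correlations must lie in [-1, 1]")
    return float(np.tanh(fisher_z(rs).mean()))


def mean_rdm(rdms: list[RDM]) -> RDM:
    """Arithmetic entrywise mean of aligned RDMs."""
    if not rdms:
        raise InputError("mean_rdm of an empty list")
    ids = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ids:
            raise AlignmentError("RDM condition_ids differ across subjects")
    return RDM(matrix=np.mean([r.matrix for r in rdms], axis=0), condition_ids=list(ids))


def summarize_correlations(
    rs, correction_ratio: float, level: float = 0.95
) -> CorrelationResult:
    """Fisher-z mean plus non-independence-adjusted confidence interval.

    With a single split the mean is reported with undefined (NaN) bounds.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size < 2:
        lo = hi = float("nan")
    else:
        lo, hi = adjusted_ci(rs, correction_ratio, level=level)
    return CorrelationResult(
        mean_r=fisher_mean(rs),
        per_split_r=rs,
        ci_low=lo,
        ci_high=hi,
        n_splits=rs.size,
    )


def split_half_brain_correlations(
    subject_rdms: list[RDM], scheme: SplitScheme, model_rdm: RDM
) -> np.ndarray:
    """Per split and half: corr(model RDM, that half's group-mean brain RDM).

    Returns an array of shape (n_splits, 2).
    """
    out = np.empty((scheme.n_splits, 2))
    for j, (half_a, half_b) in enumerate(scheme.splits):
        for h, half in enumerate((half_a, half_b)):
            group = mean_rdm([subject_rdms[s] for s in half])
            out[j, h] = rdm_correlation(model_rdm, group)
    return out


def classic_rsa_curve(
    layer_activations: list[LayerActivations],
    subject_rdms: list[RDM],
    scheme: SplitScheme,
    correction_ratio: float | None = None,
) -> dict[str, CorrelationResult]:
    """Layerwise RSA with RDMs computed directly from raw activations.

    No encoding model and no feature weighting: for each layer the
    activation RDM is correlated with group-mean brain RDMs under the same
    split-half scheme used by the encoding-model analysis.
    """
    from .stats import split_correction_ratio  # local to avoid cycle at import

    if correction_ratio is None:
        correction_ratio = split_correction_ratio(scheme.n_subjects)
    ids = subject_rdms[0].condition_ids
    results: dict[str, CorrelationResult] = {}
    for acts in layer_activations:
        model_rdm = compute_rdm(acts.matrix, condition_ids=ids)
        rs = split_half_brain_correlations(subject_rdms, scheme, model_rdm)
        results[acts.layer_name] = summarize_correlations(rs.ravel(), correction_ratio)
    return results


def save_rdm(path, rdm: RDM) -> None:
    """Delimited text with a condition-id header row and index column."""
    import pandas as pd

    pd.DataFrame(rdm.matrix, index=rdm.condition_ids, columns=rdm.condition_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def load_rdm(path) -> RDM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return RDM(matrix=df.to_numpy(dtype=float), condition_ids=[str(c) for c in df.columns])
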