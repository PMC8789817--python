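"""Voxel-wise-encoding RSA (veRSA), noise ceilings, cross-validated max layer.

The pipeline: each voxel's response profile over image conditions is fit as a
ridge-regularized weighted combination of a model layer's units, in a
leave-one-condition-out loop (the held-out condition is predicted from a fit
that never saw it). Assembling held-out predictions over all conditions gives
a cross-validated predicted response matrix R-hat per subject; its
correlation-distance RDM (the predicted geometry G-hat) is compared to the
measured brain geometry G over subject split-halves: the subjects' predicted
RDMs in each half are averaged and correlated with the same half's group-mean
brain RDM. Correlations are Fisher-z averaged with a non-independence
adjusted confidence interval.

The noise ceiling is the analogous split-half correlation between the two
halves' group-mean brain RDMs, and the cross-validated max layer picks the
best layer on one half and scores it on the other, so layer selection never
sees the evaluation data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import LayerActivations
from .errors import AlignmentError, ConfigurationError, InputError
from .rsa import (
    RDM,
    CorrelationResult,
    compute_rdm,
    mean_rdm,
    rdm_correlation,
    summarize_correlations,
)
from .splits import SplitScheme, enumerate_split_halves  # noqa: F401 (re-export)
from .stats import split_correction_ratio

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 5, 9))


@dataclass
class SubjectVoxelData:
    subject_id: str
    responses: np.ndarray  # (n_conditions, n_voxels)
    condition_ids: list[str]

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise InputError("responses must be 2-D (conditions x voxels)")
        if self.responses.shape[0] < 3:
            raise InputError("need at least 3 conditions")
        if len(self.condition_ids) != self.responses.shape[0]:
            raise AlignmentError("condition_ids length must match responses rows")

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]


@dataclass
class EncodingFit:
    """Leave-one-condition-out ridge fit for one subject and one layer."""

    predicted: np.ndarray  # R-hat, (n_conditions, n_voxels)
    lambdas: np.ndarray  # (n_conditions, n_voxels) selected per fold and voxel
    condition_ids: list[str]
    weights: dict[int, np.ndarray] | None = None  # fold -> (units, voxels)


def _standardize_train(x_train: np.ndarray, x_test_row: np.ndarray):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x_train - mu) / sd, (x_test_row - mu) / sd


def fit_voxel_encoding_loo(
    features: LayerActivations | np.ndarray,
    subject: SubjectVoxelData,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    keep_weights: bool = False,
) -> EncodingFit:
    """Cross-validated voxel-wise ridge encoding.

    For each held-out condition c, the remaining conditions are used to fit
    ridge weights per voxel; the regularization strength is selected per
    voxel by efficient leave-one-out error within the training conditions
    over ``lambda_grid``. Features are standardized (zero mean, unit
    variance per unit) with statistics frozen from each training fold; ridge
    is solved in the sample (dual) space so very wide layers are cheap.
    """
    x = features.matrix if isinstance(features, LayerActivations) else np.asarray(features)
    x = np.asarray(x, dtype=float)
    grid = np.asarray(sorted(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("lambda_grid must be nonempty")
    if np.any(grid <= 0):
        raise ConfigurationError("ridge requires strictly positive lambda values")
    n_cond, n_units = x.shape
    if n_cond != subject.n_conditions:
        raise AlignmentError("features and responses disagree on condition count")
    if n_cond < 3:
        raise InputError("need at least 3 conditions for leave-one-out encoding")
    y_all = subject.responses
    n_vox = y_all.shape[1]

    predicted = np.empty((n_cond, n_vox))
    lambdas = np.empty((n_cond, n_vox))
    weights: dict[int, np.ndarray] | None = {} if keep_weights else None

    for c in range(n_cond):
        train = np.delete(np.arange(n_cond), c)
        xs, xt = _standardize_train(x[train], x[c])
        y_mean = y_all[train].mean(axis=0)
        yc = y_all[train] - y_mean
        m = train.size

        k = xs @ xs.T  # (m, m) Gram matrix
        evals, u = np.linalg.eigh(k)
        evals = np.maximum(evals, 0.0)
        uty = u.T @ yc  # (m, n_vox)

        # per-voxel lambda by leave-one-out error within the training fold
        if grid.size == 1:
            sel = np.zeros(n_vox, dtype=int)
        else:
            best_err = np.full(n_vox, np.inf)
            sel = np.zeros(n_vox, dtype=int)
            for gi, lam in enumerate(grid):
                shrink = evals / (evals + lam)  # (m,)
                resid = yc - u @ (shrink[:, None] * uty)
                h_diag = (u * u * shrink).sum(axis=1)  # diag of hat matrix
                denom = np.clip(1.0 - h_diag, 1e-10, None)
                loo = resid / denom[:, None]
                err = (loo * loo).mean(axis=0)
                better = err < best_err
                best_err[better] = err[better]
                sel[better] = gi

        kt = xt @ xs.T  # (m,)
        utk = u.T @ kt  # (m,)
        fold_w = np.empty((n_units, n_vox)) if keep_weights else None
        for gi in np.unique(sel):
            cols = np.where(sel == gi)[0]
            inv = 1.0 / (evals + grid[gi])
            alpha = u @ (inv[:, None] * uty[:, cols])  # (m, |cols|)
            predicted[c, cols] = (utk * inv) @ uty[:, cols] + y_mean[cols]
            lambdas[c, cols] = grid[gi]
            if keep_weights:
                fold_w[:, cols] = xs.T @ alpha
        if keep_weights:
            weights[c] = fold_w

    return EncodingFit(
        predicted=predicted,
        lambdas=lambdas,
        condition_ids=list(subject.condition_ids),
        weights=weights,
    )


def model_predicted_rdm(fit: EncodingFit) -> RDM:
    """Predicted representational geometry G-hat: RDM of R-hat."""
    return compute_rdm(fit.predicted, condition_ids=fit.condition_ids)


def predicted_rdms_per_subject(
    features: LayerActivations | np.ndarray,
    subjects: list[SubjectVoxelData],
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> list[RDM]:
    return [
        model_predicted_rdm(fit_voxel_encoding_loo(features, s, lambda_grid))
        for s in subjects
    ]


def brain_rdms(subjects: list[SubjectVoxelData]) -> list[RDM]:
    return [
        compute_rdm(s.responses, condition_ids=s.condition_ids) for s in subjects
    ]


@dataclass
class VersaResult:
    layer_names: list[str]
    curve: dict[str, CorrelationResult]
    # r[L, j, h]: layer L, split j, half h (the two orientations of a split)
    split_correlations: np.ndarray
    scheme: SplitScheme


def _split_half_r(
    pred_rdms: list[RDM], subj_rdms: list[RDM], scheme: SplitScheme
) -> np.ndarray:
    """(n_splits, 2) correlations: group-mean predicted vs same-group brain RDM."""
    out = np.empty((scheme.n_splits, 2))
    for j, (half_a, half_b) in enumerate(scheme.splits):
        for h, half in enumerate((half_a, half_b)):
            g_hat = mean_rdm([pred_rdms[s] for s in half])
            g = mean_rdm([subj_rdms[s] for s in half])
            out[j, h] = rdm_correlation(g_hat, g)
    return out


def versa_curve(
    layer_activations: list[LayerActivations],
    subjects: list[SubjectVoxelData],
    scheme: SplitScheme | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    max_splits: int = 126,
    seed: int = 0,
) -> VersaResult:
    """Layerwise veRSA over subject split-halves.

    Per layer and subject, a cross-validated encoding fit yields a predicted
    RDM; per split, each half's predicted RDMs are averaged and correlated
    with that half's group-mean brain RDM (both orientations of every split
    contribute an r value). Summaries are Fisher-z means with adjusted CIs.
    """
    if scheme is None:
        scheme = enumerate_split_halves(len(subjects), max_splits=max_splits, seed=seed)
    if scheme.n_subjects != len(subjects):
        raise AlignmentError("split scheme subject count does not match data")
    ratio = split_correction_ratio(len(subjects))
    subj_rdms = brain_rdms(subjects)
    layer_names = [a.layer_name for a in layer_activations]
    r = np.empty((len(layer_activations), scheme.n_splits, 2))
    curve: dict[str, CorrelationResult] = {}
    for li, acts in enumerate(layer_activations):
        pred = predicted_rdms_per_subject(acts, subjects, lambda_grid)
        r[li] = _split_half_r(pred, subj_rdms, scheme)
        curve[acts.layer_name] = summarize_correlations(r[li].ravel(), ratio)
    return VersaResult(layer_names=layer_names, curve=curve,
                       split_correlations=r, scheme=scheme)


def noise_ceiling(
    subjects: list[SubjectVoxelData], scheme: SplitScheme | None = None,
    max_splits: int = 126, seed: int = 0,
) -> CorrelationResult:
    """Split-half reliability of the group representational geometry.

    Per split, the two halves' group-mean brain RDMs are correlated; the
    ceiling is the Fisher-z mean over splits (negative values are reported
    as-is, never clipped).
    """
    if len(subjects) < 2:
        raise InputError("noise ceiling requires at least 2 subjects")
    if scheme is None:
        scheme = enumerate_split_halves(len(subjects), max_splits=max_splits, seed=seed)
    subj_rdms = brain_rdms(subjects)
    rs = np.empty(scheme.n_splits)
    for j, (half_a, half_b) in enumerate(scheme.splits):
        ga = mean_rdm([subj_rdms[s] for s in half_a])
        gb = mean_rdm([subj_rdms[s] for s in half_b])
        rs[j] = rdm_correlation(ga, gb)
    return summarize_correlations(rs, split_correction_ratio(len(subjects)))


@dataclass
class CvMaxResult:
    result: CorrelationResult
    # selected[j, h]: layer index chosen on half h of split j (evaluated on
    # the other half)
    selected: np.ndarray
    layer_names: list[str]

    def selection_fraction(self, layer_name: str) -> float:
        li = self.layer_names.index(layer_name)
        return float((self.selected == li).mean())


def cv_max_layer(
    per_layer_per_split_r: np.ndarray,
    scheme: SplitScheme,
    layer_names: list[str],
    correction_ratio: float | None = None,
) -> CvMaxResult:
    """Cross-validated maximum layer correlation (cv max-r).

    ``per_layer_per_split_r`` has shape (layers, splits, 2): the two halves
    of each split come from disjoint subject groups. For each split and each
    orientation, the layer with the highest correlation on the selection
    half is chosen (ties break toward the earlier layer) and the other
    half's correlation for that layer is recorded.
    """
    r = np.asarray(per_layer_per_split_r, dtype=float)
    if r.ndim != 3 or r.shape[2] != 2:
        raise InputError("expected array of shape (layers, splits, 2)")
    if r.shape[0] != len(layer_names):
        raise AlignmentError("layer_names length does not match correlation matrix")
    if r.shape[1] != scheme.n_splits:
        raise AlignmentError("split count does not match scheme")
    if correction_ratio is None:
        correction_ratio = split_correction_ratio(scheme.n_subjects)
    n_splits = r.shape[1]
    evals = np.empty(2 * n_splits)
    selected = np.empty((n_splits, 2), dtype=int)
    for j in range(n_splits):
        for h in (0, 1):
            sel = int(np.argmax(r[:, j, h]))  # argmax ties -> earliest layer
            selected[j, h] = sel
            evals[2 * j + h] = r[sel, j, 1 - h]
    return CvMaxResult(
        result=summarize_correlations(evals, correction_ratio),
        selected=selected,
        layer_names=list(layer_names),
    )


def explained_proportion(
    model_result: CorrelationResult,
    ceiling: CorrelationResult,
    squared: bool = False,
) -> float:
    """Model correlation as a percentage of the noise ceiling."""
    if ceiling.mean_r <= 0:
        raise InputError("nonpositive noise ceiling: explained proportion undefined")
    ratio = model_result.mean_r / ceiling.mean_r
    if squared:
        ratio = ratio**2
    return 100.0 * ratio


def subsample_units(
    activations: LayerActivations, max_units: int, seed: int = 0
) -> LayerActivations:
    """Seeded unit subsample for very wide layers (off by default upstream)."""
    if activations.unit_count <= max_units:
        return activations
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(activations.unit_count, size=max_units, replace=False))
    return LayerActivations(activations.layer_name, activations.matrix[:, cols])


def save_subject(path, subject: SubjectVoxelData) -> None:
    """Conditions x voxels as TSV: condition-id index, voxel-id header."""
    import pandas as pd

    pd.DataFrame(
        subject.responses,
        index=subject.condition_ids,
        columns=[f"voxel_{i}" for i in range(subject.n_voxels)],
    ).to_csv(path, sep="\t", float_format="%.12g", index_label="condition")


def load_subject(path, subject_id: str | None = None) -> SubjectVoxelData:
    import pandas as pd
    from pathlib import Path

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SubjectVoxelData(
        subject_id=subject_id or Path(path).stem,
        responses=df.to_numpy(dtype=float),
        condition_ids=[str(c) for c in df.index],
    )
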