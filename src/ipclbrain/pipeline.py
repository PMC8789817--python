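"""End-to-end demo: generate -> train -> extract -> synthesize -> analyze.

One seeded config drives the whole chain: a procedural shape world is
generated, a small encoder is trained with the instance-prototype objective
(an untrained copy of the same architecture serves as the control), layerwise
activations are extracted for a set of condition images, synthetic subjects
are generated from a designated layer, and the analysis stack (noise ceiling,
veRSA, classic RSA, cross-validated max layer, corrected model comparison,
kNN readout) is run and written out as CSV/JSON reports.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import resize_normalize
from .backbone import build_backbone, extract_activations
from .config import RunConfig, config_hash, config_to_dict
from .errors import IPCLBrainError
from .fixtures import (
    SyntheticSubjectSpec,
    generate_shape_world,
    generate_synthetic_subjects,
)
from .ipcl import train_ipcl
from .readout import MemoryBank, knn_accuracy
from .rsa import classic_rsa_curve
from .splits import enumerate_split_halves
from .stats import bonferroni_threshold, corrected_paired_ttest, split_correction_ratio
from .versa import (
    brain_rdms,
    cv_max_layer,
    explained_proportion,
    noise_ceiling,
    subsample_units,
    versa_curve,
)


@dataclass
class ReportBundle:
    out_dir: Path
    knn: dict
    ceiling_mean_r: float
    versa_trained: dict  # layer -> mean_r
    versa_untrained: dict
    classic_trained: dict
    cv_max_trained: float
    cv_max_untrained: float
    explained_pct: float
    comparison: dict
    paths: dict


def _stage(name):
    """Decorator-free stage guard: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(IPCLBrainError):
    pass


def _curve_frame(analysis: str, curve: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": analysis,
                "layer": layer,
                "mean_r": res.mean_r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_splits": res.n_splits,
            }
            for layer, res in curve.items()
        ]
    )


def run_demo_pipeline(config: RunConfig, out_dir) -> ReportBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "config": config_to_dict(config),
        "stages_completed": [],
    }

    def checkpoint(stage: str):
        manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        with _stage("fixtures"):
            fixtures_spec = replace(config.fixtures, seed=config.seed)
            dataset = generate_shape_world(fixtures_spec)
        checkpoint("fixtures")

        with _stage("train"):
            ipcl_cfg = replace(config.ipcl, seed=config.seed)
            trained, history = train_ipcl(dataset, config.backbone, ipcl_cfg,
                                          config.augment)
            untrained = build_backbone(config.backbone, seed=config.seed)
            history.to_csv(out / "training_history.csv")
            trained.save(out / "checkpoint.npz")
        checkpoint("train")

        with _stage("readout"):
            eval_images = resize_normalize(dataset.images, config.augment)
            emb_trained = extract_activations(trained, eval_images, ["embedding"])[0]
            emb_untrained = extract_activations(untrained, eval_images, ["embedding"])[0]
            knn = {}
            for name, emb in (("trained", emb_trained), ("untrained", emb_untrained)):
                bank = MemoryBank.from_features(emb, dataset.class_labels)
                knn[name] = knn_accuracy(
                    bank.embeddings, dataset.class_labels, bank,
                    config.readout, exclude_self=True,
                )
            knn["chance"] = 100.0 / config.fixtures.n_classes
            pd.DataFrame([knn]).to_csv(out / "knn_accuracy.csv", index=False,
                                       float_format="%.6g")
        checkpoint("readout")

        with _stage("extract"):
            layer_names = trained.layer_names
            # stratified condition images: round-robin over classes
            per_class = int(np.ceil(config.versa.n_conditions / config.fixtures.n_classes))
            cond_idx = []
            for c in range(config.fixtures.n_classes):
                cls_items = np.where(dataset.class_labels == c)[0][:per_class]
                cond_idx.extend(cls_items.tolist())
            cond_idx = np.asarray(sorted(cond_idx[: config.versa.n_conditions]))
            cond_images = eval_images[cond_idx]
            acts_trained = extract_activations(trained, cond_images, layer_names)
            acts_untrained = extract_activations(untrained, cond_images, layer_names)
            if config.versa.max_units:
                acts_trained = [subsample_units(a, config.versa.max_units, config.seed)
                                for a in acts_trained]
                acts_untrained = [subsample_units(a, config.versa.max_units, config.seed)
                                  for a in acts_untrained]
        checkpoint("extract")

        with _stage("simulate_subjects"):
            planted = next(a for a in acts_trained
                           if a.layer_name == config.versa.planted_layer)
            subj_spec = SyntheticSubjectSpec(
                generating_features=planted,
                n_subjects=config.versa.n_subjects,
                n_voxels_per_subject=config.versa.n_voxels_per_subject,
                noise_sd=config.versa.noise_sd,
                seed=config.seed + 1,
            )
            subjects = generate_synthetic_subjects(subj_spec).subjects
            scheme = enumerate_split_halves(len(subjects),
                                            max_splits=config.versa.max_splits,
                                            seed=config.seed)
        checkpoint("simulate_subjects")

        with _stage("analysis"):
            ceiling = noise_ceiling(subjects, scheme)
            v_tr = versa_curve(acts_trained, subjects, scheme, config.versa.lambda_grid)
            v_un = versa_curve(acts_untrained, subjects, scheme, config.versa.lambda_grid)
            classic = classic_rsa_curve(acts_trained, brain_rdms(subjects), scheme)
            cv_tr = cv_max_layer(v_tr.split_correlations, scheme, v_tr.layer_names)
            cv_un = cv_max_layer(v_un.split_correlations, scheme, v_un.layer_names)
            best_layer = max(v_tr.curve, key=lambda k: v_tr.curve[k].mean_r)
            expl = explained_proportion(v_tr.curve[best_layer], ceiling)
            test = corrected_paired_ttest(
                cv_tr.result.per_split_r,
                cv_un.result.per_split_r,
                split_correction_ratio(len(subjects)),
                fisher_transform=True,
            )
            threshold = bonferroni_threshold(config.stats.alpha,
                                             config.stats.n_family_tests)
            comparison = {
                "t": test.t_statistic,
                "p": test.p_value,
                "n_splits": test.n_splits,
                "bonferroni_threshold": threshold,
                "significant": bool(test.p_value < threshold),
            }
        checkpoint("analysis")

        with _stage("report"):
            frames = [
                _curve_frame("versa_trained", v_tr.curve),
                _curve_frame("versa_untrained", v_un.curve),
                _curve_frame("classic_rsa_trained", classic),
            ]
            pd.concat(frames, ignore_index=True).to_csv(
                out / "layer_correlations.csv", index=False, float_format="%.8g")
            pd.DataFrame([{
                "mean_r": ceiling.mean_r, "ci_low": ceiling.ci_low,
                "ci_high": ceiling.ci_high, "n_splits": ceiling.n_splits,
            }]).to_csv(out / "noise_ceiling.csv", index=False, float_format="%.8g")
            cv_rows = []
            for name, cv in (("trained", cv_tr), ("untrained", cv_un)):
                counts = {
                    layer: cv.selection_fraction(layer) for layer in cv.layer_names
                }
                top = max(counts, key=counts.get)
                cv_rows.append({
                    "model": name, "cv_max_r": cv.result.mean_r,
                    "ci_low": cv.result.ci_low, "ci_high": cv.result.ci_high,
                    "modal_layer": top, "modal_fraction": counts[top],
                })
            pd.DataFrame(cv_rows).to_csv(out / "cv_max_layer.csv", index=False,
                                         float_format="%.8g")
            summary = {
                "knn": knn,
                "noise_ceiling_r": ceiling.mean_r,
                "best_layer": best_layer,
                "planted_layer": config.versa.planted_layer,
                "explained_pct": expl,
                "cv_max_trained_r": cv_tr.result.mean_r,
                "cv_max_untrained_r": cv_un.result.mean_r,
                "comparison": comparison,
            }
            (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                         sort_keys=True))
        checkpoint("report")
    except _StageError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise

    return ReportBundle(
        out_dir=out,
        knn=knn,
        ceiling_mean_r=ceiling.mean_r,
        versa_trained={k: v.mean_r for k, v in v_tr.curve.items()},
        versa_untrained={k: v.mean_r for k, v in v_un.curve.items()},
        classic_trained={k: v.mean_r for k, v in classic.items()},
        cv_max_trained=cv_tr.result.mean_r,
        cv_max_untrained=cv_un.result.mean_r,
        explained_pct=expl,
        comparison=comparison,
        paths={
            "layer_correlations": out / "layer_correlations.csv",
            "noise_ceiling": out / "noise_ceiling.csv",
            "cv_max_layer": out / "cv_max_layer.csv",
            "summary": out / "summary.json",
            "manifest": out / "manifest.json",
            "training_history": out / "training_history.csv",
            "knn_accuracy": out / "knn_accuracy.csv",
            "checkpoint": out / "checkpoint.npz",
        },
    )
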