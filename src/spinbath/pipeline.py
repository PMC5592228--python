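"""Stage-wise pipeline driver: simulate -> fit -> extract -> cluster -> report.

Each stage reads only on-disk artifacts of earlier stages, writes its own
outputs plus a manifest (config hash, seeds, inputs, outputs, package
version), and logs progress.  Re-running with an identical configuration
reproduces byte-identical CSV/JSON outputs; wall-clock details go to the
log only, never into compared artifacts.
"""

from __future__ import annotations

import json
import logging
import zlib
from importlib.metadata import version as _pkg_version
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clinical import group_summary
from .cluster import GustafsonKessel, cluster_db_report, factor_loading_table, pca_2d
from .config import PipelineConfig
from .features import (
    FEATURE_NAMES,
    FeatureMatrix,
    assemble_feature_matrix,
    extract_roi_vector,
    standardize_features,
)
from .fitting import ParameterMaps, compute_mtr_map, fit_volume
from .simulate import generate_cohort, sample_tissue_parameters, simulate_subject_stack
from .stack_io import read_stack, write_stack

logger = logging.getLogger("spinbath")

STAGES = ("simulate", "fit", "mtr", "extract", "cluster", "report")


class PipelineError(RuntimeError):
    """Raised when a stage cannot run (missing/corrupt upstream artifacts)."""


def _package_version() -> str:
    try:
        return _pkg_version("spinbath")
    except Exception:  # pragma: no cover
        return "unknown"


def _write_manifest(out: Path, stage: str, config: PipelineConfig,
                    inputs: list[str], outputs: list[str]) -> None:
    man_dir = out / "manifests"
    man_dir.mkdir(parents=True, exist_ok=True)

    def rel(paths: list[str]) -> list[str]:
        # artifact-dir-relative, so identical runs compare byte-identical
        return sorted(str(Path(p).relative_to(out)) for p in paths)

    payload = {
        "stage": stage,
        "config_sha256": config.sha256(),
        "seeds": {"effect": config.effect.seed, "cluster": config.cluster.seed},
        "inputs": rel(inputs),
        "outputs": rel(outputs),
        "package_version": _package_version(),
    }
    (man_dir / f"{stage}.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(f"missing upstream artifact {path}; run the earlier stage first")
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise PipelineError(f"corrupt artifact {path}: {exc}") from exc


def _subject_stack_seed(effect_seed: int, subject_id: str) -> int:
    return int((zlib.crc32(subject_id.encode()) ^ (effect_seed * 2654435761)) & 0x7FFFFFFF)


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    acq = config.acquisition.build()
    cohort = generate_cohort(config.n_per_group, config.effect)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    config.to_json(out / "config.json")

    truth_rows = []
    outputs = [str(cohort_path)]
    for row in cohort.to_dict("records"):
        sid = row["subject_id"]
        pl, pr = sample_tissue_parameters(row, config.effect)
        stack = simulate_subject_stack(
            pl, pr, acq,
            grid_shape=config.grid_shape,
            snr=config.effect.snr,
            seed=_subject_stack_seed(config.effect.seed, sid),
        )
        sdir = write_stack(stack, acq, out / "stacks" / sid)
        outputs.append(str(sdir))
        for hemi, p in (("left", pl), ("right", pr)):
            truth_rows.append(
                {"subject_id": sid, "hemisphere": hemi, "f": p.f, "kf": p.kf,
                 "kr": p.kr, "t2r": p.t2r, "t2f": p.t2f, "t1f": p.t1f, "sdf": p.sdf}
            )
        logger.info("simulate: wrote stack for %s", sid)
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    _write_manifest(out, "simulate", config, inputs=[], outputs=outputs + [str(truth_path)])


def _iter_subject_stacks(out: Path, cohort: pd.DataFrame):
    for sid in cohort["subject_id"]:
        sdir = out / "stacks" / sid
        if not sdir.exists():
            raise PipelineError(f"missing stack directory {sdir}; run the simulate stage first")
        try:
            stack, acq = read_stack(sdir)
        except Exception as exc:
            raise PipelineError(f"corrupt stack under {sdir}: {exc}") from exc
        yield sid, stack, acq


def stage_fit(config: PipelineConfig, out: Path) -> None:
    cohort = _read_csv(out / "cohort.csv")
    options = config.fit.build()
    summaries = {}
    outputs = []
    for sid, stack, acq in _iter_subject_stacks(out, cohort):
        mask = stack.masks["nc_left"] | stack.masks["nc_right"]
        maps = fit_volume(stack, mask, acq, options)
        mdir = out / "maps" / sid
        maps.to_dir(mdir)
        outputs.append(str(mdir))
        summaries[sid] = {
            "converged_fraction": maps.converged_fraction,
            "median_residual": maps.median_residual,
            "n_voxels": int(mask.sum()),
        }
        logger.info(
            "fit: %s converged %.1f%% of %d voxels",
            sid, 100 * summaries[sid]["converged_fraction"], summaries[sid]["n_voxels"],
        )
    summary_path = out / "fit_summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2, sort_keys=True) + "\n")
    _write_manifest(out, "fit", config, inputs=[str(out / "cohort.csv")],
                    outputs=outputs + [str(summary_path)])


def stage_mtr(config: PipelineConfig, out: Path) -> None:
    import nibabel as nib

    cohort = _read_csv(out / "cohort.csv")
    outputs = []
    for sid, stack, acq in _iter_subject_stacks(out, cohort):
        mtr_map = compute_mtr_map(stack, acq)
        mdir = out / "maps" / sid
        mdir.mkdir(parents=True, exist_ok=True)
        path = mdir / "mtr_fullvolume.nii.gz"
        nib.save(nib.Nifti1Image(mtr_map, stack.affine), str(path))
        outputs.append(str(path))
        logger.info("mtr: wrote %s", path)
    _write_manifest(out, "mtr", config, inputs=[str(out / "cohort.csv")], outputs=outputs)


def stage_extract(config: PipelineConfig, out: Path) -> None:
    cohort = _read_csv(out / "cohort.csv")
    vectors = []
    for sid, stack, _acq in _iter_subject_stacks(out, cohort):
        mdir = out / "maps" / sid
        try:
            maps = ParameterMaps.from_dir(mdir)
        except Exception as exc:
            raise PipelineError(f"missing or corrupt maps under {mdir}: {exc}") from exc
        vectors.append(
            extract_roi_vector(
                maps, stack.masks["nc_left"], stack.masks["nc_right"],
                subject_id=sid, statistic=config.roi_statistic,
            )
        )
    fm = assemble_feature_matrix(vectors, cohort)
    fm.data.to_csv(out / "features.csv")
    outputs = [str(out / "features.csv")]
    if config.standardize:
        z = standardize_features(fm)
        z.data.to_csv(out / "features_standardized.csv")
        record = {
            "center": {k: float(v) for k, v in z.center.items()},
            "scale": {k: float(v) for k, v in z.scale.items()},
        }
        (out / "standardization.json").write_text(
            json.dumps(record, indent=2, sort_keys=True) + "\n"
        )
        outputs += [str(out / "features_standardized.csv"), str(out / "standardization.json")]
    _write_manifest(out, "extract", config, inputs=[str(out / "cohort.csv")], outputs=outputs)


def _load_feature_matrix(out: Path, config: PipelineConfig) -> FeatureMatrix:
    name = "features_standardized.csv" if config.standardize else "features.csv"
    df = _read_csv(out / name).set_index("subject_id")
    return FeatureMatrix(data=df[list(FEATURE_NAMES)])


def stage_cluster(config: PipelineConfig, out: Path) -> None:
    fm = _load_feature_matrix(out, config)
    cs = config.cluster
    model = GustafsonKessel(
        n_clusters=cs.n_clusters, fuzzifier=cs.fuzzifier, tol=cs.tol,
        max_iter=cs.max_iter, n_init=cs.n_init, random_state=cs.seed,
    ).fit(fm)
    logger.info("cluster: objective %.6g after %d iterations", model.objective_, model.n_iter_)

    memb = pd.DataFrame(
        model.memberships_, index=fm.data.index,
        columns=[f"cluster_{i}" for i in range(cs.n_clusters)],
    )
    memb.to_csv(out / "membership.csv")
    pd.DataFrame({"subject_id": fm.data.index, "cluster": model.labels_}).to_csv(
        out / "labels.csv", index=False
    )
    gk_payload = {
        "n_clusters": cs.n_clusters,
        "fuzzifier": cs.fuzzifier,
        "objective": model.objective_,
        "objective_trace": list(model.objective_trace_),
        "centers": model.cluster_centers_.tolist(),
        "covariances": model.covariances_.tolist(),
        "empty_clusters": model.empty_clusters_,
    }
    (out / "gk_model.json").write_text(json.dumps(gk_payload, indent=2, sort_keys=True) + "\n")

    pca = pca_2d(fm)
    pd.DataFrame(pca.scores, index=fm.data.index, columns=["pc1", "pc2"]).to_csv(
        out / "pca_scores.csv"
    )
    factor_loading_table(pca, list(FEATURE_NAMES)).to_csv(out / "pca_loadings.csv")
    pca_payload = {
        "explained_variance_ratio": list(pca.explained_variance_ratio),
        "full_spectrum": list(pca.full_spectrum),
    }
    (out / "pca.json").write_text(json.dumps(pca_payload, indent=2, sort_keys=True) + "\n")
    _write_manifest(
        out, "cluster", config,
        inputs=[str(out / ("features_standardized.csv" if config.standardize else "features.csv"))],
        outputs=[str(out / n) for n in
                 ("membership.csv", "labels.csv", "gk_model.json",
                  "pca_scores.csv", "pca_loadings.csv", "pca.json")],
    )


def _figures(out: Path, cohort: pd.DataFrame, labels: np.ndarray) -> list[str]:
    scores = _read_csv(out / "pca_scores.csv").set_index("subject_id")
    loadings = _read_csv(out / "pca_loadings.csv").set_index("feature")
    group_markers = {"control": "o", "premanifest": "s", "manifest": "^"}
    cmap = plt.get_cmap("tab10")

    fig, ax = plt.subplots(figsize=(6, 5))
    for i, row in cohort.reset_index(drop=True).iterrows():
        sc = scores.loc[row["subject_id"]]
        ax.scatter(sc["pc1"], sc["pc2"], c=[cmap(int(labels[i]) % 10)],
                   marker=group_markers[row["group"]], s=60, edgecolor="k", linewidth=0.5)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_title("Fuzzy clusters in the PCA plane (marker = group, color = cluster)")
    fig.tight_layout()
    scores_png = out / "figure_scores.png"
    fig.savefig(scores_png, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scores["pc1"], scores["pc2"], c="0.6", s=30)
    span = max(scores["pc1"].abs().max(), scores["pc2"].abs().max())
    for feat, row in loadings.iterrows():
        ax.plot([0, row["loading_pc1"] * span], [0, row["loading_pc2"] * span],
                ls=":", c="tab:red", lw=1)
        ax.annotate(feat, (row["loading_pc1"] * span, row["loading_pc2"] * span), fontsize=7)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_title("Factor loadings over subject scores")
    fig.tight_layout()
    biplot_png = out / "figure_biplot.png"
    fig.savefig(biplot_png, dpi=120)
    plt.close(fig)
    return [str(scores_png), str(biplot_png)]


def stage_report(config: PipelineConfig, out: Path) -> None:
    cohort = _read_csv(out / "cohort.csv")
    labels_df = _read_csv(out / "labels.csv")
    labels = labels_df.set_index("subject_id").loc[cohort["subject_id"], "cluster"].to_numpy()
    report = cluster_db_report(labels, cohort, n_clusters=config.cluster.n_clusters)
    report.to_json(out / "report.json")
    group_summary(cohort).to_csv(out / "group_summary.csv", index=False)
    figures = _figures(out, cohort, labels)
    logger.info(
        "report: top cluster %d (mean DBS rank), %d empty cluster(s)",
        report.top_cluster, len(report.empty_clusters),
    )
    _write_manifest(
        out, "report", config,
        inputs=[str(out / "cohort.csv"), str(out / "labels.csv")],
        outputs=[str(out / "report.json"), str(out / "group_summary.csv")] + figures,
    )


_STAGE_FN = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "mtr": stage_mtr,
    "extract": stage_extract,
    "cluster": stage_cluster,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, mode: str, out_dir) -> Path:
    """Run one stage or the whole chain (`mode="all"`); returns the artifact dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    try:
        if mode == "all":
            for stage in ("simulate", "fit", "extract", "cluster", "report"):
                _STAGE_FN[stage](config, out)
        elif mode in _STAGE_FN:
            _STAGE_FN[mode](config, out)
        else:
            raise PipelineError(f"unknown pipeline mode {mode!r}; choose from {('all',) + STAGES}")
    finally:
        if handler:
            logger.removeHandler(handler)
            handler.close()
    return out
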