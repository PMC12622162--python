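"""Shared fixtures: synthetic data, a trained model, and a full pipeline run."""

import numpy as np
import pytest

from fevep.model import resolve_feature_config, train_classifier
from fevep.synthetic import SimConfig, simulate_feature_matrix, simulate_labeled_variants


@pytest.fixture(scope="session")
def sim_cfg():
    # 20 genes x 100 variants, 5 informative features at a 2-sd class shift
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_data(sim_cfg):
    dataset, labels = simulate_labeled_variants(sim_cfg)
    matrix, informative = simulate_feature_matrix(dataset, sim_cfg)
    return {
        "dataset": dataset,
        "labels": labels,
        "matrix": matrix,
        "informative": informative,
    }


@pytest.fixture(scope="session")
def trained_cti(sim_data):
    config = resolve_feature_config(sim_data["matrix"].features, "CTI")
    return train_classifier(
        sim_data["dataset"], sim_data["matrix"], config, trials=10, seed=1
    )


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """Full CLI chain on the small preset; returns the output directory."""
    from click.testing import CliRunner
    from fevep.cli import main

    root = tmp_path_factory.mktemp("pipeline")
    fx = root / "fx"
    runner = CliRunner()

    def run(*args):
        result = runner.invoke(main, [str(a) for a in args], catch_exceptions=False)
        assert result.exit_code == 0, result.output
        return result

    run("simulate", "--preset", "small", "--seed", "3", "--out", fx)
    run("build-dataset", "--functional", "--config", fx / "config.json",
        "--seed", "3", "--out", root / "func.tsv")
    run("build-dataset", "--clinical", "--config", fx / "config.json",
        "--seed", "3", "--out", root / "clin.tsv")
    run("mask-scores", "--matrix", fx / "features.tsv", "--meta", fx / "feature_meta.tsv",
        "--registry", fx / "registry.json", "--out", root / "masked.tsv",
        "--report", root / "mask_report.tsv")
    run("impute", "--matrix", root / "masked.tsv", "--meta", fx / "feature_meta.tsv",
        "--background", fx / "background.tsv", "--labels", fx / "labels.tsv",
        "--seed", "3", "--out", root / "imputed.tsv")
    for regime in ("CTI", "CTE", "SP"):
        run("train", "--regime", regime, "--dataset", root / "func.tsv",
            "--matrix", root / "imputed.tsv", "--meta", fx / "feature_meta.tsv",
            "--trials", "3", "--seed", "3", "--out", root / f"model_{regime.lower()}")
    run("predict", "--model", root / "model_cti", "--matrix", root / "imputed.tsv",
        "--meta", fx / "feature_meta.tsv", "--out", root / "preds.tsv")
    run("attribute", "--model", root / "model_cti", "--matrix", root / "imputed.tsv",
        "--meta", fx / "feature_meta.tsv", "--out", root / "attr.tsv")
    run("calibrate", "--scores", root / "preds.tsv", "--labels", fx / "labels.tsv",
        "--window-min", "20", "--out", root / "calib.tsv")
    run("classify", "--scores", root / "preds.tsv", "--calibration", root / "calib.tsv",
        "--out", root / "classes.tsv")
    run("epi", "--af", fx / "af.tsv", "--inheritance", fx / "inheritance.tsv",
        "--out", root / "epi.tsv")
    return root
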