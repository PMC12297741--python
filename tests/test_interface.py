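"""Survey I/O, output manifests, configuration, and pipeline orchestration."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lonenet import PipelineConfig, generate_study, run_pipeline
from lonenet.io import load_survey, write_csv, write_network_tables
from lonenet.params import IsingParameters


@pytest.fixture(scope="module")
def study():
    return generate_study(n=120, seed=5, n_heavy_missing=4)


def write_study(study, tmp_path) -> tuple[Path, Path]:
    items = tmp_path / "items.csv"
    codebook = tmp_path / "codebook.csv"
    write_csv(study["cls_responses"], items)
    write_csv(study["codebook"], codebook, index=False)
    return items, codebook


class TestLoadSurvey:
    def test_write_read_round_trip(self, study, tmp_path):
        items, codebook = write_study(study, tmp_path)
        survey, covariates = load_survey(items, codebook)
        pd.testing.assert_frame_equal(survey.responses, study["cls_responses"])
        assert survey.reverse_keyed == {
            "CLS01", "CLS04", "CLS08", "CLS10", "CLS16", "CLS22"
        }
        assert covariates.empty

    def test_codebook_missing_item_errors(self, study, tmp_path):
        items, _ = write_study(study, tmp_path)
        bad = study["codebook"].copy()
        bad.loc[len(bad)] = ["CLS99", "CLS", "no"]
        path = tmp_path / "bad_codebook.csv"
        write_csv(bad, path, index=False)
        with pytest.raises(ValueError, match="CLS99"):
            load_survey(items, path)

    def test_empty_file_errors(self, study, tmp_path):
        items, codebook = write_study(study, tmp_path)
        empty = tmp_path / "empty.csv"
        empty.touch()
        with pytest.raises(ValueError, match="empty"):
            load_survey(empty, codebook)

    def test_duplicate_participant_errors(self, study, tmp_path):
        items, codebook = write_study(study, tmp_path)
        df = pd.read_csv(items)
        df.loc[1, "participant_id"] = df.loc[0, "participant_id"]
        df.to_csv(items, index=False)
        with pytest.raises(ValueError, match="duplicated"):
            load_survey(items, codebook)

    def test_non_integer_response_errors(self, study, tmp_path):
        items, codebook = write_study(study, tmp_path)
        df = pd.read_csv(items)
        df.loc[0, "CLS03"] = 2.5
        df.to_csv(items, index=False)
        with pytest.raises(ValueError, match="CLS03"):
            load_survey(items, codebook)


class TestWriteNetworkTables:
    def test_manifest_tracks_content(self, tmp_path):
        net = IsingParameters(["A", "B"], [0.0, 0.0], [[0, 0.5], [0.5, 0]])
        m1 = write_network_tables({"net": net}, outdir=tmp_path)
        m2 = write_network_tables({"net": net}, outdir=tmp_path)
        pd.testing.assert_frame_equal(m1, m2)
        changed = IsingParameters(["A", "B"], [0.0, 0.0], [[0, 0.7], [0.7, 0]])
        m3 = write_network_tables({"net": changed}, outdir=tmp_path)
        assert (
            m1.set_index("file").loc["net_edges.csv", "sha256"]
            != m3.set_index("file").loc["net_edges.csv", "sha256"]
        )

    def test_empty_network_header_only(self, tmp_path):
        net = IsingParameters(["A"], [0.0], [[0.0]])
        write_network_tables({"solo": net}, outdir=tmp_path)
        lines = (tmp_path / "solo_edges.csv").read_text().strip().splitlines()
        assert lines == ["node_i,node_j,weight"]

    def test_labels_preserved_verbatim(self, tmp_path):
        net = IsingParameters(
            ["CLS08", "CLS22"], [0.0, 0.0], [[0, 0.3], [0.3, 0]]
        )
        write_network_tables({"cls": net}, outdir=tmp_path)
        df = pd.read_csv(tmp_path / "cls_edges.csv")
        assert df.loc[0, "node_i"] == "CLS08" and df.loc[0, "node_j"] == "CLS22"


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(outdir="x", seed=3, stages=("preprocess", "ising"))
        path = tmp_path / "cfg.yaml"
        path.write_text(json.dumps(cfg.to_dict()))  # JSON is valid YAML
        loaded = PipelineConfig.from_yaml(path)
        assert loaded == cfg

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stages"):
            PipelineConfig(stages=("preprocess", "magic"))

    def test_residualization_requires_covariates_for_file_input(self):
        with pytest.raises(ValueError, match="covariates"):
            PipelineConfig(items_csv="items.csv", codebook_csv="cb.csv")


@pytest.fixture(scope="module")
def small_cfg(tmp_path_factory):
    def make(outdir, stages=None):
        kwargs = {} if stages is None else {"stages": stages}
        return PipelineConfig(
            outdir=str(tmp_path_factory.mktemp("pipe") / outdir),
            seed=17,
            n_participants=400,
            ising_n_lambda=30,
            ggm_n_lambda=40,
            nira_n_sim=200,
            nira_burn_in=60,
            nira_n_boot=200,
            stability_n_boot=10,
            stability_cs_n_boot=5,
            stability_n_lambda=10,
            mnm_n_boot=5,
            **kwargs,
        )

    return make


class TestRunPipeline:
    def test_stage_toggling_skips_interventions(self, small_cfg):
        cfg = small_cfg("no_nira", stages=("preprocess", "ising"))
        results = run_pipeline(cfg)
        out = Path(cfg.outdir)
        assert (out / "ising_edges.csv").exists()
        assert not list(out.glob("nira_*"))
        assert "nira_alleviating" not in results

    def test_full_run_produces_expected_artifacts(self, small_cfg):
        cfg = small_cfg("full")
        results = run_pipeline(cfg)
        out = Path(cfg.outdir)
        for name in (
            "ising_edges.csv",
            "nira_alleviating.csv",
            "nira_aggravating.csv",
            "ggm_domain_edges.csv",
            "ggm_facet_edges.csv",
            "facet_bridge.csv",
            "cs_curve.csv",
            "mnm_params.csv",
            "summary.json",
            "run_log.json",
            "manifest.csv",
        ):
            assert (out / name).exists(), name
        summary = json.loads((out / "summary.json").read_text())
        assert summary["removed_items"] == ["CLS20"]
        # redundant item removal leaves the 15 core symptoms in the network
        edges = pd.read_csv(out / "ising_edges.csv")
        assert "CLS20" not in set(edges.node_i) | set(edges.node_j)
        # resolved perturbation magnitude is logged
        run_log = json.loads((out / "run_log.json").read_text())
        assert run_log["resolved"]["nira_delta_mode"] == "sd"
        assert run_log["resolved"]["nira_delta_aggravating"] > 0


class TestCli:
    def test_simulate_writes_study_and_truth(self, tmp_path):
        from click.testing import CliRunner

        from lonenet.cli import main

        out = tmp_path / "data"
        result = CliRunner().invoke(
            main, ["simulate", "--seed", "3", "-n", "50", "--outdir", str(out)]
        )
        assert result.exit_code == 0, result.output
        for name in ("cls_items.csv", "codebook.csv", "facet_scores.csv",
                     "truth_ising_edges.csv", "truth_facet_m.csv"):
            assert (out / name).exists(), name
        survey, _ = load_survey(out / "cls_items.csv", out / "codebook.csv")
        assert survey.n_participants == 50
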