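import hashlib
import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import specnet as sn
from specnet.cli import main as cli_main


def small_config(fixture50, tmp_path, **overrides):
    mgf, _ = fixture50
    defaults = dict(mgf_path=str(mgf), out_dir=str(tmp_path / "session"),
                    perplexities=(5, 10), ks=(3, 5), seed=7)
    defaults.update(overrides)
    return sn.SessionConfig(**defaults)


class TestRunSession:
    def test_all_artifacts_present_with_seed_in_manifest(self, fixture50, tmp_path):
        cfg = small_config(fixture50, tmp_path)
        result = sn.run_session(cfg)
        for key in ("coordinates", "diagnostics", "clusters", "edges",
                    "graphml", "manifest", "similarity", "library"):
            assert result.paths[key].exists(), key
        manifest = json.loads(result.paths["manifest"].read_text())
        assert manifest["seed"] == 7
        assert manifest["n_spectra"] == len(result.library)
        header = result.paths["coordinates"].read_text().splitlines()[0]
        assert header.startswith("#") and "seed=7" in header

    def test_rerun_is_byte_identical(self, fixture50, tmp_path):
        cfg = small_config(fixture50, tmp_path)
        first = sn.run_session(cfg)
        digests = {k: hashlib.sha256(p.read_bytes()).hexdigest()
                   for k, p in first.paths.items()}
        second = sn.run_session(cfg)
        for k, p in second.paths.items():
            assert hashlib.sha256(p.read_bytes()).hexdigest() == digests[k], k

    def test_loaded_primary_matrix_wins_over_computed(self, fixture50, tmp_path,
                                                      caplog):
        mgf, _ = fixture50
        lib = sn.preprocess(sn.read_mgf(mgf))
        external = sn.SimilarityMatrix(np.eye(len(lib)), lib.ids, "external")
        ext_path = tmp_path / "external.csv"
        sn.save_matrix(external, ext_path)
        cfg = small_config(fixture50, tmp_path,
                           primary_matrix_path=str(ext_path),
                           perplexities=(5,), threshold=0.5)
        with caplog.at_level("INFO"):
            result = sn.run_session(cfg)
        assert any("precedence" in r.message for r in caplog.records)
        # identity matrix as primary: no off-diagonal score passes 0.5
        assert result.network.edges == []
        assert result.paths["modified_cosine"].exists()

    def test_stage_error_carries_stage_name(self, tmp_path):
        cfg = sn.SessionConfig(mgf_path=str(tmp_path / "missing.mgf"),
                               out_dir=str(tmp_path / "out"))
        with pytest.raises(RuntimeError, match="stage 'read'"):
            sn.run_session(cfg)


class TestExportGraphml:
    def make_view(self, n, edges):
        scores = np.eye(n)
        for i, j, w in edges:
            scores[i, j] = scores[j, i] = w
        m = sn.SimilarityMatrix(scores, [f"s{i}" for i in range(n)])
        return sn.build_network(m, threshold=0.5)

    def coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return sn.EmbeddingResult(rng.normal(size=(n, 2)), 5.0, 0, 1.0, 1.0)

    def test_empty_network_exports_nodes_only(self, tmp_path):
        nv = self.make_view(3, [])
        path = tmp_path / "empty.graphml"
        sn.export_graphml(nv, self.coords(3), path)
        graph = nx.read_graphml(path)
        assert graph.number_of_nodes() == 3 and graph.number_of_edges() == 0

    def test_single_edge_carries_weight(self, tmp_path):
        nv = self.make_view(3, [(0, 1, 0.8)])
        path = tmp_path / "one.graphml"
        sn.export_graphml(nv, self.coords(3), path, ids=["s0", "s1", "s2"])
        graph = nx.read_graphml(path)
        assert graph.number_of_edges() == 1
        assert graph.edges["s0", "s1"]["weight"] == pytest.approx(0.8)

    def test_round_trip_reproduces_edges_and_weights(self, tmp_path):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 1, (10, 10))
        scores = (raw + raw.T) / 2
        np.fill_diagonal(scores, 1.0)
        m = sn.SimilarityMatrix(scores, [f"s{i}" for i in range(10)])
        nv = sn.build_network(m, threshold=0.4)
        path = tmp_path / "rt.graphml"
        sn.export_graphml(nv, self.coords(10), path, ids=m.ids)
        graph = nx.read_graphml(path)
        assert graph.number_of_edges() == len(nv.edges)
        for e in nv.edges:
            back = graph.edges[m.ids[e.a], m.ids[e.b]]["weight"]
            assert back == pytest.approx(e.weight, abs=1e-6)
        for pos, fid in enumerate(m.ids):
            assert graph.nodes[fid]["degree"] == nv.degrees[pos]

    def test_size_mismatch_rejected(self, tmp_path):
        nv = self.make_view(3, [])
        with pytest.raises(ValueError):
            sn.export_graphml(nv, self.coords(4), tmp_path / "x.graphml")


class TestJoinMetadata:
    @pytest.fixture
    def library(self, mkspec):
        return sn.SpectrumLibrary(
            [mkspec(f"s{i}", 300.0, [(100.0, 1.0), (150.0, 0.5)])
             for i in range(3)]
        )

    def test_complete_join(self, library, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"feature_id": ["s0", "s1", "s2"],
                      "klass": ["x", "y", "z"]}).to_csv(path, index=False)
        joined = sn.join_metadata(library, path)
        assert list(joined["klass"]) == ["x", "y", "z"]

    def test_extra_row_logged(self, library, tmp_path, caplog):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"feature_id": ["s0", "s1", "s2", "ghost"],
                      "klass": list("wxyz")}).to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            joined = sn.join_metadata(library, path)
        assert len(joined) == 3
        assert any("ghost" in r.message for r in caplog.records)

    def test_missing_features_get_empty_strings(self, library, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"feature_id": ["s1"], "klass": ["y"]}).to_csv(path, index=False)
        joined = sn.join_metadata(library, path)
        assert list(joined["klass"]) == ["", "y", ""]

    def test_missing_id_column_rejected(self, library, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"name": ["s1"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="feature_id"):
            sn.join_metadata(library, path)


class TestSessionConfig:
    def test_from_file_round_trip(self, tmp_path):
        cfg_path = tmp_path / "session.cfg"
        cfg_path.write_text(
            "threshold = 0.6  # inclusive\n"
            "perplexities = 5,10\n"
            "ks = 3,5\n"
            "top_k = none\n"
            "seed = 3\n"
        )
        cfg = sn.SessionConfig.from_file(cfg_path, mgf_path="x.mgf",
                                         out_dir="out")
        assert cfg.threshold == 0.6
        assert cfg.perplexities == (5.0, 10.0)
        assert cfg.ks == (3, 5)
        assert cfg.top_k is None and cfg.seed == 3

    def test_unknown_key_rejected(self, tmp_path):
        cfg_path = tmp_path / "bad.cfg"
        cfg_path.write_text("verbosity = 3\n")
        with pytest.raises(ValueError, match="verbosity"):
            sn.SessionConfig.from_file(cfg_path, mgf_path="x", out_dir="y")

    def test_parameter_ranges_validated(self):
        with pytest.raises(ValueError):
            sn.SessionConfig(mgf_path="x", out_dir="y", threshold=1.5)
        with pytest.raises(ValueError):
            sn.SessionConfig(mgf_path="x", out_dir="y", top_k=0)


class TestCli:
    def test_import_then_network_subcommands(self, fixture50, tmp_path):
        mgf, _ = fixture50
        sess = tmp_path / "sess"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "import", str(mgf), str(sess), "--seed", "3", "--threshold", "0.7",
        ])
        assert result.exit_code == 0, result.output
        assert (sess / "network.graphml").exists()
        out_csv = tmp_path / "edges.csv"
        result = runner.invoke(cli_main, [
            "network", str(sess), "--threshold", "0.8", "--out", str(out_csv),
        ])
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(out_csv)
        assert set(frame.columns) == {"id_a", "id_b", "score"}
        assert (frame["score"] >= 0.8).all()

    def test_fragmap_subcommand(self, fixture50, tmp_path):
        mgf, _ = fixture50
        sess = tmp_path / "sess"
        runner = CliRunner()
        assert runner.invoke(cli_main, ["import", str(mgf), str(sess)]
                             ).exit_code == 0
        lib = sn.read_mgf(sess / "library.mgf")
        ids = ",".join(lib.ids[:3])
        out_csv = tmp_path / "fragmap.csv"
        result = runner.invoke(cli_main, [
            "fragmap", str(sess), "--ids", ids, "--out", str(out_csv),
        ])
        assert result.exit_code == 0, result.output
        assert pd.read_csv(out_csv, index_col=0).shape[0] == 3
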