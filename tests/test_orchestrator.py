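"""Grid construction, execution, resumable logging and end-to-end scoring."""

import json

import pytest
from click.testing import CliRunner

from priobench import synthetic
from priobench.cli import main as cli_main
from priobench.cohort import ExperimentConfig
from priobench.orchestrator import (
    GridError,
    build_grid,
    make_grid,
    metrics_report_frame,
    parse_config_id,
    permute_order,
    run,
    score,
)
from priobench.prompts import ZERO_SHOT_TEMPLATES
from priobench.synthetic import ResponderParams, SimulatedBackend


class TestBuildGrid:
    def test_full_factorial_product(self):
        configs = build_grid(
            ["gpt-4", "gpt-3.5"], list(ZERO_SHOT_TEMPLATES), ["hpo", "free_text"], [10, 50]
        )
        assert len(configs) == 32
        assert len(set(c.config_id for c in configs)) == 32

    def test_single_template_three_models(self):
        configs = build_grid(
            ["llama2-7b", "llama2-13b", "llama2-70b"],
            ["original_role_instruction"], ["hpo", "free_text"], [10, 50],
        )
        assert len(configs) == 12

    def test_singleton_grid(self):
        assert len(build_grid(["m"], ["original"], ["hpo"], [10])) == 1

    def test_empty_factor_rejected(self):
        with pytest.raises(GridError):
            build_grid([], ["original"], ["hpo"], [10])

    def test_config_id_roundtrip(self):
        config = ExperimentConfig("gpt-4", "original", "free_text", 50)
        assert parse_config_id(config.config_id) == config


class TestPermuteOrder:
    @pytest.fixture
    def grid(self, synthetic_world):
        _, _, cohort = synthetic_world
        configs = build_grid(["m1", "m2"], ["original"], ["hpo"], [10])
        return make_grid(configs, cohort[:20])

    def test_same_seed_identical(self, grid):
        assert permute_order(grid, 5).order == permute_order(grid, 5).order

    def test_different_seeds_differ(self, grid):
        assert permute_order(grid, 5).order != permute_order(grid, 6).order

    def test_permutation_is_bijection(self, grid):
        permuted = permute_order(grid, 5)
        assert sorted(permuted.order) == sorted(grid.order)


class TestRun:
    def make_backend(self, lexicon, **kwargs):
        params = ResponderParams(**kwargs)
        return SimulatedBackend(params, lexicon, seed=11)

    def test_record_cardinality(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort[:2])
        out = tmp_path / "responses.jsonl"
        written = run(grid, cohort[:2], self.make_backend(lexicon), out, iterations=3)
        assert written == 6
        assert len(out.read_text().splitlines()) == 6

    def test_rerun_is_idempotent(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort[:2])
        out = tmp_path / "responses.jsonl"
        backend = self.make_backend(lexicon)
        run(grid, cohort[:2], backend, out, iterations=3)
        assert run(grid, cohort[:2], backend, out, iterations=3) == 0

    def test_responses_reproducible_across_files(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort[:3])
        texts = []
        for name in ("a.jsonl", "b.jsonl"):
            out = tmp_path / name
            run(grid, cohort[:3], self.make_backend(lexicon), out, iterations=2)
            texts.append(
                [json.loads(l)["response"] for l in out.read_text().splitlines()]
            )
        assert texts[0] == texts[1]

    def test_backend_failure_recorded_not_raised(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world

        class FailingBackend:
            backend_id = "broken"

            def respond(self, prompt, context):
                raise RuntimeError("boom")

        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort[:1])
        out = tmp_path / "responses.jsonl"
        run(grid, cohort[:1], FailingBackend(), out, iterations=1, max_retries=1)
        record = json.loads(out.read_text().splitlines()[0])
        assert record["response"] is None
        assert "boom" in record["error"]


class TestScore:
    def run_and_score(self, lexicon, cohort, tmp_path, **params):
        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort)
        out = tmp_path / "responses.jsonl"
        backend = SimulatedBackend(ResponderParams(**params), lexicon, seed=5)
        run(grid, cohort, backend, out, iterations=3)
        return score(out, cohort, lexicon, bootstrap_reps=50, seed=0)

    def rates(self, result):
        frame = metrics_report_frame(result.summaries)
        return dict(zip(frame["metric"], frame["mean_rate"]))

    def test_all_refusals(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        result = self.run_and_score(lexicon, cohort[:15], tmp_path, p_refuse=1.0)
        rates = self.rates(result)
        assert rates["completeness"] == 0.0
        assert rates["accuracy_overall"] == 0.0
        assert rates["compliance"] == 1.0

    def test_perfect_responder(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        result = self.run_and_score(
            lexicon, cohort[:15], tmp_path,
            p_refuse=0.0, p_complete=1.0, p_hit=1.0, hit_rank_q=1.0,
            p_fabricate=0.0, p_duplicate=0.0, p_comply=1.0,
        )
        rates = self.rates(result)
        assert rates == {
            "completeness": 1.0, "accuracy_completed": 1.0,
            "accuracy_overall": 1.0, "compliance": 1.0,
        }

    def test_rescoring_is_pure(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        grid = make_grid(build_grid(["sim"], ["original"], ["hpo"], [10]), cohort[:10])
        out = tmp_path / "responses.jsonl"
        run(grid, cohort[:10], SimulatedBackend(ResponderParams(), lexicon, seed=5),
            out, iterations=3)
        a = score(out, cohort[:10], lexicon, bootstrap_reps=50, seed=1)
        b = score(out, cohort[:10], lexicon, bootstrap_reps=50, seed=1)
        assert a.records == b.records
        assert [s.ci_low for s in a.summaries] == [s.ci_low for s in b.summaries]

    def test_orphan_records_counted(self, synthetic_world, tmp_path):
        lexicon, _, cohort = synthetic_world
        out = tmp_path / "responses.jsonl"
        record = {
            "experiment_id": "sim|original|hpo|k10", "case_id": "ghost",
            "iteration": 1, "prompt": "p", "response": "not applicable",
            "backend": "sim", "timestamp": "t",
        }
        lines = [json.dumps(record)]
        for t in (1, 2, 3):
            lines.append(json.dumps({**record, "case_id": cohort[0].case_id, "iteration": t}))
        out.write_text("\n".join(lines) + "\n")
        result = score(out, cohort[:1], lexicon)
        assert result.n_orphans == 1


class TestCli:
    def test_pipeline_smoke(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        invoke = lambda args: runner.invoke(cli_main, args, catch_exceptions=False)
        result = invoke([
            "simulate", "--out", str(data), "--seed", "1",
            "--n-genes", "40", "--n-cases", "12", "--pool-size", "20",
        ])
        assert result.exit_code == 0
        grid_path = tmp_path / "grid.json"
        result = invoke([
            "grid", "--models", "sim", "--templates", "original",
            "--input-types", "hpo", "--ks", "10", "--out", str(grid_path),
        ])
        assert result.exit_code == 0 and "1 configurations" in result.output
        responses = tmp_path / "responses.jsonl"
        result = invoke([
            "run", "--grid", str(grid_path), "--cohort", str(data / "cohort.jsonl"),
            "--lexicon", str(data / "lexicon.tsv"), "--out", str(responses),
            "--seed", "2", "--iterations", "2",
        ])
        assert result.exit_code == 0
        assert len(responses.read_text().splitlines()) == 24
        reports = tmp_path / "reports"
        result = invoke([
            "score", "--responses", str(responses),
            "--cohort", str(data / "cohort.jsonl"),
            "--lexicon", str(data / "lexicon.tsv"), "--out", str(reports),
            "--bootstrap-reps", "20",
        ])
        assert result.exit_code == 0
        assert (reports / "metrics.csv").exists()
        assert (reports / "bias.csv").exists()
        assert (reports / "stability.json").exists()

    def test_rag_build_and_query(self, tmp_path):
        runner = CliRunner()
        ann = tmp_path / "ann.tsv"
        synthetic.generate_gene_phenotype_map(6, 3, seed=0, path=ann)
        index_path = tmp_path / "index.json"
        result = runner.invoke(cli_main, [
            "rag-build", "--annotations", str(ann), "--direction", "G2P",
            "--out", str(index_path),
        ], catch_exceptions=False)
        assert result.exit_code == 0 and "6 G2P documents" in result.output
        result = runner.invoke(cli_main, [
            "rag-query", "--index", str(index_path),
            "--query", "phenotype feature 0001", "--top-k", "2",
        ], catch_exceptions=False)
        assert result.exit_code == 0
        assert result.output.count("[G2P:") == 2
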