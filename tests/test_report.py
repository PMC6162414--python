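import json
from types import SimpleNamespace

import pytest

from compete_scan.mirna_scan import stringent_params
from compete_scan.overlap_stats import PairKey
from compete_scan.report import (
    pair_count_length_correlation,
    run_pipeline,
    shared_pair_census,
    write_outputs,
)
from compete_scan.synthetic_data import power_fixture
from oracles import pearson_r


@pytest.fixture(scope="module")
def pipeline_run():
    transcript, mirnas, motifs, truth = power_fixture(5)
    params = stringent_params(n_permutations=100, base_seed=23)
    (result,) = run_pipeline([transcript], mirnas, motifs, params)
    return result, truth


class TestRunPipeline:
    def test_planted_pair_significant(self, pipeline_run):
        result, truth = pipeline_run
        assert PairKey("RBP-planted", "mir-planted") in {
            r.key for r in result.significant
        }

    def test_significant_subset_of_results(self, pipeline_run):
        result, _ = pipeline_run
        assert {r.key for r in result.significant} <= {
            r.key for r in result.results
        }

    def test_site_pair_rows_sum_to_observed(self, pipeline_run):
        result, _ = pipeline_run
        assert len(result.site_pairs) == sum(
            r.observed for r in result.results
        )
        tested = {r.key for r in result.results}
        for s in result.site_pairs:
            assert PairKey(s.rbp_name, s.mirna_name) in tested

    def test_empty_transcript_gives_empty_tables(self):
        from compete_scan.mirna_scan import MiRNA
        from compete_scan.sequence_io import NamedSequence

        t = NamedSequence("empty", "A" * 200)
        mir = MiRNA("m", "AGGGGGGGAAAAAAAAAAAAAA")
        (res,) = run_pipeline(
            [t], [mir], [], stringent_params(n_permutations=5)
        )
        assert res.results == [] and res.site_pairs == []
        assert res.network.n_edges() == 0

    def test_global_fdr_pools_pvalues(self):
        transcript, mirnas, motifs, _ = power_fixture(6)
        params = stringent_params(n_permutations=50, base_seed=3)
        from compete_scan.sequence_io import NamedSequence

        other = NamedSequence("power2", transcript.sequence)
        runs = run_pipeline(
            [transcript, other], mirnas, motifs, params, global_fdr=True
        )
        # identical transcripts => identical p-values; pooled BH must agree
        p1 = {r.key: (r.pvalue, r.qvalue) for r in runs[0].results}
        p2 = {r.key: (r.pvalue, r.qvalue) for r in runs[1].results}
        assert p1 == p2


class TestOutputs:
    def test_files_written_and_deterministic(self, pipeline_run, tmp_path):
        result, _ = pipeline_run
        a = write_outputs(result, tmp_path / "a")
        b = write_outputs(result, tmp_path / "b")
        for key in ("pairs", "sites", "network"):
            assert a[key].read_bytes() == b[key].read_bytes()
        manifest = json.loads(a["manifest"].read_text())
        assert manifest["n_pairs_tested"] == len(result.results)
        assert manifest["params"]["n_permutations"] == 100

    def test_pairs_table_row_count(self, pipeline_run, tmp_path):
        result, _ = pipeline_run
        paths = write_outputs(result, tmp_path)
        lines = [
            l for l in paths["pairs"].read_text().splitlines()
            if l and not l.startswith("#")
        ]
        assert len(lines) - 1 == len(result.results)  # minus header

    def test_sites_table_uses_one_based_coordinates(self, pipeline_run, tmp_path):
        result, _ = pipeline_run
        paths = write_outputs(result, tmp_path)
        text = paths["sites"].read_text()
        assert text.startswith("# coordinates are 1-based inclusive")
        first = text.splitlines()[2].split("\t")
        record = result.site_pairs[0]
        assert int(first[2]) == record.mirna_start + 1
        assert int(first[3]) == record.mirna_end


def fake_run(length, n_significant):
    return SimpleNamespace(
        transcript_length=length,
        significant=[
            SimpleNamespace(key=PairKey(f"R{i}", "m")) for i in range(n_significant)
        ],
    )


class TestCorrelation:
    def test_proportional_counts_give_r_one(self):
        runs = [fake_run(l, l // 100) for l in (500, 1000, 2000, 4000)]
        rec = pair_count_length_correlation(runs)
        assert rec["computable"] and rec["r"] == pytest.approx(1.0)

    def test_constant_counts_not_computable(self):
        runs = [fake_run(l, 3) for l in (500, 1000, 2000)]
        rec = pair_count_length_correlation(runs)
        assert rec["computable"] is False and rec["r"] is None

    def test_fewer_than_three_transcripts_rejected(self):
        with pytest.raises(ValueError):
            pair_count_length_correlation([fake_run(100, 1), fake_run(200, 2)])

    def test_matches_textbook_formula(self, rng):
        for _ in range(10):
            lengths = rng.integers(300, 5000, size=12)
            counts = rng.integers(0, 60, size=12)
            if len(set(counts)) == 1:
                continue
            runs = [fake_run(int(l), int(c)) for l, c in zip(lengths, counts)]
            rec = pair_count_length_correlation(runs)
            r, p = pearson_r([float(l) for l in lengths],
                             [float(c) for c in counts])
            assert rec["r"] == pytest.approx(r)
            assert rec["pvalue"] == pytest.approx(p)


class TestCensus:
    def _runs(self):
        shared = PairKey("Rs", "ms")
        runs = []
        for i in range(10):
            sig = [SimpleNamespace(key=PairKey(f"R{i}", f"m{i}"))]
            if i < 6:
                sig.append(SimpleNamespace(key=shared))
            runs.append(SimpleNamespace(transcript_length=1000, significant=sig))
        return runs, shared

    def test_planted_shared_pair_tops_census(self):
        runs, shared = self._runs()
        census = shared_pair_census(runs, k=5)
        assert census["census"][0] == (shared, 6)
        assert census["n_unique_pairs"] == 11
        assert census["fraction_shared_ge_k"] == pytest.approx(1 / 11)

    def test_all_private_pairs(self):
        runs, _ = self._runs()
        for r in runs:
            r.significant = r.significant[:1]
        census = shared_pair_census(runs, k=5)
        assert census["fraction_shared_ge_k"] == 0.0
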