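import pytest
from click.testing import CliRunner

from emsmotif import (
    CandidateLimitError,
    InstanceSpec,
    InvalidInputError,
    InvalidParameterError,
    SolverConfig,
    generate_instance,
    oracle_common_motifs,
    read_fasta,
    read_motifs,
    solve,
    write_instance_fasta,
    write_motifs,
)
from emsmotif.cli import main
from emsmotif.solver import _workloads

from conftest import random_dna


def random_instance(rng, n=(2, 4), m=(8, 22), l=(3, 5), d=(0, 2)):
    while True:
        li, di = rng.randint(*l), rng.randint(*d)
        if li > di:
            break
    seqs = [random_dna(rng, rng.randint(*m)) for _ in range(rng.randint(*n))]
    return seqs, li, di


class TestSolve:
    def test_both_engines_match_oracle(self, rand):
        for _ in range(15):
            seqs, l, d = random_instance(rand)
            expected = oracle_common_motifs(seqs, l, d)
            assert solve(seqs, SolverConfig(l=l, d=d, engine="trie")) == expected
            assert solve(seqs, SolverConfig(l=l, d=d, engine="radix")) == expected

    def test_worker_count_does_not_change_output(self, rand):
        for _ in range(6):
            seqs, l, d = random_instance(rand)
            base = solve(seqs, SolverConfig(l=l, d=d, engine="radix", workers=1))
            for workers in (2, 4):
                assert (
                    solve(seqs, SolverConfig(l=l, d=d, engine="radix", workers=workers))
                    == base
                )

    def test_process_pool_backend_is_equivalent(self):
        seqs = ["ACGTACGTAA", "TTACGTACGT", "ACGTTTACGA"]
        serial = solve(seqs, SolverConfig(l=4, d=1, engine="radix", workers=2))
        procs = solve(
            seqs,
            SolverConfig(l=4, d=1, engine="radix", workers=2, use_processes=True),
        )
        assert serial == procs

    def test_single_string_equals_its_motif_set(self, rand):
        S = random_dna(rand, 15)
        assert solve([S], SolverConfig(l=4, d=1)) == oracle_common_motifs([S], 4, 1)

    def test_planted_instance_recovers_motif(self):
        inst = generate_instance(InstanceSpec(l=8, d=1, n=6, m=80, seed=11))
        out = solve(inst.sequences, SolverConfig(l=8, d=1, engine="radix"))
        assert inst.planted[0] in out

    def test_early_exit_on_disjoint_strings(self):
        assert solve(["AAAAAA", "CCCCCC", "GGGGGG"], SolverConfig(l=4, d=0)) == []

    def test_workload_count_per_string(self):
        for m, l, d in [(20, 5, 2), (600, 8, 1), (30, 6, 2)]:
            assert len(_workloads(m, l, d)) == (2 * d + 1) * (m - l + 1)

    def test_candidate_guard_trips(self):
        seqs = ["ACGTACGTACGTACGT"]
        with pytest.raises(CandidateLimitError):
            solve(seqs, SolverConfig(l=5, d=2, engine="radix", max_candidates=10))

    @pytest.mark.parametrize(
        "config_kwargs",
        [
            {"l": 3, "d": 3},
            {"l": 3, "d": -1},
            {"l": 3, "d": 1, "workers": 0},
            {"l": 3, "d": 1, "engine": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, config_kwargs):
        with pytest.raises(InvalidParameterError):
            solve(["ACGT"], SolverConfig(**config_kwargs))

    def test_invalid_sequences_rejected(self):
        with pytest.raises(InvalidInputError):
            solve([], SolverConfig(l=3, d=1))
        with pytest.raises(InvalidInputError):
            solve(["ACGN"], SolverConfig(l=3, d=1))
        with pytest.raises(InvalidInputError):
            solve(["A"], SolverConfig(l=4, d=1))


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        inst = generate_instance(InstanceSpec(l=5, d=1, n=4, m=30, seed=3))
        path = tmp_path / "inst.fasta"
        write_instance_fasta(inst, path)
        records = read_fasta(path)
        assert [seq for _, seq in records] == inst.sequences

    def test_fasta_is_uppercased(self, tmp_path):
        path = tmp_path / "lower.fasta"
        path.write_text(">s1\nacgt\nacg\n")
        assert read_fasta(path) == [("s1", "ACGTACG")]

    def test_missing_or_empty_fasta_rejected(self, tmp_path):
        with pytest.raises(InvalidInputError):
            read_fasta(tmp_path / "nope.fasta")
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(InvalidInputError):
            read_fasta(empty)

    def test_motif_list_roundtrip(self, tmp_path):
        path = tmp_path / "motifs.txt"
        write_motifs(["ACG", "CGT"], path, l=3, d=1, n=2, engine="trie", seed=0)
        text = path.read_text()
        assert text.startswith("# l=3\n")
        assert text.endswith("CGT\n")
        assert read_motifs(path) == ["ACG", "CGT"]

    def test_empty_motif_list_writes_header_only(self, tmp_path):
        path = tmp_path / "none.txt"
        write_motifs([], path, l=4, d=1)
        assert read_motifs(path) == []
        assert all(line.startswith("#") for line in path.read_text().splitlines())


class TestCLI:
    def test_generate_then_search_recovers_plant(self, tmp_path):
        runner = CliRunner()
        fasta = tmp_path / "inst.fasta"
        out = tmp_path / "motifs.txt"
        res = runner.invoke(
            main,
            ["generate", "--n", "5", "--m", "60", "--l", "6", "--d", "1",
             "--seed", "4", "--output", str(fasta)],
        )
        assert res.exit_code == 0, res.output
        planted = res.output.split("planted motif: ")[1].split()[0]
        res = runner.invoke(
            main,
            ["search", "--input", str(fasta), "--l", "6", "--d", "1",
             "--engine", "radix", "--output", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert planted in read_motifs(out)

    def test_engines_write_identical_files(self, tmp_path):
        runner = CliRunner()
        fasta = tmp_path / "inst.fasta"
        runner.invoke(
            main,
            ["generate", "--n", "3", "--m", "40", "--l", "5", "--d", "1",
             "--seed", "9", "--output", str(fasta)],
        )
        outputs = {}
        for engine in ("trie", "radix"):
            out = tmp_path / f"{engine}.txt"
            res = runner.invoke(
                main,
                ["search", "--input", str(fasta), "--l", "5", "--d", "1",
                 "--engine", engine, "--output", str(out)],
            )
            assert res.exit_code == 0, res.output
            outputs[engine] = out.read_text().replace(engine, "ENGINE")
        assert outputs["trie"] == outputs["radix"]

    def test_bad_parameters_exit_nonzero(self, tmp_path):
        fasta = tmp_path / "x.fasta"
        fasta.write_text(">a\nACGTACGT\n")
        res = CliRunner().invoke(
            main, ["search", "--input", str(fasta), "--l", "2", "--d", "2"]
        )
        assert res.exit_code != 0
        assert "l > d" in res.output
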