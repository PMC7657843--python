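import numpy as np
import pytest
from click.testing import CliRunner

import dnamix as dm
from dnamix.cli import main as cli_main
from dnamix.compressor import (
    CompressorEngine,
    CostParams,
    FormatError,
    ModelSpecError,
    compressed_bits_per_base,
    load_presets,
    parse_model_spec,
    preset_configs,
    read_header,
)


class TestMixerVersusBlend:
    def test_mixer_code_length_not_worse_than_blend(self, repeat_fixture, five_model_specs):
        """On the repeat-rich fixed-seed fixture the neural mixer's total
        code length beats the soft-blend it consumes as an input (the
        learning rate follows the published per-size settings for
        sub-100 kb sequences)."""
        cfgs = [parse_model_spec(s) for s in five_model_specs]
        eng = CompressorEngine(cfgs, hidden_nodes=24, learning_rate=0.06)
        nn_bits = blend_bits = 0.0
        for sym in repeat_fixture:
            sym = int(sym)
            probs, blend_p, x, coded = eng.predict()
            nn_bits += -np.log2(coded[sym])
            blend_bits += -np.log2(blend_p[sym])
            eng.observe(sym, probs, blend_p, x, coded)
        assert nn_bits <= blend_bits


class TestModelSpecParsing:
    def test_printed_string_without_stcm(self):
        cfg = parse_model_spec("3:1:1:1:0.8/0:0:0")
        assert (cfg.order, cfg.alpha_den, cfg.ir, cfg.store_budget) == (3, 1, True, 1)
        assert cfg.gamma == pytest.approx(0.8)
        assert cfg.tolerance == 0

    def test_printed_string_with_stcm(self):
        cfg = parse_model_spec("20:500:1:40:0.85/5:20:0.85")
        assert cfg.order == 20 and cfg.tolerance == 5
        assert cfg.tol_alpha_den == 20 and cfg.tol_gamma == pytest.approx(0.85)

    def test_reference_flagging(self):
        cfg = parse_model_spec("20:500:1:35:0.95/3:100:0.95", is_reference=True)
        assert cfg.is_reference

    @pytest.mark.parametrize("bad", ["3:1:1", "3:1:1:1:0.8", "a:1:1:1:0.8/0:0:0", "3:1:1:1:0.8/0:0"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ModelSpecError):
            parse_model_spec(bad)

    def test_spec_string_round_trip(self):
        s = "20:500:1:40:0.85/5:20:0.85"
        assert parse_model_spec(s).spec_string() == s

    def test_presets_all_parse(self):
        presets = load_presets()
        assert presets
        for name in presets:
            assert preset_configs(name)


class TestLosslessness:
    @pytest.mark.parametrize(
        "text",
        ["", "A", "ACGT", "A" * 200, "ACGT" * 50],
        ids=["empty", "single", "short", "homopolymer", "periodic"],
    )
    def test_edge_sequences(self, text, small_specs):
        seq = dm.encode_symbols(text)
        blob = dm.compress(seq, target_specs=small_specs, hidden_nodes=8)
        assert np.array_equal(dm.decompress(blob), seq)

    def test_random_sequence(self, rng, small_specs):
        seq = rng.integers(0, 4, 3000, dtype=np.uint8)
        blob = dm.compress(seq, target_specs=small_specs, hidden_nodes=8)
        assert np.array_equal(dm.decompress(blob), seq)

    def test_repeat_fixture_below_two_bits(self):
        seq = dm.generate_synthetic(dm.SynthSpec(12000, 1000, 3, 0.0, 0.0, seed=9))
        blob = dm.compress(
            seq, target_specs=["3:1:1:0:0.9/0:0:0", "11:16:1:0:0.95/0:0:0"], hidden_nodes=16
        )
        assert compressed_bits_per_base(blob, len(seq)) < 2.0
        assert np.array_equal(dm.decompress(blob), seq)


class TestContainer:
    def test_header_stores_network_params_in_8_bytes(self, small_specs):
        seq = dm.encode_symbols("ACGTACGT")
        blob = dm.compress(seq, target_specs=small_specs, learning_rate=0.07, hidden_nodes=24)
        # the two network parameters occupy bytes 6..13 (f32 + u32)
        import struct

        lr, hidden = struct.unpack_from("<fI", blob, 6)
        assert lr == pytest.approx(0.07) and hidden == 24
        info = read_header(blob)
        assert info.learning_rate == pytest.approx(0.07, rel=1e-6)
        assert info.hidden_nodes == 24
        assert info.seq_len == 8

    def test_bad_magic_rejected(self, small_specs):
        blob = dm.compress(dm.encode_symbols("ACGT"), target_specs=small_specs, hidden_nodes=8)
        with pytest.raises(FormatError):
            dm.decompress(b"XXXX" + blob[4:])

    def test_truncated_payload_fails_loudly(self, small_specs):
        seq = dm.encode_symbols("ACGT" * 100)
        blob = dm.compress(seq, target_specs=small_specs, hidden_nodes=8)
        with pytest.raises((FormatError, dm.TruncatedStreamError)):
            dm.decompress(blob[:-6])


@pytest.fixture(scope="module")
def related_pair():
    """Reference plus a target derived from it by 2% substitutions."""
    ref = dm.generate_synthetic(dm.SynthSpec(8000, seed=31))
    rng = np.random.default_rng(32)
    target = ref.copy()
    mask = rng.random(len(target)) < 0.02
    target[mask] = (target[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return ref, target


class TestReferentialModes:
    def test_relative_round_trip(self, related_pair):
        ref, target = related_pair
        blob = dm.compress(
            target, ref_specs=["10:16:1:0:0.95/2:16:0.95"], reference=ref, hidden_nodes=16
        )
        assert np.array_equal(dm.decompress(blob, reference=ref), target)

    def test_conditional_round_trip(self, related_pair):
        ref, target = related_pair
        blob = dm.compress(
            target,
            target_specs=["4:1:0:0:0.9/0:0:0"],
            ref_specs=["10:16:1:0:0.95/2:16:0.95"],
            reference=ref,
            hidden_nodes=16,
        )
        assert np.array_equal(dm.decompress(blob, reference=ref), target)

    def test_relative_mode_without_reference_rejected(self, related_pair):
        _, target = related_pair
        with pytest.raises(ValueError):
            dm.compress(target, ref_specs=["10:16:1:0:0.95/0:0:0"])

    def test_wrong_reference_fails_checksum(self, related_pair):
        ref, target = related_pair
        blob = dm.compress(
            target, ref_specs=["10:16:1:0:0.95/0:0:0"], reference=ref, hidden_nodes=16
        )
        wrong = dm.generate_synthetic(dm.SynthSpec(8000, seed=99))
        with pytest.raises(ValueError):
            dm.decompress(blob, reference=wrong)
        with pytest.raises(ValueError):
            dm.decompress(blob)

    def test_relative_identity_far_cheaper_than_unrelated(self, related_pair):
        ref, _ = related_pair
        specs = ["12:16:1:0:0.95/2:16:0.95"]
        same = dm.compress(ref, ref_specs=specs, reference=ref, hidden_nodes=16)
        unrelated = dm.generate_synthetic(dm.SynthSpec(8000, seed=77))
        other = dm.compress(unrelated, ref_specs=specs, reference=ref, hidden_nodes=16)
        assert len(same) * 4 < len(other)


class TestProfile:
    def test_profile_matches_payload_bits(self, small_specs):
        seq = dm.generate_synthetic(dm.SynthSpec(5000, 500, 4, 0.0, 0.01, seed=13))
        blob = dm.compress(seq, target_specs=small_specs, hidden_nodes=8)
        info = read_header(blob)
        bits, _ = dm.emit_profile(seq, target_specs=small_specs, hidden_nodes=8)
        assert abs(len(info.payload) * 8 - bits.sum()) <= 64

    def test_cold_start_near_two_bits(self, small_specs, rng):
        seq = rng.integers(0, 4, 600, dtype=np.uint8)
        bits, _ = dm.emit_profile(seq, target_specs=small_specs, hidden_nodes=8)
        assert bits[:20].mean() == pytest.approx(2.0, abs=0.3)

    def test_repeat_region_cheaper_than_background(self):
        seq = dm.generate_synthetic(dm.SynthSpec(6000, 1000, 2, 0.0, 0.0, seed=17))
        bits, smoothed = dm.emit_profile(
            seq, target_specs=["12:16:1:0:0.95/0:0:0"], hidden_nodes=8, smooth_window=256
        )
        assert len(bits) == len(smoothed) == len(seq)
        # the two planted copies drive mean bits below the 2-bit background
        assert bits[:1000].mean() > smoothed.min() + 0.5


class TestCostModel:
    def test_storage_only(self):
        p = CostParams(n_copies=3, size=1.0, size_price=0.13)
        assert dm.estimate_storage_cost(p) == pytest.approx(0.39)

    def test_processing_only(self):
        p = CostParams(processing_time=3600.0, power=34.0, energy_price=0.12)
        assert dm.estimate_storage_cost(p) == pytest.approx(0.00408)

    def test_zero_copies_means_processing_cost_only(self):
        p = CostParams(processing_time=7200.0, power=50.0, energy_price=0.1, size=5.0, size_price=0.1)
        assert dm.estimate_storage_cost(p) == pytest.approx(2 * 0.05 * 0.1)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            CostParams(processing_time=-1.0)


class TestCLI:
    def test_compress_decompress_synth_cost(self, tmp_path):
        runner = CliRunner()
        fasta = tmp_path / "in.fa"
        fasta.write_text(">chr\n" + "ACGTTGCA" * 100 + "\n")
        out = tmp_path / "out.dmx"
        res = runner.invoke(
            cli_main,
            ["compress", "-i", str(fasta), "-o", str(out),
             "--tm", "2:1:1:0:0.9/0:0:0", "--hidden", "8",
             "--profile", str(tmp_path / "prof.tsv")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["decompress", "-i", str(out), "-o", str(tmp_path / "out.txt")])
        assert res.exit_code == 0, res.output
        assert dm.decode_symbols(dm.read_fasta_filtered(tmp_path / "out.txt")) == "ACGTTGCA" * 100
        prof_lines = (tmp_path / "prof.tsv").read_text().strip().splitlines()
        assert len(prof_lines) == 800 and prof_lines[0].startswith("0\t")

        res = runner.invoke(cli_main, ["synth", "-o", str(tmp_path / "s.txt"),
                                       "--length", "1000", "--block", "100",
                                       "--repeats", "3", "--seed", "4"])
        assert res.exit_code == 0, res.output
        assert len(dm.read_fasta_filtered(tmp_path / "s.txt")) == 1000

        res = runner.invoke(cli_main, ["cost", "--copies", "3", "--size", "1",
                                       "--size-price", "0.13"])
        assert res.exit_code == 0 and "0.39" in res.output
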