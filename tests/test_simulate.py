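"""Simulator contracts: determinism, planted features, error calibration."""

import hashlib

import numpy as np
import pytest

from amptile.errors import DesignError, PanelError, ParameterError
from amptile.panel import SampleBarcode
from amptile.sequtil import revcomp
from amptile.simulate import (
    ErrorProfile,
    barcode_panel,
    design_tiling,
    make_reference,
    random_barcodes,
    simulate_library,
    simulate_raw_read,
)


class TestMakeReference:
    def test_basic_contract(self):
        ref = make_reference(1, 1000, 0.5, 0, seed=7)
        assert len(ref.loci) == 1
        assert len(ref.loci[0].sequence) == 1000
        assert set(ref.loci[0].sequence) <= set("ACGT")

    def test_planted_homopolymer_runs(self):
        ref = make_reference(1, 1000, 0.5, 2, seed=7)
        locus = ref.loci[0]
        spans = ref.spikes[locus.locus_id]
        assert len(spans) == 2
        for s, e in spans:
            run = locus.sequence[s:e]
            assert e - s >= 8 and len(set(run)) == 1

    def test_deterministic(self):
        a = make_reference(2, 500, 0.4, 1, seed=7)
        b = make_reference(2, 500, 0.4, 1, seed=7)
        assert [l.sequence for l in a.loci] == [l.sequence for l in b.loci]
        assert a.spikes == b.spikes

    def test_gc_content_tracks_request(self):
        ref = make_reference(1, 50000, 0.7, 0, seed=1)
        seq = ref.loci[0].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.7) < 0.02

    @pytest.mark.parametrize("kwargs", [
        dict(n_loci=0, locus_length=1000),
        dict(n_loci=1, locus_length=100),
        dict(n_loci=1, locus_length=1000, gc=1.5),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            make_reference(**{"gc": 0.5, "homopolymer_spikes": 0, "seed": 0, **kwargs})


class TestDesignTiling:
    def test_spans_locus_end_to_end(self):
        ref = make_reference(1, 23000, 0.5, 0, seed=3)
        designs = design_tiling(ref, 6, (3500, 4500), (200, 400), seed=4)
        assert designs[0].start == 0
        assert designs[-1].end == 23000
        for a, b in zip(designs, designs[1:]):
            overlap = a.end - b.start
            assert 200 <= overlap <= 400
            assert b.start < a.end  # contiguous union

    def test_single_amplicon(self):
        ref = make_reference(1, 1000, 0.5, 0, seed=3)
        (d,) = design_tiling(ref, 1, (1000, 1000), (0, 0), seed=0)
        assert (d.start, d.end) == (0, 1000)

    @pytest.mark.parametrize("seed", range(100))
    def test_primer_prefix_suffix_invariant(self, seed):
        ref = make_reference(1, 2200, 0.5, 0, seed=seed)
        for d in design_tiling(ref, 3, (800, 1000), (100, 200), seed=seed):
            amplicon = ref[d.locus_id][d.start:d.end]
            assert amplicon.startswith(d.fwd_primer)
            assert amplicon.endswith(revcomp(d.rev_primer))

    def test_infeasible_geometry(self):
        ref = make_reference(1, 1000, 0.5, 0, seed=3)
        with pytest.raises(DesignError, match="infeasible"):
            design_tiling(ref, 6, (3500, 4500), (200, 400), seed=0)


class TestBarcodePanel:
    def test_row_count_six_by_six(self):
        ref = make_reference(1, 23000, 0.5, 0, seed=3)
        designs = design_tiling(ref, 6, (3500, 4500), (200, 400), seed=4)
        samples = [SampleBarcode(f"s{i}", bc)
                   for i, bc in enumerate(random_barcodes(6, seed=5))]
        panel = barcode_panel(designs, samples)
        assert len(panel) == 36
        assert panel.barcoded

    def test_empty_samples_gives_one_level_panel(self, small_designs):
        panel = barcode_panel(small_designs, [])
        assert len(panel) == len(small_designs)
        assert not panel.barcoded

    def test_padding_default(self):
        assert SampleBarcode("s", "ACGTACGTACGTACGT").padding == "GTTAG"

    def test_duplicate_barcodes_rejected(self, small_designs):
        dup = [SampleBarcode("a", "ACGTACGTACGTACGT"),
               SampleBarcode("b", "ACGTACGTACGTACGT")]
        with pytest.raises(PanelError):
            barcode_panel(small_designs, dup)


class TestSimulateRawRead:
    def test_zero_error_alternates_orientation(self):
        t = "ACGTACGTTTACGGACGT" * 10
        rr = simulate_raw_read(t, 3, ErrorProfile(0, 0, 0, seed=1), "mv/1")
        seqs = [sr.sequence for sr in rr.subreads]
        assert seqs == [t, revcomp(t), t]
        assert [sr.orientation for sr in rr.subreads] == ["sense", "antisense", "sense"]

    def test_subread_ids_parse_back(self):
        t = "ACGT" * 50
        rr = simulate_raw_read(t, 4, ErrorProfile(seed=1), "mv/42")
        assert [sr.subread_id for sr in rr.subreads] == [f"mv/42/{k}" for k in range(4)]

    def test_mean_edit_distance_matches_rate(self):
        import edlib
        t = "".join("ACGT"[i] for i in np.random.default_rng(0).integers(0, 4, 500))
        prof = ErrorProfile(sub_rate=0.1, ins_rate=0.0, del_rate=0.0, seed=2)
        dists = []
        for i in range(200):
            rr = simulate_raw_read(t, 9, prof, f"mv/{i}")
            for sr in rr.subreads:
                s = sr.sequence if sr.orientation == "sense" else revcomp(sr.sequence)
                dists.append(edlib.align(s, t)["editDistance"] / len(t))
        assert 0.05 <= float(np.mean(dists)) <= 0.2

    def test_homopolymer_insertions_concentrate_in_run(self):
        t = "ACGTCGTAGCTAGCTAAGC" + "T" * 10 + "GATCGATCGGCATCGATAA"
        prof = ErrorProfile(sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                            homopolymer_ins_rate=0.5, run_min=8, seed=4)
        in_run = out_run = 0
        for i in range(100):
            rr = simulate_raw_read(t, 2, prof, f"mv/{i}")
            for log in rr.edit_logs:
                for pos, op, _base in log:
                    assert op == "ins"
                    if 19 <= pos < 29:
                        in_run += 1
                    else:
                        out_run += 1
        assert in_run > 0 and out_run == 0

    def test_realized_error_rate_binomial(self):
        # >= 1e5 simulated bases; realized per-base rate within 3 SE
        t = "".join("ACGT"[i] for i in np.random.default_rng(3).integers(0, 4, 2000))
        rate = 0.05
        prof = ErrorProfile(sub_rate=rate, ins_rate=0.0, del_rate=0.0, seed=6)
        n_bases = n_err = 0
        for i in range(60):
            rr = simulate_raw_read(t, 1, prof, f"mv/{i}")
            n_bases += len(t)
            n_err += sum(1 for _ in rr.edit_logs[0])
        assert n_bases >= 1e5
        se = (rate * (1 - rate) / n_bases) ** 0.5
        assert abs(n_err / n_bases - rate) <= 3 * se

    def test_empty_template_rejected(self):
        with pytest.raises(ParameterError):
            simulate_raw_read("", 1, ErrorProfile(seed=0), "mv/1")

    def test_invalid_profile(self):
        with pytest.raises(ParameterError):
            ErrorProfile(sub_rate=0.3, ins_rate=0.2, del_rate=0.1)


class TestSimulateLibrary:
    def test_truth_table_bookkeeping(self, clean_library):
        rows = clean_library.truth_rows()
        assert len(rows) == len(clean_library.raw_reads) == 2 * 3 * 3
        ids_fastq = {r.molecule_id for r in clean_library.raw_reads}
        ids_truth = {r["molecule_id"] for r in rows}
        assert ids_fastq == ids_truth

    def test_mean_passes_near_nine(self, small_reference, small_designs, small_panel):
        bundle = simulate_library(small_panel, 40, 9.0, ErrorProfile(0, 0, 0, seed=1),
                                  None, reference=small_reference,
                                  designs=small_designs, seed=2)
        mean = np.mean([r.n_passes for r in bundle.raw_reads])
        assert 8.0 <= mean <= 10.0

    def test_zero_error_reads_equal_template(self, clean_library):
        for rr in clean_library.raw_reads[:6]:
            t = clean_library.templates[(rr.true_sample_id, rr.true_amplicon_id)]
            for sr in rr.subreads:
                s = sr.sequence if sr.orientation == "sense" else revcomp(sr.sequence)
                assert s == t

    def test_deterministic_files_byte_identical(self, tmp_path, small_reference,
                                                small_designs, small_panel):
        prof = ErrorProfile(0.05, 0.02, 0.02, seed=9)
        digests = []
        for d in ("a", "b"):
            out = tmp_path / d
            simulate_library(small_panel, 2, 5.0, prof, out,
                             reference=small_reference, designs=small_designs, seed=3)
            digests.append(tuple(
                hashlib.md5((out / name).read_bytes()).hexdigest()
                for name in ("subreads.fastq", "truth.tsv", "panel.tsv", "reference.fasta")))
        assert digests[0] == digests[1]

    def test_zero_depth_rejected(self, small_reference, small_designs, small_panel):
        with pytest.raises(DesignError):
            simulate_library(small_panel, 0, 9.0, ErrorProfile(seed=0), None,
                             reference=small_reference, designs=small_designs)
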