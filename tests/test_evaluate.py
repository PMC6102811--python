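"""Alignment reports, error decomposition, bootstrap depth experiment."""

import numpy as np
import pytest

from amptile.errors import ParameterError
from amptile.evaluate import (
    AlignmentReport,
    align_and_report,
    bootstrap_experiment,
    classify_errors,
    summarize_depth_accuracy,
)
from amptile.simulate import ErrorProfile, Locus, ReferenceSet, simulate_raw_read
from tests.conftest import random_dna


def gotoh_counts(query: str, target: str, match=1, mismatch=-2,
                 gap_open=-5, gap_extend=-2):
    """Oracle: global affine-gap alignment by explicit three-state
    dynamic programming; returns (matches, mismatches, ins, del).
    Insertions are query-only bases, deletions target-only."""
    n, m = len(query), len(target)
    NEG = -10**9
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in target (insertion)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query (deletion)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    nm = nx = nins = ndel = 0
    while i > 0 or j > 0:
        if state == 0:
            if query[i - 1] == target[j - 1]:
                nm += 1
            else:
                nx += 1
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i, j) != (0, 0) else 0
        elif state == 1:
            nins += 1
            state = 0 if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend else 1
            i -= 1
        else:
            ndel += 1
            state = 0 if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend else 2
            j -= 1
    return nm, nx, nins, ndel


def _ref(seq, locus_id="locus_1_1000_9999"):
    return ReferenceSet([Locus(locus_id, seq)])


class TestAlignAndReport:
    def test_exact_substring_is_complete(self):
        ref_seq = random_dna(3000, 1)
        rep = align_and_report(ref_seq[800:1800], _ref(ref_seq))
        assert rep.classification == "complete"
        assert rep.percent_identity == 100.0
        assert (rep.target_start, rep.target_end) == (800, 1800)
        assert rep.total_errors == 0

    def test_one_substitution(self):
        ref_seq = random_dna(2000, 2)
        q = ref_seq[500:1500]
        q = q[:400] + ("A" if q[400] != "A" else "C") + q[401:]
        rep = align_and_report(q, _ref(ref_seq))
        assert rep.classification == "partial"
        assert rep.n_mismatch == 1 and rep.n_insertion_bases == 0
        assert rep.percent_identity == pytest.approx(100 * 999 / 1000)

    def test_reverse_strand_hit(self):
        from amptile.sequtil import revcomp
        ref_seq = random_dna(2000, 3)
        rep = align_and_report(revcomp(ref_seq[200:1200]), _ref(ref_seq))
        assert rep.strand == "-" and rep.classification == "complete"

    def test_unmapped_when_unrelated(self):
        rep = align_and_report("A" * 30, _ref("C" * 500))
        assert rep.classification == "unmapped"

    def test_columns_identity_consistent(self):
        ref_seq = random_dna(1500, 4)
        prof = ErrorProfile(0.03, 0.02, 0.02, seed=5)
        q = simulate_raw_read(ref_seq[100:1100], 1, prof, "mv/1").subreads[0].sequence
        rep = align_and_report(q, _ref(ref_seq))
        assert (rep.n_match + rep.n_mismatch + rep.n_insertion_bases
                + rep.n_deletion_bases) == rep.alignment_columns
        assert rep.percent_identity == pytest.approx(
            100 * rep.n_match / rep.alignment_columns)

    @pytest.mark.parametrize("case", range(10))
    def test_error_counts_match_gotoh_oracle(self, case):
        """Isolated, well-separated edits on <= 100 bp pairs: counts agree
        with an exhaustive affine-gap dynamic program."""
        rng = np.random.default_rng(300 + case)
        t = random_dna(100, 400 + case)
        q = t
        edits = [("sub", 20), ("ins", 50), ("del", 80)]
        for kind, pos in edits[:int(rng.integers(1, 4))]:
            if kind == "sub":
                q = q[:pos] + ("A" if q[pos] != "A" else "G") + q[pos + 1:]
            elif kind == "ins":
                q = q[:pos] + "ACGT"[int(rng.integers(0, 4))] + q[pos:]
            else:
                q = q[:pos] + q[pos + 1:]
        rep = align_and_report(q, _ref(t))
        nm, nx, nins, ndel = gotoh_counts(q, t)
        assert (rep.n_mismatch, rep.n_insertion_bases, rep.n_deletion_bases) == (nx, nins, ndel)

    def test_empty_query_rejected(self):
        with pytest.raises(ParameterError):
            align_and_report("", _ref("ACGT" * 100))


class TestClassifyErrors:
    def _report(self, nx=0, nins=0, ndel=0, ins_ev=0, del_ev=0):
        cols = 1000
        return AlignmentReport("q", "l", 0, cols, "+", 99.0, cols - nx - nins - ndel,
                               nx, nins, ndel, ins_ev, del_ev, cols, True, "partial")

    def test_fraction_arithmetic(self):
        dec = classify_errors([self._report(nx=1, nins=2, ndel=1)])
        assert dec.fractions == (0.5, 0.25, 0.25)
        assert dec.defined

    def test_all_perfect_reports_flagged(self):
        dec = classify_errors([self._report()])
        assert not dec.defined and dec.fractions == (0.0, 0.0, 0.0)

    def test_event_mode(self):
        dec = classify_errors([self._report(nx=2, nins=6, ndel=3, ins_ev=2, del_ev=1)],
                              mode="events")
        assert (dec.n_insertion, dec.n_deletion, dec.n_substitution) == (2, 1, 2)

    def test_insertion_dominance_under_homopolymer_bias(self):
        """Polished consensus sequences from reads with a systematic
        homopolymer insertion bias show an insertion-dominated error
        decomposition: random errors wash out under the majority vote,
        the shared +1 insertions do not."""
        from amptile.consensus import polish_cluster

        ref = ReferenceSet([Locus("locus_1_1_3000",
                                  random_dna(1000, 6) + "T" * 10
                                  + random_dna(500, 7) + "A" * 9
                                  + random_dna(1000, 8))])
        t = ref.loci[0].sequence
        prof = ErrorProfile(0.04, 0.02, 0.02, homopolymer_ins_rate=0.5,
                            run_min=8, seed=9)
        reports = []
        for c in range(3):
            reads = [simulate_raw_read(t, 1, prof, f"c{c}/{i}").subreads[0].sequence
                     for i in range(30)]
            reports.append(align_and_report(polish_cluster(reads), ref))
        dec = classify_errors(reports)
        ins_frac, del_frac, sub_frac = dec.fractions
        assert dec.defined
        assert ins_frac > del_frac and ins_frac > sub_frac


@pytest.fixture(scope="module")
def bootstrap_setup():
    """Tiny unbarcoded tiled library with per-amplicon CCS clusters."""
    from amptile.ccs import build_ccs_batch
    from amptile.cluster import cluster_ccs
    from amptile.simulate import (barcode_panel, design_tiling, make_reference,
                                  simulate_library)

    ref = make_reference(1, 2200, 0.5, homopolymer_spikes=0, seed=31)
    designs = design_tiling(ref, 3, (750, 900), (100, 180), seed=32)
    panel = barcode_panel(designs, [])
    prof = ErrorProfile(0.05, 0.03, 0.02, protect_ends=30, seed=33)
    bundle = simulate_library(panel, 8, 5.0, prof, None,
                              reference=ref, designs=designs, seed=34)
    ccs_reads, _ = build_ccs_batch(bundle.raw_reads)
    cmap = cluster_ccs(ccs_reads, panel, two_level=False)
    clusters = {amp: mols for (_s, amp), mols in cmap.clusters().items()}
    raw_by = {r.molecule_id: r for r in bundle.raw_reads}
    return clusters, raw_by, ref


class TestBootstrapExperiment:
    def test_bookkeeping_and_min_depth_rule(self, bootstrap_setup):
        clusters, raw_by, ref = bootstrap_setup
        res = bootstrap_experiment(clusters, raw_by, ref,
                                   depths=[1, 5], replicates=2, seed=1)
        assert len(res) == 3 * 2 * 2  # amplicons x depths x replicates
        for r in res:
            if r.assembly_report is not None:
                assert r.assembly_n_subreads <= r.n_subreads

    def test_deterministic_under_seed(self, bootstrap_setup):
        clusters, raw_by, ref = bootstrap_setup
        a = bootstrap_experiment(clusters, raw_by, ref, depths=[2], replicates=2, seed=5)
        b = bootstrap_experiment(clusters, raw_by, ref, depths=[2], replicates=2, seed=5)
        assert [(r.amplicon_id, r.n_subreads, r.consensus_report.percent_identity)
                for r in a] == \
               [(r.amplicon_id, r.n_subreads, r.consensus_report.percent_identity)
                for r in b]

    def test_accuracy_rises_with_depth(self, bootstrap_setup):
        clusters, raw_by, ref = bootstrap_setup
        res = bootstrap_experiment(clusters, raw_by, ref,
                                   depths=[1, 8], replicates=3, seed=7)
        df = summarize_depth_accuracy(res)
        lo = df[df.ccs_sample_size == 1].consensus_mean_pid.iloc[0]
        hi = df[df.ccs_sample_size == 8].consensus_mean_pid.iloc[0]
        assert hi >= lo

    def test_summary_single_result(self, bootstrap_setup):
        clusters, raw_by, ref = bootstrap_setup
        res = bootstrap_experiment(clusters, raw_by, ref, depths=[3],
                                   replicates=1, seed=2)
        df = summarize_depth_accuracy(res[:1])
        assert len(df) == 1
        assert df.consensus_mean_pid.iloc[0] == res[0].consensus_report.percent_identity
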