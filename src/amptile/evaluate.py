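"""Accuracy evaluation: reference alignment reports, error decomposition,
and the bootstrap subread-depth experiment.

Consensus and assembly sequences are aligned locally to the reference
(match +1, mismatch -2, gap open -5, gap extend -2 — a local-aligner
approximation of common megablast-style scoring), both strands.  Percent
identity is matches over alignment columns; mismatches, inserted bases
(extra in the query) and deleted bases (missing from the query) are
recorded separately so total error can be decomposed by type.

The bootstrap experiment resamples, per amplicon, 1..40 CCS read
identifiers with replacement (25 replicates at each depth by default),
polishes a consensus from the corresponding raw subreads with the
support filter lowered to 0, assembles each replicate's overlapping
consensus set, and reports accuracy as a function of subread depth.  The
subread depth of an assembly is the minimum depth over its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from amptile.assembly import assemble_sample
from amptile.consensus import ConsensusRecord, polish_cluster_with_stats
from amptile.errors import ParameterError
from amptile.sequtil import revcomp
from amptile.simulate import RawRead, ReferenceSet


@dataclass
class AlignmentReport:
    query_id: str
    locus_id: Optional[str]
    target_start: int
    target_end: int
    strand: str
    percent_identity: float
    n_match: int
    n_mismatch: int
    n_insertion_bases: int
    n_deletion_bases: int
    n_insertion_events: int
    n_deletion_events: int
    alignment_columns: int
    query_covered: bool
    classification: str  # complete | truncated | partial | unmapped

    @property
    def total_errors(self) -> int:
        return self.n_mismatch + self.n_insertion_bases + self.n_deletion_bases


@dataclass
class BootstrapResult:
    amplicon_id: str
    ccs_sample_size: int
    replicate: int
    n_subreads: int
    consensus_report: AlignmentReport
    assembly_report: Optional[AlignmentReport] = None
    assembly_n_subreads: Optional[int] = None


def _make_aligner(match: float = 1, mismatch: float = -2,
                  gap_open: float = -5, gap_extend: float = -2) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def align_and_report(query: str, reference: ReferenceSet, query_id: str = "query",
                     aligner: Optional[Align.PairwiseAligner] = None) -> AlignmentReport:
    """Best local alignment of the query (either strand, any locus) and
    its identity/error accounting.

    classification: 'complete' = 100 % identity with the whole query
    aligned; 'truncated' = 100 % identity over a partial span;
    'partial' = identity < 100 %; 'unmapped' = no positive-score hit.
    """
    if not query:
        raise ParameterError("query must be non-empty")
    if aligner is None:
        aligner = _make_aligner()
    best = None
    for locus in reference.loci:
        for strand, q in (("+", query), ("-", revcomp(query))):
            score = aligner.score(locus.sequence, q)
            if score > 0 and (best is None or score > best[0]):
                best = (score, locus, strand, q)
    if best is None:
        return AlignmentReport(query_id, None, 0, 0, "+", 0.0, 0, 0, 0, 0, 0, 0,
                               0, False, "unmapped")
    _score, locus, strand, q = best
    aln = aligner.align(locus.sequence, q)[0]
    counts = aln.counts()
    t_blocks, q_blocks = aln.aligned
    n_ins = n_del = ins_ev = del_ev = 0
    for i in range(1, len(t_blocks)):
        tgap = int(t_blocks[i][0] - t_blocks[i - 1][1])
        qgap = int(q_blocks[i][0] - q_blocks[i - 1][1])
        if qgap > 0:
            n_ins += qgap
            ins_ev += 1
        if tgap > 0:
            n_del += tgap
            del_ev += 1
    n_match = int(counts.identities)
    n_mismatch = int(counts.mismatches)
    columns = n_match + n_mismatch + n_ins + n_del
    pid = 100.0 * n_match / columns if columns else 0.0
    q_cov = int(q_blocks[0][0]) == 0 and int(q_blocks[-1][1]) == len(q)
    if pid == 100.0 and q_cov:
        cls = "complete"
    elif pid == 100.0:
        cls = "truncated"
    else:
        cls = "partial"
    return AlignmentReport(
        query_id=query_id, locus_id=locus.locus_id,
        target_start=int(t_blocks[0][0]), target_end=int(t_blocks[-1][1]),
        strand=strand, percent_identity=pid,
        n_match=n_match, n_mismatch=n_mismatch,
        n_insertion_bases=n_ins, n_deletion_bases=n_del,
        n_insertion_events=ins_ev, n_deletion_events=del_ev,
        alignment_columns=columns, query_covered=q_cov, classification=cls)


@dataclass
class ErrorDecomposition:
    n_insertion: int
    n_deletion: int
    n_substitution: int
    mode: str = "bases"

    @property
    def total(self) -> int:
        return self.n_insertion + self.n_deletion + self.n_substitution

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(insertion, deletion, substitution) fractions; zeros when no
        errors were observed."""
        if not self.defined:
            return (0.0, 0.0, 0.0)
        t = self.total
        return (self.n_insertion / t, self.n_deletion / t, self.n_substitution / t)


def classify_errors(reports: Sequence[AlignmentReport],
                    mode: str = "bases") -> ErrorDecomposition:
    """Decompose total error into insertion / deletion / substitution.

    'bases' counts indel bases, 'events' counts indel runs; substitutions
    are single-nucleotide differences either way.
    """
    if not reports:
        raise ParameterError("classify_errors requires at least one report")
    if mode not in ("bases", "events"):
        raise ParameterError("mode must be 'bases' or 'events'")
    if mode == "bases":
        ins = sum(r.n_insertion_bases for r in reports)
        dele = sum(r.n_deletion_bases for r in reports)
    else:
        ins = sum(r.n_insertion_events for r in reports)
        dele = sum(r.n_deletion_events for r in reports)
    sub = sum(r.n_mismatch for r in reports)
    return ErrorDecomposition(ins, dele, sub, mode)


def bootstrap_experiment(ccs_clusters: Mapping[str, Sequence[str]],
                         raw_by_molecule: Mapping[str, RawRead],
                         reference: ReferenceSet,
                         depths: Sequence[int] = tuple(range(1, 41)),
                         replicates: int = 25,
                         seed: int = 0,
                         trim_bp: int = 0,
                         min_overlap: int = 40,
                         min_identity: float = 0.94,
                         max_iters: int = 5,
                         aligner: Optional[Align.PairwiseAligner] = None
                         ) -> list[BootstrapResult]:
    """Depth-resampling experiment over per-amplicon CCS clusters.

    ccs_clusters maps amplicon_id -> molecule ids of its CCS reads.  For
    each depth d and replicate, d molecule ids are drawn with replacement
    per amplicon (a molecule drawn twice contributes its subreads twice),
    the cluster is polished with the support filter at 0, the replicate's
    consensus set is assembled, and everything is aligned to the
    reference.  Deterministic for a fixed seed.
    """
    amplicons = sorted(a for a in ccs_clusters if ccs_clusters[a])
    skipped = sorted(set(ccs_clusters) - set(amplicons))
    if skipped:
        import warnings
        warnings.warn(f"amplicons with zero CCS reads skipped: {skipped}")
    if not amplicons:
        raise ParameterError("no amplicon has CCS reads")
    if aligner is None:
        aligner = _make_aligner()
    rng = np.random.default_rng(seed)
    results: list[BootstrapResult] = []
    for d in depths:
        for rep in range(1, replicates + 1):
            records: list[ConsensusRecord] = []
            depth_by_name: dict[str, tuple[str, int]] = {}
            for amp in amplicons:
                pool = list(ccs_clusters[amp])
                picks = [pool[i] for i in rng.integers(0, len(pool), size=d)]
                subreads = [sr.sequence for m in picks
                            for sr in raw_by_molecule[m].subreads]
                seq, _iters = polish_cluster_with_stats(subreads, max_iters)
                rec = ConsensusRecord((None, amp), seq, len(set(picks)),
                                      len(subreads), "emitted")
                records.append(rec)
                depth_by_name[rec.name] = (amp, len(subreads))
            assembly = assemble_sample(records, trim_bp=trim_bp,
                                       min_overlap=min_overlap,
                                       min_identity=min_identity)
            contig_of: dict[str, tuple[AlignmentReport, int]] = {}
            for contig in assembly.contigs:
                rep_aln = align_and_report(contig.sequence, reference,
                                           query_id=contig.contig_id, aligner=aligner)
                min_depth = min(depth_by_name[m][1] for m, _, _ in contig.members)
                for m, _, _ in contig.members:
                    contig_of[m] = (rep_aln, min_depth)
            for rec in records:
                amp, n_sub = depth_by_name[rec.name]
                cons_rep = align_and_report(rec.sequence, reference,
                                            query_id=rec.name, aligner=aligner)
                asm = contig_of.get(rec.name)
                results.append(BootstrapResult(
                    amplicon_id=amp, ccs_sample_size=d, replicate=rep,
                    n_subreads=n_sub, consensus_report=cons_rep,
                    assembly_report=asm[0] if asm else None,
                    assembly_n_subreads=asm[1] if asm else None))
    return results


def summarize_depth_accuracy(results: Sequence[BootstrapResult]) -> pd.DataFrame:
    """Per-depth accuracy table: mean/min/max consensus and assembly
    percent identity plus the count of perfectly accurate assemblies."""
    if not results:
        raise ParameterError("summarize_depth_accuracy requires at least one result")
    rows = []
    by_depth: dict[int, list[BootstrapResult]] = {}
    for r in results:
        by_depth.setdefault(r.ccs_sample_size, []).append(r)
    for d in sorted(by_depth):
        group = by_depth[d]
        cons = [r.consensus_report.percent_identity for r in group]
        asm = [r.assembly_report.percent_identity for r in group
               if r.assembly_report is not None]
        perfect = {(r.replicate, r.assembly_report.query_id)
                   for r in group
                   if r.assembly_report is not None
                   and r.assembly_report.percent_identity == 100.0}
        rows.append({
            "ccs_sample_size": d,
            "n_consensus": len(cons),
            "consensus_mean_pid": float(np.mean(cons)),
            "consensus_min_pid": float(np.min(cons)),
            "consensus_max_pid": float(np.max(cons)),
            "n_assemblies": len({(r.replicate, r.assembly_report.query_id)
                                 for r in group if r.assembly_report is not None}),
            "assembly_mean_pid": float(np.mean(asm)) if asm else float("nan"),
            "assembly_min_pid": float(np.min(asm)) if asm else float("nan"),
            "assembly_max_pid": float(np.max(asm)) if asm else float("nan"),
            "n_perfect_assemblies": len(perfect),
        })
    return pd.DataFrame(rows)
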