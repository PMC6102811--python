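"""Per-cluster consensus polishing of whitelisted raw subreads.

Deterministic iterative majority polishing stands in for an HMM-based
polisher: all subreads of a cluster are oriented against the current
template (initially the longest subread), pairwise-aligned to it, and a
per-column majority — including insertion and deletion columns — yields
the next template, iterating to a fixpoint.  Clusters supported by fewer
than ``min_subreads`` subreads (default 100) are filtered rather than
emitted; accuracy evaluation lowers that threshold to 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import edlib

from amptile.ccs import call_column, parse_cigar
from amptile.errors import ParameterError
from amptile.panel import PrimerPanel
from amptile.sequtil import revcomp
from amptile.simulate import RawRead

ClusterId = tuple[Optional[str], str]

DEFAULT_MIN_SUBREADS = 100


@dataclass
class ConsensusRecord:
    cluster_id: ClusterId
    sequence: Optional[str]
    n_molecules: int
    n_subreads: int
    status: str  # "emitted" | "filtered_low_support"
    iterations: int = 0

    @property
    def name(self) -> str:
        sample, amplicon = self.cluster_id
        return f"{sample if sample is not None else 'nobc'}__{amplicon}__nsub{self.n_subreads}"


def _align(query: str, template: str, task: str = "distance"):
    """Edit-distance alignment with a distance bound for speed; falls
    back to unbounded when the bound is exceeded."""
    k = max(100, int(0.45 * max(len(query), len(template))))
    res = edlib.align(query, template, mode="NW", task=task, k=k)
    if res["editDistance"] == -1:
        res = edlib.align(query, template, mode="NW", task=task)
    return res


def _orient_to(seq: str, template: str) -> str:
    rc = revcomp(seq)
    return seq if _align(seq, template)["editDistance"] <= _align(rc, template)["editDistance"] else rc


def _polish_round(template: str, subreads: Sequence[str]) -> str:
    """One voting round over the star alignment of all subreads to the
    template: per-template-column base/gap majorities, and insertion
    columns between template positions.  Insertion strings are voted
    column-wise (reads without an insertion vote gap), so a consensus
    insertion needs the non-gap votes to deny the gap a strict majority
    — the same rule as any other column."""
    S = len(template)
    n = len(subreads)
    base_votes: list[Counter] = [Counter() for _ in range(S)]
    ins_strings: list[dict[int, str]] = [dict() for _ in range(S + 1)]

    for ridx, read in enumerate(subreads):
        read = _orient_to(read, template)
        if read == template:
            for t, b in enumerate(template):
                base_votes[t][b] += 1
            continue
        res = _align(read, template, task="path")
        t = q = 0
        for length, op in parse_cigar(res["cigar"]):
            if op in "=X":
                for _ in range(length):
                    base_votes[t][read[q]] += 1
                    t += 1
                    q += 1
            elif op == "I":
                ins_strings[t][ridx] = ins_strings[t].get(ridx, "") + read[q:q + length]
                q += length
            else:  # 'D'
                for _ in range(length):
                    base_votes[t]["-"] += 1
                    t += 1

    out: list[str] = []
    for t in range(S + 1):
        if ins_strings[t]:
            width = max(len(s) for s in ins_strings[t].values())
            for c in range(width):
                col = Counter()
                n_ins = 0
                for s in ins_strings[t].values():
                    if c < len(s):
                        col[s[c]] += 1
                        n_ins += 1
                col["-"] += n - n_ins
                sym = call_column(col, n)
                if sym != "-":
                    out.append(sym)
        if t < S:
            sym = call_column(base_votes[t], n, prefer=template[t])
            if sym != "-":
                out.append(sym)
    return "".join(out)


def polish_cluster_with_stats(subreads: Sequence[str], max_iters: int = 5
                              ) -> tuple[str, int]:
    """Iterative majority polish; returns (consensus, rounds used).
    The fixpoint is zero edits between successive templates."""
    if not subreads:
        raise ParameterError("polish_cluster requires at least one subread")
    template = max(subreads, key=len)  # ties: max() keeps the first
    iters = 0
    for _ in range(max_iters):
        iters += 1
        new = _polish_round(template, subreads)
        if new == template:
            break
        template = new
    return template, iters


def polish_cluster(subreads: Sequence[str], max_iters: int = 5) -> str:
    """Deterministic iterative majority consensus of one cluster."""
    return polish_cluster_with_stats(subreads, max_iters)[0]


def consensus_all(whitelists: Mapping[ClusterId, Sequence[str]],
                  subread_source: Mapping[str, RawRead],
                  min_subreads: int = DEFAULT_MIN_SUBREADS,
                  min_subread_length: int = 0,
                  panel: Optional[PrimerPanel] = None,
                  max_iters: int = 5) -> list[ConsensusRecord]:
    """Polish every cluster; clusters with fewer than ``min_subreads``
    whitelisted subreads are filtered (no sequence).  When a panel is
    given, emitted consensus sequences are oriented to the forward-primer
    sense of their panel entry."""
    entry_by_cluster = {e.cluster_id: e for e in panel} if panel is not None else {}
    missing = [m for mols in whitelists.values() for m in mols if m not in subread_source]
    if missing:
        raise LookupError(f"whitelisted molecules missing from subread source: "
                          f"{sorted(set(missing))[:10]}{'...' if len(set(missing)) > 10 else ''}")

    records = []
    for cid in sorted(whitelists, key=lambda c: (c[0] or "", c[1])):
        mols = whitelists[cid]
        seqs: list[str] = []
        for m in mols:
            for sr in subread_source[m].subreads:
                if len(sr.sequence) >= min_subread_length:
                    seqs.append(sr.sequence)
        if not mols or len(seqs) < min_subreads or not seqs:
            records.append(ConsensusRecord(cid, None, len(mols), len(seqs),
                                           "filtered_low_support"))
            continue
        seq, iters = polish_cluster_with_stats(seqs, max_iters)
        entry = entry_by_cluster.get(cid)
        if entry is not None:
            probe = entry.composite_fwd()
            d_f = edlib.align(probe, seq, mode="HW")["editDistance"]
            d_r = edlib.align(probe, revcomp(seq), mode="HW")["editDistance"]
            if d_r < d_f:
                seq = revcomp(seq)
        records.append(ConsensusRecord(cid, seq, len(mols), len(seqs),
                                       "emitted", iters))
    return records
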