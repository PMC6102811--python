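"""Per-molecule circular consensus sequences (CCS) from subreads.

A desk-scale reads-of-insert stand-in: subreads are oriented against the
longest pass, star-aligned to it, and a per-column majority is called.
The predicted accuracy is the mean per-column agreement with the called
consensus; with the permissive defaults (minimum 1 pass at 0.90
predicted accuracy) even single-pass molecules are emitted, which by the
column definition always have accuracy 1.0.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Union

import edlib

from amptile.errors import ParameterError
from amptile.sequtil import revcomp
from amptile.simulate import RawRead

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# deterministic tie order for column majorities; gap sorts last and only
# wins on strict majority
_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


@dataclass(frozen=True)
class CCSRead:
    molecule_id: str
    sequence: str
    n_passes: int
    predicted_accuracy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.predicted_accuracy <= 1.0):
            raise ParameterError("predicted_accuracy outside [0, 1]")


@dataclass(frozen=True)
class CCSRejection:
    molecule_id: str
    n_passes: int
    predicted_accuracy: float
    reason: str  # "too_few_passes" | "low_predicted_accuracy"


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def orient_subreads(raw: RawRead) -> list[str]:
    """Return every subread in the orientation closer (by edit distance)
    to the seed subread (the longest; ties -> first in order)."""
    seqs = [sr.sequence for sr in raw.subreads]
    seed_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    seed = seqs[seed_idx]
    out = []
    for i, s in enumerate(seqs):
        if i == seed_idx:
            out.append(s)
            continue
        rc = revcomp(s)
        out.append(s if _edit_distance(s, seed) <= _edit_distance(rc, seed) else rc)
    return out


def _star_columns(oriented: list[str], seed: str) -> list[Counter]:
    """Star alignment of every read against the seed; returns the MSA as
    a list of per-column symbol Counters (reads vote 'A'...'T' or '-')."""
    S = len(seed)
    n = len(oriented)
    match_votes: list[Counter] = [Counter() for _ in range(S)]
    ins_strings: list[dict[int, str]] = [dict() for _ in range(S + 1)]

    for ridx, read in enumerate(oriented):
        if read == seed:
            for t, base in enumerate(seed):
                match_votes[t][base] += 1
            continue
        res = edlib.align(read, seed, mode="NW", task="path")
        t = q = 0
        for length, op in parse_cigar(res["cigar"]):
            if op in "=X":
                for _ in range(length):
                    match_votes[t][read[q]] += 1
                    t += 1
                    q += 1
            elif op == "I":  # extra bases in the read
                ins_strings[t][ridx] = ins_strings[t].get(ridx, "") + read[q:q + length]
                q += length
            else:  # 'D': seed base missing from the read
                for _ in range(length):
                    match_votes[t]["-"] += 1
                    t += 1
        assert t == S and q == len(read)

    columns: list[Counter] = []
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
                columns.append(col)
        if t < S:
            columns.append(match_votes[t])
    return columns


def call_column(col: Counter, n: int, prefer: str | None = None) -> str:
    """Majority symbol of a column of n voters.  The gap wins only on a
    strict majority; base ties prefer ``prefer`` when it is among the
    tied leaders, then fixed order A<C<G<T."""
    gap = col.get("-", 0)
    if gap * 2 > n:
        return "-"
    base_counts = [(b, c) for b, c in col.items() if b != "-"]
    if not base_counts:
        return "-"
    top = max(c for _, c in base_counts)
    leaders = sorted((b for b, c in base_counts if c == top), key=_BASE_ORDER.get)
    if prefer is not None and prefer in leaders:
        return prefer
    return leaders[0]


def _predicted_accuracy(agreement: float, n: int) -> float:
    """Predicted accuracy of the consensus, not of a single pass.

    The per-pass, per-column error rate is estimated from the observed
    column agreement (eps = 1 - agreement); a consensus column is wrong
    when errors form a strict majority of its n voters, so the predicted
    per-column consensus accuracy is P[Binomial(n, eps) <= n//2].  For a
    single pass eps is 0 by construction and the accuracy is 1.0, so the
    90 % filter never rejects single-pass molecules.
    """
    from math import comb

    eps = min(max(1.0 - agreement, 0.0), 0.75)
    return sum(comb(n, j) * eps**j * (1 - eps)**(n - j) for j in range(n // 2 + 1))


def build_ccs(raw: RawRead, min_passes: int = 1,
              min_predicted_accuracy: float = 0.90,
              max_iters: int = 5) -> Union[CCSRead, CCSRejection]:
    """Call the per-molecule consensus; reject molecules with too few
    passes or low predicted accuracy.

    The star alignment is iterated: the majority consensus of one round
    becomes the next round's alignment template, until the consensus is
    stable (a fixpoint) or max_iters rounds.  Subreads are the only
    voters in every round.
    """
    if not raw.subreads:
        raise ParameterError("raw read has no subreads")
    n = raw.n_passes
    if n < min_passes:
        return CCSRejection(raw.molecule_id, n, 0.0, "too_few_passes")

    oriented = orient_subreads(raw)
    seed_idx = max(range(len(oriented)), key=lambda i: (len(oriented[i]), -i))
    template = oriented[seed_idx]
    columns: list[Counter] = []
    consensus = template
    for _ in range(max_iters):
        columns = _star_columns(oriented, template)
        consensus = "".join(sym for sym in (call_column(c, n) for c in columns)
                            if sym != "-")
        if consensus == template:
            break
        template = consensus

    agree_sum = sum(c.get(call_column(c, n), 0) / n for c in columns)
    agreement = agree_sum / len(columns) if columns else 1.0
    accuracy = _predicted_accuracy(agreement, n)
    consensus_chars = consensus

    if accuracy < min_predicted_accuracy:
        return CCSRejection(raw.molecule_id, n, accuracy, "low_predicted_accuracy")
    return CCSRead(raw.molecule_id, "".join(consensus_chars), n, accuracy)


def build_ccs_batch(raw_reads, min_passes: int = 1,
                    min_predicted_accuracy: float = 0.90
                    ) -> tuple[list[CCSRead], list[CCSRejection]]:
    emitted, rejected = [], []
    for rr in raw_reads:
        res = build_ccs(rr, min_passes, min_predicted_accuracy)
        (emitted if isinstance(res, CCSRead) else rejected).append(res)
    return emitted, rejected
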