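"""Overlap-layout-consensus assembly of tiled amplicon consensus sequences.

Per sample, trimmed consensus sequences are joined along suffix-prefix
(dovetail) overlaps.  The assembly consensus follows explicit conflict
rules: a column seen by a single member takes its base; two agreeing
members take the base; two disagreeing members produce an N; with three
or more members the most frequent base is taken (ties -> N).  Ns
therefore mark exactly the two-voter disagreements and multi-voter ties.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import edlib

from amptile.consensus import ConsensusRecord
from amptile.errors import AssemblyError, ParameterError
from amptile.io import write_fasta, write_tsv
from amptile.sequtil import revcomp

DEFAULT_MIN_OVERLAP = 40
DEFAULT_MIN_IDENTITY = 0.94
OFFSET_TOLERANCE = 20  # bp of slack between redundant layout edges


def trim_ends(seq: str, trim_bp: int) -> str:
    """Remove trim_bp bases from each end (barcode/padding removal)."""
    if trim_bp < 0:
        raise ParameterError("trim_bp must be >= 0")
    if 2 * trim_bp >= len(seq):
        raise ParameterError(f"trim_bp={trim_bp} over-trims a {len(seq)} bp sequence")
    return seq[trim_bp:len(seq) - trim_bp] if trim_bp else seq


@dataclass(frozen=True)
class Overlap:
    """Dovetail: the suffix of ``left`` (forward strand) overlaps the
    prefix of ``right`` (reverse-complemented when right_rc)."""

    left: str
    right: str
    right_rc: bool
    offset: int        # start of right, in left's coordinates
    overlap_len: int
    identity: float


@dataclass
class OverlapGraph:
    seqs: dict[str, str]
    edges: list[Overlap] = field(default_factory=list)


@dataclass
class Contig:
    contig_id: str
    sequence: str
    members: list[tuple[str, int, str]]            # (member_id, first column, '+'/'-')
    n_positions: list[tuple[int, dict]] = field(default_factory=list)
    columns: list[dict] = field(default_factory=list)  # per-column member votes


@dataclass
class TiledAssembly:
    sample_id: Optional[str]
    contigs: list[Contig] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)


def _dovetail(left_seq: str, right_seq: str, min_overlap: int,
              min_identity: float) -> Optional[tuple[int, int, float]]:
    """Best suffix(left)-prefix(right) overlap, or None.
    Returns (offset_in_left, overlap_len, identity)."""
    max_ov = min(len(left_seq), len(right_seq))
    if max_ov < min_overlap:
        return None
    probe = right_seq[:min_overlap]
    k_probe = int((1 - min_identity) * 2 * len(probe)) + 2
    tail_len = min(len(left_seq), max_ov + 4 * k_probe)
    tail = left_seq[-tail_len:]
    hit = edlib.align(probe, tail, mode="HW", k=k_probe, task="locations")
    if hit["editDistance"] == -1 or not hit["locations"]:
        return None
    s = hit["locations"][0][0]
    pos = len(left_seq) - tail_len + s
    left_part = left_seq[pos:]
    k_full = int((1 - min_identity) * 2 * len(left_part)) + 4
    res = edlib.align(left_part, right_seq, mode="SHW", k=k_full, task="locations")
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    dist = res["editDistance"]
    right_len = res["locations"][0][1] + 1
    cols = max(len(left_part), right_len)
    identity = 1.0 - dist / cols
    if cols < min_overlap or identity < min_identity:
        return None
    return pos, cols, identity


def find_overlaps(seqs: Mapping[str, str], min_overlap: int = DEFAULT_MIN_OVERLAP,
                  min_identity: float = DEFAULT_MIN_IDENTITY) -> OverlapGraph:
    """All dovetail overlaps between sequences, either orientation.

    Arrangements are normalized so the left member is on its forward
    strand (a global reverse complement maps the remaining cases onto
    these).  At most one edge (the highest-identity, longest one) is
    kept per unordered pair.
    """
    if not seqs:
        raise ParameterError("find_overlaps requires at least one sequence")
    ids = list(seqs)
    best: dict[frozenset, Overlap] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            candidates = []
            for left, right in ((a, b), (b, a)):
                for right_rc in (False, True):
                    rseq = revcomp(seqs[right]) if right_rc else seqs[right]
                    hit = _dovetail(seqs[left], rseq, min_overlap, min_identity)
                    if hit is not None:
                        pos, cols, ident = hit
                        candidates.append(Overlap(left, right, right_rc, pos, cols, ident))
            if candidates:
                best[frozenset((a, b))] = max(
                    candidates, key=lambda o: (o.identity, o.overlap_len))
    return OverlapGraph(dict(seqs), list(best.values()))


def _place_neighbors(graph: OverlapGraph, placed: dict[str, tuple[int, str]]) -> None:
    """BFS placement over the overlap graph; raises on contradictions."""
    seqs = graph.seqs
    changed = True
    while changed:
        changed = False
        for e in graph.edges:
            l_len, r_len = len(seqs[e.left]), len(seqs[e.right])
            r_orient = "-" if e.right_rc else "+"
            if e.left in placed:
                off, orient = placed[e.left]
                if orient == "+":
                    cand = (off + e.offset, r_orient)
                else:
                    cand = (off + l_len - e.offset - r_len,
                            "-" if r_orient == "+" else "+")
                target = e.right
            elif e.right in placed:
                off, orient = placed[e.right]
                if orient == r_orient:
                    cand = (off - e.offset, "+")
                else:
                    cand = (off + e.offset + r_len - l_len, "-")
                target = e.left
            else:
                continue
            if target in placed:
                old = placed[target]
                if old[1] != cand[1] or abs(old[0] - cand[0]) > OFFSET_TOLERANCE:
                    raise AssemblyError(
                        f"inconsistent layout for {target}: {old} vs {cand}")
            else:
                placed[target] = cand
                changed = True


def _merge_member(cols: list[dict], member_id: str, seq: str,
                  approx_offset: int, min_overlap: int) -> list[dict]:
    """Merge one member into the running column list by aligning its
    prefix to the working consensus suffix at the expected offset."""
    working = [(i, _working_symbol(c)) for i, c in enumerate(cols)]
    working = [(i, s) for i, s in working if s != "-"]
    cur = "".join(s for _, s in working)
    colmap = [i for i, _ in working]

    if approx_offset >= len(cur):  # gap in the tiling: abut with no overlap
        cols.extend({member_id: b} for b in seq)
        return cols
    ov_start = max(0, approx_offset)
    # refine the junction with a probe alignment around the expected start
    probe = seq[:min(len(seq), max(min_overlap, 32))]
    lo = max(0, ov_start - 200)
    hi = min(len(cur), ov_start + 200 + len(probe))
    hit = edlib.align(probe, cur[lo:hi], mode="HW", task="locations")
    if hit["editDistance"] != -1 and hit["locations"]:
        ov_start = lo + hit["locations"][0][0]

    suffix = cur[ov_start:]
    res = edlib.align(suffix, seq, mode="SHW", task="path")
    ci = ov_start  # index into `cur`
    q = 0
    from amptile.ccs import parse_cigar
    new_cols = cols
    inserts: list[tuple[int, str]] = []  # (position in cols, base) for member-only bases
    for length, op in parse_cigar(res["cigar"]):
        if op in "=X":
            for _ in range(length):
                new_cols[colmap[ci]][member_id] = seq[q]
                ci += 1
                q += 1
        elif op == "I":  # base in consensus, absent from member
            for _ in range(length):
                new_cols[colmap[ci]][member_id] = "-"
                ci += 1
        else:  # 'D': extra base in member -> new column
            for _ in range(length):
                inserts.append((colmap[ci] if ci < len(colmap) else len(new_cols), seq[q]))
                q += 1
    for pos, base in reversed(inserts):
        covering = set(new_cols[pos - 1] if pos > 0 else {}) & set(new_cols[pos] if pos < len(new_cols) else {})
        col = {m: "-" for m in covering if m != member_id}
        col[member_id] = base
        new_cols.insert(pos, col)
    new_cols.extend({member_id: b} for b in seq[q:])
    return new_cols


def _working_symbol(col: dict) -> str:
    """Plain majority used while building the layout (no Ns): earlier
    members break ties, gap needs a strict majority to win."""
    counter = Counter(col.values())
    n = len(col)
    if counter.get("-", 0) * 2 > n:
        return "-"
    for sym in col.values():  # insertion order = member placement order
        if sym != "-" and counter[sym] == max(c for s, c in counter.items() if s != "-"):
            return sym
    return "-"


def final_symbol(col: dict) -> str:
    """The conflict rules: 1 voter -> its base; 2 voters agree -> base,
    disagree -> N; >=3 voters -> strict plurality base, tie -> N; a gap
    majority drops the column."""
    votes = list(col.values())
    n = len(votes)
    counter = Counter(votes)
    if n == 1:
        return votes[0] if votes[0] != "-" else ""
    if n == 2:
        return votes[0] if votes[0] == votes[1] else "N"
    if counter.get("-", 0) * 2 > n:
        return ""
    bases = {s: c for s, c in counter.items() if s != "-"}
    top = max(bases.values())
    leaders = [s for s, c in bases.items() if c == top]
    if len(leaders) > 1 or counter.get("-", 0) == top:
        return "N"
    return leaders[0]


def layout_consensus(graph: OverlapGraph, sample_id: Optional[str] = None,
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> TiledAssembly:
    """Lay members out along the overlap graph and call the per-column
    assembly consensus with the N/majority conflict rules."""
    seqs = graph.seqs
    adjacency: dict[str, set[str]] = {s: set() for s in seqs}
    for e in graph.edges:
        adjacency[e.left].add(e.right)
        adjacency[e.right].add(e.left)

    assembly = TiledAssembly(sample_id)
    visited: set[str] = set()
    k = 0
    for start in sorted(seqs, key=lambda s: (-len(seqs[s]), s)):
        if start in visited:
            continue
        component = _component(start, adjacency)
        visited |= component
        if len(component) == 1 and not adjacency[start]:
            assembly.singletons.append(start)
            continue
        k += 1
        placed: dict[str, tuple[int, str]] = {start: (0, "+")}
        sub = OverlapGraph(seqs, [e for e in graph.edges
                                  if e.left in component and e.right in component])
        _place_neighbors(sub, placed)
        if set(placed) != component:
            raise AssemblyError(f"could not place members: {sorted(component - set(placed))}")
        base = min(off for off, _ in placed.values())
        ordered = sorted(placed, key=lambda m: (placed[m][0], m))
        cols: list[dict] = []
        members_out = []
        for m in ordered:
            off, orient = placed[m]
            oriented = revcomp(seqs[m]) if orient == "-" else seqs[m]
            cols = _merge_member(cols, m, oriented, off - base, min_overlap)
            members_out.append((m, off - base, orient))
        seq_chars = []
        n_positions = []
        for col in cols:
            sym = final_symbol(col)
            if not sym:
                continue
            if sym == "N":
                n_positions.append((len(seq_chars), dict(col)))
            seq_chars.append(sym)
        assembly.contigs.append(Contig(
            contig_id=f"{sample_id if sample_id is not None else 'nobc'}__contig{k}",
            sequence="".join(seq_chars),
            members=members_out,
            n_positions=n_positions,
            columns=cols,
        ))
    return assembly


def _component(start: str, adjacency: dict[str, set[str]]) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def assemble_sample(records: Sequence[ConsensusRecord], trim_bp: int = 0,
                    min_overlap: int = DEFAULT_MIN_OVERLAP,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    sample_id: Optional[str] = None,
                    out_dir: Optional[str | Path] = None) -> TiledAssembly:
    """Trim and assemble one sample's emitted consensus sequences.

    Writes the merged pre-assembly multi-FASTA, the assembly FASTA, a
    layout TSV and an N-position BED when out_dir is given.
    """
    emitted = [r for r in records if r.status == "emitted"
               and (sample_id is None or r.cluster_id[0] == sample_id)]
    seqs = {r.name: trim_ends(r.sequence, trim_bp) for r in emitted}
    if not seqs:
        return TiledAssembly(sample_id)
    graph = find_overlaps(seqs, min_overlap, min_identity)
    assembly = layout_consensus(graph, sample_id=sample_id, min_overlap=min_overlap)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = sample_id if sample_id is not None else "nobc"
        write_fasta(seqs, out_dir / f"{tag}.merged.fasta")
        write_fasta({c.contig_id: c.sequence for c in assembly.contigs},
                    out_dir / f"{tag}.assembly.fasta")
        rows = [{"member": m, "contig": c.contig_id, "offset": off, "orientation": o}
                for c in assembly.contigs for m, off, o in c.members]
        rows += [{"member": s, "contig": "", "offset": 0, "orientation": "+"}
                 for s in assembly.singletons]
        write_tsv(rows, out_dir / f"{tag}.layout.tsv",
                  ["member", "contig", "offset", "orientation"])
        with open(out_dir / f"{tag}.n_positions.bed", "w") as fh:
            for c in assembly.contigs:
                for pos, _votes in c.n_positions:
                    fh.write(f"{c.contig_id}\t{pos}\t{pos + 1}\n")
    return assembly
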