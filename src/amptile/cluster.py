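"""CCS-based clustering of raw reads by primer (and barcode) matching.

The central idea of the pipeline: instead of clustering noisy raw reads
by pairwise similarity, each molecule's high-quality CCS is searched for
the expected forward and reverse primer sequences (barcode+primer
composites in two-level mode) inside fixed-size windows at the two read
ends.  Molecules matching exactly one panel entry are whitelisted for
per-cluster polishing; everything else is set aside with a reason.

The match function is deliberately simple: an exact substring test of
both primers, in both read orientations, within the end windows.  The
default window is 21 bases for one-level clustering and 121 bases when
barcodes (and padding) precede the primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from amptile.ccs import CCSRead
from amptile.errors import ParameterError
from amptile.io import write_tsv
from amptile.panel import PanelEntry, PrimerPanel
from amptile.sequtil import revcomp

SEARCH_SPACE_ONE_LEVEL = 21
SEARCH_SPACE_TWO_LEVEL = 121

ClusterId = tuple[Optional[str], str]


@dataclass
class ClusterMap:
    """Partition of molecules into (sample, amplicon) clusters plus the
    unassigned remainder with per-molecule reasons."""

    assignments: list[tuple[str, Optional[str], str, str]] = field(default_factory=list)
    unassigned: list[tuple[str, str]] = field(default_factory=list)  # (molecule_id, reason)

    def clusters(self) -> dict[ClusterId, list[str]]:
        out: dict[ClusterId, list[str]] = {}
        for mol, sample, amplicon, _orient in self.assignments:
            out.setdefault((sample, amplicon), []).append(mol)
        return out

    @property
    def n_molecules(self) -> int:
        return len(self.assignments) + len(self.unassigned)

    def check_partition(self) -> None:
        ids = [a[0] for a in self.assignments] + [u[0] for u in self.unassigned]
        if len(set(ids)) != len(ids):
            raise ParameterError("molecule assigned more than once")


def _window_contains(seq: str, probe: str, start: int, end: int,
                     max_mismatch: int) -> bool:
    """Is ``probe`` fully contained in seq[start:end]?  Exact substring
    by default; with max_mismatch > 0 a Hamming scan over the window."""
    if max_mismatch <= 0:
        return seq.find(probe, start, end) >= 0
    end = min(end, len(seq))
    m = len(probe)
    for off in range(start, end - m + 1):
        mism = 0
        for a, b in zip(probe, seq[off:off + m]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return True
    return False


def match_primer_pair(ccs_seq: str, fwd: str, rev: str, search_space: int,
                      max_mismatch: int = 0) -> Optional[str]:
    """Orientation of a CCS read carrying both primers of one amplicon.

    'sense' when fwd occurs within the first ``search_space`` bases and
    revcomp(rev) within the last; 'antisense' when the reverse-complement
    of the read satisfies the same; None otherwise.  Both primers must be
    found.  Sense is tested first (deterministic tie rule).
    """
    if search_space < max(len(fwd), len(rev)):
        raise ParameterError("search_space smaller than a primer length")
    n = len(ccs_seq)
    rc_rev = revcomp(rev)
    if (_window_contains(ccs_seq, fwd, 0, search_space, max_mismatch)
            and _window_contains(ccs_seq, rc_rev, max(0, n - search_space), n, max_mismatch)):
        return "sense"
    rc = revcomp(ccs_seq)
    if (_window_contains(rc, fwd, 0, search_space, max_mismatch)
            and _window_contains(rc, rc_rev, max(0, n - search_space), n, max_mismatch)):
        return "antisense"
    return None


def cluster_ccs(ccs_reads: Iterable[CCSRead], panel: PrimerPanel,
                search_space: Optional[int] = None, two_level: bool = False,
                include_padding: bool = True, max_mismatch: int = 0) -> ClusterMap:
    """Assign each CCS read to the unique panel entry whose primer pair
    (or barcode+primer composite pair) it contains.

    One-level mode matches the bare primers; two-level mode matches
    barcode+primer composites (padding outermost when included).  Reads
    matching no entry or more than one entry are left unassigned with
    reasons 'no_match' / 'ambiguous'.
    """
    entries = list(panel)
    if not entries:
        raise ParameterError("empty panel")
    if two_level and not panel.barcoded:
        raise ParameterError("two_level clustering requires a barcoded panel")
    if not two_level and panel.barcoded:
        raise ParameterError("barcoded panel requires two_level clustering")
    if search_space is None:
        search_space = SEARCH_SPACE_TWO_LEVEL if two_level else SEARCH_SPACE_ONE_LEVEL

    probes: list[tuple[PanelEntry, str, str]] = []
    for e in entries:
        if two_level:
            probes.append((e, e.composite_fwd(include_padding), e.composite_rev(include_padding)))
        else:
            probes.append((e, e.fwd_primer, e.rev_primer))

    cmap = ClusterMap()
    for ccs in ccs_reads:
        hits = []
        for e, fwd, rev in probes:
            orient = match_primer_pair(ccs.sequence, fwd, rev, search_space, max_mismatch)
            if orient is not None:
                hits.append((e, orient))
        if len(hits) == 1:
            e, orient = hits[0]
            cmap.assignments.append((ccs.molecule_id, e.sample_id, e.amplicon_id, orient))
        elif not hits:
            cmap.unassigned.append((ccs.molecule_id, "no_match"))
        else:
            cmap.unassigned.append((ccs.molecule_id, "ambiguous"))
    cmap.check_partition()
    return cmap


def cluster_file_name(cluster_id: ClusterId) -> str:
    sample, amplicon = cluster_id
    return f"{sample if sample is not None else 'nobc'}__{amplicon}"


def write_whitelists(cmap: ClusterMap, out_dir: str | Path,
                     subread_counts: Optional[dict[str, int]] = None) -> dict[ClusterId, Path]:
    """One molecule-id-per-line whitelist file per non-empty cluster,
    plus a summary TSV with per-cluster molecule and subread counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[ClusterId, Path] = {}
    rows = []
    for cid, mols in sorted(cmap.clusters().items(),
                            key=lambda kv: (kv[0][0] or "", kv[0][1])):
        if not mols:
            continue
        p = out_dir / f"{cluster_file_name(cid)}.whitelist.txt"
        p.write_text("".join(m + "\n" for m in mols))
        paths[cid] = p
        n_sub = sum(subread_counts.get(m, 0) for m in mols) if subread_counts else 0
        rows.append({"sample_id": cid[0] or "", "amplicon_id": cid[1],
                     "n_molecules": len(mols), "n_subreads": n_sub})
    write_tsv(rows, out_dir / "cluster_summary.tsv",
              ["sample_id", "amplicon_id", "n_molecules", "n_subreads"])
    write_tsv([{"molecule_id": m, "reason": r} for m, r in cmap.unassigned],
              out_dir / "unassigned.tsv", ["molecule_id", "reason"])
    return paths
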