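"""Synthetic SMRT amplicon libraries with ground truth.

The generator emulates the structure of a multiplexed long-amplicon
SMRT run: a reference with planted homopolymer tracts, a tiling path of
overlapping amplicons, per-sample symmetric barcodes behind a shared 5'
padding, and raw reads made of several error-laden passes over the same
insert (alternating strand per pass).  Defaults reflect a typical RS II
amplicon library: 3.5-4.5 kb amplicons tiling a ~23 kb target with
200-400 bp overlaps, a mean of ~9.4 passes per molecule, and raw-read
error up to 20 % per base with an extra insertion propensity inside
homopolymer runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from amptile.errors import DesignError, ParameterError, PanelError
from amptile.panel import DEFAULT_PADDING, PanelEntry, PrimerPanel, SampleBarcode
from amptile.sequtil import check_dna, homopolymer_runs, revcomp, stable_hash

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

DEFAULT_MOVIE = "m00001_000000_000000"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Locus:
    locus_id: str
    sequence: str


@dataclass
class ReferenceSet:
    """A set of reference loci; ids follow 'locus_<chrom>_<start>_<end>'
    with 1-based inclusive coordinates in the id, 0-based half-open
    everywhere else.  ``spikes`` records planted homopolymer runs."""

    loci: list[Locus]
    spikes: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ParameterError("locus_ids must be unique")
        for l in self.loci:
            check_dna(l.sequence, f"locus {l.locus_id}")

    def __getitem__(self, locus_id: str) -> str:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l.sequence
        raise KeyError(locus_id)

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for l in self.loci:
                fh.write(f">{l.locus_id}\n")
                for i in range(0, len(l.sequence), 80):
                    fh.write(l.sequence[i:i + 80] + "\n")
        return path

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        from Bio import SeqIO
        loci = [Locus(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(loci)


@dataclass(frozen=True)
class AmpliconDesign:
    """One amplicon of a tiling path; rev_primer is the oligo sequence
    (reverse-complement strand), so revcomp(rev_primer) is a suffix of
    the amplicon."""

    amplicon_id: str
    locus_id: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str

    def core(self, ref: ReferenceSet) -> str:
        return ref[self.locus_id][self.start:self.end]


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base corruption model for a single pass.

    sub/ins/del rates are independent per-base probabilities; insertions
    gain ``homopolymer_ins_rate`` extra probability inside runs of one
    base of length >= run_min (the inserted base then copies the run's
    base, mimicking the systematic homopolymer expansion seen in
    single-molecule data).  ``protect_ends`` bases at each end of the
    template are copied error-free (used to test clustering under clean
    end windows).
    """

    sub_rate: float = 0.10
    ins_rate: float = 0.05
    del_rate: float = 0.04
    homopolymer_ins_rate: float = 0.0
    run_min: int = 6
    protect_ends: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "homopolymer_ins_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate > 0.5:
            raise ParameterError("sub_rate + ins_rate + del_rate must be <= 0.5")
        if self.run_min < 2:
            raise ParameterError("run_min must be >= 2")
        if self.protect_ends < 0:
            raise ParameterError("protect_ends must be >= 0")


@dataclass(frozen=True)
class Subread:
    subread_id: str
    sequence: str
    orientation: str  # "sense" | "antisense"


@dataclass
class RawRead:
    """All passes of one molecule.  ``edit_logs[k]`` holds the truth
    edits applied to pass k as (template_pos, op, base) with op in
    {sub, ins, del}; positions are template coordinates."""

    molecule_id: str
    subreads: list[Subread]
    true_amplicon_id: Optional[str] = None
    true_sample_id: Optional[str] = None
    edit_logs: list[list[tuple[int, str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subreads:
            raise ParameterError("RawRead requires at least one subread")

    @property
    def n_passes(self) -> int:
        return len(self.subreads)


@dataclass
class LibraryBundle:
    """In-memory result of simulate_library plus any files written."""

    raw_reads: list[RawRead]
    panel: PrimerPanel
    templates: dict[tuple[Optional[str], str], str]
    reference: Optional[ReferenceSet] = None
    designs: Optional[list[AmpliconDesign]] = None
    paths: dict[str, Path] = field(default_factory=dict)

    def truth_rows(self) -> list[dict]:
        rows = []
        for r in self.raw_reads:
            key = (r.true_sample_id, r.true_amplicon_id)
            md5 = hashlib.md5(self.templates[key].encode()).hexdigest()
            rows.append({
                "molecule_id": r.molecule_id,
                "sample_id": r.true_sample_id or "",
                "amplicon_id": r.true_amplicon_id,
                "n_passes": r.n_passes,
                "template_md5": md5,
            })
        return rows


# ---------------------------------------------------------------------------
# reference and design generation


def make_reference(n_loci: int, locus_length: int, gc: float = 0.5,
                   homopolymer_spikes: int = 0, seed: int = 0) -> ReferenceSet:
    """Random reference loci with optional planted homopolymer runs.

    Each spike is a run of one base of length 8-12 at a recorded
    position; spikes are kept >= 100 bp apart and away from locus ends.
    """
    if n_loci < 1:
        raise ParameterError("n_loci must be >= 1")
    if locus_length < 200:
        raise ParameterError("locus_length must be >= 200")
    if not (0.0 < gc < 1.0):
        raise ParameterError("gc must be in (0, 1)")
    if homopolymer_spikes < 0:
        raise ParameterError("homopolymer_spikes must be >= 0")

    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    loci, spikes = [], {}
    for chrom in range(1, n_loci + 1):
        arr = rng.choice(_BASES, size=locus_length, p=probs)
        spans: list[tuple[int, int]] = []
        margin = 100
        attempts = 0
        while len(spans) < homopolymer_spikes:
            attempts += 1
            if attempts > 1000:
                raise DesignError(
                    f"cannot place {homopolymer_spikes} homopolymer spikes in a "
                    f"{locus_length} bp locus with 100 bp spacing")
            run_len = int(rng.integers(8, 13))
            pos = int(rng.integers(margin, locus_length - margin - run_len))
            if any(abs(pos - s) < 100 for s, _ in spans):
                continue
            base = _BASES[rng.integers(0, 4)]
            arr[pos:pos + run_len] = base
            # break up accidental extension of the run at its borders
            if pos > 0 and arr[pos - 1] == base:
                arr[pos - 1] = _BASES[(int(_BASE_INDEX[base]) + 1) % 4]
            endp = pos + run_len
            if endp < locus_length and arr[endp] == base:
                arr[endp] = _BASES[(int(_BASE_INDEX[base]) + 1) % 4]
            spans.append((pos, pos + run_len))
        start_1b = int(rng.integers(1_000_000, 50_000_000))
        locus_id = f"locus_{chrom}_{start_1b}_{start_1b + locus_length - 1}"
        loci.append(Locus(locus_id, arr.tobytes().decode("ascii")))
        spikes[locus_id] = sorted(spans)
    return ReferenceSet(loci, spikes)


def _partition_span(rng, n: int, length_range, overlap_range, total: int):
    """Choose n amplicon lengths and n-1 overlaps so that the tiling
    exactly spans ``total``; deterministic repair of a random draw."""
    lo_l, hi_l = length_range
    lo_o, hi_o = overlap_range
    lens = rng.integers(lo_l, hi_l + 1, size=n).astype(int)
    olaps = rng.integers(lo_o, hi_o + 1, size=max(n - 1, 0)).astype(int) if n > 1 else np.array([], dtype=int)
    diff = total - (int(lens.sum()) - int(olaps.sum()))
    # push the residue into lengths, then overlaps, one unit at a time
    guard = 0
    while diff != 0:
        guard += 1
        if guard > 10 * (n * (hi_l - lo_l + hi_o - lo_o) + 10):
            raise DesignError(
                f"tiling infeasible: {n} amplicons of {lo_l}-{hi_l} bp with "
                f"{lo_o}-{hi_o} bp overlaps cannot span {total} bp")
        moved = False
        step = 1 if diff > 0 else -1
        for i in range(n):
            if diff == 0:
                break
            if lo_l <= lens[i] + step <= hi_l:
                lens[i] += step
                diff -= step
                moved = True
        for i in range(len(olaps)):
            if diff == 0:
                break
            if lo_o <= olaps[i] - step <= hi_o:
                olaps[i] -= step
                diff -= step
                moved = True
        if not moved:
            raise DesignError(
                f"tiling infeasible: {n} amplicons of {lo_l}-{hi_l} bp with "
                f"{lo_o}-{hi_o} bp overlaps cannot span {total} bp")
    return [int(x) for x in lens], [int(x) for x in olaps]


def design_tiling(ref: ReferenceSet, n_amplicons: int,
                  amp_len: tuple[int, int] = (3500, 4500),
                  overlap: tuple[int, int] = (200, 400),
                  primer_len: int = 20, seed: int = 0,
                  locus_id: Optional[str] = None) -> list[AmpliconDesign]:
    """Design a tiling path of overlapping amplicons spanning one locus
    end-to-end.  Primers are taken verbatim from the amplicon ends, the
    reverse primer in oligo (reverse-complement) orientation."""
    if n_amplicons < 1:
        raise ParameterError("n_amplicons must be >= 1")
    if primer_len < 10:
        raise ParameterError("primer_len must be >= 10")
    locus = ref.loci[0] if locus_id is None else Locus(locus_id, ref[locus_id])
    L = len(locus.sequence)
    lo_l, hi_l = amp_len
    lo_o, hi_o = overlap
    if lo_l < 2 * primer_len:
        raise ParameterError("amp_len lower bound must be >= 2*primer_len")
    if n_amplicons > 1 and hi_o >= lo_l:
        raise DesignError("overlap upper bound must be smaller than the shortest amplicon")
    rng = np.random.default_rng(seed)
    lens, olaps = _partition_span(rng, n_amplicons, amp_len, overlap, L)

    designs = []
    start = 0
    for k in range(n_amplicons):
        end = start + lens[k]
        core = locus.sequence[start:end]
        designs.append(AmpliconDesign(
            amplicon_id=f"amp{k + 1:02d}",
            locus_id=locus.locus_id,
            start=start, end=end,
            fwd_primer=core[:primer_len],
            rev_primer=revcomp(core[-primer_len:]),
        ))
        if k < n_amplicons - 1:
            start = end - olaps[k]
    if designs[-1].end != L:
        raise DesignError("internal: tiling does not reach locus end")
    primers = [d.fwd_primer for d in designs] + [d.rev_primer for d in designs]
    if len(set(primers)) != len(primers):
        raise DesignError("degenerate locus: duplicate primer sequences across amplicons")
    return designs


def random_barcodes(n: int, length: int = 16, seed: int = 0,
                    min_hamming: int = 5) -> list[str]:
    """n distinct random barcodes with pairwise Hamming distance >= min_hamming."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 10000:
            raise DesignError(f"cannot draw {n} barcodes of length {length} "
                              f"with min Hamming {min_hamming}")
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_hamming for bc in out):
            out.append(cand)
    return out


def barcode_panel(designs: Sequence[AmpliconDesign],
                  samples: Sequence[SampleBarcode] = ()) -> PrimerPanel:
    """Cross samples with amplicon designs into a primer panel.

    With no samples, an unbarcoded (one-level) panel is produced: one
    entry per amplicon, empty barcode and padding.
    """
    barcodes = [s.barcode for s in samples]
    if len(set(barcodes)) != len(barcodes):
        raise PanelError("duplicate barcodes in sample set")
    entries = []
    if not samples:
        for d in designs:
            entries.append(PanelEntry(None, d.amplicon_id, "", "",
                                      d.fwd_primer, d.rev_primer))
    else:
        for s in samples:
            for d in designs:
                entries.append(PanelEntry(s.sample_id, d.amplicon_id,
                                          s.barcode, s.padding,
                                          d.fwd_primer, d.rev_primer))
    return PrimerPanel(entries)


# ---------------------------------------------------------------------------
# read simulation


def _corrupt(template_arr: np.ndarray, profile: ErrorProfile,
             hp_mask: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """One corrupted pass over the template (uint8 array); returns the
    corrupted array and the truth edit log in template coordinates."""
    L = template_arr.size
    live = np.ones(L, dtype=bool)
    if profile.protect_ends:
        p = min(profile.protect_ends, L)
        live[:p] = False
        live[L - p:] = False

    u_del = rng.random(L)
    u_sub = rng.random(L)
    u_ins = rng.random(L)
    sub_shift = rng.integers(1, 4, size=L)
    ins_rand = rng.integers(0, 4, size=L)

    del_mask = live & (u_del < profile.del_rate)
    sub_mask = live & ~del_mask & (u_sub < profile.sub_rate)
    ins_p = np.where(live, profile.ins_rate + profile.homopolymer_ins_rate * hp_mask, 0.0)
    ins_mask = u_ins < ins_p

    base_idx = _BASE_INDEX[template_arr].astype(np.int64)
    out_idx = base_idx.copy()
    out_idx[sub_mask] = (base_idx[sub_mask] + sub_shift[sub_mask]) % 4

    # inserted base: copy of the run base inside homopolymer tracts, random elsewhere
    ins_base_idx = np.where(hp_mask, base_idx, ins_rand)

    keep = ~del_mask
    counts = keep.astype(np.int64) + ins_mask.astype(np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    out = np.empty(int(ends[-1]) if L else 0, dtype=np.uint8)
    out[starts[keep]] = _BASES[out_idx[keep]]
    out[ends[ins_mask] - 1] = _BASES[ins_base_idx[ins_mask]]

    log: list[tuple[int, str, str]] = []
    for pos in np.nonzero(del_mask)[0]:
        log.append((int(pos), "del", chr(template_arr[pos])))
    for pos in np.nonzero(sub_mask)[0]:
        log.append((int(pos), "sub", chr(_BASES[out_idx[pos]])))
    for pos in np.nonzero(ins_mask)[0]:
        log.append((int(pos), "ins", chr(_BASES[ins_base_idx[pos]])))
    log.sort()
    return out, log


def simulate_raw_read(template: str, n_passes: int, profile: ErrorProfile,
                      molecule_id: str,
                      rng: Optional[np.random.Generator] = None) -> RawRead:
    """Simulate one molecule: n independent corrupted passes over the
    template, reverse-complemented on odd passes (alternating strand).

    Deterministic for a fixed profile seed and molecule_id when no
    generator is supplied.
    """
    if not template:
        raise ParameterError("template must be non-empty")
    if n_passes < 1:
        raise ParameterError("n_passes must be >= 1")
    check_dna(template, "template")
    if rng is None:
        rng = np.random.default_rng([profile.seed, stable_hash(molecule_id)])

    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    hp_mask = np.zeros(arr.size, dtype=bool)
    if profile.homopolymer_ins_rate > 0:
        for s, e in homopolymer_runs(template, profile.run_min):
            hp_mask[s:e] = True

    subreads, logs = [], []
    for k in range(n_passes):
        corrupted, log = _corrupt(arr, profile, hp_mask, rng)
        seq = corrupted.tobytes().decode("ascii")
        if k % 2 == 1:
            seq = revcomp(seq)
            orientation = "antisense"
        else:
            orientation = "sense"
        subreads.append(Subread(f"{molecule_id}/{k}", seq, orientation))
        logs.append(log)
    return RawRead(molecule_id, subreads, edit_logs=logs)


def _draw_passes(passes, rng: np.random.Generator) -> int:
    """Pass-count model: a number means a shifted Poisson (1 + Pois(mean-1),
    always >= 1); ('constant', k) pins every molecule to k passes."""
    if isinstance(passes, tuple) and passes and passes[0] == "constant":
        return max(1, int(passes[1]))
    mean = float(passes)
    if mean < 1:
        raise ParameterError("mean passes must be >= 1")
    return 1 + int(rng.poisson(mean - 1.0))


def entry_template(entry: PanelEntry, core: str) -> str:
    """Full sense-strand molecule template for one panel entry:
    padding+barcode outside the locus-specific primers at both ends."""
    tail = entry.padding + entry.barcode
    return tail + core + revcomp(tail)


def simulate_library(panel: PrimerPanel, depth_per_amplicon: int,
                     passes=9.39, profile: ErrorProfile = ErrorProfile(),
                     out_dir: Optional[str | Path] = None, *,
                     reference: ReferenceSet,
                     designs: Sequence[AmpliconDesign],
                     seed: Optional[int] = None,
                     movie: str = DEFAULT_MOVIE) -> LibraryBundle:
    """Simulate a whole library: depth_per_amplicon molecules for every
    panel entry, pass counts from the given distribution, per-base errors
    from the profile.  Writes subreads FASTQ, truth TSV, panel TSV and
    reference FASTA when out_dir is given.
    """
    if depth_per_amplicon < 1:
        raise DesignError("depth_per_amplicon must be >= 1")
    if not len(panel):
        raise PanelError("panel is empty")
    design_by_id = {d.amplicon_id: d for d in designs}
    master = np.random.default_rng(profile.seed if seed is None else seed)

    templates: dict[tuple[Optional[str], str], str] = {}
    for e in panel:
        core = design_by_id[e.amplicon_id].core(reference)
        templates[e.cluster_id] = entry_template(e, core)

    raw_reads: list[RawRead] = []
    zmw = 100000
    for e in panel:
        template = templates[e.cluster_id]
        for _ in range(depth_per_amplicon):
            molecule_id = f"{movie}/{zmw}"
            zmw += 1
            n_passes = _draw_passes(passes, master)
            child = np.random.default_rng(int(master.integers(0, 2**31)))
            rr = simulate_raw_read(template, n_passes, profile, molecule_id, rng=child)
            rr.true_sample_id = e.sample_id
            rr.true_amplicon_id = e.amplicon_id
            raw_reads.append(rr)

    bundle = LibraryBundle(raw_reads, panel, templates,
                           reference=reference, designs=list(designs))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from amptile import io as aio
        bundle.paths["subreads"] = aio.write_subreads_fastq(raw_reads, out_dir / "subreads.fastq")
        bundle.paths["truth"] = aio.write_truth_tsv(bundle, out_dir / "truth.tsv")
        bundle.paths["panel"] = panel.to_tsv(out_dir / "panel.tsv")
        bundle.paths["reference"] = reference.to_fasta(out_dir / "reference.fasta")
    return bundle
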