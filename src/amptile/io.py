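"""File formats: subread/CCS FASTQ, truth tables, whitelists, reports.

Molecule identifiers follow the '<movie>/<zmw>' convention with subread
records named '<movie>/<zmw>/<k>' and CCS records '<movie>/<zmw>/ccs';
grouping is by the '<movie>/<zmw>' prefix.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from amptile.errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from amptile.ccs import CCSRead, CCSRejection
    from amptile.simulate import LibraryBundle, RawRead

SUBREAD_QUAL = 20  # constant placeholder quality; the pipeline never reads it
CCS_QUAL = 30


def molecule_id_of(read_id: str) -> str:
    """'<movie>/<zmw>/<k>' or '<movie>/<zmw>/ccs' -> '<movie>/<zmw>'."""
    parts = read_id.split("/")
    if len(parts) < 2:
        raise ParameterError(f"read id {read_id!r} is not '<movie>/<zmw>/...'")
    return "/".join(parts[:2])


def write_subreads_fastq(raw_reads: Iterable["RawRead"], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for rr in raw_reads:
        for sr in rr.subreads:
            rec = SeqRecord(Seq(sr.sequence), id=sr.subread_id, description="")
            rec.letter_annotations["phred_quality"] = [SUBREAD_QUAL] * len(sr.sequence)
            records.append(rec)
    SeqIO.write(records, str(path), "fastq")
    return path


def read_subreads_fastq(path: str | Path) -> list["RawRead"]:
    """Group subread records by molecule; orientation is inferred from
    subread index parity (passes alternate strands)."""
    from amptile.simulate import RawRead, Subread

    groups: dict[str, list[Subread]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        mol = molecule_id_of(rec.id)
        k = rec.id.split("/")[2] if len(rec.id.split("/")) > 2 else "0"
        orientation = "antisense" if k.isdigit() and int(k) % 2 == 1 else "sense"
        if mol not in groups:
            groups[mol] = []
            order.append(mol)
        groups[mol].append(Subread(rec.id, str(rec.seq).upper(), orientation))
    return [RawRead(mol, groups[mol]) for mol in order]


def write_ccs_fastq(ccs_reads: Iterable["CCSRead"],
                    rejections: Iterable["CCSRejection"],
                    path: str | Path, sidecar: str | Path | None = None) -> Path:
    path = Path(path)
    records = []
    for c in ccs_reads:
        rec = SeqRecord(Seq(c.sequence), id=f"{c.molecule_id}/ccs", description="")
        rec.letter_annotations["phred_quality"] = [CCS_QUAL] * len(c.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
    if sidecar is not None:
        with open(sidecar, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["molecule_id", "n_passes", "predicted_accuracy", "status", "reason"])
            for c in ccs_reads:
                w.writerow([c.molecule_id, c.n_passes, f"{c.predicted_accuracy:.6f}", "emitted", ""])
            for r in rejections:
                w.writerow([r.molecule_id, r.n_passes, f"{r.predicted_accuracy:.6f}", "rejected", r.reason])
    return path


def read_ccs_fastq(path: str | Path) -> list["CCSRead"]:
    from amptile.ccs import CCSRead

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(CCSRead(molecule_id=molecule_id_of(rec.id),
                           sequence=str(rec.seq).upper(),
                           n_passes=0, predicted_accuracy=1.0))
    return out


def write_truth_tsv(bundle: "LibraryBundle", path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, delimiter="\t", lineterminator="\n",
                           fieldnames=["molecule_id", "sample_id", "amplicon_id",
                                       "n_passes", "template_md5"])
        w.writeheader()
        for row in bundle.truth_rows():
            w.writerow(row)
    return path


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(rows: list[dict], path: str | Path, columns: list[str],
              comment: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write("# " + comment + "\n")
        w = csv.DictWriter(fh, delimiter="\t", lineterminator="\n",
                           fieldnames=columns, extrasaction="ignore")
        w.writeheader()
        for row in rows:
            w.writerow(row)
    return path
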