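"""Primer/barcode panels: the per-(sample, amplicon) oligo bookkeeping.

A panel row records the locus-specific forward and reverse primers for one
amplicon, plus (for multiplexed libraries) the sample's symmetric barcode
and the shared 5' padding sequence that precedes the barcode on the
synthesis oligo.  The reverse primer is stored in the orientation of the
primer oligo itself, i.e. on the reverse-complement strand of the amplicon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from amptile.errors import PanelError
from amptile.sequtil import check_dna

DEFAULT_PADDING = "GTTAG"

PANEL_COLUMNS = ["sample_id", "amplicon_id", "barcode", "padding", "fwd_primer", "rev_primer"]


@dataclass(frozen=True)
class SampleBarcode:
    """A sample's symmetric barcode with its 5' padding."""

    sample_id: str
    barcode: str
    padding: str = DEFAULT_PADDING

    def __post_init__(self) -> None:
        check_dna(self.barcode, "barcode")
        check_dna(self.padding, "padding", allow_empty=True)


@dataclass(frozen=True)
class PanelEntry:
    sample_id: Optional[str]
    amplicon_id: str
    barcode: str
    padding: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        check_dna(self.fwd_primer, "fwd_primer")
        check_dna(self.rev_primer, "rev_primer")
        check_dna(self.barcode, "barcode", allow_empty=True)
        check_dna(self.padding, "padding", allow_empty=True)

    @property
    def cluster_id(self) -> tuple[Optional[str], str]:
        return (self.sample_id, self.amplicon_id)

    def composite_fwd(self, include_padding: bool = True) -> str:
        """5'->3' search sequence at the left end of a sense read."""
        pad = self.padding if include_padding else ""
        return pad + self.barcode + self.fwd_primer

    def composite_rev(self, include_padding: bool = True) -> str:
        """The right-end oligo 5'->3' (its reverse complement ends a sense read)."""
        pad = self.padding if include_padding else ""
        return pad + self.barcode + self.rev_primer


@dataclass
class PrimerPanel:
    """A collection of panel entries, unique per (sample_id, amplicon_id)."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.cluster_id in seen:
                raise PanelError(f"duplicate panel entry for {e.cluster_id}")
            seen.add(e.cluster_id)
        barcoded = [e for e in self.entries if e.barcode]
        if barcoded and len(barcoded) != len(self.entries):
            raise PanelError("panel mixes barcoded and unbarcoded entries")
        by_sample: dict[str, set[str]] = {}
        for e in barcoded:
            by_sample.setdefault(e.barcode, set()).add(e.sample_id or "")
            if len(by_sample[e.barcode]) > 1:
                raise PanelError(f"barcode {e.barcode} assigned to more than one sample")

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcoded(self) -> bool:
        return bool(self.entries) and bool(self.entries[0].barcode)

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.sample_id is not None and e.sample_id not in out:
                out.append(e.sample_id)
        return out

    @property
    def amplicon_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.amplicon_id not in out:
                out.append(e.amplicon_id)
        return out

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(PANEL_COLUMNS)
            for e in self.entries:
                w.writerow([
                    e.sample_id if e.sample_id is not None else "",
                    e.amplicon_id, e.barcode, e.padding, e.fwd_primer, e.rev_primer,
                ])
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrimerPanel":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(PANEL_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise PanelError(f"panel file {path} missing columns: {sorted(missing)}")
            for row in reader:
                entries.append(PanelEntry(
                    sample_id=row["sample_id"] or None,
                    amplicon_id=row["amplicon_id"],
                    barcode=row["barcode"],
                    padding=row["padding"],
                    fwd_primer=row["fwd_primer"],
                    rev_primer=row["rev_primer"],
                ))
        return cls(entries)

    @classmethod
    def from_entries(cls, entries: Iterable[PanelEntry]) -> "PrimerPanel":
        return cls(list(entries))
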