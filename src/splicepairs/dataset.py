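"""Per-intron splice-site element extraction, intron classification, and partitioning.

Every intron contributes three sequence elements to the analysis:

* ``junction11`` — the 11-nt splice junction: last 8 nt of the upstream exon
  joined to the first 3 nt of the downstream exon (the U5 Loop1 binding
  site in the proposed register);
* ``intron_start10`` — the first 10 nt of the intron (U6/U1 territory);
* ``intron_end60`` — the last 60 nt of the intron (polypyrimidine tract,
  -3/-2/-1 positions).

Introns are classified as ``major`` (GT..AG processed by the major
spliceosome), ``atypical_plus2`` (+2 position not T/U, e.g. GC..AG), or
``minor`` (U12-type, recognized by a U6atac-complementary 5' motif).  Minor
and atypical introns are excluded from the 5' splice-site analyses, mirroring
the exclusion of 4 minor and 13 atypical introns from the 2,007-intron
source set that leaves 1,990 major GU_AG introns.

Sequences are stored as DNA-alphabet text in files and normalized to RNA
in memory by the pairing layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import pandas as pd

from .pairing import format_position, normalize_sequence

__all__ = [
    "IntronRecord",
    "SpliceDataset",
    "Transcript",
    "extract_splice_elements",
    "classify_intron",
    "partition_dataset",
    "junction_positions",
    "MINOR_5SS_MOTIF",
]

#: default U12-type 5'ss core at intron +3..+8 (complementary to the U6atac box)
MINOR_5SS_MOTIF = "ATCCTT"

JUNCTION_LEN = 11
EXON5_FLANK = 8   # exon -8..-1
EXON3_FLANK = 3   # exon +1..+3
INTRON_START_LEN = 10
INTRON_END_LEN = 60


@dataclass
class IntronRecord:
    """One intron with its flanking exon fragments and classification labels."""

    gene_id: str
    transcript_id: str
    intron_index: int
    junction11: str
    intron_start10: str
    intron_end60: str
    spliceosome_class: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.junction11) != JUNCTION_LEN and not self.truncated:
            raise ValueError(
                f"{self.record_id}: junction11 length {len(self.junction11)} != {JUNCTION_LEN}"
            )

    @property
    def record_id(self) -> str:
        return f"{self.transcript_id}:i{self.intron_index}"

    # -- conserved-position flags ------------------------------------------

    @property
    def has_plus5G(self) -> bool:
        return len(self.intron_start10) >= 5 and self.intron_start10[4].upper() in "G"

    @property
    def has_minus1G(self) -> bool:
        return len(self.junction11) >= 8 and self.junction11[7].upper() == "G"

    @property
    def has_minus3C(self) -> bool:
        return len(self.intron_end60) >= 3 and self.intron_end60[-3].upper() == "C"

    # -- position accessors -------------------------------------------------

    def junction_base(self, label: str) -> str:
        """Residue of ``junction11`` at a labelled position (``exon:-8..+3``)."""
        return self.junction11[junction_positions().index(label)]

    def substrate(self) -> dict[str, str]:
        """All labelled positions this record exposes, as a substrate mapping."""
        sub = {lab: b for lab, b in zip(junction_positions(), self.junction11)}
        for k, b in enumerate(self.intron_start10, start=1):
            sub[format_position("intron", k)] = b
        n = len(self.intron_end60)
        for k, b in enumerate(self.intron_end60):
            sub[format_position("intron", k - n)] = b
        return sub


def junction_positions() -> list[str]:
    """The 11 junction labels: characters 1..8 are exon -8..-1, 9..11 are exon +1..+3."""
    return ([format_position("exon", k) for k in range(-8, 0)]
            + [format_position("exon", k) for k in range(1, 4)])


@dataclass
class Transcript:
    """Exon-ordered transcript sequences (already strand-resolved, 5'->3')."""

    gene_id: str
    transcript_id: str
    exons: list[str]
    introns: list[str]

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError(f"{self.transcript_id}: need >= 2 exons")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.transcript_id}: {len(self.exons)} exons require "
                f"{len(self.exons) - 1} introns, got {len(self.introns)}"
            )


def extract_splice_elements(
    transcript: Transcript, *, on_short_exon: str = "flag"
) -> list[IntronRecord]:
    """Extract one :class:`IntronRecord` per internal intron of a transcript.

    ``junction11`` spans the exon–exon boundary exactly at position 8|9.
    Introns shorter than 60 nt keep their whole sequence as ``intron_end60``
    and are flagged; exons shorter than the required flank either flag the
    record (``on_short_exon="flag"``) or drop it (``"skip"``).
    """
    if on_short_exon not in ("flag", "skip"):
        raise ValueError("on_short_exon must be 'flag' or 'skip'")
    records = []
    for i, intron in enumerate(transcript.introns):
        up, down = transcript.exons[i], transcript.exons[i + 1]
        for seq, what in ((up, "exon"), (down, "exon"), (intron, "intron")):
            normalize_sequence(seq)  # reject bad symbols early
        truncated = len(up) < EXON5_FLANK or len(down) < EXON3_FLANK
        junction = up[-EXON5_FLANK:] + down[:EXON3_FLANK]
        short_intron = len(intron) < INTRON_END_LEN
        if truncated and on_short_exon == "skip":
            continue
        records.append(IntronRecord(
            gene_id=transcript.gene_id,
            transcript_id=transcript.transcript_id,
            intron_index=i + 1,
            junction11=junction,
            intron_start10=intron[:INTRON_START_LEN],
            intron_end60=intron[-INTRON_END_LEN:],
            truncated=truncated or short_intron,
        ))
    return records


def classify_intron(record: IntronRecord, *, minor_motif: str = MINOR_5SS_MOTIF) -> str:
    """Classify an intron as ``minor``, ``atypical_plus2`` or ``major``.

    Minor (U12-type) introns are recognized by the U6atac-complementary core
    at intron +3..+8 (default ``ATCCTT``, exact match).  Major introns whose
    +2 is not T/U (GC..AG and the rarer GA starts) are ``atypical_plus2``.
    """
    start = record.intron_start10.upper().replace("U", "T")
    if start[2:8] == minor_motif.upper():
        return "minor"
    if len(start) >= 2 and start[1] != "T":
        return "atypical_plus2"
    return "major"


def classify_dataset(ds: "SpliceDataset", *, minor_motif: str = MINOR_5SS_MOTIF) -> None:
    """Assign ``spliceosome_class`` on every record in place."""
    for rec in ds.records:
        rec.spliceosome_class = classify_intron(rec, minor_motif=minor_motif)


_CRITERIA = {
    # criterion -> (flag attribute, eligible spliceosome classes)
    "plus5G": ("has_plus5G", {"major"}),
    "minus1G": ("has_minus1G", {"major"}),
    "minus3C": ("has_minus3C", {"major", "atypical_plus2"}),
}


@dataclass
class SpliceDataset:
    """An ordered collection of intron records with provenance."""

    records: list[IntronRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record identifiers: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.spliceosome_class] = counts.get(r.spliceosome_class, 0) + 1
        return counts

    # -- TSV round trip ----------------------------------------------------

    _COLS = ["gene_id", "transcript_id", "intron_index", "junction11",
             "intron_start10", "intron_end60", "spliceosome_class",
             "truncated", "has_plus5G", "has_minus1G", "has_minus3C"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            d.update(has_plus5G=r.has_plus5G, has_minus1G=r.has_minus1G,
                     has_minus3C=r.has_minus3C)
            rows.append(d)
        return pd.DataFrame(rows, columns=self._COLS)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "SpliceDataset":
        df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": str,
                                                       "transcript_id": str})
        records = [IntronRecord(
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            intron_index=int(row.intron_index),
            junction11=str(row.junction11),
            intron_start10=str(row.intron_start10),
            intron_end60=str(row.intron_end60),
            spliceosome_class=str(getattr(row, "spliceosome_class", "") or ""),
            truncated=bool(getattr(row, "truncated", False)),
        ) for row in df.itertuples(index=False)]
        src = getattr(path_or_buf, "name", None) or (
            path_or_buf if isinstance(path_or_buf, str) else "<buffer>")
        return cls(records=records, provenance={"source": str(src)})

    def to_tsv_text(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


def partition_dataset(
    ds: SpliceDataset, criterion: str
) -> tuple[list[IntronRecord], list[IntronRecord]]:
    """Split eligible records by a conserved position into (conserved, substituted).

    ``plus5G`` and ``minus1G`` operate on major GU_AG introns only;
    ``minus3C`` also admits atypical (+2-substituted, e.g. GC..AG) introns,
    i.e. everything processed by the major spliceosome.  The two subsets are
    disjoint and cover all eligible records.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {sorted(_CRITERIA)}")
    flag, classes = _CRITERIA[criterion]
    eligible = [r for r in ds.records if r.spliceosome_class in classes]
    if not eligible:
        raise ValueError(
            f"no eligible records for criterion {criterion!r} "
            f"(classes {sorted(classes)}); classify the dataset first"
        )
    conserved = [r for r in eligible if getattr(r, flag)]
    substituted = [r for r in eligible if not getattr(r, flag)]
    return conserved, substituted


def exclusion_report(ds: SpliceDataset) -> pd.DataFrame:
    """Minor and atypical records with the reason for their exclusion."""
    rows = []
    for r in ds.records:
        if r.spliceosome_class == "minor":
            rows.append({"record_id": r.record_id, "class": "minor",
                         "reason": "U6atac-complementary 5'ss motif (U12-type)"})
        elif r.spliceosome_class == "atypical_plus2":
            plus2 = r.intron_start10[1] if len(r.intron_start10) > 1 else "?"
            rows.append({"record_id": r.record_id, "class": "atypical_plus2",
                         "reason": f"intron +2 is {plus2}, not U"})
    return pd.DataFrame(rows, columns=["record_id", "class", "reason"])
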