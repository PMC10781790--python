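"""Reference sequences for small non-coding RNA annotation.

A reference bundle holds one :class:`SncRnaReference` per feature. miRNA
references are anchored inside their precursor (pre-miRNA) sequence, which is
what makes templated 3' isomiR counting possible; all other classes are plain
sequences matched by exact substring containment.

Annotation classes compete in a fixed priority order (highest first)::

    miRNA > ysRNA > tsRNA > rsRNA > snRNA > snoRNA > lncRNA > mRNA

Reads matching none of these are classified "others".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Annotation priority, highest first. A read with candidates in several
#: classes is assigned to the earliest class in this list.
RNA_CLASSES: tuple[str, ...] = (
    "miRNA",
    "ysRNA",
    "tsRNA",
    "rsRNA",
    "snRNA",
    "snoRNA",
    "lncRNA",
    "mRNA",
)

#: Label for reads that match no reference class.
OTHERS = "others"


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA (U) to the DNA alphabet (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SncRnaReference:
    """One reference feature.

    For miRNAs, ``sequence`` is the mature miRNA and must equal
    ``precursor_sequence[mature_start:mature_end]`` (0-based, half-open).
    For every other class only ``sequence`` is set.
    """

    feature_id: str
    rna_class: str
    sequence: str
    precursor_sequence: str | None = None
    mature_start: int | None = None
    mature_end: int | None = None

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.precursor_sequence is not None:
            object.__setattr__(
                self, "precursor_sequence", normalize_sequence(self.precursor_sequence)
            )
        if self.rna_class == "miRNA":
            if (
                self.precursor_sequence is None
                or self.mature_start is None
                or self.mature_end is None
            ):
                raise ValueError(
                    f"miRNA reference {self.feature_id!r} lacks precursor anchoring"
                )
            anchored = self.precursor_sequence[self.mature_start : self.mature_end]
            if anchored != self.sequence:
                raise ValueError(
                    f"mature sequence of {self.feature_id!r} does not match its "
                    f"precursor at [{self.mature_start}, {self.mature_end})"
                )


@dataclass
class ReferenceBundle:
    """All reference features, indexed by id and by class."""

    references: dict[str, SncRnaReference] = field(default_factory=dict)

    def add(self, ref: SncRnaReference) -> None:
        if ref.feature_id in self.references:
            raise ValueError(f"duplicate feature id {ref.feature_id!r}")
        self.references[ref.feature_id] = ref

    def __len__(self) -> int:
        return len(self.references)

    def __getitem__(self, feature_id: str) -> SncRnaReference:
        return self.references[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.references

    def by_class(self, rna_class: str) -> list[SncRnaReference]:
        return [r for r in self.references.values() if r.rna_class == rna_class]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.references)

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, fasta_path: str | Path, offsets_path: str | Path) -> None:
        """Write references as FASTA plus a sidecar TSV of precursor offsets.

        miRNA records store the precursor sequence in FASTA; the sidecar maps
        each mature miRNA to its [start, end) offsets within the precursor.
        """
        records = []
        for ref in self.references.values():
            seq = ref.precursor_sequence if ref.rna_class == "miRNA" else ref.sequence
            records.append(
                SeqRecord(Seq(seq), id=ref.feature_id, description=ref.rna_class)
            )
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(offsets_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["feature_id", "rna_class", "mature_start", "mature_end"])
            for ref in self.references.values():
                writer.writerow(
                    [
                        ref.feature_id,
                        ref.rna_class,
                        "" if ref.mature_start is None else ref.mature_start,
                        "" if ref.mature_end is None else ref.mature_end,
                    ]
                )

    @classmethod
    def from_fasta(
        cls, fasta_path: str | Path, offsets_path: str | Path
    ) -> "ReferenceBundle":
        meta: dict[str, tuple[str, int | None, int | None]] = {}
        with open(offsets_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                start = int(row["mature_start"]) if row["mature_start"] else None
                end = int(row["mature_end"]) if row["mature_end"] else None
                meta[row["feature_id"]] = (row["rna_class"], start, end)
        bundle = cls()
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in meta:
                raise ValueError(f"feature {rec.id!r} missing from offsets table")
            rna_class, start, end = meta[rec.id]
            seq = normalize_sequence(str(rec.seq))
            if rna_class == "miRNA":
                bundle.add(
                    SncRnaReference(
                        feature_id=rec.id,
                        rna_class=rna_class,
                        sequence=seq[start:end],
                        precursor_sequence=seq,
                        mature_start=start,
                        mature_end=end,
                    )
                )
            else:
                bundle.add(
                    SncRnaReference(feature_id=rec.id, rna_class=rna_class, sequence=seq)
                )
        return bundle
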