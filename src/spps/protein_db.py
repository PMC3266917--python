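"""File-backed store of protein sequences and annotations.

Sequences live in standard FASTA; per-protein annotations (function,
disease, tissue specificity, subcellular location, known interaction
partners) live in a six-column TSV.  The store supports the two
post-hoc refinement filters applied to a ranked partner list: a
tissue-keyword match and a known-interaction match keyed by the query's
UniProt-style entry name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import UnknownProteinError, ValidationError
from .features import ResidueClassMap

logger = logging.getLogger(__name__)

FASTA_WRAP = 60

ANNOTATION_COLUMNS = [
    "protein_id",
    "function",
    "disease",
    "tissue_specificity",
    "subcellular_location",
    "known_partners",
]


@dataclass
class ProteinRecord:
    """One protein: accession, optional entry name, amino-acid sequence."""

    id: str
    sequence: str
    entry_name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record needs a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")


@dataclass
class AnnotationRecord:
    """Free-text annotations and known interaction partners of one protein."""

    protein_id: str
    function: str = ""
    disease: str = ""
    tissue_specificity: str = ""
    subcellular_location: str = ""
    known_partners: Set[str] = field(default_factory=set)


def _parse_header(header: str) -> tuple[str, str]:
    """First whitespace token of a FASTA header -> (id, entry_name).

    The UniProt dialect ``db|ACC|ENTRY_NAME`` yields the accession and
    entry name; any other token is taken whole as the id.
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) == 3 and all(parts):
        return parts[1], parts[2]
    return token, ""


def read_fasta(path, cmap: Optional[ResidueClassMap] = None) -> List[ProteinRecord]:
    """Read protein records from a FASTA file.

    Wrapped sequence lines are concatenated, uppercased and stripped of
    whitespace.  Every sequence is validated against the featurizer's
    tolerated alphabet; offending records are reported by id and
    character.  An empty file yields an empty list.
    """
    cmap = cmap or ResidueClassMap.default()
    alphabet = cmap.alphabet
    records: List[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        pid, entry = _parse_header(rec.description or rec.id)
        if not seq:
            raise ValidationError(f"record {pid!r} has a header but no sequence")
        bad = set(seq) - alphabet
        if bad:
            raise ValidationError(
                f"record {pid!r} contains untolerated character(s) "
                f"{sorted(bad)}"
            )
        records.append(ProteinRecord(id=pid, sequence=seq, entry_name=entry))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as FASTA, 60-column wrapped.

    Records carrying an entry name are written in the UniProt dialect
    ``sp|ACC|ENTRY_NAME`` so that :func:`read_fasta` round-trips both
    fields; plain records get a bare-accession header.
    """
    seq_records = []
    for rec in records:
        header = f"sp|{rec.id}|{rec.entry_name}" if rec.entry_name else rec.id
        seq_records.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seq_records)


def load_annotations(path) -> List[AnnotationRecord]:
    """Read annotation records from a TSV with the six canonical columns.

    ``known_partners`` cells hold semicolon-separated accessions; empty
    cells become empty text / empty sets.  Unknown columns and duplicate
    protein ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown annotation column(s): {sorted(unknown)}")
    if "protein_id" not in df.columns:
        raise ValidationError("annotation table lacks the protein_id column")
    dupes = df["protein_id"][df["protein_id"].duplicated()]
    if len(dupes):
        raise ValidationError(
            f"duplicate annotation rows for protein id(s): {sorted(set(dupes))}"
        )
    records = []
    for _, row in df.iterrows():
        partners = {p for p in row.get("known_partners", "").split(";") if p}
        records.append(
            AnnotationRecord(
                protein_id=row["protein_id"],
                function=row.get("function", ""),
                disease=row.get("disease", ""),
                tissue_specificity=row.get("tissue_specificity", ""),
                subcellular_location=row.get("subcellular_location", ""),
                known_partners=partners,
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    """Write annotation records as the canonical six-column TSV."""
    rows = [
        {
            "protein_id": r.protein_id,
            "function": r.function,
            "disease": r.disease,
            "tissue_specificity": r.tissue_specificity,
            "subcellular_location": r.subcellular_location,
            "known_partners": ";".join(sorted(r.known_partners)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


class ProteinDatabase:
    """In-memory, file-backed protein store keyed by accession.

    Finalizing the store (done by the constructor) symmetrizes the
    known-partner relation: physical interaction is undirected, so if B
    lists A, A is made to list B; each repair is logged.
    """

    def __init__(
        self,
        records: Iterable[ProteinRecord],
        annotations: Iterable[AnnotationRecord] = (),
        species: str = "",
    ) -> None:
        self.records: Dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise ValidationError(f"duplicate protein id {rec.id!r}")
            self.records[rec.id] = rec
        self.annotations: Dict[str, AnnotationRecord] = {}
        for ann in annotations:
            if ann.protein_id not in self.records:
                raise ValidationError(
                    f"annotation refers to unknown protein {ann.protein_id!r}"
                )
            if ann.protein_id in self.annotations:
                raise ValidationError(
                    f"duplicate annotation for protein {ann.protein_id!r}"
                )
            self.annotations[ann.protein_id] = ann
        self.species = species
        self._symmetrize_partners()
        self._entry_index = {
            rec.entry_name: rec.id for rec in self.records.values() if rec.entry_name
        }

    def _symmetrize_partners(self) -> None:
        for ann in list(self.annotations.values()):
            for partner in list(ann.known_partners):
                if partner not in self.records:
                    continue
                back = self.annotations.setdefault(
                    partner, AnnotationRecord(protein_id=partner)
                )
                if ann.protein_id not in back.known_partners:
                    logger.info(
                        "symmetrized known-partner edge %s-%s",
                        ann.protein_id, partner,
                    )
                    back.known_partners.add(ann.protein_id)

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def __iter__(self):
        return iter(self.records.values())

    def get(self, pid: str) -> ProteinRecord:
        try:
            return self.records[pid]
        except KeyError:
            raise UnknownProteinError(f"unknown protein id {pid!r}") from None

    def sequence(self, pid: str) -> str:
        return self.get(pid).sequence

    def by_entry_name(self, entry_name: str) -> ProteinRecord:
        try:
            return self.records[self._entry_index[entry_name]]
        except KeyError:
            raise UnknownProteinError(
                f"no protein with entry name {entry_name!r}"
            ) from None

    def annotation(self, pid: str) -> AnnotationRecord:
        self.get(pid)  # id must resolve
        return self.annotations.get(pid, AnnotationRecord(protein_id=pid))

    # -- constructors / persistence --------------------------------------
    @classmethod
    def from_files(cls, fasta_path, annotations_path=None, species: str = ""):
        records = read_fasta(fasta_path)
        annotations = load_annotations(annotations_path) if annotations_path else ()
        return cls(records, annotations, species=species)

    def to_files(self, fasta_path, annotations_path=None) -> None:
        write_fasta(self.records.values(), fasta_path)
        if annotations_path is not None:
            write_annotations(self.annotations.values(), annotations_path)


# -- post-hoc filters on ranked hit lists --------------------------------

def tissue_match(hits, db: ProteinDatabase, keyword: str):
    """Hits whose partner's tissue annotation contains *keyword*.

    Case-insensitive substring match; ranking order is preserved.
    """
    if not keyword:
        raise ValidationError("tissue keyword must be non-empty")
    kw = keyword.lower()
    return [
        h for h in hits
        if kw in db.annotation(h.partner_id).tissue_specificity.lower()
    ]


def known_interaction_match(query_entry_name: str, hits, db: ProteinDatabase):
    """Hits that are experimentally known partners of the query protein.

    The query is named by its UniProt-style entry name; order is
    preserved.  An unresolvable entry name raises
    :class:`UnknownProteinError`.
    """
    query = db.by_entry_name(query_entry_name)
    partners = db.annotation(query.id).known_partners
    return [h for h in hits if h.partner_id in partners]
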