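"""Annotated reference proteome: sequences plus protein-existence annotations.

The reference emulates a Human Protein Atlas / neXtProt style export: a FASTA
file of protein sequences and a tab-separated annotation table keyed by
accession carrying the gene symbol, chromosome and protein-existence (PE)
level.  PE levels follow the five-tier neXtProt scale: PE1 has experimental
evidence at the protein level, PE2 at the transcript level, PE3 is inferred
from homology, PE4 is predicted from gene models and PE5 is uncertain.
Proteins at PE2-PE4 are the "missing proteins" of the chromosome-centric
Human Proteome Project.

A packaged fixture ships the 41 tumorigenesis-associated identifications
(groups III-V of the three-way mouse-liver comparison) in the same schema.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Residues admitted in reference sequences and observed peptides.  X is the
#: only ambiguity code accepted; it matches nothing during peptide matching.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Fixed chromosome axis used by every chromosome-centric report (human
#: numbering; mouse identifications are projected onto human chromosomes).
CHROMOSOME_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + (
    "X",
    "Y",
    "MT",
    "unplaced",
)

_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


class PELevel(Enum):
    """Protein-existence evidence level on the five-tier neXtProt scale."""

    PE1 = 1
    PE2 = 2
    PE3 = 3
    PE4 = 4
    PE5 = 5

    @property
    def label(self) -> str:
        """Canonical free-text evidence string for this level."""
        return _LEVEL_TO_LABEL[self]

    @property
    def is_missing(self) -> bool:
        """True for PE2-PE4, the missing-protein band."""
        return self in (PELevel.PE2, PELevel.PE3, PELevel.PE4)

    @classmethod
    def from_value(cls, value: "PELevel | int | str") -> "PELevel":
        """Resolve a PE level from an enum, integer 1-5, token ``PE1``..``PE5``
        or one of the canonical evidence label strings.

        Raises
        ------
        ValueError
            If the value cannot be resolved; the message lists the accepted
            labels.
        """
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            try:
                return cls(value)
            except ValueError:
                pass
        elif isinstance(value, str):
            text = value.strip()
            token = text.upper()
            if re.fullmatch(r"PE[1-5]", token):
                return cls(int(token[2]))
            if re.fullmatch(r"[1-5]", token):
                return cls(int(token))
            for label, level in _LABEL_TO_LEVEL.items():
                if label.lower() == text.lower():
                    return level
        accepted = ", ".join(
            [*(lv.name for lv in cls), *(repr(s) for s in _LABEL_TO_LEVEL)]
        )
        raise ValueError(
            f"cannot resolve protein-existence level from {value!r}; "
            f"accepted values: {accepted}"
        )


_LEVEL_TO_LABEL: dict[PELevel, str] = {
    PELevel.PE1: "Evidence at protein level",
    PELevel.PE2: "Evidence at transcript level",
    PELevel.PE3: "Protein inferred from homology",
    PELevel.PE4: "Protein predicted",
    PELevel.PE5: "Uncertain protein",
}
_LABEL_TO_LEVEL: dict[str, PELevel] = {v: k for k, v in _LEVEL_TO_LABEL.items()}

#: The four evidence strings that occur in the packaged fixture.
FIXTURE_EVIDENCE_LABELS = tuple(
    _LEVEL_TO_LABEL[lv] for lv in (PELevel.PE1, PELevel.PE2, PELevel.PE3, PELevel.PE4)
)


def normalize_chromosome(raw: str) -> str:
    """Map a raw chromosome label to a canonical token.

    Accepts the human numeric convention in which X is printed as ``23`` (the
    fixture prints X-linked entries as ``23×``) and Y as ``24``.  Anything not
    recognised maps to ``"unplaced"`` with a logged warning; the function is
    total and idempotent.
    """
    if raw is None or str(raw).strip() == "":
        raise ValueError("chromosome label must be non-empty")
    token = str(raw).strip().replace("×", "X").upper()
    if token in ("23X", "23", "X"):
        return "X"
    if token in ("24", "Y"):
        return "Y"
    if token in ("M", "MT"):
        return "MT"
    if token == "UNPLACED":
        return "unplaced"
    if token.isdigit() and 1 <= int(token) <= 22:
        return str(int(token))
    logger.warning("unrecognised chromosome label %r mapped to 'unplaced'", raw)
    return "unplaced"


@dataclass
class ReferenceProtein:
    """One annotated reference sequence entry."""

    accession: str
    sequence: str
    gene: str = ""
    chromosome: str = "unplaced"
    pe_level: PELevel = PELevel.PE1
    isoform_id: str | None = None
    gene_id: str | None = None
    protein_name: str = ""

    def __post_init__(self) -> None:
        if not self.accession or not str(self.accession).strip():
            raise ValueError("accession must be non-empty")
        self.accession = str(self.accession).strip()
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if not _SEQ_RE.fullmatch(self.sequence):
            bad = sorted(set(self.sequence) - VALID_RESIDUES)
            raise ValueError(
                f"{self.accession}: sequence contains invalid residues {bad} "
                "(must be uppercase standard amino acids, X allowed)"
            )
        if not self.gene:
            # Annotation-less entries fall back to the accession as gene symbol.
            self.gene = self.accession
        self.chromosome = normalize_chromosome(self.chromosome)
        self.pe_level = PELevel.from_value(self.pe_level)

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceDB:
    """Ordered collection of :class:`ReferenceProtein` with unique accessions."""

    def __init__(self, proteins: Iterable[ReferenceProtein]):
        self.proteins: list[ReferenceProtein] = list(proteins)
        self._by_accession: dict[str, ReferenceProtein] = {}
        for prot in self.proteins:
            if prot.accession in self._by_accession:
                raise ValueError(f"duplicate accession {prot.accession!r}")
            self._by_accession[prot.accession] = prot

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[ReferenceProtein]:
        return iter(self.proteins)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __getitem__(self, accession: str) -> ReferenceProtein:
        return self._by_accession[accession]

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    @property
    def gene_of(self) -> dict[str, str]:
        """Map accession -> gene symbol (accession itself when unannotated)."""
        return {p.accession: p.gene for p in self.proteins}

    def to_fasta(self, path: str | Path) -> None:
        """Write sequences as FASTA, annotations encoded as GN/CHR/PE tokens."""
        with open(path, "w", encoding="utf-8") as handle:
            for p in self.proteins:
                desc = p.protein_name or ""
                tokens = f"GN={p.gene} CHR={p.chromosome} PE={p.pe_level.value}"
                header = f">{p.accession} {desc + ' ' if desc else ''}{tokens}"
                handle.write(header + "\n")
                for i in range(0, len(p.sequence), 60):
                    handle.write(p.sequence[i : i + 60] + "\n")

    def to_annotation_tsv(self, path: str | Path) -> None:
        """Write the annotation table (TSV, one row per accession)."""
        frame = pd.DataFrame(
            {
                "accession": [p.accession for p in self.proteins],
                "isoform_id": [p.isoform_id or "" for p in self.proteins],
                "gene": [p.gene for p in self.proteins],
                "gene_id": [p.gene_id or "" for p in self.proteins],
                "chromosome": [p.chromosome for p in self.proteins],
                "pe_level": [p.pe_level.name for p in self.proteins],
                "protein_name": [p.protein_name for p in self.proteins],
            }
        )
        frame.to_csv(path, sep="\t", index=False)


_HEADER_TOKEN_RE = re.compile(r"\b(GN|CHR|PE|GID|ISO)=(\S+)")


def _annotation_from_description(description: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _HEADER_TOKEN_RE.finditer(description)}


def parse_reference(
    fasta_source: str | Path,
    annotation_source: str | Path | None = None,
    *,
    strict: bool = True,
) -> ReferenceDB:
    """Load an annotated reference proteome.

    Parameters
    ----------
    fasta_source
        FASTA file; the record id is the accession.  When no annotation table
        is given, ``GN=`` / ``CHR=`` / ``PE=`` tokens in the description line
        are honoured as a single-file dialect.
    annotation_source
        Optional TSV with header columns ``accession``, ``gene``,
        ``chromosome``, ``pe_level`` (``isoform_id``, ``gene_id`` and
        ``protein_name`` optional).
    strict
        When True an accession missing from the annotation table is an error;
        when False it defaults to PE1 / unplaced with a logged warning.
    """
    annotations: dict[str, dict] = {}
    if annotation_source is not None:
        table = pd.read_csv(annotation_source, sep="\t", dtype=str).fillna("")
        required = {"accession", "gene", "chromosome", "pe_level"}
        missing_cols = required - set(table.columns)
        if missing_cols:
            raise ValueError(
                f"annotation table {annotation_source} lacks required "
                f"columns: {sorted(missing_cols)}"
            )
        for _, row in table.iterrows():
            acc = row["accession"].strip()
            if acc in annotations:
                raise ValueError(f"duplicate accession {acc!r} in annotation table")
            annotations[acc] = {
                "gene": row["gene"].strip(),
                "chromosome": row["chromosome"].strip(),
                "pe_level": PELevel.from_value(row["pe_level"]),
                "isoform_id": row.get("isoform_id", "").strip() or None,
                "gene_id": row.get("gene_id", "").strip() or None,
                "protein_name": row.get("protein_name", "").strip(),
            }

    proteins: list[ReferenceProtein] = []
    for record in SeqIO.parse(str(fasta_source), "fasta"):
        accession = record.id.strip()
        if not accession:
            raise ValueError(f"{fasta_source}: FASTA record with empty id")
        sequence = str(record.seq).upper()
        if not sequence:
            raise ValueError(f"{fasta_source}: record {accession!r} has no sequence")
        if annotation_source is not None:
            ann = annotations.get(accession)
            if ann is None:
                if strict:
                    raise ValueError(
                        f"record {accession!r} has no row in the annotation table"
                    )
                logger.warning(
                    "record %r unannotated; defaulting to PE1/unplaced", accession
                )
                ann = {"gene": "", "chromosome": "unplaced", "pe_level": PELevel.PE1}
        else:
            tokens = _annotation_from_description(record.description)
            ann = {
                "gene": tokens.get("GN", ""),
                "chromosome": tokens.get("CHR", "unplaced"),
                "pe_level": PELevel.from_value(tokens["PE"])
                if "PE" in tokens
                else PELevel.PE1,
                "isoform_id": tokens.get("ISO"),
                "gene_id": tokens.get("GID"),
            }
        try:
            proteins.append(
                ReferenceProtein(
                    accession=accession,
                    sequence=sequence,
                    gene=ann.get("gene", ""),
                    chromosome=ann.get("chromosome", "unplaced"),
                    pe_level=ann.get("pe_level", PELevel.PE1),
                    isoform_id=ann.get("isoform_id"),
                    gene_id=ann.get("gene_id"),
                    protein_name=ann.get("protein_name", ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {accession!r}: {exc}") from exc

    if not proteins:
        logger.warning("reference %s contains no sequences", fasta_source)
    return ReferenceDB(proteins)


# ---------------------------------------------------------------------------
# Packaged fixture: the 41 tumorigenesis-associated identifications.

TABLE1_COLUMNS = (
    "group",
    "accession",
    "chromosome",
    "gene_name",
    "protein_name",
    "gene_id",
    "evidence_label",
)

TABLE1_GROUPS = ("III", "IV", "V")


@dataclass(frozen=True)
class Table1Record:
    """One row of the packaged 41-protein tumorigenesis table."""

    group: str
    accession: str
    chromosome: str
    gene_name: str
    protein_name: str
    gene_id: str
    evidence_label: str

    def __post_init__(self) -> None:
        for name in TABLE1_COLUMNS:
            if not getattr(self, name) or not str(getattr(self, name)).strip():
                raise ValueError(f"fixture record field {name!r} must be non-empty")
        if self.group not in TABLE1_GROUPS:
            raise ValueError(f"fixture group must be one of {TABLE1_GROUPS}")
        if self.evidence_label not in FIXTURE_EVIDENCE_LABELS:
            raise ValueError(
                f"unknown evidence label {self.evidence_label!r}; accepted: "
                f"{FIXTURE_EVIDENCE_LABELS}"
            )

    @property
    def pe_level(self) -> PELevel:
        return PELevel.from_value(self.evidence_label)

    @property
    def isoform_id(self) -> str | None:
        """Isoform suffix carried by the printed gene name (e.g. NEK10-016)."""
        m = re.fullmatch(r"(.+)-(\d{3})", self.gene_name)
        return self.gene_name if m else None

    @property
    def base_gene(self) -> str:
        m = re.fullmatch(r"(.+)-(\d{3})", self.gene_name)
        return m.group(1) if m else self.gene_name

    @property
    def chromosome_token(self) -> str:
        return normalize_chromosome(self.chromosome)


def read_table1_tsv(path: str | Path) -> list[Table1Record]:
    """Read a fixture-schema TSV into validated records, preserving row order."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = set(TABLE1_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"{path}: fixture lacks columns {sorted(missing_cols)}")
    return [
        Table1Record(**{col: row[col] for col in TABLE1_COLUMNS})
        for _, row in frame.iterrows()
    ]


def write_table1_tsv(records: Sequence[Table1Record], path: str | Path) -> None:
    frame = pd.DataFrame(
        [{col: getattr(rec, col) for col in TABLE1_COLUMNS} for rec in records],
        columns=list(TABLE1_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> list[Table1Record]:
    """Load the packaged 41-row tumorigenesis table (groups III-V)."""
    ref = resources.files("missingprot").joinpath("data/table1.tsv")
    try:
        with resources.as_file(ref) as path:
            records = read_table1_tsv(path)
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise RuntimeError("packaged fixture data/table1.tsv is missing") from exc
    if not records:
        raise RuntimeError("packaged fixture data/table1.tsv is empty")
    return records
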