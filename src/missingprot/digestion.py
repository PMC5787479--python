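"""In-silico tryptic digestion and the peptide -> protein lookup index.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the
next residue is proline.  Peptides with up to ``max_missed_cleavages``
uncut internal sites are enumerated by concatenating runs of consecutive
base fragments; the conventional observable length window (6-50 residues by
default) is applied after enumeration.

The index maps every canonical peptide string to the set of accessions whose
digest produces it; uniqueness (proteotypic status) can then be read off at
the protein or the gene level.  Optionally isoleucine and leucine are
collapsed (I -> L) because they are isobaric and indistinguishable by MS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

from .reference import VALID_RESIDUES, ReferenceDB


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of the in-silico digest.

    ``max_missed_cleavages`` defaults to 2, mirroring the common search-engine
    setting for tryptic searches; ``min_length``/``max_length`` bound the
    peptides considered observable.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    il_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0 or self.max_missed_cleavages > 10:
            raise ValueError("max_missed_cleavages must be in [0, 10]")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")

    def canonicalize(self, peptide: str) -> str:
        """Canonical key form of a peptide under these parameters."""
        return peptide.replace("I", "L") if self.il_equivalent else peptide


#: Digest parameters without a length filter, for rule-level reasoning.
UNFILTERED = DigestionParams(min_length=1, max_length=10**9)


class DigestedPeptide(NamedTuple):
    peptide: str
    start: int  # 0-based, inclusive
    missed_cleavages: int


def _validate_sequence(sequence: str) -> None:
    for pos, residue in enumerate(sequence):
        if residue not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {residue!r} at position {pos} "
                "(uppercase standard amino acids plus X expected)"
            )


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    A cut follows K or R unless the next residue is P; the C-terminus is not
    a cleavage site.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def base_fragments(sequence: str) -> list[tuple[str, int]]:
    """Fully cleaved (zero missed cleavage) fragments with start positions."""
    sites = cleavage_sites(sequence)
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(sequence)]
    return [(sequence[a:b], a) for a, b in zip(starts, ends)]


def digest(
    sequence: str, params: DigestionParams = DigestionParams()
) -> list[DigestedPeptide]:
    """Enumerate tryptic peptides with up to ``params.max_missed_cleavages``
    missed cleavages, applying the length window afterwards.

    Results are ordered by start position, then by missed-cleavage count.
    """
    if not sequence:
        return []
    _validate_sequence(sequence)
    frags = base_fragments(sequence)
    out: list[DigestedPeptide] = []
    for i, (_, start) in enumerate(frags):
        piece = ""
        for k in range(params.max_missed_cleavages + 1):
            if i + k >= len(frags):
                break
            piece += frags[i + k][0]
            if params.min_length <= len(piece) <= params.max_length:
                out.append(DigestedPeptide(piece, start, k))
    return out


@dataclass
class PeptideIndex:
    """Map from canonical tryptic peptide to the accessions containing it."""

    params: DigestionParams
    entries: dict[str, frozenset[str]]
    source_token: str

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, peptide: str) -> frozenset[str]:
        """Accessions whose digest contains the peptide (empty when absent
        or when the peptide carries an X ambiguity code)."""
        if "X" in peptide:
            return frozenset()
        return self.entries.get(self.params.canonicalize(peptide), frozenset())

    def to_tsv(self, path, params_sidecar=None) -> None:
        """Export as two-column TSV (peptide, ;-joined accessions) plus an
        optional JSON sidecar recording the digestion parameters."""
        import json

        with open(path, "w", encoding="utf-8") as handle:
            handle.write("peptide\taccessions\n")
            for peptide in sorted(self.entries):
                accs = ";".join(sorted(self.entries[peptide]))
                handle.write(f"{peptide}\t{accs}\n")
        if params_sidecar is not None:
            with open(params_sidecar, "w", encoding="utf-8") as handle:
                json.dump(
                    {
                        "enzyme": self.params.enzyme,
                        "max_missed_cleavages": self.params.max_missed_cleavages,
                        "min_length": self.params.min_length,
                        "max_length": self.params.max_length,
                        "il_equivalent": self.params.il_equivalent,
                        "source": self.source_token,
                    },
                    handle,
                    indent=2,
                    sort_keys=True,
                )


def db_token(db: ReferenceDB) -> str:
    """Cheap identity token tying an index to the database it was built from."""
    import hashlib

    digest_ = hashlib.sha1()
    for prot in db:
        digest_.update(prot.accession.encode())
        digest_.update(b"\0")
        digest_.update(prot.sequence.encode())
        digest_.update(b"\1")
    return digest_.hexdigest()


def build_index(db: ReferenceDB, params: DigestionParams = DigestionParams()) -> PeptideIndex:
    """Digest every protein and accumulate the peptide -> accession-set map."""
    if len(db) == 0:
        raise ValueError("cannot index an empty reference database")
    acc_sets: dict[str, set[str]] = {}
    for prot in db:
        for pep, _, _ in digest(prot.sequence, params):
            acc_sets.setdefault(params.canonicalize(pep), set()).add(prot.accession)
    entries = {pep: frozenset(accs) for pep, accs in acc_sets.items()}
    return PeptideIndex(params=params, entries=entries, source_token=db_token(db))


UniquenessLevel = Literal["protein", "gene"]


def peptide_uniqueness(
    index: PeptideIndex, db: ReferenceDB, level: UniquenessLevel = "gene"
) -> dict[str, bool]:
    """Proteotypic status of every indexed peptide.

    At ``protein`` level a peptide is unique when exactly one accession
    contains it; at ``gene`` level when all containing accessions belong to
    one gene (so isoform-shared peptides remain informative).
    """
    if level not in ("protein", "gene"):
        raise ValueError(f"uniqueness level must be 'protein' or 'gene', got {level!r}")
    if index.source_token != db_token(db):
        raise ValueError("index was not built from the given reference database")
    gene_of = db.gene_of
    out: dict[str, bool] = {}
    for peptide, accs in index.entries.items():
        if level == "protein":
            out[peptide] = len(accs) == 1
        else:
            out[peptide] = len({gene_of[a] for a in accs}) == 1
    return out
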