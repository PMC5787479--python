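"""Peptide matching at 100% identity and two-unique-peptide protein inference.

Observed peptide identifications (search-engine peptide-level output) are
matched against the reference either through the tryptic peptide index or as
exact contiguous substrings of the reference sequences.  A protein is called
present when at least ``min_unique`` matched peptides are unique to it
(proteotypic); one unique peptide is treated as minimal-confidence evidence
and is not sufficient.  Replicate reproducibility is summarised by the
duplicate peptide ratio: the fraction of a sample's observed peptides seen
in at least two of its replicate runs.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import PeptideIndex, UniquenessLevel
from .reference import VALID_RESIDUES, ReferenceDB

logger = logging.getLogger(__name__)

#: Canonical study groups: wild type, knockout without tumor, knockout with
#: tumor.
GROUPS = ("WT", "KO_NT", "KO_T")

OBSERVATION_COLUMNS = ("sample_id", "group", "replicate", "peptide")


class ObservationSet:
    """Observed peptides organised by sample / group / replicate.

    Repeated (sample, replicate, peptide) rows are collapsed on load and
    counted in the ``count`` column.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"observations lack columns {sorted(missing)}")
        frame = frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["group"] = frame["group"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        frame["peptide"] = frame["peptide"].astype(str).str.upper()
        if (frame["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        bad = frame.loc[~frame["peptide"].str.fullmatch(r"[A-Z]+"), "peptide"]
        if not bad.empty:
            raise ValueError(f"non-residue peptide strings: {sorted(set(bad))[:5]}")
        invalid = {
            ch for pep in frame["peptide"].unique() for ch in pep
        } - VALID_RESIDUES
        if invalid:
            raise ValueError(f"peptides contain invalid residues {sorted(invalid)}")
        if "count" not in frame.columns:
            frame["count"] = 1
        self.frame = (
            frame.groupby(list(OBSERVATION_COLUMNS), as_index=False)["count"]
            .sum()
            .sort_values(list(OBSERVATION_COLUMNS))
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, str]]
    ) -> "ObservationSet":
        frame = pd.DataFrame(records, columns=list(OBSERVATION_COLUMNS))
        return cls(frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ObservationSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"peptide": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample_id"].unique())

    def peptides(
        self,
        *,
        group: str | None = None,
        sample_id: str | None = None,
        replicate: int | None = None,
    ) -> set[str]:
        """Distinct peptides, optionally restricted by group/sample/replicate."""
        frame = self.frame
        if group is not None:
            frame = frame[frame["group"] == group]
        if sample_id is not None:
            frame = frame[frame["sample_id"] == sample_id]
        if replicate is not None:
            frame = frame[frame["replicate"] == replicate]
        return set(frame["peptide"])

    def replicates_of(self, sample_id: str) -> list[int]:
        sel = self.frame[self.frame["sample_id"] == sample_id]
        return sorted(sel["replicate"].unique())


@dataclass(frozen=True)
class MatchPolicy:
    """How observed peptides are compared with the reference.

    ``substring`` mode calls a match whenever the peptide occurs as an exact
    contiguous substring of a reference sequence; ``tryptic_index`` restricts
    matches to in-silico tryptic peptides.  Identity is fixed at 100% and is
    not configurable.
    """

    mode: str = "substring"
    il_equivalent: bool = False

    #: Exact matching only; partial-identity search is deliberately absent.
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("substring", "tryptic_index"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.identity != 1.0:
            raise ValueError("match identity is fixed at 100%")

    def canonicalize(self, peptide: str) -> str:
        return peptide.replace("I", "L") if self.il_equivalent else peptide


class SubstringCorpus:
    """Concatenated reference sequences supporting exact-substring lookup.

    Sequences are joined with a sentinel character so a single C-level
    ``str.find`` scan locates every protein containing a peptide.
    """

    _SENTINEL = "\x00"

    def __init__(self, db: ReferenceDB, il_equivalent: bool = False):
        self.db = db
        self.il_equivalent = il_equivalent
        seqs = [
            p.sequence.replace("I", "L") if il_equivalent else p.sequence for p in db
        ]
        self._accessions = db.accessions
        starts: list[int] = []
        pos = 0
        for seq in seqs:
            starts.append(pos)
            pos += len(seq) + 1
        self._starts = starts
        self.corpus = self._SENTINEL.join(seqs)

    def find_accessions(self, peptide: str) -> frozenset[str]:
        """All accessions whose sequence contains the peptide exactly."""
        if not peptide or "X" in peptide:
            return frozenset()
        query = peptide.replace("I", "L") if self.il_equivalent else peptide
        hits: set[str] = set()
        pos = self.corpus.find(query)
        while pos != -1:
            idx = bisect.bisect_right(self._starts, pos) - 1
            hits.add(self._accessions[idx])
            pos = self.corpus.find(query, pos + 1)
        return frozenset(hits)


def match_peptides(
    observed: ObservationSet | Iterable[str],
    *,
    policy: MatchPolicy = MatchPolicy(),
    index: PeptideIndex | None = None,
    db: ReferenceDB | None = None,
    corpus: SubstringCorpus | None = None,
) -> dict[str, frozenset[str]]:
    """Match observed peptides to reference accessions at 100% identity.

    Returns a map keyed by the observed peptide string; peptides matching
    nothing (contaminants, species-specific sequences) map to the empty set
    and are tallied in a log line, never raised as errors.
    """
    peptides = (
        sorted(observed.peptides())
        if isinstance(observed, ObservationSet)
        else sorted(set(observed))
    )
    if policy.mode == "tryptic_index":
        if index is None:
            raise ValueError("tryptic_index matching requires a PeptideIndex")
        if index.params.il_equivalent != policy.il_equivalent:
            raise ValueError(
                "policy.il_equivalent must agree with the index canonicalization"
            )
        matches = {pep: index.lookup(pep) for pep in peptides}
    else:
        if corpus is None:
            if db is None:
                raise ValueError("substring matching requires a ReferenceDB")
            corpus = SubstringCorpus(db, il_equivalent=policy.il_equivalent)
        elif corpus.il_equivalent != policy.il_equivalent:
            raise ValueError(
                "policy.il_equivalent must agree with the corpus canonicalization"
            )
        matches = {pep: corpus.find_accessions(pep) for pep in peptides}
    n_unmatched = sum(1 for accs in matches.values() if not accs)
    if n_unmatched:
        logger.info(
            "%d of %d observed peptides matched no reference sequence",
            n_unmatched,
            len(matches),
        )
    return matches


def uniqueness_from_matches(
    matches: Mapping[str, frozenset[str]],
    db: ReferenceDB,
    level: UniquenessLevel = "gene",
) -> dict[str, bool]:
    """Proteotypic status derived from a match map (the matching policy's own
    notion of occurrence).  Unmatched peptides are never unique."""
    if level not in ("protein", "gene"):
        raise ValueError(f"uniqueness level must be 'protein' or 'gene', got {level!r}")
    gene_of = db.gene_of
    out: dict[str, bool] = {}
    for peptide, accs in matches.items():
        if not accs:
            out[peptide] = False
        elif level == "protein":
            out[peptide] = len(accs) == 1
        else:
            out[peptide] = len({gene_of[a] for a in accs}) == 1
    return out


@dataclass
class ProteinIdentification:
    """Per-protein evidence tally and presence verdict."""

    accession: str
    group: str | None
    unique_peptides: frozenset[str]
    shared_peptides: frozenset[str]
    min_unique_required: int = 2

    def __post_init__(self) -> None:
        if self.unique_peptides & self.shared_peptides:
            raise ValueError("unique and shared peptide sets must be disjoint")

    @property
    def present(self) -> bool:
        return len(self.unique_peptides) >= self.min_unique_required

    @property
    def n_unique(self) -> int:
        return len(self.unique_peptides)

    @property
    def n_shared(self) -> int:
        return len(self.shared_peptides)


def infer_proteins(
    matches: Mapping[str, frozenset[str]],
    uniqueness: Mapping[str, bool],
    *,
    min_unique: int = 2,
    group: str | None = None,
) -> list[ProteinIdentification]:
    """Apply the >=2-unique-peptide presence rule to a match map.

    Each matched accession receives its unique and shared matched peptides;
    accessions with no matched peptide do not appear.  ``uniqueness`` must be
    computed under the same matching policy as ``matches``.
    """
    if min_unique < 1:
        raise ValueError("min_unique must be at least 1")
    unique_by_acc: dict[str, set[str]] = {}
    shared_by_acc: dict[str, set[str]] = {}
    for peptide in sorted(matches):
        accs = matches[peptide]
        if not accs:
            continue
        target = unique_by_acc if uniqueness.get(peptide, False) else shared_by_acc
        for acc in accs:
            target.setdefault(acc, set()).add(peptide)
    out = []
    for acc in sorted(set(unique_by_acc) | set(shared_by_acc)):
        out.append(
            ProteinIdentification(
                accession=acc,
                group=group,
                unique_peptides=frozenset(unique_by_acc.get(acc, ())),
                shared_peptides=frozenset(shared_by_acc.get(acc, ())),
                min_unique_required=min_unique,
            )
        )
    return out


def duplicate_peptide_ratio(obs: ObservationSet, sample_id: str) -> float:
    """Fraction of a sample's peptides observed in at least two replicates.

    The denominator is the union of peptides over the sample's replicates.
    """
    replicates = obs.replicates_of(sample_id)
    if len(replicates) < 2:
        raise ValueError(
            f"sample {sample_id!r} has {len(replicates)} replicate(s); "
            "the duplicate peptide ratio needs at least two - skip this sample"
        )
    per_rep = [obs.peptides(sample_id=sample_id, replicate=r) for r in replicates]
    union: set[str] = set().union(*per_rep)
    if not union:
        return 0.0
    seen_twice = {p for p in union if sum(p in rep for rep in per_rep) >= 2}
    return len(seen_twice) / len(union)


def duplicate_ratio_summary(obs: ObservationSet) -> dict:
    """Per-sample ratios plus unweighted per-group and overall means.

    Samples with fewer than two replicates are skipped with a warning.
    """
    per_sample: dict[str, float] = {}
    group_of: dict[str, str] = {}
    for sample in obs.samples:
        sel = obs.frame[obs.frame["sample_id"] == sample]
        group_of[sample] = sel["group"].iloc[0]
        try:
            per_sample[sample] = duplicate_peptide_ratio(obs, sample)
        except ValueError:
            logger.warning("sample %r skipped: fewer than two replicates", sample)
    per_group: dict[str, float] = {}
    for group in sorted(set(group_of.values())):
        ratios = [r for s, r in per_sample.items() if group_of[s] == group]
        if ratios:
            per_group[group] = sum(ratios) / len(ratios)
    overall = sum(per_sample.values()) / len(per_sample) if per_sample else float("nan")
    return {"per_sample": per_sample, "per_group": per_group, "overall": overall}
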