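"""Missing-protein classification, chromosome reporting and three-group
overlap partitioning.

A protein is a "missing protein" when its protein-existence level is PE2,
PE3 or PE4 (transcript-level evidence, homology inference or prediction
only); PE1 proteins are known and PE5 (uncertain) entries are excluded from
the missing band.  Present proteins from the three study groups (wild type,
knockout without tumor, knockout with tumor) are partitioned into the seven
membership patterns of a three-set Venn diagram; the regions observed only
after knockout carry the conventional labels III (both knockout groups, not
wild type), IV (knockout-without-tumor only) and V (knockout-with-tumor
only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .identification import GROUPS
from .reference import (
    CHROMOSOME_ORDER,
    PELevel,
    ReferenceDB,
    ReferenceProtein,
    Table1Record,
    normalize_chromosome,
)

_REASONS = {
    PELevel.PE1: "PE1_known",
    PELevel.PE2: "PE2_transcript",
    PELevel.PE3: "PE3_homology",
    PELevel.PE4: "PE4_predicted",
    PELevel.PE5: "PE5_uncertain",
}


@dataclass(frozen=True)
class MissingVerdict:
    accession: str
    pe_level: PELevel
    reason: str

    @property
    def is_missing(self) -> bool:
        return self.pe_level.is_missing


def classify_missing(
    protein: "ReferenceProtein | Table1Record | PELevel | str",
    accession: str | None = None,
) -> MissingVerdict:
    """Classify a protein (or bare evidence label) under the PE2-PE4 rule."""
    if isinstance(protein, ReferenceProtein):
        level, acc = protein.pe_level, protein.accession
    elif isinstance(protein, Table1Record):
        level, acc = protein.pe_level, protein.accession
    else:
        level = PELevel.from_value(protein)
        acc = accession or ""
    return MissingVerdict(accession=acc, pe_level=level, reason=_REASONS[level])


@dataclass
class ChromosomeDistribution:
    """Counts over the fixed chromosome axis (zero-count entries included)."""

    counts: dict[str, int]
    scope: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def chromosome_distribution(
    chromosomes: Iterable[str], scope: str = "all_present"
) -> ChromosomeDistribution:
    """Tally chromosome tokens over the fixed axis 1..22, X, Y, MT, unplaced.

    Labels are normalised on the way in (idempotent for already-canonical
    tokens), so fixture-style ``23×`` entries count toward X.
    """
    if scope not in ("all_present", "missing_only"):
        raise ValueError(f"unknown scope {scope!r}")
    counts = {token: 0 for token in CHROMOSOME_ORDER}
    for raw in chromosomes:
        counts[normalize_chromosome(raw)] += 1
    return ChromosomeDistribution(counts=counts, scope=scope)


def _pattern_key(pattern: Iterable[str]) -> frozenset[str]:
    pat = frozenset(pattern)
    unknown = pat - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group token(s) {sorted(unknown)}")
    if not pat:
        raise ValueError("the empty membership pattern is not admissible")
    return pat


def pattern_name(pattern: frozenset[str]) -> str:
    """Deterministic textual name of a membership pattern (WT+KO_NT+KO_T order)."""
    return "+".join(g for g in GROUPS if g in pattern)


#: Default region labels for the knockout-only patterns: III = seen in both
#: knockout groups but not wild type, IV = knockout-without-tumor only,
#: V = knockout-with-tumor only.  The remaining patterns keep their pattern
#: name.
DEFAULT_REGION_LABELS: dict[frozenset[str], str] = {
    frozenset({"KO_NT", "KO_T"}): "III",
    frozenset({"KO_NT"}): "IV",
    frozenset({"KO_T"}): "V",
}


@dataclass
class GroupPartition:
    """Membership-pattern partition of present proteins across the groups."""

    regions: dict[frozenset[str], frozenset[str]]
    labels: dict[frozenset[str], str]

    def by_label(self, label: str) -> frozenset[str]:
        for pattern, name in self.labels.items():
            if name == label:
                return self.regions[pattern]
        raise KeyError(f"no region labeled {label!r}")

    @property
    def label_of_accession(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pattern, accs in self.regions.items():
            for acc in accs:
                out[acc] = self.labels[pattern]
        return out

    def sizes(self) -> dict[str, int]:
        """Region sizes keyed by label, in deterministic label order."""
        items = sorted(
            ((self.labels[pat], len(accs)) for pat, accs in self.regions.items()),
            key=lambda kv: kv[0],
        )
        return dict(items)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for accs in self.regions.values():
            out |= accs
        return frozenset(out)


def partition_groups(
    present: Mapping[str, Iterable[str]],
    labels: Mapping[frozenset[str], str] | None = None,
) -> GroupPartition:
    """Partition accessions by their exact group-membership pattern.

    Exactly the three study groups must be supplied (empty sets allowed).
    Regions are pairwise disjoint and cover every accession present in at
    least one group; the empty pattern cannot occur.
    """
    supplied = set(present)
    if supplied != set(GROUPS):
        raise ValueError(
            f"expected exactly the groups {GROUPS}, got {sorted(supplied)}"
        )
    sets = {g: set(present[g]) for g in GROUPS}
    membership: dict[str, set[str]] = {}
    for g, accs in sets.items():
        for acc in accs:
            membership.setdefault(acc, set()).add(g)
    all_patterns = [
        frozenset(p)
        for mask in range(1, 8)
        for p in [[g for i, g in enumerate(GROUPS) if mask >> i & 1]]
    ]
    regions = {
        pat: frozenset(a for a, m in membership.items() if m == pat)
        for pat in all_patterns
    }
    label_map = {pat: DEFAULT_REGION_LABELS.get(pat, pattern_name(pat)) for pat in all_patterns}
    if labels:
        label_map.update({_pattern_key(k): v for k, v in labels.items()})
    return GroupPartition(regions=regions, labels=label_map)


REPORT_COLUMNS = (
    "group",
    "accession",
    "chromosome",
    "gene_name",
    "protein_name",
    "gene_id",
    "evidence_label",
    "is_missing",
)


@dataclass(frozen=True)
class ReportRecord:
    """One row of the tumorigenesis-style region report (fixture schema plus
    an ``is_missing`` flag)."""

    group: str
    accession: str
    chromosome: str
    gene_name: str
    protein_name: str
    gene_id: str
    evidence_label: str
    is_missing: bool

    def to_table1_record(self) -> Table1Record:
        return Table1Record(
            group=self.group,
            accession=self.accession,
            chromosome=self.chromosome,
            gene_name=self.gene_name,
            protein_name=self.protein_name,
            gene_id=self.gene_id,
            evidence_label=self.evidence_label,
        )


def _chrom_sort_key(token: str) -> int:
    return CHROMOSOME_ORDER.index(normalize_chromosome(token))


def tumorigenesis_report(
    partition: GroupPartition,
    db: ReferenceDB,
    regions_of_interest: Sequence[str] = ("III", "IV", "V"),
) -> list[ReportRecord]:
    """Emit one record per (region, accession) for the selected regions,
    ordered by region label, then chromosome, then accession."""
    known_labels = set(partition.labels.values())
    missing_labels = set(regions_of_interest) - known_labels
    if missing_labels:
        raise ValueError(f"partition has no region(s) labeled {sorted(missing_labels)}")
    records: list[ReportRecord] = []
    for label in regions_of_interest:
        accessions = partition.by_label(label)
        rows = []
        for acc in accessions:
            prot = db[acc]
            verdict = classify_missing(prot)
            rows.append(
                ReportRecord(
                    group=label,
                    accession=acc,
                    chromosome=prot.chromosome,
                    gene_name=prot.isoform_id or prot.gene,
                    protein_name=prot.protein_name or prot.gene,
                    gene_id=prot.gene_id or "-",
                    evidence_label=prot.pe_level.label,
                    is_missing=verdict.is_missing,
                )
            )
        rows.sort(key=lambda r: (_chrom_sort_key(r.chromosome), r.accession))
        records.extend(rows)
    return records


def report_from_table1(records: Sequence[Table1Record]) -> list[ReportRecord]:
    """Re-emit fixture records through the report schema, classifying each
    row's evidence label under the PE2-PE4 missing rule.  Row order is kept."""
    return [
        ReportRecord(
            group=rec.group,
            accession=rec.accession,
            chromosome=rec.chromosome,
            gene_name=rec.gene_name,
            protein_name=rec.protein_name,
            gene_id=rec.gene_id,
            evidence_label=rec.evidence_label,
            is_missing=classify_missing(rec).is_missing,
        )
        for rec in records
    ]


def write_report_tsv(records: Sequence[ReportRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {col: getattr(rec, col) for col in REPORT_COLUMNS}
            for rec in records
        ],
        columns=list(REPORT_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def read_report_tsv(path: str | Path) -> list[ReportRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(REPORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: report lacks columns {sorted(missing)}")
    return [
        ReportRecord(
            group=row["group"],
            accession=row["accession"],
            chromosome=row["chromosome"],
            gene_name=row["gene_name"],
            protein_name=row["protein_name"],
            gene_id=row["gene_id"],
            evidence_label=row["evidence_label"],
            is_missing=str(row["is_missing"]).strip().lower() in ("true", "1"),
        )
        for _, row in frame.iterrows()
    ]
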