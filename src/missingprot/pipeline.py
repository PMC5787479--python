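"""End-to-end orchestration: parse -> digest/index -> match -> infer ->
classify -> partition -> report, with deterministic output artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .digestion import DigestionParams, build_index, peptide_uniqueness
from .groups import (
    GroupPartition,
    chromosome_distribution,
    classify_missing,
    partition_groups,
    tumorigenesis_report,
    write_report_tsv,
)
from .identification import (
    GROUPS,
    MatchPolicy,
    ObservationSet,
    SubstringCorpus,
    duplicate_ratio_summary,
    infer_proteins,
    match_peptides,
    uniqueness_from_matches,
)
from .reference import parse_reference

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    reference: Path
    observations: Path
    out_dir: Path
    annotations: Path | None = None
    digestion: DigestionParams = field(default_factory=DigestionParams)
    match_mode: str = "substring"
    min_unique: int = 2
    uniqueness_level: str = "gene"
    region_labels: Mapping[frozenset, str] | None = None
    strict_annotations: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.reference = Path(self.reference)
        self.observations = Path(self.observations)
        self.out_dir = Path(self.out_dir)
        if self.annotations is not None:
            self.annotations = Path(self.annotations)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output artifacts.

    Writes ``identifications.tsv``, ``report.tsv``, ``unmatched_peptides.tsv``
    and ``summary.json`` into ``config.out_dir`` and returns the summary
    dictionary.  Outputs are byte-identical across runs with identical inputs
    and configuration.
    """
    for label, path in (
        ("reference FASTA", config.reference),
        ("observations TSV", config.observations),
        ("annotation TSV", config.annotations),
    ):
        if path is not None and not Path(path).exists():
            raise PipelineError("inputs", f"{label} not found: {path}")

    try:
        db = parse_reference(
            config.reference, config.annotations, strict=config.strict_annotations
        )
    except ValueError as exc:
        raise PipelineError("parse", str(exc)) from exc
    if len(db) == 0:
        raise PipelineError("parse", f"reference {config.reference} is empty")

    try:
        obs = ObservationSet.from_tsv(config.observations)
    except (ValueError, KeyError) as exc:
        raise PipelineError("observations", str(exc)) from exc

    policy = MatchPolicy(
        mode=config.match_mode, il_equivalent=config.digestion.il_equivalent
    )
    try:
        if policy.mode == "tryptic_index":
            index = build_index(db, config.digestion)
            matches = match_peptides(obs, policy=policy, index=index)
            uniq_all = peptide_uniqueness(index, db, config.uniqueness_level)
            uniqueness = {
                pep: uniq_all.get(config.digestion.canonicalize(pep), False)
                for pep in matches
            }
        else:
            corpus = SubstringCorpus(db, il_equivalent=policy.il_equivalent)
            matches = match_peptides(obs, policy=policy, corpus=corpus)
            uniqueness = uniqueness_from_matches(matches, db, config.uniqueness_level)
    except ValueError as exc:
        raise PipelineError("match", str(exc)) from exc

    try:
        idents_by_group = {}
        for group in obs.groups:
            group_peps = obs.peptides(group=group)
            group_matches = {p: matches[p] for p in group_peps}
            idents_by_group[group] = infer_proteins(
                group_matches, uniqueness, min_unique=config.min_unique, group=group
            )
    except ValueError as exc:
        raise PipelineError("infer", str(exc)) from exc

    present = {
        g: {pi.accession for pi in idents if pi.present}
        for g, idents in idents_by_group.items()
    }
    for g in GROUPS:
        present.setdefault(g, set())

    try:
        partition = partition_groups(
            {g: present[g] for g in GROUPS}, labels=config.region_labels
        )
        report = tumorigenesis_report(partition, db)
    except (ValueError, KeyError) as exc:
        raise PipelineError("partition", str(exc)) from exc

    union_present = sorted(set().union(*present.values()) if present else set())
    missing_union = [a for a in union_present if classify_missing(db[a]).is_missing]
    chrom_all = chromosome_distribution(
        (db[a].chromosome for a in union_present), "all_present"
    )
    chrom_missing = chromosome_distribution(
        (db[a].chromosome for a in missing_union), "missing_only"
    )
    ratios = duplicate_ratio_summary(obs)

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for group in sorted(idents_by_group):
        for pi in idents_by_group[group]:
            prot = db[pi.accession]
            rows.append(
                {
                    "group": group,
                    "accession": pi.accession,
                    "gene": prot.gene,
                    "chromosome": prot.chromosome,
                    "pe_level": prot.pe_level.name,
                    "n_unique": pi.n_unique,
                    "n_shared": pi.n_shared,
                    "present": pi.present,
                    "is_missing": classify_missing(prot).is_missing,
                }
            )
    idents_frame = pd.DataFrame(
        rows,
        columns=[
            "group",
            "accession",
            "gene",
            "chromosome",
            "pe_level",
            "n_unique",
            "n_shared",
            "present",
            "is_missing",
        ],
    )
    idents_frame.to_csv(out / "identifications.tsv", sep="\t", index=False)
    write_report_tsv(report, out / "report.tsv")

    unmatched = sorted(p for p, accs in matches.items() if not accs)
    pep_counts = obs.frame.groupby("peptide")["count"].sum()
    pd.DataFrame(
        {"peptide": unmatched, "n_records": [int(pep_counts[p]) for p in unmatched]}
    ).to_csv(out / "unmatched_peptides.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "match_mode": config.match_mode,
            "min_unique": config.min_unique,
            "uniqueness_level": config.uniqueness_level,
            "max_missed_cleavages": config.digestion.max_missed_cleavages,
            "min_length": config.digestion.min_length,
            "max_length": config.digestion.max_length,
            "il_equivalent": config.digestion.il_equivalent,
        },
        "n_reference_proteins": len(db),
        "n_observed_peptides": len(matches),
        "n_unmatched_peptides": len(unmatched),
        "present_per_group": {g: len(present[g]) for g in GROUPS},
        "missing_per_group": {
            g: sum(1 for a in present[g] if classify_missing(db[a]).is_missing)
            for g in GROUPS
        },
        "n_present_total": len(union_present),
        "n_missing_total": len(missing_union),
        "region_sizes": partition.sizes(),
        "chromosome_histogram_all_present": chrom_all.counts,
        "chromosome_histogram_missing_only": chrom_missing.counts,
        "duplicate_ratios": ratios,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
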