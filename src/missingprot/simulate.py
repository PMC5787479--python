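"""Synthetic annotated proteome and peptide-observation generator.

Emulates the study design the pipeline targets: a protein-existence
annotated reference proteome, three comparison groups (wild type, knockout
without tumor, knockout with tumor) with known ground-truth protein content,
three replicate MS runs per pooled sample, per-replicate Bernoulli peptide
detection, occasional missed-cleavage variants, and contaminant peptides
that match nothing in the reference.

Ground truth records, per group, both the designed protein content and the
subset that is detectable at all under the two-unique-peptide rule (proteins
carrying at least two substring-unique in-bounds tryptic peptides), so
end-to-end recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import DigestionParams, base_fragments, digest
from .groups import DEFAULT_REGION_LABELS, pattern_name
from .identification import GROUPS, MatchPolicy, ObservationSet, SubstringCorpus
from .reference import CHROMOSOME_ORDER, PELevel, ReferenceDB, ReferenceProtein

#: Residue alphabet for sequence generation: K and R at 5.5% each so tryptic
#: sites exist, the remaining 18 standard residues uniform.
_ALPHABET = np.array(list("ACDEFGHLMNPQSTVWY" + "I" + "KR"))
_RESIDUE_P = np.array([0.89 / 18] * 18 + [0.055, 0.055])

_PE_LEVELS = (PELevel.PE1, PELevel.PE2, PELevel.PE3, PELevel.PE4, PELevel.PE5)

#: Default chromosome weights: autosomes and X equally likely, Y and MT rare.
_DEFAULT_CHROM_WEIGHTS = tuple([1.0] * 22 + [1.0, 0.1, 0.05])
_CHROM_TOKENS = CHROMOSOME_ORDER[:25]  # 1..22, X, Y, MT


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: three groups holding 33 / 88 / 48
    proteins, three replicate runs per pooled sample, 70% per-replicate
    peptide detection (which puts the expected duplicate peptide ratio near
    80%), 15% missed-cleavage emission and 5% contaminant peptides.
    """

    n_proteins: int = 300
    pe_distribution: Sequence[float] = (0.55, 0.25, 0.05, 0.10, 0.05)
    chromosome_weights: Sequence[float] = _DEFAULT_CHROM_WEIGHTS
    mean_protein_length: int = 450
    min_protein_length: int = 60
    groups_truth_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 33, "KO_NT": 88, "KO_T": 48}
    )
    region_design: Mapping[str, int] | None = None
    detection_prob: float = 0.7
    missed_cleavage_emission: float = 0.15
    contaminant_rate: float = 0.05
    replicates: int = 3
    seed: int = 0
    digestion: DigestionParams = field(default_factory=DigestionParams)

    def __post_init__(self) -> None:
        for name, vec in (
            ("pe_distribution", self.pe_distribution),
            ("chromosome_weights", self.chromosome_weights),
        ):
            arr = np.asarray(vec, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
            if name == "pe_distribution" and abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("pe_distribution must sum to 1")
        for name, p in (
            ("detection_prob", self.detection_prob),
            ("missed_cleavage_emission", self.missed_cleavage_emission),
            ("contaminant_rate", self.contaminant_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if any(v < 0 for v in self.groups_truth_sizes.values()):
            raise ValueError("groups_truth_sizes must be non-negative")
        if set(self.groups_truth_sizes) - set(GROUPS):
            raise ValueError(f"groups_truth_sizes keys must be among {GROUPS}")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if len(self.pe_distribution) != 5:
            raise ValueError("pe_distribution must cover PE1..PE5")
        if len(self.chromosome_weights) != len(_CHROM_TOKENS):
            raise ValueError(
                f"chromosome_weights must cover the {len(_CHROM_TOKENS)} tokens "
                f"{_CHROM_TOKENS}"
            )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent child streams per stage, all rooted at the single seed.
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_proteome(config: SimulationConfig) -> ReferenceDB:
    """Generate ``n_proteins`` random annotated sequences, deterministically
    for a fixed seed.  Lengths follow a shifted geometric distribution around
    ``mean_protein_length``; accessions are SYN00001, SYN00002, ..."""
    if config.n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    rng = _rng(config, 1)
    spread = max(config.mean_protein_length - config.min_protein_length, 1)
    lengths = config.min_protein_length + rng.geometric(1.0 / spread, config.n_proteins)
    pe_levels = rng.choice(5, size=config.n_proteins, p=np.asarray(config.pe_distribution))
    chrom_w = np.asarray(config.chromosome_weights, dtype=float)
    chroms = rng.choice(len(_CHROM_TOKENS), size=config.n_proteins, p=chrom_w / chrom_w.sum())
    proteins = []
    for i in range(config.n_proteins):
        seq = "".join(rng.choice(_ALPHABET, size=int(lengths[i]), p=_RESIDUE_P))
        acc = f"SYN{i + 1:05d}"
        proteins.append(
            ReferenceProtein(
                accession=acc,
                sequence=seq,
                gene=f"SYNG{i + 1:05d}",
                gene_id=f"ENSGSYN{i + 1:011d}",
                chromosome=_CHROM_TOKENS[chroms[i]],
                pe_level=_PE_LEVELS[pe_levels[i]],
                protein_name=f"Synthetic protein {i + 1}",
            )
        )
    return ReferenceDB(proteins)


@dataclass
class SyntheticTruth:
    """Designed ground truth for one simulated study."""

    db: ReferenceDB
    present_by_group: dict[str, frozenset[str]]
    expected_detectable: dict[str, frozenset[str]]
    pattern_of: dict[str, frozenset[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "present_by_group": {
                g: sorted(accs) for g, accs in self.present_by_group.items()
            },
            "expected_detectable": {
                g: sorted(accs) for g, accs in self.expected_detectable.items()
            },
            "pattern_of": {
                acc: pattern_name(pat) for acc, pat in sorted(self.pattern_of.items())
            },
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)


def detectable_unique_peptide_counts(
    db: ReferenceDB, params: DigestionParams
) -> dict[str, int]:
    """Per accession: number of distinct in-bounds zero-missed-cleavage
    peptides occurring, as a substring, in exactly one gene's sequences."""
    corpus = SubstringCorpus(db, il_equivalent=params.il_equivalent)
    gene_of = db.gene_of
    pep_by_acc = {
        p.accession: {
            pep for pep, _, mc in digest(p.sequence, params) if mc == 0
        }
        for p in db
    }
    unique: dict[str, bool] = {}
    for pep in sorted(set().union(*pep_by_acc.values()) if pep_by_acc else set()):
        genes = {gene_of[a] for a in corpus.find_accessions(pep)}
        unique[pep] = len(genes) == 1
    return {
        acc: sum(1 for pep in peps if unique.get(pep, False))
        for acc, peps in pep_by_acc.items()
    }


_LABEL_TO_PATTERN: dict[str, frozenset[str]] = {
    **{v: k for k, v in DEFAULT_REGION_LABELS.items()},
    **{
        pattern_name(frozenset(p)): frozenset(p)
        for p in (
            {"WT"},
            {"KO_NT"},
            {"KO_T"},
            {"WT", "KO_NT"},
            {"WT", "KO_T"},
            {"KO_NT", "KO_T"},
            {"WT", "KO_NT", "KO_T"},
        )
    },
}


def make_region_design(
    config: SimulationConfig, db: ReferenceDB | None = None, *, min_unique: int = 2
) -> SyntheticTruth:
    """Assign proteins to group-membership patterns.

    With an explicit ``region_design`` (map region label or pattern name ->
    count) proteins are allotted to those patterns exactly, the remainder
    wild-type-only, so partitioning the truth reproduces the design.  Without
    one, each group independently receives ``groups_truth_sizes[group]``
    random proteins.
    """
    if db is None:
        db = generate_proteome(config)
    rng = _rng(config, 2)
    accs = list(db.accessions)
    pattern_of: dict[str, frozenset[str]] = {}

    if config.region_design is not None:
        total = sum(config.region_design.values())
        if total > len(accs):
            raise ValueError(
                f"region design needs {total} proteins but only {len(accs)} exist"
            )
        unknown = set(config.region_design) - set(_LABEL_TO_PATTERN)
        if unknown:
            raise ValueError(f"unknown region label(s) {sorted(unknown)}")
        order = list(rng.permutation(accs))
        cursor = 0
        for label in sorted(config.region_design):
            count = config.region_design[label]
            pattern = _LABEL_TO_PATTERN[label]
            for acc in order[cursor : cursor + count]:
                pattern_of[acc] = pattern
            cursor += count
        for acc in order[cursor:]:
            pattern_of[acc] = frozenset({"WT"})
    else:
        member: dict[str, set[str]] = {acc: set() for acc in accs}
        for group in GROUPS:
            size = min(config.groups_truth_sizes.get(group, 0), len(accs))
            chosen = rng.choice(len(accs), size=size, replace=False)
            for idx in chosen:
                member[accs[idx]].add(group)
        pattern_of = {
            acc: frozenset(groups) for acc, groups in member.items() if groups
        }

    present_by_group = {
        g: frozenset(acc for acc, pat in pattern_of.items() if g in pat)
        for g in GROUPS
    }
    counts = detectable_unique_peptide_counts(db, config.digestion)
    expected_detectable = {
        g: frozenset(a for a in present_by_group[g] if counts[a] >= min_unique)
        for g in GROUPS
    }
    return SyntheticTruth(
        db=db,
        present_by_group=present_by_group,
        expected_detectable=expected_detectable,
        pattern_of=pattern_of,
    )


def _mc_variants(fragments: list[tuple[str, int]], i: int, max_mc: int) -> list[str]:
    """Missed-cleavage peptides (1..max_mc uncut sites) covering fragment i."""
    variants = []
    for mc in range(1, max_mc + 1):
        for j in range(max(0, i - mc), min(i, len(fragments) - mc - 1) + 1):
            variants.append("".join(frag for frag, _ in fragments[j : j + mc + 1]))
    return variants


def simulate_observations(
    truth: SyntheticTruth, config: SimulationConfig
) -> ObservationSet:
    """Simulate per-group, per-replicate peptide detections.

    Every in-bounds zero-missed-cleavage peptide of every present protein is
    detected independently with probability ``detection_prob`` in each
    replicate; a detected peptide is, with probability
    ``missed_cleavage_emission``, reported as a missed-cleavage variant
    covering it.  Contaminants are random strings verified to match no
    reference sequence.
    """
    rng = _rng(config, 3)
    params = config.digestion
    corpus = SubstringCorpus(truth.db, il_equivalent=False)
    frag_cache = {
        acc: base_fragments(truth.db[acc].sequence)
        for accs in truth.present_by_group.values()
        for acc in accs
    }
    records: list[tuple[str, str, int, str]] = []
    for group in GROUPS:
        sample_id = f"{group}_pool"
        for rep in range(1, config.replicates + 1):
            n_real = 0
            for acc in sorted(truth.present_by_group[group]):
                frags = frag_cache[acc]
                for i, (frag, _) in enumerate(frags):
                    if not params.min_length <= len(frag) <= params.max_length:
                        continue
                    if rng.random() >= config.detection_prob:
                        continue
                    peptide = frag
                    if (
                        config.missed_cleavage_emission > 0
                        and rng.random() < config.missed_cleavage_emission
                    ):
                        variants = _mc_variants(
                            frags, i, min(params.max_missed_cleavages, 2)
                        )
                        if variants:
                            peptide = variants[rng.integers(len(variants))]
                    records.append((sample_id, group, rep, peptide))
                    n_real += 1
            if config.contaminant_rate > 0 and n_real:
                n_contam = int(
                    round(n_real * config.contaminant_rate / (1 - config.contaminant_rate))
                )
                made = 0
                while made < n_contam:
                    length = int(rng.integers(8, 26))
                    pep = "".join(rng.choice(_ALPHABET, size=length, p=_RESIDUE_P))
                    if corpus.find_accessions(pep):
                        continue  # rare: drew a real substring, redraw
                    records.append((sample_id, group, rep, pep))
                    made += 1
    return ObservationSet.from_records(records)


def write_inputs(
    truth: SyntheticTruth, obs: ObservationSet, out_dir: str | Path
) -> dict[str, Path]:
    """Emit the exact input files the pipeline consumes, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "annotations": out / "annotations.tsv",
        "observations": out / "observations.tsv",
        "truth": out / "truth.json",
    }
    truth.db.to_fasta(paths["reference"])
    truth.db.to_annotation_tsv(paths["annotations"])
    obs.to_tsv(paths["observations"])
    truth.to_json(paths["truth"])
    return paths
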