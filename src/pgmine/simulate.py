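"""Synthetic transcriptome bundles with planted pathway genes.

The generator builds MMETSP-style bundles in which everything the
pipeline should recover is known: which enzyme functions were planted in
which species, which transcripts are redundant copies of the same gene,
and what the true expression means are.  Each species gets one gene per
planted function (a random peptide backbone), each transcriptome of the
species carries ``copies_per_gene`` transcripts of that gene — the
original plus copies mutated to a controlled amino-acid identity — and a
configurable number of decoy transcripts carrying non-pathway
annotations.  A fraction of decoys carry "near-miss" descriptions that
contain the query term but canonicalize to no vocabulary entry
(e.g. "Prostaglandin transporter"), exercising the rule that keyword
matching alone must not produce assignments.

Replicate-to-replicate count variability follows a gamma-mixed Poisson
(negative-binomial-like) model with Var = m + dispersion * m^2; a
dispersion of exactly 0 selects a degenerate deterministic model
(counts = round(mean)), useful for replicate-identity checks.  The
library total is held fixed at ``total_read_pairs_mean`` so analytic
FPKM expectations are exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    AMINO_ACIDS,
    AnnotationHit,
    TranscriptRecord,
    TranscriptomeBundle,
    write_bundle,
)
from .vocabulary import FUNCTION_ORDER, EnzymeFunction, load_vocabulary

_PLAIN_DECOY_DESCRIPTIONS = [
    "60S ribosomal protein L7",
    "40S ribosomal protein S3",
    "Photosystem II protein D1",
    "Photosystem I P700 chlorophyll a apoprotein A1",
    "Heat shock protein 70",
    "ATP synthase subunit beta",
    "Tubulin alpha chain",
    "Histone H3",
    "Elongation factor 1-alpha",
    "Ribulose bisphosphate carboxylase large chain",
]

#: Contain the query term but must NOT canonicalize to any function code.
_NEAR_MISS_DESCRIPTIONS = [
    "Prostaglandin transporter",
    "Prostaglandin E2 receptor EP4 subtype",
    "Prostaglandin D2 receptor",
]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic-bundle experiment.

    Defaults describe a small desk-scale experiment: three species with
    two replicate transcriptomes each, four planted functions per
    species, three redundant copies per gene at 95% amino-acid identity,
    and fifty decoy transcripts per transcriptome with a tenth of the
    decoys carrying near-miss annotations.
    """

    n_species: int = 3
    transcriptomes_per_species: int = 2
    planted_functions: dict[str, list[str]] | None = None
    functions_per_species: int = 4
    copies_per_gene: int = 3
    copy_identity: float = 0.95
    n_decoy_transcripts: int = 50
    decoy_annotation_rate: float = 0.1
    expression_level: dict[tuple[str, str], float] | None = None
    default_expression: float = 200.0
    decoy_expression: float = 50.0
    dispersion: float = 0.5
    total_read_pairs_mean: int = 1_000_000
    peptide_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.copy_identity <= 1.0):
            raise ValueError("copy_identity must be in [0, 1]")
        if self.copies_per_gene < 1:
            raise ValueError("copies_per_gene must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.n_species, self.transcriptomes_per_species) < 1:
            raise ValueError("need at least one species and one transcriptome")
        if self.n_decoy_transcripts < 0:
            raise ValueError("n_decoy_transcripts must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "expression_level" in raw and raw["expression_level"] is not None:
            raw["expression_level"] = {
                (sp, fn): float(v)
                for key, v in raw["expression_level"].items()
                for sp, _, fn in [key.partition("|")]
            }
        return cls(**raw)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time.

    ``planted`` maps transcriptome code -> transcript id -> function
    code; ``copy_groups`` maps a per-(species, function) gene label to
    the ids of all its redundant copies across that species' replicates;
    ``expression_means`` maps ``"species|function"`` to the configured
    mean mapped read-pair count per copy.
    """

    planted: dict[str, dict[str, str]]
    copy_groups: dict[str, list[str]]
    expression_means: dict[str, float]
    species_of: dict[str, str]
    gene_lengths: dict[str, int]
    total_read_pairs: dict[str, int]

    def presence_species(self) -> pd.DataFrame:
        """True planted species x function boolean matrix (vocabulary order)."""
        species = sorted(set(self.species_of.values()))
        mat = pd.DataFrame(False, index=species, columns=FUNCTION_ORDER)
        for code, per_tid in self.planted.items():
            sp = self.species_of[code]
            for fn in per_tid.values():
                mat.loc[sp, fn] = True
        mat = mat.loc[mat.any(axis=1)]
        mat.index.name = "species"
        return mat

    def presence_transcriptome(self) -> pd.DataFrame:
        codes = sorted(self.planted)
        mat = pd.DataFrame(False, index=codes, columns=FUNCTION_ORDER)
        for code, per_tid in self.planted.items():
            for fn in per_tid.values():
                mat.loc[code, fn] = True
        mat = mat.loc[mat.any(axis=1)]
        mat.index.name = "mmetsp_code"
        return mat

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def mutate_copy(
    sequence: str, target_identity: float, rng: np.random.Generator
) -> str:
    """Substitute exactly ``round((1 - identity) * len)`` positions.

    Every substituted position receives a residue different from the
    original; there are no insertions or deletions, so the Hamming
    identity to the input is exactly the target (up to rounding).
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0, 1]")
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    n_sub = round((1.0 - target_identity) * len(sequence))
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    residues = list(sequence)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(residues[pos], "")
        residues[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(residues)


def _random_peptide(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
    )


def _draw_count(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    if dispersion == 0:
        return int(round(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return int(rng.poisson(lam))


def generate_bundles(
    config: SimulationConfig,
    vocabulary: list[EnzymeFunction] | None = None,
) -> tuple[list[TranscriptomeBundle], SyntheticTruth]:
    """Generate bundles plus the matching truth; deterministic given the seed."""
    vocabulary = vocabulary if vocabulary is not None else load_vocabulary()
    by_code = {e.code: e for e in vocabulary}
    rng = np.random.default_rng(config.seed)

    species_names = [f"Synthspecies {i + 1:02d}" for i in range(config.n_species)]
    genus_names = [f"Synthgenus{i + 1:02d}" for i in range(config.n_species)]

    if config.planted_functions is not None:
        planted_map = {sp: list(fns) for sp, fns in config.planted_functions.items()}
        unknown = {
            fn for fns in planted_map.values() for fn in fns if fn not in by_code
        }
        if unknown:
            raise ValueError(f"planted functions not in vocabulary: {sorted(unknown)}")
    else:
        k = min(config.functions_per_species, len(FUNCTION_ORDER))
        planted_map = {
            sp: [
                FUNCTION_ORDER[j]
                for j in sorted(rng.choice(len(FUNCTION_ORDER), size=k, replace=False))
            ]
            for sp in species_names
        }

    def mean_for(species: str, function: str) -> float:
        if config.expression_level is not None:
            return float(
                config.expression_level.get((species, function), config.default_expression)
            )
        return config.default_expression

    # One gene (random backbone + mutated copies) per (species, function),
    # shared across that species' replicate transcriptomes.
    gene_copies: dict[tuple[str, str], list[str]] = {}
    for sp in species_names:
        for fn in planted_map.get(sp, []):
            backbone = _random_peptide(config.peptide_length, rng)
            copies = [backbone] + [
                mutate_copy(backbone, config.copy_identity, rng)
                for _ in range(config.copies_per_gene - 1)
            ]
            gene_copies[(sp, fn)] = copies

    bundles: list[TranscriptomeBundle] = []
    planted: dict[str, dict[str, str]] = {}
    copy_groups: dict[str, list[str]] = {}
    species_of: dict[str, str] = {}
    gene_lengths: dict[str, int] = {}
    totals: dict[str, int] = {}

    for i, sp in enumerate(species_names):
        for r in range(config.transcriptomes_per_species):
            code = f"SIM{i:02d}R{r:03d}"
            species_of[code] = sp
            planted[code] = {}
            transcripts: list[TranscriptRecord] = []
            annotations: list[AnnotationHit] = []
            n = 0
            for fn in planted_map.get(sp, []):
                group = f"{sp}|{fn}"
                mean = mean_for(sp, fn)
                for copy_seq in gene_copies[(sp, fn)]:
                    tid = f"{code}_t{n:04d}"
                    n += 1
                    nt_len = 3 * len(copy_seq) + 3
                    gene_lengths.setdefault(group, nt_len)
                    transcripts.append(
                        TranscriptRecord(
                            transcript_id=tid,
                            nucleotide_length=nt_len,
                            mapped_read_pairs=_draw_count(mean, config.dispersion, rng),
                            peptide_sequence=copy_seq,
                        )
                    )
                    # Swiss-Prot descriptions are full protein names, so draw
                    # from the name-like synonyms that carry the query term.
                    pool = [
                        s
                        for s in by_code[fn].synonyms
                        if "prostaglandin" in s.lower()
                    ] or list(by_code[fn].synonyms)
                    desc = pool[int(rng.integers(len(pool)))]
                    annotations.append(
                        AnnotationHit(
                            transcript_id=tid,
                            subject_accession=f"SP_{fn}",
                            description=desc,
                            start=1,
                            end=nt_len,
                        )
                    )
                    planted[code][tid] = fn
                    copy_groups.setdefault(group, []).append(tid)
            for _ in range(config.n_decoy_transcripts):
                tid = f"{code}_t{n:04d}"
                n += 1
                pep = _random_peptide(
                    int(rng.integers(100, 2 * config.peptide_length)), rng
                )
                nt_len = 3 * len(pep) + 3
                transcripts.append(
                    TranscriptRecord(
                        transcript_id=tid,
                        nucleotide_length=nt_len,
                        mapped_read_pairs=_draw_count(
                            config.decoy_expression, config.dispersion, rng
                        ),
                        peptide_sequence=pep,
                    )
                )
                if rng.random() < config.decoy_annotation_rate:
                    pool = _NEAR_MISS_DESCRIPTIONS
                else:
                    pool = _PLAIN_DECOY_DESCRIPTIONS
                annotations.append(
                    AnnotationHit(
                        transcript_id=tid,
                        subject_accession=f"D{n:05d}",
                        description=pool[int(rng.integers(len(pool)))],
                        start=1,
                        end=nt_len,
                    )
                )
            totals[code] = int(config.total_read_pairs_mean)
            bundles.append(
                TranscriptomeBundle(
                    mmetsp_code=code,
                    species=sp,
                    genus=genus_names[i],
                    strain=None,
                    transcripts=transcripts,
                    annotations=annotations,
                    total_read_pairs=totals[code],
                    growth_metadata={"replicate": r},
                )
            )

    truth = SyntheticTruth(
        planted=planted,
        copy_groups=copy_groups,
        expression_means={
            f"{sp}|{fn}": mean_for(sp, fn)
            for sp in species_names
            for fn in planted_map.get(sp, [])
        },
        species_of=species_of,
        gene_lengths=gene_lengths,
        total_read_pairs=totals,
    )
    return bundles, truth


def simulate_to_directory(
    config: SimulationConfig,
    out_dir: str | Path,
    vocabulary: list[EnzymeFunction] | None = None,
) -> tuple[list[TranscriptomeBundle], SyntheticTruth]:
    """Generate bundles and write them as bundle directories plus truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles, truth = generate_bundles(config, vocabulary)
    for bundle in bundles:
        write_bundle(bundle, out_dir / bundle.mmetsp_code)
    truth.to_json(out_dir / "truth.json")
    return bundles, truth
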