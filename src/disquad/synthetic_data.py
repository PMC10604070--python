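"""Synthetic datasets with planted predictor-agreement structure.

The generator builds proteins as concatenations of segments drawn from a
small grammar of segment classes, each with its own class-conditional
score distributions:

* ``ordered`` — high pLDDT, low IUPred; not annotated as disordered.
* ``disordered_concordant`` — annotated disordered, both predictors agree
  (low pLDDT, high IUPred; coil): lands in Q4.
* ``helix_in_disorder`` — annotated disordered but modelled as a confident
  helix (high pLDDT, high IUPred; SS "H"): lands in Q2.  Emulates the
  tendency of structure-prediction models to build helices inside
  experimentally disordered segments.
* ``dto_transition`` — annotated disordered region that folds on binding;
  both predictors call order (high pLDDT, low IUPred): lands in Q1.
* ``linker_low_iupred`` — annotated flexible linker that the
  biophysics-based predictor misses (low pLDDT, low IUPred): lands in Q3.

Scores are Beta-distributed, parameterized by mean and concentration
(``a = mean * conc``, ``b = (1 - mean) * conc``) — this is the generator's
model of score noise, not a claim about real predictor error.  Annotated
segments also receive ontology terms (evidence, transition, function) with
class-conditional probabilities, an 8-state secondary-structure run
consistent with the class, and a region-restricted ortholog alignment with
a planted conservation depth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from . import readers
from .types import (
    CONSERVATION_LEVELS,
    AnnotatedRegion,
    MSARow,
    OrthologAlignment,
    ProteinRecord,
    SSString,
    ScoreTrack,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SEGMENT_CLASSES = (
    "ordered",
    "disordered_concordant",
    "helix_in_disorder",
    "dto_transition",
    "linker_low_iupred",
)


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional generation parameters for one segment class."""

    iupred_mean: float
    plddt_mean: float
    concentration: float
    length_range: tuple[int, int]
    ss_state: str  # dominant 8-state code for the segment
    annotated: bool
    planted_quadrant: str
    term_probs: tuple[tuple[str, float], ...] = ()


_DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "ordered": ClassParams(
        iupred_mean=0.20, plddt_mean=0.90, concentration=60.0,
        length_range=(40, 150), ss_state="H", annotated=False,
        planted_quadrant="Q1",
    ),
    "disordered_concordant": ClassParams(
        iupred_mean=0.75, plddt_mean=0.35, concentration=60.0,
        length_range=(15, 120), ss_state="-", annotated=True,
        planted_quadrant="Q4",
        term_probs=(
            ("ECO:0006165", 0.7), ("ECO:0006220", 0.3),
            ("GO:0005515", 0.2), ("ECO:0006204", 0.1),
        ),
    ),
    "helix_in_disorder": ClassParams(
        iupred_mean=0.70, plddt_mean=0.88, concentration=60.0,
        length_range=(20, 60), ss_state="H", annotated=True,
        planted_quadrant="Q2",
        term_probs=(
            ("ECO:0006204", 0.5), ("ECO:0006165", 0.4), ("GO:0005515", 0.3),
        ),
    ),
    "dto_transition": ClassParams(
        iupred_mean=0.25, plddt_mean=0.88, concentration=60.0,
        length_range=(10, 50), ss_state="H", annotated=True,
        planted_quadrant="Q1",
        term_probs=(
            ("IDPO:00051", 1.0), ("ECO:0006220", 0.8),
            ("GO:0005515", 0.5), ("GO:0098772", 0.3),
        ),
    ),
    "linker_low_iupred": ClassParams(
        iupred_mean=0.25, plddt_mean=0.35, concentration=60.0,
        length_range=(15, 60), ss_state="-", annotated=True,
        planted_quadrant="Q3",
        term_probs=(
            ("IDPO:00502", 1.0), ("ECO:0006165", 0.4), ("ECO:0006224", 0.3),
        ),
    ),
}

_DEFAULT_CLASS_PROBS = {
    "ordered": 0.45,
    "disordered_concordant": 0.30,
    "helix_in_disorder": 0.09,
    "dto_transition": 0.08,
    "linker_low_iupred": 0.08,
}

#: planted conservation depth frequencies (most regions trace back only to
#: vertebrates; deep conservation of disordered regions is rare)
_DEFAULT_LEVEL_PROBS = {
    "Vertebrata": 0.945,
    "Eumetazoa": 0.040,
    "Unicellular": 0.015,
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults give a mixed, realistic set."""

    n_proteins: int = 60
    segments_per_protein: tuple[int, int] = (3, 8)
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBS)
    )
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PARAMS)
    )
    level_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LEVEL_PROBS)
    )
    msa_depth_present: tuple[int, int] = (3, 7)  # orthologs at qualifying tiers
    msa_depth_absent: tuple[int, int] = (0, 2)  # below the >=3 rule
    gap_fraction: float = 0.15
    substitution_rate: float = 0.30
    overlap_rate: float = 0.10  # chance a region is emitted as two overlapping entries
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = self.segments_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("segments_per_protein must satisfy 1 <= lo <= hi")
        if set(self.class_probs) != set(self.class_params):
            raise ValueError("class_probs and class_params must share keys")
        if not math.isclose(sum(self.class_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_probs must sum to 1")
        if not math.isclose(sum(self.level_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("level_probs must sum to 1")
        for name, params in self.class_params.items():
            for v in (params.iupred_mean, params.plddt_mean):
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{name}: score means must be in (0, 1)")
            if params.concentration <= 0:
                raise ValueError(f"{name}: concentration must be positive")
            a, b = params.length_range
            if not 1 <= a <= b:
                raise ValueError(f"{name}: invalid length range {params.length_range}")
        for rate in (self.gap_fraction, self.substitution_rate, self.overlap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0 <= self.msa_depth_absent[0] <= self.msa_depth_absent[1]:
            raise ValueError("invalid msa_depth_absent")
        if not 0 <= self.msa_depth_present[0] <= self.msa_depth_present[1]:
            raise ValueError("invalid msa_depth_present")


@dataclass(frozen=True)
class GroundTruthSegment:
    """Planted truth for one generated segment."""

    accession: str
    start: int
    end: int
    segment_class: str
    planted_quadrant: str
    region_id: str | None  # set for annotated segments
    planted_level: str | None  # conservation depth, annotated segments only


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    config: SyntheticConfig
    proteins: list[ProteinRecord]
    iupred_tracks: dict[str, ScoreTrack]
    plddt_tracks: dict[str, ScoreTrack]
    regions: list[AnnotatedRegion]
    ss: dict[str, SSString]
    alignments: dict[str, OrthologAlignment]
    ground_truth: list[GroundTruthSegment]


def _beta_scores(
    rng: np.random.Generator, mean: float, concentration: float, n: int
) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    # quantize to 4 decimals so written fixtures round-trip losslessly
    return np.round(rng.beta(a, b, size=n), 4)


def _draw_terms(
    rng: np.random.Generator, params: ClassParams
) -> list[str]:
    terms = ["IDPO:00076"]  # every annotated region carries the disorder state
    for term, prob in params.term_probs:
        if rng.random() < prob:
            terms.append(term)
    return terms


def _make_alignment(
    rng: np.random.Generator,
    region_id: str,
    region_seq: str,
    ref_start: int,
    planted_level: str,
    config: SyntheticConfig,
) -> OrthologAlignment:
    """Build a region-restricted MSA whose per-tier depths plant one level.

    Conservation at a deep tier implies presence at shallower tiers, so the
    planted tier and everything shallower get >= 3 orthologs while deeper
    tiers stay below 3.
    """
    depth_rank = {lvl: i for i, lvl in enumerate(CONSERVATION_LEVELS)}
    rows: list[MSARow] = [
        MSARow(ortholog_id=region_id + "_ref", level="Vertebrata", sequence=region_seq)
    ]
    counter = 0
    for level in CONSERVATION_LEVELS:
        if depth_rank[level] <= depth_rank[planted_level]:
            lo, hi = config.msa_depth_present
        else:
            lo, hi = config.msa_depth_absent
        n_rows = int(rng.integers(lo, hi + 1))
        for _ in range(n_rows):
            counter += 1
            chars = list(region_seq)
            for i in range(len(chars)):
                if rng.random() < config.gap_fraction:
                    chars[i] = "-"
                elif rng.random() < config.substitution_rate:
                    chars[i] = str(rng.choice(AMINO_ACIDS))
            rows.append(
                MSARow(
                    ortholog_id=f"{region_id}_o{counter}",
                    level=level,
                    sequence="".join(chars),
                )
            )
    return OrthologAlignment(
        region_id=region_id, rows=rows, reference_row=0, ref_start=ref_start
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset per the segment grammar. Deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_names = sorted(config.class_probs)
    class_p = np.array([config.class_probs[c] for c in class_names])

    proteins: list[ProteinRecord] = []
    iupred_tracks: dict[str, ScoreTrack] = {}
    plddt_tracks: dict[str, ScoreTrack] = {}
    regions: list[AnnotatedRegion] = []
    ss: dict[str, SSString] = {}
    alignments: dict[str, OrthologAlignment] = {}
    ground_truth: list[GroundTruthSegment] = []

    level_names = sorted(config.level_probs)
    level_p = np.array([config.level_probs[lvl] for lvl in level_names])

    for p_idx in range(config.n_proteins):
        accession = f"SYN{p_idx + 1:04d}"
        n_segments = int(
            rng.integers(
                config.segments_per_protein[0], config.segments_per_protein[1] + 1
            )
        )
        seq_parts: list[str] = []
        ss_parts: list[str] = []
        iupred_parts: list[np.ndarray] = []
        plddt_parts: list[np.ndarray] = []
        cursor = 1  # next 1-based residue position
        for _ in range(n_segments):
            cls = class_names[int(rng.choice(len(class_names), p=class_p))]
            params = config.class_params[cls]
            length = int(
                rng.integers(params.length_range[0], params.length_range[1] + 1)
            )
            start, end = cursor, cursor + length - 1
            seg_seq = "".join(rng.choice(AMINO_ACIDS, size=length))
            seq_parts.append(seg_seq)
            ss_parts.append(params.ss_state * length)
            iupred_parts.append(
                _beta_scores(rng, params.iupred_mean, params.concentration, length)
            )
            plddt_parts.append(
                _beta_scores(rng, params.plddt_mean, params.concentration, length)
            )

            region_id = None
            planted_level = None
            if params.annotated:
                region_id = f"{accession}_{start}_{end}"
                term_ids = _draw_terms(rng, params)
                planted_level = level_names[
                    int(rng.choice(len(level_names), p=level_p))
                ]
                entries = [(start, end, f"{region_id}")]
                if length >= 6 and rng.random() < config.overlap_rate:
                    mid = (start + end) // 2
                    entries = [
                        (start, mid + 1, f"{region_id}a"),
                        (mid - 1, end, f"{region_id}b"),
                    ]
                for e_start, e_end, source in entries:
                    regions.append(
                        readers.region_from_terms(
                            accession, e_start, e_end, list(term_ids), source
                        )
                    )
                alignments[region_id] = _make_alignment(
                    rng, region_id, seg_seq, start, planted_level, config
                )
            ground_truth.append(
                GroundTruthSegment(
                    accession=accession,
                    start=start,
                    end=end,
                    segment_class=cls,
                    planted_quadrant=params.planted_quadrant,
                    region_id=region_id,
                    planted_level=planted_level,
                )
            )
            cursor = end + 1

        sequence = "".join(seq_parts)
        proteins.append(ProteinRecord(accession=accession, sequence=sequence))
        ss[accession] = SSString(accession=accession, states8="".join(ss_parts))
        iupred_tracks[accession] = ScoreTrack(
            accession=accession, predictor="iupred",
            scores=np.concatenate(iupred_parts),
        )
        plddt_tracks[accession] = ScoreTrack(
            accession=accession, predictor="plddt",
            scores=np.concatenate(plddt_parts),
        )

    return SyntheticDataset(
        config=config,
        proteins=proteins,
        iupred_tracks=iupred_tracks,
        plddt_tracks=plddt_tracks,
        regions=regions,
        ss=ss,
        alignments=alignments,
        ground_truth=ground_truth,
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Serialize a dataset in exactly the formats the readers consume.

    Layout under ``directory``: ``disprot.json``, ``proteins.fasta``,
    ``iupred/<acc>.tsv``, ``af2/AF-<acc>-F1-model_v4.pdb``,
    ``dssp/<acc>.dssp``, ``msa/<region_id>.afa`` and ``ground_truth.tsv``.
    """
    import json

    import pandas as pd

    directory = Path(directory)
    for sub in ("iupred", "af2", "dssp", "msa"):
        (directory / sub).mkdir(parents=True, exist_ok=True)

    seqs = {p.accession: p.sequence for p in dataset.proteins}
    entries = []
    by_acc: dict[str, list[AnnotatedRegion]] = {}
    for region in dataset.regions:
        by_acc.setdefault(region.accession, []).append(region)
    for protein in dataset.proteins:
        entries.append(
            {
                "acc": protein.accession,
                "sequence": protein.sequence,
                "regions": [
                    {
                        "region_id": sorted(r.source_ids)[0],
                        "start": r.start,
                        "end": r.end,
                        "terms": sorted(r.all_terms),
                    }
                    for r in by_acc.get(protein.accession, [])
                ],
            }
        )
    (directory / "disprot.json").write_text(json.dumps({"data": entries}, indent=1))

    readers.write_fasta(dataset.proteins, directory / "proteins.fasta")
    for acc, track in dataset.iupred_tracks.items():
        readers.write_iupred(track, directory / "iupred" / f"{acc}.tsv", seqs[acc])
    for acc, track in dataset.plddt_tracks.items():
        readers.write_plddt_pdb(
            track, seqs[acc], directory / "af2" / f"AF-{acc}-F1-model_v4.pdb"
        )
    for acc, ss_string in dataset.ss.items():
        readers.write_dssp(ss_string, seqs[acc], directory / "dssp" / f"{acc}.dssp")
    for region_id, alignment in dataset.alignments.items():
        readers.write_msa(alignment, directory / "msa" / f"{region_id}.afa")

    gt = pd.DataFrame(
        [
            {
                "accession": g.accession,
                "start": g.start,
                "end": g.end,
                "segment_class": g.segment_class,
                "planted_quadrant": g.planted_quadrant,
                "region_id": g.region_id or "",
                "planted_level": g.planted_level or "",
            }
            for g in dataset.ground_truth
        ]
    )
    readers.write_tsv(
        gt, directory / "ground_truth.tsv", {"seed": dataset.config.seed}
    )


def config_from_file(path: str | Path, **overrides) -> SyntheticConfig:
    """Load scalar generator settings from a plain ``key = value`` file.

    Recognized keys: ``n_proteins``, ``seed``, ``min_segments``,
    ``max_segments``, ``gap_fraction``, ``substitution_rate``,
    ``overlap_rate``.  Lines starting with ``#`` are comments.  Structured
    settings (grammar probabilities, class score parameters) are library
    API only.
    """
    values: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()

    config = SyntheticConfig()
    int_keys = {"n_proteins", "seed"}
    float_keys = {"gap_fraction", "substitution_rate", "overlap_rate"}
    segments = list(config.segments_per_protein)
    for key, val in values.items():
        if key in int_keys:
            config = replace(config, **{key: int(val)})
        elif key in float_keys:
            config = replace(config, **{key: float(val)})
        elif key == "min_segments":
            segments[0] = int(val)
        elif key == "max_segments":
            segments[1] = int(val)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    config = replace(config, segments_per_protein=tuple(segments))
    for key, val in overrides.items():
        config = replace(config, **{key: val})
    config.validate()
    return config
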