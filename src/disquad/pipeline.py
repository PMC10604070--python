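"""End-to-end orchestration: ingest files, run every analysis stage and
write the report tables.

The pipeline consumes a directory in the fixture layout (``disprot.json``
or ``.tsv``, ``iupred/``, ``af2/``, ``dssp/``, ``msa/``, optional
``clusters.clstr``) and writes plain TSV tables, one per analysis, each
with a ``#``-metadata header recording the parameters used.  Stages are
independently invocable through the CLI; intermediate artifacts are TSV so
any stage can be rerun in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotations as annot
from . import conservation as cons
from . import quadrants as quad
from . import readers
from . import regions as reg
from . import secondary_structure as ss_mod
from .types import AnnotatedRegion, CutoffPair, SSString, ScoreTrack

logger = logging.getLogger("disquad")


@dataclass
class PipelineConfig:
    """Paths and the analysis parameters (defaults are the conventional
    values: pLDDT 0.7 / IUPred 0.425 cutoffs, 30-residue long/short split,
    10-occurrence term filter, >= 3 orthologs at >= 50% coverage, 50 bins,
    40% redundancy identity)."""

    input_dir: Path
    output_dir: Path
    cutoffs: CutoffPair = field(default_factory=CutoffPair)
    calibrate_iupred: bool = True
    min_long: int = 30
    min_term_count: int = 10
    min_orthologs: int = 3
    min_coverage: float = 0.5
    bins: int = 50
    redundancy_identity: float = 0.40
    apply_redundancy: bool = False
    require_disordered_state: bool = True
    seed: int = 0

    def metadata(self) -> dict[str, object]:
        return {
            "tool": f"disquad {__version__}",
            "plddt_cutoff": self.cutoffs.plddt_cutoff,
            "iupred_cutoff": self.cutoffs.iupred_cutoff,
            "min_long": self.min_long,
            "min_term_count": self.min_term_count,
            "min_orthologs": self.min_orthologs,
            "min_coverage": self.min_coverage,
            "bins": self.bins,
            "redundancy_identity": self.redundancy_identity,
            "seed": self.seed,
        }


@dataclass
class IngestedData:
    proteins: list
    regions: list[AnnotatedRegion]
    iupred: dict[str, ScoreTrack]
    plddt: dict[str, ScoreTrack]
    ss: dict[str, SSString]
    alignments: dict[str, object]


def ingest(config: PipelineConfig) -> IngestedData:
    """Read every input under ``input_dir`` into domain types."""
    root = config.input_dir
    disprot_path = None
    for cand in ("disprot.json", "disprot.tsv"):
        if (root / cand).exists():
            disprot_path = root / cand
            break
    if disprot_path is None:
        raise FileNotFoundError(f"no disprot.json or disprot.tsv under {root}")
    proteins, regions = readers.read_disprot(
        disprot_path, require_disordered_state=config.require_disordered_state
    )
    logger.info("ingest: %d proteins, %d regions", len(proteins), len(regions))

    iupred: dict[str, ScoreTrack] = {}
    for path in sorted((root / "iupred").glob("*")):
        track = readers.read_iupred(path)
        iupred[track.accession] = track
    plddt: dict[str, ScoreTrack] = {}
    af2_dir = root / "af2"
    if af2_dir.exists():
        for path in sorted(af2_dir.glob("*")):
            track = readers.read_plddt(path)
            plddt[track.accession] = track
    ss: dict[str, SSString] = {}
    dssp_dir = root / "dssp"
    if dssp_dir.exists():
        for path in sorted(dssp_dir.glob("*")):
            parsed = readers.read_dssp(path)
            ss[parsed.accession] = parsed
    alignments: dict[str, object] = {}
    msa_dir = root / "msa"
    if msa_dir.exists():
        for path in sorted(msa_dir.glob("*")):
            aln = readers.read_msa(path)
            alignments[aln.region_id] = aln
    logger.info(
        "ingest: %d iupred tracks, %d plddt tracks, %d SS strings, %d MSAs",
        len(iupred), len(plddt), len(ss), len(alignments),
    )
    return IngestedData(proteins, regions, iupred, plddt, ss, alignments)


def _quadrant_table_df(table: quad.QuadrantTable) -> pd.DataFrame:
    rows = [
        {
            "quadrant": q,
            "count": table.counts.get(q, 0),
            "percentage": table.percentages.get(q, 0),
        }
        for q in ("Q1", "Q2", "Q3", "Q4")
    ]
    rows.append({"quadrant": "Sum", "count": table.total, "percentage": 100 if table.total else 0})
    return pd.DataFrame(rows)


def _region_scores(
    region: AnnotatedRegion,
    iupred: dict[str, ScoreTrack],
    plddt: dict[str, ScoreTrack],
) -> tuple[np.ndarray, np.ndarray]:
    sl = slice(region.start - 1, region.end)
    return iupred[region.accession].scores[sl], plddt[region.accession].scores[sl]


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = ingest(config)

    # --- redundancy filtering -------------------------------------------
    proteins = data.proteins
    if config.apply_redundancy:
        clstr_path = config.input_dir / "clusters.clstr"
        clusters = readers.read_clstr(clstr_path) if clstr_path.exists() else None
        proteins = reg.apply_redundancy_filter(
            proteins, clusters, config.redundancy_identity
        )
        kept = {p.accession for p in proteins}
        data.regions = [r for r in data.regions if r.accession in kept]
        logger.info("redundancy: kept %d proteins", len(proteins))

    # --- merge and split -------------------------------------------------
    pre_merge = data.regions
    merged = reg.merge_overlapping(pre_merge)
    long_regions, short_regions = reg.split_by_length(merged, config.min_long)
    for label, subset in (("all", merged), ("long", long_regions), ("short", short_regions)):
        s = reg.summarize(subset)
        logger.info(
            "regions (%s): %d regions, %d residues, %d proteins",
            label, s.n_regions, s.n_residues, s.n_proteins,
        )
    readers.write_tsv(
        pd.DataFrame(
            [
                {"set": "pre_merge", **vars(reg.summarize(pre_merge))},
                {"set": "merged", **vars(reg.summarize(merged))},
                {"set": "long", **vars(reg.summarize(long_regions))},
                {"set": "short", **vars(reg.summarize(short_regions))},
            ]
        ),
        out / "region_summary.tsv",
        config.metadata(),
    )

    # --- matched-rate calibration ---------------------------------------
    have_tracks = [
        r for r in merged
        if r.accession in data.iupred and r.accession in data.plddt
    ]
    long_tracked = [r for r in have_tracks if r.length >= config.min_long]
    short_tracked = [r for r in have_tracks if r.length < config.min_long]
    cutoffs = config.cutoffs
    if long_tracked:
        iupred_pool = np.concatenate(
            [_region_scores(r, data.iupred, data.plddt)[0] for r in long_tracked]
        )
        plddt_pool = np.concatenate(
            [_region_scores(r, data.iupred, data.plddt)[1] for r in long_tracked]
        )
        target = quad.target_fraction_from_plddt(plddt_pool, cutoffs.plddt_cutoff)
        calibration = quad.calibrate_matched_cutoff(iupred_pool, target)
        if config.calibrate_iupred:
            cutoffs = CutoffPair(
                plddt_cutoff=cutoffs.plddt_cutoff,
                iupred_cutoff=calibration.cutoff,
            )
        readers.write_tsv(
            pd.DataFrame(
                [
                    {
                        "plddt_cutoff": cutoffs.plddt_cutoff,
                        "plddt_disordered_fraction": target,
                        "iupred_cutoff_calibrated": calibration.cutoff,
                        "iupred_achieved_fraction": calibration.achieved_fraction,
                        "iupred_cutoff_used": cutoffs.iupred_cutoff,
                    }
                ]
            ),
            out / "calibration.tsv",
            config.metadata(),
        )
        logger.info(
            "calibration: target %.3f -> iupred cutoff %.4f (achieved %.3f)",
            target, calibration.cutoff, calibration.achieved_fraction,
        )

    # --- quadrant classification ----------------------------------------
    residue_quadrants: dict[str, list[tuple[str, int, str]]] = {}
    region_quadrants: dict[str, list[tuple[AnnotatedRegion, str]]] = {}
    for label, subset in (("long", long_tracked), ("short", short_tracked)):
        res_list: list[tuple[str, int, str]] = []
        reg_list: list[tuple[AnnotatedRegion, str]] = []
        for region in subset:
            iup, pld = _region_scores(region, data.iupred, data.plddt)
            labels = quad.classify_residues(iup, pld, cutoffs)
            res_list.extend(
                (region.accession, pos, q)
                for pos, q in zip(region.positions(), labels)
            )
            _, _, region_q = quad.region_mean_quadrant(
                region, data.iupred[region.accession],
                data.plddt[region.accession], cutoffs,
            )
            reg_list.append((region, region_q))
        residue_quadrants[label] = res_list
        region_quadrants[label] = reg_list

        res_table = quad.quadrant_table([q for _, _, q in res_list], "residues")
        reg_table = quad.quadrant_table([q for _, q in reg_list], "regions")
        readers.write_tsv(
            _quadrant_table_df(res_table),
            out / f"quadrants_{label}_residues.tsv", config.metadata(),
        )
        readers.write_tsv(
            _quadrant_table_df(reg_table),
            out / f"quadrants_{label}_regions.tsv", config.metadata(),
        )

        pairs = [
            (
                float(data.iupred[acc].scores[pos - 1]),
                float(data.plddt[acc].scores[pos - 1]),
            )
            for acc, pos, _ in res_list
        ]
        grid = quad.density_grid(pairs, config.bins)
        readers.write_tsv(
            pd.DataFrame(grid.matrix),
            out / f"density_{label}_residues.tsv", config.metadata(),
        )

    # --- term enrichment (pre-merge long regions, region-level quadrants) -
    pre_long = [
        r for r in pre_merge
        if r.length >= config.min_long
        and r.accession in data.iupred and r.accession in data.plddt
    ]
    pre_long_quadrants = []
    for region in pre_long:
        _, _, region_q = quad.region_mean_quadrant(
            region, data.iupred[region.accession],
            data.plddt[region.accession], cutoffs,
        )
        pre_long_quadrants.append((region, region_q))
    for namespace in ("ECO", "IDPO", "GO"):
        table = annot.quadrant_enrichment(
            pre_long_quadrants, namespace, config.min_term_count
        )
        rows = []
        for q, entries in table.per_quadrant.items():
            for term, e in entries.items():
                rows.append(
                    {
                        "term": term,
                        "namespace": namespace,
                        "quadrant": q,
                        "overall_count": table.overall.counts[term],
                        "overall_fraction": e.overall_fraction,
                        "quadrant_count": e.quadrant_count,
                        "quadrant_fraction": e.quadrant_fraction,
                        "ratio": e.ratio,
                        "log2_ratio": e.log2_ratio,
                    }
                )
        readers.write_tsv(
            pd.DataFrame(rows), out / f"enrichment_{namespace}.tsv",
            config.metadata(),
        )

    # --- secondary structure by quadrant (long regions, residue level) ---
    classified_with_ss = [
        (acc, pos, q)
        for acc, pos, q in residue_quadrants.get("long", [])
        if acc in data.ss
    ]
    if classified_with_ss:
        dist = ss_mod.ss_by_quadrant(classified_with_ss, data.ss)
        rows = []
        for q in ("Q1", "Q2", "Q3", "Q4"):
            h, e, c = dist.counts.get(q, (0, 0, 0))
            fh, fe, fc = dist.fractions.get(q, (0.0, 0.0, 0.0))
            rows.append(
                {
                    "quadrant": q, "helix": h, "sheet": e, "coil": c,
                    "helix_fraction": fh, "sheet_fraction": fe,
                    "coil_fraction": fc,
                }
            )
        readers.write_tsv(
            pd.DataFrame(rows), out / "ss_by_quadrant.tsv", config.metadata()
        )
    else:
        logger.warning("secondary structure: no DSSP data, stage skipped")

    # --- conservation -----------------------------------------------------
    if data.alignments:
        calls = []
        level_residue_quadrants: dict[str, list[str]] = {}
        for region_id, alignment in sorted(data.alignments.items()):
            ref = alignment.reference
            n_ref = sum(1 for ch in ref.sequence if ch not in "-.")
            region = AnnotatedRegion(
                accession=region_id,
                start=alignment.ref_start,
                end=alignment.ref_start + n_ref - 1,
                structural_state_terms=frozenset({"IDPO:00076"}),
            )
            call = cons.classify_conservation(
                alignment, region, config.min_orthologs, config.min_coverage
            )
            calls.append(call)
            # Table-2 analogue: residue quadrants pooled per conservation level
            acc = region_id.split("_")[0]
            if acc in data.iupred and acc in data.plddt:
                iup = data.iupred[acc].scores[region.start - 1:region.end]
                pld = data.plddt[acc].scores[region.start - 1:region.end]
                if iup.size and pld.size == iup.size:
                    labels = quad.classify_residues(iup, pld, cutoffs)
                    level_residue_quadrants.setdefault(call.level, []).extend(labels)
        readers.write_tsv(
            pd.DataFrame(
                [
                    {
                        "region_id": c.region_id,
                        "level": c.level,
                        **{f"n_{lvl}": c.counts[lvl] for lvl in c.counts},
                    }
                    for c in calls
                ]
            ),
            out / "conservation_calls.tsv", config.metadata(),
        )
        rows = []
        for level, labels in sorted(level_residue_quadrants.items()):
            table = quad.quadrant_table(labels, "residues")
            for q in ("Q1", "Q2", "Q3", "Q4"):
                rows.append(
                    {
                        "level": level, "quadrant": q,
                        "count": table.counts.get(q, 0),
                        "percentage": table.percentages.get(q, 0),
                    }
                )
        readers.write_tsv(
            pd.DataFrame(rows), out / "quadrants_by_conservation.tsv",
            config.metadata(),
        )
    else:
        logger.warning("conservation: no MSA directory, stage skipped")

    # --- proteome-style pooled fractions over all tracks ------------------
    shared = sorted(set(data.iupred) & set(data.plddt))
    if shared:
        from .proteome import proteome_fractions

        f_iupred, f_plddt, n = proteome_fractions(
            [(data.iupred[a], data.plddt[a]) for a in shared], cutoffs
        )
        readers.write_tsv(
            pd.DataFrame(
                [
                    {
                        "set": "all_proteins",
                        "n_residues": n,
                        "fraction_iupred": f_iupred,
                        "fraction_plddt": f_plddt,
                    }
                ]
            ),
            out / "proteome_fractions.tsv", config.metadata(),
        )
    logger.info("run_all: report written to %s", out)
    return out
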