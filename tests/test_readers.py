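"""File-format parsing: DisProt JSON/TSV, IUPred, PDB pLDDT, DSSP, MSA,
CD-HIT clusters, and the TSV round trip."""

import json

import numpy as np
import pytest

from disquad import readers
from disquad.types import OrthologAlignment, ScoreTrack


# ---------------------------------------------------------------------- DisProt

def _entry(acc="P1", start=5, end=12, terms=("IDPO:00076",), seq="M" * 20):
    return {
        "acc": acc,
        "sequence": seq,
        "regions": [{"start": start, "end": end, "terms": list(terms)}],
    }


def write_json(tmp_path, entries):
    path = tmp_path / "disprot.json"
    path.write_text(json.dumps({"data": entries}))
    return path


def test_read_disprot_inclusive_coordinates(tmp_path):
    proteins, regions = readers.read_disprot(write_json(tmp_path, [_entry()]))
    assert len(regions) == 1
    r = regions[0]
    assert (r.accession, r.start, r.end, r.length) == ("P1", 5, 12, 8)
    assert proteins[0].length == 20


def test_read_disprot_partitions_terms_by_namespace(tmp_path):
    entries = [_entry(terms=["ECO:0006220", "IDPO:00076", "GO:0005515",
                             "IDPO:00051"])]
    _, regions = readers.read_disprot(write_json(tmp_path, entries))
    r = regions[0]
    assert r.evidence_terms == {"ECO:0006220"}
    assert r.structural_state_terms == {"IDPO:00076"}
    assert r.function_terms == {"GO:0005515"}
    assert r.transition_terms == {"IDPO:00051"}


def test_read_disprot_empty_region_list(tmp_path):
    proteins, regions = readers.read_disprot(
        write_json(tmp_path, [{"acc": "P1", "sequence": "MA", "regions": []}])
    )
    assert regions == [] and len(proteins) == 1


def test_read_disprot_rejects_inverted_coordinates(tmp_path):
    path = write_json(tmp_path, [_entry(start=12, end=5)])
    with pytest.raises(ValueError, match="P1_r1"):
        readers.read_disprot(path)


def test_read_disprot_rejects_termless_region(tmp_path):
    path = write_json(tmp_path, [_entry(terms=[])])
    with pytest.raises(ValueError, match="no term identifiers"):
        readers.read_disprot(path)


def test_read_disprot_unknown_namespace_warns_into_function(tmp_path):
    path = write_json(tmp_path, [_entry(terms=["XXX:123", "IDPO:00076"])])
    with pytest.warns(UserWarning, match="unknown term namespace"):
        _, regions = readers.read_disprot(path)
    assert "XXX:123" in regions[0].function_terms


def test_disprot_filter_flag_keeps_only_structural_state(tmp_path):
    entries = [
        _entry(acc="P1", terms=["IDPO:00076"]),
        _entry(acc="P2", terms=["GO:0005515"]),
    ]
    _, regions = readers.read_disprot(
        write_json(tmp_path, entries), require_disordered_state=True
    )
    assert [r.accession for r in regions] == ["P1"]


def test_disprot_tsv_round_trip(tmp_path, small_dataset):
    path = tmp_path / "regions.tsv"
    readers.write_disprot_tsv(small_dataset.proteins, small_dataset.regions, path)
    proteins, regions = readers.read_disprot(path)
    assert {p.accession: p.sequence for p in proteins} == {
        p.accession: p.sequence for p in small_dataset.proteins
        if any(r.accession == p.accession for r in small_dataset.regions)
    }
    assert len(regions) == len(small_dataset.regions)
    for got, want in zip(
        sorted(regions, key=lambda r: (r.accession, r.start, sorted(r.source_ids))),
        sorted(small_dataset.regions,
               key=lambda r: (r.accession, r.start, sorted(r.source_ids))),
    ):
        assert (got.accession, got.start, got.end) == (want.accession, want.start, want.end)
        assert got.all_terms == want.all_terms
        assert got.source_ids == want.source_ids


# ---------------------------------------------------------------------- IUPred

def test_read_iupred_parses_scores(tmp_path):
    path = tmp_path / "p1.tsv"
    path.write_text("# POS RES SCORE\n1\tM\t0.90\n2\tA\t0.10\n")
    track = readers.read_iupred(path)
    assert track.predictor == "iupred"
    np.testing.assert_allclose(track.scores, [0.90, 0.10])


def test_read_iupred_rejects_position_gap(tmp_path):
    path = tmp_path / "p1.tsv"
    path.write_text("1\tM\t0.9\n3\tA\t0.1\n")
    with pytest.raises(ValueError, match="consecutive"):
        readers.read_iupred(path)


def test_read_iupred_rejects_out_of_range_score(tmp_path):
    path = tmp_path / "p1.tsv"
    path.write_text("1\tM\t1.2\n")
    with pytest.raises(ValueError, match="outside"):
        readers.read_iupred(path)


# ---------------------------------------------------------------------- pLDDT

def test_read_plddt_scales_bfactor(tmp_path):
    track = ScoreTrack("P1", "plddt", np.array([0.355, 0.982]))
    path = tmp_path / "AF-P1-F1-model_v4.pdb"
    readers.write_plddt_pdb(track, "MA", path)
    got = readers.read_plddt(path)
    assert got.accession == "P1"
    np.testing.assert_allclose(got.scores, [0.355, 0.982], atol=1e-9)


def test_read_plddt_accepts_upper_bound(tmp_path):
    track = ScoreTrack("P1", "plddt", np.array([1.0]))
    path = tmp_path / "AF-P1-F1-model_v4.pdb"
    readers.write_plddt_pdb(track, "M", path)
    assert readers.read_plddt(path).scores[0] == pytest.approx(1.0)


def test_read_plddt_times_100_matches_bfactor_column(tmp_path, small_dataset):
    acc = small_dataset.proteins[0].accession
    seq = small_dataset.proteins[0].sequence
    track = small_dataset.plddt_tracks[acc]
    path = tmp_path / f"AF-{acc}-F1-model_v4.pdb"
    readers.write_plddt_pdb(track, seq, path)
    written = [
        float(line[60:66]) for line in path.read_text().splitlines()
        if line.startswith("ATOM")
    ]
    got = readers.read_plddt(path)
    np.testing.assert_allclose(np.asarray(written), got.scores * 100.0, atol=5e-4)


# ---------------------------------------------------------------------- DSSP

CLASSIC_DSSP = """\
==== Secondary Structure Definition ====
  #  RESIDUE AA STRUCTURE
    1    1 A M  H
    2    2 A A  E
    3    3 A G
"""


def test_read_dssp_classic_layout(tmp_path):
    path = tmp_path / "p1.dssp"
    path.write_text(CLASSIC_DSSP)
    assert readers.read_dssp(path).states8 == "HE-"


def test_read_dssp_preserves_polyproline(tmp_path):
    path = tmp_path / "p1.dssp"
    path.write_text(
        "  #  RESIDUE AA STRUCTURE\n    1    1 A P  P\n"
    )
    assert readers.read_dssp(path).states8 == "P"


def test_read_dssp_chain_break_becomes_dash(tmp_path):
    path = tmp_path / "p1.dssp"
    path.write_text(
        "  #  RESIDUE AA STRUCTURE\n"
        "    1    1 A M  H\n"
        "    2      A !\n"
        "    3    3 A A  E\n"
    )
    assert readers.read_dssp(path).states8 == "H-E"


def test_read_dssp_empty_body(tmp_path):
    path = tmp_path / "p1.dssp"
    path.write_text("  #  RESIDUE AA STRUCTURE\n")
    assert readers.read_dssp(path).states8 == ""


def test_read_dssp_mmcif_layout(tmp_path):
    path = tmp_path / "p1.dssp.cif"
    path.write_text(
        "data_p1\n"
        "loop_\n"
        "_dssp_struct_summary.id\n"
        "_dssp_struct_summary.secondary_structure\n"
        "1 H\n2 E\n3 .\n"
    )
    assert readers.read_dssp(path).states8 == "HE-"


# ---------------------------------------------------------------------- MSA

def test_read_msa_tags_and_reference(tmp_path):
    path = tmp_path / "r1.afa"
    path.write_text(
        ">ref1 level=Vertebrata ref\nAC-DE\n"
        ">o1 level=Vertebrata\nACQDE\n"
        ">o2 level=Unicellular\nAC--E\n"
    )
    aln = readers.read_msa(path)
    assert [r.level for r in aln.rows] == ["Vertebrata", "Vertebrata", "Unicellular"]
    assert aln.reference_row == 0 and aln.region_id == "r1"


def test_read_msa_metazoa_alias(tmp_path):
    path = tmp_path / "r1.afa"
    path.write_text(">a level=Vertebrata ref\nAA\n>b level=Metazoa\nAA\n")
    assert readers.read_msa(path).rows[1].level == "Eumetazoa"


def test_read_msa_ragged_rows_rejected(tmp_path):
    path = tmp_path / "r1.afa"
    path.write_text(">a level=Vertebrata ref\nAAAAAAAAAA\n>b level=Vertebrata\nAAAAAAAAAAA\n")
    with pytest.raises(ValueError, match="unequal"):
        readers.read_msa(path)


def test_read_msa_missing_level_names_row(tmp_path):
    path = tmp_path / "r1.afa"
    path.write_text(">a level=Vertebrata ref\nAA\n>rowX\nAA\n")
    with pytest.raises(ValueError, match="rowX"):
        readers.read_msa(path)


@pytest.mark.parametrize("n_refs", [0, 2])
def test_read_msa_reference_row_count_enforced(tmp_path, n_refs):
    rows = [f">r{i} level=Vertebrata{' ref' if i < n_refs else ''}\nAA" for i in range(3)]
    path = tmp_path / "r1.afa"
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="reference row"):
        readers.read_msa(path)


def test_msa_round_trip(tmp_path, small_dataset):
    region_id, aln = next(iter(small_dataset.alignments.items()))
    path = tmp_path / f"{region_id}.afa"
    readers.write_msa(aln, path)
    got = readers.read_msa(path)
    assert isinstance(got, OrthologAlignment)
    assert got.rows == aln.rows
    assert got.reference_row == aln.reference_row
    assert got.ref_start == aln.ref_start


# ---------------------------------------------------------------------- clstr

def test_read_clstr_marks_representatives(tmp_path):
    path = tmp_path / "c.clstr"
    path.write_text(
        ">Cluster 0\n"
        "0\t100aa, >P1... *\n"
        "1\t90aa, >P2... at 80%\n"
        ">Cluster 1\n"
        "0\t50aa, >P3... *\n"
    )
    clusters = readers.read_clstr(path)
    assert [c.representative for c in clusters] == ["P1", "P3"]
    assert clusters[0].members == ("P1", "P2")
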