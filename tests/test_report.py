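"""Summary matrices, census operations, figures and the end-to-end pipeline."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from PIL import Image

import pgmine as pg
from pgmine import datasets


def _assignment(tid, mmetsp, species, code):
    return pg.FunctionAssignment(tid, mmetsp, species, code, "Prostaglandin thing")


def test_build_presence_basic():
    assignments = [
        _assignment("a", "X1", "Sp one", "PTGES2"),
        _assignment("b", "X2", "Sp two", "PTGES2"),
    ]
    matrix = pg.build_presence(assignments, level="species")
    assert matrix.shape == (2, 9)
    assert list(matrix.columns) == pg.FUNCTION_ORDER
    assert matrix["PTGES2"].all()
    assert matrix.drop(columns="PTGES2").to_numpy().sum() == 0


def test_build_presence_empty_and_drop_rule():
    assert pg.build_presence([], level="species").empty
    matrix = pg.build_presence(
        [_assignment("a", "X1", "Sp one", "PTGR1")], level="transcriptome"
    )
    assert matrix.any(axis=1).all()  # every kept row has >= 1 true cell


def test_fixture_presence_has_fourteen_species():
    presence = datasets.load_species_presence()
    assert presence.shape == (14, 9)
    assert pg.species_with_any(presence) == 14
    assert presence.any(axis=1).all()


def test_count_occurrences_fixture_column_sums():
    presence = datasets.load_species_presence()
    counts = pg.count_occurrences(presence)
    assert counts.loc["COX2", "n_species"] == 2
    assert counts.loc["HPGDS", "n_species"] == 9
    assert counts.loc["PTGES2", "n_species"] == 12
    assert counts.loc["PTGR1", "n_species"] == 14
    assert counts.loc["15-PGDH", "n_species"] == 1
    assert counts.loc["PTGFS2", "n_species"] == 1


def test_count_occurrences_column_mismatch_fatal():
    presence = datasets.load_species_presence()
    with pytest.raises(ValueError, match="nine function codes"):
        pg.count_occurrences(presence[pg.FUNCTION_ORDER[:5]])


def test_count_occurrences_empty_matrices_are_zero():
    empty = pd.DataFrame(columns=pg.FUNCTION_ORDER).astype(bool)
    counts = pg.count_occurrences(empty, empty)
    assert (counts == 0).all().all()


def test_species_with_any_edge_cases():
    all_false = pd.DataFrame(False, index=["a", "b", "c"], columns=pg.FUNCTION_ORDER)
    assert pg.species_with_any(all_false) == 0
    single = all_false.iloc[:1].copy()
    single.loc["a", "PTGR1"] = True
    assert pg.species_with_any(single) == 1


def test_occurrence_consistency_between_code_paths(default_sim):
    """Column sums of the presence matrix equal direct assignment grouping."""
    _, bundles, _ = default_sim
    result = pg.run_pipeline(bundles=bundles, figures=False)
    direct = defaultdict(set)
    for a in result.assignments:
        direct[a.function_code].add(a.species)
    counts = pg.count_occurrences(result.presence_species)
    for code in pg.FUNCTION_ORDER:
        assert counts.loc[code, "n_species"] == len(direct.get(code, set()))


def test_metadata_census_fixture():
    metadata = datasets.load_growth_conditions()
    assert pg.metadata_census(metadata) == (42, 15, 19)


def test_metadata_census_small_cases():
    one = pd.DataFrame(
        {"mmetsp_code": ["M1"], "genus": ["G"], "species": ["s"]}
    )
    assert pg.metadata_census(one) == (1, 1, 1)
    two_strains = pd.DataFrame(
        {"mmetsp_code": ["M1", "M2"], "genus": ["G", "G"], "species": ["s", "s"]}
    )
    assert pg.metadata_census(two_strains) == (2, 1, 1)
    dup = pd.DataFrame(
        {"mmetsp_code": ["M1", "M1"], "genus": ["G", "G"], "species": ["s", "s"]}
    )
    with pytest.raises(ValueError, match="duplicate"):
        pg.metadata_census(dup)


def test_basionym_rows_stay_distinct():
    metadata = datasets.load_growth_conditions()
    foliaceum = metadata[metadata.species == "foliaceum"]
    assert set(foliaceum.genus) == {"Glenodinium", "Kryptoperidinium"}


def test_replicate_assembly_size_difference():
    stats = datasets.load_assembly_statistics()
    assert pg.size_difference(stats, "MMETSP0201", "MMETSP0202") == 11600
    assert pg.size_difference(stats, "MMETSP0201", "MMETSP0201") == 0
    with pytest.raises(ValueError, match="unknown"):
        pg.size_difference(stats, "MMETSP0201", "MMETSP9999")
    with pytest.raises(ValueError, match="unavailable"):
        pg.size_difference(stats, "MMETSP0201", "MMETSP0380")


def test_stats_table_matches_generated_transcript_count(default_sim):
    _, bundles, _ = default_sim
    stats = pg.stats_table(bundles)
    for bundle in bundles:
        assert stats.loc[bundle.mmetsp_code, "n_sequences"] == len(bundle.transcripts)


def test_occurrence_chart_written_and_deterministic(tmp_path):
    counts = pg.count_occurrences(datasets.load_species_presence())
    p1 = pg.occurrence_chart(counts, tmp_path / "chart1.png")
    p2 = pg.occurrence_chart(counts, tmp_path / "chart2.png")
    assert p1.stat().st_size > 0
    assert p1.read_bytes() == p2.read_bytes()


def test_occurrence_chart_empty_counts(tmp_path):
    empty = pd.DataFrame(columns=["n_species"]).astype(int)
    path = pg.occurrence_chart(empty, tmp_path / "chart.png")
    assert path.stat().st_size > 0


def test_render_heatmap_missing_cell_uses_reserved_color(tmp_path):
    matrix = pd.DataFrame(
        [[1.0, np.nan], [0.5, 2.0]], index=["PTGES2", "PTGR1"], columns=["X1", "X2"]
    )
    path = pg.render_heatmap(matrix, tmp_path / "heat.png")
    img = Image.open(path).convert("RGB")
    colors = {c for _, c in img.getcolors(maxcolors=100_000)}
    assert (217, 217, 217) in colors  # reserved missing-cell grey


def test_render_heatmap_log_transform_of_zero_is_finite(tmp_path):
    matrix = pd.DataFrame([[0.0]], index=["PTGES2"], columns=["X1"])
    path = pg.render_heatmap(matrix, tmp_path / "heat.png", transform="log10p1")
    assert path.stat().st_size > 0


def test_run_pipeline_recovers_planted_truth(default_sim, tmp_path):
    _, bundles, truth = default_sim
    result = pg.run_pipeline(bundles=bundles, out_dir=tmp_path / "out")
    pd.testing.assert_frame_equal(result.presence_species, truth.presence_species())
    pd.testing.assert_frame_equal(
        result.presence_transcriptome, truth.presence_transcriptome()
    )
    group_count = defaultdict(int)
    for group in truth.copy_groups:
        sp, _, fn = group.partition("|")
        group_count[(sp, fn)] += 1
    for _, row in result.cluster_report.iterrows():
        assert row.cdhit_count == group_count[(row.species, row.function_code)]
    for name in (
        "assignments.tsv",
        "cluster_report.tsv",
        "clusters.clstr",
        "expression_matrix.tsv",
        "presence_species.tsv",
        "occurrence_counts.tsv",
        "occurrence_chart.png",
        "expression_heatmap.png",
        "run_log.txt",
    ):
        assert (tmp_path / "out" / name).exists(), name


def test_run_pipeline_outputs_are_deterministic(default_sim, tmp_path):
    _, bundles, _ = default_sim
    pg.run_pipeline(bundles=bundles, out_dir=tmp_path / "a", figures=False)
    pg.run_pipeline(bundles=bundles, out_dir=tmp_path / "b", figures=False)
    for path_a in sorted((tmp_path / "a").glob("*.tsv")):
        path_b = tmp_path / "b" / path_a.name
        assert path_a.read_bytes() == path_b.read_bytes(), path_a.name


def test_run_pipeline_from_directories(default_sim, tmp_path):
    config, bundles, _ = default_sim
    pg.simulate_to_directory(config, tmp_path / "bundles")
    dirs = sorted(p for p in (tmp_path / "bundles").iterdir() if p.is_dir())
    result = pg.run_pipeline(dirs, figures=False)
    in_memory = pg.run_pipeline(bundles=bundles, figures=False)
    assert result.assignments == in_memory.assignments
    pd.testing.assert_frame_equal(result.expression, in_memory.expression)


def test_run_pipeline_with_no_hits_succeeds(tmp_path, tiny_bundle):
    tiny_bundle.annotations = [
        pg.AnnotationHit("t1", "Q1", "Heat shock protein 70", 1, 10)
    ]
    result = pg.run_pipeline(bundles=[tiny_bundle], out_dir=tmp_path / "out")
    assert result.assignments == []
    assert result.presence_species.empty
    assert (tmp_path / "out" / "presence_species.tsv").exists()
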