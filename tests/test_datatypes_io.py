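"""Domain-type validation and CSV round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nullassembly import (
    AbundanceVector,
    BodyMassTable,
    IslandAttributes,
    PresenceAbsenceMatrix,
    QuadratCounts,
    ValidationError,
    analyze_matrix,
)
from nullassembly import io


# ---------------------------------------------------------------------------
# validation


def test_matrix_rejects_non_binary_cell_naming_it():
    with pytest.raises(ValidationError, match=r"spB.*i2|i2.*spB"):
        PresenceAbsenceMatrix(
            ("spA", "spB"), ("i1", "i2"), np.array([[1, 1], [1, 2]])
        )


def test_matrix_rejects_duplicates_and_empty_lines():
    with pytest.raises(ValidationError, match="duplicate"):
        PresenceAbsenceMatrix(("a", "a"), ("i", "j"), np.array([[1, 0], [0, 1]]))
    with pytest.raises(ValidationError, match="spB"):
        PresenceAbsenceMatrix(("spA", "spB"), ("i", "j"), np.array([[1, 1], [0, 0]]))
    with pytest.raises(ValidationError, match="i2"):
        PresenceAbsenceMatrix(("spA", "spB"), ("i1", "i2"), np.array([[1, 0], [1, 0]]))


def test_body_mass_validation():
    BodyMassTable(species=("CNS", "EUR"), mass=(0.5, 84.0))  # study's extremes
    with pytest.raises(ValidationError, match="-1"):
        BodyMassTable(species=("A",), mass=(-1.0,))


def test_island_attribute_validation():
    with pytest.raises(ValidationError, match="area"):
        IslandAttributes(island=("x",), area=(0.0,), richness=(3,))
    with pytest.raises(ValidationError, match="richness"):
        IslandAttributes(island=("x",), area=(1.0,), richness=(0,))


def test_quadrat_counts_validation():
    with pytest.raises(ValidationError, match="duplicate"):
        QuadratCounts(
            community=("c", "c"), quadrat=("q", "q"), species=("A", "A"), count=(1, 2)
        )
    with pytest.raises(ValidationError):
        QuadratCounts(community=("c",), quadrat=("q",), species=("A",), count=(-1,))


def test_abundance_vector_validation():
    with pytest.raises(ValidationError, match="descending"):
        AbundanceVector("c", (1, 5))
    with pytest.raises(ValidationError, match="positive"):
        AbundanceVector("c", (5, 0))


# ---------------------------------------------------------------------------
# readers / writers


def test_presence_absence_round_trip(tmp_path, small_matrix):
    path = tmp_path / "m.csv"
    io.write_presence_absence(small_matrix, path)
    back = io.read_presence_absence(path)
    assert back.species_labels == small_matrix.species_labels
    assert back.site_labels == small_matrix.site_labels
    assert (back.cells == small_matrix.cells).all()


def test_presence_absence_reader_rejects_bad_cells(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("species,i1,i2\nspA,1,2\nspB,1,0\n")
    with pytest.raises(ValidationError, match="i2"):
        io.read_presence_absence(path)
    path.write_text("species,i1,i2\nspA,1,\nspB,1,0\n")
    with pytest.raises(ValidationError, match="spA"):
        io.read_presence_absence(path)  # missing cell is not an implicit 0


def test_tab_delimited_matrices(tmp_path, small_matrix):
    path = tmp_path / "m.tsv"
    io.write_presence_absence(small_matrix, path, delimiter="\t")
    back = io.read_presence_absence(path, delimiter="\t")
    assert (back.cells == small_matrix.cells).all()


def test_trait_table_round_trips(tmp_path, archipelago_masses):
    p = tmp_path / "mass.csv"
    pd.DataFrame(
        {"species": archipelago_masses.species, "mass": archipelago_masses.mass}
    ).to_csv(p, index=False)
    back = io.read_body_mass(p)
    assert back.species == archipelago_masses.species
    assert np.allclose(back.mass, archipelago_masses.mass)

    p2 = tmp_path / "attrs.csv"
    pd.DataFrame(
        {"island": ["a", "b", "c"], "area": [1.5, 2.5, 3.5], "richness": [2, 3, 4]}
    ).to_csv(p2, index=False)
    attrs = io.read_island_attributes(p2)
    assert attrs.richness == (2, 3, 4)

    p3 = tmp_path / "broken.csv"
    pd.DataFrame({"species": ["a"], "weight": [1.0]}).to_csv(p3, index=False)
    with pytest.raises(ValidationError, match="mass"):
        io.read_body_mass(p3)


def test_config_reader(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("alpha: 0.01\nn_iter: 500\nseed: 7\n")
    cfg = io.read_config(p)
    assert cfg.alpha == 0.01 and cfg.n_iter == 500 and cfg.seed == 7
    assert cfg.random_band == 0.1  # defaults fill in
    p.write_text("alpa: 0.01\n")
    with pytest.raises(ValidationError, match="alpa"):
        io.read_config(p)


# ---------------------------------------------------------------------------
# report assembly


def test_report_pair_counts_conserved(tmp_path, small_matrix):
    results, summary = analyze_matrix(small_matrix)
    written = io.write_report(
        tmp_path / "out",
        config=io.AnalysisConfig(seed=3),
        pair_results={"geo": results},
        summaries={"geo": summary},
    )
    df = pd.read_csv(written["cooccurrence_summary"])
    row = df.iloc[0]
    assert (
        row["removed"] + row["positive"] + row["negative"]
        + row["random"] + row["unclassifiable"]
        == row["pairs_total"]
    )
    pairs = pd.read_csv(written["pairs_geo"])
    assert len(pairs) == row["pairs_total"]
    meta = (tmp_path / "out" / "run_metadata.yaml").read_text()
    assert "seed: 3" in meta and "alpha: 0.05" in meta


def test_report_sad_ranking_sorted(tmp_path):
    from nullassembly import fit_all, rank_by_aic
    from nullassembly.synthetic import gen_pareto_sample

    vec = gen_pareto_sample(40, 10, 0.8, seed=1)
    ranked = rank_by_aic(fit_all(vec, ["pareto", "lognormal", "broken-stick"]))
    written = io.write_report(
        tmp_path / "out", config=io.AnalysisConfig(), sad_rankings={"c": ranked}
    )
    df = pd.read_csv(written["sad_ranking_c"])
    assert (df["aic"].diff().dropna() >= 0).all()
    assert df["delta_aic"].iloc[0] == 0


def test_report_vratio_golden(tmp_path):
    """Golden check of a fixed synthetic V-ratio run: one row per community,
    SES column present, values reproducible from the seed."""
    from nullassembly import analyze_community, SizeCommunity

    rng = np.random.default_rng(8)
    table = BodyMassTable(
        species=tuple(f"s{i}" for i in range(20)),
        mass=tuple(np.exp(rng.uniform(np.log(0.5), np.log(84), 20)).tolist()),
    )
    results = []
    for k, members in enumerate((("s0", "s1", "s2", "s3"), ("s4", "s5", "s6", "s7", "s8"))):
        com = SizeCommunity(f"c{k}", members, tuple(table.mass_of(members).tolist()))
        results.append(analyze_community(table, com, n_iter=200, seed=10 + k))
    written = io.write_report(
        tmp_path / "out", config=io.AnalysisConfig(), vratio_results=results
    )
    df = pd.read_csv(written["vratio"])
    assert list(df["community"]) == ["c0", "c1"]
    assert df["ses"].notna().all()
    rerun = analyze_community(
        table,
        SizeCommunity("c0", ("s0", "s1", "s2", "s3"),
                      tuple(table.mass_of(("s0", "s1", "s2", "s3")).tolist())),
        n_iter=200, seed=10,
    )
    assert rerun.ses == pytest.approx(df["ses"].iloc[0])


def test_report_requires_some_results(tmp_path):
    with pytest.raises(ValueError):
        io.write_report(tmp_path / "out", config=io.AnalysisConfig())
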