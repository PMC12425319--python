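import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drmap.core_data import (DataError, RunConfig, make_district_graph,
                             read_adjacency, read_panel, read_population,
                             read_reference_rates, write_adjacency,
                             write_panel)


def _write_inputs(tmp_path, counts_rows, years=(2009, 2010),
                  districts=("A", "B")):
    counts = tmp_path / "counts.csv"
    counts.write_text("district_id,year,cases\n"
                      + "".join(f"{d},{y},{c}\n" for d, y, c in counts_rows))
    cov = tmp_path / "covariates.csv"
    cov.write_text("district_id,year,yos,urb,comp,wi\n"
                   + "".join(f"{d},{y},2.5,50,80,0.1\n"
                             for d in districts for y in years))
    exp = tmp_path / "expected.csv"
    exp.write_text("district_id,year,expected\n"
                   + "".join(f"{d},{y},3.5\n" for d in districts for y in years))
    return counts, cov, exp


class TestReadPanel:
    def test_complete_panel_has_all_true_mask(self, tmp_path):
        rows = [(d, y, 5) for d in "AB" for y in (2009, 2010)]
        panel = read_panel(*_write_inputs(tmp_path, rows))
        assert panel.observed_mask.all() and panel.Y.shape == (2, 2)
        assert panel.district_ids == ("A", "B")

    def test_single_missing_row_masks_exactly_that_cell(self, tmp_path):
        rows = [(d, y, 5) for d in "AB" for y in (2009, 2010)]
        rows.remove(("B", 2009, 5))
        panel = read_panel(*_write_inputs(tmp_path, rows))
        assert not panel.observed_mask[1, 0]
        assert panel.observed_mask.sum() == 3

    def test_missing_year_masks_whole_column(self, tmp_path):
        years = (2005, 2006, 2007)
        rows = [(d, y, 2) for d in "AB" for y in years if y != 2006]
        panel = read_panel(*_write_inputs(tmp_path, rows, years=years))
        assert (~panel.observed_mask[:, 1]).all()
        assert panel.observed_mask[:, [0, 2]].all()

    @pytest.mark.parametrize("bad_rows,match", [
        ([("A", 2009, 1), ("A", 2009, 2), ("B", 2009, 1), ("A", 2010, 1),
          ("B", 2010, 1)], "duplicate"),
        ([("A", 2009, -3), ("B", 2009, 1), ("A", 2010, 1), ("B", 2010, 1)],
         "negative"),
    ])
    def test_malformed_counts_raise(self, tmp_path, bad_rows, match):
        with pytest.raises(DataError, match=match):
            read_panel(*_write_inputs(tmp_path, bad_rows))

    def test_covariate_gap_names_cell(self, tmp_path):
        paths = _write_inputs(tmp_path, [(d, y, 1) for d in "AB"
                                         for y in (2009, 2010)])
        lines = paths[1].read_text().splitlines()
        paths[1].write_text("\n".join(lines[:-1]) + "\n")  # drop B,2010
        with pytest.raises(DataError, match="B.*2010"):
            read_panel(*paths)

    def test_roundtrip_is_byte_identical(self, tmp_path, small_panel):
        names = ["counts.csv", "covariates.csv", "expected.csv"]
        first = [tmp_path / n for n in names]
        write_panel(small_panel, *first)
        again = [tmp_path / ("2" + n) for n in names]
        write_panel(read_panel(*first), *again)
        for a, b in zip(first, again):
            assert a.read_bytes() == b.read_bytes()


class TestAdjacency:
    def test_reversed_duplicate_edges_merge(self, tmp_path):
        p = tmp_path / "adj.txt"
        p.write_text("A,B\nB,A\n")
        g = read_adjacency(p, ["A", "B"])
        assert len(g.edges) == 1
        assert g.neighbor_counts.tolist() == [1, 1]

    def test_empty_edge_file_gives_isolates(self, tmp_path):
        p = tmp_path / "adj.txt"
        p.write_text("")
        g = read_adjacency(p, ["A", "B", "C"])
        assert g.neighbor_counts.tolist() == [0, 0, 0]

    def test_four_cycle_degrees(self, tmp_path, square_graph):
        p = tmp_path / "adj.txt"
        write_adjacency(square_graph, p)
        g = read_adjacency(p, square_graph.district_ids)
        assert g.neighbor_counts.tolist() == [2, 2, 2, 2]
        assert g.edges == square_graph.edges

    @pytest.mark.parametrize("content,match", [
        ("A,A\n", "self-loop"),
        ("A,Z\n", "unknown district"),
    ])
    def test_bad_edges_raise(self, tmp_path, content, match):
        p = tmp_path / "adj.txt"
        p.write_text(content)
        with pytest.raises(DataError, match=match):
            read_adjacency(p, ["A", "B"])

    @settings(deadline=None, max_examples=30)
    @given(st.sets(st.tuples(st.integers(0, 9), st.integers(0, 9))
                   .filter(lambda e: e[0] != e[1]), max_size=20))
    def test_degree_sum_equals_twice_edges(self, int_edges):
        ids = [f"n{i}" for i in range(10)]
        g = make_district_graph(ids, [(f"n{a}", f"n{b}") for a, b in int_edges])
        assert g.neighbor_counts.sum() == 2 * len(g.edges)

    def test_coloring_is_proper(self, square_graph):
        colors = square_graph.coloring()
        idx = square_graph.index
        for a, b in square_graph.edges:
            assert colors[idx[a]] != colors[idx[b]]


class TestAuxiliaryReaders:
    def test_population_and_rates(self, tmp_path):
        (tmp_path / "pop.csv").write_text(
            "district_id,age_group,female_population\n"
            "A,30-34,1000\nA,35-39,500\nB,30-34,800\nB,35-39,400\n")
        (tmp_path / "rates.csv").write_text("age_group,rate\n30-34,0.001\n35-39,0.002\n")
        pop = read_population(tmp_path / "pop.csv")
        rates = read_reference_rates(tmp_path / "rates.csv")
        assert pop.population.shape == (2, 2)
        assert rates.age_groups == ("30-34", "35-39")

    def test_mismatched_age_groups_raise(self, tmp_path):
        (tmp_path / "pop.csv").write_text(
            "district_id,age_group,female_population\n"
            "A,30-34,1000\nB,35-39,400\n")
        with pytest.raises(DataError):
            read_population(tmp_path / "pop.csv")


class TestRunConfig:
    def test_defaults_give_20000_retained(self):
        cfg = RunConfig()
        assert cfg.total_retained == 20000

    def test_burn_in_must_precede_end(self):
        with pytest.raises(DataError):
            RunConfig(iterations_per_chain=100, burn_in=100)

    def test_yaml_roundtrip_preserves_hash(self, tmp_path):
        cfg = RunConfig(n_chains=3, seed=7, covariate_selection=("yos",))
        p = tmp_path / "config.yaml"
        import yaml
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert RunConfig.from_yaml(p).config_hash() == cfg.config_hash()
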