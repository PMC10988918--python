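import numpy as np
import pytest

from citegate import (
    ChainingError,
    FeatureNotFoundError,
    GateChain,
    Polygon,
    Rectangle,
    SchemaError,
    SchemaVersionError,
    ValidationError,
    apply_gate,
    canonical_schemes,
    downsample,
    export_chain,
    import_scheme,
    point_in_geometry,
    points_in_geometry,
    replay,
    summarize_chain,
)
from citegate.gates import GateSpec, GatingScheme, export_scheme

from conftest import min_edge_distance, random_simple_polygon, winding_number_inside

UNIT_SQUARE = Polygon(((0, 0), (1, 0), (1, 1), (0, 1)))


class TestGeometry:
    def test_unit_square_membership(self):
        assert point_in_geometry((0.5, 0.5), UNIT_SQUARE)
        assert not point_in_geometry((2.0, 0.5), UNIT_SQUARE)

    def test_boundary_points_are_inside(self):
        # edges and vertices count as inside, both geometries
        for p in [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0), (0.0, 0.0), (1.0, 1.0)]:
            assert point_in_geometry(p, UNIT_SQUARE)
        rect = Rectangle(0, 1, 0, 1)
        for p in [(0.0, 0.5), (1.0, 1.0), (0.3, 0.0)]:
            assert point_in_geometry(p, rect)
        assert not point_in_geometry((1.0 + 1e-12, 0.5), rect)

    def test_concave_polygon_matches_winding_oracle_on_grid(self):
        # C shape: a 3x3 block with a notch cut from the right
        c_shape = Polygon(((0, 0), (3, 0), (3, 1), (1, 1), (1, 2), (3, 2), (3, 3), (0, 3)))
        xs = np.linspace(-0.5, 3.5, 20)
        grid = np.array([(x, y) for x in xs for y in xs])
        far = min_edge_distance(grid, c_shape.vertices) > 1e-9
        ours = points_in_geometry(grid, c_shape)
        oracle = winding_number_inside(grid, c_shape.vertices)
        np.testing.assert_array_equal(ours[far], oracle[far])
        # spot-check the notch is outside and the spine inside
        assert not point_in_geometry((2.0, 1.5), c_shape)
        assert point_in_geometry((0.5, 1.5), c_shape)

    def test_random_polygons_match_winding_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            verts = random_simple_polygon(rng)
            pts = rng.uniform(-4, 4, size=(200, 2))
            far = min_edge_distance(pts, verts) > 1e-9
            ours = points_in_geometry(pts, Polygon(tuple(verts)))
            oracle = winding_number_inside(pts, verts)
            np.testing.assert_array_equal(ours[far], oracle[far])

    def test_degenerate_geometries_rejected(self):
        with pytest.raises(ValidationError):
            Rectangle(1, 1, 0, 2)
        with pytest.raises(ValidationError):
            Rectangle(0, 1, 5, 2)
        with pytest.raises(ValidationError):
            Polygon(((0, 0), (1, 1)))
        with pytest.raises(ValidationError):  # zero area: collinear
            Polygon(((0, 0), (1, 1), (2, 2)))

    def test_self_intersecting_polygon_warns(self):
        with pytest.warns(UserWarning, match="self-intersecting"):
            bowtie = Polygon(((0, 0), (2, 2), (2, 0), (0, 2)))
        # even-odd rule: the crossing center region is outside for a bowtie
        assert not point_in_geometry((1.0, 1.0 + 1e-6), bowtie)
        assert point_in_geometry((0.5, 1.0), bowtie)


class TestApplyGate:
    def test_manual_enumeration_oracle(self, toy5):
        # CD3 = (0.1, 2.0, 2.1, 0.2, 1.9); CD4 = (0.0, 1.8, 0.1, 0.0, 1.7);
        # the [1,3]x[1,3] box keeps exactly cells 2 and 5
        gate = apply_gate(
            toy5, "CD3+/CD4+", "ADT", "CD3", "ADT", "CD4", Rectangle(1.0, 3.0, 1.0, 3.0)
        )
        assert gate.output_barcodes == ("c2", "c5")
        assert gate.input_count == 5 and gate.output_count == 2
        assert gate.value_source == "normalized"

    def test_full_range_gate_is_identity(self, toy5):
        gate = apply_gate(
            toy5, "all", "ADT", "CD3", "ADT", "CD4", Rectangle(-10, 10, -10, 10)
        )
        assert gate.output_barcodes == gate.input_barcodes

    def test_empty_output_is_legal_and_warns(self, toy5):
        with pytest.warns(UserWarning, match="selected no cells"):
            gate = apply_gate(
                toy5, "none", "ADT", "CD3", "ADT", "CD4", Rectangle(50, 60, 50, 60)
            )
        assert gate.output_count == 0

    def test_empty_input_rejected(self, toy5):
        with pytest.raises(ValidationError, match="empty"):
            apply_gate(toy5, "g", "ADT", "CD3", "ADT", "CD4",
                       Rectangle(0, 1, 0, 1), input_barcodes=[])

    def test_unknown_feature_names_assay_and_feature(self, toy5):
        with pytest.raises(FeatureNotFoundError, match="'CD99'.*'ADT'"):
            apply_gate(toy5, "g", "ADT", "CD99", "ADT", "CD4", Rectangle(0, 1, 0, 1))

    def test_gates_commute_with_cell_order(self, pbmc_small):
        container, _ = pbmc_small
        rng = np.random.default_rng(0)
        perm = rng.permutation(container.n_cells)
        shuffled = container.subset(container.barcodes[np.sort(perm)])  # same set
        # subset keeps container order; emulate reordering via input_barcodes order
        geometry = Rectangle(0.5, 10.0, -10.0, 10.0)
        g1 = apply_gate(container, "g", "ADT", "CD3", "ADT", "CD4", geometry)
        g2 = apply_gate(
            container, "g", "ADT", "CD3", "ADT", "CD4", geometry,
            input_barcodes=[container.barcodes[i] for i in perm],
        )
        assert set(g1.output_barcodes) == set(g2.output_barcodes)


class TestChain:
    def test_two_step_cd8_scheme_counters_and_nesting(self, pbmc_small):
        container, truth = pbmc_small
        scheme, target = canonical_schemes(container)["cd8_t"]
        chain = replay(scheme, container)
        assert [g.counter for g in chain.gates] == [1, 2]
        assert set(chain.gates[1].input_barcodes) == set(chain.gates[0].output_barcodes)
        out1, out2 = set(chain.gates[0].output_barcodes), set(chain.gates[1].output_barcodes)
        assert out2 <= out1 <= set(chain.root_barcodes)

    def test_appending_stale_gate_rejected(self, toy5):
        g = apply_gate(toy5, "g1", "ADT", "CD3", "ADT", "CD4", Rectangle(1, 3, 1, 3))
        chain = GateChain(root_barcodes=toy5.barcodes)
        chain.append(g)
        stale = apply_gate(  # input is the root, not g1's output
            toy5, "g2", "ADT", "CD3", "ADT", "CD4", Rectangle(0, 3, -1, 3)
        )
        with pytest.raises(ChainingError, match="does not match"):
            chain.append(stale)

    def test_append_to_empty_chain_sets_root(self, toy5):
        chain = GateChain(root_barcodes=toy5.barcodes)
        g = apply_gate(toy5, "g1", "ADT", "CD3", "ADT", "CD4", Rectangle(1, 3, 1, 3))
        chain.append(g)
        assert chain.gates[0].counter == 1
        assert chain.root_barcodes == g.input_barcodes


class TestSchemeSerialization:
    def test_export_import_reexport_byte_identical(self, tmp_path, pbmc_small):
        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd8_t"]
        chain = replay(scheme, container)
        p1, audit = export_chain(chain, tmp_path / "s1.yaml")
        imported = import_scheme(p1)
        p2 = export_scheme(imported, tmp_path / "s2.yaml")
        assert p1.read_bytes() == p2.read_bytes()

    def test_audit_lists_per_gate_counts_and_barcodes(self, tmp_path, pbmc_small):
        import json

        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd4_t"]
        chain = replay(scheme, container)
        _, audit_path = export_chain(chain, tmp_path / "s.yaml")
        audit = json.loads(audit_path.read_text())
        assert audit["container_fingerprint"] == container.fingerprint()
        g = audit["gates"][0]
        assert g["output_count"] == len(g["output_barcodes"]) == chain.gates[0].output_count

    def test_missing_key_names_the_key(self, tmp_path):
        (tmp_path / "bad.yaml").write_text(
            "schema_version: 1\nname: x\ngates:\n- label: g\n  assay_x: ADT\n"
        )
        with pytest.raises(SchemaError, match="feature_x"):
            import_scheme(tmp_path / "bad.yaml")

    def test_schema_version_mismatch_reports_versions(self, tmp_path):
        (tmp_path / "v9.yaml").write_text("schema_version: 9\nname: x\ngates: []\n")
        with pytest.raises(SchemaVersionError, match="9.*expected 1"):
            import_scheme(tmp_path / "v9.yaml")


class TestReplay:
    def test_replay_reproduces_counts_exactly(self, pbmc_small, tmp_path):
        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd8_t"]
        chain = replay(scheme, container)
        scheme_path, _ = export_chain(chain, tmp_path / "s.yaml")
        chain2 = replay(import_scheme(scheme_path), container)
        assert [g.output_count for g in chain2.gates] == [g.output_count for g in chain.gates]
        assert [g.output_barcodes for g in chain2.gates] == [
            g.output_barcodes for g in chain.gates
        ]

    def test_replay_on_downsampled_container_yields_subsets(self, pbmc_small):
        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd8_t"]
        full = replay(scheme, container)
        # across-cells CLR depends on the cell set; reuse the full container's
        # normalized values by subsetting (gates must then select subsets)
        half = container.subset(
            downsample(container, container.n_cells // 2, seed=9).barcodes
        )
        part = replay(scheme, half)
        for g_full, g_half in zip(full.gates, part.gates):
            assert set(g_half.output_barcodes) <= set(g_full.output_barcodes)

    def test_missing_feature_fails_before_any_gate(self, pbmc_small):
        container, _ = pbmc_small
        scheme = GatingScheme(
            name="bad",
            gates=[
                GateSpec("g1", "ADT", "CD3", "ADT", "CD4", Rectangle(0, 1, 0, 1)),
                GateSpec("g2", "ADT", "CD99", "ADT", "CD4", Rectangle(0, 1, 0, 1)),
            ],
        )
        with pytest.raises(FeatureNotFoundError, match="CD99"):
            replay(scheme, container)

    def test_normalization_record_mismatch_warns(self, pbmc_small):
        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd4_t"]
        scheme.normalization = {"method": "clr", "margin": "within_cell",
                                "pseudocount": 1.0, "clr_variant": "log1p_centered"}
        with pytest.warns(UserWarning, match="normalization record differs"):
            replay(scheme, container)


class TestSummarize:
    def test_identity_gate_is_100_percent(self, toy5):
        chain = GateChain(root_barcodes=toy5.barcodes)
        chain.append(apply_gate(toy5, "all", "ADT", "CD3", "ADT", "CD4",
                                Rectangle(-10, 10, -10, 10)))
        row = summarize_chain(chain).iloc[0]
        assert row["pct_parent"] == 100.0 and row["pct_root"] == 100.0

    def test_percent_of_root_is_product_of_parents(self, pbmc_small):
        container, _ = pbmc_small
        scheme, _ = canonical_schemes(container)["cd8_t"]
        table = summarize_chain(replay(scheme, container))
        prod = np.prod(table["pct_parent"].to_numpy() / 100.0)
        assert table["pct_root"].iloc[-1] == pytest.approx(100.0 * prod)

    def test_empty_gate_shows_zero(self, toy5):
        chain = GateChain(root_barcodes=toy5.barcodes)
        with pytest.warns(UserWarning):
            chain.append(apply_gate(toy5, "none", "ADT", "CD3", "ADT", "CD4",
                                    Rectangle(50, 60, 50, 60)))
        assert summarize_chain(chain)["pct_parent"].iloc[0] == 0.0
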