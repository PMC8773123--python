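"""EC table parsing, filtering rules and spatial classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmtools import (
    DomainMap,
    build_pair,
    classify_spatial,
    ddm,
    filter_ecs,
    load_ec_table,
    overlay_on_ddm,
)
from ddmtools.ec import ECRecord, ECTable
from ddmtools.synthetic import MotionSpec, apply_motions, make_ec_fixture, make_ring_assembly


def write_ec(tmp_path, text, name="ec.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadECTable:
    def test_toy_table(self, tmp_path):
        p = write_ec(tmp_path, "i,j,cn\n5,9,1.2\n3,20,0.8\n7,40,2.5\n")
        table = load_ec_table(p)
        assert len(table) == 3
        assert table.records[0] == ECRecord(3, 20, 0.8)

    def test_duplicate_mirror_pairs_keep_higher_cn(self, tmp_path):
        p = write_ec(tmp_path, "i,j,cn\n5,9,1.0\n9,5,2.0\n")
        table = load_ec_table(p)
        assert len(table) == 1
        assert table.records[0].cn == 2.0

    def test_numbering_offset(self, tmp_path):
        # signal-peptide correction: sequence 30 -> structure residue 9
        p = write_ec(tmp_path, "i,j,cn\n30,60,1.5\n")
        table = load_ec_table(p, numbering_offset=-21)
        assert (table.records[0].residue_i, table.records[0].residue_j) == (9, 39)

    def test_tab_delimited_and_bad_rows_skipped(self, tmp_path):
        p = write_ec(tmp_path, "i\tj\tcn\n1\t9\t1.5\nx\ty\tz\n2\t8\t0.5\n")
        table = load_ec_table(p)
        assert len(table) == 2

    def test_missing_cn_column_errors(self, tmp_path):
        p = write_ec(tmp_path, "i,j\n1,9\n")
        with pytest.raises(ValueError, match="cn"):
            load_ec_table(p)


class TestFilterECs:
    @pytest.fixture
    def toy(self):
        return ECTable(records=[
            ECRecord(1, 10, 0.5), ECRecord(2, 11, 1.0), ECRecord(3, 12, 2.3),
        ])

    def test_inclusive_cn_floor_1(self, toy):
        assert len(filter_ecs(toy, cn_min=1.0)) == 2

    def test_cn_floor_2(self, toy):
        assert len(filter_ecs(toy, cn_min=2.0)) == 1

    def test_strict_mode_drops_boundary(self, toy):
        assert len(filter_ecs(toy, cn_min=1.0, strict_cn=True)) == 1

    def test_sequence_separation(self):
        table = ECTable(records=[ECRecord(100, 103, 2.0), ECRecord(100, 120, 2.0)])
        kept = filter_ecs(table, min_sequence_separation=5)
        assert [(r.residue_i, r.residue_j) for r in kept.records] == [(100, 120)]

    def test_same_segment_exclusion_via_domain_map(self):
        segs = DomainMap(blocks={"H3": [("A", 1, 50)], "H7": [("A", 51, 100)]})
        table = ECTable(records=[
            ECRecord(5, 40, 2.0),   # both in H3 -> removed
            ECRecord(10, 60, 2.0),  # spans helices -> kept
        ])
        kept = filter_ecs(table, exclude_same_segment=True, segments=segs)
        assert [(r.residue_i, r.residue_j) for r in kept.records] == [(10, 60)]

    def test_empty_result_allowed(self, toy):
        assert len(filter_ecs(toy, cn_min=99.0)) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 50), st.integers(51, 99),
                              st.floats(0, 5, allow_nan=False)), max_size=30),
           st.floats(0, 5), st.floats(0, 5))
    def test_monotone_in_cn_floor(self, pairs, lo, hi):
        """Raising the cn floor never increases the kept-record count."""
        seen = set()
        records = []
        for i, j, cn in pairs:
            if (i, j) not in seen:
                seen.add((i, j))
                records.append(ECRecord(i, j, cn))
        table = ECTable(records=records)
        lo, hi = min(lo, hi), max(lo, hi)
        assert len(filter_ecs(table, cn_min=hi)) <= len(filter_ecs(table, cn_min=lo))


def _line_model(n=30, spacing=1.0, chain="A"):
    """Residues along x: Cα distance between i and j is spacing * |i - j|."""
    import ddmtools.structure_io as sio
    residues, atoms = [], []
    for i in range(1, n + 1):
        key = sio.ResidueKey(chain, i)
        c = (spacing * i, 0.0, 0.0)
        residues.append(sio.Residue(key, "GLY", c))
        atoms.append(sio.Atom(key, "CA", "C", c, 1.87))
    return sio.StructureModel("line", residues, atoms)


@pytest.fixture(scope="module")
def straight_chain():
    return _line_model()


class TestClassifySpatial:

    def test_close_cutoff_is_strict(self, straight_chain):
        table = ECTable(records=[ECRecord(1, 11, 2.0),  # 10.0 Å -> distant
                                 ECRecord(1, 10, 2.0)])  # 9.0 Å -> close
        by_pair = {(o.record.residue_i, o.record.residue_j): o.spatial_class
                   for o in classify_spatial(table, straight_chain)}
        assert by_pair[(1, 10)] == "close"
        assert by_pair[(1, 11)] == "distant"

    def test_planted_distance_exact(self, straight_chain):
        table = ECTable(records=[ECRecord(5, 25, 2.0)])
        (ov,) = classify_spatial(table, straight_chain)
        assert ov.distances["intra"] == pytest.approx(20.0, abs=1e-9)
        assert ov.spatial_class == "distant"

    def test_symmetric_ring_inter_distances_equal(self, trimer):
        model, _ = trimer
        table = ECTable(records=[ECRecord(2, 9, 2.0)])
        (ov,) = classify_spatial(table, model, chain_scope="both")
        # C3 symmetry: the minimum inter-protomer distance is attained
        # identically for every adjacent protomer pair
        coords = {c: {r.key.residue_number: np.asarray(r.ca)
                      for r in model.residues if r.key.chain_id == c}
                  for c in model.chain_ids}
        dists = []
        for c1 in coords:
            for c2 in coords:
                if c1 != c2:
                    dists.append(np.linalg.norm(coords[c1][2] - coords[c2][9]))
        assert ov.distances["inter"] == pytest.approx(min(dists), abs=1e-9)

    def test_rigid_motion_invariance(self, straight_chain):
        from conftest import random_rigid_transform
        import ddmtools.structure_io as sio
        q, t = random_rigid_transform(np.random.default_rng(3))
        moved = sio.StructureModel(
            "rot",
            [sio.Residue(r.key, r.name, tuple(q @ np.asarray(r.ca) + t))
             for r in straight_chain.residues],
            [sio.Atom(a.key, a.name, a.element, tuple(q @ np.asarray(a.coord) + t),
                      a.radius) for a in straight_chain.atoms],
        )
        table = ECTable(records=[ECRecord(3, 17, 2.0)])
        (a,) = classify_spatial(table, straight_chain)
        (b,) = classify_spatial(table, moved)
        assert a.distances["intra"] == pytest.approx(b.distances["intra"], abs=1e-9)

    def test_unresolvable_table_errors(self, straight_chain):
        table = ECTable(records=[ECRecord(500, 600, 2.0)])
        with pytest.raises(ValueError):
            classify_spatial(table, straight_chain)

    def test_close_fraction_recovers_planted_composition(self):
        """Planted contacts + decoys: the close fraction matches the planted
        50/50 mixture within binomial error (n = 400 pairs)."""
        model, _ = make_ring_assembly(2, 120, 60.0, seed=9)
        table, labels = make_ec_fixture(model, contact_cutoff=10.0,
                                        n_true=200, n_decoys=200, seed=10)
        kept = filter_ecs(table, cn_min=1.0, min_sequence_separation=5)
        overlay = classify_spatial(kept, model, close_cutoff=10.0)
        frac = sum(1 for o in overlay if o.spatial_class == "close") / len(overlay)
        # 95% binomial interval around 0.5 at n=400 is ±1.96*0.025 ≈ ±0.049
        assert abs(frac - 0.5) < 0.05


class TestOverlayOnDDM:
    def test_masked_pair_has_absent_value(self, translated_trimer):
        model_a, model_b, _, _ = translated_trimer
        mat = ddm(build_pair(model_a, model_b))
        table = ECTable(records=[ECRecord(1, 8, 2.0)])
        overlay = classify_spatial(table, model_a)
        df, counts = overlay_on_ddm(overlay, mat)
        assert df.ddm_value.isna().all()
        assert counts["masked"] == 1

    def test_empty_overlay(self, translated_trimer):
        model_a, model_b, _, _ = translated_trimer
        mat = ddm(build_pair(model_a, model_b))
        df, counts = overlay_on_ddm([], mat)
        assert df.empty
        assert sum(counts.values()) == 0

    def test_planted_contraction_annotated_exactly(self):
        """A pair spanning a block moved 4 Å closer reads Δd = −4."""
        state_a = _line_model(n=40, spacing=2.0)
        dmap = DomainMap(blocks={"head": [("A", 1, 20)], "tail": [("A", 21, 40)]})
        state_b, _ = apply_motions(state_a, dmap,
                                   [MotionSpec("tail", translation=(-4.0, 0, 0))])
        mat = ddm(build_pair(state_a, state_b))
        table = ECTable(records=[ECRecord(5, 30, 2.0),   # spans the moved block
                                 ECRecord(25, 35, 2.0)])  # inside it: rigid
        overlay = classify_spatial(table, state_a)
        df, counts = overlay_on_ddm(overlay, mat)
        row = df[(df.i == 5) & (df.j == 30)].iloc[0]
        assert row.ddm_value == pytest.approx(-4.0, abs=1e-9)
        assert row.ddm_class == "contracting"
        assert counts == {"contracting": 1, "expanding": 0, "masked": 1, "outside": 0}
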