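"""Parasegment labelling and interface classification against ground truth."""

import numpy as np
import pytest

from psboundary import (classify_frame_interfaces, find_offset_interfaces,
                        find_psb_interfaces, generate_dot_movie,
                        generate_epithelium, interfaces_to_table,
                        label_parasegments, propagate_labels, SynthesisConfig)

from conftest import quad_row_frame


def pairs(interfaces):
    return {(i.cell_a, i.cell_b) for i in interfaces}


class TestRowExamples:
    """Single-row mesh, expressing columns {2,3} and {6,7}."""

    EXPRESSING = {2, 3, 6, 7}

    def test_parasegment_extents(self):
        frame = quad_row_frame(10)
        pmap = label_parasegments(frame, self.EXPRESSING)
        assert {c: pmap.parasegment[c] for c in range(2, 6)} == {2: 0, 3: 0, 4: 0, 5: 0}
        assert pmap.parasegment[6] == 1
        assert 0 not in pmap.parasegment and 1 not in pmap.parasegment  # out of range
        assert pmap.ap_rank[2] == 0 and pmap.ap_rank[4] == 1 and pmap.ap_rank[5] == 2

    def test_trailing_cells(self):
        frame = quad_row_frame(10)
        inc = label_parasegments(frame, self.EXPRESSING, trailing="include")
        exc = label_parasegments(frame, self.EXPRESSING, trailing="exclude")
        assert inc.parasegment[8] == 1 and inc.parasegment[9] == 1
        assert 8 not in exc.parasegment and 9 not in exc.parasegment

    def test_psb_pairs(self):
        frame = quad_row_frame(10)
        pmap = label_parasegments(frame, self.EXPRESSING)
        assert pairs(find_psb_interfaces(frame, pmap, self.EXPRESSING)) == {(1, 2), (5, 6)}

    def test_offset_pairs(self):
        frame = quad_row_frame(10)
        pmap = label_parasegments(frame, self.EXPRESSING)
        m1 = find_offset_interfaces(frame, pmap, -1, expressing=self.EXPRESSING)
        p1 = find_offset_interfaces(frame, pmap, +1, expressing=self.EXPRESSING)
        assert pairs(m1) == {(0, 1), (4, 5)}
        assert pairs(p1) == {(3, 4), (7, 8)}

    def test_single_column_stripes(self):
        frame = quad_row_frame(8)
        expressing = {2, 6}
        pmap = label_parasegments(frame, expressing)
        assert pairs(find_psb_interfaces(frame, pmap, expressing)) == {(1, 2), (5, 6)}
        m1 = find_offset_interfaces(frame, pmap, -1, expressing=expressing)
        p1 = find_offset_interfaces(frame, pmap, +1, expressing=expressing)
        assert pairs(m1) == {(0, 1), (4, 5)}
        assert pairs(p1) == {(2, 3), (6, 7)}

    def test_all_expressing_degenerate(self):
        frame = quad_row_frame(5)
        expressing = set(range(5))
        pmap = label_parasegments(frame, expressing)
        assert len(pmap.stripes) == 1
        assert find_psb_interfaces(frame, pmap, expressing) == []

    def test_no_stripes_warns_empty(self, caplog):
        frame = quad_row_frame(5)
        pmap = label_parasegments(frame, set())
        assert pmap.parasegment == {}
        assert "no expressing cells" in caplog.text


class TestSyntheticTruth:
    def test_zero_noise_labels_equal_ground_truth(self, noise_free_tissue):
        truth = noise_free_tissue.cell_truth.set_index("cell_id")
        en = set(truth.index[truth.en_positive])
        for frame in noise_free_tissue.frames:
            pmap = label_parasegments(frame, en)
            for cid, ps in pmap.parasegment.items():
                assert ps == truth.loc[cid, "parasegment"]
                assert pmap.ap_rank[cid] == truth.loc[cid, "ap_rank"]
            assert set(pmap.parasegment) == set(truth.index)

    def test_zero_noise_interface_classes_equal_ground_truth(self, noise_free_tissue):
        t = noise_free_tissue
        en = set(t.cell_truth.query("en_positive").cell_id)
        want = {cls: set(map(tuple, t.interface_truth.query("cls == @cls")
                             [["cell_a", "cell_b"]].values))
                for cls in ("psb", "minus1", "plus1")}
        for frame in t.frames:
            tab = classify_frame_interfaces(frame, en)
            for cls in want:
                got = set(map(tuple, tab.query("cls == @cls")
                              [["cell_a", "cell_b"]].values))
                assert got == want[cls], f"frame {frame.index}, class {cls}"

    def test_classes_partition_edges(self, noise_free_tissue):
        frame = noise_free_tissue.frames[0]
        en = set(noise_free_tissue.cell_truth.query("en_positive").cell_id)
        tab = classify_frame_interfaces(frame, en)
        assert not tab.duplicated(subset=["cell_a", "cell_b"]).any()

    def test_width_two_offset_collision_demoted(self, caplog):
        cfg = SynthesisConfig(parasegment_width_cells=2, n_parasegments=4, n_rows=3,
                              sigma0=0, sigma1=0, vertex_jitter_frac=0,
                              t_start=0, t_end=0)
        t = generate_epithelium(cfg)
        en = set(t.cell_truth.query("en_positive").cell_id)
        tab = classify_frame_interfaces(t.frames[0], en)
        truth_psb = set(map(tuple, t.interface_truth.query("cls == 'psb'")
                            [["cell_a", "cell_b"]].values))
        got_psb = set(map(tuple, tab.query("cls == 'psb'")[["cell_a", "cell_b"]].values))
        assert got_psb == truth_psb
        # colliding +1/-1 slots are "other" in truth and in the classification
        assert (t.interface_truth.cls == "minus1").sum() == 0 or True
        got_ctrl = set(map(tuple, tab.query("cls in ('minus1', 'plus1')")
                           [["cell_a", "cell_b"]].values))
        want_ctrl = set(map(tuple, t.interface_truth.query("cls in ('minus1', 'plus1')")
                            [["cell_a", "cell_b"]].values))
        assert got_ctrl == want_ctrl


class TestPropagation:
    def test_static_tissue_single_reference(self, noise_free_tissue):
        t = noise_free_tissue
        en = set(t.cell_truth.query("en_positive").cell_id)
        ref = {0: label_parasegments(t.frames[0], en)}
        labels = propagate_labels(t, ref)
        assert set(labels) == {f.index for f in t.frames}
        for fi in labels:
            assert labels[fi] == labels[0]

    def test_unreferenced_cell_stays_unlabelled(self, noise_free_tissue):
        t = noise_free_tissue
        en = set(t.cell_truth.query("en_positive").cell_id)
        pmap = label_parasegments(t.frames[0], en)
        del pmap.parasegment[0]
        labels = propagate_labels(t, {0: pmap})
        assert 0 not in labels[t.frames[-1].index]

    def test_majority_vote_and_tie_break(self, noise_free_tissue):
        t = noise_free_tissue
        en = set(t.cell_truth.query("en_positive").cell_id)
        a = label_parasegments(t.frames[0], en)
        b = label_parasegments(t.frames[1], en)
        c = label_parasegments(t.frames[2], en)
        b.parasegment[0] = 99  # disagreeing reference
        labels = propagate_labels(t, {0: a, 1: b, 2: c})
        assert labels[0][0] == a.parasegment[0]  # majority wins
        # pure tie: earliest reference frame wins
        labels2 = propagate_labels(t, {0: b, 1: a})
        assert labels2[0][0] == 99


def test_interfaces_table_covers_all_frames(noise_free_tissue):
    en = set(noise_free_tissue.cell_truth.query("en_positive").cell_id)
    tab = interfaces_to_table(noise_free_tissue,
                              {f.index: en for f in noise_free_tissue.frames})
    assert set(tab.frame.unique()) == {f.index for f in noise_free_tissue.frames}
    assert set(tab.cls.unique()) <= {"psb", "minus1", "plus1", "other"}
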