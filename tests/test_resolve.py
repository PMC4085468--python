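"""Tracking actions and the end-to-end pipeline."""

import numpy as np
import pytest

from lineagetrace.bifurcation import (Bifurcation, build_neighborhood,
                                      find_terminations)
from lineagetrace.model import (Detection, Lineage, LineageError,
                                STATUS_INTERPOLATED, STATUS_UNEXPLAINED,
                                TrackingConfig)
from lineagetrace.resolve import (apply_division, apply_fp, apply_other,
                                  apply_two_cell, trace_lineage)
from lineagetrace.simulate import SimConfig, generate_embryo, inject_errors


def det(i, t, x, y=0.0, z=0.0, r=1.0, inten=10.0):
    return Detection(id=i, t=t, x=x, y=y, z=z, radius=r, intensity=inten)


class TestApplyDivision:
    def test_parent_gets_two_successors(self, tcfg):
        lin = Lineage([det(1, 1, 0.0), det(2, 2, -1.0), det(3, 2, 1.0)])
        lin.add_link(1, 2)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=3)
        nb = build_neighborhood(bif, [], lin, tcfg)
        apply_division(nb, lin)
        assert set(lin.successors(1)) == {2, 3}

    def test_reapply_is_structural_error(self, tcfg):
        lin = Lineage([det(1, 1, 0.0), det(2, 2, -1.0), det(3, 2, 1.0),
                       det(4, 1, 8.0)])
        lin.add_link(1, 2)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=3)
        nb = build_neighborhood(bif, [], lin, tcfg)
        apply_division(nb, lin)
        bif2 = Bifurcation(parent_id=4, child_a_id=None, child_b_id=3)
        nb2 = build_neighborhood(bif2, [], lin, tcfg)
        with pytest.raises(LineageError):
            apply_division(nb2, lin)  # child 3 already has a predecessor


class TestApplyTwoCell:
    def test_midpoint_interpolation(self, tcfg):
        # termination (0,0,0)@t5, re-appearance (2,2,2)@t7 -> insert (1,1,1)@t6
        dets = [det(1, 5, 0.0, 0.0, 0.0), det(2, 6, 10.0), det(3, 7, 10.2),
                det(4, 7, 2.0, 2.0, 2.0)]
        lin = Lineage(dets)
        lin.add_link(2, 3)
        bif = Bifurcation(parent_id=2, child_a_id=3, child_b_id=4)
        nb = build_neighborhood(bif, find_terminations(lin, bif, tcfg), lin, tcfg)
        assert nb.termination_end_id == 1
        apply_two_cell(nb, lin)
        inserted = [d for d in lin.detections.values()
                    if lin.status[d.id] == STATUS_INTERPOLATED]
        assert len(inserted) == 1
        ins = inserted[0]
        assert ins.t == 6
        assert (ins.x, ins.y, ins.z) == pytest.approx((1.0, 1.0, 1.0))
        assert lin.predecessor(ins.id) == 1
        assert lin.successors(ins.id) == (4,)

    def test_gap_zero_rewires_without_insertion(self, tcfg):
        dets = [det(1, 6, 0.0), det(2, 6, 10.0), det(3, 7, 10.2), det(4, 7, 0.4)]
        lin = Lineage(dets)
        lin.add_link(2, 3)
        bif = Bifurcation(parent_id=2, child_a_id=3, child_b_id=4)
        nb = build_neighborhood(bif, find_terminations(lin, bif, tcfg), lin, tcfg)
        assert nb.termination_end_id == 1 and nb.gap_frames == 0
        apply_two_cell(nb, lin)
        assert lin.predecessor(4) == 1
        assert not any(s == STATUS_INTERPOLATED for s in lin.status.values())

    def test_three_frame_gap_linearity(self, tcfg):
        # endpoints (0,0,0)@t4 -> (3,0,0)@t7: insertions at (1,..)@t5, (2,..)@t6
        dets = [det(1, 4, 0.0), det(2, 6, 12.0), det(3, 7, 12.1),
                det(4, 7, 3.0)]
        lin = Lineage(dets)
        lin.add_link(2, 3)
        cfg = TrackingConfig(termination_window_dt=3, termination_window_dx=3.0)
        bif = Bifurcation(parent_id=2, child_a_id=3, child_b_id=4)
        nb = build_neighborhood(bif, find_terminations(lin, bif, cfg), lin, cfg)
        assert nb.termination_end_id == 1
        apply_two_cell(nb, lin)
        inserted = sorted((d.t, d.x) for d in lin.detections.values()
                          if lin.status[d.id] == STATUS_INTERPOLATED)
        assert inserted == [(5, pytest.approx(1.0)), (6, pytest.approx(2.0))]


class TestApplyFp:
    def _branching(self, len_a, len_b, inten_a=10.0, inten_b=10.0):
        """Parent 1 at t=1; branch A from id 2, branch B from id 100."""
        lin = Lineage([det(1, 1, 0.0)])
        prev = None
        for k in range(len_a):
            i = 2 + k
            lin.add_detection(det(i, 2 + k, -1.0 - 0.1 * k, inten=inten_a))
            if prev is not None:
                lin.add_link(prev, i)
            prev = i
        prev = None
        for k in range(len_b):
            i = 100 + k
            lin.add_detection(det(i, 2 + k, 1.0 + 0.1 * k, inten=inten_b))
            if prev is not None:
                lin.add_link(prev, i)
            prev = i
        lin.add_link(1, 2)
        return lin

    def test_shorter_branch_deleted(self, tcfg):
        lin = self._branching(1, 5)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=100)
        nb = build_neighborhood(bif, [], lin, tcfg)
        apply_fp(nb, lin)
        assert lin.is_deleted(2)
        assert not lin.is_deleted(100)

    def test_tie_breaks_on_intensity(self, tcfg):
        lin = self._branching(2, 2, inten_a=100.0, inten_b=10.0)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=100)
        nb = build_neighborhood(bif, [], lin, tcfg)
        apply_fp(nb, lin)
        assert lin.is_deleted(100) and lin.is_deleted(101)
        assert not lin.is_deleted(2)

    def test_simulator_fp_track_deleted(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=4, n_frames=25, cell_cycle_mean=40,
                        fp_rate=0.02, rng_seed=12)
        embryo = generate_embryo(cfg)
        observed, ann = inject_errors(embryo, cfg)
        assert ann.fp_ids
        lin, _ = trace_lineage(observed, trained_model, tcfg)
        deleted = sum(1 for i in ann.fp_ids if lin.is_deleted(i))
        assert deleted / len(ann.fp_ids) >= 0.8


class TestApplyOther:
    def test_worse_child_detached(self, tcfg):
        # child 3 continues the parent much better than distant child 4
        lin = Lineage([det(1, 1, 0.0), det(2, 2, 0.1), det(3, 2, 2.8)])
        lin.add_link(1, 2)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=3)
        nb = build_neighborhood(bif, [], lin, tcfg)
        detached = apply_other(nb, lin)
        assert detached == 3
        assert lin.successors(1) == (2,)

    def test_swap_when_existing_successor_is_worse(self, tcfg):
        lin = Lineage([det(1, 1, 0.0), det(2, 2, 2.8), det(3, 2, 0.1)])
        lin.add_link(1, 2)
        bif = Bifurcation(parent_id=1, child_a_id=2, child_b_id=3)
        nb = build_neighborhood(bif, [], lin, tcfg)
        detached = apply_other(nb, lin)
        assert detached == 2
        assert lin.successors(1) == (3,)


class TestTraceLineage:
    def test_empty_input(self, tcfg):
        lin, report = trace_lineage([], None, tcfg)
        assert lin.detections == {}
        assert report.records == []

    def test_clean_embryo_recovered(self, trained_model, tcfg, clean_embryo):
        observed = clean_embryo.observed
        lin, report = trace_lineage(observed, trained_model, tcfg)
        truth = clean_embryo.true_lineage
        assert lin.links() == truth.links()

    def test_deterministic(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=3, n_frames=25, cell_cycle_mean=10,
                        fp_rate=0.02, fn_rate=0.02, rng_seed=4)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        lin1, rep1 = trace_lineage(observed, trained_model, tcfg)
        lin2, rep2 = trace_lineage(observed, trained_model, tcfg)
        assert lin1.links() == lin2.links()
        assert lin1.status == lin2.status
        assert [r.action for r in rep1.records] == [r.action for r in rep2.records]

    def test_conservation_of_states(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=3, n_frames=30, cell_cycle_mean=12,
                        fp_rate=0.03, fn_rate=0.02, jitter_sd=0.05, rng_seed=9)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        lin, report = trace_lineage(observed, trained_model, tcfg)
        lin.validate()
        first = lin.frames()[0]
        for det_id, status in lin.status.items():
            if status in ("deleted", "interpolated", STATUS_UNEXPLAINED):
                continue
            d = lin.detections[det_id]
            assert d.t == first or lin.predecessor(det_id) is not None, \
                f"tracked detection {det_id} lacks a predecessor"

    def test_no_multiframe_links(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=3, n_frames=30, cell_cycle_mean=12,
                        fn_rate=0.03, rng_seed=14)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        lin, _ = trace_lineage(observed, trained_model, tcfg)
        for p, s in lin.links():
            assert lin.detections[s].t - lin.detections[p].t == 1

    def test_action_log_reconciles(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=3, n_frames=30, cell_cycle_mean=12,
                        fp_rate=0.03, fn_rate=0.02, rng_seed=16)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        lin, report = trace_lineage(observed, trained_model, tcfg)
        n_deleted_log = sum(len(r.deleted_ids) for r in report.records)
        n_deleted = sum(1 for i in lin.detections if lin.is_deleted(i))
        assert n_deleted == n_deleted_log
        n_inserted_log = sum(len(r.inserted_ids) for r in report.records)
        n_inserted = sum(1 for s in lin.status.values()
                         if s == STATUS_INTERPOLATED)
        assert n_inserted == n_inserted_log
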