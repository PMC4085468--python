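"""Lineage-vs-truth scoring metrics."""

import numpy as np
import pytest

from lineagetrace.evaluate import (confusion_matrix, cumulative_accuracy,
                                   density, density_binned_errors,
                                   division_scores, evaluate_lineages,
                                   instantaneous_accuracy)
from lineagetrace.model import Detection, Lineage
from lineagetrace.simulate import (SimConfig, generate_embryo, inject_errors,
                                   simulate_cumulative_accuracy)


def det(i, t, x, r=1.0):
    return Detection(id=i, t=t, x=x, y=0.0, z=0.0, radius=r, intensity=1.0)


def binary_tree_lineage(depth, cycle=3):
    """Full binary tree: each cell lives `cycle` frames then divides."""
    lin = Lineage()
    cell_of = {}
    generation_of = {}
    next_id = [1]
    next_cell = [0]

    def grow(t, gen, pred, x):
        cell = next_cell[0]
        next_cell[0] += 1
        generation_of[cell] = gen
        prev = pred
        for k in range(cycle):
            d = det(next_id[0], t + k, x + 0.01 * k)
            lin.add_detection(d)
            cell_of[d.id] = cell
            next_id[0] += 1
            if prev is not None:
                lin.add_link(prev, d.id)
            prev = d.id
        if gen < depth:
            span = 2.0 ** (depth - gen)
            grow(t + cycle, gen + 1, prev, x - span)
            grow(t + cycle, gen + 1, prev, x + span)

    grow(1, 0, None, 0.0)
    return lin, cell_of, generation_of


class TestDensity:
    def test_touching_nuclei(self):
        frame = [det(1, 1, 0.0, r=1.0), det(2, 1, 2.0, r=1.0)]
        assert density(frame[0], frame) == pytest.approx(1.0)

    def test_half_density(self):
        frame = [det(1, 1, 0.0, r=1.0), det(2, 1, 4.0, r=1.0)]
        assert density(frame[0], frame) == pytest.approx(0.5)

    def test_overlap_above_one(self):
        frame = [det(1, 1, 0.0, r=1.0), det(2, 1, 1.0, r=1.0)]
        assert density(frame[0], frame) == pytest.approx(2.0)

    def test_lone_cell(self):
        frame = [det(1, 1, 0.0)]
        assert density(frame[0], frame) is None


class TestInstantaneousAccuracy:
    def test_identical(self, chain_lineage):
        assert instantaneous_accuracy(chain_lineage, chain_lineage) == 1.0

    def test_one_wrong_link(self):
        truth, *_ = binary_tree_lineage(3)
        pred = truth.copy()
        # break one interior link
        links = sorted(pred.links())
        p, s = links[len(links) // 2]
        pred.remove_link(p, s)
        n = len(truth.detections)
        assert instantaneous_accuracy(pred, truth) == pytest.approx(1 - 1 / n)

    def test_k_perturbations_match_oracle(self):
        rng = np.random.default_rng(0)
        truth, *_ = binary_tree_lineage(3)
        pred = truth.copy()
        links = sorted(pred.links())
        k = 5
        removed = [links[i] for i in rng.choice(len(links), size=k, replace=False)]
        for p, s in removed:
            pred.remove_link(p, s)
        # oracle: recount per-cell backward-step errors directly
        errors = 0
        for i in truth.detections:
            tp = truth.predecessor(i)
            pp = pred.predecessor(i)
            if tp != pp:
                errors += 1
        got = instantaneous_accuracy(pred, truth)
        assert got == pytest.approx(1 - errors / len(truth.detections))
        assert errors == k


class TestCumulativeAccuracy:
    def test_perfect(self):
        truth, cell_of, gen_of = binary_tree_lineage(3)
        acc = cumulative_accuracy(truth, truth, cell_of, gen_of)
        assert all(v == 1.0 for v in acc.values())

    def test_early_error_propagates(self):
        truth, cell_of, gen_of = binary_tree_lineage(3)
        pred = truth.copy()
        # break the root cell's very first internal link: every cell below
        # inherits the error
        root_first = min(truth.detections)
        succ = truth.successors(root_first)[0]
        pred.remove_link(root_first, succ)
        acc = cumulative_accuracy(pred, truth, cell_of, gen_of)
        for gen, v in acc.items():
            if gen > 0:
                assert v == 0.0

    def test_subtree_share(self):
        truth, cell_of, gen_of = binary_tree_lineage(3)
        pred = truth.copy()
        # break the link into one generation-1 cell: half of every later
        # generation is wrong
        gen1_cells = [c for c, g in gen_of.items() if g == 1]
        target = min(d for d, c in cell_of.items() if c == gen1_cells[0])
        pred.remove_link(truth.predecessor(target), target)
        acc = cumulative_accuracy(pred, truth, cell_of, gen_of)
        assert acc[3] == pytest.approx(0.5)

    def test_cumulative_below_instantaneous(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=2, n_frames=40, cell_cycle_mean=12.0,
                        fn_rate=0.02, fp_rate=0.02, rng_seed=21)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        from lineagetrace.resolve import trace_lineage
        lin, _ = trace_lineage(observed, trained_model, tcfg)
        inst = instantaneous_accuracy(lin, embryo.true_lineage)
        cum = cumulative_accuracy(lin, embryo.true_lineage, embryo.cell_of,
                                  embryo.generation_of)
        assert min(cum.values()) <= inst + 1e-9

    def test_cross_module_consistency(self):
        """Random per-cell-frame link breaking reproduces the idealized
        cumulative-error simulation within Monte-Carlo error."""
        p = 0.02
        depth, cycle = 4, 4
        reps = 60
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(reps):
            truth, cell_of, gen_of = binary_tree_lineage(depth, cycle)
            pred = truth.copy()
            for pr, s in sorted(truth.links()):
                if rng.random() < p:
                    pred.remove_link(pr, s)
            acc = cumulative_accuracy(pred, truth, cell_of, gen_of)
            fracs.append(acc[depth])
        got = float(np.mean(fracs))
        n_frames = cycle * (depth + 1)
        ref = simulate_cumulative_accuracy(p, n_frames, cycle, n_reps=3000, seed=9)
        # a leaf history has cycle*(depth+1)-1 links vs n_frames error draws;
        # compare loosely at 3 sigma of the MC spread
        se = float(np.std(fracs) / np.sqrt(len(fracs)))
        assert abs(got - ref[-1]) <= 3 * se + 0.05


class TestDivisionScores:
    def test_perfect(self, division_lineage):
        ppv, sens, tp, n_pred, n_true = division_scores(division_lineage,
                                                        division_lineage)
        assert (ppv, sens, tp, n_pred, n_true) == (1.0, 1.0, 1, 1, 1)

    def test_arithmetic(self):
        # 10 real divisions; predictions find 9 and add 1 spurious
        truth = Lineage()
        pred = Lineage()
        nid = 1
        for k in range(10):
            x = 10.0 * k
            p, a, b = nid, nid + 1, nid + 2
            nid += 3
            for lin in (truth, pred):
                lin.add_detection(det(p, 1, x))
                lin.add_detection(det(a, 2, x - 1))
                lin.add_detection(det(b, 2, x + 1))
            truth.add_link(p, a)
            truth.add_link(p, b)
            if k < 9:
                pred.add_link(p, a)
                pred.add_link(p, b)
            else:
                pred.add_link(p, a)  # miss one child
        # spurious division: extra parent with two children
        extra_p, extra_a, extra_b = nid, nid + 1, nid + 2
        for lin in (truth, pred):
            lin.add_detection(det(extra_p, 1, 500.0))
            lin.add_detection(det(extra_a, 2, 499.0))
            lin.add_detection(det(extra_b, 2, 501.0))
        truth.add_link(extra_p, extra_a)   # truth: plain 1:1
        pred.add_link(extra_p, extra_a)
        pred.add_link(extra_p, extra_b)    # prediction invents a division
        ppv, sens, tp, n_pred, n_true = division_scores(pred, truth)
        assert tp == 9 and n_pred == 10 and n_true == 10
        assert ppv == pytest.approx(0.9)
        assert sens == pytest.approx(0.9)

    def test_scores_match_trace_log(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=2, n_frames=30, cell_cycle_mean=10.0,
                        cell_cycle_sd=1.0, rng_seed=17)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        from lineagetrace.resolve import trace_lineage
        lin, report = trace_lineage(observed, trained_model, tcfg)
        ppv, sens, tp, n_pred, n_true = division_scores(lin, embryo.true_lineage)
        # structural division count in the result equals the audit count
        n_structural = sum(1 for i in lin.detections
                           if not lin.is_deleted(i) and len(lin.successors(i)) == 2)
        assert n_pred == n_structural


class TestReports:
    def test_confusion_matrix_shape_and_rows(self):
        pairs = [("division", "division")] * 3 + [("fp", "other")] * 2 + \
                [("two_cell", "two_cell")]
        m = confusion_matrix(pairs)
        assert m.shape == (4, 4)
        assert m.sum() == 6
        assert m[0, 0] == 3 and m[2, 3] == 2

    def test_density_bins_partition_errors(self, trained_model, tcfg):
        cfg = SimConfig(n_start_cells=3, n_frames=30, cell_cycle_mean=12.0,
                        fn_rate=0.03, rng_seed=23)
        embryo = generate_embryo(cfg)
        observed, _ = inject_errors(embryo, cfg)
        from lineagetrace.resolve import trace_lineage
        lin, _ = trace_lineage(observed, trained_model, tcfg)
        report = evaluate_lineages(lin, embryo.true_lineage, embryo.cell_of,
                                   embryo.generation_of)
        binned = sum(n for _, _, n in report.density_bins)
        # FP errors have no true-detection density; compare against
        # true-side errors only
        true_side_errors = report.n_errors - report.error_counts["undeleted_fp"]
        assert binned <= true_side_errors
        assert binned >= 0

    def test_report_fractions_in_range(self, trained_model, tcfg, clean_embryo):
        from lineagetrace.resolve import trace_lineage
        lin, _ = trace_lineage(clean_embryo.observed, trained_model, tcfg)
        report = evaluate_lineages(lin, clean_embryo.true_lineage,
                                   clean_embryo.cell_of,
                                   clean_embryo.generation_of)
        assert 0.0 <= report.instantaneous_accuracy <= 1.0
        assert all(0.0 <= v <= 1.0 for v in report.cumulative_accuracy.values())
        d = report.to_dict()
        assert "division_ppv" in d
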