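# lineagetrace

Cell-lineage tracing from per-frame nuclear detections, built around a
layered greedy strategy:

1. **Conservative 1:1 linking** — detections in consecutive frames are
   linked only when the match is *safe* (forward displacement strictly
   below half the same-frame nearest-neighbor distance), *mutual*
   (each is the other's nearest neighbor) and *non-conflicting* (no third
   detection claims either endpoint).
2. **Tentative bifurcations** — every detection left without a backward
   link marks a local increase in cell count and is forced into a 1-to-2
   match with a nearby parent; together with a preceding terminating
   track this defines a semi-local neighborhood, whose endpoint pairing
   is chosen to minimize total displacement.
3. **Naive Bayes classification** — a 12-feature measurement vector over
   the neighborhood is scored against four classes: cell *division*, a
   pair of *two* non-dividing *cells* (large movement or a detection
   gap), a detection *false positive*, and *other*.
4. **Class-specific repair** — divisions are accepted; two-cell cases are
   dissolved into 1:1 chains with linear interpolation across detection
   gaps; FP branches are deleted; "other" children are retried against
   their next candidate parent and finally left as unexplained
   appearances.

A synthetic dividing-embryo simulator (bounded random-walk motion,
parametrized division signatures, independent FP/FN/jitter error
injection) and a full evaluation module (instantaneous and per-generation
cumulative accuracy, division PPV/sensitivity, density stratification,
confusion matrices) make every stage testable without microscopy data.

## Command line

One entry point with four subcommands:

```sh
# generate a synthetic embryo: detections + ground-truth lineage + error annotations
lineagetrace simulate --config config.json --out simdir --seed 7

# fit a classifier from labeled neighborhood feature vectors
lineagetrace train --neighborhoods features.csv --labels labels.txt --out model.json

# trace a lineage from a voxel-unit detection table (t,x,y,z,radius,intensity[,eccentricity])
lineagetrace trace --detections detections.csv --config config.json \
    --model model.json --out outdir

# score a predicted lineage CSV against a truth lineage CSV
lineagetrace evaluate --pred outdir/lineage.csv --truth simdir/truth_lineage.csv \
    --out report.json
```

The config file is JSON with optional `"tracking"` and `"simulation"`
sections (see `lineagetrace.model.TrackingConfig` and
`lineagetrace.simulate.SimConfig` for fields and defaults). Classifier
models are human-readable JSON: class priors plus per-class, per-feature
Gaussian means and standard deviations. Lineages are written as one CSV
row per detection with predecessor/successor ids and a status flag
(`tracked`, `unexplained_appearance`, `deleted`, `interpolated`);
`lineagetrace.io_formats.export_newick` renders a lineage tree as Newick
with branch lengths in frames. A read-only loader for AceTree-style
zipped per-timepoint `nuclei` files is included.

## Python API sketch

```python
from lineagetrace import classify, evaluate, resolve, simulate
from lineagetrace.model import TrackingConfig

feats, labels = simulate.make_training_set(500, seed=1)
model = classify.fit(feats, labels)

cfg = simulate.SimConfig(n_start_cells=1, n_frames=120,
                         cell_cycle_mean=20, fn_rate=0.01, rng_seed=7)
embryo = simulate.generate_embryo(cfg)
observed, annotations = simulate.inject_errors(embryo, cfg)

lineage, report = resolve.trace_lineage(observed, model, TrackingConfig())
scores = evaluate.evaluate_lineages(lineage, embryo.true_lineage,
                                    embryo.cell_of, embryo.generation_of)
print(scores.instantaneous_accuracy, scores.division_ppv)
```

## Acceptance

Property-based acceptance criteria (oracle equivalence of the linker,
clean-embryo exactness, the 99% motion regime, ≥90% FN repair with exact
midpoint interpolation, ≥90% FP deletion with ≤1% collateral deletions,
Naive Bayes correctness against closed forms, the cumulative-error Monte
Carlo simulation, minimal-displacement pairing optimality, and bitwise
determinism) live in `tests/test_acceptance.py`.

`scripts/acceptance.py --seed <int> --out <path>` runs an end-to-end
smoke of the pipeline and writes the (empty) numeric-target report; there
are no recomputable published numbers because the original quantitative
results were measured on microscopy datasets that are not distributed.
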