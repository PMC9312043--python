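#!/usr/bin/env python
"""Extract per-subtype important features from the pointwise linear model.

Trains the tuned model on the full complete-case cohort (variant b), computes
sample-wise importance scores s_k(n) = |w_k(n) x_k(n)| per subtype, keeps
features present in the top 10% of at least 30% of cases, attaches median
tailored weights, and groups features into the autonomic (A), parkinsonism
(P) and cerebellar (C) components. Writes results/importance_<subtype>.csv
and results/components.json.
"""

import json
from pathlib import Path

from msadx.encoding import build_codebook, encode_cohort, fit_normalization
from msadx.importance import (assign_components, feature_importance,
                              important_features)
from msadx.pwl import PWLConfig, forward, train
from msadx.registry import SUBTYPES, Cohort, exclude_incomplete

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cohort = Cohort.read_csv(RESULTS / "cohort.csv")
    kept, _ = exclude_incomplete(cohort)
    cb = build_codebook("b")
    matrix = encode_cohort(kept, cb, fit_normalization(kept, cb))
    params = train(matrix, PWLConfig(seed=SEED))
    pred = forward(params, matrix.values)
    groupings = {}
    for c, sub in enumerate(SUBTYPES):
        imp = feature_importance(pred.weights[:, c, :], matrix.values, cb)
        top = assign_components(important_features(imp, 0.30), cb)
        top.to_csv(RESULTS / f"importance_{sub}.csv", index=False)
        groupings[sub] = top[["feature", "component", "sign"]].to_dict("records")
        print(f"\n{sub}: {len(top)} features with score >= 0.30")
        print(top[["rank", "feature", "score", "median_weight",
                   "component", "sign"]].head(10).to_string(index=False))
    (RESULTS / "components.json").write_text(json.dumps(groupings, indent=2))


if __name__ == "__main__":
    main()
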