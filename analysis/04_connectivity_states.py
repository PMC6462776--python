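#!/usr/bin/env python
"""Connectivity-state analysis: L1 k-means over all subject-windows,
elbow-based k selection (k = 2..8), per-subject dynamics metrics, and
recovery of the generator's ground-truth states.

Reads results/dfc/ (z windows) and results/cohort/ground_truth.json,
writes state assignments, metrics, the validity curve and a stability
report under results/states/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dynstates import dfc, states
from dynstates import io as dio
from dynstates.experiments import match_accuracy
from dynstates.synthgen import window_state_labels

IN = Path("results/dfc")
TRUTH = Path("results/cohort/ground_truth.json")
OUT = Path("results/states")


def main(seed: int = 0) -> None:
    manifest = dio.read_manifest(IN / "manifest.csv")
    sids = list(manifest["subject_id"])
    z = np.stack([
        pd.read_csv(IN / f"{sid}_z.tsv", sep="\t").to_numpy() for sid in sids
    ])
    n_sub, n_win, n_pairs = z.shape
    X = z.reshape(-1, n_pairs)
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    k_star, curve, has_elbow = states.select_k(X, range(2, 9), n_init=10,
                                               seed=int(rng.integers(2**31 - 1)))
    curve.to_csv(OUT / "validity_curve.csv", index=False)
    print(f"elbow-selected k = {k_star} (elbow found: {has_elbow})")
    print(curve.to_string(index=False))

    model = states.kmeans_l1(X, k_star, n_init=50, seed=int(rng.integers(2**31 - 1)))
    model, _ = states.relabel_by_frequency(model)
    assignments = {sid: model.assignments[i * n_win:(i + 1) * n_win] + 1
                   for i, sid in enumerate(sids)}
    per_state, per_subj = states.state_metrics(assignments,
                                               states=list(range(1, k_star + 1)))
    groups = dict(zip(manifest["subject_id"], manifest["group"]))
    per_state["group"] = per_state["subject_id"].map(groups)
    per_state.to_csv(OUT / "state_metrics.csv", index=False)
    per_subj.to_csv(OUT / "subject_metrics.csv", index=False)

    print("\nmean state frequency by group:")
    print(per_state.pivot_table(index="group", columns="state",
                                values="frequency").round(3).to_string())

    if TRUTH.exists():
        truth = json.loads(TRUTH.read_text())
        taper = dfc.make_taper()
        true = np.concatenate([
            window_state_labels(np.array(truth[sid]["states"]), taper.weights)
            for sid in sids
        ])
        est = np.concatenate([assignments[sid] for sid in sids])
        if k_star == 3:
            acc, _ = match_accuracy(true, est, 3)
            print(f"\nwindow-label recovery vs ground truth: {acc:.3f}")

    stab = states.stability_analysis(X, np.repeat(sids, n_win), k_star,
                                     scheme="split_half", n_replicates=10,
                                     n_init=10, seed=int(rng.integers(2**31 - 1)))
    np.savetxt(OUT / "split_half_similarities.tsv", stab.similarities,
               delimiter="\t", fmt="%.4f")
    print(f"\nsplit-half median centroid similarity per state: "
          f"{np.round(stab.median_similarity, 3)}")


if __name__ == "__main__":
    main()
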