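# locrec

Ranked multi-label prediction of protein subcellular localization from a
bipartite annotation network and protein–protein interaction scores.

Many proteins reside in several compartments at once (a protein shuttling
between nucleus and cytoplasm, say), so a useful predictor must return a
*ranked list* of locations, not a single class. `locrec` treats the problem
as a recommender system: training proteins are "users", subcellular
locations are "items", and a new protein is recommended locations through
the proteins it interacts with — interacting proteins tend to share
compartments, which also solves the cold-start problem of a query with no
annotations of its own.

## The method

Let `A` be the n×m binary incidence of the bipartite graph linking n
annotated proteins to m locations, with vertex degrees `d(p_t)` and
`d(l_j)`. A two-step resource-allocation walk (location → protein →
location, equal splits) defines the location-to-location transfer matrix

    w_ij = (1 / d(l_j)) · Σ_t a_ti · a_tj / d(p_t)

whose columns each sum to 1. The per-protein recommendation matrix is
`R = A · Wᵀ`; row k redistributes protein k's annotation profile `f(p_k)`
over locations and conserves mass (it sums to `d(p_k)`). A query protein p
with interaction scores `S(p) = [s_pp1, …, s_ppn]` against the training
proteins (from a STRING-style table, or normalized Smith–Waterman sequence
similarity when interaction data are too sparse) is scored by

    Pred(p) = S(p) · R,

normalized by its maximum, sorted, and cut at a reliability threshold τ
(default 0.30): every location whose normalized score reaches τ is
reported, in rank order.

The package also implements the full multi-label evaluation suite used in
this problem area — Precision/Recall/F, the rank-aware OrderedPrecision
with the Δ(t, k) normalizer, per-location F1 and its macro average, mean
Jaccard accuracy ACC′, exact-match rate ATR, absolute false rate AFR, and
label-wise ACC — plus jackknife (leave-one-out) and repeated k-fold
harnesses that rebuild the model on every training split, and a synthetic
data generator whose pair scores increase with label-set overlap
(`clip(α·Jaccard + N(0, σ), 0, 1)`).

## Worked example

```python
>>> import numpy as np
>>> from locrec import NetworkRecommender
>>> model = NetworkRecommender(tau=0.3).fit([("p1", {"l1"}), ("p2", {"l1", "l2"})])
>>> model.transfer_matrix_.weights
array([[0.75, 0.5 ],
       [0.25, 0.5 ]])
>>> model.recommender_matrix_.scores
array([[0.75, 0.25],
       [1.25, 0.75]])
>>> [pred] = model.predict([[0.5, 1.0]], query_ids=["q"])
>>> pred.entries
(('l1', 1.625, 1.0), ('l2', 0.875, 0.5384615384615384))
```

The query interacts weakly (0.5) with p1 and strongly (1.0) with p2, so its
raw scores are `S·R = (1.625, 0.875)`; dividing by the top score gives
normalized reliabilities (1.0, 0.538), and both locations clear τ = 0.3
(at τ = 0.6 only `l1` would be reported). An all-zero interaction vector
yields an empty prediction flagged `cold_start` rather than a guess.

The same pipeline is scriptable from the shell:

```sh
locrec simulate --n 150 --m 9 --seed 1 --out-dir data/
locrec jackknife --annotations data/annotations.tsv --pairs data/pair_scores.tsv \
    --tau 0.3 --out jk.json
# -> jackknife |D|=150: Recall=0.907 Precision=0.754 F=0.823 cold_start=0
locrec predict --annotations data/annotations.tsv --pairs data/pair_scores.tsv \
    --query Q1 --out predictions.tsv
locrec metrics --truth truth.tsv --predictions predictions.tsv --out metrics.json
```

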