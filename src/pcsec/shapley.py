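"""Exact interventional Shapley attributions for decision-tree ensembles.

For a tree ``f``, foreground sample ``x`` and background sample ``z``, the
coalition game is v(S) = f(composite) where the composite takes feature
values from ``x`` on S and from ``z`` elsewhere.  For each leaf, the path
features split into A (only ``x`` satisfies every condition on the feature),
B (only ``z`` does), C (both) and D (neither; the leaf is unreachable).  The
leaf's exact Shapley contribution has the closed form

    phi_i += value * |A-1|! |B|! / (|A|+|B|)!      for i in A
    phi_i -= value * |A|! |B-1|! / (|A|+|B|)!      for i in B

independent of the total number of features (features off the path cancel).
Summing over leaves and averaging over a background set gives attributions
that satisfy additivity exactly: sum_i phi_i(x) = f(x) - mean_z f(z).
"""

from __future__ import annotations

from math import factorial

import numpy as np


def _leaf_paths(tree) -> list[tuple[float, dict[int, list[tuple[float, bool]]]]]:
    """[(leaf value, {feature: [(threshold, is_left), ...]}), ...]"""
    t = tree.tree_
    out = []

    def walk(node: int, conds: list[tuple[int, float, bool]]):
        if t.children_left[node] == -1:
            path: dict[int, list[tuple[float, bool]]] = {}
            for f, thr, left in conds:
                path.setdefault(f, []).append((thr, left))
            out.append((float(t.value[node][0][0]), path))
            return
        f = int(t.feature[node])
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [(f, thr, True)])
        walk(t.children_right[node], conds + [(f, thr, False)])

    walk(0, [])
    return out


def _passes(v: float, conds: list[tuple[float, bool]]) -> bool:
    return all((v <= thr) if left else (v > thr) for thr, left in conds)


def _w(a: int, b: int) -> float:
    return factorial(a) * factorial(b) / factorial(a + b + 1)


def tree_shapley(tree, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Interventional Shapley values for one fitted sklearn regression tree.

    Returns an (n_samples, n_features) array; row sums equal
    f(x) - mean_z f(z) exactly.
    """
    # sklearn evaluates trees on float32 inputs; match it so threshold
    # comparisons are bit-identical with predict()
    X = np.asarray(X, np.float32).astype(float)
    Z = np.asarray(background, np.float32).astype(float)
    leaves = _leaf_paths(tree)
    phi = np.zeros((X.shape[0], X.shape[1]))
    nz = Z.shape[0]
    for value, path in leaves:
        feats = list(path)
        for i, x in enumerate(X):
            px = {f: _passes(x[f], path[f]) for f in feats}
            for z in Z:
                A = [f for f in feats if px[f] and not _passes(z[f], path[f])]
                nB = 0
                dead = False
                for f in feats:
                    pz = _passes(z[f], path[f])
                    if not px[f] and not pz:
                        dead = True
                        break
                    if pz and not px[f]:
                        nB += 1
                if dead:
                    continue
                nA = len(A)
                if nA:
                    wa = value * _w(nA - 1, nB) / nz
                    for f in A:
                        phi[i, f] += wa
                if nB:
                    wb = value * _w(nA, nB - 1) / nz
                    for f in feats:
                        if not px[f] and _passes(z[f], path[f]):
                            phi[i, f] -= wb
    return phi


def forest_shapley(forest, X: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions for a RandomForestRegressor (mean over trees) and the
    background baseline; ``baseline + phi.sum(1) == forest.predict(X)``."""
    X = np.asarray(X, float)
    Z = np.asarray(background, float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for est in forest.estimators_:
        phi += tree_shapley(est, X, Z)
    phi /= len(forest.estimators_)
    baseline = float(np.mean([est.predict(Z).mean() for est in forest.estimators_]))
    return phi, baseline
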