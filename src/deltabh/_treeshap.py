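"""Exact path-dependent TreeSHAP over XGBoost tree dumps, in float64.

Gradient-boosted-tree predictions and their Shapley decompositions are
evaluated here by walking the parsed tree structures directly, entirely in
double precision, so that per-record attributions sum to the prediction
minus the expected model output to machine precision.  The recursion is the
standard polynomial-time TreeSHAP with node-cover weighting.
"""

from __future__ import annotations

import json

import numpy as np
from numba import njit


def parse_booster(booster) -> tuple[np.ndarray, ...]:
    """Flatten an XGBoost booster into arrays (one block of nodes per tree).

    Returns (left, right, feature, threshold, value, cover, tree_offsets,
    base_score). Leaves have feature == -1 and their value in ``value``.
    """
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    base_score = float(
        json.loads(booster.save_config())["learner"]["learner_model_param"][
            "base_score"
        ]
    )
    left, right, feat, thr, val, cov = [], [], [], [], [], []
    offsets = [0]
    for dump in dumps:
        nodes: dict[int, dict] = {}

        def collect(node: dict) -> None:
            nodes[node["nodeid"]] = node
            for child in node.get("children", []):
                collect(child)

        collect(json.loads(dump))
        ids = sorted(nodes)
        index = {nid: i for i, nid in enumerate(ids)}
        off = offsets[-1]
        for nid in ids:
            node = nodes[nid]
            if "leaf" in node:
                left.append(-1)
                right.append(-1)
                feat.append(-1)
                thr.append(0.0)
                val.append(float(node["leaf"]))
            else:
                left.append(off + index[node["yes"]])
                right.append(off + index[node["no"]])
                feat.append(int(node["split"].lstrip("f")))
                thr.append(float(node["split_condition"]))
                val.append(0.0)
            cov.append(float(node["cover"]))
        offsets.append(off + len(ids))
    return (
        np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64),
        np.array(feat, dtype=np.int64),
        np.array(thr, dtype=np.float64),
        np.array(val, dtype=np.float64),
        np.array(cov, dtype=np.float64),
        np.array(offsets, dtype=np.int64),
        base_score,
    )


@njit(cache=True)
def _predict_trees(x, left, right, feat, thr, val, offsets):  # pragma: no cover
    n = x.shape[0]
    out = np.zeros(n)
    n_trees = offsets.shape[0] - 1
    for t in range(n_trees):
        root = offsets[t]
        for s in range(n):
            node = root
            while feat[node] >= 0:
                if x[s, feat[node]] < thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[s] += val[node]
    return out


@njit(cache=True)
def _tree_expected(left, right, feat, val, cov, root):  # pragma: no cover
    """Cover-weighted expectation of one tree (iterative stack walk)."""
    stack = np.empty((64, 2))
    stack[0, 0] = root
    stack[0, 1] = 1.0
    top = 1
    total = 0.0
    while top > 0:
        top -= 1
        node = int(stack[top, 0])
        w = stack[top, 1]
        if feat[node] < 0:
            total += w * val[node]
        else:
            l, r = left[node], right[node]
            stack[top, 0] = l
            stack[top, 1] = w * cov[l] / cov[node]
            stack[top + 1, 0] = r
            stack[top + 1, 1] = w * cov[r] / cov[node]
            top += 2
    return total


@njit(cache=True)
def _extend(m_feat, m_zero, m_one, m_w, length, p_zero, p_one, p_feat):  # pragma: no cover
    m_feat[length] = p_feat
    m_zero[length] = p_zero
    m_one[length] = p_one
    m_w[length] = 1.0 if length == 0 else 0.0
    for i in range(length - 1, -1, -1):
        m_w[i + 1] += p_one * m_w[i] * (i + 1.0) / (length + 1.0)
        m_w[i] = p_zero * m_w[i] * (length - i) / (length + 1.0)


@njit(cache=True)
def _unwound_sum(m_zero, m_one, m_w, length, i):  # pragma: no cover
    one = m_one[i]
    zero = m_zero[i]
    total = 0.0
    nxt = m_w[length]
    for j in range(length - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (length + 1.0) / ((j + 1.0) * one)
            total += tmp
            nxt = m_w[j] - tmp * zero * (length - j) / (length + 1.0)
        else:
            total += m_w[j] * (length + 1.0) / (zero * (length - j))
    return total


@njit(cache=True)
def _unwind(m_feat, m_zero, m_one, m_w, length, i):  # pragma: no cover
    one = m_one[i]
    zero = m_zero[i]
    nxt = m_w[length]
    for j in range(length - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (length + 1.0) / ((j + 1.0) * one)
            nxt = m_w[j] - tmp * zero * (length - j) / (length + 1.0)
            m_w[j] = tmp
        else:
            m_w[j] = m_w[j] * (length + 1.0) / (zero * (length - j))
    for j in range(i, length):
        m_feat[j] = m_feat[j + 1]
        m_zero[j] = m_zero[j + 1]
        m_one[j] = m_one[j + 1]


@njit(cache=True)
def _shap_one(x, phi, left, right, feat, thr, val, cov, root, pathlen):  # pragma: no cover
    """TreeSHAP for one sample and one tree, explicit DFS stack (no recursion)."""
    max_stack = 2 * pathlen + 2
    s_node = np.empty(max_stack, dtype=np.int64)
    s_len = np.empty(max_stack, dtype=np.int64)
    s_pz = np.empty(max_stack)
    s_po = np.empty(max_stack)
    s_pf = np.empty(max_stack, dtype=np.int64)
    s_mf = np.empty((max_stack, pathlen), dtype=np.int64)
    s_mz = np.empty((max_stack, pathlen))
    s_mo = np.empty((max_stack, pathlen))
    s_mw = np.empty((max_stack, pathlen))

    mf = np.empty(pathlen, dtype=np.int64)
    mz = np.empty(pathlen)
    mo = np.empty(pathlen)
    mw = np.empty(pathlen)

    top = 0
    s_node[top] = root
    s_len[top] = 0
    s_pz[top] = 1.0
    s_po[top] = 1.0
    s_pf[top] = -1
    top = 1
    while top > 0:
        top -= 1
        node = s_node[top]
        length = s_len[top]
        p_zero = s_pz[top]
        p_one = s_po[top]
        p_feat = s_pf[top]
        for i in range(length):
            mf[i] = s_mf[top, i]
            mz[i] = s_mz[top, i]
            mo[i] = s_mo[top, i]
            mw[i] = s_mw[top, i]
        _extend(mf, mz, mo, mw, length, p_zero, p_one, p_feat)
        length += 1

        if feat[node] < 0:  # leaf: credit every feature on the path
            for i in range(1, length):
                w = _unwound_sum(mz, mo, mw, length - 1, i)
                phi[mf[i]] += w * (mo[i] - mz[i]) * val[node]
            continue

        f = feat[node]
        if x[f] < thr[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, length):
            if mf[i] == f:
                k = i
                break
        if k >= 0:  # feature revisited: undo its previous path entry
            iz = mz[k]
            io = mo[k]
            _unwind(mf, mz, mo, mw, length - 1, k)
            length -= 1

        for child, czero, cone in (
            (hot, iz * cov[hot] / cov[node], io),
            (cold, iz * cov[cold] / cov[node], 0.0),
        ):
            s_node[top] = child
            s_len[top] = length
            s_pz[top] = czero
            s_po[top] = cone
            s_pf[top] = f
            for i in range(length):
                s_mf[top, i] = mf[i]
                s_mz[top, i] = mz[i]
                s_mo[top, i] = mo[i]
                s_mw[top, i] = mw[i]
            top += 1
    return phi


@njit(cache=True)
def _shap_values(x, n_features, left, right, feat, thr, val, cov, offsets, max_depth):  # pragma: no cover
    n = x.shape[0]
    phi = np.zeros((n, n_features))
    n_trees = offsets.shape[0] - 1
    pathlen = max_depth + 2
    for t in range(n_trees):
        root = offsets[t]
        for s in range(n):
            _shap_one(x[s], phi[s], left, right, feat, thr, val, cov, root, pathlen)
    return phi


class TreeExplainer:
    """Float64 predictions and exact Shapley attributions for a booster."""

    def __init__(self, booster):
        (
            self.left,
            self.right,
            self.feat,
            self.thr,
            self.val,
            self.cov,
            self.offsets,
            self.base_score,
        ) = parse_booster(booster)
        self.max_depth = self._measure_depth()
        self.expected_value = self.base_score + sum(
            _tree_expected(self.left, self.right, self.feat, self.val, self.cov, off)
            for off in self.offsets[:-1]
        )

    def _measure_depth(self) -> int:
        depth = np.zeros(len(self.left), dtype=int)
        for node in range(len(self.left)):
            if self.feat[node] >= 0:
                depth[self.left[node]] = depth[node] + 1
                depth[self.right[node]] = depth[node] + 1
        return int(depth.max()) if len(depth) else 0

    @staticmethod
    def _as_f32_grid(x: np.ndarray) -> np.ndarray:
        # route samples through splits exactly as xgboost does (f32 data)
        return np.asarray(x, dtype=np.float32).astype(np.float64)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = self._as_f32_grid(np.atleast_2d(x))
        return self.base_score + _predict_trees(
            x, self.left, self.right, self.feat, self.thr, self.val, self.offsets
        )

    def shap_values(self, x: np.ndarray, n_features: int) -> np.ndarray:
        x = self._as_f32_grid(np.atleast_2d(x))
        return _shap_values(
            x, n_features, self.left, self.right, self.feat, self.thr,
            self.val, self.cov, self.offsets, self.max_depth,
        )
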