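"""Independent brute-force oracles used only by the test suite.

Each oracle re-evaluates the rules literally, with loops over plain Python
structures, and shares no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- cleaning

def brute_force_clean(records, detection_limit, min_beads, group_of):
    """Literal re-implementation of the replicate-QC pipeline.

    ``records`` is a list of dicts with keys sample_id, analyte, replicate,
    concentration, bead_count.  ``group_of`` maps sample_id -> group label.
    Returns ``{(sample_id, analyte): mean or None}`` over retained analytes,
    plus the counts of low-bead and discordant removals.
    """
    # censoring (NaN = below-detection flag)
    cens = []
    for r in records:
        c = r["concentration"]
        c = 0.0 if (c is None or (isinstance(c, float) and math.isnan(c)) or c < detection_limit) else c
        cens.append({**r, "concentration": c})

    # bead filter
    n_low = sum(1 for r in cens if r["bead_count"] < min_beads)
    kept = [r for r in cens if r["bead_count"] >= min_beads]

    # group per cell
    cells = {}
    for r in kept:
        cells.setdefault((r["sample_id"], r["analyte"]), []).append(r["concentration"])

    n_disc = 0
    means = {}
    for key, vals in cells.items():
        if len(vals) == 3:
            removed = None
            for i in range(3):
                j, k = [m for m in range(3) if m != i]
                if min(abs(vals[i] - vals[j]), abs(vals[i] - vals[k])) > 2 * abs(vals[j] - vals[k]):
                    removed = i
            if removed is not None:
                vals = [v for m, v in enumerate(vals) if m != removed]
                n_disc += 1
        means[key] = sum(vals) / len(vals)

    samples = sorted({s for s, _ in means}, key=str)
    analytes = sorted({a for _, a in means}, key=str)

    # drop samples with no surviving cell, analytes with no surviving cell
    samples = [s for s in samples if any((s, a) in means for a in analytes)]
    analytes = [a for a in analytes if any((s, a) in means for s in samples)]

    # sparse-analyte rule: overall zero fraction > 0.5 and > 0.5 in every group
    retained_analytes = []
    for a in analytes:
        obs = [(s, means[(s, a)]) for s in samples if (s, a) in means]
        frac = sum(1 for _, v in obs if v == 0) / len(obs)
        if frac > 0.5:
            groups = {}
            for s, v in obs:
                groups.setdefault(group_of[s], []).append(v)
            if all(
                sum(1 for v in vs if v == 0) / len(vs) > 0.5 for vs in groups.values()
            ):
                continue
        retained_analytes.append(a)

    out = {}
    for s in samples:
        for a in retained_analytes:
            out[(s, a)] = means.get((s, a))
    return out, n_low, n_disc, retained_analytes


# ---------------------------------------------------------------- PLS

def svd_pls_coefficients(Z, y, A):
    """PLS1 coefficients via SVD of the cross-covariance, independent route.

    Each component's weight vector is the leading left singular vector of
    the deflated cross-covariance Z'y; the final coefficient vector is
    recovered as the minimum-norm solution mapping Z to the accumulated
    fitted values (the PLS coefficients lie in the row space of Z, where
    that solution is unique).
    """
    Z = np.array(Z, dtype=float)
    y = np.array(y, dtype=float)
    Za, ya = Z.copy(), y.copy()
    yhat = np.zeros_like(y)
    for _ in range(A):
        c = (Za.T @ ya)[:, None]  # p x 1 cross-covariance
        u, _, _ = np.linalg.svd(c, full_matrices=False)
        w = u[:, 0]
        t = Za @ w
        tt = t @ t
        p_load = Za.T @ t / tt
        q = (ya @ t) / tt
        yhat += q * t
        Za = Za - np.outer(t, p_load)
        ya = ya - q * t
    return np.linalg.pinv(Z) @ yhat


# ---------------------------------------------------------------- deposits

def brute_force_classify(image, threshold):
    """Literal per-pixel neighborhood evaluation: 0 background, 2 TRUE, 1 FALSE."""
    image = np.asarray(image)
    H, W = image.shape
    labels = np.empty((H, W), dtype=np.int8)
    for i in range(H):
        for j in range(W):
            if image[i, j] == 0:
                labels[i, j] = 0
                continue
            ok = image[i, j] > threshold
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W and not (image[ii, jj] > threshold):
                        ok = False
            labels[i, j] = 2 if ok else 1
    return labels


def brute_force_percent_true(image, threshold):
    labels = brute_force_classify(image, threshold)
    n_true = int((labels == 2).sum())
    n_false = int((labels == 1).sum())
    return 100.0 * n_true / (n_true + n_false)
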