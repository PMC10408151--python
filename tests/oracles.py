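"""Independent brute-force oracles used to validate the implementation.

Every function here is deliberately naive (enumeration, exhaustive sort,
quadratic DP) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, match: float, mismatch: float,
                      gap_open: float, gap_extend: float) -> float:
    """Best local alignment score with affine gaps (Gotoh recurrences).

    Gap of length k costs gap_open + (k - 1) * gap_extend, matching the
    open/extend convention where the opening score already includes the
    first gapped column.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), 0.0)   # best ending in a match/mismatch or fresh start
    X = np.full((n + 1, m + 1), NEG)   # gap in b (a advances)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (b advances)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0)
            M[i, j] = diag + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


def knn_impute_oracle(frame: np.ndarray, target_col: int, n_neighbors: int,
                      n_helpers: int) -> np.ndarray:
    """Exhaustive-sort weighted-KNN imputation of one column.

    frame: 2D array with NaN missing.  Reproduces, by direct enumeration:
    helper ranking by |Spearman| with the target, standardization over
    observed values, correlation weighting (target weight 1), nan-aware
    Euclidean distance with total/observed rescaling, stable sort, and
    uniform averaging of the nearest observed targets.
    """
    from scipy.stats import spearmanr

    n, d = frame.shape
    tgt = frame[:, target_col]
    observed = np.isfinite(tgt)

    # correlate over rows where both the helper and the target are observed
    def rho_full(col):
        mask = np.isfinite(col) & np.isfinite(tgt)
        if mask.sum() < 2:
            return 0.0
        x, y = col[mask], tgt[mask]
        if np.all(x == x[0]) or np.all(y == y[0]):
            return 0.0
        r = spearmanr(x, y).statistic
        return 0.0 if not np.isfinite(r) else float(r)

    cand = []
    for c in range(d):
        if c == target_col:
            continue
        obs = frame[:, c][np.isfinite(frame[:, c])]
        if obs.size == 0 or np.all(obs == obs[0]):
            continue  # zero-variance helper excluded outright
        cand.append(c)
    rhos = {c: rho_full(frame[:, c]) for c in cand}
    ranked = sorted(cand, key=lambda c: (-abs(rhos[c]), cand.index(c)))
    helpers = ranked[:n_helpers]

    dims = [target_col] + helpers
    weights = np.array([1.0] + [abs(rhos[c]) for c in helpers])
    mat = frame[:, dims].astype(float)
    means = np.array([np.nanmean(mat[:, j]) if np.isfinite(mat[:, j]).any() else 0.0
                      for j in range(mat.shape[1])])
    stds = []
    for j in range(mat.shape[1]):
        s = np.nanstd(mat[:, j]) if np.isfinite(mat[:, j]).any() else 0.0
        stds.append(s if s > 0 else 1.0)
    stds = np.array(stds)
    weighted = (mat - means) / stds * weights
    ref = weighted[observed]
    ref_targets = tgt[observed]

    out = tgt.copy()
    total = weighted.shape[1]
    for i in range(n):
        if np.isfinite(tgt[i]):
            continue
        dists = []
        for r in range(ref.shape[0]):
            both = np.isfinite(weighted[i]) & np.isfinite(ref[r])
            if not both.any():
                continue
            sq = ((weighted[i][both] - ref[r][both]) ** 2).sum()
            dists.append((np.sqrt(total / both.sum() * sq), r))
        if not dists:
            continue
        dists.sort(key=lambda t: (t[0], t[1]))
        take = [r for _, r in dists[:n_neighbors]]
        out[i] = ref_targets[take].mean()
    return out


def stitch_oracle(windows: list[tuple[int, int]], position: int) -> tuple[int, int]:
    """Brute-force choice of the covering window with center closest to position."""
    best = None
    for (s, e) in windows:
        if not s <= position <= e:
            continue
        key = (abs(position - (s + e) / 2.0), s)
        if best is None or key < best[0]:
            best = (key, (s, e))
    return best[1]


def conditioned_oracle(rows: list[str], query: str, position: int,
                       wt: str, mut: str, conditioning: list[int],
                       min_rows: int = 1) -> tuple[float, float]:
    """Hand-enumerated row filtering and frequency counting (log-offset)."""
    import math

    kept = []
    for r in rows:
        if all(r[c - 1] == query[c - 1] for c in conditioning):
            kept.append(r)
    if len(kept) < min_rows:
        return (math.nan, math.nan)
    n = len(kept)
    fw = sum(1 for r in kept if r[position - 1] == wt) / n
    fm = sum(1 for r in kept if r[position - 1] == mut) / n
    return (math.log1p(fw), math.log1p(fm))


def auroc_oracle(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive pair counting with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def spec_at_sens_oracle(labels: np.ndarray, scores: np.ndarray, s: float) -> float:
    """Scan every candidate threshold; keep the most stringent feasible one."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t = None
    for t in sorted(set(scores.tolist())):
        sens = (pos >= t).mean()
        if sens >= s and (best_t is None or t > best_t):
            best_t = t
    if best_t is None:
        return float("nan")
    return float((neg < best_t).mean())


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1
            i = j
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
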