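"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here is written as a direct transcription of the relevant
definition (exhaustive scans, explicit loops, BFS), deliberately sharing no
code with the package implementations it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def otsu_brute_force(grey: np.ndarray) -> int:
    """Scan all 256 candidate thresholds, maximizing between-class variance."""
    values = np.clip(np.floor(np.asarray(grey, dtype=float)), 0, 255).ravel()
    n = values.size
    best_t, best_var = None, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def fill_holes_bfs(mask: np.ndarray) -> np.ndarray:
    """Flood-fill background from the border (4-connectivity); the rest is hole."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    reach = np.zeros_like(mask)
    q: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                q.append((rr, cc))
    return mask | ~reach


def center_of_mass_sums(mask: np.ndarray) -> tuple[float, float]:
    rs, cs, n = 0.0, 0.0, 0
    mask = np.asarray(mask, dtype=bool)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                rs += r
                cs += c
                n += 1
    return rs / n, cs / n


def largest_square_at(mask: np.ndarray) -> int:
    """Side of the largest all-true square anywhere in the mask (exhaustive)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    best = 0
    for s in range(1, min(h, w) + 1):
        found = False
        for r in range(h - s + 1):
            for c in range(w - s + 1):
                if mask[r : r + s, c : c + s].all():
                    found = True
                    break
            if found:
                break
        if found:
            best = s
        else:
            break
    return best


def kennard_stone_loops(x: np.ndarray, n_train: int) -> list[int]:
    """Plain-loop max-min selection on z-scored points."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    def dist2(a: int, b: int) -> float:
        return round(float(((z[a] - z[b]) ** 2).sum()), 12)

    best_pair, best_d = (0, 1), -1.0
    for i in range(n):
        for j in range(i + 1, n):
            d = dist2(i, j)
            if d > best_d:
                best_d, best_pair = d, (i, j)
    chosen = list(best_pair)
    while len(chosen) < n_train:
        best_k, best_min = None, -1.0
        for k in range(n):
            if k in chosen:
                continue
            m = min(dist2(k, c) for c in chosen)
            if m > best_min:
                best_min, best_k = m, k
        chosen.append(best_k)
    return sorted(chosen)


def glcm_loops(grey: np.ndarray) -> np.ndarray:
    """Symmetric normalized 256-level co-occurrence matrix, offset (0, +1)."""
    g = np.asarray(grey, dtype=int)
    m = np.zeros((256, 256), dtype=float)
    h, w = g.shape
    for r in range(h):
        for c in range(w - 1):
            i, j = g[r, c], g[r, c + 1]
            m[i, j] += 1
            m[j, i] += 1
    return m / m.sum()


def glcm_stats_loops(p: np.ndarray) -> dict[str, float]:
    """Entropy/inertia/energy/correlation/homogeneity by explicit double loop."""
    ent = ine = ene = hom = 0.0
    mu_i = mu_j = 0.0
    n = p.shape[0]
    for i in range(n):
        for j in range(n):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            if v > 0:
                ent -= v * np.log2(v)
            ine += (i - j) ** 2 * v
            ene += v * v
            hom += v / (1 + (i - j) ** 2)
            var_i += (i - mu_i) ** 2 * v
            var_j += (j - mu_j) ** 2 * v
            cov += (i - mu_i) * (j - mu_j) * v
    cor = 1.0 if var_i <= 0 or var_j <= 0 else cov / np.sqrt(var_i * var_j)
    return {
        "entropy": ent,
        "inertia": ine,
        "energy": ene,
        "correlation": cor,
        "homogeneity": hom,
    }


def dft2_loops(x: np.ndarray) -> np.ndarray:
    """O(n^4) 2-D discrete Fourier transform by explicit summation."""
    x = np.asarray(x, dtype=float)
    h, w = x.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            s = 0.0 + 0.0j
            for r in range(h):
                for c in range(w):
                    s += x[r, c] * np.exp(-2j * np.pi * (u * r / h + v * c / w))
            out[u, v] = s
    return out


def fft_stats_loops(x: np.ndarray) -> dict[str, float]:
    """Spectral-distribution statistics from the explicit DFT (DC excluded)."""
    x = np.asarray(x, dtype=float)
    f = dft2_loops(x - x.mean())
    h, w = f.shape
    power = np.abs(f) ** 2
    # centered coordinates equivalent to fftshift indexing
    ene = ent = ine = hom = 0.0
    total = 0.0
    for u in range(h):
        for v in range(w):
            if u == 0 and v == 0:
                continue
            total += power[u, v]
    if total <= 1e-12 * x.size:
        return {"energy": 0.0, "entropy": 0.0, "inertia": 0.0, "homogeneity": 0.0}
    for u in range(h):
        for v in range(w):
            if u == 0 and v == 0:
                continue
            p = power[u, v] / total
            du = u - h if u >= (h + 1) // 2 else u
            dv = v - w if v >= (w + 1) // 2 else v
            d2 = du * du + dv * dv
            ene += p * p
            if p > 0:
                ent -= p * np.log2(p)
            ine += d2 * p
            hom += p / (1 + d2)
    return {"energy": ene, "entropy": ent, "inertia": ine, "homogeneity": hom}


def shannon_entropy_loops(values: np.ndarray, bins: int = 256,
                          rng: tuple[float, float] = (0.0, 256.0)) -> float:
    counts = [0] * bins
    lo, hi = rng
    width = (hi - lo) / bins
    for v in np.asarray(values, dtype=float).ravel():
        k = min(int((v - lo) / width), bins - 1)
        counts[k] += 1
    n = sum(counts)
    ent = 0.0
    for c in counts:
        if c:
            p = c / n
            ent -= p * np.log2(p)
    return ent
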