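"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written with explicit Python loops over pixels, pairs,
runs, zones and neighborhoods, deliberately sharing no code with the
package. Slow but transparent; intended for tiny images only.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

_OFFSETS_8 = [(0, 1), (0, -1), (-1, 1), (1, -1), (-1, 0), (1, 0), (-1, -1), (1, 1)]


def glcm_matrix_bruteforce(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Count every ordered neighbor pair over the 8 unit offsets (i.e. the
    four directions, symmetric) and normalize."""
    h, w = img.shape
    P = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            for dr, dc in _OFFSETS_8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    P[img[r, c] - 1, img[rr, cc] - 1] += 1
    return P / P.sum()


def glcm_features_bruteforce(img: np.ndarray, n_levels: int) -> dict[str, float]:
    P = glcm_matrix_bruteforce(img, n_levels)
    L = n_levels
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(L))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    out: dict[str, float] = {}
    out["glcm_energy"] = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    out["glcm_entropy"] = -sum(
        P[i][j] * math.log2(P[i][j]) for i in range(L) for j in range(L) if P[i][j] > 0
    )
    out["glcm_dissimilarity"] = sum(abs(i - j) * P[i][j] for i in range(L) for j in range(L))
    out["glcm_contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    out["glcm_inverse_difference"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(L) for j in range(L)
    )
    out["glcm_homogeneity"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(L) for j in range(L)
    )
    out["glcm_cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * P[i][j] for i in range(L) for j in range(L)
    )
    out["glcm_cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * P[i][j] for i in range(L) for j in range(L)
    )
    out["glcm_max_probability"] = max(P[i][j] for i in range(L) for j in range(L))
    out["glcm_sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * P[i][j] for i in range(L) for j in range(L)
    )
    sum_avg = sum((k + 2) * p_sum[k] for k in range(2 * L - 1))
    out["glcm_sum_average"] = sum_avg
    out["glcm_sum_variance"] = sum(
        (k + 2 - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1)
    )
    out["glcm_sum_entropy"] = -sum(
        p_sum[k] * math.log2(p_sum[k]) for k in range(2 * L - 1) if p_sum[k] > 0
    )
    mu_d = sum(k * p_diff[k] for k in range(L))
    out["glcm_difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))
    out["glcm_difference_entropy"] = -sum(
        p_diff[k] * math.log2(p_diff[k]) for k in range(L) if p_diff[k] > 0
    )
    out["glcm_idn"] = sum(P[i][j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L))
    out["glcm_idmn"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / L**2) for i in range(L) for j in range(L)
    )
    if var_x <= 0 or var_y <= 0:
        corr = imc1 = imc2 = mcc = 0.0
    else:
        corr = (
            sum((i + 1) * (j + 1) * P[i][j] for i in range(L) for j in range(L))
            - mu_x * mu_y
        ) / math.sqrt(var_x * var_y)
        hxy = out["glcm_entropy"]
        hxy1 = -sum(
            P[i][j] * math.log2(px[i] * py[j])
            for i in range(L)
            for j in range(L)
            if px[i] * py[j] > 0
        )
        hxy2 = -sum(
            px[i] * py[j] * math.log2(px[i] * py[j])
            for i in range(L)
            for j in range(L)
            if px[i] * py[j] > 0
        )
        hx = -sum(v * math.log2(v) for v in px if v > 0)
        hy = -sum(v * math.log2(v) for v in py if v > 0)
        denom = max(hx, hy)
        imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
        imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
        keep = [i for i in range(L) if px[i] > 0]
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(
                    P[i][k] * P[j][k] / (px[i] * py[k]) for k in keep
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(max(0.0, eig[1])) if len(eig) > 1 else 0.0
    out["glcm_correlation"] = corr
    out["glcm_imc1"] = imc1
    out["glcm_imc2"] = imc2
    out["glcm_mcc"] = mcc
    out["glcm_mcc_repeat"] = mcc
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_in_line(line) -> list[tuple[int, int]]:
    runs = []
    i = 0
    line = list(line)
    while i < len(line):
        j = i
        while j < len(line) and line[j] == line[i]:
            j += 1
        runs.append((line[i], j - i))
        i = j
    return runs


def _lines_bruteforce(img: np.ndarray, direction: str) -> list[list[int]]:
    h, w = img.shape
    lines = []
    if direction == "horizontal":
        lines = [list(img[r, :]) for r in range(h)]
    elif direction == "vertical":
        lines = [list(img[:, c]) for c in range(w)]
    elif direction == "diagonal":
        for k in range(-h + 1, w):
            lines.append([img[r, r + k] for r in range(h) if 0 <= r + k < w])
    elif direction == "antidiagonal":
        for k in range(-h + 1, w):
            lines.append([img[r, w - 1 - (r + k)] for r in range(h) if 0 <= r + k < w])
    return [ln for ln in lines if ln]


def _rlm_descriptors_bruteforce(counts: dict[tuple[int, int], float], n_pixels: int) -> dict[str, float]:
    nr = sum(counts.values())
    mu_l = sum(i * v for (i, _), v in counts.items()) / nr
    mu_r = sum(l * v for (_, l), v in counts.items()) / nr
    return {
        "sre": sum(v / l**2 for (_, l), v in counts.items()) / nr,
        "lre": sum(v * l**2 for (_, l), v in counts.items()) / nr,
        "gln": sum(
            sum(v for (i, _), v in counts.items() if i == lvl) ** 2
            for lvl in {i for i, _ in counts}
        ) / nr,
        "rln": sum(
            sum(v for (_, l), v in counts.items() if l == ln) ** 2
            for ln in {l for _, l in counts}
        ) / nr,
        "rp": nr / n_pixels,
        "lglre": sum(v / i**2 for (i, _), v in counts.items()) / nr,
        "hglre": sum(v * i**2 for (i, _), v in counts.items()) / nr,
        "srlgle": sum(v / (i**2 * l**2) for (i, l), v in counts.items()) / nr,
        "srhgle": sum(v * i**2 / l**2 for (i, l), v in counts.items()) / nr,
        "lrlgle": sum(v * l**2 / i**2 for (i, l), v in counts.items()) / nr,
        "lrhgle": sum(v * i**2 * l**2 for (i, l), v in counts.items()) / nr,
        "glv": sum((i - mu_l) ** 2 * v for (i, _), v in counts.items()) / nr,
        "rlv": sum((l - mu_r) ** 2 * v for (_, l), v in counts.items()) / nr,
    }


def glrlm_features_bruteforce(img: np.ndarray, n_levels: int) -> dict[str, float]:
    acc: dict[str, float] = {}
    directions = ("horizontal", "vertical", "diagonal", "antidiagonal")
    for direction in directions:
        counts: dict[tuple[int, int], float] = {}
        for line in _lines_bruteforce(img, direction):
            for level, length in _runs_in_line(line):
                counts[(level, length)] = counts.get((level, length), 0.0) + 1.0
        desc = _rlm_descriptors_bruteforce(counts, img.size)
        for k, v in desc.items():
            acc[k] = acc.get(k, 0.0) + v / len(directions)
    return {f"glrlm_{k}": v for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_features_bruteforce(img: np.ndarray, n_levels: int) -> dict[str, float]:
    h, w = img.shape
    seen = np.zeros(img.shape, dtype=bool)
    counts: dict[tuple[int, int], float] = {}
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            level = img[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2] and img[r2, c2] == level:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            counts[(int(level), size)] = counts.get((int(level), size), 0.0) + 1.0
    desc = _rlm_descriptors_bruteforce(counts, img.size)
    rename = {
        "sre": "sze", "lre": "lze", "gln": "gln", "rln": "zsn", "rp": "zp",
        "lglre": "lglze", "hglre": "hglze", "srlgle": "szlgle",
        "srhgle": "szhgle", "lrlgle": "lzlgle", "lrhgle": "lzhgle",
        "glv": "glv", "rlv": "zsv",
    }
    return {f"glszm_{rename[k]}": v for k, v in desc.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features_bruteforce(img: np.ndarray, n_levels: int) -> dict[str, float]:
    h, w = img.shape
    n_total = img.size
    s = {lvl: 0.0 for lvl in range(1, n_levels + 1)}
    n_i = {lvl: 0 for lvl in range(1, n_levels + 1)}
    for r in range(h):
        for c in range(w):
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        nbrs.append(img[rr, cc])
            lvl = int(img[r, c])
            n_i[lvl] += 1
            s[lvl] += abs(lvl - sum(nbrs) / len(nbrs))
    p_i = {lvl: n / n_total for lvl, n in n_i.items()}
    present = [lvl for lvl in p_i if p_i[lvl] > 0]
    n_gp = len(present)
    ps = sum(p_i[l] * s[l] for l in present)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if n_gp > 1:
        contrast = (
            sum(p_i[a] * p_i[b] * (a - b) ** 2 for a in present for b in present)
            / (n_gp * (n_gp - 1))
            * sum(s.values())
            / n_total
        )
        denom_busy = sum(
            abs(a * p_i[a] - b * p_i[b]) for a in present for b in present
        )
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = sum(
            abs(a - b) * (p_i[a] * s[a] + p_i[b] * s[b]) / (p_i[a] + p_i[b])
            for a in present
            for b in present
        ) / n_total
        s_total = sum(s.values())
        strength = (
            sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in present for b in present) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------------------
# other oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels) -> float:
    """Mann-Whitney concordance probability with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def quadrature_envelope(signal: np.ndarray, f0: float, fs: float, taps: int = 65) -> np.ndarray:
    """Envelope via quadrature demodulation + boxcar lowpass (oracle)."""
    n = np.arange(signal.size)
    i = signal * np.cos(2 * np.pi * f0 * n / fs)
    q = signal * np.sin(2 * np.pi * f0 * n / fs)
    kernel = np.ones(taps) / taps
    i_lp = np.convolve(i, kernel, mode="same")
    q_lp = np.convolve(q, kernel, mode="same")
    return 2.0 * np.sqrt(i_lp**2 + q_lp**2)


def nakagami_samples(m: float, omega: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw Nakagami(m, omega) envelope samples: R^2 ~ Gamma(m, omega/m)."""
    return np.sqrt(rng.gamma(m, omega / m, size=n))
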