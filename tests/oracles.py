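"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: co-occurrence counting is
a literal loop over pixel pairs, and every texture metric is a literal
double sum over matrix cells.
"""

import math

import numpy as np

#: (row, col) pixel offsets of the standard 4-angle set at distance 1, in
#: the same convention as the implementation (0°, 45°, 90°, 135°).
OFFSETS_4 = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_bruteforce(q: np.ndarray, levels: int, offsets=OFFSETS_4) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by pair enumeration."""
    rows, cols = q.shape
    P = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    P[q[r, c], q[r2, c2]] += 1
                    P[q[r2, c2], q[r, c]] += 1
    total = P.sum()
    return P / total if total else P


def texture_metrics_bruteforce(P: np.ndarray) -> dict:
    """All eight texture metrics as literal double sums."""
    N = P.shape[0]
    mean = sum(i * P[i, j] for i in range(N) for j in range(N))
    var = sum((i - mean) ** 2 * P[i, j] for i in range(N) for j in range(N))
    hom = sum(P[i, j] / (1 + abs(i - j)) for i in range(N) for j in range(N))
    con = sum(abs(i - j) ** 2 * P[i, j] for i in range(N) for j in range(N))
    dis = sum(abs(i - j) * P[i, j] for i in range(N) for j in range(N))
    ent = -sum(
        P[i, j] * math.log2(P[i, j])
        for i in range(N)
        for j in range(N)
        if P[i, j] > 0
    )
    ene = sum(P[i, j] ** 2 for i in range(N) for j in range(N))
    px = [sum(P[i, j] for j in range(N)) for i in range(N)]
    py = [sum(P[i, j] for i in range(N)) for j in range(N)]
    xbar = sum(i * px[i] for i in range(N))
    ybar = sum(j * py[j] for j in range(N))
    sx = math.sqrt(sum((i - xbar) ** 2 * px[i] for i in range(N)))
    sy = math.sqrt(sum((j - ybar) ** 2 * py[j] for j in range(N)))
    if sx == 0 or sy == 0:
        cor = 0.0
    else:
        cor = sum(
            (i - xbar) * (j - ybar) * P[i, j] for i in range(N) for j in range(N)
        ) / (sx * sy)
    return {
        "MEAN": mean, "VAR": var, "HOM": hom, "CON": con,
        "DIS": dis, "ENT": ent, "ENE": ene, "COR": cor,
    }


def classification_metrics_bruteforce(counts: np.ndarray) -> dict:
    """OA, macro precision/recall/F1 and kappa by per-cell hand computation."""
    counts = counts.astype(float)
    total = counts.sum()
    K = counts.shape[0]
    oa = sum(counts[k, k] for k in range(K)) / total
    precisions, recalls, f1s = [], [], []
    for k in range(K):
        tp = counts[k, k]
        fp = counts[:, k].sum() - tp
        fn = counts[k, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    pe = sum(counts[k, :].sum() * counts[:, k].sum() for k in range(K)) / total**2
    kappa = (oa - pe) / (1 - pe) if pe != 1 else 0.0
    return {
        "OA": oa,
        "precision": sum(precisions) / K,
        "recall": sum(recalls) / K,
        "F1": sum(f1s) / K,
        "kappa": kappa,
    }


#: Direct evaluations of the ten vegetation-index formulas, written out
#: independently of the package's registry.
VI_ORACLES = {
    "NDVI": lambda b: (b["B8"] - b["B4"]) / (b["B8"] + b["B4"]),
    "EVI": lambda b: 2.5 * (b["B8"] - b["B4"]) / (b["B8"] + 6 * b["B4"] - 7.5 * b["B2"] + 1),
    "NBRI": lambda b: (b["B8"] - b["B12"]) / (b["B8"] + b["B12"]),
    "SAVI": lambda b: 1.5 * (b["B8"] - b["B4"]) / (b["B8"] + b["B4"] + 0.5),
    "RVI": lambda b: b["B8"] / b["B4"],
    "DVI": lambda b: b["B8"] - b["B4"],
    "NDBI": lambda b: (b["B11"] - b["B8"]) / (b["B11"] + b["B8"]),
    "BGRVI": lambda b: (b["B3"] - (b["B2"] + b["B4"])) / (b["B3"] + (b["B2"] + b["B4"])),
    "GNDVI": lambda b: (b["B8"] - b["B3"]) / (b["B8"] + b["B3"]),
    "NDWI": lambda b: (b["B3"] - b["B8"]) / (b["B3"] + b["B8"]),
}
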