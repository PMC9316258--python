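"""Independent brute-force oracles used to check the package's fast paths.

Everything here is written straight from the defining formulas with plain
Python loops and no reuse of package internals, so agreement with the
package is a genuine two-route check.
"""

from __future__ import annotations

import itertools
import json
import math
from importlib import resources

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def load_raw_property_values() -> tuple[list[str], dict[str, dict[str, float]]]:
    raw = json.loads(
        resources.files("sagpred.data").joinpath("properties.json").read_text()
    )
    return raw["names"], raw["values"]


def normalized_property(values: dict[str, float]) -> dict[str, float]:
    """Standardize a 20-residue scale: mean 0, population SD 1."""
    vals = [values[aa] for aa in ALPHABET]
    mean = sum(vals) / 20.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
    return {aa: (values[aa] - mean) / sd for aa in ALPHABET}


def kmer_oracle(seq: str, k: int) -> np.ndarray:
    """Naive overlapping substring counting over the lexicographic k-mer list."""
    kmers = ["".join(t) for t in itertools.product(ALPHABET, repeat=k)]
    n_windows = len(seq) - k + 1
    counts = {m: 0 for m in kmers}
    for i in range(n_windows):
        counts[seq[i : i + k]] += 1
    return np.array([counts[m] / n_windows for m in kmers])


def pseaac_oracle(seq: str, lam: int, w: float) -> np.ndarray:
    """Type-1 pseudo amino acid composition evaluated term by term."""
    names, raw = load_raw_property_values()
    props = [normalized_property(raw[name]) for name in names]
    L = len(seq)
    f = [seq.count(aa) / L for aa in ALPHABET]
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            ri, rj = seq[i], seq[i + j]
            corr = sum((p[rj] - p[ri]) ** 2 for p in props) / len(props)
            total += corr
        thetas.append(total / (L - j))
    denom = 1.0 + w * sum(thetas)
    return np.array(f + [w * t for t in thetas]) / denom


def acc_oracle(seq: str, lag: int) -> np.ndarray:
    """Auto/cross covariance by direct double-loop summation."""
    names, raw = load_raw_property_values()
    props = [normalized_property(raw[name]) for name in names]
    L = len(seq)
    tracks = [[p[aa] for aa in seq] for p in props]
    means = [sum(t) / L for t in tracks]
    out = []
    for a in range(len(props)):
        for g in range(1, lag + 1):
            s = 0.0
            for i in range(L - g):
                s += (tracks[a][i] - means[a]) * (tracks[a][i + g] - means[a])
            out.append(s / (L - g))
    for a in range(len(props)):
        for b in range(len(props)):
            if a == b:
                continue
            for g in range(1, lag + 1):
                s = 0.0
                for i in range(L - g):
                    s += (tracks[a][i] - means[a]) * (tracks[b][i + g] - means[b])
                out.append(s / (L - g))
    return np.array(out)


def lcs_length(a: str, b: str) -> int:
    """Longest common subsequence by textbook dynamic programming."""
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def identity_oracle(a: str, b: str) -> float:
    return lcs_length(a, b) / min(len(a), len(b))


def trapezoid_auc_oracle(scores, y_true) -> float:
    """Area under the ROC built over all thresholds, by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    pts = np.array(sorted(set(points)))
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
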