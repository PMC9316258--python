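"""Small constructed datasets shared by the dimension-reduction tests."""

from __future__ import annotations

import numpy as np


def xor_two_direction_data(
    n: int = 200, n_features: int = 30, scale: float = 2.5, seed: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Class signal that genuinely needs two feature directions.

    The two classes form an XOR pattern over the first two coordinates:
    positives sit at (+s, +s) and (-s, -s), negatives at (+s, -s) and
    (-s, +s), embedded in isotropic noise. No single linear direction
    separates the classes, but the first two principal components (the two
    highest-variance coordinates) do. Classes are exactly balanced.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    u = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    v = np.where((np.arange(n) // 2) % 2 == 0, 1.0, -1.0)
    y = (u * v > 0).astype(int)
    X[:, 0] += scale * u
    X[:, 1] += scale * v
    return X, y
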