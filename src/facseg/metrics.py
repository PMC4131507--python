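"""Segmentation accuracy scoring.

The percentage of mislabelled pixels compares the extracted object region
R_s against the ground-truth region R_b:

    P_mp = (|R_mb| + |R_ms|) / (|R_b| + |R_s|) * 100%

with R_mb = R_b \\ R_s (missed object pixels) and R_ms = R_s \\ R_b
(spurious object pixels). Identical masks score 0; disjoint non-empty masks
score 100; the formula is symmetric in its two arguments and can reach 200
in principle (tiny truth inside a huge prediction, or vice versa).
"""

from __future__ import annotations

import numpy as np

from .exceptions import UndefinedScoreError

__all__ = ["p_mp"]


def p_mp(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Percentage of mislabelled pixels between two binary masks.

    Raises
    ------
    UndefinedScoreError
        If both masks are empty (the denominator vanishes).
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"mask shapes differ: {t.shape} vs {p.shape}")
    n_b = int(t.sum())
    n_s = int(p.sum())
    if n_b + n_s == 0:
        raise UndefinedScoreError("both masks empty; P_mp undefined")
    missed = int((t & ~p).sum())
    spurious = int((p & ~t).sum())
    return (missed + spurious) / (n_b + n_s) * 100.0
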