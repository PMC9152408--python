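"""Segmentation evaluation criteria.

Four complementary views of agreement between a reference label map and a
segmentation result:

- similarity index: the Rand index — the fraction of unordered pixel pairs
  whose co-assignment (same class / different class) agrees between the two
  maps; 1.0 means perfect pairwise consistency and the index is invariant
  to label permutations.
- information-loss index: the variation of information
  ``H(F) + H(R) - 2 I(F; R)`` normalized by ``log N``; zero exactly when the
  maps are identical up to a label permutation.
- boundary error: mean symmetric nearest-neighbour distance between the two
  boundary-pixel sets, normalized by the image diagonal (pixel-centre
  distances), a dimensionless ~[0, 1) quantity.
- F-measure: pixelwise ``2 Pre Rec / (Pre + Rec)`` for a positive class,
  with a macro average over reference classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "MaskPair",
    "pair_consistent",
    "similarity_index",
    "information_loss",
    "boundary_error",
    "f_measure",
    "f_measure_macro",
    "match_labels",
]

#: Above this pixel count, similarity_index("all") switches to Monte Carlo.
EXACT_PAIR_LIMIT = 10_000
DEFAULT_SAMPLE_PAIRS = 1_000_000


@dataclass(frozen=True)
class MaskPair:
    """A reference label map and a segmentation result of equal shape."""

    reference: np.ndarray
    result: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference)
        res = np.asarray(self.result)
        if ref.shape != res.shape:
            raise ValidationError(f"shape mismatch: {ref.shape} vs {res.shape}")
        if ref.min() < 0 or res.min() < 0:
            raise ValidationError("labels must be non-negative integers")

    @property
    def n_pixels(self) -> int:
        return int(np.asarray(self.reference).size)


def pair_consistent(pair: MaskPair, which: str, i: int, j: int) -> int:
    """1 iff flat pixels ``i`` and ``j`` share a label in the chosen map."""
    if which not in ("reference", "result"):
        raise ValidationError(f"which must be 'reference' or 'result', got {which!r}")
    labels = np.asarray(pair.reference if which == "reference" else pair.result).ravel()
    n = labels.size
    if not (0 <= i < n and 0 <= j < n):
        raise ValidationError(f"pixel index out of range for {n} pixels")
    return int(labels[i] == labels[j])


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    return np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)


def similarity_index(pair: MaskPair, sample_pairs="all", seed: int = 0) -> float:
    """Rand index over unordered pixel pairs.

    Exact (pair-counting via the label contingency table) when
    ``sample_pairs == "all"`` and the maps have at most
    :data:`EXACT_PAIR_LIMIT` pixels; otherwise a seeded Monte-Carlo estimate
    over ``sample_pairs`` random pairs (default 1e6).
    """
    f = np.asarray(pair.reference).ravel().astype(np.int64)
    r = np.asarray(pair.result).ravel().astype(np.int64)
    n = f.size
    if n < 2:
        raise ValidationError("need at least 2 pixels")
    if sample_pairs == "all" and n <= EXACT_PAIR_LIMIT:
        cont = _contingency(f, r)
        total = n * (n - 1) / 2.0
        same_both = (cont * (cont - 1) / 2.0).sum()
        a = cont.sum(axis=1)
        b = cont.sum(axis=0)
        same_f = (a * (a - 1) / 2.0).sum()
        same_r = (b * (b - 1) / 2.0).sum()
        agree = total + 2.0 * same_both - same_f - same_r
        return float(agree / total)
    m = DEFAULT_SAMPLE_PAIRS if sample_pairs == "all" else int(sample_pairs)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, m)
    j = rng.integers(0, n, m)
    keep = i != j
    i, j = i[keep], j[keep]
    agree = (f[i] == f[j]) == (r[i] == r[j])
    return float(np.mean(agree))


def information_loss(pair: MaskPair) -> float:
    """Variation of information between the two partitions, / log(N).

    ``(H(F) + H(R) - 2 I(F; R)) / log N`` with natural logarithms.  Zero if
    and only if the maps are identical up to a label permutation.
    """
    f = np.asarray(pair.reference).ravel().astype(np.int64)
    r = np.asarray(pair.result).ravel().astype(np.int64)
    n = f.size
    cont = _contingency(f, r) / n
    pf = cont.sum(axis=1)
    pr = cont.sum(axis=0)

    def _h(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_joint = _h(cont.ravel())
    vi = 2.0 * h_joint - _h(pf) - _h(pr)  # = H(F)+H(R)-2I
    return max(vi, 0.0) / np.log(n)


def _boundary_points(labels: np.ndarray) -> np.ndarray:
    """Pixels whose right or down neighbour carries a different label."""
    right = np.zeros(labels.shape, dtype=bool)
    down = np.zeros(labels.shape, dtype=bool)
    right[:, :-1] = labels[:, :-1] != labels[:, 1:]
    down[:-1, :] = labels[:-1, :] != labels[1:, :]
    return np.argwhere(right | down)


def boundary_error(pair: MaskPair) -> float:
    """Mean symmetric boundary distance, normalized by the image diagonal.

    The boundary of each map is the set of pixels whose right/down
    neighbour differs; the error is the average of the two directed mean
    nearest-neighbour distances between the boundary sets, divided by the
    diagonal pixel-centre distance ``sqrt((H-1)^2 + (W-1)^2)``.
    """
    ref = np.asarray(pair.reference)
    res = np.asarray(pair.result)
    pf = _boundary_points(ref)
    pr = _boundary_points(res)
    if pf.size == 0 or pr.size == 0:
        raise ValidationError("boundary undefined: a map contains a single label")
    d_fr = cKDTree(pr).query(pf)[0].mean()
    d_rf = cKDTree(pf).query(pr)[0].mean()
    h, w = ref.shape
    diag = np.hypot(h - 1, w - 1)
    return float((d_fr + d_rf) / 2.0 / diag)


def f_measure(pair: MaskPair, positive_class: int) -> float:
    """Pixelwise F-measure ``2 Pre Rec / (Pre + Rec)`` for one class.

    Returns 0 when precision + recall is 0; raises if the positive class is
    absent from the reference map.
    """
    ref = np.asarray(pair.reference)
    res = np.asarray(pair.result)
    ref_pos = ref == positive_class
    if not ref_pos.any():
        raise ValidationError(f"class {positive_class} absent from the reference map")
    res_pos = res == positive_class
    tp = np.count_nonzero(ref_pos & res_pos)
    fp = np.count_nonzero(~ref_pos & res_pos)
    fn = np.count_nonzero(ref_pos & ~res_pos)
    if tp == 0:
        return 0.0
    pre = tp / (tp + fp)
    rec = tp / (tp + fn)
    return float(2.0 * pre * rec / (pre + rec))


def f_measure_macro(pair: MaskPair) -> float:
    """Mean F-measure over the classes present in the reference map."""
    classes = np.unique(np.asarray(pair.reference))
    return float(np.mean([f_measure(pair, int(c)) for c in classes]))


def match_labels(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel ``pred`` by the bijective class matching maximizing overlap.

    Hungarian assignment on the label contingency table; prediction classes
    beyond the truth's range keep fresh ids.  Use before pixel-error metrics
    when the prediction's class ids are arbitrary (e.g. from clustering).
    """
    pred = np.asarray(pred).astype(np.int64)
    truth = np.asarray(truth).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    cont = _contingency(pred.ravel(), truth.ravel())
    kp, kt = cont.shape
    k = max(kp, kt)
    pad = np.zeros((k, k))
    pad[:kp, :kt] = cont
    rows, cols = linear_sum_assignment(-pad)
    mapping = np.empty(k, dtype=np.int64)
    mapping[rows] = cols
    return mapping[pred]
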