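"""Constrained-maximum-entropy selection of 3x3 binary image features.

The reference model of early visual coding assumes the input stream is
digitized to 1 bit (black/white at the median luminance), cut into 3x3
pixel patches (512 possible patterns), and that only a small set of
patterns is transmitted downstream.  The transmitted ("optimal") set is
the one that maximizes entropy yield per unit computational cost under
two resource constraints: the number of distinct patterns the system can
represent (``n_max``, default 50) and the total output bandwidth it can
occupy (``w_max``, the summed probability of transmitted patterns,
default 0.025).

Pattern identifiers encode a 3x3 binary patch read row-major with the
top-left pixel as the most significant bit and white = 1, so id 0 is the
all-black patch and id 511 the all-white patch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

N_PATTERNS = 512
PATCH_SIDE = 3

#: Bit weights for row-major encoding, top-left pixel = MSB.
_BIT_WEIGHTS = (2 ** np.arange(8, -1, -1)).reshape(PATCH_SIDE, PATCH_SIDE)


# ---------------------------------------------------------------------------
# Binarization and patch statistics
# ---------------------------------------------------------------------------

def binarize_image(image: np.ndarray) -> np.ndarray:
    """Digitize a grayscale image to 1 bit at its median luminance.

    Pixels at or above the median map to white (1), pixels below to
    black (0).  The >= tie rule is deterministic and splits continuous
    data 50/50.

    Parameters
    ----------
    image : ndarray
        2-D numeric array of luminance values.

    Returns
    -------
    ndarray of uint8
        Binary image of the same shape with values in {0, 1}.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot binarize an empty image")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return (arr >= np.median(arr)).astype(np.uint8)


def encode_patch(patch: np.ndarray) -> int:
    """Encode one 3x3 binary patch as its pattern id in [0, 511]."""
    patch = np.asarray(patch)
    if patch.shape != (PATCH_SIDE, PATCH_SIDE):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    return int(np.sum(patch.astype(np.int64) * _BIT_WEIGHTS))


def decode_patch(pattern_id: int) -> np.ndarray:
    """Inverse of :func:`encode_patch`: pattern id -> 3x3 binary array."""
    if not 0 <= pattern_id < N_PATTERNS:
        raise ValueError(f"pattern id must be in [0, 511], got {pattern_id}")
    bits = (pattern_id >> np.arange(8, -1, -1)) & 1
    return bits.reshape(PATCH_SIDE, PATCH_SIDE).astype(np.uint8)


def _patch_ids(image: np.ndarray, mode: Literal["tile", "slide"]) -> np.ndarray:
    """Pattern ids of all 3x3 patches of a binary image."""
    img = np.asarray(image)
    h, w = img.shape
    if h < PATCH_SIDE or w < PATCH_SIDE:
        raise ValueError(f"image {img.shape} too small for 3x3 patches")
    if mode == "tile":
        th, tw = h // PATCH_SIDE, w // PATCH_SIDE
        blocks = (
            img[: th * PATCH_SIDE, : tw * PATCH_SIDE]
            .reshape(th, PATCH_SIDE, tw, PATCH_SIDE)
            .transpose(0, 2, 1, 3)
        )
    elif mode == "slide":
        blocks = np.lib.stride_tricks.sliding_window_view(
            img, (PATCH_SIDE, PATCH_SIDE)
        )
    else:
        raise ValueError(f"mode must be 'tile' or 'slide', got {mode!r}")
    ids = np.tensordot(
        blocks.astype(np.int64), _BIT_WEIGHTS, axes=([2, 3], [0, 1])
    )
    return ids.ravel()


@dataclass(frozen=True)
class PatternDistribution:
    """Empirical probability distribution over the 512 3x3 patterns.

    Attributes
    ----------
    counts : ndarray, shape (512,)
        Occurrence count per pattern id.
    n_patches : int
        Total number of patches counted (= ``counts.sum()``).
    """

    counts: np.ndarray
    n_patches: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_PATTERNS,):
            raise ValueError(f"counts must have shape (512,), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("distribution has no patches")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n_patches", int(counts.sum()))

    @property
    def probs(self) -> np.ndarray:
        """Relative frequency per pattern id; sums to 1."""
        return self.counts / self.n_patches


def extract_pattern_distribution(
    images: Iterable[np.ndarray], mode: Literal["tile", "slide"] = "tile"
) -> PatternDistribution:
    """Aggregate the 3x3 pattern distribution over a corpus of binary images.

    Parameters
    ----------
    images : iterable of ndarray
        Binary images (values in {0, 1}), each at least 3x3.
    mode : {"tile", "slide"}
        ``tile`` (default) subdivides each image into non-overlapping 3x3
        blocks, truncating remainders; ``slide`` uses a dense stride-1
        sliding window.
    """
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    n_images = 0
    for img in images:
        ids = _patch_ids(img, mode)
        counts += np.bincount(ids, minlength=N_PATTERNS)
        n_images += 1
    if n_images == 0:
        raise ValueError("no images supplied")
    return PatternDistribution(counts)


# ---------------------------------------------------------------------------
# Entropy yield per unit cost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionParams:
    """Resource constraints of the coding model.

    ``n_max`` is the maximum number of transmitted patterns; ``w_max``
    the maximum output bandwidth occupancy (total probability mass of
    transmitted patterns).
    """

    n_max: int = 50
    w_max: float = 0.025

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if not 0 < self.w_max <= 1:
            raise ValueError(f"w_max must be in (0, 1], got {self.w_max}")


def pattern_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Entropy contribution H(p) = -p log2 p of a pattern, with H(0) = 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h if h.ndim else float(h)


def default_cost(p: np.ndarray | float, params: SelectionParams) -> np.ndarray | float:
    """Transmission cost C(p) = max(p / w_max, 1 / n_max).

    A frequent pattern is charged for the bandwidth fraction it occupies
    (p / W); a rare one for the representation slot it consumes (1 / N).
    """
    p = np.asarray(p, dtype=float)
    c = np.maximum(p / params.w_max, 1.0 / params.n_max)
    return c if c.ndim else float(c)


CostFunction = Callable[[np.ndarray, SelectionParams], np.ndarray]


def efficiency(
    p: np.ndarray | float,
    params: SelectionParams,
    cost: CostFunction = default_cost,
) -> np.ndarray | float:
    """Entropy yield per unit cost, H(p) / C(p).

    Zero-probability patterns yield 0 (nothing to transmit) and the
    uniform patch at p = 1 yields 0 (no entropy), so both extremes of the
    probability axis are rejected by construction.
    """
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    eff = np.asarray(pattern_entropy(p_arr)) / np.asarray(cost(p_arr, params))
    return eff if np.ndim(p) else float(eff)


# ---------------------------------------------------------------------------
# Feature-set selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """An ordered set of selected pattern ids with bookkeeping.

    ``label`` is ``"optimal"`` for constrained-maximum-entropy selections
    and ``"non_optimal"`` for lowest-probability selections.  ``bandwidth``
    is the summed occurrence probability of the members.
    """

    label: Literal["optimal", "non_optimal"]
    members: list[int]
    member_probs: list[float]
    params: SelectionParams | None = None

    def __post_init__(self) -> None:
        if len(self.members) != len(set(self.members)):
            raise ValueError("feature set contains duplicate members")
        if len(self.members) != len(self.member_probs):
            raise ValueError("members and member_probs length mismatch")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, pattern_id: int) -> bool:
        return pattern_id in set(self.members)

    @property
    def bandwidth(self) -> float:
        return float(sum(self.member_probs))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "label": self.label,
            "params": (
                {"n_max": self.params.n_max, "w_max": self.params.w_max}
                if self.params
                else None
            ),
            "members": list(map(int, self.members)),
            "member_probs": list(map(float, self.member_probs)),
            "bandwidth": self.bandwidth,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureSet":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        payload = json.loads(text)
        params = (
            SelectionParams(**payload["params"]) if payload.get("params") else None
        )
        return cls(
            label=payload["label"],
            members=list(payload["members"]),
            member_probs=list(payload["member_probs"]),
            params=params,
        )


def _greedy_select(
    probs: np.ndarray, params: SelectionParams, cost: CostFunction
) -> list[int]:
    """Greedy pass in decreasing efficiency order (ties by ascending id)."""
    eff = np.asarray(efficiency(probs, params, cost))
    order = np.lexsort((np.arange(N_PATTERNS), -eff))
    members: list[int] = []
    bandwidth = 0.0
    for pid in order:
        if eff[pid] <= 0:
            break  # sorted: everything after is also zero
        if len(members) >= params.n_max:
            break
        p = probs[pid]
        if bandwidth + p > params.w_max + 1e-15:
            continue
        members.append(int(pid))
        bandwidth += p
    return members


def _knapsack_select(
    values: np.ndarray, weights: np.ndarray, n_max: int, capacity: int
) -> list[int]:
    """Exact 0/1 knapsack with a cardinality bound.

    Maximizes ``sum(values)`` subject to ``sum(weights) <= capacity`` and
    at most ``n_max`` items.  ``dp[n, k]`` holds the best value using
    exactly n of the processed items with total weight <= k; memory for
    backtracking is kept linear by checkpointing the table every
    ~sqrt(n_items) items and replaying one segment at a time.

    Returns indices into ``values`` of the chosen items.
    """
    n_items = len(values)
    if n_items == 0:
        return []
    n_max = min(n_max, n_items)
    capacity = min(capacity, int(weights.sum()))
    if capacity <= 0:
        return []

    def apply_item(dp: np.ndarray, w: int, v: float) -> None:
        for n in range(min(n_max, n_items), 0, -1):
            np.maximum(dp[n, w:], dp[n - 1, :-w] + v, out=dp[n, w:])

    dp = np.full((n_max + 1, capacity + 1), -np.inf)
    dp[0, :] = 0.0
    seg = max(1, int(np.ceil(np.sqrt(n_items))))
    checkpoints: dict[int, np.ndarray] = {}
    for i in range(n_items):
        if i % seg == 0:
            checkpoints[i] = dp.copy()
        apply_item(dp, int(weights[i]), float(values[i]))

    n_state = int(np.argmax(dp[:, capacity]))
    if dp[n_state, capacity] <= 0:
        return []
    k_state = capacity
    chosen: list[int] = []
    for start in sorted(checkpoints, reverse=True):
        stop = min(start + seg, n_items)
        hist = [checkpoints[start]]
        for i in range(start, stop):
            nxt = hist[-1].copy()
            apply_item(nxt, int(weights[i]), float(values[i]))
            hist.append(nxt)
        for i in range(stop - 1, start - 1, -1):
            before = hist[i - start]
            after = hist[i - start + 1]
            if before[n_state, k_state] >= after[n_state, k_state] - 1e-12:
                continue  # state reachable without item i
            chosen.append(i)
            k_state -= int(weights[i])
            n_state -= 1
        if n_state == 0:
            break
    return chosen


#: DP cell budget above which exact selection falls back to greedy.
_EXACT_CELL_LIMIT = 50_000_000


def select_optimal(
    dist: PatternDistribution,
    params: SelectionParams = SelectionParams(),
    cost: CostFunction = default_cost,
    method: Literal["exact", "greedy"] = "exact",
) -> FeatureSet:
    """Constrained-maximum-entropy selection of the optimal feature set.

    The default ``exact`` method maximizes total entropy
    ``sum(-p log2 p)`` over subsets satisfying both constraints (at most
    ``n_max`` members, total bandwidth at most ``w_max``).  Because
    probabilities are patch counts over ``n_patches``, the bandwidth
    constraint is an integer knapsack capacity and the optimum is found
    by dynamic programming.  ``greedy`` instead adds patterns in
    decreasing order of entropy yield per unit cost, skipping any whose
    probability would overflow the bandwidth; it is faster but can be
    mildly suboptimal when the constraints interact.

    Either way, patterns with zero efficiency (p = 0, and the uniform
    patches when p = 1) are never selected, and returned members are
    ordered by decreasing efficiency (ties by ascending id).
    """
    probs = dist.probs
    eff = np.asarray(efficiency(probs, params, cost))
    if method == "exact":
        capacity = int(np.floor(params.w_max * dist.n_patches * (1 + 1e-12)))
        cand = np.flatnonzero(
            (eff > 0) & (dist.counts > 0) & (dist.counts <= capacity)
        )
        cells = (params.n_max + 1) * (capacity + 1)
        if cells > _EXACT_CELL_LIMIT:
            warnings.warn(
                "exact selection table too large; falling back to greedy",
                stacklevel=2,
            )
            members = _greedy_select(probs, params, cost)
        else:
            values = np.asarray(pattern_entropy(probs[cand]))
            idx = _knapsack_select(
                values, dist.counts[cand], params.n_max, capacity
            )
            members = [int(cand[i]) for i in idx]
    elif method == "greedy":
        members = _greedy_select(probs, params, cost)
    else:
        raise ValueError(f"method must be 'exact' or 'greedy', got {method!r}")
    members.sort(key=lambda pid: (-eff[pid], pid))
    return FeatureSet(
        "optimal", members, [float(probs[pid]) for pid in members], params=params
    )


def select_nonoptimal(dist: PatternDistribution, k: int = 50) -> FeatureSet:
    """Select the k patterns with the lowest positive occurrence probability.

    Ties are broken by ascending pattern id.  If fewer than k patterns
    occur in the corpus, the set is padded with zero-probability patterns
    (ascending id) and a warning is issued.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > N_PATTERNS:
        raise ValueError(f"k must be <= {N_PATTERNS}, got {k}")
    probs = dist.probs
    positive = np.flatnonzero(probs > 0)
    order = positive[np.lexsort((positive, probs[positive]))]
    members = [int(pid) for pid in order[:k]]
    if len(members) < k:
        warnings.warn(
            f"only {len(members)} patterns have positive probability; "
            f"padding with zero-probability patterns",
            stacklevel=2,
        )
        zero = np.flatnonzero(probs == 0)
        members.extend(int(pid) for pid in zero[: k - len(members)])
    return FeatureSet(
        "non_optimal", members, [float(probs[pid]) for pid in members]
    )


def brute_force_optimal(
    dist: PatternDistribution,
    params: SelectionParams,
    candidate_ids: Sequence[int] | None = None,
) -> tuple[tuple[int, ...], float]:
    """Exact reference selection by exhaustive subset enumeration.

    Maximizes total entropy sum(-p log2 p) over all subsets satisfying the
    cardinality and bandwidth constraints.  Exponential in the number of
    candidates; intended as an oracle for small problems.

    Returns the best subset (sorted ids) and its total entropy.
    """
    probs = dist.probs
    if candidate_ids is None:
        candidate_ids = [int(i) for i in np.flatnonzero(probs > 0)]
    cand = list(candidate_ids)
    if len(cand) > 20:
        raise ValueError("brute force limited to <= 20 candidate patterns")
    p = probs[cand]
    h = np.asarray(pattern_entropy(p))
    best: tuple[int, ...] = ()
    best_h = 0.0
    for mask in range(1 << len(cand)):
        if mask.bit_count() > params.n_max:
            continue
        sel = [i for i in range(len(cand)) if mask >> i & 1]
        if p[sel].sum() > params.w_max + 1e-15:
            continue
        total = float(h[sel].sum())
        if total > best_h + 1e-12:
            best_h = total
            best = tuple(sorted(cand[i] for i in sel))
    return best, best_h


# ---------------------------------------------------------------------------
# Sketch filtering
# ---------------------------------------------------------------------------

def filter_sketch(image: np.ndarray, fset: FeatureSet) -> np.ndarray:
    """Filter a binary image through a feature set to produce a sketch.

    A stride-1 3x3 window scans the image; the sketch marks (value 1) the
    center pixel of every window whose pattern id belongs to the set.
    Border pixels, which have no complete window, stay 0.
    """
    img = np.asarray(image)
    ids = _patch_ids(img, "slide").reshape(
        img.shape[0] - PATCH_SIDE + 1, img.shape[1] - PATCH_SIDE + 1
    )
    lut = np.zeros(N_PATTERNS, dtype=np.uint8)
    lut[list(fset.members)] = 1
    sketch = np.zeros(img.shape, dtype=np.uint8)
    sketch[1:-1, 1:-1] = lut[ids]
    return sketch
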