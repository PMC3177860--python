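"""Intrinsic optical imaging pipeline: maps, patches, and two-way clustering.

Trial-structured frame stacks are registered by integer translation, turned
into single-condition activation maps (activation = reflectance decrease =
negative signal), thresholded against a control map to find response
patches, and each patch's per-color normalized response vectors are split
into two clusters with an exhaustive-seed two-phase k-means.  Cluster labels
are anchored by the blue stimulus (most negative L-M contrast), yielding the
per-color index I_pn and the per-patch outlier count N_d against the sign of
either opponent channel.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "ImagingExperiment",
    "ResponsePatch",
    "ExperimentResult",
    "register_frames",
    "conventional_activation_map",
    "svm_activation_map",
    "noise_threshold",
    "response_regions",
    "composite_patches",
    "extract_response_vectors",
    "kmeans_two",
    "label_clusters",
    "compute_ipn",
    "count_outliers",
    "quadrant_binomial_test",
    "outlier_t_test",
    "exclusion_robustness",
    "analyze_experiment",
    "pool_patch_assignments",
]

CONTROL_LABEL = "control"

#: Number of response frames: the last 5 during-stimulation + 2 after.
N_RESPONSE_FRAMES = 7


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One imaging trial: a frame stack for a single stimulus presentation."""

    stimulus: str
    block: int
    frames: np.ndarray  # (n_frames, H, W), non-negative light levels
    n_pre: int = 11

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if f.shape[0] < self.n_pre + N_RESPONSE_FRAMES:
            raise ValueError(
                f"trial needs >= {self.n_pre + N_RESPONSE_FRAMES} frames, got {f.shape[0]}"
            )
        self.frames = f

    @property
    def pre_mean(self) -> np.ndarray:
        """Average of the pre-stimulation frames."""
        return self.frames[: self.n_pre].mean(axis=0)

    @property
    def response_mean(self) -> np.ndarray:
        """Average of the response frames (last 5 during + 2 after)."""
        return self.frames[-N_RESPONSE_FRAMES:].mean(axis=0)


@dataclass
class ImagingExperiment:
    """All trials of one imaging session plus the stimulus table.

    ``stimulus_table`` has one row per color with columns
    ``label, x, y, Y, R_LM, R_Y`` (the control/gray screen is not a row; it
    is identified by ``control_label`` in the trials).
    """

    trials: list[Trial]
    stimulus_table: pd.DataFrame
    control_label: str = CONTROL_LABEL

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("experiment has no trials")
        shape = self.trials[0].frames.shape[1:]
        if any(t.frames.shape[1:] != shape for t in self.trials):
            raise ValueError("all frames must have the same shape")
        expected = set(self.stimulus_table["label"]) | {self.control_label}
        for block, group in itertools.groupby(
            sorted(self.trials, key=lambda t: t.block), key=lambda t: t.block
        ):
            labels = [t.stimulus for t in group]
            if sorted(labels) != sorted(expected):
                raise ValueError(
                    f"block {block}: expected one trial per stimulus incl. control, "
                    f"got {sorted(labels)}"
                )

    @property
    def colors(self) -> list[str]:
        return list(self.stimulus_table["label"])

    def trials_for(self, stimulus: str) -> list[Trial]:
        return [t for t in self.trials if t.stimulus == stimulus]


@dataclass
class ResponsePatch:
    """A connected suprathreshold region with its per-color response vectors."""

    mask: np.ndarray                      # boolean (H, W)
    contributing_colors: set[str]
    response_vectors: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _shift_zero_fill(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    h, w = frame.shape
    out = np.zeros_like(frame)
    out[max(0, dy): h + min(0, dy), max(0, dx): w + min(0, dx)] = frame[
        max(0, -dy): h + min(0, -dy), max(0, -dx): w + min(0, -dx)
    ]
    return out


def _overlap_views(frame, reference, dy, dx):
    h, w = frame.shape
    ref = reference[max(0, dy): h + min(0, dy), max(0, dx): w + min(0, dx)]
    mov = frame[max(0, -dy): h + min(0, -dy), max(0, -dx): w + min(0, -dx)]
    return mov, ref


def register_frames(
    stack: np.ndarray, reference: np.ndarray, max_shift: int
) -> tuple[np.ndarray, np.ndarray]:
    """Align each frame to ``reference`` by integer translation.

    For every offset within +/- ``max_shift`` the Pearson correlation between
    the translated frame and the reference is evaluated on their overlap; the
    offset maximizing the correlation wins, with ties broken in favor of the
    smallest-magnitude offset.  Returns ``(offsets, shifted)`` where
    ``offsets`` is (n, 2) of (dy, dx) applied to each frame and ``shifted``
    is the translated stack cropped by ``max_shift`` on every side (the
    common valid area).
    """
    stack = np.asarray(stack)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    h, w = stack.shape[1:]
    if 2 * max_shift >= min(h, w):
        raise ValueError("max_shift too large for frame size")
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (h, w):
        raise ValueError("reference shape mismatch")
    if np.ptp(ref) == 0:
        raise ValueError("constant reference frame: correlation undefined")

    # offsets ordered by magnitude so the first strict maximum wins ties
    candidates = sorted(
        ((dy, dx) for dy in range(-max_shift, max_shift + 1)
         for dx in range(-max_shift, max_shift + 1)),
        key=lambda o: (o[0] ** 2 + o[1] ** 2, o[0], o[1]),
    )
    offsets = np.zeros((stack.shape[0], 2), dtype=int)
    shifted = np.empty_like(stack)
    for i, frame in enumerate(stack):
        fr = frame.astype(float)
        if np.ptp(fr) == 0:
            raise ValueError(f"frame {i} is constant: correlation undefined")
        best, best_off = -np.inf, (0, 0)
        for dy, dx in candidates:
            mov, tgt = _overlap_views(fr, ref, dy, dx)
            if mov.size == 0:
                continue
            ms = mov - mov.mean()
            ts = tgt - tgt.mean()
            denom = math.sqrt(float((ms * ms).sum()) * float((ts * ts).sum()))
            if denom == 0:
                continue
            r = float((ms * ts).sum()) / denom
            if r > best:
                best, best_off = r, (dy, dx)
        offsets[i] = best_off
        shifted[i] = _shift_zero_fill(frame, *best_off)
    m = max_shift
    cropped = shifted[:, m: h - m, m: w - m] if m > 0 else shifted
    if single:
        return offsets[0], cropped[0]
    return offsets, cropped


# ---------------------------------------------------------------------------
# Activation maps
# ---------------------------------------------------------------------------

def conventional_activation_map(trial: Trial) -> np.ndarray:
    """Subtraction-and-normalization map: (resp - pre) / pre, pixel-wise.

    Activation (a reflectance decrease) is negative.
    """
    pre = trial.pre_mean
    if np.any(pre == 0):
        raise ValueError("zero pre-stimulation mean at some pixel")
    return (trial.response_mean - pre) / pre


def svm_activation_map(
    pre_means: np.ndarray, response_means: np.ndarray, regularization: float = 1.0
) -> np.ndarray:
    """Activation map from a linear classifier over pixels.

    A linear SVM is trained to discriminate per-trial mean response frames
    from per-trial mean pre-stimulation frames, with pixels as variables and
    trials as samples.  The unit weight image is scaled by the projection of
    the mean response-minus-pre difference onto it and divided by the global
    mean pre-stimulation level, giving a fractional-change map whose sign is
    stable (activation negative) regardless of the solver's sign convention.
    Artifacts common to both frame groups (vessels, illumination) carry no
    class information and receive near-zero weight.
    """
    pre = np.asarray(pre_means, dtype=float)
    resp = np.asarray(response_means, dtype=float)
    if pre.ndim != 3 or resp.ndim != 3 or pre.shape[1:] != resp.shape[1:]:
        raise ValueError("pre/response stacks must be (n_trials, H, W) with equal frame shape")
    if pre.shape[0] < 2 or resp.shape[0] < 2:
        raise ValueError("need at least 2 trials per group")
    shape = pre.shape[1:]
    X = np.concatenate([pre.reshape(pre.shape[0], -1), resp.reshape(resp.shape[0], -1)])
    y = np.concatenate([-np.ones(pre.shape[0]), np.ones(resp.shape[0])])
    if np.allclose(X.std(axis=0), 0) and np.allclose(pre.mean(0), resp.mean(0)):
        raise ValueError("degenerate input: groups are identical and constant")
    # center and uniformly rescale for solver conditioning; a scalar scaling
    # leaves the weight direction (hence the map, whose amplitude is
    # recomputed in original units below) unchanged
    Xc = X - X.mean(axis=0)
    scale = Xc.std()
    if scale == 0:
        raise ValueError("degenerate input: no variation across samples")
    clf = SVC(kernel="linear", C=regularization)
    clf.fit(Xc / scale, y)
    w = clf.coef_[0]
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros(shape)
    w_hat = w / norm
    delta = resp.reshape(resp.shape[0], -1).mean(0) - pre.reshape(pre.shape[0], -1).mean(0)
    amplitude = float(w_hat @ delta)   # sign flips with w_hat: product is stable
    baseline = float(pre.mean())
    if baseline == 0:
        raise ValueError("zero mean pre-stimulation level")
    return (w_hat * amplitude).reshape(shape) / baseline


def noise_threshold(control_map: np.ndarray) -> float:
    """Most negative value of the control map: the response/noise threshold."""
    m = np.asarray(control_map)
    if m.size == 0:
        raise ValueError("empty control map")
    return float(m.min())


def response_regions(activation_map: np.ndarray, threshold: float) -> np.ndarray:
    """Binary map: 1 where the response exceeds the threshold.

    Intrinsic signals are negative, so "exceeding" means strictly more
    negative than ``threshold``; a pixel exactly at the threshold is 0.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (np.asarray(activation_map) < threshold).astype(np.uint8)


_STRUCTS = {4: ndimage.generate_binary_structure(2, 1),
            8: ndimage.generate_binary_structure(2, 2)}


def composite_patches(
    binary_maps: Mapping[str, np.ndarray],
    min_colors: int = 5,
    connectivity: Literal[4, 8] = 8,
) -> list[ResponsePatch]:
    """OR-combine per-color binary maps into composite response patches.

    Connected components of the union are kept when (a) at least
    ``min_colors`` colors have suprathreshold pixels inside the component and
    (b) the component does not touch the outermost row/column of the map.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    maps = {c: np.asarray(m).astype(bool) for c, m in binary_maps.items()}
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError("binary maps must share a shape")
    union = np.logical_or.reduce(list(maps.values()))
    labeled, n = ndimage.label(union, structure=_STRUCTS[connectivity])
    patches: list[ResponsePatch] = []
    for lab in range(1, n + 1):
        mask = labeled == lab
        border = (
            mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()
        )
        if border:
            continue
        colors = {c for c, m in maps.items() if (m & mask).any()}
        if len(colors) >= min_colors:
            patches.append(ResponsePatch(mask=mask, contributing_colors=colors))
    return patches


def extract_response_vectors(
    patch: ResponsePatch, maps: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-color normalized (mean 0, population sd 1) vectors over the patch.

    Raises when the patch has < 2 pixels or any map is constant over the
    patch (sd = 0), in which case the caller should exclude the patch.
    """
    if patch.n_pixels < 2:
        raise ValueError("patch needs at least 2 pixels")
    out: dict[str, np.ndarray] = {}
    for color, m in maps.items():
        v = np.asarray(m, dtype=float)[patch.mask]
        sd = v.std()
        if sd == 0:
            raise ValueError(f"constant response over patch for color {color}")
        out[color] = (v - v.mean()) / sd
    patch.response_vectors = out
    return out


# ---------------------------------------------------------------------------
# Two-cluster k-means with exhaustive seeding
# ---------------------------------------------------------------------------

def _sq_dists(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    d = X - c
    return np.einsum("ij,ij->i", d, d)


def _cluster_cost(X: np.ndarray, labels: np.ndarray, squared: bool) -> float:
    cost = 0.0
    for k in (0, 1):
        pts = X[labels == k]
        if len(pts) == 0:
            continue
        mu = pts.mean(axis=0)
        d2 = _sq_dists(pts, mu)
        cost += float(d2.sum() if squared else np.sqrt(d2).sum())
    return cost


def _batch_phase(X: np.ndarray, c0: np.ndarray, c1: np.ndarray) -> np.ndarray:
    labels = None
    for _ in range(200):
        new = (_sq_dists(X, c1) < _sq_dists(X, c0)).astype(int)
        # repair an emptied cluster with the farthest point from the survivor
        if new.min() == new.max():
            survivor = c1 if new[0] == 1 else c0
            far = int(np.argmax(_sq_dists(X, survivor)))
            new[far] = 1 - new[0]
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
        c0 = X[labels == 0].mean(axis=0)
        c1 = X[labels == 1].mean(axis=0)
    return labels


def _online_phase(X: np.ndarray, labels: np.ndarray, squared: bool) -> np.ndarray:
    labels = labels.copy()
    n = len(X)
    for _ in range(200):
        moved = False
        for i in range(n):
            a = labels[i]
            b = 1 - a
            if np.sum(labels == a) == 1:
                continue  # a move may not empty a cluster
            if squared:
                xa = X[labels == a]
                xb = X[labels == b]
                na, nb = len(xa), len(xb)
                mu_a, mu_b = xa.mean(axis=0), xb.mean(axis=0)
                gain = nb / (nb + 1) * float(_sq_dists(X[i:i + 1], mu_b)[0])
                loss = na / (na - 1) * float(_sq_dists(X[i:i + 1], mu_a)[0])
                delta = gain - loss
            else:
                before = _cluster_cost(X, labels, squared)
                labels[i] = b
                delta = _cluster_cost(X, labels, squared) - before
                labels[i] = a
            if delta < -1e-12:
                labels[i] = b
                moved = True
        if not moved:
            break
    return labels


def kmeans_two(
    vectors: np.ndarray, metric: Literal["sqeuclidean", "euclidean"] = "sqeuclidean"
) -> tuple[np.ndarray, float]:
    """Two-cluster k-means with every pair of points as candidate seeds.

    Phase 1 is batch reassignment (all points to nearest centroid, centroids
    recomputed) to convergence; phase 2 reassigns single points whenever the
    move lowers the total within-cluster cost.  The whole procedure is run
    from every one of the C(n, 2) seed pairs and the minimum-cost run is
    returned, which makes the result deterministic and (for small n) the
    global optimum.  ``metric`` selects squared (default) or plain Euclidean
    point-to-centroid cost.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 vectors")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("need at least 2 distinct vectors")
    squared = metric == "sqeuclidean"
    if metric not in ("sqeuclidean", "euclidean"):
        raise ValueError("metric must be 'sqeuclidean' or 'euclidean'")
    best_labels, best_cost = None, np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(X[i], X[j]):
                continue
            labels = _batch_phase(X, X[i].copy(), X[j].copy())
            labels = _online_phase(X, labels, squared)
            cost = _cluster_cost(X, labels, squared)
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_labels = labels
    if best_labels is None:
        raise ValueError("need at least 2 distinct vectors")
    return best_labels, float(best_cost)


def label_clusters(
    bipartition: Mapping[str, int] | tuple[Sequence[str], np.ndarray],
    anchor_color: str = "B",
) -> dict[str, str]:
    """Name the two clusters: the anchor's cluster is "negative".

    Accepts either a color->cluster-id mapping or a (colors, labels) pair.
    The anchor (blue: most negative R_LM and R_Y) defines the negative
    cluster; the other cluster is positive.
    """
    if isinstance(bipartition, Mapping):
        assignment = dict(bipartition)
    else:
        colors, labels = bipartition
        assignment = {c: int(l) for c, l in zip(colors, labels)}
    if anchor_color not in assignment:
        raise ValueError(f"anchor color {anchor_color!r} not in bipartition")
    neg = assignment[anchor_color]
    return {c: ("negative" if l == neg else "positive") for c, l in assignment.items()}


def compute_ipn(assignments: Sequence[Mapping[str, str]], color: str) -> float:
    """I_pn = (N_p - N_n)/(N_p + N_n) for one color across patches."""
    n_p = sum(1 for a in assignments if a.get(color) == "positive")
    n_n = sum(1 for a in assignments if a.get(color) == "negative")
    if n_p + n_n == 0:
        raise ValueError(f"color {color!r} evaluated in no patch")
    return (n_p - n_n) / (n_p + n_n)


def count_outliers(
    patch_labels: Mapping[str, str],
    reference_signs: Mapping[str, float],
    anchor_color: str = "B",
) -> int:
    """Colors (excluding the anchor) whose cluster contradicts the reference sign.

    A color labeled positive should have a positive reference value (R_LM or
    R_Y) and vice versa.  A reference value of exactly 0 supports no
    prediction and is counted as an outlier (and logged).
    """
    n_d = 0
    for color, lab in patch_labels.items():
        if color == anchor_color:
            continue
        if color not in reference_signs:
            raise ValueError(f"no reference value for color {color!r}")
        ref = reference_signs[color]
        if ref == 0:
            logger.warning("color %s has reference value 0: counted as outlier", color)
            n_d += 1
        elif (ref > 0) != (lab == "positive"):
            n_d += 1
    return n_d


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def quadrant_binomial_test(k_concordant: int, k_discordant: int) -> float:
    """Exact two-sided binomial p-value at p = 0.5 (twice the smaller tail)."""
    n = k_concordant + k_discordant
    if n < 1:
        raise ValueError("need at least one observation")
    k = min(k_concordant, k_discordant)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def outlier_t_test(
    nd_rlm: Sequence[float], nd_ry: Sequence[float], paired: bool = True
) -> tuple[float, float]:
    """One-tailed t-test that N_d is smaller under the L-M reference.

    Returns ``(t, p)`` for the alternative mean(nd_rlm) < mean(nd_ry).
    Paired by patch by default (the same patches are scored under both
    references); set ``paired=False`` for the two-sample variant.
    """
    a = np.asarray(nd_rlm, dtype=float)
    b = np.asarray(nd_ry, dtype=float)
    if a.size < 2 or (paired and a.size != b.size):
        raise ValueError("need paired sequences of length >= 2")
    if paired:
        if np.std(a - b, ddof=1) == 0:
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(a, b, alternative="less")
    else:
        res = stats.ttest_ind(a, b, alternative="less")
    return float(res.statistic), float(res.pvalue)


def exclusion_robustness(
    patch_assign_vectors: Sequence[Mapping[str, np.ndarray]],
    stimulus_table: pd.DataFrame,
    excluded_color: str,
    anchor_color: str = "B",
) -> pd.DataFrame:
    """Re-cluster after excluding one color, both for R_LM and for responses.

    For the remaining colors this runs the two-way k-means (a) on the scalar
    R_LM values and (b) on each patch's response vectors, then reports per
    color whether each clustering follows the sign of R_LM.  This checks
    that response clustering is not a mere reflection of how the R_LM values
    themselves split.
    """
    if excluded_color == anchor_color:
        raise ValueError("cannot exclude the anchor color without re-anchoring")
    table = stimulus_table.set_index("label")
    remaining = [c for c in table.index if c != excluded_color]
    if len(remaining) < 3:
        raise ValueError("fewer than 3 colors remain")
    rlm = table.loc[remaining, "R_LM"].to_numpy()

    scalar_labels, _ = kmeans_two(rlm.reshape(-1, 1))
    neg_cluster = scalar_labels[int(np.argmin(rlm))]
    scalar_named = {
        c: ("negative" if l == neg_cluster else "positive")
        for c, l in zip(remaining, scalar_labels)
    }

    follows = {c: [] for c in remaining}
    for vectors in patch_assign_vectors:
        sub = {c: v for c, v in vectors.items() if c != excluded_color}
        if anchor_color not in sub:
            raise ValueError("anchor color missing from patch vectors")
        colors = list(sub)
        labels, _ = kmeans_two(np.array([sub[c] for c in colors]))
        named = label_clusters((colors, labels), anchor_color)
        for c in colors:
            follows[c].append((named[c] == "positive") == (table.loc[c, "R_LM"] > 0))

    rows = []
    for c in remaining:
        rows.append({
            "color": c,
            "R_LM": float(table.loc[c, "R_LM"]),
            "scalar_cluster": scalar_named[c],
            "scalar_follows_sign": (scalar_named[c] == "positive") == (table.loc[c, "R_LM"] > 0),
            "response_follows_sign_fraction": float(np.mean(follows[c])) if follows[c] else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end analysis of one experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Outputs of the per-experiment pipeline."""

    maps: dict[str, np.ndarray]            # per color, plus control
    threshold: float
    patches: list[ResponsePatch]
    assignments: list[dict[str, str]]      # per patch: color -> positive/negative
    nd_rlm: list[int]
    nd_ry: list[int]
    stimulus_table: pd.DataFrame
    anchor_color: str

    @property
    def patch_vectors(self) -> list[dict[str, np.ndarray]]:
        return [p.response_vectors for p in self.patches]


def _registered_means(exp: ImagingExperiment, max_shift: int):
    """Register every trial's pre/response mean frame to the first pre frame."""
    reference = exp.trials[0].pre_mean
    pre_stack = np.stack([t.pre_mean for t in exp.trials])
    resp_stack = np.stack([t.response_mean for t in exp.trials])
    _, pre_reg = register_frames(pre_stack, reference, max_shift)
    _, resp_reg = register_frames(resp_stack, reference, max_shift)
    return pre_reg, resp_reg


def analyze_experiment(
    exp: ImagingExperiment,
    map_method: Literal["svm", "conventional"] = "svm",
    min_colors: int = 5,
    connectivity: Literal[4, 8] = 8,
    max_shift: int = 3,
    regularization: float = 1.0,
    anchor_color: str = "B",
    metric: Literal["sqeuclidean", "euclidean"] = "sqeuclidean",
) -> ExperimentResult:
    """Run the full pipeline on one experiment.

    Registration -> single-condition maps (per color and control) ->
    control-derived threshold -> response regions -> composite patches ->
    normalized response vectors -> exhaustive-seed k-means -> anchored
    cluster labels and outlier counts against sign(R_LM) and sign(R_Y).
    """
    pre_reg, resp_reg = _registered_means(exp, max_shift)
    labels_per_trial = [t.stimulus for t in exp.trials]
    all_labels = exp.colors + [exp.control_label]

    maps: dict[str, np.ndarray] = {}
    for color in all_labels:
        idx = [i for i, lab in enumerate(labels_per_trial) if lab == color]
        if not idx:
            raise ValueError(f"no trials for stimulus {color!r}")
        pre = pre_reg[idx]
        resp = resp_reg[idx]
        if map_method == "svm":
            maps[color] = svm_activation_map(pre, resp, regularization)
        elif map_method == "conventional":
            if np.any(pre == 0):
                raise ValueError("zero pre-stimulation mean at some pixel")
            maps[color] = ((resp - pre) / pre).mean(axis=0)
        else:
            raise ValueError("map_method must be 'svm' or 'conventional'")

    threshold = noise_threshold(maps[exp.control_label])
    binary = {c: response_regions(maps[c], threshold) for c in exp.colors}
    patches = composite_patches(binary, min_colors=min_colors, connectivity=connectivity)

    table = exp.stimulus_table.set_index("label")
    rlm_signs = table["R_LM"].to_dict()
    ry_signs = table["R_Y"].to_dict()

    kept: list[ResponsePatch] = []
    assignments: list[dict[str, str]] = []
    nd_rlm: list[int] = []
    nd_ry: list[int] = []
    color_maps = {c: maps[c] for c in exp.colors}
    for patch in patches:
        try:
            vectors = extract_response_vectors(patch, color_maps)
        except ValueError as exc:
            logger.warning("patch excluded: %s", exc)
            continue
        colors = list(vectors)
        labels, _ = kmeans_two(np.array([vectors[c] for c in colors]), metric=metric)
        named = label_clusters((colors, labels), anchor_color)
        kept.append(patch)
        assignments.append(named)
        nd_rlm.append(count_outliers(named, rlm_signs, anchor_color))
        nd_ry.append(count_outliers(named, ry_signs, anchor_color))

    return ExperimentResult(
        maps=maps,
        threshold=threshold,
        patches=kept,
        assignments=assignments,
        nd_rlm=nd_rlm,
        nd_ry=nd_ry,
        stimulus_table=exp.stimulus_table,
        anchor_color=anchor_color,
    )


def pool_patch_assignments(
    results: Sequence[ExperimentResult],
) -> pd.DataFrame:
    """Pool patches across experiments into a per-color I_pn table.

    Returns a DataFrame with columns ``color, I_pn, R_LM, R_Y, n_patches``
    covering every color present in any experiment.
    """
    if not results:
        raise ValueError("no results to pool")
    assignments = [a for r in results for a in r.assignments]
    tables = pd.concat([r.stimulus_table for r in results]).drop_duplicates("label")
    rows = []
    for _, row in tables.iterrows():
        color = row["label"]
        n = sum(1 for a in assignments if color in a)
        if n == 0:
            continue
        rows.append({
            "color": color,
            "I_pn": compute_ipn(assignments, color),
            "R_LM": row["R_LM"],
            "R_Y": row["R_Y"],
            "n_patches": n,
        })
    return pd.DataFrame(rows)
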