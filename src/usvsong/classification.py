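"""Syllable typology: 5- and 13-type rule-based classification and validation.

The 5-type scheme orders by precedence: **Jumps** (any >= 20 kHz frequency
jump) > **Turns** (any qualifying direction reversal) > **Up** / **Down**
(|slope| >= 0.05 kHz/ms) > **Simple**.  The 13-type scheme refines Jumps by
where (first/second half) and in which direction the jumps go, Turns by the
shape of the reversal, and Simple by slope sign:

====== ==========================================================
code   definition
====== ==========================================================
SFL    simple, |slope| < 0.05 kHz/ms, no jumps, no turns
SDN    simple, downward slope <= -0.05 kHz/ms
SUP    simple, upward slope >= 0.05 kHz/ms
TDU    one turn, falling then rising (U-shape)
TUD    one turn, rising then falling
TRS    two or more turns
JED    one jump, down, in the first half
JLD    one jump, down, in the second half
JEU    one jump, up, in the first half
JLU    one jump, up, in the second half
JUD    two jumps, first up then down
JDU    two jumps, first down then up
JPS    more than two jumps (or two jumps in the same direction)
====== ==========================================================

Typology validation clusters *standardised* contours — every syllable
stretched to 50 ms and shifted to a mean frequency of 80 kHz — by dynamic
time warping (DTW) distance, and scores agreement between the clustering and
the rule-based labels by the adjusted Rand index with a label-permutation
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import PixelTrace
from .features import SLOPE_THRESHOLD, SyllableFeatures, syllable_features
from .profiles import TYPE13, TYPE13_TO_TYPE5

__all__ = [
    "classify5",
    "classify13",
    "classify_syllables",
    "standardize_trace",
    "StandardizedTrace",
    "dtw_distance",
    "validate_typology",
    "pca_types",
    "STANDARD_LENGTH_MS",
    "STANDARD_MEAN_KHZ",
    "STANDARD_N_POINTS",
]

STANDARD_LENGTH_MS = 50.0
STANDARD_MEAN_KHZ = 80.0
STANDARD_N_POINTS = 100  # 0.5 ms pitch over 50 ms, matching the synthesis default


def classify5(features: SyllableFeatures) -> str:
    """5-type label with precedence Jumps > Turns > Up > Down > Simple."""
    if features.n_jumps > 0:
        return "Jump"
    if features.n_turns > 0:
        return "Turn"
    if features.freq_slope >= SLOPE_THRESHOLD:
        return "Up"
    if features.freq_slope <= -SLOPE_THRESHOLD:
        return "Down"
    return "Simple"


def classify13(features: SyllableFeatures) -> str:
    """13-type label from jump events, turn events and slope.

    Early/late is decided against the temporal midpoint; an event exactly at
    0.5 counts as late.  Two jumps in the same direction fall into the
    multi-jump catch-all JPS along with everything beyond two jumps.
    """
    jumps = features.jumps
    if len(jumps) > 2:
        return "JPS"
    if len(jumps) == 2:
        d1, d2 = jumps[0].direction, jumps[1].direction
        if d1 == d2:
            return "JPS"
        return "JUD" if d1 == "up" else "JDU"
    if len(jumps) == 1:
        ev = jumps[0]
        early = ev.position < 0.5
        if ev.direction == "up":
            return "JEU" if early else "JLU"
        return "JED" if early else "JLD"
    turns = features.turns
    if len(turns) >= 2:
        return "TRS"
    if len(turns) == 1:
        return "TDU" if turns[0].shape == "down-up" else "TUD"
    if features.freq_slope >= SLOPE_THRESHOLD:
        return "SUP"
    if features.freq_slope <= -SLOPE_THRESHOLD:
        return "SDN"
    return "SFL"


def classify_syllables(syllables) -> pd.DataFrame:
    """Label table ``syllable_id, type5, type13`` for a syllable list.

    The 13 -> 5 projection is definitional, so ``type5`` always equals the
    family of ``type13``.
    """
    rows = []
    for s in syllables:
        ft = syllable_features(s.trace)
        t13 = classify13(ft)
        rows.append((s.syllable_id, TYPE13_TO_TYPE5[t13], t13))
    return pd.DataFrame(rows, columns=["syllable_id", "type5", "type13"])


@dataclass(frozen=True)
class StandardizedTrace:
    """Fixed-length contour: 50 ms span, mean frequency shifted to 80 kHz."""

    freqs_khz: np.ndarray
    source_id: str = ""

    @property
    def n(self) -> int:
        return self.freqs_khz.size


def standardize_trace(trace: PixelTrace, n_points: int = STANDARD_N_POINTS,
                      target_ms: float = STANDARD_LENGTH_MS,
                      target_khz: float = STANDARD_MEAN_KHZ) -> StandardizedTrace:
    """Stretch a contour to the standard length and shift to the standard mean.

    Linear interpolation onto ``n_points`` equally spaced samples spanning
    ``target_ms`` (the time axis is immaterial afterwards — only the shape
    remains), then an additive shift making the mean frequency exactly
    ``target_khz``.
    """
    if trace.n < 2:
        raise ValueError("cannot standardize a single-sample trace")
    x = (trace.times_ms - trace.onset_ms) / trace.duration_ms
    xi = np.linspace(0.0, 1.0, n_points)
    f = np.interp(xi, x, trace.freqs_khz)
    f = f + (target_khz - f.mean())
    return StandardizedTrace(freqs_khz=f, source_id=trace.element_id)


def dtw_distance(a: StandardizedTrace, b: StandardizedTrace) -> float:
    """Dynamic-time-warping distance between two standardized contours.

    Classic dynamic programme with the symmetric unit-weight step pattern,
    local cost |freq_a - freq_b|, no warping window, no path-length
    normalisation: the returned value is the summed frequency difference
    (kHz) of the aligned element pairs along the optimal path (so two flat
    contours 1 kHz apart at 100 points are 100 apart).  Symmetric and zero
    for identical contours; DTW violates the triangle inequality, so this is
    a pseudo-metric only.
    """
    fa, fb = a.freqs_khz, b.freqs_khz
    if fa.size != fb.size:
        raise ValueError("standardized traces must have equal length")
    n, m = fa.size, fb.size
    cost = np.abs(fa[:, None] - fb[None, :])
    acc = np.empty((n, m))
    acc[0, :] = np.cumsum(cost[0, :])
    acc[1:, 0] = acc[0, 0] + np.cumsum(cost[1:, 0])
    for i in range(1, n):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i]
        for j in range(1, m):
            row[j] = ci[j] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[n - 1, m - 1])


def _pairwise_dtw(stds) -> np.ndarray:
    n = len(stds)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(stds[i], stds[j])
    return d


def validate_typology(syllables, labels, n_permutations: int = 199, rng=None,
                      linkage_method: str = "average"):
    """Cluster standardized contours by DTW and score agreement with the labels.

    Hierarchical clustering (average linkage) of the pairwise DTW matrix is
    cut at k = number of distinct labels; agreement between the cut and the
    rule-based labels is the adjusted Rand index (ARI), with significance from
    a label-permutation null.  Returns ``(distance_matrix, linkage, ari,
    p_value)``.
    """
    from sklearn.metrics import adjusted_rand_score

    labels = list(labels)
    if len(labels) != len(syllables):
        raise ValueError("one label per syllable required")
    if len(set(labels)) < 2:
        raise ValueError("need at least two distinct types to validate")
    if rng is None:
        rng = np.random.default_rng()
    stds = [standardize_trace(s.trace) for s in syllables]
    dmat = _pairwise_dtw(stds)
    z = hierarchy.linkage(squareform(dmat, checks=False), method=linkage_method)
    k = len(set(labels))
    cut = hierarchy.fcluster(z, t=k, criterion="maxclust")
    ari = adjusted_rand_score(labels, cut)
    perm = np.empty(n_permutations)
    lab = np.asarray(labels, dtype=object)
    for b in range(n_permutations):
        perm[b] = adjusted_rand_score(rng.permutation(lab), cut)
    p = (1 + np.sum(perm >= ari)) / (n_permutations + 1)
    return dmat, z, float(ari), float(p)


def pca_types(feat_df: pd.DataFrame, jump_only: bool, label_col: str = "type13"):
    """Principal components of standardized syllable parameters, split by family.

    Jump types on one hand and non-jump types on the other occupy different
    parameter regimes (a 20 kHz step dwarfs every slope), so the analysis runs
    separately for each: pass ``jump_only=True`` for the J* types.  Constant
    features are dropped with a warning.  Returns ``(scores_df, loadings_df)``;
    loadings rows are orthonormal component vectors.
    """
    import warnings

    from sklearn.decomposition import PCA

    jump_types = {t for t, f in TYPE13_TO_TYPE5.items() if f == "Jump"}
    mask = feat_df[label_col].isin(jump_types) if jump_only \
        else ~feat_df[label_col].isin(jump_types)
    sub = feat_df[mask]
    feat_cols = ["duration", "freq_sta", "freq_slope", "freq_min", "freq_band",
                 "freq_cog", "n_jumps", "n_turns"]
    x = sub[feat_cols].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two syllables for a PCA")
    sd = x.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(feat_cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant features {dropped}")
    if keep.sum() < 2:
        raise ValueError("fewer than two non-constant features")
    cols = [c for c, k in zip(feat_cols, keep) if k]
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(len(cols), x.shape[0] - 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(xs)
    score_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(n_comp)],
                            index=sub.index)
    score_df[label_col] = sub[label_col].values
    loadings = pd.DataFrame(pca.components_, columns=cols,
                            index=[f"PC{i+1}" for i in range(n_comp)])
    return score_df, loadings
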