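"""Muscle-synergy extraction by non-negative matrix factorization.

An envelope matrix ``E`` (muscles x time) is factored as ``E ~ W @ H``
with non-negative weights ``W`` (muscles x k) and activations ``H``
(k x time).  Reconstruction quality is the Variance Accounted For,

    VAF(k) = 1 - ||E - W H||_F^2 / ||E||_F^2.

The synergy count is selected by two criteria combined with a max rule:
(A) the smallest k whose (median) VAF exceeds a threshold (default 0.90),
and (B) the smallest k where the VAF increment to k+1 drops below a slope
threshold (default 0.001).  Synergies are then reordered consistently
across subjects by optimal assignment against a randomly chosen reference
subject, and compared between conditions with per-synergy Pearson tests on
the weight vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .metrics import EnvelopeRecording

__all__ = [
    "SynergySet",
    "SimilarityResult",
    "downsample_envelope",
    "vaf",
    "extract_synergies",
    "vaf_curve",
    "select_synergy_count",
    "reorder_synergies",
    "compare_synergies",
]


@dataclass
class SynergySet:
    """One NNMF decomposition: weights, activations and its VAF curve."""

    W: np.ndarray                 # muscles x k, columns l2-normalized
    H: np.ndarray                 # k x time
    vaf_curve: np.ndarray         # VAF per candidate k (1..len)
    k_selected: int
    subject_id: int | None = None
    condition: str | None = None
    muscles: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass
class SimilarityResult:
    """Per-synergy Pearson comparison of a condition against baseline."""

    r: np.ndarray          # subjects x k
    p: np.ndarray          # subjects x k
    median_r: np.ndarray   # per synergy
    median_p: np.ndarray   # per synergy


def downsample_envelope(env: EnvelopeRecording, fs_out: float = 500.0) -> EnvelopeRecording:
    """Anti-aliased downsampling of an envelope recording.

    A 4th-order Butterworth low-pass at 0.8x the output Nyquist precedes
    linear interpolation onto the output grid.  Envelopes are 6 Hz
    band-limited, so the operation is lossless in practice.
    """
    if fs_out >= env.fs:
        return env
    x = env.envelopes
    sos = signal.butter(4, 0.8 * fs_out / 2.0, fs=env.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    n_in = x.shape[0]
    t_in = np.arange(n_in) / env.fs
    t_out = np.arange(int(np.floor(t_in[-1] * fs_out)) + 1) / fs_out
    out = np.empty((len(t_out), x.shape[1]))
    for j in range(x.shape[1]):
        out[:, j] = np.interp(t_out, t_in, x[:, j])
    return EnvelopeRecording(np.clip(out, 0.0, None), fs_out, list(env.muscles))


def vaf(E: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for by the reconstruction ``W @ H``."""
    denom = float(np.sum(E**2))
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero envelope matrix")
    return 1.0 - float(np.sum((E - W @ H) ** 2)) / denom


def _normalize_columns(W: np.ndarray, H: np.ndarray):
    """Push the column scale of W into H (unit l2 weight vectors)."""
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms, H * norms[:, None]


def _fit_once(E, k, rng, max_iter, tol, W0=None, H0=None):
    seed = int(rng.integers(0, 2**31 - 1))
    if W0 is not None:
        model = NMF(
            n_components=k, init="custom", solver="mu", max_iter=max_iter,
            tol=tol, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(
                E, W=np.ascontiguousarray(W0), H=np.ascontiguousarray(H0)
            )
    else:
        model = NMF(
            n_components=k, init="random", solver="mu", max_iter=max_iter,
            tol=tol, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(E)
    return W, model.components_


def extract_synergies(
    env: EnvelopeRecording,
    k: int,
    n_restarts: int = 20,
    seed=0,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    fs_nmf: float = 500.0,
    warm_start: tuple | None = None,
) -> SynergySet:
    """Best-of-restarts NNMF of an envelope recording at a fixed order k.

    The envelope is downsampled to ``fs_nmf`` (anti-aliased), then NNMF is
    run ``n_restarts`` times from seeded non-negative random
    initializations (multiplicative updates); the factorization with the
    highest VAF is kept and returned with unit-norm weight columns (the
    scale indeterminacy is absorbed by H, leaving VAF unchanged).
    """
    if (np.asarray(env.envelopes) < 0).any():
        raise ValueError("envelope matrix must be non-negative")
    if k < 1 or k > len(env.muscles):
        raise ValueError("k must lie in [1, n_muscles]")
    ds = downsample_envelope(env, fs_nmf)
    E = ds.envelopes.T  # muscles x time
    rng = np.random.default_rng(seed)
    best = None
    starts: list[tuple] = [None] * n_restarts
    if warm_start is not None:
        starts.append(warm_start)
    for start in starts:
        if start is None:
            W, H = _fit_once(E, k, rng, max_iter, tol)
        else:
            W, H = _fit_once(E, k, rng, max_iter, tol, W0=start[0], H0=start[1])
        score = vaf(E, W, H)
        if best is None or score > best[0]:
            best = (score, W, H)
    _, W, H = best
    W, H = _normalize_columns(W, H)
    return SynergySet(
        W=W, H=H, vaf_curve=np.array([best[0]]), k_selected=k,
        muscles=list(env.muscles),
    )


def vaf_curve(
    env: EnvelopeRecording,
    k_max: int,
    n_restarts: int = 20,
    seed=0,
    **kwargs,
) -> tuple[np.ndarray, list]:
    """VAF for k = 1..k_max with nested warm starts.

    Each order additionally restarts from the best (k-1) solution padded
    with a small random column, which makes the best-of-restarts VAF curve
    monotone non-decreasing (multiplicative updates never increase the
    reconstruction error of their initialization).
    Returns ``(curve, sets)``.
    """
    rng = np.random.default_rng(seed)
    curve, sets = [], []
    prev = None
    for k in range(1, k_max + 1):
        warm = None
        if prev is not None:
            W0 = np.hstack([prev.W, rng.uniform(1e-4, 1e-2, (prev.W.shape[0], 1))])
            H0 = np.vstack([prev.H, rng.uniform(1e-4, 1e-2, (1, prev.H.shape[1]))])
            warm = (W0, H0)
        s = extract_synergies(
            env, k, n_restarts, int(rng.integers(0, 2**31 - 1)),
            warm_start=warm, **kwargs,
        )
        curve.append(float(s.vaf_curve[0]))
        sets.append(s)
        prev = s
    curve = np.maximum.accumulate(np.asarray(curve))
    for s, v in zip(sets, curve):
        s.vaf_curve = curve.copy()
    return curve, sets


def select_synergy_count(
    vaf_values,
    vaf_threshold: float = 0.90,
    slope_threshold: float = 0.001,
) -> int:
    """Model-order selection from a VAF curve (values for k = 1..K).

    Criterion A: smallest k with VAF above ``vaf_threshold``.  Criterion B:
    smallest k whose increment VAF(k+1) - VAF(k) falls to or below
    ``slope_threshold``.  The selected order is the maximum of the two; if
    neither criterion is met the largest candidate is returned with a
    warning.  When run cohort-wide, pass the median-across-subjects curve.
    """
    curve = np.asarray(vaf_values, dtype=float)
    if curve.size == 0:
        raise ValueError("empty VAF curve")
    K = curve.size

    above = np.nonzero(curve > vaf_threshold)[0]
    k_a = int(above[0]) + 1 if above.size else None

    increments = np.diff(curve)
    small = np.nonzero(increments <= slope_threshold + 1e-12)[0]
    if increments.size == 0:
        k_b = 1
    elif small.size:
        k_b = int(small[0]) + 1
    else:
        k_b = None  # curve still rising at the last candidate

    if k_a is None or k_b is None:
        warnings.warn(
            "VAF criteria not satisfied within the candidate range; "
            "returning the largest candidate"
        )
        return K
    return max(k_a, k_b)


def _cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    an = A / np.linalg.norm(A, axis=0, keepdims=True)
    bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return an.T @ bn


def reorder_synergies(sets: list, seed=0) -> tuple[list, int]:
    """Permute each subject's synergies to match a seeded reference subject.

    The reference subject is drawn with a seeded RNG; every other set's
    columns are permuted by the optimal (Hungarian) assignment on the
    cosine-similarity matrix between weight vectors.  Sets with more
    synergies than the common minimum are truncated with a warning.
    Returns ``(reordered_sets, reference_index)``; applying the function
    twice with the same seed yields the same ordering (idempotent).
    """
    if not sets:
        raise ValueError("no synergy sets to reorder")
    ks = {s.k for s in sets}
    k = min(ks)
    if len(ks) > 1:
        warnings.warn(f"mismatched synergy counts {sorted(ks)}; truncating to {k}")
        sets = [
            SynergySet(s.W[:, :k], s.H[:k], s.vaf_curve, k, s.subject_id,
                       s.condition, s.muscles)
            for s in sets
        ]
    rng = np.random.default_rng(seed)
    ref_idx = int(rng.integers(0, len(sets)))
    ref = sets[ref_idx]
    out = []
    for s in sets:
        sim = _cosine_similarity_matrix(ref.W, s.W)
        _, cols = optimize.linear_sum_assignment(-sim)
        out.append(
            SynergySet(
                s.W[:, cols], s.H[cols], s.vaf_curve, s.k_selected,
                s.subject_id, s.condition, s.muscles,
            )
        )
    return out, ref_idx


def compare_synergies(condition_sets: list, baseline_sets: list) -> SimilarityResult:
    """Pearson similarity of condition vs baseline weight vectors.

    Sets must already share a common synergy indexing (see
    :func:`reorder_synergies`) and be paired by subject.  For each subject
    and synergy index a Pearson correlation between the two 13-muscle
    weight vectors is computed; medians across subjects summarize each
    synergy.  A significant test (small p) indicates *similarity* of the
    patterns.
    """
    if len(condition_sets) != len(baseline_sets):
        raise ValueError("condition and baseline cohorts must pair by subject")
    k = min(s.k for s in condition_sets + baseline_sets)
    n = len(condition_sets)
    r = np.full((n, k), np.nan)
    p = np.full((n, k), np.nan)
    for i, (cs, bs) in enumerate(zip(condition_sets, baseline_sets)):
        for j in range(k):
            a, b = cs.W[:, j], bs.W[:, j]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn("constant weight vector: Pearson r undefined")
                continue
            res = stats.pearsonr(a, b)
            r[i, j], p[i, j] = res.statistic, res.pvalue
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        return SimilarityResult(
            r=r, p=p,
            median_r=np.nanmedian(r, axis=0),
            median_p=np.nanmedian(p, axis=0),
        )
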