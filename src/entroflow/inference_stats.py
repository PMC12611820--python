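"""Generalization, significance, and all-pairs analysis for mixed-flow fits.

Provides the validation stack around the pairwise predictor:

* hold-out validation (fit on the first 80% of a pair of series, test on
  the remainder),
* randomized cross-validation over contiguous circular 80/20 splits,
* circular-shift permutation testing (surrogates rotate the source series
  by random offsets, destroying cross-alignment while preserving its
  marginal distribution and autocorrelation; the fit is redone per
  surrogate),
* Benjamini-Hochberg FDR and Bonferroni multiple-comparison control,
* the full directional region × region analysis with joint FDR correction
  across all off-diagonal pairs (pooled across recordings when several are
  supplied together).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from .density_estimation import fit_kde
from .flow_core import FlowParams
from .flow_fitting import (
    FitConfig,
    FitResult,
    _as_series,
    _fit_core,
    fit_pair,
    flow_features,
    predict_series,
    r_squared,
    standardize_pair,
)

__all__ = [
    "ValidationReport",
    "PermutationResult",
    "PairwiseConfig",
    "PairwiseResult",
    "holdout_validate",
    "random_cv",
    "circular_permutation_test",
    "bh_fdr",
    "bonferroni",
    "pairwise_analysis",
]

log = logging.getLogger("entroflow")


@dataclass(frozen=True)
class ValidationReport:
    """Per-split train/test R² and the train − test generalization gap."""

    train_r2: np.ndarray
    test_r2: np.ndarray
    splits: List[dict]
    mean_gap: float
    sd_gap: float


@dataclass(frozen=True)
class PermutationResult:
    """Circular-shift permutation test outcome for one ordered pair."""

    empirical_r2: float
    surrogate_r2: np.ndarray
    p_value: float
    offsets: np.ndarray
    seed: int
    n_perm: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PairwiseConfig:
    """Settings for the all-pairs directional analysis."""

    n_perm: int = 1000
    q: float = 0.01
    bonferroni_alpha: float = 0.01
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass(frozen=True)
class PairwiseResult:
    """Directional R², p-value, and significance matrices over region pairs.

    Matrices are indexed by ``labels`` in input order; diagonals are NaN
    (masks False). ``sig_fdr`` is the BH mask at level ``q`` applied jointly
    across all off-diagonal cells of every recording in the invocation.
    """

    labels: List[str]
    r2: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    sig_fdr: np.ndarray
    sig_bonferroni: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    skipped: List[dict]
    seed: int
    n_perm: int
    q: float


def _prepare_split(a_train, b_train, a_test, b_test, config: FitConfig):
    """Apply training-segment z-scoring (if configured) to all four segments."""
    if config.standardize:
        ma, sa = float(np.mean(a_train)), float(np.std(a_train))
        mb, sb = float(np.mean(b_train)), float(np.std(b_train))
        if sa == 0 or sb == 0:
            raise ValueError("training segment is constant")
        a_train = (a_train - ma) / sa
        b_train = (b_train - mb) / sb
        a_test = (a_test - ma) / sa
        b_test = (b_test - mb) / sb
    return a_train, b_train, a_test, b_test


def _fit_and_eval(a_train, b_train, a_test, b_test, config: FitConfig):
    """Fit on the training segment, evaluate R² on train and held-out test.

    The KDE, feature means, and z-scoring statistics are all derived from
    the training segment only.
    """
    a_train, b_train, a_test, b_test = _prepare_split(
        a_train, b_train, a_test, b_test, config
    )
    model = fit_kde(a_train, rule=config.bandwidth_rule)
    f_s, f_e = flow_features(a_train, model)
    alpha, beta, _, train_r2, _, _ = _fit_core(a_train, b_train, f_s, f_e, config)
    pred = predict_series(a_test, model, FlowParams(alpha, beta))
    return train_r2, r_squared(pred, b_test)


def holdout_validate(
    xA, xB, train_frac: float = 0.8, config: Optional[FitConfig] = None
) -> ValidationReport:
    """Fit on the first ``train_frac`` of the series, test on the remainder."""
    config = config or FitConfig()
    a = _as_series(xA, "xA")
    b = _as_series(xB, "xB")
    if a.size != b.size:
        raise ValueError("xA and xB must have equal length")
    T = a.size
    n_train = int(math.floor(train_frac * T))
    n_test = T - n_train
    if n_test < 10:
        raise ValueError(
            f"test segment too short ({n_test} points); need at least 10"
        )
    train_r2, test_r2 = _fit_and_eval(
        a[:n_train], b[:n_train], a[n_train:], b[n_train:], config
    )
    gap = train_r2 - test_r2
    return ValidationReport(
        train_r2=np.array([train_r2]),
        test_r2=np.array([test_r2]),
        splits=[{"kind": "holdout", "n_train": n_train, "n_test": n_test}],
        mean_gap=gap,
        sd_gap=float("nan"),
    )


def random_cv(
    xA,
    xB,
    n_splits: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    config: Optional[FitConfig] = None,
    contiguous: bool = True,
) -> ValidationReport:
    """Randomized cross-validation over independent 80/20 splits.

    Each split draws a random circular offset defining a contiguous test
    block (the remaining points, contiguous up to wrap-around, train);
    ``contiguous=False`` switches to pointwise random splits instead.
    """
    config = config or FitConfig()
    a = _as_series(xA, "xA")
    b = _as_series(xB, "xB")
    if a.size != b.size:
        raise ValueError("xA and xB must have equal length")
    T = a.size
    n_train = int(math.floor(train_frac * T))
    n_test = T - n_train
    if n_test < 10:
        raise ValueError(f"test segment too short ({n_test} points)")
    rng = np.random.default_rng(seed)
    train_scores, test_scores, splits = [], [], []
    for _ in range(n_splits):
        if contiguous:
            off = int(rng.integers(0, T))
            ar, br = np.roll(a, -off), np.roll(b, -off)
            a_tr, b_tr = ar[n_test:], br[n_test:]
            a_te, b_te = ar[:n_test], br[:n_test]
            splits.append({"kind": "circular", "test_start": off, "n_test": n_test})
        else:
            idx = rng.permutation(T)
            test_idx, train_idx = np.sort(idx[:n_test]), np.sort(idx[n_test:])
            a_tr, b_tr = a[train_idx], b[train_idx]
            a_te, b_te = a[test_idx], b[test_idx]
            splits.append({"kind": "pointwise", "n_test": n_test})
        tr, te = _fit_and_eval(a_tr, b_tr, a_te, b_te, config)
        train_scores.append(tr)
        test_scores.append(te)
    train_r2 = np.asarray(train_scores)
    test_r2 = np.asarray(test_scores)
    gaps = train_r2 - test_r2
    return ValidationReport(
        train_r2=train_r2,
        test_r2=test_r2,
        splits=splits,
        mean_gap=float(np.mean(gaps)),
        sd_gap=float(np.std(gaps, ddof=1)) if n_splits > 1 else float("nan"),
    )


def _segment_bounds(T: int, sessions: Optional[Sequence[int]]) -> List[Tuple[int, int]]:
    if not sessions:
        return [(0, T)]
    bounds = [0, *sorted(int(s) for s in sessions), T]
    if bounds[1] <= 0 or bounds[-2] >= T:
        raise ValueError("session boundaries must lie strictly inside the series")
    return list(zip(bounds[:-1], bounds[1:]))


def circular_permutation_test(
    xA,
    xB,
    n_perm: int = 1000,
    seed: int = 0,
    config: Optional[FitConfig] = None,
    sessions: Optional[Sequence[int]] = None,
    conservative: bool = False,
) -> PermutationResult:
    """Significance of a directed fit against circular-shift surrogates.

    Each surrogate rotates the *source* series by a uniform random offset in
    [1, T−1] (independently per session when boundaries are given) and refits
    (α, β) in full. A circular shift leaves the source's sample set — hence
    its KDE, z-scoring statistics, and per-sample feature values — unchanged,
    so the features are rotated with the series and only the coefficient
    solve is repeated; this is identical to a from-scratch refit.

    ``p = #{surrogate R² ≥ empirical R²} / n_perm`` by default;
    ``conservative=True`` uses (k + 1)/(n_perm + 1).
    """
    config = config or FitConfig()
    a = _as_series(xA, "xA", min_len=100)
    b = _as_series(xB, "xB", min_len=100)
    if a.size != b.size:
        raise ValueError("xA and xB must have equal length")
    T = a.size
    if config.standardize:
        a, b, _ = standardize_pair(a, b)
    model = fit_kde(a, rule=config.bandwidth_rule)
    f_s, f_e = flow_features(a, model)
    emp_r2 = _fit_core(a, b, f_s, f_e, config)[3]

    segments = _segment_bounds(T, sessions)
    rng = np.random.default_rng(seed)
    offsets = np.empty((n_perm, len(segments)), dtype=int)
    surrogate = np.empty(n_perm)
    for i in range(n_perm):
        a_s = np.empty_like(a)
        fs_s = np.empty_like(f_s)
        fe_s = np.empty_like(f_e)
        for j, (lo, hi) in enumerate(segments):
            k = int(rng.integers(1, hi - lo))
            offsets[i, j] = k
            a_s[lo:hi] = np.roll(a[lo:hi], k)
            fs_s[lo:hi] = np.roll(f_s[lo:hi], k)
            fe_s[lo:hi] = np.roll(f_e[lo:hi], k)
        surrogate[i] = _fit_core(a_s, b, fs_s, fe_s, config)[3]

    k_ge = int(np.sum(surrogate >= emp_r2))
    p = (k_ge + 1) / (n_perm + 1) if conservative else k_ge / n_perm
    return PermutationResult(
        empirical_r2=emp_r2,
        surrogate_r2=surrogate,
        p_value=float(p),
        offsets=offsets.squeeze(),
        seed=seed,
        n_perm=n_perm,
    )


def bh_fdr(p_values, q: float = 0.01) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns (rejection mask, adjusted p-values); adjusted p-values are
    monotone nondecreasing in the raw p-values. Empty input yields empty
    output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def bonferroni(p_values, alpha: float = 0.01) -> np.ndarray:
    """Bonferroni rejection mask: reject iff p ≤ alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p <= alpha / p.size


def _extract_regions(rec) -> Tuple[List[str], List[np.ndarray], Optional[List[int]]]:
    """Accept a RegionalRecording-like object or a {label: series} mapping."""
    if hasattr(rec, "labels") and hasattr(rec, "series"):
        sessions = list(getattr(rec, "sessions", None) or []) or None
        return list(rec.labels), [np.asarray(rec.series(l), float) for l in rec.labels], sessions
    if isinstance(rec, dict):
        labels = list(rec.keys())
        return labels, [np.asarray(rec[l], float) for l in labels], None
    raise TypeError("expected a RegionalRecording or a {label: series} mapping")


def pairwise_analysis(
    recordings,
    config: Optional[PairwiseConfig] = None,
) -> Union[PairwiseResult, List[PairwiseResult]]:
    """Directional analysis of every ordered region pair.

    Fits (α, β) for each ordered pair, runs the circular-shift permutation
    test per pair, and applies BH-FDR (level ``config.q``) jointly across
    all off-diagonal cells — pooled over all recordings passed in one call,
    matching a family of tests spanning pairs and animals. Constant-signal
    regions are skipped with a logged record rather than an error.

    Returns a single PairwiseResult for a single recording, else a list.
    """
    config = config or PairwiseConfig()
    single = not isinstance(recordings, (list, tuple))
    recs = [recordings] if single else list(recordings)
    ss = np.random.SeedSequence(config.seed)

    per_rec = []
    pooled_p: List[float] = []
    pooled_slots: List[Tuple[int, int, int]] = []
    for r_idx, rec in enumerate(recs):
        labels, series, sessions = _extract_regions(rec)
        R = len(labels)
        if R < 2:
            raise ValueError("need at least 2 regions")
        lengths = {s.size for s in series}
        if len(lengths) != 1:
            raise ValueError("all regions must have equal length")
        shape = (R, R)
        r2 = np.full(shape, np.nan)
        p_raw = np.full(shape, np.nan)
        a_mat = np.full(shape, np.nan)
        b_mat = np.full(shape, np.nan)
        skipped: List[dict] = []
        for i in range(R):
            for j in range(R):
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                if i == j:
                    continue
                if np.std(series[i]) == 0 or np.std(series[j]) == 0:
                    which = labels[i] if np.std(series[i]) == 0 else labels[j]
                    log.info(
                        "skipping pair %s->%s: constant region %s",
                        labels[i], labels[j], which,
                    )
                    skipped.append(
                        {"source": labels[i], "target": labels[j], "reason": "constant region"}
                    )
                    continue
                perm = circular_permutation_test(
                    series[i],
                    series[j],
                    n_perm=config.n_perm,
                    seed=child_seed,
                    config=config.fit,
                    sessions=sessions,
                )
                fit = fit_pair(
                    series[i], series[j], config=config.fit,
                    source=labels[i], target=labels[j],
                )
                log.info(
                    "fitted %s->%s: R2=%.4f p=%.4g alpha=%.4g beta=%.4g (seed %d)",
                    labels[i], labels[j], fit.r2, perm.p_value,
                    fit.alpha, fit.beta, child_seed,
                )
                r2[i, j] = fit.r2
                p_raw[i, j] = perm.p_value
                a_mat[i, j] = fit.alpha
                b_mat[i, j] = fit.beta
                pooled_p.append(perm.p_value)
                pooled_slots.append((r_idx, i, j))
        per_rec.append((labels, r2, p_raw, a_mat, b_mat, skipped))

    mask_fdr, p_adj_flat = bh_fdr(pooled_p, q=config.q)
    mask_bonf = bonferroni(pooled_p, alpha=config.bonferroni_alpha)

    results: List[PairwiseResult] = []
    for r_idx, (labels, r2, p_raw, a_mat, b_mat, skipped) in enumerate(per_rec):
        R = len(labels)
        p_adj = np.full((R, R), np.nan)
        sig_f = np.zeros((R, R), dtype=bool)
        sig_b = np.zeros((R, R), dtype=bool)
        for flat_idx, (ri, i, j) in enumerate(pooled_slots):
            if ri != r_idx:
                continue
            p_adj[i, j] = p_adj_flat[flat_idx]
            sig_f[i, j] = mask_fdr[flat_idx]
            sig_b[i, j] = mask_bonf[flat_idx]
        results.append(
            PairwiseResult(
                labels=labels,
                r2=r2,
                p_raw=p_raw,
                p_adj=p_adj,
                sig_fdr=sig_f,
                sig_bonferroni=sig_b,
                alpha=a_mat,
                beta=b_mat,
                skipped=skipped,
                seed=config.seed,
                n_perm=config.n_perm,
                q=config.q,
            )
        )
    return results[0] if single else results
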