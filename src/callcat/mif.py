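"""Informative spectrotemporal fragment model.

Training pipeline: sample rectangular candidate patches from target-call
cochleagrams; score each patch against every training call by its maximum
normalized cross-correlation (r_max, time-sliding only, anchored at the
patch's native CF rows); pick per-patch detection thresholds maximizing
mutual information (MI) with the class label; weight each patch by the
log-likelihood ratio of its binary detection; greedily assemble a small,
minimally redundant ensemble (<= 20 fragments); repeat on the depleted
candidate pool for several disjoint instantiations.

Decision pipeline: the feature-detection (FD) response of an ensemble is
the weight-normalized sum of detected fragments, in [0, 1]; a winner-take-
all (WTA) stage compares target vs distractor FD responses and maps the
winner to a Go probability (0.9 / 0.1 by default, modelling lapse and guess
rates); a stochastic stage realizes the Go/No-go response per trial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _signal

from .calls import CallCorpus
from .cochleagram import Cochleagram, CochleagramParams, compute_cochleagram

__all__ = [
    "CandidateFeature",
    "MIF",
    "MIFSet",
    "DecisionOutcome",
    "sample_candidates",
    "max_ncc",
    "fit_feature",
    "greedy_select",
    "train_instantiations",
    "fd_response",
    "wta_decide",
    "simulate_response",
    "evaluate_auc",
    "auc_from_scores",
    "relative_detection_rate",
    "best_threshold_mi",
    "save_mifsets",
    "load_mifsets",
]

_EPS = 1e-12


@dataclass
class CandidateFeature:
    """Rectangular cochleagram patch anchored at its native CF rows."""

    patch: np.ndarray  # [n_rows x n_frames], nonnegative
    cf_span: tuple[int, int]  # [low, high) row indices in the CF grid
    duration_ms: float
    source_call: str = ""
    source_offset: tuple[int, int] = (0, 0)  # (channel, frame)

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        lo, hi = self.cf_span
        if self.patch.shape[0] != hi - lo:
            raise ValueError("patch rows do not match cf_span")


@dataclass
class MIF:
    feature: CandidateFeature
    threshold: float
    weight: float  # natural-log likelihood ratio of detection
    merit: float  # mutual information of thresholded detection, bits


@dataclass
class MIFSet:
    category: str
    mifs: list[MIF]
    instantiation_index: int = 1
    training_auc: float = float("nan")
    max_feature_dur: float = 200.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.mifs) <= 20:
            raise ValueError("an ensemble holds between 1 and 20 fragments")

    @property
    def total_weight(self) -> float:
        return sum(m.weight for m in self.mifs)


@dataclass
class DecisionOutcome:
    target_response: float
    distractor_response: float
    evidence: float
    go_probability: float
    response: Literal["go", "nogo"]
    uniform_draw: float


# ---------------------------------------------------------------------------
# template matching

def max_ncc(feature: CandidateFeature, c: Cochleagram) -> float:
    """Maximum normalized cross-correlation of a patch over all valid time
    placements at its native CF rows.

    Both patch and window are zero-meaned and unit-normed, so the result
    lies in [-1, 1].  A constant (zero-variance) patch is degenerate and
    scores 0; zero-variance windows contribute 0.
    """
    P = feature.patch
    k, m = P.shape
    lo, hi = feature.cf_span
    C = c.values[lo:hi]
    T = C.shape[1]
    if m > T:
        raise ValueError("feature temporal extent exceeds cochleagram frames")
    P0 = P - P.mean()
    p_norm = np.sqrt((P0**2).sum())
    if p_norm < _EPS:
        return 0.0
    # numerator: correlation of each row with the zero-mean patch row, summed
    num = _signal.fftconvolve(C, P0[:, ::-1], mode="valid", axes=1).sum(axis=0)
    n = k * m
    ones = np.ones(m)
    win_sum = _signal.fftconvolve(C.sum(axis=0), ones, mode="valid")
    win_sq = _signal.fftconvolve((C**2).sum(axis=0), ones, mode="valid")
    w_var = np.maximum(win_sq - win_sum**2 / n, 0.0)
    w_norm = np.sqrt(w_var)
    r = np.where(w_norm > _EPS, num / (p_norm * np.maximum(w_norm, _EPS)), 0.0)
    return float(np.clip(r, -1.0, 1.0).max())


def sample_candidates(
    train_cochleagrams: Sequence[Cochleagram],
    n: int = 1500,
    max_dur_ms: float = 200.0,
    seed: int = 0,
    min_dur_ms: float = 20.0,
    min_channels: int = 4,
) -> list[CandidateFeature]:
    """Randomly sample ``n`` rectangular blocks from target cochleagrams."""
    rng = np.random.default_rng(seed)
    frame_rate = train_cochleagrams[0].frame_rate
    max_frames_all = max(c.n_frames for c in train_cochleagrams)
    min_frames = max(1, int(round(min_dur_ms / 1000 * frame_rate)))
    if max_frames_all < min_frames:
        raise ValueError("cochleagrams too short to sample candidate features")
    out: list[CandidateFeature] = []
    while len(out) < n:
        c = train_cochleagrams[rng.integers(len(train_cochleagrams))]
        max_frames = min(int(round(max_dur_ms / 1000 * frame_rate)), c.n_frames)
        if max_frames < min_frames:
            continue
        dur = int(rng.integers(min_frames, max_frames + 1))
        height = int(rng.integers(min_channels, c.n_channels + 1))
        row = int(rng.integers(0, c.n_channels - height + 1))
        col = int(rng.integers(0, c.n_frames - dur + 1))
        out.append(
            CandidateFeature(
                patch=c.values[row : row + height, col : col + dur].copy(),
                cf_span=(row, row + height),
                duration_ms=dur / frame_rate * 1000.0,
                source_call=c.source_id,
                source_offset=(row, col),
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-feature fitting

def _mi_bits(n11: int, n10: int, n01: int, n00: int) -> float:
    """MI (bits) of a 2x2 detection-by-class contingency table with
    empirical priors."""
    n = n11 + n10 + n01 + n00
    if n == 0:
        return 0.0
    joint = np.array([[n11, n10], [n01, n00]], dtype=float) / n
    pr = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pr * pc))
    return float(np.nansum(terms))


def best_threshold_mi(scores: np.ndarray, is_target: np.ndarray) -> tuple[float, float]:
    """Exhaustive sweep over midpoints of consecutive sorted unique scores;
    returns (threshold, MI in bits) maximizing MI of ``score > threshold``
    against the class label."""
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        return float(uniq[0] if len(uniq) else 0.0), 0.0
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    nt = int(is_target.sum())
    no = len(is_target) - nt
    best_thr, best_mi = mids[0], -1.0
    for thr in mids:
        det = scores > thr
        n11 = int((det & is_target).sum())
        n10 = int((det & ~is_target).sum())
        mi = _mi_bits(n11, n10, nt - n11, no - n10)
        if mi > best_mi + 1e-15:
            best_thr, best_mi = float(thr), mi
    return best_thr, max(best_mi, 0.0)


def fit_feature(
    rmax_target: Sequence[float], rmax_other: Sequence[float]
) -> tuple[float, float, float]:
    """Optimal detection threshold, MI merit (bits) and log-likelihood-ratio
    weight (add-one smoothed, natural log) for one candidate feature."""
    rt = np.asarray(rmax_target, dtype=float)
    ro = np.asarray(rmax_other, dtype=float)
    if rt.size == 0 or ro.size == 0:
        raise ValueError("both r_max lists must be non-empty")
    scores = np.concatenate([rt, ro])
    labels = np.concatenate([np.ones(rt.size, bool), np.zeros(ro.size, bool)])
    thr, merit = best_threshold_mi(scores, labels)
    det_t = int((rt > thr).sum())
    det_o = int((ro > thr).sum())
    weight = float(
        np.log(((det_t + 1) / (rt.size + 2)) / ((det_o + 1) / (ro.size + 2)))
    )
    return thr, merit, weight


# ---------------------------------------------------------------------------
# ensemble selection

def _ensemble_mi(
    detections: np.ndarray, weights: np.ndarray, labels: np.ndarray
) -> float:
    """MI of the thresholded weighted-vote score of an ensemble."""
    w = np.asarray(weights, dtype=float)
    scores = (w @ detections) / w.sum()
    _, mi = best_threshold_mi(scores, labels)
    return mi


def greedy_select(
    mifs: Sequence[MIF],
    detections: np.ndarray,
    labels: np.ndarray,
    max_n: int = 20,
    min_gain_bits: float = 1e-3,
) -> list[int]:
    """Forward selection of a maximally informative, minimally redundant
    subset.  ``detections`` is [n_candidates x n_calls] boolean; at each
    step the candidate maximizing the ensemble MI (weighted-vote score,
    re-thresholded) is added; stops at ``max_n`` features or when the
    incremental gain drops below ``min_gain_bits``.  Returns indices into
    ``mifs``.
    """
    labels = np.asarray(labels, dtype=bool)
    usable = [
        i for i, m in enumerate(mifs) if m.merit > 0 and m.weight > 0
    ]
    if not usable:
        raise ValueError("no informative candidate (merit > 0, weight > 0)")
    selected: list[int] = []
    current_mi = 0.0
    while len(selected) < max_n:
        best_i, best_mi = -1, current_mi
        for i in usable:
            if i in selected:
                continue
            idx = selected + [i]
            w = np.array([mifs[j].weight for j in idx])
            mi = _ensemble_mi(detections[idx], w, labels)
            if mi > best_mi + 1e-12:
                best_i, best_mi = i, mi
        if best_i < 0 or best_mi - current_mi < min_gain_bits:
            break
        selected.append(best_i)
        current_mi = best_mi
    if not selected:
        # fall back to the single best candidate by merit
        selected = [max(usable, key=lambda i: mifs[i].merit)]
    return selected


def train_instantiations(
    corpus: CallCorpus,
    category: str,
    n_instantiations: int = 5,
    n_candidates: int = 1500,
    max_dur_ms: float = 200.0,
    max_n: int = 20,
    min_gain_bits: float = 1e-3,
    mode: Literal["one_vs_many", "one_vs_one"] = "one_vs_many",
    partner: str | None = None,
    params: CochleagramParams = CochleagramParams(),
    cochleagrams: dict[str, Cochleagram] | None = None,
    seed: int = 0,
) -> list[MIFSet]:
    """Train several feature-wise disjoint ensembles for one category.

    Candidate patches are sampled from the category's training cochleagrams
    once; each instantiation consumes (and removes) features from this
    shared pool.  ``one_vs_many`` uses every other category's training calls
    as negatives; ``one_vs_one`` only the given task partner.
    """
    train_calls = corpus.subset(split="train")
    pos = [c for c in train_calls if c.category == category]
    if mode == "one_vs_one":
        if partner is None:
            raise ValueError("one_vs_one mode requires a partner category")
        neg = [c for c in train_calls if c.category == partner]
    else:
        neg = [c for c in train_calls if c.category != category]
    if not pos or not neg:
        raise ValueError("corpus must contain target and non-target training calls")

    if cochleagrams is None:
        cochleagrams = {}
    for call in pos + neg:
        if call.exemplar_id not in cochleagrams:
            cochleagrams[call.exemplar_id] = compute_cochleagram(call, params)
    pos_c = [cochleagrams[c.exemplar_id] for c in pos]
    neg_c = [cochleagrams[c.exemplar_id] for c in neg]
    all_c = pos_c + neg_c
    labels = np.array([True] * len(pos_c) + [False] * len(neg_c))

    candidates = sample_candidates(
        pos_c, n=n_candidates, max_dur_ms=max_dur_ms, seed=seed
    )
    rmax = np.empty((len(candidates), len(all_c)))
    for i, feat in enumerate(candidates):
        for j, coch in enumerate(all_c):
            rmax[i, j] = max_ncc(feat, coch)

    fitted: list[MIF] = []
    detections = np.empty_like(rmax, dtype=bool)
    for i, feat in enumerate(candidates):
        thr, merit, weight = fit_feature(rmax[i, labels], rmax[i, ~labels])
        fitted.append(MIF(feature=feat, threshold=thr, weight=weight, merit=merit))
        detections[i] = rmax[i] > thr

    pool = set(range(len(fitted)))
    sets: list[MIFSet] = []
    for inst in range(1, n_instantiations + 1):
        avail = sorted(pool)
        informative = [i for i in avail if fitted[i].merit > 0 and fitted[i].weight > 0]
        if not informative:
            warnings.warn(
                f"candidate pool exhausted after {len(sets)} instantiations "
                f"for category {category!r}"
            )
            break
        sub = greedy_select(
            [fitted[i] for i in avail],
            detections[avail],
            labels,
            max_n=max_n,
            min_gain_bits=min_gain_bits,
        )
        chosen = [avail[j] for j in sub]
        pool -= set(chosen)
        mifset = MIFSet(
            category=category,
            mifs=[fitted[i] for i in chosen],
            instantiation_index=inst,
            max_feature_dur=max_dur_ms,
        )
        w = np.array([m.weight for m in mifset.mifs])
        scores = (w @ detections[chosen]) / w.sum()
        mifset.training_auc = auc_from_scores(scores[labels], scores[~labels])
        sets.append(mifset)
    return sets


# ---------------------------------------------------------------------------
# detection-stage responses and decisions

def fd_response(mifset: MIFSet, c: Cochleagram) -> float:
    """Sum of detected fragment weights normalized by the sum of all
    weights; ranges from 0 (nothing detected) to 1 (all detected)."""
    detected = 0.0
    for m in mifset.mifs:
        if max_ncc(m.feature, c) > m.threshold:
            detected += m.weight
    return detected / mifset.total_weight


def wta_decide(
    target_resp: float,
    distractor_resp: float,
    p_min: float = 0.1,
    p_max: float = 0.9,
) -> float:
    """Winner-take-all Go probability: ``p_max`` if the target detector wins,
    ``p_min`` if it loses, 0.5 on an exact tie."""
    evidence = target_resp - distractor_resp
    if evidence > 0:
        return p_max
    if evidence < 0:
        return p_min
    return 0.5


def simulate_response(go_probability: float, rng: np.random.Generator) -> tuple[str, float]:
    """Stochastic trial realization: Go iff a uniform draw X < P(GO)."""
    x = float(rng.uniform())
    return ("go" if x < go_probability else "nogo"), x


def decide_trial(
    target_resp: float,
    distractor_resp: float,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    p_min: float = 0.1,
    p_max: float = 0.9,
) -> DecisionOutcome:
    go_p = wta_decide(target_resp, distractor_resp, p_min=p_min, p_max=p_max)
    if deterministic:
        response, draw = ("go" if target_resp > distractor_resp else "nogo"), float("nan")
    else:
        if rng is None:
            raise ValueError("stochastic decisions require an rng")
        response, draw = simulate_response(go_p, rng)
    return DecisionOutcome(
        target_response=target_resp,
        distractor_response=distractor_resp,
        evidence=target_resp - distractor_resp,
        go_probability=go_p,
        response=response,
        uniform_draw=draw,
    )


def auc_from_scores(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC area by threshold sweep over observed scores, trapezoidal rule;
    tied scores contribute 0.5."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append(float((pos >= thr).mean()))
        fpr.append(float((neg >= thr).mean()))
    return float(np.trapezoid(tpr, fpr))


def evaluate_auc(
    mifset: MIFSet,
    positives: Sequence[Cochleagram],
    negatives: Sequence[Cochleagram],
) -> float:
    pos = [fd_response(mifset, c) for c in positives]
    neg = [fd_response(mifset, c) for c in negatives]
    return auc_from_scores(pos, neg)


def relative_detection_rate(
    mifset: MIFSet,
    within: Sequence[Cochleagram],
    outside: Sequence[Cochleagram],
    cfs: np.ndarray | None = None,
):
    """Per-fragment detection-rate difference between within-category and
    outside-category calls, with CF / bandwidth / duration descriptors."""
    import pandas as pd

    if not within or not outside:
        raise ValueError("both call lists must be non-empty")
    if cfs is None:
        cfs = within[0].cfs
    rows = []
    for i, m in enumerate(mifset.mifs):
        r_in = np.mean([max_ncc(m.feature, c) > m.threshold for c in within])
        r_out = np.mean([max_ncc(m.feature, c) > m.threshold for c in outside])
        lo, hi = m.feature.cf_span
        f_lo, f_hi = cfs[lo], cfs[hi - 1]
        rows.append(
            {
                "mif_index": i,
                "rate_within": float(r_in),
                "rate_outside": float(r_out),
                "rate_diff": float(r_in - r_out),
                "cf_center_hz": float(np.sqrt(f_lo * f_hi)),
                "bandwidth_oct": float(np.log2(f_hi / f_lo)) if f_hi > f_lo else 0.0,
                "duration_ms": m.feature.duration_ms,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence

def save_mifsets(path_prefix, sets: Sequence[MIFSet]) -> None:
    """JSON metadata (thresholds, weights, spans) + .npz patch container."""
    prefix = Path(path_prefix)
    meta = []
    arrays = {}
    for s_i, s in enumerate(sets):
        entry = {
            "category": s.category,
            "instantiation_index": s.instantiation_index,
            "training_auc": s.training_auc,
            "max_feature_dur": s.max_feature_dur,
            "mifs": [],
        }
        for m_i, m in enumerate(s.mifs):
            key = f"patch_{s_i}_{m_i}"
            arrays[key] = m.feature.patch
            entry["mifs"].append(
                {
                    "patch_key": key,
                    "cf_span": list(m.feature.cf_span),
                    "duration_ms": m.feature.duration_ms,
                    "source_call": m.feature.source_call,
                    "source_offset": list(m.feature.source_offset),
                    "threshold": m.threshold,
                    "weight": m.weight,
                    "merit": m.merit,
                }
            )
        meta.append(entry)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(prefix.with_suffix(".npz"), **arrays)


def load_mifsets(path_prefix) -> list[MIFSet]:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    sets = []
    with np.load(prefix.with_suffix(".npz")) as z:
        for entry in meta:
            mifs = []
            for m in entry["mifs"]:
                feat = CandidateFeature(
                    patch=z[m["patch_key"]],
                    cf_span=tuple(m["cf_span"]),
                    duration_ms=m["duration_ms"],
                    source_call=m["source_call"],
                    source_offset=tuple(m["source_offset"]),
                )
                mifs.append(
                    MIF(feature=feat, threshold=m["threshold"], weight=m["weight"], merit=m["merit"])
                )
            sets.append(
                MIFSet(
                    category=entry["category"],
                    mifs=mifs,
                    instantiation_index=entry["instantiation_index"],
                    training_auc=entry["training_auc"],
                    max_feature_dur=entry["max_feature_dur"],
                )
            )
    return sets
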