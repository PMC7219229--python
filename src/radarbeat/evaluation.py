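"""Scoring detections against reference beats, with subject-wise CV.

Metrics follow the study design: the signed percentage error in the
total number of detected heartbeats, inter-pulse-interval (IPI) series
and their medians, an IPI mean relative error over matched beat pairs,
and paired statistical comparisons (Lilliefors normality gate at 0.05,
then Wilcoxon signed-rank or paired t).  Model selection quality is
estimated by three-fold cross-validation with fold assignment at the
subject level, so every reported prediction is made on subjects the
network never saw in training.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .detector import HeartbeatDetector, TrainConfig
from .ecg_reference import pan_tompkins
from .signal_core import BeatTrain, SubjectRecording

__all__ = [
    "FoldSplit",
    "EvalReport",
    "PairedTestResult",
    "count_error",
    "ipi_series",
    "ipi_mre",
    "match_beats",
    "paired_compare",
    "assign_folds",
    "crossvalidate",
]

PROC_RATE = 100.0


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------


def count_error(detected: BeatTrain, reference: BeatTrain) -> float:
    """Signed percentage error in the number of detected heartbeats.

    ``100 * (N_det - N_ref) / N_ref``; negative means under-detection.
    """
    if len(reference) == 0:
        raise ValueError("empty reference beat train")
    return 100.0 * (len(detected) - len(reference)) / len(reference)


def ipi_series(beats: BeatTrain) -> np.ndarray:
    """Inter-pulse intervals: first differences of the beat times (s)."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats for an IPI series")
    return np.diff(beats.times)


def match_beats(detected: BeatTrain, reference: BeatTrain,
                match_tol: float = 0.5) -> List[Tuple[int, int]]:
    """Greedy nearest-time matching of detected to reference beats.

    Candidate pairs within ``match_tol`` seconds are accepted in order
    of increasing time difference, each beat used at most once.
    Returns (reference index, detected index) pairs sorted by
    reference time.
    """
    pairs = []
    for di, dt in enumerate(detected.times):
        for ri, rt in enumerate(reference.times):
            d = abs(dt - rt)
            if d <= match_tol:
                pairs.append((d, ri, di))
    pairs.sort()
    used_r: set = set()
    used_d: set = set()
    matches = []
    for _, ri, di in pairs:
        if ri in used_r or di in used_d:
            continue
        used_r.add(ri)
        used_d.add(di)
        matches.append((ri, di))
    matches.sort()
    return matches


def ipi_mre(detected: BeatTrain, reference: BeatTrain,
            match_tol: float = 0.5) -> float:
    """IPI mean relative error over consecutively matched beat pairs.

    Detected beats are matched to reference beats (greedy nearest, one
    use each, within ``match_tol``); for every adjacent pair in the
    matched sequence the detected and reference IPIs are compared as
    ``|IPI_det - IPI_ref| / IPI_ref``.  Invariant to a constant time
    shift of either train.  The pairing rule is this package's own,
    with the tolerance equal to the minimum-IPI constraint.
    """
    if len(detected) < 2 or len(reference) < 2:
        raise ValueError("need at least 2 beats in each train")
    matches = match_beats(detected, reference, match_tol)
    if len(matches) < 2:
        raise ValueError("no matched beat pairs within tolerance")
    rel = []
    for (r0, d0), (r1, d1) in zip(matches, matches[1:]):
        ipi_ref = reference.times[r1] - reference.times[r0]
        ipi_det = detected.times[d1] - detected.times[d0]
        rel.append(abs(ipi_det - ipi_ref) / ipi_ref)
    return 100.0 * float(np.mean(rel))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    test: str            # "wilcoxon" | "t-test" | "degenerate"
    p_value: float
    significant: bool
    degenerate: bool = False


def paired_compare(sample_a: Sequence[float], sample_b: Sequence[float],
                   alpha: float = 0.05) -> PairedTestResult:
    """Compare paired samples with a normality-gated test.

    The paired differences go through a Lilliefors normality check at
    ``alpha``; non-normal differences are compared with the Wilcoxon
    signed-rank test (exact for n <= 25, normal approximation above),
    normal ones with a paired t-test.  Identical samples yield a
    degenerate result flagged with p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length paired samples with n >= 5")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult("degenerate", 1.0, False, degenerate=True)
    _, p_norm = _lilliefors(d, dist="norm")
    if p_norm < alpha:
        mode = "exact" if a.size <= 25 else "approx"
        try:
            _, p = _stats.wilcoxon(a, b, mode=mode)
        except ValueError:  # ties make the exact distribution unavailable
            _, p = _stats.wilcoxon(a, b, mode="approx")
        return PairedTestResult("wilcoxon", float(p), bool(p < alpha))
    _, p = _stats.ttest_rel(a, b)
    return PairedTestResult("t-test", float(p), bool(p < alpha))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Subject-level fold assignment (fold indices start at 1)."""

    assignments: Dict[str, int]

    def fold(self, k: int) -> List[str]:
        return [s for s, f in self.assignments.items() if f == k]

    @property
    def n_folds(self) -> int:
        return len(set(self.assignments.values()))


def assign_folds(subject_ids: Sequence[str], n_folds: int,
                 seed: int) -> FoldSplit:
    """Seeded shuffle then round-robin: disjoint, exhaustive, sizes +/-1."""
    ids = list(subject_ids)
    if len(ids) < n_folds:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return FoldSplit({s: (i % n_folds) + 1 for i, s in enumerate(perm)})


@dataclass
class EvalReport:
    """Per-subject and pooled detection metrics for one topology."""

    topology: str
    fold_split: FoldSplit
    per_subject: pd.DataFrame
    pooled: dict
    detections: Dict[str, object] = field(default_factory=dict)
    references: Dict[str, BeatTrain] = field(default_factory=dict)


def _subject_row(subject_id: str, fold: int, det, ref: BeatTrain) -> dict:
    beats = det.beats
    row = {
        "subject_id": subject_id,
        "fold": fold,
        "n_detected": len(beats),
        "n_reference": len(ref),
        "n_interpolated": det.n_interpolated,
        "count_error_pct": count_error(beats, ref),
        "ipi_median_det": np.nan,
        "ipi_median_det_noninterp": np.nan,
        "ipi_median_ref": np.nan,
        "ipi_mre_pct": np.nan,
        "ipi_p_value": np.nan,
        "ipi_no_difference": False,
    }
    if len(ref) >= 2:
        row["ipi_median_ref"] = float(np.median(ipi_series(ref)))
    if len(beats) >= 2:
        row["ipi_median_det"] = float(np.median(ipi_series(beats)))
    hard = BeatTrain(beats.times[~det.interpolated_flags])
    if len(hard) >= 2:
        row["ipi_median_det_noninterp"] = float(np.median(ipi_series(hard)))
    if len(beats) >= 2 and len(ref) >= 2:
        try:
            row["ipi_mre_pct"] = ipi_mre(beats, ref)
        except ValueError:
            pass
        matches = match_beats(beats, ref)
        if len(matches) >= 6:
            ipi_ref = []
            ipi_det = []
            for (r0, d0), (r1, d1) in zip(matches, matches[1:]):
                ipi_ref.append(ref.times[r1] - ref.times[r0])
                ipi_det.append(beats.times[d1] - beats.times[d0])
            res = paired_compare(ipi_det, ipi_ref)
            row["ipi_p_value"] = res.p_value
            row["ipi_no_difference"] = not res.significant
    return row


def crossvalidate(cohort: Sequence[SubjectRecording], topology: str,
                  cfg: TrainConfig, n_folds: int = 3,
                  seed: int = 0, amplitude="auto",
                  standardize: bool = False) -> EvalReport:
    """Subject-wise k-fold evaluation of one detector topology.

    For each fold the detector is trained on the other folds (the
    detection amplitude is calibrated on the training-fold recordings;
    held-out subjects never influence it) and applied to the held-out
    subjects; metrics are pooled over the predictions collected across
    all test folds.  No subject ever contributes to both training and
    testing.
    """
    ids = [r.subject_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    split = assign_folds(ids, n_folds, seed)
    by_id = {r.subject_id: r for r in cohort}

    rows = []
    detections: Dict[str, object] = {}
    references: Dict[str, BeatTrain] = {}
    for k in range(1, n_folds + 1):
        test_ids = split.fold(k)
        train_folds = [f for f in range(1, n_folds + 1) if f != k]
        train_ids = [s for f in train_folds for s in split.fold(f)]
        assert not set(train_ids) & set(test_ids)
        train_recs = [by_id[s] for s in train_ids]
        calib_recs = train_recs
        det = HeartbeatDetector(
            topology=topology, loss=cfg.loss, reg_ratio=cfg.reg_ratio,
            amplitude=amplitude,
            max_epochs=cfg.max_epochs, grad_tol=cfg.grad_tol,
            val_fraction=cfg.val_fraction, patience=cfg.patience,
            lm_mu0=cfg.lm_mu0, lm_mu_factor=cfg.lm_mu_factor,
            max_train_rows=cfg.max_train_rows, jac_dtype=cfg.jac_dtype,
            hidden_activation=cfg.hidden_activation,
            feedback_depth=cfg.feedback_depth, standardize=standardize,
            seed=cfg.seed + k)
        det.fit(train_recs, calib_recordings=calib_recs)
        for sid in test_ids:
            rec = by_id[sid]
            ref = pan_tompkins(rec.ecg)
            pred = det.predict(rec)
            detections[sid] = pred
            references[sid] = ref
            rows.append(_subject_row(sid, k, pred, ref))

    per_subject = pd.DataFrame(rows).sort_values("subject_id") \
                                    .reset_index(drop=True)
    n_det = int(per_subject["n_detected"].sum())
    n_ref = int(per_subject["n_reference"].sum())
    all_det_ipi = np.concatenate(
        [ipi_series(detections[s].beats) for s in detections
         if len(detections[s].beats) >= 2])
    all_ref_ipi = np.concatenate(
        [ipi_series(references[s]) for s in references
         if len(references[s]) >= 2])
    med_diff_s = float(np.median(all_det_ipi) - np.median(all_ref_ipi))
    med_cmp = paired_compare(per_subject["ipi_median_det"].to_numpy(),
                             per_subject["ipi_median_ref"].to_numpy()) \
        if len(per_subject) >= 5 else None
    cnt_cmp = paired_compare(per_subject["n_detected"].to_numpy(),
                             per_subject["n_reference"].to_numpy()) \
        if len(per_subject) >= 5 else None
    pooled = {
        "n_detected": n_det,
        "n_reference": n_ref,
        "count_error_pct": 100.0 * (n_det - n_ref) / n_ref,
        "ipi_median_diff_samples": med_diff_s * PROC_RATE,
        "ipi_median_diff_ms": med_diff_s * 1000.0,
        "ipi_mre_pct": float(per_subject["ipi_mre_pct"].mean()),
        "n_subjects_no_difference":
            int(per_subject["ipi_no_difference"].sum()),
        "median_ipi_test": med_cmp.test if med_cmp else None,
        "median_ipi_p_value": med_cmp.p_value if med_cmp else None,
        "count_test": cnt_cmp.test if cnt_cmp else None,
        "count_p_value": cnt_cmp.p_value if cnt_cmp else None,
    }
    return EvalReport(topology=topology, fold_split=split,
                      per_subject=per_subject, pooled=pooled,
                      detections=detections, references=references)
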