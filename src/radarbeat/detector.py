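"""The heartbeat detector: I/Q windows, shallow ANN, LM training.

The network sees a 200-sample input vector per 100 Hz time step: the
last second of the decimated in-phase channel (positions 0-99, oldest
to newest) concatenated with the same second of the quadrature channel
(positions 100-199).  It is trained against the delayed binary target
with Levenberg-Marquardt least squares under the early-stopping regime
(validation fraction 0.30, patience 6, gradient tolerance 1e-7, at
most 1000 epochs).

Two estimator front-ends follow scikit-learn conventions:
:class:`ShallowANNClassifier` (fit on a window matrix) and
:class:`HeartbeatDetector` (fit on recordings, predict beat events).
The module-level functions (:func:`build_windows`, :func:`ann_forward`,
:func:`loss`, :func:`train_lm`, :func:`narx_forward`) are the thin
functional surface over the same code.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin

from .ann import AnnModel, build_model, parse_topology
from .ecg_reference import (TARGET_DELAY, TARGET_WIDTH, BinaryTarget,
                            binarize_targets, pan_tompkins)
from .signal_core import BeatTrain, SubjectRecording, TimeSeries, decimate

__all__ = [
    "WindowSet",
    "TrainConfig",
    "build_windows",
    "ann_forward",
    "loss",
    "train_lm",
    "narx_forward",
    "narx_build_inputs",
    "narx_closed_loop",
    "prepare_recording",
    "ShallowANNClassifier",
    "HeartbeatDetector",
]

PROC_RATE = 100.0  # Hz, common processing rate


@dataclass
class WindowSet:
    """Stacked causal input windows with their binary targets.

    ``inputs`` has one row per 100 Hz step: columns 0-99 the in-phase
    window and 100-199 the quadrature window, each oldest to newest.
    ``timestamps`` is the time of the newest sample in each row.
    ``groups`` optionally labels each row with its subject for
    subject-stratified validation splits.
    """

    inputs: np.ndarray
    targets: np.ndarray
    timestamps: Optional[np.ndarray] = None
    groups: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.inputs.ndim != 2:
            raise ValueError("inputs must be a 2-D matrix")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets disagree in length")

    def __len__(self) -> int:
        return int(self.inputs.shape[0])

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        ts = None
        if all(s.timestamps is not None for s in sets):
            ts = np.concatenate([s.timestamps for s in sets])
        gr = None
        if all(s.groups is not None for s in sets):
            gr = np.concatenate([s.groups for s in sets])
        return WindowSet(np.vstack([s.inputs for s in sets]),
                         np.concatenate([s.targets for s in sets]), ts, gr)


def build_windows(i100: TimeSeries, q100: TimeSeries, target: BinaryTarget,
                  memory: float = 1.0) -> WindowSet:
    """Causal right-aligned windows, one per sample index >= memory*rate - 1.

    For ``n`` aligned samples and 1 s memory at 100 Hz this yields
    ``n - 99`` rows of length 200.
    """
    if i100.rate != q100.rate or i100.rate != target.rate:
        raise ValueError("channels and target must share one rate")
    n = len(i100)
    if len(q100) != n or len(target) != n:
        raise ValueError("channels and target must share one length")
    m = int(round(memory * i100.rate))
    if m < 1 or n < m:
        raise ValueError("recording shorter than the window memory")
    wi = sliding_window_view(i100.values, m)
    wq = sliding_window_view(q100.values, m)
    inputs = np.hstack([wi, wq])
    ts = i100.t0 + (np.arange(n - m + 1) + m - 1) / i100.rate
    return WindowSet(inputs, target.values[m - 1:].astype(float), ts)


@dataclass
class TrainConfig:
    """Levenberg-Marquardt training configuration.

    ``max_train_rows`` optionally subsamples the training rows (after
    seeding) to bound the cost of the Gauss-Newton normal equations;
    ``jac_dtype`` selects the Jacobian accumulation precision.
    """

    loss: str = "mse"                 # mse | msereg | sse
    reg_ratio: float = 0.9            # gamma for msereg
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    val_fraction: float = 0.30
    patience: int = 6
    seed: int = 0
    lm_mu0: float = 1e-3
    lm_mu_factor: float = 10.0
    max_train_rows: Optional[int] = None
    jac_dtype: str = "float64"
    hidden_activation: str = "tanh"
    feedback_depth: int = 10          # NARX only

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "msereg", "sse"):
            raise ValueError(f"unknown loss '{self.loss}'")
        if not 0 < self.reg_ratio <= 1:
            raise ValueError("reg_ratio must lie in (0, 1]")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")


def ann_forward(model: AnnModel, x: np.ndarray) -> float:
    """Probability for a single input vector (thin forward-pass wrapper)."""
    return float(model.forward(np.atleast_2d(x))[0])


def loss(model: AnnModel, ws: WindowSet, cfg: TrainConfig) -> float:
    """Training objective on a window set: MSE, SSE or regularized MSE."""
    if len(ws) == 0:
        raise ValueError("empty window set")
    a = model.forward(ws.inputs)
    r = ws.targets - a
    sse = float(r @ r)
    if cfg.loss == "sse":
        return sse
    mse = sse / len(ws)
    if cfg.loss == "mse":
        return mse
    p = model.get_flat()
    return cfg.reg_ratio * mse + (1 - cfg.reg_ratio) * float(p @ p) / p.size


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training
# ---------------------------------------------------------------------------

_CHUNK_ELEMS = 32_000_000  # J-chunk budget: rows * n_params per slab


def _normal_equations(model: AnnModel, X: np.ndarray, y: np.ndarray,
                      dtype) -> Tuple[np.ndarray, np.ndarray, float]:
    """Accumulate J^T J, J^T r and the residual sum of squares in chunks."""
    from scipy.linalg import blas as _blas

    P = model.n_params
    JtJ = np.zeros((P, P))
    Jtr = np.zeros(P)
    sse = 0.0
    chunk = max(64, _CHUNK_ELEMS // P)
    for lo in range(0, X.shape[0], chunk):
        Xc = X[lo:lo + chunk]
        J, a = model.jacobian(Xc, dtype=np.dtype(dtype))
        r = (y[lo:lo + chunk] - a).astype(J.dtype)
        # symmetric rank-k update on the lower triangle (half the FLOPs)
        syrk = _blas.get_blas_funcs("syrk", (J,))
        JtJ += syrk(1.0, J.T, lower=1).astype(np.float64)
        Jtr += (J.T @ r).astype(np.float64)
        sse += float(r @ r)
    diag = JtJ.diagonal().copy()
    JtJ += JtJ.T  # syrk filled only the lower triangle
    np.fill_diagonal(JtJ, diag)
    return JtJ, Jtr, sse


def _objective(model: AnnModel, X: np.ndarray, y: np.ndarray,
               cfg: TrainConfig) -> float:
    r = y - model.forward(X)
    sse = float(r @ r)
    if cfg.loss == "sse":
        return sse
    mse = sse / len(y)
    if cfg.loss == "mse":
        return mse
    p = model.get_flat()
    return cfg.reg_ratio * mse + (1 - cfg.reg_ratio) * float(p @ p) / p.size


def _val_split(n: int, groups: Optional[np.ndarray], frac: float,
               rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Random row split, stratified by subject when groups are known."""
    idx = np.arange(n)
    val = []
    if groups is None:
        perm = rng.permutation(idx)
        k = int(round(frac * n))
        val = perm[:k]
    else:
        for g in np.unique(groups):
            gi = idx[groups == g]
            perm = rng.permutation(gi)
            val.append(perm[:int(round(frac * gi.size))])
        val = np.concatenate(val) if val else np.empty(0, dtype=int)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[np.asarray(val, dtype=int)] = True
    return idx[~val_mask], idx[val_mask]


def train_lm(topology, ws: WindowSet, cfg: TrainConfig
             ) -> Tuple[AnnModel, dict]:
    """Train a network with damped Gauss-Newton (Levenberg-Marquardt).

    Each epoch solves ``(J^T J + mu I) delta = J^T r`` on the training
    rows (scaled per the configured loss), accepts the step only if the
    objective decreases (``mu /= lm_mu_factor``; otherwise
    ``mu *= lm_mu_factor`` and the solve is retried), and monitors a
    held-out validation MSE for early stopping.  The returned model
    carries the weights with the best validation loss; the log records
    per-epoch losses, damping and the stop reason.  Fully reproducible
    for a given ``cfg.seed``.

    NARX topologies are trained open-loop: the exogenous window is
    augmented with teacher-forced target feedback before fitting.
    """
    if cfg.max_epochs < 1:
        raise ValueError("max_epochs must be at least 1")
    if len(ws) == 0:
        raise ValueError("empty window set")
    rng = np.random.default_rng(cfg.seed)

    if isinstance(topology, AnnModel):
        model = topology
        kind = "NARX" if model.topology_name.upper().startswith("NARX") \
            else "FF"
    else:
        kind, _ = parse_topology(topology)
        n_inputs = ws.inputs.shape[1]
        if kind == "NARX":
            n_inputs += cfg.feedback_depth
        model = build_model(topology, n_inputs, cfg.hidden_activation,
                            seed=int(rng.integers(2 ** 31)))
    if kind == "NARX":
        ws = narx_build_inputs(ws, cfg.feedback_depth)

    X = ws.inputs
    y = ws.targets
    n = len(ws)
    groups = ws.groups
    if cfg.max_train_rows is not None and n > cfg.max_train_rows:
        keep = np.sort(rng.choice(n, cfg.max_train_rows, replace=False))
        X, y = X[keep], y[keep]
        groups = groups[keep] if groups is not None else None
        n = cfg.max_train_rows
    if n < 10 * model.n_params:
        warnings.warn(
            f"only {n} training rows for {model.n_params} parameters "
            "(less than 10x)", RuntimeWarning, stacklevel=2)

    tr_idx, val_idx = _val_split(n, groups, cfg.val_fraction, rng)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    mu = cfg.lm_mu0
    best_val = np.inf
    best_p = model.get_flat()
    wait = 0
    log: List[dict] = []
    stop = "max_epochs"
    F = _objective(model, Xtr, ytr, cfg)
    M = len(ytr)
    P = model.n_params

    for epoch in range(1, cfg.max_epochs + 1):
        JtJ, Jtr, _ = _normal_equations(model, Xtr, ytr, cfg.jac_dtype)
        p = model.get_flat()
        if cfg.loss == "sse":
            A, g = JtJ, Jtr
        elif cfg.loss == "mse":
            A, g = JtJ / M, Jtr / M
        else:  # msereg
            gam = cfg.reg_ratio
            A = (gam / M) * JtJ + ((1 - gam) / P) * np.eye(P)
            g = (gam / M) * Jtr - ((1 - gam) / P) * p
        if 2.0 * float(np.max(np.abs(g))) < cfg.grad_tol:
            stop = "gradient"
            break
        solve_dtype = np.float32 if cfg.jac_dtype == "float32" \
            else np.float64
        A_s = A.astype(solve_dtype, copy=True)
        g_s = g.astype(solve_dtype)
        accepted = False
        for _ in range(16):
            try:
                B = A_s.copy()
                B[np.diag_indices_from(B)] += solve_dtype(mu)
                cf = cho_factor(B, lower=True, check_finite=False,
                                overwrite_a=True)
                delta = cho_solve(cf, g_s,
                                  check_finite=False).astype(np.float64)
            except np.linalg.LinAlgError:
                mu *= cfg.lm_mu_factor
                continue
            model.set_flat(p + delta)
            F_new = _objective(model, Xtr, ytr, cfg)
            if np.isfinite(F_new) and F_new < F:
                F = F_new
                mu = max(mu / cfg.lm_mu_factor, 1e-15)
                accepted = True
                break
            model.set_flat(p)
            mu *= cfg.lm_mu_factor
            if mu > 1e12:
                break
        if not np.isfinite(F):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} (mu={mu:g})")
        val_mse = (float(np.mean((yval - model.forward(Xval)) ** 2))
                   if len(yval) else np.nan)
        log.append({"epoch": epoch, "train_loss": F, "val_mse": val_mse,
                    "mu": mu, "accepted": accepted})
        if not accepted:
            stop = "mu_limit"
            break
        if len(yval):
            if val_mse < best_val:
                best_val = val_mse
                best_p = model.get_flat()
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    stop = "early_stopping"
                    break
        else:
            best_p = model.get_flat()
    if len(yval) and np.isfinite(best_val):
        model.set_flat(best_p)
    return model, {"epochs": log, "stop_reason": stop,
                   "n_train": M, "n_val": int(len(yval))}


# ---------------------------------------------------------------------------
# NARX variant
# ---------------------------------------------------------------------------


def narx_build_inputs(ws: WindowSet, depth: int = 10) -> WindowSet:
    """Teacher-forced NARX inputs: window plus the previous target values.

    Row ``k`` is augmented with targets ``k-depth .. k-1`` (zeros before
    the start), which is how the network trains open-loop.
    """
    n = len(ws)
    fb = np.zeros((n, depth))
    for j in range(depth):
        shift = depth - j  # column j holds target[k - shift]
        fb[shift:, j] = ws.targets[:n - shift]
    return WindowSet(np.hstack([ws.inputs, fb]), ws.targets,
                     ws.timestamps, ws.groups)


def narx_forward(model: AnnModel, exog: np.ndarray,
                 feedback: np.ndarray) -> float:
    """One closed-loop step: exogenous window plus fed-back outputs."""
    exog = np.asarray(exog, dtype=float).ravel()
    feedback = np.asarray(feedback, dtype=float).ravel()
    if exog.size + feedback.size != model.n_inputs:
        raise ValueError("exogenous + feedback length must match the model")
    return ann_forward(model, np.concatenate([exog, feedback]))


def narx_closed_loop(model: AnnModel, ws: WindowSet,
                     depth: int = 10) -> np.ndarray:
    """Run the NARX network over a stream feeding back its own outputs."""
    n = len(ws)
    out = np.zeros(n)
    fb = np.zeros(depth)
    for k in range(n):
        out[k] = narx_forward(model, ws.inputs[k], fb)
        fb = np.roll(fb, -1)
        fb[-1] = out[k]
    return out


# ---------------------------------------------------------------------------
# Recording preparation
# ---------------------------------------------------------------------------


def prepare_recording(rec: SubjectRecording, memory: float = 1.0,
                      delay: float = TARGET_DELAY,
                      width: float = TARGET_WIDTH,
                      proc_rate: float = PROC_RATE,
                      with_targets: bool = True,
                      standardize: bool = False
                      ) -> Tuple[WindowSet, Optional[BeatTrain]]:
    """Decimate a recording to the processing rate and window it.

    When ``with_targets`` is set, R peaks are detected on the ECG and
    the delayed binary target is synthesized on the same grid; the
    reference beat train is returned alongside.  Without targets (or
    without an ECG channel) the target column is all zeros.

    ``standardize`` applies a per-recording affine rescaling (zero
    mean, unit variance per channel) before windowing.  The detector
    default is the raw ADC-scale signal; the flag exists because large
    per-recording DC offsets dominate the Gauss-Newton normal
    equations and slow Levenberg-Marquardt convergence markedly.
    """
    from .signal_core import align as _align

    rec = _align(rec)
    i100 = decimate(rec.i_ch, proc_rate)
    q100 = decimate(rec.q_ch, proc_rate)
    if standardize:
        for ch in (i100, q100):
            sd = ch.values.std()
            ch.values = (ch.values - ch.values.mean()) / (sd if sd else 1.0)
    n = min(len(i100), len(q100))
    refs = None
    if with_targets and rec.ecg is not None:
        refs = pan_tompkins(rec.ecg)
        target = binarize_targets(refs, proc_rate,
                                  (i100.t0, i100.t0 + n / proc_rate),
                                  delay, width)
        n = min(n, len(target))
        tvals = target.values[:n]
    else:
        tvals = np.zeros(n, dtype=np.uint8)
    i100 = TimeSeries(i100.values[:n], proc_rate, i100.t0)
    q100 = TimeSeries(q100.values[:n], proc_rate, q100.t0)
    ws = build_windows(i100, q100,
                       BinaryTarget(tvals, proc_rate, i100.t0), memory)
    ws.groups = np.full(len(ws), rec.subject_id, dtype=object)
    return ws, refs


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


class ShallowANNClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier wrapper around the LM-trained shallow network.

    ``fit(X, y)`` takes any numeric window matrix and {0,1} labels;
    ``predict_proba`` returns the sigmoid output of the single output
    neuron.  All parameters mirror :class:`TrainConfig`.
    """

    def __init__(self, topology: str = "FF 20 1", loss: str = "mse",
                 reg_ratio: float = 0.9, max_epochs: int = 1000,
                 grad_tol: float = 1e-7, val_fraction: float = 0.30,
                 patience: int = 6, lm_mu0: float = 1e-3,
                 lm_mu_factor: float = 10.0,
                 max_train_rows: Optional[int] = None,
                 jac_dtype: str = "float64",
                 hidden_activation: str = "tanh",
                 feedback_depth: int = 10, seed: int = 0):
        self.topology = topology
        self.loss = loss
        self.reg_ratio = reg_ratio
        self.max_epochs = max_epochs
        self.grad_tol = grad_tol
        self.val_fraction = val_fraction
        self.patience = patience
        self.lm_mu0 = lm_mu0
        self.lm_mu_factor = lm_mu_factor
        self.max_train_rows = max_train_rows
        self.jac_dtype = jac_dtype
        self.hidden_activation = hidden_activation
        self.feedback_depth = feedback_depth
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            loss=self.loss, reg_ratio=self.reg_ratio,
            max_epochs=self.max_epochs, grad_tol=self.grad_tol,
            val_fraction=self.val_fraction, patience=self.patience,
            seed=self.seed, lm_mu0=self.lm_mu0,
            lm_mu_factor=self.lm_mu_factor,
            max_train_rows=self.max_train_rows, jac_dtype=self.jac_dtype,
            hidden_activation=self.hidden_activation,
            feedback_depth=self.feedback_depth)

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        ws = WindowSet(X, y, groups=None if groups is None
                       else np.asarray(groups))
        self.model_, self.log_ = train_lm(self.topology, ws, self._config())
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = self.model_.forward(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X):
        return self.model_.forward(np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


class HeartbeatDetector(BaseEstimator):
    """End-to-end detector: recordings in, heartbeat events out.

    ``fit`` decimates the radar channels to 100 Hz, derives the binary
    target from the ECG (Pan-Tompkins R peaks, 400 ms pulse at 200 ms
    delay), trains the configured topology with Levenberg-Marquardt,
    and calibrates the peak-detection amplitude on a small calibration
    subset (the first training recording unless given explicitly).
    ``predict`` returns :class:`~radarbeat.postprocess.BeatDetections`
    for a new recording; ``predict_trace`` exposes the smoothed
    probability trace.
    """

    def __init__(self, topology: str = "FF 20 1", loss: str = "mse",
                 memory: float = 1.0, delay: float = TARGET_DELAY,
                 width: float = TARGET_WIDTH, ma_width: int = 10,
                 hr_range: tuple = (40.0, 120.0), amplitude="auto",
                 grid_size: int = 50, reg_ratio: float = 0.9,
                 max_epochs: int = 1000, grad_tol: float = 1e-7,
                 val_fraction: float = 0.30, patience: int = 6,
                 lm_mu0: float = 1e-3, lm_mu_factor: float = 10.0,
                 max_train_rows: Optional[int] = None,
                 jac_dtype: str = "float64",
                 hidden_activation: str = "tanh",
                 feedback_depth: int = 10, standardize: bool = False,
                 seed: int = 0):
        self.topology = topology
        self.loss = loss
        self.memory = memory
        self.delay = delay
        self.width = width
        self.ma_width = ma_width
        self.hr_range = hr_range
        self.amplitude = amplitude
        self.grid_size = grid_size
        self.reg_ratio = reg_ratio
        self.max_epochs = max_epochs
        self.grad_tol = grad_tol
        self.val_fraction = val_fraction
        self.patience = patience
        self.lm_mu0 = lm_mu0
        self.lm_mu_factor = lm_mu_factor
        self.max_train_rows = max_train_rows
        self.jac_dtype = jac_dtype
        self.hidden_activation = hidden_activation
        self.feedback_depth = feedback_depth
        self.standardize = standardize
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            loss=self.loss, reg_ratio=self.reg_ratio,
            max_epochs=self.max_epochs, grad_tol=self.grad_tol,
            val_fraction=self.val_fraction, patience=self.patience,
            seed=self.seed, lm_mu0=self.lm_mu0,
            lm_mu_factor=self.lm_mu_factor,
            max_train_rows=self.max_train_rows, jac_dtype=self.jac_dtype,
            hidden_activation=self.hidden_activation,
            feedback_depth=self.feedback_depth)

    def fit(self, recordings: Sequence[SubjectRecording], y=None,
            calib_recordings: Optional[Sequence[SubjectRecording]] = None):
        from . import postprocess as _pp

        sets = []
        for rec in recordings:
            ws, _ = prepare_recording(rec, self.memory, self.delay,
                                      self.width,
                                      standardize=self.standardize)
            sets.append(ws)
        pooled = WindowSet.concatenate(sets)
        self.model_, self.log_ = train_lm(self.topology, pooled,
                                          self._config())
        calib = list(calib_recordings) if calib_recordings \
            else list(recordings)
        traces = [self.predict_trace(rec) for rec in calib]
        refs = [pan_tompkins(rec.ecg) for rec in calib]
        if self.amplitude == "auto":
            grid = _pp.default_amplitude_grid(traces, self.grid_size)
            self.amplitude_ = _pp.calibrate_amplitude(
                traces, refs, grid, hr_range=self.hr_range)
        else:
            self.amplitude_ = float(self.amplitude)
        self.latency_shift_ = self._calibrate_latency(traces, refs)
        return self

    def _calibrate_latency(self, traces, refs) -> float:
        """Constant detector latency, estimated on the training data.

        The raw smoothed-probability peak lags the mechanical window
        by the moving-average group delay plus the network's own
        response delay (its evidence keeps accruing until the whole
        beat signature is inside the causal input window).  Both are
        constant properties of the trained chain, so a single shift is
        calibrated on the training recordings: the one that places the
        largest fraction of training peak-to-previous-R offsets inside
        the mechanical window ``[delay, delay + width)``, ties going to
        the smallest correction.  IPI statistics are invariant to it.
        """
        from . import postprocess as _pp

        offsets = []
        for trace, ref in zip(traces, refs):
            peaks = _pp.detect_peaks(trace.smoothed, self.amplitude_,
                                     self.hr_range)
            for t in peaks.times:
                prev = ref.times[ref.times <= t]
                if len(prev) and t - prev[-1] < 1.2:
                    offsets.append(t - prev[-1])
        if not offsets:  # fall back to the filter group delay alone
            return (self.ma_width - 1) / (2.0 * PROC_RATE)
        offsets = np.asarray(offsets)
        grid = np.arange(-0.1, 0.3001, 0.005)
        mass = [np.mean((offsets - s >= self.delay)
                        & (offsets - s < self.delay + self.width))
                for s in grid]
        order = sorted(range(len(grid)),
                       key=lambda j: (-mass[j], abs(grid[j])))
        return float(grid[order[0]])

    def predict_trace(self, rec: SubjectRecording):
        from . import postprocess as _pp

        ws, _ = prepare_recording(rec, self.memory, self.delay, self.width,
                                  with_targets=False,
                                  standardize=self.standardize)
        kind, _h = parse_topology(self.model_.topology_name or self.topology)
        if kind == "NARX":
            p = narx_closed_loop(self.model_, ws, self.feedback_depth)
        else:
            p = self.model_.forward(ws.inputs)
        probs = TimeSeries(p, PROC_RATE, float(ws.timestamps[0]))
        return _pp.DetectionTrace(
            probs=probs, smoothed=_pp.smooth_ma(probs, self.ma_width))

    def predict(self, rec: SubjectRecording):
        from . import postprocess as _pp

        trace = self.predict_trace(rec)
        beats = _pp.detect_peaks(trace.smoothed, self.amplitude_,
                                 self.hr_range)
        # re-reference event times by the training-calibrated constant
        # latency (moving-average group delay + network response delay);
        # processing stays causal, only the reported time is aligned
        lag = getattr(self, "latency_shift_",
                      (self.ma_width - 1) / (2.0 * PROC_RATE))
        beats = BeatTrain(beats.times - lag)
        return _pp.interpolate_missed(beats, self.hr_range,
                                      amplitude_used=self.amplitude_)
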