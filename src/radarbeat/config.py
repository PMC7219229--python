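"""Run configuration: every pipeline default in one validated record.

The YAML config mirrors the instrumentation and algorithm defaults
(rates, target delay/width, window memory, topology, loss, LM
schedule, heart-rate range, smoothing width, calibration grid size,
seeds).  Unknown keys are rejected, and the resolved configuration is
written alongside every artifact so runs are reproducible from their
outputs alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "derive_seed"]


@dataclass
class RunConfig:
    seed: int = 0
    # cohort
    n_subjects: int = 21
    duration: float = 200.0
    # rates (Hz)
    fs_radar: float = 1000.0
    fs_ecg: float = 250.0
    fs_proc: float = 100.0
    # target
    delay: float = 0.200
    width: float = 0.400
    memory: float = 1.0
    # network / training
    topology: str = "FF 20 1"
    loss: str = "mse"
    reg_ratio: float = 0.9
    max_epochs: int = 1000
    grad_tol: float = 1.0e-7
    val_fraction: float = 0.30
    patience: int = 6
    lm_mu0: float = 1.0e-3
    lm_mu_factor: float = 10.0
    max_train_rows: int = 0          # 0 = no subsampling
    jac_dtype: str = "float64"
    hidden_activation: str = "tanh"
    feedback_depth: int = 10
    standardize: bool = False        # per-recording affine input rescaling
    # postprocess
    ma_width: int = 10
    hr_min: float = 40.0
    hr_max: float = 120.0
    amplitude: str = "auto"          # "auto" or a number as string
    grid_size: int = 50
    # evaluation
    n_folds: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError(
                f"val_fraction must lie in (0, 1), got {self.val_fraction}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")
        for key in ("fs_radar", "fs_ecg", "fs_proc", "duration"):
            if not getattr(self, key) > 0:
                raise ValueError(f"{key} must be positive")
        if not 0 < self.hr_min < self.hr_max:
            raise ValueError("need 0 < hr_min < hr_max")

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        txt = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(txt, encoding="utf-8")
        return txt

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def train_overrides(self) -> dict:
        """Keyword arguments for the detector estimators."""
        return dict(
            topology=self.topology, loss=self.loss,
            reg_ratio=self.reg_ratio, max_epochs=self.max_epochs,
            grad_tol=self.grad_tol, val_fraction=self.val_fraction,
            patience=self.patience, lm_mu0=self.lm_mu0,
            lm_mu_factor=self.lm_mu_factor,
            max_train_rows=self.max_train_rows or None,
            jac_dtype=self.jac_dtype,
            hidden_activation=self.hidden_activation,
            feedback_depth=self.feedback_depth,
            standardize=self.standardize,
        )


def derive_seed(master_seed: int, module: str) -> int:
    """Deterministic per-module seed below 2**31 from one master seed."""
    digest = hashlib.sha256(f"{master_seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
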