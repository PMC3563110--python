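"""Analysis configuration: every threshold of the pipeline in one place.

Defaults follow the conventional values for micro-movement correction in
developmental resting-state data: FD censoring threshold 0.2 mm (with 1
frame removed before and 2 after each trigger), DVARS threshold 4 on a
median-1000 intensity scale, 1.5 mm run RMS exclusion, top-300 edges for
age regression and top-150 for diagnosis classification, BH FDR q = 0.05.
Configurations load from YAML so a whole run is reproducible from one
file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    # motion metrics
    radius_mm: float = 50.0
    rms_exclusion: float = 1.5
    fd_threshold: float = 0.2
    dvars_threshold: float = 4.0
    frames_before: int = 1
    frames_after: int = 2
    # time-series cleaning
    f_lo: float = 0.009
    f_hi: float = 0.08
    min_frames: int = 30
    # procedures
    poly_degree: int = 3
    match_alpha: float = 0.05
    # statistics
    fdr_q: float = 0.05
    # feature selection / learners
    top_k_age: int = 300
    top_k_dx: int = 150
    svr_c: float = 1e6          # finite surrogate for a hard margin
    svr_epsilon: float = 1e-5
    svm_c: float = 1.0
    kernel_sigma: float = 2.0   # RBF K = exp(-||x-y||^2 / (2 sigma^2))
    seed: int = 0

    @property
    def gamma(self) -> float:
        """The solver's RBF rate parameter for the sigma convention."""
        return 1.0 / (2.0 * self.kernel_sigma ** 2)


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return AnalysisConfig(**data)


def save_config(path, config: AnalysisConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
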