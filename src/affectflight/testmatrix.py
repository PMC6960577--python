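"""The 34-run evaluation matrix.

Runs 1–2 feed normalized raw windows straight into the network (no feature
extraction); runs 3–18 use the full 90-feature set; runs 19–34 add SVD
selection down to 50 features. Within each feature regime the four
activation/optimizer combinations cycle (ReLU+adam, sigmoid+sgd,
sigmoid+adam, ReLU+sgd) over four modality masks (all, −HR, −GSR, −EEG).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .evaluate import EvalReport, PipelineConfig, loocv
from .rtor import RTORConfig
from .session import FlightSession


@dataclass(frozen=True)
class TestSpec:
    __test__ = False  # evaluation-matrix row, not a pytest case

    test_id: int
    detrend: bool
    outliers: bool
    feature_extraction: bool
    svd: bool
    column_center: bool
    activation: str  # sigmoid | relu
    optimizer: str  # sgd | adam
    hr: bool
    gsr: bool
    eeg: bool

    def __post_init__(self) -> None:
        if not (self.hr or self.gsr or self.eeg):
            raise ValueError("at least one modality must be enabled")
        if self.svd and not self.feature_extraction:
            raise ValueError("SVD requires feature extraction")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(
            m for m, on in (("hr", self.hr), ("gsr", self.gsr), ("eeg", self.eeg))
            if on
        )


_COMBOS = (("relu", "adam"), ("sigmoid", "sgd"), ("sigmoid", "adam"), ("relu", "sgd"))
_MASKS = (
    (True, True, True),
    (False, True, True),
    (True, False, True),
    (True, True, False),
)


def _build_table() -> dict[int, TestSpec]:
    table: dict[int, TestSpec] = {}
    table[1] = TestSpec(1, False, False, False, False, False,
                        "sigmoid", "sgd", True, True, True)
    table[2] = TestSpec(2, False, False, False, False, False,
                        "sigmoid", "adam", True, True, True)
    tid = 3
    for use_svd in (False, True):
        for mask in _MASKS:
            for act, opt in _COMBOS:
                table[tid] = TestSpec(
                    tid, True, True, True, use_svd, True, act, opt, *mask
                )
                tid += 1
    return table


#: Test id → specification, ids 1..34.
TEST_TABLE: dict[int, TestSpec] = _build_table()


def pipeline_config_for(
    spec: TestSpec, base: PipelineConfig | None = None, seed: int = 0
) -> PipelineConfig:
    """Translate a test-matrix row into a runnable pipeline configuration.

    Matrix runs always correct the prediction stream with RTOR (every row of
    the emulated protocol ran "recognition + RTOR"), unless the caller's base
    config already sets one.
    """
    base = base or PipelineConfig()
    if base.rtor is None:
        base = replace(base, rtor=RTORConfig())
    return replace(
        base,
        detrend=spec.detrend,
        outliers=spec.outliers,
        feature_extraction=spec.feature_extraction,
        svd=spec.svd,
        column_center=spec.column_center,
        activation=spec.activation,
        optimizer=spec.optimizer,
        modalities=spec.modalities,
        seed=seed,
    )


def run_test(
    spec: TestSpec | int,
    cohort: list[FlightSession],
    seed: int = 0,
    base: PipelineConfig | None = None,
) -> EvalReport:
    """Execute one matrix row end-to-end over a cohort."""
    if isinstance(spec, int):
        spec = TEST_TABLE[spec]
    cfg = pipeline_config_for(spec, base, seed)
    return loocv(cohort, cfg)
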