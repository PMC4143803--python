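"""Result containers shared by the per-gene association tests."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneTestResult:
    """One gene x method test outcome.

    ``df_or_params`` carries method-specific diagnostics, e.g. the SKAT-O
    optimal rho, the SUM 1-df statistic, or the rPLS selected-set size; the
    ``flags`` list records degenerate outcomes (constant supervariant,
    perfect separation, Liu fallback, ...).
    """

    gene: str
    method: str
    p_value: float
    statistic: float | None = None
    df_or_params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
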