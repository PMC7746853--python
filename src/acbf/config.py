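"""Run configuration for the full segmentation pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .bilateral import BilateralParams
from .convergence import ConvergenceParams
from .levelset import RD_COEFF


@dataclass(frozen=True)
class AcbfConfig:
    """All pipeline tunables, JSON round-trippable.

    sigma_s / sigma_i / window_radius : bilateral filter parameters.
    dt : explicit Euler step of every level-set update.
    theta / check_interval / stable_checks : convergence criterion.
    max_iter : iteration cap per evolution phase (global, then local).
    polarity : "dark" segments hypoechoic (darker) lesions, "bright"
        hyperechoic ones.
    rd_coeff : diffusion coefficient of the regularization pass (fixed
        scheme constant, exposed read-only for provenance).
    use_bf : disable to run the hybrid evolution on the raw image
        (ablation arm).
    seed : master seed for any randomized fixture driven by the config.
    """

    sigma_s: float = 3.0
    sigma_i: float = 0.1
    window_radius: int | None = None
    dt: float = 10.0
    theta: float = 0.0
    check_interval: int = 10
    stable_checks: int = 3
    max_iter: int = 2000
    polarity: str = "dark"
    rd_coeff: float = RD_COEFF
    use_bf: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if self.dt <= 0 or self.max_iter < 1:
            raise ValueError("dt must be > 0 and max_iter >= 1")
        if self.rd_coeff != RD_COEFF:
            raise ValueError("rd_coeff is a fixed scheme constant")

    @property
    def polarity_sign(self) -> int:
        return 1 if self.polarity == "dark" else -1

    @property
    def bilateral_params(self) -> BilateralParams:
        return BilateralParams(
            sigma_s=self.sigma_s, sigma_i=self.sigma_i, window_radius=self.window_radius
        )

    @property
    def convergence_params(self) -> ConvergenceParams:
        return ConvergenceParams(
            theta=self.theta,
            check_interval=self.check_interval,
            stable_checks=self.stable_checks,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AcbfConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = json.loads(text)
        return cls(**data)
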