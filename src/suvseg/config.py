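"""Run configuration with the published parameter set as defaults.

The level-set parameters follow the method's reference setting:
``lambda_tol`` (threshold-iteration tolerance) 0.1, entropy neighbourhood
radius ``r_px`` 15 px, Gaussian fitting kernel ``sigma_g`` 1.5 px, length
coefficient ``nu`` 0.001*255^2, distance-regulariser weight ``mu`` 1,
energy-stability tolerance ``chi`` 1e-3 and iteration cap ``k_max`` 300,
with Heaviside width ``epsilon`` 1 and unit region/channel weights.

Parameters the method leaves open (time step, guide band width, the sigma
floor of the entropy model, the opening radius of the lung mask) are
numerical choices of this implementation and are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    # initial contour (threshold iteration)
    lambda_tol: float = 0.1
    # entropy edge guide
    r_px: int = 15
    band_px: float = 3.0
    sigma_floor: float = 1e-3
    use_entropy_guide: bool = True
    # LBF fitting / level-set evolution
    sigma_g: float = 1.5
    nu: float = 0.001 * 255.0**2
    mu: float = 1.0
    chi: float = 1e-3
    k_max: int = 300
    epsilon: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    Lambda1: float = 1.0
    Lambda2: float = 1.0
    dt: float = 0.01
    max_dt_halvings: int = 6
    # ROI extraction
    R_mm: float = 30.0
    open_radius_px: int = 2
    # geometry
    pixel_spacing_mm: float = 1.0

    def validate(self) -> "RunConfig":
        positive = {
            "lambda_tol": self.lambda_tol,
            "r_px": self.r_px,
            "sigma_floor": self.sigma_floor,
            "sigma_g": self.sigma_g,
            "mu": self.mu,
            "chi": self.chi,
            "epsilon": self.epsilon,
            "dt": self.dt,
            "R_mm": self.R_mm,
            "pixel_spacing_mm": self.pixel_spacing_mm,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be positive, got {value!r}")
        if self.nu < 0 or self.band_px < 0 or self.k_max < 0:
            raise ParameterError("nu, band_px and k_max must be nonnegative")
        if self.open_radius_px < 0 or self.max_dt_halvings < 0:
            raise ParameterError("open_radius_px and max_dt_halvings must be >= 0")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ParameterError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
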