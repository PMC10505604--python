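"""Field containers passed between pipeline stages.

``RawPhaseSeries`` holds wrapped (or unwrapped) MR phase sampled over
wave-phase offsets; ``ComplexWaveField`` holds the complex fundamental
harmonic of the displacement proxy per frequency and encoding component.
Both carry the acquisition grid and a provenance trail so downstream code
can verify what processing has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import AcquisitionGrid

__all__ = ["RawPhaseSeries", "ComplexWaveField", "wrap_phase"]

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, TWO_PI) - np.pi


@dataclass
class RawPhaseSeries:
    """Phase volumes indexed (frequency, component, offset, z, y, x), radians.

    ``wrapped`` records whether values are constrained to [-pi, pi);
    the unwrapping stages flip it to False.
    """

    data: np.ndarray
    grid: AcquisitionGrid
    noise_sigma: float = 0.0
    wrapped: bool = True
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (
            self.grid.n_frequencies,
            self.grid.n_components,
            self.grid.n_offsets,
            *self.grid.shape,
        )
        if self.data.shape != expected:
            raise ValueError(
                f"phase series shape {self.data.shape} does not match grid "
                f"expectation {expected}"
            )
        if self.wrapped:
            lo, hi = self.data.min(initial=0.0), self.data.max(initial=0.0)
            if lo < -np.pi - 1e-9 or hi >= np.pi + 1e-9:
                raise ValueError(
                    f"wrapped phase must lie in [-pi, pi); found range [{lo}, {hi}]"
                )

    def with_data(self, data: np.ndarray, step: str, *, wrapped: bool | None = None) -> "RawPhaseSeries":
        return replace(
            self,
            data=data,
            wrapped=self.wrapped if wrapped is None else wrapped,
            provenance=self.provenance + (step,),
        )


@dataclass
class ComplexWaveField:
    """Complex fundamental-harmonic field, indexed (frequency, component, z, y, x)."""

    data: np.ndarray
    grid: AcquisitionGrid
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        expected = (self.grid.n_frequencies, self.grid.n_components, *self.grid.shape)
        if self.data.shape != expected:
            raise ValueError(
                f"wave field shape {self.data.shape} does not match grid "
                f"expectation {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("wave field contains non-finite values")

    def with_data(self, data: np.ndarray, step: str) -> "ComplexWaveField":
        return ComplexWaveField(data, self.grid, self.provenance + (step,))
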