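"""Parameter containers and configuration file handling.

All public containers carry the model's physiological constants in the
units in which they are conventionally quoted (F/cm^2, S/cm^2, mV, ms,
micrometres).  The simulation engine converts to its internal working
units (uF/cm^2, mS/cm^2, mV, ms) at build time.

Configuration files are YAML with one section per container; every
physiological constant is a named key so a run is fully specified by its
config plus seeds.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml


class ConfigurationError(ValueError):
    """A parameter container violates one of its invariants."""


@dataclass
class NeuronParameters:
    """Single-compartment Hodgkin-Huxley membrane constants.

    Capacitance and conductances are per unit membrane area (F/cm^2 and
    S/cm^2); reversal potentials in mV.  Gating kinetics are the standard
    squid-axon rate functions displaced along the voltage axis by the two
    ``*_kinetics_shift`` constants; see :mod:`gammares.hh`.
    """

    membrane_capacitance: float = 1.0e-6
    leak_conductance: float = 50.0e-6
    leak_reversal: float = -70.0
    na_reversal: float = 55.0
    k_reversal: float = -80.0
    exc_reversal: float = 0.0
    inh_reversal: float = -80.0
    na_max_conductance: float = 120.0e-3
    k_max_conductance: float = 36.0e-3
    spike_detection_threshold: float = 0.0
    spike_lockout: float = 2.0  # ms
    # Voltage-axis displacement of the squid-axon gating rates (mV).  The K
    # shift is solved so the full membrane (leak + Na window + K at steady
    # state) rests exactly at leak_reversal; see gammares.hh.
    na_kinetics_shift: float = 5.0
    k_kinetics_shift: float = 12.5814

    def __post_init__(self) -> None:
        import math

        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if not math.isfinite(v):
                raise ConfigurationError(f"non-finite neuron parameter {f_.name!r}")
        if not (self.inh_reversal <= self.leak_reversal < self.na_reversal):
            raise ConfigurationError(
                "reversal potentials must satisfy inh_reversal <= leak_reversal < na_reversal"
            )
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ConfigurationError("membrane_capacitance and leak_conductance must be positive")

    @property
    def membrane_time_constant(self) -> float:
        """Passive time constant C/g_L in ms."""
        return 1e3 * self.membrane_capacitance / self.leak_conductance


@dataclass
class SynapticKernelParameters:
    """Difference-of-exponentials conductance kernel, peak-normalised to 1.

    ``source_type`` selects which presynaptic population the kernel
    describes: excitatory synapses decay in 3 ms, inhibitory in 7 ms,
    both rising in 1 ms.
    """

    decay_time_constant: float
    rise_time_constant: float
    source_type: Literal["E", "I"]

    def __post_init__(self) -> None:
        if not self.decay_time_constant > self.rise_time_constant > 0:
            raise ConfigurationError(
                "kernel time constants must satisfy decay > rise > 0 "
                f"(got decay={self.decay_time_constant}, rise={self.rise_time_constant})"
            )
        if self.source_type not in ("E", "I"):
            raise ConfigurationError(f"source_type must be 'E' or 'I', got {self.source_type!r}")


def default_kernels() -> dict[str, SynapticKernelParameters]:
    return {
        "E": SynapticKernelParameters(3.0, 1.0, "E"),
        "I": SynapticKernelParameters(7.0, 1.0, "I"),
    }


@dataclass
class ConnectivitySpec:
    """Distance-decayed recurrent coupling.

    Weights are the peak synaptic conductance (mS/cm^2) contributed by a
    single presynaptic spike at zero distance, per ordered population
    pair: ``weight_EI`` couples I sources onto E targets, etc.  The
    spatial profile decays with the source population's length constant
    (exc 200 um, inh 100 um) and is cut off at ``connection_radius_cutoff``.
    """

    decay_length_exc: float = 200.0
    decay_length_inh: float = 100.0
    weight_EE: float = 0.0
    weight_EI: float = 0.0
    weight_IE: float = 0.0
    weight_II: float = 0.0
    connection_radius_cutoff: float = 600.0
    spatial_profile: Literal["exponential", "gaussian"] = "exponential"

    def __post_init__(self) -> None:
        if self.decay_length_exc <= 0 or self.decay_length_inh <= 0:
            raise ConfigurationError("spatial decay lengths must be positive")
        for name in ("weight_EE", "weight_EI", "weight_IE", "weight_II"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.connection_radius_cutoff < max(self.decay_length_exc, self.decay_length_inh):
            raise ConfigurationError(
                "connection_radius_cutoff must be at least the largest decay length"
            )
        if self.spatial_profile not in ("exponential", "gaussian"):
            raise ConfigurationError(f"unknown spatial_profile {self.spatial_profile!r}")

    def weight(self, target_type: str, source_type: str) -> float:
        return getattr(self, f"weight_{target_type}{source_type}")


@dataclass
class GeometrySpec:
    """Requested sheet geometry (sizes in mm)."""

    sheet_width: float = 1.0
    sheet_height: float = 1.0
    neuron_count: int = 3341
    excitatory_fraction: float = 0.75
    grid_jitter: float = 0.25  # fraction of grid pitch

    def __post_init__(self) -> None:
        if self.neuron_count < 1:
            raise ConfigurationError(f"neuron_count must be >= 1, got {self.neuron_count}")
        if not (0.0 < self.excitatory_fraction < 1.0):
            raise ConfigurationError(
                f"excitatory_fraction must be in (0, 1), got {self.excitatory_fraction}"
            )
        if self.sheet_width <= 0 or self.sheet_height <= 0:
            raise ConfigurationError("sheet dimensions must be positive")


@dataclass
class SimulationConfig:
    """Integration settings for one run."""

    time_step: float = 0.05  # ms
    duration: float = 10.0  # s
    warmup_discard: float = 0.5  # s
    seed: int = 0
    record_voltages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.time_step > 0.1:
            raise ConfigurationError(
                f"time_step must be in (0, 0.1] ms, got {self.time_step}"
            )
        if not self.duration > self.warmup_discard >= 0:
            raise ConfigurationError("require duration > warmup_discard >= 0")


@dataclass
class ModelConfig:
    """Bundle of everything needed to build and run the network."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    connectivity: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    neuron: NeuronParameters = field(default_factory=NeuronParameters)
    feedforward_gmax: float = 30.0  # uS/cm^2, swept 30-70 as the plasticity knob
    gmax_bounds: tuple[float, float] = (30.0, 70.0)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        lo, hi = self.gmax_bounds
        if not (lo <= self.feedforward_gmax <= hi):
            raise ConfigurationError(
                f"feedforward_gmax={self.feedforward_gmax} outside bounds {self.gmax_bounds}"
            )

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "geometry": dataclasses.asdict(self.geometry),
            "connectivity": dataclasses.asdict(self.connectivity),
            "neuron": dataclasses.asdict(self.neuron),
            "feedforward_gmax": self.feedforward_gmax,
            "gmax_bounds": list(self.gmax_bounds),
            "simulation": dataclasses.asdict(self.simulation),
        }
        d["simulation"]["record_voltages"] = list(self.simulation.record_voltages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        sim = dict(d.get("simulation", {}))
        if "record_voltages" in sim:
            sim["record_voltages"] = tuple(sim["record_voltages"])
        return cls(
            geometry=GeometrySpec(**d.get("geometry", {})),
            connectivity=ConnectivitySpec(**d.get("connectivity", {})),
            neuron=NeuronParameters(**d.get("neuron", {})),
            feedforward_gmax=d.get("feedforward_gmax", 30.0),
            gmax_bounds=tuple(d.get("gmax_bounds", (30.0, 70.0))),
            simulation=SimulationConfig(**sim),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> ModelConfig:
    """The shipped configuration with calibrated recurrent weights."""
    ref = importlib.resources.files("gammares") / "configs" / "default.yaml"
    return ModelConfig.from_dict(yaml.safe_load(ref.read_text()))
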