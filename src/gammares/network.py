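"""Network construction: cell sheet geometry, synaptic kernels and
distance-decayed recurrent connectivity.

The model cortex is a 1 mm x 1 mm sheet of 3341 single-compartment
neurons, 75% excitatory and 25% inhibitory.  Cells sit on a jittered
regular grid; every ordered pair within a cutoff radius is coupled with
a weight W_(target,source) x f(r), where f is an isotropic spatial decay
evaluated with the source population's length constant (200 um for
excitatory sources, 100 um for inhibitory).  Connectivity is therefore
deterministic given the seed that fixes positions and type labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    ConfigurationError,
    ConnectivitySpec,
    GeometrySpec,
    NeuronParameters,
    SynapticKernelParameters,
    default_kernels,
)


@dataclass
class NetworkGeometry:
    """Realised cell sheet: positions in um, boolean E/I labels."""

    sheet_width: float
    sheet_height: float
    positions: np.ndarray  # (n, 2) um
    is_excitatory: np.ndarray  # (n,) bool

    @property
    def neuron_count(self) -> int:
        return self.positions.shape[0]

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def n_inhibitory(self) -> int:
        return self.neuron_count - self.n_excitatory


def spatial_factor(distance, source_type: str,
                   connectivity: ConnectivitySpec | None = None):
    """Dimensionless distance decay of recurrent coupling, in [0, 1].

    Equals 1 at zero distance and decreases monotonically; the length
    constant is the source population's (``'E'`` -> 200 um, ``'I'`` ->
    100 um by default).  The profile is exponential ``exp(-r/lambda)``
    or, if configured, Gaussian ``exp(-r^2/lambda^2)``.
    """
    if connectivity is None:
        connectivity = ConnectivitySpec()
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    if source_type == "E":
        lam = connectivity.decay_length_exc
    elif source_type == "I":
        lam = connectivity.decay_length_inh
    else:
        raise ValueError(f"source_type must be 'E' or 'I', got {source_type!r}")
    if connectivity.spatial_profile == "gaussian":
        out = np.exp(-(distance / lam) ** 2)
    else:
        out = np.exp(-distance / lam)
    return out if out.ndim else float(out)


def synaptic_kernel(t, kernel: SynapticKernelParameters):
    """Unitless conductance waveform of one synaptic event, peak 1.

    Difference of exponentials ``exp(-t/tau_d) - exp(-t/tau_r)`` scaled
    so its maximum is exactly 1; zero at t = 0 and for t < 0.
    """
    t = np.asarray(t, dtype=float)
    peak = kernel_peak(kernel)
    raw = np.exp(-t / kernel.decay_time_constant) - np.exp(-t / kernel.rise_time_constant)
    out = np.where(t >= 0, raw / peak[1], 0.0)
    return out if out.ndim else float(out)


def kernel_peak(kernel: SynapticKernelParameters) -> tuple[float, float]:
    """(time of peak in ms, unnormalised peak value) of the kernel."""
    td, tr = kernel.decay_time_constant, kernel.rise_time_constant
    t_peak = td * tr / (td - tr) * np.log(td / tr)
    value = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return float(t_peak), float(value)


def build_geometry(spec: GeometrySpec, seed: int) -> NetworkGeometry:
    """Place neurons on a jittered square grid and assign E/I labels.

    The grid has ``ceil(sqrt(n))`` columns; the required number of cells
    is selected from the full grid by a seeded draw, positions are
    jittered uniformly by up to ``grid_jitter`` of the pitch, and type
    labels are a seeded shuffle hitting the nearest-integer E count
    (2506 E / 835 I for the defaults).
    """
    if seed < 0:
        raise ConfigurationError(f"seed must be non-negative, got {seed}")
    n = spec.neuron_count
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0DE)))
    w_um, h_um = 1e3 * spec.sheet_width, 1e3 * spec.sheet_height
    side = int(np.ceil(np.sqrt(n)))
    pitch_x, pitch_y = w_um / side, h_um / side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    centers = np.column_stack([(gx.ravel() + 0.5) * pitch_x, (gy.ravel() + 0.5) * pitch_y])
    keep = rng.choice(side * side, size=n, replace=False)
    keep.sort()
    pos = centers[keep]
    jitter = rng.uniform(-spec.grid_jitter, spec.grid_jitter, size=(n, 2))
    pos = pos + jitter * np.array([pitch_x, pitch_y])
    pos[:, 0] = np.clip(pos[:, 0], 0.0, w_um)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, h_um)

    n_exc = int(round(spec.excitatory_fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[:n_exc] = True
    rng.shuffle(labels)
    return NetworkGeometry(spec.sheet_width, spec.sheet_height, pos, labels)


class Network:
    """The built model cortex.

    Holds the realised geometry, the dense recurrent weight matrix and
    the constants the integrator needs.  ``weights[j, i]`` is the peak
    conductance (mS/cm^2) that one spike of source neuron ``j``
    contributes to target ``i`` -- source-major layout so that spike
    propagation touches contiguous memory.  The kernel shape of the
    contribution is set by the source's population (E or I).

    ``feedforward_gmax`` (uS/cm^2) is the peak EPSC conductance evoked
    by one thalamocortical input spike -- the synaptic-plasticity knob.
    """

    def __init__(
        self,
        geometry: NetworkGeometry,
        connectivity: ConnectivitySpec,
        neuron_params: NeuronParameters,
        kernels: dict[str, SynapticKernelParameters],
        feedforward_gmax: float,
        weights: np.ndarray,
    ):
        self.geometry = geometry
        self.connectivity = connectivity
        self.neuron_params = neuron_params
        self.kernels = kernels
        self.feedforward_gmax = feedforward_gmax
        self.weights = weights

    @property
    def n_neurons(self) -> int:
        return self.geometry.neuron_count

    def connection_table(self, include_zero: bool = False) -> pd.DataFrame:
        """Three-column (source, target, weight) view of the connectivity."""
        src, tgt = np.nonzero(self.weights) if not include_zero else np.meshgrid(
            np.arange(self.n_neurons), np.arange(self.n_neurons), indexing="ij"
        )
        if include_zero:
            src, tgt = src.ravel(), tgt.ravel()
        return pd.DataFrame(
            {"source": src, "target": tgt, "weight": self.weights[src, tgt]}
        )


def build_network(
    geometry_spec: GeometrySpec,
    connectivity_spec: ConnectivitySpec,
    neuron_params: NeuronParameters | None = None,
    seed: int = 0,
    feedforward_gmax: float = 30.0,
    kernels: dict[str, SynapticKernelParameters] | None = None,
) -> Network:
    """Build the full network deterministically from its specs and seed.

    Pairwise weights are ``W_(sigma sigma') * f(r)`` with the spatial
    factor evaluated from the source type's decay length; pairs beyond
    the cutoff radius, and self-pairs, get weight zero.
    """
    neuron_params = neuron_params or NeuronParameters()
    kernels = kernels or default_kernels()
    geom = build_geometry(geometry_spec, seed)
    n = geom.neuron_count

    d = np.linalg.norm(geom.positions[:, None, :] - geom.positions[None, :, :], axis=-1)
    w = np.zeros((n, n))
    for src_exc in (True, False):
        stype = "E" if src_exc else "I"
        src_mask = geom.is_excitatory == src_exc
        factor = np.asarray(spatial_factor(d[src_mask], stype, connectivity_spec))
        factor[d[src_mask] > connectivity_spec.connection_radius_cutoff] = 0.0
        for tgt_exc in (True, False):
            ttype = "E" if tgt_exc else "I"
            tgt_mask = geom.is_excitatory == tgt_exc
            coupling = connectivity_spec.weight(ttype, stype)
            w[np.ix_(src_mask, tgt_mask)] = coupling * factor[:, tgt_mask]
    np.fill_diagonal(w, 0.0)
    return Network(geom, connectivity_spec, neuron_params, kernels,
                   feedforward_gmax, w)
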