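"""Fixed physiological constants and parameter templates for the microcircuit.

Every quantity that the model treats as a *template* (scaled multiplicatively
by free log-parameters) or as a fixed biophysical constant lives here, so that
alternative conventions can be loaded from a YAML file without touching code.

Conventions
-----------
* Time is measured in seconds inside the dynamics; channel rate templates are
  quoted as time constants in **milliseconds** (AMPA 4 ms, GABA 16 ms,
  NMDA 100 ms), the convention of the conductance microcircuit literature.
* Voltages are in mV.  Reversal potentials default to leak -70, excitatory
  (AMPA) 60, inhibitory (GABA) -90 and NMDA 60 mV.
* Intrinsic coupling templates are 4x4 matrices over the populations
  (SS, SP, INH, DP); entry (i, j) couples presynaptic population j to
  postsynaptic population i.  The inhibitory template ``H_GABA`` and the
  excitatory template ``H_EXC`` partition the default intrinsic template
  ``H_DEFAULT = H_GABA + H_EXC``, so the single-glutamate and the separated
  AMPA/NMDA parameterisations coincide at the prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

POPULATIONS = ("ss", "sp", "inh", "dp")
SS, SP, INH, DP = 0, 1, 2, 3

# Default intrinsic coupling templates (dimensionless synaptic gains).
_H_GABA = [
    [8.0, 0.0, 2.0, 0.0],
    [0.0, 8.0, 2.0, 0.0],
    [0.0, 0.0, 32.0, 0.0],
    [0.0, 0.0, 8.0, 128.0],
]
_H_EXC = [
    [0.0, 0.0, 0.0, 0.0],
    [4.0, 0.0, 0.0, 0.0],
    [4.0, 0.0, 0.0, 2.0],
    [0.0, 4.0, 0.0, 0.0],
]
# Extrinsic template: rows are target populations, columns the projecting
# populations of the source region (superficial pyramidal, deep pyramidal).
_A_TEMPLATE = [
    [1.0, 0.0],
    [0.0, 1.0],
    [0.0, 2.0],
    [0.0, 0.0],
]


@dataclass
class CircuitConfig:
    """Biophysical constants and multiplicative templates of the microcircuit."""

    # Channel kinetics: time constants in ms for AMPA, GABA, NMDA.
    kappa: tuple = (4.0, 16.0, 100.0)
    # Membrane capacitance template for SS, SP, INH, DP.
    capacitance: tuple = (0.128, 0.128, 0.256, 0.032)
    # Reversal potentials (mV): leak, excitatory, inhibitory, NMDA.
    v_leak: float = -70.0
    v_exc: float = 60.0
    v_inh: float = -90.0
    v_nmda: float = 60.0
    leak_conductance: float = 1.0
    # Firing-rate sigmoid: expected rate in [0, 1].
    sigmoid_slope: float = 0.25       # 1/mV
    sigmoid_threshold: float = -52.0  # mV
    # Voltage-dependent magnesium block of the NMDA channel.
    mg_scale: float = 0.33
    mg_slope: float = 0.06            # 1/mV
    # Constant background drive onto the AMPA conductance of every population,
    # setting a depolarised operating point with non-trivial loop gain.
    background_drive: float = 0.6
    # Synaptic delay templates in ms: within-region, between-region.
    delays: tuple = (2.0, 16.0)
    # Intrinsic coupling templates.
    h_gaba: list = field(default_factory=lambda: [row[:] for row in _H_GABA])
    h_exc: list = field(default_factory=lambda: [row[:] for row in _H_EXC])
    # Extrinsic coupling template (applies to both AMPA- and NMDA-mediated
    # projections, separately scaled).
    a_template: list = field(default_factory=lambda: [row[:] for row in _A_TEMPLATE])
    extrinsic_scale: float = 0.125   # the "/8" of the printed template
    # Observation: fixed SP weight 1; template weights for SS and DP.
    obs_weight_ss: float = 0.2
    obs_weight_dp: float = 0.2
    # Spectral templates: endogenous fluctuations gu0 * f^-1 and sensor noise.
    gu_amplitude: float = 1.0e-3
    gu_exponent: float = 1.0
    gb_amplitude: float = 1.0e-6
    gb_exponent: float = 1.0
    gc_amplitude: float = 1.0e-6
    gc_exponent: float = 1.0

    @property
    def h_default(self) -> np.ndarray:
        """Single-glutamate intrinsic template (GABA + excitatory parts)."""
        return np.asarray(self.h_gaba) + np.asarray(self.h_exc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: tuple(v) if isinstance(cls.__dataclass_fields__[k].default, tuple) else v
                      for k, v in raw.items()})


_DEFAULT = CircuitConfig()


def default_config() -> CircuitConfig:
    """Return the shared default :class:`CircuitConfig` instance."""
    return _DEFAULT
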