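"""Condition-specific matrices linking baseline to follow-up parameters.

Disease progression between the baseline (BL) and follow-up (AF) recordings is
modelled as an additive perturbation of the baseline parameters,

    theta_AF = theta_BL + X o B,

where ``X`` is a fixed sensitivity mask over named parameter groups and ``B``
the unknown condition effects estimated from data.  Two designs are shipped:
a non-informative design enabling every condition-modifiable parameter
("ones"), and a clinically informed design of twelve connection groups within
the four-region default mode network ("clinical12") restricting progression to
intrinsic gains of MPFC/PCC and AMPA/NMDA-mediated projections among the DMN
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DesignError, LayoutError
from .model import ModelVariant, ParameterVector, get_layout, DMN_LABELS


@dataclass(frozen=True)
class ConditionGroup:
    """One named group of parameter indices sharing a condition effect."""

    name: str
    indices: tuple
    X: float = 1.0


@dataclass
class ConditionDesign:
    """Sensitivity mask X over named parameter groups.

    Groups are disjoint sets of indices into the flat parameter vector; a
    group with ``X = 0`` contributes nothing to the follow-up parameters.
    """

    label: str
    groups: list
    n_params: int

    def __post_init__(self):
        seen = set()
        for g in self.groups:
            overlap = seen.intersection(g.indices)
            if overlap:
                raise DesignError(
                    f"design {self.label!r}: group {g.name!r} reuses indices {sorted(overlap)}"
                )
            if g.indices and max(g.indices) >= self.n_params:
                raise DesignError(f"group {g.name!r} indexes beyond the parameter vector")
            seen.update(g.indices)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_names(self) -> list:
        return [g.name for g in self.groups]

    def expand(self, B) -> np.ndarray:
        """Map condition effects ``B`` (..., n_groups) to a parameter shift."""
        B = np.asarray(B, dtype=float)
        if B.shape[-1] != self.n_groups:
            raise DesignError(
                f"B has {B.shape[-1]} entries; design {self.label!r} has "
                f"{self.n_groups} groups"
            )
        delta = np.zeros(B.shape[:-1] + (self.n_params,))
        for k, g in enumerate(self.groups):
            for idx in g.indices:
                delta[..., idx] = delta[..., idx] + g.X * B[..., k]
        return delta

    def to_yaml(self, path) -> None:
        import yaml
        payload = {
            "label": self.label,
            "n_params": int(self.n_params),
            "groups": [{"name": g.name, "indices": [int(i) for i in g.indices],
                        "X": float(g.X)} for g in self.groups],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConditionDesign":
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        groups = [ConditionGroup(g["name"], tuple(g["indices"]), g.get("X", 1.0))
                  for g in payload["groups"]]
        return cls(payload["label"], groups, payload["n_params"])

    def drop(self, name: str) -> "ConditionDesign":
        """Design with one group's sensitivity switched off (for reductions)."""
        if name not in self.group_names:
            raise DesignError(f"no group named {name!r} in design {self.label!r}")
        groups = [replace(g, X=0.0) if g.name == name else g for g in self.groups]
        return ConditionDesign(f"{self.label}-no-{name}", groups, self.n_params)


def apply_condition_effects(theta_bl, design: ConditionDesign, B):
    """theta_AF = theta_BL + X o B; blocks outside the design are untouched."""
    if isinstance(theta_bl, ParameterVector):
        out = theta_bl.copy()
        out.values = theta_bl.values + design.expand(B)
        out.B = np.asarray(B, dtype=float).copy()
        out.design_label = design.label
        return out
    vec = np.asarray(theta_bl, dtype=float)
    if vec.shape[-1] != design.n_params:
        raise DesignError("parameter vector length does not match design")
    return vec + design.expand(B)


# ---------------------------------------------------------------------------
# Shipped designs
# ---------------------------------------------------------------------------

def _intrinsic_block_index(layout, block: str, region: int, position) -> int:
    """Flat index of one intrinsic-gain entry (i, j) of ``block`` in ``region``."""
    positions = {
        "H": layout.h_positions,
        "Hi": layout.gaba_positions,
        "Hnmda": layout.exc_positions,
        "Hampa": layout.exc_positions,
    }[block]
    sl, shape = layout.blocks[block]
    k = positions.index(tuple(position))
    return sl.start + region * shape[1] + k


def ones_design(variant: ModelVariant) -> ConditionDesign:
    """Non-informative design: every modifiable parameter has its own group, X = 1.

    Modifiable parameters are the intrinsic gains and the extrinsic AMPA- and
    NMDA-mediated connection scalings.
    """
    layout = get_layout(variant)
    labels = variant.region_labels
    groups = []
    if variant.dual_glutamate:
        intrinsic = [("Hi", layout.gaba_positions), ("Hnmda", layout.exc_positions),
                     ("Hampa", layout.exc_positions)]
    else:
        intrinsic = [("H", layout.h_positions)]
    pops = ("ss", "sp", "inh", "dp")
    for block, positions in intrinsic:
        for r in range(variant.n_regions):
            for (i, j) in positions:
                idx = _intrinsic_block_index(layout, block, r, (i, j))
                groups.append(ConditionGroup(
                    f"{block}.{labels[r]}.{pops[i]}<-{pops[j]}", (idx,), 1.0))
    for block in ("A", "AN"):
        sl, _ = layout.blocks[block]
        for k, (s, t) in enumerate(layout.edges):
            groups.append(ConditionGroup(
                f"{block}.{labels[s]}->{labels[t]}", (sl.start + k,), 1.0))
    return ConditionDesign("ones", groups, layout.n_params)


# The twelve clinically motivated connection groups of the DMN analysis:
# intrinsic superficial/deep self-inhibition and excitatory intrinsic chains
# of MPFC and PCC, plus AMPA- and NMDA-mediated projections among the nodes.
_CLINICAL_GROUPS = [
    ("1.selfinh.MPFC", "selfinh", "MPFC"),
    ("2.ampa.MPFC-PCC", "ampa", ("MPFC", "PCC")),
    ("3.selfinh.PCC", "selfinh", "PCC"),
    ("4.ampa.PCC-LAG", "ampa", ("PCC", "LAG")),
    ("5.ampa.MPFC-RAG", "ampa", ("MPFC", "RAG")),
    ("6.ampa.PCC-RAG", "ampa", ("PCC", "RAG")),
    ("7.intrinsic.MPFC", "exc_intrinsic", "MPFC"),
    ("8.nmda.MPFC-PCC", "nmda", ("MPFC", "PCC")),
    ("9.intrinsic.PCC", "exc_intrinsic", "PCC"),
    ("10.nmda.PCC-RAG", "nmda", ("PCC", "RAG")),
    ("11.nmda.MPFC-RAG", "nmda", ("MPFC", "RAG")),
    ("12.nmda.PCC-LAG", "nmda", ("PCC", "LAG")),
]


def clinical_design(variant: ModelVariant = None) -> ConditionDesign:
    """Clinically informed design of 12 groups for the 4-region DMN.

    Self-inhibition groups address the SP and DP intrinsic gains of the named
    region; excitatory intrinsic groups the SS->SP and SP->DP chains; distal
    AMPA/NMDA groups both directed extrinsic scalings of the named pair
    (undirected clinical statements map to symmetric groups with per-direction
    parameters).  All other parameters are insensitive (X = 0).
    """
    variant = variant or ModelVariant(dual_glutamate=True, regional_stl=True)
    labels = variant.region_labels
    if variant.n_regions != 4 or set(labels) != set(DMN_LABELS):
        raise DesignError(
            "the clinical design requires the 4-region DMN labelling "
            f"{DMN_LABELS}; got {labels}"
        )
    layout = get_layout(variant)
    region_of = {lab: k for k, lab in enumerate(labels)}
    groups = []
    for name, kind, where in _CLINICAL_GROUPS:
        if kind == "selfinh":
            r = region_of[where]
            block = "Hi" if variant.dual_glutamate else "H"
            idx = (
                _intrinsic_block_index(layout, block, r, (1, 1)),  # SP self-inhibition
                _intrinsic_block_index(layout, block, r, (3, 3)),  # DP self-inhibition
            )
        elif kind == "exc_intrinsic":
            r = region_of[where]
            blocks = ("Hnmda", "Hampa") if variant.dual_glutamate else ("H",)
            idx = tuple(
                _intrinsic_block_index(layout, blk, r, pos)
                for blk in blocks
                for pos in ((1, 0), (3, 1))  # SS->SP and SP->DP chains
            )
        else:
            x, y = (region_of[w] for w in where)
            block = "A" if kind == "ampa" else "AN"
            sl, _ = layout.blocks[block]
            idx = (sl.start + layout.edge_index(x, y), sl.start + layout.edge_index(y, x))
        groups.append(ConditionGroup(name, idx, 1.0))
    return ConditionDesign("clinical12", groups, layout.n_params)


# ---------------------------------------------------------------------------
# Model space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelEntry:
    label: str
    variant: ModelVariant
    design: ConditionDesign
    parent: str = None   # label of the full model this is a reduction of


@dataclass
class ModelSpace:
    """Ordered list of (variant, condition design) candidate models."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            raise DesignError("model-space labels must be unique")

    @property
    def labels(self) -> list:
        return [e.label for e in self.entries]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_model_space(include_submodels: bool = False,
                      region_labels: tuple = DMN_LABELS) -> ModelSpace:
    """The 2x2 variant grid crossed with the two condition designs.

    With ``include_submodels=True``, nested reductions of the full clinical
    model (one per clinical group, sensitivity switched off) are appended for
    Bayesian model reduction from the full fit.
    """
    entries = []
    for dual in (False, True):
        for rstl in (False, True):
            variant = ModelVariant(dual_glutamate=dual, regional_stl=rstl,
                                   n_regions=4, region_labels=region_labels)
            for design_fn in (ones_design, clinical_design):
                design = design_fn(variant)
                entries.append(ModelEntry(f"{variant.name}+{design.label}",
                                          variant, design))
    if include_submodels:
        full_variant = ModelVariant(dual_glutamate=True, regional_stl=True,
                                    n_regions=4, region_labels=region_labels)
        full = clinical_design(full_variant)
        parent = f"{full_variant.name}+{full.label}"
        for g in full.groups:
            entries.append(ModelEntry(f"drop:{g.name}", full_variant,
                                      full.drop(g.name), parent=parent))
    return ModelSpace(entries)
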