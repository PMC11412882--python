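"""Core domain types for natural-number reaction networks.

A model is a set of named chemical elements with natural-number molecule
counts, an ordered list of stoichiometric reactions, optional scheduled
molecule inflow/outflow events, a simulation time window, and plot requests.
Counts are arbitrary-precision Python integers so that macroscopic systems
(e.g. 2e24 water molecules) are represented exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FAMILIES",
    "NAME_RE",
    "ElementDecl",
    "Reaction",
    "InOutEvent",
    "SimulationConfig",
    "Model",
    "Diagnostic",
    "ModelError",
    "validate_model",
    "initial_state",
]

#: Reaction families.  ``standard`` is the general multi-reactant rule;
#: ``mono`` is the single-reactant rule with success probability k/(1+k);
#: ``decay_zero`` destroys its reactant with no products; ``linear_dec`` /
#: ``linear_inc`` remove/add a fixed quantum with at most one trial per step.
FAMILIES = ("standard", "mono", "decay_zero", "linear_dec", "linear_inc")

#: Element names are case-sensitive identifiers; the character class admits
#: chemical labels such as ``H+``, ``OH-``, ``Hb(O2)4`` and ``pX*``.
NAME_RE = re.compile(r"^[A-Za-z0-9_+\-*()]+$")

# A name must never itself parse as a number, otherwise reaction lines in the
# text format would be ambiguous.
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _looks_numeric(token: str) -> bool:
    return bool(_NUMBER_RE.match(token))


@dataclass
class ElementDecl:
    """One chemical element (molecular species) declaration."""

    name: str
    initial_count: int
    color: str | None = None
    marker: str | None = None


@dataclass
class Reaction:
    """One stoichiometric rule.

    ``reactants`` and ``products`` are ordered ``(order, element)`` pairs;
    orders are the natural-number stoichiometric coefficients.  ``rate_constant``
    (k) sets the per-trial success probability and ``normalization`` (N) is the
    system-size parameter dividing reactant counts inside that probability,
    which makes rate constants transferable across system sizes.
    """

    label: str
    family: str
    reactants: list[tuple[int, str]]
    products: list[tuple[int, str]]
    rate_constant: float
    normalization: float


@dataclass
class InOutEvent:
    """Scheduled molecule inflow (delta > 0) or outflow (delta < 0)."""

    time: int
    element: str
    delta: int


@dataclass
class SimulationConfig:
    """Time window, output intervals and reproducibility settings.

    One simulation step advances time by exactly one unit; ``time_unit`` is a
    pass-through label (default ``"Steps"``).
    """

    start_time: int
    end_time: int
    console_interval: int = 1000
    plot_interval: int = 1000
    csv_interval: int = 1
    time_unit: str = "Steps"
    seed: int | None = None
    capture_events: bool = False


@dataclass
class Model:
    """A complete, simulatable reaction network."""

    elements: list[ElementDecl]
    reactions: list[Reaction]
    config: SimulationConfig
    inout: list[InOutEvent] = field(default_factory=list)
    plots: list[tuple[str, list[str]]] = field(default_factory=list)

    def element_names(self) -> list[str]:
        return [e.name for e in self.elements]


@dataclass
class Diagnostic:
    """One validation finding; ``where`` identifies the offending entity."""

    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.where}: {self.message}"


class ModelError(ValueError):
    """Raised when a model fails validation before simulation."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        super().__init__("; ".join(str(d) for d in diagnostics))


# arity rules per family: (min_reactants, max_reactants, min_products, max_products)
_ARITY = {
    "standard": (2, None, 0, None),
    "mono": (1, 1, 1, None),
    "decay_zero": (1, 1, 0, 0),
    "linear_dec": (1, 1, 0, 0),
    "linear_inc": (0, 0, 1, 1),
}


def validate_model(model: Model) -> list[Diagnostic]:
    """Check every structural invariant; return diagnostics (empty iff valid).

    Never raises: all findings are reported, so a caller can show them all.
    """
    diags: list[Diagnostic] = []
    seen: set[str] = set()
    for el in model.elements:
        where = f"element {el.name!r}"
        if not el.name or not NAME_RE.match(el.name):
            diags.append(Diagnostic(where, "invalid element name"))
        elif _looks_numeric(el.name):
            diags.append(Diagnostic(where, "element name must not look like a number"))
        if el.name in seen:
            diags.append(Diagnostic(where, "duplicate element name"))
        seen.add(el.name)
        if not isinstance(el.initial_count, int) or el.initial_count < 0:
            diags.append(Diagnostic(where, "initial count must be a natural number"))

    cfg = model.config
    if cfg.start_time >= cfg.end_time:
        diags.append(Diagnostic("config", "start_time must be < end_time"))
    for name in ("console_interval", "plot_interval", "csv_interval"):
        if getattr(cfg, name) < 1:
            diags.append(Diagnostic("config", f"{name} must be >= 1"))

    labels: set[str] = set()
    for rxn in model.reactions:
        where = f"reaction {rxn.label!r}"
        if not rxn.label:
            diags.append(Diagnostic(where, "empty reaction label"))
        if rxn.label in labels:
            diags.append(Diagnostic(where, "duplicate reaction label"))
        labels.add(rxn.label)
        if rxn.family not in FAMILIES:
            diags.append(Diagnostic(where, f"unknown family {rxn.family!r}"))
            continue
        lo_r, hi_r, lo_p, hi_p = _ARITY[rxn.family]
        nr, np_ = len(rxn.reactants), len(rxn.products)
        if nr < lo_r or (hi_r is not None and nr > hi_r):
            diags.append(
                Diagnostic(where, f"family {rxn.family!r} cannot have {nr} reactant(s)")
            )
        if np_ < lo_p or (hi_p is not None and np_ > hi_p):
            diags.append(
                Diagnostic(where, f"family {rxn.family!r} cannot have {np_} product(s)")
            )
        for side, pairs in (("reactant", rxn.reactants), ("product", rxn.products)):
            side_names = [name for _, name in pairs]
            # a species may appear once per side: "A + A" must be written "2A",
            # otherwise the limiting-reactant trial bound would not apply
            for dup in {n for n in side_names if side_names.count(n) > 1}:
                diags.append(Diagnostic(where, f"duplicate {side} element {dup!r}"))
            for order, name in pairs:
                if not isinstance(order, int) or order < 1:
                    diags.append(Diagnostic(where, f"order for {name!r} must be >= 1"))
                if name not in seen:
                    diags.append(Diagnostic(where, f"undeclared element {name!r}"))
        if rxn.rate_constant < 0:
            diags.append(Diagnostic(where, "rate constant must be >= 0"))
        if not rxn.normalization > 0:
            diags.append(Diagnostic(where, "normalization parameter must be > 0"))

    if not model.elements:
        diags.append(Diagnostic("model", "at least one element is required"))

    for ev in model.inout:
        where = f"inout at t={ev.time}"
        if ev.element not in seen:
            diags.append(Diagnostic(where, f"undeclared element {ev.element!r}"))
        if not (cfg.start_time <= ev.time <= cfg.end_time):
            diags.append(Diagnostic(where, "event time outside simulation window"))

    for ptype, names in model.plots:
        where = f"plot {ptype!r}"
        if ptype != "line":
            diags.append(Diagnostic(where, "only plot type 'line' is supported"))
        if not names:
            diags.append(Diagnostic(where, "plot has no elements"))
        for name in names:
            if name not in seen:
                diags.append(Diagnostic(where, f"undeclared element {name!r}"))

    return diags


def initial_state(model: Model) -> dict[str, int]:
    """Mutable element-count map at ``start_time``."""
    return {e.name: e.initial_count for e in model.elements}
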