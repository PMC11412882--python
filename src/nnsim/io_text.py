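"""Text model format, CSV trajectory output and plot rendering.

The model file is a line-oriented command format (see ``docs/format.md`` for
the EBNF).  Commands start with ``*``; any run of spaces/tabs separates
fields; ``#`` starts a comment line; blank lines are ignored.

::

    *Time
    0  10000  1000  1000  100  Steps
    *Element
    A   10000  blue  o
    B   10000
    C   0
    *Reaction  10000
    standard  bind  1 A 1 B  1.0  1 C
    *ElementInOut
    5000  A  1000
    *Plot  line
    A B C

A ``*Reaction`` header carries the normalization parameter ``N`` applied to
every reaction in its block.  Reaction lines read: family keyword, label,
``order element`` reactant pairs, the rate constant (the only bare number
between the two pair lists), then ``order element`` product pairs.  Element
names may therefore not themselves look like numbers.

Initial counts accept integer or scientific notation (``2e24``) and are held
as exact arbitrary-precision integers; CSV output always renders full digit
strings so macroscopic counts survive a round trip losslessly.
"""

from __future__ import annotations

import re
from decimal import Decimal, InvalidOperation
from pathlib import Path

from .model import (
    FAMILIES,
    ElementDecl,
    InOutEvent,
    Model,
    ModelError,
    Reaction,
    SimulationConfig,
    validate_model,
    _looks_numeric,
)
from .engine import Trajectory

__all__ = [
    "ParseError",
    "parse_model",
    "parse_model_file",
    "write_model",
    "write_model_file",
    "write_csv",
    "write_events_csv",
    "render_plot",
    "read_sbml",
]


class ParseError(ValueError):
    """A malformed model file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_INT_RE = re.compile(r"^\d+$")


def _parse_count(token: str, lineno: int) -> int:
    """Exact natural-number parse accepting scientific notation (2e24)."""
    try:
        value = Decimal(token)
    except InvalidOperation:
        raise ParseError(f"not a number: {token!r}", lineno) from None
    if value != value.to_integral_value() or value < 0:
        raise ParseError(f"count must be a natural number: {token!r}", lineno)
    return int(value)


def _parse_float(token: str, lineno: int, what: str) -> float:
    if not _looks_numeric(token):
        raise ParseError(f"{what} must be numeric, got {token!r}", lineno)
    return float(token)


def _parse_int(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{what} must be an integer, got {token!r}", lineno) from None


def _parse_pairs_and_rate(
    toks: list[str], lineno: int
) -> tuple[list[tuple[int, str]], float, list[tuple[int, str]]]:
    """Split ``q el ... k r el ...`` — the rate constant is the only bare
    number between the two order/element pair lists."""

    def read_pairs(i: int) -> tuple[list[tuple[int, str]], int]:
        pairs: list[tuple[int, str]] = []
        while (
            i + 1 < len(toks)
            and _INT_RE.match(toks[i])
            and not _looks_numeric(toks[i + 1])
        ):
            order = int(toks[i])
            if order < 1:
                raise ParseError("reaction order must be >= 1", lineno)
            pairs.append((order, toks[i + 1]))
            i += 2
        return pairs, i

    reactants, i = read_pairs(0)
    if i >= len(toks) or not _looks_numeric(toks[i]):
        raise ParseError("rate constant missing on reaction line", lineno)
    rate = float(toks[i])
    products, i = read_pairs(i + 1)
    if i != len(toks):
        raise ParseError(f"unexpected token {toks[i]!r} on reaction line", lineno)
    return reactants, rate, products


def parse_model(text: str) -> Model:
    """Parse and validate a model document; every error names its line."""
    config: SimulationConfig | None = None
    elements: list[ElementDecl] = []
    element_names: set[str] = set()
    reactions: list[Reaction] = []
    inout: list[InOutEvent] = []
    plots: list[tuple[str, list[str]]] = []

    mode: str | None = None
    current_norm: float | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if toks[0].startswith("*"):
            cmd = toks[0].lower()
            if cmd == "*time":
                if config is not None:
                    raise ParseError("duplicate *Time section", lineno)
                mode = "time"
            elif cmd == "*element":
                mode = "element"
            elif cmd == "*reaction":
                if len(toks) < 2:
                    raise ParseError(
                        "*Reaction header requires the normalization parameter", lineno
                    )
                current_norm = _parse_float(toks[1], lineno, "normalization parameter")
                mode = "reaction"
            elif cmd == "*elementinout":
                mode = "inout"
            elif cmd == "*plot":
                if len(toks) < 2:
                    raise ParseError("*Plot header requires a plot type", lineno)
                plots.append((toks[1], []))
                mode = "plot"
            else:
                raise ParseError(f"unknown command {toks[0]!r}", lineno)
            continue

        if mode == "time":
            if len(toks) != 6:
                raise ParseError(
                    "*Time needs: start end console plot csv time-unit", lineno
                )
            config = SimulationConfig(
                start_time=_parse_int(toks[0], lineno, "start time"),
                end_time=_parse_int(toks[1], lineno, "end time"),
                console_interval=_parse_int(toks[2], lineno, "console interval"),
                plot_interval=_parse_int(toks[3], lineno, "plot interval"),
                csv_interval=_parse_int(toks[4], lineno, "csv interval"),
                time_unit=toks[5],
            )
            mode = None  # exactly one data line
        elif mode == "element":
            if len(toks) < 2 or len(toks) > 4:
                raise ParseError("element line: name count [color] [marker]", lineno)
            name = toks[0]
            if name in element_names:
                raise ParseError(f"duplicate element {name!r}", lineno)
            element_names.add(name)
            elements.append(
                ElementDecl(
                    name=name,
                    initial_count=_parse_count(toks[1], lineno),
                    color=toks[2] if len(toks) > 2 else None,
                    marker=toks[3] if len(toks) > 3 else None,
                )
            )
        elif mode == "reaction":
            family = toks[0]
            if family not in FAMILIES:
                raise ParseError(f"unknown reaction family {family!r}", lineno)
            if len(toks) < 2:
                raise ParseError("reaction line missing label", lineno)
            label = toks[1]
            reactants, rate, products = _parse_pairs_and_rate(toks[2:], lineno)
            reactions.append(
                Reaction(
                    label=label,
                    family=family,
                    reactants=reactants,
                    products=products,
                    rate_constant=rate,
                    normalization=current_norm,  # type: ignore[arg-type]
                )
            )
        elif mode == "inout":
            if len(toks) != 3:
                raise ParseError("in/out line: time element delta", lineno)
            inout.append(
                InOutEvent(
                    time=_parse_int(toks[0], lineno, "event time"),
                    element=toks[1],
                    delta=_parse_int(toks[2], lineno, "event delta"),
                )
            )
        elif mode == "plot":
            plots[-1][1].extend(toks)
        else:
            raise ParseError(f"data before any command: {line!r}", lineno)

    if config is None:
        raise ParseError("missing required *Time section")
    if not elements:
        raise ParseError("missing required *Element section")
    if not reactions:
        raise ParseError("missing required *Reaction section")

    model = Model(
        elements=elements, reactions=reactions, config=config, inout=inout, plots=plots
    )
    diags = validate_model(model)
    if diags:
        raise ModelError(diags)
    return model


def parse_model_file(path) -> Model:
    return parse_model(Path(path).read_text())


def _fmt_float(x: float) -> str:
    """Shortest exact float rendering; '2e+19' is canonicalized to '2e19'."""
    return repr(float(x)).replace("e+", "e")


def write_model(model: Model) -> str:
    """Canonical tab-separated text; ``parse_model`` maps it back to an
    identical model (structural round trip)."""
    cfg = model.config
    out: list[str] = ["*Time"]
    out.append(
        "\t".join(
            str(v)
            for v in (
                cfg.start_time,
                cfg.end_time,
                cfg.console_interval,
                cfg.plot_interval,
                cfg.csv_interval,
                cfg.time_unit,
            )
        )
    )
    out.append("*Element")
    for el in model.elements:
        fields = [el.name, str(el.initial_count)]
        if el.color is not None:
            fields.append(el.color)
            if el.marker is not None:
                fields.append(el.marker)
        out.append("\t".join(fields))
    prev_norm: float | None = None
    for rxn in model.reactions:
        if prev_norm is None or rxn.normalization != prev_norm:
            out.append(f"*Reaction\t{_fmt_float(rxn.normalization)}")
            prev_norm = rxn.normalization
        fields = [rxn.family, rxn.label]
        for q, name in rxn.reactants:
            fields += [str(q), name]
        fields.append(_fmt_float(rxn.rate_constant))
        for r, name in rxn.products:
            fields += [str(r), name]
        out.append("\t".join(fields))
    if model.inout:
        out.append("*ElementInOut")
        for ev in model.inout:
            out.append(f"{ev.time}\t{ev.element}\t{ev.delta}")
    for ptype, names in model.plots:
        out.append(f"*Plot\t{ptype}")
        out.append("\t".join(names))
    return "\n".join(out) + "\n"


def write_model_file(model: Model, path) -> None:
    Path(path).write_text(write_model(model))


def write_csv(trajectory: Trajectory, sink) -> None:
    """Trajectory as CSV: ``time`` column then elements in declaration order;
    counts are exact integer digit strings (never exponent notation)."""
    close = False
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        sink = open(sink, "w", newline="")
        close = True
    try:
        sink.write(",".join(["time"] + trajectory.order) + "\n")
        series = [trajectory.counts[name] for name in trajectory.order]
        for i, t in enumerate(trajectory.times):
            sink.write(",".join([str(t)] + [str(s[i]) for s in series]) + "\n")
    finally:
        if close:
            sink.close()


def write_events_csv(trajectory: Trajectory, sink) -> None:
    """Event log as CSV: step, reaction label, trials, prob, successes."""
    if trajectory.events is None:
        raise ValueError("trajectory was recorded without event capture")
    close = False
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        sink = open(sink, "w", newline="")
        close = True
    try:
        sink.write("step,reaction,trials,prob,successes\n")
        for ev in trajectory.events:
            sink.write(f"{ev.step},{ev.label},{ev.trials},{ev.prob!r},{ev.successes}\n")
    finally:
        if close:
            sink.close()


def render_plot(
    trajectory: Trajectory,
    plot_spec: tuple[str, list[str]],
    sink,
    elements=None,
) -> None:
    """Render one plot request to an image file.

    ``plot_spec`` is a ``(plot_type, element_names)`` pair; only ``"line"``
    is supported.  ``elements`` (optional ElementDecl list) supplies declared
    colors and markers.
    """
    ptype, names = plot_spec
    if ptype != "line":
        raise ValueError(f"unsupported plot type {ptype!r}")
    if not names:
        raise ValueError("nothing to plot: empty element list")
    missing = [n for n in names if n not in trajectory.counts]
    if missing:
        raise ValueError(f"unknown element(s) in plot spec: {missing}")

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    style = {}
    if elements is not None:
        style = {e.name: (e.color, e.marker) for e in elements}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in names:
        color, marker = style.get(name, (None, None))
        ax.plot(
            trajectory.times,
            [float(v) for v in trajectory.counts[name]],
            label=name,
            color=color,
            marker=marker,
            markevery=max(len(trajectory.times) // 25, 1),
        )
    ax.set_xlabel(f"time ({trajectory.time_unit})")
    ax.set_ylabel("number of elements")
    ax.legend()
    fig.tight_layout()
    fig.savefig(sink)
    plt.close(fig)


def read_sbml(path) -> Model:
    """Reserved entry point for SBML import (not implemented)."""
    raise NotImplementedError(
        "SBML import is not implemented; convert to the text model format instead"
    )
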