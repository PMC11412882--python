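"""Programmatic builders for six canonical example systems.

Each builder returns a ready-to-run, validated :class:`~nnsim.model.Model`:

* protein binding ``A + B -> C`` (optionally reversible),
* water ionization ``H2O <-> H+ + OH-`` at macroscopic copy numbers,
* Michaelis–Menten enzyme kinetics ``S + E <-> ES -> E + P``,
* sequential oxygen binding to hemoglobin with allosterically increasing
  rate constants (Monod–Wyman–Changeux-style cooperativity),
* a one-gene negative-feedback loop (protein product shuts its own gene off),
* a coherent feed-forward loop with two timed stimulus inflows.

Numeric defaults (initial counts and most rate constants) are documented
reconstructions chosen to reproduce the qualitative behaviour of each
system; see ``docs/methods.md`` for the defaults table.  The water rate
constants are the exception: they are derived analytically from the
flux-balance condition so that pure water settles at a proton-to-water
count ratio of 1e-7 (pseudo-pH 7) — see :func:`water_rate_constants`.

``flux balance``: at stationarity the expected per-step forward flux
``n_f * p_f`` equals the backward flux ``n_b * p_b``.  The solvers here
evaluate that condition in continuous counts and are used as independent
oracles for equilibrium tests.
"""

from __future__ import annotations

from scipy.optimize import brentq

from .model import ElementDecl, InOutEvent, Model, Reaction, SimulationConfig

__all__ = [
    "ALLOSTERIC_RATES",
    "NULL_RATES",
    "EXAMPLE_BUILDERS",
    "build_binding",
    "build_water",
    "build_michaelis_menten",
    "build_mwc_hemoglobin",
    "build_feedback",
    "build_feedforward",
    "water_rate_constants",
    "water_equilibrium",
    "binding_equilibrium",
]


def _saturating(u: float) -> float:
    """The per-factor probability u/(1+u), u = k*X/(q*N)."""
    return u / (1.0 + u)


# ---------------------------------------------------------------------------
# simple binding


def build_binding(
    k_on: float = 1.0,
    k_off: float = 0.0,
    a0: int = 10_000,
    b0: int = 10_000,
    N: float = 10_000.0,
    end_time: int = 10_000,
) -> Model:
    """Irreversible (or, with ``k_off > 0``, reversible) binding A + B -> C."""
    reactions = [
        Reaction("bind", "standard", [(1, "A"), (1, "B")], [(1, "C")], k_on, N)
    ]
    if k_off > 0:
        reactions.append(
            Reaction("unbind", "mono", [(1, "C")], [(1, "A"), (1, "B")], k_off, N)
        )
    return Model(
        elements=[
            ElementDecl("A", a0, "tab:blue"),
            ElementDecl("B", b0, "tab:orange"),
            ElementDecl("C", 0, "tab:green"),
        ],
        reactions=reactions,
        config=SimulationConfig(0, end_time, 1000, 1000, 10),
        plots=[("line", ["A", "B", "C"])],
    )


def binding_equilibrium(
    k_on: float, k_off: float, a0: int, b0: int, N: float
) -> tuple[float, float, float]:
    """Continuous flux-balance root of A + B <-> C; returns (A, B, C).

    Forward flux: ``min(A, B) * saturating(k_on * other / N)`` (the limiting
    reactant sets the trials and drops out of the probability product).
    Because reactions apply sequentially within a step (bind before unbind),
    the unbinding draw sees the mid-step complex count ``C + F``; the
    stationary *recorded* state therefore satisfies ``F = (C + F) *
    k_off/(1+k_off)``, i.e. ``F = C * k_off``.
    """
    if k_off <= 0:
        raise ValueError("reversible equilibrium requires k_off > 0")

    def imbalance(c: float) -> float:
        a, b = a0 - c, b0 - c
        lim, other = (a, b) if a <= b else (b, a)
        return lim * _saturating(k_on * other / N) - c * k_off

    c = brentq(imbalance, 0.0, min(a0, b0) - 1e-9, xtol=1e-9)
    return a0 - c, b0 - c, c


# ---------------------------------------------------------------------------
# water ionization


def water_rate_constants(
    k_rec: float = 1e5, ion_ratio: float = 1e-7
) -> tuple[float, float]:
    """Derive the dissociation constant pairing with ``k_rec`` at neutrality.

    At stationarity the per-step dissociation flux ``d = H2O * k_d/(1+k_d)``
    must equal the recombination flux.  Reactions apply sequentially within
    a step (dissociation first), so recombination sees the mid-step ion
    count ``y = x + d`` and the stationary recorded state satisfies ``y *
    saturating(k_rec * y / N) = d``.  Imposing the pure-water ion ratio
    ``H+/H2O = ion_ratio`` on the recorded state (with exact conservation
    ``H2O = N - x`` for ``h2o0 = N``) fixes ``x/N = r/(1+r)``; the resulting
    ``k_d`` depends only on ratios of counts to N, so the same constant pair
    works at any system size.
    """
    r = ion_ratio
    chi = r / (1.0 + r)  # stationary x / N for h2o0 = N
    delta = 0.0  # per-step flux / N; fixed point of a contraction (slope < 1)
    for _ in range(200):
        delta = (chi + delta) * _saturating(k_rec * (chi + delta))
    kd_eff = delta / (1.0 - chi)  # k_d / (1 + k_d)
    k_diss = kd_eff / (1.0 - kd_eff)
    return k_diss, k_rec


def water_equilibrium(k_diss: float, k_rec: float, N: float, h2o0: float) -> float:
    """Stationary recorded ion count x for given constants.

    Solves ``(x + d) * saturating(k_rec*(x+d)/N) = d`` with the per-step
    dissociation flux ``d = (h2o0 - x) * k_d/(1+k_d)`` (sequential within-step
    semantics: dissociation before recombination).
    """
    p_diss = k_diss / (1.0 + k_diss)

    def imbalance(x: float) -> float:
        d = (h2o0 - x) * p_diss
        y = x + d
        return y * _saturating(k_rec * y / N) - d

    return brentq(imbalance, 0.0, h2o0 / 2.0, rtol=1e-15)


def build_water(
    N: float = 2e19,
    h2o0: int | None = None,
    k_diss: float | None = None,
    k_rec: float = 1e5,
    end_time: int = 20_000,
    csv_interval: int = 10,
) -> Model:
    """Water dissociation/recombination at macroscopic copy numbers.

    Default rate constants come from :func:`water_rate_constants`, i.e. the
    flux-balance pair that makes pure water neutral (pseudo-pH 7) at any N.
    ``h2o0`` defaults to ``int(N)``; pass an exact integer for counts beyond
    float precision (e.g. ``2 * 10**24``).
    """
    if h2o0 is None:
        h2o0 = int(N)
    if k_diss is None:
        k_diss, k_rec = water_rate_constants(k_rec)
    return Model(
        elements=[
            ElementDecl("H2O", h2o0, "tab:blue"),
            ElementDecl("H+", 0, "tab:red"),
            ElementDecl("OH-", 0, "tab:green"),
        ],
        reactions=[
            Reaction(
                "dissociation", "mono", [(1, "H2O")], [(1, "H+"), (1, "OH-")], k_diss, N
            ),
            Reaction(
                "recombination",
                "standard",
                [(1, "H+"), (1, "OH-")],
                [(1, "H2O")],
                k_rec,
                N,
            ),
        ],
        config=SimulationConfig(0, end_time, 1000, 1000, csv_interval),
        plots=[("line", ["H+", "OH-"])],
    )


# ---------------------------------------------------------------------------
# Michaelis–Menten


def build_michaelis_menten(
    e0: int = 1000,
    s0: int = 10_000,
    k1: float = 1.0,
    k_1: float = 0.1,
    k2: float = 0.1,
    N: float = 10_000.0,
    end_time: int = 10_000,
) -> Model:
    """Enzyme kinetics S + E <-> ES -> E + P as three reactions.

    Both conservation laws hold exactly at every step: E + ES = e0 and
    S + ES + P = s0.
    """
    return Model(
        elements=[
            ElementDecl("S", s0, "tab:blue"),
            ElementDecl("E", e0, "tab:orange"),
            ElementDecl("ES", 0, "tab:green"),
            ElementDecl("P", 0, "tab:red"),
        ],
        reactions=[
            Reaction("binding", "standard", [(1, "S"), (1, "E")], [(1, "ES")], k1, N),
            Reaction("unbinding", "mono", [(1, "ES")], [(1, "S"), (1, "E")], k_1, N),
            Reaction("catalysis", "mono", [(1, "ES")], [(1, "E"), (1, "P")], k2, N),
        ],
        config=SimulationConfig(0, end_time, 1000, 1000, 10),
        plots=[("line", ["E", "ES"]), ("line", ["S", "P"])],
    )


# ---------------------------------------------------------------------------
# MWC hemoglobin

#: Cooperative (allosteric) oxygen-binding rate constants for the four
#: sequential binding steps, and the no-cooperativity control.
ALLOSTERIC_RATES = (0.1, 0.5, 10.0, 50.0)
NULL_RATES = (0.1, 0.1, 0.1, 0.1)

_HB_SPECIES = ("Hb", "Hb(O2)", "Hb(O2)2", "Hb(O2)3", "Hb(O2)4")


def build_mwc_hemoglobin(
    rates: tuple[float, float, float, float] = ALLOSTERIC_RATES,
    hb0: int = 1000,
    o2_0: int = 10_000,
    N: float = 10_000.0,
    end_time: int = 10_000,
) -> Model:
    """Four sequential O2-binding steps Hb(O2)_i + O2 -> Hb(O2)_{i+1}.

    With ``rates=ALLOSTERIC_RATES`` each bound oxygen increases the next
    step's rate constant (cooperative binding); ``rates=NULL_RATES`` is the
    non-cooperative control.  Total hemoglobin is conserved exactly.
    """
    if len(rates) != 4:
        raise ValueError("exactly four binding rate constants are required")
    elements = [ElementDecl("O2", o2_0, "tab:cyan")]
    colors = ("tab:blue", "tab:orange", "tab:green", "tab:red", "tab:purple")
    for name, color in zip(_HB_SPECIES, colors):
        elements.append(ElementDecl(name, hb0 if name == "Hb" else 0, color))
    reactions = [
        Reaction(
            f"bind_o2_{i + 1}",
            "standard",
            [(1, _HB_SPECIES[i]), (1, "O2")],
            [(1, _HB_SPECIES[i + 1])],
            rates[i],
            N,
        )
        for i in range(4)
    ]
    return Model(
        elements=elements,
        reactions=reactions,
        config=SimulationConfig(0, end_time, 1000, 1000, 10),
        plots=[("line", list(_HB_SPECIES))],
    )


# ---------------------------------------------------------------------------
# one-gene feedback loop


def build_feedback(
    stimulus0: int = 50,
    ribonucleotide0: int = 10_000,
    amino0: int = 10_000,
    ribosome0: int = 10,
    k_act: float = 100.0,
    k_txn: float = 1.0,
    k_tln: float = 10.0,
    k_deact: float = 1.0,
    N: float = 10_000.0,
    end_time: int = 5_000,
    include_feedback: bool = True,
) -> Model:
    """One-gene negative feedback: the protein product silences its own gene.

    The single-copy gene moves through three states: DNA_i (inactive, the
    initial state) is switched on by a stimulus molecule to DNA, which is
    transcribed (consuming one Ribonucleotide per mRNA) and translated
    (consuming one Amino per protein, ribosome-catalyzed) until a protein
    molecule binds the gene and retires it permanently as DNA_d.  The gene
    conservation DNA_i + DNA + DNA_d = 1 holds exactly, and because DNA_i
    is single-copy the gene can never be re-activated after deactivation:
    transcription stops forever once DNA returns to zero.

    ``include_feedback=False`` drops the deactivation reaction (the
    no-feedback control; DNA_d then stays at zero).
    """
    reactions = [
        Reaction(
            "activation", "standard", [(1, "Stimulus"), (1, "DNA_i")], [(1, "DNA")],
            k_act, N,
        ),
        Reaction(
            "transcription",
            "standard",
            [(1, "DNA"), (1, "Ribonucleotide")],
            [(1, "DNA"), (1, "mRNA")],
            k_txn,
            N,
        ),
        Reaction(
            "translation",
            "standard",
            [(1, "mRNA"), (1, "Ribosome"), (1, "Amino")],
            [(1, "mRNA"), (1, "Ribosome"), (1, "Protein")],
            k_tln,
            N,
        ),
    ]
    if include_feedback:
        reactions.append(
            Reaction(
                "deactivation", "standard", [(1, "Protein"), (1, "DNA")],
                [(1, "DNA_d")], k_deact, N,
            )
        )
    return Model(
        elements=[
            ElementDecl("Stimulus", stimulus0, "tab:gray"),
            ElementDecl("DNA_i", 1),
            ElementDecl("DNA", 0, "tab:blue"),
            ElementDecl("DNA_d", 0, "tab:red"),
            ElementDecl("Ribonucleotide", ribonucleotide0),
            ElementDecl("mRNA", 0, "tab:green"),
            ElementDecl("Ribosome", ribosome0),
            ElementDecl("Amino", amino0),
            ElementDecl("Protein", 0, "tab:purple"),
        ],
        reactions=reactions,
        config=SimulationConfig(0, end_time, 1000, 1000, 10),
        plots=[("line", ["DNA", "DNA_d"]), ("line", ["mRNA", "Protein"])],
    )


# ---------------------------------------------------------------------------
# feed-forward loop


def build_feedforward(
    sx_time: int = 10_000,
    sy_time: int = 20_000,
    sx_amount: int = 500,
    sy_amount: int = 500,
    px0: int = 500,
    k_act: float = 10.0,
    k_bind: float = 10.0,
    k_expr: float = 1.0,
    N: float = 1000.0,
    end_time: int = 50_000,
) -> Model:
    """Coherent feed-forward loop driven by two timed stimulus inflows.

    Stimulus Sx activates protein pX to pX*; pX* switches on gene DNA-Y
    (complex DNA-Y_X*), which expresses pY; stimulus Sy activates pY to
    pY*; pX* and pY* together switch on gene DNA-Z (AND-gate complex
    DNA-Z_X*_Y*), which expresses pZ.  Sx and Sy enter as scheduled inflows
    at ``sx_time`` and ``sy_time`` — with the default times pZ cannot
    appear before the later stimulus, so delaying Sy delays pZ.
    """
    return Model(
        elements=[
            ElementDecl("Sx", 0, "tab:blue"),
            ElementDecl("Sy", 0, "tab:orange"),
            ElementDecl("pX", px0),
            ElementDecl("pX*", 0, "tab:green"),
            ElementDecl("pY", 0),
            ElementDecl("pY*", 0, "tab:red"),
            ElementDecl("pZ", 0, "tab:purple"),
            ElementDecl("DNA-Y", 1),
            ElementDecl("DNA-Y_X*", 0, "tab:brown"),
            ElementDecl("DNA-Z", 1),
            ElementDecl("DNA-Z_X*_Y*", 0, "tab:pink"),
        ],
        reactions=[
            Reaction(
                "x_activation", "standard", [(1, "Sx"), (1, "pX")], [(1, "pX*")],
                k_act, N,
            ),
            Reaction(
                "y_activation", "standard", [(1, "Sy"), (1, "pY")], [(1, "pY*")],
                k_act, N,
            ),
            Reaction(
                "y_gene_binding", "standard", [(1, "pX*"), (1, "DNA-Y")],
                [(1, "DNA-Y_X*")], k_bind, N,
            ),
            Reaction(
                "y_expression", "mono", [(1, "DNA-Y_X*")],
                [(1, "DNA-Y_X*"), (1, "pY")], k_expr, N,
            ),
            Reaction(
                "z_gene_binding",
                "standard",
                [(1, "pX*"), (1, "pY*"), (1, "DNA-Z")],
                [(1, "DNA-Z_X*_Y*")],
                k_bind,
                N,
            ),
            Reaction(
                "z_expression", "mono", [(1, "DNA-Z_X*_Y*")],
                [(1, "DNA-Z_X*_Y*"), (1, "pZ")], k_expr, N,
            ),
        ],
        config=SimulationConfig(0, end_time, 1000, 1000, 100),
        inout=[
            ev
            for ev in (
                InOutEvent(sx_time, "Sx", sx_amount),
                InOutEvent(sy_time, "Sy", sy_amount),
            )
            # a stimulus scheduled past the horizon or with nothing to add
            # is simply omitted (shortened control runs)
            if ev.time <= end_time and ev.delta != 0
        ],
        plots=[("line", ["Sx", "Sy"]), ("line", ["pX*", "pY*", "pZ"])],
    )


#: Builder registry used by the CLI ``example`` command and the shipped
#: ``examples/`` text files (which are generated by ``write_model``).
EXAMPLE_BUILDERS = {
    "binding": build_binding,
    "water": build_water,
    "michaelis_menten": build_michaelis_menten,
    "mwc_hemoglobin": build_mwc_hemoglobin,
    "feedback": build_feedback,
    "feedforward": build_feedforward,
}
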