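# The model file format

A model file is plain text, line oriented, and command driven.  Any run of
spaces or tabs separates fields (the canonical writer emits tabs); lines
starting with `#` are comments; blank lines are ignored.

## Commands

| Command | Header arguments | Data lines |
|---|---|---|
| `*Time` | — | exactly one: `start end console-interval plot-interval csv-interval time-unit` |
| `*Element` | — | one per species: `name initial-count [color] [marker]` |
| `*Reaction` | normalization parameter `N` | one per reaction (grammar below) |
| `*ElementInOut` | — | one per event: `time element delta` |
| `*Plot` | plot type (only `line`) | element names, whitespace separated |

Exactly one `*Time` section is required, along with at least one `*Element`
and one `*Reaction` section.  Several `*Reaction` sections may appear;
each header's `N` applies to every reaction in its block.  Several `*Plot`
sections produce several images.

## Reaction line grammar

```ebnf
reaction   = family , label , { pair } , rate , { pair } ;
family     = "standard" | "mono" | "decay_zero" | "linear_dec" | "linear_inc" ;
pair       = order , element-name ;        (* reactants before the rate,
                                              products after it *)
order      = digit , { digit } ;           (* natural number >= 1 *)
rate       = number ;                      (* rate constant k *)
element-name = name-char , { name-char } ;
name-char  = letter | digit | "_" | "+" | "-" | "*" | "(" | ")" ;
```

The rate constant is the only bare number standing between the two pair
lists, which makes the split unambiguous — provided element names never
look like numbers, which validation enforces.  A species may appear at most
once per side; write `2 A` rather than `1 A 1 A`.

Examples:

```
*Reaction	10000
standard	bind	1	A	1	B	1.0	1	C
mono	unbind	1	C	0.1	1	A	1	B
decay_zero	clear	2	X	0.01
linear_inc	supply	0.5	3	Y
```

## Numbers

* Initial counts are natural numbers and may use scientific notation
  (`2e24`); they are parsed exactly into arbitrary-precision integers.
* Rate constants and `N` are floats; the writer uses the shortest exact
  rendering (`2e19`, `0.1`, `1.010100909090919e-09`), so a written file
  reparses to a structurally identical model.
* Times are integer steps; the time-unit field is a pass-through label.

## Outputs

* `trajectory.csv` — header `time,<element...>` in declaration order, one
  row per recorded step, counts as exact digit strings (never exponent
  notation, so counts like 2×10²⁴ survive a CSV round trip).
* `events.csv` (with `--info`) — `step,reaction,trials,prob,successes`.
* `info_<reaction>.csv` / `entropy_<reaction>.csv` — `step,bits`.
* `plot_<n>.png` — one per `*Plot` section.
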