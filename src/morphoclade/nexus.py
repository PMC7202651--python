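"""NEXUS reading and writing for morphological matrices.

Parsing is delegated to dendropy (DATA or CHARACTERS blocks, interleaved or
not, quoted labels) and the result converted into the package's own
:class:`~morphoclade.matrix.CharacterMatrix`. Writing is a small native
emitter so the dialect is fully controlled: ``?`` missing, ``-``
inapplicable, ``{..}`` polymorphism (``(..)`` also accepted on read, as
written by TNT), and an optional ``[...]`` provenance comment line.
"""

from __future__ import annotations

import io
import re

import dendropy

from .matrix import CharacterMatrix, MatrixError, StateSet

__all__ = ["parse_nexus", "write_nexus", "NexusFormatError"]

# single-token state symbols, in code order: state 0 is '0', state 10 is 'A', ...
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class NexusFormatError(MatrixError):
    """Malformed NEXUS input."""


def _decode_symbol(sym: str) -> int:
    code = _SYMBOLS.find(sym.upper())
    if code < 0:
        raise NexusFormatError(f"unknown state symbol {sym!r}")
    return code


def parse_nexus(text: str) -> CharacterMatrix:
    """Read a DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    Cell semantics: ``?`` missing, ``-`` (gap) inapplicable, ``{..}`` or
    ``(..)`` polymorphic. Character ids are assigned 1..NCHAR in file order.
    """
    declared = _declared_dimensions(text)
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus"
        )
    except Exception as exc:  # dendropy raises several error types
        raise NexusFormatError(f"NEXUS parse failed: {exc}") from exc

    labels: list[str] = []
    rows: list[list[StateSet]] = []
    for taxon in dmat:
        label = taxon.label
        if label in labels:
            raise NexusFormatError(f"duplicate taxon label: {label!r}")
        seq = dmat[taxon]
        row: list[StateSet] = []
        for pos, state in enumerate(seq, start=1):
            row.append(_cell_from_dendropy(state, label, pos))
        labels.append(label)
        rows.append(row)

    if not rows:
        raise NexusFormatError("no taxa found in matrix")
    nchar = len(rows[0])
    for label, row in zip(labels, rows):
        if len(row) != nchar:
            raise NexusFormatError(
                f"taxon {label!r} has {len(row)} characters, expected {nchar}"
            )
    ntax_decl, nchar_decl = declared
    if ntax_decl is not None and ntax_decl != len(labels):
        raise NexusFormatError(
            f"declared NTAX={ntax_decl} but parsed {len(labels)} taxa"
        )
    if nchar_decl is not None and nchar_decl != nchar:
        raise NexusFormatError(
            f"declared NCHAR={nchar_decl} but parsed {nchar} characters"
        )
    return CharacterMatrix(
        taxon_labels=labels,
        char_ids=list(range(1, nchar + 1)),
        cells=rows,
    )


def _declared_dimensions(text: str) -> tuple[int | None, int | None]:
    ntax = nchar = None
    m = re.search(r"\bNTAX\s*=\s*(\d+)", text, re.IGNORECASE)
    if m:
        ntax = int(m.group(1))
    m = re.search(r"\bNCHAR\s*=\s*(\d+)", text, re.IGNORECASE)
    if m:
        nchar = int(m.group(1))
    return ntax, nchar


def _cell_from_dendropy(state, label: str, pos: int) -> StateSet:
    sym = state.symbol
    if sym == "?":
        return StateSet(is_missing=True)
    if sym == "-":
        return StateSet(is_inapplicable=True)
    if sym is not None:
        return StateSet(states=frozenset({_decode_symbol(sym)}))
    members = state.member_states or []
    codes = {
        _decode_symbol(s.symbol)
        for s in members
        if s.symbol not in ("?", "-")
    }
    if not codes:
        raise NexusFormatError(
            f"uninterpretable cell for taxon {label!r} at character {pos}"
        )
    return StateSet(states=frozenset(codes))


# ----------------------------------------------------------------------
def _encode_cell(cell: StateSet) -> str:
    if cell.is_missing:
        return "?"
    if cell.is_inapplicable:
        return "-"
    syms = [_SYMBOLS[s] for s in sorted(cell.states)]
    return syms[0] if len(syms) == 1 else "{" + "".join(syms) + "}"


def _quote_label(label: str) -> str:
    # whitespace → underscore; anything still NEXUS-unsafe gets quoted
    label = re.sub(r"\s+", "_", label)
    if re.search(r"[^\w\.\-]", label):
        label = "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(m: CharacterMatrix, comment: str | None = None) -> str:
    """Emit a DATA block that round-trips through :func:`parse_nexus`."""
    if m.n_taxa == 0:
        raise MatrixError("refusing to write a matrix with no taxa")
    max_state = 0
    for row in m.cells:
        for cell in row:
            if cell.states:
                max_state = max(max_state, max(cell.states))
    symbols = _SYMBOLS[: max_state + 1]
    out = io.StringIO()
    out.write("#NEXUS\n")
    if comment:
        out.write(f"[{comment}]\n")
    out.write("BEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};\n")
    out.write(
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
    )
    out.write("  MATRIX\n")
    width = max(len(_quote_label(t)) for t in m.taxon_labels) + 2
    for label, row in zip(m.taxon_labels, m.cells):
        cells = "".join(_encode_cell(c) for c in row)
        out.write(f"    {_quote_label(label):<{width}}{cells}\n")
    out.write("  ;\nEND;\n")
    return out.getvalue()
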