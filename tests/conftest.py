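from pathlib import Path

import pytest

from morphoclade.matrix import CharacterMatrix, StateSet

DATA_DIR = Path(__file__).parents[1] / "data"


def cell(token: str) -> StateSet:
    """'?' missing, '-' inapplicable, '01' polymorphic {0,1}, '2' state 2."""
    if token == "?":
        return StateSet(is_missing=True)
    if token == "-":
        return StateSet(is_inapplicable=True)
    return StateSet(states=frozenset(int(c) for c in token))


def matrix_from_rows(rows: dict[str, list[str]]) -> CharacterMatrix:
    labels = list(rows)
    nchar = len(next(iter(rows.values())))
    return CharacterMatrix(
        taxon_labels=labels,
        char_ids=list(range(1, nchar + 1)),
        cells=[[cell(tok) for tok in rows[t]] for t in labels],
    )


def column(assignment: dict[str, str]) -> dict[str, StateSet]:
    return {t: cell(tok) for t, tok in assignment.items()}


@pytest.fixture(scope="session")
def clean_fixture():
    """A 6-taxon tree with a homoplasy-free 20-characters-per-edge matrix."""
    from morphoclade.simulate import SimConfig, make_clean_signal_matrix, simulate_tree

    tree = simulate_tree(SimConfig(n_taxa=6, n_chars=1, seed=3))
    matrix = make_clean_signal_matrix(tree, chars_per_edge=20)
    return tree, matrix
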