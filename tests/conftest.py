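import re

import numpy as np
import pytest

from ringfam.ring_grammar import AMINO_ACIDS, MotifGrammar, ProteinRecord


@pytest.fixture
def default_grammar() -> MotifGrammar:
    return MotifGrammar()


def random_protein(rng: np.random.Generator, length: int, pid: str = "p") -> ProteinRecord:
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
    return ProteinRecord(pid, seq)


def grammar_regex(grammar: MotifGrammar) -> re.Pattern:
    """Independent regular-expression oracle for the motif grammar.

    Builds one alternation per proline reading over the literal ligand
    letters; used with a lookahead wrapper so overlapping starts are
    found.  Only valid for grammars with the standard C3H2C3 ligand
    pattern and the W-after-sixth-ligand arrangement.
    """
    (g1lo, g1hi), (g2lo, g2hi), (g3lo, g3hi), (g4lo, g4hi), (g5lo, g5hi), (
        g6lo,
        g6hi,
    ), (g7lo, g7hi) = grammar.spacer_ranges

    def rep(lo, hi):
        return f".{{{lo},{hi}}}" if lo != hi else f".{{{lo}}}"

    mid_variants = []
    if grammar.proline_rule in ("PC", "either"):
        mid_variants.append(rep(max(g2lo - 1, 0), g2hi - 1) + "P")
    if grammar.proline_rule in ("PxC", "either"):
        mid_variants.append(rep(max(g2lo - 2, 0), g2hi - 2) + "P.")
    mid = "(?:" + "|".join(mid_variants) + ")"
    if grammar.require_w4:
        gap6 = rep(3, 3) + "W" + rep(g6lo - 4, g6hi - 4)
    else:
        gap6 = rep(g6lo, g6hi)
    pattern = (
        "C" + rep(g1lo, g1hi) + "C" + mid + "C" + rep(g3lo, g3hi) + "H"
        + rep(g4lo, g4hi) + "H" + rep(g5lo, g5hi) + "C" + gap6 + "C"
        + rep(g7lo, g7hi) + "C"
    )
    if grammar.require_trailing_w:
        pattern += "W"
    return re.compile(f"(?=({pattern}))")


def oracle_match_starts(sequence: str, grammar: MotifGrammar) -> set[int]:
    """1-based first-ligand positions found by the regex oracle."""
    rx = grammar_regex(grammar)
    return {m.start() + 1 for m in rx.finditer(sequence)}


def is_valid_match(seq: str, match, grammar: MotifGrammar) -> bool:
    """Direct predicate check of a reported match against the grammar."""
    pos = match.ligand_positions
    for p, want in zip(pos, grammar.ligand_pattern):
        if seq[p - 1] != want:
            return False
    for (a, b), (lo, hi) in zip(zip(pos, pos[1:]), grammar.spacer_ranges):
        if not lo <= b - a - 1 <= hi:
            return False
    c3 = pos[2]
    if match.subtype == "PC" and seq[c3 - 2] != "P":
        return False
    if match.subtype == "PxC" and seq[c3 - 3] != "P":
        return False
    if grammar.proline_rule != "either" and match.subtype != grammar.proline_rule:
        return False
    if grammar.require_w4 and seq[pos[5] + 3] != "W":
        return False
    if grammar.require_trailing_w and seq[pos[7]] != "W":
        return False
    return True
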