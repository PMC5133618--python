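"""RING-H2 motif grammar scanning and family-member classification.

The family-defining domain is an eight-ligand zinc finger (C3H2C3 ligand
order C-C-C-H-H-C-C-C) with constrained spacing between consecutive
ligands, a proline one or two residues before the third cysteine, and a
conserved tryptophan four residues after the sixth ligand.  The scanner
enumerates every placement of the eight ligands that satisfies a
:class:`MotifGrammar` and reports each as a :class:`RingH2Match`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AMINO_ACIDS",
    "MotifGrammar",
    "ProteinRecord",
    "RingH2Match",
    "classify_family_member",
    "classify_subtype",
    "position_frequency_summary",
    "scan_ring_h2",
    "seed_grammar",
    "write_match_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AMINO_ACIDS + "X")

#: Ligand order of the RING-H2 variant: three Cys, two His, three Cys.
LIGAND_PATTERN = ("C", "C", "C", "H", "H", "C", "C", "C")

#: N-terminal structural categories used for the family summary.
CATEGORIES = ("TM_PxC", "BZF_PC", "Hyd_PC", "BZF_Hyd_PC", "NoNterm")


class InvalidSequenceError(ValueError):
    """Raised when a protein sequence contains non-amino-acid characters."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier, the unit of scanning."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def validate_alphabet(self) -> None:
        bad = set(self.sequence.upper()) - _VALID_CHARS
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r} contains invalid characters: "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class MotifGrammar:
    """Spacing grammar for the eight-ligand RING-H2 motif.

    Parameters
    ----------
    spacer_ranges
        Seven ``(min, max)`` pairs giving the allowed number of residues
        between consecutive ligands.  The second and sixth gaps are the
        variable regions; the proline and tryptophan constraints live
        inside them and are expressed separately.
    proline_rule
        ``"PxC"`` requires P two residues before the third ligand,
        ``"PC"`` immediately before it, ``"either"`` accepts both.
    require_w4
        Demand a tryptophan exactly four positions after the sixth
        ligand (three intervening residues, the ``CxxxW`` arrangement).
    require_trailing_w
        Demand a tryptophan immediately after the eighth ligand.
    """

    ligand_pattern: Sequence[str] = LIGAND_PATTERN
    spacer_ranges: Sequence[tuple[int, int]] = (
        (2, 2),
        (5, 32),  # variable region between C2 and C3, includes P or Px
        (1, 1),
        (2, 2),
        (2, 2),
        (8, 34),  # variable region between C6 and C7, includes xxxW
        (2, 2),
    )
    proline_rule: str = "either"
    require_w4: bool = True
    require_trailing_w: bool = False

    def __post_init__(self) -> None:
        if tuple(self.ligand_pattern) != LIGAND_PATTERN:
            if len(self.ligand_pattern) != 8:
                raise ValueError("grammar must define exactly 8 ligands")
            if any(s not in "CH" for s in self.ligand_pattern):
                raise ValueError("ligand symbols must be C or H")
        if len(self.spacer_ranges) != 7:
            raise ValueError("exactly 7 spacer ranges required")
        for lo, hi in self.spacer_ranges:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid spacer range ({lo}, {hi})")
        if self.proline_rule not in ("PxC", "PC", "either"):
            raise ValueError(f"unknown proline_rule {self.proline_rule!r}")

    @property
    def min_span(self) -> int:
        return 8 + sum(lo for lo, _ in self.spacer_ranges)


def seed_grammar() -> MotifGrammar:
    """The fixed-spacing grammar instantiating the canonical consensus
    ``CxxC(13x)PxCxHxxHxxCxxxW(7x)CxxCW``: all spacers pinned, PxC
    proline, W after the sixth ligand and after the last one."""
    return MotifGrammar(
        spacer_ranges=((2, 2), (15, 15), (1, 1), (2, 2), (2, 2), (11, 11), (2, 2)),
        proline_rule="PxC",
        require_w4=True,
        require_trailing_w=True,
    )


@dataclass(frozen=True)
class RingH2Match:
    """One placement of the eight zinc ligands (1-based coordinates)."""

    ligand_positions: tuple[int, ...]
    spacer_lengths: tuple[int, ...]
    proline_position: int
    subtype: str  # "PxC" or "PC"
    w4_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.ligand_positions) != 8:
            raise ValueError("expected 8 ligand positions")
        if any(b <= a for a, b in zip(self.ligand_positions, self.ligand_positions[1:])):
            raise ValueError("ligand positions must be strictly increasing")
        c3 = self.ligand_positions[2]
        expected = {"PC": c3 - 1, "PxC": c3 - 2}[self.subtype]
        if self.proline_position != expected:
            raise ValueError(
                f"proline at {self.proline_position} inconsistent with "
                f"subtype {self.subtype} (third ligand at {c3})"
            )

    @property
    def start(self) -> int:
        return self.ligand_positions[0]

    @property
    def end(self) -> int:
        return self.ligand_positions[-1]


def _proline_subtype(seq: str, c3_pos: int, rule: str) -> str | None:
    """Subtype implied by the proline near the third ligand, or None.

    When both offsets carry a proline the adjacent (PC) reading wins.
    """
    has_pc = c3_pos >= 2 and seq[c3_pos - 2] == "P"
    has_pxc = c3_pos >= 3 and seq[c3_pos - 3] == "P"
    if rule in ("PC", "either") and has_pc:
        return "PC"
    if rule in ("PxC", "either") and has_pxc:
        return "PxC"
    return None


def scan_ring_h2(protein: ProteinRecord, grammar: MotifGrammar) -> list[RingH2Match]:
    """Return every placement of the motif grammar in ``protein``.

    Matches are ordered by first-ligand position, then by the full
    position vector.  ``X`` never matches a ligand position.  Sequences
    with characters outside the 20-letter alphabet plus X are rejected.
    """
    protein.validate_alphabet()
    seq = protein.sequence.upper()
    n = len(seq)
    if n < grammar.min_span:
        return []

    pattern = tuple(grammar.ligand_pattern)
    matches: list[RingH2Match] = []

    def extend(positions: list[int]) -> None:
        k = len(positions)
        if k == 8:
            _finalize(positions)
            return
        lo, hi = grammar.spacer_ranges[k - 1]
        prev = positions[-1]
        want = pattern[k]
        for gap in range(lo, hi + 1):
            pos = prev + gap + 1  # 1-based position of next ligand
            if pos > n:
                break
            if seq[pos - 1] == want:
                positions.append(pos)
                extend(positions)
                positions.pop()

    def _finalize(positions: list[int]) -> None:
        c3 = positions[2]
        subtype = _proline_subtype(seq, c3, grammar.proline_rule)
        if subtype is None:
            return
        w4_pos: int | None = None
        if grammar.require_w4:
            w4 = positions[5] + 4
            if w4 >= positions[6] or seq[w4 - 1] != "W":
                return
            w4_pos = w4
        if grammar.require_trailing_w:
            tw = positions[7] + 1
            if tw > n or seq[tw - 1] != "W":
                return
        spacers = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
        matches.append(
            RingH2Match(
                ligand_positions=tuple(positions),
                spacer_lengths=spacers,
                proline_position=c3 - (1 if subtype == "PC" else 2),
                subtype=subtype,
                w4_position=w4_pos,
            )
        )

    for start in range(1, n - grammar.min_span + 2):
        if seq[start - 1] == pattern[0]:
            extend([start])

    matches.sort(key=lambda m: m.ligand_positions)
    return matches


def classify_subtype(match: RingH2Match) -> str:
    """Map a match to its family label: ``ATL_PxC`` or ``BTL_PC``."""
    if match.subtype == "PxC":
        return "ATL_PxC"
    if match.subtype == "PC":
        return "BTL_PC"
    raise ValueError(f"match has no recognised proline spacing: {match.subtype!r}")


def classify_family_member(subtype: str, tm_h_code: float, has_bzf: bool) -> str:
    """Assign the mutually exclusive N-terminal structural category.

    ``tm_h_code`` follows the family-table convention: 0 = no
    membrane-associated region, 0.5 = one or more hydrophobic regions,
    integer >= 1 = that many transmembrane segments.
    """
    if subtype not in ("PC", "PxC"):
        raise ValueError(f"subtype must be PC or PxC, got {subtype!r}")
    if tm_h_code < 0 or (tm_h_code != 0.5 and tm_h_code != int(tm_h_code)):
        raise ValueError(f"tm_h_code {tm_h_code!r} is not a valid code")
    if tm_h_code == 0 and not has_bzf:
        return "NoNterm"
    if has_bzf:
        return "BZF_Hyd_PC" if tm_h_code > 0 else "BZF_PC"
    if subtype == "PxC":
        return "TM_PxC"
    return "Hyd_PC"


def position_frequency_summary(
    segments: Iterable[str],
) -> list[dict[str, float]]:
    """Per-column residue frequencies over equal-length aligned segments.

    Numeric stand-in for a sequence LOGO: one dict per column mapping
    each residue observed there to its frequency; columns sum to 1.
    """
    segs = [s.upper() for s in segments]
    if not segs:
        raise ValueError("at least one segment required")
    length = len(segs[0])
    if any(len(s) != length for s in segs):
        raise ValueError("aligned segments must have equal length")
    table: list[dict[str, float]] = []
    for col in range(length):
        counts: dict[str, int] = {}
        for s in segs:
            counts[s[col]] = counts.get(s[col], 0) + 1
        table.append({res: c / len(segs) for res, c in counts.items()})
    return table


def write_match_table(matches_by_protein: dict[str, list[RingH2Match]], path) -> None:
    """Write a TSV of matches (protein_id, start, end, ligand positions,
    subtype), one row per match, proteins in input order."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tligand_positions\tsubtype\n")
        for pid, matches in matches_by_protein.items():
            for m in matches:
                lig = ",".join(str(p) for p in m.ligand_positions)
                fh.write(f"{pid}\t{m.start}\t{m.end}\t{lig}\t{m.subtype}\n")
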