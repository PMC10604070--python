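"""Secondary-structure condensation and per-quadrant distributions.

DSSP assigns one of eight states per residue; the standard 3-state
condensation groups them as helix (H, G, I), sheet (E, B) and coil
(T, S, P, blank/unassigned).  DSSP-4's polyproline-II state ``P`` is
treated as coil — PPII is an extended, non-hydrogen-bonded conformation
typical of disordered segments.

Quadrant labels here are residue-level (not region means): secondary
structure is a per-residue property, so each classified residue is tallied
in its own quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import QUADRANTS, SSString

#: 8-state -> 3-state condensation table.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "P": "C", "-": "C", " ": "C",
}


def to_three_state(ss: SSString | str) -> str:
    """Condense an 8-state DSSP string to H/E/C."""
    states8 = ss.states8 if isinstance(ss, SSString) else ss
    out = []
    for i, ch in enumerate(states8):
        try:
            out.append(SS8_TO_SS3[ch])
        except KeyError:
            raise ValueError(
                f"unknown secondary-structure code {ch!r} at position {i + 1}"
            ) from None
    return "".join(out)


@dataclass(frozen=True)
class SS3Distribution:
    """Per-quadrant helix/sheet/coil fractions and residue counts."""

    fractions: dict[str, tuple[float, float, float]]  # quadrant -> (H, E, C)
    counts: dict[str, tuple[int, int, int]]

    def n_residues(self, quadrant: str) -> int:
        return sum(self.counts.get(quadrant, (0, 0, 0)))


def ss_by_quadrant(
    residue_quadrants: list[tuple[str, int, str]],
    ss: dict[str, SSString],
) -> SS3Distribution:
    """Tally 3-state secondary structure per quadrant.

    ``residue_quadrants`` lists (accession, 1-based position, quadrant) for
    every classified residue; ``ss`` maps accession to its 8-state string.
    """
    tallies = {q: [0, 0, 0] for q in QUADRANTS}  # H, E, C
    idx = {"H": 0, "E": 1, "C": 2}
    three_state_cache: dict[str, str] = {}
    for accession, position, quadrant in residue_quadrants:
        if accession not in ss:
            raise ValueError(f"no secondary structure available for {accession}")
        if accession not in three_state_cache:
            three_state_cache[accession] = to_three_state(ss[accession])
        ss3 = three_state_cache[accession]
        if not 1 <= position <= len(ss3):
            raise ValueError(
                f"{accession}: position {position} outside SS string "
                f"of length {len(ss3)}"
            )
        if quadrant not in tallies:
            raise ValueError(f"unknown quadrant {quadrant!r}")
        tallies[quadrant][idx[ss3[position - 1]]] += 1

    fractions: dict[str, tuple[float, float, float]] = {}
    counts: dict[str, tuple[int, int, int]] = {}
    for q, (h, e, c) in ((q, tuple(v)) for q, v in tallies.items()):
        counts[q] = (h, e, c)
        n = h + e + c
        if n:
            fractions[q] = (h / n, e / n, c / n)
    return SS3Distribution(fractions=fractions, counts=counts)
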