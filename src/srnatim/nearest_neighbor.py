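"""Simplified nearest-neighbor RNA energy parameters.

A small, self-contained stacking model over Watson-Crick and GU wobble
pairs.  The same table drives both the inter-molecular duplex algorithm
and the intra-molecular partition function, so duplex energies, opening
energies and unpaired probabilities are mutually consistent and every
quantity can be cross-checked against exhaustive enumeration.

Free energies are in kcal/mol at 37 degrees C.  The table is
published-style nearest-neighbor data rounded to two decimals; it is not
a full Turner-2004 parameter set (no dangles, no terminal-AU penalties,
no sequence-dependent loop energies).
"""

from __future__ import annotations

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol*K)
DEFAULT_TEMPERATURE = 310.15  # K (37 C)


def rt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """R*T in kcal/mol."""
    return GAS_CONSTANT_KCAL * temperature


RNA_ALPHABET = frozenset("ACGU")

#: Allowed base pairs (Watson-Crick + GU wobble).
PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def can_pair(x: str, y: str) -> bool:
    return (x, y) in PAIRS


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _rev(pair: str) -> str:
    return pair[::-1]


# Stack entries keyed "XY/ZW": top strand 5'-XY-3' over bottom strand
# 3'-ZW-5'; X pairs with Z, Y pairs with W.  In nested notation this is
# the stack of pair (X,Z) on the inner pair (Y,W).  21 unique entries;
# the remaining orientations follow from strand-flip symmetry.
_BASE_STACKS = {
    # Watson-Crick on Watson-Crick
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # Watson-Crick on GU wobble
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.27,
    ("UA", "UG"): -0.90,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -1.80,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    # GU on GU
    ("GU", "GU"): 0.47,
    ("GU", "UG"): -0.44,
    ("UG", "GU"): 0.30,
}


def _build_stack_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for (p1, p2), e in _BASE_STACKS.items():
        table[(p1, p2)] = e
        mirror = (_rev(p2), _rev(p1))
        if mirror in table and table[mirror] != e:
            raise AssertionError(f"inconsistent stack symmetry for {p1}/{p2}")
        table[mirror] = e
    # every ordered combination of the six pair types must be covered
    ptypes = ["AU", "UA", "CG", "GC", "GU", "UG"]
    for a in ptypes:
        for b in ptypes:
            if (a, b) not in table:
                raise AssertionError(f"missing stack entry {a}/{b}")
    return table


#: Stack free energy keyed by (outer pair, inner pair), e.g.
#: ``STACK[("CG", "GC")]`` is 5'-CG-3' paired with 3'-GC-5'.
STACK: dict[tuple[str, str], float] = _build_stack_table()


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Stacking free energy of ``inner`` pair on ``outer`` pair (kcal/mol)."""
    return STACK[(outer[0] + outer[1], inner[0] + inner[1])]


# Intra-molecular folding: each helix pays a constant initiation cost,
# charged at its innermost pair (the pair whose immediate inner
# neighbors are not paired with each other, i.e. the pair closing a
# loop).  Isolated pairs are thereby strongly suppressed while long
# stacked helices remain stable -- the qualitative shape of real
# loop-entropy penalties.  Without this term the ensemble is dominated
# by myriads of energetically neutral single pairs and every long
# interval looks inaccessible.
HELIX_OPEN = 4.5  # kcal/mol per helix (loop initiation)

# Inter-molecular duplex parameters (kcal/mol).
DUPLEX_INIT = 4.10  # duplex initiation penalty
LOOP_OPEN = 3.20  # affine opening cost of a bulge/interior loop
LOOP_PER_NT = 0.60  # per unpaired nucleotide inside the loop
MAX_LOOP_SIDE = 6  # maximal unpaired stretch per strand between pairs

# Minimal number of unpaired bases enclosed by an intra-molecular hairpin.
MIN_HAIRPIN_LOOP = 3


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map DNA T to U and validate the alphabet.

    Raises ``ValueError`` naming the offending character; ambiguity codes
    are rejected because every downstream energy rule needs a concrete
    base.
    """
    out = seq.upper().replace("T", "U")
    for ch in out:
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"invalid character {ch!r} in {context}: only A/C/G/U (or T) allowed"
            )
    return out
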