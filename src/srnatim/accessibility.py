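"""RDS accessibility: partition-function unpaired probabilities.

The probability that an interval is completely unpaired is the ratio
Z_u/Z of two partition functions over all nested secondary structures
(minimum hairpin loop 3), where Z_u additionally forbids every base of
the interval from pairing.  Constraint folding -- forbidding the bases
bound by an sRNA from intra-molecular pairing -- uses the same machinery
and yields the sRNA-influenced exposure probability P_ES next to the
free-mRNA P_EF.  Opening energies and probabilities interconvert via
P = exp(-dE / RT).

Structure energies are the stack sums of the package's simplified
nearest-neighbor model, so these probabilities are exactly checkable
against exhaustive structure enumeration (provided here as the reference
path for short sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from . import nearest_neighbor as nn
from .duplex import BindingSite, RibosomeSite
from .sequence_io import RelativeInterval, Transcript, relative_to_absolute

_PTYPES = ["AU", "UA", "CG", "GC", "GU", "UG"]
_PT_INDEX = {p: i for i, p in enumerate(_PTYPES)}


def _pair_type_matrix(seq: str) -> np.ndarray:
    """ptype[i, j] = index of pair (seq[i], seq[j]) in _PTYPES, or -1."""
    n = len(seq)
    pt = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            p = seq[i] + seq[j]
            if p in _PT_INDEX:
                pt[i, j] = _PT_INDEX[p]
    return pt


@lru_cache(maxsize=8)
def _stack_weight_table(temperature: float) -> np.ndarray:
    beta = 1.0 / nn.rt_kcal(temperature)
    W = np.empty((len(_PTYPES), len(_PTYPES)))
    for a, pa in enumerate(_PTYPES):
        for b, pb in enumerate(_PTYPES):
            W[a, b] = math.exp(-beta * nn.STACK[(pa, pb)])
    return W


def _log_partition(
    seq: str,
    forbidden: frozenset[int],
    max_span: int | None,
    temperature: float,
    scale: float,
) -> float:
    """log Z over all structures in which no forbidden base pairs.

    Diagonal-vectorized McCaskill-style recursion with per-base rescaling
    by ``scale`` to avoid overflow; returns the unscaled log Z.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    pt = _pair_type_matrix(seq)
    W = _stack_weight_table(temperature)
    w_open = math.exp(-nn.HELIX_OPEN / nn.rt_kcal(temperature))
    allowed = pt >= 0
    if forbidden:
        idx = np.fromiter(forbidden, dtype=np.int64)
        allowed[idx, :] = False
        allowed[:, idx] = False
    s = scale
    # Z[i, j] for j >= i - 1 (empty interval = 1 scaled as s**0 -> stored
    # on the superdiagonal implicitly); use dense (n, n) arrays per span.
    Z = np.zeros((n, n))
    Zb = np.zeros((n, n))
    # span d = j - i
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        # --- Zb: (i, j) paired ---
        if d >= nn.MIN_HAIRPIN_LOOP + 1:
            ok = allowed[i, j]
            if max_span is not None:
                ok = ok & (d + 1 <= max_span)
            inner_Z = Z[i + 1, j - 1]
            inner_Zb = Zb[i + 1, j - 1]
            # split the inner ensemble on whether (i+1, j-1) is paired:
            # if so this pair stacks on it, otherwise it opens a new helix
            sw = W[pt[i, j], pt[i + 1, j - 1]]  # -1 indices are masked by ok/Zb=0
            zb = (w_open * (inner_Z - inner_Zb) + sw * inner_Zb) / (s * s)
            Zb[i, j] = np.where(ok, zb, 0.0)
        # --- Z: first position unpaired or paired to k ---
        if d == 0:
            Z[i, j] = 1.0 / s
            continue
        z = Z[i + 1, j] / s  # i unpaired
        # i paired with k in [i+4, j]; inner [i+1, k-1], outer [k+1, j]
        for toff in range(nn.MIN_HAIRPIN_LOOP + 1, d + 1):
            k = i + toff
            outer = Z[k + 1, j] if toff < d else np.full_like(z, 1.0)
            z = z + Zb[i, k] * outer
        Z[i, j] = z
    total = Z[0, n - 1]
    if not np.isfinite(total) or total <= 0.0:
        raise OverflowError("partition function over/underflow; retry with new scale")
    return math.log(total) + n * math.log(s)


def _log_z(
    seq: str,
    forbidden: frozenset[int] = frozenset(),
    max_span: int | None = None,
    temperature: float = nn.DEFAULT_TEMPERATURE,
) -> float:
    for scale in (1.0, 4.0, 32.0):
        try:
            return _log_partition(seq, forbidden, max_span, temperature, scale)
        except OverflowError:
            continue
    raise OverflowError(f"partition function overflow for length {len(seq)}")


def unpaired_probability(
    seq: str,
    interval: tuple[int, int],
    forbidden_bases: Iterable[int] = (),
    max_span: int | None = None,
    temperature: float = nn.DEFAULT_TEMPERATURE,
) -> float:
    """Probability that every base of ``interval`` (0-based, inclusive) is unpaired.

    ``forbidden_bases`` are excluded from intra-molecular pairing in both
    the numerator and denominator ensembles (constraint folding).
    """
    seq = nn.normalize_rna(seq, context="accessibility sequence")
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"empty interval {interval}")
    if lo < 0 or hi >= len(seq):
        raise ValueError(f"interval {interval} outside sequence of length {len(seq)}")
    forb = frozenset(int(b) for b in forbidden_bases)
    if any(b < 0 or b >= len(seq) for b in forb):
        raise ValueError("forbidden base outside sequence")
    log_z = _log_z(seq, forb, max_span, temperature)
    log_zu = _log_z(seq, forb | frozenset(range(lo, hi + 1)), max_span, temperature)
    return math.exp(min(log_zu - log_z, 0.0))


# --- exhaustive enumeration reference (short sequences) -------------------


def enumerate_structures(
    seq: str, max_span: int | None = None
) -> list[tuple[tuple[int, int], ...]]:
    """All nested secondary structures (as sorted pair tuples); n <= ~25."""
    seq = nn.normalize_rna(seq, context="enumeration sequence")
    n = len(seq)

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if i > j:
            return [()]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + nn.MIN_HAIRPIN_LOOP + 1, j + 1):
            if not nn.can_pair(seq[i], seq[k]):
                continue
            if max_span is not None and k - i + 1 > max_span:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append(((i, k),) + inner + outer)
        return out

    return [tuple(sorted(s)) for s in rec(0, n - 1)]


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of one structure: helix initiations plus stack terms.

    A pair whose immediate inner neighbors are also paired with each
    other contributes the stacking energy of the two pairs; every other
    pair closes a loop and contributes the helix-initiation penalty.
    """
    pset = set(pairs)
    e = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pset:
            e += nn.stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
        else:
            e += nn.HELIX_OPEN
    return e


def unpaired_probability_brute(
    seq: str,
    interval: tuple[int, int],
    forbidden_bases: Iterable[int] = (),
    max_span: int | None = None,
    temperature: float = nn.DEFAULT_TEMPERATURE,
) -> float:
    """Reference unpaired probability by summing over every structure."""
    seq = nn.normalize_rna(seq, context="enumeration sequence")
    if len(seq) > 28:
        raise ValueError("brute-force enumeration is limited to <= 28 nt")
    lo, hi = interval
    forb = set(forbidden_bases)
    beta = 1.0 / nn.rt_kcal(temperature)
    z = zu = 0.0
    for s in enumerate_structures(seq, max_span):
        if any(i in forb or j in forb for i, j in s):
            continue
        w = math.exp(-beta * structure_energy(seq, s))
        z += w
        if not any(lo <= i <= hi or lo <= j <= hi for i, j in s):
            zu += w
    return zu / z


# --- opening energy conversions ------------------------------------------


def opening_energy_to_probability(
    delta_E: float, temperature: float = nn.DEFAULT_TEMPERATURE
) -> float:
    """P = exp(-dE / RT); an opening energy cannot be favorable."""
    if delta_E < 0:
        raise ValueError(f"opening energy must be >= 0, got {delta_E}")
    return math.exp(-delta_E / nn.rt_kcal(temperature))


def probability_to_opening_energy(
    p: float, temperature: float = nn.DEFAULT_TEMPERATURE
) -> float:
    """dE = -RT ln P, inverse of :func:`opening_energy_to_probability`."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return -nn.rt_kcal(temperature) * math.log(p)


# --- RDS exposure ---------------------------------------------------------


@dataclass(frozen=True)
class AccessibilityResult:
    """Exposure of the RDS, free (P_EF) or under sRNA constraint (P_ES)."""

    interval: RelativeInterval  # the RDS in relative coordinates
    opening_energy: float  # kcal/mol (dE_F or dE_S)
    probability: float  # P_EF or P_ES
    constrained: bool
    window_used: tuple[int, int]  # absolute, 0-based inclusive

    @property
    def K_open(self) -> float:
        """Equilibrium constant of the opening reaction, K = P/(1-P)."""
        if self.probability >= 1.0:
            return math.inf
        return self.probability / (1.0 - self.probability)


def rds_exposure(
    t: Transcript,
    rds_site: RibosomeSite,
    site: "BindingSite | None",
    backend,
    flank: int = 250,
) -> AccessibilityResult:
    """Probability that the whole RDS is unpaired, +-``flank`` nt context.

    Without a site this is P_EF; with a site, the site's mRNA bases are
    forbidden from intra-molecular pairing (they are occupied by the
    sRNA) and the result is P_ES.  The folding window is clipped at the
    transcript ends without recentering.
    """
    lo = relative_to_absolute(t, rds_site.rds.rel_start)
    hi = relative_to_absolute(t, rds_site.rds.rel_end)
    if lo < 0 or hi >= len(t.sequence):
        raise ValueError(f"transcript {t.id!r}: RDS extends beyond the sequence")
    wlo = max(0, lo - flank)
    whi = min(len(t.sequence) - 1, hi + flank)
    window = t.sequence[wlo : whi + 1]
    forbidden: set[int] = set()
    if site is not None:
        s_lo = relative_to_absolute(t, site.mrna.rel_start)
        s_hi = relative_to_absolute(t, site.mrna.rel_end)
        forbidden = {b - wlo for b in range(max(s_lo, wlo), min(s_hi, whi) + 1)}
    p = backend.unpaired_prob(window, (lo - wlo, hi - wlo), forbidden)
    return AccessibilityResult(
        interval=rds_site.rds,
        opening_energy=probability_to_opening_energy(p, backend.temperature),
        probability=p,
        constrained=site is not None,
        window_used=(wlo, whi),
    )
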