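"""Pluggable RNA energy backends.

A backend supplies the three thermodynamic primitives the screening
model needs: the best inter-molecular duplex, sub-optimal duplex sites,
and constrained unpaired probabilities.  The default
:class:`NearestNeighborBackend` is self-contained and exactly checkable
against exhaustive enumeration; :class:`ViennaRNABackend` adapts the
ViennaRNA bindings for full Turner-parameter energetics when they are
installed.
"""

from __future__ import annotations

import math
from typing import Iterable, Protocol, runtime_checkable

from . import nearest_neighbor as nn
from .accessibility import probability_to_opening_energy, unpaired_probability
from .duplex import DuplexHit, duplex_fold, suboptimal_duplexes

#: Accessibility-profile parameters for site opening energies: folding
#: window length and maximal base-pair span (clipped for short inputs).
OPENING_WINDOW = 200
OPENING_MAX_SPAN = 150


@runtime_checkable
class EnergyBackend(Protocol):
    """Interface every energy backend implements."""

    name: str
    temperature: float

    def duplex(self, target: str, query: str) -> DuplexHit | None:
        """Best inter-molecular duplex; None if nothing below 0 kcal/mol."""
        ...

    def suboptimal_sites(
        self, query: str, target: str, energy_cutoff: float
    ) -> list[DuplexHit]:
        """Distinct sub-optimal duplex sites of query on target."""
        ...

    def unpaired_prob(
        self, seq: str, interval: tuple[int, int], forbidden_bases: Iterable[int] = ()
    ) -> float:
        """P that ``interval`` is entirely unpaired, under constraints."""
        ...

    def opening_energy(self, seq: str, interval: tuple[int, int]) -> float:
        """Free-energy cost of keeping ``interval`` unpaired (>= 0)."""
        ...


class NearestNeighborBackend:
    """Bundled backend on the package's simplified stacking model.

    Duplex and intra-molecular energetics share one stack table, so the
    accessibility-corrected site energies are internally consistent.
    """

    def __init__(self, temperature: float = nn.DEFAULT_TEMPERATURE):
        self.name = "nearest-neighbor"
        self.temperature = temperature

    def duplex(self, target: str, query: str) -> DuplexHit | None:
        return duplex_fold(target, query)

    def suboptimal_sites(
        self, query: str, target: str, energy_cutoff: float
    ) -> list[DuplexHit]:
        # pre-filter on raw duplex energy: the accessibility correction
        # only ever makes a site less favorable, so no site with a raw
        # energy above the cutoff can survive
        return suboptimal_duplexes(target, query, energy_cutoff)

    def unpaired_prob(
        self,
        seq: str,
        interval: tuple[int, int],
        forbidden_bases: Iterable[int] = (),
        max_span: int | None = None,
    ) -> float:
        return unpaired_probability(
            seq, interval, forbidden_bases, max_span=max_span,
            temperature=self.temperature,
        )

    def opening_energy(self, seq: str, interval: tuple[int, int]) -> float:
        lo, hi = interval
        # local folding window centered on the interval, span-limited
        half = max(0, (OPENING_WINDOW - (hi - lo + 1)) // 2)
        wlo = max(0, lo - half)
        whi = min(len(seq) - 1, hi + half)
        p = unpaired_probability(
            seq[wlo : whi + 1],
            (lo - wlo, hi - wlo),
            max_span=OPENING_MAX_SPAN,
            temperature=self.temperature,
        )
        return probability_to_opening_energy(p, self.temperature)


class ViennaRNABackend:
    """Adapter for the ViennaRNA Python bindings (Turner energies).

    Sub-optimal sites come from ``RNA.duplex_subopt``; unpaired
    probabilities are computed as constrained partition-function ratios
    with hard constraints.  Requires the optional ``RNA`` module.
    """

    def __init__(self, temperature: float = nn.DEFAULT_TEMPERATURE):
        import RNA  # deferred: optional dependency

        self._RNA = RNA
        self.name = "viennarna"
        self.temperature = temperature
        self._md = RNA.md()
        self._md.temperature = temperature - 273.15

    def duplex(self, target: str, query: str) -> DuplexHit | None:
        d = self._RNA.duplexfold(target, query)
        if d is None or d.energy >= 0:
            return None
        return self._hit_from_duplexT(d, target, query)

    def _hit_from_duplexT(self, d, target: str, query: str) -> DuplexHit:
        left, right = d.structure.split("&")
        # ViennaRNA reports i as the END on seq1 and j as the START on seq2
        a_end = d.i - 1
        a_start = a_end - len(left) + 1
        b_start = d.j - 1
        b_end = b_start + len(right) - 1
        pairs = []
        bs = [b_start + k for k, c in enumerate(right) if c == ")"]
        as_ = [a_start + k for k, c in enumerate(left) if c == "("]
        for i, j in zip(as_, reversed(bs)):
            pairs.append((i, j))
        return DuplexHit(d.energy, a_start, a_end, b_start, b_end, tuple(pairs))

    def suboptimal_sites(
        self, query: str, target: str, energy_cutoff: float
    ) -> list[DuplexHit]:
        subs = self._RNA.duplex_subopt(target, query, int(-energy_cutoff * 100), 0)
        hits = [
            self._hit_from_duplexT(d, target, query)
            for d in subs
            if d.energy < min(energy_cutoff, 0.0)
        ]
        hits.sort(key=lambda h: (h.energy, h.a_start))
        kept: list[DuplexHit] = []
        for h in hits:
            if not any(
                min(h.a_end, k.a_end) - max(h.a_start, k.a_start) + 1
                > 0.5 * (min(h.a_end - h.a_start, k.a_end - k.a_start) + 1)
                and min(h.b_end, k.b_end) >= max(h.b_start, k.b_start)
                for k in kept
            ):
                kept.append(h)
        return kept

    def unpaired_prob(
        self,
        seq: str,
        interval: tuple[int, int],
        forbidden_bases: Iterable[int] = (),
        max_span: int | None = None,
    ) -> float:
        RNA = self._RNA
        kT = nn.rt_kcal(self.temperature)

        def pf_dG(extra_unpaired: Iterable[int]) -> float:
            fc = RNA.fold_compound(seq, self._md)
            for b in extra_unpaired:
                fc.hc_add_up(b + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
            _, dG = fc.pf()
            return dG

        base = sorted(set(int(b) for b in forbidden_bases))
        lo, hi = interval
        dG = pf_dG(base)
        dG_u = pf_dG(sorted(set(base) | set(range(lo, hi + 1))))
        return math.exp(min(-(dG_u - dG) / kT, 0.0))

    def opening_energy(self, seq: str, interval: tuple[int, int]) -> float:
        p = self.unpaired_prob(seq, interval)
        return probability_to_opening_energy(p, self.temperature)


def get_backend(name: str = "nearest-neighbor", temperature: float = nn.DEFAULT_TEMPERATURE) -> EnergyBackend:
    """Backend factory keyed by config name."""
    if name in ("nearest-neighbor", "builtin", "nn"):
        return NearestNeighborBackend(temperature)
    if name in ("viennarna", "vienna", "rna"):
        return ViennaRNABackend(temperature)
    raise ValueError(f"unknown energy backend {name!r}")
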