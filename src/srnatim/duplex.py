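"""Inter-molecular hybridization: RRS/RDS location and sRNA binding sites.

The ribosome recognition site (RRS) generalizes the Shine-Dalgarno
sequence: it is the energetically best duplex of the 16S rRNA 3' end
(the anti-RRS, ``UCACCUCCUU`` in E. coli) in a short window upstream of
the start codon.  The ribosome docking site (RDS) is the 30-nt stretch
occupied by the initiating 30S subunit, starting at the RRS start.

The duplex algorithm considers inter-molecular base pairs only;
inter-molecular bulges and interior loops are permitted with an affine
penalty.  Intra-molecular structure enters separately, as the opening
energies that turn a raw hybridization energy into the
accessibility-corrected binding energy of a candidate sRNA site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

from . import nearest_neighbor as nn
from .sequence_io import (
    RelativeInterval,
    Transcript,
    WindowExtract,
    absolute_to_relative,
    extract_window,
    intervals_overlap,
    linear_to_rel,
    rel_to_linear,
)

if TYPE_CHECKING:  # pragma: no cover
    from .backends import EnergyBackend

log = logging.getLogger(__name__)

DEFAULT_ANTI_RRS = "UCACCUCCUU"
DEFAULT_RRS_WINDOW = RelativeInterval(-30, +3)
DEFAULT_SITE_WINDOW = RelativeInterval(-150, +20)
DEFAULT_ENERGY_CUTOFF = -7.0  # kcal/mol, accessibility-corrected
DEFAULT_MIN_SITE_LEN = 10  # nt on the mRNA, interior bulges included
RDS_LENGTH = 30  # nt occupied by the initiating 30S subunit

# start-codon / anti-codon stabilization added to the RRS duplex energy
_START_CODON_BONUS = {"AUG": -1.19, "GUG": -0.075}


def start_codon_bonus(codon: str) -> float:
    """Anti-codon interaction bonus in kcal/mol (AUG/GUG; 0 otherwise)."""
    codon = nn.normalize_rna(codon, context="start codon")
    if len(codon) != 3:
        raise ValueError(f"start codon must be 3 nt, got {codon!r}")
    return _START_CODON_BONUS.get(codon, 0.0)


@dataclass(frozen=True)
class DuplexHit:
    """One inter-molecular duplex between target ``a`` and query ``b``.

    Coordinates are 0-based inclusive on each strand; ``pairs`` lists the
    paired index tuples (i on a, j on b), 5'->3' along ``a``.
    """

    energy: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    pairs: tuple[tuple[int, int], ...]


def duplex_energy_min(a: str, b: str) -> list[list[float]]:
    """DP matrix E[i][j]: best energy of a duplex whose last pair is (a_i, b_j)."""
    la, lb = len(a), len(b)
    inf = float("inf")
    E = [[inf] * lb for _ in range(la)]
    for i in range(la):
        for j in range(lb):
            if not nn.can_pair(a[i], b[j]):
                continue
            best = nn.DUPLEX_INIT
            for k in range(max(0, i - 1 - nn.MAX_LOOP_SIDE), i):
                ga = i - k - 1
                for l in range(j + 1, min(lb, j + 2 + nn.MAX_LOOP_SIDE)):
                    if E[k][l] == inf:
                        continue
                    gb = l - j - 1
                    if ga == 0 and gb == 0:
                        cost = nn.stack_energy((a[k], b[l]), (a[i], b[j]))
                    else:
                        cost = nn.LOOP_OPEN + nn.LOOP_PER_NT * (ga + gb)
                    if E[k][l] + cost < best:
                        best = E[k][l] + cost
            E[i][j] = best
    return E


def _traceback(a: str, b: str, E: list[list[float]], i: int, j: int) -> DuplexHit:
    pairs = [(i, j)]
    energy = E[i][j]
    while abs(E[i][j] - nn.DUPLEX_INIT) > 1e-9:
        found = False
        for k in range(max(0, i - 1 - nn.MAX_LOOP_SIDE), i):
            ga = i - k - 1
            for l in range(j + 1, min(len(b), j + 2 + nn.MAX_LOOP_SIDE)):
                if E[k][l] == float("inf"):
                    continue
                gb = l - j - 1
                if ga == 0 and gb == 0:
                    cost = nn.stack_energy((a[k], b[l]), (a[i], b[j]))
                else:
                    cost = nn.LOOP_OPEN + nn.LOOP_PER_NT * (ga + gb)
                if abs(E[k][l] + cost - E[i][j]) < 1e-9:
                    pairs.append((k, l))
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        if not found:  # numerical safety: treat as helix start
            break
    pairs.reverse()
    return DuplexHit(
        energy=energy,
        a_start=pairs[0][0],
        a_end=pairs[-1][0],
        b_start=min(p[1] for p in pairs),
        b_end=max(p[1] for p in pairs),
        pairs=tuple(pairs),
    )


def duplex_fold(a: str, b: str) -> DuplexHit | None:
    """Best inter-molecular duplex of query ``b`` on target ``a``.

    Returns ``None`` when no duplex with negative free energy exists.
    Ties in energy resolve to the most 5' site on ``a``.
    """
    a = nn.normalize_rna(a, context="duplex target")
    b = nn.normalize_rna(b, context="duplex query")
    if not a or not b:
        return None
    E = duplex_energy_min(a, b)
    best: tuple[float, int, int] | None = None
    for i in range(len(a)):
        for j in range(len(b)):
            e = E[i][j]
            if e >= 0 or e == float("inf"):
                continue
            hit = _traceback(a, b, E, i, j)
            key = (round(e, 9), hit.a_start, i, j)
            if best is None or key < best[0]:
                best = (key, i, j)  # type: ignore[assignment]
    if best is None:
        return None
    _, i, j = best
    return _traceback(a, b, E, i, j)


def suboptimal_duplexes(a: str, b: str, energy_cutoff: float = 0.0) -> list[DuplexHit]:
    """All distinct duplex sites of ``b`` on ``a`` below ``energy_cutoff``.

    Every DP end point below the cutoff is traced back; hits are then
    deduplicated: two hits are the same site when their spans on ``a``
    overlap by more than half (of the shorter span) and their spans on
    ``b`` intersect; the lower-energy one is kept.
    """
    a = nn.normalize_rna(a, context="duplex target")
    b = nn.normalize_rna(b, context="duplex query")
    if not a or not b:
        return []
    E = duplex_energy_min(a, b)
    raw: list[DuplexHit] = []
    for i in range(len(a)):
        for j in range(len(b)):
            e = E[i][j]
            if e == float("inf") or e >= min(energy_cutoff, 0.0):
                continue
            raw.append(_traceback(a, b, E, i, j))
    raw.sort(key=lambda h: (h.energy, h.a_start, h.b_start))
    kept: list[DuplexHit] = []
    for h in raw:
        dup = False
        for k in kept:
            ov = min(h.a_end, k.a_end) - max(h.a_start, k.a_start) + 1
            shorter = min(h.a_end - h.a_start, k.a_end - k.a_start) + 1
            same_b = min(h.b_end, k.b_end) >= max(h.b_start, k.b_start)
            if ov > 0.5 * shorter and same_b:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


@dataclass(frozen=True)
class RibosomeSite:
    """RRS/RDS location and ribosome hybridization energy for one transcript."""

    rrs: RelativeInterval
    rds: RelativeInterval
    delta_G_R: float  # kcal/mol, duplex energy + start-codon bonus

    def __post_init__(self) -> None:
        if self.rds.length != RDS_LENGTH:
            raise ValueError(f"RDS must span {RDS_LENGTH} nt, got {self.rds.length}")
        if self.rds.rel_start != self.rrs.rel_start:
            raise ValueError("RDS must start at the RRS start")


def _shift_rel(rel: int, offset: int) -> int:
    return linear_to_rel(rel_to_linear(rel) + offset)


def find_rrs(
    t: Transcript,
    backend: "EnergyBackend",
    anti_rrs: str = DEFAULT_ANTI_RRS,
    search_window: RelativeInterval = DEFAULT_RRS_WINDOW,
) -> RibosomeSite | None:
    """Locate the RRS as the best anti-RRS duplex near the start codon.

    Returns ``None`` (the "no RRS" condition; the transcript is skipped
    downstream) when no duplex with negative energy exists in the
    window.  delta_G_R includes the start-codon bonus of the annotated
    codon.  At equal energies the most upstream site wins.
    """
    win = extract_window(t, search_window)
    if win.empty:
        log.warning("transcript %s: RRS search window empty after clipping", t.id)
        return None
    hit = backend.duplex(win.sequence, nn.normalize_rna(anti_rrs, context="anti-RRS"))
    if hit is None:
        log.info("transcript %s: no RRS (no favorable anti-RRS duplex)", t.id)
        return None
    rrs_start = absolute_to_relative(t, win.abs_start + hit.a_start)
    rrs_end = absolute_to_relative(t, win.abs_start + hit.a_end)
    rds = RelativeInterval(rrs_start, _shift_rel(rrs_start, RDS_LENGTH - 1))
    dG_R = hit.energy + start_codon_bonus(t.start_codon)
    return RibosomeSite(RelativeInterval(rrs_start, rrs_end), rds, dG_R)


@dataclass(frozen=True)
class BindingSite:
    """A candidate sRNA binding site on an mRNA.

    ``delta_G_S`` is the accessibility-corrected binding energy: raw
    duplex energy plus the opening energies of the bound intervals on
    both molecules.  ``length_nt`` is the span on the mRNA including
    interior unpaired bases; the sRNA span is recorded separately.
    """

    mrna: RelativeInterval
    srna_start: int  # 1-based on the sRNA
    srna_end: int
    delta_G_S: float
    delta_G_duplex: float
    open_energy_mrna: float
    open_energy_srna: float

    @property
    def length_nt(self) -> int:
        return self.mrna.length

    @property
    def srna_span_nt(self) -> int:
        return self.srna_end - self.srna_start + 1


def overlaps(rds: RibosomeSite, site: BindingSite) -> bool:
    """True iff the sRNA site shares at least one mRNA base with the RDS.

    Overlap means simultaneous ribosome and sRNA binding is sterically
    impossible, selecting the competition (overlap) topology.
    """
    return intervals_overlap(rds.rds, site.mrna)


def apply_site_filters(
    sites: list[BindingSite],
    window: RelativeInterval = DEFAULT_SITE_WINDOW,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    min_len: int = DEFAULT_MIN_SITE_LEN,
) -> list[BindingSite]:
    """Keep sites with dG_S <= cutoff, length >= min_len, fully inside window.

    Boundary values pass: a site at exactly the cutoff energy, exactly
    ``min_len`` long, or touching a window edge is retained.
    """
    out = []
    for s in sites:
        if s.delta_G_S > energy_cutoff:
            continue
        if s.length_nt < min_len:
            continue
        if rel_to_linear(s.mrna.rel_start) < rel_to_linear(window.rel_start):
            continue
        if rel_to_linear(s.mrna.rel_end) > rel_to_linear(window.rel_end):
            continue
        out.append(s)
    return sorted(out, key=lambda s: (s.delta_G_S, rel_to_linear(s.mrna.rel_start)))


def find_srna_sites(
    srna: str,
    t: Transcript,
    backend: "EnergyBackend",
    window: RelativeInterval = DEFAULT_SITE_WINDOW,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    min_len: int = DEFAULT_MIN_SITE_LEN,
) -> list[BindingSite]:
    """Enumerate filtered sub-optimal sRNA binding sites on a transcript.

    The search window (default -150..+20 around the translation start,
    clipped to the transcript) is scanned for sub-optimal duplexes; each
    hit's energy is corrected by the opening energies of the bound
    stretches on mRNA and sRNA, then the standard filters apply
    (dG_S <= -7 kcal/mol, >= 10 nt on the mRNA, full containment in the
    window).  An empty list is a valid outcome.  Results are sorted by
    corrected energy, best first.
    """
    srna = nn.normalize_rna(srna, context="sRNA")
    win = extract_window(t, window)
    if win.empty or not srna:
        return []
    sites = []
    for hit in backend.suboptimal_sites(srna, win.sequence, energy_cutoff):
        site = _corrected_site(hit, t, win, srna, backend)
        sites.append(site)
    clipped = RelativeInterval(
        absolute_to_relative(t, win.abs_start), absolute_to_relative(t, win.abs_end)
    )
    return apply_site_filters(sites, clipped, energy_cutoff, min_len)


def _corrected_site(
    hit: DuplexHit,
    t: Transcript,
    win: WindowExtract,
    srna: str,
    backend: "EnergyBackend",
) -> BindingSite:
    """Accessibility-correct one duplex hit into a BindingSite."""
    m_lo = win.abs_start + hit.a_start
    m_hi = win.abs_start + hit.a_end
    open_m = backend.opening_energy(t.sequence, (m_lo, m_hi))
    open_s = backend.opening_energy(srna, (hit.b_start, hit.b_end))
    return BindingSite(
        mrna=RelativeInterval(
            absolute_to_relative(t, m_lo), absolute_to_relative(t, m_hi)
        ),
        srna_start=hit.b_start + 1,
        srna_end=hit.b_end + 1,
        delta_G_S=hit.energy + open_m + open_s,
        delta_G_duplex=hit.energy,
        open_energy_mrna=open_m,
        open_energy_srna=open_s,
    )
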