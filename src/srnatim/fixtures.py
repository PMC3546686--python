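"""Synthetic mRNA/sRNA scenarios with known intended behavior.

Each generator plants a mechanism -- RDS occlusion (repression), stem
release upstream of the RDS (activation), no complementarity (null), or
a decoy best-energy site far upstream next to a weaker effective site
(upstream_weak) -- into a random low-GC background, then verifies the
scenario end to end through the screening pipeline before emitting it.
Generation uses Python's integer Mersenne Twister exclusively, so a seed
reproduces identical sequences on any platform.

Backgrounds are pairing-poor -- strongly A-biased with sparse U/G/C --
so that complementary runs are rare, the only stable structure in a
scenario is the planted one, and the free RDS stays exposed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .accessibility import rds_exposure
from .backends import EnergyBackend, NearestNeighborBackend
from .duplex import find_rrs, find_srna_sites
from .expression import ConcentrationSet, available_ribosomes, default_srna_copies
from .nearest_neighbor import reverse_complement
from .screening import ScreenConfig, ScreenRecord, evaluate_site
from .sequence_io import RelativeInterval, Transcript, relative_to_absolute

UTR_LEN = 160  # nt upstream of the start codon in generated transcripts
CDS_LEN = 80  # nt of coding sequence after the start codon
RRS_MOTIF = reverse_complement("UCACCUCCUU")  # perfect anti-RRS complement
# Generated target expression.  Kept below r_T/n even at the top of the
# usual occupancy range (n = 100 -> 114 ribosome slots) so the scenarios
# stay sRNA-limited, not ribosome-limited, across sensitivity sweeps.
DEFAULT_M_T = 150.0  # copies/cell

_GC_FRACTION = 0.25
_MAX_TRIES = 40


@dataclass(frozen=True)
class FixtureScenario:
    """One self-verified synthetic screening scenario."""

    label: str  # repression | activation | null | upstream_weak
    transcript: Transcript
    srna_id: str
    srna: str
    planted_site: RelativeInterval | None
    expected_topology: str  # overlap | nonoverlap | n/a
    expected_call: str  # repressed | activated | no_sites | no_effect
    seed: int

    @property
    def concentrations(self) -> ConcentrationSet:
        return ConcentrationSet(
            m_T=DEFAULT_M_T,
            s_T=default_srna_copies(DEFAULT_M_T),
            r_T=available_ribosomes(),
        )


def _random_bases(rng: random.Random, k: int, gc: float = _GC_FRACTION) -> str:
    w = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choices("AUGC", weights=w, k=k))


#: Pairing-poor background weights (A, U, G, C): A dominates and U/G/C
#: are sparse, so complementary runs -- and with them spurious stems over
#: the ribosome docking site -- are rare.
_BACKGROUND_WEIGHTS = (0.70, 0.10, 0.10, 0.10)


def _background(rng: random.Random) -> list[str]:
    """Random pairing-poor transcript with the RRS motif at -12..-3, AUG at +1."""
    seq = list(rng.choices("AUGC", weights=_BACKGROUND_WEIGHTS, k=UTR_LEN + CDS_LEN))
    seq[UTR_LEN : UTR_LEN + 3] = "AUG"
    seq[UTR_LEN - 12 : UTR_LEN - 2] = RRS_MOTIF
    return seq


def _plant(seq: list[str], t_start: int, rel_start: int, fragment: str) -> None:
    """Overwrite the transcript at a relative coordinate with ``fragment``."""
    lin = rel_start if rel_start < 0 else rel_start - 1
    pos = t_start + lin
    seq[pos : pos + len(fragment)] = fragment


def _rel_interval(rel_start: int, length: int) -> RelativeInterval:
    lin_start = rel_start if rel_start < 0 else rel_start - 1
    lin_end = lin_start + length - 1
    rel_end = lin_end + 1 if lin_end >= 0 else lin_end
    return RelativeInterval(rel_start, rel_end)


def _segment(t: Transcript, iv: RelativeInterval) -> str:
    lo = relative_to_absolute(t, iv.rel_start)
    hi = relative_to_absolute(t, iv.rel_end)
    return t.sequence[lo : hi + 1]


class FixtureConstructionError(RuntimeError):
    """Raised when no verifying scenario emerges; try another seed."""


def _verified(
    label: str,
    seed: int,
    build: Callable[[random.Random, int], FixtureScenario],
    verify: Callable[[FixtureScenario, EnergyBackend], bool],
) -> FixtureScenario:
    backend = NearestNeighborBackend()
    for attempt in range(_MAX_TRIES):
        # stable, platform-independent stream key per (seed, label, attempt)
        rng = random.Random(seed * 1_000_003 + attempt * 97 + sum(map(ord, label)))
        scenario = build(rng, seed)
        if verify(scenario, backend):
            return scenario
    raise FixtureConstructionError(
        f"could not construct a verifying {label!r} fixture from seed {seed}; "
        "try a different seed"
    )


def _planted_record(
    scenario: FixtureScenario, backend: EnergyBackend
) -> ScreenRecord | None:
    """The evaluated record of the planted site, or None if absent."""
    cfg = ScreenConfig()
    t = scenario.transcript
    rrs = find_rrs(t, backend, cfg.anti_rrs, cfg.rrs_window)
    if rrs is None:
        return None
    sites = find_srna_sites(scenario.srna, t, backend, cfg.window,
                            cfg.energy_cutoff, cfg.min_len)
    assert scenario.planted_site is not None
    target = None
    for s in sites:
        if (
            abs(s.mrna.rel_start - scenario.planted_site.rel_start) <= 2
            and abs(s.mrna.rel_end - scenario.planted_site.rel_end) <= 2
        ):
            target = s
            break
    if target is None:
        return None
    return evaluate_site(t, scenario.srna, target, rrs, scenario.concentrations,
                         backend, cfg)


def make_repression_fixture(seed: int) -> FixtureScenario:
    """RDS-occluding site: sRNA perfectly complementary across the RDS.

    The planted 24-nt site covers the start codon, so ribosome and sRNA
    binding are mutually exclusive; binding is strong enough to outcompete
    the ribosome and sequester 2/3 of the mRNA pool (alpha near -3 at the
    default 2/3 ratio).
    """

    def build(rng: random.Random, seed_: int) -> FixtureScenario:
        seq = _background(rng)
        site = _rel_interval(-5, 24)  # -5..+19: overlaps RDS and start codon
        t = Transcript(f"rep{seed_:04d}", "".join(seq), UTR_LEN)
        srna = reverse_complement(_segment(t, site))
        return FixtureScenario(
            label="repression", transcript=t, srna_id=f"sRNA-rep{seed_:04d}",
            srna=srna, planted_site=site, expected_topology="overlap",
            expected_call="repressed", seed=seed_,
        )

    def verify(sc: FixtureScenario, backend: EnergyBackend) -> bool:
        rrs = find_rrs(sc.transcript, backend)
        if rrs is None or rrs.rds.rel_start != -12:
            return False
        # background must leave the RDS reasonably exposed
        if rds_exposure(sc.transcript, rrs, None, backend).probability < 0.1:
            return False
        rec = _planted_record(sc, backend)
        return (
            rec is not None
            and rec.topology == "overlap"
            and rec.call == "repressed"
        )

    return _verified("repression", seed, build, verify)


def make_activation_fixture(seed: int) -> FixtureScenario:
    """Stem-release site: the sRNA opens a hairpin that hides the RDS.

    A 14-bp GC-rich stem pairs an upstream arm (-94..-81) with the RDS
    core, so the free mRNA is essentially inaccessible (tiny P_EF, large
    opening energy).  The sRNA is complementary to the upstream arm plus
    flanks only; binding melts the stem, P_ES >> P_EF, and translation
    initiation is activated far beyond the 2-fold threshold.
    """

    def build(rng: random.Random, seed_: int) -> FixtureScenario:
        seq = _background(rng)
        # arm B at -5..+9 covers the RRS tail and the start codon; its free
        # positions are GC-rich so the stem is stable enough to bury the RDS
        arm_b = ("UGA" + _random_bases(rng, 2, gc=0.9) + "AUG"
                 + _random_bases(rng, 6, gc=0.9))
        _plant(seq, UTR_LEN, -5, arm_b)
        _plant(seq, UTR_LEN, -94, reverse_complement(arm_b))  # arm A: -94..-81
        t = Transcript(f"act{seed_:04d}", "".join(seq), UTR_LEN)
        srna_site = _rel_interval(-100, 26)  # arm A plus 6-nt flanks each side
        srna = reverse_complement(_segment(t, srna_site))
        return FixtureScenario(
            label="activation", transcript=t, srna_id=f"sRNA-act{seed_:04d}",
            srna=srna, planted_site=srna_site, expected_topology="nonoverlap",
            expected_call="activated", seed=seed_,
        )

    def verify(sc: FixtureScenario, backend: EnergyBackend) -> bool:
        rec = _planted_record(sc, backend)
        return (
            rec is not None
            and rec.topology == "nonoverlap"
            and rec.P_ES is not None
            and rec.P_EF is not None
            and rec.P_ES > rec.P_EF
            and rec.call == "activated"
        )

    return _verified("activation", seed, build, verify)


def make_null_fixture(seed: int) -> FixtureScenario:
    """Negative control: an sRNA with no passing site on the transcript."""

    def build(rng: random.Random, seed_: int) -> FixtureScenario:
        seq = _background(rng)
        t = Transcript(f"nul{seed_:04d}", "".join(seq), UTR_LEN)
        srna = _random_bases(rng, 30)
        return FixtureScenario(
            label="null", transcript=t, srna_id=f"sRNA-nul{seed_:04d}",
            srna=srna, planted_site=None, expected_topology="n/a",
            expected_call="no_sites", seed=seed_,
        )

    def verify(sc: FixtureScenario, backend: EnergyBackend) -> bool:
        if find_rrs(sc.transcript, backend) is None:
            return False
        return not find_srna_sites(sc.srna, sc.transcript, backend)

    return _verified("null", seed, build, verify)


def make_upstream_weak_fixture(seed: int) -> FixtureScenario:
    """Decoy pattern: the best-energy site is inert, a weaker site represses.

    The sRNA carries two complementary stretches: a long (24-nt) perfect
    complement far upstream (-150..-127) whose occupancy leaves RDS
    accessibility unchanged (alpha near +1), and a short (12-nt)
    complement overlapping the RDS that clears the energy filter only
    barely -- yet it is the site that represses.  The expected gene-level
    call therefore hinges on evaluating every site, not only the best.
    """

    def build(rng: random.Random, seed_: int) -> FixtureScenario:
        seq = _background(rng)
        t0 = Transcript(f"upw{seed_:04d}", "".join(seq), UTR_LEN)
        decoy_iv = _rel_interval(-150, 28)
        weak_iv = _rel_interval(+3, 16)  # inside the RDS (-12..+18)
        decoy = _segment(t0, decoy_iv)
        weak = _segment(t0, weak_iv)
        srna = reverse_complement(weak) + "AAA" + reverse_complement(decoy)
        return FixtureScenario(
            label="upstream_weak", transcript=t0, srna_id=f"sRNA-upw{seed_:04d}",
            srna=srna, planted_site=weak_iv, expected_topology="overlap",
            expected_call="repressed", seed=seed_,
        )

    def verify(sc: FixtureScenario, backend: EnergyBackend) -> bool:
        cfg = ScreenConfig()
        t = sc.transcript
        rrs = find_rrs(t, backend)
        if rrs is None:
            return False
        sites = find_srna_sites(sc.srna, t, backend)
        if len(sites) < 2:
            return False
        # the energetically best site must be the upstream decoy ...
        best = sites[0]
        if best.mrna.rel_start > -100:
            return False
        recs = [
            evaluate_site(t, sc.srna, s, rrs, sc.concentrations, backend, cfg)
            for s in sites
        ]
        best_rec = recs[0]
        weak_recs = [
            r for s, r in zip(sites, recs)
            if r.topology == "overlap" and r.call == "repressed"
        ]
        return (
            best_rec.topology == "nonoverlap"
            and best_rec.call == "no_effect"
            and abs((best_rec.alpha or 0.0)) < 1.2
            and len(weak_recs) >= 1
        )

    return _verified("upstream_weak", seed, build, verify)


def fixture_set(seed: int) -> list[FixtureScenario]:
    """The four bundled scenarios, each self-verified at construction."""
    return [
        make_repression_fixture(seed),
        make_activation_fixture(seed),
        make_null_fixture(seed),
        make_upstream_weak_fixture(seed),
    ]


def make_cohort(
    seed: int, n_background: int = 7
) -> tuple[str, list[Transcript], dict[str, ConcentrationSet], set[str]]:
    """A multi-gene screen: one sRNA, its true target, unflagged background genes.

    Returns (srna, transcripts, concentrations, expected flagged gene ids).
    The sRNA is the repression fixture's; background transcripts are
    random genes verified not to be flagged by it -- they may carry weak
    spurious sites, which is realistic, but none may move translation
    initiation beyond the 2-fold threshold.
    """
    rep = make_repression_fixture(seed)
    transcripts = [rep.transcript]
    conc = {rep.transcript.id: rep.concentrations}
    backend = NearestNeighborBackend()
    cfg = ScreenConfig()
    rng = random.Random(seed * 7_919 + 13)
    made = 0
    tries = 0
    while made < n_background and tries < 25 * n_background:
        tries += 1
        seq = _background(rng)
        t = Transcript(f"bg{seed:04d}_{made:02d}", "".join(seq), UTR_LEN)
        rrs = find_rrs(t, backend)
        if rrs is None:
            continue
        flagged = False
        for s in find_srna_sites(rep.srna, t, backend):
            rec = evaluate_site(t, rep.srna, s, rrs, rep.concentrations,
                                backend, cfg)
            if rec.flagged:
                flagged = True
                break
        if flagged:
            continue
        transcripts.append(t)
        conc[t.id] = rep.concentrations
        made += 1
    if made < n_background:
        raise FixtureConstructionError(
            f"could not build {n_background} inert background genes from seed {seed}"
        )
    return rep.srna, transcripts, conc, {rep.transcript.id}


def write_fixture_files(scenarios: Sequence[FixtureScenario], outdir: str | Path) -> None:
    """Emit FASTA + annotation TSV + counts TSV + expected-calls TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "transcripts.fa", "w") as fh:
        for sc in scenarios:
            fh.write(f">{sc.transcript.id}\n{sc.transcript.sequence}\n")
    with open(outdir / "srnas.fa", "w") as fh:
        for sc in scenarios:
            fh.write(f">{sc.srna_id}\n{sc.srna}\n")
    with open(outdir / "annotation.tsv", "w") as fh:
        for sc in scenarios:
            fh.write(f"{sc.transcript.id}\t{sc.transcript.start_pos}\n")
    with open(outdir / "counts.tsv", "w") as fh:
        fh.write("gene_id\tlength_nt\tcount\n")
        # counts chosen so the 16S anchor maps each gene to DEFAULT_M_T copies
        for i in range(1, 8):
            fh.write(f"rrsA{i}\t1542\t100000\n")
        for sc in scenarios:
            L = len(sc.transcript.sequence)
            # copies = rpkm/(rrna_sum) * 57000 = DEFAULT_M_T solves to:
            rrna_rpkm_unit = 100000 / 1.542  # per-gene, total_mapped cancels
            count = DEFAULT_M_T * 7 * rrna_rpkm_unit / 57000 * (L / 1000)
            fh.write(f"{sc.transcript.id}\t{L}\t{count:.6f}\n")
    with open(outdir / "expected.tsv", "w") as fh:
        fh.write("gene_id\tsrna_id\tlabel\texpected_call\texpected_topology\tplanted_site\n")
        for sc in scenarios:
            fh.write(
                f"{sc.transcript.id}\t{sc.srna_id}\t{sc.label}\t{sc.expected_call}"
                f"\t{sc.expected_topology}\t{sc.planted_site or 'NA'}\n"
            )
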