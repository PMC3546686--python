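"""Per-site evaluation and the target-screening pipeline.

For every transcript: locate the RRS/RDS, enumerate filtered sRNA
binding sites, and evaluate each site independently -- the biologically
effective site is not always the energetically best one.  A site's
topology (overlap vs nonoverlap with the RDS) selects the equilibrium
system; the signed fold change alpha of translationally active mRNA
classifies the site as repressed (alpha <= -2), activated (alpha >= +2)
or no_effect.  A gene is flagged when any of its sites passes the
threshold.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__ as _version
from .accessibility import rds_exposure
from .backends import EnergyBackend, get_backend
from .duplex import (
    DEFAULT_ANTI_RRS,
    BindingSite,
    RibosomeSite,
    find_rrs,
    find_srna_sites,
    overlaps,
)
from .equilibrium import (
    EquilibriumError,
    EquilibriumParams,
    energy_to_constant,
    fold_change,
    solve,
    solve_no_srna,
)
from .expression import ConcentrationSet
from .nearest_neighbor import DEFAULT_TEMPERATURE
from .sequence_io import RelativeInterval, Transcript

log = logging.getLogger(__name__)

ALPHA_THRESHOLD = 2.0


@dataclass(frozen=True)
class ScreenConfig:
    """Run configuration; every run embeds it in the output header."""

    window: RelativeInterval = RelativeInterval(-150, +20)
    energy_cutoff: float = -7.0
    min_len: int = 10
    rrs_window: RelativeInterval = RelativeInterval(-30, +3)
    anti_rrs: str = DEFAULT_ANTI_RRS
    flank: int = 250
    temperature: float = DEFAULT_TEMPERATURE
    n: float = 20.0
    ratio: float = 2.0 / 3.0
    alpha_threshold: float = ALPHA_THRESHOLD
    backend: str = "nearest-neighbor"
    seed: int = 0

    def to_mapping(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = str(v)
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Parse a key=value configuration file (intervals as 'a..b')."""
        kwargs: dict[str, object] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("window", "rrs_window"):
                a, _, b = value.partition("..")
                kwargs[key] = RelativeInterval(int(a), int(b))
            elif key in ("min_len", "seed"):
                kwargs[key] = int(value)
            elif key in ("anti_rrs", "backend"):
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)  # type: ignore[arg-type]


def classify(alpha: float, threshold: float = ALPHA_THRESHOLD) -> str:
    """Pure classification of a signed fold change."""
    if alpha <= -threshold:
        return "repressed"
    if alpha >= threshold:
        return "activated"
    return "no_effect"


@dataclass(frozen=True)
class ScreenRecord:
    """One evaluated sRNA binding site on one gene."""

    gene_id: str
    site: BindingSite | None
    ribosome_site: RibosomeSite | None
    topology: str  # overlap | nonoverlap | n/a
    delta_G_R: float | None
    delta_G_S: float | None
    P_EF: float | None
    P_ES: float | None
    concentrations: ConcentrationSet | None
    m_TA_with: float | None
    m_TA_without: float | None
    alpha: float | None
    call: str  # repressed | activated | no_effect | skipped
    reason: str = ""

    @property
    def flagged(self) -> bool:
        return self.call in ("repressed", "activated")


def _skipped(gene_id: str, reason: str, rrs: RibosomeSite | None = None,
             site: BindingSite | None = None) -> ScreenRecord:
    return ScreenRecord(
        gene_id=gene_id, site=site, ribosome_site=rrs, topology="n/a",
        delta_G_R=rrs.delta_G_R if rrs else None, delta_G_S=site.delta_G_S if site else None,
        P_EF=None, P_ES=None, concentrations=None, m_TA_with=None,
        m_TA_without=None, alpha=None, call="skipped", reason=reason,
    )


def evaluate_site(
    t: Transcript,
    srna: str,
    site: BindingSite,
    rrs: RibosomeSite,
    conc: ConcentrationSet,
    backend: EnergyBackend,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenRecord:
    """Evaluate one binding site: topology, exposure, equilibrium, alpha."""
    topology = "overlap" if overlaps(rrs, site) else "nonoverlap"
    acc_free = rds_exposure(t, rrs, None, backend, flank=config.flank)
    P_EF = acc_free.probability
    if P_EF <= 0.0:
        return _skipped(t.id, "untranslatable baseline (P_EF = 0)", rrs, site)
    P_ES = None
    if topology == "nonoverlap":
        P_ES = rds_exposure(t, rrs, site, backend, flank=config.flank).probability
    K_R = energy_to_constant(rrs.delta_G_R, config.temperature)
    K_S = energy_to_constant(site.delta_G_S, config.temperature)
    try:
        baseline = solve_no_srna(K_R, P_EF, conc.m_T, conc.r_T, conc.n)
        params = EquilibriumParams(
            K_R=K_R, K_S=K_S, P_EF=P_EF, m_T=conc.m_T, s_T=conc.s_T,
            r_T=conc.r_T, n=conc.n, P_ES=P_ES, topology=topology,  # type: ignore[arg-type]
        )
        if baseline <= 0.0:
            return _skipped(t.id, "untranslatable baseline (m_TA(0) = 0)", rrs, site)
        if conc.s_T == 0:
            # the baseline system itself: alpha is +1 by definition
            with_srna, alpha = baseline, 1.0
        else:
            with_srna = solve(params).m_TA
            alpha = fold_change(with_srna, baseline)
    except (EquilibriumError, ValueError) as exc:
        log.warning("gene %s: solver failure at site %s: %s", t.id, site.mrna, exc)
        return _skipped(t.id, f"solver failure: {exc}", rrs, site)
    return ScreenRecord(
        gene_id=t.id, site=site, ribosome_site=rrs, topology=topology,
        delta_G_R=rrs.delta_G_R, delta_G_S=site.delta_G_S, P_EF=P_EF, P_ES=P_ES,
        concentrations=conc, m_TA_with=with_srna, m_TA_without=baseline,
        alpha=alpha, call=classify(alpha, config.alpha_threshold),
    )


def screen(
    srna: str,
    transcripts: Sequence[Transcript],
    concentrations: dict[str, ConcentrationSet],
    config: ScreenConfig = ScreenConfig(),
    backend: EnergyBackend | None = None,
) -> list[ScreenRecord]:
    """Screen one sRNA against a set of transcripts, site by site.

    Per-gene failures become skipped records, never fatal errors.
    Records are ordered by gene, then ascending delta_G_S.
    """
    if backend is None:
        backend = get_backend(config.backend, config.temperature)
    records: list[ScreenRecord] = []
    for t in transcripts:
        log.info("screening %s (%d nt)", t.id, len(t.sequence))
        conc = concentrations.get(t.id)
        if conc is None:
            records.append(_skipped(t.id, "no concentration data"))
            continue
        if conc.m_T <= 0:
            records.append(_skipped(t.id, "gene not expressed (m_T = 0)"))
            continue
        rrs = find_rrs(t, backend, config.anti_rrs, config.rrs_window)
        if rrs is None:
            records.append(_skipped(t.id, "no RRS found"))
            continue
        sites = find_srna_sites(
            srna, t, backend, config.window, config.energy_cutoff, config.min_len
        )
        for site in sites:
            records.append(evaluate_site(t, srna, site, rrs, conc, backend, config))
    return records


def flagged_genes(records: Iterable[ScreenRecord]) -> set[str]:
    """Genes with at least one site beyond the alpha threshold."""
    return {r.gene_id for r in records if r.flagged}


# --- reporting ------------------------------------------------------------

_COLUMNS = [
    "gene_id", "site_start", "site_end", "srna_start", "srna_end",
    "rrs_start", "rrs_end", "rds_start", "rds_end", "topology",
    "delta_G_R", "delta_G_S", "P_EF", "P_ES", "m_T", "s_T", "r_T", "n",
    "m_TA_with", "m_TA_without", "alpha", "call", "reason",
]


def _fmt(v, digits: int | None = None) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isinf(v):
            return "-inf" if v < 0 else "inf"
        return f"{v:.{digits}f}" if digits is not None else repr(v)
    return str(v)


def write_results(
    records: Sequence[ScreenRecord], path: str | Path, config: ScreenConfig = ScreenConfig()
) -> None:
    """Write the per-site TSV with a config-echo header block.

    alpha is rounded to 2 decimals in the table; full precision stays in
    the in-memory records.  Output is deterministic for fixed inputs.
    """
    lines = [f"# srnatim {_version} screening report"]
    for k, v in sorted(config.to_mapping().items()):
        lines.append(f"# config {k} = {v}")
    lines.append("\t".join(_COLUMNS))
    for r in records:
        site, rrs, conc = r.site, r.ribosome_site, r.concentrations
        row = [
            r.gene_id,
            _fmt(site.mrna.rel_start if site else None),
            _fmt(site.mrna.rel_end if site else None),
            _fmt(site.srna_start if site else None),
            _fmt(site.srna_end if site else None),
            _fmt(rrs.rrs.rel_start if rrs else None),
            _fmt(rrs.rrs.rel_end if rrs else None),
            _fmt(rrs.rds.rel_start if rrs else None),
            _fmt(rrs.rds.rel_end if rrs else None),
            r.topology,
            _fmt(r.delta_G_R, 2),
            _fmt(r.delta_G_S, 2),
            _fmt(r.P_EF),
            _fmt(r.P_ES),
            _fmt(conc.m_T if conc else None),
            _fmt(conc.s_T if conc else None),
            _fmt(conc.r_T if conc else None),
            _fmt(conc.n if conc else None),
            _fmt(r.m_TA_with),
            _fmt(r.m_TA_without),
            _fmt(r.alpha, 2),
            r.call,
            r.reason,
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> list[dict[str, str]]:
    """Parse a screening TSV back into row dictionaries."""
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        # the trailing reason column may be empty
        while len(parts) < len(header):
            parts.append("")
        rows.append(dict(zip(header, parts)))
    return rows
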