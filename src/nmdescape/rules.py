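"""The five NMD-escape rules.

A transcript carrying a premature termination codon (PTC) is normally
degraded by nonsense-mediated decay. Established exceptions, used here as
per-rule boolean predictions:

* **last exon** — the PTC lies in the last coding exon (no exon-junction
  complex downstream of it),
* **penultimate exon** — the PTC lies within ``d_pen`` bp (default 50)
  upstream of the 3' boundary of the penultimate coding exon, measured along
  the spliced CDS,
* **CSS-proximal** — the PTC lies within ``d_css`` bp (default 150)
  downstream of the coding start site, measured in the mutant CDS,
* **407-bp exon** — the PTC lies in an exon spanning more than 407 bp,
* **single exon** — the transcript is intronless.

A PTC conforming to any enabled rule is predicted to escape NMD; all rules
are reported individually.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .ptc import PtcLocation
    from .transcripts import TranscriptModel

RULE_NAMES = ("last_exon", "penultimate", "css_proximal", "exon407", "single_exon")


@dataclass(frozen=True)
class RuleParams:
    """Rule distances (bp) and the enabled-rule subset.

    ``d_pen``/``d_css`` boundaries are inclusive ("within d bp" read as
    <= d); the exon-size rule is strict ("more than 407 bp").
    """

    d_pen: int = 50
    d_css: int = 150
    exon_size_min: int = 407
    enabled: frozenset = frozenset(RULE_NAMES)

    def __post_init__(self):
        if min(self.d_pen, self.d_css, self.exon_size_min) < 0:
            raise ValueError("rule distances must be >= 0")
        unknown = set(self.enabled) - set(RULE_NAMES)
        if unknown:
            raise ValueError(f"unknown rules: {sorted(unknown)}")


@dataclass(frozen=True)
class RuleResults:
    """Per-rule flags plus their disjunction over the enabled subset."""

    is_ptc: bool = False
    last_exon: bool = False
    penultimate: bool = False
    css_proximal: bool = False
    exon407: bool = False
    single_exon: bool = False
    escape_any: bool = False

    def rule_flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in RULE_NAMES}


def rule_last_exon(p: "PtcLocation", tm: "TranscriptModel") -> bool:
    """PTC in the last coding exon (the exon holding the canonical stop).

    Frameshift PTCs located in 3'UTR sequence (reference position past the
    CDS end) count as downstream of the last junction and return True.
    """
    return p.ref_first_nt >= tm.last_cds_exon_start_cds


def rule_penultimate(p: "PtcLocation", tm: "TranscriptModel", d_pen: int) -> bool:
    """PTC within ``d_pen`` bp upstream of the penultimate-exon 3' boundary.

    Distance is measured along the spliced CDS from the PTC nucleotide
    closest to (and not past) the boundary, so a PTC codon spanning the last
    junction anchors at its boundary-proximal base, and short penultimate
    exons let PTCs in earlier exons qualify.
    """
    if tm.n_exons < 2 or tm.n_coding_exons < 2:
        return False
    boundary = tm.penultimate_junction_cds
    upstream = [q for q in p.ref_nt_positions if q <= boundary]
    return bool(upstream) and boundary - max(upstream) <= d_pen


def rule_css_proximal(p: "PtcLocation", d_css: int) -> bool:
    """PTC within ``d_css`` bp of the coding start site, in mutant-CDS
    coordinates (the PTC may sit inside inserted sequence)."""
    return p.alt_first_nt <= d_css


def rule_exon407(p: "PtcLocation", threshold: int) -> bool:
    """PTC inside an exon spanning strictly more than ``threshold`` bp."""
    return p.exon_width > threshold


def rule_single_exon(tm: "TranscriptModel") -> bool:
    """Intronless transcript."""
    return tm.n_exons == 1


def apply_rules(
    p: "PtcLocation | None", tm: "TranscriptModel", params: RuleParams
) -> RuleResults:
    """Evaluate every rule for a located PTC (or the all-false record).

    Individual flags are always reported as computed; ``escape_any`` is the
    disjunction restricted to ``params.enabled``.
    """
    if p is None:
        return RuleResults()
    flags = {
        "last_exon": rule_last_exon(p, tm),
        "penultimate": rule_penultimate(p, tm, params.d_pen),
        "css_proximal": rule_css_proximal(p, params.d_css),
        "exon407": rule_exon407(p, params.exon_size_min),
        "single_exon": rule_single_exon(tm),
    }
    return RuleResults(
        is_ptc=True,
        escape_any=any(flags[name] for name in params.enabled),
        **flags,
    )
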