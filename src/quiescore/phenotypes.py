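"""Seven-state cell-phenotype taxonomy and the marker-triple classification rule.

A cell's state is read off a triple of binary marker calls:

* **Ki67** — nuclear proliferation marker; present in cycling cells,
  lost on durable cell-cycle exit.
* **pRPS6** — phosphorylated ribosomal protein S6, an mTOR-pathway output
  marking active protein synthesis.
* **SA-β-gal** — senescence-associated beta-galactosidase activity
  (lysosomal hydrolase assayed at pH 6.0), marking senescent and acutely
  stressed cells.

SA-β-gal-negative (healthy) cells fall into four states — cycling,
G0-entry, G0 (quiescence) and G0-alert — tracing entry into and exit from
quiescence.  SA-β-gal-positive cells fall into three — stressed,
pre-senescent and senescent — tracing the path from an acute genotoxic
insult into full senescence.  Two marker combinations (Ki67+/pRPS6− and
Ki67−/pRPS6−, both SA-β-gal+) map to the single pre-senescent state; an
optional sub-code distinguishes the early (Ki67 still detectable) from the
late-entry (Ki67 lost, protein synthesis still off) route.
"""

from __future__ import annotations

import enum
from typing import NamedTuple


class Phenotype(str, enum.Enum):
    """The seven cell states resolvable by the Ki67/pRPS6/SA-β-gal panel."""

    CYCLING = "cycling"
    G0_ENTRY = "g0_entry"
    G0 = "g0"
    G0_ALERT = "g0_alert"
    STRESSED = "stressed"
    PRE_SENESCENT = "pre_senescent"
    SENESCENT = "senescent"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: States available to SA-β-gal-negative (healthy) cells.
HEALTHY_STATES = (
    Phenotype.CYCLING,
    Phenotype.G0_ENTRY,
    Phenotype.G0,
    Phenotype.G0_ALERT,
)

#: States available to SA-β-gal-positive (stressed/senescent) cells.
STRESS_STATES = (
    Phenotype.STRESSED,
    Phenotype.PRE_SENESCENT,
    Phenotype.SENESCENT,
)

ALL_STATES = HEALTHY_STATES + STRESS_STATES


class MarkerProfile(NamedTuple):
    """Binary positivity calls for one cell, in panel order."""

    ki67: bool
    prps6: bool
    sa_b_gal: bool


# Sub-codes for the two marker routes that both read "pre-senescent".
PRESEN_EARLY = "early"  # Ki67+, pRPS6-: cycle exit under way, synthesis off
PRESEN_LATE_ENTRY = "late_entry"  # Ki67-, pRPS6-: generic G0 before senescence programs

# Total lookup over {0,1}^3: (ki67, prps6, sa_b_gal) -> (phenotype, subcode)
_TRUTH_TABLE: dict[MarkerProfile, tuple[Phenotype, str | None]] = {
    MarkerProfile(True, True, False): (Phenotype.CYCLING, None),
    MarkerProfile(True, False, False): (Phenotype.G0_ENTRY, None),
    MarkerProfile(False, False, False): (Phenotype.G0, None),
    MarkerProfile(False, True, False): (Phenotype.G0_ALERT, None),
    MarkerProfile(True, True, True): (Phenotype.STRESSED, None),
    MarkerProfile(True, False, True): (Phenotype.PRE_SENESCENT, PRESEN_EARLY),
    MarkerProfile(False, False, True): (Phenotype.PRE_SENESCENT, PRESEN_LATE_ENTRY),
    MarkerProfile(False, True, True): (Phenotype.SENESCENT, None),
}


def classify_profile(
    profile: MarkerProfile, with_subcode: bool = False
) -> Phenotype | tuple[Phenotype, str | None]:
    """Map one marker triple onto its cell state.

    The mapping is total and deterministic over the eight possible triples.
    With ``with_subcode=True`` the pre-senescent routes are distinguished
    (``"early"`` for Ki67+/pRPS6−, ``"late_entry"`` for Ki67−/pRPS6−);
    all other states return ``None`` as sub-code.
    """
    key = MarkerProfile(bool(profile[0]), bool(profile[1]), bool(profile[2]))
    phenotype, subcode = _TRUTH_TABLE[key]
    if with_subcode:
        return phenotype, subcode
    return phenotype


def marker_truth(state: Phenotype, subcode: str | None = None) -> MarkerProfile:
    """Inverse of :func:`classify_profile`: the marker triple a state implies.

    ``PRE_SENESCENT`` needs a sub-code to pick the Ki67 sign; it defaults to
    the early route.
    """
    if state is Phenotype.PRE_SENESCENT:
        sub = subcode if subcode is not None else PRESEN_EARLY
        if sub not in (PRESEN_EARLY, PRESEN_LATE_ENTRY):
            raise ValueError(f"unknown pre-senescent sub-code {sub!r}")
        return MarkerProfile(sub == PRESEN_EARLY, False, True)
    for profile, (phen, _) in _TRUTH_TABLE.items():
        if phen is state:
            return profile
    raise ValueError(f"unknown phenotype {state!r}")
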