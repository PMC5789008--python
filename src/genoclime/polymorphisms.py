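"""Canonical dopamine-pathway polymorphisms and allele coding.

The index is built from nine commonly studied polymorphisms in genes of the
dopaminergic system: the DAT1/SLC6A3 40-bp VNTR, six DRD2 variants, the DRD3
Ser9Gly substitution and the DRD4 C-521T promoter variant.  Each polymorphism
has a *canonical* allele — the allele whose frequency enters the composite
index — and a complementary allele.  Literature samples may report either
allele; :func:`genoclime.aggregation.orient_allele` converts to the canonical
orientation.

The DAT1 entry is special: what circulates in the literature, and what the
index consumes, is the frequency of carrying at least one 9-repeat allele
(a carrier frequency, not an allele frequency).  It lives in the same [0, 1]
column and is treated identically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Polymorphism:
    """Static description of one polymorphism in the index."""

    rsid: str
    gene: str
    label: str
    canonical_allele: str
    other_allele: str
    #: first-principal-component loading reported for the published index;
    #: used as the default latent-factor weight by the synthetic generator
    #: and as the sign convention for orientation checks.
    reference_loading: float


POLYMORPHISMS: tuple[Polymorphism, ...] = (
    Polymorphism("rs28363170", "DAT1", "40-bp VNTR (9R carrier)", "9R", "10R", 0.75),
    Polymorphism("rs1800497", "DRD2", "Taq1A", "A1", "A2", -0.89),
    Polymorphism("rs1079597", "DRD2", "Taq1B", "B1", "B2", -0.67),
    Polymorphism("rs1800498", "DRD2", "Taq1D", "D1", "D2", 0.86),
    Polymorphism("rs6275", "DRD2", "C939T", "C", "T", 0.34),
    Polymorphism("rs6277", "DRD2", "C957T", "C", "T", -0.87),
    Polymorphism("rs1799732", "DRD2", "-141C ins/del", "ins", "del", 0.44),
    Polymorphism("rs6280", "DRD3", "Ser9Gly", "Ser", "Gly", 0.50),
    Polymorphism("rs1800955", "DRD4", "C-521T", "T", "C", 0.63),
)

CANONICAL_IDS: tuple[str, ...] = tuple(p.rsid for p in POLYMORPHISMS)

#: default loading weights, in canonical order, used by the synthetic generator
REFERENCE_LOADINGS: tuple[float, ...] = tuple(p.reference_loading for p in POLYMORPHISMS)

#: anchor for deterministic orientation of the first principal component:
#: the DAT1 9R-carrier frequency must load positively.
ORIENTATION_ANCHOR = "rs28363170"

# Common literature names accepted wherever a polymorphism id is expected.
_ALIASES: dict[str, str] = {
    "DAT1_VNTR": "rs28363170",
    "DAT1": "rs28363170",
    "SLC6A3_VNTR": "rs28363170",
    "DRD2_TAQ1A": "rs1800497",
    "TAQ1A": "rs1800497",
    "DRD2_TAQ1B": "rs1079597",
    "TAQ1B": "rs1079597",
    "DRD2_TAQ1D": "rs1800498",
    "TAQ1D": "rs1800498",
    "DRD2_C939T": "rs6275",
    "C939T": "rs6275",
    "DRD2_C957T": "rs6277",
    "C957T": "rs6277",
    "DRD2_141C_INDEL": "rs1799732",
    "DRD3_SER9GLY": "rs6280",
    "SER9GLY": "rs6280",
    "DRD4_C521T": "rs1800955",
    "C521T": "rs1800955",
}

_BY_RSID: dict[str, Polymorphism] = {p.rsid: p for p in POLYMORPHISMS}


def resolve_id(polymorphism_id: str) -> str:
    """Return the canonical rs id for ``polymorphism_id`` (rs id or alias)."""
    key = polymorphism_id.strip()
    if key in _BY_RSID:
        return key
    canon = _ALIASES.get(key.upper().replace("-", "_").replace(" ", "_"))
    if canon is None:
        raise ValueError(
            f"unknown polymorphism id {polymorphism_id!r}; "
            f"expected one of {CANONICAL_IDS} or a known alias"
        )
    return canon


def get(polymorphism_id: str) -> Polymorphism:
    """Look up the :class:`Polymorphism` for an rs id or alias."""
    return _BY_RSID[resolve_id(polymorphism_id)]
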