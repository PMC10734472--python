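"""Built-in gene-content signatures for island version typing.

Two island classes are modelled: phosphate-acquisition islands centred on the
pst operon (versions A-H) and phosphonate-utilisation islands centred on the
C-P lyase complex (versions A-D).  Each signature lists the genes required
for the version, in a synteny-like order that the simulator also uses to lay
cassettes out, plus genes whose presence disqualifies the version outright
(documented gene losses).  The table is user-overridable at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import PRODUCT_LABELS

#: High-affinity phosphate ABC transport operon; present in every fGIp version.
PST_CORE: tuple[str, ...] = ("pstS", "pstC", "pstA", "pstB", "phoU")

#: C-P lyase complex genes.
CP_LYASE: tuple[str, ...] = ("phnG", "phnH", "phnI", "phnJ", "phnK", "phnL", "phnM")

#: Lyase genes shared by every fGIphn version (phnG is lost in one version).
CP_LYASE_MIN: tuple[str, ...] = tuple(g for g in CP_LYASE if g != "phnG")


@dataclass(frozen=True)
class VersionSignature:
    """A named gene-content signature for one island version."""

    island_class: str  # "fGIp" | "fGIphn"
    label: str
    required: tuple[str, ...]
    forbidden: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        req, forb = set(self.required), set(self.forbidden)
        if req & forb:
            raise ValueError(f"{self.label}: required and forbidden overlap")
        unknown = (req | forb) - PRODUCT_LABELS
        if unknown:
            raise ValueError(f"{self.label}: unknown product labels {sorted(unknown)}")

    @property
    def required_set(self) -> frozenset[str]:
        return frozenset(self.required)


def _fgip(label: str, required: tuple[str, ...], forbidden: tuple[str, ...] = ()):
    return VersionSignature("fGIp", label, required, forbidden)


def _fgiphn(label: str, required: tuple[str, ...], forbidden: tuple[str, ...] = ()):
    return VersionSignature("fGIphn", label, required, forbidden)


# The longest phosphate island: pst operon, PhoR-PhoB two-component system,
# alkaline phosphatase, polyphosphate kinase, phosphohistidine phosphatase,
# exopolyphosphatase, tyrosine phosphatase, LpxH, glycosyltransferase,
# diacylglycerol kinase, glycerol facilitator, LPS core biosynthesis protein,
# methyltransferase and a hypothetical protein: 19 genes in total.
_C_INVENTORY: tuple[str, ...] = PST_CORE + (
    "phoR", "phoB", "phoX_ALP", "ppk", "sixA", "ppx_gppA", "wzb", "lpxH",
    "glycosyltransferase", "dgk", "glpF", "rfaG", "set_mtase", "hp",
)

_D_INVENTORY = tuple(g for g in _C_INVENTORY if g not in {"phoX_ALP", "hp"})
_E_INVENTORY = tuple(g for g in _C_INVENTORY if g not in {"glpF", "hp"})
# Version H mirrors C without the methyltransferase, diacylglycerol kinase and
# alkaline phosphatase, and is rearranged: the auxiliary genes sit upstream of
# the pst operon.
_H_AUX = tuple(
    g
    for g in _C_INVENTORY
    if g not in set(PST_CORE) | {"phoR", "phoB", "set_mtase", "dgk", "phoX_ALP"}
)
_H_INVENTORY = _H_AUX + PST_CORE + ("phoR", "phoB")

FGIP_SIGNATURES: dict[str, VersionSignature] = {
    # The simplest version: pst operon plus a methyltransferase only.
    "A": _fgip("A", PST_CORE + ("set_mtase",), forbidden=("phoR", "phoB")),
    # Lost the methyltransferase; gained a tyrosine phosphatase and PhoR-PhoB.
    "B": _fgip("B", PST_CORE + ("wzb", "phoR", "phoB"), forbidden=("set_mtase",)),
    "C": _fgip("C", _C_INVENTORY),
    "D": _fgip("D", _D_INVENTORY, forbidden=("phoX_ALP",)),
    "E": _fgip("E", _E_INVENTORY, forbidden=("glpF",)),
    "F": _fgip("F", PST_CORE + ("phoR", "phoB")),
    # Three gene-content subtypes collapse onto one label.
    "G": _fgip("G", PST_CORE + ("phoR", "phoB", "glycosyltransferase")),
    "H": _fgip("H", _H_INVENTORY, forbidden=("set_mtase", "dgk")),
}

FGIPHN_SIGNATURES: dict[str, VersionSignature] = {
    # Full complement: C-P lyase, both ABC transporters and four auxiliaries.
    "A": _fgiphn(
        "A",
        ("phnD", "phnC", "phnE") + CP_LYASE
        + ("set_mtase", "had_hydrolase", "tp", "nucleotidase_5p"),
    ),
    # One transporter; phnG lost.
    "B": _fgiphn("B", ("phnC", "phnD", "phnE") + CP_LYASE_MIN, forbidden=("phnG",)),
    "C": _fgiphn("C", ("phnC", "phnD", "phnE") + CP_LYASE),
    # Lyase only, no dedicated transporter.
    "D": _fgiphn("D", CP_LYASE, forbidden=("phnC", "phnD", "phnE")),
}

SIGNATURE_TABLES: dict[str, dict[str, VersionSignature]] = {
    "fGIp": FGIP_SIGNATURES,
    "fGIphn": FGIPHN_SIGNATURES,
}


def signatures_for(island_class: str) -> dict[str, VersionSignature]:
    try:
        return SIGNATURE_TABLES[island_class]
    except KeyError:
        raise ValueError(f"unknown island class {island_class!r}") from None


def version_rank(island_class: str, label: str) -> float:
    """Rank of a version by gene-content richness, normalised to [0, 1].

    0 is the gene-poorest version of the class, 1 the gene-richest; ties in
    required-set size share a rank.
    """
    table = signatures_for(island_class)
    sig = table.get(label)
    if sig is None:
        raise ValueError(f"unknown version {label!r} for class {island_class}")
    sizes = sorted({len(s.required_set) for s in table.values()})
    if len(sizes) == 1:
        return 0.5
    return sizes.index(len(sig.required_set)) / (len(sizes) - 1)
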