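"""Nutrient composition containers and trait/marker vocabularies.

A :class:`NutrientProfile` holds the wet-chemistry composition of a diet or
faecal sample, every field expressed in % of dry matter (DM).  Four fields are
defined by difference from the others and are kept exactly consistent:

* ``soluble_cp = cp - ndicp`` (CP soluble in neutral detergent)
* ``hemicellulose = andfom - adfom``
* ``cellulose = adfom - adl``
* ``pdndf = andfom - undf`` (potentially degradable NDF)

Profiles built with :meth:`NutrientProfile.from_primary` satisfy these
identities by construction; linear blends of valid profiles remain valid
because the identities are linear.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum


class MarkerKind(str, Enum):
    """The three internal digestibility markers."""

    UNDF = "uNDF"
    UNDFOM = "uNDFom"
    AIA = "AIA"

    @property
    def profile_field(self) -> str:
        return _MARKER_FIELD[self]


_MARKER_FIELD = {
    MarkerKind.UNDF: "undf",
    MarkerKind.UNDFOM: "undfom",
    MarkerKind.AIA: "aia",
}


class TraitKind(str, Enum):
    """Digestibility traits: total-tract apparent (tta) and total-tract (tt)."""

    TTADMD = "ttaDMD"
    TTACPD = "ttaCPD"
    TTASOLCPD = "ttaSolCPD"
    TTASHD = "ttAshD"
    TTNDFD = "ttNDFD"
    TTADFD = "ttADFD"
    TTHEMICELD = "ttHemicelD"
    TTCELD = "ttCelD"
    TTNDICPD = "ttNDICPD"
    TTADICPD = "ttADICPD"
    TTPDNDFD = "ttpdNDFD"

    @property
    def profile_field(self) -> str | None:
        """NutrientProfile field the trait refers to; None for whole DM."""
        return _TRAIT_FIELD[self]


_TRAIT_FIELD = {
    TraitKind.TTADMD: None,
    TraitKind.TTACPD: "cp",
    TraitKind.TTASOLCPD: "soluble_cp",
    TraitKind.TTASHD: "ash",
    TraitKind.TTNDFD: "andfom",
    TraitKind.TTADFD: "adfom",
    TraitKind.TTHEMICELD: "hemicellulose",
    TraitKind.TTCELD: "cellulose",
    TraitKind.TTNDICPD: "ndicp",
    TraitKind.TTADICPD: "adicp",
    TraitKind.TTPDNDFD: "pdndf",
}

ALL_TRAITS: tuple[TraitKind, ...] = tuple(TraitKind)
ALL_MARKERS: tuple[MarkerKind, ...] = tuple(MarkerKind)


@dataclass(frozen=True)
class NutrientProfile:
    """Composition of a diet or faecal sample, each field in % of DM."""

    ash: float
    cp: float
    soluble_cp: float
    ee: float
    andfom: float
    ndicp: float
    adfom: float
    adicp: float
    adl: float
    starch: float
    hemicellulose: float
    cellulose: float
    pdndf: float
    undf: float
    undfom: float
    aia: float

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_primary(
        cls,
        *,
        ash: float,
        cp: float,
        ndicp: float,
        ee: float,
        andfom: float,
        adfom: float,
        adicp: float,
        adl: float,
        starch: float,
        undf: float,
        undfom: float,
        aia: float,
    ) -> "NutrientProfile":
        """Build a profile from the independently measured fractions.

        The by-difference fractions (soluble CP, hemicellulose, cellulose,
        pdNDF) are derived, so the defining identities hold exactly.
        """
        return cls(
            ash=ash,
            cp=cp,
            soluble_cp=cp - ndicp,
            ee=ee,
            andfom=andfom,
            ndicp=ndicp,
            adfom=adfom,
            adicp=adicp,
            adl=adl,
            starch=starch,
            hemicellulose=andfom - adfom,
            cellulose=adfom - adl,
            pdndf=andfom - undf,
            undf=undf,
            undfom=undfom,
            aia=aia,
        )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def blend(self, other: "NutrientProfile", fraction: float) -> "NutrientProfile":
        """Mass-weighted mixture: ``fraction`` of self + (1-fraction) of other."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"blend fraction must be in [0, 1], got {fraction}")
        vals = {
            f.name: fraction * getattr(self, f.name)
            + (1.0 - fraction) * getattr(other, f.name)
            for f in fields(self)
        }
        return NutrientProfile(**vals)

    def validate(self, name: str = "profile") -> None:
        """Check range, ordering and by-difference invariants.

        Intended for diet/ingredient profiles and user-supplied data.  Faecal
        profiles produced by the mass-balance simulator are only subject to
        the feasibility rules of the generator (marker measurement noise can
        legitimately place e.g. faecal uNDF above faecal NDF).
        """
        d = self.as_dict()
        for key, value in d.items():
            if not -1e-9 <= value <= 100 + 1e-9:
                raise ValueError(f"{name}.{key} = {value} outside [0, 100]")
        orderings = [
            ("adfom", "andfom"),
            ("adl", "adfom"),
            ("undf", "andfom"),
            ("undfom", "undf"),
            ("ndicp", "cp"),
            ("adicp", "ndicp"),
            ("aia", "ash"),
        ]
        for lo, hi in orderings:
            if d[lo] > d[hi] + 1e-9:
                raise ValueError(f"{name}: {lo} ({d[lo]}) exceeds {hi} ({d[hi]})")
        identities = [
            ("hemicellulose", d["andfom"] - d["adfom"]),
            ("cellulose", d["adfom"] - d["adl"]),
            ("soluble_cp", d["cp"] - d["ndicp"]),
            ("pdndf", d["andfom"] - d["undf"]),
        ]
        for key, expected in identities:
            if abs(d[key] - expected) > 1e-9:
                raise ValueError(
                    f"{name}.{key} = {d[key]} violates by-difference identity "
                    f"(expected {expected})"
                )
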