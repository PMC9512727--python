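"""Diagnosis / procedure code map.

The analysis never hard-codes claim codes: everything flows through a
:class:`CodeMap`, an ordered prefix map from ICD-10-GM-like diagnosis codes to
fracture sites, plus exclusion-diagnosis prefixes (cancer, Paget's disease,
osteogenesis imperfecta), fracture-related OPS-like procedure prefixes and
hysterectomy procedure prefixes (used by the oestrogen-only HRT rule).

The map that ships with the package is a documented *synthetic* placeholder:
the code lists used on the real claims database are not public, so a miniature
self-consistent set of codes is used for simulation and testing.  Users with
real data supply their own YAML/JSON map with the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: The seven osteoporosis-related fracture sites analysed.
FRACTURE_SITES = (
    "hip",
    "clinical_vertebral",
    "wrist_forearm",
    "humerus",
    "clavicle",
    "pelvis",
    "femur",
)

#: Fracture types reported in the rate / IRR tables.
FRACTURE_TYPES = ("all", "clinical_vertebral", "hip", "wrist_forearm")

# Ordered (prefix, site) pairs; first match wins, so narrow codes must precede
# broader ones (e.g. S32.0 vertebral before S32 pelvis).  Synthetic placeholder
# for the non-public study code list.
_DEFAULT_SITE_MAP = [
    ("S22.0", "clinical_vertebral"),
    ("S32.0", "clinical_vertebral"),
    ("M80.0", "clinical_vertebral"),
    ("S32", "pelvis"),
    ("S42.0", "clavicle"),
    ("S42.2", "humerus"),
    ("S42.3", "humerus"),
    ("S52", "wrist_forearm"),
    ("S72.0", "hip"),
    ("S72.1", "hip"),
    ("S72.2", "hip"),
    ("S72", "femur"),
]

_DEFAULT_EXCLUSIONS = ["C", "M88", "Q78.0"]
_DEFAULT_FRACTURE_PROCEDURES = ["5-79", "5-78", "8-310"]
_DEFAULT_HYSTERECTOMY = ["5-683"]


@dataclass
class CodeMap:
    """Ordered prefix lookup from claim codes to analysis concepts."""

    site_map: list[tuple[str, str]] = field(
        default_factory=lambda: list(_DEFAULT_SITE_MAP)
    )
    exclusions: list[str] = field(default_factory=lambda: list(_DEFAULT_EXCLUSIONS))
    fracture_procedures: list[str] = field(
        default_factory=lambda: list(_DEFAULT_FRACTURE_PROCEDURES)
    )
    hysterectomy_procedures: list[str] = field(
        default_factory=lambda: list(_DEFAULT_HYSTERECTOMY)
    )

    def __post_init__(self) -> None:
        self.site_map = [(str(p), str(s)) for p, s in self.site_map]
        for prefix, site in self.site_map:
            if site not in FRACTURE_SITES:
                raise ValueError(f"unknown fracture site {site!r} for prefix {prefix!r}")

    # -- lookups ---------------------------------------------------------

    def site_of(self, code: str) -> str | None:
        """Fracture site of a diagnosis code, or None if unmapped (ordered, first match)."""
        for prefix, site in self.site_map:
            if code.startswith(prefix):
                return site
        return None

    def is_exclusion(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.exclusions)

    def is_fracture_procedure(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.fracture_procedures)

    def is_hysterectomy(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.hysterectomy_procedures)

    # vectorised variants: evaluate once per unique code, then map
    def site_series(self, codes) -> "object":
        u = {c: self.site_of(c) for c in codes.unique()}
        return codes.map(u)

    def exclusion_mask(self, codes):
        u = {c: self.is_exclusion(c) for c in codes.unique()}
        return codes.map(u).astype(bool)

    def fracture_procedure_mask(self, codes):
        u = {c: self.is_fracture_procedure(c) for c in codes.unique()}
        return codes.map(u).astype(bool)

    def hysterectomy_mask(self, codes):
        u = {c: self.is_hysterectomy(c) for c in codes.unique()}
        return codes.map(u).astype(bool)

    def example_code(self, site: str) -> str:
        """A representative diagnosis code for a site (used by the simulator)."""
        for prefix, s in self.site_map:
            if s == site:
                # pad bare prefixes into plausible full codes
                return prefix if "." in prefix else prefix + ".1"
        raise KeyError(site)

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fracture_sites": [{"prefix": p, "site": s} for p, s in self.site_map],
            "exclusions": list(self.exclusions),
            "fracture_procedures": list(self.fracture_procedures),
            "hysterectomy_procedures": list(self.hysterectomy_procedures),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeMap":
        return cls(
            site_map=[(e["prefix"], e["site"]) for e in d["fracture_sites"]],
            exclusions=list(d.get("exclusions", [])),
            fracture_procedures=list(d.get("fracture_procedures", [])),
            hysterectomy_procedures=list(d.get("hysterectomy_procedures", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_code_map() -> CodeMap:
    """The synthetic placeholder map shipped with the package."""
    return CodeMap()
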