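"""Reference biomarker parameters for the six-metal, six-medium exposure panel.

Six metals (Mn, Pb, Cr, Cu, Ni, Zn) measured in six biological media
(saliva, hair, fingernails, toenails, urine, blood), each summarised by a
geometric mean (GM), geometric standard deviation (GSD), the percentage of
samples above the limit of detection (LOD), and the LOD itself.  Units are
µg/L for fluids (saliva, urine, blood) and µg/g for keratinous media
(hair, fingernails, toenails).

These 36 parameter sets drive the log-normal synthetic-biomarker generator
(:mod:`neuroexposome.synthetic`); they describe a cohort of adolescents and
young adults living near ferro-manganese industry.

One value in the source descriptive table is internally inconsistent: the blood-nickel GSD is
printed as 0.136, which is impossible — a geometric standard deviation is
``exp`` of a standard deviation of logs and therefore always >= 1.  The
value stored here (2.715) is imputed so that a log-normal with the tabulated
GM (1.901) and LOD (0.791) yields exactly the printed detection rate
(81% above LOD); it is also in line with the nickel GSDs of the other
five media (2.57-5.52).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

METALS = ("Mn", "Pb", "Cr", "Cu", "Ni", "Zn")
MEDIA = ("saliva", "hair", "fingernails", "toenails", "urine", "blood")

#: One-letter medium prefixes used in feature names (e.g. ``UPb`` = urinary lead).
MEDIUM_LETTER = {
    "saliva": "S",
    "blood": "B",
    "urine": "U",
    "hair": "H",
    "fingernails": "F",
    "toenails": "T",
}


@dataclass(frozen=True)
class BiomarkerSpec:
    """Log-normal description of one metal in one medium.

    Parameters
    ----------
    metal : str
        Element symbol, one of :data:`METALS`.
    medium : str
        Biological medium, one of :data:`MEDIA`.
    gm : float
        Geometric mean concentration (µg/L or µg/g). Must be positive.
    gsd : float
        Geometric standard deviation (unitless, >= 1).
    lod : float
        Limit of detection, same units as ``gm``.
    pct_above_lod : float
        Percentage of cohort samples above the LOD (0-100).
    """

    metal: str
    medium: str
    gm: float
    gsd: float
    lod: float
    pct_above_lod: float

    def __post_init__(self) -> None:
        if self.metal not in METALS:
            raise ValueError(f"unknown metal {self.metal!r}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")
        if not self.gm > 0:
            raise ValueError(f"{self.medium}-{self.metal}: gm must be > 0, got {self.gm}")
        if not self.gsd >= 1:
            raise ValueError(f"{self.medium}-{self.metal}: gsd must be >= 1, got {self.gsd}")
        if self.lod < 0:
            raise ValueError(f"{self.medium}-{self.metal}: lod must be >= 0, got {self.lod}")
        if not 0 <= self.pct_above_lod <= 100:
            raise ValueError(f"{self.medium}-{self.metal}: pct_above_lod outside [0, 100]")

    @property
    def feature_name(self) -> str:
        """Medium-letter + metal-symbol column label, e.g. ``BZn``."""
        return MEDIUM_LETTER[self.medium] + self.metal


# (medium, metal) -> (GM, GSD, %>LOD, LOD)
_PANEL = [
    ("saliva", "Pb", 0.181, 3.386, 89, 0.052),
    ("saliva", "Cr", 0.393, 3.729, 90, 0.125),
    ("saliva", "Mn", 3.178, 3.084, 100, 0.084),
    ("saliva", "Ni", 1.204, 3.014, 93, 0.198),
    ("saliva", "Cu", 8.653, 2.403, 99, 0.418),
    ("saliva", "Zn", 45.865, 2.898, 100, 2.3189),
    ("hair", "Pb", 0.108, 2.744, 100, 0.003),
    ("hair", "Cr", 0.044, 2.542, 100, 0.004),
    ("hair", "Mn", 0.072, 2.557, 100, 0.006),
    ("hair", "Ni", 0.071, 4.024, 88, 0.014),
    ("hair", "Cu", 10.190, 1.629, 100, 0.048),
    ("hair", "Zn", 85.750, 1.619, 100, 0.209),
    ("fingernails", "Pb", 0.030, 3.326, 96, 0.003),
    ("fingernails", "Cr", 0.082, 2.348, 99, 0.004),
    ("fingernails", "Mn", 0.097, 2.244, 99, 0.006),
    ("fingernails", "Ni", 0.192, 5.522, 94, 0.017),
    ("fingernails", "Cu", 2.813, 1.523, 100, 0.046),
    ("fingernails", "Zn", 39.818, 1.702, 100, 0.209),
    ("toenails", "Pb", 0.058, 2.530, 100, 0.003),
    ("toenails", "Cr", 0.113, 3.113, 100, 0.004),
    ("toenails", "Mn", 0.096, 3.081, 99, 0.006),
    ("toenails", "Ni", 0.073, 3.756, 80, 0.017),
    ("toenails", "Cu", 2.475, 1.352, 100, 0.046),
    ("toenails", "Zn", 26.665, 1.763, 100, 0.208),
    ("urine", "Pb", 0.338, 1.980, 100, 0.063),
    ("urine", "Cr", 0.339, 2.702, 97, 0.101),
    ("urine", "Mn", 0.259, 3.043, 85, 0.115),
    ("urine", "Ni", 1.193, 2.566, 97, 0.231),
    ("urine", "Cu", 5.604, 1.800, 100, 0.325),
    ("urine", "Zn", 368.526, 1.942, 100, 4.241),
    ("blood", "Pb", 8.409, 1.509, 100, 0.161),
    ("blood", "Cr", 0.442, 4.287, 75, 0.205),
    ("blood", "Mn", 8.364, 1.509, 100, 0.482),
    # GSD imputed from the 81% detection rate; see module docstring.
    ("blood", "Ni", 1.901, 2.715, 81, 0.791),
    ("blood", "Cu", 574.459, 1.310, 100, 1.108),
    ("blood", "Zn", 3599.253, 1.448, 100, 7.651),
]


def reference_specs() -> list[BiomarkerSpec]:
    """The complete 36-cell metal x medium reference panel."""
    return [
        BiomarkerSpec(metal=metal, medium=medium, gm=gm, gsd=gsd, lod=lod, pct_above_lod=pct)
        for medium, metal, gm, gsd, pct, lod in _PANEL
    ]


def get_spec(metal: str, medium: str) -> BiomarkerSpec:
    """Look up the reference spec for one metal/medium cell."""
    for s in reference_specs():
        if s.metal == metal and s.medium == medium:
            return s
    raise KeyError(f"no reference spec for metal={metal!r} medium={medium!r}")


def load_parcel_names() -> list[str]:
    """Names of the 111 parcels of the cortical+subcortical atlas.

    48 left and 48 right cortical areas, 7 left and 7 right subcortical
    structures, and the brainstem.
    """
    text = resources.files("neuroexposome.data").joinpath("parcels_111.tsv").read_text()
    names = [line.strip() for line in text.splitlines() if line.strip()]
    if len(names) != 111:
        raise RuntimeError(f"parcel fixture corrupt: expected 111 names, found {len(names)}")
    return names
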