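"""Permethylated N-glycan monoisotopic masses and MALDI peak annotation.

Released N-glycans are conventionally permethylated before MALDI-TOF MS and
detected as sodiated molecular ions [M+Na]+.  A permethylated glycan's
monoisotopic mass is additive over residue-class increments:

    M = sum(count_i * residue_mass_i) + end-group correction
    m/z = M + adduct ion mass

where each permethylated residue increment is the in-chain (dehydro) residue
formula plus one CH2 per exchangeable hydroxyl/amide hydrogen, and the
end-group correction accounts for the water of the free reducing terminus
plus the two terminal methyl groups (H2O + 2 CH2).  The frozen residue table
below was derived from those elemental formulas with standard monoisotopic
atomic masses; the test suite re-derives it independently.

Composition classes follow glycomics convention: HexNAc (GlcNAc/GalNAc),
Hex (Man/Gal/Glc), dHex (fucose), NeuAc (N-acetylneuraminic acid).  MS1
masses are composition-level only: core and antennal fucose are isobaric
and distinguishable only by MS/MS.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GlycanComposition",
    "MassTable",
    "PeakAnnotation",
    "CompositionBounds",
    "DEFAULT_MASS_TABLE",
    "DEFAULT_BOUNDS",
    "permethylated_mz",
    "enumerate_compositions",
    "annotate_peaks",
    "fucose_isomer_masses",
    "read_peak_list",
]

#: elemental formulas behind the frozen table (in-chain residue, CH2 per methyl site)
RESIDUE_FORMULAS = {
    "Hex": ({"C": 6, "H": 10, "O": 5}, 3),
    "HexNAc": ({"C": 8, "H": 13, "N": 1, "O": 5}, 3),
    "dHex": ({"C": 6, "H": 10, "O": 4}, 2),
    "NeuAc": ({"C": 11, "H": 17, "N": 1, "O": 8}, 5),
}


@dataclass(frozen=True)
class MassTable:
    """Permethylated monoisotopic residue increments and corrections, in Da."""

    residues: dict = field(
        default_factory=lambda: {
            "Hex": 204.0997735,
            "HexNAc": 245.1263236,
            "dHex": 174.0892089,
            "NeuAc": 361.1736669,
        }
    )
    # free reducing end, fully methylated termini: H2O + 2 CH2
    end_group: float = 46.0418648
    adducts: dict = field(
        default_factory=lambda: {"Na": 22.9892207, "K": 38.9631579}
    )

    @staticmethod
    def from_json(path) -> "MassTable":
        with open(path) as fh:
            d = json.load(fh)
        return MassTable(
            residues=d["residues"], end_group=d["end_group"], adducts=d["adducts"]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"residues": self.residues, "end_group": self.end_group, "adducts": self.adducts},
                fh,
                indent=2,
            )


DEFAULT_MASS_TABLE = MassTable()

_COMPONENT_RE = re.compile(r"(HexNAc|Hex|dHex|Fuc|NeuAc|Sia)(\d+)")
_ALIASES = {"Fuc": "dHex", "Sia": "NeuAc"}


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide-class counts of one N-glycan composition."""

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        counts = (self.hexnac, self.hex, self.dhex, self.neuac)
        if any(c < 0 for c in counts):
            raise ValueError("residue counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("composition must contain at least one residue")

    @property
    def counts(self) -> dict[str, int]:
        return {"HexNAc": self.hexnac, "Hex": self.hex, "dHex": self.dhex, "NeuAc": self.neuac}

    def is_plausible_n_glycan(self) -> bool:
        """Trimmed N-glycan core requirement: at least 2 HexNAc and 3 Hex."""
        return self.hexnac >= 2 and self.hex >= 3

    @staticmethod
    def parse(text: str) -> "GlycanComposition":
        """Parse e.g. ``"HexNAc4Hex5Fuc1"`` or ``"Hex5HexNAc2"``."""
        counts = {"HexNAc": 0, "Hex": 0, "dHex": 0, "NeuAc": 0}
        consumed = 0
        for m in _COMPONENT_RE.finditer(text):
            cls = _ALIASES.get(m.group(1), m.group(1))
            counts[cls] += int(m.group(2))
            consumed += len(m.group(0))
        if consumed != len(re.sub(r"[\s_-]", "", text)):
            raise ValueError(f"unparsable composition string: {text!r}")
        return GlycanComposition(
            hexnac=counts["HexNAc"], hex=counts["Hex"], dhex=counts["dHex"], neuac=counts["NeuAc"]
        )

    def __str__(self) -> str:
        parts = [
            f"{name}{n}"
            for name, n in (
                ("HexNAc", self.hexnac),
                ("Hex", self.hex),
                ("dHex", self.dhex),
                ("NeuAc", self.neuac),
            )
            if n
        ]
        return "".join(parts)


def permethylated_mz(
    composition: GlycanComposition | str,
    adduct: str = "Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Permethylated, adducted monoisotopic m/z (Da) of a composition."""
    if isinstance(composition, str):
        composition = GlycanComposition.parse(composition)
    if adduct not in table.adducts:
        raise ValueError(f"unknown adduct {adduct!r}; available: {sorted(table.adducts)}")
    mass = table.end_group + table.adducts[adduct]
    for name, count in composition.counts.items():
        if count and name not in table.residues:
            raise ValueError(f"mass table has no residue class {name!r}")
        mass += count * table.residues.get(name, 0.0)
    return mass


@dataclass(frozen=True)
class CompositionBounds:
    """Inclusive per-class search bounds for composition enumeration."""

    hexnac: tuple[int, int] = (2, 8)
    hex: tuple[int, int] = (3, 12)
    dhex: tuple[int, int] = (0, 3)
    neuac: tuple[int, int] = (0, 4)


DEFAULT_BOUNDS = CompositionBounds()


def enumerate_compositions(
    mz: float,
    tolerance: float = 0.5,
    bounds: CompositionBounds = DEFAULT_BOUNDS,
    adduct: str = "Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[GlycanComposition, float, float]]:
    """All in-bounds compositions whose computed m/z is within ``tolerance`` of ``mz``.

    Returns ``(composition, computed_mz, error)`` sorted by absolute error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    out = []
    for hn, hx, dh, na in itertools.product(
        range(bounds.hexnac[0], bounds.hexnac[1] + 1),
        range(bounds.hex[0], bounds.hex[1] + 1),
        range(bounds.dhex[0], bounds.dhex[1] + 1),
        range(bounds.neuac[0], bounds.neuac[1] + 1),
    ):
        comp = GlycanComposition(hexnac=hn, hex=hx, dhex=dh, neuac=na)
        computed = permethylated_mz(comp, adduct=adduct, table=table)
        err = computed - mz
        if abs(err) <= tolerance:
            out.append((comp, computed, err))
    out.sort(key=lambda rec: abs(rec[2]))
    return out


@dataclass
class PeakAnnotation:
    """Composition matches for one observed peak (empty list when unassigned)."""

    observed_mz: float
    intensity: float
    matches: list  # (GlycanComposition, computed_mz, error)
    tolerance: float

    @property
    def assigned(self) -> bool:
        return bool(self.matches)

    @property
    def best(self):
        return self.matches[0] if self.matches else None


def annotate_peaks(
    peaks,
    tolerance: float = 0.5,
    bounds: CompositionBounds = DEFAULT_BOUNDS,
    adduct: str = "Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[PeakAnnotation]:
    """Annotate an (m/z, intensity) peak list with candidate compositions.

    ``peaks`` is an iterable of m/z values or (m/z, intensity) pairs.  An
    empty list yields an empty result.
    """
    annotations = []
    for peak in peaks:
        try:
            mz, intensity = float(peak[0]), float(peak[1])
        except (TypeError, IndexError):
            mz, intensity = float(peak), 0.0
        if mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {mz}")
        matches = enumerate_compositions(mz, tolerance, bounds, adduct, table)
        annotations.append(
            PeakAnnotation(observed_mz=mz, intensity=intensity, matches=matches, tolerance=tolerance)
        )
    return annotations


def fucose_isomer_masses(
    composition: GlycanComposition | str,
    adduct: str = "Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> dict:
    """Core vs antennal fucose masses for a fucosylated composition.

    The two positional isomers share one composition, so their MS1 masses are
    identical; the returned note records that only MS/MS fragmentation can
    place the fucose.
    """
    if isinstance(composition, str):
        composition = GlycanComposition.parse(composition)
    if composition.dhex < 1:
        raise ValueError("composition carries no fucose (dHex = 0)")
    mz = permethylated_mz(composition, adduct=adduct, table=table)
    return {
        "core_fucose_mz": mz,
        "antennal_fucose_mz": mz,
        "isobaric": True,
        "note": (
            "Core and antennal fucose are isobaric at MS1; "
            "the fucose position requires MS/MS fragmentation."
        ),
    }


def read_peak_list(path, sep: str | None = None) -> list[tuple[float, float]]:
    """Read a delimited (m/z, intensity) peak list; intensity defaults to 0."""
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+|\t|,", engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    mz_col = next((cols[k] for k in ("mz", "m/z", "mass") if k in cols), None)
    if mz_col is None:
        raise ValueError(f"{path}: no m/z column found (expected 'mz', 'm/z' or 'mass')")
    int_col = next((cols[k] for k in ("intensity", "int", "height") if k in cols), None)
    intensities = df[int_col] if int_col else [0.0] * len(df)
    return [(float(m), float(i)) for m, i in zip(df[mz_col], intensities)]
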