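"""Exact-mass arithmetic for isotopically labeled glucagon species.

Glucagon is a 29-residue single-chain peptide
(``HSQGTFTSDYSKYLDSRRAQDFVQWLMNT``).  Stable-isotope tracers are built by
substituting uniformly labeled amino acids at specific positions:

* ``F22``  — Phe22 ¹³C₉,¹⁵N₁ (spike-in internal standard),
* ``FF``   — Phe6 + Phe22 ¹³C₉,¹⁵N₁ (first infused tracer),
* ``FFLA`` — Phe6, Phe22 ¹³C₉,¹⁵N₁; Leu14 ¹³C₆,¹⁵N₁; Ala19 ¹³C₃
  (second infused tracer).

Each substitution shifts the monoisotopic mass by an exactly known amount
(¹³C−¹²C = 1.0033548 Da, ¹⁵N−¹⁴N = 0.9970349 Da) while leaving the
chemistry untouched, so all four species co-elute and are distinguished
purely by m/z.  This module computes precursor (SIM, MS1) and N-terminal
b-fragment (PRM, MS2) m/z values, including higher isotopologues (M+1,
M+2, ...), and assembles them into the transition table driving targeted
acquisition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "C13_MINUS_C12",
    "N15_MINUS_N14",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MONOISOTOPIC",
    "GLUCAGON_SEQUENCE",
    "IsotopeLabel",
    "PeptideSpecies",
    "builtin_species",
    "monoisotopic_mass",
    "label_mass_shift",
    "precursor_mz",
    "b_ion_mz",
    "TransitionLayout",
    "transition_table",
    "write_transition_csv",
    "read_transition_csv",
    "species_from_config",
]

# Heavy-isotope mass differences, Da (CODATA/AME values).
C13_MINUS_C12 = 1.0033548
N15_MINUS_N14 = 0.9970349

# Physical proton mass, Da.  Used to turn neutral masses into m/z; kept as a
# module default rather than a literal inside formulas so an alternative
# convention (e.g. 1.00728 or hydrogen-atom mass) can be passed explicitly.
PROTON_MASS = 1.0072765

WATER_MASS = 18.010565

# Monoisotopic residue masses of the 20 standard amino acids, Da
# (IUPAC/unimod standard values, as tabulated by common proteomics tools).
RESIDUE_MONOISOTOPIC: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

GLUCAGON_SEQUENCE = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"


@dataclass(frozen=True)
class IsotopeLabel:
    """A uniform heavy-isotope substitution on one residue.

    Parameters
    ----------
    element
        Chemical element symbol of the substituted atoms (``"C"`` or ``"N"``
        for the built-in tracers).
    heavy_count
        Number of atoms replaced by the heavy isotope.
    per_atom_shift
        Mass difference per substituted atom in Da (defaults resolved via
        :func:`IsotopeLabel.c13` / :func:`IsotopeLabel.n15`).
    """

    element: str
    heavy_count: int
    per_atom_shift: float

    def __post_init__(self) -> None:
        if self.heavy_count < 0:
            raise ValueError(f"heavy_count must be >= 0, got {self.heavy_count}")
        if self.per_atom_shift <= 0:
            raise ValueError(
                f"per_atom_shift must be > 0, got {self.per_atom_shift}"
            )

    @property
    def mass_shift(self) -> float:
        return self.heavy_count * self.per_atom_shift

    @classmethod
    def c13(cls, count: int) -> "IsotopeLabel":
        return cls("C", count, C13_MINUS_C12)

    @classmethod
    def n15(cls, count: int) -> "IsotopeLabel":
        return cls("N", count, N15_MINUS_N14)


# Residue-level label sets used by the built-in tracers.
_PHE_C9N1 = (IsotopeLabel.c13(9), IsotopeLabel.n15(1))
_LEU_C6N1 = (IsotopeLabel.c13(6), IsotopeLabel.n15(1))
_ALA_C3 = (IsotopeLabel.c13(3),)


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide sequence with residue-indexed isotope labels.

    ``labels`` maps 1-based residue positions to the isotope substitutions
    carried by that residue.  The unlabeled (light) species has an empty
    map.
    """

    name: str
    sequence: str
    labels: Mapping[int, tuple[IsotopeLabel, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        for pos in self.labels:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"label position {pos} outside sequence of length "
                    f"{len(self.sequence)} for species {self.name!r}"
                )

    def label_shift(self, up_to: int | None = None) -> float:
        """Total heavy-label mass shift in Da.

        ``up_to`` restricts the sum to labeled positions <= ``up_to``
        (the labels contained in an N-terminal fragment of that length).
        """
        total = 0.0
        for pos, labels in self.labels.items():
            if up_to is None or pos <= up_to:
                total += label_mass_shift(labels)
        return total

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.sequence) + self.label_shift()


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for ch in sequence:
        if ch not in RESIDUE_MONOISOTOPIC:
            raise ValueError(f"unknown amino-acid residue {ch!r}")


_BUILTIN_LABELS: dict[str, dict[int, tuple[IsotopeLabel, ...]]] = {
    "light": {},
    "F22": {22: _PHE_C9N1},
    "FF": {6: _PHE_C9N1, 22: _PHE_C9N1},
    "FFLA": {6: _PHE_C9N1, 14: _LEU_C6N1, 19: _ALA_C3, 22: _PHE_C9N1},
}

# Residue identity expected at each labeled position on glucagon.
_EXPECTED_RESIDUE = {6: "F", 14: "L", 19: "A", 22: "F"}


def builtin_species(names: Sequence[str] | None = None) -> list[PeptideSpecies]:
    """Return the built-in glucagon species (light, F22, FF, FFLA)."""
    if names is None:
        names = ["light", "F22", "FF", "FFLA"]
    out = []
    for name in names:
        try:
            labels = _BUILTIN_LABELS[name]
        except KeyError:
            raise ValueError(
                f"unknown built-in species {name!r}; "
                f"choose from {sorted(_BUILTIN_LABELS)}"
            ) from None
        for pos in labels:
            assert GLUCAGON_SEQUENCE[pos - 1] == _EXPECTED_RESIDUE[pos]
        out.append(PeptideSpecies(name, GLUCAGON_SEQUENCE, labels))
    return out


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of an unlabeled peptide in Da.

    Sum of standard residue masses plus one water for the termini.
    """
    _validate_sequence(sequence)
    return sum(RESIDUE_MONOISOTOPIC[ch] for ch in sequence) + WATER_MASS


def label_mass_shift(labels: Iterable[IsotopeLabel]) -> float:
    """Total mass shift of a list of isotope labels in Da (empty -> 0)."""
    return sum(label.mass_shift for label in labels)


def precursor_mz(
    species: PeptideSpecies,
    charge: int,
    isotopologue: int = 0,
    proton_mass: float = PROTON_MASS,
) -> float:
    """m/z of the intact-peptide precursor at the given charge state.

    ``isotopologue`` selects the M+k peak: each step adds one ¹³C−¹²C mass
    difference to the neutral mass (the dominant heavy-isotope spacing for
    peptides).
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if isotopologue < 0:
        raise ValueError(f"isotopologue index must be >= 0, got {isotopologue}")
    neutral = species.neutral_mass + isotopologue * C13_MINUS_C12
    return (neutral + charge * proton_mass) / charge


def b_ion_mz(
    species: PeptideSpecies,
    n: int,
    charge: int,
    isotopologue: int = 0,
    proton_mass: float = PROTON_MASS,
) -> float:
    """m/z of the bN fragment (first ``n`` residues, N-terminal acylium ion).

    The b-ion neutral fragment mass is the residue-mass sum without water;
    labels at positions <= ``n`` are retained by the fragment.
    """
    if not 1 <= n < len(species.sequence):
        raise ValueError(
            f"fragment length n={n} out of range [1, {len(species.sequence) - 1}]"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if isotopologue < 0:
        raise ValueError(f"isotopologue index must be >= 0, got {isotopologue}")
    residues = sum(RESIDUE_MONOISOTOPIC[ch] for ch in species.sequence[:n])
    neutral = residues + species.label_shift(up_to=n) + isotopologue * C13_MINUS_C12
    return (neutral + charge * proton_mass) / charge


@dataclass(frozen=True)
class TransitionLayout:
    """Which ions and isotopologues the transition table emits.

    Defaults mirror the study's targeted method: SIM precursors at 4+ (the
    unlabeled species monitored from M+1 because its M+0 overlaps matrix
    background, labeled species from M+0), and PRM b25/b26/b27 fragments at
    3+ with two isotopologues each.
    """

    precursor_charge: int = 4
    precursor_isotopologues_light: tuple[int, ...] = (1, 2)
    precursor_isotopologues_labeled: tuple[int, ...] = (0, 1, 2)
    fragments: tuple[int, ...] = (25, 26, 27)
    fragment_charge: int = 3
    fragment_isotopologues: tuple[int, ...] = (0, 1)
    proton_mass: float = PROTON_MASS


def transition_table(
    species_list: Sequence[PeptideSpecies],
    layout: TransitionLayout | None = None,
) -> pd.DataFrame:
    """Assemble the SIM/PRM target-ion table for a list of species.

    Returns a DataFrame with columns ``species, ms_level, ion, charge,
    isotopologue, mz``, sorted by species (input order), level (MS1 before
    MS2), then ion.
    """
    layout = layout or TransitionLayout()
    rows: list[dict] = []
    for sp in species_list:
        is_labeled = bool(sp.labels)
        iso_list = (
            layout.precursor_isotopologues_labeled
            if is_labeled
            else layout.precursor_isotopologues_light
        )
        for k in iso_list:
            rows.append(
                {
                    "species": sp.name,
                    "ms_level": "MS1",
                    "ion": "precursor",
                    "charge": layout.precursor_charge,
                    "isotopologue": k,
                    "mz": precursor_mz(
                        sp, layout.precursor_charge, k, layout.proton_mass
                    ),
                }
            )
        for n in layout.fragments:
            for k in layout.fragment_isotopologues:
                rows.append(
                    {
                        "species": sp.name,
                        "ms_level": "MS2",
                        "ion": f"b{n}",
                        "charge": layout.fragment_charge,
                        "isotopologue": k,
                        "mz": b_ion_mz(
                            sp, n, layout.fragment_charge, k, layout.proton_mass
                        ),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["species", "ms_level", "ion", "charge", "isotopologue", "mz"],
    )
    order = {sp.name: i for i, sp in enumerate(species_list)}
    df = df.sort_values(
        by=["species", "ms_level", "ion", "isotopologue"],
        key=lambda col: col.map(order) if col.name == "species" else col,
        kind="stable",
    ).reset_index(drop=True)
    return df


def write_transition_csv(table: pd.DataFrame, path) -> None:
    """Write a transition table as CSV with m/z to 6 decimal places."""
    out = table.copy()
    out["mz"] = out["mz"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_transition_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["species", "ms_level", "ion", "charge", "isotopologue", "mz"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"transition CSV missing columns: {missing}")
    return df[expected]


def species_from_config(text_or_path) -> list[PeptideSpecies]:
    """Parse species definitions from a YAML config.

    Schema::

        species:
          - name: FF
            sequence: HSQGTF...
            labels: ["6:C:9", "6:N:1", "22:C:9", "22:N:1"]

    Each label triple is ``position:element:count``; the per-atom shift is
    resolved from the element (C -> ¹³C, N -> ¹⁵N).
    """
    if hasattr(text_or_path, "read"):
        data = yaml.safe_load(text_or_path)
    elif isinstance(text_or_path, str) and "\n" in text_or_path:
        data = yaml.safe_load(io.StringIO(text_or_path))
    else:
        with open(text_or_path) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "species" not in data:
        raise ValueError("species config must contain a top-level 'species' list")
    shift_for = {"C": C13_MINUS_C12, "N": N15_MINUS_N14}
    out = []
    for entry in data["species"]:
        labels: dict[int, tuple[IsotopeLabel, ...]] = {}
        for triple in entry.get("labels", []) or []:
            pos_s, element, count_s = str(triple).split(":")
            pos, count = int(pos_s), int(count_s)
            if element not in shift_for:
                raise ValueError(f"unsupported label element {element!r}")
            labels[pos] = labels.get(pos, ()) + (
                IsotopeLabel(element, count, shift_for[element]),
            )
        out.append(PeptideSpecies(entry["name"], entry["sequence"], labels))
    return out
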