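"""Monoisotopic mass arithmetic for peptides, modifications, and charged ions.

This is the numeric foundation of the pipeline: residue-level monoisotopic
sums, water/proton constants, variable modifications (methyl and friends),
and the m/z arithmetic used by the fingerprint and fragment predictors.
Average masses are deliberately not provided — reflectron MALDI and
Orbitrap data are monoisotopic-resolved, so every downstream comparison is
monoisotopic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError

#: Monoisotopic residue masses (Da) for the 20 standard amino acids,
#: i.e. the mass each residue contributes inside a peptide chain
#: (free amino acid minus water).
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
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

#: Monoisotopic mass of water (Da), added once per intact peptide.
WATER: float = 18.010565

#: Mass of the proton (Da) used for charging; the charged-species value,
#: not the hydrogen atomic weight.
PROTON: float = 1.007276

#: One methyl group (CH2) as a delta mass — the nominal "+14 Da" shift.
METHYL_DELTA: float = 14.015650


@dataclass(frozen=True)
class Modification:
    """A variable modification: a named delta mass restricted to target residues.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"methyl"``.
    delta_mass : float
        Monoisotopic mass shift in Da (may be negative).
    targets : frozenset of str
        One-letter codes of residues this modification may sit on.
    max_per_peptide : int
        Cap on simultaneous placements of this modification on one peptide
        when enumerating variable-modification combinations.
    """

    name: str
    delta_mass: float
    targets: frozenset[str] = field(default_factory=frozenset)
    max_per_peptide: int = 2

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise InputError(f"modification {self.name!r}: delta_mass must be finite")
        if not self.targets:
            raise InputError(f"modification {self.name!r}: targets must be non-empty")
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.max_per_peptide < 1:
            raise InputError(f"modification {self.name!r}: max_per_peptide must be >= 1")


METHYL = Modification("methyl", METHYL_DELTA, frozenset("CKRH"))
DIMETHYL = Modification("dimethyl", 28.031300, frozenset("KR"))
TRIMETHYL = Modification("trimethyl", 42.046950, frozenset("K"))
CARBAMIDOMETHYL = Modification("carbamidomethyl", 57.021464, frozenset("C"))

#: Built-in modification registry. Note that no fixed cysteine alkylation is
#: applied anywhere by default: the workflow this package reproduces digests
#: without reduction/alkylation, so carbamidomethyl is available but off.
BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    m.name: m for m in (METHYL, DIMETHYL, TRIMETHYL, CARBAMIDOMETHYL)
}


def load_modifications(path: str | Path) -> dict[str, Modification]:
    """Load modification definitions from a JSON config file.

    The file holds a list of objects with keys ``name``, ``delta_mass``,
    ``targets`` (string or list of one-letter codes) and optionally
    ``max_per_peptide``. Returns built-ins merged with (and overridden by)
    the file's entries.
    """
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise InputError(f"{path}: expected a JSON list of modification objects")
    mods = dict(BUILTIN_MODIFICATIONS)
    for i, e in enumerate(entries):
        try:
            mod = Modification(
                name=e["name"],
                delta_mass=float(e["delta_mass"]),
                targets=frozenset(e["targets"]),
                max_per_peptide=int(e.get("max_per_peptide", 2)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"{path}: entry {i}: {exc}") from exc
        mods[mod.name] = mod
    return mods


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with zero or more placed modifications.

    ``mods`` is a tuple of ``(position, Modification)`` with 1-based
    positions inside the peptide; each position's residue must be a valid
    target of its modification.
    """

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        object.__setattr__(self, "mods", tuple(self.mods))
        n = len(self.sequence)
        for pos, mod in self.mods:
            if not 1 <= pos <= n:
                raise InputError(
                    f"modification {mod.name!r} at position {pos} outside peptide "
                    f"of length {n}"
                )
            residue = self.sequence[pos - 1]
            if residue not in mod.targets:
                raise InputError(
                    f"modification {mod.name!r} targets {sorted(mod.targets)} but "
                    f"position {pos} is {residue!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str) -> None:
    """Reject sequences containing non-standard residue codes."""
    if not sequence:
        raise InputError("empty peptide sequence")
    for i, ch in enumerate(sequence, start=1):
        if ch not in MONOISOTOPIC_RESIDUE_MASSES:
            raise InputError(f"unknown residue code {ch!r} at position {i}")


def peptide_neutral_mass(peptide: ModifiedPeptide | str) -> float:
    """Monoisotopic neutral mass of a (modified) peptide in Da.

    Sum of residue masses plus one water, plus the delta of every placed
    modification.
    """
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    mass = WATER + sum(MONOISOTOPIC_RESIDUE_MASSES[r] for r in peptide.sequence)
    mass += sum(mod.delta_mass for _, mod in peptide.mods)
    return mass


def mz(mass: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons.

    ``(mass + charge * PROTON) / charge``; charge must be a positive integer.
    """
    if charge < 1 or int(charge) != charge:
        raise InputError(f"charge must be a positive integer, got {charge!r}")
    return (mass + charge * PROTON) / charge


def peptide_mz(peptide: ModifiedPeptide | str, charge: int = 1) -> float:
    """Convenience: m/z of a (modified) peptide at the given charge."""
    return mz(peptide_neutral_mass(peptide), charge)
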