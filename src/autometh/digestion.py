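"""In silico proteolysis and theoretical peptide-mass fingerprints.

Cleaves a protein construct with a protease rule (trypsin by default:
after K/R, blocked by a following proline), tracks missed cleavages and
parent coordinates, and expands each peptide into its variable-modification
forms with theoretical m/z — the table an observed fingerprint spectrum is
matched against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import pandas as pd

from .chem import Modification, ModifiedPeptide, mz, peptide_neutral_mass, validate_sequence
from .errors import InputError


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut C-terminal to ``cleave_after`` residues
    unless the next residue is in ``block_if_next``."""

    name: str
    cleave_after: frozenset[str]
    block_if_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise InputError(f"protease {self.name!r}: cleave_after must be non-empty")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "block_if_next", frozenset(self.block_if_next))


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide with parent coordinates.

    ``start``/``end`` are 1-based inclusive positions in the construct;
    ``parent_offset`` maps construct position 1 to the full-protein residue
    number, so the full-protein number of construct position p is
    ``parent_offset + p - 1``.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    parent_offset: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"peptide end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise InputError(
                f"sequence length {len(self.sequence)} inconsistent with "
                f"coordinates {self.start}-{self.end}"
            )
        if self.missed_cleavages < 0:
            raise InputError("missed_cleavages must be >= 0")

    def residue_number(self, position_in_peptide: int) -> int:
        """Full-protein residue number of a 1-based position in this peptide."""
        if not 1 <= position_in_peptide <= len(self.sequence):
            raise InputError(
                f"position {position_in_peptide} outside peptide of length "
                f"{len(self.sequence)}"
            )
        return self.parent_offset + self.start + position_in_peptide - 2


def cleavage_sites(parent: str, rule: ProteaseRule = TRYPSIN) -> list[int]:
    """1-based positions p such that the bond after residue p is cleaved."""
    sites = []
    for p in range(1, len(parent)):
        if parent[p - 1] in rule.cleave_after and parent[p] not in rule.block_if_next:
            sites.append(p)
    return sites


def digest(
    parent: str,
    rule: ProteaseRule = TRYPSIN,
    max_missed: int = 0,
    parent_offset: int = 1,
    min_length: int = 1,
) -> list[PeptideRecord]:
    """All proteolytic peptides of ``parent`` with 0..max_missed missed cleavages.

    Fully cleaved fragments are joined into every consecutive run of at most
    ``max_missed + 1`` fragments; the result is ordered by start position,
    then length. Peptides shorter than ``min_length`` residues are dropped.
    """
    validate_sequence(parent)
    if max_missed < 0:
        raise InputError("max_missed must be >= 0")
    sites = cleavage_sites(parent, rule)
    # boundaries between fully cleaved fragments, as 0-based slice indices
    bounds = [0] + sites + [len(parent)]
    records = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + max_missed + 2, n_frag + 1)):
            start, end = bounds[i] + 1, bounds[j]
            seq = parent[start - 1 : end]
            if len(seq) < min_length:
                continue
            records.append(
                PeptideRecord(
                    sequence=seq,
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                    parent_offset=parent_offset,
                )
            )
    records.sort(key=lambda r: (r.start, len(r.sequence)))
    return records


@dataclass(frozen=True)
class FingerprintRow:
    """One theoretical fingerprint entry: a peptide in one modification state."""

    record: PeptideRecord
    mods: tuple[tuple[int, Modification], ...]
    charge: int
    mz: float

    @property
    def n_mods(self) -> int:
        return len(self.mods)

    @property
    def peptide(self) -> ModifiedPeptide:
        return ModifiedPeptide(self.record.sequence, self.mods)

    def mods_label(self) -> str:
        return ";".join(f"{m.name}@{p}" for p, m in self.mods) or "-"


def _mod_placements(
    sequence: str, mods: tuple[Modification, ...] | list[Modification]
) -> list[tuple[tuple[int, Modification], ...]]:
    """Enumerate variable-modification placement combinations for one peptide.

    Each modification independently occupies 0..max_per_peptide of its target
    positions; combinations across modifications may not share a position.
    The empty (unmodified) placement is always first.
    """
    per_mod: list[list[tuple[tuple[int, Modification], ...]]] = []
    for mod in mods:
        positions = [i for i, r in enumerate(sequence, start=1) if r in mod.targets]
        choices: list[tuple[tuple[int, Modification], ...]] = [()]
        for k in range(1, min(mod.max_per_peptide, len(positions)) + 1):
            choices.extend(tuple((p, mod) for p in c) for c in combinations(positions, k))
        per_mod.append(choices)
    placements = []
    for combo in product(*per_mod):
        placed = tuple(sorted((pm for group in combo for pm in group)))
        used = [p for p, _ in placed]
        if len(set(used)) == len(used):
            placements.append(placed)
    return placements or [()]


def theoretical_fingerprint(
    peptides: list[PeptideRecord],
    mods: tuple[Modification, ...] | list[Modification] = (),
    charge: int = 1,
) -> list[FingerprintRow]:
    """Expand digest peptides into theoretical (peptide, mod state, m/z) rows.

    One row per peptide per allowed variable-modification placement (the
    unmodified row always included), at the given charge state.
    """
    if charge < 1:
        raise InputError("charge must be >= 1")
    rows = []
    for rec in peptides:
        for placed in _mod_placements(rec.sequence, tuple(mods)):
            neutral = peptide_neutral_mass(ModifiedPeptide(rec.sequence, placed))
            rows.append(FingerprintRow(rec, placed, charge, mz(neutral, charge)))
    return rows


def fingerprint_table(rows: list[FingerprintRow]) -> pd.DataFrame:
    """Tabular view of a theoretical fingerprint (TSV-writable)."""
    return pd.DataFrame(
        {
            "peptide": [r.record.sequence for r in rows],
            "start": [r.record.start for r in rows],
            "end": [r.record.end for r in rows],
            "missed": [r.record.missed_cleavages for r in rows],
            "mods": [r.mods_label() for r in rows],
            "z": [r.charge for r in rows],
            "mz": [r.mz for r in rows],
        }
    )
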