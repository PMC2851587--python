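"""Peptide catalog, monoisotopic mass computation and prohormone cleavage sites.

Endogenous neuropeptides are excised from their precursor proteins by
prohormone convertases that cut at basic-residue motifs: pairs of basic
residues (KK, KR, RK, RR) and the spaced ``RxnR`` motif (two arginines
separated by exactly 2, 4 or 6 residues).  This module houses the bundled
peptide catalog of the quail diencephalon study, computes singly protonated
monoisotopic masses (MH+) for modified peptides, and enumerates candidate
peptides between predicted cleavage sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER_MONO",
    "PROTON_MONO",
    "MOD_DELTAS",
    "ModificationSpec",
    "PeptideRecord",
    "CleavageSite",
    "InvalidSequenceError",
    "InvalidModificationError",
    "monoisotopic_mh",
    "load_catalog",
    "bundled_catalog_path",
    "find_cleavage_sites",
    "enumerate_candidate_peptides",
]

#: Monoisotopic residue (amino-acid minus water) masses in Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MONO = 1.007276

#: Canonical (Unimod) monoisotopic mass deltas for the supported modifications.
MOD_DELTAS: dict[str, float] = {
    "phosphorylation": +79.96633,
    "amidation": -0.98402,          # C-terminal amidation
    "pyroglutamate": -17.02655,     # from N-terminal Q
    "oxidation": +15.99491,         # Met oxidation
    "acetylation": +42.01057,       # N-terminal acetylation
}

#: Residues a given modification may sit on (None = any; terminus rules apply).
_MOD_RESIDUES: dict[str, str | None] = {
    "phosphorylation": "STY",
    "amidation": None,
    "pyroglutamate": "Q",
    "oxidation": "M",
    "acetylation": None,
}

N_TERM = "N-term"
C_TERM = "C-term"

_DIBASIC = {"KK", "KR", "RK", "RR"}
_RXNR_GAPS = (2, 4, 6)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a non-standard residue."""


class InvalidModificationError(ValueError):
    """Raised when a modification site or kind is inconsistent with a sequence."""


@dataclass(frozen=True)
class ModificationSpec:
    """A single post-translational modification.

    ``site`` is a 0-based residue index, or the markers ``"N-term"`` /
    ``"C-term"`` for terminal modifications.
    """

    kind: str
    site: int | str

    def __post_init__(self) -> None:
        if self.kind not in MOD_DELTAS:
            raise InvalidModificationError(
                f"unknown modification kind {self.kind!r}; "
                f"expected one of {sorted(MOD_DELTAS)}"
            )

    @property
    def mass_delta(self) -> float:
        return MOD_DELTAS[self.kind]

    def validate(self, sequence: str) -> None:
        site = self.site
        if site == N_TERM:
            idx = 0
        elif site == C_TERM:
            idx = len(sequence) - 1
        elif isinstance(site, int):
            if not 0 <= site < len(sequence):
                raise InvalidModificationError(
                    f"{self.kind} site {site} out of range for sequence of "
                    f"length {len(sequence)}"
                )
            idx = site
        else:
            raise InvalidModificationError(f"bad site specifier {site!r}")
        allowed = _MOD_RESIDUES[self.kind]
        if allowed is not None and sequence[idx] not in allowed:
            raise InvalidModificationError(
                f"{self.kind} requires residue in {allowed!r} but sequence has "
                f"{sequence[idx]!r} at site {site}"
            )
        if self.kind == "pyroglutamate" and idx != 0:
            raise InvalidModificationError("pyroglutamate applies to the N-terminal Q")
        if self.kind == "acetylation" and site != N_TERM and idx != 0:
            raise InvalidModificationError("acetylation applies to the N-terminus")
        if self.kind == "amidation" and site != C_TERM and idx != len(sequence) - 1:
            raise InvalidModificationError("amidation applies to the C-terminus")


@dataclass(frozen=True)
class PeptideRecord:
    """One catalog row: an identified endogenous peptide."""

    precursor_name: str
    peptide_name: str
    sequence: str
    modifications: tuple[ModificationSpec, ...] = ()
    reported_mh: float | None = None
    comment: str = ""
    analyzable: bool = False

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        for mod in self.modifications:
            mod.validate(self.sequence)

    @property
    def theoretical_mh(self) -> float:
        return monoisotopic_mh(self.sequence, self.modifications)


@dataclass(frozen=True)
class CleavageSite:
    """A predicted convertase cleavage point.

    ``position`` is the 0-based index of the residue AFTER which the cut
    occurs (the last residue of the motif).
    """

    position: int
    motif: str           # "dibasic" or "RxnR"
    matched_text: str

    def motif_span(self) -> tuple[int, int]:
        """Half-open span of the basic residues removed with the cut.

        For a dibasic pair both residues are consumed; for RxnR only the
        final arginine adjacent to the cut.
        """
        if self.motif == "dibasic":
            return (self.position - 1, self.position + 1)
        return (self.position, self.position + 1)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    for ch in sequence:
        if ch not in MONOISOTOPIC_RESIDUE_MASS:
            raise InvalidSequenceError(
                f"invalid residue {ch!r} in sequence {sequence!r}"
            )


def monoisotopic_mh(sequence: str, mods: Iterable[ModificationSpec] = ()) -> float:
    """Monoisotopic MH+ (singly protonated mass, Da) of a modified peptide.

    Sum of residue masses + water + one proton + the modification deltas.
    Full precision is returned; round for display.
    """
    _check_sequence(sequence)
    mass = sum(MONOISOTOPIC_RESIDUE_MASS[ch] for ch in sequence)
    mass += WATER_MONO + PROTON_MONO
    for mod in mods:
        mod.validate(sequence)
        mass += mod.mass_delta
    return mass


def bundled_catalog_path():
    """Path-like handle to the packaged peptide catalog TSV."""
    return resources.files("pepquant.data").joinpath("table1_catalog.tsv")


def load_catalog(source=None) -> list[PeptideRecord]:
    """Load a peptide catalog from a TSV (default: the bundled quail catalog).

    Expected columns: precursor, peptide, sequence, and optionally
    mh_printed, comment, analyzable ("Yes" marks peptides quantified in all
    experimental groups and usable for multivariate analysis).
    """
    if source is None:
        with resources.as_file(bundled_catalog_path()) as path:
            df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"precursor", "peptide", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing required columns: {sorted(missing)}")
    records: list[PeptideRecord] = []
    for i, row in df.iterrows():
        try:
            mh = row.get("mh_printed")
            mh_val = float(mh) if isinstance(mh, str) and mh.strip() else None
            comment = row.get("comment")
            comment = comment if isinstance(comment, str) else ""
            flag = row.get("analyzable")
            analyzable = isinstance(flag, str) and flag.strip().lower() == "yes"
            records.append(
                PeptideRecord(
                    precursor_name=str(row["precursor"]),
                    peptide_name=str(row["peptide"]),
                    sequence=str(row["sequence"]).strip(),
                    reported_mh=mh_val,
                    comment=comment,
                    analyzable=analyzable,
                )
            )
        except (InvalidSequenceError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed catalog row {i + 2}: {exc}") from exc
    return records


def find_cleavage_sites(precursor: str) -> list[CleavageSite]:
    """All dibasic and RxnR convertase cleavage sites in a precursor.

    Dibasic: any pair from {KK, KR, RK, RR}; cut after the pair.  RxnR: two
    arginines separated by exactly n residues, n in {2, 4, 6}; cut after the
    final R.  Overlapping matches are all reported, sorted by position.
    """
    _check_sequence(precursor)
    sites: list[CleavageSite] = []
    for i in range(len(precursor) - 1):
        pair = precursor[i : i + 2]
        if pair in _DIBASIC:
            sites.append(CleavageSite(position=i + 1, motif="dibasic", matched_text=pair))
    for i, ch in enumerate(precursor):
        if ch != "R":
            continue
        for n in _RXNR_GAPS:
            j = i + n + 1
            if j < len(precursor) and precursor[j] == "R":
                sites.append(
                    CleavageSite(position=j, motif="RxnR",
                                 matched_text=precursor[i : j + 1])
                )
    sites.sort(key=lambda s: (s.position, s.motif))
    return sites


def enumerate_candidate_peptides(precursor: str) -> list[tuple[str, int, int]]:
    """Maximal candidate peptides between consecutive cleavage motifs.

    Returns (sequence, start, end) with 0-based half-open coordinates,
    excluding the basic residues consumed by each motif.  A precursor with no
    sites yields itself.
    """
    sites = find_cleavage_sites(precursor)
    if not sites:
        return [(precursor, 0, len(precursor))]
    # Merge motif spans into excluded intervals.
    spans = sorted(s.motif_span() for s in sites)
    merged: list[list[int]] = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    candidates: list[tuple[str, int, int]] = []
    cursor = 0
    for lo, hi in merged:
        if lo > cursor:
            candidates.append((precursor[cursor:lo], cursor, lo))
        cursor = max(cursor, hi)
    if cursor < len(precursor):
        candidates.append((precursor[cursor:], cursor, len(precursor)))
    return candidates
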