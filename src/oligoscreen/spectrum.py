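"""Core domain types and centroided peak-list I/O.

A spectrum here is an ordered collection of :class:`Peak` objects, one per
centroided ion signal, carrying m/z (Th), ion-mobility drift time (ms) and
intensity (arbitrary units).  Species arithmetic uses *average* masses
throughout: the peptides of interest are in the 4 kDa range and their
oligomers appear as unresolved isotope envelopes, so centroid positions track
the average mass.  Pass monoisotopic masses into the same functions if your
data are isotopically resolved; nothing downstream assumes either convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

#: Mass of the proton in Da (positive-mode charging agent).  The electron
#: mass correction is negligible at the ppm tolerances used here.
PROTON_MASS = 1.007276


class PeaklistFormatError(ValueError):
    """Raised when a peak-list file lacks a required column."""


@dataclass(frozen=True)
class Peak:
    """One centroided ion signal.

    Parameters
    ----------
    mz:
        Mass-to-charge ratio in Th.  Must be positive.
    drift_time:
        Ion-mobility arrival time in ms.  Zero is allowed (no-IMS data).
    intensity:
        Non-negative abundance in arbitrary detector units.
    """

    mz: float
    drift_time: float
    intensity: float

    def __post_init__(self) -> None:
        # normalise numpy scalars to builtin floats (keeps I/O round-trips clean)
        object.__setattr__(self, "mz", float(self.mz))
        object.__setattr__(self, "drift_time", float(self.drift_time))
        object.__setattr__(self, "intensity", float(self.intensity))
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.drift_time < 0:
            raise ValueError(f"drift_time must be >= 0, got {self.drift_time}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeptideSpec:
    """Target peptide description.

    ``monomer_mass`` is the average mass in Da; ``charge_range`` is the
    inclusive (low, high) interval of positive charge states considered for
    any oligomer; ``n_max`` is the largest oligomer order searched.
    """

    name: str
    monomer_mass: float
    charge_range: tuple[int, int]
    n_max: int

    def __post_init__(self) -> None:
        if not self.monomer_mass > 0:
            raise ValueError("monomer_mass must be positive")
        lo, hi = self.charge_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid charge_range {self.charge_range}")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    @property
    def charges(self) -> range:
        lo, hi = self.charge_range
        return range(lo, hi + 1)


@dataclass(frozen=True)
class LigandSpec:
    """Small-molecule description for a single screened compound.

    ``l_max`` bounds the number of ligand adducts considered on a peptide
    species; ``j_max`` bounds the order of ligand-only self-multimers (the
    ``jL`` series diagnostic of colloidal aggregators).
    """

    compound_id: str
    ligand_mass: float
    l_max: int = 5
    j_max: int = 6

    def __post_init__(self) -> None:
        if not self.ligand_mass > 0:
            raise ValueError("ligand_mass must be positive")
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.j_max < 1:
            raise ValueError("j_max must be >= 1")


def species_mz(
    n: int,
    z: int,
    l: int = 0,
    peptide: PeptideSpec | None = None,
    ligand: LigandSpec | None = None,
    *,
    monomer_mass: float | None = None,
    ligand_mass: float | None = None,
) -> float:
    """m/z of the [n·P + l·L + z·H]^z+ ion.

    Standard positive-mode relation ``(n*M + l*M_L + z*m_H) / z`` with M the
    peptide monomer average mass and M_L the ligand average mass.  Masses may
    be given via spec objects or as raw numbers.

    Note the degeneracy family: scaling (n, z, l) by a common integer leaves
    the m/z unchanged, which is why e.g. the dimer 4+ and trimer 6+ ions
    overlap in m/z and need ion mobility to be told apart.
    """
    if z < 1:
        raise ValueError(f"charge z must be >= 1, got {z}")
    if n < 1:
        raise ValueError(f"oligomer order n must be >= 1, got {n}")
    if l < 0:
        raise ValueError(f"ligand count l must be >= 0, got {l}")
    M = peptide.monomer_mass if peptide is not None else monomer_mass
    if M is None:
        raise ValueError("monomer mass required")
    ML = ligand.ligand_mass if ligand is not None else (ligand_mass or 0.0)
    if l > 0 and ML == 0.0:
        raise ValueError("ligand mass required when l > 0")
    return (n * M + l * ML + z * PROTON_MASS) / z


def multimer_mz(j: int, z: int, ligand: LigandSpec) -> float:
    """m/z of a ligand-only self-multimer ion [j·L + z·H]^z+."""
    if j < 1:
        raise ValueError(f"multimer order j must be >= 1, got {j}")
    if z < 1:
        raise ValueError(f"charge z must be >= 1, got {z}")
    return (j * ligand.ligand_mass + z * PROTON_MASS) / z


def ion_mass(
    n: int, z: int, l: int, peptide: PeptideSpec, ligand: LigandSpec | None = None
) -> float:
    """Mass in Da of the intact [n·P + l·L + z·H]^z+ ion (protons included)."""
    ML = ligand.ligand_mass if ligand is not None else 0.0
    return n * peptide.monomer_mass + l * ML + z * PROTON_MASS


COLUMNS = ("mz", "drift_time", "intensity")


@dataclass
class PeaklistReadResult(Sequence):
    """Peaks read from a delimited file plus a malformed-row report.

    Behaves as a sequence of :class:`Peak` (sorted by ascending m/z);
    ``n_rejected`` counts rows dropped for non-numeric or invariant-violating
    values and ``rejected_lines`` gives their 1-based line numbers.
    """

    peaks: list[Peak]
    n_rejected: int = 0
    rejected_lines: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


def read_peaklist(path: str | Path) -> PeaklistReadResult:
    """Read a centroided peak list from CSV.

    The file must have a header row naming the columns ``mz``, ``drift_time``
    and ``intensity`` (extra columns are ignored).  Rows with non-numeric
    cells or values violating the :class:`Peak` invariants are rejected and
    counted, not fatal.  Peaks are returned sorted by ascending m/z.
    """
    path = Path(path)
    peaks: list[Peak] = []
    rejected: list[int] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PeaklistFormatError(f"{path}: empty file, no header row")
        for col in COLUMNS:
            if col not in reader.fieldnames:
                raise PeaklistFormatError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                peak = Peak(
                    mz=float(row["mz"]),
                    drift_time=float(row["drift_time"]),
                    intensity=float(row["intensity"]),
                )
            except (TypeError, ValueError):
                rejected.append(lineno)
                continue
            peaks.append(peak)
    peaks.sort(key=lambda p: p.mz)
    return PeaklistReadResult(peaks=peaks, n_rejected=len(rejected), rejected_lines=rejected)


def write_peaklist(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks to CSV with full float precision (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for p in peaks:
            writer.writerow([repr(float(p.mz)), repr(float(p.drift_time)), repr(float(p.intensity))])
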