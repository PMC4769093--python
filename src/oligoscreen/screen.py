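"""Plate-screen orchestration, cross-target comparison, and motif comparison.

``run_screen`` drives the assignment + classification chain over every
compound of a plate against one apo reference and tallies the verdicts;
``compare_targets`` counts per-compound mode agreement between two screens
of the same plate against different target peptides; and
``motif_identity_similarity`` performs the ungapped positional comparison of
two equal-length core amyloid motifs (percent identity, and percent
similarity under the positive-BLOSUM62-score convention).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

from oligoscreen.assignment import (
    AssignmentConfig,
    AssignmentResult,
    assign_spectrum,
)
from oligoscreen.calibration import CcsCalibration
from oligoscreen.classifier import BindingVerdict, ClassifierConfig, classify
from oligoscreen.growth import GrowthFit
from oligoscreen.spectrum import LigandSpec, Peak, PeptideSpec, read_peaklist

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CompoundResult:
    compound_id: str
    well: str = ""
    verdict: BindingVerdict | None = None
    failed: bool = False
    error: str = ""

    @property
    def mode(self) -> str:
        if self.failed or self.verdict is None:
            return "failed"
        return self.verdict.mode


@dataclass
class ScreenReport:
    """Per-compound verdicts and the plate-level mode tally."""

    results: list[CompoundResult]
    seed: int | None = None

    @property
    def mode_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.results:
            counts[r.mode] = counts.get(r.mode, 0) + 1
        return counts

    @property
    def modes(self) -> dict[str, str]:
        return {r.compound_id: r.mode for r in self.results}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            v = r.verdict
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "well": r.well,
                    "mode": r.mode,
                    "bound_fraction": v.bound_fraction if v else None,
                    "margin": v.margin if v else None,
                    "colloid_orders": v.colloid_orders if v else None,
                    "max_order_holo": (v.depletion or {}).get("max_order_holo") if v else None,
                    "max_order_apo": (v.depletion or {}).get("max_order_apo") if v else None,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MotifPair:
    """Two equal-length core-motif sequences in one-letter residue codes."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"motifs must be equal length, got {len(self.seq_a)} and {len(self.seq_b)}"
            )
        for seq in (self.seq_a, self.seq_b):
            bad = set(seq.upper()) - _AA_ALPHABET
            if bad:
                raise ValueError(f"invalid residue codes {sorted(bad)} in {seq!r}")


def run_screen(
    plate: Mapping[str, Sequence[Peak] | str | Path],
    apo_peaks: Sequence[Peak],
    peptide: PeptideSpec,
    ligand_table: pd.DataFrame,
    assignment_config: AssignmentConfig = AssignmentConfig(),
    classifier_config: ClassifierConfig = ClassifierConfig(),
    calibration: CcsCalibration | None = None,
    growth_prior: GrowthFit | None = None,
    seed: int | None = None,
) -> ScreenReport:
    """Classify every compound of a plate against one apo reference.

    ``plate`` maps compound_id to a peak list (or a peak-list CSV path);
    ``ligand_table`` needs columns compound_id, ligand_mass and optionally
    well, l_max, j_max.  A compound whose peak list cannot be read or
    classified is recorded as failed and the screen continues.
    """
    ids = list(plate)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in plate")
    lig_rows = ligand_table.set_index("compound_id")

    apo_result = assign_spectrum(
        apo_peaks, peptide, None, assignment_config, calibration, growth_prior
    )

    results: list[CompoundResult] = []
    for cid in ids:
        t0 = time.perf_counter()
        well = str(lig_rows.at[cid, "well"]) if "well" in lig_rows.columns else ""
        try:
            row = lig_rows.loc[cid]
            ligand = LigandSpec(
                compound_id=cid,
                ligand_mass=float(row["ligand_mass"]),
                l_max=int(row.get("l_max", 5)),
                j_max=int(row.get("j_max", 6)),
            )
            peaks = plate[cid]
            if isinstance(peaks, (str, Path)):
                peaks = list(read_peaklist(peaks))
            holo_result = assign_spectrum(
                peaks, peptide, ligand, assignment_config, calibration, growth_prior
            )
            verdict = classify(holo_result, apo_result, classifier_config)
            results.append(CompoundResult(cid, well, verdict))
            logger.info(
                "compound %s: %s (%.3f s)", cid, verdict.mode, time.perf_counter() - t0
            )
        except Exception as exc:  # screen robustness: record and continue
            results.append(CompoundResult(cid, well, None, failed=True, error=str(exc)))
            logger.warning("compound %s failed: %s", cid, exc)
    return ScreenReport(results=results, seed=seed)


def compare_targets(
    report_a: ScreenReport | Mapping[str, str],
    report_b: ScreenReport | Mapping[str, str],
) -> tuple[int, pd.DataFrame]:
    """Per-compound binding-mode agreement between two screens.

    Both screens must cover the same compound ids.  Returns the agreement
    count and a per-compound table.
    """
    modes_a = report_a.modes if isinstance(report_a, ScreenReport) else dict(report_a)
    modes_b = report_b.modes if isinstance(report_b, ScreenReport) else dict(report_b)
    if set(modes_a) != set(modes_b):
        raise ValueError("compound ids differ between the two reports")
    rows = [
        {
            "compound_id": cid,
            "mode_a": modes_a[cid],
            "mode_b": modes_b[cid],
            "agree": modes_a[cid] == modes_b[cid],
        }
        for cid in modes_a
    ]
    table = pd.DataFrame(rows)
    return int(table["agree"].sum()), table


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def motif_identity_similarity(pair: MotifPair | tuple[str, str]) -> tuple[int, int]:
    """Percent identity and similarity of two equal-length motifs.

    Ungapped positional comparison: identity counts identical residues;
    similarity additionally counts residue pairs with a positive BLOSUM62
    substitution score (conservative replacements).  Percentages are rounded
    to the nearest integer.
    """
    if not isinstance(pair, MotifPair):
        pair = MotifPair(*pair)
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    matrix = _blosum62()
    identical = sum(x == y for x, y in zip(a, b))
    similar = sum(x == y or matrix[x][y] > 0 for x, y in zip(a, b))
    length = len(a)
    return round(identical / length * 100), round(similar / length * 100)
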