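"""DEER distance-restraint bookkeeping and the sigma_DEER agreement score.

A restraint is a pair of spin-label sites with an experimental mean
inter-label distance delta_exp (Angstrom).  Multimodal experimental
distributions are reduced to the arithmetic mean of their peak positions.
Restraints are categorized by the bodies their sites live on:

* ``interdomain`` - one site on each rigid body; these drive the
  rigid-body pose search (N = 13 for the packaged experimental table).
* ``linker`` - one site on the flexible interdomain linker; added when
  scoring composite models (N = 15 total for the packaged table).
* ``intradomain`` - both sites on one body; excluded from sigma_DEER,
  kept only for label-model calibration.

sigma_DEER is the root-mean-square deviation between experimental and
model mean distances over the N restraints considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from deerdock.labelmodel import LabelSite

__all__ = [
    "DistanceRestraint",
    "RestraintSet",
    "load_restraint_table",
    "sigma_deer",
    "model_distances_for_pose",
    "DEER_WINDOW",
]

#: measurable DEER distance window, Angstrom
DEER_WINDOW = (10.0, 80.0)

_VALID_BODIES = {"fixed", "moving", "linker"}


@dataclass
class DistanceRestraint:
    site_i: LabelSite
    site_j: LabelSite
    delta_exp: float  # mean inter-spin distance, Angstrom
    peaks: list[float] | None = None
    category: str = "interdomain"
    excluded: bool = False  # outside the measurable window

    def __post_init__(self) -> None:
        if self.peaks is not None:
            mean = float(np.mean(self.peaks))
            if abs(mean - self.delta_exp) > 0.05:
                raise ValueError(
                    f"delta_exp {self.delta_exp} does not match peak mean {mean:.3f}")
        if not (DEER_WINDOW[0] <= self.delta_exp <= DEER_WINDOW[1]):
            warnings.warn(
                f"restraint {self.site_i.residue_number}-{self.site_j.residue_number}: "
                f"{self.delta_exp:.1f} A outside the DEER window {DEER_WINDOW}",
                stacklevel=2)
            self.excluded = True


class RestraintSet:
    """Ordered collection of restraints with category bookkeeping."""

    def __init__(self, restraints: list[DistanceRestraint]):
        self.restraints = list(restraints)

    def by_category(self, *categories: str) -> list[DistanceRestraint]:
        return [r for r in self.restraints if r.category in categories
                and not r.excluded]

    @property
    def interdomain(self) -> list[DistanceRestraint]:
        return self.by_category("interdomain")

    @property
    def linker(self) -> list[DistanceRestraint]:
        return self.by_category("linker")

    @property
    def n_interdomain(self) -> int:
        return len(self.interdomain)

    @property
    def n_total(self) -> int:
        """Restraints entering composite-model scoring: interdomain + linker."""
        return self.n_interdomain + len(self.linker)

    def deltas(self, categories=("interdomain",)) -> np.ndarray:
        return np.array([r.delta_exp for r in self.by_category(*categories)])

    def __len__(self) -> int:
        return len(self.restraints)


def _categorize(body_i: str, body_j: str) -> str:
    if "linker" in (body_i, body_j):
        return "linker"
    return "interdomain" if body_i != body_j else "intradomain"


def load_restraint_table(path: str | Path) -> RestraintSet:
    """Load a tab-separated restraint table.

    Columns: ``site_i_res  site_i_body  site_j_res  site_j_body  mean_A
    peaks_A  category``; ``peaks_A`` slash-separated or ``.``; ``category``
    optional (``.`` = derive from the bodies).  Multimodal rows are reduced
    to the arithmetic mean of the listed peaks.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"site_i_res", "site_i_body", "site_j_res", "site_j_body", "mean_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"restraint table missing columns: {sorted(missing)}")
    out: list[DistanceRestraint] = []
    for _, row in df.iterrows():
        bi, bj = row["site_i_body"].strip(), row["site_j_body"].strip()
        for b in (bi, bj):
            if b not in _VALID_BODIES:
                raise ValueError(f"unknown body id {b!r} (expected {_VALID_BODIES})")
        peaks = None
        raw_peaks = str(row.get("peaks_A", ".")).strip()
        if raw_peaks not in (".", "", "nan"):
            peaks = [float(x) for x in raw_peaks.split("/")]
        delta = float(np.mean(peaks)) if peaks else float(row["mean_A"])
        cat = str(row.get("category", ".")).strip()
        if cat in (".", "", "nan"):
            cat = _categorize(bi, bj)
        out.append(DistanceRestraint(
            site_i=LabelSite(int(row["site_i_res"]), bi),
            site_j=LabelSite(int(row["site_j_res"]), bj),
            delta_exp=delta, peaks=peaks, category=cat))
    return RestraintSet(out)


def packaged_table3() -> RestraintSet:
    """The packaged experimental FnIII-3,4 restraint table (13 interdomain,
    2 linker, 4 unique intradomain calibration rows)."""
    return load_restraint_table(Path(__file__).parent / "data" / "table3.tsv")


# ---------------------------------------------------------------------------
# scoring

def sigma_deer(delta_exp: np.ndarray, delta_model: np.ndarray,
               method: str = "rms") -> float:
    """Agreement between experimental and model mean label distances.

    ``rms`` (default): sqrt((1/N) sum_i (delta_i,exp - delta_i,model)^2);
    ``mad``: mean absolute deviation, for sensitivity analysis.  Units
    Angstrom; permutation-invariant; equals |c| under a constant offset c.
    """
    e = np.asarray(delta_exp, dtype=float)
    m = np.asarray(delta_model, dtype=float)
    if e.shape != m.shape:
        raise ValueError("correspondence error: restraint/model length mismatch")
    if e.size == 0:
        raise ValueError("empty restraint set")
    dev = e - m
    if method == "rms":
        return float(np.sqrt(np.mean(dev * dev)))
    if method == "mad":
        return float(np.mean(np.abs(dev)))
    raise ValueError(f"unknown sigma_DEER method {method!r}")


def model_distances_for_pose(fixed_label_positions: dict[int, np.ndarray],
                             moving_label_positions: dict[int, np.ndarray],
                             pose, restraint_set: RestraintSet) -> np.ndarray:
    """Model distances delta_i,MODEL for the interdomain restraints.

    ``fixed_label_positions`` maps residue number -> mean label position in
    the fixed-body (global) frame; ``moving_label_positions`` likewise in
    the moving *body* frame; ``pose`` transports moving-body points into
    the global frame (any object with ``apply``).
    """
    out = []
    for r in restraint_set.interdomain:
        pair = {r.site_i.domain_id: r.site_i, r.site_j.domain_id: r.site_j}
        if set(pair) != {"fixed", "moving"}:
            raise ValueError("interdomain restraint must join fixed and moving bodies")
        try:
            pf = fixed_label_positions[pair["fixed"].residue_number]
            pm = moving_label_positions[pair["moving"].residue_number]
        except KeyError as err:
            raise ValueError(f"restraint references unplaced site {err}") from err
        out.append(np.linalg.norm(np.asarray(pf) - pose.apply(np.asarray(pm))))
    return np.asarray(out)
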