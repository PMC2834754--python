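"""Druggability comparison of a query interface against the reference set.

Each of the six key descriptors of the query is placed on the reference
distribution as a standardized distance z = |x - mean| / sd over the 17
reference complexes; descriptors within 0.5 sd are "very close", within
1 sd "close", otherwise "far".  The overall score is the mean z-distance:
low scores indicate interfaces resembling those already disrupted by
small molecules, i.e. attractive targets.  An affinity indication is
derived from whether the query is nearer (in standardized space) to the
class-I centroid (peptide-like, weak micromolar binders) or the class-II
centroid (globular, strong nano/sub-nanomolar binders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppiface.reference_data import (
    ReferenceDataset, KEY_DESCRIPTORS, aggregate, load_reference,
    PCT_CHARGED_OVERALL,
)

VERY_CLOSE_Z = 0.5
CLOSE_Z = 1.0


@dataclass
class ComparisonReport:
    z_distance: dict[str, float]
    proximity: dict[str, str]            # very_close / close / far
    n_close_or_very_close: int
    overall_score: float
    affinity_indication: str             # weak_like / strong_like / indeterminate

    def to_dict(self) -> dict:
        return {
            "z_distance": self.z_distance,
            "proximity": self.proximity,
            "n_close_or_very_close": self.n_close_or_very_close,
            "overall_score": self.overall_score,
            "affinity_indication": self.affinity_indication,
        }

    def summary(self) -> str:
        lines = ["Druggability comparison to the reference interface set",
                 "=" * 54]
        for name in self.z_distance:
            lines.append(
                f"  {name:<22s} z = {self.z_distance[name]:5.2f}  "
                f"({self.proximity[name]})"
            )
        lines.append("")
        lines.append(f"close or very close parameters: "
                     f"{self.n_close_or_very_close} / {len(self.z_distance)}")
        lines.append(f"overall score (mean z): {self.overall_score:.2f} "
                     "(lower = more reference-like, higher druggability potential)")
        lines.append(f"affinity indication: {self.affinity_indication}")
        return "\n".join(lines)


def _reference_moments(reference: ReferenceDataset, descriptor: str, subset: str):
    """Group mean/sd with the charged-residue fallback.

    Per-complex charged-residue percentages are not part of the bundled
    panel; its published group moments are used instead.
    """
    try:
        g = aggregate(reference, descriptor, subset)
        return g.mean, g.sd, g.n
    except ValueError:
        if descriptor == "pct_charged_residues":
            mean, sd = PCT_CHARGED_OVERALL
            return mean, sd, len(reference.subset(subset))
        raise


def compare_to_reference(
    query: dict[str, float],
    reference: ReferenceDataset | None = None,
    very_close_z: float = VERY_CLOSE_Z,
    close_z: float = CLOSE_Z,
) -> ComparisonReport:
    """Score a query descriptor panel against the reference distribution.

    *query* must provide the six key descriptors (``asa_mean_side``,
    ``n_segments``, ``gap_volume``, ``pocket_volume``, ``hb_per_100A2``,
    ``pct_charged_residues``).
    """
    if reference is None:
        reference = load_reference()
    missing = [d for d in KEY_DESCRIPTORS if d not in query
               or not np.isfinite(query[d])]
    if missing:
        raise ValueError(f"query is missing descriptors: {missing}")

    z: dict[str, float] = {}
    proximity: dict[str, str] = {}
    z1 = []
    z2 = []
    for d in KEY_DESCRIPTORS:
        mean, sd, _ = _reference_moments(reference, d, "all")
        if sd <= 0:
            raise ValueError(f"reference sd is zero for descriptor {d!r}")
        zd = abs(query[d] - mean) / sd
        z[d] = float(zd)
        if zd <= very_close_z:
            proximity[d] = "very_close"
        elif zd <= close_z:
            proximity[d] = "close"
        else:
            proximity[d] = "far"
        # class centroids in the same standardized space
        m1, _, _ = _reference_moments(reference, d, "classI")
        m2, _, _ = _reference_moments(reference, d, "classII")
        z1.append((query[d] - m1) / sd)
        z2.append((query[d] - m2) / sd)

    d1 = float(np.linalg.norm(z1))
    d2 = float(np.linalg.norm(z2))
    if abs(d1 - d2) < 1e-9:
        indication = "indeterminate"
    elif d1 < d2:
        indication = "weak_like"
    else:
        indication = "strong_like"

    n_close = sum(p in ("very_close", "close") for p in proximity.values())
    return ComparisonReport(
        z_distance=z,
        proximity=proximity,
        n_close_or_very_close=n_close,
        overall_score=float(np.mean(list(z.values()))),
        affinity_indication=indication,
    )
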